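"""Reference normalization and censored-regression differential expression.

Normalized expression is ΔCt_is = Cq_is − F_s, where F_s is the
per-sample arithmetic mean of the selected reference Cqs.  Because the
raw detection limit L = 40 is common to all wells, the *normalized*
censor point becomes sample-specific, L_s = 40 − F_s; the tobit fits
receive those per-sample limits.

For a case/control comparison the model per target is

    ΔCt*_s = β0 + β1·[s is case] + ε_s,   ε ~ N(0, σ²),

observed when below L_s, censored otherwise.  β1 is the ΔΔCt estimate
and fold change FC = 2^(−β1) (lower Ct ⇒ more abundant, hence the
sign).  p-values are two-sided Wald; Benjamini–Hochberg q-values are
reported as an extra column but, following common qPCR practice for
confirmatory panels, significance calls default to raw p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .censored import tobit_two_group
from .containers import CtMatrix, analysis_samples, group_members
from .qc import detected_fraction

logger = logging.getLogger(__name__)

#: the four standard comparisons, (case, control)
DEFAULT_COMPARISONS = (
    ("END", "CNT"),
    ("OMA", "CNT"),
    ("DIE", "CNT"),
    ("DIE", "OMA"),
)


@dataclass
class NormalizedMatrix:
    """ΔCt values with per-sample censor limits and the post-QC mask."""

    delta_ct: pd.DataFrame          # targets × samples, NaN = missing
    censor_limits: pd.Series        # per-sample L_s = limit − norm_factor_s
    excluded: pd.DataFrame          # QC-excluded wells (not censored)
    reference_ids: list[str]

    @property
    def censored_mask(self) -> pd.DataFrame:
        return self.delta_ct.isna() & ~self.excluded


def normalize(matrix: CtMatrix, refset) -> NormalizedMatrix:
    """ΔCt = Cq − per-sample reference factor; references leave the test set.

    Samples without a normalization factor (a reference missing after
    QC) are dropped with a warning.  The missing-value mask is exactly
    the post-QC mask: no imputed value enters differential expression.
    """
    factor = refset.norm_factor
    keep = [s for s in matrix.sample_ids if s in factor.index]
    dropped = [s for s in matrix.sample_ids if s not in factor.index]
    if dropped:
        logger.warning("normalize: dropping %d samples without norm factor", len(dropped))
    targets = [t for t in matrix.target_ids if t not in set(refset.reference_ids)]
    delta = matrix.values.loc[targets, keep].sub(factor[keep], axis=1)
    limits = (matrix.detection_limit - factor[keep]).rename("censor_limit")
    return NormalizedMatrix(
        delta_ct=delta,
        censor_limits=limits,
        excluded=matrix.excluded.loc[targets, keep],
        reference_ids=list(refset.reference_ids),
    )


def compare_groups(
    norm: NormalizedMatrix,
    samples: pd.DataFrame,
    case_label: str,
    control_label: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tobit differential expression for one case/control pair.

    Returns one row per target: ΔΔCt (β1), FC = 2^(−β1), Wald p, BH q,
    per-group observed/censored counts and the convergence flag, sorted
    by fold change descending.  Fit failures yield NA-statistic rows,
    never silent drops.
    """
    kept = analysis_samples(samples)
    avail = norm.delta_ct.columns
    case_ids = group_members(samples, case_label).intersection(kept).intersection(avail)
    control_ids = (
        group_members(samples, control_label).intersection(kept).intersection(avail)
    )
    if len(case_ids) == 0 or len(control_ids) == 0:
        raise ValueError("empty group after exclusions")

    cols = list(control_ids) + list(case_ids)
    g = np.r_[np.zeros(len(control_ids)), np.ones(len(case_ids))]
    limits_all = norm.censor_limits[cols].to_numpy()

    rows = []
    for target in norm.delta_ct.index:
        vals = norm.delta_ct.loc[target, cols].to_numpy(dtype=float)
        excl = norm.excluded.loc[target, cols].to_numpy(dtype=bool)
        use = ~excl
        y = vals[use]
        cens = np.isnan(y)
        lim = limits_all[use]
        gg = g[use]
        record = {
            "target_id": target,
            "n_obs_case": int((~cens & (gg == 1)).sum()),
            "n_cens_case": int((cens & (gg == 1)).sum()),
            "n_obs_control": int((~cens & (gg == 0)).sum()),
            "n_cens_control": int((cens & (gg == 0)).sum()),
        }
        try:
            fit = tobit_two_group(np.where(cens, lim, y), cens, gg, lim)
            record.update(
                delta_delta_ct=fit.beta1,
                fold_change=float(2.0 ** (-fit.beta1)),
                p_value=fit.p_value,
                sigma=fit.sigma,
                se=fit.se_beta1,
                converged=fit.converged,
            )
        except (ValueError, np.linalg.LinAlgError) as err:
            logger.warning("compare_groups: fit failed for %s: %s", target, err)
            record.update(
                delta_delta_ct=np.nan, fold_change=np.nan, p_value=np.nan,
                sigma=np.nan, se=np.nan, converged=False,
            )
        rows.append(record)

    table = pd.DataFrame(rows).set_index("target_id")
    pvals = table["p_value"]
    q = pd.Series(np.nan, index=table.index)
    ok = pvals.notna()
    if ok.any():
        q[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    table["q_value"] = q
    table["significant"] = pvals < alpha
    return table.sort_values("fold_change", ascending=False)


def run_all_comparisons(
    matrix: CtMatrix,
    samples: pd.DataFrame,
    refset,
    comparisons=DEFAULT_COMPARISONS,
    min_detect_frac: float = 0.75,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Run every comparison with its own detection filter.

    The ≥75% detection rule is evaluated per comparison pair ("either
    group" is pair-specific), so each table may test a different target
    set.  Keys are "CASE_vs_CONTROL".
    """
    norm_full = normalize(matrix, refset)
    results: dict[str, pd.DataFrame] = {}
    kept = analysis_samples(samples)
    for case, control in comparisons:
        fracs = []
        for label in (case, control):
            ids = group_members(samples, label).intersection(kept).intersection(
                norm_full.delta_ct.columns
            )
            sub = matrix.subset_targets(norm_full.delta_ct.index)
            fracs.append(detected_fraction(sub, ids))
        keep = (fracs[0] >= min_detect_frac) | (fracs[1] >= min_detect_frac)
        norm = NormalizedMatrix(
            delta_ct=norm_full.delta_ct.loc[keep],
            censor_limits=norm_full.censor_limits,
            excluded=norm_full.excluded.loc[keep],
            reference_ids=norm_full.reference_ids,
        )
        results[f"{case}_vs_{control}"] = compare_groups(
            norm, samples, case, control, alpha=alpha
        )
    return results


def wide_summary(results: dict[str, pd.DataFrame], p_mask: float = 0.1) -> pd.DataFrame:
    """Publication-style wide table: FC and p side by side per comparison.

    Cells with p ≥ ``p_mask`` are printed as "-", mirroring the usual
    reporting convention for exploratory qPCR panels.
    """
    pieces = {}
    for name, table in results.items():
        fc = table["fold_change"].round(3).astype(object)
        p = table["p_value"].round(4).astype(object)
        hide = ~(table["p_value"] < p_mask)
        fc[hide] = "-"
        p[hide] = "-"
        pieces[f"FC ({name})"] = fc
        pieces[f"p ({name})"] = p
    wide = pd.DataFrame(pieces)
    return wide.fillna("-")
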