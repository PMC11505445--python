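"""Reference-miRNA selection: imputation, four stability algorithms,
consensus ranking, TOST screening.

Candidate reference genes are judged on a *complete* Cq matrix, so
non-detects are first imputed: per target and per group (END vs CNT),
(μ, σ) are estimated by censored-normal MLE and each missing well gets
a draw from that normal truncated to [limit, ∞).  Estimating within
group avoids manufacturing spurious between-group homogeneity.  The
imputed values exist only for stability scoring and the TOST screen;
they are discarded before differential expression.

Four stability algorithms vote:

* geNorm — M_i = mean over j≠i of SD(Cq_i − Cq_j), with iterative
  worst-gene elimination; the ranking is the reverse elimination order
  (last surviving pair tied at rank 1.5);
* comparative ΔCt — the same pairwise-SD mean, single pass, no
  elimination;
* BestKeeper — per-gene raw-Cq SD (ranked), plus CV and the Pearson
  correlation with the per-sample mean index (reported);
* NormFinder — model-based: intra-group variances with the small-panel
  bias correction and shrunken inter-group biases.

The consensus score is the geometric mean of the four ranks (the
RefFinder aggregation rule); references are then the k most stable
candidates that are TOST-equivalent between END and CNT and amplified
in at least 95% of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .censored import fit_censored_normal, sample_truncated_normal, tost_two_group
from .containers import CtMatrix, analysis_samples, group_members
from .qc import detected_fraction

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# imputation (steps: censored fit per group, truncated-normal draws)
# ---------------------------------------------------------------------------

def impute_censored(matrix: CtMatrix, samples: pd.DataFrame, seed=0):
    """Return ``(complete, excluded_ids)``: a complete Cq DataFrame and
    the targets dropped as non-identifiable.

    Missing wells are imputed per group (END = OMA ∪ DIE, CNT) from the
    censored-normal fit of that target within that group: genuine
    non-detects from the fitted normal truncated to [detection_limit, ∞)
    (that is all a non-detect says), QC-excluded wells from the
    untruncated fitted normal (a technical failure carries no abundance
    information, so it must not be forced beyond the limit).  Observed
    wells are never modified.  Targets with fewer than 2 uncensored
    wells in any group cannot be fitted and are excluded (logged).
    """
    rng = np.random.default_rng(seed)
    kept = analysis_samples(samples)
    limit = matrix.detection_limit
    complete = matrix.values[list(kept)].copy()
    excluded_ids: list[str] = []

    group_cols = {
        label: list(group_members(samples, label).intersection(kept))
        for label in ("END", "CNT")
    }
    for target in matrix.target_ids:
        ok = True
        draws: list[tuple[list[str], np.ndarray]] = []
        for label, cols in group_cols.items():
            vals = matrix.values.loc[target, cols]
            cens = matrix.censored_mask.loc[target, cols]
            excl = matrix.excluded.loc[target, cols]
            obs = vals[~vals.isna()]
            missing_cols = vals.index[vals.isna()]
            if len(missing_cols) == 0:
                continue
            if len(obs) < 2:
                ok = False
                break
            # QC-excluded wells carry no abundance evidence: they are
            # dropped from the likelihood (neither observed nor censored)
            use = ~excl.to_numpy()
            try:
                fit = fit_censored_normal(
                    vals.fillna(limit).to_numpy()[use],
                    cens.to_numpy()[use],
                    limit,
                )
            except ValueError:
                ok = False
                break
            sig = max(fit.sigma, 1e-6)
            excl_here = excl[missing_cols].to_numpy()
            imputed = np.empty(len(missing_cols))
            n_cens = int((~excl_here).sum())
            if n_cens:
                imputed[~excl_here] = sample_truncated_normal(
                    fit.mu, sig, limit, n_cens, rng=rng
                )
            if excl_here.any():
                imputed[excl_here] = rng.normal(fit.mu, sig, int(excl_here.sum()))
            draws.append((list(missing_cols), imputed))
        if not ok:
            excluded_ids.append(target)
            continue
        for cols, imputed in draws:
            complete.loc[target, cols] = imputed

    if excluded_ids:
        logger.info(
            "impute_censored: %d targets excluded as non-identifiable", len(excluded_ids)
        )
        complete = complete.drop(index=excluded_ids)
    return complete, excluded_ids


# ---------------------------------------------------------------------------
# geNorm and the comparative ΔCt method
# ---------------------------------------------------------------------------

def _pairwise_sd_mean(x: np.ndarray) -> np.ndarray:
    """geNorm M for every gene of x (genes × samples), vectorised."""
    diffs = x[:, None, :] - x[None, :, :]          # k × k × n
    sd = diffs.std(axis=2, ddof=1)                 # SD of Cq_i − Cq_j
    k = x.shape[0]
    return sd.sum(axis=1) / (k - 1)                # mean over j ≠ i (diag = 0)


def genorm(complete: pd.DataFrame):
    """Classic geNorm: first-pass M values and elimination ranking.

    Returns ``(m_values, ranks)``.  ``m_values`` are the M of the full
    candidate panel (the quantity the brute-force pairwise definition
    gives); ``ranks`` come from iterative exclusion of the least stable
    gene, the final pair sharing rank 1.5.
    """
    if complete.shape[0] < 3:
        raise ValueError("geNorm needs at least 3 candidate genes")
    if complete.shape[1] < 2:
        raise ValueError("geNorm needs at least 2 samples")
    genes = list(complete.index)
    x = complete.to_numpy(dtype=float)
    m_first = pd.Series(_pairwise_sd_mean(x), index=complete.index, name="genorm_m")

    remaining = list(range(len(genes)))
    elimination: list[int] = []
    while len(remaining) > 2:
        m = _pairwise_sd_mean(x[remaining])
        worst = int(np.argmax(m))
        elimination.append(remaining.pop(worst))
    ranks = pd.Series(index=complete.index, dtype=float, name="genorm_rank")
    ranks.iloc[remaining] = 1.5
    for pos, idx in enumerate(reversed(elimination)):
        ranks.iloc[idx] = 3.0 + pos
    return m_first, ranks


def comparative_deltact(complete: pd.DataFrame) -> pd.Series:
    """Single-pass mean pairwise-difference SD per gene (lower = stabler).

    Kept as an explicit double loop: it is the independent, literal
    reading of the comparative ΔCt definition and doubles as a check on
    the vectorised geNorm first pass.
    """
    if complete.shape[0] < 2:
        raise ValueError("comparative ΔCt needs at least 2 genes")
    genes = list(complete.index)
    x = complete.to_numpy(dtype=float)
    scores = np.zeros(len(genes))
    for i in range(len(genes)):
        acc = 0.0
        for j in range(len(genes)):
            if i == j:
                continue
            acc += np.std(x[i] - x[j], ddof=1)
        scores[i] = acc / (len(genes) - 1)
    return pd.Series(scores, index=complete.index, name="deltact_score")


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def bestkeeper_stats(complete: pd.DataFrame) -> pd.DataFrame:
    """Per-gene SD (n−1), CV% and correlation with the BestKeeper index.

    The index is the per-sample arithmetic mean of all candidate Cqs.
    Ranking uses SD (BestKeeper's primary criterion); a zero-variance
    gene has undefined r, set to 1 by convention.
    """
    if complete.shape[1] < 2:
        raise ValueError("BestKeeper needs at least 2 samples")
    sd = complete.std(axis=1, ddof=1)
    cv = 100.0 * sd / complete.mean(axis=1)
    index = complete.mean(axis=0)
    r = pd.Series(index=complete.index, dtype=float)
    for gene in complete.index:
        g = complete.loc[gene]
        if sd[gene] == 0 or index.std(ddof=1) == 0:
            r[gene] = 1.0
            logger.info("bestkeeper: zero-variance gene %s, r set to 1", gene)
        else:
            r[gene] = sps.pearsonr(g, index)[0]
    return pd.DataFrame(
        {"bestkeeper_sd": sd, "bestkeeper_cv": cv, "bestkeeper_r": r}
    )


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def normfinder_stability(complete: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Model-based stability: shrunken inter-group bias + intra-group noise.

    Per group g, residuals after two-way (gene × sample) centering give
    intra-group gene variances with the small-panel bias correction

        v̂_ig = k/(k−2) · (z_ig − Σ_l z_lg / (k(k−1))),   z_ig = RSS_ig/(n_g−1),

    clipped at 0.  Gene-centred group means give biases d_ig (summing
    to 0 over groups and over genes), shrunk by their sampling variance:
    d̃ = d·γ²/(γ² + v̂/n).  Stability = mean_g |d̃_ig| + mean_g √(v̂_ig/n_g);
    lower is stabler.  With one group only the noise term remains.
    """
    k = complete.shape[0]
    if k < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    groups = pd.Series(groups).reindex(complete.columns)
    labels = [g for g in pd.unique(groups.dropna())]
    if len(labels) > 1 and any((groups == g).sum() < 3 for g in labels):
        raise ValueError("NormFinder needs >= 3 samples per group")

    var_hat = pd.DataFrame(index=complete.index, columns=labels, dtype=float)
    gene_group_mean = pd.DataFrame(index=complete.index, columns=labels, dtype=float)
    n_per = {}
    for g in labels:
        sub = complete.loc[:, groups == g].to_numpy(dtype=float)
        n_g = sub.shape[1]
        n_per[g] = n_g
        gene_mean = sub.mean(axis=1)
        samp_mean = sub.mean(axis=0)
        resid = sub - gene_mean[:, None] - samp_mean[None, :] + sub.mean()
        z = (resid**2).sum(axis=1) / (n_g - 1)
        v = k / (k - 2) * (z - z.sum() / (k * (k - 1)))
        var_hat[g] = np.clip(v, 0.0, None)
        gene_group_mean[g] = gene_mean

    noise = np.sqrt(var_hat.div(pd.Series(n_per))).mean(axis=1)
    if len(labels) < 2:
        logger.info("normfinder: single group, intra-group term only")
        return pd.Series(noise, index=complete.index, name="normfinder_stability")

    # biases: gene-centred group means, centred across groups per gene
    centred = gene_group_mean.sub(gene_group_mean.mean(axis=0), axis=1)
    d = centred.sub(centred.mean(axis=1), axis=0)
    d_tilde = pd.DataFrame(index=complete.index, columns=labels, dtype=float)
    for g in labels:
        samp_var = var_hat[g] / n_per[g]
        gamma2 = max(0.0, (d[g] ** 2).sum() / (k - 1) - samp_var.mean())
        shrink = gamma2 / (gamma2 + samp_var) if gamma2 > 0 else 0.0
        d_tilde[g] = d[g] * shrink
    stability = d_tilde.abs().mean(axis=1) + noise
    return pd.Series(stability, index=complete.index, name="normfinder_stability")


# ---------------------------------------------------------------------------
# consensus and selection
# ---------------------------------------------------------------------------

def aggregate_ranks(ranks: pd.DataFrame) -> pd.Series:
    """RefFinder consensus: geometric mean of the per-algorithm ranks."""
    if ranks.isna().any().any():
        dropped = ranks.index[ranks.isna().any(axis=1)]
        logger.info("aggregate_ranks: dropping candidates with missing ranks: %s",
                    list(dropped))
        ranks = ranks.dropna()
    return pd.Series(
        sps.gmean(ranks.to_numpy(dtype=float), axis=1),
        index=ranks.index,
        name="overall_rank_score",
    )


def stability_table(
    complete: pd.DataFrame,
    samples: pd.DataFrame,
    matrix: CtMatrix,
    tost_margin: float = 0.5,
    tost_alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every candidate with the four algorithms, TOST and detection.

    One row per candidate gene: the four stability scores, their ranks
    (average ranks on ties), the geometric-mean consensus score, the
    END-vs-CNT TOST p-value on the imputed matrix, and the detected
    fraction over all analysis samples.
    """
    kept = analysis_samples(samples)
    m_first, genorm_rank = genorm(complete)
    deltact = comparative_deltact(complete)
    bk = bestkeeper_stats(complete)
    nf = normfinder_stability(
        complete, samples.loc[list(kept), "group"].isin(("OMA", "DIE")).map(
            {True: "END", False: "CNT"}
        ),
    )

    table = pd.DataFrame(
        {
            "genorm_m": m_first,
            "normfinder_stability": nf,
            "bestkeeper_sd": bk["bestkeeper_sd"],
            "bestkeeper_cv": bk["bestkeeper_cv"],
            "bestkeeper_r": bk["bestkeeper_r"],
            "deltact_score": deltact,
        }
    )
    table["genorm_rank"] = genorm_rank
    table["normfinder_rank"] = nf.rank(method="average")
    table["bestkeeper_rank"] = bk["bestkeeper_sd"].rank(method="average")
    table["deltact_rank"] = deltact.rank(method="average")
    table["overall_rank_score"] = aggregate_ranks(
        table[["genorm_rank", "normfinder_rank", "bestkeeper_rank", "deltact_rank"]]
    )

    end_cols = list(group_members(samples, "END").intersection(kept))
    cnt_cols = list(group_members(samples, "CNT").intersection(kept))
    tost_p = {}
    for gene in complete.index:
        tost_p[gene] = tost_two_group(
            complete.loc[gene, end_cols], complete.loc[gene, cnt_cols],
            margin=tost_margin, alpha=tost_alpha,
        ).p_tost
    table["tost_p"] = pd.Series(tost_p)
    table["detected_frac"] = detected_fraction(matrix, kept).reindex(table.index)
    return table.sort_values("overall_rank_score")


@dataclass
class ReferenceSet:
    """The selected reference genes and the per-sample normalization factor."""

    reference_ids: list[str]
    #: per-sample arithmetic mean of the reference Cqs (observed only)
    norm_factor: pd.Series
    #: samples missing at least one reference post-QC (dropped by default)
    incomplete_samples: list[str]


def select_references(
    table: pd.DataFrame,
    k: int = 3,
    min_detect: float = 0.95,
    tost_alpha: float = 0.05,
    matrix: CtMatrix | None = None,
    samples: pd.DataFrame | None = None,
    require_complete: bool = True,
) -> ReferenceSet:
    """Pick the k most stable TOST-equivalent, ≥95%-detected candidates.

    The normalization factor is computed from *observed* Cq values only
    (imputed values are discarded after selection).  A sample missing
    any selected reference is flagged; by default it is dropped rather
    than normalized by a mean over fewer references.
    """
    eligible = table[(table["detected_frac"] >= min_detect)
                     & (table["tost_p"] < tost_alpha)]
    if len(eligible) < k:
        raise ValueError(
            f"only {len(eligible)} candidates pass the detection (≥{min_detect:.0%}) "
            f"and TOST screens; need {k}. Consider relaxing the TOST margin "
            "or the detection threshold."
        )
    chosen = (
        eligible.sort_values(["overall_rank_score", "genorm_m"]).head(k).index.tolist()
    )
    if matrix is None:
        return ReferenceSet(chosen, pd.Series(dtype=float), [])

    kept = analysis_samples(samples) if samples is not None else matrix.sample_ids
    ref_vals = matrix.values.loc[chosen, list(kept)]
    incomplete = list(ref_vals.columns[ref_vals.isna().any(axis=0)])
    if incomplete:
        logger.warning(
            "select_references: %d samples miss a reference Cq post-QC: %s",
            len(incomplete), incomplete,
        )
    factor = ref_vals.mean(axis=0)
    if require_complete:
        factor = factor.drop(index=incomplete)
    return ReferenceSet(chosen, factor.rename("norm_factor"), incomplete)
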