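"""Well-level and sample-level quality control and detection filtering.

Three screens are applied before any modelling:

1. well QC — a well is usable only if amplification score > 1,
   Cq confidence > 0.8 and Cq ≥ 6 (boundary operators exactly as the
   instrument criteria are stated: the score/confidence thresholds are
   strict, the Cq floor is inclusive);
2. hemolysis — serum samples with ΔCq = Cq(miR-23a-3p) − Cq(miR-451a)
   ≥ 8 are contaminated by red-blood-cell miRNAs and excluded
   (acceptance requires ΔCq < 8, strictly);
3. detection — a target is analysable for a two-group comparison only
   if it amplified in at least 75% of samples of either group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    CtMatrix,
    HEMOLYSIS_RBC_MARKER,
    HEMOLYSIS_STABLE_MARKER,
    analysis_samples,
    group_members,
)


@dataclass
class WellQcReport:
    n_wells: int
    n_removed: int
    n_fail_amp: int
    n_fail_conf: int
    n_fail_cq_floor: int


def apply_well_qc(
    matrix: CtMatrix,
    min_amp_score: float = 1.0,
    min_cq_conf: float = 0.8,
    min_cq: float = 6.0,
) -> tuple[CtMatrix, WellQcReport]:
    """Remove wells failing any instrument QC criterion.

    Failing wells become missing *and* are marked excluded: unlike true
    non-detects they carry no abundance information, so downstream
    censored models drop them rather than treating them as censored at
    the limit.  Idempotent: passing wells are untouched.
    """
    values = matrix.values
    present = values.notna()
    fail_amp = present & ~(matrix.amp_score > min_amp_score)
    fail_conf = present & ~(matrix.cq_confidence > min_cq_conf)
    fail_floor = present & ~(values >= min_cq)
    fail = fail_amp | fail_conf | fail_floor

    out = matrix.copy()
    out.values = values.mask(fail)
    out.excluded = matrix.excluded | fail
    report = WellQcReport(
        n_wells=int(present.to_numpy().sum()),
        n_removed=int(fail.to_numpy().sum()),
        n_fail_amp=int(fail_amp.to_numpy().sum()),
        n_fail_conf=int(fail_conf.to_numpy().sum()),
        n_fail_cq_floor=int(fail_floor.to_numpy().sum()),
    )
    return out, report


def hemolysis_check(
    matrix: CtMatrix,
    samples: pd.DataFrame,
    threshold: float = 8.0,
    keep_indeterminate: bool = True,
) -> pd.DataFrame:
    """Flag hemolysed samples from the miR-23a-3p / miR-451a pair.

    Adds ``hemolysis_delta_cq`` and ``hemolysis_pass`` columns.  A
    sample with either marker missing is indeterminate (ΔCq = NaN) and
    is kept or dropped according to ``keep_indeterminate``.
    """
    for marker in (HEMOLYSIS_STABLE_MARKER, HEMOLYSIS_RBC_MARKER):
        if marker not in matrix.target_ids:
            raise ValueError(f"hemolysis marker {marker!r} absent from matrix")
    delta = (
        matrix.values.loc[HEMOLYSIS_STABLE_MARKER]
        - matrix.values.loc[HEMOLYSIS_RBC_MARKER]
    )
    out = samples.copy()
    out["hemolysis_delta_cq"] = delta.reindex(out.index)
    passing = out["hemolysis_delta_cq"] < threshold
    indeterminate = out["hemolysis_delta_cq"].isna()
    out["hemolysis_pass"] = np.where(
        indeterminate, keep_indeterminate, passing
    ).astype(bool)
    out["hemolysis_indeterminate"] = indeterminate
    return out


def detected_fraction(
    matrix: CtMatrix, sample_ids=None
) -> pd.Series:
    """Per-target fraction of QC-valid wells with an amplification call.

    QC-excluded wells are removed from both numerator and denominator:
    a technically failed well is evidence of nothing.
    """
    values = matrix.values if sample_ids is None else matrix.values[list(sample_ids)]
    excl = matrix.excluded if sample_ids is None else matrix.excluded[list(sample_ids)]
    valid = (~excl).sum(axis=1)
    detected = (values.notna() & ~excl).sum(axis=1)
    return (detected / valid.replace(0, np.nan)).fillna(0.0)


def detection_filter(
    matrix: CtMatrix,
    samples: pd.DataFrame,
    groups: tuple[str, str],
    min_frac: float = 0.75,
) -> CtMatrix:
    """Keep targets detected in ≥ ``min_frac`` of samples of either group.

    Fractions use post-QC counts within hemolysis-passing samples.  The
    END label denotes OMA ∪ DIE.  With ``min_frac = 0`` this is the
    identity; the target set never grows.
    """
    kept = analysis_samples(samples)
    frac = {}
    for label in groups:
        ids = group_members(samples, label).intersection(kept)
        if len(ids) == 0:
            raise ValueError(f"group {label!r} is empty after exclusions")
        frac[label] = detected_fraction(matrix, ids)
    keep = (frac[groups[0]] >= min_frac) | (frac[groups[1]] >= min_frac)
    return matrix.subset_targets(matrix.target_ids[keep])


def mir16_replicate_report(
    samples: pd.DataFrame, warn_sd: float = 0.5
) -> pd.DataFrame:
    """Summarise the miR-16-5p replicate spread per sample.

    The array spots miR-16-5p repeatedly as a process control; there is
    no published hard threshold, so samples are only flagged (default
    SD > 0.5 Ct), never excluded.
    """
    out = pd.DataFrame(index=samples.index)
    sd = samples.get("mir16_replicate_sd")
    out["mir16_replicate_sd"] = sd if sd is not None else np.nan
    out["mir16_flag"] = out["mir16_replicate_sd"] > warn_sd
    return out
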