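"""In-memory containers for Cq panel data.

A :class:`CtMatrix` holds one quantification-cycle (Cq) value per
(target, sample) well together with per-well QC covariates.  Non-detects
(reactions that never cross threshold) are stored as NaN and are treated
downstream as right-censored at ``detection_limit``.  Wells removed by
technical QC are also NaN but are tracked separately in ``excluded`` so
that censored-likelihood code can distinguish "no signal by cycle 40"
(informative, censored) from "unreliable well" (excluded observation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Finest-resolution clinical group labels. The END super-group (all
#: endometriosis) is the union OMA ∪ DIE and is derived, never stored.
GROUP_LABELS = ("CNT", "OMA", "DIE")

#: Hemolysis marker pair: miR-451a is carried by red blood cells,
#: miR-23a-3p is insensitive to hemolysis.
HEMOLYSIS_RBC_MARKER = "miR-451a"
HEMOLYSIS_STABLE_MARKER = "miR-23a-3p"


@dataclass
class CtMatrix:
    """Cq values for ``n_targets × n_samples`` wells.

    Parameters
    ----------
    values
        DataFrame indexed by target id, columns sample ids; NaN marks a
        well with no usable Cq (non-detect or QC-excluded).
    amp_score, cq_confidence
        Per-well QC covariates, same shape as ``values``.
    detection_limit
        Last qPCR cycle; present values never exceed it after QC.
    excluded
        Boolean frame marking wells removed by technical QC.  Excluded
        wells are *not* censored observations: they carry no evidence
        about abundance.
    """

    values: pd.DataFrame
    amp_score: pd.DataFrame
    cq_confidence: pd.DataFrame
    detection_limit: float = 40.0
    excluded: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for frame in (self.amp_score, self.cq_confidence):
            if frame.shape != self.values.shape:
                raise ValueError("QC covariate shape does not match values")
        if self.excluded is None:
            self.excluded = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )

    # -- basic views ---------------------------------------------------
    @property
    def target_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        """True where no Cq value is available (non-detect or excluded)."""
        return self.values.isna()

    @property
    def censored_mask(self) -> pd.DataFrame:
        """True where the well is a genuine non-detect (censored at limit)."""
        return self.values.isna() & ~self.excluded

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "CtMatrix":
        return CtMatrix(
            values=self.values.copy(),
            amp_score=self.amp_score.copy(),
            cq_confidence=self.cq_confidence.copy(),
            detection_limit=self.detection_limit,
            excluded=self.excluded.copy(),
        )

    def subset_targets(self, target_ids) -> "CtMatrix":
        idx = pd.Index(target_ids)
        return CtMatrix(
            values=self.values.loc[idx],
            amp_score=self.amp_score.loc[idx],
            cq_confidence=self.cq_confidence.loc[idx],
            detection_limit=self.detection_limit,
            excluded=self.excluded.loc[idx],
        )

    def subset_samples(self, sample_ids) -> "CtMatrix":
        cols = pd.Index(sample_ids)
        return CtMatrix(
            values=self.values[cols],
            amp_score=self.amp_score[cols],
            cq_confidence=self.cq_confidence[cols],
            detection_limit=self.detection_limit,
            excluded=self.excluded[cols],
        )


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check a sample annotation table and return it indexed by sample id.

    Required columns: ``sample_id`` (or an index named so) and ``group``
    with labels drawn from :data:`GROUP_LABELS`.  "END" is rejected: the
    all-endometriosis super-group is computed as OMA ∪ DIE at comparison
    time, never stored.
    """
    table = samples.copy()
    if "sample_id" in table.columns:
        table = table.set_index("sample_id")
    if table.index.has_duplicates:
        raise ValueError("duplicate sample ids in sample table")
    if "group" not in table.columns:
        raise ValueError("sample table lacks required column 'group'")
    bad = set(table["group"].unique()) - set(GROUP_LABELS)
    if bad:
        raise ValueError(
            f"unknown group labels {sorted(bad)}; allowed: {GROUP_LABELS} "
            "(END is derived as OMA ∪ DIE, not stored)"
        )
    return table


def group_members(samples: pd.DataFrame, label: str) -> pd.Index:
    """Sample ids belonging to a group; ``"END"`` means OMA ∪ DIE."""
    if label == "END":
        mask = samples["group"].isin(("OMA", "DIE"))
    elif label in GROUP_LABELS:
        mask = samples["group"] == label
    else:
        raise ValueError(f"unknown group label {label!r}")
    return samples.index[mask]


def analysis_samples(samples: pd.DataFrame) -> pd.Index:
    """Sample ids retained for analysis (hemolysis-pass or unchecked)."""
    if "hemolysis_pass" in samples.columns:
        keep = samples["hemolysis_pass"].fillna(True).astype(bool)
        return samples.index[keep]
    return samples.index


def _as_bool(frame: pd.DataFrame) -> np.ndarray:
    return frame.to_numpy(dtype=bool)
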