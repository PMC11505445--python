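"""Reading and writing the long-format Cq exchange files.

The on-disk format is deliberately minimal and text-only:

* Cq table (TSV): columns ``sample_id, target_id, Cq, amp_score,
  cq_confidence`` — one row per well, blank Cq meaning non-detect.
* Sample table (TSV): columns ``sample_id, group`` with group in
  {CNT, OMA, DIE}.

miR-16-5p may legitimately appear multiple times per sample (it is
spotted repeatedly on the array as a process control); its replicates
are collapsed to their mean and the per-sample replicate SD is kept as
a QC column.  Any other duplicated (target, sample) pair is an error.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import CtMatrix, validate_sample_table

MIR16 = "miR-16-5p"
CQ_COLUMNS = ["sample_id", "target_id", "Cq", "amp_score", "cq_confidence"]


def write_fixture(matrix: CtMatrix, samples: pd.DataFrame, path_cq, path_samples) -> None:
    """Write a CtMatrix + sample table as the long-format TSV pair.

    Round-tripping through :func:`read_ct_long` reproduces the matrix
    exactly (values, missing mask, QC covariates).
    """
    long = matrix.values.stack(future_stack=True).rename("Cq").reset_index()
    long.columns = ["target_id", "sample_id", "Cq"]
    long["amp_score"] = matrix.amp_score.stack(future_stack=True).to_numpy()
    long["cq_confidence"] = matrix.cq_confidence.stack(future_stack=True).to_numpy()
    long = long[CQ_COLUMNS]
    long.to_csv(path_cq, sep="\t", index=False, float_format="%.6g")

    out = samples.copy()
    if out.index.name == "sample_id" or "sample_id" not in out.columns:
        out = out.reset_index().rename(columns={"index": "sample_id"})
    out.to_csv(path_samples, sep="\t", index=False)


def read_ct_long(path_cq, path_samples, detection_limit: float = 40.0):
    """Read the long-format Cq TSV and sample TSV.

    Returns ``(CtMatrix, samples)`` where ``samples`` is a DataFrame
    indexed by sample id with a validated ``group`` column and, when
    miR-16-5p replicates are present, a ``mir16_replicate_sd`` column.
    """
    for path in (path_cq, path_samples):
        if not os.path.exists(path):
            raise FileNotFoundError(path)

    long = pd.read_csv(path_cq, sep="\t", dtype={"sample_id": str, "target_id": str})
    missing_cols = set(CQ_COLUMNS) - set(long.columns)
    if missing_cols:
        raise ValueError(f"Cq table lacks required columns: {sorted(missing_cols)}")

    samples = pd.read_csv(path_samples, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in samples.columns:
        raise ValueError("sample table lacks required column 'sample_id'")
    samples = validate_sample_table(samples)

    dup = long.duplicated(subset=["sample_id", "target_id"], keep=False)
    dup_other = long.loc[dup & (long["target_id"] != MIR16)]
    if len(dup_other):
        pairs = sorted(
            set(zip(dup_other["sample_id"], dup_other["target_id"]))
        )[:5]
        raise ValueError(f"duplicate (sample, target) rows, e.g. {pairs}")

    # collapse miR-16-5p replicates; keep their spread as a process-QC metric
    is16 = long["target_id"] == MIR16
    if is16.sum() and long.loc[is16].duplicated(subset="sample_id").any():
        reps = long.loc[is16].groupby("sample_id")["Cq"]
        sd = reps.std(ddof=1)
        mean = reps.mean()
        first16 = long.loc[is16].drop_duplicates(subset="sample_id").copy()
        first16["Cq"] = first16["sample_id"].map(mean).to_numpy()
        long = pd.concat([long.loc[~is16], first16], ignore_index=True)
        samples = samples.copy()
        samples["mir16_replicate_sd"] = samples.index.map(sd)

    def pivot(col):
        return long.pivot(index="target_id", columns="sample_id", values=col)

    values = pivot("Cq").astype(float)
    amp = pivot("amp_score").astype(float)
    conf = pivot("cq_confidence").astype(float)

    extra = values.columns.difference(samples.index)
    if len(extra):
        raise ValueError(f"samples present in Cq table but not annotated: {list(extra)[:5]}")
    # preserve annotation order for samples; Cq-table order for targets
    cols = [s for s in samples.index if s in values.columns]
    values, amp, conf = values[cols], amp[cols], conf[cols]

    matrix = CtMatrix(
        values=values,
        amp_score=amp,
        cq_confidence=conf,
        detection_limit=detection_limit,
    )
    return matrix, samples.loc[samples.index.intersection(cols, sort=False)]


def write_matrix_tsv(matrix: CtMatrix, path) -> None:
    """Write the wide Cq matrix (targets × samples) as TSV."""
    matrix.values.to_csv(path, sep="\t", float_format="%.6g")
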