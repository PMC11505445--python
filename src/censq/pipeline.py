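"""End-to-end orchestration: QC → reference selection → DE → enrichment.

`run_all` is a pure function of (input files or in-memory data, config,
seed): rerunning with the same config produces byte-identical output
tables.  The single seed is expanded into per-stage substreams via
``numpy.random.SeedSequence.spawn`` so adding a stage never perturbs an
earlier stage's randomness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import CtMatrix, validate_sample_table
from .de import DEFAULT_COMPARISONS, run_all_comparisons, wide_summary
from .enrichment import enrich_de_mirnas, read_gmt, read_target_map
from .io import read_ct_long
from .qc import (
    apply_well_qc,
    detection_filter,
    hemolysis_check,
    mir16_replicate_report,
)
from .stability import impute_censored, select_references, stability_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with their conventional defaults."""

    # paths (optional when data is passed in memory)
    cq_path: str | None = None
    samples_path: str | None = None
    target_map_path: str | None = None
    gmt_path: str | None = None
    outdir: str = "censq_out"

    # well QC
    min_amp_score: float = 1.0
    min_cq_conf: float = 0.8
    min_cq: float = 6.0
    # sample QC
    hemolysis_threshold: float = 8.0
    # filtering
    detection_frac: float = 0.75
    ref_detection_frac: float = 0.95
    # reference selection
    k_refs: int = 3
    tost_margin: float = 0.5
    tost_alpha: float = 0.05
    # testing
    alpha: float = 0.05
    comparisons: tuple = DEFAULT_COMPARISONS
    seed: int = 0

    def validate(self) -> None:
        for name in ("detection_frac", "ref_detection_frac", "tost_alpha", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0, 1]: {v}")
        if self.tost_margin <= 0 or self.hemolysis_threshold <= 0:
            raise ValueError("tost_margin and hemolysis_threshold must be > 0")
        if self.k_refs < 1:
            raise ValueError("k_refs must be >= 1")


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus where it was written."""

    samples: pd.DataFrame
    well_qc: object
    stability: pd.DataFrame
    refset: object
    de_tables: dict[str, pd.DataFrame]
    wide: pd.DataFrame
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    outdir: Path | None = None


def run_all(
    config: PipelineConfig,
    matrix: CtMatrix | None = None,
    samples: pd.DataFrame | None = None,
    write: bool = True,
) -> PipelineResult:
    """Run the full analysis; inputs come from config paths or memory.

    Stages: well QC → hemolysis screen → (per comparison-pair) 75%
    detection filter → imputation of non-detects → stability scoring →
    reference selection (TOST + ≥95% detection + consensus rank) →
    ΔΔCt tobit DE → optional ORA of significant miRNAs' targets.
    """
    config.validate()
    substreams = np.random.SeedSequence(config.seed).spawn(2)
    seed_impute = int(substreams[0].generate_state(1)[0] % (2**31))
    # substreams[1] reserved: adding a stochastic stage later must not
    # perturb the imputation stream

    if matrix is None:
        if config.cq_path is None or config.samples_path is None:
            raise ValueError("either pass matrix+samples or set cq_path/samples_path")
        matrix, samples = read_ct_long(config.cq_path, config.samples_path)
    else:
        samples = validate_sample_table(samples)

    # --- QC -------------------------------------------------------------
    matrix, well_report = apply_well_qc(
        matrix, config.min_amp_score, config.min_cq_conf, config.min_cq
    )
    samples = hemolysis_check(matrix, samples, config.hemolysis_threshold)
    n_hem = int((~samples["hemolysis_pass"]).sum())
    logger.info("hemolysis: %d samples excluded", n_hem)

    # --- reference selection --------------------------------------------
    candidates = detection_filter(
        matrix, samples, ("END", "CNT"), config.detection_frac
    )
    complete, excluded = impute_censored(candidates, samples, seed=seed_impute)
    stab = stability_table(
        complete, samples, candidates,
        tost_margin=config.tost_margin, tost_alpha=config.tost_alpha,
    )
    refset = select_references(
        stab, k=config.k_refs, min_detect=config.ref_detection_frac,
        tost_alpha=config.tost_alpha, matrix=matrix, samples=samples,
    )
    logger.info("selected references: %s", refset.reference_ids)

    # --- differential expression (imputed values never enter) -----------
    de_tables = run_all_comparisons(
        matrix, samples, refset,
        comparisons=config.comparisons,
        min_detect_frac=config.detection_frac,
        alpha=config.alpha,
    )
    wide = wide_summary(de_tables)

    # --- enrichment (optional) ------------------------------------------
    enrichment: dict[str, pd.DataFrame] = {}
    if config.target_map_path and config.gmt_path:
        target_map = read_target_map(config.target_map_path)
        pathways = read_gmt(config.gmt_path)
        for name, table in de_tables.items():
            enrichment[name] = enrich_de_mirnas(
                table, target_map, pathways, alpha=config.alpha
            )
    else:
        logger.info("no target map / GMT supplied; enrichment skipped")

    result = PipelineResult(
        samples=samples, well_qc=well_report, stability=stab,
        refset=refset, de_tables=de_tables, wide=wide, enrichment=enrichment,
    )
    if write:
        result.outdir = _write_outputs(config, result)
    return result


def _write_outputs(config: PipelineConfig, result: PipelineResult) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = dict(sep="\t", float_format="%.6g")

    qc = result.samples.copy()
    qc = qc.join(mir16_replicate_report(result.samples)[["mir16_flag"]], how="left")
    qc.to_csv(out / "qc_report.tsv", **fmt)
    result.stability.to_csv(out / "stability_report.tsv", **fmt)
    pd.DataFrame({"reference_id": result.refset.reference_ids}).to_csv(
        out / "reference_set.tsv", sep="\t", index=False
    )
    result.refset.norm_factor.to_csv(out / "norm_factor.tsv", **fmt)
    for name, table in result.de_tables.items():
        table.to_csv(out / f"de_{name}.tsv", **fmt)
    result.wide.to_csv(out / "de_wide_summary.tsv", sep="\t")
    for name, table in result.enrichment.items():
        table.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)

    manifest = {
        "censq_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_samples_analysed": int(result.samples["hemolysis_pass"].sum()),
        "references": result.refset.reference_ids,
        "wells_removed_by_qc": result.well_qc.n_removed,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
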