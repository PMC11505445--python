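"""Synthetic serum-miRNA cohort generator with planted ground truth.

The generator emulates an OpenArray-style Cq panel: 754 miRNA targets
measured in three clinical groups (CNT controls, OMA endometrioma, DIE
deep-infiltrating endometriosis; END = OMA ∪ DIE).  Each target i has a
group mean μ_ig and SD σ_i on the Ct scale; wells are drawn from
N(μ_ig, σ_i²) and any draw beyond the detection limit (Ct = 40) is
recorded as a non-detect — so censoring probability is exactly the
normal upper-tail mass beyond the limit.

Serum is miRNA-poor: in real panels only a minority of targets are
quantifiable.  Baseline means are therefore drawn from a two-component
mixture — an "expressed" fraction with means well below the limit and a
majority near or above it — so that the detected-in-≥75% count lands in
the low hundreds out of 754, as observed on real serum cohorts.

Planted structure (recorded in :class:`TruthTable`):

* reference targets with group-invariant means and small SDs,
* differential targets with a group shift on the Ct scale
  (effect = mean Ct(case) − mean Ct(control); negative = up-regulated),
* hemolysed samples, simulated by shifting miR-451a (the red-blood-cell
  marker) downward until ΔCq = Cq(miR-23a-3p) − Cq(miR-451a) ≥ 8,
* wells with failing amplification score / Cq confidence at a given
  rate; they keep their raw Cq until well QC blanks them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CtMatrix, HEMOLYSIS_RBC_MARKER, HEMOLYSIS_STABLE_MARKER


@dataclass
class SimConfig:
    """Stated world of the synthetic cohort.

    Defaults mirror the study design the generator emulates: 754
    targets, 60 controls and 67 endometriosis samples (40 OMA + 27
    DIE), detection limit Ct = 40.
    """

    n_targets: int = 754
    n_cnt: int = 60
    n_oma: int = 40
    n_die: int = 27
    detection_limit: float = 40.0
    #: baseline mean Ct of the expressed (quantifiable) component
    mu_range: tuple[float, float] = (22.0, 34.0)
    #: baseline mean Ct of the low/absent component (at or beyond limit)
    mu_absent_range: tuple[float, float] = (38.0, 50.0)
    #: fraction of targets in the expressed component
    frac_expressed: float = 0.2
    sigma_range: tuple[float, float] = (0.5, 2.5)
    n_refs: int = 3
    ref_mu_range: tuple[float, float] = (24.0, 30.0)
    ref_sigma_range: tuple[float, float] = (0.15, 0.35)
    n_de: int = 20
    effect_range: tuple[float, float] = (0.5, 4.0)
    frac_hemolysed: float = 0.03
    qc_fail_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_targets=self.n_targets, n_cnt=self.n_cnt,
                      n_oma=self.n_oma, n_die=self.n_die)
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        # markers occupy 2 slots; refs and DE targets must fit beside them
        if self.n_refs + self.n_de > self.n_targets - 2:
            raise ValueError(
                "n_refs + n_de exceeds the number of available targets"
            )
        for name in ("frac_hemolysed", "qc_fail_rate", "frac_expressed"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a proportion, got {value}")
        if self.n_refs < 0 or self.n_de < 0:
            raise ValueError("n_refs and n_de must be >= 0")


@dataclass
class TruthTable:
    """Planted ground truth of a simulated cohort."""

    reference_ids: list[str]
    #: comparison -> {target id -> true ΔCt effect (case − control)}
    de_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    hemolysed_ids: list[str] = field(default_factory=list)


def simulate_cohort(config: SimConfig):
    """Generate ``(CtMatrix, samples, TruthTable)`` for one cohort.

    Reproducible: identical config (including seed) gives bit-identical
    outputs.  The planted DE effect is applied to all endometriosis
    samples (OMA and DIE alike), i.e. it is an END-vs-CNT effect.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_samples = config.n_cnt + config.n_oma + config.n_die
    groups = (["CNT"] * config.n_cnt + ["OMA"] * config.n_oma
              + ["DIE"] * config.n_die)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    samples = pd.DataFrame({"group": groups}, index=pd.Index(sample_ids, name="sample_id"))

    n_generic = config.n_targets - 2
    target_ids = ([HEMOLYSIS_STABLE_MARKER, HEMOLYSIS_RBC_MARKER]
                  + [f"miR-sim-{i + 1:04d}" for i in range(n_generic)])

    # --- baseline means and SDs -----------------------------------------
    mu = np.empty(config.n_targets)
    sigma = np.empty(config.n_targets)
    expressed = rng.random(config.n_targets) < config.frac_expressed
    mu[expressed] = rng.uniform(*config.mu_range, expressed.sum())
    mu[~expressed] = rng.uniform(*config.mu_absent_range, (~expressed).sum())
    sigma[:] = rng.uniform(*config.sigma_range, config.n_targets)
    # hemolysis markers are abundant in every serum sample; clean samples
    # sit near ΔCq(23a − 451a) ≈ 4.5, well below the 8-cycle threshold
    mu[0], sigma[0] = 26.0, 0.8   # miR-23a-3p
    mu[1], sigma[1] = 21.5, 0.8   # miR-451a

    generic = np.arange(2, config.n_targets)
    special = rng.choice(generic, size=config.n_refs + config.n_de, replace=False)
    ref_idx = special[: config.n_refs]
    de_idx = special[config.n_refs:]

    # planted references: group-invariant, quantifiable, tight
    mu[ref_idx] = rng.uniform(*config.ref_mu_range, config.n_refs)
    sigma[ref_idx] = rng.uniform(*config.ref_sigma_range, config.n_refs)
    # planted DE targets must be quantifiable for recovery to be defined
    mu[de_idx] = rng.uniform(*config.mu_range, config.n_de)

    effects = np.zeros(config.n_targets)
    magnitudes = rng.uniform(*config.effect_range, config.n_de)
    signs = rng.choice([-1.0, 1.0], size=config.n_de)
    effects[de_idx] = magnitudes * signs

    # --- draw the wells -------------------------------------------------
    is_end = samples["group"].isin(("OMA", "DIE")).to_numpy()
    mean_matrix = mu[:, None] + effects[:, None] * is_end[None, :]
    raw = rng.normal(mean_matrix, sigma[:, None])

    # hemolysed samples: excess red-blood-cell miRNA pushes miR-451a down
    n_hem = int(round(config.frac_hemolysed * n_samples))
    hem_pos = rng.choice(n_samples, size=n_hem, replace=False) if n_hem else np.array([], int)
    if n_hem:
        raw[1, hem_pos] = raw[0, hem_pos] - rng.uniform(8.0, 12.0, n_hem)

    censored = raw > config.detection_limit
    values = np.where(censored, np.nan, raw)

    # --- per-well QC covariates -----------------------------------------
    amp = rng.uniform(1.1, 2.0, raw.shape)
    conf = rng.uniform(0.85, 1.0, raw.shape)
    qc_fail = (rng.random(raw.shape) < config.qc_fail_rate) & ~censored
    fail_mode = rng.random(raw.shape) < 0.5
    amp = np.where(qc_fail & fail_mode, rng.uniform(0.0, 1.0, raw.shape), amp)
    conf = np.where(qc_fail & ~fail_mode, rng.uniform(0.0, 0.8, raw.shape), conf)
    amp[censored] = 0.0
    conf[censored] = 0.0

    index = pd.Index(target_ids, name="target_id")
    cols = pd.Index(sample_ids, name="sample_id")
    matrix = CtMatrix(
        values=pd.DataFrame(values, index=index, columns=cols),
        amp_score=pd.DataFrame(amp, index=index, columns=cols),
        cq_confidence=pd.DataFrame(conf, index=index, columns=cols),
        detection_limit=config.detection_limit,
    )

    de_map = {target_ids[i]: float(effects[i]) for i in de_idx}
    truth = TruthTable(
        reference_ids=sorted(target_ids[i] for i in ref_idx),
        de_effects={"END_vs_CNT": de_map} if de_map else {},
        hemolysed_ids=sorted(sample_ids[j] for j in hem_pos),
    )
    return matrix, samples, truth
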