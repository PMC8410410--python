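"""Synthetic multi-study data with the structure the pipeline assumes.

Three generators cover the pipeline's inputs without any downloads:

* ``gen_multistudy_expression`` — a collection of two-arm case/control
  expression datasets whose study-level true effects are drawn from a
  normal random-effects distribution (mean ``delta``, between-study
  variance ``tau2``), mimicking a set of independent public cohorts with
  heterogeneous effect sizes.  Defaults emulate the 19-dataset structure
  of the packaged summary tables: k = 19, δ = −0.6, τ² = 0.3, arm sizes
  3–60 cases / 3–40 controls.
* ``gen_deg_tables`` — per-dataset (gene, logFC, P) tables with planted
  signal genes that exceed the DEG thresholds in exactly a chosen number
  of datasets, against a uniform-p, sub-threshold-logFC background
  (emulating 39 reprocessed arrays).
* ``gen_survival_cohort`` — exponential event times with a group hazard
  ratio and independent exponential censoring.

All generators are pure functions of (config, seed).  The global seed
fans out to per-study substreams, so adding a study leaves earlier
studies' data unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import StudyRecord
from .summary import ArmSummary, summarize_arm

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "gen_multistudy_expression",
    "gen_deg_tables",
    "gen_survival_cohort",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the multi-study expression generator.

    ``delta`` is the true standardized mean difference (case − control, in
    within-study SD units); ``tau2`` the between-study variance of the
    study-level effect; ranges are inclusive integer/real intervals.
    ``direction_flip_prob`` flips the sign of a study's effect, emulating
    platforms reported on opposite scales.
    """

    k: int = 19
    delta: float = -0.6
    tau2: float = 0.3
    n_case_range: tuple[int, int] = (3, 60)
    n_control_range: tuple[int, int] = (3, 40)
    sd_range: tuple[float, float] = (0.5, 3.0)
    location_range: tuple[float, float] = (1.0, 9.0)
    direction_flip_prob: float = 0.0
    distribution: str = "normal"  # or "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        for lo, hi in (self.n_case_range, self.n_control_range):
            if lo > hi or lo < 2:
                raise ValueError("arm-size ranges must be non-empty with lo >= 2")
        if self.sd_range[0] <= 0 or self.sd_range[0] > self.sd_range[1]:
            raise ValueError("sd_range must be positive and non-empty")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


@dataclass(frozen=True)
class SimulatedStudy:
    """A simulated dataset: its summary record plus the raw value table."""

    record: StudyRecord
    expression: pd.DataFrame  # columns sample_id, group, value
    true_effect: float


def _study_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    # per-(stream, study) substream: earlier studies are unaffected by k
    return np.random.default_rng(np.random.SeedSequence((seed, stream, index)))


def gen_multistudy_expression(cfg: SimConfig) -> list[SimulatedStudy]:
    """Draw ``cfg.k`` independent two-arm expression datasets.

    Study i draws its true effect δ_i ~ Normal(delta, tau2), arm sizes and
    a within-study SD/location, then samples control values around the
    location and case values offset by δ_i standard deviations.  Identical
    configuration (including seed) gives bit-identical output.
    """
    out = []
    for i in range(cfg.k):
        rng = _study_rng(cfg.seed, 0, i)
        delta_i = cfg.delta + np.sqrt(cfg.tau2) * rng.standard_normal()
        if cfg.direction_flip_prob > 0 and rng.random() < cfg.direction_flip_prob:
            delta_i = -delta_i
        n1 = int(rng.integers(cfg.n_case_range[0], cfg.n_case_range[1] + 1))
        n2 = int(rng.integers(cfg.n_control_range[0], cfg.n_control_range[1] + 1))
        sd = float(rng.uniform(*cfg.sd_range))
        loc = float(rng.uniform(*cfg.location_range))
        control = loc + sd * rng.standard_normal(n2)
        case = loc + delta_i * sd + sd * rng.standard_normal(n1)
        if cfg.distribution == "lognormal":
            case, control = np.exp(case / 4.0), np.exp(control / 4.0)
        sid = f"SIM{i + 1:03d}"
        expr = pd.DataFrame(
            {
                "sample_id": [f"{sid}_case{j}" for j in range(n1)]
                + [f"{sid}_ctrl{j}" for j in range(n2)],
                "group": ["case"] * n1 + ["control"] * n2,
                "value": np.concatenate([case, control]),
            }
        )
        record = StudyRecord(
            study_id=sid,
            case=summarize_arm(case),
            control=summarize_arm(control),
            country="",
            year=None,
        )
        out.append(SimulatedStudy(record=record, expression=expr, true_effect=float(delta_i)))
    return out


def gen_deg_tables(
    n_datasets: int,
    n_genes: int,
    planted: Mapping[str, tuple[str, int]],
    seed: int = 0,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> list[pd.DataFrame]:
    """Per-dataset DEG tables with planted signal genes.

    ``planted`` maps gene → (direction, support count): the gene exceeds
    both thresholds in exactly ``support`` datasets (chosen at random) and
    stays below the logFC threshold elsewhere.  Background genes have
    uniform p-values and |logFC| < ``lfc_threshold``.
    """
    for gene, (direction, support) in planted.items():
        if support > n_datasets:
            raise ValueError(f"{gene}: support {support} exceeds {n_datasets} datasets")
        if direction not in ("up", "down"):
            raise ValueError(f"{gene}: bad direction {direction!r}")
    background = [f"BG{i:05d}" for i in range(n_genes)]
    support_sets = {}
    for idx, (gene, (_, support)) in enumerate(sorted(planted.items())):
        rng = _study_rng(seed, 1, idx)
        support_sets[gene] = set(rng.choice(n_datasets, size=support, replace=False))
    tables = []
    for d in range(n_datasets):
        rng = _study_rng(seed, 2, d)
        genes, lfc, pv = [], [], []
        for g in background:
            genes.append(g)
            lfc.append(rng.uniform(-0.95 * lfc_threshold, 0.95 * lfc_threshold))
            pv.append(rng.uniform())
        for gene, (direction, _) in sorted(planted.items()):
            sign = 1.0 if direction == "up" else -1.0
            genes.append(gene)
            if d in support_sets[gene]:
                lfc.append(sign * rng.uniform(1.2 * lfc_threshold, 3.0 * lfc_threshold))
                pv.append(rng.uniform(0.0, 0.8 * p_threshold))
            else:
                lfc.append(sign * rng.uniform(0.0, 0.9 * lfc_threshold))
                pv.append(rng.uniform())
        tables.append(pd.DataFrame({"gene": genes, "logFC": lfc, "P": pv}))
    return tables


def gen_survival_cohort(
    n: int,
    hazard_ratio: float,
    censor_rate: float = 0.2,
    seed: int = 0,
    baseline_hazard: float = 0.1,
) -> pd.DataFrame:
    """Two-group survival cohort with exponential times.

    Group "high" has its hazard scaled by ``hazard_ratio`` relative to
    group "low"; censoring is independent exponential, tuned so that
    roughly ``censor_rate`` of baseline-group subjects are censored.
    ``censor_rate = 1`` censors every record.
    """
    if n < 2:
        raise ValueError("need n >= 2 subjects")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not (0.0 <= censor_rate <= 1.0):
        raise ValueError("censor_rate must be in [0,1]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    group = np.array(["low", "high"])[(np.arange(n) % 2)]
    rate = np.where(group == "high", baseline_hazard * hazard_ratio, baseline_hazard)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate >= 1.0:
        time, event = t_event, np.zeros(n, dtype=int)
    elif censor_rate == 0.0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        c_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "time": time,
            "event": event,
            "group": group,
        }
    )
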