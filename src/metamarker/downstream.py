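"""Target-gene verification: enrichment, hub counting, correlation, survival.

Over-representation of a query gene list in user-supplied gene-set
collections is tested with the upper hypergeometric tail; genes recurring
across enriched pathways are ranked by membership count; marker/target
co-expression uses the Pearson product-moment correlation; and prognostic
value is assessed with Kaplan–Meier curves compared by the two-group
log-rank test (via lifelines).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "EnrichmentRow",
    "SurvivalCurve",
    "hypergeom_ora",
    "pathway_membership_count",
    "pearson_corr",
    "km_logrank",
    "median_split",
]


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    p_adj: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.query_size):
            raise ValueError("overlap exceeds margin")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p out of (0,1]: {self.p}")


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate for one group: step values at event times."""

    group: str
    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]


def hypergeom_ora(
    query: Iterable[str],
    collections: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Each collection set is intersected with the universe before testing;
    the p-value is the upper tail P(X ≥ overlap).  Rows are sorted by
    ascending p, with a Benjamini–Hochberg column.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query) & uni
    if set(query) - uni:
        raise ValueError("query contains genes outside the universe")
    rows = []
    for name, members in collections.items():
        m = set(members) & uni
        overlap = len(q & m)
        # P(X >= overlap) for X ~ Hypergeom(N=|uni|, K=|set|, n=|query|)
        p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(m), len(q)))
        rows.append((name, overlap, len(m), len(q), len(uni), min(p, 1.0)))
    pvals = np.array([r[5] for r in rows])
    padj = stats.false_discovery_control(pvals, method="bh") if len(rows) else pvals
    out = [
        EnrichmentRow(name, ov, ss, qs, us, p, float(pa))
        for (name, ov, ss, qs, us, p), pa in zip(rows, padj)
    ]
    out.sort(key=lambda r: (r.p, r.set_name))
    return out


def pathway_membership_count(
    gene_lists: Mapping[str, Iterable[str]], min_pathways: int = 1
) -> list[tuple[str, int]]:
    """Count, per gene, how many of the named pathways contain it.

    Returns (gene, count) for genes in at least ``min_pathways`` lists,
    sorted by descending count then gene name.
    """
    counts: dict[str, int] = {}
    for members in gene_lists.values():
        for g in set(members):
            counts[g] = counts.get(g, 0) + 1
    kept = [(g, n) for g, n in counts.items() if n >= min_pathways]
    kept.sort(key=lambda t: (-t[1], t[0]))
    return kept


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with the two-sided t-distribution p-value.

    Requires length ≥ 3 and non-zero variance in both vectors.
    """
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


def km_logrank(
    records: pd.DataFrame, group_col: str = "group"
) -> tuple[dict[str, SurvivalCurve], float, float]:
    """Kaplan–Meier curves per group plus the two-group log-rank test.

    ``records`` needs columns ``time``, ``event`` (0/1) and ``group_col``
    with exactly two levels, each non-empty.  Returns (curves, chi2, p).
    With no events at all the curves are identically 1 and the test
    carries no information (chi2 = 0, p = 1).
    """
    levels = sorted(records[group_col].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    no_events = int(records["event"].sum()) < 1
    curves = {}
    subsets = {}
    for lv in levels:
        sub = records[records[group_col].astype(str) == lv]
        if sub.empty:
            raise ValueError(f"group {lv!r} is empty")
        subsets[lv] = sub
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        times = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = kmf.event_table["at_risk"].to_numpy(dtype=int)
        curves[lv] = SurvivalCurve(lv, tuple(times), tuple(surv), tuple(at_risk))
    if no_events:
        return curves, 0.0, 1.0
    a, b = subsets[levels[0]], subsets[levels[1]]
    res = logrank_test(a["time"], b["time"], event_observed_A=a["event"],
                       event_observed_B=b["event"])
    return curves, float(res.test_statistic), float(res.p_value)


def median_split(values: pd.Series) -> pd.Series:
    """Label samples 'high'/'low' by the median (ties go to 'low')."""
    med = values.median()
    return pd.Series(np.where(values > med, "high", "low"), index=values.index)
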