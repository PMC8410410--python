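"""Multi-dataset differential-expression screening by vote counting.

Each dataset contributes gene-level calls thresholded on |log2 fold
change| and p-value; a gene's vote is the number of datasets calling it,
counted once per dataset regardless of direction.  Genes reaching a
minimum number of appearances are then combined with external evidence
(transfection-response DEGs, predicted target lists, sequencing DEGs)
into final up/down gene sets, with the combination policy configurable.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["DegCall", "VoteTally", "call_degs", "vote_count", "final_deg_set"]

logger = logging.getLogger(__name__)

POLICIES = ("intersect_any", "intersect_all", "union")


@dataclass(frozen=True)
class DegCall:
    gene: str
    logfc: float
    p: float
    direction: str

    def __post_init__(self) -> None:
        if (self.direction == "up") != (self.logfc > 0):
            raise ValueError(f"{self.gene}: direction inconsistent with logFC sign")


@dataclass
class VoteTally:
    """Per-gene dataset support: count plus the multiset of call directions."""

    counts: dict[str, int]
    directions: dict[str, Counter]

    def majority_direction(self, gene: str) -> str | None:
        """'up'/'down' by majority of dataset calls; None on a tie."""
        c = self.directions[gene]
        if c["up"] == c["down"]:
            return None
        return "up" if c["up"] > c["down"] else "down"


def call_degs(
    table: pd.DataFrame, lfc_threshold: float = 1.0, p_threshold: float = 0.05
) -> list[DegCall]:
    """Threshold one dataset's (gene, logFC, P) table into DEG calls.

    Keeps rows with |logFC| strictly above ``lfc_threshold`` AND p strictly
    below ``p_threshold``; direction follows the logFC sign.
    """
    if lfc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    out = []
    for row in table.itertuples(index=False):
        if abs(row.logFC) > lfc_threshold and row.P < p_threshold:
            out.append(
                DegCall(str(row.gene), float(row.logFC), float(row.P),
                        "up" if row.logFC > 0 else "down")
            )
    return out


def vote_count(
    call_sets: Sequence[Sequence[DegCall]], min_appearances: int = 9
) -> VoteTally:
    """Count per-gene dataset support and keep genes at/above the threshold.

    A gene counts at most once per dataset, whatever its direction there.
    """
    if min_appearances < 1:
        raise ValueError("min_appearances must be >= 1")
    counts: Counter = Counter()
    directions: dict[str, Counter] = {}
    for calls in call_sets:
        seen: dict[str, str] = {}
        for c in calls:
            seen.setdefault(c.gene, c.direction)
        for gene, d in seen.items():
            counts[gene] += 1
            directions.setdefault(gene, Counter())[d] += 1
    kept = {g: n for g, n in counts.items() if n >= min_appearances}
    return VoteTally(counts=kept, directions={g: directions[g] for g in kept})


def final_deg_set(
    tally: VoteTally,
    transfection_degs: Iterable[str],
    predicted_targets: Iterable[str],
    sequencing_degs: Iterable[str] = (),
    policy: str = "intersect_any",
) -> tuple[set[str], set[str]]:
    """Combine vote-count survivors with external evidence into (up, down).

    policy:
      - ``intersect_any`` (default): keep tally genes present in at least
        one non-empty evidence set;
      - ``intersect_all``: keep tally genes present in every non-empty
        evidence set;
      - ``union``: keep all tally genes plus all evidence genes that have
        a direction in the tally.

    Direction is assigned by majority vote across datasets; ties are
    excluded with a warning.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    evidence = [set(transfection_degs), set(predicted_targets), set(sequencing_degs)]
    nonempty = [s for s in evidence if s]
    genes = set(tally.counts)
    if policy == "intersect_any":
        pool = set().union(*nonempty) if nonempty else set()
        genes &= pool
    elif policy == "intersect_all":
        for s in nonempty:
            genes &= s
        if not nonempty:
            genes = set()
    # union keeps all tally genes

    up, down = set(), set()
    for g in sorted(genes):
        d = tally.majority_direction(g)
        if d is None:
            logger.warning("gene %s has tied up/down votes; excluded", g)
            continue
        (up if d == "up" else down).add(g)
    return up, down
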