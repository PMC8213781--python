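"""Tail-fiber (Afp13) target-kingdom classification.

The tail fiber mediates attachment to the target cell, so its closest
homologs hint at whether a particle targets bacteria or eukaryotes.  Each
fiber protein is BLASTed against a tailed-phage protein set and a
eukaryotic-virus protein set; hits with E-value >= the cutoff (default
1e-3) are discarded, and the two best remaining bitscores are compared.
A difference strictly greater than ``delta`` (default 15 bits) calls the
fiber for that database; a difference within ``delta`` is inconclusive;
no surviving hit on either side is a no-hit.  When only one database
yields a hit the call follows that database (the two-score comparison
degenerates naturally).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import BlastHit, HmmHit, ParameterError

__all__ = ["FiberCall", "select_fiber_set", "classify_fiber", "classify_all"]


@dataclass(frozen=True)
class FiberCall:
    gene_id: str
    best_phage_bitscore: float | None
    best_virus_bitscore: float | None
    call: str  # phage | euk_virus | inconclusive | no_hit


def select_fiber_set(
    afp13_hits: Sequence[HmmHit], top_fraction: float = 0.25
) -> set[str]:
    """Genes whose best afp13 bitscore ranks in the top ``top_fraction``.

    The kept count is ``ceil(top_fraction * n)`` over distinct genes;
    ties with the last kept score are kept.  Empty input yields an empty
    set.
    """
    if not 0 < top_fraction <= 1:
        raise ParameterError(f"top_fraction must lie in (0, 1], got {top_fraction}")
    best: dict[str, float] = {}
    for h in afp13_hits:
        if h.gene_id not in best or h.bitscore > best[h.gene_id]:
            best[h.gene_id] = h.bitscore
    if not best:
        return set()
    scores = sorted(best.values(), reverse=True)
    k = math.ceil(top_fraction * len(scores))
    cutoff = scores[k - 1]
    return {g for g, s in best.items() if s >= cutoff}


def classify_fiber(
    best_phage: BlastHit | None,
    best_virus: BlastHit | None,
    evalue_cut: float = 1e-3,
    delta: float = 15.0,
    gene_id: str | None = None,
) -> FiberCall:
    """Call one fiber gene from its per-database best hits."""
    if best_phage is not None and best_phage.evalue >= evalue_cut:
        best_phage = None
    if best_virus is not None and best_virus.evalue >= evalue_cut:
        best_virus = None
    gene_id = gene_id or (
        best_phage.query_id if best_phage else best_virus.query_id if best_virus else "NA"
    )
    pb = best_phage.bitscore if best_phage else None
    vb = best_virus.bitscore if best_virus else None
    if pb is None and vb is None:
        call = "no_hit"
    elif vb is None:
        call = "phage"
    elif pb is None:
        call = "euk_virus"
    elif pb - vb > delta:
        call = "phage"
    elif vb - pb > delta:
        call = "euk_virus"
    else:
        call = "inconclusive"
    return FiberCall(gene_id, pb, vb, call)


def classify_all(
    phage_hits: Iterable[BlastHit],
    virus_hits: Iterable[BlastHit],
    gene_ids: Iterable[str] | None = None,
    evalue_cut: float = 1e-3,
    delta: float = 15.0,
) -> list[FiberCall]:
    """Classify every query gene from its two BLAST hit lists.

    ``gene_ids`` optionally fixes the query universe (genes with no hit
    in either file are then reported as no-hit); otherwise the universe
    is every query seen in either list.  Per database, the best hit is
    the maximum-bitscore hit passing the E-value cut.
    """

    seen: set[str] = set()

    def best_by_query(hits: Iterable[BlastHit]) -> dict[str, BlastHit]:
        best: dict[str, BlastHit] = {}
        for h in hits:
            seen.add(h.query_id)
            if h.evalue >= evalue_cut:
                continue
            if h.query_id not in best or h.bitscore > best[h.query_id].bitscore:
                best[h.query_id] = h
        return best

    phage_best = best_by_query(phage_hits)
    virus_best = best_by_query(virus_hits)
    universe = sorted(set(gene_ids)) if gene_ids is not None else sorted(seen)
    return [
        classify_fiber(
            phage_best.get(g), virus_best.get(g), evalue_cut, delta, gene_id=g
        )
        for g in universe
    ]


def call_counts(calls: Sequence[FiberCall]) -> dict[str, int]:
    counts = Counter(c.call for c in calls)
    return {k: counts.get(k, 0) for k in ("phage", "euk_virus", "inconclusive", "no_hit")}
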