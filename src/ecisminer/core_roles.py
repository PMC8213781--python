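"""Assignment of eCIS core roles (afp1..afp16) to genes.

Two evidence streams are merged: pfam annotations already on the gene
(via the configurable pfam -> role map) and hmmsearch hits against the
Afp1-16 core profiles.  HMM hits are first rank-filtered by bitscore:
per profile, only the top ``keep_fraction`` of hits survive (the survey's
"drop the bottom half" rule), which suppresses the long tail of spurious
homology among contractile-machine families.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import (
    AFP_ROLES,
    CoreConfig,
    GeneRecord,
    HmmHit,
    ParameterError,
    normalize_profile_name,
)

__all__ = ["CoreRoleAssignment", "percentile_filter", "assign_core_roles"]


@dataclass
class CoreRoleAssignment:
    """Core roles carried by one gene, with per-role evidence sources."""

    gene_id: str
    roles: frozenset[str]
    sources: dict[str, frozenset[str]] = field(default_factory=dict)
    # sources maps role -> subset of {"pfam_map", "hmm"}


def percentile_filter(
    hits: Sequence[HmmHit],
    keep_fraction: float = 0.5,
    per_profile: bool = True,
) -> list[HmmHit]:
    """Keep the top ``keep_fraction`` of hits by bitscore.

    Ranking is per profile by default (one global ranking when
    ``per_profile`` is False).  The kept count is ``ceil(keep_fraction * n)``
    so a lone hit always survives, and any hit tied with the last kept
    bitscore is also kept: equal evidence is never discarded by rank
    arbitrariness.  Input order is preserved.
    """
    if not 0 < keep_fraction <= 1:
        raise ParameterError(f"keep_fraction must lie in (0, 1], got {keep_fraction}")
    if not hits:
        return []
    groups: dict[str, list[int]] = defaultdict(list)
    for i, h in enumerate(hits):
        groups[h.profile_id if per_profile else ""].append(i)
    kept: set[int] = set()
    for idxs in groups.values():
        ranked = sorted(idxs, key=lambda i: -hits[i].bitscore)
        k = math.ceil(keep_fraction * len(ranked))
        cutoff = hits[ranked[k - 1]].bitscore
        kept.update(i for i in idxs if hits[i].bitscore >= cutoff)
    return [hits[i] for i in sorted(kept)]


def assign_core_roles(
    genes: Iterable[GeneRecord],
    hits: Sequence[HmmHit],
    config: CoreConfig,
) -> list[CoreRoleAssignment]:
    """Merge pfam-map roles with (already percentile-filtered) HMM hits.

    A gene's role set is the union of the two streams; genes with no core
    evidence are absent from the output.  Hits referencing unknown gene
    IDs are ignored with a warning.  The result is independent of hit
    order.
    """
    gene_ids = {g.gene_id for g in genes}
    evidence: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for g in genes:
        for pfam in g.pfams:
            role = config.ecis_pfam_to_role.get(pfam)
            if role is not None:
                evidence[g.gene_id][role].add("pfam_map")
    unknown: set[str] = set()
    for h in hits:
        if h.gene_id not in gene_ids:
            unknown.add(h.gene_id)
            continue
        role = normalize_profile_name(h.profile_id, config.profile_aliases)
        if role in AFP_ROLES:
            evidence[h.gene_id][role].add("hmm")
    if unknown:
        warnings.warn(
            f"{len(unknown)} HMM hit gene id(s) not in the gene set, ignored: "
            f"{sorted(unknown)[:5]}..."
        )
    out = []
    for g in genes:  # preserve gene order
        ev = evidence.get(g.gene_id)
        if not ev:
            continue
        out.append(
            CoreRoleAssignment(
                gene_id=g.gene_id,
                roles=frozenset(ev),
                sources={r: frozenset(s) for r, s in ev.items()},
            )
        )
    return out


def write_core_assignments(assignments: Iterable[CoreRoleAssignment], path) -> None:
    """Emit the core-assignment TSV consumed by locus detection."""
    lines = ["gene_id\troles\tsources"]
    for a in assignments:
        srcs = ";".join(
            f"{r}:{'+'.join(sorted(a.sources.get(r, ())))}" for r in sorted(a.roles)
        )
        lines.append(f"{a.gene_id}\t{';'.join(sorted(a.roles))}\t{srcs}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
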