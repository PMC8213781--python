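"""eCIS operon detection from annotated genes and core-role assignments.

The detection chain, run per genome:

1. *seed collection* -- protein-coding genes carrying any pfam from the
   eCIS pfam -> role map;
2. *seed chaining* -- single-linkage grouping of seeds within
   ``linkage_gap_bp`` (nearest-boundary distance, inclusive) on one
   scaffold;
3. *seed filter* -- keep groups with >= ``min_seed_genes`` members of
   which >= ``min_distinct_seed_pfams`` distinct eCIS-associated pfams;
4. *contamination screen* -- discard groups with a phage-blocklist pfam
   or T6SS-blocklist COG within ``contamination_window_bp`` of any member
   (members included), scanning the whole scaffold;
5. *expansion* -- extend by ``expansion_genes`` protein-coding genes on
   each side (non-coding features are skipped and do not consume the
   budget); overlapping expanded candidates on one scaffold are merged;
6. *finalization* -- require >= ``min_core_genes`` genes carrying a core
   role (gene multiplicity, so paralogous cores count) and at least one
   eCIS-specific core (afp12/13/14/16, the families absent from R-type
   pyocins); the reported locus runs from ``boundary_flank_genes``
   coding genes upstream of the first core gene to the same number
   downstream of the last, clipped at scaffold ends.

Every stage decision is recorded in a per-run provenance ledger.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_roles import CoreRoleAssignment, assign_core_roles, percentile_filter
from .model import CoreConfig, GeneRecord, HmmHit, intergenic_gap, sort_genes

__all__ = [
    "SeedGroup",
    "CandidateLocus",
    "EcisLocus",
    "DetectionReport",
    "collect_seed_genes",
    "chain_seed_groups",
    "seed_filter",
    "contamination_screen",
    "expand_group",
    "finalize_locus",
    "detect_loci",
    "detect_loci_report",
]


@dataclass
class SeedGroup:
    """A physically linked run of seed genes on one scaffold."""

    scaffold_id: str
    members: list[GeneRecord]  # ordered by start
    distinct_ecis_pfams: frozenset[str]

    @property
    def span(self) -> tuple[int, int]:
        return min(g.start for g in self.members), max(g.end for g in self.members)


@dataclass
class CandidateLocus:
    """A clean seed group after +/- n-gene expansion."""

    scaffold_id: str
    genes: list[GeneRecord]  # protein-coding, ordered by start
    seed_groups: list[SeedGroup]

    @property
    def span(self) -> tuple[int, int]:
        return min(g.start for g in self.genes), max(g.end for g in self.genes)


@dataclass
class EcisLocus:
    """A finalized eCIS locus."""

    locus_id: str
    genome_id: str
    scaffold_id: str
    member_gene_ids: list[str]  # ordered by start, boundary to boundary
    core_roles: dict[str, frozenset[str]]  # gene_id -> roles
    n_core_genes: int
    boundary: tuple[str, str]  # (first gene_id, last gene_id)
    provenance: dict = field(default_factory=dict)

    @property
    def roles_present(self) -> frozenset[str]:
        return frozenset(r for roles in self.core_roles.values() for r in roles)


@dataclass
class DetectionReport:
    """Per-genome stage tallies: how many groups died at each rule."""

    genome_id: str
    n_genes: int = 0
    n_seed_genes: int = 0
    n_seed_groups: int = 0
    rejected_seed_filter: int = 0
    rejected_contamination: int = 0
    n_candidates: int = 0
    n_candidates_merged: int = 0
    rejected_core_count: int = 0
    rejected_no_specific_core: int = 0
    n_loci: int = 0
    rejections: list[dict] = field(default_factory=list)


def collect_seed_genes(
    genes: Iterable[GeneRecord], config: CoreConfig
) -> list[GeneRecord]:
    """Protein-coding genes whose pfams intersect the eCIS pfam map."""
    ecis_pfams = config.ecis_pfam_to_role.keys()
    return [
        g
        for g in sort_genes(genes)
        if g.is_protein_coding and g.pfams & ecis_pfams
    ]


def chain_seed_groups(
    seeds: Sequence[GeneRecord], max_gap_bp: int, config: CoreConfig | None = None
) -> list[SeedGroup]:
    """Single-linkage chaining of seeds within ``max_gap_bp`` (inclusive).

    The gap is measured from the rightmost boundary reached so far, so a
    long gene bridges its neighbours even when a short one is nested
    inside it.  Seeds on different scaffolds never co-group.
    """
    ecis_pfams = config.ecis_pfam_to_role.keys() if config else None
    groups: list[SeedGroup] = []
    current: list[GeneRecord] = []
    reach = 0  # rightmost end in the current group
    for g in sort_genes(seeds):
        gap = max(0, g.start - reach - 1)
        if current and (g.scaffold_id != current[0].scaffold_id or gap > max_gap_bp):
            groups.append(_make_group(current, ecis_pfams))
            current = []
        if not current:
            reach = g.end
        else:
            reach = max(reach, g.end)
        current.append(g)
    if current:
        groups.append(_make_group(current, ecis_pfams))
    return groups


def _make_group(members: list[GeneRecord], ecis_pfams) -> SeedGroup:
    pf = set()
    for g in members:
        pf |= g.pfams if ecis_pfams is None else (g.pfams & ecis_pfams)
    return SeedGroup(
        scaffold_id=members[0].scaffold_id,
        members=list(members),
        distinct_ecis_pfams=frozenset(pf),
    )


def seed_filter(group: SeedGroup, config: CoreConfig) -> tuple[bool, str | None]:
    """Accept groups with enough members and enough distinct eCIS pfams."""
    t = config.thresholds
    if len(group.members) < t.min_seed_genes:
        return False, f"members {len(group.members)} < {t.min_seed_genes}"
    if len(group.distinct_ecis_pfams) < t.min_distinct_seed_pfams:
        return (
            False,
            f"distinct eCIS pfams {len(group.distinct_ecis_pfams)}"
            f" < {t.min_distinct_seed_pfams}",
        )
    return True, None


def contamination_screen(
    group: SeedGroup,
    all_genes_on_scaffold: Sequence[GeneRecord],
    config: CoreConfig,
) -> tuple[bool, GeneRecord | None]:
    """Screen for phage/T6SS marker genes near (or inside) the group.

    Returns ``(clean, offending_gene)``.  The whole scaffold is scanned:
    a blocklisted gene within ``contamination_window_bp`` (inclusive,
    nearest-boundary) of any group member contaminates the group; group
    members themselves count.
    """
    window = config.thresholds.contamination_window_bp
    for g in all_genes_on_scaffold:
        if g.scaffold_id != group.scaffold_id:
            continue
        if not (
            g.pfams & config.phage_blocklist_pfams
            or g.cogs & config.t6ss_blocklist_cogs
        ):
            continue
        if any(intergenic_gap(g, m) <= window for m in group.members):
            return False, g
    return True, None


def expand_group(
    group: SeedGroup,
    all_genes_on_scaffold: Sequence[GeneRecord],
    n: int,
) -> CandidateLocus:
    """Extend the group by up to ``n`` protein-coding genes per side.

    The candidate carries every protein-coding gene between the expanded
    extrema (interior genes included); non-coding features are skipped
    and do not consume the n-gene budget.  Expansion truncates at
    scaffold ends.
    """
    scaffold = sort_genes(
        g for g in all_genes_on_scaffold if g.scaffold_id == group.scaffold_id
    )
    coding = [g for g in scaffold if g.is_protein_coding]
    index = {g.gene_id: i for i, g in enumerate(coding)}
    first = min(index[m.gene_id] for m in group.members)
    last = max(index[m.gene_id] for m in group.members)
    lo = max(0, first - n)
    hi = min(len(coding) - 1, last + n)
    return CandidateLocus(
        scaffold_id=group.scaffold_id,
        genes=coding[lo : hi + 1],
        seed_groups=[group],
    )


def merge_overlapping(cands: list[CandidateLocus]) -> list[CandidateLocus]:
    """Merge candidates whose expanded spans overlap on one scaffold."""
    by_scaffold: dict[str, list[CandidateLocus]] = defaultdict(list)
    for c in cands:
        by_scaffold[c.scaffold_id].append(c)
    merged: list[CandidateLocus] = []
    for scaffold_id in sorted(by_scaffold):
        group = sorted(by_scaffold[scaffold_id], key=lambda c: c.span)
        acc = group[0]
        for c in group[1:]:
            if c.span[0] <= acc.span[1]:  # overlap (coordinates inclusive)
                genes = {g.gene_id: g for g in acc.genes + c.genes}
                acc = CandidateLocus(
                    scaffold_id=scaffold_id,
                    genes=sort_genes(genes.values()),
                    seed_groups=acc.seed_groups + c.seed_groups,
                )
            else:
                merged.append(acc)
                acc = c
        merged.append(acc)
    return merged


def finalize_locus(
    cand: CandidateLocus,
    roles: Mapping[str, frozenset[str]] | Sequence[CoreRoleAssignment],
    config: CoreConfig,
    all_genes_on_scaffold: Sequence[GeneRecord] | None = None,
    locus_id: str = "locus",
) -> tuple[EcisLocus | None, str | None]:
    """Apply the core-census and specific-core rules; fix locus boundaries.

    ``roles`` maps gene_id -> core role set (or is a list of
    CoreRoleAssignment).  Returns ``(locus, None)`` on acceptance or
    ``(None, reason)`` on rejection.
    """
    if not isinstance(roles, Mapping):
        roles = {a.gene_id: a.roles for a in roles}
    t = config.thresholds
    core_genes = [g for g in cand.genes if roles.get(g.gene_id)]
    if config.count_core_roles_distinct:
        n_core = len({r for g in core_genes for r in roles[g.gene_id]})
    else:
        n_core = len(core_genes)
    if n_core < t.min_core_genes:
        return None, f"core count {n_core} < {t.min_core_genes}"
    present = {r for g in core_genes for r in roles[g.gene_id]}
    if not present & config.ecis_specific_cores:
        return None, "no eCIS-specific core"
    # boundaries: +/- boundary_flank_genes coding genes around the extreme
    # core genes, on the scaffold's full coding gene list
    scaffold = cand.genes if all_genes_on_scaffold is None else sort_genes(
        g
        for g in all_genes_on_scaffold
        if g.scaffold_id == cand.scaffold_id and g.is_protein_coding
    )
    index = {g.gene_id: i for i, g in enumerate(scaffold)}
    first_core = min(index[g.gene_id] for g in core_genes)
    last_core = max(index[g.gene_id] for g in core_genes)
    lo = max(0, first_core - t.boundary_flank_genes)
    hi = min(len(scaffold) - 1, last_core + t.boundary_flank_genes)
    members = scaffold[lo : hi + 1]
    genome_id = members[0].genome_id
    locus = EcisLocus(
        locus_id=locus_id,
        genome_id=genome_id,
        scaffold_id=cand.scaffold_id,
        member_gene_ids=[g.gene_id for g in members],
        core_roles={
            g.gene_id: frozenset(roles[g.gene_id]) for g in core_genes
        },
        n_core_genes=n_core,
        boundary=(members[0].gene_id, members[-1].gene_id),
        provenance={
            "n_seed_groups": len(cand.seed_groups),
            "seed_gene_ids": sorted(
                m.gene_id for sg in cand.seed_groups for m in sg.members
            ),
            "roles_present": sorted(present),
        },
    )
    return locus, None


def detect_loci_report(
    genome: Sequence[GeneRecord],
    hits: Sequence[HmmHit],
    config: CoreConfig | None = None,
    hits_prefiltered: bool = False,
) -> tuple[list[EcisLocus], DetectionReport]:
    """Run the full detection chain on one genome; return loci + tallies."""
    config = config or CoreConfig.default()
    genes = sort_genes(genome)
    genome_id = genes[0].genome_id if genes else "NA"
    report = DetectionReport(genome_id=genome_id, n_genes=len(genes))
    if not genes:
        return [], report

    by_scaffold: dict[str, list[GeneRecord]] = defaultdict(list)
    for g in genes:
        by_scaffold[g.scaffold_id].append(g)

    if not hits_prefiltered:
        hits = percentile_filter(
            hits,
            config.thresholds.hmm_keep_fraction,
            per_profile=config.percentile_per_profile,
        )
    gene_ids = {g.gene_id for g in genes}
    genome_hits = [h for h in hits if h.gene_id in gene_ids]

    seeds = collect_seed_genes(genes, config)
    report.n_seed_genes = len(seeds)
    groups = chain_seed_groups(seeds, config.thresholds.linkage_gap_bp, config)
    report.n_seed_groups = len(groups)

    candidates: list[CandidateLocus] = []
    for group in groups:
        ok, reason = seed_filter(group, config)
        if not ok:
            report.rejected_seed_filter += 1
            report.rejections.append(
                {"stage": "seed_filter", "scaffold": group.scaffold_id,
                 "span": group.span, "reason": reason}
            )
            continue
        clean, offender = contamination_screen(
            group, by_scaffold[group.scaffold_id], config
        )
        if not clean:
            report.rejected_contamination += 1
            report.rejections.append(
                {"stage": "contamination", "scaffold": group.scaffold_id,
                 "span": group.span, "reason": f"blocklisted gene {offender.gene_id}"}
            )
            continue
        candidates.append(
            expand_group(
                group, by_scaffold[group.scaffold_id], config.thresholds.expansion_genes
            )
        )
    report.n_candidates = len(candidates)
    candidates = merge_overlapping(candidates)
    report.n_candidates_merged = len(candidates)

    loci: list[EcisLocus] = []
    for cand in candidates:
        cand_ids = {g.gene_id for g in cand.genes}
        cand_hits = [h for h in genome_hits if h.gene_id in cand_ids]
        assignments = assign_core_roles(cand.genes, cand_hits, config)
        role_map = {a.gene_id: a.roles for a in assignments}
        locus, reason = finalize_locus(
            cand,
            role_map,
            config,
            all_genes_on_scaffold=by_scaffold[cand.scaffold_id],
            locus_id=f"{genome_id}|{cand.scaffold_id}|{len(loci) + 1}",
        )
        if locus is None:
            if "core count" in (reason or ""):
                report.rejected_core_count += 1
            else:
                report.rejected_no_specific_core += 1
            report.rejections.append(
                {"stage": "finalize", "scaffold": cand.scaffold_id,
                 "span": cand.span, "reason": reason}
            )
            continue
        loci.append(locus)
    # candidates arrive sorted by (scaffold, span), so loci already are
    report.n_loci = len(loci)
    return loci, report


def detect_loci(
    genome: Sequence[GeneRecord],
    hits: Sequence[HmmHit],
    config: CoreConfig | None = None,
    hits_prefiltered: bool = False,
) -> list[EcisLocus]:
    """Detect eCIS loci in one genome (see module docstring for the chain)."""
    loci, _ = detect_loci_report(genome, hits, config, hits_prefiltered)
    return loci
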