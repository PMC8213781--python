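"""Synthetic annotated genomes, trees and hit tables with planted truth.

The generator emulates the pipeline's four input surfaces at the
annotation level (no nucleotide realism is attempted or needed):

* genomes as gene tables, with planted eCIS operons and decoy loci
  (pyocin-like operons lacking a specific core, undersized operons,
  phage-contaminated and T6SS-contaminated cassettes) whose expected
  detection outcome is recorded in a truth manifest;
* HMM hit tables in which planted core genes score strictly above a
  matched population of decoy hits, so they survive the top-half
  bitscore filter by construction;
* random rooted binary trees with binary trait tables under three
  scenarios (association scattered across clades, association confined
  to one clade, and a no-association null);
* paired BLAST hit tables realizing a chosen mixture of tail-fiber
  calls.

Geometry defaults: planted core genes are 300-4,500 bp long with 5-500 bp
intergenic gaps (comfortably inside the 12 kb linkage rule); decoy
contaminants sit 8 kb from the operon (inside the 10 kb contamination
window) so the window's boundary is what kills them.  The background pfam
vocabulary is disjoint from both the eCIS map and the blocklists, keeping
truth labels exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .model import BlastHit, CoreConfig, GeneRecord, GenerationError, HmmHit

__all__ = [
    "PlantSpec",
    "ScaffoldTruth",
    "TruthManifest",
    "make_genome",
    "make_tree_traits",
    "make_fiber_hits",
    "write_simulation",
]

PLANT_KINDS = (
    "ecis_valid",
    "ecis_no_specific_core",
    "ecis_undersized",
    "phage_decoy",
    "t6ss_decoy",
    "empty",
)

#: Core roles without a pfam in the default map get their evidence from
#: HMM hits alone; the valid-operon role draw order guarantees the seed
#: rules are met through the mapped roles listed first.
_MAPPED_ROLE_ORDER = ["afp1", "afp2", "afp7", "afp9", "afp8", "afp10", "afp15"]
_HMM_ONLY_ROLES = ["afp3", "afp4", "afp5", "afp6", "afp11"]
_BACKGROUND_PFAMS = [f"PF9{n:04d}" for n in range(1, 41)]  # disjoint vocabulary


@dataclass
class PlantSpec:
    """One planted feature on one scaffold.

    ``ecis_valid`` plants satisfy every detection threshold by
    construction; each decoy kind violates exactly one named rule
    (no specific core / core count / phage window / T6SS marker).
    """

    kind: str
    n_core_genes: int | None = None
    specific_cores: tuple[str, ...] = ("afp13", "afp16")
    gap_range: tuple[int, int] = (5, 500)
    length_range: tuple[int, int] = (300, 4500)
    contaminant_offset: int = 8000

    def resolved_n_core(self, config: CoreConfig) -> int:
        if self.n_core_genes is not None:
            return self.n_core_genes
        return 9 if self.kind == "ecis_undersized" else 12

    def validate(self, config: CoreConfig) -> None:
        if self.kind not in PLANT_KINDS:
            raise GenerationError(f"unknown plant kind {self.kind!r}")
        n = self.resolved_n_core(config)
        t = config.thresholds
        if self.kind in ("ecis_valid", "phage_decoy", "t6ss_decoy"):
            if n < t.min_core_genes:
                raise GenerationError(
                    f"{self.kind} plant with {n} cores cannot satisfy the "
                    f"{t.min_core_genes}-core rule"
                )
            if not set(self.specific_cores) & config.ecis_specific_cores:
                raise GenerationError(f"{self.kind} plant without a specific core")
        if self.kind == "ecis_undersized" and n >= t.min_core_genes:
            raise GenerationError(
                f"ecis_undersized plant with {n} >= {t.min_core_genes} cores"
            )
        if self.gap_range[1] > t.linkage_gap_bp:
            raise GenerationError("planted gaps exceed the linkage rule")


@dataclass
class ScaffoldTruth:
    scaffold_id: str
    kind: str
    planted_gene_ids: list[str]
    core_gene_ids: list[str]
    expected_loci: int


@dataclass
class TruthManifest:
    genome_id: str
    scaffolds: list[ScaffoldTruth] = field(default_factory=list)

    @property
    def expected_total(self) -> int:
        return sum(s.expected_loci for s in self.scaffolds)

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "scaffolds": [vars(s) for s in self.scaffolds],
        }


def _plant_roles(spec: PlantSpec, config: CoreConfig, n: int) -> list[str]:
    """Role draw for a planted operon.

    Roles whose pfam is in the default map (the seed genes) are
    interleaved with HMM-only roles so that consecutive seed genes are
    never separated by more than one unmapped gene -- the planted operon
    then always chains into a single seed group under the 12 kb rule.
    Paralogous copies of structural cores pad large operons.
    """
    if spec.kind == "ecis_no_specific_core":
        pool = _MAPPED_ROLE_ORDER + _HMM_ONLY_ROLES
        roles = [r for r in pool if r not in config.ecis_specific_cores]
    else:
        specifics = list(spec.specific_cores)
        roles = _MAPPED_ROLE_ORDER[: max(4, n - len(_HMM_ONLY_ROLES) - len(specifics))]
        roles += _HMM_ONLY_ROLES + specifics
    if len(roles) < n:  # pad with paralogous copies of structural cores
        roles += [
            _MAPPED_ROLE_ORDER[i % len(_MAPPED_ROLE_ORDER)]
            for i in range(n - len(roles))
        ]
    roles = roles[:n]
    if spec.kind != "ecis_no_specific_core":
        if not set(roles) & config.ecis_specific_cores:
            roles[-1] = spec.specific_cores[0]
    role_to_pfam = {r: p for p, r in config.ecis_pfam_to_role.items()}
    mapped = [r for r in roles if r in role_to_pfam]
    unmapped = [r for r in roles if r not in role_to_pfam]
    out: list[str] = []
    while mapped or unmapped:
        if mapped:
            out.append(mapped.pop(0))
        if unmapped:
            out.append(unmapped.pop(0))
    return out


def make_genome(
    seed: int,
    plants: Sequence[PlantSpec],
    n_background_genes: int = 60,
    genome_id: str | None = None,
    config: CoreConfig | None = None,
) -> tuple[list[GeneRecord], list[HmmHit], TruthManifest]:
    """Generate one genome (one scaffold per plant) with planted truth.

    Deterministic given ``seed``.  Background genes carry pfams from a
    vocabulary disjoint from the eCIS map and the blocklists; planted
    core genes carry eCIS pfams and HMM hits whose bitscores (120-200)
    sit strictly above the decoy hit population (10-60) emitted for the
    same profiles, so every planted core survives the top-half filter.
    """
    config = config or CoreConfig.default()
    rng = np.random.default_rng(seed)
    genome_id = genome_id or f"G{seed:06d}"
    role_to_pfam = {r: p for p, r in config.ecis_pfam_to_role.items()}

    genes: list[GeneRecord] = []
    hits: list[HmmHit] = []
    manifest = TruthManifest(genome_id=genome_id)
    plants = list(plants) or [PlantSpec(kind="empty")]
    for spec in plants:
        spec.validate(config)
    per_scaffold_bg = max(4, n_background_genes // len(plants))
    gene_serial = 0

    def new_gene_id() -> str:
        nonlocal gene_serial
        gene_serial += 1
        return f"{genome_id}_g{gene_serial:04d}"

    def add_background(
        scaffold: str, pos: int, count: int, out: list[GeneRecord]
    ) -> int:
        for _ in range(count):
            length = int(rng.integers(300, 3000))
            pfams = (
                frozenset({str(rng.choice(_BACKGROUND_PFAMS))})
                if rng.random() < 0.7
                else frozenset()
            )
            out.append(
                GeneRecord(
                    gene_id=new_gene_id(),
                    genome_id=genome_id,
                    scaffold_id=scaffold,
                    start=pos,
                    end=pos + length - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                    pfams=pfams,
                )
            )
            pos += length + int(rng.integers(200, 2000))
        return pos

    for s_idx, spec in enumerate(plants, start=1):
        scaffold = f"{genome_id}_s{s_idx}"
        scaffold_genes: list[GeneRecord] = []
        pos = int(rng.integers(1, 500))
        pos = add_background(scaffold, pos, per_scaffold_bg // 2, scaffold_genes)

        planted_ids: list[str] = []
        core_ids: list[str] = []
        if spec.kind != "empty":
            n_core = spec.resolved_n_core(config)
            roles = _plant_roles(spec, config, n_core)
            # a non-coding RNA feature just upstream exercises expansion skips
            rna_len = 120
            scaffold_genes.append(
                GeneRecord(
                    gene_id=new_gene_id(), genome_id=genome_id, scaffold_id=scaffold,
                    start=pos, end=pos + rna_len - 1, strand="+",
                    is_protein_coding=False,
                )
            )
            pos += rna_len + int(rng.integers(*spec.gap_range))
            for j, role in enumerate(roles):
                length = int(rng.integers(spec.length_range[0], spec.length_range[1]))
                pfam = role_to_pfam.get(role)
                cogs = frozenset()
                if spec.kind == "t6ss_decoy" and j == n_core // 2:
                    # a group member itself carries the T6SS marker COG
                    cogs = frozenset({sorted(config.t6ss_blocklist_cogs)[0]})
                gid = new_gene_id()
                g = GeneRecord(
                    gene_id=gid,
                    genome_id=genome_id,
                    scaffold_id=scaffold,
                    start=pos,
                    end=pos + length - 1,
                    strand="+",
                    pfams=frozenset({pfam}) if pfam else frozenset(),
                    cogs=cogs,
                )
                scaffold_genes.append(g)
                planted_ids.append(gid)
                core_ids.append(gid)
                hits.append(
                    HmmHit(
                        gene_id=gid,
                        profile_id=role,
                        bitscore=float(np.round(rng.uniform(120, 200), 1)),
                        evalue=float(10 ** -rng.uniform(20, 60)),
                    )
                )
                pos += length + int(rng.integers(*spec.gap_range))
            if spec.kind == "phage_decoy":
                # capsid-like gene at a fixed nearest-boundary offset from
                # the last *seed* gene (the contamination window is
                # anchored on seed-group members)
                seed_ends = [
                    g.end
                    for g in scaffold_genes
                    if g.pfams & config.ecis_pfam_to_role.keys()
                ]
                length = 900
                start = max(seed_ends) + spec.contaminant_offset + 1
                gid = new_gene_id()
                scaffold_genes.append(
                    GeneRecord(
                        gene_id=gid, genome_id=genome_id, scaffold_id=scaffold,
                        start=start, end=start + length - 1, strand="+",
                        pfams=frozenset({sorted(config.phage_blocklist_pfams)[0]}),
                    )
                )
                planted_ids.append(gid)
                last_end = max(g.end for g in scaffold_genes)
                pos = last_end + int(rng.integers(200, 2000))
        pos = add_background(scaffold, pos, per_scaffold_bg - per_scaffold_bg // 2,
                             scaffold_genes)
        genes.extend(scaffold_genes)
        manifest.scaffolds.append(
            ScaffoldTruth(
                scaffold_id=scaffold,
                kind=spec.kind,
                planted_gene_ids=planted_ids,
                core_gene_ids=core_ids,
                expected_loci=1 if spec.kind == "ecis_valid" else 0,
            )
        )

    # decoy hit population: one low-scoring hit per planted-profile hit,
    # against random background genes, so the top-half cut keeps exactly
    # the planted cores
    planted_cores = {g for s in manifest.scaffolds for g in s.core_gene_ids}
    background_ids = [
        g.gene_id
        for g in genes
        if g.is_protein_coding
        and g.gene_id not in planted_cores
        and not (g.pfams & config.ecis_pfam_to_role.keys())
    ]
    if background_ids:
        for h in list(hits):
            hits.append(
                HmmHit(
                    gene_id=str(rng.choice(background_ids)),
                    profile_id=h.profile_id,
                    bitscore=float(np.round(rng.uniform(10, 60), 1)),
                    evalue=float(10 ** -rng.uniform(1, 5)),
                )
            )
    return genes, hits, manifest


# ---------------------------------------------------------------------------
# trees and traits
# ---------------------------------------------------------------------------


def _random_newick(labels: Sequence[str], rng: np.random.Generator,
                   split_root_even: bool = False) -> str:
    def build(lbls: Sequence[str], at_root: bool) -> str:
        if len(lbls) == 1:
            return f"{lbls[0]}:1.0"
        k = len(lbls) // 2 if (at_root and split_root_even) else int(
            rng.integers(1, len(lbls))
        )
        return f"({build(lbls[:k], False)},{build(lbls[k:], False)}):1.0"

    return build(labels, True) + ";"


def make_tree_traits(
    seed: int, n_tips: int, scenario: str
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Random rooted binary tree plus a genotype/phenotype trait table.

    Scenarios: ``independent_assoc`` scatters genotype = phenotype = 1
    tips so that every cherry-level neighbourhood contrasts (max pairs =
    n/2 by construction); ``clade_confounded`` sets both traits to one
    clade's indicator (a single independent event, max pairs = 1);
    ``null`` draws both traits independently (fair coins).
    """
    if n_tips < 4:
        raise GenerationError("n_tips must be >= 4")
    if scenario not in ("independent_assoc", "clade_confounded", "null"):
        raise GenerationError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    labels = [f"G{i:04d}" for i in range(1, n_tips + 1)]
    newick = _random_newick(
        labels, rng, split_root_even=(scenario == "clade_confounded")
    )
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    # trait assignment keyed to construction (= DFS) order of labels
    if scenario == "independent_assoc":
        geno = {lbl: i % 2 for i, lbl in enumerate(labels)}
        pheno = dict(geno)
    elif scenario == "clade_confounded":
        half = n_tips // 2
        geno = {lbl: 1 if i < half else 0 for i, lbl in enumerate(labels)}
        pheno = dict(geno)
    else:
        geno = {lbl: int(rng.integers(0, 2)) for lbl in labels}
        pheno = {lbl: int(rng.integers(0, 2)) for lbl in labels}
    traits = pd.DataFrame({"ecis": pd.Series(geno), "trait": pd.Series(pheno)})
    traits.index.name = "genome"
    return tree, traits


def make_fiber_hits(
    seed: int,
    n_genes: int,
    class_mix: dict[str, float] | None = None,
    delta: float = 15.0,
    evalue_cut: float = 1e-3,
) -> tuple[list[BlastHit], list[BlastHit], dict[str, str]]:
    """Paired BLAST hit lists realizing an intended mixture of fiber calls.

    Returns (phage hits, eukaryotic-virus hits, truth labels).
    """
    class_mix = class_mix or {
        "phage": 0.25, "euk_virus": 0.25, "inconclusive": 0.25, "no_hit": 0.25
    }
    if abs(sum(class_mix.values()) - 1) > 1e-9:
        raise GenerationError("class_mix proportions must sum to 1")
    if set(class_mix) - {"phage", "euk_virus", "inconclusive", "no_hit"}:
        raise GenerationError(f"unknown fiber classes in mix: {sorted(class_mix)}")
    rng = np.random.default_rng(seed)
    counts = {k: int(v * n_genes) for k, v in class_mix.items()}
    ordered = sorted(class_mix)
    i = 0
    while sum(counts.values()) < n_genes:  # distribute rounding remainder
        counts[ordered[i % len(ordered)]] += 1
        i += 1
    labels_pool = [k for k in ordered for _ in range(counts[k])]
    rng.shuffle(labels_pool)

    phage_hits: list[BlastHit] = []
    virus_hits: list[BlastHit] = []
    labels: dict[str, str] = {}
    for i, label in enumerate(labels_pool, start=1):
        gid = f"fiber_{i:04d}"
        labels[gid] = label
        base = float(np.round(rng.uniform(60, 120), 1))
        good_e = lambda: float(10 ** -rng.uniform(10, 40))  # noqa: E731
        bad_e = lambda: float(np.round(rng.uniform(evalue_cut, 1.0), 4))  # noqa: E731
        if label == "phage":
            hi = base + delta + float(np.round(rng.uniform(1, 40), 1))
            phage_hits.append(BlastHit(gid, f"phage_sub_{i}", "phage", hi, good_e()))
            virus_hits.append(BlastHit(gid, f"virus_sub_{i}", "euk_virus", base, good_e()))
        elif label == "euk_virus":
            hi = base + delta + float(np.round(rng.uniform(1, 40), 1))
            phage_hits.append(BlastHit(gid, f"phage_sub_{i}", "phage", base, good_e()))
            virus_hits.append(BlastHit(gid, f"virus_sub_{i}", "euk_virus", hi, good_e()))
        elif label == "inconclusive":
            diff = float(np.round(rng.uniform(-delta, delta), 1))
            phage_hits.append(BlastHit(gid, f"phage_sub_{i}", "phage", base, good_e()))
            virus_hits.append(
                BlastHit(gid, f"virus_sub_{i}", "euk_virus", base + diff, good_e())
            )
        else:  # no_hit: hits exist but fail the E-value cut
            phage_hits.append(BlastHit(gid, f"phage_sub_{i}", "phage", base, bad_e()))
            virus_hits.append(BlastHit(gid, f"virus_sub_{i}", "euk_virus", base, bad_e()))
    return phage_hits, virus_hits, labels


def standard_plant_mixture() -> list[PlantSpec]:
    """The five-decoy-plus-valid mixture used throughout the test surface."""
    return [
        PlantSpec(kind="ecis_valid"),
        PlantSpec(kind="ecis_no_specific_core"),
        PlantSpec(kind="ecis_undersized"),
        PlantSpec(kind="phage_decoy"),
        PlantSpec(kind="t6ss_decoy"),
        PlantSpec(kind="empty"),
    ]


def write_simulation(
    outdir: str | Path,
    seed: int,
    n_genomes: int = 10,
    plants: Sequence[PlantSpec] | None = None,
    n_background_genes: int = 60,
    n_tips: int = 32,
    fiber_genes: int = 40,
    config: CoreConfig | None = None,
) -> dict:
    """Write a complete simulated input set plus manifest JSON to a dir."""
    import json

    from .io import (
        write_blast_tab,
        write_gene_table,
        write_gff,
        write_hmm_hits,
        write_trait_table,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or CoreConfig.default()
    plants = list(plants) if plants is not None else standard_plant_mixture()
    all_manifests = []
    all_genes: list[GeneRecord] = []
    all_hits: list[HmmHit] = []
    for i in range(n_genomes):
        genes, hits, manifest = make_genome(
            seed + i, plants, n_background_genes, config=config
        )
        all_genes.extend(genes)
        all_hits.extend(hits)
        all_manifests.append(manifest.to_dict())
    write_gene_table(all_genes, outdir / "genes.tsv")
    write_gff(all_genes, outdir / "genes.gff3")
    write_hmm_hits(all_hits, outdir / "hmm_hits.tsv")
    tree, traits = make_tree_traits(seed, n_tips, "independent_assoc")
    tree.write(path=str(outdir / "tree.nwk"), schema="newick")
    write_trait_table(traits, outdir / "traits.tsv")
    phage, virus, fiber_labels = make_fiber_hits(seed, fiber_genes)
    write_blast_tab(phage, outdir / "blast_phage.tsv")
    write_blast_tab(virus, outdir / "blast_virus.tsv")
    config.to_yaml(outdir / "config.yaml")
    manifest_doc = {
        "seed": seed,
        "n_genomes": n_genomes,
        "genomes": all_manifests,
        "fiber_labels": fiber_labels,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest_doc, indent=1))
    return manifest_doc
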