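"""Run-level orchestration: batch detection, enrichment and fiber calling.

Each ``run_*`` function reads the declared inputs, executes the library
modules and writes TSV/JSON outputs whose headers carry the tool version,
configuration hash and seed, so two runs with equal configuration are
byte-identical.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .core_roles import percentile_filter
from .enrichment import enrich_all, write_enrichment_table
from .fibers import call_counts, classify_all, select_fiber_set
from .io import (
    read_blast_tab,
    read_gene_table,
    read_hmm_hits,
    read_newick,
    read_trait_table,
)
from .loci import DetectionReport, EcisLocus, detect_loci_report
from .model import CoreConfig, GeneRecord, HmmHit
from .stats import genus_enrichment, trait_association

__all__ = ["RunConfig", "detect_batch", "run_detect", "run_enrich", "run_fibers"]


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline invocation."""

    gene_tables: list[Path] = field(default_factory=list)
    hmm_hits: Path | None = None
    hmm_dialect: str = "simple_tsv"
    blast_phage: Path | None = None
    blast_virus: Path | None = None
    tree: Path | None = None
    traits: Path | None = None
    taxonomy: Path | None = None
    core_config: CoreConfig = field(default_factory=CoreConfig.default)
    outdir: Path = Path(".")
    seed: int = 0

    def validate_paths(self) -> None:
        for p in [
            *self.gene_tables, self.hmm_hits, self.blast_phage, self.blast_virus,
            self.tree, self.traits, self.taxonomy,
        ]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def header(self) -> dict:
        return {
            "tool": "ecisminer",
            "version": __version__,
            "config_hash": self.core_config.config_hash(),
            "seed": self.seed,
        }


def detect_batch(
    genomes: Mapping[str, Sequence[GeneRecord]],
    hits: Sequence[HmmHit],
    config: CoreConfig | None = None,
) -> tuple[dict[str, list[EcisLocus]], dict[str, DetectionReport], dict]:
    """Detect loci across a batch of genomes.

    The HMM bitscore percentile filter runs once over the whole batch
    (one global survey), then each genome is processed independently.
    Returns (loci per genome, per-genome reports, run summary).
    """
    config = config or CoreConfig.default()
    filtered = percentile_filter(
        hits,
        config.thresholds.hmm_keep_fraction,
        per_profile=config.percentile_per_profile,
    )
    loci_by_genome: dict[str, list[EcisLocus]] = {}
    reports: dict[str, DetectionReport] = {}
    for genome_id in sorted(genomes):
        loci, report = detect_loci_report(
            genomes[genome_id], filtered, config, hits_prefiltered=True
        )
        loci_by_genome[genome_id] = loci
        reports[genome_id] = report
    summary = summarize_detection(loci_by_genome)
    return loci_by_genome, reports, summary


def summarize_detection(loci_by_genome: Mapping[str, Sequence[EcisLocus]]) -> dict:
    """Run-level summary: genome counts, locus counts, copy histogram."""
    scanned = len(loci_by_genome)
    with_loci = sum(1 for l in loci_by_genome.values() if l)
    n_loci = sum(len(l) for l in loci_by_genome.values())
    histogram = Counter(len(l) for l in loci_by_genome.values() if l)
    return {
        "genomes_scanned": scanned,
        "genomes_with_loci": with_loci,
        "pct_genomes_with_loci": percentage(with_loci, scanned),
        "n_loci": n_loci,
        "copies_histogram": dict(sorted(histogram.items())),
    }


def percentage(part: int, whole: int) -> float:
    """``100 * part / whole`` (0 when the denominator is 0)."""
    return 100.0 * part / whole if whole else 0.0


def load_genomes(
    gene_tables: Sequence[Path],
) -> dict[str, list[GeneRecord]]:
    genomes: dict[str, list[GeneRecord]] = defaultdict(list)
    for path in gene_tables:
        for g in read_gene_table(path):
            genomes[g.genome_id].append(g)
    return dict(genomes)


def _locus_rows(loci_by_genome: Mapping[str, Sequence[EcisLocus]],
                genomes: Mapping[str, Sequence[GeneRecord]]) -> list[dict]:
    rows = []
    for genome_id in sorted(loci_by_genome):
        gene_map = {g.gene_id: g for g in genomes[genome_id]}
        for locus in loci_by_genome[genome_id]:
            members = [gene_map[g] for g in locus.member_gene_ids]
            specific = sorted(
                locus.roles_present & {"afp12", "afp13", "afp14", "afp16"}
            )
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "genome": locus.genome_id,
                    "scaffold": locus.scaffold_id,
                    "start": min(g.start for g in members),
                    "end": max(g.end for g in members),
                    "n_genes": len(members),
                    "n_core_genes": locus.n_core_genes,
                    "roles_present": ";".join(sorted(locus.roles_present)),
                    "specific_cores": ";".join(specific),
                }
            )
    return rows


def run_detect(run: RunConfig) -> dict:
    """Detect loci for every input genome; write tables and a summary."""
    run.validate_paths()
    if not run.gene_tables:
        raise ValueError("no input gene tables")
    genomes = load_genomes(run.gene_tables)
    hits = (
        read_hmm_hits(run.hmm_hits, run.hmm_dialect) if run.hmm_hits else []
    )
    loci_by_genome, reports, summary = detect_batch(genomes, hits, run.core_config)
    outdir = Path(run.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        _locus_rows(loci_by_genome, genomes),
        columns=["locus_id", "genome", "scaffold", "start", "end", "n_genes",
                 "n_core_genes", "roles_present", "specific_cores"],
    ).to_csv(outdir / "loci.tsv", sep="\t", index=False)
    loci_json = {
        "header": run.header(),
        "loci": [
            {
                "locus_id": l.locus_id,
                "genome": l.genome_id,
                "scaffold": l.scaffold_id,
                "member_gene_ids": l.member_gene_ids,
                "core_roles": {g: sorted(r) for g, r in l.core_roles.items()},
                "n_core_genes": l.n_core_genes,
                "boundary": list(l.boundary),
                "provenance": l.provenance,
            }
            for loci in loci_by_genome.values()
            for l in loci
        ],
    }
    (outdir / "loci.json").write_text(json.dumps(loci_json, indent=1, sort_keys=True))
    doc = {
        "header": run.header(),
        "summary": summary,
        "filter_tallies": {
            gid: {
                k: v
                for k, v in vars(rep).items()
                if k not in ("rejections", "genome_id")
            }
            for gid, rep in reports.items()
        },
    }
    (outdir / "detect_summary.json").write_text(
        json.dumps(doc, indent=1, sort_keys=True)
    )
    return doc


def run_enrich(run: RunConfig) -> dict:
    """Genus, trait and pfam enrichment over a detected batch."""
    run.validate_paths()
    genomes = load_genomes(run.gene_tables)
    hits = read_hmm_hits(run.hmm_hits, run.hmm_dialect) if run.hmm_hits else []
    loci_by_genome, _, summary = detect_batch(genomes, hits, run.core_config)
    outdir = Path(run.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    taxonomy = (
        pd.read_csv(run.taxonomy, sep="\t", index_col=0, dtype=str)
        if run.taxonomy
        else pd.DataFrame(columns=["genus", "phylum"])
    )
    presence = {gid: int(bool(loci)) for gid, loci in loci_by_genome.items()}

    genus_df = genus_enrichment(
        presence,
        taxonomy["genus"].to_dict() if "genus" in taxonomy.columns else {},
    )
    genus_df.to_csv(outdir / "genus_enrichment.tsv", sep="\t", index=False)

    all_loci = [l for loci in loci_by_genome.values() for l in loci]
    universe = [g for genes in genomes.values() for g in genes]
    phylum_of = (
        taxonomy["phylum"].to_dict() if "phylum" in taxonomy.columns else None
    )
    rows = enrich_all(all_loci, universe, phylum_of)
    write_enrichment_table(rows, outdir / "pfam_enrichment.tsv")

    trait_doc = {}
    if run.tree and run.traits:
        tree = read_newick(run.tree)
        traits = read_trait_table(run.traits)
        traits["ecis"] = pd.Series(presence).reindex(traits.index)
        trait_df = trait_association(tree, traits, "ecis")
        trait_df.to_csv(outdir / "trait_association.tsv", sep="\t", index=False)
        trait_doc = {"n_traits": int(len(trait_df))}
    doc = {
        "header": run.header(),
        "summary": summary,
        "n_genera_tested": int(len(genus_df)),
        "n_pfams_tested": len(rows),
        **trait_doc,
    }
    (outdir / "enrich_summary.json").write_text(
        json.dumps(doc, indent=1, sort_keys=True)
    )
    return doc


def run_fibers(run: RunConfig) -> dict:
    """Select the fiber gene set from afp13 hits and classify via BLAST."""
    run.validate_paths()
    import warnings

    t = run.core_config.thresholds
    hits = read_hmm_hits(run.hmm_hits, run.hmm_dialect) if run.hmm_hits else []
    afp13 = [h for h in hits if h.profile_id == "afp13"]
    fiber_genes = select_fiber_set(afp13, t.fiber_select_fraction) if afp13 else None
    phage = read_blast_tab(run.blast_phage, "phage") if run.blast_phage else []
    virus = read_blast_tab(run.blast_virus, "euk_virus") if run.blast_virus else []
    if not run.blast_phage or not run.blast_virus:
        warnings.warn(
            "only one BLAST database supplied; calls limited to that database"
        )
    calls = classify_all(
        phage, virus,
        gene_ids=fiber_genes,
        evalue_cut=t.fiber_evalue_cut,
        delta=t.fiber_bitscore_delta,
    )
    outdir = Path(run.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "best_phage_bitscore": c.best_phage_bitscore,
                "best_virus_bitscore": c.best_virus_bitscore,
                "call": c.call,
            }
            for c in calls
        ],
        columns=["gene_id", "best_phage_bitscore", "best_virus_bitscore", "call"],
    ).to_csv(outdir / "fiber_calls.tsv", sep="\t", index=False)
    doc = {"header": run.header(), "counts": call_counts(calls), "n_genes": len(calls)}
    (outdir / "fiber_summary.json").write_text(
        json.dumps(doc, indent=1, sort_keys=True)
    )
    return doc
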