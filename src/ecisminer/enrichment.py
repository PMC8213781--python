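"""Pfam-domain enrichment inside eCIS loci vs the genomic background.

Counting is at gene granularity: a gene either carries a pfam or it does
not, and repeated copies of a domain within one gene (typically repeat
domains) count once -- this keeps repeat expansions from inflating the
enrichment.  Each pfam seen inside at least one locus gets a 2x2 table
(in-locus with / in-locus without / background with / background without),
a sample odds ratio, a two-sided Fisher p and a BH q (q values that
underflow to exactly 0 are clamped to 1e-250 so they survive a -log10
axis).  Domains are classed by phylum spread of their in-locus
occurrences, in pan-genome vocabulary: core (>10 phyla), shell (4-10),
cloud (<4).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .loci import EcisLocus
from .model import GeneRecord, ParameterError
from .stats import bh_adjust, fisher_exact_2x2

__all__ = ["PfamEnrichmentRow", "per_gene_domain_set", "pan_class", "enrich_all"]

#: q values reported as exactly zero in floating point are clamped here.
Q_FLOOR = 1e-250


@dataclass
class PfamEnrichmentRow:
    pfam: str
    a: int  # in-locus genes carrying the pfam
    b: int  # in-locus genes without it
    c: int  # background genes carrying it
    d: int  # background genes without it
    odds_ratio: float
    p: float
    q: float
    n_phyla: int
    pan_class: str


def per_gene_domain_set(gene: GeneRecord) -> frozenset[str]:
    """The deduplicated pfam set of one gene (each domain counts once)."""
    return frozenset(gene.pfams)


def pan_class(n_phyla: int) -> str:
    """Core (>10 phyla) / shell (4-10) / cloud (<4) classification."""
    if n_phyla < 0:
        raise ParameterError(f"n_phyla must be >= 0, got {n_phyla}")
    if n_phyla > 10:
        return "core"
    if n_phyla >= 4:
        return "shell"
    return "cloud"


def enrich_all(
    loci: Sequence[EcisLocus],
    background_genes: Iterable[GeneRecord],
    phylum_of: Mapping[str, str] | Callable[[str], str] | None = None,
) -> list[PfamEnrichmentRow]:
    """Per-pfam enrichment of in-locus genes against the supplied universe.

    ``background_genes`` is the whole gene universe of the run and must
    include the in-locus genes.  ``phylum_of`` maps genome_id -> phylum;
    genomes without a mapping count as the single pseudo-phylum
    "unclassified" (flagged with a warning).
    """
    if not loci:
        warnings.warn("no loci supplied; enrichment table is empty")
        return []
    if phylum_of is None:
        lookup = lambda genome: "unclassified"  # noqa: E731
    elif callable(phylum_of):
        lookup = phylum_of
    else:
        mapping = dict(phylum_of)
        unknown_genomes = {l.genome_id for l in loci} - mapping.keys()
        if unknown_genomes:
            warnings.warn(
                f"{len(unknown_genomes)} genome(s) without phylum mapping counted "
                "as 'unclassified'"
            )
        lookup = lambda genome: mapping.get(genome, "unclassified")  # noqa: E731

    in_locus_ids: set[str] = set()
    genome_of_locus_gene: dict[str, str] = {}
    for locus in loci:
        for gid in locus.member_gene_ids:
            in_locus_ids.add(gid)
            genome_of_locus_gene[gid] = locus.genome_id

    universe = {g.gene_id: g for g in background_genes if g.is_protein_coding}
    missing = in_locus_ids - universe.keys()
    if missing:
        raise ValueError(
            f"{len(missing)} in-locus gene(s) absent from the background universe"
        )
    n_in = len(in_locus_ids)
    n_out = len(universe) - n_in

    # per-pfam counts and phylum spread, computed per gene via the
    # deduplicated domain set
    a_counts: dict[str, int] = {}
    phyla: dict[str, set[str]] = {}
    for gid in in_locus_ids:
        for pfam in per_gene_domain_set(universe[gid]):
            a_counts[pfam] = a_counts.get(pfam, 0) + 1
            phyla.setdefault(pfam, set()).add(lookup(genome_of_locus_gene[gid]))
    bg_counts: dict[str, int] = {}
    for gid, gene in universe.items():
        if gid in in_locus_ids:
            continue
        for pfam in per_gene_domain_set(gene):
            if pfam in a_counts:
                bg_counts[pfam] = bg_counts.get(pfam, 0) + 1

    rows: list[PfamEnrichmentRow] = []
    pvals = []
    for pfam in sorted(a_counts):
        a = a_counts[pfam]
        c = bg_counts.get(pfam, 0)
        b, d = n_in - a, n_out - c
        oratio, p = fisher_exact_2x2(a, b, c, d)
        n_phyla = len(phyla[pfam])
        rows.append(
            PfamEnrichmentRow(
                pfam=pfam, a=a, b=b, c=c, d=d, odds_ratio=oratio, p=p,
                q=math.nan, n_phyla=n_phyla, pan_class=pan_class(n_phyla),
            )
        )
        pvals.append(p)
    for row, q in zip(rows, bh_adjust(pvals)):
        row.q = max(float(q), Q_FLOOR) if q == 0.0 else float(q)
    return rows


def write_enrichment_table(rows: Sequence[PfamEnrichmentRow], path: str | Path) -> None:
    """TSV mirroring a volcano plot's axes: log2 OR and -log10 q."""

    def log2_or(x: float) -> str:
        if math.isnan(x):
            return "NA"
        if x == 0:
            return "-inf"
        if math.isinf(x):
            return "inf"
        return f"{math.log2(x):.6g}"

    recs = [
        {
            "pfam": r.pfam, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
            "odds_ratio": r.odds_ratio, "log2_odds_ratio": log2_or(r.odds_ratio),
            "p": r.p, "q": r.q, "neg_log10_q": f"{-math.log10(r.q):.6g}",
            "n_phyla": r.n_phyla, "pan_class": r.pan_class,
        }
        for r in rows
    ]
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)
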