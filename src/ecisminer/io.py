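"""Readers and writers for every external format the pipeline touches.

Dialects
--------
* gene table: tab-separated, one row per gene, columns
  ``gene_id  genome  scaffold  start  end  strand  feature_type  pfams  cogs``
  with ``pfams``/``cogs`` semicolon-joined accession lists (the shape of an
  IMG-style annotation export).  ``genome`` and ``feature_type`` are
  optional on input.
* GFF3 + protein FASTA: CDS (and RNA) features with ``ID`` attributes;
  pfam/COG annotations carried as ``Dbxref=Pfam:PFxxxxx,COG:COGxxxx``.
* HMM hits: hmmsearch ``--domtblout`` or a simplified 4-column TSV
  (``gene_id  profile  bitscore  evalue``).
* BLAST: tabular outfmt 6 (12 standard columns).
* trees: newick (rooted, polytomies preserved).
* trait tables: TSV, genomes as rows, binary trait columns.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import gffutils
import pandas as pd
from Bio import SeqIO

from .model import (
    BlastHit,
    FormatError,
    GeneRecord,
    HmmHit,
    RecordError,
    normalize_profile_name,
    sort_genes,
)

__all__ = [
    "read_gene_table",
    "write_gene_table",
    "read_gff_fasta",
    "write_gff",
    "read_hmm_hits",
    "write_hmm_hits",
    "read_blast_tab",
    "write_blast_tab",
    "read_newick",
    "read_trait_table",
    "write_trait_table",
]

_GENE_COLUMNS = ["gene_id", "scaffold", "start", "end", "strand", "pfams", "cogs"]

#: GFF3 feature types treated as non-coding (parsed, but excluded from all
#: gene counting downstream).
_NONCODING_TYPES = {"rRNA", "tRNA", "ncRNA", "tmRNA", "misc_RNA"}


def _split_accessions(cell: str) -> frozenset[str]:
    return frozenset(p for p in (s.strip() for s in cell.split(";")) if p)


def read_gene_table(path: str | Path, genome_id: str | None = None) -> list[GeneRecord]:
    """Read an IMG-style gene annotation TSV into GeneRecords.

    Rows are returned sorted by (scaffold, start).  Non-protein-coding rows
    (``feature_type`` other than CDS) are flagged, not dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    default_genome = genome_id or (
        df["genome"].iloc[0] if "genome" in df.columns and len(df) else path.stem
    )
    records: list[GeneRecord] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        row = row._asdict()
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError as exc:
            raise RecordError(f"{path} line {i}: non-numeric coordinate ({exc})")
        if end < start:
            raise RecordError(f"{path} line {i}: end {end} < start {start}")
        gid = row["gene_id"]
        if gid in seen:
            raise FormatError(
                f"{path}: duplicated gene_id {gid!r} (lines {seen[gid]} and {i})"
            )
        seen[gid] = i
        records.append(
            GeneRecord(
                gene_id=gid,
                genome_id=row.get("genome") or default_genome,
                scaffold_id=row["scaffold"],
                start=start,
                end=end,
                strand=row["strand"],
                is_protein_coding=row.get("feature_type", "CDS") in ("", "CDS"),
                pfams=_split_accessions(row["pfams"]),
                cogs=_split_accessions(row["cogs"]),
            )
        )
    return sort_genes(records)


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write GeneRecords in the gene-table dialect (lossless round-trip)."""
    rows = [
        {
            "gene_id": g.gene_id,
            "genome": g.genome_id,
            "scaffold": g.scaffold_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "feature_type": "CDS" if g.is_protein_coding else "ncRNA",
            "pfams": ";".join(sorted(g.pfams)),
            "cogs": ";".join(sorted(g.cogs)),
        }
        for g in sort_genes(genes)
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "genome", "scaffold", "start", "end", "strand",
                 "feature_type", "pfams", "cogs"],
    ).to_csv(path, sep="\t", index=False)


def _dbxref_accessions(feature) -> tuple[frozenset[str], frozenset[str]]:
    pfams, cogs = set(), set()
    for xref in feature.attributes.get("Dbxref", []):
        for part in xref.split(","):
            part = part.strip()
            if part.startswith("Pfam:"):
                pfams.add(part[5:])
            elif part.startswith("COG:"):
                cogs.add(part[4:])
    return frozenset(pfams), frozenset(cogs)


def read_gff_fasta(
    gff: str | Path, faa: str | Path | None = None, genome_id: str | None = None
) -> list[GeneRecord]:
    """Read GFF3 CDS/RNA features (+ optional protein FASTA) into GeneRecords.

    Multi-line CDS features sharing one ``ID`` collapse to a single record
    spanning min(start)..max(end).  FASTA sequences whose ID matches no GFF
    feature are dropped with a warning.
    """
    gff = Path(gff)
    genome_id = genome_id or gff.stem
    grouped: dict[str, dict] = {}
    order: list[str] = []
    for feat in gffutils.iterators.DataIterator(str(gff)):
        if feat.featuretype != "CDS" and feat.featuretype not in _NONCODING_TYPES:
            continue
        fid = (feat.attributes.get("ID") or feat.attributes.get("Parent") or [None])[0]
        if fid is None:
            warnings.warn(f"{gff}: {feat.featuretype} feature without ID skipped")
            continue
        pfams, cogs = _dbxref_accessions(feat)
        if fid not in grouped:
            order.append(fid)
            grouped[fid] = {
                "scaffold": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand if feat.strand in "+-" else "+",
                "coding": feat.featuretype == "CDS",
                "pfams": set(pfams),
                "cogs": set(cogs),
            }
        else:
            rec = grouped[fid]
            rec["start"] = min(rec["start"], feat.start)
            rec["end"] = max(rec["end"], feat.end)
            rec["pfams"] |= pfams
            rec["cogs"] |= cogs
    proteins: dict[str, str] = {}
    if faa is not None:
        for seq in SeqIO.parse(str(faa), "fasta"):
            if seq.id not in grouped:
                warnings.warn(f"{faa}: FASTA id {seq.id!r} absent from GFF3, dropped")
                continue
            proteins[seq.id] = str(seq.seq)
    records = [
        GeneRecord(
            gene_id=fid,
            genome_id=genome_id,
            scaffold_id=rec["scaffold"],
            start=rec["start"],
            end=rec["end"],
            strand=rec["strand"],
            is_protein_coding=rec["coding"],
            pfams=frozenset(rec["pfams"]),
            cogs=frozenset(rec["cogs"]),
            protein=proteins.get(fid),
        )
        for fid, rec in grouped.items()
    ]
    return sort_genes(records)


def write_gff(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Export GeneRecords as GFF3 (Dbxref carries pfam/COG accessions)."""
    lines = ["##gff-version 3"]
    for g in sort_genes(genes):
        xrefs = [f"Pfam:{p}" for p in sorted(g.pfams)] + [
            f"COG:{c}" for c in sorted(g.cogs)
        ]
        attrs = f"ID={g.gene_id}"
        if xrefs:
            attrs += f";Dbxref={','.join(xrefs)}"
        ftype = "CDS" if g.is_protein_coding else "ncRNA"
        lines.append(
            "\t".join(
                [g.scaffold_id, "ecisminer", ftype, str(g.start), str(g.end),
                 ".", g.strand, "0" if g.is_protein_coding else ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_hmm_hits(
    path: str | Path,
    dialect: str = "domtblout",
    aliases: Mapping[str, str] | None = None,
) -> list[HmmHit]:
    """Read hmmsearch hits (``domtblout`` or ``simple_tsv`` dialect).

    Profile names are normalized to lowercase ``afpN`` where recognizable.
    Duplicate (gene, profile) lines are retained as separate hits; the
    percentile filter downstream sees every domain hit.
    """
    path = Path(path)
    if dialect not in ("domtblout", "simple_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hits: list[HmmHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split()
            try:
                if dialect == "domtblout":
                    # target(0) tacc tlen query(3) qacc qlen full_E(6) full_score(7)
                    gene, profile = f[0], f[3]
                    evalue, score = float(f[6]), float(f[7])
                else:
                    if f[0] == "gene_id":
                        continue
                    gene, profile = f[0], f[1]
                    score, evalue = float(f[2]), float(f[3])
            except (IndexError, ValueError) as exc:
                raise RecordError(f"{path} line {lineno}: unparseable hit ({exc})")
            hits.append(
                HmmHit(
                    gene_id=gene,
                    profile_id=normalize_profile_name(profile, aliases),
                    bitscore=score,
                    evalue=evalue,
                )
            )
    return hits


def write_hmm_hits(hits: Iterable[HmmHit], path: str | Path) -> None:
    """Write hits in the simple 4-column TSV dialect."""
    lines = ["gene_id\tprofile\tbitscore\tevalue"]
    lines += [
        f"{h.gene_id}\t{h.profile_id}\t{h.bitscore:g}\t{h.evalue:g}" for h in hits
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_blast_tab(path: str | Path, db_label: str) -> list[BlastHit]:
    """Read BLAST outfmt-6 hits, tagging each with ``db_label``."""
    if db_label not in ("phage", "euk_virus"):
        raise ValueError(f"db_label must be 'phage' or 'euk_virus', got {db_label!r}")
    path = Path(path)
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(
                    f"{path} line {lineno}: expected >=12 outfmt-6 columns, got {len(f)}"
                )
            try:
                evalue, bitscore = float(f[10]), float(f[11])
            except ValueError as exc:
                raise RecordError(f"{path} line {lineno}: unparseable hit ({exc})")
            hits.append(
                BlastHit(
                    query_id=f[0],
                    subject_id=f[1],
                    subject_db=db_label,
                    bitscore=bitscore,
                    evalue=evalue,
                )
            )
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path: str | Path) -> None:
    """Write hits as minimal outfmt-6 rows (unused columns zero-filled)."""
    lines = [
        "\t".join(
            [h.query_id, h.subject_id, "0", "0", "0", "0", "0", "0", "0", "0",
             f"{h.evalue:g}", f"{h.bitscore:g}"]
        )
        for h in hits
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted newick tree; polytomies are preserved."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises its own hierarchy
        raise FormatError(f"{path}: newick parse error ({exc})") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    dups = {l for l in labels if labels.count(l) > 1}
    if dups:
        raise FormatError(f"{path}: duplicate tip label(s) {sorted(dups)}")
    return tree


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a binary trait table (rows = genomes, columns = traits).

    Values must be 0, 1 or missing.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = set(df.stack().dropna().unique()) - {0, 1}
    if bad:
        raise FormatError(f"{path}: non-binary trait values {sorted(bad)}")
    return df


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="genome")
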