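"""Domain types shared across the eCIS mining pipeline.

Coordinate convention: all gene coordinates are 1-based and inclusive on
both ends (the convention of IMG annotation exports and GFF3).  Half-open
arithmetic never leaks into any record or file.

Distance convention: the distance between two genes on a scaffold is the
number of bases strictly between their nearest boundaries,
``max(0, start_downstream - end_upstream - 1)``, regardless of strand.
Overlapping or abutting genes are at distance 0.  Every physical-linkage
threshold in the pipeline (operon chaining, contamination windows) uses
this one definition, compared inclusively.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "FormatError",
    "RecordError",
    "ParameterError",
    "GenerationError",
    "GeneRecord",
    "HmmHit",
    "BlastHit",
    "Thresholds",
    "CoreConfig",
    "intergenic_gap",
    "normalize_profile_name",
    "AFP_ROLES",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class RecordError(ValueError):
    """A single record within an otherwise well-formed file is invalid."""


class ParameterError(ValueError):
    """A numeric parameter is outside its legal range."""


class GenerationError(ValueError):
    """A synthetic-data plant specification is internally contradictory."""


#: The sixteen eCIS core gene families, named after the Serratia
#: Antifeeding Prophage (Afp) genes.
AFP_ROLES: frozenset[str] = frozenset(f"afp{i}" for i in range(1, 17))

_AFP_RE = re.compile(r"^afp[_\-]?0*(\d{1,2})$", re.IGNORECASE)


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene from one genome.

    ``pfams`` and ``cogs`` are deduplicated accession sets
    (e.g. ``PF14065``, ``COG3523``).  ``protein`` optionally carries the
    translated sequence for downstream HMM/BLAST export; it takes no part
    in any pipeline decision.
    """

    gene_id: str
    genome_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    is_protein_coding: bool = True
    pfams: frozenset[str] = frozenset()
    cogs: frozenset[str] = frozenset()
    protein: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise RecordError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise RecordError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise RecordError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        object.__setattr__(self, "pfams", frozenset(self.pfams))
        object.__setattr__(self, "cogs", frozenset(self.cogs))

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def intergenic_gap(a: GeneRecord, b: GeneRecord) -> int:
    """Nearest-boundary distance in bp between two genes on one scaffold."""
    if a.scaffold_id != b.scaffold_id:
        raise ValueError("genes are on different scaffolds")
    return max(0, max(a.start, b.start) - min(a.end, b.end) - 1)


@dataclass(frozen=True)
class HmmHit:
    """One profile-vs-protein hit from hmmsearch (full-sequence score)."""

    gene_id: str
    profile_id: str
    bitscore: float
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if not (self.bitscore == self.bitscore and abs(self.bitscore) != float("inf")):
            raise RecordError(f"hit {self.gene_id}/{self.profile_id}: non-finite bitscore")
        if self.evalue < 0:
            raise RecordError(f"hit {self.gene_id}/{self.profile_id}: negative E-value")


@dataclass(frozen=True)
class BlastHit:
    """One BLASTP hit of a tail-fiber query against a tagged database."""

    query_id: str
    subject_id: str
    subject_db: str  # "phage" or "euk_virus"
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.subject_db not in ("phage", "euk_virus"):
            raise RecordError(f"bad subject_db {self.subject_db!r}")
        if self.evalue < 0:
            raise RecordError(f"hit {self.query_id}: negative E-value")


def normalize_profile_name(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Normalize an HMM profile name to lowercase ``afpN`` where recognizable.

    Unrecognized names are returned stripped but otherwise untouched, so
    hits against non-core profiles survive for inspection.
    """
    name = name.strip()
    if aliases and name in aliases:
        return aliases[name]
    m = _AFP_RE.match(name)
    if m and 1 <= int(m.group(1)) <= 16:
        return f"afp{int(m.group(1))}"
    return name


@dataclass(frozen=True)
class Thresholds:
    """Every numeric knob of the detection and classification rules.

    Units are base pairs for distances, gene counts for *_genes, and
    fractions in (0, 1] for percentile cuts.  Defaults are the published
    operating point of the genome survey this pipeline reimplements.
    """

    linkage_gap_bp: int = 12_000
    contamination_window_bp: int = 10_000
    expansion_genes: int = 10
    min_seed_genes: int = 4
    min_distinct_seed_pfams: int = 3
    min_core_genes: int = 10
    boundary_flank_genes: int = 4
    hmm_keep_fraction: float = 0.5
    fiber_select_fraction: float = 0.25
    fiber_evalue_cut: float = 1e-3
    fiber_bitscore_delta: float = 15.0
    plasmid_score_cut: float = 0.7

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v <= 0:
                raise ParameterError(f"threshold {f.name} must be > 0, got {v}")
        for name in ("hmm_keep_fraction", "fiber_select_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ParameterError(f"{name} must lie in (0, 1], got {v}")


# Default pfam -> core-role map.  Covers the classical structural domains of
# the particle: tube, sheath, baseplate, spike, cap/tail terminator and the
# AAA ATPase.  The map is deliberately small and user-extensible -- most
# core-role evidence in a real run comes from the Afp1-16 HMM profiles, and
# organisms differ in which domains their annotation pipeline assigns.
_DEFAULT_PFAM_TO_ROLE: dict[str, str] = {
    "PF06841": "afp1",   # Phage_T4_gp19, tail tube
    "PF04984": "afp2",   # Phage_sheath_1
    "PF04865": "afp7",   # Baseplate_J
    "PF05954": "afp8",   # Phage_GPD, baseplate hub
    "PF04965": "afp9",   # GPW_gp25, baseplate wedge
    "PF05488": "afp10",  # PAAR_motif, spike tip
    "PF00004": "afp15",  # AAA ATPase
    "PF14065": "afp16",  # DUF4255, cap / tail terminator
}

# Phage-specific domains whose presence near a candidate operon marks it as
# a prophage cassette rather than an eCIS (capsid/portal/terminase genes
# have no business inside a headless particle).
_DEFAULT_PHAGE_BLOCKLIST: frozenset[str] = frozenset(
    {
        "PF03864",  # Phage_cap_E, major capsid protein E
        "PF05065",  # Phage_capsid
        "PF04860",  # Phage_portal
        "PF03237",  # Terminase_6
    }
)

# Membrane-complex COGs diagnostic of the (membrane-anchored) T6SS, which
# shares most structural families with eCIS but is a different machine.
_DEFAULT_T6SS_BLOCKLIST: frozenset[str] = frozenset(
    {
        "COG3523",  # TssM, membrane core complex
        "COG3522",  # TssA
        "COG3516",  # TssB sheath
        "COG3517",  # TssC sheath
        "COG3519",  # TssJ lipoprotein
    }
)


@dataclass
class CoreConfig:
    """Run-level configuration: role maps, blocklists and thresholds.

    ``count_core_roles_distinct`` switches the "at least ten core genes"
    rule from gene multiplicity (default: two afp1 paralogs count twice)
    to distinct roles.  ``percentile_per_profile`` switches the HMM
    bitscore percentile filter between per-profile ranking (default) and
    one global ranking across profiles.
    """

    ecis_pfam_to_role: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_PFAM_TO_ROLE)
    )
    ecis_specific_cores: frozenset[str] = frozenset(
        {"afp12", "afp13", "afp14", "afp16"}
    )
    phage_blocklist_pfams: frozenset[str] = _DEFAULT_PHAGE_BLOCKLIST
    t6ss_blocklist_cogs: frozenset[str] = _DEFAULT_T6SS_BLOCKLIST
    thresholds: Thresholds = field(default_factory=Thresholds)
    profile_aliases: dict[str, str] = field(default_factory=dict)
    count_core_roles_distinct: bool = False
    percentile_per_profile: bool = True

    def __post_init__(self) -> None:
        self.ecis_specific_cores = frozenset(self.ecis_specific_cores)
        self.phage_blocklist_pfams = frozenset(self.phage_blocklist_pfams)
        self.t6ss_blocklist_cogs = frozenset(self.t6ss_blocklist_cogs)
        bad_roles = set(self.ecis_pfam_to_role.values()) - AFP_ROLES
        if bad_roles:
            raise ParameterError(f"unknown core roles in pfam map: {sorted(bad_roles)}")
        if not self.ecis_specific_cores <= AFP_ROLES:
            raise ParameterError("ecis_specific_cores must be a subset of afp1..afp16")

    @classmethod
    def default(cls) -> "CoreConfig":
        """The shipped default profile (published survey operating point)."""
        return cls()

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "ecis_pfam_to_role": dict(sorted(self.ecis_pfam_to_role.items())),
            "ecis_specific_cores": sorted(self.ecis_specific_cores),
            "phage_blocklist_pfams": sorted(self.phage_blocklist_pfams),
            "t6ss_blocklist_cogs": sorted(self.t6ss_blocklist_cogs),
            "thresholds": {
                f.name: getattr(self.thresholds, f.name) for f in fields(Thresholds)
            },
            "profile_aliases": dict(sorted(self.profile_aliases.items())),
            "count_core_roles_distinct": self.count_core_roles_distinct,
            "percentile_per_profile": self.percentile_per_profile,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoreConfig":
        d = dict(d)
        if "thresholds" in d:
            d["thresholds"] = Thresholds(**d["thresholds"])
        known = {f.name for f in fields(cls)}
        extra = set(d) - known
        if extra:
            raise FormatError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CoreConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for output provenance."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def with_thresholds(self, **kwargs) -> "CoreConfig":
        """Copy with some thresholds replaced."""
        return replace(self, thresholds=replace(self.thresholds, **kwargs))


def sort_genes(genes: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Canonical gene ordering: (scaffold, start, end, gene_id)."""
    return sorted(genes, key=lambda g: (g.scaffold_id, g.start, g.end, g.gene_id))
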