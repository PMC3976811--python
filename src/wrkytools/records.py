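"""Core record types shared across the pipeline.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open.  GFF3 input (1-based,
end-inclusive) and the printed chromosome locations of the packaged gene
table (1-based bp, kept as printed) are converted at the I/O boundary.

A :class:`GeneRecord`'s ``exons`` live on the gene's *own* coordinate frame:
position 0 is the first transcribed base of the gene on its coding strand,
and exon intervals include the intervening introns in their genomic extent.
The ``cds`` string is the spliced coding sequence read 5'->3' on the mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

UNPLACED = "UNPLACED"

GROUPS = ("I", "II", "III", "UNCLASSIFIED")
SUBGROUPS = ("IIa", "IIb", "IIc", "IId", "IIe", "IIx")


@dataclass
class GeneRecord:
    """One gene: identity, placement, sequences and (optional) annotation."""

    gene_id: str
    chromosome: str = UNPLACED          # "1".."6" or UNPLACED
    start: Optional[int] = None         # 1-based bp on the chromosome
    protein: str = ""
    cds: str = ""
    exons: list[tuple[int, int]] = field(default_factory=list)
    strand: str = "+"
    group_label: Optional[str] = None
    subgroup_label: Optional[str] = None
    pseudogene: bool = False

    def __post_init__(self) -> None:
        self.validate_exons()

    def validate_exons(self) -> None:
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty/inverted exon ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def placed(self) -> bool:
        return self.chromosome != UNPLACED


@dataclass
class WRKYDomain:
    """A detected WRKY domain on a protein.

    ``hepta_start`` indexes the first residue of the heptapeptide
    (WRKYGQK or a tolerated variant); ``zf_coords`` holds the protein
    indices of the zinc-chelating residues (C, C, H, H) for a C2H2
    finger or (C, C, H, C) for a C2HC finger.
    """

    hepta_start: int
    heptapeptide: str
    zf_class: str = "ABSENT"            # C2H2 | C2HC | ABSENT
    zf_coords: tuple[int, ...] = ()
    terminal: str = "SINGLE"            # N | C | SINGLE
    complete: bool = False

    @property
    def hepta_end(self) -> int:
        """Protein index one past the heptapeptide."""
        return self.hepta_start + len(self.heptapeptide)

    @property
    def end(self) -> int:
        """One past the last residue of the domain (zinc finger end if found)."""
        if self.zf_coords:
            return self.zf_coords[-1] + 1
        return self.hepta_end

    @property
    def span(self) -> int:
        return self.end - self.hepta_start


@dataclass
class Classification:
    group: str                          # I | II | III | UNCLASSIFIED
    subgroup: Optional[str] = None      # IIa..IIe, IIx, "unplaced" or None
    domains: list[WRKYDomain] = field(default_factory=list)
    nearest_reference: Optional[str] = None
    reference_distance: Optional[float] = None


@dataclass
class PseudogeneFlags:
    premature_stop: bool
    frameshift: bool

    @property
    def any(self) -> bool:
        return self.premature_stop or self.frameshift


@dataclass
class GeneLocus:
    gene_id: str
    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if self.chromosome != UNPLACED and self.position < 1:
            raise ValueError(f"{self.gene_id}: placed locus needs position >= 1")


@dataclass
class ClusterCall:
    chromosome: str
    member_ids: list[str]               # ordered by position
    span_bp: int


@dataclass
class DuplicatePair:
    id_a: str
    id_b: str
    nt_coverage: float
    aa_identity: float
    mode: str                           # TANDEM | SEGMENTAL
    unplaced_member: bool = False

    def __post_init__(self) -> None:
        if self.id_b < self.id_a:
            self.id_a, self.id_b = self.id_b, self.id_a
        for v in (self.nt_coverage, self.aa_identity):
            if not 0.0 <= v <= 1.0:
                raise ValueError("coverage/identity must lie in [0,1]")


@dataclass
class IntronAnnotation:
    index: int
    length_bp: int
    phase: int                          # 0 | 1 | 2
    type: str = "OTHER"                 # R | V | OTHER
    anchor: Optional[int] = None        # protein position of the adjoining codon


@dataclass
class MotifHit:
    motif_id: str
    start: int
    matched: str
    mismatches: int


def as_loci(records: Sequence[GeneRecord]) -> list[GeneLocus]:
    """Project gene records onto bare loci (used by clustering/mapping)."""
    return [
        GeneLocus(r.gene_id, r.chromosome, r.start if r.placed and r.start else 0)
        for r in records
    ]
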