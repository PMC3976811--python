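"""Intron phases and conserved R-/V-type intron classification.

An intron's phase is the cumulative coding length upstream of it modulo 3
(phase 0 = between codons; phase 1/2 = after the first/second base of a
codon).  Two conserved intron types recur inside WRKY domains:

* R-type: a phase-2 intron that splits an R codon lying between the
  heptapeptide and the first zinc-finger cysteine;
* V-type: a phase-0 intron immediately before the codon six residues after
  the second cysteine of a C2H2 finger (canonically a V).
"""

from __future__ import annotations

from statistics import mean, median
from typing import Optional, Sequence

from .records import GeneRecord, IntronAnnotation, WRKYDomain


def compute_intron_phases(record: GeneRecord) -> list[IntronAnnotation]:
    """Introns between consecutive coding exons, with phase and length.

    Exon intervals live on the gene's own (genomic) coordinate frame, so
    intron length is the gap between consecutive exons.
    """
    if not record.exons:
        raise ValueError(f"{record.gene_id}: no coding exons")
    record.validate_exons()
    introns: list[IntronAnnotation] = []
    coding_upstream = 0
    for idx in range(len(record.exons) - 1):
        s, e = record.exons[idx]
        next_s = record.exons[idx + 1][0]
        coding_upstream += e - s
        introns.append(
            IntronAnnotation(
                index=idx,
                length_bp=next_s - e,
                phase=coding_upstream % 3,
                anchor=coding_upstream // 3,
            )
        )
    return introns


def classify_intron_type(
    record: GeneRecord, domain: WRKYDomain
) -> list[IntronAnnotation]:
    """Label each intron R, V or OTHER relative to a detected domain.

    The R rule wants the split codon (phase 2) to encode R between the
    heptapeptide start and the first zinc-finger C.  The V rule wants a
    phase-0 junction exactly before the codon at second-C + 6 within a
    C2H2 finger.  Positions are protein indices; the protein sequence is
    consulted for the R residue itself.
    """
    introns = compute_intron_phases(record)
    protein = record.protein.upper()
    first_c = domain.zf_coords[0] if domain.complete else None
    second_c = domain.zf_coords[1] if domain.complete else None
    for intron in introns:
        pos = intron.anchor                     # codon index touching the junction
        if intron.phase == 2 and first_c is not None:
            in_window = domain.hepta_start <= pos < first_c
            if in_window and pos < len(protein) and protein[pos] == "R":
                intron.type = "R"
                continue
        if (
            intron.phase == 0
            and domain.zf_class == "C2H2"
            and second_c is not None
            and pos == second_c + 6
        ):
            intron.type = "V"
            continue
        intron.type = "OTHER"
    return introns


def conserved_introns(
    annotated: Sequence[IntronAnnotation],
) -> list[IntronAnnotation]:
    return [i for i in annotated if i.type in ("R", "V")]


def intron_length_summary(
    per_gene: Sequence[Sequence[IntronAnnotation]],
) -> dict[str, Optional[float]]:
    """Mean/median length of conserved (R/V) introns across genes.

    An input without conserved introns yields a zero-count summary rather
    than an error.
    """
    lengths = [
        i.length_bp for annots in per_gene for i in conserved_introns(annots)
    ]
    if not lengths:
        return {"count": 0, "mean": None, "median": None}
    return {
        "count": len(lengths),
        "mean": float(mean(lengths)),
        "median": float(median(lengths)),
    }
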