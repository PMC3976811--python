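"""WRKY domain detection, group/subgroup classification and candidate filtering.

The WRKY domain is ~60 residues: a nearly invariant heptapeptide (canonically
WRKYGQK) followed by a zinc finger.  The scanner implements a sequence
grammar rather than a profile HMM:

* heptapeptide: ``W p2 p3 Y G p6 K`` with p2 in {R,K,L,S,V}, p3 in {R,K,C}
  and p6 in {Q,Y,E,L,K} — the union of the named natural variants (WRRY,
  WSKY, WKRY, WVKY, WKKY) and the observed single-residue substitutions.
* zinc finger, searched downstream of the heptapeptide:
  C2H2 = ``C X{4,5} C X{22,23} H X H`` and
  C2HC = ``C X{5,8} C X{25,28} H X{1,2} C``.

Family groups follow the standard scheme: group I proteins carry two WRKY
domains, group II one domain with a C2H2 finger, group III one domain with
a C2HC finger.  Group II subgroups (IIa-IIe, plus the provisional IIx) are
assigned by nearest labelled reference domain under alignment p-distance.
"""

from __future__ import annotations

import re
from typing import Optional, Sequence

from .align import global_align, aligned_p_distance
from .records import Classification, GeneRecord, PseudogeneFlags, WRKYDomain

HEPTA_P2 = "RKLSV"
HEPTA_P3 = "RKC"
HEPTA_P6 = "QYELK"
HEPTA_RE = re.compile(f"W[{HEPTA_P2}][{HEPTA_P3}]YG[{HEPTA_P6}]K")

# Anchored finger grammars; X is tolerated in spacer positions but can never
# satisfy a C/H position because those are matched literally.
C2H2_RE = re.compile(r"C.{4,5}C.{22,23}H.H")
C2HC_RE = re.compile(r"C.{5,8}C.{25,28}H.{1,2}C")

ZF_SEARCH_WINDOW = 50       # residues downstream of the heptapeptide end
MIN_DOMAIN_SPAN = 40        # 2/3 of the nominal 60-aa domain
STOP_CODONS = {"TAA", "TAG", "TGA"}


def _finger_coords(match: re.Match, cls: str) -> tuple[int, ...]:
    s = match.start()
    text = match.group(0)
    coords = [s]                                 # first C
    second_c = text.index("C", 1)
    coords.append(s + second_c)
    h = text.index("H", second_c + 1)
    coords.append(s + h)
    coords.append(s + len(text) - 1)             # terminal H (C2H2) or C (C2HC)
    return tuple(coords)


def scan_wrky_domains(protein: str) -> list[WRKYDomain]:
    """Find all WRKY domains in a protein, ordered by position.

    For each heptapeptide hit the nearest downstream zinc finger starting
    within ``ZF_SEARCH_WINDOW`` residues is attached; the C2H2 grammar takes
    precedence over C2HC when both match at the same anchor.  A heptapeptide
    with no finger yields an incomplete domain.
    """
    if not protein:
        raise ValueError("scan_wrky_domains: empty protein sequence")
    protein = protein.upper()
    domains: list[WRKYDomain] = []
    for m in HEPTA_RE.finditer(protein):
        hepta_start = m.start()
        hepta_end = m.end()
        domain = WRKYDomain(hepta_start=hepta_start, heptapeptide=m.group(0))
        limit = min(hepta_end + ZF_SEARCH_WINDOW, len(protein))
        for s in range(hepta_end, limit):
            if protein[s] != "C":
                continue
            hit = C2H2_RE.match(protein, s)
            if hit is not None:
                domain.zf_class = "C2H2"
            else:
                hit = C2HC_RE.match(protein, s)
                if hit is not None:
                    domain.zf_class = "C2HC"
            if hit is not None:
                domain.zf_coords = _finger_coords(hit, domain.zf_class)
                domain.complete = True
                break
        domains.append(domain)
    if len(domains) == 2:
        domains[0].terminal = "N"
        domains[1].terminal = "C"
    return domains


def classify_group(domains: Sequence[WRKYDomain]) -> Classification:
    """Group I/II/III call from scanned domains.

    Two heptapeptide hits make group I provided at least one domain is
    complete (a degraded C-terminal domain does not disqualify an otherwise
    intact two-domain protein).  A single complete domain is II or III by
    finger class; anything weaker is UNCLASSIFIED.
    """
    domains = list(domains)
    n_complete = sum(d.complete for d in domains)
    if len(domains) == 2 and n_complete >= 1:
        group = "I"
    elif len(domains) == 1 and n_complete == 1:
        group = "II" if domains[0].zf_class == "C2H2" else "III"
    else:
        group = "UNCLASSIFIED"
    return Classification(group=group, domains=domains)


def domain_sequence(protein: str, domain: WRKYDomain) -> str:
    """Heptapeptide-through-zinc-finger slice of the protein."""
    return protein[domain.hepta_start:domain.end]


def assign_subgroup(
    domain_seq: str,
    references: Sequence[tuple[str, str, str]],
    unplaced_threshold: float = 0.6,
) -> tuple[str, str, float]:
    """Nearest-reference subgroup assignment for a group II domain.

    ``references`` are ``(reference_id, subgroup, sequence)`` triples; the
    query gets the subgroup of the closest reference by p-distance on a
    pairwise global alignment.  Ties go to the earlier reference.  If no
    reference lies within ``unplaced_threshold`` the query is labelled
    ``"unplaced"`` (an IIx-like orphan).

    Returns ``(subgroup, reference_id, distance)``.
    """
    if not references:
        raise ValueError("assign_subgroup: empty reference set")
    best: Optional[tuple[float, str, str]] = None
    for ref_id, subgroup, ref_seq in references:
        res = global_align(domain_seq, ref_seq, mode="aa")
        dist = aligned_p_distance(res.aligned_a, res.aligned_b)
        if best is None or dist < best[0]:
            best = (dist, subgroup, ref_id)
    dist, subgroup, ref_id = best
    if dist > unplaced_threshold:
        return "unplaced", ref_id, dist
    return subgroup, ref_id, dist


def classify_record(
    record: GeneRecord,
    references: Optional[Sequence[tuple[str, str, str]]] = None,
) -> Classification:
    """Scan + group call (+ subgroup for group II when references given)."""
    domains = scan_wrky_domains(record.protein)
    cls = classify_group(domains)
    if cls.group == "II" and references:
        dom = next(d for d in domains if d.complete)
        subgroup, ref_id, dist = assign_subgroup(
            domain_sequence(record.protein, dom), references
        )
        cls.subgroup = subgroup
        cls.nearest_reference = ref_id
        cls.reference_distance = dist
    return cls


def filter_candidates(
    classified: Sequence[tuple[GeneRecord, Classification]],
) -> tuple[list[tuple[GeneRecord, Classification]], list[tuple[GeneRecord, Classification]]]:
    """Drop weak candidates: no complete domain, or a domain shorter than
    2/3 of the nominal length (< 40 aa heptapeptide-to-finger-end).

    Two-domain (group I) proteins with one intact domain are retained even
    if the other domain is degraded.
    """
    kept, excluded = [], []
    for rec, cls in classified:
        complete = [d for d in cls.domains if d.complete]
        ok_span = any(d.span >= MIN_DOMAIN_SPAN for d in complete)
        if cls.group == "I" and complete:
            keep = any(d.span >= MIN_DOMAIN_SPAN for d in complete)
        else:
            keep = cls.group in ("II", "III") and ok_span
        (kept if keep else excluded).append((rec, cls))
    return kept, excluded


def detect_pseudogene(cds: str) -> PseudogeneFlags:
    """Pseudogene evidence from the CDS alone.

    ``premature_stop``: any in-frame stop codon before the final codon.
    ``frameshift``: CDS length not divisible by 3 (operational definition;
    no alignment to an intact paralog is attempted).
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) < 3:
        raise ValueError("detect_pseudogene: CDS shorter than one codon")
    n_codons = len(cds) // 3
    premature = any(
        cds[3 * i: 3 * i + 3] in STOP_CODONS for i in range(n_codons - 1)
    )
    return PseudogeneFlags(premature_stop=premature, frameshift=len(cds) % 3 != 0)


def spacing_signature(domain: WRKYDomain) -> Optional[str]:
    """Diagnostic zinc-finger spacing label, e.g. ``CX4CX23HXH``.

    Reported for inspection only: spacing classes overlap between subgroups
    (the same subgroup can show two spacings), so classification never uses
    this signature.
    """
    if not domain.complete:
        return None
    c1, c2, h1, last = domain.zf_coords
    inner1 = c2 - c1 - 1
    inner2 = h1 - c2 - 1
    tail = last - h1 - 1
    tail_sym = "X" * tail
    end = "H" if domain.zf_class == "C2H2" else "C"
    return f"CX{inner1}CX{inner2}H{tail_sym}{end}"
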