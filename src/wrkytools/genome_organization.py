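"""Chromosomal mapping, 200-kb gene clusters and duplicated gene pairs.

Definitions used throughout the family survey:

* duplicate pair: aligned nucleotide coverage of the longer CDS > 70% AND
  amino-acid identity > 70% (both strict);
* tandem vs segmental: a duplicate pair on one chromosome is tandem, any
  other placement is segmental;
* gene cluster: two or more genes whose representative coordinates chain
  within a 200-kb window on one chromosome (single linkage).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Optional, Sequence

import pandas as pd

from .align import global_align
from .records import UNPLACED, ClusterCall, DuplicatePair, GeneLocus, GeneRecord

COVERAGE_THRESHOLD = 0.70
IDENTITY_THRESHOLD = 0.70
CLUSTER_WINDOW_BP = 200_000

CHROMOSOMES = [str(i) for i in range(1, 7)]

# re-export: the aligner lives in align.py but is part of this module's surface
from .align import global_align  # noqa: F401,E402


def detect_duplications(
    records: Sequence[GeneRecord],
    coverage_threshold: float = COVERAGE_THRESHOLD,
    identity_threshold: float = IDENTITY_THRESHOLD,
) -> list[DuplicatePair]:
    """Test all unordered pairs against the 70/70 duplication rule.

    Coverage comes from a nucleotide global alignment of the CDS pair;
    identity from an amino-acid global alignment of the proteins.  Pairs
    with an unplaced member cannot be called tandem and are labelled
    SEGMENTAL with ``unplaced_member=True``.
    """
    pairs: list[DuplicatePair] = []
    recs = list(records)
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            if not (a.cds and b.cds and a.protein and b.protein):
                continue
            nt = global_align(a.cds, b.cds, mode="nt")
            if nt.coverage <= coverage_threshold:
                continue
            aa = global_align(a.protein, b.protein, mode="aa")
            if aa.identity <= identity_threshold:
                continue
            both_placed = a.placed and b.placed
            tandem = both_placed and a.chromosome == b.chromosome
            pairs.append(
                DuplicatePair(
                    id_a=a.gene_id,
                    id_b=b.gene_id,
                    nt_coverage=nt.coverage,
                    aa_identity=aa.identity,
                    mode="TANDEM" if tandem else "SEGMENTAL",
                    unplaced_member=not both_placed,
                )
            )
    return pairs


def detect_clusters(
    loci: Sequence[GeneLocus], window_bp: int = CLUSTER_WINDOW_BP
) -> list[ClusterCall]:
    """Single-linkage chaining of per-chromosome sorted coordinates.

    Consecutive genes separated by at most ``window_bp`` join one cluster;
    clusters of >= 2 members are reported.  Output is independent of input
    order and deterministic (ties sorted by position, then gene id).
    """
    by_chrom: dict[str, list[GeneLocus]] = defaultdict(list)
    for locus in loci:
        if locus.chromosome != UNPLACED:
            by_chrom[locus.chromosome].append(locus)
    calls: list[ClusterCall] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda l: (l.position, l.gene_id))
        block: list[GeneLocus] = []
        for locus in ordered:
            if block and locus.position - block[-1].position > window_bp:
                if len(block) >= 2:
                    calls.append(_call(chrom, block))
                block = []
            block.append(locus)
        if len(block) >= 2:
            calls.append(_call(chrom, block))
    return calls


def _call(chrom: str, block: list[GeneLocus]) -> ClusterCall:
    return ClusterCall(
        chromosome=chrom,
        member_ids=[l.gene_id for l in block],
        span_bp=block[-1].position - block[0].position,
    )


def chromosome_distribution(
    loci: Sequence[GeneLocus],
    groups: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Gene counts per chromosome 1..6 plus UNPLACED.

    With a ``gene_id -> group`` mapping the table gains one column per
    group label alongside the total.
    """
    index = CHROMOSOMES + [UNPLACED]
    counts = {c: 0 for c in index}
    group_labels = sorted(set(groups.values())) if groups else []
    breakdown = {c: {g: 0 for g in group_labels} for c in index}
    for locus in loci:
        chrom = locus.chromosome if locus.chromosome in counts else UNPLACED
        counts[chrom] += 1
        if groups and locus.gene_id in groups:
            breakdown[chrom][groups[locus.gene_id]] += 1
    data = {"total": [counts[c] for c in index]}
    for g in group_labels:
        data[g] = [breakdown[c][g] for c in index]
    return pd.DataFrame(data, index=pd.Index(index, name="chromosome"))
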