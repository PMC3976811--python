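"""File I/O: FASTA, GFF3, Newick, and the packaged curated gene table.

The packaged table lists all 71 WRKY family entries curated from the
*Lotus japonicus* genome survey (build 2.5): gene name, group/subgroup
assignment, chromosome, representative 1-based coordinate and pseudogene
status.  Ten entries could not be classified ("nd") and 23 could not be
placed on chromosomes 1-6.
"""

from __future__ import annotations

import importlib.resources
from collections import namedtuple
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import UNPLACED, GeneLocus, GeneRecord
from .tree import TreeNode, parse_newick

ND = "nd"


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, nucleotide: bool = False, u_to_t: bool = False) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, SEQUENCE), ...]`` in file order.

    Sequences are upper-cased; with ``nucleotide=True`` and ``u_to_t=True``
    any U is rewritten to T.  Duplicate ids and empty files are errors.
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if nucleotide and u_to_t:
            seq = seq.replace("U", "T")
        out.append((rec.id, seq))
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

def _norm_chromosome(seqid: str) -> str:
    s = seqid.removeprefix("chr").removeprefix("Chr")
    return s if s else UNPLACED


def read_gff3(path) -> list[GeneRecord]:
    """Read gene models from GFF3 into :class:`GeneRecord` skeletons.

    One record per mRNA.  CDS intervals are converted to the internal
    0-based half-open convention on the gene's own coordinate frame
    (position 0 = first base of the mRNA on the coding strand; minus-strand
    features are flipped so exons come out in transcript order).
    Sequences are not populated here; see :func:`attach_sequences`.
    """
    path = Path(path)
    header_seen = False
    mrnas: dict[str, dict] = {}
    cds_by_parent: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##gff-version"):
                    header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            attrd = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            if ftype == "mRNA":
                mid = attrd.get("ID")
                if not mid:
                    raise ValueError(f"{path}:{lineno}: mRNA without ID")
                mrnas[mid] = {
                    "seqid": seqid,
                    "start": int(start),
                    "end": int(end),
                    "strand": strand,
                }
            elif ftype == "CDS":
                parent = attrd.get("Parent")
                if not parent:
                    raise ValueError(f"{path}:{lineno}: CDS without Parent attribute")
                cds_by_parent.setdefault(parent, []).append((int(start), int(end)))
    if not header_seen:
        raise ValueError(f"{path}: missing ##gff-version header")

    records = []
    for parent in cds_by_parent:
        if parent not in mrnas:
            raise ValueError(f"{path}: CDS parent {parent!r} has no mRNA feature")
    for mid, info in mrnas.items():
        segments = sorted(cds_by_parent.get(mid, []))
        for s, e in segments:
            if s < info["start"] or e > info["end"]:
                raise ValueError(
                    f"{path}: CDS [{s},{e}] of {mid} outside its mRNA bounds"
                )
        if info["strand"] == "-":
            exons = [
                (info["end"] - e, info["end"] - s + 1) for s, e in reversed(segments)
            ]
        else:
            exons = [(s - info["start"], e - info["start"] + 1) for s, e in segments]
        records.append(
            GeneRecord(
                gene_id=mid,
                chromosome=_norm_chromosome(info["seqid"]),
                start=info["start"],
                exons=exons,
                strand=info["strand"],
            )
        )
    records.sort(key=lambda r: r.gene_id)
    return records


def write_gff3(records: Sequence[GeneRecord], path, chrom_prefix: str = "chr") -> None:
    """Write gene models (gene/mRNA/CDS features) back to GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            if rec.start is None:
                continue
            length = rec.exons[-1][1] if rec.exons else len(rec.cds)
            g_start, g_end = rec.start, rec.start + length - 1
            seqid = f"{chrom_prefix}{rec.chromosome}"
            base = (seqid, "wrkytools")
            fh.write(
                "\t".join(
                    [*base, "gene", str(g_start), str(g_end), ".", rec.strand, ".",
                     f"ID={rec.gene_id}_gene"]
                ) + "\n"
            )
            fh.write(
                "\t".join(
                    [*base, "mRNA", str(g_start), str(g_end), ".", rec.strand, ".",
                     f"ID={rec.gene_id};Parent={rec.gene_id}_gene"]
                ) + "\n"
            )
            segments = []
            for s, e in rec.exons:
                if rec.strand == "-":
                    segments.append((g_end - e + 1, g_end - s))
                else:
                    segments.append((g_start + s, g_start + e - 1))
            phase_acc = 0
            rows = []
            for s, e in segments:
                rows.append((s, e, (3 - phase_acc % 3) % 3))
                phase_acc += e - s + 1
            for ftype in ("exon", "CDS"):
                for s, e, phase in sorted(rows):
                    fh.write(
                        "\t".join(
                            [*base, ftype, str(s), str(e), ".", rec.strand,
                             str(phase) if ftype == "CDS" else ".",
                             f"Parent={rec.gene_id}"]
                        ) + "\n"
                    )


def attach_sequences(
    records: Sequence[GeneRecord],
    proteins: Optional[Iterable[tuple[str, str]]] = None,
    cds: Optional[Iterable[tuple[str, str]]] = None,
) -> list[GeneRecord]:
    """Fill ``protein``/``cds`` fields from FASTA-derived (id, seq) pairs."""
    pmap = dict(proteins) if proteins is not None else {}
    cmap = dict(cds) if cds is not None else {}
    for rec in records:
        if rec.gene_id in pmap:
            rec.protein = pmap[rec.gene_id]
        if rec.gene_id in cmap:
            rec.cds = cmap[rec.gene_id]
    return list(records)


# ---------------------------------------------------------------------------
# Packaged gene table

FixtureRow = namedtuple(
    "FixtureRow",
    ["annotation_id", "gene_name", "group", "chromosome", "start", "pseudogene"],
)

_GROUP_VOCAB = {"I", "IIa", "IIb", "IIc", "IId", "IIe", "IIx", "III", ND}


class GeneTable:
    """The packaged 71-entry curated WRKY gene table."""

    def __init__(self, rows: list[FixtureRow]):
        self.rows = rows
        self._by_name = {r.gene_name: r for r in rows}

    def __len__(self) -> int:
        return len(self.rows)

    def lookup(self, gene_name: str) -> FixtureRow:
        return self._by_name[gene_name]

    def loci(self) -> list[GeneLocus]:
        """Placed genes as loci (entries without a chromosome are dropped)."""
        return [
            GeneLocus(r.gene_name, r.chromosome, r.start)
            for r in self.rows
            if r.chromosome != ND
        ]

    def all_loci(self) -> list[GeneLocus]:
        """All 71 entries; unplaced ones carry the UNPLACED sentinel."""
        return [
            GeneLocus(
                r.gene_name,
                r.chromosome if r.chromosome != ND else UNPLACED,
                r.start if r.start is not None else 0,
            )
            for r in self.rows
        ]

    def classified(self) -> list[FixtureRow]:
        return [r for r in self.rows if r.group != ND]

    def pseudogene_count(self) -> int:
        return sum(r.pseudogene for r in self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=FixtureRow._fields)
        df["start"] = df["start"].astype("Int64")
        return df


def load_gene_table() -> GeneTable:
    """Load the packaged curated gene table (71 rows).

    Printed thousands separators were stripped when the table was packaged;
    coordinates stay 1-based as printed.  Pseudogene flags follow the
    table's italicised entries (9 genes).
    """
    ref = importlib.resources.files("wrkytools.data") / "lotus_wrky_gene_table.tsv"
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    rows = []
    for _, r in df.iterrows():
        group = r["group"]
        if group not in _GROUP_VOCAB:
            raise ValueError(f"unexpected group label {group!r} in packaged table")
        chrom = r["chromosome"]
        start = None if r["location"] == ND else int(r["location"])
        rows.append(
            FixtureRow(
                r["annotation_id"], r["gene_name"], group, chrom, start,
                bool(int(r["pseudogene"])),
            )
        )
    if len(rows) != 71:
        raise ValueError(f"packaged gene table has {len(rows)} rows, expected 71")
    return GeneTable(rows)


# ---------------------------------------------------------------------------
# Newick

def read_newick(path) -> TreeNode:
    return parse_newick(Path(path).read_text())


def write_newick(tree: TreeNode, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
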