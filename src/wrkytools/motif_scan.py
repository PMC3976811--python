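"""Scan proteins for the family's conserved motifs.

The packaged motif set holds the 20 MEME-derived consensus strings reported
for this family (motif1 carries the WRKYGQK core; motif7 is a Leu zipper,
motif13 an NLS, motif16 a HARF motif), plus the transcriptional coactivator
patterns LXXLL and LXLXLX.  Consensus strings are fuzzy by nature, so the
scanner is a sliding-window Hamming match with a mismatch budget
(default 20% of the motif width; 'x' in a consensus matches anything).
"""

from __future__ import annotations

import importlib.resources
import re
from typing import Sequence

import pandas as pd

from .records import MotifHit


def load_motif_table() -> pd.DataFrame:
    ref = importlib.resources.files("wrkytools.data") / "wrky_motif_consensus.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", dtype={"motif_id": str, "consensus": str})


_MOTIFS: dict[str, str] = {}


def motif_consensus(motif_id: str) -> str:
    if not _MOTIFS:
        df = load_motif_table()
        _MOTIFS.update(dict(zip(df["motif_id"], df["consensus"])))
    if motif_id not in _MOTIFS:
        raise KeyError(f"unknown motif id {motif_id!r}")
    return _MOTIFS[motif_id]


def scan_consensus(
    protein: str,
    motif_id: str,
    max_mismatch_frac: float = 0.2,
) -> list[MotifHit]:
    """All windows matching a packaged consensus within the mismatch budget.

    The budget is ``floor(max_mismatch_frac * width)``; overlapping hits are
    all reported.  Positions with 'x' in the consensus never count as
    mismatches.
    """
    consensus = motif_consensus(motif_id).upper()
    protein = protein.upper()
    width = len(consensus)
    budget = int(max_mismatch_frac * width)
    wildcard = [c in "xX" for c in motif_consensus(motif_id)]
    hits: list[MotifHit] = []
    for start in range(len(protein) - width + 1):
        window = protein[start:start + width]
        mism = sum(
            1
            for w, c, is_x in zip(window, consensus, wildcard)
            if not is_x and w != c
        )
        if mism <= budget:
            hits.append(MotifHit(motif_id, start, window, mism))
    return hits


_LXXLL = re.compile(r"(?=(L..LL))")
_LXLXLX = re.compile(r"(?=(L.L.L.))")


def scan_coactivator(protein: str) -> list[MotifHit]:
    """All coactivator-motif matches: LXXLL and LXLXLX (L = Leu, X = any)."""
    protein = protein.upper()
    hits = [
        MotifHit("coactivator_LXXLL", m.start(), m.group(1), 0)
        for m in _LXXLL.finditer(protein)
    ]
    hits += [
        MotifHit("coactivator_LXLXLX", m.start(), m.group(1), 0)
        for m in _LXLXLX.finditer(protein)
    ]
    return sorted(hits, key=lambda h: (h.start, h.motif_id))


def scan_all(
    proteins: Sequence[tuple[str, str]],
    motif_ids: Sequence[str] | None = None,
    max_mismatch_frac: float = 0.2,
) -> pd.DataFrame:
    """Hit table over a protein set for the packaged motifs + coactivator."""
    if motif_ids is None:
        motif_ids = list(load_motif_table()["motif_id"])
    rows = []
    for name, seq in proteins:
        for mid in motif_ids:
            for hit in scan_consensus(seq, mid, max_mismatch_frac):
                rows.append((name, hit.motif_id, hit.start, hit.matched, hit.mismatches))
        for hit in scan_coactivator(seq):
            rows.append((name, hit.motif_id, hit.start, hit.matched, hit.mismatches))
    return pd.DataFrame(
        rows, columns=["gene_id", "motif_id", "start", "matched", "mismatches"]
    )
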