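"""Global alignment primitives.

Pairwise global (Needleman-Wunsch, affine gaps) alignment backs duplication
screening, reference-based subgroup assignment and guide-tree distances.
Scoring follows common practice for this kind of family survey:

* amino acids: BLOSUM62, gap open 10 / extend 1
* nucleotides: match +2 / mismatch -3, gap open 5 / extend 2

A gap of length k costs ``open + k * extend``.  Identity is counted over all
aligned columns (a residue opposite a gap counts as a difference); coverage
is the fraction of the longer sequence aligned residue-on-residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
NT_ALPHABET = set("ACGTUN")

AA_GAP_OPEN, AA_GAP_EXTEND = 10.0, 1.0
NT_MATCH, NT_MISMATCH = 2.0, -3.0
NT_GAP_OPEN, NT_GAP_EXTEND = 5.0, 2.0


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    identity: float
    coverage: float
    score: float

    def __iter__(self):
        return iter((self.aligned_a, self.aligned_b, self.identity, self.coverage))


@lru_cache(maxsize=None)
def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if mode == "aa":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        # first gap position costs open+extend, each further one costs extend
        aligner.open_gap_score = -(AA_GAP_OPEN + AA_GAP_EXTEND)
        aligner.extend_gap_score = -AA_GAP_EXTEND
    elif mode == "nt":
        aligner.match_score = NT_MATCH
        aligner.mismatch_score = NT_MISMATCH
        aligner.open_gap_score = -(NT_GAP_OPEN + NT_GAP_EXTEND)
        aligner.extend_gap_score = -NT_GAP_EXTEND
    else:
        raise ValueError(f"unknown alignment mode {mode!r} (want 'nt' or 'aa')")
    return aligner


def _check_alphabet(seq: str, mode: str, which: str) -> None:
    alphabet = NT_ALPHABET if mode == "nt" else AA_ALPHABET
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(
            f"sequence {which} contains {sorted(bad)} not valid for mode {mode!r}"
        )


def global_align(a: str, b: str, mode: str = "aa") -> AlignmentResult:
    """Needleman-Wunsch global alignment of two sequences.

    Returns the aligned strings plus identity (identical columns / aligned
    columns) and coverage (residue-on-residue columns / longer length).
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    a, b = a.upper(), b.upper()
    _check_alphabet(a, mode, "a")
    _check_alphabet(b, mode, "b")
    aligner = _aligner(mode)
    alignments = aligner.align(a, b)
    best = alignments[0]
    aligned_a, aligned_b = str(best[0]), str(best[1])
    ncols = len(aligned_a)
    matches = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    paired = sum(x != "-" and y != "-" for x, y in zip(aligned_a, aligned_b))
    identity = matches / ncols if ncols else 0.0
    coverage = paired / max(len(a), len(b))
    return AlignmentResult(aligned_a, aligned_b, identity, coverage, float(best.score))


def aligned_p_distance(aligned_a: str, aligned_b: str) -> float:
    """Proportion of differing sites among columns ungapped in both sequences."""
    compared = diffs = 0
    for x, y in zip(aligned_a, aligned_b):
        if x != "-" and y != "-":
            compared += 1
            if x != y:
                diffs += 1
    if compared == 0:
        raise ValueError("no comparable (ungapped) sites between sequences")
    return diffs / compared


def pairwise_p_distance(a: str, b: str, mode: str = "aa") -> float:
    """p-distance after a fresh pairwise global alignment."""
    res = global_align(a, b, mode=mode)
    return aligned_p_distance(res.aligned_a, res.aligned_b)


# ---------------------------------------------------------------------------
# Profile-profile alignment (used by the progressive aligner)

_B62 = substitution_matrices.load("BLOSUM62")
_B62_ALPH = _B62.alphabet
_B62_INDEX = {c: i for i, c in enumerate(_B62_ALPH)}
_B62_ARR = np.asarray(_B62)


def _profile_matrix(rows: list[str]) -> np.ndarray:
    """Column x alphabet frequency matrix; gaps contribute zero weight."""
    ncols = len(rows[0])
    freq = np.zeros((ncols, len(_B62_ALPH)))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != "-":
                freq[j, _B62_INDEX.get(ch, _B62_INDEX["X"])] += 1.0
    return freq / len(rows)


def align_profiles(
    rows_a: list[str],
    rows_b: list[str],
    gap_open: float = AA_GAP_OPEN,
    gap_extend: float = AA_GAP_EXTEND,
) -> tuple[list[str], list[str]]:
    """Merge two aligned blocks with affine-gap NW on mean BLOSUM62 scores.

    Deterministic tie-break prefers diagonal, then a gap in ``rows_b``.
    Returns both blocks expanded to the merged set of columns.
    """
    fa = _profile_matrix(rows_a)
    fb = _profile_matrix(rows_b)
    score = fa @ _B62_ARR @ fb.T                    # ncols_a x ncols_b
    n, m = score.shape
    neg = -np.inf
    open_cost = gap_open + gap_extend

    mmat = np.full((n + 1, m + 1), neg)
    xmat = np.full((n + 1, m + 1), neg)             # gap in rows_b (consume a)
    ymat = np.full((n + 1, m + 1), neg)             # gap in rows_a (consume b)
    mmat[0, 0] = 0.0
    for i in range(1, n + 1):
        xmat[i, 0] = -open_cost - (i - 1) * gap_extend
    for j in range(1, m + 1):
        ymat[0, j] = -open_cost - (j - 1) * gap_extend

    for i in range(1, n + 1):
        srow = score[i - 1]
        for j in range(1, m + 1):
            best_prev = max(mmat[i - 1, j - 1], xmat[i - 1, j - 1], ymat[i - 1, j - 1])
            mmat[i, j] = best_prev + srow[j - 1]
            xmat[i, j] = max(mmat[i - 1, j] - open_cost, xmat[i - 1, j] - gap_extend)
            ymat[i, j] = max(mmat[i, j - 1] - open_cost, ymat[i, j - 1] - gap_extend)

    # traceback
    i, j = n, m
    state = int(np.argmax([mmat[n, m], xmat[n, m], ymat[n, m]]))
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            ops.append("D")
            prev = [mmat[i - 1, j - 1], xmat[i - 1, j - 1], ymat[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1 or (j == 0 and i > 0):
            ops.append("A")                          # column from a, gap in b
            state = 0 if xmat[i, 0 if j < 0 else j] == mmat[i - 1, j] - open_cost else 1
            if i > 0 and not np.isinf(xmat[i, j]):
                state = 0 if mmat[i - 1, j] - open_cost >= xmat[i - 1, j] - gap_extend else 1
            i -= 1
        else:
            ops.append("B")                          # column from b, gap in a
            if j > 0 and not np.isinf(ymat[i, j]):
                state = 0 if mmat[i, j - 1] - open_cost >= ymat[i, j - 1] - gap_extend else 2
            j -= 1
    ops.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "D":
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ia += 1
            ib += 1
        elif op == "A":
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            for k in range(len(rows_b)):
                out_b[k] += "-"
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
    return out_a, out_b
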