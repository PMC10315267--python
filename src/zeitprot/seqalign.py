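"""Global pairwise protein alignment with affine gap costs.

Implements the classic three-state (match / gap-in-a / gap-in-b) affine-gap
global alignment with the gap-cost and identity conventions of the EMBOSS
``needle`` tool: a gap of length L costs ``gap_open + L * gap_extend``, end
gaps are free by default, and percent identity is computed over the full
alignment length including gap columns. The substitution matrix defaults to
BLOSUM62. Traceback is deterministic: on score ties the diagonal move is
preferred, then a gap in the first sequence, then a gap in the second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

GAP = "-"
NEG_INF = -1e30


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment with its score and identity statistics."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_count: int
    alignment_length: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.identity_count / self.alignment_length

    def __str__(self) -> str:
        marks = "".join(
            "|" if x == y and x != GAP else " " for x, y in zip(self.aligned_a, self.aligned_b)
        )
        return (
            f"{self.aligned_a}\n{marks}\n{self.aligned_b}\n"
            f"# score {self.score:.1f}  length {self.alignment_length}  "
            f"identity {self.identity_count}/{self.alignment_length} "
            f"({self.percent_identity:.1f}%)"
        )


def load_matrix(name: str = "BLOSUM62") -> dict[tuple[str, str], float]:
    """Load a substitution matrix as a symbol-pair dictionary."""
    mat = substitution_matrices.load(name)
    alphabet = mat.alphabet
    return {
        (a, b): float(mat[a, b]) for a in alphabet for b in alphabet
    }


def _validate(seq: str, scores: dict, which: str) -> str:
    if not seq:
        raise ValueError(f"sequence {which} is empty")
    seq = seq.upper()
    alphabet = {a for a, _ in scores}
    for i, res in enumerate(seq):
        if res not in alphabet:
            raise ValueError(f"sequence {which}: unknown residue {res!r} at position {i + 1}")
    return seq


def global_affine_align(
    a: str,
    b: str,
    matrix: dict[tuple[str, str], float] | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    penalize_end_gaps: bool = False,
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences with affine gaps.

    A gap of length L costs ``gap_open + L * gap_extend``; leading and
    trailing gaps are free unless ``penalize_end_gaps`` is set.
    """
    scores = matrix if matrix is not None else load_matrix("BLOSUM62")
    a = _validate(a, scores, "a")
    b = _validate(b, scores, "b")
    m, n = len(a), len(b)
    first = gap_open + gap_extend  # cost of the first residue of a gap

    # state 0: a[i] ~ b[j]; state 1: a[i] ~ gap (gap in b); state 2: gap ~ b[j]
    M = np.full((m + 1, n + 1), NEG_INF)
    X = np.full((m + 1, n + 1), NEG_INF)
    Y = np.full((m + 1, n + 1), NEG_INF)
    M[0, 0] = 0.0
    lead = 0.0 if not penalize_end_gaps else None
    for i in range(1, m + 1):
        X[i, 0] = 0.0 if lead is not None else -(gap_open + i * gap_extend)
    for j in range(1, n + 1):
        Y[0, j] = 0.0 if lead is not None else -(gap_open + j * gap_extend)

    # traceback: state entered from, per (state, i, j)
    tb = np.zeros((3, m + 1, n + 1), dtype=np.int8)
    tb[1, 1:, 0] = 1
    tb[2, 0, 1:] = 2
    tb[1, 1, 0] = 0
    tb[2, 0, 1] = 0

    for i in range(1, m + 1):
        ai = a[i - 1]
        row_scores = [scores[ai, b[j - 1]] for j in range(1, n + 1)]
        for j in range(1, n + 1):
            s = row_scores[j - 1]
            # match state: on ties prefer diagonal, then gap-in-a, then gap-in-b
            best, state = M[i - 1, j - 1], 0
            if Y[i - 1, j - 1] > best:
                best, state = Y[i - 1, j - 1], 2
            if X[i - 1, j - 1] > best:
                best, state = X[i - 1, j - 1], 1
            M[i, j] = best + s
            tb[0, i, j] = state
            # gap in b (consume a[i])
            open_x = M[i - 1, j] - first
            ext_x = X[i - 1, j] - gap_extend
            switch_x = Y[i - 1, j] - first
            best, state = open_x, 0
            if ext_x > best:
                best, state = ext_x, 1
            if switch_x > best:
                best, state = switch_x, 2
            X[i, j] = best
            tb[1, i, j] = state
            # gap in a (consume b[j])
            open_y = M[i, j - 1] - first
            ext_y = Y[i, j - 1] - gap_extend
            switch_y = X[i, j - 1] - first
            best, state = open_y, 0
            if ext_y > best:
                best, state = ext_y, 2
            if switch_y > best:
                best, state = switch_y, 1
            Y[i, j] = best
            tb[2, i, j] = state

    if penalize_end_gaps:
        end_i, end_j = m, n
        finals = (M[m, n], X[m, n], Y[m, n])
        score = max(finals)
        state = int(np.argmax(finals))
    else:
        # free trailing gaps: best cell on the last row or column
        best = NEG_INF
        end_i = end_j = 0
        state = 0
        for i in range(m + 1):
            for st, mat_ in ((0, M), (1, X), (2, Y)):
                v = mat_[i, n]
                if v > best:
                    best, end_i, end_j, state = v, i, n, st
        for j in range(n + 1):
            for st, mat_ in ((0, M), (1, X), (2, Y)):
                v = mat_[m, j]
                if v > best:
                    best, end_i, end_j, state = v, m, j, st
        score = best

    out_a: list[str] = []
    out_b: list[str] = []
    # free trailing gap fill
    for i in range(m, end_i, -1):
        out_a.append(a[i - 1])
        out_b.append(GAP)
    for j in range(n, end_j, -1):
        out_a.append(GAP)
        out_b.append(b[j - 1])

    i, j, st = end_i, end_j, state
    while i > 0 or j > 0:
        prev = tb[st, i, j]
        if st == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif st == 1:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
        st = int(prev)

    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    identity = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != GAP)
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score),
        identity_count=identity,
        alignment_length=len(aligned_a),
    )
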