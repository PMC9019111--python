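"""Global protein alignment and cross-species codon-number maps.

Resistance alleles in the voltage-gated sodium channel are reported in the
literature under two numbering schemes: the vector species' own transcript
and the *Musca domestica* frame in which the gene was first characterised
(e.g. L995F in *An. gambiae* is the classic L1014F *kdr* allele).  The map
between them is derived from an end-to-end (Needleman–Wunsch) alignment of
the two protein sequences: aligned residue pairs become codon-number pairs,
gapped residues are listed as unmapped.

The dynamic program is written out here (Gotoh three-state affine-gap
recursion) so the traceback tie-break is fully deterministic: at equal
score, a match/mismatch step is preferred over a gap in the second
sequence, which is preferred over a gap in the first.  Scoring defaults to
BLOSUM62 with gap open 10 and extension 1 (a gap of length k costs
``open + (k-1) * extend``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

__all__ = ["CodonMap", "build_codon_map", "needleman_wunsch"]

_NEG = -1e9


@dataclass
class CodonMap:
    """Residue-number correspondence between two protein sequences.

    ``pairs`` holds 1-based (codon_A, codon_B) tuples, strictly increasing
    in both coordinates; residues falling in alignment gaps are listed in
    ``unmapped_a`` / ``unmapped_b``.
    """

    pairs: list[tuple[int, int]] = field(default_factory=list)
    unmapped_a: list[int] = field(default_factory=list)
    unmapped_b: list[int] = field(default_factory=list)
    score: float = 0.0

    def a_to_b(self, codon_a: int) -> int | None:
        """Equivalent codon number in B, or None when unaligned."""
        for a, b in self.pairs:
            if a == codon_a:
                return b
        return None

    def b_to_a(self, codon_b: int) -> int | None:
        for a, b in self.pairs:
            if b == codon_b:
                return a
        return None

    def as_dict(self) -> dict[int, int]:
        return dict(self.pairs)


def _validate_protein(seq: str, name: str) -> str:
    seq = seq.upper()
    valid = set("ACDEFGHIKLMNPQRSTVWY*X")
    bad = set(seq) - valid
    if not seq:
        raise ValueError(f"protein {name} is empty")
    if bad:
        raise ValueError(f"protein {name} contains non-amino-acid symbols: {sorted(bad)}")
    return seq


def needleman_wunsch(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[str, str, float]:
    """End-to-end alignment of two protein sequences.

    Returns the two gapped strings and the optimal score.  Ties in the
    traceback are broken deterministically: diagonal, then gap-in-b (up),
    then gap-in-a (left).
    """
    a = _validate_protein(a, "A")
    b = _validate_protein(b, "B")
    if matrix is None:
        matrix = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)

    sub = np.empty((n, m))
    for i, ca in enumerate(a):
        for j, cb in enumerate(b):
            sub[i, j] = matrix[ca, cb]

    # M: a[i-1] aligned to b[j-1]; X: gap in b (consume a); Y: gap in a.
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend

    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        subi = sub[i - 1]
        for j in range(1, m + 1):
            best_prev = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Mi[j] = best_prev + subi[j - 1]
            Xi[j] = max(Mi1[j] - gap_open, Xi1[j] - gap_extend, Yi1[j] - gap_open)
            Yi[j] = max(Mi[j - 1] - gap_open, Yi[j - 1] - gap_extend, Xi[j - 1] - gap_open)

    # Traceback from the best final state; state preference M > X > Y.
    i, j = n, m
    finals = [(M[n, m], "M"), (X[n, m], "X"), (Y[n, m], "Y")]
    score = max(s for s, _ in finals)
    state = next(name for s, name in finals if s == score)
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            for s, name in ((M[i, j], "M"), (X[i, j], "X"), (Y[i, j], "Y")):
                if np.isclose(s, target):
                    state = name
                    break
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            here = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            opts = (
                (M[i, j] - gap_open, "M"),
                (X[i, j] - gap_extend, "X"),
                (Y[i, j] - gap_open, "Y"),
            )
            for s, name in opts:
                if np.isclose(s, here):
                    state = name
                    break
        else:  # Y
            out_a.append("-")
            out_b.append(b[j - 1])
            here = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            opts = (
                (M[i, j] - gap_open, "M"),
                (Y[i, j] - gap_extend, "Y"),
                (X[i, j] - gap_open, "X"),
            )
            for s, name in opts:
                if np.isclose(s, here):
                    state = name
                    break
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)


def build_codon_map(
    protein_a: str,
    protein_b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> CodonMap:
    """Align two proteins end-to-end and read off the codon-number map."""
    aligned_a, aligned_b, score = needleman_wunsch(
        protein_a, protein_b, matrix=matrix, gap_open=gap_open, gap_extend=gap_extend
    )
    pairs: list[tuple[int, int]] = []
    unmapped_a: list[int] = []
    unmapped_b: list[int] = []
    ia = ib = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-" and cb != "-":
            ia += 1
            ib += 1
            pairs.append((ia, ib))
        elif ca != "-":
            ia += 1
            unmapped_a.append(ia)
        else:
            ib += 1
            unmapped_b.append(ib)
    return CodonMap(pairs=pairs, unmapped_a=unmapped_a, unmapped_b=unmapped_b, score=score)
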