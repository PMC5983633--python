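"""Deterministic RNA secondary-structure prediction for hairpin screening.

The folder maximizes a weighted base-pair count (G:C = 3, A:U = 2,
G:U wobble = 1, minimum hairpin loop of 3 unpaired nt) by dynamic
programming with a fixed traceback order, so identical inputs always
yield identical dot-bracket structures.  The score is reported as a
pseudo-energy, -(total pair weight): it ranks hairpin stability and
fixes duplex geometry, but it is not a thermodynamic free energy.  When
calibrated kcal/mol values are needed (e.g. for MFEI reporting), supply
them from an external table or the optional ViennaRNA plugin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PAIR_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}
MIN_LOOP = 3  # unpaired nt enclosed by any pair


def pair_weight(a: str, b: str) -> int:
    return PAIR_WEIGHTS.get((a, b), 0)


@dataclass
class FoldResult:
    """Dot-bracket structure plus its pseudo-energy score."""

    structure: str
    score: float  # -(total pair weight); <= 0
    energy: float | None = None  # kcal/mol if a thermodynamic source was used

    def pair_table(self) -> list[int]:
        """0-based partner per position, -1 if unpaired."""
        table = [-1] * len(self.structure)
        stack: list[int] = []
        for i, char in enumerate(self.structure):
            if char == "(":
                stack.append(i)
            elif char == ")":
                j = stack.pop()
                table[i], table[j] = j, i
        return table


def _weight_matrix(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros((256, 256), dtype=np.int32)
    for (a, b), w in PAIR_WEIGHTS.items():
        lut[ord(a), ord(b)] = w
    return lut[codes[:, None], codes[None, :]]


def _fill(seq: str) -> np.ndarray:
    n = len(seq)
    weights = _weight_matrix(seq)
    table = np.zeros((n, n), dtype=np.int32)
    idx = np.arange(n)
    for span in range(MIN_LOOP + 1, n):
        i = idx[: n - span]
        j = i + span
        best = np.maximum(table[i + 1, j], table[i, j - 1])
        paired = table[i + 1, j - 1] + weights[i, j]
        best = np.maximum(best, np.where(weights[i, j] > 0, paired, -1))
        if span >= 2:
            # bifurcation: max over split points k of T[i,k] + T[k+1,j]
            d = np.arange(span - 1)
            left = table[i[:, None], i[:, None] + d]
            right = table[i[:, None] + d + 1, j[:, None]]
            best = np.maximum(best, (left + right).max(axis=1))
        table[i, j] = best
    return table


def fold_rna(sequence: str) -> FoldResult:
    """Fold a sequence into its maximum-weight nested structure.

    Traceback preference at score ties is fixed (leave i unpaired, then
    leave j unpaired, then pair i:j, then the leftmost bifurcation), so
    the structure is a pure function of the sequence.
    """
    from .seqio import normalize

    seq = normalize(sequence)
    n = len(seq)
    if n < 15:
        raise ValueError(f"sequence of length {n} is too short to fold (< 15 nt)")
    weights = _weight_matrix(seq)
    table = _fill(seq)
    structure = ["."] * n

    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or table[i, j] == 0:
            continue
        if table[i, j] == table[i + 1, j]:
            stack.append((i + 1, j))
        elif table[i, j] == table[i, j - 1]:
            stack.append((i, j - 1))
        elif weights[i, j] > 0 and j - i > MIN_LOOP and \
                table[i, j] == table[i + 1, j - 1] + weights[i, j]:
            structure[i], structure[j] = "(", ")"
            stack.append((i + 1, j - 1))
        else:
            for k in range(i, j):
                if table[i, j] == table[i, k] + table[k + 1, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    return FoldResult("".join(structure), -float(table[0, n - 1]))


def fold_vienna(sequence: str) -> FoldResult:
    """Thermodynamic folding through the optional ViennaRNA plugin.

    Returns a genuine MFE in kcal/mol; raises ImportError when the
    bindings are not installed.
    """
    import RNA  # noqa: PLC0415 - optional plugin

    from .seqio import to_rna

    structure, mfe = RNA.fold(to_rna(sequence))
    return FoldResult(structure, float(mfe), energy=float(mfe))
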