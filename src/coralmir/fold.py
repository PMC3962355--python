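"""Weighted Nussinov secondary-structure folding.

A maximum-weight, pseudoknot-free pairing model over DNA-encoded RNA:
GC pairs weigh 3, AU(=AT) 2, GU(=GT) 1, hairpin loops must enclose at least
``min_loop`` unpaired bases.  The dynamic program returns one optimal
structure via a deterministic traceback that prefers pairing the 5'-most base
(and, among its partners, the 5'-most one) on ties, so identical inputs give
identical structures.

The same engine folds precursor-candidate windows (hairpin topology, arm
pairing) and, with a set of positions forced unpaired, the constrained folds
used for target-site opening costs.  Scores are integers; the target module
interprets one score unit as 1 kcal/mol of the simplified pair-energy model.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError

__all__ = ["FoldResult", "fold", "fold_hairpin", "pair_weight"]

_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}


def pair_weight(a: str, b: str) -> int:
    """Pairing weight of two DNA-encoded bases (0 if they do not pair)."""
    return _WEIGHTS.get((a, b), 0)


@dataclass
class FoldResult:
    structure: str          # dot-bracket, same length as the input
    score: int              # total pair weight
    pairs: dict[int, int]   # symmetric map position -> partner

    def paired(self, i: int) -> bool:
        return i in self.pairs


def fold(seq: str, min_loop: int = 3, blocked: frozenset[int] | set[int] = frozenset()) -> FoldResult:
    """Maximum-weight non-crossing pairing of ``seq``.

    ``blocked`` positions are forced unpaired (used for opening-cost folds).
    """
    n = len(seq)
    if n == 0:
        return FoldResult("", 0, {})
    blocked = frozenset(blocked)

    def w(i: int, j: int) -> int:
        if i in blocked or j in blocked:
            return 0
        return _WEIGHTS.get((seq[i], seq[j]), 0)

    # M[i][j] = best score for seq[i..j]; row lists avoid dict overhead.
    M = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            row_i1 = M[i + 1]
            best = row_i1[j]  # i unpaired
            # i paired with some k in (i+min_loop, j]
            for k in range(i + min_loop + 1, j + 1):
                wk = w(i, k)
                if wk:
                    s = wk + (row_i1[k - 1] if k - 1 > i else 0)
                    if k + 1 <= j:
                        s += M[k + 1][j]
                    if s > best:
                        best = s
            M[i][j] = best

    # Deterministic traceback: prefer pairing i, smallest partner k on ties.
    pairs: dict[int, int] = {}
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        target = M[i][j]
        chosen = None
        for k in range(i + min_loop + 1, j + 1):
            wk = w(i, k)
            if not wk:
                continue
            s = wk + (M[i + 1][k - 1] if k - 1 > i else 0)
            if k + 1 <= j:
                s += M[k + 1][j]
            if s == target:
                chosen = k
                break
        if chosen is None:
            stack.append((i + 1, j))
        else:
            pairs[i] = chosen
            pairs[chosen] = i
            if chosen - 1 > i:
                stack.append((i + 1, chosen - 1))
            if chosen + 1 <= j:
                stack.append((chosen + 1, j))

    struct = []
    for idx in range(n):
        if idx in pairs:
            struct.append("(" if pairs[idx] > idx else ")")
        else:
            struct.append(".")
    return FoldResult("".join(struct), M[0][n - 1], pairs)


def fold_hairpin(seq: str, min_len: int = 30, max_len: int = 150,
                 min_loop: int = 3) -> FoldResult:
    """Fold a precursor-candidate window, enforcing a plausible length range.

    Precursor windows shorter than ~30 nt cannot hold a mature:star duplex
    and windows beyond 150 nt are outside the animal pre-miRNA size range, so
    both are rejected as input errors rather than folded.
    """
    if not (min_len <= len(seq) <= max_len):
        raise ConfigError(
            f"hairpin window length {len(seq)} outside [{min_len}, {max_len}]"
        )
    return fold(seq, min_loop=min_loop)
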