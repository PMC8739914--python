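"""RNA secondary-structure prediction with a pluggable engine.

The default engine is ViennaRNA's minimum-free-energy fold when its python
bindings are importable; otherwise a Nussinov-style base-pair maximization
(minimum loop 3 nt, pairs AU/UA/GC/CG/GU/UG) is used. Both return balanced
dot-bracket strings over the input length.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Protocol

_VALID = set("ACGU")
_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_LOOP = 3


def _as_rna(seq: str) -> str:
    rna = seq.upper().replace("T", "U")
    bad = set(rna) - _VALID
    if bad:
        raise ValueError(f"non-ACGU characters in sequence: {sorted(bad)}")
    return rna


class FoldEngine(Protocol):
    def fold(self, seq: str) -> tuple[str, float]:
        """Return (dot-bracket structure, score). Lower score = more stable."""


class ViennaEngine:
    """Thermodynamic MFE folding via the ViennaRNA python bindings."""

    def __init__(self) -> None:
        import RNA  # noqa: F401 — fails here if bindings absent
        self._RNA = RNA

    def fold(self, seq: str) -> tuple[str, float]:
        structure, mfe = self._RNA.fold(_as_rna(seq))
        return structure, float(mfe)


class NussinovEngine:
    """Base-pair maximization fallback.

    Score is the negated pair count so that, like free energy, lower is
    better. Traceback prefers pairing i with the largest admissible j,
    which yields the outermost-stem structure on designed hairpins.
    """

    def fold(self, seq: str) -> tuple[str, float]:
        s = _as_rna(seq)
        n = len(s)
        if n == 0:
            return "", 0.0
        dp = [[0] * n for _ in range(n)]
        for span in range(MIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = dp[i][j - 1]
                for k in range(i, j - MIN_LOOP):
                    if (s[k], s[j]) in _PAIRS:
                        left = dp[i][k - 1] if k > i else 0
                        cand = left + 1 + dp[k + 1][j - 1]
                        if cand > best:
                            best = cand
                dp[i][j] = best
        struct = ["."] * n

        def trace(i: int, j: int) -> None:
            while j > i:
                if dp[i][j] == (dp[i][j - 1] if j - 1 >= i else 0):
                    j -= 1
                    continue
                for k in range(j - MIN_LOOP - 1, i - 1, -1):
                    if (s[k], s[j]) in _PAIRS:
                        left = dp[i][k - 1] if k > i else 0
                        if left + 1 + dp[k + 1][j - 1] == dp[i][j]:
                            struct[k], struct[j] = "(", ")"
                            if k > i:
                                trace(i, k - 1)
                            i, j = k + 1, j - 1
                            break
                else:
                    j -= 1

        trace(0, n - 1)
        return "".join(struct), -float(dp[0][n - 1])


@lru_cache(maxsize=1)
def default_engine() -> FoldEngine:
    try:
        return ViennaEngine()
    except ImportError:
        return NussinovEngine()


def fold(seq: str, engine: FoldEngine | None = None) -> tuple[str, float]:
    """Fold one sequence (>= 40 nt for hairpin candidates is enforced upstream)."""
    return (engine or default_engine()).fold(seq)


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 if unpaired); raises on unbalanced input."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"bad structure character {c!r}")
    if stack:
        raise ValueError("unbalanced structure")
    return pt
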