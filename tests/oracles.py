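"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity with a deliberately different method from
the implementation it checks: full-matrix alignment over every genome
position, regex enumeration of motif variants, memoised top-down pairing
maximisation, and exhaustive matching enumeration.
"""

from __future__ import annotations

import itertools
import re
from functools import lru_cache

import numpy as np

from nanosmallrna.model import revcomp

IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "N": "ACGT"}


def exhaustive_alignment_cost(
    read: str,
    genome: str,
    mismatch: int = 2,
    insertion: int = 3,
    deletion: int = 3,
) -> tuple[float, set[tuple[int, str]]]:
    """Minimum semi-global cost of ``read`` over both strands of ``genome``.

    Full dynamic-programming matrix (no seeds, no band); genome-side end
    gaps are free.  Returns the cost and the set of optimal (end, strand)
    placements.
    """
    best = float("inf")
    ends: set[tuple[int, str]] = set()
    for strand, seq in (("+", read), ("-", revcomp(read))):
        n, m = len(seq), len(genome)
        prev = np.zeros(m + 1)
        for i in range(1, n + 1):
            cur = np.full(m + 1, np.inf)
            cur[0] = prev[0] + insertion
            sub = np.array([0 if genome[j] == seq[i - 1] else mismatch for j in range(m)])
            for j in range(1, m + 1):
                cur[j] = min(
                    prev[j - 1] + sub[j - 1],
                    prev[j] + insertion,
                    cur[j - 1] + deletion,
                )
            prev = cur
        row_best = prev.min()
        if row_best < best - 1e-9:
            best = row_best
            ends = set()
        if abs(row_best - best) < 1e-9:
            for j in range(m + 1):
                if abs(prev[j] - best) < 1e-9:
                    ends.add((j, strand))
    return best, ends


def _expand(pattern: str) -> list[str]:
    pools = [IUPAC[c] for c in pattern]
    return ["".join(p) for p in itertools.product(*pools)]


def regex_motif_positions(
    seq: str, pattern: str, max_mm: int, exact_positions: tuple[int, ...] = ()
) -> list[tuple[int, int]]:
    """Motif hits by regex enumeration of every string within the budget."""
    variants: dict[str, int] = {}
    for exact in _expand(pattern):
        positions = [p for p in range(len(pattern)) if p not in exact_positions]
        for n_mm in range(max_mm + 1):
            for mut_pos in itertools.combinations(positions, n_mm):
                pools = []
                for p, base in enumerate(exact):
                    if p in mut_pos:
                        pools.append([b for b in "ACGT" if b not in IUPAC[pattern[p]]])
                    else:
                        pools.append([base])
                for combo in itertools.product(*pools):
                    s = "".join(combo)
                    mm = sum(
                        1 for p, b in enumerate(s) if b not in IUPAC[pattern[p]]
                    )
                    if s not in variants or mm < variants[s]:
                        variants[s] = mm
    hits = []
    for s, mm in variants.items():
        for match in re.finditer(f"(?={re.escape(s)})", seq):
            hits.append((match.start(), mm))
    return sorted(set(hits))


def brute_force_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum nested WC/GU pair count by memoised top-down recursion."""
    pairable = {
        ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
    }

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        result = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in pairable:
                result = max(result, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return result

    return best(0, len(seq) - 1) if seq else 0


def brute_force_best_matching(scores: np.ndarray) -> float:
    """Maximum-weight bipartite assignment by permutation enumeration."""
    n_rows, n_cols = scores.shape
    best = 0.0
    k = min(n_rows, n_cols)
    for rows in itertools.permutations(range(n_rows), k):
        for cols in itertools.permutations(range(n_cols), k):
            total = sum(scores[r, c] for r, c in zip(rows, cols))
            best = max(best, total)
    return best
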