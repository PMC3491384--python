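"""Maximum-base-pairing secondary structure (Nussinov) with traceback.

Used for H/ACA hairpin identification.  Pairing maximisation is a desk-scale
stand-in for free-energy folding.  Because the maximum pair count is highly
degenerate, the recurrence carries an infinitesimal bonus for stacked pairs:
the returned structure still attains the exact maximum number of pairs (the
total bonus is kept below 1), but among co-optimal structures a helical one
is chosen -- scattered isolated pairs would defeat hairpin decomposition.
"""

from __future__ import annotations

PAIRABLE = {
    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
}


def can_pair(a: str, b: str) -> bool:
    return (a, b) in PAIRABLE


def max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum number of nested WC/GU pairs (no structure)."""
    return len(nussinov(seq, min_loop))


def nussinov(seq: str, min_loop: int = 3) -> list[tuple[int, int]]:
    """A maximum set of nested base pairs (WC + GU), loops >= ``min_loop``.

    Returns sorted (i, j) pairs, i < j.  Ties between co-optimal structures
    are broken towards stacked helices.
    """
    n = len(seq)
    if n < min_loop + 2:
        return []
    eps = 0.25 / n  # total stacking bonus stays < 1: pair count is exact
    NEG = float("-inf")
    # F[i][j]: best score of segment; P[i][j]: best score given (i,j) paired
    F = [[0.0] * n for _ in range(n)]
    P = [[NEG] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            if can_pair(seq[i], seq[j]):
                inner_free = F[i + 1][j - 1] if j - i > min_loop + 1 else 0.0
                best_in = inner_free
                if j - i - 2 > min_loop and P[i + 1][j - 1] > NEG:
                    best_in = max(best_in, P[i + 1][j - 1] + eps)
                P[i][j] = 1.0 + best_in
            best = F[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if P[i][k] > NEG:
                    right = F[k + 1][j] if k + 1 <= j else 0.0
                    cand = P[i][k] + right
                    if cand > best:
                        best = cand
            F[i][j] = best
    pairs: list[tuple[int, int]] = []
    tol = 1e-9
    stack: list[tuple[int, int, str]] = [(0, n - 1, "F")]
    while stack:
        i, j, state = stack.pop()
        if i >= j:
            continue
        if state == "P":
            pairs.append((i, j))
            if j - i - 2 > min_loop and P[i + 1][j - 1] > NEG:
                inner_free = F[i + 1][j - 1]
                if abs(P[i][j] - (1.0 + P[i + 1][j - 1] + eps)) < tol and (
                    P[i + 1][j - 1] + eps >= inner_free - tol
                ):
                    stack.append((i + 1, j - 1, "P"))
                    continue
            if j - i > min_loop + 1:
                stack.append((i + 1, j - 1, "F"))
            continue
        # state F
        if abs(F[i][j] - F[i + 1][j]) < tol and F[i + 1][j] >= F[i][j] - tol:
            # prefer pairing i when it is strictly better; otherwise skip i
            paired_better = False
            for k in range(j, i + min_loop, -1):
                if P[i][k] > NEG:
                    right = F[k + 1][j] if k + 1 <= j else 0.0
                    if P[i][k] + right > F[i + 1][j] + tol:
                        paired_better = True
                        break
            if not paired_better:
                stack.append((i + 1, j, "F"))
                continue
        for k in range(j, i + min_loop, -1):
            if P[i][k] > NEG:
                right = F[k + 1][j] if k + 1 <= j else 0.0
                if abs(F[i][j] - (P[i][k] + right)) < tol:
                    stack.append((i, k, "P"))
                    if k + 1 <= j:
                        stack.append((k + 1, j, "F"))
                    break
        else:
            stack.append((i + 1, j, "F"))
    return sorted(pairs)


def pair_map(pairs: list[tuple[int, int]], n: int) -> list[int]:
    """Partner array: partner[i] = j or -1."""
    partner = [-1] * n
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    return partner


def hairpins_from_pairs(
    pairs: list[tuple[int, int]], min_span: int = 25, min_pairs: int = 5
) -> list[tuple[int, int, list[tuple[int, int]]]]:
    """Decompose a nested structure into hairpin domains.

    A hairpin is grown outward from each terminal loop through enclosing
    pairs that enclose only that loop; growth stops at a pair enclosing two
    or more terminal loops (a multiloop or spurious long-range pair).
    Returns (start, end, stem pairs) per qualifying hairpin, 5' to 3'.
    """
    if not pairs:
        return []
    sorted_pairs = sorted(pairs)
    terminal = []
    for i, j in sorted_pairs:
        if not any(i < a and b < j for a, b in sorted_pairs):
            terminal.append((i, j))
    hairpins = []
    for ti, tj in terminal:
        stem = [(ti, tj)]
        cur = (ti, tj)
        while True:
            enclosing = [
                (a, b) for a, b in sorted_pairs if a < cur[0] and cur[1] < b
            ]
            if not enclosing:
                break
            a, b = max(enclosing, key=lambda p: p[0])  # innermost enclosing
            n_loops = sum(1 for x, y in terminal if a < x and y < b)
            if n_loops > 1:
                break
            stem.append((a, b))
            cur = (a, b)
        if len(stem) >= min_pairs and cur[1] - cur[0] + 1 >= min_span:
            hairpins.append((cur[0], cur[1] + 1, sorted(stem)))
    hairpins.sort()
    out = []
    for h in hairpins:
        if not out or h[0] >= out[-1][1]:
            out.append(h)
    return out
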