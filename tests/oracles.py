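"""Independent brute-force oracles used to check the implementation.

These deliberately share no code with the package: a cubic-time
exhaustive three-sequence alignment DP, a dictionary k-mer counter and
a naive sum-of-pairs scorer.
"""

from __future__ import annotations

import itertools

_COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def brute_force_kmer_counts(seqs: list[str], k: int) -> dict[str, int]:
    """Canonical k-mer counts by dictionary, both orientations."""
    out: dict[str, int] = {}
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if any(c not in "ACGT" for c in km):
                continue
            canon = min(km, rc(km))
            out[canon] = out.get(canon, 0) + 1
    return out


def _pair_cost(x: str, y: str) -> int:
    if x == "-" and y == "-":
        return 0
    if x == "-" or y == "-":
        return 1
    return 0 if x == y else 1


def sp_cost(rows: list[str]) -> int:
    """Sum-of-pairs cost of a multiple alignment (unit costs)."""
    total = 0
    for col in zip(*rows):
        for x, y in itertools.combinations(col, 2):
            total += _pair_cost(x, y)
    return total


def optimal_msa3_cost(a: str, b: str, c: str) -> int:
    """Exhaustive 3-sequence alignment DP: minimal sum-of-pairs cost."""
    la, lb, lc = len(a), len(b), len(c)
    INF = 10**9
    dp = [[[INF] * (lc + 1) for _ in range(lb + 1)] for _ in range(la + 1)]
    dp[0][0][0] = 0
    moves = [m for m in itertools.product((0, 1), repeat=3) if any(m)]
    for i in range(la + 1):
        for j in range(lb + 1):
            for k in range(lc + 1):
                cur = dp[i][j][k]
                if cur == INF:
                    continue
                for da, db, dc in moves:
                    ni, nj, nk = i + da, j + db, k + dc
                    if ni > la or nj > lb or nk > lc:
                        continue
                    col = (
                        a[i] if da else "-",
                        b[j] if db else "-",
                        c[k] if dc else "-",
                    )
                    cost = (
                        _pair_cost(col[0], col[1])
                        + _pair_cost(col[0], col[2])
                        + _pair_cost(col[1], col[2])
                    )
                    if cur + cost < dp[ni][nj][nk]:
                        dp[ni][nj][nk] = cur + cost
    return dp[la][lb][lc]
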