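"""Independent reference implementations used only to check the package.

These deliberately share no code with ``npnamematch``: the Gestalt oracle
is a direct recursive transcription of the algorithm, and the Levenshtein
oracle fills the full DP matrix.
"""

from __future__ import annotations


def brute_force_gestalt(x: str, y: str) -> float:
    """Recursive Ratcliff-Obershelp similarity, written independently."""

    def longest(a: str, b: str) -> tuple[int, int, int]:
        # all (i, j) start pairs, longest first, ties by smallest i then j
        best = (0, 0, 0)  # i, j, length
        for i in range(len(a)):
            for j in range(len(b)):
                n = 0
                while i + n < len(a) and j + n < len(b) and a[i + n] == b[j + n]:
                    n += 1
                if n > best[2]:
                    best = (i, j, n)
        return best

    def matched(a: str, b: str) -> int:
        if not a or not b:
            return 0
        i, j, n = longest(a, b)
        if n == 0:
            return 0
        return n + matched(a[:i], b[:j]) + matched(a[i + n :], b[j + n :])

    return 2.0 * matched(x, y) / (len(x) + len(y))


def full_matrix_levenshtein(x: str, y: str) -> int:
    """Classic full-matrix edit-distance DP."""
    m, n = len(x), len(y)
    D = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        D[i][0] = i
    for j in range(n + 1):
        D[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            D[i][j] = min(
                D[i - 1][j] + 1,
                D[i][j - 1] + 1,
                D[i - 1][j - 1] + (x[i - 1] != y[j - 1]),
            )
    return D[m][n]
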