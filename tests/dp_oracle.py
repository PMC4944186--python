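"""Independent brute-force affine-gap DP used as the alignment score oracle.

Deliberately written as a plain dense three-layer recurrence over python
lists, sharing no code with the package's aligner.
"""

NEG = -(10**9)


def oracle_score(a: str, b: str, match: int, mismatch: int, open_: int, ext: int,
                 local: bool) -> int:
    m, n = len(a), len(b)
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0
    for j in range(1, n + 1):
        E[0][j] = max(E[0][j - 1] - ext, H[0][j - 1] - open_ - ext)
        H[0][j] = 0 if local else E[0][j]
    for i in range(1, m + 1):
        F[i][0] = max(F[i - 1][0] - ext, H[i - 1][0] - open_ - ext)
        H[i][0] = 0 if local else F[i][0]
        for j in range(1, n + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else -mismatch
            E[i][j] = max(E[i][j - 1] - ext, H[i][j - 1] - open_ - ext)
            F[i][j] = max(F[i - 1][j] - ext, H[i - 1][j] - open_ - ext)
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if local and H[i][j] < 0:
                H[i][j] = 0
    if local:
        return max(max(row) for row in H)
    return H[m][n]
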