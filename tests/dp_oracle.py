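"""Independent exhaustive dynamic-programming oracles used only by tests.

Deliberately separate from the package's alignment code: a plain
Smith-Waterman / Needleman-Wunsch with affine gaps implemented from the
recurrences, against which the package's seed-and-extend results and
pairwise identities are checked.
"""

import numpy as np

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 1, -2, -4, -1
NEG = -10**9


def sw_max_score(query: str, target: str) -> int:
    """Best local alignment score (affine gaps), vectorised over the target."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    m = len(t)
    h_prev = np.zeros(m + 1)
    e_prev = np.full(m + 1, float(NEG))
    best = 0.0
    for qi in range(len(q)):
        sub = np.where(t == q[qi], MATCH, MISMATCH)
        e = np.maximum(h_prev + GAP_OPEN, e_prev + GAP_EXT)  # gap in query
        h = np.zeros(m + 1)
        f = float(NEG)  # gap in target, scalar carried along the row
        for tj in range(1, m + 1):
            f = max(h[tj - 1] + GAP_OPEN, f + GAP_EXT)
            h[tj] = max(0.0, h_prev[tj - 1] + sub[tj - 1], e[tj], f)
        best = max(best, h.max())
        h_prev, e_prev = h, e
    return int(best)


def sw_align(query: str, target: str):
    """Full Smith-Waterman with traceback; returns (score, identity, columns).

    Quadratic in memory; only for small test instances.
    """
    n, m = len(query), len(target)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), float(NEG))
    F = np.full((n + 1, m + 1), float(NEG))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + GAP_OPEN, E[i, j - 1] + GAP_EXT)
            F[i, j] = max(H[i - 1, j] + GAP_OPEN, F[i - 1, j] + GAP_EXT)
            s = MATCH if query[i - 1] == target[j - 1] else MISMATCH
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
    i, j = np.unravel_index(np.argmax(H), H.shape)
    score = H[i, j]
    matches = mismatches = gaps = 0
    state = "H"
    while H[i, j] > 0 if state == "H" else True:
        if state == "H":
            if H[i, j] == 0:
                break
            s = MATCH if query[i - 1] == target[j - 1] else MISMATCH
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                matches += query[i - 1] == target[j - 1]
                mismatches += query[i - 1] != target[j - 1]
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            gaps += 1
            if E[i, j] == H[i, j - 1] + GAP_OPEN:
                state = "H"
            j -= 1
        else:
            gaps += 1
            if F[i, j] == H[i - 1, j] + GAP_OPEN:
                state = "H"
            i -= 1
    columns = matches + mismatches + gaps
    identity = matches / columns if columns else 0.0
    return int(score), identity, columns


def nw_identity(a: str, b: str) -> float:
    """Global alignment identity = matches / columns, affine gaps."""
    n, m = len(a), len(b)
    H = np.full((n + 1, m + 1), float(NEG))
    E = np.full((n + 1, m + 1), float(NEG))
    F = np.full((n + 1, m + 1), float(NEG))
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = GAP_OPEN + GAP_EXT * (j - 1)
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = GAP_OPEN + GAP_EXT * (i - 1)
        H[i, 0] = F[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + GAP_OPEN, E[i, j - 1] + GAP_EXT)
            F[i, j] = max(H[i - 1, j] + GAP_OPEN, F[i - 1, j] + GAP_EXT)
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            H[i, j] = max(H[i - 1, j - 1] + s, E[i, j], F[i, j])
    # traceback for identity
    i, j = n, m
    matches = columns = 0
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            s = MATCH if i > 0 and j > 0 and a[i - 1] == b[j - 1] else MISMATCH
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                matches += a[i - 1] == b[j - 1]
                columns += 1
                i, j = i - 1, j - 1
            elif j > 0 and H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i, j] == H[i, j - 1] + GAP_OPEN:
                state = "H"
            j -= 1
        else:
            columns += 1
            if F[i, j] == H[i - 1, j] + GAP_OPEN:
                state = "H"
            i -= 1
    return matches / columns
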