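"""Independent brute-force reference implementations used only by tests.

Everything here is written in plain Python loops against the definitions,
deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math

AA = "ACDEFGHIKLMNPQRSTVWY"


def naive_identity(a: str, b: str) -> float:
    both = same = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        both += 1
        if x == y and x in AA:
            same += 1
    return same / both if both else 0.0


def naive_weights(seqs: list[str], threshold: float = 0.80) -> list[float]:
    out = []
    for a in seqs:
        neighborhood = sum(1 for b in seqs if naive_identity(a, b) > threshold)
        out.append(1.0 / max(neighborhood, 1))
    return out


def naive_pair_counts(seqs, query_idx, weights, i, j, alphabet):
    """Weighted joint state counts for 1-based columns i, j; returns
    (joint dict, n_eff)."""
    query = seqs[query_idx]
    joint: dict[tuple, float] = {}
    n_eff = 0.0
    for seq, w in zip(seqs, weights):
        a, b = seq[i - 1], seq[j - 1]
        if a in "-X" or b in "-X":
            continue
        n_eff += w
        if alphabet == "2-letter":
            state = (int(a == query[i - 1]), int(b == query[j - 1]))
        else:
            state = (a, b)
        joint[state] = joint.get(state, 0.0) + w
    return joint, n_eff


def _probs(joint, n_eff, alphabet):
    denom = n_eff + 1.0
    if alphabet == "2-letter":
        xs = ys = [0, 1]
    else:
        xs = ys = list(AA)
    p = {(x, y): joint.get((x, y), 0.0) / denom for x in xs for y in ys}
    px = {x: sum(p[(x, y)] for y in ys) for x in xs}
    py = {y: sum(p[(x, y)] for x in xs) for y in ys}
    return p, px, py, xs, ys


def naive_mi(seqs, query_idx, weights, i, j, alphabet="2-letter"):
    joint, n_eff = naive_pair_counts(seqs, query_idx, weights, i, j, alphabet)
    if n_eff == 0:
        return None
    p, px, py, xs, ys = _probs(joint, n_eff, alphabet)
    total = 0.0
    for x in xs:
        for y in ys:
            if p[(x, y)] > 0:
                total += p[(x, y)] * math.log(p[(x, y)] / (px[x] * py[y]))
    return total


def naive_chi2(seqs, query_idx, weights, i, j, alphabet="2-letter"):
    joint, n_eff = naive_pair_counts(seqs, query_idx, weights, i, j, alphabet)
    if n_eff == 0:
        return None
    p, px, py, xs, ys = _probs(joint, n_eff, alphabet)
    total = 0.0
    for x in xs:
        for y in ys:
            expected = px[x] * py[y]
            if expected > 0:
                total += (p[(x, y)] - expected) ** 2 / expected
    return total


def chi2_cdf_df1(x: float) -> float:
    """Closed-form chi-squared(df=1) lower-tail CDF: erf(sqrt(x/2))."""
    return math.erf(math.sqrt(x / 2.0))


def naive_pearson(seqs, weights, i, j, score):
    """|r| oracle; ``score(pos, aa)`` looks up the PSSM value (1-based pos)."""
    rows = [
        (score(i, s[i - 1]), score(j, s[j - 1]), w)
        for s, w in zip(seqs, weights)
        if s[i - 1] not in "-X" and s[j - 1] not in "-X"
    ]
    if not rows:
        return None
    n_eff = sum(w for _, _, w in rows)
    mx = sum(w * x for x, _, w in rows) / n_eff
    my = sum(w * y for _, y, w in rows) / n_eff
    sx = math.sqrt(sum(w * (x - mx) ** 2 for x, _, w in rows) / n_eff)
    sy = math.sqrt(sum(w * (y - my) ** 2 for _, y, w in rows) / n_eff)
    if sx == 0 or sy == 0:
        return None
    r = sum(w * (x - mx) * (y - my) for x, y, w in rows) / (n_eff * sx * sy)
    return abs(max(-1.0, min(1.0, r)))


def brute_force_maximal_cliques(nodes, edges, min_size=2):
    """All maximal cliques by exhaustive subset enumeration (<= ~15 nodes)."""
    nodes = list(nodes)
    edge_set = {frozenset(e) for e in edges}

    def complete(subset):
        return all(
            frozenset((a, b)) in edge_set for a, b in itertools.combinations(subset, 2)
        )

    cliques = []
    for r in range(min_size, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if complete(subset):
                cliques.append(set(subset))
    maximal = [
        tuple(sorted(c))
        for c in cliques
        if not any(c < other for other in cliques)
    ]
    maximal.sort(key=lambda c: (-len(c), c))
    return maximal


def lasso_cd(Q, b, rho, n_iter=5000, tol=1e-13):
    """Coordinate descent for 1/2 x'Qx - b'x + rho*||x||_1 (lists of lists)."""
    p = len(b)
    x = [0.0] * p
    for _ in range(n_iter):
        delta = 0.0
        for k in range(p):
            r = b[k] - sum(Q[k][m] * x[m] for m in range(p)) + Q[k][k] * x[k]
            new = math.copysign(max(abs(r) - rho, 0.0), r) / Q[k][k]
            delta = max(delta, abs(new - x[k]))
            x[k] = new
        if delta < tol:
            break
    return x


def glasso_oracle(S, rho, n_sweeps=1000, tol=1e-13):
    """Block coordinate-descent graphical lasso (diagonal unpenalized).

    Returns (W, Theta) as lists of lists; independent of any solver library.
    """
    p = len(S)
    W = [row[:] for row in S]
    B = [[0.0] * p for _ in range(p)]
    for _ in range(n_sweeps):
        W_old = [row[:] for row in W]
        for j in range(p):
            idx = [k for k in range(p) if k != j]
            W11 = [[W[a][b] for b in idx] for a in idx]
            s12 = [S[a][j] for a in idx]
            beta = lasso_cd(W11, s12, rho)
            w12 = [sum(W11[a][b] * beta[b] for b in range(p - 1)) for a in range(p - 1)]
            for a, k in enumerate(idx):
                W[k][j] = W[j][k] = w12[a]
                B[k][j] = beta[a]
        if max(abs(W[a][b] - W_old[a][b]) for a in range(p) for b in range(p)) < tol:
            break
    Theta = [[0.0] * p for _ in range(p)]
    for j in range(p):
        idx = [k for k in range(p) if k != j]
        tjj = 1.0 / (W[j][j] - sum(W[k][j] * B[k][j] for k in idx))
        Theta[j][j] = tjj
        for k in idx:
            Theta[k][j] = -B[k][j] * tjj
    for a in range(p):
        for b in range(a + 1, p):
            avg = (Theta[a][b] + Theta[b][a]) / 2.0
            Theta[a][b] = Theta[b][a] = avg
    return W, Theta
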