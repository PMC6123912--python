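"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written as plain loops over definitions,
sharing no code path with the package internals it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def _mm(a: str, b: str) -> int:
    """Hamming distance with N mismatching everything."""
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def align_oracle(r: str, s: str, d_th: float, o_th: int):
    """Exhaustive scan over every read placement against a representative.

    Returns (mode, offset, n, d) with mode in {complete, partial_left,
    partial_right, contained, none}.  Complete placements are preferred
    (smallest distance, then smallest offset); otherwise the widest overlap
    wins, ties broken by smaller distance, then the fixed mode order
    left < right < contained, then the smallest containment offset.
    """
    m, l = len(r), len(s)
    completes = []
    partials = []
    if m >= o_th:
        for a in range(-(m - 1), l):
            lo, hi = max(a, 0), min(a + m, l)
            n = hi - lo
            if n < o_th:
                continue
            d = _mm(r[lo - a:hi - a], s[lo:hi])
            if d > int(n * d_th):
                continue
            if a >= 0 and a + m <= l:
                completes.append((d, a))
            elif a < 0 and a + m <= l:
                partials.append((-n, d, 0, a))          # partial_left
            elif a >= 0 and a + m > l:
                partials.append((-n, d, 1, a))          # partial_right
            else:
                partials.append((-n, d, 2, -a))         # contained, key: pos
    if completes:
        d, a = min(completes)
        return "complete", a, m, d
    if partials:
        negn, d, rank, key = min(partials)
        mode = ("partial_left", "partial_right", "contained")[rank]
        offset = key if rank != 2 else -key
        return mode, offset, -negn, d
    return "none", 0, 0, 0


def enumerate_paths_oracle(edges: list[tuple[int, int]], nodes: list[int]):
    """All maximal source-to-sink paths, recursively, with the loop rule
    applied at emission: no node more than twice, at most two distinct
    nodes repeated."""
    succ = {n: sorted(v for u, v in edges if u == n) for n in nodes}
    indeg = {n: sum(1 for u, v in edges if v == n) for n in nodes}
    out = []

    def rec(path):
        node = path[-1]
        if not succ[node]:
            counts = {}
            for n in path:
                counts[n] = counts.get(n, 0) + 1
            if max(counts.values()) <= 2 and \
                    sum(1 for c in counts.values() if c > 1) <= 2:
                out.append(tuple(path))
            return
        for nxt in succ[node]:
            if path.count(nxt) >= 2:   # cannot be emitted anyway; terminates
                continue
            rec(path + [nxt])

    for s in sorted(n for n in nodes if indeg[n] == 0):
        rec([s])
    return out


def nn_lasso_qp_oracle(y: np.ndarray, A: np.ndarray, lam: float) -> np.ndarray:
    """Solve min ||y-Ax||^2 + lam*sum(x), x >= 0 as a bound-constrained QP."""
    n = A.shape[1]

    def f(x):
        r = y - A @ x
        return float(r @ r + lam * x.sum())

    def grad(x):
        return -2.0 * A.T @ (y - A @ x) + lam

    res = minimize(f, np.zeros(n), jac=grad, method="L-BFGS-B",
                   bounds=[(0.0, None)] * n,
                   options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
    return res.x


def union_find_components(n_items: list[int], links: list[tuple[int, int]]):
    """Plain union-find; returns a frozenset of frozenset components."""
    parent = {i: i for i in n_items}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in links:
        parent[find(a)] = find(b)
    comps: dict[int, set[int]] = {}
    for i in n_items:
        comps.setdefault(find(i), set()).add(i)
    return frozenset(frozenset(c) for c in comps.values())


def random_related_pair(rng: np.random.Generator, *, min_len=30, max_len=200):
    """A (read, representative) pair that may share a mutated overlap, plus
    unrelated cases; exercises all alignment modes."""
    bases = "ACGT"

    def rand(n):
        return "".join(bases[i] for i in rng.integers(0, 4, n))

    l = int(rng.integers(min_len, max_len))
    m = int(rng.integers(min_len, max_len))
    s = rand(l)
    kind = rng.integers(0, 4)
    if kind == 0:          # unrelated
        r = rand(m)
    elif kind == 1:        # read from inside s (complete-ish)
        m = min(m, l)
        a = int(rng.integers(0, l - m + 1))
        r = s[a:a + m]
    elif kind == 2:        # dovetail overlap
        n = int(rng.integers(5, min(m, l)))
        if rng.random() < 0.5:
            r = rand(m - n) + s[:n]
        else:
            r = s[l - n:] + rand(m - n)
    else:                  # read containing s
        if m <= l:
            m = l + int(rng.integers(1, 20))
        pad = m - l
        p = int(rng.integers(0, pad + 1))
        r = rand(p) + s + rand(pad - p)
    # sprinkle substitutions
    r = list(r)
    for i in range(len(r)):
        if rng.random() < 0.02:
            r[i] = bases[int(rng.integers(0, 4))]
    return "".join(r), s
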