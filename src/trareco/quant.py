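"""Joint isoform detection and abundance estimation on splicing graphs.

Candidate isoforms are the maximal paths of the compacted graph (source =
in-degree-0 node, sink = out-degree-0 node).  Cycles caused by sequence
repeats are handled by letting a node be included twice; paths where any
node appears more than twice, or where more than two distinct nodes repeat,
are discarded.  Abundances are estimated jointly by a non-negative
L1-penalized least-squares fit of the path inclusion matrix A to the vector
of per-node mean coverage depths y:

    min ||y - A x||^2 + lambda * ||x||_1   subject to x >= 0,

solved by cyclic coordinate descent with non-negative soft-thresholding.
Candidates shorter than L_th or with an estimated depth below CD_th are
dropped; depths convert to RPKM as 1e9 * depth / (read_len * library_reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .graph import SplicingGraph

logger = logging.getLogger(__name__)


@dataclass
class PathCandidate:
    """A maximal path: node sequence (repeats allowed), reconstructed
    sequence and node-multiplicity (inclusion) vector."""

    nodes: tuple[int, ...]
    seq: str
    group_id: int = 0

    @property
    def length(self) -> int:
        return len(self.seq)

    def inclusion(self, order: list[int]) -> np.ndarray:
        vec = np.zeros(len(order), dtype=np.int64)
        pos = {n: i for i, n in enumerate(order)}
        for n in self.nodes:
            vec[pos[n]] += 1
        return vec


@dataclass
class IsoformReport:
    candidate_id: str
    group_id: int
    length: int
    depth: float
    rpkm: float
    nodes: tuple[int, ...]
    seq: str


def enumerate_paths(G: SplicingGraph, max_paths: int = 10_000) -> list[PathCandidate]:
    """Depth-first enumeration of maximal paths with the loopy-graph caps:
    no node more than twice, at most two distinct nodes repeated.

    Aborts with a warning once ``max_paths`` paths have been collected.
    """
    if G.n_nodes == 0:
        return []
    sources = sorted(n for n in G.g.nodes if G.g.in_degree(n) == 0)
    paths: list[PathCandidate] = []
    truncated = False

    def dfs(node: int, path: list[int], counts: dict[int, int], repeated: int) -> bool:
        if len(paths) >= max_paths:
            return False
        succs = sorted(G.g.successors(node))
        if not succs:
            seq = "".join(G.data[n].rep_str() for n in path)
            paths.append(PathCandidate(tuple(path), seq, G.group_id))
            return True
        for nxt in succs:
            c = counts.get(nxt, 0)
            if c >= 2:
                continue  # a node may be included at most twice
            rep = repeated + (1 if c == 1 else 0)
            if rep > 2:
                continue  # at most two distinct nodes may repeat
            counts[nxt] = c + 1
            path.append(nxt)
            ok = dfs(nxt, path, counts, rep)
            path.pop()
            counts[nxt] = c
            if not ok:
                return False
        return True

    for s in sources:
        if not dfs(s, [s], {s: 1}, 0):
            truncated = True
            break
    if truncated:
        logger.warning("path enumeration aborted at max_paths=%d", max_paths)
    return paths


def path_gaps(path: PathCandidate, node_len: dict[int, int]):
    """Yield (u, v, gap) for every ordered node pair on the path, where gap
    is the number of bases strictly between u's end and v's start."""
    offs = np.cumsum([0] + [node_len[n] for n in path.nodes])
    for i in range(len(path.nodes)):
        for j in range(i + 1, len(path.nodes)):
            yield path.nodes[i], path.nodes[j], int(offs[j] - offs[i + 1])


def pair_filter(paths: list[PathCandidate],
                mate_pairs: list[tuple[int, int]],
                node_len: dict[int, int] | None = None,
                reach: float | None = None,
                min_node_len: int = 0) -> list[PathCandidate]:
    """Remove paths incompatible with the observed paired-end placements.

    Observed mate pairs define which node pairs genuinely co-occur on a
    transcript.  A path is dropped when two of its nodes (each at least
    ``min_node_len`` long) sit within ``reach`` bases of each other along the
    path but no mate pair ever linked them: a fragment of the sequenced
    library would have spanned that stretch, so its absence marks the path
    as a spurious combination of real junctions.  Single-end data (no mate
    pairs) leaves the path set unchanged.
    """
    if not mate_pairs or not paths:
        return list(paths)
    if node_len is None or reach is None:
        return list(paths)
    evidence = {frozenset(p) for p in mate_pairs}
    kept = []
    for path in paths:
        ok = True
        for u, v, gap in path_gaps(path, node_len):
            if u == v:
                continue
            if node_len[u] < min_node_len or node_len[v] < min_node_len:
                continue
            if gap <= reach and frozenset((u, v)) not in evidence:
                ok = False
                break
        if ok:
            kept.append(path)
    logger.info("pair filter: %d -> %d paths", len(paths), len(kept))
    return kept


def inclusion_matrix(G: SplicingGraph, paths: list[PathCandidate],
                     order: list[int] | None = None) -> np.ndarray:
    """|N| x |Pi| matrix; entry (i, j) counts inclusions of node i in path j."""
    order = order if order is not None else sorted(G.g.nodes)
    if not paths:
        return np.zeros((len(order), 0), dtype=np.int64)
    return np.stack([p.inclusion(order) for p in paths], axis=1)


def nn_lasso(y: np.ndarray, A: np.ndarray, lam: float,
             tol: float = 1e-8, max_sweeps: int = 10_000) -> np.ndarray:
    """Non-negative lasso min ||y - Ax||^2 + lam*||x||_1, x >= 0, by cyclic
    coordinate descent with non-negative soft-thresholding.

    Deterministic (zero initialization, fixed coordinate order); the
    objective is non-increasing per sweep and the result satisfies the KKT
    conditions within tolerance.
    """
    y = np.asarray(y, dtype=float)
    A = np.asarray(A, dtype=float)
    if not (np.isfinite(y).all() and np.isfinite(A).all() and np.isfinite(lam)):
        raise ValueError("non-finite inputs")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n_paths = A.shape[1]
    x = np.zeros(n_paths)
    if n_paths == 0:
        return x
    AtA = A.T @ A
    Aty = A.T @ y
    diag = np.diag(AtA).copy()
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(n_paths):
            if diag[j] == 0.0:
                continue
            # gradient of ||y-Ax||^2 wrt x_j is -2(Aty - AtA x)_j
            rho = Aty[j] - AtA[j] @ x + diag[j] * x[j]
            new = max(0.0, (rho - lam / 2.0) / diag[j])
            delta = max(delta, abs(new - x[j]))
            x[j] = new
        if delta < tol:
            break
    return x


def kkt_residual(y: np.ndarray, A: np.ndarray, lam: float,
                 x: np.ndarray) -> float:
    """Max violation of the KKT conditions of the non-negative lasso at x."""
    g = -2.0 * (A.T @ (y - A @ x)) + lam
    active = x > 0
    res = 0.0
    if active.any():
        res = float(np.abs(g[active]).max())
    if (~active).any():
        res = max(res, float(np.maximum(0.0, -g[~active]).max()))
    return res


def lasso_objective(y: np.ndarray, A: np.ndarray, lam: float,
                    x: np.ndarray) -> float:
    r = y - A @ x
    return float(r @ r + lam * np.abs(x).sum())


def to_rpkm(depth: float, read_len: float, library_reads: int) -> float:
    """Reads per kilobase per million: 1e9 * depth / (read_len * N)."""
    if read_len <= 0 or library_reads <= 0:
        raise ValueError("read_len and library_reads must be positive")
    return 1e9 * depth / (read_len * library_reads)


def select_candidates(paths: list[PathCandidate], x: np.ndarray,
                      l_th: int = 200, cd_th: float = 0.0,
                      read_len: float = 100.0,
                      library_reads: int = 1_000_000) -> list[IsoformReport]:
    """Emit candidates with length >= L_th and estimated depth >= CD_th
    (CD_th = 0 keeps every positive-abundance path)."""
    out = []
    for k, (path, depth) in enumerate(zip(paths, x)):
        if depth <= 0 or depth < cd_th or path.length < l_th:
            continue
        out.append(IsoformReport(
            candidate_id=f"trc_{path.group_id}_{k}",
            group_id=path.group_id,
            length=path.length,
            depth=float(depth),
            rpkm=to_rpkm(float(depth), read_len, library_reads),
            nodes=path.nodes,
            seq=path.seq,
        ))
    return out
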