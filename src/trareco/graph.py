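"""Junction search between contigs and splicing-graph construction.

A junction is evidence that a prefix or suffix of one contig aligns *inside*
another: the chimeric reads spanning two consecutive exons put the shared
exon at the end of one contig and in the middle of another, so the inner end
of the aligned prefix/suffix marks the exon boundary.  Contigs linked by
junctions form groups (one group per putative gene); oversized groups are
decomposed by iteratively invalidating the weakest junction.  Each group's
contigs are then cut at the junction boundaries, equivalent segments are
unified into shared nodes, and consecutive segments are connected by
directed edges, yielding a splicing graph (possibly cyclic when a repeat
longer than the junction threshold is present).  The graph is finally
compacted so that no singly-connected node pair remains.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .assembly import Contig, pigeonhole_word, _kmer_codes
from .consensus import ConsensusProfile, N_CODE, revcomp

logger = logging.getLogger(__name__)

PREFIX = "prefix"
SUFFIX = "suffix"


@dataclass(frozen=True)
class Junction:
    """A prefix/suffix of contig ``src`` aligned inside contig ``dst``."""

    jid: int
    src: int
    dst: int
    side: str              # which end of src aligned: PREFIX or SUFFIX
    overlap: int           # aligned width n
    mismatches: int
    dst_start: int         # aligned region on dst: [dst_start, dst_start+n)
    src_rc: bool = False   # src was reverse-complemented for this alignment

    @property
    def src_span(self) -> tuple[int, int]:
        raise NotImplementedError  # needs src length; see spans()

    def spans(self, src_len: int) -> tuple[tuple[int, int], tuple[int, int]]:
        """((src_start, src_end), (dst_start, dst_end)) of the aligned region."""
        if self.side == PREFIX:
            s = (0, self.overlap)
        else:
            s = (src_len - self.overlap, src_len)
        return s, (self.dst_start, self.dst_start + self.overlap)

    def boundary_on_src(self, src_len: int) -> int:
        """Inner end of the aligned prefix/suffix on the source contig."""
        return self.overlap if self.side == PREFIX else src_len - self.overlap

    def boundary_on_dst(self) -> int:
        """Implied junction point on the destination contig."""
        if self.side == PREFIX:
            return self.dst_start + self.overlap
        return self.dst_start


@dataclass
class ContigGroup:
    """Contigs linked together by valid junctions (one putative gene)."""

    contig_ids: list[int]
    junctions: list[Junction]


def _budget_per_n(max_n: int, d_th: float) -> np.ndarray:
    return (np.arange(1, max_n + 1) * d_th).astype(np.int64)


def _best_internal_prefix(q: np.ndarray, t: np.ndarray, j_th: int,
                          d_th: float) -> tuple[int, int, int] | None:
    """Widest alignment of a strict prefix of ``q`` inside ``t``.

    Returns ``(a, n, d)`` maximizing n (ties: smallest a), with
    ``mismatches(q[:n], t[a:a+n]) <= floor(n*d_th)`` and ``j_th <= n < len(q)``,
    or None.
    """
    lq, lt = q.shape[0], t.shape[0]
    L = min(lq - 1, lt)
    if L < j_th or lt < j_th:
        return None
    pad = np.full(L, N_CODE, dtype=np.int8)  # N mismatches everything
    tpad = np.concatenate([t, pad])
    win = np.lib.stride_tricks.sliding_window_view(tpad, L)[:lt - j_th + 1]
    qq = q[:L]
    bad = (win != qq[None, :]) | (win == N_CODE) | (qq[None, :] == N_CODE)
    cum = np.cumsum(bad, axis=1)
    budget = _budget_per_n(L, d_th)
    ok = cum <= budget[None, :]
    # overlap may not run past the end of t
    a_idx = np.arange(ok.shape[0])
    n_idx = np.arange(1, L + 1)
    ok &= (a_idx[:, None] + n_idx[None, :]) <= lt
    ok[:, :j_th - 1] = False
    if not ok.any():
        return None
    n_per_a = np.where(ok.any(axis=1), L - np.argmax(ok[:, ::-1], axis=1), 0)
    a = int(np.argmax(n_per_a))  # first max -> smallest a
    n = int(n_per_a[a])
    return a, n, int(cum[a, n - 1])


def _best_internal(q: np.ndarray, t: np.ndarray, side: str, j_th: int,
                   d_th: float) -> tuple[int, int, int] | None:
    """Widest internal alignment of q's prefix or suffix inside t."""
    if side == PREFIX:
        return _best_internal_prefix(q, t, j_th, d_th)
    hit = _best_internal_prefix(q[::-1], t[::-1], j_th, d_th)
    if hit is None:
        return None
    a_r, n, d = hit
    return t.shape[0] - a_r - n, n, d


def find_junctions(pool: list[Contig], j_th: int = 24, d_th: float = 0.06,
                   both_strands: bool = True) -> list[Junction]:
    """Search every ordered contig pair for prefix/suffix-inside alignments
    of width >= J_th within the distance margin.

    A w-mer prescreen (pigeonhole word for J_th) skips unrelated pairs.  For
    each (pair, side) the single widest alignment is kept, preferring the
    forward orientation on ties.
    """
    w = pigeonhole_word(j_th, d_th)
    reps = {c.id: c.rep() for c in pool}
    words = {cid: set(_kmer_codes(rep, w).tolist()) for cid, rep in reps.items()}
    words_rc = {cid: set(_kmer_codes(revcomp(rep), w).tolist())
                for cid, rep in reps.items()}
    out: list[Junction] = []
    jid = 0
    for a_c, b_c in itertools.permutations(sorted(reps), 2):
        share_f = not words[a_c].isdisjoint(words[b_c])
        share_r = both_strands and not words_rc[a_c].isdisjoint(words[b_c])
        if not (share_f or share_r):
            continue
        orients = [(False, reps[a_c])]
        if share_r:
            orients.append((True, revcomp(reps[a_c])))
        for side in (PREFIX, SUFFIX):
            best: tuple[int, int, int, bool, int] | None = None
            for rc, q in orients:
                if rc and not share_r:
                    continue
                if not rc and not share_f:
                    continue
                hit = _best_internal(q, reps[b_c], side, j_th, d_th)
                if hit is None:
                    continue
                a0, n, d = hit
                key = (-n, d, rc)
                if best is None or key < (-best[1], best[2], best[3]):
                    best = (a0, n, d, rc, 0)
            if best is not None:
                a0, n, d, rc, _ = best
                out.append(Junction(jid, a_c, b_c, side, n, d, a0, rc))
                jid += 1
    logger.info("junctions: %d found among %d contigs", len(out), len(pool))
    return out


def group_contigs(pool: list[Contig], junctions: list[Junction]) -> list[ContigGroup]:
    """Connected components of the contig-junction graph; singletons included."""
    g = nx.Graph()
    g.add_nodes_from(c.id for c in pool)
    for j in junctions:
        g.add_edge(j.src, j.dst)
    groups = []
    for comp in sorted(nx.connected_components(g), key=min):
        ids = sorted(comp)
        idset = set(ids)
        js = [j for j in junctions if j.src in idset]
        groups.append(ContigGroup(ids, js))
    return groups


def filter_junctions_by_group_size(group: ContigGroup,
                                   max_size: int = 40) -> list[ContigGroup]:
    """Iteratively invalidate the smallest-overlap junction (ties: larger
    mismatch count, then lower id) until every component has <= max_size
    contigs."""
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    junctions = list(group.junctions)
    while True:
        g = nx.Graph()
        g.add_nodes_from(group.contig_ids)
        for j in junctions:
            g.add_edge(j.src, j.dst, )
        comps = sorted(nx.connected_components(g), key=min)
        oversized = [c for c in comps if len(c) > max_size]
        if not oversized:
            break
        big = set().union(*oversized)
        pool_js = [j for j in junctions if j.src in big and j.dst in big]
        victim = min(pool_js, key=lambda j: (j.overlap, -j.mismatches, j.jid))
        junctions.remove(victim)
    out = []
    for comp in comps:
        ids = sorted(comp)
        idset = set(ids)
        out.append(ContigGroup(ids, [j for j in junctions
                                     if j.src in idset and j.dst in idset]))
    return out


def resolve_strands(group: ContigGroup, contigs: dict[int, Contig],
                    j_th: int, d_th: float) -> ContigGroup:
    """Assign a consistent strand to every contig of a group.

    BFS over the junction relation propagates flips (a reverse-complement
    junction means the two contigs are on opposite strands); junctions whose
    parity contradicts the assignment are dropped.  Flipped contigs'
    profiles and placements are mirrored in place, and junctions are then
    recomputed forward-only so all coordinates refer to the final strands.
    """
    if not any(j.src_rc for j in group.junctions):
        return group
    adj: dict[int, list[tuple[int, bool]]] = {c: [] for c in group.contig_ids}
    for j in group.junctions:
        adj[j.src].append((j.dst, j.src_rc))
        adj[j.dst].append((j.src, j.src_rc))
    flip: dict[int, bool] = {}
    for root in group.contig_ids:
        if root in flip:
            continue
        flip[root] = False
        queue = [root]
        while queue:
            u = queue.pop(0)
            for v, rc in adj[u]:
                want = flip[u] ^ rc
                if v not in flip:
                    flip[v] = want
                    queue.append(v)
                # contradictions are resolved implicitly: the junction will
                # not reappear in the forward-only re-search below
    for cid, fl in flip.items():
        if fl:
            contigs[cid].flip()
    sub = [contigs[c] for c in group.contig_ids]
    js = find_junctions(sub, j_th, d_th, both_strands=False)
    return ContigGroup(group.contig_ids, js)


@dataclass
class NodeData:
    profile: ConsensusProfile
    label: str

    @property
    def length(self) -> int:
        return self.profile.length

    @property
    def v(self) -> np.ndarray:
        return self.profile.coverage()

    @property
    def y(self) -> float:
        return self.profile.mean_depth()

    def rep_str(self) -> str:
        return self.profile.rep_str()


class SplicingGraph:
    """Directed graph of segments; cycles permitted; minimal after compaction."""

    def __init__(self, group_id: int = 0):
        self.group_id = group_id
        self.g = nx.DiGraph()
        self.data: dict[int, NodeData] = {}
        # per contig: ordered (start, end, node_id) in final contig coordinates
        self.seg_map: dict[int, list[tuple[int, int, int]]] = {}

    def add_node(self, nid: int, data: NodeData) -> None:
        self.g.add_node(nid)
        self.data[nid] = data

    def node_of(self, cid: int, pos: int) -> int | None:
        for start, end, nid in self.seg_map.get(cid, ()):
            if start <= pos < end:
                return nid
        return None

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def coverage_total(self) -> int:
        return sum(int(d.v.sum()) for d in self.data.values())

    def y_vector(self, order: list[int] | None = None) -> np.ndarray:
        order = order if order is not None else sorted(self.g.nodes)
        return np.array([self.data[n].y for n in order], dtype=float)

    def is_minimal(self) -> bool:
        for u, v in self.g.edges:
            if u != v and self.g.out_degree(u) == 1 and self.g.in_degree(v) == 1:
                return False
        return True


def _cluster_cuts(cuts: dict[int, int], tol: int) -> list[int]:
    """Merge cut positions within ``tol`` of each other, keeping the position
    with the largest support (ties: smaller position)."""
    out: list[int] = []
    pending: list[tuple[int, int]] = []

    def emit() -> None:
        if pending:
            out.append(min(pending, key=lambda t: (-t[1], t[0]))[0])
            pending.clear()

    for pos in sorted(cuts):
        if pending and pos - pending[-1][0] > tol:
            emit()
        pending.append((pos, cuts[pos]))
    emit()
    return out


def _snap(pos: int, cuts: list[int]) -> int:
    return min(cuts, key=lambda c: (abs(c - pos), c))


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if rb < ra:  # smallest key is canonical -> deterministic
            ra, rb = rb, ra
        self.parent[rb] = ra


def build_graph(group: ContigGroup, contigs: dict[int, Contig],
                merge_tol: int = 2) -> SplicingGraph:
    """Cut each contig at every valid junction boundary, unify the aligned
    (equivalent) segments into shared nodes and connect consecutive segments
    of each contig by directed edges.

    Boundaries are propagated between the two sides of every junction until
    a fixed point, so a cut interior to a shared exon on one contig also
    cuts its copies; boundaries within ``merge_tol`` bp collapse to the one
    with the larger supporting overlap.  Unified nodes carry the element-wise
    sum of their member profiles, so per-base coverage is conserved.
    """
    lens = {cid: contigs[cid].length for cid in group.contig_ids}
    cuts: dict[int, dict[int, int]] = {
        cid: {0: 1 << 30, lens[cid]: 1 << 30} for cid in group.contig_ids}

    def add_cut(cid: int, pos: int, support: int) -> bool:
        pos = int(min(max(pos, 0), lens[cid]))
        for p in cuts[cid]:
            if abs(p - pos) <= merge_tol:
                if pos != p and support > cuts[cid][p]:
                    break  # replace a weaker nearby cut
                return False
        cuts[cid][pos] = max(cuts[cid].get(pos, 0), support)
        return True

    spans = []
    for j in group.junctions:
        (s0, s1), (t0, t1) = j.spans(lens[j.src])
        spans.append((j.src, s0, s1, j.dst, t0, t1, j.overlap))
        add_cut(j.src, j.boundary_on_src(lens[j.src]), j.overlap)
        add_cut(j.dst, t0, j.overlap)
        add_cut(j.dst, t1, j.overlap)

    # propagate boundaries across junction spans to a fixed point
    for _ in range(64):
        changed = False
        for src, s0, s1, dst, t0, t1, n in spans:
            for p in list(cuts[src]):
                if s0 < p < s1:
                    changed |= add_cut(dst, t0 + (p - s0), cuts[src][p])
            for p in list(cuts[dst]):
                if t0 < p < t1:
                    changed |= add_cut(src, s0 + (p - t0), cuts[dst][p])
        if not changed:
            break

    final_cuts = {cid: _cluster_cuts(c, merge_tol) for cid, c in cuts.items()}
    for cid in final_cuts:  # endpoints always survive clustering
        if final_cuts[cid][0] != 0:
            final_cuts[cid][0] = 0
        final_cuts[cid][-1] = lens[cid]

    segments: dict[int, list[tuple[int, int]]] = {}
    for cid, cl in final_cuts.items():
        segments[cid] = [(cl[i], cl[i + 1]) for i in range(len(cl) - 1)
                         if cl[i + 1] > cl[i]]

    uf = _UnionFind()
    for cid, segs in segments.items():
        for seg in segs:
            uf.find((cid, seg[0], seg[1]))

    def segs_in(cid: int, lo: int, hi: int) -> list[tuple[int, int, int]]:
        lo, hi = _snap(lo, final_cuts[cid]), _snap(hi, final_cuts[cid])
        return [(cid, a, b) for a, b in segments[cid] if lo <= a and b <= hi]

    for src, s0, s1, dst, t0, t1, n in spans:
        ss, ts = segs_in(src, s0, s1), segs_in(dst, t0, t1)
        if len(ss) != len(ts):
            logger.warning("junction span segment mismatch (%d vs %d); "
                           "matching leading segments", len(ss), len(ts))
        for a, b in zip(ss, ts):
            uf.union(a, b)

    graph = SplicingGraph()
    node_ids: dict[tuple[int, int, int], int] = {}
    roots = sorted({uf.find((cid, a, b))
                    for cid, segs in segments.items() for a, b in segs})
    for nid, root in enumerate(roots):
        node_ids[root] = nid
    members: dict[int, list[tuple[int, int, int]]] = {nid: [] for nid in node_ids.values()}
    for cid in sorted(segments):
        for a, b in segments[cid]:
            members[node_ids[uf.find((cid, a, b))]].append((cid, a, b))
    for nid, mem in members.items():
        base_cid, a, b = mem[0]
        counts = contigs[base_cid].profile.counts[:, a:b].copy()
        for cid, c, d in mem[1:]:
            piece = contigs[cid].profile.counts[:, c:d]
            lmin = min(counts.shape[1], piece.shape[1])
            counts[:, :lmin] += piece[:, :lmin]
        graph.add_node(nid, NodeData(ConsensusProfile(counts, 0),
                                     label=f"{base_cid}:{a}-{b}"))
    for cid in sorted(segments):
        graph.seg_map[cid] = [(a, b, node_ids[uf.find((cid, a, b))])
                              for a, b in segments[cid]]
        chain = graph.seg_map[cid]
        for (a0, b0, u), (a1, b1, v) in zip(chain, chain[1:]):
            graph.g.add_edge(u, v)
    return graph


def compact(G: SplicingGraph) -> SplicingGraph:
    """Merge every singly-connected node pair (outdeg(u) = indeg(v) = 1,
    u != v) until none remains; idempotent, path structure preserved."""
    out = SplicingGraph(G.group_id)
    out.g = G.g.copy()
    out.data = dict(G.data)
    alias: dict[int, int] = {}

    def find_pair() -> tuple[int, int] | None:
        for u, v in sorted(out.g.edges):
            if u != v and out.g.out_degree(u) == 1 and out.g.in_degree(v) == 1:
                return u, v
        return None

    while (pair := find_pair()) is not None:
        u, v = pair
        du, dv = out.data[u], out.data[v]
        merged = ConsensusProfile(
            np.concatenate([du.profile.counts, dv.profile.counts], axis=1), 0)
        out.data[u] = NodeData(merged, label=f"{du.label}+{dv.label}")
        for succ in list(out.g.successors(v)):
            out.g.add_edge(u, u if succ == v or succ == u else succ)
        out.g.remove_node(v)
        del out.data[v]
        alias[v] = u

    def resolve(n: int) -> int:
        while n in alias:
            n = alias[n]
        return n

    out.seg_map = {cid: [(a, b, resolve(n)) for a, b, n in segs]
                   for cid, segs in G.seg_map.items()}
    return out


def to_gfa(G: SplicingGraph) -> str:
    """GFA1 dump: S-lines carry segment representatives and mean depth (DP
    tag), L-lines carry 0M overlaps."""
    lines = ["H\tVN:Z:1.0"]
    for nid in sorted(G.g.nodes):
        d = G.data[nid]
        lines.append(f"S\t{nid}\t{d.rep_str()}\tDP:f:{d.y:.3f}")
    for u, v in sorted(G.g.edges):
        lines.append(f"L\t{u}\t+\t{v}\t+\t0M")
    return "\n".join(lines) + "\n"
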