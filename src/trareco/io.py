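"""File I/O, run configuration and the end-to-end assembly pipeline.

The pipeline wires the three stages together: (1) greedy contig growing with
consensus-matrix error correction, (2) junction search and splicing-graph
construction, and (3) joint isoform detection and abundance estimation via
the non-negative lasso.  Outputs are a transcript FASTA, a TSV abundance
table, optional per-group GFA graph dumps and a JSON run manifest.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from . import __version__
from .assembly import (Contig, GrowParams, ReadStore, combine_contigs,
                       filter_contigs, grow_contigs)
from .consensus import AlignParams
from .graph import (SplicingGraph, build_graph, compact, find_junctions,
                    filter_junctions_by_group_size, group_contigs,
                    resolve_strands, to_gfa)
from .quant import (IsoformReport, PathCandidate, enumerate_paths,
                    inclusion_matrix, nn_lasso, pair_filter, select_candidates)

logger = logging.getLogger(__name__)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_records(path: str | Path, fmt: str) -> tuple[list[str], list[str]]:
    names, seqs = [], []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, fmt):
                names.append(rec.id)
                seqs.append(str(rec.seq).upper())
        except ValueError as exc:
            raise ValueError(
                f"malformed {fmt} record #{len(names) + 1} in {path}: {exc}"
            ) from exc
    return names, seqs


def read_fasta(path: str | Path) -> ReadStore:
    names, seqs = _read_records(path, "fasta")
    return ReadStore(names, seqs)


def read_fastq(path: str | Path, path2: str | Path | None = None) -> ReadStore:
    """Load single-end reads, or a mate pair of FASTQ files (reads of file 1
    first, mates of file 2 appended in the same order)."""
    names, seqs = _read_records(path, "fastq")
    if path2 is None:
        return ReadStore(names, seqs)
    names2, seqs2 = _read_records(path2, "fastq")
    if len(seqs2) != len(seqs):
        raise ValueError("mate files differ in read count")
    n = len(seqs)
    mate = np.concatenate([np.arange(n) + n, np.arange(n)])
    return ReadStore(names + names2, seqs + seqs2, mate)


def write_fasta(records: list[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(names: list[str], seqs: list[str], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in zip(names, seqs):
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


@dataclass
class RunConfig:
    """All tuning parameters of the assembly pipeline."""

    d_th: float = 0.06            # normalized distance margin
    o_th: int = 44                # minimum grow-overlap width
    c_th: int = 24                # post-combining overlap threshold
    j_th: int = 24                # junction overlap threshold
    l_th: int = 200               # minimum emitted candidate length
    cd_th: float = 0.0            # minimum emitted coverage depth
    lam: float = 1.0              # L1 penalty, in coverage-depth units
    group_cap: int = 40           # maximum contigs per junction group
    min_contig_len: int = 150
    min_depth: float = 2.0
    max_paths: int = 10_000
    merge_tol: int = 2            # junction-boundary collapse tolerance (bp)
    pair_reach: float | None = None  # max mate gap; None = estimate from data
    seed: int = 0
    write_gfa: bool = False

    def __post_init__(self) -> None:
        if self.c_th > self.o_th:
            raise ValueError("C_th must not exceed O_th")
        if self.j_th < 1 or self.l_th < 1 or self.cd_th < 0:
            raise ValueError("invalid thresholds")

    def grow_params(self) -> GrowParams:
        return GrowParams(align=AlignParams(self.d_th, self.o_th),
                          c_th=self.c_th, min_contig_len=self.min_contig_len,
                          min_depth=self.min_depth)


@dataclass
class GraphResult:
    graph: SplicingGraph
    paths: list[PathCandidate]
    node_order: list[int]
    y: np.ndarray
    A: np.ndarray
    x: np.ndarray


@dataclass
class PipelineResult:
    contigs: list[Contig]
    graphs: list[GraphResult]
    reports: list[IsoformReport]
    n_reads: int
    read_len: float

    def candidate_seqs(self) -> list[str]:
        return [r.seq for r in self.reports]

    def reselect(self, l_th: int, cd_th: float) -> list[IsoformReport]:
        """Re-apply the candidate thresholds without re-running the solver."""
        out = []
        for gr in self.graphs:
            out.extend(select_candidates(gr.paths, gr.x, l_th, cd_th,
                                         self.read_len, self.n_reads))
        return out


def _node_placements(contigs: list[Contig], graphs: list[SplicingGraph]
                     ) -> tuple[dict[int, tuple[int, int]], dict[int, int]]:
    """Map every absorbed read to (graph index, node id) via its midpoint,
    and record its midpoint position on the contig."""
    seg_owner = {cid: gi for gi, g in enumerate(graphs) for cid in g.seg_map}
    node_of: dict[int, tuple[int, int]] = {}
    midpos: dict[int, int] = {}
    for contig in contigs:
        gi = seg_owner.get(contig.id)
        if gi is None:
            continue
        g = graphs[gi]
        for pl in contig.final_placements():
            mid = pl.pos + pl.length // 2
            nid = g.node_of(contig.id, mid)
            if nid is not None:
                node_of[pl.read_id] = (gi, nid)
                midpos[pl.read_id] = (contig.id, mid)
    return node_of, midpos


def _mate_evidence(reads: ReadStore, node_of, midpos,
                   n_graphs: int) -> tuple[list[list[tuple[int, int]]], list[float]]:
    """Observed mate node pairs per graph plus same-contig mate separations
    (used to estimate the fragment reach)."""
    pairs: list[list[tuple[int, int]]] = [[] for _ in range(n_graphs)]
    seps: list[float] = []
    for rid, mid in enumerate(reads.mate_of.tolist()):
        if mid < 0 or mid <= rid:
            continue
        a, b = node_of.get(rid), node_of.get(mid)
        if a is None or b is None or a[0] != b[0]:
            continue
        pairs[a[0]].append((a[1], b[1]))
        ca, pa = midpos[rid]
        cb, pb = midpos[mid]
        if ca == cb:
            seps.append(abs(pb - pa))
    return pairs, seps


def run_pipeline(cfg: RunConfig, reads: ReadStore,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Execute grow -> combine -> filter -> junctions -> groups -> graphs ->
    compact -> paths -> lasso -> select, then write outputs if requested.

    Deterministic for a fixed configuration and input order.
    """
    if len(reads) == 0:
        raise ValueError("no input reads")
    gp = cfg.grow_params()
    read_len = float(np.median([len(s) for s in reads.seqs]))
    pool = grow_contigs(reads, gp)
    pool = combine_contigs(pool, gp)
    pool = filter_contigs(pool, cfg.min_contig_len, cfg.min_depth)
    contigs = {c.id: c for c in pool}

    junctions = find_junctions(pool, cfg.j_th, cfg.d_th)
    groups = group_contigs(pool, junctions)
    groups = [sub for g in groups
              for sub in filter_junctions_by_group_size(g, cfg.group_cap)]
    graphs: list[SplicingGraph] = []
    for gi, group in enumerate(groups):
        group = resolve_strands(group, contigs, cfg.j_th, cfg.d_th)
        g = build_graph(group, contigs, cfg.merge_tol)
        g = compact(g)
        g.group_id = gi
        graphs.append(g)
    logger.info("graphs: %d groups, %d nodes, %d edges",
                len(graphs), sum(g.n_nodes for g in graphs),
                sum(g.n_edges for g in graphs))

    paired = bool((reads.mate_of >= 0).any())
    node_of, midpos = _node_placements(pool, graphs)
    if paired:
        mate_pairs, seps = _mate_evidence(reads, node_of, midpos, len(graphs))
        if cfg.pair_reach is not None:
            reach = cfg.pair_reach
        elif seps:
            # the 90th percentile of observed mate separations bounds the
            # span a fragment can be expected to cover
            reach = float(np.percentile(seps, 90)) - read_len
        else:
            reach = None
    else:
        mate_pairs, reach = [[] for _ in graphs], None

    results: list[GraphResult] = []
    reports: list[IsoformReport] = []
    for gi, g in enumerate(graphs):
        paths = enumerate_paths(g, cfg.max_paths)
        if paired and reach is not None:
            node_len = {n: g.data[n].length for n in g.g.nodes}
            paths = pair_filter(paths, mate_pairs[gi], node_len, reach,
                                min_node_len=int(read_len))
        order = sorted(g.g.nodes)
        y = g.y_vector(order)
        A = inclusion_matrix(g, paths, order)
        x = nn_lasso(y, A, cfg.lam)
        results.append(GraphResult(g, paths, order, y, A, x))
        reports.extend(select_candidates(paths, x, cfg.l_th, cfg.cd_th,
                                         read_len, len(reads)))
    result = PipelineResult(pool, results, reports, len(reads), read_len)
    if out_dir is not None:
        write_outputs(result, cfg, out_dir)
    return result


def write_outputs(result: PipelineResult, cfg: RunConfig,
                  out_dir: str | Path) -> None:
    """Transcript FASTA, abundance TSV, optional GFA per group and a JSON
    run manifest (config + version; no timestamps, for reproducibility)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = [(f"{r.candidate_id} len={r.length} depth={r.depth:.4f} "
              f"rpkm={r.rpkm:.4f}", r.seq) for r in result.reports]
    write_fasta(fasta, out / "transcripts.fasta")
    with open(out / "abundance.tsv", "w") as fh:
        fh.write("candidate_id\tgroup\tlength\tdepth\trpkm\tnode_path\n")
        for r in result.reports:
            path_s = "->".join(map(str, r.nodes))
            fh.write(f"{r.candidate_id}\t{r.group_id}\t{r.length}\t"
                     f"{r.depth:.6g}\t{r.rpkm:.6g}\t{path_s}\n")
    if cfg.write_gfa:
        for gr in result.graphs:
            with open(out / f"group_{gr.graph.group_id}.gfa", "w") as fh:
                fh.write(to_gfa(gr.graph))
    manifest = {
        "tool": "trareco",
        "version": __version__,
        "config": asdict(cfg),
        "n_reads": result.n_reads,
        "n_contigs": len(result.contigs),
        "n_graphs": len(result.graphs),
        "n_candidates": len(result.reports),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
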