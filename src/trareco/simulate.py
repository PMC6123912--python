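"""Synthetic transcriptome and RNA-seq read generator, plus ground-truth
evaluation of assembled candidates.

The generator emulates, at desk scale, a simulation experiment that provides
full prior knowledge: a set of reference transcripts built from genes as
exon chains (isoforms share exons within a gene; optional tandem repeats
longer than the junction threshold exercise loopy graphs), per-transcript
expression levels, uniform read sampling with substitution errors, and the
per-transcript "expressed coverage" and "sequenced number" annotations from
which the true coverage depth follows as

    depth = n_reads * read_len / (length * expressed_coverage).

The error model is substitution-only, matching the assembler's
Hamming-distance alignment; no indels, no quality scores, no positional or
library-preparation bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import decode, encode, mismatches, revcomp, revcomp_str

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticTranscript:
    id: str
    seq: str
    abundance: float                  # target coverage depth, > 0
    exons: list[str] = field(default_factory=list)  # exon ids, in order
    repeat_span: tuple[int, int] | None = None      # tandem-repeat location

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class SimulatedReads:
    names: list[str]
    seqs: list[str]
    mate_of: np.ndarray               # mate index or -1
    truth: pd.DataFrame               # the per-transcript truth table
    read_len: int

    def __len__(self) -> int:
        return len(self.seqs)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_transcriptome(n_genes: int = 4,
                       isoforms_per_gene: int = 2,
                       exon_len_range: tuple[int, int] = (150, 400),
                       shared_exon_prob: float = 1.0,
                       repeat_prob: float = 0.0,
                       seed: int = 0,
                       n_exons_range: tuple[int, int] = (3, 6),
                       repeat_unit_len: int = 80,
                       abundance_range: tuple[float, float] = (2.0, 200.0),
                       ) -> list[SyntheticTranscript]:
    """Generate genes as exon chains and isoforms as exon subsets.

    The first isoform of a gene uses every exon; with probability
    ``shared_exon_prob`` each further isoform reuses the gene's exons
    (keeping the first and last, dropping each internal exon with
    probability 1/2), otherwise it receives its own private exon chain.
    With probability ``repeat_prob`` a gene carries a tandem repeat (two
    adjacent copies of a ``repeat_unit_len``-bp unit) inside one exon.
    Abundances are log-uniform over ``abundance_range``.  Deterministic for
    a fixed seed.
    """
    lo, hi = exon_len_range
    if lo < 1 or hi < lo:
        raise ValueError("degenerate exon_len_range")
    if n_genes < 1 or isoforms_per_gene < 1:
        raise ValueError("need at least one gene and one isoform")
    rng = np.random.default_rng(seed)
    out: list[SyntheticTranscript] = []

    def exon_chain(gene: int, tag: str, n: int) -> tuple[list[str], list[str]]:
        names = [f"g{gene}{tag}e{k}" for k in range(n)]
        seqs = [_random_seq(rng, int(rng.integers(lo, hi + 1))) for _ in range(n)]
        return names, seqs

    for g in range(n_genes):
        n_exons = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        names, seqs = exon_chain(g, "", n_exons)
        if rng.random() < repeat_prob:
            k = int(rng.integers(0, n_exons))
            unit = _random_seq(rng, repeat_unit_len)
            pos = len(seqs[k]) // 2
            seqs[k] = seqs[k][:pos] + unit + unit + seqs[k][pos:]
        exons = dict(zip(names, seqs))
        picks: list[tuple[str, ...]] = [tuple(names)]
        for i in range(1, isoforms_per_gene):
            if rng.random() < shared_exon_prob and n_exons >= 3:
                for _ in range(20):  # find a subset not seen yet
                    keep = [names[0]] + \
                        [e for e in names[1:-1] if rng.random() < 0.5] + \
                        [names[-1]]
                    if tuple(keep) not in picks:
                        picks.append(tuple(keep))
                        break
            else:
                own_names, own_seqs = exon_chain(g, f"p{i}", n_exons)
                exons.update(zip(own_names, own_seqs))
                picks.append(tuple(own_names))
        for i, pick in enumerate(picks):
            seq = "".join(exons[e] for e in pick)
            abundance = float(np.exp(rng.uniform(np.log(abundance_range[0]),
                                                 np.log(abundance_range[1]))))
            out.append(SyntheticTranscript(f"g{g}_iso{i}", seq, abundance,
                                           exons=list(pick)))
    return out


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return arr
    hit = np.nonzero(rng.random(arr.shape[0]) < rate)[0]
    if hit.size:
        arr = arr.copy()
        # substitute with one of the three other bases, uniformly
        arr[hit] = (arr[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return arr


def sample_reads(transcripts: list[SyntheticTranscript],
                 abundances: list[float] | None = None,
                 read_len: int = 100,
                 paired: bool = False,
                 frag_len_mean: float = 500.0,
                 frag_len_sd: float = 50.0,
                 error_rate: float = 0.0,
                 seed: int = 0,
                 strand: str = "both",
                 shuffle: bool = True) -> SimulatedReads:
    """Sample uniform-start reads with per-base substitution errors.

    Single-end mode draws a Poisson number of reads with mean
    ``depth * length / read_len`` per transcript; paired mode draws
    fragments (Gaussian length, clipped to [2*read_len, transcript length])
    and emits proper forward/reverse mate pairs.  ``strand='both'``
    reverse-complements each read or fragment with probability 1/2.
    Transcripts shorter than a read are skipped with a warning.  The truth
    table records expressed coverage, sequenced read count and the implied
    coverage depth for every transcript.
    """
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must lie in [0, 0.1]")
    rng = np.random.default_rng(seed)
    names: list[str] = []
    seqs: list[str] = []
    mates: list[int] = []
    rows = []
    for t_i, t in enumerate(transcripts):
        depth = float(abundances[t_i]) if abundances is not None else t.abundance
        if depth <= 0:
            raise ValueError(f"abundance of {t.id} must be > 0")
        L = t.length
        if L < read_len or (paired and L < 2 * read_len):
            logger.warning("transcript %s shorter than a %s; skipped",
                           t.id, "fragment" if paired else "read")
            rows.append((t.id, L, depth, 0, 0.0, 0.0))
            continue
        arr = encode(t.seq)
        covered = np.zeros(L, dtype=bool)
        n_reads_t = 0

        def emit(sub: np.ndarray, name: str, flip: bool) -> None:
            read = decode(_mutate(rng, sub, error_rate))
            seqs.append(revcomp_str(read) if flip else read)
            names.append(name)

        if not paired:
            n = int(rng.poisson(depth * L / read_len))
            starts = rng.integers(0, L - read_len + 1, size=n)
            for k, s in enumerate(sorted(starts.tolist())):
                flip = strand == "both" and rng.random() < 0.5
                emit(arr[s:s + read_len], f"{t.id}_r{k}", flip)
                mates.append(-1)
                covered[s:s + read_len] = True
                n_reads_t += 1
        else:
            n = int(rng.poisson(depth * L / (2 * read_len)))
            flens = np.clip(rng.normal(frag_len_mean, frag_len_sd, size=n),
                            2 * read_len, L).astype(int)
            for k, fl in enumerate(flens.tolist()):
                s = int(rng.integers(0, L - fl + 1))
                flip = strand == "both" and rng.random() < 0.5
                i1 = len(seqs)
                emit(arr[s:s + read_len], f"{t.id}_f{k}/1", flip)
                emit(revcomp(arr[s + fl - read_len:s + fl]).copy(),
                     f"{t.id}_f{k}/2", flip)
                mates.extend([i1 + 1, i1])
                covered[s:s + read_len] = True
                covered[s + fl - read_len:s + fl] = True
                n_reads_t += 2
        expr_cov = float(covered.mean())
        cov_depth = (n_reads_t * read_len / (L * expr_cov)) if expr_cov > 0 else 0.0
        rows.append((t.id, L, depth, n_reads_t, expr_cov, cov_depth))
    truth = pd.DataFrame(rows, columns=["transcript_id", "length", "target_depth",
                                        "n_reads", "expressed_coverage",
                                        "coverage_depth"])
    mate_of = np.array(mates, dtype=np.int64)
    if shuffle and len(seqs) > 1:
        # interleave reads from all transcripts, as a real library would be
        perm = rng.permutation(len(seqs))
        new_pos = np.empty_like(perm)
        new_pos[perm] = np.arange(len(perm))
        names = [names[i] for i in perm]
        seqs = [seqs[i] for i in perm]
        mate_of = np.where(mate_of[perm] >= 0, new_pos[mate_of[perm]], -1)
    return SimulatedReads(names, seqs, mate_of, truth, read_len)


def _best_span(cand: np.ndarray, ref: np.ndarray, k: int = 16) -> int:
    """Matched bases of the best gap-free (single-diagonal) alignment of
    ``cand`` against ``ref``, found by exact k-mer seeding."""
    lc, lr = cand.shape[0], ref.shape[0]
    if lc < k or lr < k:
        return 0
    from .assembly import _kmer_codes  # same integer k-mer encoding
    ref_pos: dict[int, list[int]] = {}
    win = np.lib.stride_tricks.sliding_window_view(ref, k).astype(np.int64)
    codes = win @ (4 ** np.arange(k, dtype=np.int64))
    clean = (win != 4).all(axis=1)
    for p in np.nonzero(clean)[0].tolist():
        ref_pos.setdefault(int(codes[p]), []).append(p)
    winc = np.lib.stride_tricks.sliding_window_view(cand, k).astype(np.int64)
    codesc = winc @ (4 ** np.arange(k, dtype=np.int64))
    cleanc = (winc != 4).all(axis=1)
    diagonals = set()
    for q in np.nonzero(cleanc)[0].tolist():
        for p in ref_pos.get(int(codesc[q]), ()):  # diagonal = ref - cand offset
            diagonals.add(p - q)
    best = 0
    for d in diagonals:
        r0, r1 = max(0, d), min(lr, lc + d)
        if r1 - r0 <= best:
            continue
        mm = mismatches(cand[r0 - d:r1 - d], ref[r0:r1])
        best = max(best, (r1 - r0) - mm)
    return best


def evaluate(candidates: list[str], truths: list[SyntheticTranscript],
             targets: tuple[float, ...] = (0.95, 0.90, 0.80),
             seed_k: int = 16) -> dict:
    """Sensitivity, precision and wide-sense sensitivity of an assembly
    against known reference transcripts.

    Per (reference, candidate) pair the coverage is the best gap-free
    alignment length (exact k-mer seeding + Hamming extension; adequate for
    substitution-only data) divided by the reference length.  Sensitivity
    pairs references and candidates one-to-one (greedy, by coverage);
    wide-sense sensitivity lets one candidate recover several references.
    Percentages are reported on the 0-100 scale.
    """
    n_ref, n_cand = len(truths), len(candidates)
    res = {
        "n_candidates": n_cand,
        "n_references": n_ref,
        "sensitivity": {t: 0.0 for t in targets},
        "precision": {t: 0.0 for t in targets},
        "ws_sensitivity": {t: 0.0 for t in targets},
        "recovered": {t: 0 for t in targets},
    }
    if n_cand == 0 or n_ref == 0:
        return res
    refs = [encode(t.seq) for t in truths]
    cov = np.zeros((n_ref, n_cand))
    for j, cand in enumerate(candidates):
        c_f = encode(cand)
        c_r = encode(revcomp_str(cand))
        for i, ref in enumerate(refs):
            m = max(_best_span(c_f, ref, seed_k), _best_span(c_r, ref, seed_k))
            cov[i, j] = m / ref.shape[0]
    pairs = sorted(((cov[i, j], i, j) for i in range(n_ref) for j in range(n_cand)
                    if cov[i, j] >= min(targets)),
                   key=lambda t: (-t[0], t[1], t[2]))
    used_ref: set[int] = set()
    used_cand: set[int] = set()
    matched: list[tuple[float, int, int]] = []
    for c, i, j in pairs:
        if i in used_ref or j in used_cand:
            continue
        used_ref.add(i)
        used_cand.add(j)
        matched.append((c, i, j))
    best_ref = cov.max(axis=1)
    for t in targets:
        hits = sum(1 for c, _, _ in matched if c >= t)
        res["recovered"][t] = hits
        res["sensitivity"][t] = 100.0 * hits / n_ref
        res["precision"][t] = 100.0 * hits / n_cand
        res["ws_sensitivity"][t] = 100.0 * float((best_ref >= t).sum()) / n_ref
    return res
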