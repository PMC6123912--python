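"""Greedy contig growing over a read set, post contig combining and filtering.

Reads are processed in input order.  Each read is aligned (both strands)
against the representatives of the current contig pool; the contig with the
widest valid overlap absorbs the read through a consensus-matrix update, and
reads matching nothing become new seed contigs.  A w-mer index over the
representatives prefilters alignment candidates; the word size is chosen by
the pigeonhole bound w <= floor(O_th / (floor(O_th * D_th) + 1)) so the
prefilter can never lose a valid overlap relative to the exhaustive scan.

After growing, the pool is combined once more with a smaller overlap
threshold C_th (contig representatives act as pseudo-reads and overlapping
consensus columns add element-wise), which connects low-expression fragments
the stricter O_th left apart.  Finally, short *and* shallow contigs - very
likely error debris - are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .consensus import (AlignmentResult, AlignParams, ConsensusProfile, Mode,
                        N_CODE, Orientation, align_read_both, apply_alignment,
                        encode, profile_from_seq, revcomp)

logger = logging.getLogger(__name__)


@dataclass
class GrowParams:
    align: AlignParams = field(default_factory=AlignParams)
    c_th: int = 24              # post-combining overlap threshold (< O_th)
    min_contig_len: int = 150
    min_depth: float = 2.0
    skip_short_reads: bool = False  # reads shorter than O_th: seed (False) or drop

    def __post_init__(self) -> None:
        if self.c_th > self.align.o_th:
            raise ValueError("C_th must not exceed O_th")


@dataclass
class Placement:
    """Record of one absorbed read: where it landed on which contig."""

    read_id: int
    pos: int              # start on the contig, in *final* contig coordinates
    length: int
    reverse: bool


@dataclass
class ReadStore:
    """Ordered read collection with optional mate pairing.

    ``mate_of[i]`` is the mate read index of read ``i`` or -1.  Mates are
    grown as independent single-end reads; pairing is only consulted by the
    paired-end path filter downstream.
    """

    names: list[str]
    seqs: list[str]
    mate_of: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mate_of is None:
            self.mate_of = np.full(len(self.seqs), -1, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.seqs)

    @classmethod
    def from_seqs(cls, seqs: list[str], paired: bool = False) -> "ReadStore":
        names = [f"read_{i}" for i in range(len(seqs))]
        mate = np.full(len(seqs), -1, dtype=np.int64)
        if paired:
            # interleaved mates: (0,1), (2,3), ...
            for i in range(0, len(seqs) - 1, 2):
                mate[i], mate[i + 1] = i + 1, i
        return cls(names, seqs, mate)


class Contig:
    """A consensus profile plus bookkeeping of absorbed read placements."""

    __slots__ = ("id", "profile", "_left", "placements")

    def __init__(self, cid: int, profile: ConsensusProfile):
        self.id = cid
        self.profile = profile
        self._left = 0  # cumulative growth on the left, shifts old placements
        self.placements: list[tuple[int, int, int, bool]] = []  # id, raw pos, len, rev

    @property
    def n_reads(self) -> int:
        return self.profile.n_reads

    @property
    def length(self) -> int:
        return self.profile.length

    def rep(self) -> np.ndarray:
        return self.profile.rep()

    def rep_str(self) -> str:
        return self.profile.rep_str()

    def mean_depth(self) -> float:
        return self.profile.mean_depth()

    def add_placement(self, read_id: int, pos_now: int, length: int, rev: bool) -> None:
        self.placements.append((read_id, pos_now - self._left, length, rev))

    def shift_left(self, grow: int) -> None:
        self._left += grow

    def final_placements(self) -> list[Placement]:
        return [Placement(rid, raw + self._left, ln, rev)
                for rid, raw, ln, rev in self.placements]

    def absorb_placements(self, other: "Contig", offset: int) -> None:
        """Import ``other``'s placements, whose final coordinates map to this
        contig's final coordinates by ``+ offset``."""
        for pl in other.final_placements():
            self.placements.append((pl.read_id, pl.pos + offset - self._left,
                                    pl.length, pl.reverse))

    def flip(self) -> None:
        """Reverse-complement the contig in place (profile and placements)."""
        l = self.length
        self.profile = self.profile.reverse_complement()
        self._left, old = 0, self._left
        self.placements = [(rid, l - (raw + old) - ln, ln, not rev)
                           for rid, raw, ln, rev in self.placements]


def pigeonhole_word(o_th: int, d_th: float) -> int:
    """Largest lossless index word size: any valid overlap (width >= O_th,
    mismatches <= floor(n*D_th)) must contain an exact run of this length."""
    return o_th // (int(o_th * d_th) + 1)


def _kmer_codes(arr: np.ndarray, w: int) -> np.ndarray:
    """Integer codes of all N-free w-mers of an encoded sequence."""
    if arr.shape[0] < w:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr, w).astype(np.int64)
    codes = win @ (4 ** np.arange(w, dtype=np.int64))
    clean = (win != N_CODE).all(axis=1)
    return np.unique(codes[clean])


class KmerIndex:
    """w-mer postings over contig representatives, lossless by pigeonhole."""

    def __init__(self, w: int):
        self.w = w
        self._post: dict[int, set[int]] = {}
        self._words: dict[int, np.ndarray] = {}

    def add(self, cid: int, rep: np.ndarray) -> None:
        codes = _kmer_codes(rep, self.w)
        self._words[cid] = codes
        for c in codes:
            self._post.setdefault(int(c), set()).add(cid)

    def remove(self, cid: int) -> None:
        for c in self._words.pop(cid, ()):  # pragma: no branch
            s = self._post.get(int(c))
            if s is not None:
                s.discard(cid)

    def update(self, cid: int, rep: np.ndarray) -> None:
        self.remove(cid)
        self.add(cid, rep)

    def candidates(self, arr: np.ndarray, rc: np.ndarray) -> set[int]:
        out: set[int] = set()
        for codes in (_kmer_codes(arr, self.w), _kmer_codes(rc, self.w)):
            for c in codes:
                s = self._post.get(int(c))
                if s:
                    out |= s
        return out


def best_alignment(r: np.ndarray, pool: dict[int, Contig], p: AlignParams,
                   index: KmerIndex | None = None,
                   rc: np.ndarray | None = None,
                   exclude: int | None = None,
                   ) -> tuple[Contig, AlignmentResult] | None:
    """Contig with the widest valid overlap for read ``r`` across both
    orientations; ties break by smaller distance, then smaller contig id.

    With an index, only contigs sharing a w-mer with the read are tested,
    which cannot change the winner when ``w`` obeys the pigeonhole bound.
    """
    if rc is None:
        rc = revcomp(r)
    if index is not None:
        cand_ids = sorted(index.candidates(r, rc))
    else:
        cand_ids = sorted(pool)
    best: tuple[int, int, int] | None = None  # (-n, d, cid)
    best_pair: tuple[Contig, AlignmentResult] | None = None
    for cid in cand_ids:
        if cid == exclude or cid not in pool:
            continue
        contig = pool[cid]
        res = align_read_both(r, contig.rep(), p, rc=rc)
        if not res.found:
            continue
        key = (-res.n, res.d, cid)
        if best is None or key < best:
            best, best_pair = key, (contig, res)
    return best_pair


def _absorb(contig: Contig, r: np.ndarray, rc: np.ndarray, read_id: int,
            res: AlignmentResult) -> None:
    seq = rc if res.orientation is Orientation.REVERSE_COMPLEMENT else r
    new_profile, grow, pos = apply_alignment(contig.profile, seq, res)
    contig.profile = new_profile
    contig.shift_left(grow)
    contig.add_placement(read_id, pos, seq.shape[0],
                         res.orientation is Orientation.REVERSE_COMPLEMENT)


def grow_contigs(reads: ReadStore, p: GrowParams) -> list[Contig]:
    """Greedy contig-growing loop: every read is absorbed into the contig
    with the widest valid overlap, or becomes a new seed."""
    if len(reads) == 0:
        raise ValueError("cannot grow contigs from an empty read set")
    w = pigeonhole_word(p.align.o_th, p.align.d_th)
    index = KmerIndex(w) if w >= 6 else None
    pool: dict[int, Contig] = {}
    next_id = 0
    n_absorbed = 0
    for read_id, seq in enumerate(reads.seqs):
        r = encode(seq)
        if r.shape[0] < p.align.o_th:
            if p.skip_short_reads or r.shape[0] == 0:
                continue
            hit = None
        else:
            rc = revcomp(r)
            hit = best_alignment(r, pool, p.align, index, rc=rc)
        if hit is None:
            contig = Contig(next_id, profile_from_seq(r))
            contig.add_placement(read_id, 0, r.shape[0], False)
            pool[next_id] = contig
            if index is not None:
                index.add(next_id, contig.rep())
            next_id += 1
        else:
            contig, res = hit
            _absorb(contig, r, rc, read_id, res)
            n_absorbed += 1
            if index is not None:
                index.update(contig.id, contig.rep())
    logger.info("grow: %d reads -> %d contigs (%d absorbed, %d seeds)",
                len(reads), len(pool), n_absorbed, len(pool))
    return [pool[cid] for cid in sorted(pool)]


def _merge_profiles(a: ConsensusProfile, b: ConsensusProfile,
                    res: AlignmentResult) -> tuple[ConsensusProfile, int, int]:
    """Matrix-to-matrix merge of contig B into contig A given the alignment
    of rep(B) against rep(A): overlap columns add element-wise, extension
    columns are B's own.  Returns (profile, left_growth, offset_of_B)."""
    A, B = a.counts, b.counts
    la, lb = A.shape[1], B.shape[1]
    if res.mode is Mode.COMPLETE:
        new = A.copy()
        new[:, res.offset:res.offset + lb] += B
        out = res.offset, 0
    elif res.mode is Mode.PARTIAL_LEFT:
        n = res.n
        new = np.concatenate([B[:, :lb - n], A], axis=1)
        new[:, lb - n:lb] += B[:, lb - n:]
        out = 0, lb - n
    elif res.mode is Mode.PARTIAL_RIGHT:
        n = res.n
        new = np.concatenate([A, B[:, n:]], axis=1)
        new[:, la - n:la] += B[:, :n]
        out = la - n, 0
    elif res.mode is Mode.CONTAINED:
        pos = -res.offset
        new = np.concatenate([B[:, :pos], A, B[:, pos + la:]], axis=1)
        new[:, pos:pos + la] += B[:, pos:pos + la]
        out = 0, pos
    else:
        raise ValueError("cannot merge on a non-alignment")
    offset_b, grow = out
    return ConsensusProfile(new, a.n_reads + b.n_reads), grow, offset_b


def combine_contigs(pool: list[Contig], p: GrowParams) -> list[Contig]:
    """Repeat the greedy merge with representatives as pseudo-reads at the
    lower overlap threshold C_th, until no merge applies."""
    params = AlignParams(d_th=p.align.d_th, o_th=p.c_th)
    w = pigeonhole_word(p.c_th, p.align.d_th)
    index = KmerIndex(w) if w >= 6 else None
    live: dict[int, Contig] = {c.id: c for c in pool}
    if index is not None:
        for c in live.values():
            index.add(c.id, c.rep())
    merged = True
    while merged:
        merged = False
        for cid in sorted(live):
            if cid not in live:
                continue
            b = live[cid]
            r = b.rep()
            hit = best_alignment(r, live, params, index, exclude=cid)
            if hit is None:
                continue
            a, res = hit
            if res.orientation is Orientation.REVERSE_COMPLEMENT:
                b.flip()
            new_profile, grow, offset_b = _merge_profiles(a.profile, b.profile, res)
            a.profile = new_profile
            a.shift_left(grow)
            a.absorb_placements(b, offset_b)
            del live[cid]
            if index is not None:
                index.remove(cid)
                index.update(a.id, a.rep())
            merged = True
    out = [live[cid] for cid in sorted(live)]
    logger.info("combine: %d -> %d contigs", len(pool), len(out))
    return out


def filter_contigs(pool: list[Contig], min_len: int = 150,
                   min_depth: float = 2.0) -> list[Contig]:
    """Drop contigs that are both short and shallow (likely error debris);
    anything long enough OR deep enough survives."""
    kept = [c for c in pool
            if not (c.length < min_len and c.mean_depth() < min_depth)]
    logger.info("filter: %d -> %d contigs", len(pool), len(kept))
    return kept
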