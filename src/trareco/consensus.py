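"""Consensus-matrix kernel: base-count profiles, majority representatives and
distance-margin overlap tests.

A contig of length ``l`` is represented by a 4 x ``l`` integer *consensus
matrix* whose rows count, per column, how many aligned reads carried A, C, G
or T there.  The per-column majority base is the *representative* sequence
used for all further alignment, so read errors are outvoted instead of
breaking the assembly.  Alignment between a read ``r`` (length ``m``) and a
representative ``s`` (length ``l``) is Hamming-distance based within a
normalized margin ``D_th``: an overlap of width ``n`` is valid when the
distance does not exceed ``floor(n * D_th)`` and ``n`` is at least the
minimum overlap width ``O_th``.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

# Base encoding: A=0, C=1, G=2, T=3, N=4.  N never matches anything
# (including another N) and contributes no count to a consensus matrix.
_LETTERS = "ACGTN"
_LUT = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i
N_CODE = 4


def encode(seq: str) -> np.ndarray:
    """Encode a base string into an int8 array (A=0,C=1,G=2,T=3, other=N=4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return "".join(_LETTERS[b] for b in arr)


def revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of an encoded sequence (N stays N)."""
    out = np.where(arr < 4, 3 - arr, np.int8(N_CODE)).astype(np.int8)
    return out[::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def mismatches(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance between equal-length encoded sequences.

    N mismatches every letter, including N itself.
    """
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    return int(np.count_nonzero((a != b) | (a == N_CODE) | (b == N_CODE)))


def hamming(a: str, b: str) -> int:
    """Hamming distance between two base strings of equal length."""
    return mismatches(encode(a), encode(b))


class Mode(enum.Enum):
    """Overlap geometry of a read against a representative."""

    COMPLETE = "complete"          # read lies entirely inside s
    PARTIAL_LEFT = "partial_left"  # read suffix matches s prefix (extends left)
    PARTIAL_RIGHT = "partial_right"  # read prefix matches s suffix (extends right)
    CONTAINED = "contained"        # s lies strictly inside the read (l < m)
    NONE = "none"


class Orientation(enum.Enum):
    FORWARD = "forward"
    REVERSE_COMPLEMENT = "reverse_complement"


@dataclass(frozen=True)
class AlignParams:
    """Distance margin and minimum overlap width for a valid alignment."""

    d_th: float = 0.06
    o_th: int = 44

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_th < 0.5):
            raise ValueError("d_th must lie in [0, 0.5)")
        if self.o_th < 1:
            raise ValueError("o_th must be >= 1")

    def budget(self, n: int) -> int:
        """Allowed mismatches in an overlap of width ``n``: floor(n * D_th)."""
        return int(n * self.d_th)


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of a read-vs-representative overlap test.

    ``offset`` is the read start in representative coordinates and may be
    negative (read hanging off the left end, or containing the
    representative).  ``n`` is the overlap width, ``d`` the Hamming distance
    over the overlap.
    """

    mode: Mode
    offset: int = 0
    n: int = 0
    d: int = 0
    orientation: Orientation = Orientation.FORWARD

    @property
    def found(self) -> bool:
        return self.mode is not Mode.NONE


NO_ALIGNMENT = AlignmentResult(Mode.NONE)


class ConsensusProfile:
    """4 x l base-count matrix with a derived majority representative."""

    __slots__ = ("counts", "n_reads", "_rep")

    def __init__(self, counts: np.ndarray, n_reads: int = 1):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError("counts must be a 4 x l matrix with l >= 1")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.n_reads = n_reads
        self._rep: np.ndarray | None = None

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def total(self) -> int:
        """Grand total of all matrix entries (absorbed non-N bases)."""
        return int(self.counts.sum())

    def coverage(self) -> np.ndarray:
        """Per-base coverage: column sums of the matrix."""
        return self.counts.sum(axis=0)

    def mean_depth(self) -> float:
        return float(self.coverage().mean())

    def rep(self) -> np.ndarray:
        """Majority representative (encoded).

        Per column the row with the highest count wins; ties break by the
        fixed base order A < C < G < T.  All-zero columns (pure-N input)
        yield N.
        """
        if self._rep is None:
            rep = np.argmax(self.counts, axis=0).astype(np.int8)
            empty = self.counts.sum(axis=0) == 0
            if empty.any():
                rep[empty] = N_CODE
            self._rep = rep
        return self._rep

    def rep_str(self) -> str:
        return decode(self.rep())

    def _invalidate(self) -> None:
        self._rep = None

    def copy(self) -> "ConsensusProfile":
        return ConsensusProfile(self.counts.copy(), self.n_reads)

    def reverse_complement(self) -> "ConsensusProfile":
        """Profile of the reverse-complement contig: columns reversed,
        A<->T and C<->G rows swapped."""
        return ConsensusProfile(self.counts[::-1, ::-1].copy(), self.n_reads)


def cns(arr: np.ndarray) -> np.ndarray:
    """Count matrix of a single encoded sequence: one 1 per non-N column."""
    m = arr.shape[0]
    out = np.zeros((4, m), dtype=np.int64)
    idx = np.nonzero(arr < 4)[0]
    out[arr[idx], idx] = 1
    return out


def profile_from_seq(seq: str | np.ndarray) -> ConsensusProfile:
    """Initialize a consensus matrix from one sequence (N columns all-zero)."""
    arr = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.int8)
    if arr.shape[0] == 0:
        raise ValueError("cannot build a profile from an empty sequence")
    return ConsensusProfile(cns(arr), n_reads=1)


def representative(profile: ConsensusProfile) -> str:
    """Majority representative of a consensus matrix, as a string."""
    return profile.rep_str()


def _scan_partials(r: np.ndarray, s: np.ndarray, p: AlignParams) -> AlignmentResult:
    """Best non-complete placement: largest overlap n, then smallest d, then
    left < right < contained, then smallest containment offset."""
    m, l = r.shape[0], s.shape[0]
    n_max = min(m, l)
    if n_max == m:  # partial widths are strictly below the read length
        n_max = m - 1
    for n in range(n_max, p.o_th - 1, -1):
        best: AlignmentResult | None = None
        d = mismatches(r[m - n:], s[:n])
        if d <= p.budget(n):
            best = AlignmentResult(Mode.PARTIAL_LEFT, offset=n - m, n=n, d=d)
        d = mismatches(r[:n], s[l - n:])
        if d <= p.budget(n) and (best is None or d < best.d):
            best = AlignmentResult(Mode.PARTIAL_RIGHT, offset=l - n, n=n, d=d)
        if n == l and l < m:
            # the representative strictly inside the read
            budget = p.budget(l)
            for pos in range(1, m - l):
                d = mismatches(r[pos:pos + l], s)
                if d <= budget and (best is None or d < best.d):
                    best = AlignmentResult(Mode.CONTAINED, offset=-pos, n=l, d=d)
        if best is not None:
            return best
    return NO_ALIGNMENT


def align_read(r: str | np.ndarray, s: str | np.ndarray,
               p: AlignParams) -> AlignmentResult:
    """Test the overlap of read ``r`` against representative ``s``.

    A *complete* overlap (the whole read inside ``s`` within the margin) is
    preferred; among complete placements the smallest distance wins, ties
    going to the smallest offset.  Otherwise the partial placement with the
    largest overlap width wins.  Returns ``NO_ALIGNMENT`` when nothing
    reaches ``O_th`` within the distance margin.  Strand-agnostic: callers
    test the reverse complement themselves.
    """
    r = encode(r) if isinstance(r, str) else np.asarray(r, dtype=np.int8)
    s = encode(s) if isinstance(s, str) else np.asarray(s, dtype=np.int8)
    m, l = r.shape[0], s.shape[0]
    if l < 1:
        raise ValueError("representative must be non-empty")
    if m < p.o_th or m == 0:
        return NO_ALIGNMENT
    if l >= m:
        win = np.lib.stride_tricks.sliding_window_view(s, m)
        bad = (win != r[None, :]) | (win == N_CODE) | (r[None, :] == N_CODE)
        dists = bad.sum(axis=1)
        a = int(np.argmin(dists))
        d = int(dists[a])
        if d <= p.budget(m):
            return AlignmentResult(Mode.COMPLETE, offset=a, n=m, d=d)
    return _scan_partials(r, s, p)


def align_read_both(r: np.ndarray, s: np.ndarray, p: AlignParams,
                    rc: np.ndarray | None = None) -> AlignmentResult:
    """Strand-aware wrapper: align ``r`` and its reverse complement, keep the
    wider overlap (ties: smaller distance, then forward)."""
    fwd = align_read(r, s, p)
    if rc is None:
        rc = revcomp(r)
    rev = align_read(rc, s, p)
    if not rev.found:
        return fwd
    if not fwd.found or (rev.n, -rev.d) > (fwd.n, -fwd.d):
        return AlignmentResult(rev.mode, rev.offset, rev.n, rev.d,
                               Orientation.REVERSE_COMPLEMENT)
    return fwd


def _check_range(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def apply_partial_left(C: ConsensusProfile, r: np.ndarray, n: int) -> ConsensusProfile:
    """Absorb a read whose suffix of width ``n`` overlaps the contig prefix.

    New matrix: [cns(r[:m-n]) | C[:, :n] + cns(r[m-n:]) | C[:, n:]], so the
    contig grows by ``m - n`` columns on the left.
    """
    m, l = r.shape[0], C.length
    _check_range(1 <= n < m and n <= l, f"overlap n={n} out of range (m={m}, l={l})")
    new = np.concatenate([cns(r[:m - n]), C.counts], axis=1)
    new[:, m - n:m] += cns(r[m - n:])
    out = ConsensusProfile(new, C.n_reads + 1)
    return out


def apply_partial_right(C: ConsensusProfile, r: np.ndarray, n: int) -> ConsensusProfile:
    """Mirror of :func:`apply_partial_left`: read prefix overlaps the contig
    suffix; the contig grows by ``m - n`` columns on the right."""
    m, l = r.shape[0], C.length
    _check_range(1 <= n < m and n <= l, f"overlap n={n} out of range (m={m}, l={l})")
    new = np.concatenate([C.counts, cns(r[n:])], axis=1)
    new[:, l - n:l] += cns(r[:n])
    return ConsensusProfile(new, C.n_reads + 1)


def apply_complete(C: ConsensusProfile, r: np.ndarray, a: int) -> ConsensusProfile:
    """Absorb a read completely overlapping the contig at offset ``a``;
    the length is unchanged."""
    m, l = r.shape[0], C.length
    _check_range(0 <= a <= l - m, f"offset a={a} out of range (m={m}, l={l})")
    new = C.counts.copy()
    new[:, a:a + m] += cns(r)
    return ConsensusProfile(new, C.n_reads + 1)


def apply_contained(C: ConsensusProfile, r: np.ndarray, pos: int) -> ConsensusProfile:
    """Absorb a read that strictly contains the contig, whose representative
    sits at ``r[pos:pos+l]``; the contig is extended on both sides."""
    m, l = r.shape[0], C.length
    _check_range(0 <= pos and pos + l <= m, f"pos={pos} out of range (m={m}, l={l})")
    new = np.concatenate([cns(r[:pos]), C.counts, cns(r[pos + l:])], axis=1)
    new[:, pos:pos + l] += cns(r[pos:pos + l])
    return ConsensusProfile(new, C.n_reads + 1)


def apply_alignment(C: ConsensusProfile, r: np.ndarray,
                    res: AlignmentResult) -> tuple[ConsensusProfile, int, int]:
    """Dispatch the profile update for a found alignment.

    Returns ``(new_profile, left_growth, read_pos)`` where ``left_growth`` is
    the number of columns added on the left and ``read_pos`` the read start
    position in the *new* contig coordinates.
    """
    if res.mode is Mode.COMPLETE:
        return apply_complete(C, r, res.offset), 0, res.offset
    if res.mode is Mode.PARTIAL_LEFT:
        grow = r.shape[0] - res.n
        return apply_partial_left(C, r, res.n), grow, 0
    if res.mode is Mode.PARTIAL_RIGHT:
        return apply_partial_right(C, r, res.n), 0, C.length - res.n
    if res.mode is Mode.CONTAINED:
        pos = -res.offset
        return apply_contained(C, r, pos), pos, 0
    raise ValueError("cannot apply a non-alignment")
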