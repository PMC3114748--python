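"""Dense 60-mer tiling capture probe design with uniqueness filtering.

A design window slides along the unmasked target in small steps; within
each window the best-scoring 60-mer (melting temperature near target,
moderate GC, no long homopolymers) is selected.  The reverse strand gets
a completely independent design with an offset first window.  Probes
matching more than two genomic loci at above 60% identity are discarded.

:func:`probe_score` is the scalar reference scorer; the design and
uniqueness scans use vectorized equivalents so megabase regions stay
tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from Bio.Seq import Seq

from ffg.synthetic_cross import Genome

PROBE_LEN = 60
DEFAULT_SLIDE = 2
DEFAULT_WINDOW = 10
DEFAULT_MAX_HITS = 2
DEFAULT_MIN_IDENTITY = 0.60
SEED_LEN = 12
SEED_STEP = 6  # probe offsets probed for seeds; trades scan cost for recall

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_MASKED = np.zeros(256, dtype=bool)
for _b in "acgtn":
    _MASKED[ord(_b)] = True
    _MASKED[ord(_b.upper())] = _b == "n"


@dataclass(frozen=True)
class ScoreParams:
    # the GC-fraction Tm formula maps the acceptable GC band [0.35, 0.65]
    # to ~84.6-96.9 C for 60-mers; 90 C sits at its middle
    target_tm: float = 90.0
    gc_low: float = 0.35
    gc_high: float = 0.65
    w_gc: float = 40.0
    w_homopolymer: float = 2.0
    max_ok_homopolymer: int = 5


@dataclass
class Probe:
    chrom: str
    start: int  # 0-based genome start of the probed segment
    strand: str
    sequence: str  # probe sequence 5'->3' (revcomp of genome for - strand)
    tm: float
    gc: float
    max_homopolymer: int
    score: float
    n_hits: int | None = None
    kept: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ProbeDesign:
    chrom: str
    region_start: int
    region_end: int
    forward: list[Probe]
    reverse: list[Probe]
    slide: int
    window: int
    params: ScoreParams

    @property
    def probes(self) -> list[Probe]:
        return self.forward + self.reverse


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def probe_score(
    sequence: str, params: ScoreParams = ScoreParams()
) -> tuple[float, float, float, int]:
    """Score a candidate probe; returns (score, tm, gc, max_homopolymer).

    Tm uses the GC-fraction formula Tm = 81.5 + 0.41*GC% - 675/length.
    Masked (lowercase) or non-ACGT bases make the probe ineligible
    (score -inf).
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("empty probe sequence")
    gc = sum(1 for b in sequence if b in "GCgc") / n
    tm = 81.5 + 0.41 * gc * 100.0 - 675.0 / n
    homopolymer = _max_homopolymer(sequence.upper())
    if any(b not in "ACGT" for b in sequence):
        return float("-inf"), tm, gc, homopolymer
    gc_penalty = max(0.0, params.gc_low - gc) + max(0.0, gc - params.gc_high)
    score = (
        -abs(tm - params.target_tm)
        - params.w_gc * gc_penalty
        - params.w_homopolymer * max(0, homopolymer - params.max_ok_homopolymer)
    )
    return score, tm, gc, homopolymer


def _score_all_starts(
    seq: str, probe_len: int, params: ScoreParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized scores for every probe start in ``seq``.

    Returns (scores, tm, gc, max_homopolymer) arrays of length
    ``len(seq) - probe_len + 1``; ineligible starts score -inf.
    """
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    n_starts = len(seq) - probe_len + 1
    if n_starts <= 0:
        empty = np.empty(0)
        return empty, empty, empty, np.empty(0, dtype=np.int64)
    codes = _CODE[raw]
    bad = (codes < 0) | _MASKED[raw]

    is_gc = (codes == 1) | (codes == 2)
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    gc_count = cum_gc[probe_len:] - cum_gc[:-probe_len]
    gc = gc_count / probe_len
    tm = 81.5 + 0.41 * gc * 100.0 - 675.0 / probe_len

    cum_bad = np.concatenate([[0], np.cumsum(bad)])
    any_bad = (cum_bad[probe_len:] - cum_bad[:-probe_len]) > 0

    # homopolymer run length ending at each base (case-insensitive)
    upper = np.where((raw >= 97) & (raw <= 122), raw - 32, raw)
    same = np.concatenate([[False], upper[1:] == upper[:-1]])
    boundaries = np.flatnonzero(~same)
    seg_idx = np.searchsorted(boundaries, np.arange(len(seq)), side="right") - 1
    run = np.arange(len(seq)) - boundaries[seg_idx] + 1
    # within a window the run ending at column j is capped at j+1 (runs
    # beginning before the window must not leak in); chunked to bound the
    # n_starts x probe_len temporary
    windows = np.lib.stride_tricks.sliding_window_view(run, probe_len)
    cap = np.arange(1, probe_len + 1)
    max_homo = np.empty(n_starts, dtype=np.int64)
    step = 200_000
    for i in range(0, n_starts, step):
        max_homo[i : i + step] = np.minimum(windows[i : i + step], cap).max(axis=1)

    gc_penalty = np.maximum(0.0, params.gc_low - gc) + np.maximum(0.0, gc - params.gc_high)
    scores = (
        -np.abs(tm - params.target_tm)
        - params.w_gc * gc_penalty
        - params.w_homopolymer * np.maximum(0, max_homo - params.max_ok_homopolymer)
    )
    scores = np.where(any_bad, -np.inf, scores)
    return scores, tm, gc, max_homo


def _design_strand(
    seq: str,
    probe_len: int,
    slide: int,
    window: int,
    offset: int,
    params: ScoreParams,
) -> list[tuple[int, float, float, float, int]]:
    """Best eligible probe start per design window over a linear sequence.

    Returns (start, score, tm, gc, homopolymer) tuples with starts
    relative to ``seq``; duplicate picks from overlapping windows are
    collapsed.
    """
    scores, tm, gc, homo = _score_all_starts(seq, probe_len, params)
    n_starts = scores.size
    if n_starts == 0:
        return []
    anchors = np.arange(offset, n_starts, slide)
    if anchors.size == 0:
        return []
    padded = np.concatenate([scores, np.full(window, -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(padded, window)[anchors]
    best_off = windows.argmax(axis=1)
    best = anchors + best_off
    eligible = np.isfinite(scores[best])
    best = best[eligible]
    # collapse duplicate picks, preserving scan order
    _, first = np.unique(best, return_index=True)
    best = best[np.sort(first)]
    return [
        (int(s), float(scores[s]), float(tm[s]), float(gc[s]), int(homo[s]))
        for s in best
    ]


def design_probes(
    genome: Genome,
    region: tuple[str, int, int],
    probe_len: int = PROBE_LEN,
    slide: int = DEFAULT_SLIDE,
    window: int = DEFAULT_WINDOW,
    reverse_offset: int | None = None,
    params: ScoreParams = ScoreParams(),
) -> ProbeDesign:
    """Tile a target region with locally best probes on both strands.

    Forward and reverse designs are generated independently; the reverse
    design runs on the reverse complement with its first window offset
    by ``reverse_offset`` (default: slide/2 rounded up).  Probes touching
    any masked base are never emitted.
    """
    if slide < 1:
        raise ValueError("slide must be >= 1")
    chrom, start, end = region
    if not (0 <= start < end <= genome.lengths[chrom]):
        raise ValueError(f"region {chrom}:{start}-{end} outside genome")
    if reverse_offset is None:
        reverse_offset = (slide + 1) // 2
    target = genome.sequence(chrom)[start:end]
    if len(target) < probe_len:
        import warnings

        warnings.warn(
            f"region {chrom}:{start}-{end} shorter than probe length {probe_len}; "
            "empty design",
            stacklevel=2,
        )
        return ProbeDesign(chrom, start, end, [], [], slide, window, params)

    forward = [
        Probe(
            chrom, start + s, "+", target[s : s + probe_len].upper(),
            tm, gc, homo, score,
        )
        for s, score, tm, gc, homo in _design_strand(
            target, probe_len, slide, window, 0, params
        )
    ]
    rc = str(Seq(target).reverse_complement())
    reverse = [
        # start in rc coords s maps to genome start = end - s - probe_len
        Probe(
            chrom, end - s - probe_len, "-", rc[s : s + probe_len].upper(),
            tm, gc, homo, score,
        )
        for s, score, tm, gc, homo in _design_strand(
            rc, probe_len, slide, window, reverse_offset, params
        )
    ]
    reverse.sort(key=lambda p: p.start)
    return ProbeDesign(chrom, start, end, forward, reverse, slide, window, params)


class _GenomeIndex:
    """Sorted k-mer code index over the uppercase forward genome.

    Chromosomes are concatenated into one padded coordinate space (with
    sentinel separators so matches never span a boundary); the k-mer
    codes of every genomic position are kept sorted for binary-search
    seed lookup.
    """

    _PAD = 64  # sentinel gap between chromosomes, > probe length

    def __init__(self, genome: Genome, k: int = SEED_LEN):
        if k > 16:
            raise ValueError("seed length must be <= 16")
        self.k = k
        self.names = genome.names
        parts = []
        starts = []
        cursor = 0
        for name, seq in genome.chromosomes:
            starts.append(cursor)
            parts.append(_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)])
            cursor += len(seq)
            parts.append(np.full(self._PAD, -2, dtype=np.int8))
            cursor += self._PAD
        self.chrom_starts = np.array(starts, dtype=np.int64)
        self.codes = np.concatenate(parts).astype(np.int8)
        kmers = _rolling_codes(self.codes.astype(np.int64), k)
        valid = np.flatnonzero(kmers >= 0)
        self.kmer_pos = valid
        order = np.argsort(kmers[valid], kind="stable")
        self.kmer_pos = valid[order]
        self.sorted_kmers = kmers[valid][order]

    def to_local(self, gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self.chrom_starts, gpos, side="right")) - 1
        return self.names[ci], gpos - int(self.chrom_starts[ci])

    def to_global(self, chrom: str, pos: int) -> int:
        return int(self.chrom_starts[self.names.index(chrom)]) + pos

    def candidate_starts(
        self, probe_codes: np.ndarray, seed_step: int = SEED_STEP
    ) -> np.ndarray:
        """Global start coordinates of seed-matched candidate loci."""
        k = self.k
        n = len(probe_codes) - k + 1
        if n <= 0:
            return np.empty(0, dtype=np.int64)
        query = _rolling_codes(probe_codes.astype(np.int64), k)
        keep = np.zeros(n, dtype=bool)
        keep[::seed_step] = True
        keep[n - 1] = True
        valid = np.flatnonzero((query >= 0) & keep)
        if valid.size == 0:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self.sorted_kmers, query[valid], side="left")
        hi = np.searchsorted(self.sorted_kmers, query[valid], side="right")
        starts = []
        for qi, l, h in zip(valid.tolist(), lo.tolist(), hi.tolist()):
            starts.append(self.kmer_pos[l:h] - qi)
        return np.unique(np.concatenate(starts)) if starts else np.empty(0, dtype=np.int64)

    def identity(self, probe_codes: np.ndarray, gstart: int) -> float:
        if gstart < 0 or gstart + len(probe_codes) > len(self.codes):
            return 0.0
        segment = self.codes[gstart : gstart + len(probe_codes)]
        return float(np.mean((probe_codes == segment) & (probe_codes >= 0)))


def _rolling_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer code per k-mer; -1 where any base is non-ACGT."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    view = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = view @ powers
    invalid = (view < 0).any(axis=1)
    return np.where(invalid, -1, vals)


def _probe_codes(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)].astype(np.int64)


def count_hits(
    index: _GenomeIndex, probe: Probe, min_identity: float = DEFAULT_MIN_IDENTITY
) -> int:
    """Genomic loci (both strands) matching above ``min_identity``.

    Ungapped full-probe-length identity, found by k-mer seed and extend;
    the probe's own origin locus counts as one hit.
    """
    n = 0
    fwd = _probe_codes(probe.sequence)
    rev = _probe_codes(str(Seq(probe.sequence).reverse_complement()))
    for codes in (fwd, rev):
        for gstart in index.candidate_starts(codes):
            if index.identity(codes, int(gstart)) > min_identity:
                n += 1
    return n


def _batched_hits(
    index: _GenomeIndex,
    sequences: list[str],
    min_identity: float,
    chunk: int = 200_000,
) -> np.ndarray:
    """Vectorized ``count_hits`` over many equal-length probes."""
    if not sequences:
        return np.empty(0, dtype=np.int64)
    length = len(sequences[0])
    mat = _CODE[
        np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    ].reshape(len(sequences), length).astype(np.int64)
    rc_mat = (3 - mat)[:, ::-1]  # complement code is 3 - code
    k = index.k
    n_all = length - k + 1
    offsets = np.unique(np.append(np.arange(0, n_all, SEED_STEP), n_all - 1))
    n_kmers = offsets.size
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    total_hits = np.zeros(len(sequences), dtype=np.int64)

    for codes in (mat, rc_mat):
        kcodes = np.zeros((len(sequences), n_kmers), dtype=np.int64)
        for t in range(k):
            kcodes += codes[:, offsets + t] * powers[t]
        flat = kcodes.ravel()
        lo = np.searchsorted(index.sorted_kmers, flat, side="left")
        hi = np.searchsorted(index.sorted_kmers, flat, side="right")
        counts = hi - lo
        nz = counts > 0
        if not nz.any():
            continue
        c = counts[nz]
        within = np.arange(int(c.sum())) - np.repeat(np.cumsum(c) - c, c)
        gather = index.kmer_pos[np.repeat(lo[nz], c) + within]
        flat_probe = np.repeat(np.arange(len(sequences)), n_kmers)
        flat_offset = np.tile(offsets, len(sequences))
        probe_idx = np.repeat(flat_probe[nz], c)
        offset_idx = np.repeat(flat_offset[nz], c)
        starts = gather - offset_idx
        # unique (probe, candidate start) pairs
        key = probe_idx * (len(index.codes) + 2 * length) + starts + length
        key_u, key_first = np.unique(key, return_index=True)
        probe_u = probe_idx[key_first]
        start_u = starts[key_first]
        ok = (start_u >= 0) & (start_u + length <= len(index.codes))
        probe_u, start_u = probe_u[ok], start_u[ok]
        for c0 in range(0, len(start_u), chunk):
            p = probe_u[c0 : c0 + chunk]
            s = start_u[c0 : c0 + chunk]
            segs = index.codes[s[:, None] + np.arange(length)]
            ident = ((segs == codes[p]) & (segs >= 0)).mean(axis=1)
            np.add.at(total_hits, p[ident > min_identity], 1)
    return total_hits


def uniqueness_filter(
    design: ProbeDesign,
    genome: Genome,
    max_hits: int = DEFAULT_MAX_HITS,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    seed_len: int = SEED_LEN,
) -> ProbeDesign:
    """Discard probes matching more than ``max_hits`` genomic loci."""
    index = _GenomeIndex(genome, seed_len)
    probes = design.probes
    if probes and len({p.length for p in probes}) == 1:
        hits = _batched_hits(index, [p.sequence for p in probes], min_identity)
    else:
        hits = np.array(
            [count_hits(index, p, min_identity) for p in probes], dtype=np.int64
        )
    annotated = [
        replace(p, n_hits=int(h), kept=bool(h <= max_hits))
        for p, h in zip(probes, hits)
    ]
    n_fwd = len(design.forward)
    return ProbeDesign(
        design.chrom,
        design.region_start,
        design.region_end,
        annotated[:n_fwd],
        annotated[n_fwd:],
        design.slide,
        design.window,
        design.params,
    )
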