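"""Forward simulator of a mutagenesis-and-mapping experiment.

Builds a soft-masked reference genome with an ecotype marker panel,
applies chemically induced point mutations, selfs an F1 hybrid into an
F2 population, sorts the F2 by a recessive phenotype into bulk-segregant
pools, and emits pooled sequencing observations as pileup columns.

Coordinates are 0-based half-open throughout; 1-based coordinates appear
only in the on-disk TSV/VCF formats (see :mod:`ffg.io`).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

MUT = 0  # haplotype segment inherited from the mutagenized ecotype
MAP = 1  # haplotype segment inherited from the mapping ecotype

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

DEFAULT_EMS_RATE = 1.0 / 100_000
DEFAULT_GC_TO_AT_BIAS = 0.85

PoolLabel = Literal["mutant", "wildtype"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMapSegment:
    start: int
    end: int
    cm_per_mb: float


class GeneticMap:
    """Piecewise-constant recombination rates, one track per chromosome.

    Rates are in cM/Mb.  Provides conversion between physical (bp) and
    genetic (Morgan) coordinates and sampling of crossover positions.
    """

    def __init__(self, segments: dict[str, list[GeneticMapSegment]]):
        self.segments = segments
        self._cum: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, segs in segments.items():
            if not segs:
                raise ValueError(f"empty genetic map for chromosome {chrom!r}")
            pos = 0
            for seg in segs:
                if seg.cm_per_mb < 0:
                    raise ValueError("recombination rates must be >= 0")
                if seg.start != pos:
                    raise ValueError(f"genetic map segments must tile {chrom!r}")
                pos = seg.end
            bounds = np.array([s.start for s in segs] + [segs[-1].end], dtype=float)
            rates = np.array([s.cm_per_mb for s in segs], dtype=float)
            # cumulative genetic position (Morgans) at each segment boundary
            morgans = np.concatenate(
                [[0.0], np.cumsum(np.diff(bounds) * rates / 1e6 / 100.0)]
            )
            self._cum[chrom] = (bounds, morgans)

    @classmethod
    def uniform(cls, chrom_lengths: dict[str, int], cm_per_mb: float) -> "GeneticMap":
        return cls(
            {
                chrom: [GeneticMapSegment(0, length, cm_per_mb)]
                for chrom, length in chrom_lengths.items()
            }
        )

    def length_morgans(self, chrom: str) -> float:
        return float(self._cum[chrom][1][-1])

    def bp_to_morgans(self, chrom: str, pos) -> np.ndarray:
        bounds, morgans = self._cum[chrom]
        pos = np.asarray(pos, dtype=float)
        i = np.clip(np.searchsorted(bounds, pos, side="right") - 1, 0, len(bounds) - 2)
        span = bounds[i + 1] - bounds[i]
        frac = np.where(span > 0, (pos - bounds[i]) / np.where(span > 0, span, 1), 0.0)
        return morgans[i] + frac * (morgans[i + 1] - morgans[i])

    def morgans_to_bp(self, chrom: str, d) -> np.ndarray:
        bounds, morgans = self._cum[chrom]
        d = np.asarray(d, dtype=float)
        i = np.clip(np.searchsorted(morgans, d, side="right") - 1, 0, len(morgans) - 2)
        span = morgans[i + 1] - morgans[i]
        frac = np.where(span > 0, (d - morgans[i]) / np.where(span > 0, span, 1), 0.0)
        return bounds[i] + frac * (bounds[i + 1] - bounds[i])

    def sample_crossovers(self, chrom: str, rng: np.random.Generator) -> np.ndarray:
        """Poisson crossover count, positions uniform on the genetic map."""
        total = self.length_morgans(chrom)
        if total <= 0:
            return np.empty(0, dtype=np.int64)
        k = rng.poisson(total)
        if k == 0:
            return np.empty(0, dtype=np.int64)
        d = np.sort(rng.uniform(0.0, total, size=k))
        return np.unique(self.morgans_to_bp(chrom, d).astype(np.int64))


def haldane_r(d_morgans: float) -> float:
    """Recombination fraction for a genetic distance under the Haldane map."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_morgans))


@dataclass
class Genome:
    """Reference sequence with lowercase soft-masking and a genetic map."""

    chromosomes: list[tuple[str, str]]
    genetic_map: GeneticMap

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        for name, seq in self.chromosomes:
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}

    def sequence(self, chrom: str) -> str:
        for name, seq in self.chromosomes:
            if name == chrom:
                return seq
        raise KeyError(chrom)

    def base(self, chrom: str, pos: int) -> str:
        return self.sequence(chrom)[pos]

    def is_masked(self, chrom: str, pos: int) -> bool:
        return self.sequence(chrom)[pos].islower()

    def unmasked_length(self) -> int:
        return sum(sum(1 for b in seq if b.isupper()) for _, seq in self.chromosomes)


@dataclass(frozen=True)
class SnpRecord:
    chrom: str
    pos: int
    ref_allele: str
    map_allele: str


@dataclass
class SnpPanel:
    """Fixed differences between the mutagenized and mapping ecotypes."""

    records: list[SnpRecord]

    def __post_init__(self) -> None:
        last: dict[str, int] = {}
        for rec in self.records:
            if rec.ref_allele.upper() == rec.map_allele.upper():
                raise ValueError(f"SNP at {rec.chrom}:{rec.pos} is not polymorphic")
            if rec.chrom in last and rec.pos <= last[rec.chrom]:
                raise ValueError("SNP positions must be sorted and unique per chromosome")
            last[rec.chrom] = rec.pos

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def positions(self, chrom: str) -> np.ndarray:
        return np.array([r.pos for r in self.records if r.chrom == chrom], dtype=np.int64)

    def position_set(self) -> set[tuple[str, int]]:
        return {(r.chrom, r.pos) for r in self.records}

    def validate_against(self, genome: Genome) -> None:
        for rec in self.records:
            ref = genome.base(rec.chrom, rec.pos)
            if ref.upper() != rec.ref_allele.upper():
                raise ValueError(
                    f"panel ref allele {rec.ref_allele} does not match genome base "
                    f"{ref} at {rec.chrom}:{rec.pos}"
                )


@dataclass(frozen=True)
class Mutation:
    chrom: str
    pos: int
    ref: str
    alt: str
    is_causal: bool = False

    @property
    def is_gc_to_at(self) -> bool:
        return (self.ref.upper(), self.alt.upper()) in {("G", "A"), ("C", "T")}


@dataclass
class MutationSet:
    records: list[Mutation]

    def __post_init__(self) -> None:
        causal = [m for m in self.records if m.is_causal]
        if len(causal) != 1:
            raise ValueError(f"expected exactly one causal mutation, got {len(causal)}")
        for m in self.records:
            if m.ref.upper() == m.alt.upper():
                raise ValueError(f"mutation at {m.chrom}:{m.pos} has ref == alt")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def causal(self) -> Mutation:
        return next(m for m in self.records if m.is_causal)

    def positions(self, chrom: str) -> np.ndarray:
        return np.array([m.pos for m in self.records if m.chrom == chrom], dtype=np.int64)


@dataclass
class Haplotype:
    """One gamete: per chromosome an alternating MUT/MAP segment mosaic.

    Stored as the first segment's origin plus the ordered crossover
    breakpoints; origins alternate at every breakpoint.
    """

    first_origin: dict[str, int]
    breakpoints: dict[str, np.ndarray]
    lengths: dict[str, int]

    def origin_at(self, chrom: str, pos: int) -> int:
        k = bisect_right(self.breakpoints[chrom], pos)
        return (self.first_origin[chrom] + k) % 2

    def origins_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        k = np.searchsorted(self.breakpoints[chrom], positions, side="right")
        return (self.first_origin[chrom] + k) % 2

    def segments(self, chrom: str) -> list[tuple[int, int, int]]:
        """Tiling (start, end, origin) triples for one chromosome."""
        bps = [0, *self.breakpoints[chrom].tolist(), self.lengths[chrom]]
        origin = self.first_origin[chrom]
        out = []
        for start, end in zip(bps[:-1], bps[1:]):
            if end > start:
                out.append((start, end, origin))
            origin = 1 - origin
        return out


@dataclass
class Individual:
    haplotype_a: Haplotype
    haplotype_b: Haplotype
    phenotype: str = field(init=False)
    _causal: tuple[str, int] = ("", -1)

    def __post_init__(self) -> None:
        self.phenotype = "mutant" if self.causal_dosage() == 2 else "wildtype"

    def causal_dosage(self) -> int:
        chrom, pos = self._causal
        return sum(
            h.origin_at(chrom, pos) == MUT for h in (self.haplotype_a, self.haplotype_b)
        )

    def mutation_dosage(self, mutation: Mutation) -> int:
        return sum(
            h.origin_at(mutation.chrom, mutation.pos) == MUT
            for h in (self.haplotype_a, self.haplotype_b)
        )

    def carried_mutations(self, mutations: MutationSet) -> set[tuple[str, int]]:
        return {
            (m.chrom, m.pos) for m in mutations if self.mutation_dosage(m) > 0
        }


@dataclass
class Pool:
    label: PoolLabel
    individuals: list[Individual]

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def is_pure(self) -> bool:
        if self.label == "mutant":
            return all(i.phenotype == "mutant" for i in self.individuals)
        return all(i.phenotype == "wildtype" for i in self.individuals)


@dataclass
class PileupColumn:
    """All sequencing observations covering one genomic position."""

    chrom: str
    pos: int
    bases: np.ndarray  # unicode length-1, in {A,C,G,T,N}
    strands: np.ndarray  # '+'/'-'
    read_starts: np.ndarray  # 0-based
    quals: np.ndarray  # phred ints

    @property
    def depth(self) -> int:
        return len(self.bases)

    def observations(self) -> list[tuple[str, str, int, int]]:
        return list(
            zip(
                self.bases.tolist(),
                self.strands.tolist(),
                self.read_starts.tolist(),
                self.quals.tolist(),
            )
        )

    def take(self, idx: np.ndarray) -> "PileupColumn":
        return PileupColumn(
            self.chrom,
            self.pos,
            self.bases[idx],
            self.strands[idx],
            self.read_starts[idx],
            self.quals[idx],
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def simulate_genome(
    n_chrom: int,
    lengths: Sequence[int],
    snp_density: float,
    masked_fraction: float = 0.0,
    seed: int | None = None,
    cm_per_mb: float = 4.0,
    bin_size: int = 25,
    mask_block_mean: int = 500,
) -> tuple[Genome, SnpPanel]:
    """Generate a random soft-masked genome and an ecotype SNP panel.

    SNP positions are drawn per unmasked base with probability
    ``snp_density``; masked bases never carry panel SNPs.  Densities so
    low that a chromosome expects fewer than ``2 * bin_size`` SNPs are
    rejected because downstream binned mapping would be impossible.
    """
    if n_chrom < 1:
        raise ValueError("need at least one chromosome")
    if len(lengths) != n_chrom:
        raise ValueError("lengths must have one entry per chromosome")
    if any(l <= 0 for l in lengths):
        raise ValueError("chromosome lengths must be positive")
    if not (0.0 <= masked_fraction < 1.0):
        raise ValueError("masked_fraction must be in [0, 1)")
    if snp_density <= 0:
        raise ValueError("snp_density must be > 0")
    for length in lengths:
        if snp_density * length * (1 - masked_fraction) < 2 * bin_size:
            raise ValueError(
                f"snp_density {snp_density} yields fewer than {2 * bin_size} expected "
                f"SNPs on a {length} bp chromosome; mapping would be impossible"
            )

    rng = np.random.default_rng(seed)
    chromosomes: list[tuple[str, str]] = []
    records: list[SnpRecord] = []
    for ci, length in enumerate(lengths):
        name = f"chr{ci + 1}"
        seq = rng.integers(0, 4, size=length)
        masked = np.zeros(length, dtype=bool)
        if masked_fraction > 0:
            # geometric-length blocks until the target masked fraction is hit
            target = int(masked_fraction * length)
            n_masked = 0
            while n_masked < target:
                start = int(rng.integers(0, length))
                block = 1 + int(rng.geometric(1.0 / mask_block_mean))
                end = min(length, start + block)
                newly = int(np.count_nonzero(~masked[start:end]))
                masked[start:end] = True
                n_masked += newly
        chars = _BASES[seq].astype("U1")
        chars[masked] = np.char.lower(chars[masked])
        seq_str = "".join(chars.tolist())

        unmasked_idx = np.flatnonzero(~masked)
        snp_mask = rng.random(unmasked_idx.size) < snp_density
        snp_pos = unmasked_idx[snp_mask]
        alt_offsets = rng.integers(1, 4, size=snp_pos.size)
        for pos, off in zip(snp_pos.tolist(), alt_offsets.tolist()):
            ref = seq_str[pos]
            alt = "ACGT"[(_BASE_INDEX[ref] + int(off)) % 4]
            records.append(SnpRecord(name, pos, ref, alt))
        chromosomes.append((name, seq_str))

    gmap = GeneticMap.uniform({n: len(s) for n, s in chromosomes}, cm_per_mb)
    genome = Genome(chromosomes, gmap)
    panel = SnpPanel(records)
    panel.validate_against(genome)
    return genome, panel


def apply_ems(
    genome: Genome,
    rate: float = DEFAULT_EMS_RATE,
    gc_to_at_bias: float = DEFAULT_GC_TO_AT_BIAS,
    causal_pos: tuple[str, int] | str = "random",
    seed: int | None = None,
    snp_panel: SnpPanel | None = None,
) -> MutationSet:
    """Scatter induced point mutations over the unmasked genome.

    The mutation count is Poisson with mean ``rate`` times the unmasked
    length (floored at one so a causal mutation always exists).  A G or C
    reference base mutates to A or T (the canonical transition) with
    probability ``gc_to_at_bias``.  Mutations never collide with panel
    SNP positions or masked bases.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if not (0.0 <= gc_to_at_bias <= 1.0):
        raise ValueError("gc_to_at_bias must be in [0, 1]")
    rng = np.random.default_rng(seed)
    panel_pos = snp_panel.position_set() if snp_panel is not None else set()

    # eligible positions: unmasked, not a panel SNP (vectorized per chrom)
    chrom_names: list[str] = []
    chrom_eligible: list[np.ndarray] = []
    for name, seq in genome.chromosomes:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        unmasked = np.flatnonzero(arr < ord("a"))  # lowercase = masked
        if snp_panel is not None:
            snp = snp_panel.positions(name)
            if snp.size:
                unmasked = unmasked[~np.isin(unmasked, snp)]
        chrom_names.append(name)
        chrom_eligible.append(unmasked)
    offsets = np.concatenate([[0], np.cumsum([e.size for e in chrom_eligible])])
    total_eligible = int(offsets[-1])
    if total_eligible == 0:
        raise ValueError("genome has no eligible (unmasked, SNP-free) positions")

    def site_at(global_idx: int) -> tuple[str, int]:
        ci = int(np.searchsorted(offsets, global_idx, side="right")) - 1
        return chrom_names[ci], int(chrom_eligible[ci][global_idx - offsets[ci]])

    n = int(rng.poisson(rate * total_eligible))

    if causal_pos == "random":
        causal_chrom, causal_position = site_at(int(rng.integers(total_eligible)))
    else:
        causal_chrom, causal_position = causal_pos  # type: ignore[misc]
        if (causal_chrom, causal_position) in panel_pos:
            raise ValueError("causal position collides with a panel SNP")
        if genome.is_masked(causal_chrom, causal_position):
            raise ValueError("causal position lies on a masked base")

    n_other = max(n, 1) - 1
    idx = rng.choice(total_eligible, size=min(n_other, total_eligible), replace=False)
    sites = [site_at(int(i)) for i in idx]
    sites = [s for s in sites if s != (causal_chrom, causal_position)]
    sites.append((causal_chrom, causal_position))

    records: list[Mutation] = []
    for chrom, pos in sites:
        ref = genome.base(chrom, pos).upper()
        if ref in "GC":
            if rng.random() < gc_to_at_bias:
                alt = "A" if ref == "G" else "T"
            else:
                others = [b for b in "ACGT" if b != ref and b not in ("A" if ref == "G" else "T")]
                alt = others[int(rng.integers(len(others)))]
        else:
            others = [b for b in "ACGT" if b != ref]
            alt = others[int(rng.integers(len(others)))]
        records.append(
            Mutation(chrom, pos, ref, alt, is_causal=(chrom, pos) == (causal_chrom, causal_position))
        )
    records.sort(key=lambda m: (m.chrom, m.pos))
    return MutationSet(records)


def _make_gamete(genome: Genome, rng: np.random.Generator) -> Haplotype:
    first_origin: dict[str, int] = {}
    breakpoints: dict[str, np.ndarray] = {}
    for chrom in genome.names:
        first_origin[chrom] = int(rng.integers(2))
        breakpoints[chrom] = genome.genetic_map.sample_crossovers(chrom, rng)
    return Haplotype(first_origin, breakpoints, genome.lengths)


def simulate_f2(
    genome: Genome,
    snp_panel: SnpPanel,
    mutations: MutationSet,
    n_f2: int,
    seed: int | None = None,
) -> list[Individual]:
    """Self an F1 hybrid into ``n_f2`` F2 individuals.

    Each F2 is formed from two independent F1 gametes.  Per gamete the
    crossover count per chromosome is Poisson with mean equal to the map
    length in Morgans and crossovers are placed uniformly on the genetic
    map (no interference).  The phenotype is mutant iff both haplotypes
    carry the causal allele.
    """
    if n_f2 < 1:
        raise ValueError("n_f2 must be >= 1")
    rng = np.random.default_rng(seed)
    causal = mutations.causal
    out = []
    for _ in range(n_f2):
        a = _make_gamete(genome, rng)
        b = _make_gamete(genome, rng)
        out.append(Individual(a, b, _causal=(causal.chrom, causal.pos)))
    return out


def build_pools(
    individuals: Sequence[Individual],
    pool_size: int = 200,
    seed: int | None = None,
    missort_rate: float = 0.0,
) -> tuple[Pool, Pool]:
    """Draw phenotype-sorted bulk pools without replacement.

    ``missort_rate`` swaps ``round(rate * pool_size)`` randomly chosen
    members across the two pools after drawing, modeling phenotyping
    mistakes at the sorting bench.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if not (0.0 <= missort_rate < 1.0):
        raise ValueError("missort_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mutants = [i for i in individuals if i.phenotype == "mutant"]
    wildtypes = [i for i in individuals if i.phenotype == "wildtype"]
    for label, avail in (("mutant", mutants), ("wildtype", wildtypes)):
        if len(avail) < pool_size:
            raise ValueError(
                f"pool_size {pool_size} exceeds available {label} individuals "
                f"({len(avail)}); short by {pool_size - len(avail)}"
            )
    mut_sel = [mutants[i] for i in rng.choice(len(mutants), pool_size, replace=False)]
    wt_sel = [wildtypes[i] for i in rng.choice(len(wildtypes), pool_size, replace=False)]
    n_swap = int(round(missort_rate * pool_size))
    if n_swap:
        mi = rng.choice(pool_size, n_swap, replace=False)
        wi = rng.choice(pool_size, n_swap, replace=False)
        for a, b in zip(mi.tolist(), wi.tolist()):
            mut_sel[a], wt_sel[b] = wt_sel[b], mut_sel[a]
    return Pool("mutant", mut_sel), Pool("wildtype", wt_sel)


def _pool_allele_vectors(
    pool: Pool,
    genome: Genome,
    snp_panel: SnpPanel,
    mutations: MutationSet,
    chrom: str,
    positions: np.ndarray,
) -> np.ndarray:
    """(2n, P) matrix of base codes carried by each pool haplotype."""
    seq = genome.sequence(chrom)
    ref_codes = np.array([_BASE_INDEX[seq[p].upper()] for p in positions.tolist()], dtype=np.uint8)
    mut_codes = ref_codes.copy()  # allele if the haplotype is MUT-origin
    map_codes = ref_codes.copy()  # allele if the haplotype is MAP-origin
    pos_index = {int(p): i for i, p in enumerate(positions)}
    for m in mutations:
        if m.chrom == chrom and m.pos in pos_index:
            mut_codes[pos_index[m.pos]] = _BASE_INDEX[m.alt.upper()]
    for r in snp_panel:
        if r.chrom == chrom and r.pos in pos_index:
            map_codes[pos_index[r.pos]] = _BASE_INDEX[r.map_allele.upper()]

    haplotypes = [h for ind in pool.individuals for h in (ind.haplotype_a, ind.haplotype_b)]
    alleles = np.empty((len(haplotypes), len(positions)), dtype=np.uint8)
    for hi, hap in enumerate(haplotypes):
        origins = hap.origins_at(chrom, positions)
        alleles[hi] = np.where(origins == MAP, map_codes, mut_codes)
    return alleles


def variant_positions(
    snp_panel: SnpPanel, mutations: MutationSet, chrom: str
) -> np.ndarray:
    both = np.concatenate([snp_panel.positions(chrom), mutations.positions(chrom)])
    return np.unique(both)


def recombinant_flank_interval(
    individuals: Iterable[Individual], genome: Genome, chrom: str, causal_pos: int
) -> tuple[int, int, float]:
    """Minimal mapping interval bounded by the nearest crossovers.

    Scans every haplotype that carries the mutagenized-ecotype origin at
    ``causal_pos`` and returns the tightest (left, right) physical bounds
    set by the nearest flanking crossover breakpoints across the pool
    (chromosome ends when no crossover flanks the locus), plus the
    interval's genetic length in centiMorgans.
    """
    left = 0
    right = genome.lengths[chrom]
    for ind in individuals:
        for hap in (ind.haplotype_a, ind.haplotype_b):
            if hap.origin_at(chrom, causal_pos) != MUT:
                continue
            bps = hap.breakpoints[chrom]
            i = int(np.searchsorted(bps, causal_pos, side="right"))
            if i > 0:
                left = max(left, int(bps[i - 1]))
            if i < len(bps):
                right = min(right, int(bps[i]))
    gmap = genome.genetic_map
    cm = 100.0 * float(
        gmap.bp_to_morgans(chrom, right) - gmap.bp_to_morgans(chrom, left)
    )
    return left, right, cm


def sequence_pool(
    pool: Pool,
    genome: Genome,
    snp_panel: SnpPanel,
    mutations: MutationSet,
    positions: Literal["variants", "all"] | dict[str, np.ndarray] = "variants",
    depth: float = 10.0,
    error_rate: float = 1e-3,
    read_len: int = 50,
    seed: int | None = None,
) -> list[PileupColumn]:
    """Simulate pooled shotgun sequencing as per-position pileup columns.

    Per position the coverage is Poisson(``depth``); each observation
    samples one of the ``2n`` pool haplotypes uniformly with replacement,
    reads its allele, and substitutes a uniformly chosen different base
    with probability ``error_rate``.  ``positions`` selects the emitted
    columns: ``"variants"`` (panel SNP and mutation sites — the compact
    default), ``"all"`` (every base; use on small genomes only), or an
    explicit per-chromosome position mapping.
    """
    if pool.n == 0:
        raise ValueError("cannot sequence an empty pool")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not (0.0 <= error_rate < 0.25):
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    base_qual = 40 if error_rate == 0 else max(2, int(round(-10 * math.log10(error_rate))))

    columns: list[PileupColumn] = []
    for chrom in genome.names:
        if positions == "variants":
            pos = variant_positions(snp_panel, mutations, chrom)
        elif positions == "all":
            pos = np.arange(genome.lengths[chrom], dtype=np.int64)
        else:
            pos = np.asarray(positions.get(chrom, np.empty(0, dtype=np.int64)), dtype=np.int64)
        if pos.size == 0:
            continue
        alleles = _pool_allele_vectors(pool, genome, snp_panel, mutations, chrom, pos)
        n_hap = alleles.shape[0]

        cov = rng.poisson(depth, size=pos.size)
        total = int(cov.sum())
        if total == 0:
            continue
        pos_idx = np.repeat(np.arange(pos.size), cov)
        hap_idx = rng.integers(0, n_hap, size=total)
        codes = alleles[hap_idx, pos_idx]
        err = rng.random(total) < error_rate
        if err.any():
            codes = np.where(
                err, (codes + rng.integers(1, 4, size=total)) % 4, codes
            ).astype(np.uint8)
        strands = np.where(rng.random(total) < 0.5, "+", "-")
        offsets = rng.integers(0, read_len, size=total)
        starts = np.maximum(0, pos[pos_idx] - offsets)
        quals = base_qual + rng.integers(-3, 4, size=total)
        quals = np.maximum(2, quals)

        base_chars = _BASES.astype("U1")[codes]
        bounds = np.concatenate([[0], np.cumsum(cov)])
        for i in range(pos.size):
            lo, hi = int(bounds[i]), int(bounds[i + 1])
            if hi == lo:
                continue
            columns.append(
                PileupColumn(
                    chrom,
                    int(pos[i]),
                    base_chars[lo:hi],
                    strands[lo:hi],
                    starts[lo:hi].astype(np.int64),
                    quals[lo:hi].astype(np.int64),
                )
            )
    return columns
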