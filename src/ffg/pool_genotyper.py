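"""Pooled SNP discovery and genotyping under strict read-level filters.

Variant discovery runs on the merged pools (the "virtual F1", which is
heterozygous at every ecotype polymorphism); discovered variable
positions are then genotyped per pool, including an explicit
fully-reference check.

Filter criteria per called allele: minimum accepted-read coverage,
more-than-three unique read start sites, a phred-scaled variant quality
above 10, variant alleles observed on both strands, and a clonality cap
of twice the pool's individual count on identical reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.stats import binom

from ffg.synthetic_cross import Genome, PileupColumn

logger = logging.getLogger(__name__)

PASS = "PASS"
FAIL = "FAIL"
FULLY_REFERENCE = "FULLY_REFERENCE"

DEFAULT_ERROR_PRIOR = 1e-3
MAX_PHRED = 1000.0


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds for accepting a pooled variant call.

    ``max_identical_reads_per_allele`` defaults to None, meaning "twice
    the number of pooled individuals"; resolve it with
    :meth:`with_pool_size` before calling.
    """

    min_coverage: int = 20
    min_unique_starts_per_allele: int = 4  # "more than 3"
    min_variant_quality: float = 10.0  # strict: quality must exceed this
    require_both_strands: bool = True
    max_identical_reads_per_allele: int | None = None
    # an allele is subject to the unique-start rule once it reaches this
    # fraction of accepted reads (keeps near-fixed sites from failing on
    # a couple of error reads carrying the reference base)
    min_called_fraction: float = 0.10
    unique_starts_include_strand: bool = False

    def __post_init__(self) -> None:
        if self.min_coverage < 0 or self.min_unique_starts_per_allele < 0:
            raise ValueError("thresholds must be >= 0")
        if self.max_identical_reads_per_allele is not None and self.max_identical_reads_per_allele < 1:
            raise ValueError("max_identical_reads_per_allele must be >= 1")

    def with_pool_size(self, n_individuals: int) -> "FilterCriteria":
        if self.max_identical_reads_per_allele is not None:
            return self
        return replace(self, max_identical_reads_per_allele=2 * n_individuals)


#: relaxed criteria used when genotyping a single pool at already
#: discovered positions (raw read counting; the strict filter belongs to
#: the discovery phase on the merged pools)
GENOTYPING_CRITERIA = FilterCriteria(
    min_coverage=0,
    min_unique_starts_per_allele=0,
    min_variant_quality=0.0,
    require_both_strands=False,
)


@dataclass
class SnpCall:
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str | None
    ref_fwd: int
    ref_rev: int
    alt_fwd: int
    alt_rev: int
    variant_quality: float
    status: str
    fail_reasons: frozenset[str] = frozenset()

    @property
    def ref_reads(self) -> int:
        return self.ref_fwd + self.ref_rev

    @property
    def alt_reads(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def nonref_fraction(self) -> float:
        total = self.ref_reads + self.alt_reads
        return self.alt_reads / total if total else 0.0


def merge_virtual_f1(
    mutant_pileup: Iterable[PileupColumn],
    wildtype_pileup: Iterable[PileupColumn],
) -> list[PileupColumn]:
    """Position-wise concatenation of two sorted pileup streams.

    Inputs must be sorted by (chromosome appearance order, position);
    unsorted input raises instead of silently re-sorting.
    """
    streams = [_checked_sorted(mutant_pileup), _checked_sorted(wildtype_pileup)]
    by_pos: dict[tuple[str, int], list[PileupColumn]] = {}
    order: list[tuple[str, int]] = []
    for stream in streams:
        for col in stream:
            key = (col.chrom, col.pos)
            if key not in by_pos:
                by_pos[key] = []
                order.append(key)
            by_pos[key].append(col)
    order.sort(key=lambda k: (_chrom_rank(streams, k[0]), k[1]))
    merged = []
    for key in order:
        cols = by_pos[key]
        if len(cols) == 1:
            merged.append(cols[0])
        else:
            merged.append(
                PileupColumn(
                    cols[0].chrom,
                    cols[0].pos,
                    np.concatenate([c.bases for c in cols]),
                    np.concatenate([c.strands for c in cols]),
                    np.concatenate([c.read_starts for c in cols]),
                    np.concatenate([c.quals for c in cols]),
                )
            )
    return merged


def _checked_sorted(stream: Iterable[PileupColumn]) -> list[PileupColumn]:
    cols = list(stream)
    seen: dict[str, int] = {}
    last_pos = -1
    current = None
    for col in cols:
        if col.chrom != current:
            if col.chrom in seen:
                raise ValueError(f"pileup stream not sorted: chromosome {col.chrom} revisited")
            seen[col.chrom] = len(seen)
            current = col.chrom
            last_pos = -1
        if col.pos <= last_pos:
            raise ValueError(
                f"pileup stream not sorted at {col.chrom}:{col.pos} (previous {last_pos})"
            )
        last_pos = col.pos
    return cols


def _chrom_rank(streams: list[list[PileupColumn]], chrom: str) -> int:
    for stream in streams:
        for i, col in enumerate(stream):
            if col.chrom == chrom:
                return i
    return 0


def clonality_cap(column: PileupColumn, cap: int) -> PileupColumn:
    """Retain at most ``cap`` observations per (allele, read start, strand).

    Within each identity group the highest-quality observations are kept,
    ties broken by input order, suppressing PCR/optical clonality.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    n = column.depth
    if n == 0:
        return column
    base_codes = np.searchsorted(np.array(list("ACGNT")), column.bases)
    strand_codes = column.strands == "+"
    # sort by group then quality desc then input order; stable within keys
    order = np.lexsort((np.arange(n), -column.quals, column.read_starts, strand_codes, base_codes))
    sorted_groups = np.stack(
        [base_codes[order], strand_codes[order], column.read_starts[order]]
    )
    new_group = np.ones(n, dtype=bool)
    new_group[1:] = (np.diff(sorted_groups, axis=1) != 0).any(axis=0)
    group_id = np.cumsum(new_group) - 1
    rank_in_group = np.arange(n) - np.concatenate([[0], np.flatnonzero(new_group[1:]) + 1])[group_id]
    keep_sorted = rank_in_group < cap
    keep = np.zeros(n, dtype=bool)
    keep[order[keep_sorted]] = True
    return column.take(np.flatnonzero(keep))


def variant_quality_phred(
    alt_count: int, coverage: int, error_rate_prior: float
) -> float:
    """Phred-scaled probability that >= alt_count reads arise from error alone."""
    if alt_count <= 0:
        return 0.0
    if error_rate_prior <= 0:
        return MAX_PHRED
    p = float(binom.sf(alt_count - 1, coverage, error_rate_prior))
    if p <= 0:
        return MAX_PHRED
    return min(MAX_PHRED, -10.0 * np.log10(p))


def call_snp(
    column: PileupColumn,
    ref_base: str,
    criteria: FilterCriteria,
    error_rate_prior: float = DEFAULT_ERROR_PRIOR,
    alt_allele: str | None = None,
    ambiguous_fraction: float = 0.10,
) -> SnpCall:
    """Evaluate one pileup column against the filter criteria.

    ``alt_allele`` forces the variant allele (used when genotyping a pool
    at an already discovered site); otherwise the most frequent non-
    reference base is taken.  A third allele above ``ambiguous_fraction``
    of accepted reads marks the site ambiguous (excluded from binning).
    """
    ref_base = ref_base.upper()
    cap = criteria.max_identical_reads_per_allele
    if cap is None:
        raise ValueError("criteria.max_identical_reads_per_allele unresolved; "
                         "call FilterCriteria.with_pool_size first")
    col = clonality_cap(column, cap)
    valid = col.bases != "N"
    col = col.take(np.flatnonzero(valid))
    coverage = col.depth

    counts = {b: int(np.count_nonzero(col.bases == b)) for b in "ACGT"}
    if alt_allele is None:
        nonref = sorted(
            ((c, b) for b, c in counts.items() if b != ref_base), reverse=True
        )
        alt = nonref[0][1] if nonref and nonref[0][0] > 0 else None
    else:
        alt = alt_allele.upper()

    def strand_counts(base: str | None) -> tuple[int, int]:
        if base is None:
            return 0, 0
        mask = col.bases == base
        fwd = int(np.count_nonzero(mask & (col.strands == "+")))
        return fwd, int(np.count_nonzero(mask)) - fwd

    ref_fwd, ref_rev = strand_counts(ref_base)
    alt_fwd, alt_rev = strand_counts(alt)
    alt_count = alt_fwd + alt_rev
    ref_count = ref_fwd + ref_rev

    reasons: set[str] = set()
    if coverage < criteria.min_coverage:
        reasons.add("min_coverage")

    if alt is None or alt_count == 0:
        if reasons:
            status = FAIL
        else:
            status = FULLY_REFERENCE
        return SnpCall(
            column.chrom, column.pos, ref_base, alt, ref_fwd, ref_rev, 0, 0,
            0.0, status, frozenset(reasons),
        )

    quality = variant_quality_phred(alt_count, coverage, error_rate_prior)
    if not quality > criteria.min_variant_quality:
        reasons.add("variant_quality")
    if criteria.require_both_strands and (alt_fwd == 0 or alt_rev == 0):
        reasons.add("both_strands")

    if criteria.min_unique_starts_per_allele > 0:
        for base, count in ((ref_base, ref_count), (alt, alt_count)):
            if count == 0:
                continue
            if coverage and count / coverage < criteria.min_called_fraction and base == ref_base:
                continue  # reference residue too small to be a called allele
            mask = col.bases == base
            if criteria.unique_starts_include_strand:
                starts = set(zip(col.read_starts[mask].tolist(), col.strands[mask].tolist()))
            else:
                starts = set(col.read_starts[mask].tolist())
            if len(starts) < criteria.min_unique_starts_per_allele:
                reasons.add("unique_starts")

    third = sum(
        c for b, c in counts.items() if b not in (ref_base, alt)
    )
    if coverage and third / coverage > ambiguous_fraction:
        reasons.add("ambiguous")

    status = PASS if not reasons else FAIL
    return SnpCall(
        column.chrom, column.pos, ref_base, alt, ref_fwd, ref_rev, alt_fwd, alt_rev,
        quality, status, frozenset(reasons),
    )


def discover_and_genotype(
    mutant_pileup: Iterable[PileupColumn],
    wildtype_pileup: Iterable[PileupColumn],
    genome: Genome,
    criteria: FilterCriteria,
    error_rate_prior: float = DEFAULT_ERROR_PRIOR,
    genotype_criteria: FilterCriteria | None = None,
) -> tuple[dict[str, list[SnpCall]], list[tuple[str, int]]]:
    """Discover variable positions on the virtual F1, genotype each pool.

    Returns per-pool calls (keys ``"mutant"``/``"wildtype"``) at exactly
    the discovered positions, plus the variable-position list.  Per-pool
    genotyping counts accepted reads for the discovered alleles under
    ``genotype_criteria`` (default: relaxed raw-read counting with the
    same clonality cap) so low-coverage pools still contribute to binned
    mapping; sites with no variant reads come back FULLY_REFERENCE.
    """
    mutant_cols = _checked_sorted(mutant_pileup)
    wildtype_cols = _checked_sorted(wildtype_pileup)
    merged = merge_virtual_f1(mutant_cols, wildtype_cols)
    gcrit = genotype_criteria or GENOTYPING_CRITERIA
    if gcrit.max_identical_reads_per_allele is None:
        gcrit = replace(
            gcrit,
            max_identical_reads_per_allele=criteria.max_identical_reads_per_allele,
        )

    variable: list[tuple[str, int]] = []
    alt_by_site: dict[tuple[str, int], str] = {}
    for col in merged:
        try:
            ref = genome.base(col.chrom, col.pos).upper()
            call = call_snp(col, ref, criteria, error_rate_prior)
        except Exception:  # pragma: no cover - per-site robustness
            logger.exception("SNP discovery failed at %s:%d", col.chrom, col.pos)
            continue
        if call.status == PASS and call.alt_allele is not None:
            variable.append((col.chrom, col.pos))
            alt_by_site[(col.chrom, col.pos)] = call.alt_allele

    calls: dict[str, list[SnpCall]] = {"mutant": [], "wildtype": []}
    for label, cols in (("mutant", mutant_cols), ("wildtype", wildtype_cols)):
        by_site = {(c.chrom, c.pos): c for c in cols}
        for site in variable:
            ref = genome.base(site[0], site[1]).upper()
            col = by_site.get(site)
            if col is None:
                col = PileupColumn(
                    site[0], site[1],
                    np.empty(0, dtype="U1"), np.empty(0, dtype="U1"),
                    np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
                )
            try:
                # ambiguity is disabled here so both pools stay genotyped at
                # exactly the same sites (bins must align across pools)
                call = call_snp(
                    col, ref, gcrit, error_rate_prior,
                    alt_allele=alt_by_site[site], ambiguous_fraction=1.1,
                )
            except Exception:  # pragma: no cover
                logger.exception("genotyping failed at %s:%d (%s)", site[0], site[1], label)
                continue
            calls[label].append(call)
    return calls, variable
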