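"""Binned mapping-allele-frequency analysis and linked-region detection.

The mapping statistic: reads at discovered ecotype SNPs are pooled over
consecutive windows of 25 SNPs per chromosome and the mapping-allele
fraction per bin is compared between the mutant and wild-type pools.  A
linked region shows the mutant pool's fraction dropping toward 0 and the
wild-type pool's rising toward 2/3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ffg.pool_genotyper import FULLY_REFERENCE, PASS, SnpCall

DEFAULT_BIN_SIZE = 25
DEFAULT_DIP_THRESHOLD = 0.25
DEFAULT_WT_THRESHOLD = 0.55
DEFAULT_STRONG_DIP = 0.10
MIN_RUN_BINS = 2
DEFAULT_MERGE_GAP_BINS = 3


@dataclass
class BinFrequency:
    chrom: str
    bin_index: int
    start: int  # position of the bin's first SNP (0-based)
    end: int  # position just past the bin's last SNP
    n_snps: int
    ref_read_total: int
    map_read_total: int

    @property
    def map_fraction(self) -> float:
        total = self.ref_read_total + self.map_read_total
        return self.map_read_total / total if total else float("nan")


@dataclass
class LinkageRegion:
    chrom: str
    start: int
    end: int
    min_bin_index: int
    min_map_fraction: float
    wt_support_fraction: float
    n_bins: int
    supported: bool


def bin_frequencies(
    calls: Sequence[SnpCall],
    bin_size: int = DEFAULT_BIN_SIZE,
    mode: str = "pooled",
) -> list[BinFrequency]:
    """Pool reads over consecutive runs of ``bin_size`` genotyped SNPs.

    Only PASS and FULLY_REFERENCE calls contribute; bins never span
    chromosomes.  In the default ``pooled`` mode raw reads are summed
    across the bin's SNPs before the ratio is taken; ``mean`` averages
    per-SNP fractions instead (comparison mode).  A trailing bin smaller
    than half of ``bin_size`` is dropped.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if mode not in ("pooled", "mean"):
        raise ValueError(f"unknown binning mode {mode!r}")
    usable = [c for c in calls if c.status in (PASS, FULLY_REFERENCE)]
    by_chrom: dict[str, list[SnpCall]] = {}
    for c in usable:
        by_chrom.setdefault(c.chrom, []).append(c)

    bins: list[BinFrequency] = []
    for chrom, chrom_calls in by_chrom.items():
        pos = [c.pos for c in chrom_calls]
        if pos != sorted(pos):
            raise ValueError(f"calls must be sorted by position on {chrom}")
        for bi in range(0, len(chrom_calls), bin_size):
            chunk = chrom_calls[bi : bi + bin_size]
            if len(chunk) < bin_size and len(chunk) < bin_size / 2:
                continue
            ref_total = sum(c.ref_reads for c in chunk)
            map_total = sum(c.alt_reads for c in chunk)
            b = BinFrequency(
                chrom,
                bi // bin_size,
                chunk[0].pos,
                chunk[-1].pos + 1,
                len(chunk),
                ref_total,
                map_total,
            )
            if mode == "mean":
                fracs = [
                    c.nonref_fraction for c in chunk if c.ref_reads + c.alt_reads > 0
                ]
                if fracs:
                    # represent the mean fraction with a fixed pseudo-denominator
                    mean = float(np.mean(fracs))
                    b.map_read_total = int(round(mean * 10_000))
                    b.ref_read_total = 10_000 - b.map_read_total
            bins.append(b)
    return bins


def expected_map_fraction(pool_label: str, r: float) -> float:
    """Expected mapping-allele frequency at recombination fraction ``r``.

    Closed forms from conditioning the F2 genotype distribution on the
    recessive phenotype: the mutant pool converges to ``r`` (0 at the
    causal locus) and the wild-type pool to ``(2 - r) / 3`` (2/3 at the
    causal locus); both give 1/2 for unlinked markers (r = 1/2).
    """
    if not (0.0 <= r <= 0.5):
        raise ValueError("recombination fraction must be in [0, 0.5]")
    if pool_label == "mutant":
        return r
    if pool_label == "wildtype":
        return (2.0 - r) / 3.0
    raise ValueError(f"unknown pool label {pool_label!r}")


def single_allele_frequency(n_individuals: int) -> float:
    """Frequency contributed by one allele copy in a diploid pool."""
    if n_individuals < 1:
        raise ValueError("pool must contain at least one individual")
    return 1.0 / (2 * n_individuals)


def error_floor_accuracy(n_individuals: int) -> float:
    """Sequencing accuracy (%) at which per-base error equals the
    single-allele frequency of a diploid pool; above this pool size,
    single crossover events drown in sequencing noise."""
    return (1.0 - single_allele_frequency(n_individuals)) * 100.0


def detect_linkage(
    mutant_bins: Sequence[BinFrequency],
    wildtype_bins: Sequence[BinFrequency],
    dip_threshold: float = DEFAULT_DIP_THRESHOLD,
    wt_threshold: float = DEFAULT_WT_THRESHOLD,
    min_run: int = MIN_RUN_BINS,
    merge_gap_bins: int = DEFAULT_MERGE_GAP_BINS,
    strong_dip_threshold: float = DEFAULT_STRONG_DIP,
) -> list[LinkageRegion]:
    """Find maximal runs of low mapping-allele bins in the mutant pool.

    A region is a run of at least ``min_run`` consecutive mutant-pool
    bins with map_fraction below ``dip_threshold``; runs on the same
    chromosome separated by at most ``merge_gap_bins`` above-threshold
    bins are merged (the dip's shoulders flicker around the threshold).
    A region is flagged supported when the wild-type pool's mean
    fraction over the same bins exceeds ``wt_threshold`` and the
    region's lowest bin falls below ``strong_dip_threshold`` (the
    mapping fraction is expected to approach 0 at the causal locus;
    shoulder runs hovering just under ``dip_threshold`` are not
    causal-locus evidence).  Regions are
    ranked by their minimum bin fraction, lowest first.  Both bin lists
    must come from the same SNP set (same chrom/bin_index/n_snps per
    bin).
    """
    if len(mutant_bins) != len(wildtype_bins):
        raise ValueError("mutant and wild-type bin lists differ in length")
    for mb, wb in zip(mutant_bins, wildtype_bins):
        if (mb.chrom, mb.bin_index, mb.n_snps) != (wb.chrom, wb.bin_index, wb.n_snps):
            raise ValueError(
                f"bin mismatch at {mb.chrom}:{mb.bin_index}: pools were binned "
                "over different SNP sets"
            )

    # collect maximal low runs per chromosome, then merge across short gaps
    runs: list[list[int]] = []
    run: list[int] = []
    prev_chrom = None
    for i, b in enumerate(mutant_bins):
        low = (not np.isnan(b.map_fraction)) and b.map_fraction < dip_threshold
        if b.chrom != prev_chrom or not low:
            if run:
                runs.append(run)
            run = []
        if low:
            run.append(i)
        prev_chrom = b.chrom
    if run:
        runs.append(run)

    merged: list[list[int]] = []
    for r in runs:
        if (
            merged
            and mutant_bins[r[0]].chrom == mutant_bins[merged[-1][-1]].chrom
            and r[0] - merged[-1][-1] - 1 <= merge_gap_bins
        ):
            merged[-1] = merged[-1] + list(range(merged[-1][-1] + 1, r[0])) + r
        else:
            merged.append(r)

    regions: list[LinkageRegion] = []

    def flush(run_idx: list[int]) -> None:
        if len(run_idx) < min_run:
            return
        mbins = [mutant_bins[i] for i in run_idx]
        wbins = [wildtype_bins[i] for i in run_idx]
        wt_mean = float(
            np.mean([b.map_fraction for b in wbins if not np.isnan(b.map_fraction)])
        )
        min_i = min(run_idx, key=lambda i: mutant_bins[i].map_fraction)
        regions.append(
            LinkageRegion(
                chrom=mbins[0].chrom,
                start=mbins[0].start,
                end=mbins[-1].end,
                min_bin_index=mutant_bins[min_i].bin_index,
                min_map_fraction=float(mutant_bins[min_i].map_fraction),
                wt_support_fraction=wt_mean,
                n_bins=len(run_idx),
                supported=(
                    wt_mean > wt_threshold
                    and mutant_bins[min_i].map_fraction < strong_dip_threshold
                ),
            )
        )

    for r in merged:
        flush(r)

    regions.sort(key=lambda r: r.min_map_fraction)
    return regions
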