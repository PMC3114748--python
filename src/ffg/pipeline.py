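"""End-to-end orchestration: simulate, genotype, map, design, call.

The pipeline runs the two-step procedure — light pooled sequencing for
binned linkage mapping, then enriched deep sequencing of the detected
interval for candidate calling — either on a fully simulated cross (the
default test surface) or on user-supplied files.  All stage outputs are
written in the plain-text formats of :mod:`ffg.io`, and simulate mode
always reports a truth comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from ffg import bsa_mapper, candidate_finder, io, pool_genotyper, probe_designer
from ffg import synthetic_cross as sc

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every knob of the pipeline, with explicit seeds throughout."""

    mode: str = "simulate"
    outdir: str = "ffg_run"
    seed: int = 0

    # genome / panel
    n_chrom: int = 1
    chrom_lengths: list[int] = field(default_factory=lambda: [10_000_000])
    snp_density: float = 1e-3
    masked_fraction: float = 0.0
    cm_per_mb: float = 4.0

    # mutagenesis
    ems_rate: float = sc.DEFAULT_EMS_RATE
    gc_to_at_bias: float = sc.DEFAULT_GC_TO_AT_BIAS
    causal_pos: Any = "random"

    # cross and pools
    n_f2: int = 1000
    pool_size: int = 200
    missort_rate: float = 0.0

    # sequencing
    light_depth: float = 10.0
    enriched_depth: float = 1600.0
    on_target_fraction: float = 0.87
    error_rate: float = 1e-3
    read_len: int = 50

    # genotyping / mapping
    min_coverage: int = 20
    bin_size: int = 25
    dip_threshold: float = 0.25
    wt_threshold: float = 0.55

    # candidates / enrichment
    freq_threshold: float = 0.70
    capture_width: int = 1_000_000
    design_capture_probes: bool = True

    # probes
    probe_slide: int = 2
    probe_window: int = 10

    # real-data inputs
    genome_fasta: str | None = None
    mutant_pileup: str | None = None
    wildtype_pileup: str | None = None
    enriched_pileup: str | None = None
    snp_panel_tsv: str | None = None
    gff3: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    version: str
    mode: str
    n_variable_positions: int = 0
    n_bins: int = 0
    n_regions_supported: int = 0
    regions: list[dict] = field(default_factory=list)
    n_probes_kept: int = 0
    n_candidates: int = 0
    candidates: list[dict] = field(default_factory=list)
    truth: dict | None = None
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


@dataclass
class _SimulatedExperiment:
    genome: sc.Genome
    panel: sc.SnpPanel
    mutations: sc.MutationSet
    mutant_pool: sc.Pool
    wildtype_pool: sc.Pool


def _valley_center(chrom_bins: list, smooth_window: int = 15) -> int:
    """Physical midpoint of the lowest smoothed stretch of a bin track."""
    fr = np.array(
        [0.5 if np.isnan(b.map_fraction) else b.map_fraction for b in chrom_bins]
    )
    w = min(smooth_window, len(fr))
    kernel = np.ones(w)
    smooth = np.convolve(fr, kernel, "same") / np.convolve(
        np.ones_like(fr), kernel, "same"
    )
    low = np.flatnonzero(smooth <= smooth.min() + 1e-12)
    # middle of the longest contiguous low run
    runs = np.split(low, np.flatnonzero(np.diff(low) > 1) + 1)
    run = max(runs, key=len)
    mid = chrom_bins[int(run[len(run) // 2])]
    return (mid.start + mid.end) // 2


def _derive_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def simulate_experiment(
    config: RunConfig, genome_panel: tuple[sc.Genome, sc.SnpPanel] | None = None
) -> _SimulatedExperiment:
    """Build the simulated cross shared by the pipeline stages."""
    if genome_panel is None:
        genome, panel = sc.simulate_genome(
            config.n_chrom,
            config.chrom_lengths,
            config.snp_density,
            config.masked_fraction,
            seed=_derive_seed(config.seed, "genome"),
            cm_per_mb=config.cm_per_mb,
            bin_size=config.bin_size,
        )
    else:
        genome, panel = genome_panel
    causal = (
        tuple(config.causal_pos)
        if isinstance(config.causal_pos, (list, tuple))
        else config.causal_pos
    )
    mutations = sc.apply_ems(
        genome,
        rate=config.ems_rate,
        gc_to_at_bias=config.gc_to_at_bias,
        causal_pos=causal,
        seed=_derive_seed(config.seed, "ems"),
        snp_panel=panel,
    )
    f2 = sc.simulate_f2(
        genome, panel, mutations, config.n_f2, seed=_derive_seed(config.seed, "f2")
    )
    mutant_pool, wildtype_pool = sc.build_pools(
        f2,
        pool_size=config.pool_size,
        seed=_derive_seed(config.seed, "pools"),
        missort_rate=config.missort_rate,
    )
    return _SimulatedExperiment(genome, panel, mutations, mutant_pool, wildtype_pool)


def run_pipeline(
    config: RunConfig,
    write_files: bool = True,
    genome_panel: tuple[sc.Genome, sc.SnpPanel] | None = None,
) -> RunReport:
    """Execute simulate -> genotype -> map -> probes -> deep -> candidates."""
    outdir = Path(config.outdir)
    if write_files:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
    report = RunReport(config.config_hash(), _version(), config.mode)
    timer = _StageTimer(report)

    if config.mode == "simulate":
        with timer("simulate"):
            exp = simulate_experiment(config, genome_panel)
            mut_cols = sc.sequence_pool(
                exp.mutant_pool, exp.genome, exp.panel, exp.mutations,
                depth=config.light_depth, error_rate=config.error_rate,
                read_len=config.read_len,
                seed=_derive_seed(config.seed, "seq-mutant"),
            )
            wt_cols = sc.sequence_pool(
                exp.wildtype_pool, exp.genome, exp.panel, exp.mutations,
                depth=config.light_depth, error_rate=config.error_rate,
                read_len=config.read_len,
                seed=_derive_seed(config.seed, "seq-wildtype"),
            )
            if write_files:
                io.write_genome_fasta(exp.genome, outdir / "genome.fasta")
                io.write_snp_panel_tsv(exp.panel, outdir / "panel.tsv")
                io.write_snp_panel_vcf(exp.panel, outdir / "panel.vcf")
                io.write_mutations_tsv(exp.mutations, outdir / "mutations.tsv")
                io.write_pileup(mut_cols, outdir / "mutant_pileup.tsv")
                io.write_pileup(wt_cols, outdir / "wildtype_pileup.tsv")
        genome, panel, gene_models = exp.genome, exp.panel, None
    elif config.mode == "real-data":
        if not (config.genome_fasta and config.mutant_pileup and config.wildtype_pileup):
            raise ValueError("real-data mode needs genome_fasta and both pileups")
        genome = io.read_genome_fasta(config.genome_fasta, config.cm_per_mb)
        mut_cols = io.read_pileup(config.mutant_pileup)
        wt_cols = io.read_pileup(config.wildtype_pileup)
        panel = (
            io.read_snp_panel_tsv(config.snp_panel_tsv)
            if config.snp_panel_tsv
            else None
        )
        gene_models = io.read_gene_models_gff3(config.gff3) if config.gff3 else None
        exp = None
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    criteria = pool_genotyper.FilterCriteria(
        min_coverage=config.min_coverage
    ).with_pool_size(config.pool_size)

    with timer("genotype"):
        calls, variable = pool_genotyper.discover_and_genotype(
            mut_cols, wt_cols, genome, criteria
        )
        report.n_variable_positions = len(variable)
        # ecotype filter list for the candidate stage: wild-type pool
        # re-called under the strict criteria.  The relaxed per-pool
        # genotypes would also flag causal-linked heterozygous sites
        # (present at ~1/3 in the wild-type pool) and veto the causal
        # mutation itself.
        wt_by_site = {(c.chrom, c.pos): c for c in wt_cols}
        wt_strict = []
        for call in calls["wildtype"]:
            col = wt_by_site.get((call.chrom, call.pos))
            if col is None or call.alt_allele is None:
                continue
            wt_strict.append(
                pool_genotyper.call_snp(
                    col, call.ref_allele, criteria,
                    alt_allele=call.alt_allele,
                )
            )
        if write_files:
            io.write_calls_tsv(calls, outdir / "calls.tsv")
            for pool in ("mutant", "wildtype"):
                io.write_calls_vcf(calls[pool], outdir / f"calls_{pool}.vcf", pool)

    with timer("map"):
        bins = {
            pool: bsa_mapper.bin_frequencies(calls[pool], config.bin_size)
            for pool in ("mutant", "wildtype")
        }
        report.n_bins = len(bins["mutant"])
        regions = bsa_mapper.detect_linkage(
            bins["mutant"], bins["wildtype"],
            config.dip_threshold, config.wt_threshold,
        )
        supported = [r for r in regions if r.supported]
        report.n_regions_supported = len(supported)
        report.regions = [
            {
                "chrom": r.chrom, "start": r.start, "end": r.end,
                "min_map_fraction": r.min_map_fraction,
                "wt_support_fraction": r.wt_support_fraction,
                "supported": r.supported,
            }
            for r in regions
        ]
        if write_files:
            io.write_bins_tsv(bins, outdir / "bins.tsv")
            io.write_regions_bed(regions, outdir / "regions.bed")

    region = None
    if supported:
        # capture interval: fixed width centered on the middle of the
        # smoothed minimum valley of the mutant-pool track (the dip run
        # itself can span many megabases of linkage, and the single
        # lowest bin sits anywhere on the zero-fraction valley floor)
        best = supported[0]
        center = _valley_center(
            [b for b in bins["mutant"] if b.chrom == best.chrom]
        )
        half = config.capture_width // 2
        lo = max(0, center - half)
        hi = min(genome.lengths[best.chrom], center + half)
        region = (best.chrom, lo, hi)

    if region is not None and config.design_capture_probes:
        with timer("probes"):
            design = probe_designer.design_probes(
                genome, region, slide=config.probe_slide, window=config.probe_window
            )
            design = probe_designer.uniqueness_filter(design, genome)
            report.n_probes_kept = sum(p.kept for p in design.probes)
            if write_files:
                io.write_probes_fasta(design, outdir / "probes.fasta")
                io.write_probes_bed(design, outdir / "probes.bed")
                io.write_probes_tsv(design, outdir / "probes.tsv")

    if region is not None:
        with timer("candidates"):
            if config.mode == "simulate":
                # enrichment: deep sequencing restricted to the detected
                # region; off-target reads are dropped, thinning depth by
                # the on-target fraction
                eff_depth = config.enriched_depth * config.on_target_fraction
                chrom, rs, re_ = region
                pos = sc.variant_positions(exp.panel, exp.mutations, chrom)
                pos = pos[(pos >= rs) & (pos < re_)]
                deep_cols = sc.sequence_pool(
                    exp.mutant_pool, exp.genome, exp.panel, exp.mutations,
                    positions={chrom: pos},
                    depth=eff_depth, error_rate=config.error_rate,
                    read_len=config.read_len,
                    seed=_derive_seed(config.seed, "seq-deep"),
                )
                if write_files:
                    io.write_pileup(deep_cols, outdir / "enriched_pileup.tsv")
            else:
                deep_cols = (
                    io.read_pileup(config.enriched_pileup)
                    if config.enriched_pileup
                    else []
                )
            candidates, coverage = candidate_finder.call_candidates(
                deep_cols, region, genome, criteria,
                freq_threshold=config.freq_threshold,
                wildtype_calls=wt_strict,
                snp_panel=panel,
                gene_models=gene_models,
            )
            report.n_candidates = len(candidates)
            report.candidates = [
                {
                    "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
                    "nonref_fraction": c.nonref_fraction, "effect": c.effect,
                    "protein_label": c.protein_label, "gc_to_at": c.is_gc_to_at,
                }
                for c in candidates
            ]
            if write_files:
                io.write_candidates_vcf(candidates, outdir / "candidates.vcf")
                io.write_candidates_tsv(candidates, outdir / "candidates.tsv")
                io.write_intervals_bed(
                    region[0], coverage.uninspected_intervals,
                    outdir / "uninspected.bed",
                )

    if config.mode == "simulate":
        causal = exp.mutations.causal
        in_region = region is not None and (
            region[0] == causal.chrom and region[1] <= causal.pos < region[2]
        )
        causal_hit = next(
            (
                c
                for c in (report.candidates or [])
                if (c["chrom"], c["pos"]) == (causal.chrom, causal.pos)
            ),
            None,
        )
        report.truth = {
            "causal_chrom": causal.chrom,
            "causal_pos": causal.pos,
            "causal_in_region": bool(in_region),
            "region_center_distance": (
                abs((region[1] + region[2]) // 2 - causal.pos) if in_region else None
            ),
            "causal_among_candidates": causal_hit is not None,
            "causal_nonref_fraction": (
                causal_hit["nonref_fraction"] if causal_hit else None
            ),
        }

    if write_files:
        report.to_json(outdir / "report.json")
    return report


def multiplex(configs: Sequence[RunConfig]) -> list[RunReport]:
    """Run several mutants against one shared reference structure.

    All configs must describe the same genome (same genome-shaping
    parameters and seed); each mutant keeps its own mutagenesis, cross
    and sequencing randomness.
    """
    if not configs:
        return []

    def genome_key(c: RunConfig):
        return (
            c.n_chrom, tuple(c.chrom_lengths), c.snp_density,
            c.masked_fraction, c.cm_per_mb,
        )

    keys = {genome_key(c) for c in configs}
    if len(keys) > 1:
        raise ValueError("multiplexed configs disagree on the shared genome")
    ref = configs[0]
    shared = sc.simulate_genome(
        ref.n_chrom, ref.chrom_lengths, ref.snp_density, ref.masked_fraction,
        seed=_derive_seed(ref.seed, "genome"), cm_per_mb=ref.cm_per_mb,
        bin_size=ref.bin_size,
    )
    return [run_pipeline(c, genome_panel=shared) for c in configs]


class _StageTimer:
    def __init__(self, report: RunReport):
        self.report = report

    def __call__(self, stage: str):
        return _StageContext(self.report, stage)


class _StageContext:
    def __init__(self, report: RunReport, stage: str):
        self.report, self.stage = report, stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.stage)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        self.report.stage_seconds[self.stage] = round(dt, 3)
        if exc_type is not None:
            logger.error("stage %s failed after %.1fs", self.stage, dt)
            raise RuntimeError(f"pipeline stage {self.stage!r} failed") from exc
        logger.info("stage %s: done in %.1fs", self.stage, dt)
        return False


def _version() -> str:
    from ffg import __version__

    return __version__
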