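"""High-frequency candidate mutation calling and coding-effect annotation.

Deep-sequenced pileups from the enriched linked interval are screened
for novel alleles above a loose non-reference frequency threshold
(default >70%, tolerant of pool missorting), known ecotype polymorphisms
are filtered out, and the surviving variants are annotated against gene
models (stop gain, missense, silent, UTR, intron, pseudogene) and
classified by the G/C-to-A/T mutagen signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

from ffg.pool_genotyper import (
    DEFAULT_ERROR_PRIOR,
    PASS,
    FilterCriteria,
    SnpCall,
    call_snp,
)
from ffg.synthetic_cross import Genome, PileupColumn, SnpPanel

DEFAULT_FREQ_THRESHOLD = 0.70

EFFECTS = (
    "intergenic",
    "intron",
    "5'UTR",
    "3'UTR",
    "silent",
    "missense",
    "nonsense",
    "pseudogene",
    "unannotated",
)


@dataclass
class GeneModel:
    """Minimal gene model: exon/CDS/UTR spans on one strand.

    Spans are 0-based half-open genome intervals, sorted by start.  CDS
    spans must splice to a length divisible by three.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    pseudogene: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        for name in ("exons", "cds", "utr5", "utr3"):
            spans = getattr(self, name)
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping {name} spans in {self.gene_id}")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def spliced_cds(self, genome: Genome) -> str:
        """Coding-strand CDS sequence (reverse-complemented for - strand)."""
        seq = genome.sequence(self.chrom)
        forward = "".join(seq[s:e] for s, e in self.cds).upper()
        if self.strand == "-":
            return str(Seq(forward).reverse_complement())
        return forward

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the spliced CDS."""
        if not any(s <= pos < e for s, e in self.cds):
            return None
        forward_offset = 0
        for s, e in self.cds:
            if pos < s:
                break
            if pos < e:
                forward_offset += pos - s
                break
            forward_offset += e - s
        if self.strand == "-":
            return self.cds_length() - 1 - forward_offset
        return forward_offset


@dataclass
class CandidateVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    nonref_fraction: float
    coverage: int
    effect: str = "unannotated"
    protein_label: str = ""
    gene_id: str = ""

    @property
    def is_gc_to_at(self) -> bool:
        return (self.ref.upper(), self.alt.upper()) in {("G", "A"), ("C", "T")}


@dataclass
class CoverageReport:
    """Coverage adequacy over the assessed region positions."""

    region_chrom: str
    region_start: int
    region_end: int
    n_assessed: int
    n_covered_20x: int
    uninspected_intervals: list[tuple[int, int]]

    @property
    def fraction_covered_20x(self) -> float:
        return self.n_covered_20x / self.n_assessed if self.n_assessed else 0.0


def annotate_effect(
    variant: CandidateVariant | tuple[str, int, str, str],
    gene_models: Sequence[GeneModel],
    genome: Genome,
) -> tuple[str, str, str]:
    """Classify a substitution against gene models.

    Returns (effect, protein_label, gene_id).  Pseudogene overlap
    dominates; otherwise UTR, then CDS (codon translated on the coding
    strand with the standard nuclear code; label like ``Q467X``), then
    intron, then intergenic.
    """
    if isinstance(variant, tuple):
        chrom, pos, ref, alt = variant
    else:
        chrom, pos, ref, alt = variant.chrom, variant.pos, variant.ref, variant.alt
    overlapping = [
        g for g in gene_models if g.chrom == chrom and g.start <= pos < g.end
    ]
    if not overlapping:
        return "intergenic", "", ""
    pseudo = [g for g in overlapping if g.pseudogene]
    if pseudo:
        return "pseudogene", "", pseudo[0].gene_id

    for g in overlapping:
        if any(s <= pos < e for s, e in g.utr5):
            return "5'UTR", "", g.gene_id
        if any(s <= pos < e for s, e in g.utr3):
            return "3'UTR", "", g.gene_id

    for g in overlapping:
        offset = g.cds_offset(pos)
        if offset is None:
            continue
        if g.cds_length() % 3 != 0:
            raise ValueError(
                f"gene {g.gene_id}: spliced CDS length {g.cds_length()} "
                "is not divisible by 3"
            )
        cds = g.spliced_cds(genome)
        ref_coding = ref.upper() if g.strand == "+" else str(Seq(ref).reverse_complement()).upper()
        alt_coding = alt.upper() if g.strand == "+" else str(Seq(alt).reverse_complement()).upper()
        if cds[offset] != ref_coding:
            raise ValueError(
                f"gene {g.gene_id}: reference base mismatch at CDS offset {offset}"
            )
        codon_i = offset // 3
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        mutated = codon[: offset % 3] + alt_coding + codon[offset % 3 + 1 :]
        ref_aa = str(Seq(codon).translate())
        alt_aa = str(Seq(mutated).translate())
        ref_aa = "X" if ref_aa == "*" else ref_aa
        alt_aa = "X" if alt_aa == "*" else alt_aa
        label = f"{ref_aa}{codon_i + 1}{alt_aa}"
        if alt_aa == "X":
            return "nonsense", label, g.gene_id
        if ref_aa == alt_aa:
            return "silent", label, g.gene_id
        return "missense", label, g.gene_id

    return "intron", "", overlapping[0].gene_id


def call_candidates(
    enriched_pileup: Iterable[PileupColumn],
    region: tuple[str, int, int],
    genome: Genome,
    criteria: FilterCriteria,
    freq_threshold: float = DEFAULT_FREQ_THRESHOLD,
    wildtype_calls: Sequence[SnpCall] | None = None,
    snp_panel: SnpPanel | None = None,
    gene_models: Sequence[GeneModel] | None = None,
    error_rate_prior: float = DEFAULT_ERROR_PRIOR,
) -> tuple[list[CandidateVariant], CoverageReport]:
    """Call novel high-frequency alleles in the enriched interval.

    A candidate is a PASS site with non-reference fraction strictly above
    ``freq_threshold`` that is neither a known ecotype polymorphism
    (``snp_panel``) nor variable in the wild-type pool.  Also reports how
    much of the assessed region reached 20x coverage and which intervals
    were left uninspected.
    """
    chrom, start, end = region
    if not (0 <= start < end <= genome.lengths[chrom]):
        raise ValueError(f"region {chrom}:{start}-{end} outside genome")
    panel_sites = snp_panel.position_set() if snp_panel is not None else set()
    wt_variable = {
        (c.chrom, c.pos)
        for c in (wildtype_calls or [])
        if c.status == PASS and c.alt_reads > 0
    }

    covered_20x: list[int] = []
    assessed: list[int] = []
    candidates: list[CandidateVariant] = []
    for col in enriched_pileup:
        if col.chrom != chrom or not (start <= col.pos < end):
            continue
        assessed.append(col.pos)
        if col.depth >= 20:
            covered_20x.append(col.pos)
        ref = genome.base(chrom, col.pos).upper()
        call = call_snp(col, ref, criteria, error_rate_prior)
        if call.status != PASS or call.alt_allele is None:
            continue
        if not call.nonref_fraction > freq_threshold:
            continue
        if (chrom, col.pos) in panel_sites or (chrom, col.pos) in wt_variable:
            continue
        cand = CandidateVariant(
            chrom,
            col.pos,
            ref,
            call.alt_allele,
            call.nonref_fraction,
            call.ref_reads + call.alt_reads,
        )
        if gene_models is not None:
            cand.effect, cand.protein_label, cand.gene_id = annotate_effect(
                cand, gene_models, genome
            )
        candidates.append(cand)

    uninspected = _complement_intervals(start, end, sorted(covered_20x))
    report = CoverageReport(
        chrom, start, end, len(assessed), len(covered_20x), uninspected
    )
    return candidates, report


def _complement_intervals(
    start: int, end: int, covered_positions: list[int]
) -> list[tuple[int, int]]:
    """Merge positions NOT covered at threshold into intervals."""
    intervals: list[tuple[int, int]] = []
    prev = start
    for p in covered_positions:
        if p > prev:
            intervals.append((prev, p))
        prev = p + 1
    if prev < end:
        intervals.append((prev, end))
    return intervals


def ems_spectrum(
    candidates: Iterable[CandidateVariant | tuple[str, str]],
) -> tuple[int, int]:
    """Partition variants into G/C-to-A/T transitions vs. everything else."""
    n_gc_to_at = 0
    n_other = 0
    for c in candidates:
        if isinstance(c, tuple):
            flag = (c[0].upper(), c[1].upper()) in {("G", "A"), ("C", "T")}
        else:
            flag = c.is_gc_to_at
        if flag:
            n_gc_to_at += 1
        else:
            n_other += 1
    return n_gc_to_at, n_other
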