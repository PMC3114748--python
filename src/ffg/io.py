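"""On-disk formats: FASTA, pileup TSV, VCF 4.2, BED, GFF3, TSV tables.

Everything is plain text.  Internal coordinates are 0-based half-open;
files use the conventions of their formats (1-based for VCF/GFF and the
pileup/panel TSVs, 0-based half-open for BED).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ffg.bsa_mapper import BinFrequency, LinkageRegion
from ffg.candidate_finder import CandidateVariant, GeneModel
from ffg.pool_genotyper import PASS, SnpCall
from ffg.probe_designer import ProbeDesign
from ffg.synthetic_cross import (
    GeneticMap,
    Genome,
    Mutation,
    MutationSet,
    PileupColumn,
    SnpPanel,
    SnpRecord,
)

PILEUP_MAGIC = "##ffpileup=v1"
PILEUP_COLUMNS = ["chrom", "pos1", "base", "strand", "read_start1", "qual"]


# -- FASTA ------------------------------------------------------------------


def write_genome_fasta(genome: Genome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.chromosomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | Path, cm_per_mb: float = 4.0) -> Genome:
    chromosomes = [
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    gmap = GeneticMap.uniform({n: len(s) for n, s in chromosomes}, cm_per_mb)
    return Genome(chromosomes, gmap)


# -- pileup TSV (ffpileup v1) ----------------------------------------------


def write_pileup(columns: Iterable[PileupColumn], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(PILEUP_MAGIC + "\n")
        fh.write("#" + "\t".join(PILEUP_COLUMNS) + "\n")
        for col in columns:
            pos1 = col.pos + 1
            for base, strand, start, qual in zip(
                col.bases.tolist(),
                col.strands.tolist(),
                col.read_starts.tolist(),
                col.quals.tolist(),
            ):
                fh.write(f"{col.chrom}\t{pos1}\t{base}\t{strand}\t{start + 1}\t{qual}\n")


def read_pileup(path: str | Path) -> list[PileupColumn]:
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != PILEUP_MAGIC:
            raise ValueError(f"{path}: not an ffpileup v1 file (got {magic!r})")
    df = pd.read_csv(
        path,
        sep="\t",
        skiprows=2,
        names=PILEUP_COLUMNS,
        dtype={"chrom": str, "pos1": np.int64, "base": str, "strand": str,
               "read_start1": np.int64, "qual": np.int64},
    )
    columns: list[PileupColumn] = []
    if df.empty:
        return columns
    for (chrom, pos1), grp in df.groupby(["chrom", "pos1"], sort=False):
        columns.append(
            PileupColumn(
                str(chrom),
                int(pos1) - 1,
                grp["base"].to_numpy(dtype="U1"),
                grp["strand"].to_numpy(dtype="U1"),
                grp["read_start1"].to_numpy(dtype=np.int64) - 1,
                grp["qual"].to_numpy(dtype=np.int64),
            )
        )
    return columns


# -- SNP panel --------------------------------------------------------------


def write_snp_panel_tsv(panel: SnpPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos1\tref\talt\n")
        for r in panel:
            fh.write(f"{r.chrom}\t{r.pos + 1}\t{r.ref_allele}\t{r.map_allele}\n")


def read_snp_panel_tsv(path: str | Path) -> SnpPanel:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, pos1, ref, alt = line.rstrip("\n").split("\t")
            records.append(SnpRecord(chrom, int(pos1) - 1, ref, alt))
    return SnpPanel(records)


def write_snp_panel_vcf(panel: SnpPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ffg\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in panel:
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref_allele.upper()}\t"
                f"{r.map_allele.upper()}\t.\tPASS\t.\n"
            )


# -- mutation truth ---------------------------------------------------------


def write_mutations_tsv(mutations: MutationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos1\tref\talt\tis_causal\n")
        for m in mutations:
            fh.write(f"{m.chrom}\t{m.pos + 1}\t{m.ref}\t{m.alt}\t{int(m.is_causal)}\n")


def read_mutations_tsv(path: str | Path) -> MutationSet:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, pos1, ref, alt, causal = line.rstrip("\n").split("\t")
            records.append(Mutation(chrom, int(pos1) - 1, ref, alt, bool(int(causal))))
    return MutationSet(records)


# -- SNP calls --------------------------------------------------------------


def write_calls_tsv(calls: dict[str, Sequence[SnpCall]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tpos1\tpool\tref\talt\tref_reads\talt_reads\t"
            "nonref_fraction\tvariant_quality\tstatus\n"
        )
        for pool, pool_calls in calls.items():
            for c in pool_calls:
                fh.write(
                    f"{c.chrom}\t{c.pos + 1}\t{pool}\t{c.ref_allele}\t"
                    f"{c.alt_allele or '.'}\t{c.ref_reads}\t{c.alt_reads}\t"
                    f"{c.nonref_fraction:.6f}\t{c.variant_quality:.2f}\t{c.status}\n"
                )


def read_calls_tsv(path: str | Path) -> dict[str, list[SnpCall]]:
    calls: dict[str, list[SnpCall]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            (chrom, pos1, pool, ref, alt, ref_reads, alt_reads,
             _frac, qual, status) = line.rstrip("\n").split("\t")
            nr, na = int(ref_reads), int(alt_reads)
            calls.setdefault(pool, []).append(
                SnpCall(
                    chrom, int(pos1) - 1, ref, None if alt == "." else alt,
                    nr, 0, na, 0, float(qual), status,
                )
            )
    return calls


def write_calls_vcf(
    calls: Sequence[SnpCall], path: str | Path, sample: str = "pool"
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ffg\n")
        fh.write('##INFO=<ID=NRF,Number=1,Type=Float,Description="Non-reference fraction">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Accepted read depth">\n')
        for reason in ("min_coverage", "unique_starts", "variant_quality",
                       "both_strands", "ambiguous"):
            fh.write(f'##FILTER=<ID={reason},Description="Failed {reason} criterion">\n')
        fh.write('##FILTER=<ID=FULLY_REFERENCE,Description="No variant reads at adequate coverage">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            if c.status == PASS:
                filt = "PASS"
            elif c.status == "FULLY_REFERENCE":
                filt = "FULLY_REFERENCE"
            else:
                filt = ";".join(sorted(c.fail_reasons)) or "FAIL"
            alt = c.alt_allele or "."
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref_allele}\t{alt}\t"
                f"{c.variant_quality:.1f}\t{filt}\t"
                f"NRF={c.nonref_fraction:.4f};DP={c.ref_reads + c.alt_reads}\n"
            )


# -- bins / regions ---------------------------------------------------------


def write_bins_tsv(
    bins: dict[str, Sequence[BinFrequency]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tbin_index\tstart1\tend1\tn_snps\tref_reads\tmap_reads\t"
            "map_fraction\tpool\n"
        )
        for pool, pool_bins in bins.items():
            for b in pool_bins:
                fh.write(
                    f"{b.chrom}\t{b.bin_index}\t{b.start + 1}\t{b.end}\t{b.n_snps}\t"
                    f"{b.ref_read_total}\t{b.map_read_total}\t{b.map_fraction:.6f}\t{pool}\n"
                )


def write_regions_bed(regions: Sequence[LinkageRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = f"region{i + 1}" + ("" if r.supported else "_unsupported")
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t"
                     f"{r.min_map_fraction:.4f}\t.\n")


def read_region_bed(path: str | Path) -> tuple[str, int, int]:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith(("#", "track")):
                parts = line.split("\t")
                return parts[0], int(parts[1]), int(parts[2])
    raise ValueError(f"{path}: no region found")


# -- candidates -------------------------------------------------------------


def write_candidates_vcf(
    candidates: Sequence[CandidateVariant], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ffg\n")
        fh.write('##INFO=<ID=NRF,Number=1,Type=Float,Description="Non-reference fraction">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Accepted read depth">\n')
        fh.write('##INFO=<ID=EFFECT,Number=1,Type=String,Description="Predicted effect">\n')
        fh.write('##INFO=<ID=AALABEL,Number=1,Type=String,Description="Protein change">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write('##INFO=<ID=GCAT,Number=0,Type=Flag,Description="G/C to A/T transition">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in candidates:
            info = f"NRF={c.nonref_fraction:.4f};DP={c.coverage};EFFECT={c.effect}"
            if c.protein_label:
                info += f";AALABEL={c.protein_label}"
            if c.gene_id:
                info += f";GENE={c.gene_id}"
            if c.is_gc_to_at:
                info += ";GCAT"
            fh.write(f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n")


def write_candidates_tsv(
    candidates: Sequence[CandidateVariant], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos1\tref\talt\tnonref_fraction\tcoverage\teffect\t"
                 "protein_label\tgene\tgc_to_at\n")
        for c in candidates:
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t{c.ref}\t{c.alt}\t{c.nonref_fraction:.4f}\t"
                f"{c.coverage}\t{c.effect}\t{c.protein_label}\t{c.gene_id}\t"
                f"{int(c.is_gc_to_at)}\n"
            )


def write_intervals_bed(
    chrom: str, intervals: Sequence[tuple[int, int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# -- GFF3 gene models -------------------------------------------------------


def write_gene_models_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            gtype = "pseudogene" if g.pseudogene else "gene"
            fh.write(
                f"{g.chrom}\tffg\t{gtype}\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for ftype, spans in (
                ("exon", g.exons),
                ("CDS", g.cds),
                ("five_prime_UTR", g.utr5),
                ("three_prime_UTR", g.utr3),
            ):
                for s, e in spans:
                    frame = "0" if ftype == "CDS" else "."
                    fh.write(
                        f"{g.chrom}\tffg\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t"
                        f"{frame}\tParent={g.gene_id}\n"
                    )


def read_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            chrom, _src, ftype, start1, end, _score, strand, _frame, attrs = fields[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            span = (int(start1) - 1, int(end))
            if ftype in ("gene", "pseudogene"):
                gid = attr.get("ID", f"gene{len(genes)}")
                genes[gid] = {
                    "chrom": chrom,
                    "strand": strand,
                    "pseudogene": ftype == "pseudogene",
                    "exons": [],
                    "cds": [],
                    "utr5": [],
                    "utr3": [],
                }
                order.append(gid)
            else:
                parent = attr.get("Parent")
                if parent not in genes:
                    continue
                key = {
                    "exon": "exons",
                    "CDS": "cds",
                    "five_prime_UTR": "utr5",
                    "three_prime_UTR": "utr3",
                }.get(ftype)
                if key:
                    genes[parent][key].append(span)
    models = []
    for gid in order:
        g = genes[gid]
        if not g["exons"]:
            # gene row without exon children: treat the whole span as exon
            continue
        models.append(
            GeneModel(
                gid, g["chrom"], g["strand"], g["exons"], g["cds"],
                g["utr5"], g["utr3"], g["pseudogene"],
            )
        )
    return models


# -- probes -----------------------------------------------------------------


def write_probes_fasta(design: ProbeDesign, path: str | Path) -> None:
    records = []
    for p in design.probes:
        if not p.kept:
            continue
        pid = f"{p.chrom}:{p.start + 1}-{p.start + p.length}:{p.strand}"
        records.append(SeqRecord(Seq(p.sequence), id=pid, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_probes_bed(design: ProbeDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sorted(design.probes, key=lambda p: (p.start, p.strand)):
            if not p.kept:
                continue
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.start + p.length}\t"
                f"probe\t{p.score:.2f}\t{p.strand}\n"
            )


def write_probes_tsv(design: ProbeDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart1\tend1\tstrand\ttm\tgc\tmax_homopolymer\t"
                 "n_hits\tkept\n")
        for p in design.probes:
            fh.write(
                f"{p.chrom}\t{p.start + 1}\t{p.start + p.length}\t{p.strand}\t"
                f"{p.tm:.2f}\t{p.gc:.4f}\t{p.max_homopolymer}\t"
                f"{p.n_hits if p.n_hits is not None else '.'}\t{int(p.kept)}\n"
            )
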