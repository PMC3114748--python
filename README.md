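# ffg — bulk-segregant mutation mapping toolkit

`ffg` implements a two-step strategy for pinpointing a recessive,
chemically induced causal mutation from pooled sequencing of an F2
mapping cross:

1. **Light sequencing + linkage mapping.** Phenotype-sorted bulk pools
   (mutant and wild type) are sequenced at low depth. SNPs between the
   mutagenized and mapping ecotypes are discovered on the merged pools
   (the "virtual F1") under strict read-level filters, each pool is
   genotyped at the discovered sites, and mapping-allele fractions are
   pooled over windows of 25 SNPs. At markers linked to the causal locus
   the mutant pool's mapping-allele fraction drops toward 0% while the
   wild-type pool's rises toward 67%; unlinked markers sit at 50%.
2. **Capture enrichment + deep sequencing.** A ~1 Mb interval around the
   detected dip is tiled with 60-mer capture probes (2 bp slide,
   independent offset reverse-strand design, genome-uniqueness filter)
   and deep-sequenced. Sites above 70% non-reference frequency that are
   not ecotype polymorphisms become candidate mutations, annotated for
   coding effect (nonsense/missense/silent/UTR/intron/pseudogene) and
   classified against the G/C→A/T mutagen signature.

The package ships a forward simulator of the whole experiment (genome,
ecotype SNP panel, mutagenesis, meiosis with a Poisson/Haldane crossover
model, phenotype sorting, pooled sequencing at pileup level), so every
stage can be exercised and validated end to end without external data.
Real pileup/FASTA/GFF3 inputs are supported through the same pipeline.

## Layout

| module | role |
| --- | --- |
| `ffg.synthetic_cross` | genome/panel simulation, EMS mutagenesis, F2 meiosis, pools, pooled sequencing |
| `ffg.pool_genotyper` | virtual-F1 SNP discovery, strict filter criteria, per-pool genotyping |
| `ffg.bsa_mapper` | 25-SNP binned mapping-allele fractions, expected-frequency curves, linked-region detection |
| `ffg.candidate_finder` | >70% candidate calling, ecotype filtering, effect annotation, mutagen spectrum |
| `ffg.probe_designer` | 60-mer tiling design, scoring (Tm/GC/homopolymer), seed-and-extend uniqueness filter |
| `ffg.pipeline` / `ffg.cli` | end-to-end orchestration, config, reports, CLI |
| `ffg.io` | FASTA, `ffpileup v1` TSV, VCF 4.2, BED, GFF3, TSV tables |

## CLI

```sh
ffg run --config config.yaml            # full pipeline (simulate or real-data mode)
ffg simulate --seed 1 --outdir sim      # write genome, truth files and pileups
ffg genotype --mutant-pileup m.tsv --wildtype-pileup w.tsv --genome g.fasta
ffg map --calls calls.tsv --bin-size 25 --plot
ffg design-probes --genome g.fasta --region chr1:4500001-5500000 --slide 2
ffg candidates --pileup deep.tsv --region regions.bed --genome g.fasta \
    --gff genes.gff3 --panel panel.tsv --threshold 0.70
ffg multiplex --config m1.yaml --config m2.yaml
```

Every stochastic step takes an explicit seed; a config file (YAML)
round-trips losslessly and re-running it reproduces byte-identical
outputs. `report.json` includes a truth-comparison block in simulate
mode (was the causal locus inside the detected region? was the causal
variant among the candidates?).

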