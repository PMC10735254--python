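# herbseq

Long-read target-capture analysis for degraded herbarium DNA.

Herbarium specimens are a vast genomic archive, but their DNA is fragmented
and chemically damaged, so they are usually sequenced with short reads.
Probe-based target capture of long (> 1 kb) fragments can recover long reads
from archival material — when the analysis copes with three problems the
material creates: heavy PCR duplication of low-complexity libraries,
chimeric molecules, and **cross-contamination** from related samples
processed in the same lab, which capture cannot exclude and which only
sequence divergence can reveal. herbseq implements that analysis chain as a
tested Python library, together with a synthetic-data generator that
reproduces the statistical structure of such an experiment end to end, with
a per-read truth table, so every stage is testable without any sequencing
data.

The pipeline, for each barcoded sample:

1. **Demultiplex & trim** — reads carry a 6-nt barcode between fixed
   3-nt flanks (`GAT-XXXXXX-GTG` on forward reads, `CAC-XXXXXX-ATC` on
   reverse reads); reads are assigned, re-oriented and trimmed.
2. **Deduplicate** — exact-sequence collapse (PCR duplicates are exact
   copies), keeping the first-seen read.
3. **Chimera screen** — a read is flagged when splitting it at some
   breakpoint lets two *distinct* parents each explain their segment better
   (by ≥ 0.02 identity) than any single parent explains the whole read.
4. **Cross-contaminant screen** — each read's best local alignment against
   a database of the co-processed taxa's target loci, grouped by taxonomic
   section; a wrong-section best hit with alignment > 600 bp and identity
   ≥ 95 % is a possible cross-contaminant, any other wrong-section hit is
   ambiguous; both are removed. The screen is valid only if the database
   has a distance gap, which is checked with Kimura two-parameter (K80)
   distances, `d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`.
5. **Assemble & map** — cleaned reads build per-sample de-novo reference
   contigs (greedy overlap-consensus), contigs are matched to the 48 target
   loci, and reads are mapped iteratively (≤ 25 rounds, majority consensus
   rebuilt each round). Mapped reads are the **on-target** set; the summary
   reports on-target counts and lengths, loci recovered, mean depth and
   total contig length.
6. **Authenticate** — terminal deamination (C→T at 5′, G→A at 3′ over the
   first/last 25 aligned positions) is profiled from the final alignments,
   the classical degraded-DNA signal.

The simulator plants every effect the pipeline must undo — age-dependent
fragmentation at 1.66 × 10⁻⁴ breaks/nt/year, terminal deamination,
logistic size selection at 500/900/1000 bp, length-biased PCR over 25
cycles, chimeras, cross-contamination at 0.03–0.9 % of reads, Phred-40
point errors — and records each read's true class (endogenous / duplicate /
chimera / cross-contaminant), source and pre-error sequence.

## Worked example

Four specimens spanning 2–73 years of age, with 1 % of the 1987 sample's
reads injected from the co-processed 2017 specimen of a different section:

```python
from herbseq import pipeline, simulate

cfg = pipeline.RunConfig(sim=simulate.SimConfig(
    n_loci=6, total_length=9000, members_per_section=2,
    samples=[
        simulate.SampleSpec(name="fresh_2019", section="Siphonomorpha", age=2,
                            depth=250, genome_copies=150),
        simulate.SampleSpec(name="mid_1987", section="Silene", age=34,
                            depth=250, genome_copies=150),
        simulate.SampleSpec(name="old_1948", section="Elisanthe", age=73,
                            depth=250, genome_copies=150),
        simulate.SampleSpec(name="donor_2017", section="Physolychnis", age=4,
                            depth=250, genome_copies=150),
    ],
    contamination=simulate.ContaminationPlan(rates={("donor_2017", "mid_1987"): 0.01}),
))
result = pipeline.run(cfg, seed=11)
print(result.summary[["sample", "barcoded_reads", "duplicates_pct", "contaminants_pct",
                      "on_target_reads", "on_target_gt_1kb", "loci_recovered",
                      "mean_depth", "total_contig_length"]].to_string(index=False))
```

```
    sample  barcoded_reads  duplicates_pct  contaminants_pct  on_target_reads  on_target_gt_1kb  loci_recovered  mean_depth  total_contig_length
donor_2017             250            23.2               0.0              186               179               6     26.8904                 8990
fresh_2019             250            14.0               0.0              210               207               6     31.8965                 8989
  mid_1987             250            92.4               1.2               14                 8               5      2.3121                 5921
  old_1948               0             0.0               0.0                0                 0               0      0.0000                    0
```

Reading the table: the two young specimens yield mostly distinct molecules
(low duplication), map essentially all cleaned reads on target and recover
all six loci at ~30× depth. The 34-year-old specimen's library has
collapsed to a handful of distinct molecules (92 % duplication), recovers
five loci at ~2× — and 1.2 % of its barcoded reads are flagged as
cross-contaminants from the donor's section, right at the planted rate. The
73-year-old specimen yields no library at all: at 1.66 × 10⁻⁴ breaks/nt/yr,
essentially no fragment survives the 1-kb size selection.

Every stage is also callable on its own (`simulate`, `qc`, `readproc`,
`decontam`, `assemble`, `damage`), and a thin CLI wraps the common entry
points: `herbseq simulate`, `herbseq run`, `herbseq qc regions|fragrate`,
`herbseq decontam validate|screen`, `herbseq readproc dedup`.

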