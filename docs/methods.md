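# Methods

herbseq models and analyses probe-based target-capture sequencing of long
reads from degraded (herbarium-archived) plant DNA. This note records the
models, the parameter choices and their rationale, the numerical decisions,
and what the synthetic data can and cannot establish about real runs.

## Degradation model

**Strand breakage.** DNA in dried specimens accumulates single-bond breaks
at an approximately constant per-nucleotide rate. herbseq models each
internucleotide bond as failing independently with probability
`p = 1 − exp(−λ·t)` where `λ = 1.66e-4 breaks/nt/year` (the rate reported
for herbarium material) and `t` is specimen age in years. Fragment lengths
are then geometric with parameter `p`; mean length `1/p` falls from ~3 kb at
2 years to ~100 bp at 60 years. This random-breakage model has a closed-form
oracle for every statistic the package computes from fragment lengths, which
is why it was chosen over more elaborate kinetics. Preservation covariates
(drying method, chemical treatment) are known to modulate real degradation
but are not modelled; only age and λ are exposed.

**Rate estimation.** `qc.estimate_fragmentation_rate` inverts the model by
method of moments on the left-truncated geometric: `p̂ = 1/(mean(L) −
min_observable + 1)`, `λ̂ = −ln(1−p̂)/t`, with a delta-method standard error.
Geometric memorylessness makes the estimator exact under left truncation, so
`min_observable` should be set to the most recent size-selection midpoint
when estimating from post-selection pools (default 1 for raw extracts).
Recovery is within 10 % relative error for `λ·t ∈ [0.001, 0.02]` at ≥ 1e4
fragments (verified by the test suite).

**Terminal deamination.** Post-mortem cytosine deamination is planted as
position-specific C→T conversion over the first 25 bases (and G→A over the
last 25), the window in which the signal is conventionally profiled. The
age-default amplitude is `1 − exp(−0.005·t)` with a 10-bp positional
e-folding: ~0.01 at 2 years, ~0.36 at 90 years, reproducing the observed
contrast between young specimens (frequencies ≤ 0.15) and old ones
(approaching saturation at terminal positions when denominators are small).
Interior damage is out of model. The damage profiler reports per-position
denominators and flags positions resting on fewer than 10 reference bases
rather than interpreting them; sequencing error alone contributes an
expected C→T floor of `error_rate/3`.

## Library construction model

**End resection.** After fragmentation, a geometric number of bases (mean
40 per end) is trimmed from each fragment, emulating bead cleanup and
end-repair nibbling. This also removes a degeneracy the pure breakage model
would otherwise have: unfragmented copies of the same locus would be
byte-identical molecules, which no real library contains because genomic
breakpoints fall in flanking DNA that herbseq does not simulate.

**Size selection.** Bead selection is a logistic retention curve with
midpoint at the nominal cutoff (500, 900, 1000 bp for the three protocol
steps) and default sharpness `ln(19)/(0.2·midpoint)`, i.e. 50 % retention at
the midpoint and 5 % at 0.8×midpoint. The high-sharpness limit is a hard
cutoff.

**PCR.** Each molecule copy duplicates per cycle with probability
`efficiency · exp(−length_bias · L)` (defaults 0.8 and 1e-4/bp, 25 cycles),
a length-biased branching process tracked as copy numbers. Sequencing draws
reads from molecules proportionally to copy number, so duplication level
emerges from the ratio of sequencing depth to distinct surviving molecules:
young samples land at ~10–30 % duplication and old, low-complexity libraries
at 90 %+, reproducing the qualitative pattern that degraded samples waste
sequencing on duplicates. Duplicates are exact copies: point errors are
applied once per distinct molecule and inherited by its copies, so the
exact-match deduplicator has a well-defined truth.

**Chimeras, contamination, tagging, errors.** A configurable fraction of
sampled reads (default 2 %) is converted to two-parent chimeras joined at
uniform interior breakpoints, with both parents and breakpoints recorded.
Cross-contamination replaces a Binomial(depth, rate) subset of a recipient's
reads with molecules drawn from a donor sample's library (rates of
0.03–0.9 % in the study-like configurations), before barcoding — so
contaminant reads carry the recipient's barcode, which is exactly what makes
them detectable only by sequence. Each molecule is tagged GAT-barcode-GTG at
the 5′ end and GAT-rc(barcode)-GTG at the 3′ end; a read sequenced from the
reverse strand therefore starts CAC-barcode-ATC, making orientation
unambiguous. Point substitutions are applied at the Phred-40 rate (1e-4) and
qualities are flat at the corresponding character; indels and
instrument-specific artefacts are not modelled.

## Reference database and decontamination

The section database is generated by a two-level substitution process:
section ancestors diverge from a common root, members from their ancestor,
with rates calibrated so realized mean pairwise K80 distances match the
requested within-section values (defaults 0.38–0.9 % per section) and the
between-section target (default 5.5 %, comfortably above the 3.8 % floor a
usable screen needs). Transitions are favoured 2:1 over transversions.

K80 distances drop gap/ambiguity columns pairwise and raise a saturation
error when a logarithm argument reaches zero; per-locus means are averaged
unweighted across loci. `validate_database` requires min(between) ≥
`min_gap_ratio` × max(within) (default ratio 2) and names the offending
section pair on failure. The implementation agrees with R ape's `dist.dna`
(model K80) to ten decimals on fixed pairs (frozen in the test suite).

Read screening assigns each read its single best local alignment over the
database (both strands, deterministic tie-break by score, then entry order,
then forward strand) and applies the rule: best hit in the expected section
→ clean; wrong section with alignment length > 600 bp and identity ≥ 0.95 →
possible cross-contaminant; any other wrong-section hit → ambiguous; no hit
→ retained (the on-target mapping filters those later). Length exactly
600 bp counts as ambiguous, and long wrong-section hits *below* the identity
floor are also classified ambiguous — the conservative reading — unless
`keep_low_identity` is set. Identity counts gap columns as mismatches, over
the locally aligned segment. Both flagged classes are removed.

## Alignment engine

All read-vs-reference comparisons use edlib's banded semi-global aligner.
Local (Smith-Waterman-like) scores are obtained by rescoring the edlib path
with a blastn-like scheme (+2/−3, gap −5/−2) and trimming it to its
maximum-scoring sub-path; because every cigar run scores uniformly positive
or negative, run-level trimming is exact, the trimmed score never exceeds
the true Smith-Waterman optimum, and at the divergences the pipeline
operates at it equals it (both properties verified against a brute-force
Gotoh aligner in the tests). Candidate references are shortlisted by shared
k-mers (k = 14); shortlisting is a ranking heuristic in the same spirit as
any seeded aligner. Two corrections handle cases a unit-cost edit aligner
gets wrong: alignments stopping just short of a reference boundary are
extended diagonally to the end ("snap"), and short dovetail overlaps —
which edit distance prefers to smear across the reference — are recovered
from the modal shared-k-mer diagonal. The diagonal rescue is gap-free and
therefore assumes substitution-dominated overlaps; with strongly
indel-bearing data an external overlap aligner should be substituted.

## Assembly and on-target definition

Per-sample references are built by a deterministic greedy
overlap-layout-consensus: reads longest-first, each joining the
best-scoring existing cluster it overlaps by ≥ 100 columns at ≥ 0.85
identity (extending the backbone when it protrudes) or founding a new one;
cluster consensus is a column-majority vote. Iterative mapping then places
every read on its best reference (same thresholds), rebuilds the majority
consensus — extending the ends from protruding reads — and repeats until
the mapped set and consensus stabilize, capped at 25 rounds. Reads mapped
after the final round are the on-target set, the operational definition the
analysis inherits. A read mapping to several references goes to its best
score, ties to the lower reference index. Consensus voting ignores
insertions (no reference coordinate) and breaks base ties alphabetically;
base-quality-aware consensus and polyploid phasing are out of scope
(tetraploid specimens are simulated as single haplotypes).

These components are documented stand-ins for production assemblers and
mappers: what the package preserves is the decision structure (de novo
references → iterative mapping → mapped = on-target, with the stated
thresholds), not any particular tool's internals. Both are behind plain
function interfaces so external tools can be substituted for real data.

## Statistics

`compute_stats` reports, per sample: on-target reads; on-target ratio
(mapped / cleaned input × 100); loci recovered (loci whose assigned contigs
received ≥ 1 read); mean depth (aligned bases / reference length); percent
coverage (positions with depth ≥ 1); total contig length; and on-target
read-length summaries. Depth counts aligned (match/mismatch) columns only.
The long-fragment QC statistic is the summed molarity of region-table rows
above 1 kb divided by total molarity, ×100; rows straddling the threshold
contribute pro-rata by length by default (a `whole_region` flag reproduces
the convention of summing whole instrument regions), and a mass-weighted
variant is provided because molar fractions over-weight long molecules.
Duplication level is the percentage of sample-assigned reads flagged as
exact duplicates. Cross-contamination percentages in the pipeline summary
are quoted against barcoded reads.

## Chimera screen

The chimera test flags a read when some breakpoint splits it into two
segments (each ≥ 300 bp) whose best-parent identities both exceed the whole
read's best single-parent identity by ≥ 0.02, with distinct parents —
capturing the detection intent of reference-based chimera screens in a
fully testable rule. Breakpoints are scanned on a 50-bp grid and the
best-supported breakpoint is reported. Reads whose whole-read identity is
already within the margin of 1 are cleared without scanning, which keeps
the false-positive rate at the measured 0 on clean synthetic reads.
Sensitivity is ≥ 0.9 (measured ~1.0) on planted chimeras whose true
segments are both comfortably above the minimum segment length; chimeras
with one short segment are intrinsically undetectable by any
breakpoint-improvement rule and are excluded from the sensitivity
denominator.

## Problem sizes

The full-scale locus set (48 loci, 104 kb) is used wherever it is cheap:
locus generation, database distance structure, fragmentation-rate recovery
(~1e5 fragments). The multi-sample pipeline runs use a scaled target set —
6 loci / 9 kb, 2–4 database members per section, 120–400 reads per sample,
genome input of 120–300 haploid copies — chosen so the full twelve-specimen
study design, and a seven-age ladder repeated over ten seeds, run in
minutes on one core while keeping every age-dependent contrast (young
specimens recover all loci at high depth; specimens older than ~60 years
fail outright) well clear of sampling noise.

## What the synthetic data does not show

The generator reproduces the statistical structure the pipeline's decision
rules depend on, not the full messiness of real runs. In particular: there
is no off-target genomic or microbial background (on-target ratios of
cleaned synthetic reads are therefore near 100 %, unlike real captures);
flanking DNA around loci is not simulated (reads never extend past locus
boundaries); the error model is substitution-only and flat-quality;
fragment-length distributions are exactly geometric, so instrument region
tables derived from them are much more age-sensitive than real
electrophoresis traces — the young/old ordering of long-fragment fractions
is meaningful, their absolute values are not; and preservation-method
effects on degradation are not modelled. Passing tests establish that each
stage implements its stated decision rule and recovers planted parameters,
not that real data would yield the same numbers.
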