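# Methods

This note records the model, the tunable parameters, and the design choices
made where the analysis left genuine latitude, together with what the
synthetic-data tests do and do not establish about real data.

## Data model

Signals are abstract non-negative abundance values per gene and sample, read
from a TSV with a sample sheet describing genotype (WT/MUT), condition
(CK/COLD), fraction (TOTAL/POLY) and replicate. They are assumed
already normalized across libraries; the pipeline applies no implicit
library-size correction (an explicit `total_sum_scale` helper exists for
inputs that need it). Transcript input is either a flat table
(transcript_id, gene_id, utr5_seq, cds_seq) or genome FASTA + GFF3, in which
case `five_prime_UTR` and `CDS` segments are grouped by `Parent`, spliced,
and reverse-complemented into transcript orientation for minus-strand genes.
GFF3 coordinates are 1-based inclusive; all internal offsets are 0-based
half-open. One representative isoform per gene is chosen by lowest-sorting
transcript id (the common ".1" convention) or, optionally, longest CDS;
transcripts whose CDS does not begin with ATG are skipped with a logged
count. `N` bases are permitted and never match ATG or a stop codon.

## Contrast statistics

For a contrast of design cell *alt* against *ref* within one fraction:

- Means are arithmetic replicate averages of raw signals.
- ratio = mean_alt / mean_ref; signed fold = ratio when ≥ 1, else −1/ratio.
  If exactly one side has mean zero the fold is reported as missing (NaN)
  and the gene can never be selected — no infinite folds are fabricated. A
  gene at zero on both sides is an exact no-change (fold 1, p 1).
- Expression filter: mean_ref + mean_alt > `expr_sum_min` (default 10,
  strict). A `replicate_sum` basis (summing raw replicate values instead of
  means) is available because published per-gene tables are more consistent
  with that reading for one low-expressed gene; the default follows the rule
  as stated.
- Significance: computed on log2(signal + pseudocount), pseudocount 1.0.
  The default test pools the within-cell log-scale variance across **all**
  genes of the contrast and applies a two-sided z-test. With two replicates
  per cell a per-gene variance estimate has one degree of freedom per side
  and essentially no power (Monte Carlo: a per-gene Welch t at α = 0.05
  detects a 1.8-fold shift under 10% CV noise about half the time); pooling
  across genes is the standard escape and matches the generator's
  constant-CV noise model. The per-gene Welch t (with Welch–Satterthwaite
  degrees of freedom) remains available as `test="welch"` and as
  `replicate_test` for workflows with more replicates. With zero replicate
  variance everywhere (noise-free fixtures) both tests degenerate to exact
  comparison: p = 1 for equal means, 0 otherwise.
- q-values: Benjamini–Hochberg step-up over all genes of the contrast
  (statsmodels), order-preserving, capped at 1, always ≥ p.

Thresholds default to fold ≥ 1.5, expression sum > 10, α = 0.05 on the
q-value; the significance metric (q or p) is configurable because published
descriptions of this style of filtering alternate between the two.

## Gene-set definitions

Eight labels. Cold, per fraction: a gene joins the DOWN (UP) set when the
wild-type call is DOWN (UP) — |signed fold| ≥ 1.5, expressed, significant —
and the mutant is a non-responder — expressed and |signed fold| ≤ 1.5, with
*no* significance requirement on non-response. Both boundary operators admit
a fold of exactly 1.5, verbatim from the selection rules being reproduced;
the two roles belong to different contrasts, so no contradiction arises.
Translational (polysomal) sets then exclude every gene in the union of the
transcriptional (total-RNA) up/down sets of the same comparison scheme.
Normal-temperature sets contrast MUT_CK against WT_CK per fraction, with the
same exclusion applied to the polysomal side for symmetry. Set assembly is a
pure function of the contrast results and thresholds; a `grant_significance`
switch waives the significance requirement for noise-free data, where any
test is degenerate.

## Sequence features

Kozak context: −3 is the third-from-last UTR base (missing for UTRs shorter
than 3 nt), +4 the fourth CDS base. Strong = purine at −3 **and** G at +4;
adequate = exactly one match; weak = neither; a missing base never matches.
Transcripts with an empty 5′-UTR form the separate no-UTR category; 1–2 nt
UTRs are *not* no-UTR and classify through +4 alone.

uORFs: every UTR offset with ATG starts a frame walked in triplets across
UTR+CDS until TAA/TAG/TGA or sequence end. Default CONTAINED mode keeps
only uORFs whose stop codon ends at or before the main start; ANY_START
keeps all upstream ATGs (stop possibly in the CDS or absent). The minimum
uORF is one codon (ATG immediately followed by a stop). Both modes are
exposed because published uORF percentages rarely state which convention
was used; the two bracket the plausible values.

Frequency tables report per-set percentages over *resolved* members (those
with a representative transcript); unresolved members are counted in a
separate column. Rounding is half-up to one decimal, mirroring printed
tables; category percentages partition to 100 before rounding and to
100 ± 0.2 after.

## Clustering

Rows are log2(x + 1)-transformed and z-scored per gene (population SD;
constant rows map to zero). Distances: Pearson (1 − r, range [0, 2]; rows
with zero variance sit at distance 0 from identical rows and 1 from all
others) or Euclidean. Linkage: average (default), complete, or single, via
Lance–Williams updates, so average linkage is the unweighted mean of
original pairwise distances (UPGMA). Determinism is fully specified: among
tied minimal pairs the one whose smallest (then next-smallest) original row
indices sort lowest merges first, and the leaf order is a left-first
traversal with the left child holding the smaller earliest original index.
The specific distance/linkage behind any given published heatmap is rarely
stated; Pearson + average is the common convention and is configurable.

## Synthetic data

The generator emulates the study conditions directly: 2 genotypes × 2
conditions × 2 fractions, `n_reps = 2` replicates per cell. Planted classes
and their signal effects:

| class | effect |
|---|---|
| NULL | flat everywhere |
| COLD_TX | wild-type cold cells × fold in **both** fractions |
| COLD_TL | wild-type cold **polysomal** cells × fold only |
| NT_GENOTYPE | mutant **CK** cells × fold in both fractions |

Mutant cold responses are scaled on the log scale by `mutant_attenuation`
(default 0: abolished). Fold magnitudes are uniform in `effect_range`
(default [1.5, 3.0]) with random sign. Baselines are log-normal
(`baseline_logmean` 4.0, `baseline_logsd` 1.0 — median ≈ 55, matching the
magnitude range of typical normalized signal tables and keeping ~99% of
genes above the expression floor). Replicates multiply the cell mean by
LogNormal(0, σ) noise with σ = √ln(1 + CV²), CV = `noise_cv` (default 0.1).
Transcripts: UTR length geometric with mean `utr_len_mean` (100 nt),
floored at 3 nt so the −3 position exists (9 nt when a uORF cassette is
planted; `utr_len_mean` < 12 with `uorf_prob` > 0 is rejected); bases i.i.d.
uniform; the −3/+4 positions are overwritten to force a Kozak class drawn
from `kozak_probs` (default 34/44.5/10.6/10.8%, a genome-wide background);
an ATGTAA cassette is written into the UTR with probability `uorf_prob`
(0.5). Sequences are rescanned after construction, so recorded truth is the
*realized* uORF count — accidental background ATGs occur exactly as in real
UTRs, which is why realized background uORF rates exceed `uorf_prob` at
realistic UTR lengths. All draws descend from one seed through SeedSequence
spawn keys (0: transcriptome, 1: signals), so each output is independently
reproducible.

What passing tests show — and don't: the simulator shares the analysis's
own noise family (log-normal, constant CV) and plants clean single-class
effects. Recovery benchmarks therefore validate the selection logic,
thresholds, exclusion rule and their interplay, not robustness to real
RNA-seq pathologies (count overdispersion varying with abundance, library
composition effects, correlated replicates, partial mutant attenuation).
The standard benchmark (2000 genes, 5% + 5% planted responders, folds
1.8–3.0, CV 0.1, two replicates, p-based selection) is run at a size chosen
to keep the whole suite fast; precision and recall for the translational
union are ≥ 0.9 there, and exact (= 1) in the zero-noise closed loop with
significance waived and baselines clear of the expression floor.

## Numerical and degenerate-input choices

- Pseudocount 1.0 before log2, for testing and standardization only; fold
  means always use raw signals.
- BH input p-values outside [0, 1] are a validation error, not clipped.
- `summarize_contrast` refuses design cells with fewer than 2 replicates;
  `replicate_test` directs single-replicate users to fold-only selection.
- Empty gene sets produce rows with missing percentages and n = 0 rather
  than NaN arithmetic.
- Pipeline outputs carry no timestamps; a manifest of SHA-256 hashes makes
  end-to-end determinism checkable. Stage failures quarantine partial
  outputs.

## Known limitations

- No dispersion-modelling differential-expression framework: the procedure
  is deliberately threshold-based, and its error control under real
  overdispersed counts is not characterized here.
- Genome-wide feature percentages depend on the annotation release and the
  isoform-per-gene rule; the package computes them for whatever transcript
  set it is given and makes no claim about any specific release.
- Translation-efficiency modelling (polysomal/total ratios as a single
  statistic) and ribosome profiling are out of scope.
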