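# Methods

## Ψ site calling from deletion signatures

**Model.** During reverse transcription of bisulfite-treated RNA, a Ψ
site produces a deletion in the cDNA with probability close to the
fraction of modified transcripts; unmodified positions delete only at a
small background error rate. Per-site observations are the pileup pair
(depth, deletion count) in each library. The caller makes no
distributional assumption — it is a deterministic filter cascade — but
the simulator's binomial model is the implicit sampling model under
which the recovery properties are tested.

**Filters.** The five criteria (treated ratio > 0.05 with count > 4;
input ratio < 0.02; depth > 20 in every library; U reference base on the
transcribed strand; presence in every replicate) are implemented with
strict inequalities exactly as stated, and boundary tests pin each one
(a site at deletion count 4, input ratio 0.020, or depth 20 is
rejected). The depth criterion is enforced per library, not on pooled
depth, consistent with the per-replicate reading of criterion 5. A site
present in treated tables but absent from an input table fails the
depth criterion rather than being treated as zero background: absence
of evidence is not evidence of a clean input.

**Strand and reference base.** The transcribed strand comes from
overlapping gene models; intergenic sites default to "+" with a
`strand_assumed` flag (U is then T in the DNA reference; on "−" genes it
is A). When genes on both strands overlap a site, "+" is chosen
deterministically and flagged.

**Ψ fraction.** Reported per replicate as the raw deletion ratio
(identity calibration). Published calibration curves relating deletion
rate to stoichiometry are chemistry- and enzyme-specific; the caller
exposes a `calibration` hook (ratio → fraction) and defaults to
identity, which is also what the simulator inverts.

**Differential test.** Two-tailed two-sample Student's t with pooled
variance on replicate fractions, significance at raw p < 0.05 with no
multiple-testing correction; a Benjamini–Hochberg FDR column is attached
for users but never gates the default call. Welch's correction is
available behind a flag. Degenerate zero-variance sites get p = 1
(equal means) or p = 0 (unequal, flagged). The test is applied to
fractions directly, not to a variance-stabilised transform — at the
fraction ranges and replicate noise involved the transform changes
little, and fractions match how such estimates are usually reported.

**Annotation.** Motif: the transcribed-strand 5-mer with the called U at
offset 2 is matched against UGUAR (IUPAC R = A/G); minus-strand sites
use the reverse complement; N never matches; contig-edge sites return
False with a warning. Species: highest-priority overlapping feature with
default priority tRNA > snRNA > lncRNA > intron > mRNA > other;
protein-coding overlap resolves to intron/exon via the optional exon
list.

## Pol II release ratio

**Windows.** With 0-based TSS t: plus-strand promoter [t−100, t+300),
body [t+300, t+2000); minus-strand windows cover the same
transcript-relative offsets ([t−299, t+101) and [t−1999, t−299)).
Widths are 400 and 1700 bp; windows are truncated at the contig origin
and genes whose body would be empty are dropped. Multi-isoform genes
should be reduced to the 5′-most TSS upstream of this package (the gene
model carries a single TSS).

**Statistic.** PRR = sum of per-base coverage over the body window
divided by the promoter sum, with no length normalisation — the window
widths are part of the statistic's definition, and condition
comparisons are per-gene so the geometry cancels. A `per_bp` flag gives
the mean-per-base variant. Genes with promoter coverage < 20 are
discarded (coverage exactly 20 is kept). Zero body coverage gives
PRR 0 with log₂PRR = −∞, excluded (and counted) by the rank test. The
coverage-20 filter presumes raw count-scale tracks; RPKM scaling exists
only in the metagene display, where a global filter would be
meaningless.

**Comparison.** Unpaired two-sided Mann–Whitney U on the two log₂PRR
samples over genes kept in both conditions, matching a
distribution-shift comparison; a paired signed-rank variant is exposed
behind a flag. Per-gene Δlog₂PRR and the descending ranking are
reported alongside.

## BIHIND-qPCR estimator

Ψ fraction = 1 − 0.5^ΔΔCt, ΔΔCt = (Ct_BS^Ψ − Ct_BS^U) −
(Ct_unt^Ψ − Ct_unt^U). Amplification is assumed exactly 2-fold per
cycle; no efficiency-correction knob is offered, keeping the estimator
in its printed closed form. qPCR noise can push the raw estimate
outside [0, 1]; the default clamps with a flag and retains the raw
value in a diagnostics column. Replicates are aggregated as mean ± SEM
(sample SD/√n, undefined at n = 1) on the fraction scale, not on ΔΔCt —
the Jensen gap between the two averages is negligible at realistic Ct
noise (≈0.1 cycles) and fractions are the scale on which such results
are stated. Ct values outside [5, 45] trigger a soft warning only.

## Synthetic data

* **Pileups** — depth ~ Poisson(depth_mean) per site and library
  (negative binomial behind an `nb_size` knob for robustness tests);
  treated deletions ~ Binomial(depth, f·c + (1−f)·e_t) with conversion
  rate c (default 1.0) and treated background e_t (default 0.002);
  input deletions ~ Binomial(depth, e_i) (default 0.002). Deletion
  events are independent across sites — adequate for a per-site caller,
  but it does not emulate read-level correlation, misalignment around
  indels, or multimapping. Decoy classes: non-U reference base,
  depth-starved (mean 10), and dirty-input (e_i = 0.05).
* **Coverage** — genes laid out non-overlapping on a toy chromosome
  with alternating strands; promoter sum ~ Poisson(λ), body sum ~
  Poisson(λ·ρ); condition B multiplies ρ by the effect size for the
  affected gene fraction. Sums are deposited uniformly over the exact
  analysis windows, so the track route and the count route agree to
  floating-point accuracy; real Pol II tracks have sharper pause peaks
  and signal outside the windows, which this model deliberately omits.
* **Ct quartets** — the exact algebraic inverse of the estimator:
  ct_bs_psi = a′ − log₂(1−f) + ε with matched probe offsets
  (a − b = a′ − b′) and homoscedastic Gaussian ε per Ct value. f = 1 is
  rejected (use 1 − 1e−9 near saturation).
* **Fixture** — a complete ≤1 MB run: 20 kb genome with 40 planted
  sites (UGUAR contexts planted at every even-indexed site, consensus
  explicitly broken at the others), 6 genes across 4 biotypes on both
  strands, 20 decoys, two conditions (15 sites reduced to 0.6× in
  "kd"), fractions uniform on [0.3, 0.9] at depth 100 with c = 0.95,
  e_t = 0.002, e_i = 0.001, 200 PRR genes with a 2× effect in half, and
  Ct tables at true fractions 0.72 / 0.48 with σ = 0.1. Everything is a
  pure function of the seed; repeated generation is byte-identical.

Passing tests on these generators demonstrate correctness of the
statistics and plumbing under the stated sampling models — they do not
validate alignment, deduplication, or other upstream processing, which
this package deliberately excludes (it ingests pre-tabulated pileup
TSVs and bedGraphs, not BAMs).

## Numerical and interface choices

* Internal coordinates are 0-based half-open everywhere; 1-based
  conventions (GTF, pileup `pos`) are converted at file boundaries
  only. Overlapping bedGraph records are summed, supporting
  replicate-merged tracks.
* Output orderings are deterministic: sites by (chrom, position),
  differential results by (p, site key), PRR rankings by (−Δ, gene id).
* Coverage tracks are dense per-chromosome float arrays — simple and
  exact for the toy and gene-scale inputs targeted here; genome-scale
  tracks would want a run-length or bigWig-backed store (out of scope).
* Problem sizes in the test and acceptance runs (10,000-site oracle
  table, 2,000-gene PRR simulations, 100-repeat null coverage, 1,000
  noisy Ct quartets) were chosen as the smallest sizes at which the
  binomial/rank-test tolerances are comfortably non-flaky.

## Known limitations

* No multiple-testing correction in the default differential call (by
  design, mirroring the p < 0.05 rule it implements); use the FDR
  column for genome-scale candidate lists.
* The identity calibration understates Ψ fraction when the deletion
  chemistry converts less than fully; inject a calibration function for
  quantitative cross-chemistry comparisons.
* Pseudogene/multimapping disambiguation, indel left-alignment in the
  pileup engine, and isoform-level TSS selection are upstream of this
  package's contract.
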