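# Methods

## Scope and model of the data

`ervscan` analyzes bulk RNA-seq one cohort at a time: a set of control
samples and a set of patient samples from the same study, aligned to the
same genome. Cohorts are never pooled or cross-normalized, because basal ERV
expression is strongly cell-type- and protocol-specific; the unit of
inference is always the within-cohort contrast.

The unit of quantification is the RepeatMasker **subfamily**. Individual ERV
copies are too repetitive for reliable per-locus quantification with short
reads, so all copies of a subfamily are treated as parts of one meta-feature
and a fragment counts once toward the subfamily no matter how many of its
copies it touches. The method does not attempt multimapper rescue
(Telescope-style EM reassignment) or per-copy expression; "uniquely mapped"
is operationalized as MAPQ ≥ 20 primary alignments.

## Intergenic restriction

A copy is kept iff it overlaps **no** gene-body interval by ≥ 1 bp, on
either strand. Gene-body (not exon-only) masking is the strictest simple
rule: it also removes intronic copies, whose read coverage can come from
pre-mRNA rather than the repeat. The rule is strand-blind because antisense
transcription through a gene locus still confounds attribution. Subfamilies
with zero intergenic copies are flagged and excluded from expression
analysis. The overlap rule operates on whatever gene annotation is supplied;
promoter-proximal flanks are not excluded (no flank padding), which is the
conservative reading when the annotation's TSS precision is unknown.

## Counting and FPKM

Counting is fragment-level: one count per sequenced template. For a proper
pair the fragment is the template span (outer mates' extent); a read whose
mate was filtered or absent contributes its own span once. Filters (defaults
in `CountingParams`): MAPQ ≥ 20, primary alignments only, duplicate-flagged
records dropped, reverse strandedness — the fragment (strand of read 1) must
be antisense to the copy, matching dUTP library preparation. A fragment
strand-compatibly overlapping copies of ≥ 2 distinct subfamilies is
ambiguous and dropped; counts therefore satisfy the conservation identity
`assigned + ambiguous + unassigned = fragments`, asserted per sample.

FPKM uses the subfamily's **merged** (union) intergenic copy length, not the
sum of copy lengths, so overlapping annotations are not double-counted. The
per-sample denominator is the total of fragments *assigned* across the
counted features. The alternative denominator (all filtered fragments) is
supported; per-feature statistics are insensitive to the choice because the
Welch t-statistic is invariant to per-feature rescaling, but fold-changes of
low-count features can shift slightly.

One consequence worth knowing: FPKM is compositional. If a large fraction
of the counted signal rises in one condition, every other feature's FPKM
mechanically falls. On small panels with strong planted effects this
produces spurious "down" calls (visible in the README example: 8 planted of
40 at fold-change 8 drag 3 bystanders below the down threshold). At
realistic panel sizes (hundreds of subfamilies, few responders) the effect
is negligible — the planted-recovery checks at 10/500 show zero false calls
in either direction.

## Differential expression

Per feature: Welch's unequal-variance t-test between patient and control
FPKM values, two-sided, with Welch–Satterthwaite degrees of freedom.
Features that are all-zero in both groups are excluded (and listed) before
testing; the Holm step-down family is exactly the set of tested features of
the run. Conventions for degenerate inputs: both groups zero-variance with
equal means → t = 0, p = 1; zero variance with unequal means → t = ±∞,
p = 0. Tests run on raw FPKM by default; a `log_transform` mode tests
log₂(FPKM + ε) instead.

A feature is called **up** iff (Holm-adjusted p < α) **and**
((mean_case + ε)/(mean_control + ε) > minimum fold-change); **down**
symmetrically. Defaults: α = 0.05, fold-change 2, pseudocount ε = 0.01 FPKM.
Requiring both conditions is standard volcano semantics — an OR rule would
label near-zero-fold-change features "up" whenever the test is powered. The
pseudocount enters fold-changes only, never the t-test, and only keeps
log₂ fold-changes finite; its value is echoed in output headers.

The severity contrast (ICU vs non-ICU patients) reuses the same statistics
with **no** multiplicity adjustment by default, reflecting its descriptive,
hypothesis-generating role on small groups (6 vs 4); healthy controls are
reported alongside as a descriptive mean, never tested.

## Evolutionary age comparison

Subfamily age proxy: the unweighted mean of the RepeatMasker per-copy
divergence (% substitution from consensus) over the *intergenic* copies —
the copies actually quantified. A length-weighted mean is available behind a
flag; unweighted is the default because each insertion event is one
observation of the subfamily's age regardless of how much of it survives.

The age question is answered with a two-tailed Mann–Whitney U test between
(a) the divergences of subfamilies called up and (b) the divergences of the
remaining **tested** subfamilies — the analysis-eligible pool, not the full
genomic roster, so the comparison is against subfamilies that had the same
opportunity to be called. `U_a` counts pairs with a > b plus half the ties.
The p-value is exact (null distribution by the standard count recursion)
when `n_a·n_b ≤ 400` and the data are tie-free; otherwise a normal
approximation with tie-corrected variance and 0.5 continuity correction is
used. The exact/normal crossover at 400 pairs keeps the exact path
affordable while the two agree within 0.02 well before the cutoff (checked
on 15-vs-15 instances). `direction = younger` requires both a lower median
divergence in the upregulated group *and* p < α — with very few upregulated
subfamilies (e.g. 2 vs 3) the test is structurally unable to reach
significance and the direction stays `none`; an empty upregulated set yields
a flagged result rather than an error.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not any real
genome:

* **Annotation** — `n_subfamilies` (default 578, the analyzed roster size)
  with 3–8 copies each of 400–1500 bp placed uniformly and non-overlapping
  on a small multi-chromosome genome; a configurable fraction is forced to
  overlap gene bodies to exercise the intergenic filter. Subfamily ages are
  two-tiered: young (divergence uniform on 0.5–8%) and old (8–30%), with
  per-copy divergence scattered (sd 0.5, clipped to tier) around the
  subfamily value.
* **Counts** — negative-binomial with Var = μ + φμ², dispersion φ = 0.1 by
  default (typical bulk RNA-seq), per-subfamily baselines uniform on a
  configurable range, and log-normal per-sample size factors (σ = 0.15).
  Group sizes default to the platelet-like design: 10 patients (6 non-ICU /
  4 ICU) vs 5 controls. A planted set of subfamilies (default 10, drawn from
  a chosen age tier) is multiplied by the planted fold-change (default 8) in
  patient samples only.
* **Reads** — each target count is realized as a properly-paired fragment
  (read length 100, insert 250 ± 30 — generic short-read geometry) wholly
  inside one intergenic copy of the subfamily, antisense to the copy strand,
  so reverse-stranded counting assigns it deterministically; counting the
  generated SAM reproduces the target matrix exactly. Optional spike-ins
  (low-MAPQ, duplicate-flagged, sense-strand, and cross-subfamily-straddling
  fragments) are recorded with their expected fate to test every filter.

Every output is a pure function of (config, seed); independent RNG streams
for truth, annotation, counts, and reads keep the stages decoupled.

What the generator does **not** model — sequence content and alignment
(MAPQ is assigned, not earned), mapping ambiguity between homologous
subfamilies, library-preparation biases (GC, length), gene expression
surrounding the repeats, or single-cell structure. Passing recovery tests
therefore demonstrate that the statistical machinery recovers effects of the
planted form at the stated sizes; they do not certify performance against
alignment artifacts on real repetitive DNA.

## Numerical and design choices

* Coordinates are 0-based half-open internally; 1-based conventions exist
  only inside parsers and writers.
* ERV membership is a configurable class/family pattern set
  (`LTR/ERV1|ERVK|ERVL|ERVL-MaLR` plus any `LTR/ERV*`); the exact subfamily
  roster is RepeatMasker-version-dependent, so no count is hard-coded.
* Holm adjustment is the step-down max-prefix form with a stable sort, so
  tied p-values keep input order and the output is monotone in the sorted
  order.
* Interval overlap uses an interval tree; a quadratic per-fragment ×
  per-copy scan with identical assignment rules is kept as a test oracle.
* The pipeline writes a JSON manifest (parameter echo, input SHA-256
  checksums, stage outputs); reruns from identical inputs are
  byte-identical except for manifest timestamps.
* Problem sizes in the checks: counting-oracle equivalence uses five
  fixtures up to 8 000 fragments × 800 copies; null calibration uses one
  578-feature replicate for the type-I fraction and 200 replicates for the
  family-wise error rate; recovery uses 20 replicates (DE) and 100 per tier
  (age) at 500 subfamilies. These sizes make the Monte-Carlo standard errors
  small relative to the margins being tested while keeping the whole suite
  in the tens of seconds.

## Known limitations

* Welch's t-test on raw FPKM from overdispersed counts at n = 10 vs 5 is
  slightly anti-conservative in the extreme tail; the measured family-wise
  error rate of the Holm procedure on null simulations runs near 0.06–0.09
  rather than 0.05. This is a property of applying a normal-theory test to
  skewed data at small n — the published analysis design — not of the
  implementation, which matches reference implementations to < 10⁻¹⁰.
* FPKM's compositional coupling (above) can produce bystander "down" calls
  when a large share of the counted signal responds.
* No batch correction, no dispersion-shrinkage DE model, no multimapper
  rescue; these are deliberate non-goals to keep the pipeline faithful to
  the simple, auditable design it implements.
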