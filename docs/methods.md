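# Methods

This note records the models, parameter choices, numerical decisions, and
known limitations behind `egoddn`.

## Disease–disease network construction

The input is a PheWAS-style summary table of (phenotype, variant)
associations. Filtering keeps associations with p ≤ `p_max` (default 1e−4,
inclusive), minor allele frequency ≥ `maf_min` (0.01), and case count ≥
`min_cases` (200); phenotypes flagged male-specific are dropped wholesale
(the networks target female cohorts), as are PheCodes specified to the
hundredth's place ("642.11"), which denote sub-sub-phenotypes too granular
for network interpretation. The hundredths test is a plain string test on the
decimal part — PheCode strings are canonical and never zero-padded, so
"642.10" counts as hundredths.

LD pruning runs **per phenotype** over its surviving SNPs: candidates are
swept in ascending p-value order (ties broken by position, then SNP id), and
a SNP is kept iff its squared Pearson correlation of dosages with every
already-kept SNP on the same chromosome within `ld_window_kb` (250 kb) is
≤ `ld_r2_max` (0.2). This is PLINK-like `--indep-pairwise` semantics with
p-value prioritization, which preserves the strongest signal of each LD
clump; a `global` scope (one sweep over distinct SNPs at their best p) and a
position-first order are available for sensitivity analysis. Whether pruning
should act per phenotype or globally is genuinely open; per-phenotype is the
default because association strength is phenotype-specific. R² is computed
from whatever `GenotypeMatrix` is supplied, so a reference panel can stand in
for cohort genotypes.

The surviving associations define the binary disease × SNP matrix. Two
diseases are connected iff their row supports intersect; each edge stores the
sorted shared-SNP ids, the shared count, and the cosine similarity of the
binary vectors. Cosine is the default propagation weight for both the full
and the egocentric network — the count weight is stored on every edge and
selectable with `weighting="count"` — because cosine normalizes away the
large differences in per-disease association counts that would otherwise let
heavily-studied phenotypes dominate the Laplacian. Egocentric networks are
**induced** subgraphs (alter–alter edges kept): propagation is meant to see
the local topology, not just the star; `star_only=True` provides the ablation.

## Label propagation (GSSL)

With one-hot label y on the ego and Laplacian L = D − W, the score vector
minimizes (f−y)ᵀ(f−y) + μ fᵀLf, solved from the SPD system (I + μL) f = y by
sparse factorization — never an explicit inverse, for numerical stability at
diseasome scale. Properties used as test oracles: Σf = Σy = 1 on connected
graphs (the matrix is symmetric with unit row sums under (I+μL)·1 = 1),
strict positivity on the labelled component, f → y as μ → 0, and f → 1/n as
μ → ∞. Disconnected graphs solve blockwise; components without the label
score exactly 0 (enforced by snapping factorization dust).

μ defaults to 1.0. No principled value is available — μ trades label
fidelity against smoothness, and the downstream quantities are ranks, which
are nearly unchanged across μ ∈ {0.1, 1, 10} on the reference study (mean
rank correlation ≈ 0.9, reported by the acceptance script; only near-tied
alters ever swap) — so the default is the scale-free middle, exposed as
`--mu`.

Min-max normalization is computed over **all** nodes of the solved graph,
ego included, because the transform is defined on the full score vector;
quartile stratification then acts on alters only, ranking by normalized
score descending with ties broken by PheCode, in ceil(n/4) chunks
(very_high, high, intermediate, low). A constant score vector has no
min-max transform; normalized scores are set to zero with a warning.

## Comorbidity ground truth

Diagnosis records ("ever had" semantics, no temporal ordering) are mapped
ICD→PheCode (one ICD code may expand to several PheCodes; unmapped codes are
dropped with a logged count) and deduplicated per person. For a pair (i, j)
over a cohort of N persons, φ_ij is the Pearson correlation of the two
binary indicators, computed from counts. Significance uses the classical
identity χ² = N·φ² on 1 df — algebraically the 2×2 Pearson statistic without
continuity correction; the source analyses report only "p < 0.05" without
naming a test, and this is the standard choice linking φ to a test statistic.
Fisher's exact test is available behind `use_fisher=True` for small counts.
A pair is a true comorbidity iff φ > 0, p < 0.05, and C_ij > 0. Degenerate
margins (a disease absent from or universal in the cohort) yield φ = 0,
p = 1, flagged.

One property worth recording: with counts C, P_i, P_j fixed, enlarging the
unaffected background N *increases* a positive φ monotonically toward
C/√(P_i·P_j) — dilution does not shrink the correlation, it makes joint
occurrence of two rare diseases more surprising. The cohort denominator
therefore matters: the caller supplies `cohort_ids` (e.g. the female subset),
and the package never silently restricts it.

## Evaluation

AUC uses the rank (Mann–Whitney) method with mid-ranks for ties and is
undefined (None, excluded from averages with a log line) when labels are
one-class. Spearman ρ uses mid-ranks with a two-sided t-approximation
p-value; an exact permutation p is available for n ≤ 10. The full-DDN
condition is always evaluated on the ego's alter set so both conditions
score identical instances — truth labels exist only for alters, and any
other comparison would be ill-posed. Egos with fewer than three alters have
no meaningful rank correlation and report ρ = NaN.

## Synthetic cohort generator

The generator is a stand-in for non-shareable biobank data; its job is to
reproduce the one structural assumption the method needs — more shared
causal variants ⇒ higher co-occurrence — under full experimental control,
not to imitate human genomes.

* **Genotypes:** per SNP, maf ~ Uniform(maf_low, maf_high), dosages
  Binomial(2, maf) under Hardy–Weinberg, one synthetic chromosome with SNPs
  `spacing_bp` = 50 kb apart, no LD by default. An optional block-LD mode
  (followers copy each anchor allele with probability √R²) exists solely to
  exercise the pruning step.
* **Disease model:** liability = effect_size · Σ_causal sign·z + ε, with z
  the maf-standardized dosage, ε ~ N(0,1); case iff liability exceeds
  √(causal_per_disease·effect² + 1) · Φ⁻¹(1 − prevalence), so realized
  prevalence matches the target in expectation (tested as a Monte-Carlo
  bound). The liability-threshold form was chosen over logistic sampling
  because it gives analytically controllable prevalence and induces
  comorbidity directly through shared causal SNPs.
* **Pleiotropy blocks** assign a common causal SNP set to a disease group;
  shared sets of distinct blocks and all private fills are mutually
  disjoint, so pairwise causal overlap is exactly the summed block sizes. A
  block may flip the effect sign for a member (antagonistic pleiotropy):
  such a pair shares associated variants — association tests are two-sided —
  yet co-occurs *less* than chance. This is the realistic failure mode of
  the shared-variant assumption and the generator's source of true negative
  validation labels; without it, every connected alter at these sample sizes
  is significantly comorbid and ranking metrics are undefined.
* **Association scan:** per (disease, SNP), a 2×2 allele-count table tested
  with the Pearson chi-squared closed form on 1 df (p floored at 1e−300 to
  keep the p > 0 invariant under extreme statistics). An allelic test rather
  than a mixed model: the pipeline consumes only p-values, the simulated
  cohort is unrelated and homogeneous, and the test is calibrated (null
  rejection rate 5% ± 2% is a standing test).
* **Diagnosis emission:** true cases recorded with probability
  `diagnosis_sensitivity` (default 0.9), non-cases with
  1 − `diagnosis_specificity` (default 0.99) — EHR under-coding is common,
  false coding rare.

What the generator does **not** model: realistic LD maps, population
structure and relatedness, sex chromosomes, variable effect sizes,
covariates, temporal disease ordering. Passing tests therefore demonstrate
correctness of the pipeline's logic and statistics on the planted structure,
not performance on real biobank data.

## Reference study conditions

The end-to-end checks and `scripts/acceptance.py` use one fixed design:
5,000 individuals, 500 SNPs, 15 diseases in three independent groups of
five, causal_per_disease 25, effect size 0.5, prevalence 0.2,
maf ~ U(0.02, 0.10), ten seeded replicates. Low-frequency variants keep
shared-SNP carrier status informative (≈ 30% non-carriers of a ten-SNP set);
at common frequencies nearly everyone is a carrier and the stratification
table degenerates. Each group contains an ego; an alter sharing 10 causal
SNPs; an alter sharing 5 with the ego, 5 with the first alter, and 10 with a
decoy; an antagonistic alter sharing 5 with flipped sign; and a decoy with
zero ego overlap. Ego–alter causal overlaps thus lie in {0, 5, 10}. The
design makes the egocentric ranking (strong > moderate > antagonistic)
deterministic while the decoy — invisible to the egocentric network —
drains the moderate alter's score in the full diseasome and inverts its
rank: the scaled-down analogue of the finding that egocentric propagation
outperforms full-diseasome propagation. These problem sizes run the whole
ten-replicate study in seconds on one core.

## Numerical and formatting choices

Floats serialize to 6 significant digits, scientific below 1e−4, making
every artifact byte-stable and diffable; edge lists sort by (phecode_a,
phecode_b); shared SNP ids are stored sorted and joined by ";" in exports.
Delimiters come from file extensions only (TSV for data, CSV for metadata),
never sniffed. The pipeline's single global seed expands into per-stage
sub-seeds by SHA-256 of "seed:stage", so stages rerun in isolation reproduce
their outputs; identical config and seed give byte-identical manifests.
Odds ratios apply the Haldane 0.5 correction when a contingency cell is
zero; the chi-squared test warns when an expected cell count is below 5.
Carrier status reads "dosage ≥ 1 at ≥ 1 shared SNP"; risk-allele orientation
is not modelled (effect alleles for shared SNPs are not part of the edge
annotation) — a documented limitation.

## Known limitations

* Variant sharing is association sharing: the networks carry no causal
  claim, and antagonistic pleiotropy shows that a shared edge need not mean
  positive comorbidity.
* The φ ground truth and the network derive from the same simulated cohort,
  mirroring the circularity of single-biobank validation; an external
  validation cohort is out of scope.
* The summary-statistic schema is a normalized stand-in; real PheWAS export
  dialects (SAIGE columns, PLINK formats, BGEN/VCF genotypes) are not parsed.
* Quartile boundaries use ceil(n/4) chunks of the ranked alters; with heavy
  score ties the grouping falls back to PheCode order (warned).
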