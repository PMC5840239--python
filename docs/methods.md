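# Methods

This note records the statistical models, the calibrated generator
presets, and the numerical and design choices behind `painmark`, at the
level of detail a maintainer needs to trust or change them.

## Differential-expression screen and refinement

The screen operates on a genes × samples log2 expression matrix with a
two-level group map. Per gene, the test is a one-way ANOVA across the two
groups; for two groups this is algebraically the pooled-variance two-sided
t test (F = t²), and the implementation uses the vectorised t form with an
oracle-equivalence test against `scipy.stats.f_oneway`. The signed fold
change is the antilog of the difference of group means on the log2 scale
(the scale the data are analysed on), reported as a magnitude ≥ 1 plus an
up/down direction; the no-change tie reports "up". Genes whose two groups
both have zero variance get an undefined p and a `zero_variance` flag —
they are never silently dropped. A Benjamini–Hochberg FDR column is
emitted for information only; no decision in the pipeline uses it, because
the screen being modelled applies none.

Screen thresholds: FC ≥ 1.2 and p ≤ 0.05, boundaries inclusive.

The refinement gate classifies screened genes into branches A/B/C
(README) with precedence A → B → C. Two interval-reading choices make the
branches a partition: the FC window of branch C is [1.2, 1.5) so A and C
are disjoint, and the p window of branch B is (0.005, 0.05] so A and B are
disjoint. Whether branch C requires prior evidence is genuinely ambiguous
in the source gate's phrasing; the default requires it (every known gene
in that regime carries literature support, and the clause structure
parallels branch B), and `branch_c_requires_evidence=False` preserves the
other reading. Acceptance is monotone: lowering p or raising FC can never
flip an accepted gene to rejected (property-tested).

## Compendium correlations

A two-colour-array compendium is a long table of per-experiment log2
ratios with per-platform gene presence. The prior correlation of a gene
pair is Pearson r over exactly the experiments containing both genes —
pairwise-complete, delegated to `pandas.DataFrame.corr(min_periods=…)`,
which uses a numerically stable mean-centred computation; an in-repo
brute-force two-pass implementation serves as the test oracle. Pairs with
fewer than `min_pairs` co-presences are *undefined* (NaN), not zero;
co-presence counts are recorded for every pair. `min_pairs` defaults to 6:
no minimum is documented for the original analysis, and 6 keeps r from
being dominated by 2–3-point artefacts. Zero variance on the co-present
subset also yields an undefined (flagged) r.

Module detection thresholds the correlation graph (edge: defined r ≥
threshold) within each direction set and enumerates maximal cliques of
size ≥ 2 exactly (`networkx.find_cliques`); at the intended scale (tens of
genes) exactness is cheap and beats heuristics. Overlapping cliques are
all reported, never merged. Per module, same-direction genes whose mean
defined r against the module is ≤ −threshold are listed as anticorrelated
— the signature of a coherent module embedded in an otherwise opposed
regulon. The correlation threshold is an explicit parameter with no
claimed canonical default (0.6 in the demo configuration). A heatmap gene
ordering (average-linkage leaves on distance 1 − r, undefined r treated as
distance 1) is exported as text; no plotting is performed.

## qPCR quantification and geNorm

Relative quantities use the efficiency-corrected delta-Cq convention
RQ(g, s) = E_g^(C̄q_g − Cq(g, s)) with a gene-wise mean calibrator. Fold
changes and p values are invariant to the calibrator, so the choice is
cosmetic, but it is fixed for reproducibility. Efficiency defaults to 2.0
(no per-assay efficiencies are available) and must lie in (1, 2].
Technical replicates are arithmetically averaged per gene × sample first;
a QC flag marks replicate spreads above 0.5 cycles.

geNorm stability: for candidates j, k, V_jk is the sample SD across shared
samples of log2(RQ_j/RQ_k); M_j is the mean of V_jk over k ≠ j. M is
invariant to scaling any candidate's RQ by a constant (shifts cancel in
the log ratios; property-tested). CV_j is SD/mean of the candidate's
normalised relative quantity after dividing by the per-sample geometric
mean of all candidates. The iterative ranking repeatedly removes the
highest-M gene, recomputing M on the remainder; the last two genes are the
most stable pair. Candidates are analysed over the intersection of samples
measured for all of them (≥ 3 required).

Normalisation divides each gene's RQ by the per-sample geometric mean of
the chosen reference genes; afterwards the references' per-sample geomean
is exactly 1 (asserted in tests). Group comparisons run an unpaired
two-sided t test on log2 NRQs, equal-variance pooling by default (Welch
selectable); fold change is 2^(Δ mean log2). The proprietary
error-propagation model of commercial qPCR suites is *not* reproduced;
plain averaging is a documented deviation. Genes with fewer than two
quantifiable samples in a group are reported as `not_analysable`, never
dropped.

## ddPCR quantification

Droplet digital PCR partitions a reaction into ~nanolitre droplets; with
copies Poisson-distributed over droplets, the negative fraction estimates
e^(−λ). Wells are pooled per gene × sample (positives and totals summed)
before inversion — pooling before, not after, inversion is the unbiased
order. λ = −ln(1 − positives/total) copies per droplet; copies per
reaction = λ · V_reaction/V_droplet. Defaults: droplet volume 0.85 nl (the
QX200-class instrument convention — a configuration constant, not a
measurement) and reaction volume 20 µl, so one reaction holds ≈ 23529
droplet volumes. Saturated gene × samples (all droplets positive) are
undefined and flagged; zero positives is a valid measurement of zero.
Normalisation divides target copies by the per-sample geometric mean of
reference-gene copies (Rpl13a/Ubc in the validation preset); group
comparison reuses the log2-scale t test. Whether the original group
comparisons ran on normalised copies per reaction or per-µl concentrations
is not documented; normalised copies per reaction is implemented, matching
the stated normalisation.

## Plasma ELISA and clinical statistics

The standard curve is the four-parameter logistic
A(x) = D + (A₀ − D)/(1 + (x/C)^B) — the immunoassay standard; the kit's
actual curve model is unknown, and a log-log linear fallback can be had by
fitting in that regime (B → 1 with a distant asymptote behaves linearly;
tested). The fit is least squares (`scipy.optimize.curve_fit`) initialised
from the level means (asymptotes from the extreme levels, C at the
geometric mid-concentration, B = 1) with positivity bounds. Standards must
span ≥ 4 distinct concentrations and be monotone beyond noise (Spearman
|ρ| ≥ 0.8 across level means), else the fit aborts with diagnostics.
Inversion is closed-form and defined strictly between the asymptotes;
out-of-range replicates are flagged per replicate. Duplicates are averaged
on the *concentration* scale so curve nonlinearity does not bias the mean,
then multiplied by the dilution factor (default ×20: 10 µl plasma in
200 µl).

Group comparisons: Mann–Whitney U uses the exact permutation null when the
combined sample is ≤ 25 and tie-free — the clinical group sizes (10–12 per
group) sit inside that range — and the tie-corrected normal approximation
(no continuity correction, so identical groups give p = 1) otherwise.
Kruskal–Wallis uses the tie-corrected H with a χ²_{k−1} p value. Both
delegate to scipy; tests verify the exact route against full enumeration
of group assignments and the H statistic against a from-first-principles
rank computation. The protein–mRNA association is a plain Pearson R on the
raw concentration scale (the scale choice is undocumented in the source;
raw is the default) with the t-transform p. Covariates: sex by unpaired t
test (undefined when a sex has < 2 subjects), age by one-way ANOVA over
decade bins (bins with < 2 subjects dropped; a continuous-age regression F
test is selectable since the original age model is unstated).

## Synthetic-data generators and their calibration

Every generator takes a validated spec with a mandatory seed (no global
RNG state); identical spec + seed reproduces byte-identical tables, and
every table round-trips through its TSV reader.

**Compendium.** Presence is i.i.d. Bernoulli per gene per experiment.
A planted module with target correlation r gives its members loading
√r on one shared standard-normal factor per experiment plus independent
noise, the simplest exchangeable structure with expected pairwise
correlation exactly r; negative targets are supported for 2-gene modules
via opposite-sign loadings. Not emulated: hybridisation/probe effects,
batch structure, platform-specific normalisation — so passing tests show
estimator correctness under clean co-presence patterns, not robustness to
array artefacts.

**Blood expression.** Per-gene uniform baselines (5–11 log2 units),
i.i.d. Gaussian residuals (default SD 0.3 log2 units — chosen so the
planted printed fold changes of 1.2–2.23 at n = 10 + 10 land in the
printed p regime of ~5·10⁻⁴–5·10⁻²), cases shifted by the direction-signed
log2 fold change. No gene–gene correlation within the case/control matrix.

**qPCR.** Cq = base − log_E(q · f_s) + ε, where f_s is a per-sample
log2-normal loading factor shared by all genes (default SD 0.25 log2
units) and ε is per-gene technical noise; with E = 2 a doubling of
template lowers Cq by exactly one cycle. Reference genes have constant
underlying quantity, so multi-reference normalisation removes f_s — in the
noiseless, no-spread limit the pipeline recovers a planted ratio exactly
(tested at the validation preset's 2.19).

**Reference-gene panel calibration.** With independent log2-RQ noise σ_j
per candidate, the sample SD of log2(RQ_j/RQ_k) over n samples has
expectation c₄(n)·√(σ_j² + σ_k²), where c₄ is the small-sample expectation
factor of the sample SD. The 12-gene preset uses two stable candidates at
σ_a = 0.20/c₄(18) and ten rougher ones at σ_b solved in closed form so the
expected M of each stable candidate equals the published kit stability of
0.419 at 18 samples. Measured mean top-pair M over 100 replicate runs:
0.415.

**ddPCR.** Per well, positives ~ Binomial(droplets, 1 − e^(−λ)) with λ
from the planted copies and the volume constants; 15000 droplets/well, 2
wells/sample in the preset. Droplet-volume variation and rain
(intermediate fluorescence) are not modelled.

**Plasma.** Concentrations are zero-truncated normal by default (lognormal
selectable — the printed ranges suggest right skew, and no family is
documented, so both are provided). The preset location/scale are the
*printed group mean/SD*, and the underlying normal parameters are solved
numerically so the truncated distribution's mean and SD match them —
naive truncation of N(278.4, 131.4²) would bias the generated mean by
≈ +5.6 ng/ml. Paired mRNA levels (arbitrary units, mean 1, SD 0.3) are
coupled by regression on the realised protein value standardised by those
known moments, which makes the population correlation equal the preset ρ
exactly on the raw scale regardless of truncation or family. The
correlation preset models the paired cohort as a single group of n = 20
(only a pooled R of 0.68 is printed; mean of the two group locations,
pooled SD including between-group spread). Mean estimated R at n = 20 over
500 panels: 0.674 — the residual gap from 0.68 is the standard
small-sample Pearson bias ≈ ρ(1 − ρ²)/2n. Ages are uniform over 30–70,
sexes Bernoulli(0.5), neither influencing concentration (the null under
which the covariate checks are validated).

## Pipeline orchestration and concordance

`run_pipeline` executes synthesis (optional) → DE screen → refinement →
compendium correlation → qPCR → ddPCR → plasma statistics → concordance,
writing per-stage outputs and a manifest (config hash, seed, version,
per-stage row counts, SHA-256 of every output). Reruns with identical
config are byte-identical (asserted). A disabled upstream stage makes a
dependent stage fail fast with a machine-readable error record naming the
stage.

Concordance consumes an explicit human→rat ortholog table (the original
mapping was hand-picked, e.g. CASP5→Casp4, ARHGAP11B→Arhgap11a; no
automatic inference). A panel gene is *concordant* when both directions
agree and both p values are ≤ the significance threshold (default 0.05),
*discordant* when testable but failing either condition, *untestable* when
unmapped, absent or not analysable. A separate trend flag (default
p ≤ 0.10) records near-threshold same-direction results without promoting
them to significance — informal "strong trend" language is deliberately
not encoded as a decision rule.

## Problem sizes and limitations

The validation suite uses desk-scale Monte-Carlo sizes chosen to make the
stated tolerances meaningful: 200 replicate plasma panels for group-mean
recovery (3-SE criterion), 2500 replicates per route for the
Mann–Whitney power cross-check (±0.03 on a frequency difference needs
~0.013 SD), 500 panels for correlation recovery (±0.05), 200 runs for
qPCR fold-change recovery (±5%), 100 runs for geNorm stability (±10%), and
1000 simulations for type-I-error calibration (±0.02).

Known limitations: raw-data reprocessing (array CEL files, amplification
curves, droplet fluorescence, plate layouts) is out of scope — the
pipeline starts from expression matrices, Cq values, droplet counts and
absorbances; published per-gene p values are treated as fixture inputs,
not reproduction targets, since the underlying raw data are not public;
the generators produce i.i.d. Gaussian noise structures and therefore
validate estimator correctness and calibration, not robustness to batch
effects, outliers or assay drift.
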