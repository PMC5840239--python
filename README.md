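# painmark

Translational blood-biomarker triage for chronic neuropathic pain.

Objective diagnosis of chronic neuropathic back pain (CNBP) is an open
problem: the condition is defined by questionnaires and clinical judgement,
and no circulating marker separates neuropathic from inflammatory back
pain. One discovery route screens the whole-blood transcriptome of
patients against controls, filters candidates through statistical and
prior-evidence gates, and validates the survivors across species (rat
spinal-nerve-ligation dorsal horn) and across molecular levels (plasma
protein). `painmark` implements that entire chain as a tested, reusable
Python library:

* **Differential-expression screen** — per-gene one-way ANOVA (for two
  groups identical to the pooled t test, F = t²) with signed fold change
  FC = 2^(x̄_case − x̄_control); screen keeps FC ≥ 1.2 and p ≤ 0.05.
* **Candidate refinement gate** — a gene is accepted on one of three
  branches: (A) p ≤ 0.005 and FC ≥ 1.5; (B) prior evidence (correlation
  analysis or pain literature) with 0.005 < p ≤ 0.05 and FC ≥ 1.5;
  (C) prior evidence with p ≤ 0.005 and 1.2 ≤ FC < 1.5.
* **Compendium correlations** — pairwise-complete Pearson r over a
  heterogeneous two-colour-microarray compendium (each pair computed on
  exactly the experiments where both genes are present), with maximal-clique
  module detection among up-/downregulated gene sets.
* **qPCR quantification** — efficiency-corrected relative quantities
  RQ = E^(ΔCq), geNorm reference-gene stability
  M_j = mean_k sd(log₂ RQ_j/RQ_k), multi-reference normalisation by the
  geometric mean of reference RQs, unpaired t tests on log₂ scale.
* **ddPCR quantification** — Poisson inversion of droplet counts,
  λ = −ln(1 − positives/total), copies per reaction = λ · V_reaction/V_droplet,
  normalised by the geometric mean of reference-gene copies.
* **Plasma ELISA statistics** — four-parameter-logistic standard curves
  with inversion, Mann–Whitney U (exact for small tie-free samples),
  Kruskal–Wallis H, protein–mRNA Pearson correlation, age/sex covariate
  checks.
* **Cross-species concordance** — human panel vs rat ortholog results
  through an explicit mapping, with significance and trend reported
  separately.
* **Synthetic-data generators** — every input above can be simulated with
  known ground truth, with presets calibrated to the published summary
  statistics (group means/SDs, fold changes, correlation strength, geNorm
  stability), so each estimator can be shown to recover what was planted.

## Worked example

Feed the published 15-gene human blood panel (per-gene p, fold change and
evidence flags) through the refinement gate:

```python
from painmark import datasets, refine_panel

panel = refine_panel(datasets.cnbp_blood_panel())
print(panel[["gene", "p", "direction", "fc", "branch"]].to_string(index=False))
```

```
     gene      p direction   fc branch
    CASP5 0.0449        up 2.23      B
      CLU 0.0489        up 1.85      B
     DPP3 0.0028        up 1.50      A
     ELF3 0.0095        up 1.62      B
   FAM99A 0.0017        up 1.64      A
   ICOSLG 0.0007        up 1.20      C
   LIN28A 0.0183      down 1.50      B
     MC1R 0.0005        up 1.40      C
    NLRC4 0.0437        up 1.99      B
     ORM2 0.0225        up 1.97      B
ARHGAP11B 0.0025        up 1.57      A
   RNF185 0.0032      down 1.68      A
 RNU6-76P 0.0049      down 1.54      A
    TIMP1 0.0049        up 1.50      A
     TLR5 0.0428        up 1.75      B
```

All 15 genes are accepted — 6 on statistical stringency alone (branch A),
7 via supporting evidence at moderate significance (branch B), and 2
low-fold-change genes rescued by strong significance plus literature
support (branch C). TIMP1, the headline candidate, clears branch A and is
additionally flagged by the compendium correlation analysis.

The `examples/` directory holds one narrative script per capability
(screen + refinement, compendium correlation, qPCR with geNorm, ddPCR,
plasma ELISA, full pipeline); each builds a small input, runs the method
and prints what the numbers mean. A thin CLI mirrors the library:
`painmark synth|corr|de|pcr|plasma|pipeline --help`.

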