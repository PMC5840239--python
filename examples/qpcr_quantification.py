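"""qPCR relative quantification with geNorm reference stability.

Simulates the rat dorsal-horn validation run: the Timp1 target planted at
an SNL/sham ratio of 2.19 (n = 8 sham vs 10 SNL) alongside the calibrated
12-candidate reference panel. geNorm ranks the candidates by stability M,
the Atp5b/Ubc pair normalises the target, and an unpaired t test on log2
normalised quantities recovers the planted fold change.
"""

from painmark import pcr, presets, synth

spec = presets.timp1_qpcr_preset(seed=3).model_copy(
    update={"reference_noise_sd":
            presets.refgene_panel_preset(seed=3).reference_noise_sd})
cq, truth = synth.gen_cq_experiment(spec)
print(f"Cq table: {cq.gene.nunique()} genes x {cq['sample'].nunique()} samples "
      f"(planted Timp1 ratio {truth.ratio.iloc[0]})")

rq = pcr.relative_quantities(cq, efficiency=2.0)
stability = pcr.genorm(rq, candidates=sorted(spec.reference_noise_sd))
print("\ngeNorm stability (most stable first):")
print(stability.table.head(4).round(3).to_string(index=False))
print(f"most stable pair: {stability.final_pair}")

nrq = pcr.normalize(rq, references=["Atp5b", "Ubc"])
result = pcr.group_stats(nrq[~nrq.is_reference], case="snl", control="sham")
row = result.iloc[0]
print(f"\nTimp1: {row.direction} {row.fc:.2f}-fold in SNL, p = {row.p:.4f} "
      f"(planted 2.19-fold up)")
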