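"""Study-condition presets for the synthetic generators.

Each preset parameterises a generator spec from the published summary
statistics of the chronic-back-pain biomarker study, so that the estimator
implemented downstream is expected to recover the printed value:

* plasma groups: healthy controls 157.3 +/- 33.2 ng/ml (n=10), chronic
  neuropathic back pain (CNBP) 278.4 +/- 131.4 ng/ml (n=10), chronic
  inflammatory back pain (CIBP) 147.8 +/- 75.55 ng/ml (n=12);
* pooled protein-mRNA Pearson correlation 0.68 over the paired
  control + CNBP cohort (n=20);
* rat dorsal-horn Timp1 ratio 2.19 (sham n=8 vs SNL n=10), normalised to
  Atp5b and Ubc;
* a 12-candidate reference-gene panel whose two most stable genes have an
  expected geNorm stability M of 0.419;
* droplet-digital PCR counts for the ddPCR-validated genes at QX200-like
  droplet numbers and volumes.
"""

from __future__ import annotations

import math

from scipy.special import gammaln

from .datasets import (
    DOWNREGULATED_HEATMAP_GENES,
    UPREGULATED_HEATMAP_GENES,
    cnbp_blood_panel,
)
from .synth import (
    CompendiumSpec,
    DdpcrSpec,
    DEGeneTruth,
    DESpec,
    PlasmaGroup,
    PlasmaSpec,
    QpcrGene,
    QpcrSpec,
)

__all__ = [
    "plasma_groups_preset",
    "plasma_correlation_preset",
    "timp1_qpcr_preset",
    "snl_qpcr_preset",
    "refgene_panel_preset",
    "ddpcr_preset",
    "blood_expression_preset",
    "compendium_preset",
    "GENORM_M_TARGET",
]

#: geNorm stability of the two most stable reference genes in the rat kit.
GENORM_M_TARGET = 0.419

#: Printed group summaries: label -> (mean ng/ml, SD ng/ml, n).
PLASMA_GROUP_STATS = {
    "control": (157.3, 33.2, 10),
    "CNBP": (278.4, 131.4, 10),
    "CIBP": (147.8, 75.55, 12),
}


def plasma_groups_preset(seed: int, family: str = "truncnorm") -> PlasmaSpec:
    """Three-group clinical plasma panel at the printed means/SDs/sizes."""
    groups = {
        label: PlasmaGroup(location=m, scale=s, n=n)
        for label, (m, s, n) in PLASMA_GROUP_STATS.items()
    }
    return PlasmaSpec(groups=groups, family=family, seed=seed)


def plasma_correlation_preset(seed: int, n: int = 20, r: float = 0.68) -> PlasmaSpec:
    """Paired protein/mRNA cohort at the printed pooled correlation.

    Only one pooled Pearson R over the paired control + CNBP subjects is
    printed, so the preset models that cohort as a single group whose
    location is the mean of the two group locations and whose scale is the
    pooled SD including the between-group spread:
    sqrt(mean(SD_g^2) + Var(mean_g)).
    """
    m_c, s_c, _ = PLASMA_GROUP_STATS["control"]
    m_n, s_n, _ = PLASMA_GROUP_STATS["CNBP"]
    location = (m_c + m_n) / 2.0
    between = ((m_c - location) ** 2 + (m_n - location) ** 2) / 2.0
    scale = math.sqrt((s_c**2 + s_n**2) / 2.0 + between)
    return PlasmaSpec(
        groups={"paired": PlasmaGroup(location=location, scale=scale, n=n)},
        mrna_protein_r=r,
        seed=seed,
    )


def timp1_qpcr_preset(seed: int, noise_sd: float = 0.35) -> QpcrSpec:
    """Rat dorsal-horn Timp1 run: true SNL/sham ratio 2.19, n = 8 vs 10,
    normalised to the Atp5b/Ubc reference pair."""
    return QpcrSpec(
        genes={"Timp1": QpcrGene(ratio=2.19, noise_sd=noise_sd)},
        reference_noise_sd={"Atp5b": 0.2, "Ubc": 0.2},
        n_control=8,
        n_case=10,
        seed=seed,
    )


def snl_qpcr_preset(seed: int, noise_sd: float = 0.35) -> QpcrSpec:
    """Full rat dorsal-horn qPCR validation run.

    Plants every qPCR-validated gene at its printed SNL/sham ratio
    (direction-encoded: a 2.18-fold downregulation becomes ratio 1/2.18),
    normalised to Atp5b/Ubc, sham n=8 vs SNL n=10.
    """
    from .datasets import snl_dorsal_horn_results

    rows = snl_dorsal_horn_results()
    genes = {
        row.gene: QpcrGene(
            ratio=row.fc if row.direction == "up" else 1.0 / row.fc,
            noise_sd=noise_sd,
        )
        for row in rows.itertuples()
        if row.method == "qpcr"
    }
    return QpcrSpec(
        genes=genes,
        reference_noise_sd={"Atp5b": 0.2, "Ubc": 0.2},
        n_control=8,
        n_case=10,
        seed=seed,
    )


def _c4(n: int) -> float:
    """Small-sample expectation factor of the sample SD: E[s] = c4(n) * sigma."""
    return math.sqrt(2.0 / (n - 1)) * math.exp(
        gammaln(n / 2.0) - gammaln((n - 1) / 2.0)
    )


def refgene_panel_preset(seed: int, n_samples: int = 18) -> QpcrSpec:
    """12-candidate reference-gene panel calibrated to the kit's stability.

    All candidates have constant underlying quantity (they are reference
    genes), differing only in technical noise. With independent log2-RQ
    noise sd sigma_j per gene, the sample SD of log2(RQ_j/RQ_k) over n
    samples has expectation c4(n) * sqrt(sigma_j^2 + sigma_k^2), so the
    geNorm M of gene j is expected at
    c4(n)/11 * sum_{k != j} sqrt(sigma_j^2 + sigma_k^2).

    Two stable candidates share sigma_a and ten rougher ones share sigma_b.
    With sigma_a fixed at 0.20/c4, sigma_b is solved in closed form so that
    the expected M of each stable candidate equals ``GENORM_M_TARGET``:
    11*M = sqrt(2)*sigma_a*c4 + 10*c4*sqrt(sigma_a^2 + sigma_b^2).
    """
    c4 = _c4(n_samples)
    sigma_a = 0.20 / c4
    rhs = (11.0 * GENORM_M_TARGET / c4 - math.sqrt(2.0) * sigma_a) / 10.0
    sigma_b = math.sqrt(rhs**2 - sigma_a**2)
    stable = ["Atp5b", "Ubc"]
    rough = [
        "Actb", "B2m", "Gapdh", "Hprt1", "Rpl13a", "Sdha",
        "Tbp", "Ywhaz", "Canx", "Cyc1",
    ]
    noise = {g: sigma_a for g in stable} | {g: sigma_b for g in rough}
    n_control = n_samples - n_samples // 2 - 1  # 8 when n_samples = 18
    n_case = n_samples - n_control  # 10 when n_samples = 18
    return QpcrSpec(
        genes={},
        reference_noise_sd=noise,
        n_control=n_control,
        n_case=n_case,
        size_factor_sd=0.3,
        seed=seed,
    )


def ddpcr_preset(seed: int, base_copies: float = 2000.0) -> DdpcrSpec:
    """Droplet-count run for the ddPCR-validated genes.

    Target genes carry the printed SNL/sham ratios (Mc1r 2.72 up, Casp4
    1.22 up, Nlrc4 1.15 up, Arhgap11a 1.03 down); Rpl13a and Ubc are the
    reference genes (ratio 1). Copies are per 20 ul reaction at QX200-like
    droplet numbers (15000/well) and droplet volume 0.85 nl.
    """
    ratios = {
        "Mc1r": 2.72,
        "Casp4": 1.22,
        "Nlrc4": 1.15,
        "Arhgap11a": 1.0 / 1.03,
        "Rpl13a": 1.0,
        "Ubc": 1.0,
    }
    samples = [(f"sham_{i:02d}", "sham") for i in range(8)] + [
        (f"snl_{i:02d}", "snl") for i in range(10)
    ]
    copies = {
        gene: {
            s: base_copies * (ratio if grp == "snl" else 1.0)
            for s, grp in samples
        }
        for gene, ratio in ratios.items()
    }
    return DdpcrSpec(
        copies=copies,
        groups=dict(samples),
        wells_per_sample=2,
        seed=seed,
    )


def blood_expression_preset(seed: int, n_null_genes: int = 200) -> DESpec:
    """Human blood screen: the printed 15-gene panel planted at its printed
    fold changes and directions over 10 cases vs 10 controls, on a bed of
    null genes. The residual SD of 0.3 log2 units puts the planted effects
    in the printed p-value regime (~5e-4 to 5e-2) at n = 10 + 10."""
    panel = cnbp_blood_panel()
    genes = {
        row.gene: DEGeneTruth(fold_change=row.fc, direction=row.direction)
        for row in panel.itertuples()
    }
    return DESpec(
        n_cases=10,
        n_controls=10,
        genes=genes,
        n_null_genes=n_null_genes,
        residual_sd=0.3,
        seed=seed,
    )


def compendium_preset(
    seed: int, n_experiments: int = 500, presence_prob: float = 0.6
) -> tuple[CompendiumSpec, list[str], list[str], list[str]]:
    """Two-colour-array compendium with the published heatmap gene sets and
    a planted positively correlated TIMP1/ORM2/PROX1 triad (r = 0.75).

    Returns (spec, gene_names, up_set, down_set); generated integer gene
    ids G00000.. map positionally onto ``gene_names``.
    """
    genes = list(UPREGULATED_HEATMAP_GENES) + list(DOWNREGULATED_HEATMAP_GENES)
    triad = [genes.index(g) for g in ("TIMP1", "ORM2", "PROX1")]
    spec = CompendiumSpec(
        n_experiments=n_experiments,
        n_genes=len(genes),
        presence_prob=presence_prob,
        modules=[(triad, 0.75)],
        noise_sd=1.0,
        seed=seed,
    )
    return spec, genes, list(UPREGULATED_HEATMAP_GENES), list(DOWNREGULATED_HEATMAP_GENES)
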