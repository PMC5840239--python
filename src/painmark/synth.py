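"""Synthetic-data generators for every input the triage pipeline consumes.

Each generator is driven by a validated spec (pydantic model) carrying an
explicit, mandatory seed, and returns tidy pandas tables in the same layout
the readers in :mod:`painmark.io` expect, plus a ground-truth record where
an estimator downstream is supposed to recover a planted parameter.

The generators emulate, with known truth:

* a heterogeneous two-colour microarray compendium with per-platform gene
  presence and planted correlated gene modules;
* a case/control blood expression matrix with planted fold changes;
* qPCR quantification-cycle (Cq) plates with shared per-sample loading
  ("size") factors and designated reference genes;
* digital-droplet PCR droplet counts under a Poisson occupancy model;
* plasma protein panels (three clinical groups) with optional paired
  whole-blood mRNA levels at a prescribed Pearson correlation.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, stats

__all__ = [
    "CompendiumSpec",
    "DESpec",
    "QpcrSpec",
    "DdpcrSpec",
    "PlasmaGroup",
    "PlasmaSpec",
    "gen_compendium",
    "gen_blood_expression",
    "gen_cq_experiment",
    "gen_droplet_counts",
    "gen_plasma_panel",
    "truncated_normal_params",
]


class _Spec(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


# ---------------------------------------------------------------------------
# Compendium
# ---------------------------------------------------------------------------

class CompendiumSpec(_Spec):
    """Spec for a two-colour-array log2-ratio compendium.

    ``modules`` plants correlated gene sets: each module is a (gene ids,
    target pairwise correlation) pair. Correlation is induced by one shared
    latent factor per module per experiment with loading sqrt(r), the
    simplest exchangeable structure whose expected pairwise Pearson
    correlation equals r exactly.
    """

    n_experiments: int = Field(ge=1)
    n_genes: int = Field(ge=1)
    presence_prob: float = Field(gt=0.0, le=1.0, default=0.6)
    modules: list[tuple[list[int], float]] = Field(default_factory=list)
    noise_sd: float = Field(gt=0.0, default=1.0)
    seed: int

    @model_validator(mode="after")
    def _check_modules(self) -> "CompendiumSpec":
        for genes, r in self.modules:
            if not -1.0 < r < 1.0:
                raise ValueError(f"module correlation {r} outside (-1, 1)")
            if r < 0.0 and len(genes) > 2:
                raise ValueError(
                    "a negative pairwise correlation is only realisable for a "
                    "2-gene module under the shared-factor construction"
                )
            if any(g < 0 or g >= self.n_genes for g in genes):
                raise ValueError("module gene id outside [0, n_genes)")
        return self


def gen_compendium(spec: CompendiumSpec) -> pd.DataFrame:
    """Generate a long-format compendium table.

    Returns a DataFrame ``experiment_id, gene_id, log2_ratio`` containing
    one row per (experiment, present gene). Presence is drawn independently
    per gene per experiment; present genes in a planted module share a
    latent factor so their expected pairwise correlation equals the module's
    target.
    """
    rng = np.random.default_rng(spec.seed)
    n_e, n_g = spec.n_experiments, spec.n_genes

    # loading[g] = +/- sqrt(|r|) for module members; a negative target
    # correlation (2-gene modules only) gets opposite-sign loadings
    loading = np.zeros(n_g)
    module_of = np.full(n_g, -1)
    for m, (genes, r) in enumerate(spec.modules):
        for i, g in enumerate(genes):
            sign = -1.0 if (r < 0 and i % 2 == 1) else 1.0
            loading[g] = sign * math.sqrt(abs(r))
            module_of[g] = m
    n_modules = len(spec.modules)

    present = rng.random((n_e, n_g)) < spec.presence_prob
    latent = rng.standard_normal((n_e, max(n_modules, 1)))
    eps = rng.standard_normal((n_e, n_g))

    shared = np.zeros((n_e, n_g))
    for g in range(n_g):
        if module_of[g] >= 0:
            shared[:, g] = loading[g] * latent[:, module_of[g]]
    resid = np.sqrt(1.0 - loading**2) * eps
    values = spec.noise_sd * (shared + resid)

    e_idx, g_idx = np.nonzero(present)
    return pd.DataFrame(
        {
            "experiment_id": [f"E{i:05d}" for i in e_idx],
            "gene_id": [f"G{j:05d}" for j in g_idx],
            "log2_ratio": values[e_idx, g_idx],
        }
    )


# ---------------------------------------------------------------------------
# Blood expression (case/control DE)
# ---------------------------------------------------------------------------

class DEGeneTruth(_Spec):
    fold_change: float = Field(ge=1.0, description="linear-scale magnitude")
    direction: Literal["up", "down"] = "up"


class DESpec(_Spec):
    """Spec for a two-group log2 expression matrix with planted effects.

    ``genes`` maps gene id -> planted (fold change magnitude, direction);
    genes not listed are null (fold change 1). Case samples receive the
    direction-signed log2 fold change on top of a per-gene baseline.
    """

    n_cases: int = Field(ge=2)
    n_controls: int = Field(ge=2)
    genes: dict[str, DEGeneTruth] = Field(default_factory=dict)
    n_null_genes: int = Field(ge=0, default=0)
    residual_sd: float = Field(gt=0.0, default=0.3)
    baseline_range: tuple[float, float] = (5.0, 11.0)
    seed: int


def gen_blood_expression(spec: DESpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (expression matrix, truth table).

    The matrix is genes x samples on log2 scale, columns named
    ``case_*`` / ``ctrl_*``; the truth table lists each planted gene's
    signed fold change.
    """
    rng = np.random.default_rng(spec.seed)
    planted = list(spec.genes)
    nulls = [f"NULL{i:04d}" for i in range(spec.n_null_genes)]
    genes = planted + nulls
    n_genes = len(genes)
    if n_genes == 0:
        raise ValueError("spec plants no genes")

    samples = [f"case_{i:02d}" for i in range(spec.n_cases)] + [
        f"ctrl_{i:02d}" for i in range(spec.n_controls)
    ]
    lo, hi = spec.baseline_range
    baseline = rng.uniform(lo, hi, size=n_genes)
    mat = baseline[:, None] + spec.residual_sd * rng.standard_normal(
        (n_genes, len(samples))
    )
    for i, g in enumerate(planted):
        t = spec.genes[g]
        delta = math.log2(t.fold_change)
        if t.direction == "down":
            delta = -delta
        mat[i, : spec.n_cases] += delta

    matrix = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "fold_change": [spec.genes[g].fold_change for g in planted]
            + [1.0] * len(nulls),
            "direction": [spec.genes[g].direction for g in planted]
            + ["up"] * len(nulls),
        }
    )
    return matrix, truth


def de_group_map(spec: DESpec) -> pd.DataFrame:
    """Sample -> group table matching :func:`gen_blood_expression` columns."""
    rows = [(f"case_{i:02d}", "case") for i in range(spec.n_cases)] + [
        (f"ctrl_{i:02d}", "control") for i in range(spec.n_controls)
    ]
    return pd.DataFrame(rows, columns=["sample", "group"])


# ---------------------------------------------------------------------------
# qPCR Cq plates
# ---------------------------------------------------------------------------

class QpcrGene(_Spec):
    ratio: float = Field(gt=0.0, description="true case/control quantity ratio")
    noise_sd: float = Field(ge=0.0, default=0.35, description="log2-quantity noise")


class QpcrSpec(_Spec):
    """Spec for a two-group qPCR Cq experiment.

    Per sample s a shared loading ("size") factor f_s (log2-normal) scales
    every gene's true quantity; reference genes have constant underlying
    quantity and thus carry the size factor plus their own technical noise
    only, which is what multi-reference normalisation removes. Cq is
    generated as  base - log_E(quantity * f_s) + noise  so that with
    efficiency E=2 a doubling of template lowers Cq by exactly one cycle.
    """

    genes: dict[str, QpcrGene] = Field(default_factory=dict)
    reference_noise_sd: dict[str, float] = Field(
        default_factory=lambda: {"Atp5b": 0.2, "Ubc": 0.2}
    )
    n_control: int = Field(ge=2, default=8)
    n_case: int = Field(ge=2, default=10)
    control_label: str = "sham"
    case_label: str = "snl"
    base_cq: float = Field(gt=0.0, lt=40.0, default=24.0)
    efficiency: float = Field(gt=1.0, le=2.0, default=2.0)
    size_factor_sd: float = Field(ge=0.0, default=0.25, description="log2 scale")
    seed: int


def gen_cq_experiment(spec: QpcrSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (CqTable, truth table).

    CqTable columns: ``gene, sample, group, is_reference, cq``; the truth
    table records each target gene's planted case/control ratio.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [(f"{spec.control_label}_{i:02d}", spec.control_label) for i in range(spec.n_control)] + [
        (f"{spec.case_label}_{i:02d}", spec.case_label) for i in range(spec.n_case)
    ]
    log2_sf = spec.size_factor_sd * rng.standard_normal(len(samples))
    log_e_2 = math.log2(spec.efficiency)  # cycles per log2 unit: 1/log2(E)

    rows = []
    for gene, g in spec.genes.items():
        log2_ratio = math.log2(g.ratio)
        for (sample, group), sf in zip(samples, log2_sf):
            log2_q = (log2_ratio if group == spec.case_label else 0.0) + sf
            log2_q += g.noise_sd * rng.standard_normal()
            cq = spec.base_cq - log2_q / log_e_2
            rows.append((gene, sample, group, False, cq))
    for gene, noise_sd in spec.reference_noise_sd.items():
        for (sample, group), sf in zip(samples, log2_sf):
            log2_q = sf + noise_sd * rng.standard_normal()
            cq = spec.base_cq - log2_q / log_e_2
            rows.append((gene, sample, group, True, cq))

    cq_table = pd.DataFrame(
        rows, columns=["gene", "sample", "group", "is_reference", "cq"]
    )
    bad = cq_table[(cq_table.cq <= 0) | (cq_table.cq >= 40)]
    if not bad.empty:
        raise ValueError(
            "generated Cq outside (0, 40); lower noise or adjust base_cq "
            f"(first offender: {bad.iloc[0].to_dict()})"
        )
    truth = pd.DataFrame(
        {
            "gene": list(spec.genes),
            "ratio": [g.ratio for g in spec.genes.values()],
        }
    )
    return cq_table, truth


# ---------------------------------------------------------------------------
# ddPCR droplet counts
# ---------------------------------------------------------------------------

class DdpcrSpec(_Spec):
    """Spec for digital-droplet PCR counts.

    ``copies`` maps gene -> sample -> true copies per reaction. Per well,
    positives ~ Binomial(droplets, 1 - exp(-lambda)) with
    lambda = copies * droplet_volume / reaction_volume (copies per droplet).
    """

    copies: dict[str, dict[str, float]]
    groups: dict[str, str]
    wells_per_sample: int = Field(ge=1, default=1)
    droplets_per_well: int = Field(ge=1, default=15000)
    droplet_volume_nl: float = Field(gt=0.0, default=0.85)
    reaction_volume_ul: float = Field(gt=0.0, default=20.0)
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "DdpcrSpec":
        for gene, per_sample in self.copies.items():
            for sample, c in per_sample.items():
                if c < 0:
                    raise ValueError(f"negative true copies for {gene}/{sample}")
                if sample not in self.groups:
                    raise ValueError(f"sample {sample} missing from groups")
        return self


def gen_droplet_counts(spec: DdpcrSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (DropletCounts table, truth table).

    DropletCounts columns: ``gene, sample, group, well, positives, total``.
    """
    rng = np.random.default_rng(spec.seed)
    vol_ratio = spec.droplet_volume_nl / (spec.reaction_volume_ul * 1000.0)
    rows = []
    truth_rows = []
    for gene, per_sample in spec.copies.items():
        for sample, copies in per_sample.items():
            lam = copies * vol_ratio
            p_pos = 1.0 - math.exp(-lam)
            for w in range(spec.wells_per_sample):
                pos = int(rng.binomial(spec.droplets_per_well, p_pos))
                rows.append(
                    (gene, sample, spec.groups[sample], f"W{w}", pos, spec.droplets_per_well)
                )
            truth_rows.append((gene, sample, copies))
    counts = pd.DataFrame(
        rows, columns=["gene", "sample", "group", "well", "positives", "total"]
    )
    truth = pd.DataFrame(truth_rows, columns=["gene", "sample", "copies_per_reaction"])
    return counts, truth


# ---------------------------------------------------------------------------
# Plasma panels
# ---------------------------------------------------------------------------

def truncated_normal_params(mean: float, sd: float) -> tuple[float, float]:
    """Solve for (mu, sigma) of a normal truncated at zero whose truncated
    mean and SD equal ``mean`` and ``sd``.

    The printed clinical summaries are sample mean/SD of strictly positive
    concentrations, so the generator targets those moments on the truncated
    distribution rather than naively truncating N(mean, sd^2) (which would
    bias the generated mean upward, noticeably so when mean/sd is small).
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")

    def resid(x: np.ndarray) -> np.ndarray:
        mu, log_sigma = x
        sigma = math.exp(log_sigma)
        a = -mu / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return np.array([m - mean, math.sqrt(v) - sd])

    sol = optimize.root(resid, x0=np.array([mean, math.log(sd)]), tol=1e-12)
    if not sol.success:  # pragma: no cover - solver is robust in this range
        raise RuntimeError(f"truncated-normal moment match failed: {sol.message}")
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


class PlasmaGroup(_Spec):
    location: float = Field(gt=0.0, description="target mean, ng/ml")
    scale: float = Field(gt=0.0, description="target SD, ng/ml")
    n: int = Field(ge=2)


class PlasmaSpec(_Spec):
    """Spec for a clinical plasma-protein panel.

    ``family`` selects the concentration law: a zero-truncated normal whose
    truncated moments match (location, scale), or a lognormal with the same
    mean/SD. ``mrna_protein_r`` plants a Pearson correlation between
    concentration and a paired whole-blood mRNA level; by default the
    coupling is applied on the raw (linear) scale for both variables.
    """

    groups: dict[str, PlasmaGroup]
    family: Literal["truncnorm", "lognormal"] = "truncnorm"
    mrna_protein_r: Optional[float] = None
    mrna_location: float = Field(gt=0.0, default=1.0)
    mrna_scale: float = Field(gt=0.0, default=0.3)
    age_range: tuple[int, int] = (30, 70)
    female_fraction: float = Field(ge=0.0, le=1.0, default=0.5)
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "PlasmaSpec":
        if self.mrna_protein_r is not None and not -1.0 < self.mrna_protein_r < 1.0:
            raise ValueError("mrna_protein_r must lie strictly inside (-1, 1)")
        return self


def _draw_group(
    rng: np.random.Generator, g: PlasmaGroup, family: str, r: Optional[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (protein, standardised mRNA latent) for one group.

    The protein marginal is drawn first (rejection-sampled truncated normal
    or lognormal, both with mean ``location`` and SD ``scale``); the mRNA
    latent is then coupled by regression on the realised protein value
    standardised by those known moments,

        z_mrna = r * (protein - location) / scale + sqrt(1 - r^2) * eps,

    which makes the population correlation between protein and mRNA equal
    r exactly on the raw scale, unaffected by the truncation.
    """
    rho = 0.0 if r is None else r
    if family == "truncnorm":
        mu, sigma = truncated_normal_params(g.location, g.scale)
        prot = np.empty(g.n)
        filled = 0
        while filled < g.n:
            need = g.n - filled
            x = mu + sigma * rng.standard_normal(need)
            x = x[x > 0]
            prot[filled : filled + len(x)] = x
            filled += len(x)
    else:  # lognormal matched to mean/SD
        s2 = math.log(1.0 + (g.scale / g.location) ** 2)
        mu, sigma = math.log(g.location) - s2 / 2.0, math.sqrt(s2)
        prot = np.exp(mu + sigma * rng.standard_normal(g.n))

    eps = rng.standard_normal(g.n)
    z2 = rho * (prot - g.location) / g.scale + math.sqrt(1.0 - rho**2) * eps
    return prot, z2


def gen_plasma_panel(spec: PlasmaSpec) -> pd.DataFrame:
    """Generate a plasma panel table.

    Columns: ``subject, group, age, sex, conc_ng_ml, mrna_level`` (mRNA is
    NaN when the spec plants no correlation).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label, g in spec.groups.items():
        prot, z2 = _draw_group(rng, g, spec.family, spec.mrna_protein_r)
        ages = rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=g.n)
        sexes = np.where(rng.random(g.n) < spec.female_fraction, "F", "M")
        for i in range(g.n):
            mrna = (
                spec.mrna_location + spec.mrna_scale * z2[i]
                if spec.mrna_protein_r is not None
                else float("nan")
            )
            rows.append(
                (f"{label}_{i:02d}", label, int(ages[i]), sexes[i], prot[i], mrna)
            )
    return pd.DataFrame(
        rows, columns=["subject", "group", "age", "sex", "conc_ng_ml", "mrna_level"]
    )
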