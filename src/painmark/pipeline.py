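"""End-to-end orchestration and the cross-species concordance report.

``run_pipeline`` executes the stages in dependency order — synthesis (when
requested) -> DE screen -> refinement -> compendium correlation -> PCR
quantification (qPCR + ddPCR) -> plasma statistics -> concordance — writing
per-stage outputs plus a manifest (config hash, seed, package version,
per-stage row counts, content hash of every output file) so a rerun with
the identical config reproduces byte-identical outputs.

``concordance`` compares the human blood panel with the rat dorsal-horn
results through an explicit, hand-curated ortholog map: a panel gene is
*concordant* when both species' directions agree and both p values clear
the significance threshold, *discordant* when testable but failing either
condition, and *untestable* when unmapped, absent from the rat results or
not analysable. A separate trend flag (default p <= 0.10) records
near-threshold agreement without conflating it with significance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__ as _version
from . import compendium as comp
from . import datasets, diffexpr, io, pcr, plasma, presets, synth

__all__ = ["RunConfig", "run_pipeline", "concordance", "PipelineError"]


class PipelineError(RuntimeError):
    """Stage failure carrying a machine-readable error record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.record = {"stage": stage, "error": message}


class _Stage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True


class SynthStage(_Stage):
    seed: int = 0


class DEStage(_Stage):
    matrix: Optional[str] = None
    groups: Optional[str] = None
    evidence: Optional[str] = None
    branch_c_requires_evidence: bool = True


class CorrStage(_Stage):
    compendium: Optional[str] = None
    up_genes: Optional[str] = None
    down_genes: Optional[str] = None
    min_pairs: int = Field(ge=3, default=6)
    threshold: float = Field(gt=0.0, lt=1.0, default=0.6)


class QpcrStage(_Stage):
    cq: Optional[str] = None
    references: list[str] = Field(default_factory=lambda: ["Atp5b", "Ubc"])
    efficiency: float = Field(gt=1.0, le=2.0, default=2.0)
    case: str = "snl"
    control: str = "sham"


class DdpcrStage(_Stage):
    droplets: Optional[str] = None
    references: list[str] = Field(default_factory=lambda: ["Rpl13a", "Ubc"])
    droplet_volume_nl: float = Field(gt=0.0, default=pcr.DROPLET_VOLUME_NL)
    reaction_volume_ul: float = Field(gt=0.0, default=pcr.REACTION_VOLUME_UL)
    case: str = "snl"
    control: str = "sham"


class PlasmaStage(_Stage):
    panel: Optional[str] = None


class ConcordanceStage(_Stage):
    ortholog_map: Optional[str] = None
    p_threshold: float = Field(gt=0.0, le=1.0, default=0.05)
    trend_threshold: float = Field(gt=0.0, le=1.0, default=0.10)


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    synth: SynthStage = SynthStage(enabled=False)
    de: DEStage = DEStage()
    corr: CorrStage = CorrStage()
    qpcr: QpcrStage = QpcrStage()
    ddpcr: DdpcrStage = DdpcrStage()
    plasma: PlasmaStage = PlasmaStage()
    concordance: ConcordanceStage = ConcordanceStage()

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


def concordance(
    human_panel: pd.DataFrame,
    rat_results: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    p_threshold: float = 0.05,
    trend_threshold: float = 0.10,
) -> pd.DataFrame:
    """Cross-species concordance of the accepted human panel.

    ``human_panel``: refinement output (``gene, p, direction, fc, branch``);
    only accepted genes (branch != rejected) are compared. ``rat_results``:
    ``gene, p, direction, fc, method`` (method "not_analysable" marks genes
    without robust quantification). ``ortholog_map``: ``human_gene,
    rat_gene`` — duplicate human entries raise, listing the collisions.
    """
    dup = ortholog_map[ortholog_map.duplicated("human_gene", keep=False)]
    if not dup.empty:
        raise ValueError(
            f"duplicate ortholog mappings: {sorted(dup.human_gene.unique())}"
        )
    rat_ix = rat_results.drop_duplicates("gene").set_index("gene")
    orth = ortholog_map.set_index("human_gene")["rat_gene"]

    rows = []
    panel = human_panel[human_panel.get("branch", "A") != "rejected"]
    for row in panel.itertuples():
        rat_gene = orth.get(row.gene)
        rec = {
            "human_gene": row.gene,
            "rat_gene": rat_gene,
            "human_direction": row.direction,
            "human_fc": row.fc,
            "human_p": row.p,
            "branch": getattr(row, "branch", ""),
            "rat_direction": None,
            "rat_fc": np.nan,
            "rat_p": np.nan,
            "rat_method": None,
            "agreement": "untestable",
            "trend": False,
        }
        if rat_gene is not None and rat_gene in rat_ix.index:
            rat = rat_ix.loc[rat_gene]
            rec.update(
                rat_direction=rat["direction"], rat_fc=rat["fc"], rat_p=rat["p"],
                rat_method=rat["method"],
            )
            if rat["method"] != "not_analysable" and np.isfinite(rat["p"]):
                same_dir = rat["direction"] == row.direction
                significant = rat["p"] <= p_threshold and row.p <= p_threshold
                rec["agreement"] = (
                    "concordant" if (same_dir and significant) else "discordant"
                )
                rec["trend"] = bool(
                    same_dir and not significant and rat["p"] <= trend_threshold
                )
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _synthesise_inputs(cfg: RunConfig, in_dir: Path) -> dict[str, str]:
    """Generate every pipeline input from the calibrated presets."""
    seed = cfg.synth.seed
    paths: dict[str, str] = {}

    de_spec = presets.blood_expression_preset(seed=seed)
    matrix, truth = synth.gen_blood_expression(de_spec)
    paths["matrix"] = str(io.write_expression_matrix(matrix, in_dir / "expression.tsv"))
    paths["groups"] = str(io.write_group_map(synth.de_group_map(de_spec), in_dir / "groups.tsv"))
    io.write_json(truth.to_dict(orient="records"), in_dir / "expression_truth.json")

    ev = datasets.cnbp_blood_panel()[["gene", "ca", "literature"]]
    paths["evidence"] = str(io.write_evidence(ev, in_dir / "evidence.tsv"))

    comp_spec, gene_names, up, down = presets.compendium_preset(seed=seed + 1)
    table = synth.gen_compendium(comp_spec)
    name_of = {f"G{i:05d}": g for i, g in enumerate(gene_names)}
    table["gene_id"] = table["gene_id"].map(name_of)
    paths["compendium"] = str(io.write_compendium(table, in_dir / "compendium.tsv"))
    paths["up_genes"] = str(io.write_gene_list(up, in_dir / "up_genes.txt"))
    paths["down_genes"] = str(io.write_gene_list(down, in_dir / "down_genes.txt"))

    # every qPCR-validated target plus the full 12-candidate reference
    # panel, so the run exercises geNorm before settling on Atp5b/Ubc
    qpcr_spec = presets.snl_qpcr_preset(seed=seed + 2).model_copy(
        update={"reference_noise_sd":
                presets.refgene_panel_preset(seed=seed + 2).reference_noise_sd})
    cq, cq_truth = synth.gen_cq_experiment(qpcr_spec)
    paths["cq"] = str(io.write_cq_table(cq, in_dir / "cq.tsv"))
    io.write_json(cq_truth.to_dict(orient="records"), in_dir / "cq_truth.json")

    droplets, dd_truth = synth.gen_droplet_counts(presets.ddpcr_preset(seed=seed + 3))
    paths["droplets"] = str(io.write_droplet_counts(droplets, in_dir / "droplets.tsv"))
    io.write_json(dd_truth.to_dict(orient="records"), in_dir / "droplet_truth.json")

    panel = synth.gen_plasma_panel(presets.plasma_groups_preset(seed=seed + 4))
    paths["panel"] = str(io.write_plasma_panel(panel, in_dir / "plasma.tsv"))

    io.write_ortholog_map(datasets.human_rat_ortholog_map(), in_dir / "orthologs.tsv")
    paths["ortholog_map"] = str(in_dir / "orthologs.tsv")
    return paths


def _require(value: Optional[str], stage: str, what: str) -> str:
    if value is None:
        raise PipelineError(stage, f"missing required input: {what} "
                            "(provide a path or enable the synth stage)")
    return value


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the configured stages; returns the run directory.

    Outputs land under ``out_dir`` (created if needed): per-stage TSV/JSON
    files plus ``manifest.json``. Any stage failure aborts with a
    :class:`PipelineError` whose record is also written to ``error.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    stage = "config"
    try:
        cfg = config
        paths: dict[str, str] = {}
        if cfg.synth.enabled:
            stage = "synth"
            paths = _synthesise_inputs(cfg, out / "inputs")

        de_out = None
        panel_out = None
        if cfg.de.enabled:
            stage = "de"
            matrix = io.read_expression_matrix(
                cfg.de.matrix or _require(paths.get("matrix"), stage, "expression matrix"))
            groups = io.read_group_map(
                cfg.de.groups or _require(paths.get("groups"), stage, "group map"))
            de_out = diffexpr.de_test(matrix, groups)
            screened = diffexpr.primary_screen(de_out)
            counts["de_genes_tested"] = len(de_out)
            counts["de_genes_screened"] = len(screened)
            de_out.to_csv(out / "de.tsv", sep="\t", index=False, float_format="%.10g")

            stage = "refine"
            ev_path = cfg.de.evidence or paths.get("evidence")
            evidence = io.read_evidence(ev_path) if ev_path else None
            panel_out = diffexpr.refine_panel(
                screened, evidence,
                branch_c_requires_evidence=cfg.de.branch_c_requires_evidence)
            accepted = panel_out[panel_out.branch != "rejected"]
            counts["panel_accepted"] = len(accepted)
            panel_out.to_csv(out / "panel.tsv", sep="\t", index=False, float_format="%.10g")

        if cfg.corr.enabled:
            stage = "corr"
            comp_tbl = io.read_compendium(
                cfg.corr.compendium or _require(paths.get("compendium"), stage, "compendium"))
            up = io.read_gene_list(
                cfg.corr.up_genes or _require(paths.get("up_genes"), stage, "up gene list"))
            down = io.read_gene_list(
                cfg.corr.down_genes or _require(paths.get("down_genes"), stage, "down gene list"))
            cm = comp.pairwise_correlation(comp_tbl, min_pairs=cfg.corr.min_pairs)
            cm.r.to_csv(out / "correlation_r.tsv", sep="\t", float_format="%.10g")
            cm.n_pairs.to_csv(out / "correlation_n.tsv", sep="\t")
            report = comp.correlated_modules(cm, up, down, threshold=cfg.corr.threshold)
            io.write_json(
                {"up": report.up, "down": report.down, "diagnostics": report.diagnostics},
                out / "modules.json")
            order = comp.heatmap_order(cm, up + down)
            io.write_gene_list(order, out / "heatmap_order.txt")
            counts["corr_genes"] = len(cm.genes)
            counts["corr_modules_up"] = len(report.up)
            counts["corr_modules_down"] = len(report.down)

        rat_frames = []
        if cfg.qpcr.enabled:
            stage = "qpcr"
            cq = io.read_cq_table(
                cfg.qpcr.cq or _require(paths.get("cq"), stage, "Cq table"))
            rq = pcr.relative_quantities(cq, efficiency=cfg.qpcr.efficiency)
            candidates = sorted(cq.loc[cq.is_reference, "gene"].unique())
            if len(candidates) >= 3:
                report = pcr.genorm(rq, candidates)
                io.write_json(
                    {"table": report.table.to_dict(orient="records"),
                     "exclusion_order": report.exclusion_order,
                     "final_pair": list(report.final_pair)},
                    out / "genorm.json")
            nrq = pcr.normalize(rq, cfg.qpcr.references)
            nrq.to_csv(out / "nrq.tsv", sep="\t", index=False, float_format="%.10g")
            targets = nrq[~nrq.is_reference]
            res = pcr.group_stats(targets, case=cfg.qpcr.case, control=cfg.qpcr.control)
            res["method"] = res["method"].replace({"t_test": "qpcr"})
            rat_frames.append(res)
            counts["qpcr_genes"] = len(res)

        if cfg.ddpcr.enabled:
            stage = "ddpcr"
            droplets = io.read_droplet_counts(
                cfg.ddpcr.droplets or _require(paths.get("droplets"), stage, "droplet counts"))
            copies = pcr.poisson_copies(
                droplets, droplet_volume_nl=cfg.ddpcr.droplet_volume_nl,
                reaction_volume_ul=cfg.ddpcr.reaction_volume_ul)
            copies.to_csv(out / "copies.tsv", sep="\t", index=False, float_format="%.10g")
            normed = pcr.normalize_copies(copies, cfg.ddpcr.references)
            targets = normed[~normed.gene.isin(cfg.ddpcr.references)]
            res = pcr.group_stats(
                targets, case=cfg.ddpcr.case, control=cfg.ddpcr.control,
                value_col="normalized")
            res["method"] = res["method"].replace({"t_test": "ddpcr"})
            rat_frames.append(res)
            counts["ddpcr_genes"] = len(res)

        if rat_frames:
            rat_results = pd.concat(rat_frames, ignore_index=True)
            rat_results.to_csv(out / "rat_results.tsv", sep="\t", index=False,
                               float_format="%.10g")

        if cfg.plasma.enabled:
            stage = "plasma"
            panel = io.read_plasma_panel(
                cfg.plasma.panel or _require(paths.get("panel"), stage, "plasma panel"))
            by_group = {g: sub["conc_ng_ml"].tolist()
                        for g, sub in panel.groupby("group", sort=True)}
            report: dict = {"groups": plasma.group_summaries(panel).to_dict(orient="records")}
            labels = sorted(by_group)
            pairwise = {}
            for i, a in enumerate(labels):
                for b in labels[i + 1:]:
                    r = plasma.compare_two_groups(by_group[a], by_group[b])
                    pairwise[f"{a}_vs_{b}"] = {"U": r.u, "p": r.p, "method": r.method}
            report["mann_whitney"] = pairwise
            if len(labels) >= 3:
                kw = plasma.compare_k_groups(by_group)
                report["kruskal_wallis"] = {"H": kw.h, "p": kw.p, "df": kw.df}
            if panel["mrna_level"].notna().sum() >= 3:
                corr_res = plasma.protein_mrna_correlation(panel)
                report["protein_mrna_pearson"] = {
                    "R": corr_res.r, "p": corr_res.p, "n": corr_res.n}
            cov = plasma.covariate_check(panel)
            report["covariates"] = {"age_p": cov.age_p, "sex_p": cov.sex_p}
            io.write_json(report, out / "plasma_stats.json")
            counts["plasma_subjects"] = len(panel)

        if cfg.concordance.enabled:
            stage = "concordance"
            if panel_out is None:
                raise PipelineError(stage, "needs the DE/refinement stage output")
            if not rat_frames:
                raise PipelineError(stage, "needs qPCR and/or ddPCR stage output")
            omap = io.read_ortholog_map(
                cfg.concordance.ortholog_map
                or _require(paths.get("ortholog_map"), stage, "ortholog map"))
            table = concordance(
                panel_out, rat_results, omap,
                p_threshold=cfg.concordance.p_threshold,
                trend_threshold=cfg.concordance.trend_threshold)
            table.to_csv(out / "concordance.tsv", sep="\t", index=False,
                         float_format="%.10g")
            counts["concordance_rows"] = len(table)
            counts["concordant"] = int((table.agreement == "concordant").sum())

        stage = "manifest"
        cfg_json = json.dumps(cfg.model_dump(), sort_keys=True)
        files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
        manifest = {
            "config": cfg.model_dump(),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": cfg.synth.seed if cfg.synth.enabled else None,
            "version": _version,
            "row_counts": counts,
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
        }
        io.write_json(manifest, out / "manifest.json")
        return out
    except PipelineError as err:
        io.write_json(err.record, out / "error.json")
        raise
    except Exception as err:  # wrap with the failing stage's name
        perr = PipelineError(stage, str(err))
        io.write_json(perr.record, out / "error.json")
        raise perr from err
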