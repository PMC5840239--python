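"""qPCR relative quantification, geNorm reference stability and ddPCR
Poisson copy estimation.

Relative quantities follow the efficiency-corrected delta-Cq convention
with a gene-wise mean calibrator: RQ(g, s) = E_g ** (mean_s' Cq(g, s') -
Cq(g, s)). Fold changes and p values are invariant to the calibrator, so
the choice is cosmetic but fixed for reproducibility.

geNorm stability of a candidate reference gene j is the arithmetic mean
over the other candidates k of V_jk, the standard deviation across samples
of log2(RQ_j / RQ_k); a gene whose expression tracks every other candidate
has small M and is a stable normaliser. The coefficient of variation is
computed on the candidate's normalised relative quantities (its RQ divided
per sample by the geometric mean of all candidates' RQs).

Digital-droplet PCR partitions a reaction into ~nanolitre droplets; with
template molecules Poisson-distributed over droplets, the fraction of
negative droplets estimates exp(-lambda), so lambda = -ln(1 - positives /
total) mean copies per droplet, and copies per reaction = lambda x
(reaction volume / droplet volume). Wells are pooled per gene x sample by
summing positives and totals before inversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DROPLET_VOLUME_NL",
    "REACTION_VOLUME_UL",
    "collapse_replicates",
    "relative_quantities",
    "genorm",
    "GenormReport",
    "normalize",
    "group_stats",
    "poisson_copies",
    "normalize_copies",
]

#: QX200-style droplet volume (nanolitres); instrument convention, not a
#: measured value — override via function arguments where needed.
DROPLET_VOLUME_NL = 0.85
#: Standard reaction volume (microlitres).
REACTION_VOLUME_UL = 20.0

_META_COLS = ["gene", "sample", "group", "is_reference"]


def collapse_replicates(cq: pd.DataFrame, max_spread: float = 0.5) -> pd.DataFrame:
    """Average technical replicate Cq values per gene x sample.

    Adds a ``noisy`` QC flag where the replicate max-min spread exceeds
    ``max_spread`` cycles (default 0.5). Tables already collapsed pass
    through with spread 0.
    """
    grouped = cq.groupby(_META_COLS, sort=False, as_index=False)["cq"]
    out = grouped.mean()
    spread = grouped.agg(lambda v: v.max() - v.min())["cq"]
    out["noisy"] = spread > max_spread
    return out


def relative_quantities(
    cq: pd.DataFrame,
    efficiency: float | Mapping[str, float] = 2.0,
    max_spread: float = 0.5,
) -> pd.DataFrame:
    """Efficiency-corrected relative quantities with a gene-mean calibrator.

    ``efficiency`` is the amplification factor per cycle, global or per
    gene, in (1, 2]. Missing gene x sample cells simply yield no row;
    downstream operations tolerate the absence.
    """
    table = collapse_replicates(cq, max_spread=max_spread)
    if not ((table["cq"] > 0) & (table["cq"] < 45)).all():
        raise ValueError("Cq values outside (0, 45)")

    def eff(gene: str) -> float:
        e = efficiency[gene] if isinstance(efficiency, Mapping) else efficiency
        if not 1.0 < e <= 2.0:
            raise ValueError(f"efficiency {e} for {gene} outside (1, 2]")
        return float(e)

    mean_cq = table.groupby("gene")["cq"].transform("mean")
    e_vec = table["gene"].map(eff).astype(float)
    table["rq"] = e_vec ** (mean_cq - table["cq"])
    return table[_META_COLS + ["rq", "noisy"]]


@dataclass(frozen=True)
class GenormReport:
    """Per-candidate stability (M), CV and exclusion-order ranking."""

    table: pd.DataFrame  # gene, M, CV, rank (rank 1 = most stable)
    pairwise_v: pd.DataFrame  # symmetric V_jk matrix
    exclusion_order: list[str]  # least stable first
    final_pair: tuple[str, str]


def _rq_wide(rq: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    wide = rq[rq.gene.isin(genes)].pivot(index="sample", columns="gene", values="rq")
    shared = wide.dropna()
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} samples measured for all of {genes}; need >= 3"
        )
    return shared[genes]


def genorm(rq: pd.DataFrame, candidates: Iterable[str]) -> GenormReport:
    """geNorm stability analysis over candidate reference genes.

    Computed over the samples where every candidate is measured. M_j is the
    mean over k != j of the sample SD of log2(RQ_j/RQ_k); CV_j is SD/mean
    of the candidate's normalised relative quantities (normalised by the
    geometric mean of all candidates). The iterative ranking repeatedly
    drops the highest-M gene from the working set, recording the exclusion
    order; the last two genes form the top (most stable) pair.
    """
    genes = sorted(set(candidates))
    if len(genes) < 3:
        raise ValueError("geNorm needs >= 3 candidate genes")
    wide = _rq_wide(rq, genes)
    logq = np.log2(wide.values)
    n = len(genes)

    v = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            v[j, k] = v[k, j] = np.std(logq[:, j] - logq[:, k], ddof=1)
    m = v.sum(axis=1) / (n - 1)

    geomean = np.exp(np.log(wide.values).mean(axis=1, keepdims=True))
    nrq = wide.values / geomean
    cv = nrq.std(axis=0, ddof=1) / nrq.mean(axis=0)

    # iterative exclusion on recomputed M over the remaining set
    remaining = list(range(n))
    exclusion: list[str] = []
    while len(remaining) > 2:
        sub = v[np.ix_(remaining, remaining)]
        m_sub = sub.sum(axis=1) / (len(remaining) - 1)
        worst = remaining[int(np.argmax(m_sub))]
        exclusion.append(genes[worst])
        remaining.remove(worst)
    final_pair = tuple(sorted(genes[i] for i in remaining))

    order = np.argsort(m, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    table = pd.DataFrame({"gene": genes, "M": m, "CV": cv, "rank": rank}).sort_values(
        "rank", ignore_index=True
    )
    return GenormReport(
        table=table,
        pairwise_v=pd.DataFrame(v, index=genes, columns=genes),
        exclusion_order=exclusion,
        final_pair=final_pair,  # type: ignore[arg-type]
    )


def normalize(rq: pd.DataFrame, references: Iterable[str]) -> pd.DataFrame:
    """Normalise relative quantities by the per-sample geometric mean of
    the reference genes.

    Every sample must carry all reference genes; the per-sample geometric
    mean of the references' NRQ equals 1 afterwards.
    """
    refs = sorted(set(references))
    ref_rows = rq[rq.gene.isin(refs)]
    ref_wide = ref_rows.pivot(index="sample", columns="gene", values="rq")
    missing_genes = set(refs) - set(ref_wide.columns)
    if missing_genes:
        raise ValueError(f"reference genes absent from table: {sorted(missing_genes)}")
    all_samples = pd.Index(sorted(rq["sample"].unique()), name="sample")
    ref_wide = ref_wide.reindex(all_samples)
    bad = ref_wide.index[ref_wide[refs].isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"samples missing a reference measurement: {bad}")
    norm_factor = np.exp(np.log(ref_wide[refs]).mean(axis=1))

    out = rq.copy()
    out["nrq"] = out["rq"] / out["sample"].map(norm_factor)
    return out.drop(columns=["rq"])


def group_stats(
    values: pd.DataFrame,
    case: str,
    control: str,
    value_col: str = "nrq",
    equal_var: bool = True,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Per-gene two-group comparison of normalised quantities.

    The two-sided unpaired t test runs on log2-transformed values
    (equal-variance pooling by default, Welch via ``equal_var=False``);
    fold change is 2**(mean log2 case - mean log2 control) reported with
    the magnitude >= 1 plus direction convention. Genes with fewer than
    ``min_per_group`` quantifiable samples in either group are reported
    with method "not_analysable" rather than dropped.
    """
    rows = []
    for gene, sub in values.groupby("gene", sort=True):
        sub = sub.dropna(subset=[value_col])
        a = np.log2(sub.loc[sub.group == case, value_col].values.astype(float))
        b = np.log2(sub.loc[sub.group == control, value_col].values.astype(float))
        if len(a) < min_per_group or len(b) < min_per_group:
            rows.append((gene, "up", np.nan, np.nan, len(a), len(b), "not_analysable"))
            continue
        direction, fc = "up", 2.0 ** (a.mean() - b.mean())
        if fc < 1.0:
            direction, fc = "down", 1.0 / fc
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            p = np.nan
        else:
            p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
        rows.append((gene, direction, fc, p, len(a), len(b), "t_test"))
    return pd.DataFrame(
        rows, columns=["gene", "direction", "fc", "p", "n_case", "n_control", "method"]
    )


def poisson_copies(
    droplets: pd.DataFrame,
    droplet_volume_nl: float = DROPLET_VOLUME_NL,
    reaction_volume_ul: float = REACTION_VOLUME_UL,
) -> pd.DataFrame:
    """Absolute copies per reaction from droplet counts.

    Wells are pooled per gene x sample (positives and totals summed), then
    lambda = -ln(1 - positives/total) and copies = lambda x reaction
    volume / droplet volume (consistent units; 20 ul = 20000 nl). Saturated
    gene x samples (all droplets positive) have undefined copies and are
    flagged; zero positives is a valid measurement of zero.
    """
    if droplet_volume_nl <= 0 or reaction_volume_ul <= 0:
        raise ValueError("volumes must be positive")
    if (droplets["positives"] > droplets["total"]).any() or (
        droplets["positives"] < 0
    ).any() or (droplets["total"] <= 0).any():
        raise ValueError("droplet counts must satisfy 0 <= positives <= total, total > 0")

    pooled = droplets.groupby(["gene", "sample", "group"], sort=True, as_index=False)[
        ["positives", "total"]
    ].sum()
    frac = pooled["positives"] / pooled["total"]
    saturated = frac >= 1.0
    lam = np.where(saturated, np.nan, -np.log1p(-frac.where(~saturated, 0.0)))
    n_droplets_per_reaction = reaction_volume_ul * 1000.0 / droplet_volume_nl
    pooled["lambda"] = lam
    pooled["copies_per_reaction"] = lam * n_droplets_per_reaction
    pooled["saturated"] = saturated
    return pooled


def normalize_copies(copies: pd.DataFrame, references: Iterable[str]) -> pd.DataFrame:
    """Divide target copies by the per-sample geometric mean of reference
    copies (e.g. Rpl13a and Ubc).

    Raises, naming the sample, when a reference has zero or undefined
    copies. Reference rows are retained with their (tautological) values so
    the per-sample geometric-mean invariant can be audited.
    """
    refs = sorted(set(references))
    ref_wide = copies[copies.gene.isin(refs)].pivot(
        index="sample", columns="gene", values="copies_per_reaction"
    )
    missing = set(refs) - set(ref_wide.columns)
    if missing:
        raise ValueError(f"reference genes absent: {sorted(missing)}")
    bad = ref_wide.index[
        (ref_wide[refs].isna() | (ref_wide[refs] <= 0)).any(axis=1)
    ].tolist()
    if bad:
        raise ValueError(f"reference copies zero/undefined for samples: {bad}")
    geo = np.exp(np.log(ref_wide[refs]).mean(axis=1))

    out = copies.copy()
    out["normalized"] = out["copies_per_reaction"] / out["sample"].map(geo)
    return out
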