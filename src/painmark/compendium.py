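"""Prior gene-gene correlations over a heterogeneous array compendium.

A two-colour-array compendium reports, per experiment, a log2 expression
ratio for the genes present on that platform. Because platforms differ,
any two genes are co-measured only on a subset of experiments; the prior
correlation of a pair is the Pearson coefficient computed over exactly the
experiments containing both genes (pairwise-complete), left undefined when
the co-presence count falls below ``min_pairs``.

Module detection then looks for maximal subsets of same-direction
differentially regulated genes whose pairwise prior correlations all clear
a threshold (exact maximal-clique enumeration on the thresholded graph),
plus, per module, the same-direction genes that are on average *negatively*
correlated with it — the signature of a coherent transcriptional response
embedded in an otherwise anti-correlated regulon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "CorrelationMatrix",
    "compendium_to_wide",
    "pairwise_correlation",
    "correlated_modules",
    "heatmap_order",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations with co-presence counts.

    ``r`` is symmetric with NaN where the correlation is undefined (too few
    co-presences or zero variance on the co-present subset); ``n_pairs``
    records the co-presence count for every pair regardless.
    """

    r: pd.DataFrame
    n_pairs: pd.DataFrame
    min_pairs: int

    @property
    def genes(self) -> list[str]:
        return list(self.r.index)


def compendium_to_wide(compendium: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long compendium table to experiments x genes with NaN for
    absent genes.

    Raises if a gene appears more than once within one experiment.
    """
    dup = compendium.duplicated(["experiment_id", "gene_id"])
    if dup.any():
        first = compendium[dup].iloc[0]
        raise ValueError(
            f"gene {first.gene_id!r} appears twice in experiment "
            f"{first.experiment_id!r}"
        )
    if not np.isfinite(compendium["log2_ratio"]).all():
        raise ValueError("non-finite log2 ratio in compendium")
    return compendium.pivot(
        index="experiment_id", columns="gene_id", values="log2_ratio"
    )


def pairwise_correlation(
    compendium: pd.DataFrame,
    genes: Sequence[str] | None = None,
    min_pairs: int = 6,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation over the compendium.

    Parameters
    ----------
    compendium
        Long table ``experiment_id, gene_id, log2_ratio`` or an already
        pivoted experiments x genes frame (NaN = absent).
    genes
        Gene subset to correlate (default: all genes in the table). Genes
        absent from the compendium raise.
    min_pairs
        Minimum co-presence count (>= 3) for a correlation to be defined.
    """
    if min_pairs < 3:
        raise ValueError("min_pairs must be >= 3")
    wide = (
        compendium_to_wide(compendium)
        if "gene_id" in compendium.columns
        else compendium
    )
    if genes is not None:
        missing = sorted(set(genes) - set(wide.columns))
        if missing:
            raise KeyError(f"genes not in compendium universe: {missing}")
        wide = wide[list(genes)]

    # pandas corr() is pairwise-complete by construction; min_periods
    # implements the "undefined, not zero" contract.
    r = wide.corr(method="pearson", min_periods=min_pairs)
    present = wide.notna().astype(np.int64)
    n_pairs = pd.DataFrame(
        present.T.values @ present.values, index=wide.columns, columns=wide.columns
    )
    # self-correlation is 1 whenever the gene has >= 2 observations with
    # spread, independent of the pair-level min_pairs rule
    diag_n = np.diag(n_pairs.values)
    has_var = wide.var(ddof=1) > 0
    diag = np.where((diag_n >= 2) & has_var.values, 1.0, np.nan)
    rv = r.values
    rv[np.diag_indices_from(rv)] = diag
    return CorrelationMatrix(r=r, n_pairs=n_pairs, min_pairs=min_pairs)


@dataclass(frozen=True)
class ModuleReport:
    """Maximal correlated modules within each direction set."""

    up: list[dict] = field(default_factory=list)
    down: list[dict] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


def _modules_for_set(
    corr: CorrelationMatrix, gene_set: list[str], threshold: float
) -> list[dict]:
    genes = [g for g in gene_set if g in corr.r.index]
    sub = corr.r.loc[genes, genes]
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for i, gi in enumerate(genes):
        for gj in genes[i + 1 :]:
            rij = sub.at[gi, gj]
            # membership needs a defined AND above-threshold correlation
            if np.isfinite(rij) and rij >= threshold:
                graph.add_edge(gi, gj)

    modules = []
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue
        members = sorted(clique)
        block = sub.loc[members, members].values
        off = block[~np.eye(len(members), dtype=bool)]
        # same-direction genes anti-correlated with the module on average
        outside = [g for g in genes if g not in clique]
        anti = []
        for g in outside:
            vals = sub.loc[g, members].values.astype(float)
            if np.isfinite(vals).any() and np.nanmean(vals) <= -threshold:
                anti.append(g)
        modules.append(
            {
                "genes": members,
                "min_r": float(np.nanmin(off)),
                "mean_r": float(np.nanmean(off)),
                "anticorrelated": sorted(anti),
            }
        )
    # deterministic order: largest then strongest then lexicographic
    modules.sort(key=lambda m: (-len(m["genes"]), -m["mean_r"], m["genes"]))
    return modules


def correlated_modules(
    corr: CorrelationMatrix,
    up_set: Iterable[str],
    down_set: Iterable[str],
    threshold: float,
) -> ModuleReport:
    """Report maximal modules of mutually correlated genes per direction.

    A module is a maximal gene subset (size >= 2) within ``up_set`` (and
    separately ``down_set``) whose defined pairwise correlations are all
    >= ``threshold``; overlapping maximal cliques are all reported, never
    merged. Per module the report also lists the same-direction genes whose
    mean correlation against the module is <= -threshold.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    up = sorted(set(up_set))
    down = sorted(set(down_set))
    if set(up) & set(down):
        raise ValueError(f"up/down sets overlap: {sorted(set(up) & set(down))}")

    vals = corr.r.values[np.triu_indices(len(corr.r), k=1)]
    diagnostics = {
        "n_pairs_defined": int(np.isfinite(vals).sum()),
        "n_pairs_undefined": int(np.isnan(vals).sum()),
        "threshold": threshold,
    }
    return ModuleReport(
        up=_modules_for_set(corr, up, threshold),
        down=_modules_for_set(corr, down, threshold),
        diagnostics=diagnostics,
    )


def heatmap_order(corr: CorrelationMatrix, genes: Sequence[str]) -> list[str]:
    """Average-linkage leaf order on distance 1 - r, for heatmap export.

    Undefined correlations are treated as distance 1 (uninformative).
    """
    genes = [g for g in genes if g in corr.r.index]
    if len(genes) < 3:
        return list(genes)
    sub = corr.r.loc[genes, genes].to_numpy(copy=True)
    sub[~np.isfinite(sub)] = 0.0
    np.fill_diagonal(sub, 1.0)
    dist = squareform(1.0 - sub, checks=False)
    link = hierarchy.linkage(dist, method="average")
    leaves = hierarchy.leaves_list(hierarchy.optimal_leaf_ordering(link, dist))
    return [genes[i] for i in leaves]
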