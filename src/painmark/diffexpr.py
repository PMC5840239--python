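"""Two-group differential-expression screen and candidate refinement.

The screen follows the array-analysis convention of the study: per gene a
one-way ANOVA across the two groups (identical, for two groups, to the
pooled-variance two-sided t test) and a signed linear-scale fold change
computed as the antilog of the difference of group means on log2 scale.
Transcripts with fold change >= 1.2 and p <= 0.05 pass the primary screen.

Refinement then applies the stricter multi-criteria gate used to assemble
the validation panel. A gene is accepted on one of three branches,
evaluated in order:

A. p <= 0.005 and FC >= 1.5 (statistical stringency alone);
B. supporting evidence (correlation analysis or pain literature) with
   0.005 < p <= 0.05 and FC >= 1.5;
C. supporting evidence with p <= 0.005 and 1.2 <= FC < 1.5.

The FC interval of branch C is half-open and branch B's p interval is
open at 0.005 so the three branches partition the accepted region. Whether
branch C really requires evidence is a documented reading of the published
gate (both printed genes in that regime carry literature support); the
alternative reading is available via ``branch_c_requires_evidence=False``.

No multiple-testing correction is applied to any decision; a
Benjamini-Hochberg FDR column is emitted for information only.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "signed_fold_change",
    "de_test",
    "primary_screen",
    "refine_panel",
    "SCREEN_FC",
    "SCREEN_P",
]

#: Primary-screen thresholds (inclusive).
SCREEN_FC = 1.2
SCREEN_P = 0.05


def signed_fold_change(
    case_values: np.ndarray, control_values: np.ndarray
) -> tuple[Literal["up", "down"], float]:
    """Signed linear fold change from log2 expression values.

    ratio = 2**(mean(case) - mean(control)); returns ("up", ratio) when
    ratio >= 1 and ("down", 1/ratio) otherwise, so the magnitude is always
    >= 1. The no-change tie (ratio exactly 1) is reported as "up".
    """
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if case_values.size == 0 or control_values.size == 0:
        raise ValueError("both groups need at least one value")
    ratio = 2.0 ** (case_values.mean() - control_values.mean())
    if ratio >= 1.0:
        return "up", float(ratio)
    return "down", float(1.0 / ratio)


def de_test(matrix: pd.DataFrame, groups: pd.DataFrame) -> pd.DataFrame:
    """Per-gene two-group test plus signed fold change.

    Parameters
    ----------
    matrix
        genes x samples log2 expression, columns = sample ids.
    groups
        ``sample, group`` table with exactly two group labels, each with
        >= 2 samples. The *case* group is the first label encountered in
        ``groups`` row order (no label is special-cased), so list case
        samples first; fold-change direction is case relative to control.

    Returns a DataFrame ``gene, p, direction, fc, bh_fdr, zero_variance``.
    Genes with zero within-group variance in both groups have undefined p
    (NaN) and are flagged, never dropped.
    """
    groups = groups.drop_duplicates("sample")
    labels = list(dict.fromkeys(groups["group"]))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    case_label, control_label = labels
    case_ids = groups.loc[groups.group == case_label, "sample"].tolist()
    ctrl_ids = groups.loc[groups.group == control_label, "sample"].tolist()
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("each group needs >= 2 samples")
    missing = (set(case_ids) | set(ctrl_ids)) - set(matrix.columns)
    if missing:
        raise KeyError(f"samples not in matrix: {sorted(missing)}")

    case = matrix[case_ids].to_numpy(dtype=float)
    ctrl = matrix[ctrl_ids].to_numpy(dtype=float)

    # two-group one-way ANOVA == pooled-variance t test (F = t^2)
    res = stats.ttest_ind(case, ctrl, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    zero_var = (case.var(axis=1, ddof=1) == 0) & (ctrl.var(axis=1, ddof=1) == 0)
    p[zero_var] = np.nan

    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    ratio = 2.0**diff
    direction = np.where(ratio >= 1.0, "up", "down")
    fc = np.where(ratio >= 1.0, ratio, 1.0 / ratio)

    bh = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        bh[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": matrix.index,
            "p": p,
            "direction": direction,
            "fc": fc,
            "bh_fdr": bh,
            "zero_variance": zero_var,
        }
    ).reset_index(drop=True)


def primary_screen(de: pd.DataFrame) -> pd.DataFrame:
    """Keep genes with fc >= 1.2 and p <= 0.05 (both boundaries inclusive)."""
    keep = (de["fc"] >= SCREEN_FC) & (de["p"] <= SCREEN_P)
    return de[keep.fillna(False)].reset_index(drop=True)


def _branch(p: float, fc: float, evidence: bool, branch_c_requires_evidence: bool) -> str:
    if not np.isfinite(p) or not np.isfinite(fc):
        return "rejected"
    if p <= 0.005 and fc >= 1.5:
        return "A"
    if evidence and 0.005 < p <= 0.05 and fc >= 1.5:
        return "B"
    if (evidence or not branch_c_requires_evidence) and p <= 0.005 and 1.2 <= fc < 1.5:
        return "C"
    return "rejected"


def refine_panel(
    de: pd.DataFrame,
    evidence: pd.DataFrame | None = None,
    branch_c_requires_evidence: bool = True,
) -> pd.DataFrame:
    """Apply the multi-criteria refinement gate.

    Parameters
    ----------
    de
        DE table with columns ``gene, p, direction, fc`` (``ca`` and
        ``literature`` columns are honoured if already merged in).
    evidence
        Optional ``gene, ca, literature`` table; genes without an evidence
        row get both flags False.
    branch_c_requires_evidence
        Whether the low-FC/strong-p branch demands CA/literature support
        (default True, the reading under which every printed panel gene in
        that regime carries support).

    Returns the DE table with ``ca``, ``literature`` and ``branch`` columns
    (branch in {A, B, C, rejected}).
    """
    panel = de.copy()
    if evidence is not None:
        ev = evidence.drop_duplicates("gene").set_index("gene")
        ca_map = ev["ca"].to_dict()
        lit_map = ev["literature"].to_dict()
        panel["ca"] = [bool(ca_map.get(g, False)) for g in panel["gene"]]
        panel["literature"] = [bool(lit_map.get(g, False)) for g in panel["gene"]]
    else:
        for col in ("ca", "literature"):
            if col not in panel.columns:
                panel[col] = False
            panel[col] = panel[col].fillna(False).astype(bool)
    panel["branch"] = [
        _branch(p, fc, bool(ca or lit), branch_c_requires_evidence)
        for p, fc, ca, lit in zip(
            panel["p"], panel["fc"], panel["ca"], panel["literature"]
        )
    ]
    return panel
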