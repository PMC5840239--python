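"""ELISA concentration calculation and plasma-protein group statistics.

The standard curve is the immunoassay-standard four-parameter logistic
(4PL),

    A(x) = D + (A0 - D) / (1 + (x / C)**B),

with A0 the zero-concentration asymptote, D the saturating asymptote, C
the inflection concentration (the midpoint: A(C) = (A0 + D) / 2) and B the
slope. Sample absorbances are inverted through the fitted curve, duplicate
wells are averaged on the concentration scale (so curve nonlinearity does
not bias the mean), and the result is multiplied by the dilution factor
(10 ul plasma diluted to 200 ul => x20).

Group comparisons are nonparametric: Mann-Whitney U for two groups (exact
null distribution when the combined sample is small and tie-free,
tie-corrected normal approximation otherwise) and Kruskal-Wallis H for
three or more. The protein-mRNA association is a plain Pearson correlation
with its t-transform p value. Covariate checks: unpaired two-sided t test
for sex, one-way ANOVA over age bins (decades by default) or a
continuous-age regression F test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "concentration",
    "compare_two_groups",
    "compare_k_groups",
    "protein_mrna_correlation",
    "covariate_check",
    "DEFAULT_DILUTION",
]

#: 10 ul plasma diluted to 200 ul.
DEFAULT_DILUTION = 20.0

#: Combined-sample-size cutoff below which the exact Mann-Whitney null is
#: used (tie-free data only).
EXACT_MW_MAX_N = 25


def _four_pl(x: np.ndarray, a0: float, b: float, c: float, d: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        u = np.where(x > 0, (x / c) ** b, 0.0)
    return d + (a0 - d) / (1.0 + u)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted 4PL standard curve with inversion."""

    a0: float  # zero-concentration asymptote
    b: float  # slope
    c: float  # midpoint concentration
    d: float  # saturating asymptote
    residuals: np.ndarray
    r_squared: float

    @property
    def absorbance_range(self) -> tuple[float, float]:
        """Open interval of invertible absorbances (between the asymptotes)."""
        return (min(self.a0, self.d), max(self.a0, self.d))

    def absorbance(self, conc: np.ndarray) -> np.ndarray:
        return _four_pl(conc, self.a0, self.b, self.c, self.d)

    def invert(self, absorbance: float) -> float:
        """Concentration at a given absorbance; NaN outside the open
        invertible range."""
        lo, hi = self.absorbance_range
        if not lo < absorbance < hi:
            return float("nan")
        u = (self.a0 - absorbance) / (absorbance - self.d)
        return float(self.c * u ** (1.0 / self.b))


def fit_standard_curve(standards: pd.DataFrame) -> StandardCurve:
    """Least-squares 4PL fit to ELISA standards.

    ``standards`` columns: ``conc_known`` (ng/ml) and ``absorbance``;
    replicate rows are used as independent observations. Requires >= 4
    distinct concentrations whose mean absorbances are monotone beyond
    noise (Spearman |rho| must reach 0.8), otherwise a ValueError with
    diagnostics is raised.
    """
    conc = standards["conc_known"].to_numpy(dtype=float)
    absb = standards["absorbance"].to_numpy(dtype=float)
    if not (np.isfinite(absb).all() and (absb >= 0).all()):
        raise ValueError("absorbances must be finite and >= 0")
    levels = np.unique(conc)
    if len(levels) < 4:
        raise ValueError(f"need >= 4 distinct standard concentrations, got {len(levels)}")
    level_means = np.array([absb[conc == c].mean() for c in levels])
    rho = stats.spearmanr(levels, level_means).statistic
    if not np.isfinite(rho) or abs(rho) < 0.8:
        raise ValueError(
            f"standards are not monotone beyond noise (Spearman rho={rho:.3f}); "
            f"level means: {dict(zip(levels, level_means))}"
        )

    increasing = level_means[-1] > level_means[0]
    a0_init = level_means[0] if increasing else level_means[-1]
    d_init = level_means[-1] if increasing else level_means[0]
    pos = levels[levels > 0]
    c_init = float(np.exp(np.log(pos).mean()))
    p0 = [a0_init, 1.0, c_init, d_init]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        popt, _ = optimize.curve_fit(
            _four_pl, conc, absb, p0=p0, maxfev=20000,
            bounds=([0.0, 1e-3, 1e-9, 0.0], [np.inf] * 4),
        )
    fitted = _four_pl(conc, *popt)
    resid = absb - fitted
    ss_tot = ((absb - absb.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(
        a0=float(popt[0]), b=float(popt[1]), c=float(popt[2]), d=float(popt[3]),
        residuals=resid, r_squared=float(r2),
    )


def concentration(
    curve: StandardCurve,
    samples: pd.DataFrame,
    dilution_factor: float = DEFAULT_DILUTION,
) -> pd.DataFrame:
    """Invert sample absorbances to plasma concentrations.

    ``samples`` columns: ``id, absorbance`` (one row per replicate well).
    Replicates are inverted individually, flagged when outside the
    invertible range, averaged on the concentration scale and multiplied
    by the dilution factor. Returns ``id, conc_ng_ml, n_replicates,
    n_out_of_range``.
    """
    rows = []
    for sid, sub in samples.groupby("id", sort=False):
        concs = np.array([curve.invert(a) for a in sub["absorbance"]])
        ok = np.isfinite(concs)
        mean_conc = concs[ok].mean() * dilution_factor if ok.any() else float("nan")
        rows.append((sid, mean_conc, len(concs), int((~ok).sum())))
    return pd.DataFrame(
        rows, columns=["id", "conc_ng_ml", "n_replicates", "n_out_of_range"]
    )


class TwoGroupResult(NamedTuple):
    u: float
    p: float
    method: str  # "exact" | "asymptotic"


def compare_two_groups(a: Sequence[float], b: Sequence[float]) -> TwoGroupResult:
    """Two-sided Mann-Whitney U comparison of two concentration groups.

    The exact permutation null is used when the combined sample size is at
    most 25 and the pooled data are tie-free; otherwise the tie-corrected
    normal approximation (without continuity correction, so tied datasets
    degrade gracefully). U is reported for the first group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and len(pooled) <= EXACT_MW_MAX_N:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return TwoGroupResult(float(res.statistic), float(res.pvalue), method)


class KGroupResult(NamedTuple):
    h: float
    p: float
    df: int


def compare_k_groups(groups: Mapping[str, Sequence[float]]) -> KGroupResult:
    """Kruskal-Wallis H test (tie-corrected) across concentration groups."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(len(x) < 2 for x in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    h, p = stats.kruskal(*arrays)
    return KGroupResult(float(h), float(p), len(arrays) - 1)


class CorrelationResult(NamedTuple):
    r: float
    p: float
    n: int


def protein_mrna_correlation(panel: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation between plasma concentration and paired
    whole-blood mRNA level over subjects carrying both measurements.

    Returns (R, two-sided p from the t transform, n pairs); R is NaN
    (flagged by the NaN itself) if either variable has zero variance.
    """
    paired = panel.dropna(subset=["conc_ng_ml", "mrna_level"])
    if len(paired) < 3:
        raise ValueError(f"need >= 3 paired subjects, got {len(paired)}")
    x = paired["conc_ng_ml"].to_numpy(dtype=float)
    y = paired["mrna_level"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(float("nan"), float("nan"), len(paired))
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(paired))


class CovariateResult(NamedTuple):
    age_p: float
    sex_p: float


def covariate_check(
    panel: pd.DataFrame,
    age_mode: Literal["bins", "continuous"] = "bins",
    bin_width: int = 10,
) -> CovariateResult:
    """Check whether age or sex influences concentration.

    Sex: two-sided unpaired t test between the sexes (NaN when a sex has
    fewer than 2 subjects). Age: one-way ANOVA across occupied age bins of
    ``bin_width`` years (bins with < 2 subjects are dropped; NaN if fewer
    than 2 bins remain), or with ``age_mode="continuous"`` the F test of a
    linear regression of concentration on age.
    """
    conc = panel["conc_ng_ml"].to_numpy(dtype=float)

    by_sex = [g["conc_ng_ml"].to_numpy(dtype=float)
              for _, g in panel.groupby("sex", sort=True)]
    if len(by_sex) == 2 and all(len(g) >= 2 for g in by_sex):
        sex_p = float(stats.ttest_ind(*by_sex, equal_var=True).pvalue)
    else:
        sex_p = float("nan")

    if age_mode == "continuous":
        age_p = float(stats.linregress(panel["age"], conc).pvalue)
    else:
        bins = (panel["age"] // bin_width).astype(int)
        groups = [conc[bins == b] for b in sorted(bins.unique())]
        groups = [g for g in groups if len(g) >= 2]
        age_p = (
            float(stats.f_oneway(*groups).pvalue) if len(groups) >= 2 else float("nan")
        )
    return CovariateResult(age_p, sex_p)


def group_summaries(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean/SD/range/n of concentrations (report mirror)."""
    rows = []
    for label, g in panel.groupby("group", sort=True):
        c = g["conc_ng_ml"].to_numpy(dtype=float)
        rows.append((label, len(c), c.mean(), c.std(ddof=1), c.min(), c.max()))
    return pd.DataFrame(rows, columns=["group", "n", "mean", "sd", "min", "max"])
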