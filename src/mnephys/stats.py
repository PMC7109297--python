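"""Assumption-gated group-comparison engine and results-table builder.

Each variable is tested across groups with a normality/homogeneity gate:
Shapiro-Wilk on group-mean-centred residuals and Levene's test (median
centred, Brown-Forsythe) both at the gate alpha.  Variables passing both go
through one-way ANOVA with Tukey's HSD post hoc; the rest go through
Kruskal-Wallis with Dunn's z-tests, Holm-adjusted over all pairwise
comparisons.  Reported post hoc p values are the contrasts of each group
against the reference (sham) level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["VariableSeries", "GateResult", "GroupComparison",
           "assess_assumptions", "compare_groups", "dunn_test",
           "anova_from_summary", "build_results_table", "DEFAULT_ALPHA"]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class VariableSeries:
    """Per-cell values of one variable with a group label per cell."""
    name: str
    values: np.ndarray
    labels: np.ndarray          # group label per cell
    reference: str = "sham"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        l = np.asarray(self.labels)
        if v.shape != l.shape or v.ndim != 1:
            raise ValueError("values and labels must be equal-length 1-D")
        keep = np.isfinite(v)
        object.__setattr__(self, "values", v[keep])
        object.__setattr__(self, "labels", l[keep])

    def level_arrays(self) -> dict[str, np.ndarray]:
        """Values per level, reference first, insertion order otherwise."""
        levels = list(dict.fromkeys(self.labels.tolist()))
        if self.reference in levels:
            levels.remove(self.reference)
            levels.insert(0, self.reference)
        return {g: self.values[self.labels == g] for g in levels}


@dataclass(frozen=True)
class GateResult:
    normal: bool
    homogeneous: bool
    shapiro_p: float
    levene_p: float
    degenerate: bool = False

    @property
    def parametric(self) -> bool:
        return self.normal and self.homogeneous and not self.degenerate


@dataclass
class GroupComparison:
    """Result of one variable's omnibus + post hoc comparison."""
    variable: str
    gate: GateResult
    test: str                      # "anova_tukey" | "kruskal_dunn"
    statistic: float
    p_omnibus: float
    posthoc_p: dict[str, float]    # level -> p vs reference
    adjustment: str
    levels: list[str]
    n: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]
    reference: str = "sham"


def assess_assumptions(series: VariableSeries,
                       alpha: float = DEFAULT_ALPHA) -> GateResult:
    """Normality (Shapiro-Wilk on pooled group-centred residuals) and
    homogeneity (Brown-Forsythe Levene) gate.

    All-constant input is degenerate and routes non-parametric with a
    warning.  Requires >= 3 values per level for the normality test.
    """
    groups = series.level_arrays()
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty factor levels")
    arrays = list(groups.values())
    if any(len(a) < 3 for a in arrays):
        raise ValueError("need >= 3 values per level for the gate")
    resid = np.concatenate([a - a.mean() for a in arrays])
    if np.allclose(resid, 0):
        warnings.warn(f"variable {series.name!r}: constant within groups; "
                      "routing non-parametric", stacklevel=2)
        return GateResult(False, False, math.nan, math.nan, degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-n Shapiro p-value warnings
        sh_p = float(sps.shapiro(resid).pvalue)
        lev_p = float(sps.levene(*arrays, center="median").pvalue)
    return GateResult(normal=sh_p > alpha, homogeneous=lev_p > alpha,
                      shapiro_p=sh_p, levene_p=lev_p)


def dunn_test(groups: dict[str, np.ndarray],
              adjust: str = "holm") -> dict[tuple[str, str], float]:
    """Dunn's rank-based z-tests for all pairwise comparisons after
    Kruskal-Wallis, with tie correction and p adjustment over all pairs.

    Returns adjusted two-sided p per (level_i, level_j) pair.
    """
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    N = len(all_vals)
    ranks = sps.rankdata(all_vals)
    mean_rank: dict[str, float] = {}
    i0 = 0
    for g in names:
        n = len(groups[g])
        mean_rank[g] = float(ranks[i0:i0 + n].mean())
        i0 += n
    # tie correction
    _, counts = np.unique(all_vals, return_counts=True)
    tie = (counts ** 3 - counts).sum() / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie
    pairs, raw = [], []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ga, gb = names[a], names[b]
            se = math.sqrt(var_base * (1.0 / len(groups[ga]) +
                                       1.0 / len(groups[gb])))
            z = (mean_rank[ga] - mean_rank[gb]) / se if se > 0 else 0.0
            pairs.append((ga, gb))
            raw.append(2.0 * sps.norm.sf(abs(z)))
    if adjust == "none":
        adj = raw
    else:
        adj = multipletests(raw, method=adjust)[1]
    return {pair: float(p) for pair, p in zip(pairs, adj)}


def compare_groups(series: VariableSeries,
                   gate: GateResult | None = None,
                   alpha: float = DEFAULT_ALPHA,
                   adjust: str = "holm") -> GroupComparison:
    """Run the gated omnibus test and reference-contrast post hocs.

    Parametric route: one-way ANOVA omnibus, Tukey HSD p for each level vs
    the reference.  Non-parametric: Kruskal-Wallis omnibus, Dunn's z-tests
    adjusted (default Holm) over all pairwise comparisons.  Levels with
    n < 2 are excluded from post hocs with a warning.
    """
    if gate is None:
        gate = assess_assumptions(series, alpha)
    groups = series.level_arrays()
    ref = series.reference
    if ref not in groups:
        raise ValueError(f"reference level {ref!r} absent")
    small = [g for g, a in groups.items() if len(a) < 2]
    if small:
        warnings.warn(f"levels {small} have n < 2; excluded from post hoc",
                      stacklevel=2)
    usable = {g: a for g, a in groups.items() if len(a) >= 2}
    names = list(usable)
    arrays = [usable[g] for g in names]
    posthoc: dict[str, float] = {}
    if gate.parametric:
        stat, p_omni = sps.f_oneway(*arrays)
        if not np.isfinite(stat):   # zero variance everywhere
            stat, p_omni = 0.0, 1.0
        res = sps.tukey_hsd(*arrays)
        iref = names.index(ref)
        for j, g in enumerate(names):
            if g != ref:
                posthoc[g] = float(res.pvalue[iref, j])
        test = "anova_tukey"
        adjustment = "tukey_hsd"
    else:
        try:
            stat, p_omni = sps.kruskal(*arrays)
        except ValueError:          # all values identical
            stat, p_omni = 0.0, 1.0
        dunn = dunn_test(usable, adjust=adjust)
        for g in names:
            if g == ref:
                continue
            key = (ref, g) if (ref, g) in dunn else (g, ref)
            posthoc[g] = dunn[key]
        test = "kruskal_dunn"
        adjustment = adjust
    return GroupComparison(
        variable=series.name, gate=gate, test=test, statistic=float(stat),
        p_omnibus=float(p_omni), posthoc_p=posthoc, adjustment=adjustment,
        levels=list(groups), n={g: len(a) for g, a in groups.items()},
        mean={g: float(a.mean()) for g, a in groups.items()},
        sd={g: float(a.std(ddof=1)) if len(a) > 1 else math.nan
            for g, a in groups.items()},
        reference=ref)


def anova_from_summary(means, sds, ns, reference: int = 0):
    """One-way ANOVA and Tukey-Kramer reference contrasts reconstructed
    from per-level summaries (mean, SD, N).

    Exactly equals raw-data ANOVA whenever raw data have these summaries.
    Returns (F, p, posthoc) with posthoc[j] the Tukey p of level j vs the
    reference level.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if not (len(means) == len(sds) == len(ns)) or len(means) < 2:
        raise ValueError("need >= 2 levels of equal-length summaries")
    if (ns < 2).any():
        raise ValueError("every level needs n >= 2")
    if (sds < 0).any():
        raise ValueError("SDs must be >= 0")
    k = len(means)
    N = int(ns.sum())
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds ** 2).sum())
    dfb, dfw = k - 1, N - k
    msw = ssw / dfw
    if msw == 0:
        F = math.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    else:
        F = (ssb / dfb) / msw
        p = float(sps.f.sf(F, dfb, dfw))
    posthoc = {}
    for j in range(k):
        if j == reference:
            continue
        if msw == 0:
            posthoc[j] = 1.0 if means[j] == means[reference] else 0.0
            continue
        se = math.sqrt(msw / 2.0 * (1.0 / ns[j] + 1.0 / ns[reference]))
        q = abs(means[j] - means[reference]) / se
        posthoc[j] = float(sps.studentized_range.sf(q, k, dfw))
    return F, p, posthoc


_META_COLS = {"cell_id", "group", "age", "region", "qc", "depol_block",
              "rebound"}


def build_results_table(features: pd.DataFrame, *,
                        factor: str = "group", reference: str = "sham",
                        alpha: float = DEFAULT_ALPHA, adjust: str = "holm",
                        variables: list[str] | None = None,
                        ) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Per-variable gated comparisons over a feature table.

    Only QC-included cells enter; each variable uses all cells with that
    measurement (casewise deletion).  Returns the rendered long table
    (Variable / Condition / Mean / SD / N / p / significant) and the
    structured comparisons.
    """
    if "qc" in features.columns:
        features = features[features["qc"] == "included"]
    if variables is None:
        variables = [c for c in features.columns
                     if c not in _META_COLS and c != factor
                     and pd.api.types.is_numeric_dtype(features[c])]
    rows = []
    comparisons: list[GroupComparison] = []
    for var in variables:
        sub = features[[factor, var]].dropna()
        counts = sub.groupby(factor, sort=False)[var].count()
        if (counts >= 3).sum() < 2:
            warnings.warn(f"variable {var!r}: fewer than 2 populated groups; "
                          "skipped", stacklevel=2)
            continue
        keep = sub[factor].isin(counts[counts >= 3].index)
        sub = sub[keep]
        series = VariableSeries(var, sub[var].to_numpy(),
                                sub[factor].to_numpy(), reference=reference)
        try:
            comp = compare_groups(series, alpha=alpha, adjust=adjust)
        except ValueError as e:
            warnings.warn(f"variable {var!r}: {e}; skipped", stacklevel=2)
            continue
        comparisons.append(comp)
        for g in comp.levels:
            p = comp.posthoc_p.get(g, math.nan)
            rows.append({
                "Variable": var, "Condition": g, "Mean": comp.mean[g],
                "SD": comp.sd[g], "N": comp.n[g],
                "p": p if g != comp.reference else math.nan,
                "significant": bool(np.isfinite(p) and p <= alpha)
                if g != comp.reference else False,
                "test": comp.test,
            })
    return pd.DataFrame(rows, columns=["Variable", "Condition", "Mean", "SD",
                                       "N", "p", "significant", "test"]), \
        comparisons
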