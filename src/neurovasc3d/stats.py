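"""Group-comparison statistics for per-animal metric tables.

The analysis chain per metric and region: two-sided iterative Grubbs
outlier removal within each diet × sex group, a Shapiro–Wilk normality
gate, and — for normally distributed data — a two-way Diet × Sex ANOVA
with all six pairwise Bonferroni-adjusted comparisons when the interaction
is significant.  Non-normal datasets are flagged (the parametric branch is
reported as inappropriate); no nonparametric fallback model is fitted.

The ANOVA uses Type II sums of squares via nested least-squares model
comparisons with sum-coded factors, which coincides with Type III on
balanced designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrubbsResult", "NormalityDecision", "AnovaResult",
    "grubbs_filter", "grubbs_critical_value", "normality_gate",
    "two_way_anova", "analyze_metric_table",
]

ALPHA = 0.05
DIETS = ("CD", "mHFD")
SEXES = ("F", "M")


@dataclass
class GrubbsResult:
    retained: np.ndarray
    removed: list[float]
    alpha: float = ALPHA


@dataclass
class NormalityDecision:
    decision: str                       # 'parametric' | 'nonparametric'
    p_values: dict[str, float]
    alpha: float = ALPHA


@dataclass
class AnovaResult:
    """Effects: name -> (F, df_effect, df_residual, p)."""

    effects: dict[str, tuple[float, int, int, float]]
    posthoc: pd.DataFrame | None = None
    residual_df: int = 0
    mse: float = float("nan")


def grubbs_critical_value(n: int, alpha: float = ALPHA) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))


def grubbs_filter(values, alpha: float = ALPHA) -> GrubbsResult:
    """Iterative two-sided Grubbs outlier removal.

    Removes the single most extreme point while G = max|x − mean| / sd
    exceeds the critical value at ``alpha``; stops when nothing is rejected
    or fewer than three points remain.  Zero-variance samples remove
    nothing (G undefined).
    """
    x = np.asarray(values, dtype=float).copy()
    removed: list[float] = []
    if len(x) < 3:
        warnings.warn(f"Grubbs test needs n >= 3, got n = {len(x)}; sample untouched",
                      stacklevel=2)
        return GrubbsResult(x, removed, alpha)
    while len(x) >= 3:
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - x.mean())
        i = int(np.argmax(dev))
        if dev[i] / sd > grubbs_critical_value(len(x), alpha):
            removed.append(float(x[i]))
            x = np.delete(x, i)
        else:
            break
    return GrubbsResult(x, removed, alpha)


def normality_gate(groups: dict[str, np.ndarray], alpha: float = ALPHA) -> NormalityDecision:
    """Shapiro–Wilk gate: parametric iff every group has p ≥ alpha.

    A constant-valued group (test undefined) fails safe to nonparametric.
    Groups with fewer than three values raise, naming the group.
    """
    p_values: dict[str, float] = {}
    decision = "parametric"
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 3:
            raise ValueError(f"group '{name}' has n = {len(vals)} < 3; "
                             "normality cannot be assessed")
        if np.ptp(vals) == 0:
            p_values[name] = float("nan")
            decision = "nonparametric"
            continue
        p = float(stats.shapiro(vals).pvalue)
        p_values[name] = p
        if p < alpha:
            decision = "nonparametric"
    return NormalityDecision(decision, p_values, alpha)


def _design(diet01: np.ndarray, sex01: np.ndarray) -> dict[str, np.ndarray]:
    a = 2.0 * diet01 - 1.0   # sum coding: -1 / +1
    b = 2.0 * sex01 - 1.0
    one = np.ones_like(a)
    return {"1": one, "A": a, "B": b, "AB": a * b}


def _rss(y: np.ndarray, cols: list[np.ndarray]) -> float:
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def two_way_anova(df: pd.DataFrame, value: str = "value",
                  diet: str = "diet", sex: str = "sex",
                  alpha: float = ALPHA) -> AnovaResult:
    """Two-way Diet × Sex ANOVA with Bonferroni post-hoc on interaction.

    Type II sums of squares from nested model comparisons (sum coding);
    equals Type III on balanced designs.  If the interaction p < alpha all
    six pairwise group comparisons are emitted with Bonferroni-adjusted p
    (pooled-MSE t-tests on the residual degrees of freedom).
    """
    d = df.copy()
    for col, levels in ((diet, DIETS), (sex, SEXES)):
        bad = set(d[col]) - set(levels)
        if bad:
            raise ValueError(f"unknown {col} levels {sorted(bad)}; expected {levels}")
    cells = d.groupby([diet, sex], observed=True)[value].count()
    if len(cells) < 4 or (cells == 0).any():
        raise ValueError("every diet × sex cell must contain data")

    y = d[value].to_numpy(dtype=float)
    a01 = (d[diet] == DIETS[1]).to_numpy(float)
    b01 = (d[sex] == SEXES[1]).to_numpy(float)
    X = _design(a01, b01)
    n = len(y)
    rss_full = _rss(y, [X["1"], X["A"], X["B"], X["AB"]])
    rss_ab = _rss(y, [X["1"], X["A"], X["B"]])
    ss_inter = rss_ab - rss_full
    # Type II main effects: adjust for the other main effect, not the interaction
    ss_diet = _rss(y, [X["1"], X["B"]]) - rss_ab
    ss_sex = _rss(y, [X["1"], X["A"]]) - rss_ab

    df_res = n - 4
    if df_res <= 0:
        raise ValueError("not enough observations for residual degrees of freedom")
    mse = rss_full / df_res

    effects = {}
    for name, ss in (("Diet", ss_diet), ("Sex", ss_sex), ("Diet:Sex", ss_inter)):
        F = max(ss, 0.0) / mse if mse > 0 else float("inf")
        p = float(stats.f.sf(F, 1, df_res)) if np.isfinite(F) else 0.0
        effects[name] = (F, 1, df_res, p)

    posthoc = None
    if effects["Diet:Sex"][3] < alpha:
        groups = {(dt, sx): g[value].to_numpy(float)
                  for (dt, sx), g in d.groupby([diet, sex], observed=True)}
        rows = []
        pairs = list(combinations(sorted(groups), 2))
        m = len(pairs)
        for g1, g2 in pairs:
            x1, x2 = groups[g1], groups[g2]
            se = np.sqrt(mse * (1 / len(x1) + 1 / len(x2)))
            t = (x1.mean() - x2.mean()) / se if se > 0 else float("inf")
            p_raw = float(2 * stats.t.sf(abs(t), df_res))
            rows.append({"group1": "-".join(g1), "group2": "-".join(g2),
                         "mean_diff": x1.mean() - x2.mean(), "t": t,
                         "p_raw": p_raw, "p_bonferroni": min(1.0, p_raw * m)})
        posthoc = pd.DataFrame(rows)
    return AnovaResult(effects, posthoc, df_res, mse)


def analyze_metric_table(table: pd.DataFrame, alpha: float = ALPHA,
                         apply_grubbs: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full chain per (metric, region) of a tidy table.

    ``table`` columns: animal_id, diet, sex, region, metric, value
    (litter_id optional).  Returns (stats table, outlier log).  Metrics
    gated nonparametric get a row with the decision and no F values.
    """
    results, outliers = [], []
    for (metric, region), sub in table.groupby(["metric", "region"], observed=True):
        sub = sub.dropna(subset=["value"])
        if apply_grubbs:
            kept = []
            for (dt, sx), g in sub.groupby(["diet", "sex"], observed=True):
                if len(g) >= 3:
                    res = grubbs_filter(g["value"].to_numpy(), alpha)
                    for v in res.removed:
                        outliers.append({"metric": metric, "region": region,
                                         "diet": dt, "sex": sx, "value": v})
                    drop = set()
                    removed = list(res.removed)
                    for idx, v in zip(g.index, g["value"]):
                        if v in removed:
                            removed.remove(v)
                            drop.add(idx)
                    kept.append(g.drop(index=drop))
                else:
                    kept.append(g)
            sub = pd.concat(kept) if kept else sub
        groups = {f"{dt}-{sx}": g["value"].to_numpy()
                  for (dt, sx), g in sub.groupby(["diet", "sex"], observed=True)}
        try:
            gate = normality_gate(groups, alpha)
        except ValueError as exc:
            results.append({"metric": metric, "region": region,
                            "decision": f"error: {exc}"})
            continue
        row = {"metric": metric, "region": region, "decision": gate.decision}
        row.update({f"shapiro_p_{k}": v for k, v in gate.p_values.items()})
        if gate.decision == "parametric":
            try:
                res = two_way_anova(sub, alpha=alpha)
            except ValueError as exc:
                row["decision"] = f"error: {exc}"
            else:
                for eff, (F, d1, d2, p) in res.effects.items():
                    key = eff.replace(":", "_x_")
                    row[f"F_{key}"] = F
                    row[f"p_{key}"] = p
                row["df_residual"] = res.residual_df
        results.append(row)
    return pd.DataFrame(results), pd.DataFrame(outliers)
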