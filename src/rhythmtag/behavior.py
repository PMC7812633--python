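"""Signal-detection and reaction-time statistics.

Sensitivity is d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate) with a log-linear
correction for extreme rates. Condition effects are assessed with fully
within-subject repeated-measures ANOVAs on cell means, reporting the
generalized eta squared η_G² = SS_effect / (SS_effect + Σ subject-related
SS), plus planned one-sided paired contrasts and Bonferroni adjustment.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats


# -- signal detection --------------------------------------------------------

def dprime(
    n_hits: int,
    n_targets: int,
    n_false_alarms: int,
    n_opportunities: int,
    correction: str = "loglinear",
) -> float:
    """Sensitivity d′ from hit and false-alarm counts.

    ``correction='loglinear'`` adds 0.5 to each count and 1 to each total,
    keeping rates off 0 and 1; ``'none'`` uses raw rates and raises on
    extremes.
    """
    if n_targets <= 0 or n_opportunities <= 0:
        raise ValueError("zero targets or false-alarm opportunities")
    if not (0 <= n_hits <= n_targets and 0 <= n_false_alarms <= n_opportunities):
        raise ValueError("counts out of range")
    if correction == "loglinear":
        ph = (n_hits + 0.5) / (n_targets + 1.0)
        pf = (n_false_alarms + 0.5) / (n_opportunities + 1.0)
    elif correction == "none":
        ph = n_hits / n_targets
        pf = n_false_alarms / n_opportunities
        if ph in (0.0, 1.0) or pf in (0.0, 1.0):
            raise ValueError("extreme rate; use the log-linear correction")
    else:
        raise ValueError("correction must be 'loglinear' or 'none'")
    return float(scipy.stats.norm.ppf(ph) - scipy.stats.norm.ppf(pf))


def sdt_counts(
    trials: pd.DataFrame,
    by=("participant", "metricality", "regularity"),
) -> pd.DataFrame:
    """Hit/false-alarm counts per cell from a long trial table.

    False-alarm opportunities are counted per nontarget measure (one
    opportunity each). Adds a ``dprime`` column.
    """
    rows = []
    for key, sub in trials.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        tgt = sub[sub.is_target]
        non = sub[~sub.is_target]
        cell = dict(zip(by, key))
        cell.update(
            n_targets=len(tgt),
            n_hits=int(tgt.response.sum()),
            n_opportunities=len(non),
            n_false_alarms=int(non.response.sum()),
        )
        cell["dprime"] = dprime(
            cell["n_hits"], cell["n_targets"], cell["n_false_alarms"], cell["n_opportunities"]
        )
        rows.append(cell)
    return pd.DataFrame(rows)


# -- repeated-measures ANOVA -------------------------------------------------

def _rm_anova_array(arr: np.ndarray, factor_names) -> pd.DataFrame:
    """Fully within-subject ANOVA on an (S, l1, ..., lk) cell-mean array.

    Effects are estimated by recursive marginal-mean decomposition; each
    effect is tested against its interaction with subjects. η_G² divides an
    effect's SS by itself plus all subject-containing SS (the generalized
    eta squared for fully repeated designs).
    """
    arr = np.asarray(arr, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("missing cells in the design")
    n_axes = arr.ndim
    sizes = arr.shape
    grand = arr.mean()
    axes_all = tuple(range(n_axes))  # axis 0 = subject

    effects, ss = {}, {}
    for order in range(1, n_axes + 1):
        for keep in combinations(axes_all, order):
            m = arr.mean(axis=tuple(a for a in axes_all if a not in keep))
            e = m - grand
            for sub_order in range(1, order):
                for sub in combinations(keep, sub_order):
                    # broadcast the lower-order effect onto this margin
                    shape = [sizes[a] if a in sub else 1 for a in keep]
                    e = e - effects[sub].reshape(shape)
            effects[keep] = e
            ss[keep] = float(np.prod([sizes[a] for a in axes_all if a not in keep]) * (e**2).sum())

    error_ss_total = sum(v for k, v in ss.items() if 0 in k)
    rows = []
    for order in range(1, n_axes):
        for fac in combinations(range(1, n_axes), order):
            df1 = int(np.prod([sizes[a] - 1 for a in fac]))
            df2 = (sizes[0] - 1) * df1
            ss_eff = ss[fac]
            ss_err = ss[(0,) + fac]
            ms_eff = ss_eff / df1
            ms_err = ss_err / df2
            if ms_err == 0:
                warnings.warn("zero error variance; F undefined for this effect")
                f = p = np.nan
            else:
                f = ms_eff / ms_err
                p = float(scipy.stats.f.sf(f, df1, df2))
            rows.append(
                {
                    "effect": " * ".join(factor_names[a - 1] for a in fac),
                    "df1": df1,
                    "df2": df2,
                    "F": f,
                    "p": p,
                    "ng2": ss_eff / (ss_eff + error_ss_total) if (ss_eff + error_ss_total) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within,
    subject: str = "participant",
) -> pd.DataFrame:
    """Repeated-measures ANOVA on a long table (1–3 within factors).

    Trial-level rows are first aggregated to cell means per subject. The
    design must be balanced (every subject contributes every cell).
    Returns an effect table with F, dfs, p and generalized eta squared.
    """
    within = [within] if isinstance(within, str) else list(within)
    cells = data.groupby([subject] + within, sort=True)[dv].mean()
    wide = cells.unstack(within)
    if wide.isna().any().any():
        raise ValueError("missing cells: the design must be balanced")
    levels = [data[w].nunique() for w in within]
    arr = wide.to_numpy().reshape([len(wide)] + levels)
    return _rm_anova_array(arr, within)


# -- contrasts and adjustment ------------------------------------------------

def planned_contrast(x, y, alternative: str = "greater") -> tuple[float, float]:
    """Paired one-sided t-test of x vs y (``alternative`` for mean(x−y))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired samples of equal length (n ≥ 2) required")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 0.5
        warnings.warn("zero variance of differences; t is unbounded")
        return float(np.sign(d[0]) * np.inf), 0.0
    res = scipy.stats.ttest_rel(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m·p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


def rt_cell_means(
    trials: pd.DataFrame,
    by=("participant", "metricality", "regularity"),
) -> pd.DataFrame:
    """Mean reaction time on hit trials per cell."""
    hits = trials[trials.is_target & trials.response]
    out = hits.groupby(list(by), sort=True)["rt_ms"].mean().reset_index()
    return out.rename(columns={"rt_ms": "mean_rt_ms"})
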