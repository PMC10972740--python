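"""Group-level statistics: omnibus tests, corrections, and report assembly.

Standard tests are delegated to scipy / statsmodels / pingouin; this module
owns only the data marshaling, multiple-comparison handling (Benjamini-
Hochberg FDR; Tukey-Kramer for unequal group sizes), and the report
structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.multivariate.manova import MANOVA
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .types import ValidationError

log = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    name: str
    statistic: float
    df: float
    p_value: float
    post_hoc: list = field(default_factory=list)
    correction: str = "none"
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Distance distributions (subspace separation per condition)
# ---------------------------------------------------------------------------


def compare_distance_distributions(distances: dict[str, np.ndarray]) -> GroupComparison:
    """Rank-based omnibus (Kruskal-Wallis) across the per-condition subspace
    distance distributions, followed by Tukey-Kramer pairwise comparisons
    with confidence intervals."""
    if len(distances) < 2:
        raise ValidationError("compare_distance_distributions: need >= 2 groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in distances.items()}
    for name, vals in groups.items():
        if vals.size < 3:
            raise ValidationError(f"group {name!r} has fewer than 3 values")
    flags = [f"group {n} is constant" for n, v in groups.items() if np.ptp(v) == 0]

    values = list(groups.values())
    if np.ptp(np.concatenate(values)) == 0:
        # all observations identical: no rank information at all
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(*values)
    comp = GroupComparison(
        name="distance_kruskal",
        statistic=float(stat),
        df=float(len(groups) - 1),
        p_value=float(p),
        correction="TukeyKramer",
        flags=flags,
    )
    data = np.concatenate(values)
    labels = np.concatenate([[n] * len(v) for n, v in groups.items()])
    if np.ptp(data) > 0:
        tk = pairwise_tukeyhsd(data, labels)  # Tukey-Kramer under unequal n
        for row in tk.summary().data[1:]:
            comp.post_hoc.append(
                {
                    "group1": str(row[0]),
                    "group2": str(row[1]),
                    "meandiff": float(row[2]),
                    "p_adj": float(row[3]),
                    "ci_low": float(row[4]),
                    "ci_high": float(row[5]),
                    "reject": bool(row[6]),
                }
            )
    return comp


# ---------------------------------------------------------------------------
# Outcome proportions over trials (chi-square + FDR)
# ---------------------------------------------------------------------------


def _mc_chi2_pvalue(table: np.ndarray, seed: int = 0, n_perm: int = 2000) -> float:
    """Monte-Carlo permutation test on the chi-square statistic, used when
    expected counts are too small for the asymptotic test."""
    rng = np.random.default_rng(seed)
    obs = sps.chi2_contingency(table, correction=False).statistic
    row_labels = np.repeat(np.arange(table.shape[0]), table.sum(axis=1).astype(int))
    col_labels = np.concatenate(
        [np.repeat(np.arange(table.shape[1]), r.astype(int)) for r in table]
    )
    count = 1
    for _ in range(n_perm):
        perm = rng.permutation(col_labels)
        t = np.zeros_like(table)
        np.add.at(t, (row_labels, perm), 1)
        if sps.chi2_contingency(t, correction=False).statistic >= obs - 1e-12:
            count += 1
    return count / (n_perm + 1)


def proportions_over_trials(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trial 2 x 3 chi-square between two session types' outcome counts
    (correct / incorrect / omission), BH-FDR corrected across trials.

    ``counts_a``/``counts_b`` are (n_trials, 3) count tables.  Trials where
    any expected cell is below 1 fall back to a seeded Monte-Carlo
    permutation test (logged and flagged in the output).
    """
    A = np.asarray(counts_a, dtype=float)
    B = np.asarray(counts_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValidationError("proportions_over_trials: shape mismatch")
    raw_p, stats_, exact = [], [], []
    for t in range(A.shape[0]):
        table = np.vstack([A[t], B[t]])
        keep = table.sum(axis=0) > 0  # drop all-zero outcome columns
        table = table[:, keep]
        if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
            raw_p.append(1.0)
            stats_.append(0.0)
            exact.append(False)
            continue
        res = sps.chi2_contingency(table, correction=False)
        if (res.expected_freq < 1).any():
            log.info("proportions_over_trials: trial %d uses permutation fallback", t)
            raw_p.append(_mc_chi2_pvalue(table, seed=seed + t))
            stats_.append(float(res.statistic))
            exact.append(True)
        else:
            raw_p.append(float(res.pvalue))
            stats_.append(float(res.statistic))
            exact.append(False)
    reject, p_adj = fdr_correct(np.asarray(raw_p), alpha=alpha)
    return pd.DataFrame(
        {
            "trial": np.arange(1, A.shape[0] + 1),
            "chi2": stats_,
            "p_raw": raw_p,
            "p_fdr": p_adj,
            "significant": reject,
            "exact_fallback": exact,
        }
    )


def fdr_correct(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg; adjusted p-values never decrease and preserve
    the ordering of the raw p-values."""
    reject, p_adj, _, _ = multipletests(np.asarray(p_values), alpha=alpha, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# Latency ~ distance regression (session-level)
# ---------------------------------------------------------------------------


def latency_distance_regression(df: pd.DataFrame) -> dict:
    """Fit Latency ~ Distance * Session over sessions and report the
    coefficient table plus within-session-type Pearson correlations.

    ``df`` needs columns latency, distance, session_type (two levels;
    coded 0/1 in fit order congruent=0, incongruent=1 when named so).
    """
    for col in ("latency", "distance", "session_type"):
        if col not in df.columns:
            raise ValidationError(f"latency_distance_regression: missing column {col}")
    levels = sorted(df["session_type"].unique(), key=lambda s: (s != "congruent", s))
    if len(levels) not in (1, 2):
        raise ValidationError("latency_distance_regression: need 1 or 2 session types")
    for level in levels:
        if (df["session_type"] == level).sum() < 3:
            raise ValidationError(f"fewer than 3 sessions of type {level!r}")
    if df["distance"].std() == 0:
        raise ValidationError("latency_distance_regression: zero variance in distance")
    work = df.copy()
    if len(levels) == 2:
        work["session"] = (work["session_type"] == levels[1]).astype(float)
        fit = ols("latency ~ distance * session", data=work).fit()
    else:
        fit = ols("latency ~ distance", data=work).fit()
    correlations = {}
    for level in levels:
        sub = work[work["session_type"] == level]
        if sub["distance"].std() == 0 or sub["latency"].std() == 0:
            correlations[level] = {"r": float("nan"), "p": float("nan")}
        else:
            r, p = sps.pearsonr(sub["distance"], sub["latency"])
            correlations[level] = {"r": float(r), "p": float(p)}
    return {
        "params": fit.params.to_dict(),
        "p_values": fit.pvalues.to_dict(),
        "conf_int": {k: list(v) for k, v in fit.conf_int().iterrows()},
        "r_squared": float(fit.rsquared),
        "f_statistic": float(fit.fvalue),
        "f_p_value": float(fit.f_pvalue),
        "session_coding": {lvl: i for i, lvl in enumerate(levels)},
        "correlations": correlations,
    }


# ---------------------------------------------------------------------------
# Behavioral omnibus (per-metric ANOVA + per-strain MANOVA)
# ---------------------------------------------------------------------------


def omnibus_behavior_tests(
    metrics_df: pd.DataFrame,
    metric_columns: Sequence[str],
    drop: Sequence[str] = (),
) -> dict:
    """Two-way (strain x session type) ANOVA per metric and a per-strain
    multivariate omnibus (MANOVA) across the metric vector, with Tukey HSD
    post hocs on the strain x session-type groups.

    ``drop`` removes collinear metrics from the multivariate test (session
    outcome counts are collinear by construction since they partition the
    CS+ trials).  Metrics whose covariance is singular are dropped with a
    warning.
    """
    needed = {"strain", "session_type"} | set(metric_columns)
    missing = needed - set(metrics_df.columns)
    if missing:
        raise ValidationError(f"omnibus_behavior_tests: missing columns {sorted(missing)}")
    per_metric = {}
    for col in metric_columns:
        model = ols(f"Q('{col}') ~ C(strain) * C(session_type)", data=metrics_df).fit()
        table = anova_lm(model, typ=2)
        groups = (metrics_df["strain"] + "_" + metrics_df["session_type"]).to_numpy()
        post = []
        if metrics_df[col].std() > 0 and len(np.unique(groups)) > 1:
            tk = pairwise_tukeyhsd(metrics_df[col].to_numpy(float), groups)
            for row in tk.summary().data[1:]:
                post.append(
                    {
                        "group1": str(row[0]),
                        "group2": str(row[1]),
                        "meandiff": float(row[2]),
                        "p_adj": float(row[3]),
                        "reject": bool(row[6]),
                    }
                )
        per_metric[col] = {
            "anova": {
                effect: {
                    "F": float(table.loc[effect, "F"]),
                    "p": float(table.loc[effect, "PR(>F)"]),
                }
                for effect in table.index
                if effect != "Residual"
            },
            "tukey_hsd": post,
        }

    mv_cols = [c for c in metric_columns if c not in set(drop)]
    mv_cols = [c for c in mv_cols if metrics_df[c].std() > 0]
    per_strain_manova = {}
    for strain, sub in metrics_df.groupby("strain"):
        cols = list(mv_cols)
        result = None
        while cols:
            try:
                formula = " + ".join(f"Q('{c}')" for c in cols) + " ~ C(session_type)"
                mv = MANOVA.from_formula(formula, data=sub)
                tab = mv.mv_test().results["C(session_type)"]["stat"]
                result = {
                    "wilks_lambda": float(tab.loc["Wilks' lambda", "Value"]),
                    "F": float(tab.loc["Wilks' lambda", "F Value"]),
                    "p": float(tab.loc["Wilks' lambda", "Pr > F"]),
                    "metrics": cols,
                }
                break
            except Exception:  # singular covariance: drop the last metric
                log.warning("MANOVA singular for strain %s; dropping %s", strain, cols[-1])
                cols = cols[:-1]
        per_strain_manova[str(strain)] = result
    return {"per_metric": per_metric, "per_strain_manova": per_strain_manova}


# ---------------------------------------------------------------------------
# Repeated-measures time x side screen (per PC, per loading-sign group)
# ---------------------------------------------------------------------------


def rm_time_side_anova(
    left_rates: np.ndarray,
    right_rates: np.ndarray,
    n_time_levels: Optional[int] = 8,
) -> dict:
    """Two-way repeated-measures ANOVA (within factors: side, time; subject
    = unit) on units x bins rate matrices for the left and right trials.

    Time bins are averaged down to ``n_time_levels`` levels to keep the
    within-subject design well conditioned.  Requires a balanced design
    (identical unit sets and bin grids on both sides).
    """
    L = np.asarray(left_rates, dtype=float)
    R = np.asarray(right_rates, dtype=float)
    if L.shape != R.shape or L.ndim != 2:
        raise ValidationError("rm_time_side_anova: unbalanced design (shape mismatch)")
    if L.shape[0] < 3:
        raise ValidationError("rm_time_side_anova: need >= 3 units")
    n_units, n_bins = L.shape
    if n_time_levels and n_time_levels < n_bins:
        splits = np.array_split(np.arange(n_bins), n_time_levels)
        L = np.stack([L[:, s].mean(axis=1) for s in splits], axis=1)
        R = np.stack([R[:, s].mean(axis=1) for s in splits], axis=1)
        n_bins = L.shape[1]
    rows = []
    for u in range(n_units):
        for b in range(n_bins):
            rows.append({"unit": u, "side": "left", "time": b, "rate": L[u, b]})
            rows.append({"unit": u, "side": "right", "time": b, "rate": R[u, b]})
    df = pd.DataFrame(rows)
    aov = pg.rm_anova(
        data=df, dv="rate", within=["side", "time"], subject="unit", detailed=True
    )
    out = {}
    for _, row in aov.iterrows():
        key = str(row["Source"]).replace(" * ", "_x_").lower()
        out[key] = {"F": float(row["F"]), "p": float(row["p_unc"])}
    return {
        "p_side": out.get("side", {}).get("p", float("nan")),
        "p_time": out.get("time", {}).get("p", float("nan")),
        "p_interaction": out.get("side_x_time", {}).get("p", float("nan")),
        "table": out,
    }


def interaction_screen(
    groups: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]],
    n_time_levels: Optional[int] = 8,
) -> dict[int, dict[str, dict]]:
    """Run the repeated-measures side x time screen for every PC and
    loading-sign group.  ``groups[pc][sign] = (left_rates, right_rates)``.
    Feeds :func:`twocap.geometry.select_interaction_pc`."""
    out: dict[int, dict[str, dict]] = {}
    for pc, by_sign in groups.items():
        out[pc] = {}
        for sign, (L, R) in by_sign.items():
            out[pc][sign] = rm_time_side_anova(L, R, n_time_levels=n_time_levels)
    return out
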