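"""Fixed-effects two-way ANOVA, Tukey–Kramer contrasts, bootstrap CIs.

The treatment×biome analysis is a fixed-effects Type III ANOVA: sum-to-zero
(effect) coding, each term tested by comparing the full model against the
model with that term's columns removed. This is the fixed-effects analogue
of the mixed-model analysis commonly run on such designs; random intercepts
(species, family, growth form, plant identity) are deliberately not fitted
here, so F values are comparable in structure, not numerically, to a
mixed-model fit.

Pairwise comparisons use Tukey's honest significant difference with the
Tukey–Kramer adjustment for unequal group sizes; Holm-adjusted pooled-t
comparisons are available as an alternative. Group-mean confidence
intervals use the seeded nonparametric percentile bootstrap.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AnovaTable:
    """Type III ANOVA summary for a two-factor fixed-effects model."""

    terms: list[str]
    ss: dict[str, float]
    df_num: dict[str, int]
    df_den: int
    f: dict[str, float]
    p: dict[str, float]
    r_squared: float
    rss: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "sum_sq": [self.ss[t] for t in self.terms],
                "df_num": [self.df_num[t] for t in self.terms],
                "df_den": self.df_den,
                "F": [self.f[t] for t in self.terms],
                "p": [self.p[t] for t in self.terms],
            }
        )


def _effect_code(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero coding: k−1 columns, last level coded −1 throughout."""
    levels = sorted(pd.unique(labels).tolist())
    if len(levels) < 2:
        raise ValueError(f"factor needs ≥2 levels, has {levels}")
    cols = np.zeros((labels.size, len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[labels == lev, j] = 1.0
    cols[labels == levels[-1], :] = -1.0
    return cols, levels


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def two_way_anova(values, treatment_labels, biome_labels) -> AnovaTable:
    """Type III two-way ANOVA of ``values`` on two categorical factors.

    Unbalanced designs are allowed; each term's sum of squares is the RSS
    increase when its effect-coded columns are dropped from the full
    (interaction-included) model.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(treatment_labels, dtype=object)
    if y.size != a.size:
        raise ValueError("values and factor labels must have equal length")
    A, _ = _effect_code(a)
    ones = np.ones((y.size, 1))
    if biome_labels is None:
        # Degenerate one-factor design: test treatment only.
        blocks = {"treatment": A}
        X_full = np.column_stack([ones, A])
    else:
        b = np.asarray(biome_labels, dtype=object)
        if y.size != b.size:
            raise ValueError("values and factor labels must have equal length")
        B, _ = _effect_code(b)
        AB = np.column_stack(
            [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
        )
        blocks = {"treatment": A, "biome": B, "treatment:biome": AB}
        X_full = np.column_stack([ones, A, B, AB])
    p_full = X_full.shape[1]
    df_den = y.size - p_full
    if df_den <= 0:
        raise ValueError("not enough observations for the full model")
    rss_full = _rss(X_full, y)
    tss = float(((y - y.mean()) ** 2).sum())
    terms, ss, df_num, f, p = [], {}, {}, {}, {}
    for term, block in blocks.items():
        keep = [blk for name, blk in blocks.items() if name != term]
        X_red = np.column_stack([ones, *keep])
        ss_term = max(_rss(X_red, y) - rss_full, 0.0)
        k = block.shape[1]
        f_term = (ss_term / k) / (rss_full / df_den) if rss_full > 0 else (
            0.0 if ss_term == 0 else np.inf
        )
        terms.append(term)
        ss[term] = ss_term
        df_num[term] = k
        f[term] = f_term
        p[term] = float(sps.f.sf(f_term, k, df_den)) if np.isfinite(f_term) else 0.0
    r2 = 1.0 - rss_full / tss if tss > 0 else 0.0
    return AnovaTable(terms, ss, df_num, df_den, f, p, r2, rss_full)


@dataclass(frozen=True)
class Contrast:
    """One pairwise group comparison."""

    group_a: str
    group_b: str
    diff: float
    se: float
    p_adj: float


def pairwise_contrasts(values, group_labels, method: str = "tukey") -> list[Contrast]:
    """All pairwise mean differences with multiplicity-adjusted p values.

    ``method="tukey"`` uses the studentized range (Tukey–Kramer for unequal
    n); ``method="holm"`` uses Holm-adjusted pooled-variance t tests.
    Groups with a single observation are excluded with a warning.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group_labels, dtype=object)
    groups = {}
    for lev in pd.unique(g):
        vals = y[g == lev]
        if vals.size < 2:
            warnings.warn(f"group {lev!r} has n={vals.size}; excluded", stacklevel=2)
            continue
        groups[str(lev)] = vals
    k = len(groups)
    if k < 2:
        raise ValueError("need ≥2 groups with n ≥ 2")
    n_total = sum(v.size for v in groups.values())
    df = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df
    out: list[Contrast] = []
    for (na, va), (nb, vb) in itertools.combinations(sorted(groups.items()), 2):
        diff = float(va.mean() - vb.mean())
        se_tk = np.sqrt(mse / 2.0 * (1.0 / va.size + 1.0 / vb.size))
        if method == "tukey":
            q = abs(diff) / se_tk
            p_adj = float(sps.studentized_range.sf(q, k, df))
        elif method == "holm":
            se_t = np.sqrt(mse * (1.0 / va.size + 1.0 / vb.size))
            p_adj = 2.0 * float(sps.t.sf(abs(diff) / se_t, df))
        else:
            raise ValueError(f"unknown method {method!r}")
        out.append(Contrast(na, nb, diff, float(se_tk * np.sqrt(2.0)), min(p_adj, 1.0)))
    if method == "holm":
        # Holm step-down on the raw pooled-t p values.
        raw = np.array([c.p_adj for c in out])
        m = len(raw)
        idx = np.argsort(raw)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(idx):
            running = max(running, (m - rank) * raw[i])
            adj[i] = min(running, 1.0)
        out = [
            Contrast(c.group_a, c.group_b, c.diff, c.se, float(adj[i]))
            for i, c in enumerate(out)
        ]
    return out


def contrasts_to_frame(contrasts: list[Contrast]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group_a": [c.group_a for c in contrasts],
            "group_b": [c.group_b for c in contrasts],
            "diff": [c.diff for c in contrasts],
            "se": [c.se for c in contrasts],
            "p_adj": [c.p_adj for c in contrasts],
        }
    )


def bootstrap_mean_ci(
    values,
    n_boot: int = 1000,
    level: float = 0.95,
    seed=None,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI of the mean: (mean, lo, hi).

    ``seed`` may be an int or a numpy Generator; identical seeds give
    bit-identical intervals.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise ValueError(f"need n ≥ 2 observations, have {y.size}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, y.size, size=(n_boot, y.size))
    means = y[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(y.mean()), float(lo), float(hi)
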