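"""Rank and linear correlation screens against environmental parameters.

Spearman's rank correlation (average ranks for ties; the coefficient is
the product-moment correlation of the ranks) and Pearson's r, each with a
two-sided p-value from the t approximation on n - 2 degrees of freedom;
Spearman additionally offers a seeded Monte-Carlo permutation p-value.
``correlation_screen`` runs every (row, parameter) pair of an abundance or
expression matrix against a sample x parameter table, flags entries at a
raw alpha (no multiplicity correction by default, Benjamini–Hochberg
optional), and can blank non-significant cells of the wide coefficient
matrix for heatmap display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CorrelationEntry:
    x_id: str
    y_id: str
    coefficient: float
    p_value: float
    n: int
    method: str
    significant: bool = False


def _pair_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def spearman(
    x,
    y,
    *,
    p_method: str = "t-approx",
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
    x_id: str = "x",
    y_id: str = "y",
) -> CorrelationEntry:
    """Spearman's rank correlation with a two-sided p-value.

    ``p_method="t-approx"`` uses the t distribution on n - 2 df;
    ``"permutation"`` draws ``n_perm`` seeded permutations of ``y`` and
    reports the add-one Monte-Carlo p.  Constant vectors give an
    undefined (NaN) coefficient.
    """
    x, y = _pair_complete(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector: Spearman coefficient undefined")
        return CorrelationEntry(x_id, y_id, np.nan, np.nan, n, "spearman")
    rho, p = stats.spearmanr(x, y)
    if p_method == "permutation":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(ry)
            if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    elif p_method != "t-approx":
        raise ValueError(f"unknown p_method {p_method!r}")
    return CorrelationEntry(x_id, y_id, float(rho), float(p), n, "spearman")


def pearson(x, y, *, x_id: str = "x", y_id: str = "y") -> CorrelationEntry:
    """Pearson product-moment correlation with two-sided t-test p-value."""
    x, y = _pair_complete(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector: Pearson coefficient undefined")
        return CorrelationEntry(x_id, y_id, np.nan, np.nan, n, "pearson")
    r, p = stats.pearsonr(x, y)
    return CorrelationEntry(x_id, y_id, float(r), float(p), n, "pearson")


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaN-safe)."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    pv = p[ok]
    m = len(pv)
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q


def correlation_screen(
    matrix: pd.DataFrame,
    env: pd.DataFrame,
    method: str = "spearman",
    alpha: float = 0.05,
    *,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Correlate every matrix row with every environmental parameter.

    ``matrix`` is feature x sample; ``env`` is sample x parameter.  Missing
    parameter values are handled pairwise-complete, with the effective
    ``n`` recorded per entry.  Returns a long table (x_id, y_id, method,
    coefficient, p_value, n, significant); with ``bh_correct`` the
    significance flag uses Benjamini–Hochberg adjusted p-values.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    samples = [s for s in matrix.columns if s in env.index]
    if len(samples) < 3:
        raise ValueError("matrix and env share fewer than 3 samples")
    func = spearman if method == "spearman" else pearson
    rows = []
    for x_id, xvals in matrix[samples].iterrows():
        for y_id in env.columns:
            entry = func(xvals.to_numpy(), env.loc[samples, y_id].to_numpy(),
                         x_id=str(x_id), y_id=str(y_id))
            rows.append(entry)
    out = pd.DataFrame(
        {
            "x_id": [e.x_id for e in rows],
            "y_id": [e.y_id for e in rows],
            "method": method,
            "coefficient": [e.coefficient for e in rows],
            "p_value": [e.p_value for e in rows],
            "n": [e.n for e in rows],
        }
    )
    p_eff = _bh_adjust(out["p_value"].to_numpy()) if bh_correct else out["p_value"].to_numpy()
    out["significant"] = pd.Series(p_eff, index=out.index) < alpha
    out.loc[out["p_value"].isna(), "significant"] = False
    return out


def significant_counts(screen: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter counts of significant positive/negative correlations."""
    sig = screen[screen["significant"]]
    pos = sig[sig["coefficient"] > 0].groupby("y_id").size()
    neg = sig[sig["coefficient"] < 0].groupby("y_id").size()
    params = screen["y_id"].unique()
    return pd.DataFrame(
        {"positive": pos.reindex(params, fill_value=0), "negative": neg.reindex(params, fill_value=0)}
    )


def masked_matrix(screen: pd.DataFrame) -> pd.DataFrame:
    """Wide coefficient matrix with non-significant cells blanked (NaN)."""
    wide = screen.pivot(index="x_id", columns="y_id", values="coefficient")
    sig = screen.pivot(index="x_id", columns="y_id", values="significant")
    return wide.where(sig.astype(bool))
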