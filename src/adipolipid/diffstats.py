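"""Paired twin differential analysis, FDR q-values, ANOVA and PLS.

The discordant-twin design compares each heavy co-twin with its lean
sibling, eliminating genetic confounding. The core operations:

* twin normalization ``X_norm = log2(X_heavy / X_lean)`` per pair;
* paired two-sided tests per species (paired t on the chosen scale, or
  Wilcoxon signed-rank);
* Storey FDR q-values with the fixed-lambda tail estimator of the null
  proportion pi0 (q < 0.05 primary significance, q < 0.1 marginal);
* one-way ANOVA for multi-group designs (e.g. knockdown experiments);
* NIPALS partial least squares regression of twin-normalized lipid
  profiles on twin-normalized fat cell size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lipids import AbundanceTable

__all__ = [
    "discordant_pairs",
    "twin_log_ratio",
    "twin_log_ratio_matrix",
    "paired_test",
    "paired_test_values",
    "storey_qvalues",
    "group_anova",
    "differential_analysis",
    "paired_frame_analysis",
    "PlsModel",
    "pls_on_fcs",
]

Q_SIGNIFICANT = 0.05
Q_MARGINAL = 0.1


def discordant_pairs(metadata: pd.DataFrame) -> pd.DataFrame:
    """Pair table (index pair_id, columns heavy/lean subject ids)."""
    disc = metadata[metadata["group"] == "discordant"]
    out = {}
    for pair_id, sub in disc.groupby("pair_id"):
        heavy = sub.index[sub["role"] == "heavy"]
        lean = sub.index[sub["role"] == "lean"]
        if len(heavy) != 1 or len(lean) != 1:
            raise ValueError(f"pair {pair_id!r} lacks a heavy/lean twin")
        out[pair_id] = {"heavy": heavy[0], "lean": lean[0]}
    if not out:
        raise ValueError("no discordant pairs in metadata")
    return pd.DataFrame.from_dict(out, orient="index").sort_index()


def twin_log_ratio(table: AbundanceTable, variable: str) -> pd.Series:
    """Twin normalization log2(heavy / lean) per discordant pair.

    ``variable`` is a species name (row of the abundance matrix) or a
    numeric metadata column such as ``fcs``. Values must be strictly
    positive; zero or negative entries raise an error naming the pair.
    """
    if variable in table.data.index:
        values = table.data.loc[variable]
    elif variable in table.metadata.columns:
        values = table.metadata[variable]
    else:
        raise KeyError(f"unknown variable {variable!r}")
    pairs = discordant_pairs(table.metadata)
    heavy = values.loc[pairs["heavy"]].to_numpy(float)
    lean = values.loc[pairs["lean"]].to_numpy(float)
    bad = pairs.index[(heavy <= 0) | (lean <= 0)]
    if len(bad):
        raise ValueError(
            f"non-positive value for variable {variable!r} in pair(s) "
            f"{list(bad)}; twin log-ratio requires positive values")
    return pd.Series(np.log2(heavy / lean), index=pairs.index, name=variable)


def twin_log_ratio_matrix(data: pd.DataFrame,
                          metadata: pd.DataFrame) -> pd.DataFrame:
    """log2(heavy/lean) for every row variable; rows = pairs, cols = variables.

    ``data`` is variables x subjects (an abundance matrix or any paired
    per-subject table).
    """
    pairs = discordant_pairs(metadata)
    heavy = data[pairs["heavy"]].to_numpy(float)
    lean = data[pairs["lean"]].to_numpy(float)
    if (heavy <= 0).any() or (lean <= 0).any():
        si, pi = np.argwhere((heavy <= 0) | (lean <= 0))[0]
        raise ValueError(
            f"non-positive value for {data.index[si]!r} in pair "
            f"{pairs.index[pi]!r}")
    return pd.DataFrame(np.log2(heavy / lean).T, index=pairs.index,
                        columns=data.index)


def paired_test_values(heavy, lean, method: str = "t",
                       log_transform: bool = True,
                       label: str = "variable") -> tuple[float, float]:
    """Two-sided paired test on heavy/lean value vectors.

    The ``"t"`` method equals the one-sample t-test on within-pair
    differences; ``"wilcoxon"`` is the signed-rank test. With
    ``log_transform`` (default) values are log2-transformed first.
    All-zero differences give the degenerate branch (0, 1) with a warning.
    """
    heavy = np.asarray(heavy, dtype=float)
    lean = np.asarray(lean, dtype=float)
    if heavy.shape != lean.shape or heavy.ndim != 1:
        raise ValueError("heavy and lean must be equal-length vectors")
    if len(heavy) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(heavy)}")
    if log_transform:
        if (heavy <= 0).any() or (lean <= 0).any():
            raise ValueError(
                f"non-positive values for {label!r}; disable log_transform")
        heavy, lean = np.log2(heavy), np.log2(lean)
    diffs = heavy - lean
    if np.allclose(diffs, 0.0):
        warnings.warn(f"all within-pair differences are zero for {label!r}; "
                      "p-value set to 1", stacklevel=2)
        return 0.0, 1.0
    if method == "t":
        res = stats.ttest_rel(heavy, lean)
    elif method == "wilcoxon":
        res = stats.wilcoxon(heavy, lean)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def paired_test(table: AbundanceTable, species: str, method: str = "t",
                log_transform: bool = True) -> tuple[float, float]:
    """Two-sided paired heavy-vs-lean test for one species of a table."""
    values = table.data.loc[species]
    pairs = discordant_pairs(table.metadata)
    return paired_test_values(values.loc[pairs["heavy"]],
                              values.loc[pairs["lean"]],
                              method=method, log_transform=log_transform,
                              label=species)


def storey_qvalues(p_values, lambda_: float = 0.5, pi0: float | None = None,
                   smoother: bool = False) -> np.ndarray:
    """Storey FDR q-values.

    pi0 is estimated by the fixed-lambda tail estimator
    ``#{p > lambda} / ((1 - lambda) m)`` clipped to (0, 1], or by a cubic
    smoother over a lambda grid when ``smoother`` is set; passing ``pi0``
    overrides the estimate. q_i is the minimum of ``pi0 * m * p_(j) / j``
    over all p_(j) >= p_i (step-up), so q-values are monotone in the
    p-value ranking and never exceed 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if smoother:
            grid = np.arange(0.05, 0.95, 0.05)
            pi0_grid = np.array([(p > lam).sum() / ((1 - lam) * m)
                                 for lam in grid])
            coef = np.polynomial.polynomial.polyfit(grid, pi0_grid, 3)
            pi0 = float(np.polynomial.polynomial.polyval(grid[-1], coef))
        else:
            pi0 = float((p > lambda_).sum() / ((1 - lambda_) * m))
    pi0 = min(max(pi0, 1.0 / m), 1.0)  # clip to (0, 1]
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_ranked = pi0 * m * ranked / np.arange(1, m + 1)
    q_ranked = np.minimum.accumulate(q_ranked[::-1])[::-1]
    q_ranked = np.minimum(q_ranked, 1.0)
    q = np.empty(m)
    q[order] = q_ranked
    return q


def group_anova(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Requires >= 2 groups with >= 2 samples each. Degenerate inputs:
    zero between- and within-group variance gives (0, 1); zero
    within-group variance with distinct means gives (inf, 0).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        sizes = {str(g): int((groups == g).sum()) for g in pd.unique(groups)}
        raise ValueError(f"every group needs >= 2 samples, got {sizes}")
    grand = values.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ssw == 0.0:
        if ssb == 0.0:
            warnings.warn("all values identical; F undefined, returning (0, 1)",
                          stacklevel=2)
            return 0.0, 1.0
        return float("inf"), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.f_oneway(*samples)
    return float(res.statistic), float(res.pvalue)


def paired_frame_analysis(data: pd.DataFrame, metadata: pd.DataFrame,
                          method: str = "t", log_transform: bool = True,
                          lambda_: float = 0.5,
                          smoother: bool = False) -> pd.DataFrame:
    """Paired heavy-vs-lean analysis for every row of a variables x
    subjects frame, with Storey q-values and direction calls."""
    pairs = discordant_pairs(metadata)
    heavy_cols, lean_cols = pairs["heavy"], pairs["lean"]
    rows = []
    for var in data.index:
        values = data.loc[var]
        stat, p = paired_test_values(values.loc[heavy_cols],
                                     values.loc[lean_cols], method=method,
                                     log_transform=log_transform, label=var)
        rows.append({"variable": var, "statistic": stat, "p_value": p})
    res = pd.DataFrame(rows).set_index("variable")
    res["mean_heavy"] = data[heavy_cols].mean(axis=1)
    res["mean_lean"] = data[lean_cols].mean(axis=1)
    res["log2_ratio"] = twin_log_ratio_matrix(data, metadata).mean(axis=0)
    res["q_value"] = storey_qvalues(res["p_value"].to_numpy(),
                                    lambda_=lambda_, smoother=smoother)
    res["direction"] = np.where(res["log2_ratio"] >= 0, "up", "down")
    res["significant"] = res["q_value"] < Q_SIGNIFICANT
    res["marginal"] = res["q_value"] < Q_MARGINAL
    return res[["mean_heavy", "mean_lean", "log2_ratio", "statistic",
                "p_value", "q_value", "direction", "significant", "marginal"]]


def differential_analysis(table: AbundanceTable, method: str = "t",
                          log_transform: bool = True,
                          lambda_: float = 0.5,
                          smoother: bool = False) -> pd.DataFrame:
    """Per-species paired heavy-vs-lean analysis with q-values.

    Returns a DataFrame indexed by species with columns ``mean_heavy``,
    ``mean_lean`` (group means on the table's scale), ``log2_ratio``
    (mean twin log-ratio), ``statistic``, ``p_value``, ``q_value``,
    ``direction`` (up = elevated in heavy co-twins) and ``significant``
    / ``marginal`` flags at q < 0.05 / q < 0.1.
    """
    res = paired_frame_analysis(table.data, table.metadata, method=method,
                                log_transform=log_transform, lambda_=lambda_,
                                smoother=smoother)
    res.index.name = "species"
    return res


@dataclass
class PlsModel:
    """A fitted NIPALS partial least squares regression (PLS1)."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    scores: np.ndarray  # T (n x a)
    loadings: np.ndarray  # P (p x a)
    weights: np.ndarray  # W (p x a)
    y_loadings: np.ndarray  # q (a,)
    regression_coefficients: np.ndarray  # B (p,)
    explained_variance: np.ndarray  # per-component fraction of var(y)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.regression_coefficients + self.y_mean


def pls_on_fcs(X, y, n_components: int = 2) -> PlsModel:
    """NIPALS PLS1 regression of twin-normalized lipids on FCS.

    Rows of ``X`` are pairs (twin log-ratios per species), ``y`` is the
    corresponding twin-normalized fat cell size. Components are extracted
    iteratively: weight w proportional to X'y, score t = Xw, loading
    p = X't/t't, y-loading q = y't/t't, then X and y are deflated. Raises
    when ``n_components`` exceeds the rank of centered X.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X rows must match y length")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    rank = np.linalg.matrix_rank(Xc)
    if n_components > rank:
        raise ValueError(f"n_components = {n_components} exceeds rank {rank}")
    n, p = Xc.shape
    ss_y = float(yc @ yc)
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    W = np.zeros((p, n_components))
    q = np.zeros(n_components)
    explained = np.zeros(n_components)
    Xd, yd = Xc.copy(), yc.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError(f"component {a + 1}: X carries no covariance "
                             "with y (deflated X'y = 0)")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError(f"component {a + 1}: degenerate zero score")
        pvec = Xd.T @ t / tt
        qa = float(yd @ t / tt)
        Xd = Xd - np.outer(t, pvec)
        yd = yd - qa * t
        T[:, a], P[:, a], W[:, a], q[a] = t, pvec, w, qa
        explained[a] = qa ** 2 * tt / ss_y if ss_y > 0 else 0.0
    B = W @ np.linalg.solve(P.T @ W, q)
    return PlsModel(n_components=n_components, x_mean=x_mean, y_mean=y_mean,
                    scores=T, loadings=P, weights=W, y_loadings=q,
                    regression_coefficients=B, explained_variance=explained)
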