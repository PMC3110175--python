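"""Dependency network inference by q-order partial correlations.

Builds an undirected Gaussian graphical dependency network over a mixed
variable table (lipids, fatty-acid ratios, gene expression, clinical
variables). Two variables are considered directly dependent when their
partial correlation, adjusting for conditioning sets of exactly ``q``
other variables, is significantly non-zero. Because testing all
conditioning sets is infeasible, ``n_samplings`` subsets of size q are
drawn uniformly per pair and the **non-rejection rate** (NRR) — the
fraction of subsets where the zero-partial-correlation hypothesis is NOT
rejected — summarizes the evidence: a low NRR indicates a robust direct
dependency. The default edge rule keeps a pair when it "tested positive"
(rejected) in at least a ``threshold`` fraction of samplings, i.e.
``1 - NRR >= threshold`` with threshold 0.55 over 500 samplings; the
alternative ``nrr-below`` rule keeps pairs with ``NRR <= threshold``.

The per-subset test uses the exact null distribution of the sample
partial correlation: ``t = r * sqrt((n - q - 2) / (1 - r^2))`` on
``n - q - 2`` degrees of freedom.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NetworkVariable",
    "DependencyNetwork",
    "partial_correlation",
    "test_zero_pcor",
    "non_rejection_rate",
    "build_network",
    "hub_report",
    "write_graphml",
    "write_sif",
    "edge_table",
]


@dataclass(frozen=True)
class NetworkVariable:
    """A typed network node.

    ``var_type`` follows the platform legend: L (lipid), FA (fatty acid /
    ratio), GE (gene expression), clinical, pathway_profile. ``regulation``
    annotates differential significance: up, down or ns.
    """

    name: str
    var_type: str = "clinical"
    regulation: str = "ns"

    VALID_TYPES = ("L", "FA", "GE", "clinical", "pathway_profile")

    def __post_init__(self) -> None:
        if self.var_type not in self.VALID_TYPES:
            raise ValueError(f"var_type {self.var_type!r} not in "
                             f"{self.VALID_TYPES}")
        if self.regulation not in ("up", "down", "ns"):
            raise ValueError(f"regulation {self.regulation!r} not in up/down/ns")


@dataclass
class DependencyNetwork:
    """An inferred NRR-weighted dependency network."""

    graph: nx.Graph
    nrr: pd.DataFrame  # all-pairs table: i, j, nrr, mean_abs_pcor
    parameters: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    arr = np.asarray(data, dtype=float)
    return arr, [f"X{i + 1}" for i in range(arr.shape[1])]


def _pcor_from_cov(cov: np.ndarray) -> float:
    """Partial correlation of variables 0, 1 given the rest, from their
    joint covariance submatrix, via precision-matrix inversion."""
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance submatrix for conditioning set"
                         ) from exc
    return float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))


def partial_correlation(data, i: int, j: int, conditioning=()) -> float:
    """Sample partial correlation of columns i, j given a conditioning set.

    ``conditioning`` is an iterable of column indices. With an empty set
    this reduces exactly to the Pearson correlation. Computed by
    inverting the (i, j, Q) sub-covariance matrix; raises naming the
    conditioning set when that submatrix is singular.
    """
    X, _ = _as_matrix(data)
    q_idx = list(conditioning)
    if i == j or i in q_idx or j in q_idx:
        raise ValueError("i, j and conditioning set must be disjoint")
    n = X.shape[0]
    if n <= len(q_idx) + 2:
        raise ValueError(f"need n > q + 2 samples (n = {n}, q = {len(q_idx)})")
    sub = X[:, [i, j, *q_idx]]
    cov = np.cov(sub, rowvar=False)
    try:
        return _pcor_from_cov(cov)
    except ValueError as exc:
        raise ValueError(
            f"singular sub-covariance for pair ({i}, {j}) given "
            f"conditioning set {q_idx}") from exc


def pairwise_bonferroni_alpha(p: int, family_alpha: float = 0.05) -> float:
    """Per-pair test level controlling the family-wise error over all
    p(p-1)/2 variable pairs.

    With the per-subset level left at ``family_alpha`` itself, roughly
    ``family_alpha`` x (number of null pairs) marginal-correlation flukes
    survive the samplings and become spurious edges, which no analysis
    aiming at *structure recovery* can afford; divide the level by the
    number of tested pairs for recovery studies. The exploratory NRR
    analysis of a small mixed-variable panel keeps the unadjusted level.
    """
    if p < 2:
        raise ValueError("need at least two variables")
    return family_alpha / (p * (p - 1) / 2)


def test_zero_pcor(r: float, n: int, q: int,
                   alpha: float = 0.05) -> tuple[bool, float]:
    """Two-sided test of H0: partial correlation = 0.

    Uses ``t = r sqrt((n - q - 2) / (1 - r^2))`` on ``n - q - 2`` degrees
    of freedom. Returns (reject, p_value); |r| = 1 rejects with p = 0.
    """
    df = n - q - 2
    if df < 1:
        raise ValueError(f"n - q - 2 must be >= 1 (n = {n}, q = {q})")
    if abs(r) >= 1.0:
        return True, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return bool(p < alpha), float(p)


def _pair_nrr(X: np.ndarray, cov: np.ndarray, i: int, j: int, q: int,
              n_samplings: int, alpha: float,
              rng: np.random.Generator) -> tuple[float, float]:
    """(NRR, mean |pcor|) for one pair by batched subset sampling."""
    n, p = X.shape
    others = np.array([k for k in range(p) if k != i and k != j])
    if q == 0:
        r = _pcor_from_cov(cov[np.ix_([i, j], [i, j])])
        reject, _ = test_zero_pcor(r, n, 0, alpha)
        return (0.0 if reject else 1.0), abs(r)
    if q > len(others):
        raise ValueError(f"q = {q} exceeds available conditioning variables "
                         f"({len(others)})")
    # uniform subsets without replacement within each subset (may repeat
    # across samplings): take the first q of a random permutation each time
    ranks = np.argsort(rng.random((n_samplings, len(others))), axis=1)[:, :q]
    subsets = others[ranks]
    idx = np.concatenate(
        [np.broadcast_to([i, j], (n_samplings, 2)), subsets], axis=1)
    sub = cov[idx[:, :, None], idx[:, None, :]]  # (S, q+2, q+2)
    prec = np.linalg.inv(sub)
    r = -prec[:, 0, 1] / np.sqrt(prec[:, 0, 0] * prec[:, 1, 1])
    r = np.clip(r, -1.0, 1.0)
    df = n - q - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    nrr = float((pvals >= alpha).mean())
    return nrr, float(np.abs(r).mean())


def non_rejection_rate(data, i: int, j: int, q: int = 3,
                       n_samplings: int = 500, alpha: float = 0.05,
                       seed: int | np.random.Generator = 0) -> float:
    """Non-rejection rate of H0: pcor(i, j | Q) = 0 over sampled Q sets.

    Draws ``n_samplings`` uniform subsets Q of size q from the remaining
    variables (subsets may repeat across samplings) and returns the
    fraction where H0 was NOT rejected at level ``alpha``. With q = 0 all
    samplings coincide and the NRR is exactly 0 or 1.
    """
    X, _ = _as_matrix(data)
    n, p = X.shape
    if q >= p - 1:
        raise ValueError(f"q = {q} leaves no valid conditioning subsets "
                         f"(p = {p})")
    if n <= q + 2:
        raise ValueError(f"need n > q + 2 (n = {n}, q = {q})")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    cov = np.cov(X, rowvar=False)
    nrr, _ = _pair_nrr(X, cov, i, j, q, n_samplings, alpha, rng)
    return nrr


def build_network(data, var_meta: list[NetworkVariable] | None = None,
                  q: int = 3, n_samplings: int = 500,
                  threshold: float = 0.55, alpha: float = 0.05,
                  seed: int = 0,
                  edge_rule: str = "rejection-rate") -> DependencyNetwork:
    """Infer the dependency network over all variable pairs.

    ``edge_rule``: ``"rejection-rate"`` (default) retains an edge when
    the pair tested positive in at least ``threshold`` of the samplings,
    i.e. ``1 - NRR >= threshold``; ``"nrr-below"`` retains when
    ``NRR <= threshold``. Edge strength is the mean |partial correlation|
    across samplings. Degenerate (zero-variance) columns are dropped with
    a warning. Deterministic given ``seed``.
    """
    X, names = _as_matrix(data)
    n, p = X.shape
    if edge_rule not in ("rejection-rate", "nrr-below"):
        raise ValueError(f"unknown edge_rule {edge_rule!r}")
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [names[k] for k in np.flatnonzero(~keep)]
        warnings.warn(f"dropping degenerate constant columns: {dropped}",
                      stacklevel=2)
        X = X[:, keep]
        names = [nm for nm, k in zip(names, keep) if k]
        p = X.shape[1]
    if var_meta is None:
        var_meta = [NetworkVariable(name=nm) for nm in names]
    meta_by_name = {v.name: v for v in var_meta}
    missing = [nm for nm in names if nm not in meta_by_name]
    if missing:
        raise ValueError(f"variables without metadata: {missing}")

    rng = np.random.default_rng(seed)
    cov = np.cov(X, rowvar=False)
    rows = []
    for i, j in itertools.combinations(range(p), 2):
        nrr, strength = _pair_nrr(X, cov, i, j, q, n_samplings, alpha, rng)
        rows.append({"i": names[i], "j": names[j], "nrr": nrr,
                     "mean_abs_pcor": strength})
    nrr_table = pd.DataFrame(rows)

    graph = nx.Graph()
    for nm in names:
        v = meta_by_name[nm]
        graph.add_node(nm, var_type=v.var_type, regulation=v.regulation)
    for row in nrr_table.itertuples():
        if edge_rule == "rejection-rate":
            keep_edge = (1.0 - row.nrr) >= threshold
        else:
            keep_edge = row.nrr <= threshold
        if keep_edge:
            graph.add_edge(row.i, row.j, nrr=row.nrr,
                           strength=row.mean_abs_pcor)
    params = {"q": q, "n_samplings": n_samplings, "alpha": alpha,
              "threshold": threshold, "edge_rule": edge_rule, "seed": seed,
              "n_samples": n}
    return DependencyNetwork(graph=graph, nrr=nrr_table, parameters=params)


def hub_report(net: DependencyNetwork) -> pd.DataFrame:
    """Nodes ranked by degree (ties broken lexicographically) with their
    neighbor lists; empty network gives an empty report."""
    rows = []
    for node in net.graph.nodes:
        deg = net.graph.degree[node]
        if deg == 0:
            continue
        rows.append({"node": node, "degree": deg,
                     "neighbors": ",".join(sorted(net.graph.neighbors(node)))})
    if not rows:
        return pd.DataFrame(columns=["node", "degree", "neighbors"])
    df = pd.DataFrame(rows).sort_values(["degree", "node"],
                                        ascending=[False, True])
    return df.reset_index(drop=True)


def edge_table(net: DependencyNetwork) -> pd.DataFrame:
    """Retained edges as a TSV-ready frame sorted by node names."""
    rows = [{"source": a, "target": b, "nrr": d["nrr"],
             "strength": d["strength"]}
            for a, b, d in net.graph.edges(data=True)]
    df = pd.DataFrame(rows, columns=["source", "target", "nrr", "strength"])
    return df.sort_values(["source", "target"]).reset_index(drop=True)


def write_graphml(net: DependencyNetwork, path) -> None:
    nx.write_graphml(net.graph, path)


def write_sif(net: DependencyNetwork, path,
              interaction: str = "pcor") -> None:
    """Simple interaction format: source <interaction> target per edge."""
    with open(path, "w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{interaction}\t{b}\n")
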