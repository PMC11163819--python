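"""Weighted co-editing network: soft threshold, adjacency/TOM, modules, hubs.

The network follows the weighted co-expression recipe applied to editing
levels: unsigned adjacency a_ij = |cor(x_i, x_j)|^beta with the soft power
beta chosen by scale-free topology fit; topological overlap

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity k_i = sum_{u != i} a_iu; average-linkage hierarchical
clustering on 1 − TOM with a static tree cut; module eigengenes as the first
principal component of each module's standardized level matrix; and hub
extraction by degree centrality inside a module.  Modules are named with the
conventional color sequence by decreasing size (largest = turquoise;
unassigned = grey).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
]

__all__ = [
    "CoEditingNetwork", "pick_soft_threshold", "build_network",
    "detect_modules", "module_eigengene", "module_trait_correlation",
    "hub_events", "scale_free_fit_table",
]


@dataclass
class CoEditingNetwork:
    """Adjacency, TOM and per-node bookkeeping for a co-editing network."""

    nodes: list[str]
    beta: int
    corr: np.ndarray          # |Pearson r|, pairwise-complete
    adjacency: np.ndarray     # corr ** beta, unit diagonal
    tom: np.ndarray
    excluded: list[tuple[str, str]] = field(default_factory=list)
    modules: dict[str, str] = field(default_factory=dict)
    eigengenes: dict[str, np.ndarray] = field(default_factory=dict)

    def module_members(self, color: str) -> list[str]:
        return [n for n in self.nodes if self.modules.get(n) == color]

    def connectivity(self) -> np.ndarray:
        return self.adjacency.sum(axis=1) - 1.0


def _abs_corr(levels: pd.DataFrame, max_missing: float = 0.5,
              ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Pairwise-complete |Pearson r| over events; drop bad rows with a log."""
    excluded: list[tuple[str, str]] = []
    keep = []
    for eid, row in levels.iterrows():
        frac_missing = row.isna().mean()
        if frac_missing > max_missing:
            excluded.append((str(eid), "missing_fraction"))
        elif row.dropna().nunique() <= 1:
            excluded.append((str(eid), "constant"))
        else:
            keep.append(eid)
    sub = levels.loc[keep]
    corr = sub.T.corr(min_periods=3).abs()
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr, excluded


def scale_free_fit_table(levels: pd.DataFrame,
                         powers: range = range(1, 21),
                         n_bins: int = 10) -> pd.DataFrame:
    """Scale-free topology fit index per candidate soft power.

    For each beta, connectivities k_i are binned into ``n_bins`` equal-width
    bins; log10 frequency is regressed on log10 mean bin connectivity.  The
    signed fit is R^2 when the slope is negative (scale-free-like decay) and
    −R^2 otherwise.
    """
    corr, _exc = _abs_corr(levels)
    a_base = corr.to_numpy()
    rows = []
    for beta in powers:
        a = a_base ** beta
        k = a.sum(axis=1) - 1.0
        if np.ptp(k) <= 0:
            raise ValueError("degenerate connectivity: all nodes equal")
        edges = np.linspace(k.min(), k.max(), n_bins + 1)
        which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
        log_p, log_k = [], []
        for b in range(n_bins):
            mask = which == b
            if mask.sum() == 0 or k[mask].mean() <= 0:
                continue
            log_p.append(np.log10(mask.mean()))
            log_k.append(np.log10(k[mask].mean()))
        if len(log_k) >= 3 and np.ptp(log_k) > 0:
            fit = stats.linregress(log_k, log_p)
            rsq = fit.rvalue ** 2
            signed = rsq if fit.slope < 0 else -rsq
            slope = fit.slope
        else:
            signed, slope = np.nan, np.nan
        rows.append({"power": beta, "sft_rsq": signed, "slope": slope,
                     "mean_k": float(k.mean()),
                     "median_k": float(np.median(k)),
                     "max_k": float(k.max())})
    return pd.DataFrame(rows)


def pick_soft_threshold(levels: pd.DataFrame, powers: range = range(1, 21),
                        rsq_cut: float = 0.8,
                        ) -> tuple[int, pd.DataFrame]:
    """Smallest power reaching the scale-free fit cut, else the argmax.

    Returns (beta, fit table).  When no power reaches ``rsq_cut`` a warning
    is emitted and the best-fitting power is returned.
    """
    if len(levels) < 20:
        raise ValueError("need >= 20 events to assess scale-free fit")
    if levels.shape[1] < 8:
        raise ValueError("need >= 8 samples to assess scale-free fit")
    table = scale_free_fit_table(levels, powers=powers)
    ok = table[table["sft_rsq"] >= rsq_cut]
    if len(ok):
        return int(ok["power"].iloc[0]), table
    warnings.warn("no power reaches the scale-free fit threshold; "
                  "returning the best-fitting power")
    best = table["sft_rsq"].idxmax()
    return int(table.loc[best, "power"]), table


def build_network(levels: pd.DataFrame, beta: int) -> CoEditingNetwork:
    """Unsigned adjacency |r|^beta and topological overlap matrix."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    corr_df, excluded = _abs_corr(levels)
    nodes = list(corr_df.index)
    corr = corr_df.to_numpy()
    a = corr ** beta
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1.0
    # shared-neighbor sums: (A @ A)_ij counts u = i and u = j once each as
    # a_ij (unit diagonal), so subtract 2 a_ij off-diagonal
    num = a @ a - 2.0 * a + a                     # sum_{u!=i,j} + a_ij
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / denom, 1.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return CoEditingNetwork(nodes=nodes, beta=int(beta), corr=corr,
                            adjacency=a, tom=tom, excluded=excluded)


def detect_modules(network: CoEditingNetwork, min_size: int = 10,
                   cut_height: float = 0.9) -> dict[str, str]:
    """Average-linkage clustering of 1 − TOM with a static tree cut.

    ``cut_height`` is a fraction of the dendrogram's merge-height range:
    the tree is cut at h_min + cut_height * (h_max − h_min), which keeps
    the cut meaningful across soft powers (raising beta compresses all
    topological-overlap dissimilarities toward 1).  Clusters smaller than
    ``min_size`` fall into ``grey``; surviving modules are named by
    decreasing size with the conventional color sequence.  The result is
    stored on the network and returned.
    """
    if not 0.0 <= cut_height <= 1.0:
        raise ValueError("cut_height must lie in [0, 1]")
    diss = 1.0 - network.tom
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    z = linkage(condensed, method="average")
    heights = z[:, 2]
    t = float(heights.min()
              + cut_height * (heights.max() - heights.min()))
    raw = fcluster(z, t=t, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    ordered = [c for c in sizes.index if sizes[c] >= min_size]
    # deterministic order: size desc, then smallest member node id
    first_member = {c: min(n for n, r in zip(network.nodes, raw) if r == c)
                    for c in ordered}
    ordered.sort(key=lambda c: (-sizes[c], first_member[c]))
    if not ordered:
        warnings.warn("no module reaches min_size; all nodes grey")
    color_of = {c: MODULE_COLORS[i % len(MODULE_COLORS)]
                for i, c in enumerate(ordered)}
    network.modules = {n: color_of.get(r, "grey")
                       for n, r in zip(network.nodes, raw)}
    return network.modules


def module_eigengene(levels: pd.DataFrame, members: list[str]) -> np.ndarray:
    """First PC of the module's standardized samples x events matrix.

    Missing cells are mean-imputed per event.  The eigengene has unit norm
    and is sign-oriented so its correlation with the module's mean
    standardized profile is non-negative.
    """
    if len(members) < 2:
        raise ValueError("module eigengene needs >= 2 events")
    X = levels.loc[members].to_numpy(dtype=float).T     # samples x events
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X = X / sd
    u, s, _vt = np.linalg.svd(X, full_matrices=False)
    e = u[:, 0]
    profile = X.mean(axis=1)
    if np.dot(e, profile) < 0:
        e = -e
    return e / np.linalg.norm(e)


def compute_eigengenes(network: CoEditingNetwork,
                       levels: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for color in sorted(set(network.modules.values()) - {"grey"}):
        out[color] = module_eigengene(levels,
                                      network.module_members(color))
    network.eigengenes = out
    return out


def module_trait_correlation(eigengenes: Mapping[str, np.ndarray],
                             traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson R and two-sided p per module x trait; key module by group p.

    ``traits`` is samples x features and must include a ``group`` column
    coded control = 0, case = 1.  Constant traits are skipped.
    """
    rows = []
    for module in sorted(eigengenes):
        e = np.asarray(eigengenes[module], dtype=float)
        for trait in traits.columns:
            t = traits[trait].to_numpy(dtype=float)
            ok = ~np.isnan(t)
            if ok.sum() < 3 or np.std(t[ok]) == 0:
                continue
            r, p = stats.pearsonr(e[ok], t[ok])
            rows.append({"module": module, "trait": trait,
                         "R": float(r), "p": float(p), "n": int(ok.sum())})
    return pd.DataFrame(rows, columns=["module", "trait", "R", "p", "n"])


def key_module(module_trait: pd.DataFrame, trait: str = "group") -> str:
    sub = module_trait[module_trait["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no module-trait rows for trait {trait!r}")
    return str(sub.loc[sub["p"].idxmin(), "module"])


def hub_events(network: CoEditingNetwork, module: str, n: int = 10,
               edge_threshold: float = 0.4,
               dre: pd.DataFrame | None = None) -> pd.DataFrame:
    """Top-n intramodular nodes by degree centrality.

    Edges are the intramodular pairs whose |correlation| reaches
    ``edge_threshold`` (a correlation-scale cutoff, so the exported edge
    list does not depend on the soft power); degree is the incident-edge
    count.  Ties are broken by smaller differential-editing p (when ``dre``
    is given), then lexicographic event id.
    """
    members = network.module_members(module)
    if not members:
        raise ValueError(f"module {module!r} is empty or grey")
    idx = [network.nodes.index(m) for m in members]
    sub = network.corr[np.ix_(idx, idx)]
    edges = (sub >= edge_threshold)
    np.fill_diagonal(edges, False)
    if not edges.any():
        raise ValueError(
            f"edge threshold {edge_threshold} yields no edges in module "
            f"{module!r}; lower the threshold")
    degree = edges.sum(axis=1)
    pvals = {m: float(dre.loc[m, "p_glm"]) if dre is not None
             and m in dre.index else np.inf for m in members}
    order = sorted(range(len(members)),
                   key=lambda i: (-degree[i], pvals[members[i]], members[i]))
    top = order[:min(n, len(members))]
    return pd.DataFrame({
        "event_id": [members[i] for i in top],
        "degree": [int(degree[i]) for i in top],
        "module": module,
    })


def edge_list(network: CoEditingNetwork, module: str | None = None,
              edge_threshold: float = 0.4) -> pd.DataFrame:
    """Thresholded (node1, node2, weight) edge table, weight = |r|."""
    nodes = network.nodes if module is None else network.module_members(module)
    idx = [network.nodes.index(m) for m in nodes]
    sub = network.corr[np.ix_(idx, idx)]
    rows = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if sub[i, j] >= edge_threshold:
                rows.append({"node1": nodes[i], "node2": nodes[j],
                             "weight": round(float(sub[i, j]), 6)})
    return pd.DataFrame(rows, columns=["node1", "node2", "weight"])
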