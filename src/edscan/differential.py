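"""Differential editing between groups, consensus, DEGs, expression screen.

The core test is a binomial-family GLM with logit link fit per event on the
per-sample (edited, unedited) read-count pairs, with group as the sole
covariate, compared against the intercept-only model by likelihood-ratio
test (chi-square, 1 df).  With a single binary covariate the GLM maximum
likelihood has a closed form — the fitted group probabilities are the
group-pooled editing fractions — so the LRT statistic is computed exactly:

    stat = 2 * [ ll(E1,U1) + ll(E0,U0) - ll(E1+E0, U1+U0) ]
    ll(E,U) = E*log(E/(E+U)) + U*log(U/(E+U))        (0*log 0 = 0)

which is finite even at boundary (all-edited / all-unedited) groups, so
perfect separation needs no special-casing.  Significance is raw P < 0.05
(no multiplicity correction); a Benjamini–Hochberg column is reported
alongside.  A Gaussian-on-levels mode is available for sensitivity analysis.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calling import EditingMatrix, strand_counts
from .counts import SiteCountTable

__all__ = [
    "binomial_lrt", "gaussian_lrt", "dre_test", "consensus",
    "differentially_edited_genes", "de_expression_screen", "pca_editing",
]


def _binom_ll(e: float, u: float) -> float:
    """Profile binomial log-likelihood at the MLE p = e/(e+u)."""
    n = e + u
    if n == 0:
        return 0.0
    ll = 0.0
    if e > 0:
        ll += e * np.log(e / n)
    if u > 0:
        ll += u * np.log(u / n)
    return ll


def binomial_lrt(e_case: float, u_case: float,
                 e_ctrl: float, u_ctrl: float) -> tuple[float, float]:
    """LRT statistic and chi-square(1) p for group-pooled binomial counts."""
    stat = 2.0 * (_binom_ll(e_case, u_case) + _binom_ll(e_ctrl, u_ctrl)
                  - _binom_ll(e_case + e_ctrl, u_case + u_ctrl))
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df=1))


def gaussian_lrt(levels_case: np.ndarray,
                 levels_ctrl: np.ndarray) -> tuple[float, float]:
    """Gaussian-on-levels LRT (sensitivity mode): n*log(RSS0/RSS1), 1 df."""
    x = np.concatenate([levels_case, levels_ctrl])
    n = x.size
    rss0 = float(np.sum((x - x.mean()) ** 2))
    rss1 = float(np.sum((levels_case - levels_case.mean()) ** 2)
                 + np.sum((levels_ctrl - levels_ctrl.mean()) ** 2))
    if rss1 <= 0:
        stat = 0.0 if rss0 <= 0 else np.inf
    else:
        stat = max(n * np.log(rss0 / rss1), 0.0)
    return stat, float(stats.chi2.sf(stat, df=1))


def dre_test(matrix: EditingMatrix, counts: SiteCountTable,
             groups: Mapping[str, str], family: str = "binomial",
             min_depth: int = 10, alpha: float = 0.05) -> pd.DataFrame:
    """Per-event differential-editing test between case and control.

    A sample contributes to an event when its sequencing depth at the site
    reaches ``min_depth``; events with fewer than two usable samples in
    either group are flagged untestable (p is NaN there, never 1).

    Returns a frame indexed by event_id with the LRT statistic, p, BH q,
    per-group mean levels, delta = mean(case) − mean(control), per-group
    sample counts, the consequence category and a significance flag.
    """
    if family not in ("binomial", "gaussian"):
        raise ValueError(f"unknown GLM family {family!r}")
    samples = list(matrix.levels.columns)
    unknown = [s for s in samples if s not in groups]
    if unknown:
        raise ValueError(f"samples missing group labels: {unknown}")
    is_case = np.array([groups[s] == "case" for s in samples])
    edited, unedited = strand_counts(counts, matrix.events)
    levels = matrix.levels.to_numpy()

    rows = []
    for i, eid in enumerate(matrix.levels.index):
        usable = (edited[i] + unedited[i] >= 0) & ~np.isnan(levels[i])
        ca, ct = usable & is_case, usable & ~is_case
        n_case, n_ctrl = int(ca.sum()), int(ct.sum())
        mean_case = float(np.mean(levels[i][ca])) if n_case else np.nan
        mean_ctrl = float(np.mean(levels[i][ct])) if n_ctrl else np.nan
        row = {"event_id": eid,
               "gene_id": matrix.events["gene_id"].iloc[i],
               "consequence": matrix.events["consequence"].iloc[i],
               "mean_case": mean_case, "mean_control": mean_ctrl,
               "delta": mean_case - mean_ctrl,
               "n_case": n_case, "n_control": n_ctrl,
               "testable": n_case >= 2 and n_ctrl >= 2}
        if row["testable"]:
            if family == "binomial":
                stat, p = binomial_lrt(
                    float(edited[i][ca].sum()), float(unedited[i][ca].sum()),
                    float(edited[i][ct].sum()), float(unedited[i][ct].sum()))
            else:
                stat, p = gaussian_lrt(levels[i][ca], levels[i][ct])
            row["lrt_stat"], row["p_glm"] = stat, p
        else:
            row["lrt_stat"], row["p_glm"] = np.nan, np.nan
        rows.append(row)
    df = pd.DataFrame(rows).set_index("event_id")
    df["q_bh"] = np.nan
    testable = df["testable"].to_numpy()
    if testable.any():
        df.loc[testable, "q_bh"] = multipletests(
            df.loc[testable, "p_glm"], method="fdr_bh")[1]
    df["significant"] = df["p_glm"] < alpha
    return df


def consensus(dre_by_dataset: Mapping[str, pd.DataFrame], k: int,
              by: str = "event", require_same_sign: bool = False,
              alpha: float = 0.05) -> pd.DataFrame:
    """Events (or genes) significant in at least ``k`` datasets.

    Events are matched across datasets by (contig, pos) parsed from the
    event_id "GENE:contig:pos"; gene-level consensus counts a dataset when
    any event in the gene is significant there.  With ``require_same_sign``
    the delta sign must agree across the supporting datasets.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if by not in ("event", "gene"):
        raise ValueError(f"unknown consensus unit {by!r}")
    support: dict[str, dict[str, float]] = {}
    for ds, df in dre_by_dataset.items():
        sig = df[(df["p_glm"] < alpha) & df["testable"]]
        for eid, row in sig.iterrows():
            if by == "event":
                gene, contig, pos = str(eid).rsplit(":", 2)
                key = f"{contig}:{pos}"
            else:
                key = str(row["gene_id"])
            support.setdefault(key, {})
            if by == "event":
                support[key][ds] = float(np.sign(row["delta"]))
            else:
                support[key][ds] = 1.0
    rows = []
    for key, ds_map in sorted(support.items()):
        datasets = sorted(ds_map)
        if require_same_sign and by == "event":
            signs = {ds_map[d] for d in datasets}
            if len(signs) > 1:
                # keep the largest same-sign subset
                pos_ds = [d for d in datasets if ds_map[d] > 0]
                neg_ds = [d for d in datasets if ds_map[d] < 0]
                datasets = pos_ds if len(pos_ds) >= len(neg_ds) else neg_ds
        if len(datasets) >= k:
            rows.append({"key": key, "n_datasets": len(datasets),
                         "datasets": ",".join(datasets)})
    return pd.DataFrame(rows, columns=["key", "n_datasets", "datasets"])


def differentially_edited_genes(dre: pd.DataFrame,
                                alpha: float = 0.05) -> list[str]:
    """Genes containing at least one differential editing event (P < alpha)."""
    sig = dre[(dre["p_glm"] < alpha) & dre["testable"]]
    return sorted(sig["gene_id"].unique())


def de_expression_screen(expr: pd.DataFrame, groups: Mapping[str, str],
                         fdr_cut: float = 0.05, lfc_cut: float = 1.0,
                         ) -> pd.DataFrame:
    """Two-sample t-test differential-expression screen on log2(x+1).

    ``expr`` is genes x samples of non-negative expression values.  logFC is
    the mean log2 difference (case − control); genes pass when BH FDR <=
    ``fdr_cut`` and |logFC| >= ``lfc_cut`` (both thresholds inclusive).
    Genes with zero variance in both groups get p = 1 by convention.
    """
    samples = list(expr.columns)
    is_case = np.array([groups[s] == "case" for s in samples])
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    logx = np.log2(expr.to_numpy(dtype=float) + 1.0)
    case, ctrl = logx[:, is_case], logx[:, ~is_case]
    logfc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=True)
    zero_var = (case.std(axis=1) == 0) & (ctrl.std(axis=1) == 0)
    p = np.where(zero_var, 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({
        "gene": expr.index, "logFC": logfc, "t": tstat, "p": p, "fdr": q,
        "flag": (q <= fdr_cut) & (np.abs(logfc) >= lfc_cut),
    }).set_index("gene")
    return out


def pca_editing(matrix: EditingMatrix | pd.DataFrame,
                n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the editing matrix via column-centered SVD (prcomp-style).

    Missing cells are mean-imputed per event before centering.  Returns the
    per-sample scores (PC1, PC2, ...) and the explained-variance fractions.
    Scores are deterministic up to sign; the sign is fixed so each score
    vector's largest-magnitude entry is positive.
    """
    levels = matrix.levels if isinstance(matrix, EditingMatrix) else matrix
    if len(levels) < 2:
        raise ValueError("need >= 2 events for PCA")
    X = levels.to_numpy(dtype=float).T          # samples x events
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("degenerate PCA: editing matrix is constant")
    u, s, _vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, s.size)
    scores = u[:, :k] * s[:k]
    for j in range(k):                          # deterministic sign
        pivot = np.argmax(np.abs(scores[:, j]))
        if scores[pivot, j] < 0:
            scores[:, j] = -scores[:, j]
    var_frac = (s ** 2) / np.sum(s ** 2)
    cols = [f"PC{i+1}" for i in range(k)]
    return (pd.DataFrame(scores, index=levels.columns, columns=cols),
            var_frac[:k])
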