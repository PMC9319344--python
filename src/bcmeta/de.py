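"""Covariate-adjusted moderated differential expression on the merged matrix.

Per gene, a linear model with intercept, case/control group, and study
indicators is fit by least squares; gene-wise residual variances are shrunk
toward an empirical-Bayes prior estimated by method of moments on log s²
(the scaled-F hierarchical model), yielding a moderated t-statistic with
augmented degrees of freedom.  The group effect (a mean Z-score difference)
is additionally reported as a *corrected* log2 fold change: the effect
divided by the across-gene SD of all effects, which puts fold changes from
heterogeneous platforms on one comparable scale.  A grid of |corrected FC|
thresholds is scanned with a linear margin classifier to pick the cut that
maximizes held-out AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import LinearSVC
from statsmodels.stats.multitest import multipletests

from .harmonize import MergedMatrix

DEFAULT_FC_GRID = tuple(np.round(np.arange(1.0, 2.01, 0.1), 1))


@dataclass
class GroupModelFit:
    """Per-gene least-squares fit of effect ~ intercept + group + study."""

    genes: list[str]
    effect: np.ndarray  # group (case - control) coefficient per gene
    s2: np.ndarray  # residual variance per gene
    df_residual: float
    se_unit: float  # sqrt of the group entry of (X'X)^-1; SE = se_unit * s


@dataclass
class DEResult:
    table: pd.DataFrame  # gene-indexed: log2FC_raw, log2FC_corrected, t, p, p_adj, direction
    effect_sd: float  # the across-gene SD used to correct fold changes
    d0: float  # prior degrees of freedom of the variance model
    s0_sq: float  # prior variance


@dataclass
class ThresholdScan:
    table: pd.DataFrame  # threshold-indexed: n_features, auc, sensitivity, specificity
    selected_threshold: float
    features: dict[float, list[str]] = field(default_factory=dict)

    @property
    def selected_genes(self) -> list[str]:
        return self.features[self.selected_threshold]


def _design(merged: MergedMatrix) -> tuple[np.ndarray, list[str]]:
    group = merged.group
    studies = pd.get_dummies(merged.samples["study_id"], drop_first=True)
    cols = ["intercept", "group"] + [f"study[{c}]" for c in studies.columns]
    x = np.column_stack([np.ones(len(group)), group, studies.to_numpy(dtype=float)])
    return x, cols


def fit_group_model(merged: MergedMatrix) -> GroupModelFit:
    """Least-squares fit per gene; effect = case-vs-control group coefficient."""
    y = merged.values.to_numpy(dtype=float)  # genes x samples
    x, cols = _design(merged)
    n, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        aliased = []
        base_rank = 0
        for j in range(p):
            r = np.linalg.matrix_rank(x[:, : j + 1])
            if r == base_rank:
                aliased.append(cols[j])
            base_rank = r
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    group = merged.group
    if group.sum() < 2 or (1 - group).sum() < 2:
        raise ValueError("need at least 2 samples per phenotype group")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv.T  # genes x p
    resid = y - beta @ x.T
    df = n - p
    s2 = (resid**2).sum(axis=1) / df
    return GroupModelFit(
        genes=merged.genes,
        effect=beta[:, 1],
        s2=s2,
        df_residual=float(df),
        se_unit=float(np.sqrt(xtx_inv[1, 1])),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (d0, s0²) on log s².

    Under s² = s0² · F(df, d0): E[log s²] = log s0² + ψ(df/2) − log(df/2)
    − ψ(d0/2) + log(d0/2) and Var[log s²] = ψ′(df/2) + ψ′(d0/2).  If the
    observed variance of log s² does not exceed ψ′(df/2), the prior df is
    infinite and all variances shrink to a common value.
    """
    if len(s2) < 10:
        raise ValueError("need at least 10 genes to estimate the variance prior")
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        # no excess spread: the observed variances are taken as the common
        # value directly (geometric mean, no sampling-bias correction)
        d0 = np.inf
        s0_sq = float(np.exp(z.mean()))
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def moderate_statistics(
    fit: GroupModelFit, prior: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-statistics and two-sided p-values.

    ``prior`` overrides the estimated (d0, s0²); d0 = 0 recovers the ordinary
    t-statistic, d0 = inf fully shrinks every variance to s0².
    """
    if prior is None:
        d0, s0_sq = estimate_variance_prior(fit.s2, fit.df_residual)
    else:
        d0, s0_sq = prior
    df = fit.df_residual
    if np.isinf(d0):
        s2_post = np.full_like(fit.s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * fit.s2) / (d0 + df)
        df_total = d0 + df
    t = fit.effect / (fit.se_unit * np.sqrt(s2_post))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {"t": t, "p": p, "s2_post": s2_post, "d0": d0, "s0_sq": s0_sq},
        index=pd.Index(fit.genes, name="gene"),
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    return multipletests(p, method="fdr_bh")[1]


def corrected_log2fc(effects: np.ndarray) -> tuple[np.ndarray, float]:
    """Divide each gene's effect by the across-gene SD of all effects.

    One global scalar (n−1 denominator) for the whole matrix; makes the
    statistic invariant to a common rescaling of effects.
    """
    effects = np.asarray(effects, dtype=float)
    if len(effects) < 2:
        raise ValueError("need at least 2 genes")
    sd = float(np.std(effects, ddof=1))
    if sd == 0.0:
        raise ValueError("effect SD is zero; corrected fold change undefined")
    return effects / sd, sd


def differential_expression(merged: MergedMatrix) -> DEResult:
    """Full per-gene moderated DE analysis of a merged matrix."""
    fit = fit_group_model(merged)
    mod = moderate_statistics(fit)
    corrected, sd = corrected_log2fc(fit.effect)
    table = pd.DataFrame(
        {
            "log2FC_raw": fit.effect,
            "log2FC_corrected": corrected,
            "t": mod["t"].to_numpy(),
            "p": mod["p"].to_numpy(),
            "p_adj": bh_adjust(mod["p"].to_numpy()),
            "direction": np.where(fit.effect >= 0, "up", "down"),
        },
        index=pd.Index(fit.genes, name="gene"),
    )
    return DEResult(table, sd, float(mod["d0"].iloc[0]), float(mod["s0_sq"].iloc[0]))


def classify_auc(
    features: np.ndarray,
    labels: np.ndarray,
    scheme: str = "repeated_split",
    n_splits: int = 10,
    test_size: float = 0.1,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Held-out AUC / sensitivity / specificity of a linear margin classifier.

    ``scheme='repeated_split'`` (default) uses ``n_splits`` stratified 90:10
    train/test splits and averages the metrics; ``scheme='kfold'`` uses plain
    stratified 10-fold CV.  Sensitivity is recall on the case (positive)
    class at the zero decision threshold.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if scheme == "repeated_split":
        splitter = StratifiedShuffleSplit(
            n_splits=n_splits, test_size=test_size, random_state=seed
        )
    elif scheme == "kfold":
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    aucs, sens, spec = [], [], []
    for train, test in splitter.split(features, y):
        clf = LinearSVC(C=1.0)
        clf.fit(features[train], y[train])
        scores = clf.decision_function(features[test])
        y_test = y[test]
        if len(np.unique(y_test)) == 2:
            aucs.append(roc_auc_score(y_test, scores))
        pred = (scores > 0).astype(int)
        pos, neg = y_test == 1, y_test == 0
        if pos.any():
            sens.append(float((pred[pos] == 1).mean()))
        if neg.any():
            spec.append(float((pred[neg] == 0).mean()))
    return float(np.mean(aucs)), float(np.mean(sens)), float(np.mean(spec))


def select_deg_threshold(
    de: DEResult,
    merged: MergedMatrix,
    p_cut: float = 0.01,
    grid: tuple[float, ...] = DEFAULT_FC_GRID,
    scheme: str = "repeated_split",
    seed: int = 0,
) -> ThresholdScan:
    """Scan |corrected log2FC| thresholds; pick the AUC-maximizing cut.

    Features at threshold τ are genes with p_adj < p_cut and
    |log2FC_corrected| ≥ τ.  Ties in AUC break toward the smaller τ (the more
    inclusive gene set); thresholds with zero features are recorded with
    undefined AUC and excluded from the argmax.
    """
    if not len(grid):
        raise ValueError("empty threshold grid")
    tab = de.table
    y = merged.group
    rows, features = [], {}
    for tau in grid:
        sel = tab[(tab["p_adj"] < p_cut) & (tab["log2FC_corrected"].abs() >= tau)]
        genes = list(sel.index)
        features[float(tau)] = genes
        if not genes:
            warnings.warn(f"no features at threshold {tau}", stacklevel=2)
            rows.append((tau, 0, np.nan, np.nan, np.nan))
            continue
        x = merged.values.loc[genes].to_numpy(dtype=float).T
        auc, sens, spec = classify_auc(x, y, scheme=scheme, seed=seed)
        rows.append((tau, len(genes), auc, sens, spec))
    table = pd.DataFrame(
        rows, columns=["threshold", "n_features", "auc", "sensitivity", "specificity"]
    ).set_index("threshold")
    valid = table.dropna(subset=["auc"])
    if valid.empty:
        raise ValueError("no threshold produced a non-empty feature set")
    best = valid["auc"].max()
    selected = float(valid.index[valid["auc"] >= best - 1e-12][0])
    return ThresholdScan(table, selected, features)
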