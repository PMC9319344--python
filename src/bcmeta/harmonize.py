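"""Study harmonization: QC, probe collapse, Z-scoring, merging, batch adjustment.

The harmonization contract is the classic early-integration recipe for
cross-platform microarray meta-analysis: collapse probes to gene symbols,
flag outlying arrays on three complementary quality metrics, standardize each
sample over its genes (the per-sample Z-score), intersect gene panels across
studies into one merged matrix carrying the study of origin as a covariate,
and — where a stage needs batch-free values — adjust known batches with a
parametric empirical-Bayes location/scale model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from sklearn.decomposition import PCA

QC_METRICS = ("distance", "distribution", "ma")


@dataclass
class ExpressionStudy:
    """One study's gene × sample log2 expression matrix with phenotype labels."""

    study_id: str
    values: pd.DataFrame  # genes x samples
    phenotype: pd.Series  # sample -> {"case", "control"}

    def __post_init__(self) -> None:
        self.values.index.name = "gene"
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError(f"{self.study_id}: non-finite expression values")
        if self.values.index.has_duplicates:
            raise ValueError(f"{self.study_id}: duplicate gene identifiers")
        missing = set(self.values.columns) - set(self.phenotype.index)
        if missing:
            raise ValueError(f"{self.study_id}: samples without phenotype: {missing}")
        bad = set(self.phenotype.loc[list(self.values.columns)]) - {"case", "control"}
        if bad:
            raise ValueError(f"{self.study_id}: unknown phenotype labels {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples: list[str]) -> "ExpressionStudy":
        return ExpressionStudy(
            self.study_id, self.values[samples].copy(), self.phenotype.loc[samples]
        )


@dataclass
class QCReport:
    """Per-sample quality metrics, per-metric flags, and the ≥2-of-3 decision."""

    metrics: pd.DataFrame  # samples x QC_METRICS
    flags: pd.DataFrame  # samples x QC_METRICS, boolean
    outliers: pd.Series  # boolean, flagged on >= 2 metrics
    skipped: bool = False


@dataclass
class MergedMatrix:
    """Z-scored, gene-intersected multi-study matrix with per-sample covariates."""

    values: pd.DataFrame  # common genes x all samples
    samples: pd.DataFrame  # index = sample, columns = study_id, phenotype

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def group(self) -> np.ndarray:
        """Case indicator (1 = case) aligned to the sample columns."""
        return (self.samples["phenotype"] == "case").to_numpy().astype(float)


def collapse_probes(
    probe_matrix: pd.DataFrame, probe_to_gene: dict[str, list[str]]
) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    Probes mapping to exactly one gene are kept; a gene's row is the
    arithmetic mean of its probes' rows.  Probes with zero or multiple gene
    annotations are excluded.
    """
    keep, gene_of = [], []
    for probe in probe_matrix.index:
        genes = probe_to_gene.get(probe, [])
        if isinstance(genes, str):
            genes = [genes]
        if len(genes) == 1:
            keep.append(probe)
            gene_of.append(genes[0])
    if not keep:
        raise ValueError("no probe maps uniquely to a gene; nothing to collapse")
    sub = probe_matrix.loc[keep]
    return sub.groupby(pd.Index(gene_of, name="gene")).mean()


def qc_outlier_flags(study: ExpressionStudy) -> QCReport:
    """Flag outlying arrays on three quality metrics; outlier = ≥2 flags.

    Metrics per sample: mean Euclidean distance to all other samples; the
    Kolmogorov–Smirnov statistic of the sample's value distribution versus the
    pooled distribution of the remaining samples; and the mean |M| of the
    sample against the gene-wise median pseudo-reference.  Each metric flags
    values above the Tukey upper fence (Q3 + 1.5·IQR) across samples.
    """
    x = study.values.to_numpy(dtype=float)
    samples = study.samples
    n = len(samples)
    if n < 4:
        warnings.warn(
            f"{study.study_id}: fewer than 4 samples, QC skipped", stacklevel=2
        )
        empty = pd.DataFrame(
            np.nan, index=samples, columns=list(QC_METRICS)
        )
        flags = pd.DataFrame(False, index=samples, columns=list(QC_METRICS))
        return QCReport(empty, flags, pd.Series(False, index=samples), skipped=True)

    diff = x.T[:, None, :] - x.T[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    m_distance = dist.sum(axis=1) / (n - 1)

    m_distribution = np.empty(n)
    for j in range(n):
        pooled = np.delete(x, j, axis=1).ravel()
        m_distribution[j] = ks_2samp(x[:, j], pooled).statistic

    reference = np.median(x, axis=1)
    m_ma = np.abs(x - reference[:, None]).mean(axis=0)

    metrics = pd.DataFrame(
        {"distance": m_distance, "distribution": m_distribution, "ma": m_ma},
        index=samples,
    )
    q1 = metrics.quantile(0.25)
    q3 = metrics.quantile(0.75)
    fence = q3 + 1.5 * (q3 - q1)
    flags = metrics.gt(fence, axis=1)
    outliers = flags.sum(axis=1) >= 2
    return QCReport(metrics, flags, outliers)


def zscore_transform(study: ExpressionStudy) -> ExpressionStudy:
    """Standardize each sample over its genes (subtract mean, divide by SD).

    The SD uses the n−1 denominator.  A zero-SD sample is an error.
    """
    x = study.values
    sd = x.std(axis=0, ddof=1)
    zero = sd[sd <= 0.0]
    if len(zero):
        raise ValueError(
            f"{study.study_id}: zero-SD sample(s): {list(zero.index)}"
        )
    z = (x - x.mean(axis=0)) / sd
    return ExpressionStudy(study.study_id, z, study.phenotype.copy())


def merge_studies(studies: list[ExpressionStudy]) -> MergedMatrix:
    """Concatenate Z-scored studies over their common gene set.

    Columns are re-standardized over the intersected genes so each merged
    sample has mean 0 and SD 1 exactly; every sample carries its study of
    origin as a covariate.
    """
    if not studies:
        raise ValueError("no studies to merge")
    common = set(studies[0].genes)
    for st in studies[1:]:
        common &= set(st.genes)
    if not common:
        sizes = {st.study_id: len(st.genes) for st in studies}
        raise ValueError(f"empty gene intersection across studies; panels: {sizes}")
    genes = [g for g in studies[0].genes if g in common]

    blocks, meta = [], []
    for st in studies:
        sub = st.values.loc[genes]
        sub = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
        blocks.append(sub)
        for s in st.samples:
            meta.append((s, st.study_id, st.phenotype.loc[s]))
    values = pd.concat(blocks, axis=1)
    samples = pd.DataFrame(
        meta, columns=["sample", "study_id", "phenotype"]
    ).set_index("sample")
    if samples.index.has_duplicates:
        raise ValueError("duplicate sample identifiers across studies")
    return MergedMatrix(values, samples)


def batch_adjust(matrix: pd.DataFrame, batch_labels: pd.Series) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale adjustment for known batches.

    Implements the classic two-moment model: genes are standardized against a
    grand-mean fit, per-batch location (gamma) and scale (delta²) effects are
    estimated gene-wise and shrunk toward across-gene normal / inverse-gamma
    priors by iterated EB updates, and the data are back-transformed.  With a
    single batch the input is returned unchanged.

    ``matrix`` is genes × samples; ``batch_labels`` maps sample → batch.
    """
    batch = pd.Series(batch_labels).loc[list(matrix.columns)]
    levels = list(pd.unique(batch))
    counts = batch.value_counts()
    single = counts[counts < 2]
    if len(single):
        raise ValueError(f"singleton batch(es): {list(single.index)}")
    if len(levels) == 1:
        return matrix.copy()

    x = matrix.to_numpy(dtype=float)
    n_genes, _ = x.shape
    groups = [np.flatnonzero((batch == b).to_numpy()) for b in levels]
    n_b = np.array([len(g) for g in groups], dtype=float)
    n_total = n_b.sum()

    # grand mean per gene weighted by batch size, and pooled variance
    batch_means = np.stack([x[:, g].mean(axis=1) for g in groups], axis=1)
    grand = batch_means @ (n_b / n_total)
    var_pooled = ((x - grand[:, None]) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    s = np.sqrt(var_pooled)
    z = (x - grand[:, None]) / s[:, None]

    x_adj = np.empty_like(z)
    for g_idx, nb in zip(groups, n_b):
        zb = z[:, g_idx]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        delta_hat = np.maximum(delta_hat, 1e-12)

        # hyperpriors across genes (method of moments)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        d_mean = delta_hat.mean()
        d_var = delta_hat.var(ddof=1)
        lam = (2.0 * d_var + d_mean**2) / max(d_var, 1e-12)
        theta = (d_mean**3 + d_mean * d_var) / max(d_var, 1e-12)

        gamma_star, delta_star = gamma_hat.copy(), delta_hat.copy()
        for _ in range(100):
            g_new = (nb * tau2 * gamma_hat + delta_star * gamma_bar) / (
                nb * tau2 + delta_star
            )
            ssq = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta + 0.5 * ssq) / (nb / 2.0 + lam - 1.0)
            if (
                np.abs(g_new - gamma_star).max() < 1e-8
                and np.abs(d_new - delta_star).max() < 1e-8
            ):
                gamma_star, delta_star = g_new, d_new
                break
            gamma_star, delta_star = g_new, d_new

        x_adj[:, g_idx] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = x_adj * s[:, None] + grand[:, None]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class PCAEmbedding:
    scores: pd.DataFrame  # samples x components
    variance_fractions: np.ndarray = field(default_factory=lambda: np.array([]))


def pca_embedding(matrix: pd.DataFrame, n_components: int = 2) -> PCAEmbedding:
    """Centered principal-component scores of the samples (genes × samples in)."""
    n_max = min(matrix.shape)
    if n_components > n_max:
        raise ValueError(f"n_components={n_components} exceeds min(genes, samples)={n_max}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix.to_numpy(dtype=float).T)
    return PCAEmbedding(
        pd.DataFrame(
            scores,
            index=matrix.columns,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        pca.explained_variance_ratio_,
    )
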