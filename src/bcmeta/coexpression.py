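"""Consensus weighted co-expression modules across studies.

Per dataset, an unsigned weighted network a_ij = |cor(x_i, x_j)|^β is built
at a soft power β chosen for approximate scale-free topology, and converted
to a topological overlap matrix (TOM).  Per-dataset TOMs are quantile-scaled
to a common 95th percentile and combined by an elementwise minimum — the
consensus TOM — which is clustered (average linkage on 1 − TOM) into modules.
Module–trait relationships are summarized across datasets by a conservative
sign-consistency rule (signed minimum absolute correlation when all datasets
agree in sign, zero otherwise), and per-gene module membership (MM) and gene
significance (GS) correlations are combined into Stouffer meta-Z scores with
√n weights.  Module hubs are genes whose MM and GS meta-Z both fall in the
same outer quartile of their module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)
GREY = "grey"


@dataclass
class SoftThresholdScan:
    table: pd.DataFrame  # power-indexed: fit_index, slope, median_k
    power: int | None


@dataclass
class ModulePartition:
    labels: pd.Series  # gene -> color (GREY = unassigned)
    eigengenes: list[dict[str, pd.Series]]  # per dataset: color -> sample ME

    def module_genes(self, color: str) -> list[str]:
        return list(self.labels.index[self.labels == color])

    @property
    def colors(self) -> list[str]:
        return [c for c in pd.unique(self.labels) if c != GREY]


@dataclass
class GeneModuleStats:
    table: pd.DataFrame  # gene-indexed: module, mm_meta_z, gs_meta_z, hub


def _abs_cor_adjacency(data: pd.DataFrame, power: float) -> np.ndarray:
    """Unsigned adjacency |cor|^power over gene rows, zero diagonal."""
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(data.to_numpy(dtype=float))
    cor = np.nan_to_num(cor, nan=0.0)
    a = np.abs(cor) ** power
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index of a connectivity vector.

    Connectivities are binned (equal width), log10 of the bin frequency is
    regressed on log10 of the bin-mean connectivity; returns
    (−sign(slope)·R², slope) so positive values require a decreasing tail.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    dk, p = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() > 0:
            dk.append(k[sel].mean())
            p.append(sel.mean())
    if len(dk) < 3:
        return 0.0, 0.0
    lx, ly = np.log10(dk), np.log10(p)
    slope, intercept = np.polyfit(lx, ly, 1)
    fitted = slope * lx + intercept
    ss_res = ((ly - fitted) ** 2).sum()
    ss_tot = ((ly - ly.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), float(slope)


def pick_soft_threshold(
    data: pd.DataFrame,
    powers: tuple[int, ...] = tuple(range(1, 21)),
    r2_min: float = 0.77,
    median_k_max: float = 30.0,
    min_samples: int = 20,
    median_k_min: float = 1.0,
) -> SoftThresholdScan:
    """Smallest power with scale-free fit ≥ r2_min and median connectivity
    below median_k_max.  ``data`` is genes × samples with > min_samples
    samples (smaller datasets are too noisy for network topology).

    ``median_k_min`` guards against the degenerate regime where raising the
    power collapses connectivity toward zero: there the log-log fit becomes
    spuriously linear on pure noise, so powers whose median connectivity
    falls below this floor never qualify.
    """
    if data.shape[1] <= min_samples:
        raise ValueError(
            f"dataset has {data.shape[1]} samples; need more than {min_samples}"
        )
    rows = []
    chosen = None
    base = _abs_cor_adjacency(data, 1.0)
    for power in powers:
        a = base**power
        k = a.sum(axis=1)
        fit, slope = scale_free_fit(k)
        med_k = float(np.median(k))
        rows.append((power, fit, slope, med_k))
        if (chosen is None and fit >= r2_min
                and median_k_min <= med_k < median_k_max):
            chosen = int(power)
    table = pd.DataFrame(
        rows, columns=["power", "fit_index", "slope", "median_k"]
    ).set_index("power")
    if chosen is None:
        raise ValueError(
            "no power satisfies the scale-free topology criteria; scan table:\n"
            + table.to_string()
        )
    return SoftThresholdScan(table, chosen)


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij).

    Requires a symmetric adjacency in [0, 1] with zero diagonal; the TOM
    diagonal is set to 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.abs(np.diag(a)).max() > 1e-10:
        raise ValueError("adjacency diagonal must be zero")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    num = a @ a + a
    den = np.minimum.outer(k, k) + 1.0 - a
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return tom


def module_eigengene(data: pd.DataFrame, module_genes: list[str]) -> pd.Series:
    """First principal component of the module's standardized expression,
    sign-oriented so its correlation with the module mean profile is ≥ 0."""
    if not module_genes:
        raise ValueError("empty module")
    x = data.loc[module_genes].to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    if len(module_genes) == 1:
        me = z[0]
    else:
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(me, mean_profile) < 0:
        me = -me
    return pd.Series(me, index=data.columns)


def _consensus_tom(datasets: list[pd.DataFrame], power: float) -> np.ndarray:
    toms = []
    for d in datasets:
        tom = tom_similarity(_abs_cor_adjacency(d, power))
        toms.append(tom)
    tri = np.triu_indices_from(toms[0], k=1)
    q_ref = np.quantile(toms[0][tri], 0.95)
    scaled = []
    for tom in toms:
        q = np.quantile(tom[tri], 0.95)
        if 0.0 < q < 1.0 and 0.0 < q_ref < 1.0:
            tom = tom ** (np.log(q_ref) / np.log(q))
        scaled.append(tom)
    return np.minimum.reduce(scaled)


def detect_consensus_modules(
    datasets: list[pd.DataFrame],
    power: float = 7,
    min_size: int = 30,
    merge_height: float = 0.25,
    cut_height_quantile: float = 0.5,
    reassign_kme_min: float = 0.5,
) -> ModulePartition:
    """Consensus modules: min-scaled TOM, average-linkage tree, height cut.

    All datasets must share the gene universe (rows).  The tree is cut at the
    ``cut_height_quantile`` of its merge heights; clusters below ``min_size``
    fall to grey; modules whose consensus eigengenes correlate above
    1 − merge_height (minimum across datasets) are merged.  With a single
    dataset the same procedure runs on its own TOM (with a warning).
    """
    genes = list(datasets[0].index)
    for d in datasets[1:]:
        if list(d.index) != genes:
            raise ValueError("datasets must share an identical gene universe")
    if len(datasets) < 2:
        warnings.warn(
            "single dataset: consensus reduces to one-dataset modules",
            stacklevel=2,
        )
    consensus = _consensus_tom(datasets, power)
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    height = np.quantile(z[:, 2], cut_height_quantile)
    raw = fcluster(z, t=height, criterion="distance")

    # proto-modules: every raw cluster with >= 3 genes participates in the
    # eigengene merge step; the minimum-size rule applies only afterwards, so
    # an over-split module is reassembled instead of falling to grey
    labels = pd.Series(0, index=pd.Index(genes, name="gene"))
    next_id = 1
    for cid in np.unique(raw):
        members = np.flatnonzero(raw == cid)
        if len(members) >= 3:
            labels.iloc[members] = next_id
            next_id += 1

    labels = _merge_similar_modules(labels, datasets, merge_height)
    for mid in np.unique(labels):
        if mid != 0 and (labels == mid).sum() < min_size:
            labels[labels == mid] = 0
    labels = _reassign_by_kme(labels, datasets, kme_min=reassign_kme_min)

    # color names by decreasing module size
    sizes = labels[labels > 0].value_counts()
    color_of = {0: GREY}
    for rank, mid in enumerate(sizes.index):
        color_of[mid] = (
            MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        )
    colored = labels.map(color_of)
    eigengenes = [
        {
            color_of[mid]: module_eigengene(d, list(labels.index[labels == mid]))
            for mid in sizes.index
        }
        for d in datasets
    ]
    return ModulePartition(colored, eigengenes)


def _merge_similar_modules(
    labels: pd.Series, datasets: list[pd.DataFrame], merge_height: float
) -> pd.Series:
    """Iteratively merge module pairs whose consensus (minimum across
    datasets) eigengene correlation exceeds 1 − merge_height."""
    labels = labels.copy()
    threshold = 1.0 - merge_height

    def me_of(mid: int) -> list[np.ndarray]:
        members = list(labels.index[labels == mid])
        return [module_eigengene(d, members).to_numpy() for d in datasets]

    mes = {int(m): me_of(int(m)) for m in np.unique(labels) if m != 0}
    while True:
        ids = sorted(mes)
        best, best_cor = None, threshold
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                c = min(
                    float(np.corrcoef(x, y)[0, 1])
                    for x, y in zip(mes[a], mes[b])
                )
                if c > best_cor:
                    best, best_cor = (a, b), c
        if best is None:
            return labels
        a, b = best
        labels[labels == b] = a
        del mes[b]
        mes[a] = me_of(a)


def _reassign_by_kme(
    labels: pd.Series, datasets: list[pd.DataFrame], kme_min: float
) -> pd.Series:
    """Assign grey genes to the module whose eigengene they track.

    A grey gene joins the module with the highest consensus eigengene
    correlation (sign-consistent minimum across datasets) when that
    consensus reaches ``kme_min``; otherwise it stays grey.
    """
    mods = [int(m) for m in np.unique(labels) if m != 0]
    grey_idx = np.flatnonzero((labels == 0).to_numpy())
    if not mods or not len(grey_idx):
        return labels
    labels = labels.copy()
    kmes = []  # per module: consensus correlation of every gene with its ME
    for mid in mods:
        per_dataset = []
        for d in datasets:
            me = module_eigengene(d, list(labels.index[labels == mid]))
            x = d.to_numpy(dtype=float)
            xc = x - x.mean(axis=1, keepdims=True)
            xs = x.std(axis=1, ddof=0)
            xs[xs == 0] = 1.0
            mc = me.to_numpy() - me.to_numpy().mean()
            r = (xc @ mc) / (x.shape[1] * xs * me.std(ddof=0))
            per_dataset.append(r)
        per_dataset = np.stack(per_dataset)
        agree = (per_dataset >= 0).all(axis=0) | (per_dataset <= 0).all(axis=0)
        idx_min = np.argmin(np.abs(per_dataset), axis=0)
        consensus = per_dataset[idx_min, np.arange(per_dataset.shape[1])]
        kmes.append(np.where(agree, np.abs(consensus), 0.0))
    kmes = np.stack(kmes)  # modules x genes
    best = kmes[:, grey_idx].argmax(axis=0)
    best_val = kmes[:, grey_idx].max(axis=0)
    for pos, mod_i, val in zip(grey_idx, best, best_val):
        if val >= kme_min:
            labels.iloc[pos] = mods[mod_i]
    return labels


def consensus_module_trait(
    per_dataset_cor: np.ndarray, per_dataset_p: np.ndarray
) -> tuple[float, float]:
    """Sign-consistency consensus of module–trait correlations.

    If every dataset's correlation shares one sign, the consensus is the
    signed minimum absolute correlation with the maximum p-value; any sign
    disagreement yields consensus 0 (p = 1).
    """
    cor = np.asarray(per_dataset_cor, dtype=float)
    p = np.asarray(per_dataset_p, dtype=float)
    if len(cor) == 0:
        raise ValueError("need at least one dataset")
    if (cor >= 0).all() or (cor <= 0).all():
        i = int(np.argmin(np.abs(cor)))
        return float(cor[i]), float(p.max())
    return 0.0, 1.0


def module_trait_table(
    partition: ModulePartition, traits: list[np.ndarray]
) -> pd.DataFrame:
    """Per-module consensus correlation with a binary trait (case=1/control=0).

    ``traits`` aligns with ``partition.eigengenes`` (one vector per dataset).
    """
    rows = []
    for color in partition.colors:
        cors, ps = [], []
        for me_map, trait in zip(partition.eigengenes, traits):
            me = me_map[color].to_numpy()
            t = np.asarray(trait, dtype=float)
            r = float(np.corrcoef(me, t)[0, 1])
            n = len(t)
            z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)) * np.sqrt(n - 3)
            ps.append(2.0 * norm.sf(abs(z)))
            cors.append(r)
        c, p = consensus_module_trait(np.array(cors), np.array(ps))
        rows.append((color, c, p))
    return pd.DataFrame(
        rows, columns=["module", "consensus_cor", "consensus_p"]
    ).set_index("module")


def fisher_meta_z(correlations: list[float], sizes: list[int]) -> tuple[float, float]:
    """Stouffer meta-Z of Fisher-transformed correlations with √n weights.

    Per dataset Z = arctanh(r)·√(n−3); meta-Z = Σ w Z / √(Σ w²), w = √n.
    Datasets with n ≤ 3 are skipped with a warning.
    """
    zs, ws = [], []
    for r, n in zip(correlations, sizes):
        if n <= 3:
            warnings.warn(f"dataset with n={n} skipped in meta-Z", stacklevel=2)
            continue
        z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)) * np.sqrt(n - 3)
        zs.append(z)
        ws.append(np.sqrt(n))
    if not zs:
        raise ValueError("no dataset with n > 3")
    zs, ws = np.array(zs), np.array(ws)
    meta = float((ws * zs).sum() / np.sqrt((ws**2).sum()))
    return meta, float(2.0 * norm.sf(abs(meta)))


def gene_trait_meta_z(
    datasets: list[pd.DataFrame],
    traits: list[np.ndarray],
    partition: ModulePartition,
) -> GeneModuleStats:
    """Per-gene MM and GS meta-Z scores plus quartile hub flags."""
    genes = list(datasets[0].index)
    sizes = [d.shape[1] for d in datasets]
    mm = np.zeros(len(genes))
    gs = np.zeros(len(genes))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for color in partition.colors:
        members = partition.module_genes(color)
        mm_cors = {g: [] for g in members}
        gs_cors = {g: [] for g in members}
        for d, trait, me_map in zip(datasets, traits, partition.eigengenes):
            me = me_map[color].to_numpy()
            t = np.asarray(trait, dtype=float)
            x = d.loc[members].to_numpy(dtype=float)
            xc = x - x.mean(axis=1, keepdims=True)
            xs = x.std(axis=1, ddof=0)
            xs[xs == 0] = 1.0
            me_c = me - me.mean()
            t_c = t - t.mean()
            mm_r = (xc @ me_c) / (len(me) * xs * me.std(ddof=0))
            t_sd = t_c.std(ddof=0) if t_c.std(ddof=0) > 0 else 1.0
            gs_r = (xc @ t_c) / (len(t) * xs * t_sd)
            for g, r1, r2 in zip(members, mm_r, gs_r):
                mm_cors[g].append(float(r1))
                gs_cors[g].append(float(r2))
        for g in members:
            mm[gene_pos[g]] = fisher_meta_z(mm_cors[g], sizes)[0]
            gs[gene_pos[g]] = fisher_meta_z(gs_cors[g], sizes)[0]
    table = pd.DataFrame(
        {"module": partition.labels.to_numpy(), "mm_meta_z": mm, "gs_meta_z": gs},
        index=pd.Index(genes, name="gene"),
    )
    table["hub"] = _quartile_hub_flags(table)
    return GeneModuleStats(table)


def _quartile_hub_flags(table: pd.DataFrame) -> pd.Series:
    hub = pd.Series(False, index=table.index)
    for color, sub in table.groupby("module"):
        if color == GREY:
            continue
        mm_lo, mm_hi = sub["mm_meta_z"].quantile([0.25, 0.75])
        gs_lo, gs_hi = sub["gs_meta_z"].quantile([0.25, 0.75])
        upper = (sub["mm_meta_z"] >= mm_hi) & (sub["gs_meta_z"] >= gs_hi)
        lower = (sub["mm_meta_z"] <= mm_lo) & (sub["gs_meta_z"] <= gs_lo)
        hub.loc[sub.index] = upper | lower
    return hub


def select_module_hubs(stats: GeneModuleStats) -> dict[str, list[str]]:
    """Hub genes per module: MM and GS meta-Z both in the same outer quartile."""
    out: dict[str, list[str]] = {}
    t = stats.table
    for color, sub in t[t["module"] != GREY].groupby("module"):
        out[str(color)] = list(sub.index[sub["hub"]])
    return out


def key_hub_genes(
    ppi_hubs: list[str],
    module_hubs: dict[str, list[str]],
    key_modules: list[str],
) -> dict[str, list[str]]:
    """Per key module, the module hubs that are also PPI hubs."""
    ppi = set(ppi_hubs)
    return {
        color: [g for g in module_hubs.get(color, []) if g in ppi]
        for color in key_modules
    }
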