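import numpy as np
import pandas as pd
import pytest

from bcmeta import synthetic as syn
from bcmeta.harmonize import MergedMatrix, merge_studies, zscore_transform


def null_sim_config(seed: int, n_genes: int = 200) -> syn.SimConfig:
    """Pure-noise generator: no differential genes, no modules, full overlap."""
    return syn.SimConfig(
        seed=seed,
        n_studies=2,
        samples_per_study=[(10, 10), (10, 10)],
        n_genes=n_genes,
        de_fraction=0.0,
        effect_size_log2=0.0,
        n_modules=0,
        module_gene_fraction=0.0,
        module_trait_cor=0.0,
        panel_overlap_fraction=1.0,
    )


@pytest.fixture
def small_collection():
    cfg = syn.SimConfig(seed=11, n_genes=300)
    studies, truth = syn.simulate_study_collection(cfg)
    return studies, truth


@pytest.fixture
def merged_small(small_collection):
    studies, truth = small_collection
    merged = merge_studies([zscore_transform(s) for s in studies])
    return merged, truth


def make_merged(
    n_genes: int = 100,
    n_per_group: int = 20,
    n_studies: int = 2,
    effect: float = 0.0,
    study_offsets=None,
    seed: int = 0,
) -> MergedMatrix:
    """Direct MergedMatrix construction (no z-scoring) with a planted group
    effect on the first half of the genes and optional per-study offsets."""
    rng = np.random.default_rng(seed)
    blocks, meta = [], []
    genes = [f"g{i}" for i in range(n_genes)]
    for s in range(n_studies):
        n = 2 * n_per_group
        x = rng.normal(size=(n_genes, n))
        case = np.r_[np.ones(n_per_group), np.zeros(n_per_group)]
        x[: n_genes // 2] += effect * case[None, :]
        if study_offsets is not None:
            x += study_offsets[s]
        cols = [f"s{s}_{j}" for j in range(n)]
        blocks.append(pd.DataFrame(x, index=genes, columns=cols))
        meta += [
            (c, f"study{s}", "case" if case[j] else "control")
            for j, c in enumerate(cols)
        ]
    values = pd.concat(blocks, axis=1)
    samples = pd.DataFrame(
        meta, columns=["sample", "study_id", "phenotype"]
    ).set_index("sample")
    return MergedMatrix(values, samples)
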