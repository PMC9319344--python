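"""Synthetic cohort, graph and survival generators with known ground truth.

Every generator draws from a child stream of one master seed via
``numpy.random.SeedSequence(seed, spawn_key=(slot,))`` with a fixed slot per
generator, so adding a new generator never perturbs existing outputs and a
fixed ``SimConfig`` + seed reproduces byte-identical data.

The expression model is Gaussian on the log2 scale (microarray convention):

    x[g, j] = mu_g + loading_g * F[m(g), j] + s_g * delta * case_j
              + gamma[study, g] + d[study, g] * eps[g, j]

with latent module factors ``F`` optionally correlated with the phenotype,
a signed planted shift ``delta`` on differential genes (cases only), and a
per-study location/scale batch effect matching the model the empirical-Bayes
batch adjuster assumes (additive shift ``gamma``, multiplicative error scale
``d``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .harmonize import ExpressionStudy
from .survival import SurvivalCohort

# fixed child-seed slots (counter-based fan-out; append only, never reorder)
_SLOT_STUDIES = 0
_SLOT_SURVIVAL = 1
_SLOT_PHENOTYPE = 2
_SLOT_GRAPH = 3


def _rng(seed: int, slot: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(slot,)))


@dataclass
class SurvivalSimConfig:
    """Planted-hazard survival cohort settings."""

    n_patients: int = 300
    n_genes: int = 61
    baseline_hazard: float = 0.1
    log_hr: dict[str, float] = field(
        default_factory=lambda: {"G0001": 0.7, "G0002": -0.7, "G0003": 0.7}
    )
    censoring_rate: float = 0.3


@dataclass
class ResponseSimConfig:
    """Proportional-odds therapy-response cohort settings."""

    n_patients: int = 120
    n_genes: int = 61
    coefficients: dict[str, float] = field(default_factory=lambda: {"G0001": 1.0})
    base_rates: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)


@dataclass
class FluidSimConfig:
    """Small biofluid case/control cohort settings."""

    n_case: int = 15
    n_control: int = 15
    n_genes: int = 61
    shifted_genes: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0


@dataclass
class GraphSimConfig:
    """Erdős–Rényi background with planted dense cliques and optional hub."""

    n_nodes: int = 300
    edge_prob: float = 0.01
    clique_sizes: tuple[int, ...] = (9,)
    hub_fraction: float = 0.0  # wire one hub node to this fraction of all nodes


@dataclass
class SimConfig:
    """Study-collection generator settings; defaults are the study conditions."""

    n_studies: int = 3
    samples_per_study: list[tuple[int, int]] = field(
        default_factory=lambda: [(30, 30), (30, 30), (30, 30)]
    )
    n_genes: int = 1000
    panel_overlap_fraction: float = 0.8
    de_fraction: float = 0.05
    effect_size_log2: float = 1.5
    batch_shift_sd: float = 0.5
    batch_scale_sd: float = 0.2
    noise_sd: float = 0.5
    n_modules: int = 4
    module_gene_fraction: float = 0.4
    module_trait_cor: float = 0.5
    survival: SurvivalSimConfig = field(default_factory=SurvivalSimConfig)
    response: ResponseSimConfig = field(default_factory=ResponseSimConfig)
    fluid: FluidSimConfig = field(default_factory=FluidSimConfig)
    graph: GraphSimConfig = field(default_factory=GraphSimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("panel_overlap_fraction", "de_fraction", "module_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.survival.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        for name in ("n_studies", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.samples_per_study) != self.n_studies:
            raise ValueError(
                f"samples_per_study has {len(self.samples_per_study)} entries "
                f"but n_studies = {self.n_studies}"
            )
        if any(s > self.graph.n_nodes for s in self.graph.clique_sizes):
            raise ValueError("planted clique sizes must not exceed n_nodes")


@dataclass
class SimTruth:
    """Ground-truth record of everything the generators planted."""

    de_effects: dict[str, float] = field(default_factory=dict)
    module_assignment: dict[str, int] = field(default_factory=dict)
    prognostic_genes: dict[str, float] = field(default_factory=dict)
    responsive_genes: set[str] = field(default_factory=set)
    hub_nodes: set[str] = field(default_factory=set)
    planted_cliques: list[set[str]] = field(default_factory=list)

    @property
    def de_genes(self) -> set[str]:
        return set(self.de_effects)


def _gene_names(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def simulate_study_collection(
    config: SimConfig,
) -> tuple[list[ExpressionStudy], SimTruth]:
    """Generate a multi-study case/control expression collection.

    Each study receives the full panel for ``panel_overlap_fraction`` of the
    genes and an independent random subset of the remainder, so downstream
    gene-set intersection is exercised.  Returns the studies plus the truth
    record (signed planted effects and module assignment).
    """
    rng = _rng(config.seed, _SLOT_STUDIES)
    genes = np.array(_gene_names(config.n_genes))
    n_g = config.n_genes

    # planted differential genes with random signs
    n_de = int(round(config.de_fraction * n_g))
    de_idx = rng.choice(n_g, size=n_de, replace=False)
    de_sign = rng.choice([-1.0, 1.0], size=n_de)
    de_effect = np.zeros(n_g)
    de_effect[de_idx] = de_sign * config.effect_size_log2

    # latent module structure on a fraction of genes
    module_of = np.full(n_g, -1)
    n_mod_genes = int(round(config.module_gene_fraction * n_g))
    if config.n_modules > 0 and n_mod_genes > 0:
        mod_idx = rng.choice(n_g, size=n_mod_genes, replace=False)
        module_of[mod_idx] = rng.integers(0, config.n_modules, size=n_mod_genes)
    loadings = rng.uniform(0.7, 1.0, size=n_g)
    baseline = rng.normal(7.0, 1.0, size=n_g)

    truth = SimTruth(
        de_effects={genes[i]: de_effect[i] for i in de_idx},
        module_assignment={
            genes[i]: int(module_of[i]) for i in range(n_g) if module_of[i] >= 0
        },
    )

    studies: list[ExpressionStudy] = []
    core = rng.choice(n_g, size=int(round(config.panel_overlap_fraction * n_g)),
                      replace=False)
    core_mask = np.zeros(n_g, dtype=bool)
    core_mask[core] = True

    for s, (n_case, n_control) in enumerate(config.samples_per_study):
        n_s = n_case + n_control
        case = np.r_[np.ones(n_case), np.zeros(n_control)]
        case_std = (case - case.mean()) / case.std() if case.std() > 0 else case * 0.0

        # module factors, tilted toward the phenotype
        c = config.module_trait_cor
        factors = (
            c * case_std[None, :]
            + math.sqrt(max(0.0, 1.0 - c * c))
            * rng.normal(size=(max(config.n_modules, 1), n_s))
        )

        gamma = rng.normal(0.0, config.batch_shift_sd, size=n_g)
        scale = np.exp(rng.normal(0.0, config.batch_scale_sd, size=n_g))

        x = baseline[:, None] + gamma[:, None] + de_effect[:, None] * case[None, :]
        in_mod = module_of >= 0
        if in_mod.any():
            x[in_mod] += loadings[in_mod, None] * factors[module_of[in_mod]]
        x += scale[:, None] * rng.normal(0.0, config.noise_sd, size=(n_g, n_s))

        # per-study panel: core genes always present, the rest drop out randomly
        keep = core_mask | (rng.random(n_g) < 0.5)
        samples = [f"S{s + 1}_{j + 1:03d}" for j in range(n_s)]
        values = pd.DataFrame(x[keep], index=genes[keep], columns=samples)
        phenotype = pd.Series(
            ["case"] * n_case + ["control"] * n_control, index=samples
        )
        studies.append(
            ExpressionStudy(study_id=f"study{s + 1}", values=values,
                            phenotype=phenotype)
        )
    return studies, truth


def _censor_bound(rates: np.ndarray, target: float) -> float:
    """Upper bound C of Uniform(0, C) censoring hitting the target rate.

    For T ~ Exp(rate) and U ~ Uniform(0, C), P(censored) = P(T > U)
    = E[exp(−rate·U)] = (1 − exp(−rate·C)) / (rate·C), which decreases from 1
    to 0 in C; the mean over patients is solved for C by bisection.
    """

    def mean_censor(C: float) -> float:
        rc = rates * C
        return float(np.mean((1.0 - np.exp(-rc)) / rc))

    lo, hi = 1e-9, 1.0
    while mean_censor(hi) > target and hi < 1e12:
        hi *= 2.0
    return brentq(lambda C: mean_censor(C) - target, lo, hi, xtol=1e-10)


def simulate_survival_cohort(config: SimConfig) -> tuple[SurvivalCohort, SimTruth]:
    """Exponential-hazard survival cohort with planted prognostic genes.

    Event times follow h0 · exp(Σ β_g x_g) with independent Uniform(0, C)
    censoring, C solved numerically to achieve the configured censoring rate.
    """
    sc = config.survival
    if not sc.log_hr:
        raise ValueError("at least one planted prognostic gene is required")
    if not 0.0 <= sc.censoring_rate < 1.0:
        raise ValueError("censoring_rate must be in [0, 1)")
    rng = _rng(config.seed, _SLOT_SURVIVAL)
    genes = _gene_names(sc.n_genes)
    missing = set(sc.log_hr) - set(genes)
    if missing:
        raise ValueError(f"planted prognostic genes outside gene universe: {missing}")

    x = rng.normal(size=(sc.n_patients, sc.n_genes))
    expr = pd.DataFrame(x, columns=genes,
                        index=[f"P{i + 1:04d}" for i in range(sc.n_patients)])
    beta = np.array([sc.log_hr.get(g, 0.0) for g in genes])
    rates = sc.baseline_hazard * np.exp(x @ beta)
    times = rng.exponential(1.0 / rates)
    if sc.censoring_rate == 0.0:
        event = np.ones(sc.n_patients, dtype=int)
        obs = times
    else:
        C = _censor_bound(rates, sc.censoring_rate)
        cens = rng.uniform(0.0, C, size=sc.n_patients)
        event = (times <= cens).astype(int)
        obs = np.minimum(times, cens)
    obs = np.maximum(obs, 1e-12)
    cohort = SurvivalCohort(
        time=pd.Series(obs, index=expr.index),
        event=pd.Series(event, index=expr.index),
        expression=expr,
        endpoint="OS",
    )
    truth = SimTruth(prognostic_genes=dict(sc.log_hr))
    return cohort, truth


RESPONSE_LEVELS = ("no", "partial", "complete")


def simulate_phenotype_cohorts(
    config: SimConfig,
) -> tuple[tuple[pd.DataFrame, pd.Series], dict[str, tuple[pd.DataFrame, pd.DataFrame]], SimTruth]:
    """Ordinal therapy-response cohort plus small biofluid cohorts.

    Response follows a proportional-odds model on the configured responsive
    genes: P(Y ≤ k) = logistic(θ_k − η) with thresholds θ placed at the
    configured base rates.  Fluid cohorts are small case/control matrices with
    the configured genes mean-shifted in cases.

    Returns ``(response_expr, response_labels), {"urine": (case, control),
    "blood": (case, control)}, truth``.
    """
    rc, fc = config.response, config.fluid
    rng = _rng(config.seed, _SLOT_PHENOTYPE)
    genes = _gene_names(rc.n_genes)
    x = rng.normal(size=(rc.n_patients, rc.n_genes))
    expr = pd.DataFrame(x, columns=genes,
                        index=[f"R{i + 1:04d}" for i in range(rc.n_patients)])
    beta = np.array([rc.coefficients.get(g, 0.0) for g in genes])
    eta = x @ beta
    cum = np.cumsum(rc.base_rates)[:2] / sum(rc.base_rates)
    theta = np.log(cum / (1.0 - cum))  # logit of cumulative base rates
    p_le = expit(theta[None, :] - eta[:, None])  # P(Y<=no), P(Y<=partial)
    u = rng.random(rc.n_patients)
    codes = (u[:, None] > p_le).sum(axis=1)
    labels = pd.Series([RESPONSE_LEVELS[k] for k in codes], index=expr.index)

    fgenes = _gene_names(fc.n_genes)
    shift = np.array([fc.shifted_genes.get(g, 0.0) for g in fgenes])
    fluids = {}
    for name in ("urine", "blood"):
        case = rng.normal(size=(fc.n_case, fc.n_genes)) * fc.noise_sd + shift
        ctrl = rng.normal(size=(fc.n_control, fc.n_genes)) * fc.noise_sd
        fluids[name] = (
            pd.DataFrame(case, columns=fgenes,
                         index=[f"{name}_case_{i + 1}" for i in range(fc.n_case)]),
            pd.DataFrame(ctrl, columns=fgenes,
                         index=[f"{name}_ctrl_{i + 1}" for i in range(fc.n_control)]),
        )
    truth = SimTruth(
        responsive_genes={g for g, b in rc.coefficients.items() if b != 0.0}
    )
    return (expr, labels), fluids, truth


def simulate_ppi_graph(
    config: SimConfig, node_names: list[str] | None = None
) -> tuple[nx.Graph, SimTruth]:
    """Erdős–Rényi background with planted cliques (and optionally one hub).

    Planted edges carry combined scores in [0.7, 1.0); background edges in
    [0.4, 0.7), so planted structure always survives score thresholds ≤ 0.7.
    ``node_names`` relabels the nodes (e.g. with DEG symbols); extra names
    are ignored, short lists are padded with synthetic node ids.
    """
    gc = config.graph
    rng = _rng(config.seed, _SLOT_GRAPH)
    nodes = [f"N{i + 1:04d}" for i in range(gc.n_nodes)]
    if node_names is not None:
        nodes = list(node_names[: gc.n_nodes]) + nodes[len(node_names):]
    g = nx.Graph()
    g.add_nodes_from(nodes)

    iu, ju = np.triu_indices(gc.n_nodes, k=1)
    mask = rng.random(iu.size) < gc.edge_prob
    for i, j in zip(iu[mask], ju[mask]):
        g.add_edge(nodes[i], nodes[j],
                   combined_score=float(rng.uniform(0.4, 0.7)))

    truth = SimTruth()
    free = np.arange(gc.n_nodes)
    for size in gc.clique_sizes:
        pick = rng.choice(free, size=size, replace=False)
        free = np.setdiff1d(free, pick)
        members = [nodes[i] for i in pick]
        for a in range(size):
            for b in range(a + 1, size):
                g.add_edge(members[a], members[b],
                           combined_score=float(rng.uniform(0.7, 1.0)))
        truth.planted_cliques.append(set(members))

    if gc.hub_fraction > 0.0:
        hub = nodes[int(free[0]) if free.size else 0]
        n_wire = int(round(gc.hub_fraction * gc.n_nodes))
        targets = rng.choice(
            [n for n in nodes if n != hub], size=n_wire, replace=False
        )
        for t in targets:
            g.add_edge(hub, t, combined_score=float(rng.uniform(0.7, 1.0)))
        truth.hub_nodes.add(hub)
    return g, truth
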