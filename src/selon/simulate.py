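"""Sequence simulation along rooted trees.

Ancestral states are drawn from each site's stationary distribution (the
model assumes the process starts at equilibrium) and evolved down every
branch by sampling from the exact transition matrix P(t) — no within-branch
event simulation is needed.  Includes the two desk-scale benchmark scenarios:
ten-taxon trees (nine ingroup taxa plus an outgroup) whose branch lengths
take only the values 0.10 (long) and 0.025 (short), carrying a set of UCEs
with varied Gaussian selection profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    MutationModel,
    PopulationConfig,
    SelectionProfile,
    build_mutation_matrix,
    build_site_rate_matrices,
    stationary_distributions,
    stationary_rates,
)
from .engine import GtrUceParams  # noqa: F401  (public type in signatures)
from .io import UCEAlignment, UCEDataset
from .likelihood import EigSystem, GammaRateModel, gtr_rate_matrix, laguerre_gamma_rates
from .tree import RootedTree

LONG_BRANCH = 0.10
SHORT_BRANCH = 0.025

_SCENARIO_NEWICKS = {
    1: (
        "((((A:0.1,B:0.025):0.025,(C:0.1,D:0.025):0.025):0.025,"
        "(((E:0.1,F:0.025):0.025,(G:0.025,H:0.025):0.1):0.025,I:0.1):0.025):0.025,"
        "OUT:0.1);"
    ),
    2: (
        "((((A:0.025,B:0.025):0.1,(C:0.025,D:0.025):0.1):0.025,"
        "(((E:0.025,F:0.025):0.1,(G:0.1,H:0.025):0.025):0.025,I:0.025):0.1):0.025,"
        "OUT:0.1);"
    ),
}

#: fixed generating mutation matrix for the scenario fixtures: mild
#: transition bias (transitions 2.0, transversions 1.0, G->T pinned at 1)
SCENARIO_MUTATION_RATES = np.array([1, 2, 1, 1, 1, 2, 2, 1, 1, 2, 1], dtype=float)


def _sample_categorical(prob_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw per row from (n, 4) probability rows."""
    cdf = np.cumsum(prob_rows, axis=1)
    u = rng.random(prob_rows.shape[0]) * cdf[:, -1]
    return np.minimum((u[:, None] > cdf).sum(axis=1), 3).astype(np.int8)


def evolve_states(
    tree: RootedTree,
    q_scaled: np.ndarray,
    pi: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate leaf states for sites with per-site matrices.

    Parameters
    ----------
    q_scaled : (n_sites, 4, 4) or (1, 4, 4) scaled rate matrices.
    pi : (n_sites, 4) or (1, 4) root state frequencies.

    Returns (n_taxa, n_sites) leaf states ordered as ``tree.taxa``.
    """
    n_sites = max(q_scaled.shape[0], pi.shape[0])
    pi_rows = np.broadcast_to(pi, (n_sites, 4))
    eig = EigSystem(q_scaled)
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int8)
    states[tree.root] = _sample_categorical(pi_rows, rng)
    sites = np.arange(n_sites)
    for node in tree.postorder[::-1]:
        if node == tree.root:
            continue
        p = eig.transition(float(tree.lengths[node]))
        if p.shape[0] == 1:
            rows = p[0][states[tree.parent[node]]]
        else:
            rows = p[sites, states[tree.parent[node]]]
        states[node] = _sample_categorical(rows, rng)
    return states[: tree.n_taxa]


def simulate_uce(
    tree: RootedTree,
    sites: list,
    seed_or_rng,
    uce_id: str = "uce",
) -> UCEAlignment:
    """Simulate one UCE from a list of (scaled) per-site models."""
    rng = _as_rng(seed_or_rng)
    q = np.stack([s.q_scaled if s.q_scaled is not None else s.q_raw for s in sites])
    pi = np.stack([s.pi for s in sites])
    codes = evolve_states(tree, q, pi, rng)
    return UCEAlignment(uce_id=uce_id, taxa=tree.taxa, codes=codes)


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class UCESpec:
    """Generating truth for one simulated UCE."""

    uce_id: str
    length: int
    profile: SelectionProfile
    optimal: np.ndarray


@dataclass
class SimulationScenario:
    """A benchmark condition: tree, per-UCE truth, mutation model, ploidy."""

    scenario_id: int
    tree: RootedTree
    uce_specs: list[UCESpec]
    mutation: MutationModel
    pop: PopulationConfig
    seed: int

    def manifest(self) -> dict:
        from .io import decode_codes

        return {
            "scenario_id": self.scenario_id,
            "seed": self.seed,
            "tree_newick": self.tree.to_newick(),
            "mutation_free_rates": list(self.mutation.free_rates),
            "ne": self.pop.ne,
            "ploidy_b": self.pop.ploidy_b,
            "uces": [
                {
                    "uce_id": s.uce_id,
                    "length": s.length,
                    "nes_max": s.profile.nes_max,
                    "center": s.profile.center,
                    "width": s.profile.width,
                    "optimal": decode_codes(s.optimal),
                }
                for s in self.uce_specs
            ],
        }


def scenario_tree(scenario_id: int) -> RootedTree:
    if scenario_id not in _SCENARIO_NEWICKS:
        raise ValueError("scenario_id must be 1 or 2")
    return RootedTree.from_newick(_SCENARIO_NEWICKS[scenario_id])


def scenario_site_matrices(scenario: SimulationScenario, scaling: str = "per_site"):
    """Scaled per-site matrices and stationary distributions for a scenario.

    Sites are calibrated exactly as in fitting (per-site by default: each
    matrix divided by its own stationary rate); the returned C is the mean
    stationary rate across the scenario's sites."""
    from .core import RATE_FLOOR

    f = np.concatenate(
        [s.profile.sensitivity(np.arange(1.0, s.length + 1.0)) for s in scenario.uce_specs]
    )
    opt = np.concatenate([s.optimal for s in scenario.uce_specs]).astype(np.int64)
    q = build_site_rate_matrices(opt, f, scenario.mutation, scenario.pop)
    pi = stationary_distributions(q)
    rates = stationary_rates(q, pi)
    c = float(rates.mean())
    if scaling == "per_site":
        q_scaled = q / np.maximum(rates, RATE_FLOOR)[:, None, None]
    else:
        q_scaled = q / c
    return q_scaled, pi, c


def simulate_scenario_dataset(
    scenario: SimulationScenario, seed_or_rng
) -> UCEDataset:
    """One replicate dataset simulated under a scenario's generating truth."""
    rng = _as_rng(seed_or_rng)
    q_scaled, pi, _ = scenario_site_matrices(scenario)
    codes = evolve_states(scenario.tree, q_scaled, pi, rng)
    alignments = []
    offset = 0
    for s in scenario.uce_specs:
        alignments.append(
            UCEAlignment(
                uce_id=s.uce_id,
                taxa=scenario.tree.taxa,
                codes=codes[:, offset : offset + s.length],
            )
        )
        offset += s.length
    return UCEDataset(alignments=alignments, taxa=scenario.tree.taxa)


def generate_scenario_fixtures(
    scenario_id: int,
    n_uces: int = 22,
    seed: int = 0,
    total_sites: int = 10_000,
    nes_range: tuple[float, float] = (4.0, 32.0),
) -> tuple[SimulationScenario, UCEDataset]:
    """Benchmark scenario plus one simulated replicate dataset.

    Per-UCE Gaussian profiles are drawn (seeded) with centers uniform in
    [0.3 l, 0.7 l], widths uniform in [l/10, l/4] and Nes_max log-uniform
    over ``nes_range``; optimal sequences are uniform random.  The default
    Nes_max range [4, 32] makes the conserved cores effectively frozen —
    the defining property of ultraconserved elements, where any core
    deviation is purged — while the flanks decay to neutrality.  UCE
    lengths partition ``total_sites`` with mild (±30%) variation.
    """
    rng = np.random.default_rng(seed)
    tree = scenario_tree(scenario_id)
    weights = rng.uniform(0.7, 1.3, size=n_uces)
    lengths = np.maximum(np.rint(total_sites * weights / weights.sum()).astype(int), 20)
    specs = []
    for u, l in enumerate(lengths):
        profile = SelectionProfile(
            nes_max=float(
                np.exp(rng.uniform(np.log(nes_range[0]), np.log(nes_range[1])))
            ),
            center=float(rng.uniform(0.3 * l, 0.7 * l)),
            width=float(rng.uniform(l / 10.0, l / 4.0)),
        )
        optimal = rng.integers(0, 4, size=int(l)).astype(np.int64)
        specs.append(
            UCESpec(uce_id=f"uce{u:03d}", length=int(l), profile=profile, optimal=optimal)
        )
    mutation = build_mutation_matrix("UNREST", SCENARIO_MUTATION_RATES)
    scenario = SimulationScenario(
        scenario_id=scenario_id,
        tree=tree,
        uce_specs=specs,
        mutation=mutation,
        pop=PopulationConfig(),
        seed=seed,
    )
    dataset = simulate_scenario_dataset(scenario, rng)
    return scenario, dataset


# ---------------------------------------------------------------------------
# GTR(+Gamma) simulation (model-adequacy checks)
# ---------------------------------------------------------------------------


def simulate_gtr_gamma(
    tree: RootedTree,
    exchangeabilities,
    base_freqs,
    gamma: GammaRateModel | None,
    n_sites: int,
    seed_or_rng,
    site_rates: np.ndarray | None = None,
    uce_id: str = "uce",
) -> UCEAlignment:
    """Simulate one alignment under GTR(+Gamma).

    Per-site rate multipliers are drawn from the discrete Gamma categories
    unless ``site_rates`` supplies fixed values (e.g. model-averaged rates
    when replicating an observed dataset)."""
    rng = _as_rng(seed_or_rng)
    q = gtr_rate_matrix(exchangeabilities, base_freqs)
    freqs = np.asarray(base_freqs, dtype=float)
    if site_rates is None:
        if gamma is None:
            site_rates = np.ones(n_sites)
        else:
            cats = rng.choice(gamma.ncat, size=n_sites, p=gamma.weights)
            site_rates = gamma.rates[cats]
    q_sites = q[None, :, :] * np.asarray(site_rates)[:, None, None]
    codes = evolve_states(tree, q_sites, freqs[None], rng)
    return UCEAlignment(uce_id=uce_id, taxa=tree.taxa, codes=codes)


def simulate_selon_dataset(
    params,
    tree: RootedTree,
    site_counts,
    seed_or_rng,
    uce_ids=None,
) -> UCEDataset:
    """Simulate a dataset under a fitted (or true) SelON parameter bundle."""
    rng = _as_rng(seed_or_rng)
    specs = [
        UCESpec(
            uce_id=(uce_ids[u] if uce_ids else f"uce{u:03d}"),
            length=int(n),
            profile=params.profiles[u],
            optimal=np.asarray(params.optima[u], dtype=np.int64),
        )
        for u, n in enumerate(site_counts)
    ]
    scenario = SimulationScenario(
        scenario_id=0,
        tree=tree,
        uce_specs=specs,
        mutation=params.mutation,
        pop=params.pop,
        seed=-1,
    )
    return simulate_scenario_dataset(scenario, rng)


def simulate_gtr_dataset(
    thetas: list[GtrUceParams],
    tree: RootedTree,
    site_counts,
    ncat: int,
    seed_or_rng,
    uce_ids=None,
    site_rates: list | None = None,
) -> UCEDataset:
    rng = _as_rng(seed_or_rng)
    alignments = []
    for u, n in enumerate(site_counts):
        t = thetas[u]
        gamma = laguerre_gamma_rates(t.alpha, ncat) if t.alpha is not None else None
        alignments.append(
            simulate_gtr_gamma(
                tree,
                t.exchangeabilities,
                t.base_freqs,
                gamma,
                int(n),
                rng,
                site_rates=None if site_rates is None else site_rates[u],
                uce_id=(uce_ids[u] if uce_ids else f"uce{u:03d}"),
            )
        )
    return UCEDataset(alignments=alignments, taxa=tree.taxa)
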