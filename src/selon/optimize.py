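"""Maximum-likelihood fitting.

The selection model is fit by a four-stage hill-climbing cycle:

1. branch lengths, one bounded 1-D search per branch, sweeping from the
   pendant edges toward the root in "generations" (an edge is optimized only
   after every edge below it), repeated until the log-likelihood improves by
   less than 1% between sweeps or 10 total sweeps;
2. the per-UCE Gaussian shape parameters (Nes_max, center, width) by a
   bounded derivative-free simplex search;
3. the 11 free global mutation rates (G->T pinned at 1), same search;
4. the optimal nucleotide of every site, by scoring the four candidates and
   keeping the incumbent on ties.

The cycle repeats until the total log-likelihood improves by less than 1%
or 12 total cycles.  The scale factor C is held fixed within stages 1, 2 and
4 and refreshed between stages; every stage is wrapped so the exact total
log-likelihood never decreases (a stage whose refresh loses likelihood is
re-run once against the new scale and reverted if it still loses).

Starting values: majority-rule optimal bases, all mutation rates at 1,
randomized (seeded) shape profiles, and branch lengths from an F81 fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

logger = logging.getLogger(__name__)

from .core import (
    MutationModel,
    PopulationConfig,
    SelectionProfile,
    build_mutation_matrix,
)
from .engine import GtrGammaEngine, GtrUceParams, SelonEngine, SelonParams
from .io import UCEDataset, decode_codes
from .likelihood import aicc
from .tree import RootedTree

_TINY = 1e-9


@dataclass
class OptimizerConfig:
    """Tunable knobs of the hill-climbing fit (defaults follow the printed
    stopping rules: 10 total branch sweeps, 12 total outer cycles, 1%
    relative improvement threshold)."""

    branch_cycle_max: int = 10
    outer_cycle_max: int = 12
    rel_tol: float = 0.01
    branch_min: float = 1e-9
    branch_max: float = 10.0
    branch_xatol: float = 1e-7
    subplex_maxeval: int = 5000
    shape_maxeval: int = 400
    mutation_maxeval: int = 1200
    gtr_maxeval: int = 500
    nes_max_bound: float = 50.0
    # a Gaussian narrower than the inter-site spacing is not a spatial
    # profile, and permitting it invites degenerate one-site spikes
    sigma_min: float = 1.0
    sigma_max_factor: float = 10.0
    shape_restarts: int = 3
    seed: int = 0
    count_optima_as_params: bool = True

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_file(cls, path) -> "OptimizerConfig":
        """Load a config from JSON or simple ``key = value`` lines."""
        import json

        text = open(path).read()
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            raw = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                raw[key.strip()] = value.strip()
        fields = cls.__dataclass_fields__
        kwargs = {}
        for key, value in raw.items():
            if key not in fields:
                raise ValueError(f"unknown optimizer option {key!r}")
            typ = type(getattr(cls(), key))
            if isinstance(value, str):
                value = typ(value) if typ is not bool else value.lower() in ("1", "true", "yes")
            kwargs[key] = value
        return cls(**kwargs)


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    model: str
    log_likelihood: float
    n_parameters: int
    aicc: float
    per_uce_lnl: dict
    tree_newick: str
    n_cycles: int
    lnl_trace: list
    seed: int | None
    params: dict
    tree: RootedTree | None = None
    selon_params: SelonParams | None = None
    gtr_thetas: list | None = None
    gamma_ncat: int | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "log_likelihood": self.log_likelihood,
            "n_parameters": self.n_parameters,
            "aicc": self.aicc,
            "per_uce_lnl": self.per_uce_lnl,
            "tree_newick": self.tree_newick,
            "n_cycles": self.n_cycles,
            "lnl_trace": list(self.lnl_trace),
            "seed": self.seed,
            "params": self.params,
        }

    def save(self, path) -> None:
        from .io import write_json

        write_json(self.to_dict(), path)

    @classmethod
    def from_dict(cls, payload: dict) -> "FitResult":
        from .core import NUC_INDEX

        res = cls(
            model=payload["model"],
            log_likelihood=payload["log_likelihood"],
            n_parameters=payload["n_parameters"],
            aicc=payload["aicc"],
            per_uce_lnl=payload["per_uce_lnl"],
            tree_newick=payload["tree_newick"],
            n_cycles=payload["n_cycles"],
            lnl_trace=payload["lnl_trace"],
            seed=payload.get("seed"),
            params=payload["params"],
        )
        res.tree = RootedTree.from_newick(res.tree_newick)
        p = res.params
        if res.model == "selon":
            res.selon_params = SelonParams(
                mutation=build_mutation_matrix(
                    p["mutation_flavor"], p["mutation_free_rates"]
                ),
                profiles=[SelectionProfile(**d) for d in p["profiles"]],
                optima=[
                    np.array([NUC_INDEX[ch] for ch in s], dtype=np.int64)
                    for s in p["optima"]
                ],
                pop=PopulationConfig(ne=p["ne"], ploidy_b=p["ploidy_b"]),
            )
        else:
            res.gamma_ncat = p.get("ncat")
            res.gtr_thetas = [
                GtrUceParams(
                    exchangeabilities=np.asarray(d["exchangeabilities"], dtype=float),
                    base_freqs=np.asarray(d["base_freqs"], dtype=float),
                    alpha=d["alpha"],
                )
                for d in p["uces"]
            ]
        return res

    @classmethod
    def load(cls, path) -> "FitResult":
        import json

        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def majority_rule_optima(codes: np.ndarray) -> np.ndarray:
    """Most frequent base per column; ties break to the alphabetically first
    (A < C < G < T); all-missing columns default to A."""
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])
    return counts.argmax(axis=0).astype(np.int64)  # argmax takes first max


def empirical_base_freqs(codes: np.ndarray) -> np.ndarray:
    counts = np.array([(codes == b).sum() for b in range(4)], dtype=float) + 1.0
    return counts / counts.sum()


def _conservation_start(codes: np.ndarray, length: int) -> tuple[float, float, float]:
    """Heuristic shape start: centroid and spread of the invariant columns."""
    opt = majority_rule_optima(codes)
    observed = codes < 4
    mono = ((codes == opt[None, :]) | ~observed).all(axis=0) & observed.any(axis=0)
    pos = np.flatnonzero(mono) + 1.0
    if pos.size < 3:
        return 2.0, length / 2.0, length / 4.0
    center = float(pos.mean())
    sigma = float(np.clip(pos.std(), 1.0, length))
    return 2.0, center, sigma


def random_profiles(dataset: UCEDataset, rng: np.random.Generator) -> list[SelectionProfile]:
    out = []
    for n in dataset.site_counts:
        nes = float(np.exp(rng.uniform(np.log(0.5), np.log(10.0))))
        center = float(rng.uniform(0.25 * n, 0.75 * n))
        width = float(rng.uniform(n / 10.0, n / 2.0))
        out.append(SelectionProfile(nes_max=nes, center=center, width=width))
    return out


def fit_f81_branch_lengths(
    dataset: UCEDataset, tree: RootedTree, config: OptimizerConfig
) -> np.ndarray:
    """Starting branch lengths from an F81 fit on the concatenated data."""
    freqs = empirical_base_freqs(dataset.concatenated_codes())
    theta = GtrUceParams(
        exchangeabilities=np.ones(5), base_freqs=freqs, alpha=None
    )
    engine = GtrGammaEngine(dataset, tree, ncat=1)
    thetas = [theta] * dataset.n_uces
    ev = _GtrBranchEvaluator(engine, thetas, tree.lengths.copy())
    _branch_sweeps(ev, tree, config)
    return ev.lengths


def initialize_fit(
    dataset: UCEDataset,
    tree: RootedTree,
    config: OptimizerConfig | None = None,
    pop: PopulationConfig | None = None,
    seed: int | None = None,
) -> tuple[SelonParams, np.ndarray]:
    """Starting parameter bundle: majority optima, unit mutation rates,
    seeded random profiles, F81 branch lengths."""
    config = config or OptimizerConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    params = SelonParams(
        mutation=build_mutation_matrix("UNREST", np.ones(11)),
        profiles=random_profiles(dataset, rng),
        optima=[majority_rule_optima(a.codes) for a in dataset.alignments],
        pop=pop or PopulationConfig(),
    )
    lengths = fit_f81_branch_lengths(dataset, tree, config)
    return params, lengths


# ---------------------------------------------------------------------------
# branch-length stage (shared by both models)
# ---------------------------------------------------------------------------


class _SelonBranchEvaluator:
    def __init__(self, engine: SelonEngine, params: SelonParams, c: float, lengths):
        from .likelihood import EigSystem, prune_loglik

        self._prune = prune_loglik
        self.engine = engine
        ss = engine.site_set(params)
        self.eig = EigSystem(ss.scaled_q_unique(engine.scaling == "per_site", c))
        self.inv = ss.inverse
        self.pi = ss.pi_sites
        self.lengths = np.array(lengths, dtype=float)
        nodes = [int(n) for n in engine.tree.branch_nodes]
        ps = self.eig.transitions(np.array([float(self.lengths[n]) for n in nodes]))
        self.p = {n: ps[i][self.inv] for i, n in enumerate(nodes)}

    def set_branch(self, node: int, t: float) -> None:
        self.lengths[node] = t
        self.p[node] = self.eig.transition(float(t))[self.inv]

    def total(self) -> float:
        lnl = self._prune(self.engine.tree, self.engine.codes, self.p, self.pi)
        return float(lnl.sum())


class _GtrBranchEvaluator:
    def __init__(self, engine: GtrGammaEngine, thetas, lengths):
        from scipy.special import logsumexp

        from .likelihood import prune_loglik

        self._prune = prune_loglik
        self._logsumexp = logsumexp
        self.engine = engine
        self.eig, self.rates, weights, freqs = engine._components(thetas)
        self.logw = np.log(weights[engine.uce_of_site]).T
        self.freqs = freqs[engine.uce_of_site]
        self.lengths = np.array(lengths, dtype=float)
        self.p = {}
        for n in engine.tree.branch_nodes:
            self.set_branch(int(n), float(self.lengths[n]))

    def set_branch(self, node: int, t: float) -> None:
        self.lengths[node] = t
        pm = self.engine.branch_matrices(self.eig, self.rates, float(t))
        self.p[node] = pm[self.engine.uce_of_site]  # (n_sites, ncat, 4, 4)

    def total(self) -> float:
        ncat = self.engine.ncat
        cat = np.empty((ncat, self.engine.n_sites))
        for c in range(ncat):
            pc = {n: p[:, c] for n, p in self.p.items()}
            cat[c] = self._prune(self.engine.tree, self.engine.codes, pc, self.freqs)
        return float(self._logsumexp(cat + self.logw, axis=0).sum())


def _branch_order(tree: RootedTree) -> list[int]:
    gen = tree.branch_generations()
    nodes = [int(n) for n in tree.branch_nodes]
    pos = {n: i for i, n in enumerate(nodes)}
    return sorted(nodes, key=lambda n: (gen[n], pos[n]))


def _branch_sweeps(evaluator, tree: RootedTree, config: OptimizerConfig) -> float:
    """Generation-ordered bounded 1-D branch optimization; returns final lnL.

    Sweeps stop after a <1% relative improvement or ``branch_cycle_max``
    total sweeps; a proposed length is accepted only if it improves the
    likelihood, so the trace is monotone."""
    order = _branch_order(tree)
    lnl = evaluator.total()
    for _ in range(config.branch_cycle_max):
        prev = lnl
        for node in order:
            t_old = float(evaluator.lengths[node])

            def neg(t, node=node):
                evaluator.set_branch(node, float(t))
                return -evaluator.total()

            res = minimize_scalar(
                neg,
                bounds=(config.branch_min, config.branch_max),
                method="bounded",
                options={"xatol": config.branch_xatol},
            )
            if -res.fun > lnl:
                evaluator.set_branch(node, float(res.x))
                lnl = float(-res.fun)
            else:
                evaluator.set_branch(node, t_old)
        if abs(lnl - prev) < config.rel_tol * abs(prev):
            break
    return lnl


# ---------------------------------------------------------------------------
# SelON fit
# ---------------------------------------------------------------------------


@dataclass
class _FitState:
    engine: SelonEngine
    params: SelonParams
    lengths: np.ndarray
    c: float = 0.0
    lnl: float = -np.inf

    def refresh(self) -> None:
        ss = self.engine.site_set(self.params)
        self.c = ss.mean_rate
        branch_p = self.engine.branch_matrices(ss, self.c, self.lengths)
        from .likelihood import prune_loglik

        self.lnl = float(
            prune_loglik(self.engine.tree, self.engine.codes, branch_p, ss.pi_sites).sum()
        )

    def snapshot(self):
        return (self.params.copy(), self.lengths.copy(), self.c, self.lnl)

    def restore(self, snap) -> None:
        self.params, self.lengths, self.c, self.lnl = (
            snap[0].copy(),
            snap[1].copy(),
            snap[2],
            snap[3],
        )


def _guarded(state: _FitState, stage_fn) -> None:
    """Run a stage, refresh the scale factor, and never lose likelihood:
    re-run once against the refreshed scale, else revert."""
    snap = state.snapshot()
    stage_fn(state)
    state.refresh()
    if state.lnl < snap[3] - _TINY:
        stage_fn(state)
        state.refresh()
        if state.lnl < snap[3] - _TINY:
            state.restore(snap)


def optimize_branch_lengths(state: _FitState, config: OptimizerConfig) -> None:
    ev = _SelonBranchEvaluator(state.engine, state.params, state.c, state.lengths)
    lnl = _branch_sweeps(ev, state.engine.tree, config)
    state.lengths = ev.lengths
    state.lnl = lnl  # C is branch-length independent, so this is exact


def optimize_shape_params(
    state: _FitState, config: OptimizerConfig, rng: np.random.Generator, restarts: int = 1
) -> None:
    engine, params = state.engine, state.params
    nes_floor = 1e-4  # log-scale lower bound; effectively neutral
    for u in range(engine.dataset.n_uces):
        n = int(engine.dataset.site_counts[u])
        # log coordinates for nes and sigma: the likelihood saturates in
        # nes once the core freezes, and log scaling keeps the simplex
        # well-conditioned there
        bounds = [
            (np.log(nes_floor), np.log(config.nes_max_bound)),
            (1.0, float(n)),
            (np.log(config.sigma_min), np.log(config.sigma_max_factor * n)),
        ]
        pr = params.profiles[u]
        current = engine.uce_loglik(params, u, state.c, lengths=state.lengths)

        def neg(x, u=u):
            prof = SelectionProfile(
                nes_max=float(np.exp(x[0])), center=float(x[1]), width=float(np.exp(x[2]))
            )
            return -engine.uce_loglik(params, u, state.c, profile=prof, lengths=state.lengths)

        starts = [np.array([np.log(max(pr.nes_max, nes_floor)), pr.center, np.log(pr.width)])]
        if restarts > 1:
            sl = engine.uce_slices[u]
            nes0, cen0, sig0 = _conservation_start(engine.codes[:, sl], n)
            starts.append(np.array([np.log(nes0), cen0, np.log(sig0)]))
        for _ in range(max(0, restarts - len(starts))):
            starts.append(
                np.array(
                    [
                        rng.uniform(np.log(0.5), np.log(10.0)),
                        rng.uniform(0.25 * n, 0.75 * n),
                        np.log(rng.uniform(n / 10.0, n / 2.0)),
                    ]
                )
            )
        best_x, best_lnl = None, current
        for x0 in starts:
            x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
            res = minimize(
                neg,
                x0,
                method="Nelder-Mead",
                bounds=bounds,
                options={
                    "maxfev": min(config.subplex_maxeval, config.shape_maxeval),
                    "xatol": 1e-5,
                    "fatol": 1e-6,
                },
            )
            if -res.fun > best_lnl + _TINY:
                best_x, best_lnl = res.x, float(-res.fun)
        if best_x is not None:
            params.profiles[u] = SelectionProfile(
                nes_max=float(np.exp(best_x[0])),
                center=float(best_x[1]),
                width=float(np.exp(best_x[2])),
            )


def optimize_mutation_rates(state: _FitState, config: OptimizerConfig) -> None:
    engine, params = state.engine, state.params
    x0 = np.log(np.maximum(np.asarray(params.mutation.free_rates, dtype=float), 1e-6))
    if x0.size != 11:  # promote JC/other flavors to the unrestricted model
        x0 = np.zeros(11)
    bounds = [(np.log(1e-4), np.log(1e4))] * 11

    def neg(x):
        mut = build_mutation_matrix("UNREST", np.exp(x))
        trial = SelonParams(mut, params.profiles, params.optima, params.pop)
        return -engine.loglik(trial, state.lengths)  # exact: C recomputed

    res = minimize(
        neg,
        x0,
        method="Nelder-Mead",
        bounds=bounds,
        options={
            "maxfev": min(config.subplex_maxeval, config.mutation_maxeval),
            "xatol": 1e-5,
            "fatol": 1e-4,
        },
    )
    if -res.fun > state.lnl + _TINY:
        params.mutation = build_mutation_matrix("UNREST", np.exp(res.x))


def optimize_optimal_sequence(state: _FitState, config: OptimizerConfig) -> None:
    engine, params = state.engine, state.params
    cand = engine.candidate_site_logliks(params, state.c, state.lengths)
    opt = np.concatenate(params.optima).astype(np.int64)
    sites = np.arange(opt.size)
    incumbent = cand[opt, sites]
    best = cand.argmax(axis=0)
    new_opt = np.where(cand[best, sites] > incumbent + _TINY, best, opt)
    for u, sl in enumerate(engine.uce_slices):
        params.optima[u] = new_opt[sl].copy()


def fit_selon(
    dataset: UCEDataset,
    tree: RootedTree,
    config: OptimizerConfig | None = None,
    pop: PopulationConfig | None = None,
    initial: tuple[SelonParams, np.ndarray] | None = None,
) -> FitResult:
    """Four-stage maximum-likelihood fit of the selection model.

    ``initial`` may supply a (params, branch_lengths) starting point (e.g.
    the generating values in simulation studies); otherwise the standard
    randomized initialization is used.
    """
    config = config or OptimizerConfig()
    rng = np.random.default_rng(config.seed)
    work_tree = tree.copy()
    if initial is not None:
        params, lengths = initial[0].copy(), np.array(initial[1], dtype=float)
    else:
        params, lengths = initialize_fit(dataset, work_tree, config, pop, seed=config.seed)
    engine = SelonEngine(dataset, work_tree, params.pop)
    state = _FitState(engine=engine, params=params, lengths=lengths)
    state.refresh()
    if not np.isfinite(state.lnl):
        raise RuntimeError(
            "non-finite starting log-likelihood; check alignment and tree inputs"
        )
    trace = [state.lnl]
    n_cycles = 0
    for cycle in range(config.outer_cycle_max):
        prev = state.lnl
        stages = [
            ("branch_lengths", lambda s: optimize_branch_lengths(s, config)),
            (
                "shape_params",
                lambda s: optimize_shape_params(
                    s, config, rng, config.shape_restarts if cycle == 0 else 1
                ),
            ),
            ("mutation_rates", lambda s: optimize_mutation_rates(s, config)),
            ("optimal_sequence", lambda s: optimize_optimal_sequence(s, config)),
        ]
        for name, stage in stages:
            if name == "branch_lengths":
                stage(state)  # exact by construction; C unaffected
            else:
                _guarded(state, stage)
            trace.append(state.lnl)
            logger.info("cycle %d stage %s: lnL = %.6f", cycle + 1, name, state.lnl)
        n_cycles = cycle + 1
        if state.lnl - prev < config.rel_tol * abs(prev):
            break
    work_tree.lengths = state.lengths
    k = 11 + 3 * dataset.n_uces + work_tree.n_branches
    if config.count_optima_as_params:
        k += dataset.total_sites
    per_uce = engine.per_uce_loglik(state.params, state.lengths, state.c)
    result = FitResult(
        model="selon",
        log_likelihood=state.lnl,
        n_parameters=k,
        aicc=aicc(state.lnl, k, dataset.alignments[0].n_taxa, dataset.total_sites),
        per_uce_lnl=dict(zip(dataset.uce_ids, per_uce.tolist())),
        tree_newick=work_tree.to_newick(),
        n_cycles=n_cycles,
        lnl_trace=trace,
        seed=config.seed,
        params={
            "mutation_flavor": state.params.mutation.flavor,
            "mutation_free_rates": list(state.params.mutation.free_rates),
            "ne": state.params.pop.ne,
            "ploidy_b": state.params.pop.ploidy_b,
            "profiles": [
                {"nes_max": p.nes_max, "center": p.center, "width": p.width}
                for p in state.params.profiles
            ],
            "optima": [decode_codes(o) for o in state.params.optima],
            "uce_ids": dataset.uce_ids,
            "scale_factor": state.c,
        },
        tree=work_tree,
        selon_params=state.params,
    )
    return result


# ---------------------------------------------------------------------------
# GTR(+Gamma) fit
# ---------------------------------------------------------------------------


def _theta_to_x(theta: GtrUceParams) -> np.ndarray:
    x = np.log(theta.exchangeabilities)
    f = np.log(theta.base_freqs / theta.base_freqs[3])[:3]
    out = np.concatenate([x, f])
    if theta.alpha is not None:
        out = np.concatenate([out, [np.log(theta.alpha)]])
    return out


def _x_to_theta(x: np.ndarray, with_alpha: bool) -> GtrUceParams:
    exch = np.exp(x[:5])
    logits = np.concatenate([x[5:8], [0.0]])
    freqs = np.exp(logits - logits.max())
    freqs /= freqs.sum()
    alpha = float(np.exp(x[8])) if with_alpha else None
    return GtrUceParams(exchangeabilities=exch, base_freqs=freqs, alpha=alpha)


def fit_gtr_gamma(
    dataset: UCEDataset,
    tree: RootedTree,
    config: OptimizerConfig | None = None,
    ncat: int = 4,
    gamma: bool = True,
    shared_branches: bool = True,
) -> FitResult:
    """Partitioned GTR(+Gamma) fit: per-UCE exchangeabilities, frequencies
    and Gamma shape (all by ML), branch lengths shared across UCEs by
    default; ``shared_branches=False`` fits every UCE separately."""
    config = config or OptimizerConfig()
    if not shared_branches:
        return _fit_gtr_per_uce(dataset, tree, config, ncat, gamma)
    work_tree = tree.copy()
    engine = GtrGammaEngine(dataset, work_tree, ncat=ncat if gamma else 1)
    thetas = [
        GtrUceParams(
            exchangeabilities=np.ones(5),
            base_freqs=np.clip(empirical_base_freqs(a.codes), 0.02, None)
            / np.clip(empirical_base_freqs(a.codes), 0.02, None).sum(),
            alpha=1.0 if gamma else None,
        )
        for a in dataset.alignments
    ]
    lengths = fit_f81_branch_lengths(dataset, work_tree, config)
    lnl = engine.loglik(thetas, lengths)
    trace = [lnl]
    n_params_per_uce = 9 if gamma else 8
    bounds = [(-8.0, 8.0)] * 8 + ([(np.log(0.02), np.log(100.0))] if gamma else [])
    n_cycles = 0
    for cycle in range(config.outer_cycle_max):
        prev = lnl
        ev = _GtrBranchEvaluator(engine, thetas, lengths)
        lnl = _branch_sweeps(ev, work_tree, config)
        lengths = ev.lengths
        trace.append(lnl)
        for u in range(dataset.n_uces):
            def neg(x, u=u):
                return -engine.uce_loglik(u, _x_to_theta(x, gamma), lengths)

            x0 = _theta_to_x(thetas[u])
            res = minimize(
                neg,
                x0,
                method="Nelder-Mead",
                bounds=bounds,
                options={
                    "maxfev": min(config.subplex_maxeval, config.gtr_maxeval),
                    "xatol": 1e-5,
                    "fatol": 1e-6,
                },
            )
            if -res.fun > -neg(x0) + _TINY:
                thetas[u] = _x_to_theta(res.x, gamma)
        lnl = engine.loglik(thetas, lengths)
        trace.append(lnl)
        n_cycles = cycle + 1
        if lnl - prev < config.rel_tol * abs(prev):
            break
    work_tree.lengths = lengths
    k = n_params_per_uce * dataset.n_uces + work_tree.n_branches
    per_uce = engine.per_uce_loglik(thetas, lengths)
    return FitResult(
        model="gtr_gamma" if gamma else "gtr",
        log_likelihood=lnl,
        n_parameters=k,
        aicc=aicc(lnl, k, dataset.alignments[0].n_taxa, dataset.total_sites),
        per_uce_lnl=dict(zip(dataset.uce_ids, per_uce.tolist())),
        tree_newick=work_tree.to_newick(),
        n_cycles=n_cycles,
        lnl_trace=trace,
        seed=config.seed,
        params={
            "ncat": engine.ncat,
            "uces": [
                {
                    "exchangeabilities": t.exchangeabilities.tolist(),
                    "base_freqs": t.base_freqs.tolist(),
                    "alpha": t.alpha,
                }
                for t in thetas
            ],
            "uce_ids": dataset.uce_ids,
        },
        tree=work_tree,
        gtr_thetas=thetas,
        gamma_ncat=engine.ncat,
    )


def _fit_gtr_per_uce(dataset, tree, config, ncat, gamma) -> FitResult:
    """Independent GTR(+Gamma) fit per UCE (own branch lengths each)."""
    results = []
    for a in dataset.alignments:
        sub = UCEDataset(alignments=[a], taxa=dataset.taxa)
        results.append(fit_gtr_gamma(sub, tree, config, ncat, gamma, shared_branches=True))
    lnl = sum(r.log_likelihood for r in results)
    k = sum(r.n_parameters for r in results)
    return FitResult(
        model="gtr_gamma_per_uce",
        log_likelihood=lnl,
        n_parameters=k,
        aicc=aicc(lnl, k, dataset.alignments[0].n_taxa, dataset.total_sites),
        per_uce_lnl={r.params["uce_ids"][0]: r.log_likelihood for r in results},
        tree_newick=tree.to_newick(),
        n_cycles=max(r.n_cycles for r in results),
        lnl_trace=[lnl],
        seed=config.seed,
        params={"per_uce_fits": [r.to_dict() for r in results]},
        tree=tree,
        gamma_ncat=ncat if gamma else 1,
    )
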