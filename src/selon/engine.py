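"""Vectorised whole-dataset likelihood evaluators used by the optimizer.

Two engines share the pruning core in :mod:`selon.likelihood`:

* :class:`SelonEngine` — every site of every UCE has its own rate matrix,
  built from the shared mutation matrix, the UCE's Gaussian selection
  profile, and its optimal base.  Sites with identical (sensitivity,
  optimal-base) pairs share one decomposition.  Matrices are calibrated to
  substitutions-per-site units per site by default (each divided by its own
  stationary rate); the reported scale factor C is the dataset mean rate.
* :class:`GtrGammaEngine` — the spatially invariant comparison model: one
  GTR matrix and Gamma shape per UCE, discrete rate categories via Laguerre
  quadrature, branch lengths shared across UCEs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    MutationModel,
    PopulationConfig,
    SelectionProfile,
    build_site_rate_matrices,
    stationary_distributions,
    stationary_rates,
)
from .likelihood import (
    EigSystem,
    gtr_rate_matrix,
    laguerre_gamma_rates,
    prune_loglik,
)
from .tree import RootedTree


@dataclass
class SelonParams:
    """Complete SelON parameter bundle (branch lengths live on the tree)."""

    mutation: MutationModel
    profiles: list[SelectionProfile]
    optima: list[np.ndarray]
    pop: PopulationConfig

    def copy(self) -> "SelonParams":
        return SelonParams(
            mutation=self.mutation,
            profiles=list(self.profiles),
            optima=[o.copy() for o in self.optima],
            pop=self.pop,
        )


#: floor on a per-site stationary rate before rescaling (see core.scale_sites)
_RATE_FLOOR = 1e-12


@dataclass
class SiteSet:
    """Deduplicated per-site rate matrices for one parameter setting."""

    inverse: np.ndarray  # site -> unique-class index
    q_unique: np.ndarray  # (n_unique, 4, 4), raw (unscaled) rates
    pi_unique: np.ndarray  # (n_unique, 4)
    rates_unique: np.ndarray  # (n_unique,) stationary substitution rates
    mean_rate: float  # stationary rate averaged over *sites* (the reported C)

    @property
    def pi_sites(self) -> np.ndarray:
        return self.pi_unique[self.inverse]

    def scaled_q_unique(self, per_site: bool, c: float | None = None) -> np.ndarray:
        if per_site:
            div = np.maximum(self.rates_unique, _RATE_FLOOR)[:, None, None]
        else:
            div = c if c is not None else self.mean_rate
        return self.q_unique / div


def _dataset_order(dataset, tree: RootedTree) -> np.ndarray:
    if set(dataset.taxa) != set(tree.taxa):
        raise ValueError("tree and dataset taxon sets differ")
    return np.array([dataset.taxa.index(t) for t in tree.taxa])


class SelonEngine:
    """Whole-dataset likelihood for the selection model.

    ``scaling`` selects how raw site matrices are calibrated to
    substitutions-per-site units: ``"per_site"`` (default; each site by its
    own stationary rate) or ``"mean"`` (all sites by the dataset mean rate).
    """

    def __init__(
        self,
        dataset,
        tree: RootedTree,
        pop: PopulationConfig | None = None,
        scaling: str = "per_site",
    ):
        if scaling not in ("per_site", "mean"):
            raise ValueError("scaling must be 'per_site' or 'mean'")
        self.dataset = dataset
        self.tree = tree
        self.scaling = scaling
        self.pop = pop or PopulationConfig()
        order = _dataset_order(dataset, tree)
        self.codes = dataset.concatenated_codes()[order]
        bounds = np.concatenate([[0], np.cumsum(dataset.site_counts)])
        self.uce_slices = [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]
        self.positions = [np.arange(1.0, n + 1.0) for n in dataset.site_counts]
        self.n_sites = int(bounds[-1])
        # column-pattern ids let evaluations collapse sites that share both
        # a rate-matrix class and an observed pattern (big win for neutral
        # or low-diversity data; no-op when every site is distinct)
        _, self.pattern_id = np.unique(self.codes.T, axis=0, return_inverse=True)
        self.pattern_id = self.pattern_id.astype(np.int64)

    # -- site-model assembly ----------------------------------------------

    def site_arrays(self, params: SelonParams) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated per-site sensitivities f(k) and optimal bases."""
        f = np.concatenate(
            [pr.sensitivity(pos) for pr, pos in zip(params.profiles, self.positions)]
        )
        opt = np.concatenate(params.optima)
        return f, opt.astype(np.int64)

    def site_set(self, params: SelonParams, f=None, opt=None) -> SiteSet:
        if f is None or opt is None:
            f, opt = self.site_arrays(params)
        key = np.column_stack([f, opt.astype(float)])
        uniq, inverse = np.unique(key, axis=0, return_inverse=True)
        q = build_site_rate_matrices(
            uniq[:, 1].astype(np.int64), uniq[:, 0], params.mutation, params.pop
        )
        pi = stationary_distributions(q)
        rates = stationary_rates(q, pi)
        mean_rate = float(rates[inverse].mean())
        return SiteSet(
            inverse=inverse,
            q_unique=q,
            pi_unique=pi,
            rates_unique=rates,
            mean_rate=mean_rate,
        )

    def scale_factor(self, params: SelonParams) -> float:
        return self.site_set(params).mean_rate

    # -- likelihood --------------------------------------------------------

    def branch_matrices(
        self,
        site_set: SiteSet,
        c: float | None,
        lengths: np.ndarray,
        gather: np.ndarray | None = None,
    ) -> dict:
        eig = EigSystem(site_set.scaled_q_unique(self.scaling == "per_site", c))
        nodes = [int(n) for n in self.tree.branch_nodes]
        idx = site_set.inverse if gather is None else gather
        ps = eig.transitions(np.array([float(lengths[n]) for n in nodes]))
        return {n: ps[i][idx] for i, n in enumerate(nodes)}

    def loglik(
        self,
        params: SelonParams,
        lengths: np.ndarray | None = None,
        c: float | None = None,
        per_site: bool = False,
    ):
        """Total (or per-site) log-likelihood.

        Under per-site scaling ``c`` is irrelevant; under mean scaling it
        overrides the recomputed dataset mean rate when given.
        """
        lengths = self.tree.lengths if lengths is None else lengths
        ss = self.site_set(params)
        combo = ss.inverse * (self.pattern_id.max() + 1) + self.pattern_id
        uniq, first, inv = np.unique(combo, return_index=True, return_inverse=True)
        if uniq.size < 0.7 * self.n_sites:
            cls = ss.inverse[first]
            branch_p = self.branch_matrices(ss, c, lengths, gather=cls)
            lnl = prune_loglik(
                self.tree, self.codes[:, first], branch_p, ss.pi_unique[cls]
            )[inv]
        else:
            branch_p = self.branch_matrices(ss, c, lengths)
            lnl = prune_loglik(self.tree, self.codes, branch_p, ss.pi_sites)
        return lnl if per_site else float(lnl.sum())

    def per_uce_loglik(self, params: SelonParams, lengths=None, c=None) -> np.ndarray:
        site = self.loglik(params, lengths, c, per_site=True)
        return np.array([site[sl].sum() for sl in self.uce_slices])

    def uce_loglik(
        self,
        params: SelonParams,
        uce_index: int,
        c: float | None = None,
        profile: SelectionProfile | None = None,
        lengths: np.ndarray | None = None,
    ) -> float:
        """Log-likelihood of a single UCE (scale factor ``c`` held fixed in
        mean-scaling mode, so the per-UCE shape objective is separable).

        Only this UCE's site models are rebuilt (optionally under a trial
        ``profile``).
        """
        lengths = self.tree.lengths if lengths is None else lengths
        pr = profile if profile is not None else params.profiles[uce_index]
        pos = self.positions[uce_index]
        f = pr.sensitivity(pos)
        opt = params.optima[uce_index].astype(np.int64)
        q = build_site_rate_matrices(opt, f, params.mutation, params.pop)
        pi = stationary_distributions(q)
        if self.scaling == "per_site":
            rates = np.maximum(stationary_rates(q, pi), _RATE_FLOOR)
            eig = EigSystem(q / rates[:, None, None])
        else:
            eig = EigSystem(q / c)
        sl = self.uce_slices[uce_index]
        nodes = [int(n) for n in self.tree.branch_nodes]
        ps = eig.transitions(np.array([float(lengths[n]) for n in nodes]))
        branch_p = {n: ps[i] for i, n in enumerate(nodes)}
        lnl = prune_loglik(self.tree, self.codes[:, sl], branch_p, pi)
        return float(lnl.sum())

    def candidate_site_logliks(
        self, params: SelonParams, c: float | None = None, lengths: np.ndarray | None = None
    ) -> np.ndarray:
        """(4, n_sites) per-site log-likelihood for each candidate optimum.

        The scale factor is held fixed at ``c`` during the sweep.
        """
        lengths = self.tree.lengths if lengths is None else lengths
        f, _ = self.site_arrays(params)
        out = np.empty((4, self.n_sites))
        for cand in range(4):
            opt = np.full(self.n_sites, cand, dtype=np.int64)
            ss = self.site_set(params, f=f, opt=opt)
            branch_p = self.branch_matrices(ss, c, lengths)
            out[cand] = prune_loglik(self.tree, self.codes, branch_p, ss.pi_sites)
        return out


# ---------------------------------------------------------------------------
# GTR(+Gamma) partitioned engine
# ---------------------------------------------------------------------------


@dataclass
class GtrUceParams:
    """Per-UCE GTR+Gamma parameters (exchangeabilities, frequencies, shape)."""

    exchangeabilities: np.ndarray  # (5,) with G-T pinned at 1
    base_freqs: np.ndarray  # (4,) summing to 1
    alpha: float | None  # None disables rate heterogeneity


class GtrGammaEngine:
    """Partitioned GTR(+Gamma) likelihood: per-UCE rate matrices and Gamma
    shapes, branch lengths shared across UCEs.

    Alignment columns are compressed once at construction into unique
    (UCE, site-pattern) combinations with multiplicities — the per-UCE
    rate matrices make columns within a UCE exchangeable, so this is exact
    and permanent.
    """

    def __init__(self, dataset, tree: RootedTree, ncat: int = 4):
        self.dataset = dataset
        self.tree = tree
        self.ncat = int(ncat)
        order = _dataset_order(dataset, tree)
        self.codes = dataset.concatenated_codes()[order]
        bounds = np.concatenate([[0], np.cumsum(dataset.site_counts)])
        self.uce_slices = [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]
        self.uce_of_site = np.repeat(np.arange(dataset.n_uces), dataset.site_counts)
        self.n_sites = int(bounds[-1])
        _, pattern_id = np.unique(self.codes.T, axis=0, return_inverse=True)
        combo = self.uce_of_site * (pattern_id.max() + 1) + pattern_id.astype(np.int64)
        _, first, inv, counts = np.unique(
            combo, return_index=True, return_inverse=True, return_counts=True
        )
        self.combo_first = first
        self.combo_inv = inv
        self.combo_counts = counts.astype(float)
        self.codes_c = self.codes[:, first]
        self.uce_of_combo = self.uce_of_site[first]
        self.n_combos = first.size
        # per-UCE compressed views for the per-UCE objective
        self._uce_combo_idx = [
            np.flatnonzero(self.uce_of_combo == u) for u in range(dataset.n_uces)
        ]

    def _components(self, thetas: list[GtrUceParams]):
        q = np.stack(
            [gtr_rate_matrix(t.exchangeabilities, t.base_freqs) for t in thetas]
        )
        rates = np.ones((len(thetas), self.ncat))
        weights = np.ones((len(thetas), self.ncat)) / self.ncat
        for u, t in enumerate(thetas):
            if t.alpha is not None:
                g = laguerre_gamma_rates(t.alpha, self.ncat)
                rates[u], weights[u] = g.rates, g.weights
        freqs = np.stack([t.base_freqs for t in thetas])
        return EigSystem(q), rates, weights, freqs

    def branch_matrices(self, eig: EigSystem, rates: np.ndarray, t: float) -> np.ndarray:
        """(n_uce, ncat, 4, 4) transition matrices for one branch length."""
        wt = eig.w[:, None, :] * (rates[:, :, None] * t)
        wt = np.minimum(wt.real, 0.0) + 1j * wt.imag
        ew = np.exp(wt)
        p = np.real((eig.v[:, None] * ew[:, :, None, :]) @ eig.vinv[:, None])
        for k in eig.bad:
            from scipy.linalg import expm

            for c in range(rates.shape[1]):
                p[k, c] = expm(eig.q[k] * rates[k, c] * t)
        np.clip(p, 0.0, None, out=p)
        s = p.sum(axis=3, keepdims=True)
        p /= np.where(s > 0, s, 1.0)
        return p

    def _combo_logliks(self, thetas: list[GtrUceParams], lengths=None) -> np.ndarray:
        """(n_combos,) category-averaged log-likelihood per unique column."""
        from scipy.special import logsumexp

        lengths = self.tree.lengths if lengths is None else lengths
        eig, rates, weights, freqs = self._components(thetas)
        branch_p = {
            int(n): self.branch_matrices(eig, rates, float(lengths[n]))
            for n in self.tree.branch_nodes
        }
        cat = np.empty((self.ncat, self.n_combos))
        for c in range(self.ncat):
            pc = {n: p[self.uce_of_combo, c] for n, p in branch_p.items()}
            cat[c] = prune_loglik(self.tree, self.codes_c, pc, freqs[self.uce_of_combo])
        logw = np.log(weights[self.uce_of_combo]).T  # (ncat, n_combos)
        return logsumexp(cat + logw, axis=0)

    def site_logliks(self, thetas: list[GtrUceParams], lengths=None) -> np.ndarray:
        """Per-site log-likelihood, category-averaged with per-UCE weights."""
        return self._combo_logliks(thetas, lengths)[self.combo_inv]

    def loglik(self, thetas: list[GtrUceParams], lengths=None) -> float:
        return float(self._combo_logliks(thetas, lengths) @ self.combo_counts)

    def per_uce_loglik(self, thetas, lengths=None) -> np.ndarray:
        combo = self._combo_logliks(thetas, lengths) * self.combo_counts
        return np.array([combo[idx].sum() for idx in self._uce_combo_idx])

    def uce_loglik(self, uce_index: int, theta: GtrUceParams, lengths=None) -> float:
        from scipy.special import logsumexp

        lengths = self.tree.lengths if lengths is None else lengths
        q = gtr_rate_matrix(theta.exchangeabilities, theta.base_freqs)
        w, v = np.linalg.eig(q)
        vinv = np.linalg.inv(v)
        if theta.alpha is not None:
            g = laguerre_gamma_rates(theta.alpha, self.ncat)
            rates, weights = g.rates, g.weights
        else:
            rates = np.ones(self.ncat)
            weights = np.full(self.ncat, 1.0 / self.ncat)
        idx = self._uce_combo_idx[uce_index]
        codes = self.codes_c[:, idx]
        counts = self.combo_counts[idx]
        nodes = [int(n) for n in self.tree.branch_nodes]
        ts = np.array([float(lengths[n]) for n in nodes])
        wt = w[None, None, :] * (ts[:, None, None] * rates[None, :, None])
        wt = np.minimum(wt.real, 0.0) + 1j * wt.imag
        p = np.real((v[None, None] * np.exp(wt)[..., None, :]) @ vinv[None, None])
        np.clip(p, 0.0, None, out=p)
        s = p.sum(axis=3, keepdims=True)
        p /= np.where(s > 0, s, 1.0)  # (n_branch, ncat, 4, 4)
        cat = np.empty((self.ncat, idx.size))
        freqs = theta.base_freqs[None]
        for c in range(self.ncat):
            branch_p = {n: p[i, c][None] for i, n in enumerate(nodes)}
            cat[c] = prune_loglik(self.tree, codes, branch_p, freqs)
        lnl = logsumexp(cat + np.log(weights)[:, None], axis=0)
        return float(lnl @ counts)

    def site_mean_rates(self, thetas: list[GtrUceParams], lengths=None) -> np.ndarray:
        """Posterior model-averaged Gamma rate per site."""
        from scipy.special import logsumexp

        lengths = self.tree.lengths if lengths is None else lengths
        eig, rates, weights, freqs = self._components(thetas)
        cat = np.empty((self.ncat, self.n_combos))
        for c in range(self.ncat):
            branch_p = {
                int(n): self.branch_matrices(eig, rates[:, c : c + 1], float(lengths[n]))[
                    self.uce_of_combo, 0
                ]
                for n in self.tree.branch_nodes
            }
            cat[c] = prune_loglik(self.tree, self.codes_c, branch_p, freqs[self.uce_of_combo])
        logw = np.log(weights[self.uce_of_combo]).T
        post = np.exp(cat + logw - logsumexp(cat + logw, axis=0, keepdims=True))
        combo_rates = np.einsum("sc,cs->s", rates[self.uce_of_combo], post)
        return combo_rates[self.combo_inv]
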