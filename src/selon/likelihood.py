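"""Phylogenetic likelihood primitives.

Felsenstein pruning on rooted trees with per-site rate matrices (the
selection model is non-reversible, so every site carries its own Q and its
own stationary root distribution), transition probabilities via the matrix
exponential, discrete Gamma rate heterogeneity through generalized Laguerre
quadrature, a GTR(+Gamma) comparison likelihood, and AICc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.linalg import eigh_tridiagonal
from scipy.special import logsumexp

from .core import MISSING, _gtr_exchange_matrix, stationary_distributions
from .tree import RootedTree

_LEAF_PARTIALS = np.vstack([np.eye(4), np.ones((1, 4))])  # row 4 = MISSING


def transition_probabilities(q_scaled: np.ndarray, t: float) -> np.ndarray:
    """Transition matrix P(t) = exp(Q t) for a single rate matrix."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    q = np.asarray(q_scaled, dtype=float)
    p = expm(q * t)
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


class EigSystem:
    """Batched eigen decomposition of (n, 4, 4) rate matrices.

    P(t) for all matrices at once is ``V exp(w t) V^-1``; matrices whose
    eigenbasis is ill-conditioned (near-defective Q) fall back to
    scaling-and-squaring via :func:`scipy.linalg.expm`.
    """

    def __init__(self, q_batch: np.ndarray):
        q = np.ascontiguousarray(q_batch, dtype=float)
        self.q = q
        w, v = np.linalg.eig(q)
        self.w = w
        self.v = v
        self.vinv = np.linalg.inv(v)
        cond = np.linalg.norm(v, axis=(1, 2)) * np.linalg.norm(self.vinv, axis=(1, 2))
        self.bad = np.flatnonzero(cond > 1e8)

    def transition(self, t: float) -> np.ndarray:
        """(n, 4, 4) stochastic matrices exp(Q t)."""
        return self.transitions(np.array([t]))[0]

    def transitions(self, ts: np.ndarray) -> np.ndarray:
        """(len(ts), n, 4, 4) transition matrices, all times in one batch."""
        ts = np.asarray(ts, dtype=float)
        wt = self.w[None, :, :] * ts[:, None, None]
        # rate-matrix eigenvalues have non-positive real part; roundoff on
        # strongly rescaled matrices can flip the sign and overflow exp
        wt = np.minimum(wt.real, 0.0) + 1j * wt.imag
        ew = np.exp(wt)
        p = np.real((self.v[None] * ew[:, :, None, :]) @ self.vinv[None])
        for k in self.bad:
            for b, t in enumerate(ts):
                p[b, k] = expm(self.q[k] * t)
        np.clip(p, 0.0, None, out=p)
        s = p.sum(axis=3, keepdims=True)
        p /= np.where(s > 0, s, 1.0)
        return p


def leaf_partials(codes: np.ndarray) -> np.ndarray:
    """Partial likelihoods of observed leaf states; MISSING contributes 1."""
    return _LEAF_PARTIALS[np.asarray(codes, dtype=np.int64)]


def prune_loglik(
    tree: RootedTree,
    codes: np.ndarray,
    branch_p: dict | list,
    root_freq: np.ndarray,
) -> np.ndarray:
    """Per-site log-likelihoods by postorder pruning with rescaling.

    Parameters
    ----------
    codes : (n_taxa, n_sites) integer states with 4 meaning missing.
    branch_p : mapping from non-root node index to its branch's transition
        matrices, shaped (n_sites, 4, 4) or (1, 4, 4) shared across sites.
    root_freq : (n_sites, 4) or (1, 4) root state frequencies.
    """
    n_sites = codes.shape[1]
    partial = [None] * tree.n_nodes
    logscale = np.zeros(n_sites)
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            partial[node] = leaf_partials(codes[node])
            continue
        acc = None
        for c in kids:
            contrib = (branch_p[c] @ partial[c][..., None])[..., 0]
            acc = contrib if acc is None else acc * contrib
            partial[c] = None
        scale = acc.max(axis=1)
        safe = np.where(scale > 0, scale, 1.0)
        partial[node] = acc / safe[:, None]
        with np.errstate(divide="ignore"):
            logscale += np.where(scale > 0, np.log(safe), -np.inf)
    like = (np.asarray(root_freq) * partial[tree.root]).sum(axis=1)
    with np.errstate(divide="ignore"):
        return np.log(like) + logscale


def site_log_likelihood(tree: RootedTree, pattern: np.ndarray, site) -> float:
    """Log-likelihood of one site pattern under its site model.

    Root frequencies are the site's stationary distribution (the model
    assumes the process starts at equilibrium).  Uses the scaled rate matrix
    when present, else the raw one.
    """
    pattern = np.asarray(pattern, dtype=np.int64)
    if pattern.size != tree.n_taxa:
        raise ValueError("pattern length must match the tree's taxa")
    q = site.q_scaled if site.q_scaled is not None else site.q_raw
    branch_p = {}
    for node in tree.branch_nodes:
        branch_p[int(node)] = transition_probabilities(q, float(tree.lengths[node]))[None]
    lnl = prune_loglik(tree, pattern[:, None], branch_p, site.pi[None])
    return float(lnl[0])


def uce_log_likelihood(tree: RootedTree, alignment, sites: list) -> np.ndarray | float:
    """Sum of per-site log-likelihoods of one UCE alignment."""
    if len(sites) != alignment.codes.shape[1]:
        raise ValueError("one site model per alignment column is required")
    if tuple(alignment.taxa) != tuple(tree.taxa):
        alignment = alignment.reordered(tree.taxa)
    q = np.stack([s.q_scaled if s.q_scaled is not None else s.q_raw for s in sites])
    pi = np.stack([s.pi for s in sites])
    eig = EigSystem(q)
    branch_p = {int(n): eig.transition(float(tree.lengths[n])) for n in tree.branch_nodes}
    lnl = prune_loglik(tree, alignment.codes, branch_p, pi)
    return float(lnl.sum())


# ---------------------------------------------------------------------------
# Gamma rate heterogeneity via generalized Laguerre quadrature
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GammaRateModel:
    """Discrete rate categories approximating a unit-mean Gamma density."""

    alpha: float
    ncat: int
    rates: np.ndarray
    weights: np.ndarray


def laguerre_gamma_rates(alpha: float, ncat: int = 4) -> GammaRateModel:
    """Rate categories for Gamma(alpha, alpha) by generalized Laguerre
    quadrature.

    The quadrature nodes x_i and weights w_i of the weight function
    x^(alpha-1) e^(-x) turn expectations under the unit-mean Gamma density
    into the weighted sum of f(x_i / alpha); weights are normalized to sum to
    one and rates rescaled so the mean rate is exactly one.
    """
    if alpha <= 0:
        raise ValueError("Gamma shape alpha must be positive")
    if ncat < 1:
        raise ValueError("need at least one rate category")
    # Golub-Welsch on the generalized-Laguerre Jacobi matrix: eigenvalues are
    # the nodes and squared first eigenvector components the normalized
    # weights (robust for large alpha, where the raw weights overflow).
    a = alpha - 1.0
    i = np.arange(ncat, dtype=float)
    diag = 2.0 * i + a + 1.0
    off = np.sqrt((i[1:]) * (i[1:] + a))
    x, vec = eigh_tridiagonal(diag, off)
    weights = vec[0] ** 2
    weights = weights / weights.sum()
    rates = x / alpha
    rates = rates / float(weights @ rates)
    return GammaRateModel(alpha=float(alpha), ncat=int(ncat), rates=rates, weights=weights)


# ---------------------------------------------------------------------------
# GTR(+Gamma) comparison model
# ---------------------------------------------------------------------------


def gtr_rate_matrix(exchangeabilities, base_freqs) -> np.ndarray:
    """Reversible GTR rate matrix normalized to mean rate 1 at stationarity.

    ``exchangeabilities`` are the five free symmetric rates (A-C, A-G, A-T,
    C-G, C-T) with G-T pinned at 1.
    """
    exch = np.asarray(exchangeabilities, dtype=float)
    freqs = np.asarray(base_freqs, dtype=float)
    if np.any(exch <= 0):
        raise ValueError("GTR exchangeabilities must be positive")
    if np.any(freqs <= 0) or abs(freqs.sum() - 1.0) > 1e-8:
        raise ValueError("base frequencies must be positive and sum to 1")
    q = _gtr_exchange_matrix(exch) * freqs[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    c = -float(freqs @ np.diag(q))
    return q / c


def gtr_gamma_site_logliks(
    tree: RootedTree,
    codes: np.ndarray,
    exchangeabilities,
    base_freqs,
    gamma: GammaRateModel | None = None,
) -> np.ndarray:
    """(n_categories, n_sites) per-category per-site log-likelihoods."""
    q = gtr_rate_matrix(exchangeabilities, base_freqs)
    freqs = np.asarray(base_freqs, dtype=float)[None]
    rates = gamma.rates if gamma is not None else np.array([1.0])
    out = np.empty((rates.size, codes.shape[1]))
    for c, r in enumerate(rates):
        branch_p = {
            int(n): transition_probabilities(q, r * float(tree.lengths[n]))[None]
            for n in tree.branch_nodes
        }
        out[c] = prune_loglik(tree, codes, branch_p, freqs)
    return out


def gtr_gamma_log_likelihood(
    tree: RootedTree,
    alignment,
    exchangeabilities,
    base_freqs,
    gamma: GammaRateModel | None = None,
    per_site: bool = False,
):
    """GTR(+Gamma) log-likelihood of one alignment.

    A site's likelihood is the category-weight-averaged pruning likelihood;
    with ``gamma=None`` (one unit-rate category) this is the plain GTR
    likelihood.
    """
    cat = gtr_gamma_site_logliks(tree, alignment.codes, exchangeabilities, base_freqs, gamma)
    logw = np.log(gamma.weights)[:, None] if gamma is not None else np.zeros((1, 1))
    site_lnl = logsumexp(cat + logw, axis=0)
    return site_lnl if per_site else float(site_lnl.sum())


def gamma_site_mean_rates(cat_logliks: np.ndarray, gamma: GammaRateModel) -> np.ndarray:
    """Posterior model-averaged rate per site, sum_c r_c w_c L_c / sum_c w_c L_c."""
    logw = np.log(gamma.weights)[:, None]
    post = np.exp(cat_logliks + logw - logsumexp(cat_logliks + logw, axis=0, keepdims=True))
    return gamma.rates @ post


def aicc(lnl: float, k: int, n_taxa: int, n_sites: int) -> float:
    """Sample-size corrected AIC with n = taxa x sites."""
    n = n_taxa * n_sites
    if n <= k + 1:
        raise ValueError("AICc undefined: sample size must exceed k + 1")
    return -2.0 * lnl + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)
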