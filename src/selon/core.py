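"""Core mutation-selection-drift model mathematics.

The substitution process at each site of an ultraconserved element (UCE) is
assembled from three ingredients:

* a global 4x4 nucleotide mutation-rate matrix ``M`` shared by every UCE;
* a per-UCE Gaussian selection-sensitivity profile ``f(x)`` describing how
  strongly each position is held to an optimal target nucleotide; and
* the fixation probability of a new mutant under genetic drift in a finite
  population of effective size ``Ne``.

The per-site substitution rate from resident nucleotide ``i`` to mutant ``j``
is ``q_ij = 2 b mu_ij Ne u_ij``, where ``u_ij`` is the probability that the
mutant fixes given the fitness ratio of the two sequences.  Each site gets its
own rate matrix and stationary distribution; a global scale factor ``C``
(the mean stationary substitution rate across the analysed sites) calibrates
branch lengths to expected substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NUCLEOTIDES: tuple[str, str, str, str] = ("A", "C", "G", "T")
NUC_INDEX: dict[str, int] = {b: i for i, b in enumerate(NUCLEOTIDES)}
#: integer code used at the alignment level for gaps / ambiguity codes
MISSING: int = 4

_G = NUC_INDEX["G"]
_T = NUC_INDEX["T"]

# off-diagonal (row, col) pairs in row-major order
_OFFDIAG = [(i, j) for i in range(4) for j in range(4) if i != j]
#: free UNREST entries: all off-diagonals except the pinned G->T rate
UNREST_FREE_ENTRIES = [p for p in _OFFDIAG if p != (_G, _T)]

_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


class DegenerateMatrixError(ValueError):
    """Raised when a rate matrix has no unique stationary distribution."""


@dataclass(frozen=True)
class MutationModel:
    """Global nucleotide mutation-rate specification.

    ``matrix`` holds the 4x4 rate matrix ``M`` with off-diagonal entries
    ``mu_ij >= 0`` and diagonals set to negative row sums.  ``flavor`` records
    the parameterisation the matrix was built from (JC, HKY, GTR or the
    unrestricted 12-rate model UNREST, whose G->T rate is pinned at 1 to fix
    the relative scale).
    """

    flavor: str
    free_rates: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("mutation matrix must be 4x4")
        object.__setattr__(self, "matrix", m)


def build_mutation_matrix(flavor: str, free_rates=()) -> MutationModel:
    """Build a :class:`MutationModel` from a flavor and its free parameters.

    Parameter conventions:

    * ``JC``: no parameters; every off-diagonal rate is 1.
    * ``HKY``: ``[kappa, piA, piC, piG, piT]`` with ``mu_ij = pi_j * kappa``
      for transitions and ``pi_j`` for transversions.
    * ``GTR``: five exchangeabilities ``[rAC, rAG, rAT, rCG, rCT]`` (G-T
      pinned at 1) followed by four base frequencies.
    * ``UNREST``: eleven nonnegative rates for the off-diagonal entries in
      row-major order skipping (G, T), which is pinned at 1.
    """
    rates = np.asarray(free_rates, dtype=float).ravel()
    if np.any(rates < 0):
        raise ValueError("mutation rates must be nonnegative")
    m = np.zeros((4, 4))
    flavor = flavor.upper()
    if flavor == "JC":
        if rates.size != 0:
            raise ValueError("JC takes no free parameters")
        m[:] = 1.0
    elif flavor == "HKY":
        if rates.size != 5:
            raise ValueError("HKY takes 5 parameters (kappa + 4 frequencies)")
        kappa, freqs = rates[0], rates[1:]
        _check_freqs(freqs)
        for i, j in _OFFDIAG:
            m[i, j] = freqs[j] * (kappa if (i, j) in _TRANSITIONS else 1.0)
    elif flavor == "GTR":
        if rates.size != 9:
            raise ValueError("GTR takes 9 parameters (5 exchangeabilities + 4 frequencies)")
        exch, freqs = rates[:5], rates[5:]
        _check_freqs(freqs)
        x = _gtr_exchange_matrix(exch)
        for i, j in _OFFDIAG:
            m[i, j] = x[i, j] * freqs[j]
    elif flavor == "UNREST":
        if rates.size != 11:
            raise ValueError("UNREST takes 11 free rates (G->T pinned at 1)")
        for (i, j), r in zip(UNREST_FREE_ENTRIES, rates):
            m[i, j] = r
        m[_G, _T] = 1.0
    else:
        raise ValueError(f"unknown mutation model flavor: {flavor!r}")
    np.fill_diagonal(m, 0.0)
    np.fill_diagonal(m, -m.sum(axis=1))
    return MutationModel(flavor=flavor, free_rates=tuple(rates), matrix=m)


def _check_freqs(freqs):
    if np.any(np.asarray(freqs) < 0) or abs(np.sum(freqs) - 1.0) > 1e-8:
        raise ValueError("base frequencies must be nonnegative and sum to 1")


def _gtr_exchange_matrix(exch):
    """Symmetric exchangeability matrix with the G-T entry pinned at 1."""
    x = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]
    for (i, j), r in zip(pairs, exch):
        x[i, j] = x[j, i] = r
    x[_G, _T] = x[_T, _G] = 1.0
    return x


@dataclass(frozen=True)
class SelectionProfile:
    """Gaussian spatial selection-sensitivity profile of one UCE.

    ``nes_max`` is the composite Ne*s_max at the peak, ``center`` the 1-based
    position of the most conserved site (continuous), and ``width`` the
    Gaussian standard deviation in site units.
    """

    nes_max: float
    center: float
    width: float

    def __post_init__(self):
        if self.nes_max < 0:
            raise ValueError("nes_max must be nonnegative")
        if self.width <= 0:
            raise ValueError("width must be positive")

    def sensitivity(self, position):
        """Evaluate f(x) = Nes_max * exp(-(x - center)^2 / (2 width^2))."""
        x = np.asarray(position, dtype=float)
        out = self.nes_max * np.exp(-((x - self.center) ** 2) / (2.0 * self.width**2))
        return float(out) if np.isscalar(position) else out


def selection_sensitivity(profile: SelectionProfile, position):
    """Functional form of the spatial sensitivity curve (module-level alias)."""
    return profile.sensitivity(position)


@dataclass(frozen=True)
class PopulationConfig:
    """Effective population size and ploidy convention.

    ``ne`` is fixed, not estimated: the selection profile already estimates
    the composite Ne*s, so ``ne`` only enters through the drift exponent
    ``2*Ne`` (and cancels in the neutral limit).  ``ploidy_b`` is 1 for a
    diploid population and 2 for a haploid one.
    """

    ne: float = 1e6
    ploidy_b: int = 1

    def __post_init__(self):
        if self.ne <= 1:
            raise ValueError("effective population size must exceed 1")
        if self.ploidy_b not in (1, 2):
            raise ValueError("ploidy_b must be 1 (diploid) or 2 (haploid)")


def sequence_fitness(observed, optimal, profile: SelectionProfile) -> float:
    """Population-scaled fitness exp(-sum_k d(n_k, n*_k) f(k)).

    ``observed`` and ``optimal`` are equal-length vectors of nucleotide codes
    (0..3); the distance d is binary (0 on match, 1 on mismatch) and
    contributions are independent (multiplicative) across positions.

    The sensitivity f(k) is the composite Ne*s(k), so this quantity is the
    per-copy fitness raised to the Ne power; the fixation machinery divides
    the log by Ne to recover per-copy selection coefficients (only the
    composite is identifiable, which is why the profile parameterises it
    directly).
    """
    obs = np.asarray(observed)
    opt = np.asarray(optimal)
    if obs.shape != opt.shape:
        raise ValueError("observed and optimal sequences must have equal length")
    positions = np.arange(1, obs.size + 1, dtype=float)
    mismatch = (obs != opt).astype(float)
    return float(np.exp(-np.sum(mismatch * profile.sensitivity(positions))))


def fixation_probability(fitness_ratio, pop: PopulationConfig):
    """Probability that a new mutant fixes, u = (1 - r^b) / (1 - r^(2Ne)).

    ``fitness_ratio`` is r = W(resident)/W(mutant); r < 1 means the mutant is
    fitter.  At r = 1 the neutral limit b/(2Ne) is returned.  Computed in log
    space so strongly deleterious mutants underflow gracefully to 0.
    """
    r = np.asarray(fitness_ratio, dtype=float)
    if np.any(r <= 0):
        raise ValueError("fitness ratio must be positive")
    u = fixation_probability_from_log(np.log(r), pop)
    return float(u) if np.isscalar(fitness_ratio) else u


def fixation_probability_from_log(log_ratio, pop: PopulationConfig):
    """Vectorised fixation probability from a = ln(r); overflow-safe."""
    a = np.atleast_1d(np.asarray(log_ratio, dtype=float))
    b, two_ne = float(pop.ploidy_b), 2.0 * pop.ne
    u = np.empty_like(a)

    # the neutral limit is valid only when the drift exponent 2Ne*a is tiny;
    # expm1 is exact for small arguments, so the guard is conservative
    near = np.abs(a) * two_ne < 1e-10
    u[near] = b / two_ne  # analytic r -> 1 limit

    big = (~near) & (two_ne * a > 700.0)  # denominator would overflow
    if np.any(big):
        # u ~ expm1(b a) * exp(-2Ne a); underflows to 0 for strong selection
        u[big] = np.expm1(np.minimum(b * a[big], 700.0)) * np.exp(-two_ne * a[big])

    rest = ~(near | big)
    if np.any(rest):
        u[rest] = np.expm1(b * a[rest]) / np.expm1(two_ne * a[rest])

    np.clip(u, 0.0, 1.0, out=u)
    return u if np.ndim(log_ratio) else u[0]


@dataclass
class SiteModel:
    """Per-site substitution model: raw and scaled rate matrices plus pi."""

    position: int
    sensitivity: float
    q_raw: np.ndarray
    pi: np.ndarray
    q_scaled: np.ndarray | None = None


@dataclass(frozen=True)
class ScaleFactor:
    """Global rate scale C and the identifier of the site set it averages."""

    value: float
    scope: str = "dataset"

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("scale factor must be positive")


def equilibrium_frequencies(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a single 4x4 rate matrix.

    Solves the left null-space system pi Q = 0 with the normalisation
    sum(pi) = 1; tiny negative entries from roundoff are clamped before
    renormalising.  Raises :class:`DegenerateMatrixError` when the matrix has
    no unique stationary vector (reducible or defective input).
    """
    pi = stationary_distributions(np.asarray(q, dtype=float)[None, :, :])[0]
    return pi


def stationary_distributions(q_batch: np.ndarray) -> np.ndarray:
    """Batched stationary distributions of (n, 4, 4) rate matrices.

    Replaces the last equation of Q^T pi = 0 with the simplex constraint and
    solves the resulting linear systems; falls back to an eigen decomposition
    for any site where the direct solve is singular or leaves a residual.
    """
    q = np.asarray(q_batch, dtype=float)
    n = q.shape[0]
    a = np.swapaxes(q, -1, -2).copy()
    a[:, -1, :] = 1.0
    rhs = np.zeros((n, 4, 1))
    rhs[:, -1, 0] = 1.0
    try:
        pi = np.linalg.solve(a, rhs)[..., 0]
    except np.linalg.LinAlgError:
        pi = np.full((n, 4), np.nan)
        for k in range(n):
            try:
                pi[k] = np.linalg.solve(a[k], rhs[k][:, 0])
            except np.linalg.LinAlgError:
                pass
    bad = ~np.isfinite(pi).all(axis=1)
    pi = np.where(np.isfinite(pi), pi, 0.0)
    pi[pi < 0] = np.where(pi[pi < 0] > -1e-9, 0.0, np.nan)
    bad |= ~np.isfinite(pi).all(axis=1)
    # residual check against the defining equation pi Q = 0
    resid = np.einsum("ni,nij->nj", pi, q)
    scale = np.maximum(np.abs(q).max(axis=(1, 2)), 1.0)
    bad |= np.abs(resid).max(axis=1) > 1e-8 * scale
    if np.any(bad):
        for k in np.flatnonzero(bad):
            pi[k] = _stationary_eig(q[k])
    pi /= pi.sum(axis=1, keepdims=True)
    return pi


def _stationary_eig(q: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(q.T)
    order = np.argsort(np.abs(w))
    k = int(order[0])
    scale = max(1.0, np.abs(q).max())
    if abs(w[k]) > 1e-6 * scale:
        raise DegenerateMatrixError("rate matrix has no zero eigenvalue")
    if abs(w[order[1]]) < 1e-10 * scale:
        raise DegenerateMatrixError(
            "stationary distribution is not unique (reducible rate matrix)"
        )
    pi = np.real(v[:, k])
    if pi.sum() < 0:
        pi = -pi
    pi[np.abs(pi) < 1e-12] = 0.0
    if np.any(pi < 0) or pi.sum() <= 0:
        raise DegenerateMatrixError("rate matrix has no valid stationary vector")
    return pi / pi.sum()


def build_site_rate_matrices(
    optimal: np.ndarray,
    sensitivity: np.ndarray,
    mut: MutationModel,
    pop: PopulationConfig,
) -> np.ndarray:
    """Vectorised raw per-site rate matrices Q (n_sites, 4, 4).

    For a single-site substitution at a site with optimal base ``o`` and
    composite sensitivity ``f = Ne*s``, the per-copy selection coefficient
    is s = f/Ne, so the resident/mutant log fitness ratio is +f/Ne when the
    resident is optimal (deleterious change), -f/Ne when the mutant is
    optimal (beneficial change), and 0 between two non-optimal bases.  The
    rate is q_ij = 2 b mu_ij Ne u_ij with diagonals set to negative row
    sums; it depends on Ne only through the composite (for a deleterious
    change q_ij -> 2 b mu_ij f / (e^(2f) - 1) as Ne grows).
    """
    opt = np.asarray(optimal, dtype=np.int64)
    f = np.asarray(sensitivity, dtype=float)
    if opt.shape != f.shape:
        raise ValueError("optimal and sensitivity vectors must align")
    n = opt.size
    b, ne = float(pop.ploidy_b), pop.ne
    pref = 2.0 * b * ne

    s = f / ne  # per-copy selection coefficient from the composite
    u_del = fixation_probability_from_log(s, pop)  # away from the optimum
    u_ben = fixation_probability_from_log(-s, pop)  # toward the optimum
    u_neu = b / (2.0 * ne)

    mu = mut.matrix.copy()
    np.fill_diagonal(mu, 0.0)

    q = np.empty((n, 4, 4))
    q[:] = pref * u_neu * mu  # neutral background (non-optimal <-> non-optimal)
    rows = np.arange(n)
    # substitutions leaving the optimal base are deleterious
    q[rows, opt, :] = pref * u_del[:, None] * mu[opt, :]
    # substitutions into the optimal base are beneficial
    q[rows, :, opt] = pref * u_ben[:, None] * mu[:, opt].T
    q[rows, opt, opt] = 0.0
    diag = -q.sum(axis=2)
    q[rows[:, None], np.arange(4)[None, :], np.arange(4)[None, :]] = diag
    return q


def site_rate_matrix(
    position: int,
    optimal_base: int,
    mut: MutationModel,
    profile: SelectionProfile,
    pop: PopulationConfig,
) -> SiteModel:
    """Raw rate matrix and stationary distribution of one site."""
    f = profile.sensitivity(float(position))
    q = build_site_rate_matrices(
        np.array([optimal_base]), np.array([f]), mut, pop
    )[0]
    pi = equilibrium_frequencies(q)
    return SiteModel(position=int(position), sensitivity=float(f), q_raw=q, pi=pi)


def stationary_rates(q_batch: np.ndarray, pi_batch: np.ndarray) -> np.ndarray:
    """Per-site expected substitution rate at equilibrium, -sum_i pi_i q_ii."""
    return -np.einsum("ni,nii->n", pi_batch, q_batch)


#: floor on a per-site stationary rate before rescaling; an effectively
#: frozen site (f near the upper bound) otherwise divides by ~e^(-2f)
RATE_FLOOR = 1e-12


def scale_sites(
    sites: list[SiteModel], scope: str = "dataset", per_site: bool = True
) -> ScaleFactor:
    """Rescale rate matrices so one branch-length unit is one expected
    substitution per site, and fill each site's q_scaled.

    With ``per_site=True`` (default) every site's matrix is divided by that
    site's own stationary rate -sum_i pi_i q_ii, so the calibration holds at
    every site exactly; apparent rate variation along the element then comes
    from how concentrated each site's stationary distribution is.  With
    ``per_site=False`` all sites are divided by the scope-wide mean rate,
    which preserves relative substitution-flux differences instead.  Either
    way the reported C is the scope's mean stationary rate, the mean scaled
    rate is 1, and stationary distributions are unchanged by scaling.
    """
    if not sites:
        raise ValueError("scale_sites requires at least one site")
    q = np.stack([s.q_raw for s in sites])
    pi = np.stack([s.pi for s in sites])
    rates = stationary_rates(q, pi)
    c = float(np.mean(rates))
    factor = ScaleFactor(value=c, scope=scope)
    for s, r in zip(sites, rates):
        s.q_scaled = s.q_raw / (max(float(r), RATE_FLOOR) if per_site else c)
    return factor
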