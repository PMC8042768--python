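"""Downstream UCE analytics.

Topology comparison by independent full fits, UCE-level bootstrap of the
summed log-likelihood differences, parsimony-guided trimming to the most
conserved contiguous window, posterior-predictive model adequacy by
similarity of simulated to observed matrices, and site-wise support
profiles relative to the inferred conservation center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING
from .engine import GtrGammaEngine, SelonEngine
from .io import UCEAlignment, UCEDataset
from .optimize import FitResult, OptimizerConfig, fit_gtr_gamma, fit_selon
from .simulate import simulate_gtr_dataset, simulate_selon_dataset
from .tree import RootedTree

_TIE_TOL = 1e-9


@dataclass
class TopologySupport:
    """Per-UCE and total log-likelihood differences between two topologies.

    The sign convention is delta = lnL(topology A) - lnL(topology B), so
    positive values favor A."""

    uce_ids: list
    per_uce_delta: np.ndarray
    total_delta: float
    n_favor_a: int
    n_favor_b: int
    n_tie: int
    delta_aicc: float
    fit_a: FitResult
    fit_b: FitResult

    def table(self) -> pd.DataFrame:
        side = np.where(
            self.per_uce_delta > _TIE_TOL,
            "A",
            np.where(self.per_uce_delta < -_TIE_TOL, "B", "tie"),
        )
        return pd.DataFrame(
            {"uce_id": self.uce_ids, "delta_lnl": self.per_uce_delta, "favors": side}
        )


def compare_topologies(
    dataset: UCEDataset,
    tree_a: RootedTree,
    tree_b: RootedTree,
    model: str = "selon",
    config: OptimizerConfig | None = None,
    ncat: int = 4,
) -> TopologySupport:
    """Fit both candidate topologies independently and tabulate support."""
    if set(tree_a.taxa) != set(tree_b.taxa):
        raise ValueError("topologies must share one taxon set")
    config = config or OptimizerConfig()
    if model == "selon":
        fit_a = fit_selon(dataset, tree_a, config)
        fit_b = fit_selon(dataset, tree_b, config)
    elif model in ("gtr_gamma", "gtr+g"):
        fit_a = fit_gtr_gamma(dataset, tree_a, config, ncat=ncat)
        fit_b = fit_gtr_gamma(dataset, tree_b, config, ncat=ncat)
    else:
        raise ValueError(f"unknown model {model!r}")
    ids = dataset.uce_ids
    delta = np.array([fit_a.per_uce_lnl[i] - fit_b.per_uce_lnl[i] for i in ids])
    return TopologySupport(
        uce_ids=ids,
        per_uce_delta=delta,
        total_delta=float(delta.sum()),
        n_favor_a=int((delta > _TIE_TOL).sum()),
        n_favor_b=int((delta < -_TIE_TOL).sum()),
        n_tie=int((np.abs(delta) <= _TIE_TOL).sum()),
        delta_aicc=float(fit_a.aicc - fit_b.aicc),
        fit_a=fit_a,
        fit_b=fit_b,
    )


def bootstrap_topology_support(
    per_uce_deltas, n_boot: int = 1000, seed: int = 0
) -> dict:
    """Resample whole UCEs with replacement and record the sign of the
    summed log-likelihood difference in each pseudoreplicate."""
    deltas = np.asarray(per_uce_deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("bootstrap requires at least one UCE")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, deltas.size, size=(n_boot, deltas.size))
    sums = deltas[idx].sum(axis=1)
    return {
        "prop_a": float((sums > _TIE_TOL).mean()),
        "prop_b": float((sums < -_TIE_TOL).mean()),
        "prop_tie": float((np.abs(sums) <= _TIE_TOL).mean()),
        "n_boot": int(n_boot),
        "seed": int(seed),
    }


# ---------------------------------------------------------------------------
# parsimony trimming
# ---------------------------------------------------------------------------

_FULL_SET = 0b1111


def fitch_parsimony_site(pattern, tree: RootedTree) -> int:
    """Fitch small-parsimony score of one site pattern.

    Missing states are fully ambiguous leaf sets; the score is invariant to
    the rooting of a binary tree, so the analysis topology's rooted form is
    used directly."""
    pattern = np.asarray(pattern, dtype=np.int64)
    sets = np.zeros(tree.n_nodes, dtype=np.int64)
    score = 0
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            st = pattern[node]
            sets[node] = _FULL_SET if st == MISSING else (1 << int(st))
            continue
        inter = _FULL_SET
        union = 0
        for c in kids:
            inter &= sets[c]
            union |= sets[c]
        if inter:
            sets[node] = inter
        else:
            sets[node] = union
            score += 1
    return score


def site_parsimony_scores(alignment: UCEAlignment, tree: RootedTree) -> np.ndarray:
    codes = alignment.reordered(tree.taxa).codes
    return np.array(
        [fitch_parsimony_site(codes[:, k], tree) for k in range(codes.shape[1])]
    )


@dataclass
class TrimResult:
    """Kept window of a parsimony-guided trim (1-based, inclusive)."""

    start: int
    end: int
    score: int
    per_site_scores: np.ndarray

    @property
    def window_length(self) -> int:
        return self.end - self.start + 1

    def bed_interval(self) -> tuple[int, int]:
        """0-based half-open companion coordinates."""
        return (self.start - 1, self.end)


def trim_uce(
    alignment: UCEAlignment, tree: RootedTree, keep_fraction: float = 0.5
) -> TrimResult:
    """Keep the contiguous window of round(keep_fraction * l) sites with the
    lowest summed per-site parsimony score (leftmost window on ties).

    Trimming is asymmetric by construction: the window slides to wherever
    the conserved block sits, so either flank may lose more sites."""
    l = alignment.n_sites
    if l < 4:
        raise ValueError("alignment too short to trim")
    w = int(np.rint(keep_fraction * l))
    w = max(1, min(w, l))
    scores = site_parsimony_scores(alignment, tree)
    csum = np.concatenate([[0], np.cumsum(scores)])
    window_sums = csum[w:] - csum[:-w]
    start0 = int(np.argmin(window_sums))  # first minimum = leftmost window
    return TrimResult(
        start=start0 + 1,
        end=start0 + w,
        score=int(window_sums[start0]),
        per_site_scores=scores,
    )


def trimmed_dataset(
    dataset: UCEDataset, tree: RootedTree, keep_fraction: float = 0.5
) -> tuple[UCEDataset, list[TrimResult]]:
    trims = []
    alignments = []
    for a in dataset.alignments:
        tr = trim_uce(a, tree, keep_fraction)
        trims.append(tr)
        alignments.append(
            UCEAlignment(a.uce_id, a.taxa, a.codes[:, tr.start - 1 : tr.end])
        )
    return UCEDataset(alignments=alignments, taxa=dataset.taxa), trims


# ---------------------------------------------------------------------------
# model adequacy
# ---------------------------------------------------------------------------


@dataclass
class AdequacyResult:
    mean_similarity: float
    sd_similarity: float
    similarities: np.ndarray
    n_rep: int
    seed: int


def _similarity(observed: UCEDataset, simulated: UCEDataset) -> float:
    obs = observed.concatenated_codes()
    sim = simulated.concatenated_codes()
    mask = obs != MISSING
    return float((obs[mask] == sim[mask]).mean())


def model_adequacy(
    fit: FitResult,
    dataset: UCEDataset,
    n_rep: int = 100,
    seed: int = 0,
) -> AdequacyResult:
    """Posterior-predictive similarity of data simulated at the MLEs.

    Each replicate is simulated on the fitted tree at the fitted parameters;
    similarity is the fraction of alignment cells matching the observed
    matrix, with observed-missing cells excluded.  Replicate r uses the
    child stream seeded by (seed, r), so a replicate can be reproduced
    exactly."""
    sims = np.empty(n_rep)
    counts = dataset.site_counts
    for r in range(n_rep):
        rng = np.random.default_rng([seed, r])
        if fit.model == "selon":
            sim = simulate_selon_dataset(
                fit.selon_params, fit.tree, counts, rng, uce_ids=dataset.uce_ids
            )
        else:
            sim = simulate_gtr_dataset(
                fit.gtr_thetas,
                fit.tree,
                counts,
                fit.gamma_ncat,
                rng,
                uce_ids=dataset.uce_ids,
            )
        order = [sim.taxa.index(t) for t in dataset.taxa]
        sim_re = UCEDataset(
            alignments=[
                UCEAlignment(a.uce_id, dataset.taxa, a.codes[order])
                for a in sim.alignments
            ],
            taxa=dataset.taxa,
        )
        sims[r] = _similarity(dataset, sim_re)
    return AdequacyResult(
        mean_similarity=float(sims.mean()),
        sd_similarity=float(sims.std(ddof=1)) if n_rep > 1 else 0.0,
        similarities=sims,
        n_rep=n_rep,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# site-wise support
# ---------------------------------------------------------------------------


def _per_site_lnl(fit: FitResult, dataset: UCEDataset) -> np.ndarray:
    if fit.model == "selon":
        engine = SelonEngine(dataset, fit.tree, fit.selon_params.pop)
        return engine.loglik(fit.selon_params, per_site=True)
    engine = GtrGammaEngine(dataset, fit.tree, ncat=fit.gamma_ncat or 4)
    return engine.site_logliks(fit.gtr_thetas)


def sitewise_support(
    dataset: UCEDataset, fit_a: FitResult, fit_b: FitResult
) -> pd.DataFrame:
    """Per-site support for topology A over B, with distance-from-center
    metadata (selection-model fits) or model-averaged Gamma rates (GTR+Gamma
    fits) and cumulative support ordered by distance within each UCE."""
    lnl_a = _per_site_lnl(fit_a, dataset)
    lnl_b = _per_site_lnl(fit_b, dataset)
    rows = []
    offset = 0
    for u, a in enumerate(dataset.alignments):
        n = a.n_sites
        pos = np.arange(1, n + 1)
        rec = {
            "uce_id": a.uce_id,
            "position": pos,
            "delta_lnl": lnl_a[offset : offset + n] - lnl_b[offset : offset + n],
        }
        if fit_a.model == "selon":
            center = fit_a.selon_params.profiles[u].center
            rec["dist_from_center"] = np.abs(pos - center)
        rows.append(pd.DataFrame(rec))
        offset += n
    df = pd.concat(rows, ignore_index=True)
    if fit_a.model != "selon":
        engine = GtrGammaEngine(dataset, fit_a.tree, ncat=fit_a.gamma_ncat or 4)
        df["gamma_rate"] = engine.site_mean_rates(fit_a.gtr_thetas)
    if "dist_from_center" in df:
        df = df.sort_values(["uce_id", "dist_from_center"], kind="stable")
        df["cumulative_abs_delta"] = df.groupby("uce_id")["delta_lnl"].transform(
            lambda s: s.abs().cumsum()
        )
        df = df.sort_index()
    return df
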