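"""Desk-scale benchmark: simulate scenario replicates, fit both models,
and measure recovery, model fit, and branch-length behavior.

This drives both the acceptance evaluation and any quick local study of
estimator behavior.  Problem sizes default to a scaled-down version of the
full benchmark design (22 UCEs; total sites configurable) so a complete
multi-replicate run stays within desktop budgets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optimize import OptimizerConfig, fit_gtr_gamma, fit_selon
from .simulate import generate_scenario_fixtures

INGROUP = tuple("ABCDEFGHI")


@dataclass
class ReplicateResult:
    scenario_id: int
    seed: int
    true_ingroup_length: float
    selon_ingroup_length: float
    gtr_ingroup_length: float
    selon_aicc: float
    gtr_aicc: float
    selon_lnl_trace: list
    selon_n_cycles: int
    nes_ratios: np.ndarray
    sigma_ratios: np.ndarray
    center_err_frac: np.ndarray
    long_branch_fitted: np.ndarray
    short_branch_fitted: np.ndarray
    selon_fit: object | None = None
    gtr_fit: object | None = None
    dataset: object | None = None

    @property
    def selon_length_ratio(self) -> float:
        return self.selon_ingroup_length / self.true_ingroup_length

    @property
    def gtr_length_ratio(self) -> float:
        return self.gtr_ingroup_length / self.true_ingroup_length

    @property
    def ranks_long_short_correctly(self) -> bool:
        return float(np.median(self.long_branch_fitted)) > float(
            np.median(self.short_branch_fitted)
        )


def run_replicate(
    scenario_id: int,
    seed: int,
    total_sites: int = 2200,
    n_uces: int = 22,
    config: OptimizerConfig | None = None,
    keep_fits: bool = False,
) -> ReplicateResult:
    """Simulate one scenario replicate and fit both models to it."""
    scen, ds = generate_scenario_fixtures(
        scenario_id, n_uces=n_uces, seed=seed, total_sites=total_sites
    )
    config = config or OptimizerConfig(
        seed=seed, shape_maxeval=150, mutation_maxeval=350, gtr_maxeval=250
    )
    selon_fit = fit_selon(ds, scen.tree, config)
    gtr_fit = fit_gtr_gamma(ds, scen.tree, config)

    ingroup = [t for t in scen.tree.taxa if t in INGROUP]
    tt = scen.tree
    long_nodes = [
        int(n) for n in tt.branch_nodes if abs(tt.lengths[n] - 0.10) < 1e-9
    ]
    short_nodes = [
        int(n) for n in tt.branch_nodes if abs(tt.lengths[n] - 0.025) < 1e-9
    ]
    fitted = selon_fit.tree.lengths
    return ReplicateResult(
        scenario_id=scenario_id,
        seed=seed,
        true_ingroup_length=tt.clade_length(ingroup),
        selon_ingroup_length=selon_fit.tree.clade_length(ingroup),
        gtr_ingroup_length=gtr_fit.tree.clade_length(ingroup),
        selon_aicc=selon_fit.aicc,
        gtr_aicc=gtr_fit.aicc,
        selon_lnl_trace=list(selon_fit.lnl_trace),
        selon_n_cycles=selon_fit.n_cycles,
        nes_ratios=np.array(
            [
                p.nes_max / s.profile.nes_max
                for s, p in zip(scen.uce_specs, selon_fit.selon_params.profiles)
            ]
        ),
        sigma_ratios=np.array(
            [
                p.width / s.profile.width
                for s, p in zip(scen.uce_specs, selon_fit.selon_params.profiles)
            ]
        ),
        center_err_frac=np.array(
            [
                abs(p.center - s.profile.center) / s.length
                for s, p in zip(scen.uce_specs, selon_fit.selon_params.profiles)
            ]
        ),
        long_branch_fitted=fitted[long_nodes],
        short_branch_fitted=fitted[short_nodes],
        selon_fit=selon_fit if keep_fits else None,
        gtr_fit=gtr_fit if keep_fits else None,
        dataset=ds if keep_fits else None,
    )


def run_benchmark(
    seed: int,
    scenario_ids=(1, 2, 1, 2, 1),
    total_sites: int = 2200,
    n_uces: int = 22,
) -> list[ReplicateResult]:
    """Run the scaled-down multi-replicate benchmark (both scenarios)."""
    out = []
    for r, sid in enumerate(scenario_ids):
        rep_seed = (seed * 1000 + r) % (2**31 - 1)
        out.append(run_replicate(sid, rep_seed, total_sites=total_sites, n_uces=n_uces))
    return out


def summarize(replicates: list[ReplicateResult]) -> dict:
    nes = np.concatenate([r.nes_ratios for r in replicates])
    sig = np.concatenate([r.sigma_ratios for r in replicates])
    cen = np.concatenate([r.center_err_frac for r in replicates])
    return {
        "n_replicates": len(replicates),
        "median_nes_ratio": float(np.median(nes)),
        "median_sigma_ratio": float(np.median(sig)),
        "median_center_err_frac": float(np.median(cen)),
        "selon_length_ratios": [r.selon_length_ratio for r in replicates],
        "gtr_length_ratios": [r.gtr_length_ratio for r in replicates],
        "selon_aicc": [r.selon_aicc for r in replicates],
        "gtr_aicc": [r.gtr_aicc for r in replicates],
        "selon_wins_aicc": [r.selon_aicc < r.gtr_aicc for r in replicates],
        "ranks_long_short": [r.ranks_long_short_correctly for r in replicates],
    }
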