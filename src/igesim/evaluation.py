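"""Replicate orchestration and evaluation metrics.

Runs complete Monte-Carlo replicates of a scenario — population, contact
networks, phenotypes, analysis design per the scenario's analysis
options, REML fit — and summarises across replicates the way the study
reports results: means and standard deviations of the estimates, a bias
flag (true value outside the 95% confidence interval of the mean),
EBV accuracies (Pearson correlation of true and estimated breeding
values) and dispersion slopes (regression of true breeding value on
EBV; < 1 overdispersion, > 1 underdispersion), separately for sires and
phenotyped cows and for the direct and indirect effect.  Non-converged
replicates are excluded from all summary statistics and reported as a
count.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import replicate_seed, rng_streams
from . import network as net
from . import population as pop
from .phenotype import simulate_phenotypes
from .reml import REMLFit, REMLOptions, a_inverse, build_design, reml_fit
from .scenarios import ScenarioConfig, VarianceComponents

__all__ = [
    "ReplicateResult",
    "ReplicateSummary",
    "ebv_accuracy",
    "ebv_dispersion",
    "simulate_replicate",
    "run_replicate",
    "run_scenario",
    "summarize_replicates",
]

PARAMS = ("sigma2_aD", "sigma2_aI", "sigma_aDI", "sigma2_eI", "sigma2_e", "r_g")
GROUPS = ("sires", "phenotyped_cows")
EFFECTS = ("DGE", "IGE")


def ebv_accuracy(true_bv: np.ndarray, ebv: np.ndarray, group: str | None = None) -> float:
    """Pearson correlation of true and estimated breeding values."""
    true_bv = np.asarray(true_bv, dtype=float)
    ebv = np.asarray(ebv, dtype=float)
    if true_bv.size < 3:
        raise ValueError("need at least 3 animals")
    if np.std(true_bv) == 0 or np.std(ebv) == 0:
        return float("nan")
    return float(np.corrcoef(true_bv, ebv)[0, 1])


def ebv_dispersion(true_bv: np.ndarray, ebv: np.ndarray, group: str | None = None) -> float:
    """Least-squares slope of true breeding value regressed on EBV."""
    true_bv = np.asarray(true_bv, dtype=float)
    ebv = np.asarray(ebv, dtype=float)
    if true_bv.size < 3:
        raise ValueError("need at least 3 animals")
    v = np.var(ebv, ddof=1)
    if v == 0:
        return float("nan")
    return float(np.cov(true_bv, ebv)[0, 1] / v)


# --------------------------------------------------------------------------
# one replicate
# --------------------------------------------------------------------------

@dataclass
class SimulatedReplicate:
    """All truth-side artifacts of one replicate."""

    pedigree: pd.DataFrame
    bvs: pd.DataFrame
    env: pd.DataFrame
    herds: pd.DataFrame
    network: net.ContactNetwork
    phenotypes: pd.DataFrame


def simulate_replicate(config: ScenarioConfig, seed: int) -> SimulatedReplicate:
    """Simulate population, network and phenotypes for one replicate.

    Each stochastic component uses its own named stream spawned from
    ``seed``, so scenarios sharing a seed share pedigree and breeding
    values and differ only in the features they switch on.
    """
    streams = rng_streams(seed)
    ped, parent_bvs = pop.simulate_parents(
        config.n_cows, config.n_sires, config.vc, streams["pedigree"]
    )
    ped = pop.assign_matings(
        ped, config.n_herds, config.herd_size, config.n_sire_draws_per_herd,
        streams["pedigree"],
    )
    bvs, env = pop.simulate_offspring_effects(
        ped, parent_bvs, config.vc, streams["breeding_values"],
        env_seed=streams["environment"],
    )
    herds = pop.simulate_herd_effects(
        config.n_herds, config.herd_effect_range, streams["herd"]
    )
    network = net.simulate_contact_networks(
        ped,
        mean_contacts=config.mean_contacts,
        max_contacts=config.max_contacts,
        directed=config.direction_mode == "directed",
        rng=streams["network"],
    )
    if config.intensity_mode != "none":
        network = net.sample_intensities(
            network,
            standardize=config.intensity_mode == "standardized",
            rng=streams["intensity"],
        )
    if config.intensity_noise_var > 0:
        network = net.add_intensity_noise(
            network, config.intensity_noise_var, rng=streams["noise"]
        )
    phenos = simulate_phenotypes(
        bvs, env, herds, network, use_intensity=config.intensity_mode != "none"
    )
    return SimulatedReplicate(ped, bvs, env, herds, network, phenos)


@dataclass
class ReplicateResult:
    seed: int
    fit: REMLFit
    accuracy: dict  # (group, effect) -> float
    dispersion: dict  # (group, effect) -> float
    wall_time: float


def _group_metrics(sim: SimulatedReplicate, fit: REMLFit) -> tuple[dict, dict]:
    merged = sim.bvs.merge(fit.ebv, on="animal").merge(
        sim.pedigree[["animal", "role"]], on="animal"
    )
    masks = {
        "sires": merged["role"] == "sire",
        "phenotyped_cows": merged["role"] == "cow",
    }
    cols = {"DGE": ("a_D", "aD_hat"), "IGE": ("a_I", "aI_hat")}
    acc, disp = {}, {}
    for g, mask in masks.items():
        sub = merged[mask]
        for eff, (t, e) in cols.items():
            acc[g, eff] = ebv_accuracy(sub[t].to_numpy(), sub[e].to_numpy())
            disp[g, eff] = ebv_dispersion(sub[t].to_numpy(), sub[e].to_numpy())
    return acc, disp


def run_replicate(
    config: ScenarioConfig,
    seed: int,
    options: REMLOptions | None = None,
) -> ReplicateResult:
    """Simulate one replicate and fit the estimation model per the
    scenario's analysis options."""
    t0 = time.perf_counter()
    sim = simulate_replicate(config, seed)
    spec = build_design(
        sim.phenotypes,
        sim.network,
        sim.pedigree,
        analysis_intensity=config.analysis_intensity,
        analysis_direction=config.analysis_direction,
    )
    ainv = a_inverse(sim.pedigree)
    fit = reml_fit(spec, ainv, options=options)
    acc, disp = _group_metrics(sim, fit)
    return ReplicateResult(
        seed=seed,
        fit=fit,
        accuracy=acc,
        dispersion=disp,
        wall_time=time.perf_counter() - t0,
    )


# --------------------------------------------------------------------------
# summaries across replicates
# --------------------------------------------------------------------------

@dataclass
class ReplicateSummary:
    scenario_id: int
    n_attempted: int
    n_converged: int
    parameters: pd.DataFrame  # index: parameter; columns mean, sd, ci_low, ci_high, biased
    accuracy: pd.DataFrame  # index (group, effect); columns mean, sd
    dispersion: pd.DataFrame  # index (group, effect); columns mean, sd

    def parameter(self, name: str, stat: str = "mean") -> float:
        return float(self.parameters.loc[name, stat])


def _estimate_row(fit: REMLFit) -> dict[str, float]:
    d = fit.estimates.as_dict()
    d["r_g"] = fit.r_g_hat
    return d


def summarize_replicates(
    fits: list[REMLFit],
    truth: VarianceComponents,
    confidence: float = 0.95,
    scenario_id: int = 0,
    accuracies: list[dict] | None = None,
    dispersions: list[dict] | None = None,
) -> ReplicateSummary:
    """Means, SDs, t-based confidence intervals and bias flags over the
    converged replicates; an estimate is flagged biased when the simulated
    value falls outside the CI for the mean."""
    n_attempted = len(fits)
    keep = [i for i, f in enumerate(fits) if f.converged]
    if len(keep) == 0:
        empty = pd.DataFrame(
            columns=["mean", "sd", "ci_low", "ci_high", "biased"], index=list(PARAMS)
        )
        return ReplicateSummary(scenario_id, n_attempted, 0, empty, pd.DataFrame(), pd.DataFrame())
    est = pd.DataFrame([_estimate_row(fits[i]) for i in keep])
    R = len(keep)
    truth_map = truth.as_dict()
    truth_map["r_g"] = truth.r_g
    rows = {}
    tcrit = stats.t.ppf(0.5 + confidence / 2, R - 1) if R > 1 else np.inf
    for pname in PARAMS:
        vals = est[pname].to_numpy()
        mean, sd = float(vals.mean()), float(vals.std(ddof=1)) if R > 1 else 0.0
        half = tcrit * sd / np.sqrt(R) if R > 1 else np.inf
        lo, hi = mean - half, mean + half
        rows[pname] = {
            "mean": mean,
            "sd": sd,
            "ci_low": lo,
            "ci_high": hi,
            "biased": not (lo <= truth_map[pname] <= hi),
        }
    params = pd.DataFrame(rows).T

    def _metric_frame(dicts):
        if dicts is None:
            return pd.DataFrame()
        sel = [dicts[i] for i in keep]
        idx = pd.MultiIndex.from_product([GROUPS, EFFECTS], names=["group", "effect"])
        data = {
            key: np.array([d[key] for d in sel], dtype=float) for key in idx
        }
        return pd.DataFrame(
            {
                "mean": [np.nanmean(data[k]) for k in idx],
                "sd": [np.nanstd(data[k], ddof=1) if R > 1 else 0.0 for k in idx],
            },
            index=idx,
        )

    return ReplicateSummary(
        scenario_id=scenario_id,
        n_attempted=n_attempted,
        n_converged=R,
        parameters=params,
        accuracy=_metric_frame(accuracies),
        dispersion=_metric_frame(dispersions),
    )


def run_scenario(
    config: ScenarioConfig,
    n_replicates: int,
    base_seed: int,
    options: REMLOptions | None = None,
    log=None,
) -> tuple[ReplicateSummary, list[ReplicateResult]]:
    """Run ``n_replicates`` seeded replicates of a scenario and summarise.

    A failing replicate is logged and skipped, never aborting the
    scenario.  Deterministic given ``base_seed``.
    """
    results: list[ReplicateResult] = []
    for r in range(n_replicates):
        seed = replicate_seed(base_seed, r)
        try:
            res = run_replicate(config, seed, options=options)
        except Exception as exc:  # noqa: BLE001 - replicate isolation
            if log is not None:
                log(f"replicate {r} seed {seed} failed: {exc}")
            continue
        if log is not None:
            log(
                f"replicate {r} seed {seed} iters {res.fit.n_iter} "
                f"converged {res.fit.converged} wall {res.wall_time:.1f}s"
            )
        results.append(res)
    summary = summarize_replicates(
        [r.fit for r in results],
        config.vc,
        scenario_id=config.scenario_id,
        accuracies=[r.accuracy for r in results],
        dispersions=[r.dispersion for r in results],
    )
    return summary, results
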