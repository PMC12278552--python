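"""Two-generation pedigree and true-effect simulation.

The simulated population mirrors a progeny-testing-like dairy structure:
an unrelated parent generation of dams and sires, and one offspring
generation of phenotyped cows, each dam contributing exactly one cow.
Direct and indirect breeding values are bivariate normal with covariance
matrix G; offspring values are built from parent averages plus Mendelian
sampling terms drawn with covariance G/2, so the additive variance among
offspring reconstitutes the founder variance under random mating.

Animal ids are assigned parents-first: sires ``1..n_sires``, dams
``n_sires+1..n_sires+n_dams``, cows thereafter.  Unknown parents are
coded 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import rng_streams
from .scenarios import VarianceComponents

__all__ = [
    "simulate_parents",
    "assign_matings",
    "simulate_offspring_effects",
    "simulate_herd_effects",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root; exact zeros for zero-variance margins."""
    w, V = np.linalg.eigh(np.asarray(cov, dtype=float))
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError("covariance matrix is not positive semi-definite")
    return (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T


def _mvn(rng: np.random.Generator, cov: np.ndarray, size: int) -> np.ndarray:
    z = rng.standard_normal((size, cov.shape[0]))
    return z @ _psd_factor(cov).T


def simulate_parents(
    n_dams: int, n_sires: int, vc: VarianceComponents, seed
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the unrelated parent generation and its breeding values.

    Returns
    -------
    pedigree : DataFrame with columns animal, sire, dam, role, herd
        (sire/dam are 0: founders; herd is 0 for parents).
    bvs : DataFrame with columns animal, a_D, a_I.
    """
    if n_dams <= 0 or n_sires <= 0:
        raise ValueError("n_dams and n_sires must be positive")
    rng = _as_rng(seed)
    n = n_sires + n_dams
    pedigree = pd.DataFrame(
        {
            "animal": np.arange(1, n + 1),
            "sire": 0,
            "dam": 0,
            "role": ["sire"] * n_sires + ["dam"] * n_dams,
            "herd": 0,
        }
    )
    a = _mvn(rng, vc.G, n)
    bvs = pd.DataFrame({"animal": pedigree["animal"], "a_D": a[:, 0], "a_I": a[:, 1]})
    return pedigree, bvs


def assign_matings(
    parents: pd.DataFrame,
    n_herds: int,
    herd_size: int,
    n_sire_draws_per_herd: int,
    seed,
) -> pd.DataFrame:
    """Create the offspring generation: one cow per dam, herd-wise sire pools.

    Dams are partitioned over herds by a random permutation.  For each
    herd a pool of ``n_sire_draws_per_herd`` sires is drawn with
    replacement from all sires, and each cow's sire is then drawn with
    replacement from that pool — so herds contain paternal half-sib
    families of varying size from about nine distinct sires.
    """
    rng = _as_rng(seed)
    sires = parents.loc[parents["role"] == "sire", "animal"].to_numpy()
    dams = parents.loc[parents["role"] == "dam", "animal"].to_numpy()
    if n_herds * herd_size != dams.size:
        raise ValueError(
            f"n_herds * herd_size = {n_herds * herd_size} must equal the "
            f"number of dams ({dams.size}): one offspring per dam"
        )
    dams = rng.permutation(dams)
    herd_of_cow = np.repeat(np.arange(1, n_herds + 1), herd_size)
    sire_of_cow = np.empty(dams.size, dtype=np.int64)
    for h in range(n_herds):
        pool = rng.choice(sires, size=n_sire_draws_per_herd, replace=True)
        sl = slice(h * herd_size, (h + 1) * herd_size)
        sire_of_cow[sl] = rng.choice(pool, size=herd_size, replace=True)
    next_id = int(parents["animal"].max()) + 1
    cows = pd.DataFrame(
        {
            "animal": np.arange(next_id, next_id + dams.size),
            "sire": sire_of_cow,
            "dam": dams,
            "role": "cow",
            "herd": herd_of_cow,
        }
    )
    return pd.concat([parents, cows], ignore_index=True)


def simulate_offspring_effects(
    pedigree: pd.DataFrame,
    parent_bvs: pd.DataFrame,
    vc: VarianceComponents,
    seed,
    env_seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Breeding values of cows (parent average + Mendelian sampling) and
    their direct/indirect environmental effects.

    Mendelian sampling terms are bivariate normal with covariance G/2;
    environmental effects are independent with variances (sigma2_e,
    sigma2_eI) and zero covariance.  When ``env_seed`` is omitted the
    environmental draws share the breeding-value stream.
    """
    rng = _as_rng(seed)
    env_rng = rng if env_seed is None else _as_rng(env_seed)
    cows = pedigree[pedigree["role"] == "cow"]
    bv_of = parent_bvs.set_index("animal")
    missing = ~cows["sire"].isin(bv_of.index) | ~cows["dam"].isin(bv_of.index)
    if missing.any():
        bad = cows.loc[missing, "animal"].iloc[0]
        raise ValueError(f"cow {bad} has a parent without breeding values")
    ms = _mvn(rng, 0.5 * vc.G, len(cows))
    sire_bv = bv_of.loc[cows["sire"], ["a_D", "a_I"]].to_numpy()
    dam_bv = bv_of.loc[cows["dam"], ["a_D", "a_I"]].to_numpy()
    cow_bv = 0.5 * sire_bv + 0.5 * dam_bv + ms
    cow_table = pd.DataFrame(
        {
            "animal": cows["animal"].to_numpy(),
            "a_D": cow_bv[:, 0],
            "a_I": cow_bv[:, 1],
            "MS_D": ms[:, 0],
            "MS_I": ms[:, 1],
        }
    )
    bvs = pd.concat(
        [parent_bvs.assign(MS_D=np.nan, MS_I=np.nan), cow_table], ignore_index=True
    )
    env = pd.DataFrame(
        {
            "animal": cows["animal"].to_numpy(),
            "e_D": env_rng.normal(0.0, np.sqrt(vc.sigma2_e), len(cows)),
            "e_I": env_rng.normal(0.0, np.sqrt(vc.sigma2_eI), len(cows)),
        }
    )
    return bvs, env


def simulate_herd_effects(n_herds: int, herd_range: tuple[float, float], seed) -> pd.DataFrame:
    """Iid uniform herd effects (kg ECM), one per herd."""
    lo, hi = herd_range
    if lo >= hi:
        raise ValueError("herd effect range must satisfy min < max")
    rng = _as_rng(seed)
    return pd.DataFrame(
        {"herd": np.arange(1, n_herds + 1), "herd_effect": rng.uniform(lo, hi, n_herds)}
    )
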