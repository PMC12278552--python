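import numpy as np
import pandas as pd
import pytest

from igesim import a_inverse, build_design, get_scenario, simulate_replicate
from igesim.scenarios import ScenarioConfig, VarianceComponents


@pytest.fixture(scope="session")
def vc1() -> VarianceComponents:
    """Basic-scenario variance components."""
    return get_scenario(1).vc


@pytest.fixture(scope="session")
def tiny_config() -> ScenarioConfig:
    """A miniature population: 2 herds x 50 cows, full contact density."""
    return get_scenario(1).scaled(n_herds=2, herd_size=50)


@pytest.fixture(scope="session")
def tiny_sim(tiny_config):
    return simulate_replicate(tiny_config, 123)


@pytest.fixture(scope="session")
def tiny_system(tiny_sim):
    spec = build_design(tiny_sim.phenotypes, tiny_sim.network, tiny_sim.pedigree)
    ainv = a_inverse(tiny_sim.pedigree)
    return spec, ainv


def psd_candidate(est: VarianceComponents, **changes) -> VarianceComponents:
    """Copy of an estimate with some components changed; the covariance is
    clipped so the genetic matrix stays positive semi-definite."""
    d = est.as_dict()
    d.update(changes)
    bound = 0.999 * np.sqrt(d["sigma2_aD"] * d["sigma2_aI"])
    d["sigma_aDI"] = float(np.clip(d["sigma_aDI"], -bound, bound))
    return VarianceComponents(**d)


def dense_tabular_A(pedigree: pd.DataFrame) -> np.ndarray:
    """Independent oracle: numerator relationship matrix by the tabular method."""
    animals = pedigree["animal"].to_numpy()
    pos = {int(a): i for i, a in enumerate(animals)}
    A = np.zeros((len(animals), len(animals)))
    for i, (s, d) in enumerate(pedigree[["sire", "dam"]].to_numpy()):
        s = pos[int(s)] if s != 0 else None
        d = pos[int(d)] if d != 0 else None
        for j in range(i):
            a_js = A[j, s] if s is not None else 0.0
            a_jd = A[j, d] if d is not None else 0.0
            A[i, j] = A[j, i] = 0.5 * (a_js + a_jd)
        a_sd = A[s, d] if (s is not None and d is not None) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
    return A


def dense_restricted_loglik(spec, a_inv, vc) -> float:
    """Independent oracle: dense-V REML log-likelihood (2*pi constant omitted)."""
    A = np.linalg.inv(a_inv.toarray())
    X = spec.X.toarray()
    W = np.hstack([spec.Z_D.toarray(), spec.Z_I.toarray()])
    Zc = spec.Z_c.toarray()
    V = (
        W @ np.kron(vc.G, A) @ W.T
        + Zc @ Zc.T * vc.sigma2_eI
        + np.eye(spec.n) * vc.sigma2_e
    )
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, ld1 = np.linalg.slogdet(V)
    _, ld2 = np.linalg.slogdet(XtViX)
    return -0.5 * (ld1 + ld2 + float(spec.y @ P @ spec.y))


def dense_blup(spec, a_inv, vc):
    """Independent oracle: GLS fixed effects and BLUP from the dense V."""
    A = np.linalg.inv(a_inv.toarray())
    X = spec.X.toarray()
    W = np.hstack([spec.Z_D.toarray(), spec.Z_I.toarray()])
    Zc = spec.Z_c.toarray()
    Sig = np.kron(vc.G, A)
    V = W @ Sig @ W.T + Zc @ Zc.T * vc.sigma2_eI + np.eye(spec.n) * vc.sigma2_e
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ spec.y)
    resid = spec.y - X @ b
    u = Sig @ W.T @ Vi @ resid
    e_I = vc.sigma2_eI * Zc.T @ Vi @ resid
    return b, u[: spec.m], u[spec.m :], e_I
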