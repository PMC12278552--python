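"""Scenario parameterizations and closed-form heritable-variance quantities.

The simulation study is driven by 22 scenario configurations that vary herd
size, the direct-indirect genetic correlation, the magnitude of the indirect
genetic variance, and whether contact intensities / contact direction are
present in the simulation and honoured in the genetic analysis.  This module
holds the variance-component container, the scenario registry (packaged as a
plain YAML file so users can add scenarios without code edits), and the
closed-form quantities derived from the variance components: phenotypic
variance, total heritable variance, and the ratios T², I²_P, S²_P, I²_TBV.

Notation
--------
``sigma2_aD``/``sigma2_aI``: direct/indirect additive-genetic variances;
``sigma_aDI``: their covariance; ``sigma2_eI``: indirect (permanent)
environmental variance; ``sigma2_e``: residual (direct environmental)
variance.  All variances are in kg² energy-corrected milk (ECM); ``n`` is
the mean number of social contacts per cow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "VarianceComponents",
    "ScenarioConfig",
    "DerivedGeneticQuantities",
    "derive_base_components",
    "derived_quantities",
    "study_scenarios",
    "load_scenarios",
    "get_scenario",
]

IntensityMode = Literal["none", "standardized", "unstandardized"]
DirectionMode = Literal["undirected", "directed"]
AnalysisIntensity = Literal["use_true", "ignore", "use_noisy"]
AnalysisDirection = Literal["as_simulated", "ignore_direction"]


@dataclass(frozen=True)
class VarianceComponents:
    """The five (co)variance components of the direct/indirect animal model."""

    sigma2_aD: float
    sigma2_aI: float
    sigma_aDI: float
    sigma2_eI: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if self.sigma2_aD < 0 or self.sigma2_aI < 0 or self.sigma2_eI < 0:
            raise ValueError("genetic and indirect environmental variances must be >= 0")
        if self.sigma2_e <= 0:
            raise ValueError("residual variance must be > 0")
        bound = math.sqrt(self.sigma2_aD * self.sigma2_aI)
        if abs(self.sigma_aDI) > bound + 1e-9 * max(bound, 1.0):
            raise ValueError(
                "direct-indirect covariance implies |r_g| > 1; G is not positive semi-definite"
            )

    @property
    def G(self) -> np.ndarray:
        """2x2 direct/indirect genetic covariance matrix."""
        return np.array(
            [[self.sigma2_aD, self.sigma_aDI], [self.sigma_aDI, self.sigma2_aI]]
        )

    @property
    def C(self) -> np.ndarray:
        """2x2 diagonal direct/indirect environmental covariance matrix."""
        return np.diag([self.sigma2_e, self.sigma2_eI])

    @property
    def r_g(self) -> float:
        """Direct-indirect genetic correlation; 0 when either variance is 0."""
        denom = math.sqrt(self.sigma2_aD * self.sigma2_aI)
        return 0.0 if denom == 0.0 else self.sigma_aDI / denom

    def as_dict(self) -> dict[str, float]:
        return {
            "sigma2_aD": self.sigma2_aD,
            "sigma2_aI": self.sigma2_aI,
            "sigma_aDI": self.sigma_aDI,
            "sigma2_eI": self.sigma2_eI,
            "sigma2_e": self.sigma2_e,
        }


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one simulation/analysis scenario."""

    scenario_id: int
    n_herds: int
    herd_size: int
    vc: VarianceComponents
    mean_contacts: int = 30
    max_contacts: int = 43
    herd_effect_range: tuple[float, float] = (8000.0, 13000.0)
    intensity_mode: IntensityMode = "none"
    intensity_noise_var: float = 0.0
    direction_mode: DirectionMode = "undirected"
    analysis_intensity: AnalysisIntensity = "ignore"
    analysis_direction: AnalysisDirection = "as_simulated"
    n_sire_draws_per_herd: int = 9
    n_sires: int = 100
    name: str = ""

    def __post_init__(self) -> None:
        if self.max_contacts >= self.herd_size:
            raise ValueError("max_contacts must be smaller than the herd size")
        if self.n_herds <= 0 or self.herd_size <= 0:
            raise ValueError("herd counts must be positive")
        if self.herd_effect_range[0] >= self.herd_effect_range[1]:
            raise ValueError("herd effect range must satisfy min < max")
        if self.intensity_mode == "none" and self.analysis_intensity in ("use_true", "use_noisy"):
            raise ValueError("analysis cannot use intensities that were not simulated")
        if self.intensity_noise_var < 0:
            raise ValueError("intensity noise variance must be >= 0")
        if self.analysis_intensity == "use_noisy" and self.intensity_noise_var == 0:
            raise ValueError("use_noisy analysis requires a positive intensity_noise_var")
        if self.direction_mode == "undirected" and self.analysis_direction == "ignore_direction":
            raise ValueError("ignore_direction only applies to directed simulations")

    @property
    def n_cows(self) -> int:
        return self.n_herds * self.herd_size

    def scaled(self, n_herds: int | None = None, herd_size: int | None = None) -> "ScenarioConfig":
        """Copy with a reduced/enlarged population, keeping everything else."""
        return replace(
            self,
            n_herds=self.n_herds if n_herds is None else n_herds,
            herd_size=self.herd_size if herd_size is None else herd_size,
        )


@dataclass(frozen=True)
class DerivedGeneticQuantities:
    """Closed-form variance quantities for a cow with the mean contact count."""

    sigma2_P: float
    sigma2_TBV: float
    T2: float
    h2_D: float
    I2_P: float
    S2_P: float
    I2_TBV: float


def derive_base_components(
    sigma_P: float,
    h2_D: float,
    n: float,
    ige_share: float,
    r_g: float,
) -> VarianceComponents:
    """Solve the phenotypic variance budget for the simulation inputs.

    The phenotypic variance of a cow with ``n`` contacts decomposes as

        sigma2_P = sigma2_aD + n * (sigma2_aI + sigma2_eI) + sigma2_e,

    with the conventions used throughout the study: ``sigma2_aD = h2_D *
    sigma2_P``, the received indirect genetic effects explain ``ige_share``
    of sigma2_P (so ``sigma2_aI = ige_share * sigma2_P / n``), and the
    indirect environmental variance equals the indirect genetic variance.

    Parameters
    ----------
    sigma_P : phenotypic standard deviation in kg ECM.
    h2_D : direct heritability.
    n : mean number of social contacts.
    ige_share : share of phenotypic variance explained by received IGEs.
    r_g : direct-indirect genetic correlation.
    """
    if sigma_P <= 0:
        raise ValueError("sigma_P must be positive")
    if not 0 <= h2_D <= 1:
        raise ValueError("h2_D must be in [0, 1]")
    if ige_share < 0:
        raise ValueError("ige_share must be >= 0")
    sigma2_P = sigma_P**2
    sigma2_aD = h2_D * sigma2_P
    sigma2_aI = ige_share * sigma2_P / n
    sigma2_eI = sigma2_aI
    sigma2_e = sigma2_P - sigma2_aD - n * (sigma2_aI + sigma2_eI)
    if sigma2_e <= 0:
        raise ValueError(
            "variance budget violated: h2_D + 2*ige_share leaves a non-positive "
            f"residual variance ({sigma2_e:.1f} kg^2 ECM)"
        )
    sigma_aDI = r_g * math.sqrt(sigma2_aD * sigma2_aI)
    return VarianceComponents(sigma2_aD, sigma2_aI, sigma_aDI, sigma2_eI, sigma2_e)


def derived_quantities(
    vc: VarianceComponents,
    n: float,
    tbv_convention: Literal["n_squared", "n_minus_1"] = "n_squared",
) -> DerivedGeneticQuantities:
    """Phenotypic and total heritable variance and the derived ratios.

    The total breeding value of an animal is ``a_D + (n-1) a_I`` — its
    heritable effect on the population mean — with variance

        sigma2_TBV = sigma2_aD + 2(n-1) sigma_aDI + (n-1)^2 sigma2_aI.

    ``tbv_convention`` selects the group-mate count: ``"n_minus_1"`` uses the
    exact ``n - 1`` multipliers above, while the default ``"n_squared"`` uses the
    mean contact count ``n`` itself with a zero covariance,
    ``sigma2_TBV = sigma2_aD + n^2 sigma2_aI``, the convention under which
    the study's summary table of derived quantities is computed.  The two
    agree when ``sigma_aDI = 0`` and ``n`` is substituted for ``n - 1``.
    """
    if n < 1:
        raise ValueError("mean contact count must be >= 1")
    sigma2_P = vc.sigma2_aD + n * (vc.sigma2_aI + vc.sigma2_eI) + vc.sigma2_e
    if tbv_convention == "n_squared":
        sigma2_TBV = vc.sigma2_aD + n**2 * vc.sigma2_aI
    elif tbv_convention == "n_minus_1":
        sigma2_TBV = (
            vc.sigma2_aD + 2 * (n - 1) * vc.sigma_aDI + (n - 1) ** 2 * vc.sigma2_aI
        )
    else:
        raise ValueError(f"unknown tbv_convention {tbv_convention!r}")
    return DerivedGeneticQuantities(
        sigma2_P=sigma2_P,
        sigma2_TBV=sigma2_TBV,
        T2=sigma2_TBV / sigma2_P,
        h2_D=vc.sigma2_aD / sigma2_P,
        I2_P=n * vc.sigma2_aI / sigma2_P,
        S2_P=n * (vc.sigma2_aI + vc.sigma2_eI) / sigma2_P,
        I2_TBV=(n**2 * vc.sigma2_aI / sigma2_TBV) if sigma2_TBV > 0 else 0.0,
    )


def _config_from_record(rec: dict) -> ScenarioConfig:
    rec = dict(rec)
    r_g = float(rec.pop("r_g", 0.0))
    sigma2_aD = float(rec.pop("sigma2_aD"))
    sigma2_aI = float(rec.pop("sigma2_aI"))
    sigma2_eI = float(rec.pop("sigma2_eI"))
    sigma2_e = float(rec.pop("sigma2_e"))
    # r_g is the primitive; the covariance is carried at full precision.
    sigma_aDI = r_g * math.sqrt(sigma2_aD * sigma2_aI)
    vc = VarianceComponents(sigma2_aD, sigma2_aI, sigma_aDI, sigma2_eI, sigma2_e)
    if "herd_effect_range" in rec:
        rec["herd_effect_range"] = tuple(float(v) for v in rec["herd_effect_range"])
    return ScenarioConfig(vc=vc, **rec)


def load_scenarios(path=None) -> list[ScenarioConfig]:
    """Load a scenario registry from a YAML file (default: the packaged one)."""
    if path is None:
        text = (resources.files("igesim") / "data" / "scenarios.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    records = yaml.safe_load(text)["scenarios"]
    return [_config_from_record(rec) for rec in records]


def study_scenarios() -> list[ScenarioConfig]:
    """The 22 scenario configurations of the simulation study, in order."""
    configs = load_scenarios()
    assert [c.scenario_id for c in configs] == list(range(1, 23))
    return configs


def get_scenario(scenario_id: int) -> ScenarioConfig:
    for cfg in study_scenarios():
        if cfg.scenario_id == scenario_id:
            return cfg
    raise KeyError(f"no scenario with id {scenario_id}")
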