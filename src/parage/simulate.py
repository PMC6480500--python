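"""Synthetic birth cohorts with known parental-age truth.

The generator emulates the structure of national natality cross-tabs:
maternal ages 15-49 and paternal ages 15-65, strongly correlated
parental ages (couples tend to be of similar age), a rare outcome
(around 5 cases per 10,000 births), and nonlinear log-odds age curves
that start rising near age 30 and plateau near 45. Births land in age
cells by a multinomial draw from a discretised bivariate-normal age-pair
distribution; cases are binomial within cells with probability
logit^-1(alpha* + m*(j) + p*(k)).

Truth curves are returned centred to sum to zero over each parent's age
grid so they are directly comparable with the sum-to-zero CAR effect
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import expit, logit

from .crosstab import AgeCrossTab
from .mcmc import PosteriorDraws

__all__ = [
    "AgeCurve",
    "SimScenario",
    "simulate_crosstab",
    "recovery_report",
    "aggregate_recovery",
]


@dataclass(frozen=True)
class AgeCurve:
    """Parametric true log-OR curve over age.

    kinds: ``flat`` (zero), ``linear`` (slope per year around ``center``),
    ``ramp`` (smoothstep rise of ``height`` log-odds between the two
    inflection ages ``start`` and ``stop`` — the shape reported for the
    maternal trisomy-risk curve, inflections near 30 and 45).
    """

    kind: str = "flat"
    slope: float = 0.0
    center: float = 30.0
    start: float = 30.0
    stop: float = 45.0
    height: float = 0.0

    def __call__(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        if self.kind == "flat":
            return np.zeros_like(ages)
        if self.kind == "linear":
            return self.slope * (ages - self.center)
        if self.kind == "ramp":
            x = np.clip((ages - self.start) / (self.stop - self.start), 0.0, 1.0)
            return self.height * x * x * (3.0 - 2.0 * x)  # smoothstep
        raise ValueError(f"unknown curve kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("kind", "slope", "center", "start", "stop", "height")}


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for one synthetic cohort.

    Defaults mimic the scale of the US natality cross-tab: ~10 million
    eligible births, baseline prevalence 5.4 per 10,000, maternal mean
    age 29 (SD 6), paternal mean 32 (SD 7), age correlation 0.8.
    """

    total_births: int = 10_000_000
    maternal_lo: int = 15
    maternal_hi: int = 49
    paternal_lo: int = 15
    paternal_hi: int = 65
    maternal_mean: float = 29.0
    maternal_sd: float = 6.0
    paternal_mean: float = 32.0
    paternal_sd: float = 7.0
    rho: float = 0.8
    base_rate: float = 5.4e-4  # prevalence at the curve baseline (curve value 0)
    maternal_curve: AgeCurve = field(default_factory=AgeCurve)
    paternal_curve: AgeCurve = field(default_factory=AgeCurve)
    zero_outcome: bool = False  # surrogate for alpha* = -inf: no cases at all
    seed: int = 0
    outcome_label: str = "synthetic"

    def __post_init__(self):
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if self.total_births <= 0:
            raise ValueError("total_births must be positive")
        if not 0.0 < self.base_rate < 1.0:
            raise ValueError("base_rate must lie in (0, 1)")

    @property
    def maternal_ages(self) -> np.ndarray:
        return np.arange(self.maternal_lo, self.maternal_hi + 1)

    @property
    def paternal_ages(self) -> np.ndarray:
        return np.arange(self.paternal_lo, self.paternal_hi + 1)

    def to_yaml(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if not isinstance(v, AgeCurve)}
        d["maternal_curve"] = self.maternal_curve.to_dict()
        d["paternal_curve"] = self.paternal_curve.to_dict()
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimScenario":
        d = yaml.safe_load(text)
        for key in ("maternal_curve", "paternal_curve"):
            if key in d and isinstance(d[key], dict):
                d[key] = AgeCurve(**d[key])
        return cls(**d)


@dataclass(frozen=True)
class TruthRecord:
    """True generating quantities, centred for comparison with CAR fits."""

    alpha: float  # intercept after centring both curves
    maternal_ages: np.ndarray
    paternal_ages: np.ndarray
    maternal_effects: np.ndarray  # sum-to-zero log-OR curve
    paternal_effects: np.ndarray
    cell_probs: np.ndarray  # per-cell event probability (J, K)


def _age_pair_probs(sc: SimScenario) -> np.ndarray:
    """Discretised bivariate-normal probability of each (maternal, paternal) cell."""
    m = sc.maternal_ages[:, None]
    p = sc.paternal_ages[None, :]
    zm = (m - sc.maternal_mean) / sc.maternal_sd
    zp = (p - sc.paternal_mean) / sc.paternal_sd
    r = sc.rho
    log_dens = -(zm**2 - 2 * r * zm * zp + zp**2) / (2 * (1 - r**2))
    dens = np.exp(log_dens - log_dens.max())
    return dens / dens.sum()


def simulate_crosstab(
    scenario: SimScenario, rng: np.random.Generator | None = None
) -> tuple[AgeCrossTab, TruthRecord]:
    """Draw one cohort; deterministic given (scenario, scenario.seed)."""
    sc = scenario
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    m_eff_raw = sc.maternal_curve(sc.maternal_ages)
    p_eff_raw = sc.paternal_curve(sc.paternal_ages)
    m_eff = m_eff_raw - m_eff_raw.mean()
    p_eff = p_eff_raw - p_eff_raw.mean()
    alpha = logit(sc.base_rate) + m_eff_raw.mean() + p_eff_raw.mean()

    eta = alpha + m_eff[:, None] + p_eff[None, :]
    probs = expit(eta)
    if np.any((probs <= 0) | (probs >= 1)):
        j, k = np.argwhere((probs <= 0) | (probs >= 1))[0]
        raise ValueError(
            f"event probability outside (0,1) at age pair "
            f"({sc.maternal_ages[j]}, {sc.paternal_ages[k]})"
        )

    pair = _age_pair_probs(sc)
    births = rng.multinomial(sc.total_births, pair.reshape(-1)).reshape(pair.shape)
    if sc.zero_outcome:
        cases = np.zeros_like(births)
    else:
        cases = rng.binomial(births, probs)
    tab = AgeCrossTab(sc.maternal_ages, sc.paternal_ages, births, cases, sc.outcome_label)
    truth = TruthRecord(
        alpha=float(alpha),
        maternal_ages=sc.maternal_ages,
        paternal_ages=sc.paternal_ages,
        maternal_effects=m_eff,
        paternal_effects=p_eff,
        cell_probs=probs,
    )
    return tab, truth


def _truth_effects(truth: TruthRecord, parent: str) -> tuple[np.ndarray, np.ndarray]:
    if parent == "maternal":
        return truth.maternal_ages, truth.maternal_effects
    return truth.paternal_ages, truth.paternal_effects


def recovery_report(fit: PosteriorDraws, truth: TruthRecord, parent: str = "maternal") -> dict:
    """Per-age recovery metrics of one fit against its generating truth.

    Compares posterior sum-to-zero effect draws with the centred truth
    curve: bias of the posterior median, RMSE, and whether the equal-
    tailed 95% interval covers the truth at each age.
    """
    ages, true_eff = _truth_effects(truth, parent)
    eff = fit.effects(parent)
    eff = eff.reshape(-1, eff.shape[-1])
    if eff.shape[1] != ages.size or not np.array_equal(fit.ages(parent), ages):
        raise ValueError("fit and truth are on different age grids")
    eff = eff - eff.mean(axis=1, keepdims=True)
    lo, med, hi = np.percentile(eff, [2.5, 50.0, 97.5], axis=0)
    bias = med - true_eff
    return {
        "ages": ages,
        "bias": bias,
        "rmse": float(np.sqrt(np.mean(bias**2))),
        "covered": (lo - 1e-10 <= true_eff) & (true_eff <= hi + 1e-10),
    }


def aggregate_recovery(reports: list[dict]) -> dict:
    """Pool per-replicate recovery reports: mean bias, RMSE, empirical coverage."""
    bias = np.mean([r["bias"] for r in reports], axis=0)
    coverage = np.mean([r["covered"] for r in reports], axis=0)
    return {
        "ages": reports[0]["ages"],
        "mean_bias": bias,
        "rmse": float(np.mean([r["rmse"] for r in reports])),
        "coverage": coverage,
        "mean_coverage": float(np.mean(coverage)),
    }
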