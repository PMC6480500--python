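"""Model specifications and exact log-density mathematics.

Every model has the form

    Y_jk ~ Binomial(n_jk, mu_jk),   logit(mu_jk) = alpha + m(j) + p(k)

where each parent term ``m`` / ``p`` is one of

* ``car``        — one free effect per year of age under a first-order
                   random-walk (RW1 / intrinsic CAR) prior that penalises
                   squared differences between adjacent ages;
* ``linear``     — beta * (age - center);
* ``curvilinear``— beta * (age - center) + gamma * (age - center)^2;
* ``category5``  — a constant per 5-year age band, youngest band as
                   reference;
* ``none``       — term absent (single-parent / intercept-only models).

The RW1 prior is improper (invariant to a level shift), so CAR effect
vectors carry a sum-to-zero constraint and the intercept absorbs the
level. The RW1 precision tau relates to the smoothing standard deviation
by sigma = 1/sqrt(tau); sigma is given a Uniform(0, 10) hyperprior.
Fixed effects (linear, quadratic, band coefficients) get N(0, 1000)
priors, and the intercept is flat for CAR models and N(0, 1000) for the
comparison models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import gammaln

from .crosstab import AgeCrossTab, MarginalAgeTab

__all__ = [
    "RW1Prior",
    "FixedEffectPrior",
    "AgeBandScheme",
    "ModelSpec",
    "PRESETS",
    "binomial_loglik",
    "linear_predictor",
    "rw1_logdensity",
    "rw1_structure_matrix",
    "sd_hyperprior_logdensity",
    "design_matrix",
    "MATERNAL_CENTER",
    "PATERNAL_CENTER",
]

FORMS = ("none", "car", "linear", "curvilinear", "category5")

# Centering constants for the linear / curvilinear age covariates
# (midpoint of each parent's age range); pure reparameterisation that
# leaves fitted probabilities and DIC unchanged.
MATERNAL_CENTER = 32.0
PATERNAL_CENTER = 40.0


@dataclass(frozen=True)
class RW1Prior:
    """First-order random-walk prior on an ordered effect vector.

    ``sd_upper``/``sd_lower`` bound the Uniform hyperprior on the
    smoothing standard deviation sigma = 1/sqrt(tau); the support is the
    open interval (sd_lower, sd_upper).
    """

    length: int
    sd_upper: float = 10.0
    sd_lower: float = 0.0

    def __post_init__(self):
        if self.length < 2:
            raise ValueError("RW1 prior needs length >= 2")
        if not 0 <= self.sd_lower < self.sd_upper:
            raise ValueError("need 0 <= sd_lower < sd_upper")


@dataclass(frozen=True)
class FixedEffectPrior:
    """Independent Normal prior for fixed-effect coefficients."""

    mean: float = 0.0
    variance: float = 1000.0

    def __post_init__(self):
        if self.variance <= 0:
            raise ValueError("variance must be positive")


@dataclass(frozen=True)
class AgeBandScheme:
    """5-year age bands: 15-19 ... 45-49, plus 50-54, 55-59, 60-65 for fathers."""

    parent: str

    @property
    def band_edges(self) -> list[tuple[int, int]]:
        bands = [(a, a + 4) for a in range(15, 50, 5)]
        if self.parent == "paternal":
            bands += [(50, 54), (55, 59), (60, 65)]  # last band spans 6 years
        return bands

    @property
    def n_bands(self) -> int:
        return len(self.band_edges)

    def band_index(self, ages) -> np.ndarray:
        ages = np.asarray(ages)
        edges = self.band_edges
        lo = edges[0][0]
        hi = edges[-1][1]
        if np.any(ages < lo) or np.any(ages > hi):
            raise ValueError(f"age outside {self.parent} band range [{lo}, {hi}]")
        idx = np.minimum((ages - lo) // 5, self.n_bands - 1)
        return idx.astype(np.int64)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model variant.

    ``maternal_form`` / ``paternal_form`` pick the age term per parent;
    an intercept-only model (both ``none``) is allowed and is used by
    the sampler-correctness oracles.
    """

    outcome: str = ""
    maternal_form: str = "car"
    paternal_form: str = "car"
    intercept_prior: str = "flat"  # 'flat' or 'normal'
    car_sd_upper: float = 10.0
    fixed_prior: FixedEffectPrior = field(default_factory=FixedEffectPrior)

    def __post_init__(self):
        for form, who in ((self.maternal_form, "maternal"), (self.paternal_form, "paternal")):
            if form not in FORMS:
                raise ValueError(f"{who}_form must be one of {FORMS}, got {form!r}")
        if self.intercept_prior not in ("flat", "normal"):
            raise ValueError("intercept_prior must be 'flat' or 'normal'")

    @property
    def is_marginal(self) -> bool:
        return "none" in (self.maternal_form, self.paternal_form)

    def form(self, parent: str) -> str:
        return self.maternal_form if parent == "maternal" else self.paternal_form

    @classmethod
    def preset(cls, name: str, outcome: str = "") -> "ModelSpec":
        """Named presets: model1, model2, model3, linear, curvilinear, category5."""
        try:
            kwargs = PRESETS[name]
        except KeyError:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return cls(outcome=outcome, **kwargs)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "maternal_form": self.maternal_form,
            "paternal_form": self.paternal_form,
            "intercept_prior": self.intercept_prior,
            "car_sd_upper": self.car_sd_upper,
            "fixed_prior": {"mean": self.fixed_prior.mean, "variance": self.fixed_prior.variance},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        fp = d.pop("fixed_prior", None)
        if fp is not None:
            d["fixed_prior"] = FixedEffectPrior(**fp)
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(text))


# Single-parent CAR models (model1/model2) use a flat improper intercept;
# the fully conditional comparison models use N(0, 1000) intercepts.
PRESETS: dict[str, dict] = {
    "model1": dict(maternal_form="car", paternal_form="none", intercept_prior="flat"),
    "model2": dict(maternal_form="none", paternal_form="car", intercept_prior="flat"),
    "model3": dict(maternal_form="car", paternal_form="car", intercept_prior="flat"),
    "linear": dict(maternal_form="linear", paternal_form="linear", intercept_prior="normal"),
    "curvilinear": dict(
        maternal_form="curvilinear", paternal_form="curvilinear", intercept_prior="normal"
    ),
    "category5": dict(
        maternal_form="category5", paternal_form="category5", intercept_prior="normal"
    ),
}


# ---------------------------------------------------------------------------
# Log densities


def binomial_loglik(tab, mu) -> float:
    """Sum over cells of log Binomial(Y | n, mu); empty cells contribute 0.

    Works for both :class:`AgeCrossTab` and :class:`MarginalAgeTab`.
    ``mu`` must lie strictly inside (0, 1) wherever births > 0.
    """
    n = np.asarray(tab.births, dtype=float)
    y = np.asarray(tab.cases, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if mu.shape != n.shape:
        raise ValueError(f"mu shape {mu.shape} != count shape {n.shape}")
    if np.any((mu < 0) | (mu > 1)):
        raise ValueError("mu outside [0, 1]")
    occ = n > 0
    if np.any((mu[occ] <= 0) | (mu[occ] >= 1)):
        raise ValueError("mu must be strictly inside (0, 1) where births > 0")
    n, y, mu = n[occ], y[occ], mu[occ]
    const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    return float(np.sum(const + y * np.log(mu) + (n - y) * np.log1p(-mu)))


def rw1_structure_matrix(L: int) -> np.ndarray:
    """RW1 structure matrix Q: 1 at the corners, 2 on the interior diagonal,
    -1 on the first off-diagonals; effects' prior quadratic form is e'Qe."""
    Q = 2.0 * np.eye(L) - np.eye(L, k=1) - np.eye(L, k=-1)
    Q[0, 0] = Q[-1, -1] = 1.0
    return Q


def rw1_logdensity(effects, precision: float) -> float:
    """Improper RW1 log density, up to an additive constant.

    ((L-1)/2) log(tau) - (tau/2) * sum of squared first differences.
    Invariant under adding a constant to all effects (rank deficiency 1).
    """
    e = np.asarray(effects, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise ValueError("effects must be a vector of length >= 2")
    if not np.all(np.isfinite(e)) or not np.isfinite(precision):
        raise ValueError("non-finite inputs")
    if precision <= 0:
        raise ValueError("precision must be positive")
    d = np.diff(e)
    L = e.size
    return float(0.5 * (L - 1) * np.log(precision) - 0.5 * precision * np.sum(d * d))


def sd_hyperprior_logdensity(sd: float, prior: RW1Prior) -> float:
    """Uniform hyperprior on the smoothing SD: 0 inside the open support, -inf outside."""
    if prior.sd_lower < sd < prior.sd_upper:
        return 0.0
    return -np.inf


# ---------------------------------------------------------------------------
# Design matrices and the linear predictor


def design_matrix(form: str, ages, parent: str) -> np.ndarray:
    """Covariate columns for one parent's term, evaluated at ``ages``.

    car        -> one indicator column per age (identity over the grid)
    linear     -> (age - center)
    curvilinear-> (age - center), (age - center)^2
    category5  -> one indicator per non-reference band (reference = 15-19)
    none       -> zero columns
    """
    ages = np.asarray(ages, dtype=float)
    center = MATERNAL_CENTER if parent == "maternal" else PATERNAL_CENTER
    if form == "none":
        return np.zeros((ages.size, 0))
    if form == "car":
        # indices into the parent's own age grid; built by the caller for
        # identity grids — here ages are the grid itself
        return np.eye(ages.size)
    if form == "linear":
        return (ages - center)[:, None]
    if form == "curvilinear":
        c = ages - center
        return np.column_stack([c, c * c])
    if form == "category5":
        scheme = AgeBandScheme(parent)
        idx = scheme.band_index(ages.astype(int))
        X = np.zeros((ages.size, scheme.n_bands))
        X[np.arange(ages.size), idx] = 1.0
        return X[:, 1:]  # drop reference band 15-19
    raise ValueError(f"unknown form {form!r}")


def _term_value(form: str, params, age: int, parent: str, age_grid) -> float:
    if form == "none":
        return 0.0
    age_grid = np.asarray(age_grid)
    if age < age_grid[0] or age > age_grid[-1]:
        raise ValueError(f"{parent} age {age} outside declared range "
                         f"[{age_grid[0]}, {age_grid[-1]}]")
    theta = np.asarray(params, dtype=float)
    if form == "car":
        return float(theta[age - age_grid[0]])
    if form == "category5":
        # theta holds one coefficient per band with the reference fixed at 0
        scheme = AgeBandScheme(parent)
        if theta.size == scheme.n_bands - 1:
            theta = np.concatenate([[0.0], theta])
        return float(theta[scheme.band_index([age])[0]])
    X = design_matrix(form, [age], parent)
    return float(X[0] @ theta)


def linear_predictor(
    spec: ModelSpec,
    params: dict,
    ages: tuple[int, int],
    maternal_grid=None,
    paternal_grid=None,
) -> float:
    """Log-odds alpha + maternal term + paternal term at an age pair.

    ``params`` maps ``alpha`` to the intercept and ``maternal`` /
    ``paternal`` to each term's parameter vector (per-age effects for
    ``car``/``category5``, regression coefficients otherwise).
    """
    m_age, p_age = ages
    if maternal_grid is None:
        maternal_grid = np.arange(15, 50)
    if paternal_grid is None:
        paternal_grid = np.arange(15, 66)
    out = float(params.get("alpha", 0.0))
    if spec.maternal_form != "none":
        out += _term_value(spec.maternal_form, params["maternal"], m_age, "maternal", maternal_grid)
    if spec.paternal_form != "none":
        out += _term_value(spec.paternal_form, params["paternal"], p_age, "paternal", paternal_grid)
    return out
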