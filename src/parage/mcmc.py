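"""Posterior simulation for parental-age models.

The engine is an exact Metropolis-within-Gibbs sampler built on
Gaussian (Laplace / iteratively-reweighted-least-squares) proposals.
Each iteration performs

1. an independence Metropolis-Hastings refresh of the full coefficient
   vector (intercept plus every age term) proposed from the multivariate
   normal approximation of its conditional posterior at the IWLS mode,
   accepted or rejected against the exact binomial-logit target; and
2. for each RW1 (CAR) smoothing precision tau, a joint move that
   proposes tau on the log scale and a fresh coefficient vector from the
   Laplace approximation at the proposed tau, accepted jointly — so tau
   never has to crawl through the sticky tau <-> effects conditional.

Binomial counts in natality tables are huge and events rare, a regime in
which the conditional posterior is extremely close to Gaussian, so the
proposals are near-perfect and the chain mixes almost like independent
draws while detailed balance keeps it exact. (Pólya-Gamma-style
augmentation, by contrast, is known to mix poorly for rare events: its
augmented conditionals are far tighter than the posterior.)

CAR effect vectors live in a sum-to-zero basis, so the identification
constraint holds by construction and the intercept absorbs the level.
The default protocol is 5000 burn-in iterations followed by 10000
retained iterations on each of two chains with diverse starting values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import expit, gammaln

from .crosstab import AgeCrossTab, MarginalAgeTab, marginalize
from .model import ModelSpec, binomial_loglik, design_matrix, rw1_structure_matrix

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "ConvergenceReport",
    "DICResult",
    "fit_model",
    "check_convergence",
    "compute_dic",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampling protocol; defaults follow the source analysis.

    ``adapt_every`` is the batch length used to tune the log-scale
    proposal SD of the precision moves during burn-in; tuning freezes
    when sampling starts.
    """

    burn_in: int = 5000
    samples: int = 10000
    chains: int = 2
    seed: int = 0
    thinning: int = 1
    adapt_every: int = 50

    def __post_init__(self):
        if self.burn_in < 0 or self.samples < 1 or self.chains < 1 or self.thinning < 1:
            raise ValueError("invalid MCMC configuration")

    @property
    def n_retained(self) -> int:
        return self.samples // self.thinning


@dataclass
class PosteriorDraws:
    """Retained MCMC draws with chain metadata.

    ``maternal`` / ``paternal`` always hold per-age effect draws
    (chains, draws, n_ages) regardless of model form; for the fixed
    forms the underlying regression coefficients are additionally kept
    in ``maternal_coef`` / ``paternal_coef``. ``mu_mean`` is the
    posterior mean of the per-cell event probability (the DIC plug-in
    point).
    """

    spec: ModelSpec
    config: MCMCConfig
    data: AgeCrossTab | MarginalAgeTab
    alpha: np.ndarray
    deviance: np.ndarray
    mu_mean: np.ndarray
    maternal: np.ndarray | None = None
    paternal: np.ndarray | None = None
    maternal_coef: np.ndarray | None = None
    paternal_coef: np.ndarray | None = None
    sd_maternal: np.ndarray | None = None
    sd_paternal: np.ndarray | None = None
    chain_seeds: list = field(default_factory=list)
    accept_rates: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    def ages(self, parent: str) -> np.ndarray:
        if isinstance(self.data, AgeCrossTab):
            return self.data.maternal_ages if parent == "maternal" else self.data.paternal_ages
        if self.data.parent != parent:
            raise ValueError(f"fit contains no {parent} term")
        return self.data.ages

    def effects(self, parent: str) -> np.ndarray:
        eff = self.maternal if parent == "maternal" else self.paternal
        if eff is None:
            raise ValueError(f"fit contains no {parent} term")
        return eff

    def to_dict(self) -> dict:
        """Plain dict of draw arrays keyed by parameter name (chains, draws[, dim])."""
        out = {"alpha": self.alpha, "deviance": self.deviance}
        for name in ("maternal", "paternal", "sd_maternal", "sd_paternal",
                     "maternal_coef", "paternal_coef"):
            arr = getattr(self, name)
            if arr is not None:
                out[name] = arr
        return out

    def to_inference_data(self):
        """ArviZ InferenceData view for standard diagnostics tooling."""
        import arviz as az

        dims = {}
        coords = {}
        posterior = {}
        for name, arr in self.to_dict().items():
            if name == "deviance":
                continue
            posterior[name] = arr
            if arr.ndim == 3:
                dim = f"{name}_dim"
                dims[name] = [dim]
                coords[dim] = np.arange(arr.shape[2])
        return az.from_dict(posterior=posterior, dims=dims, coords=coords)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per retained iteration per chain; columns per scalar parameter."""
        cols = {}
        c, s = self.alpha.shape
        cols["chain"] = np.repeat(np.arange(c), s)
        cols["draw"] = np.tile(np.arange(s), c)
        for name, arr in self.to_dict().items():
            if arr.ndim == 2:
                cols[name] = arr.reshape(-1)
            else:
                for i in range(arr.shape[2]):
                    cols[f"{name}[{i}]"] = arr[:, :, i].reshape(-1)
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class ConvergenceReport:
    rhat: dict
    ess: dict
    threshold: float
    passed: bool

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def min_ess(self) -> float:
        return min(self.ess.values())


@dataclass(frozen=True)
class DICResult:
    mean_deviance: float
    plugin_deviance: float
    p_d: float
    dic: float


# ---------------------------------------------------------------------------
# sampler internals


def _sum_zero_basis(L: int) -> np.ndarray:
    """L x (L-1) basis A spanning {theta : sum(theta) = 0}.

    theta = A @ gamma has exact zero sum for any gamma, so CAR effect
    vectors satisfy the identification constraint by construction and
    the joint coefficient precision is nonsingular.
    """
    return np.vstack([np.eye(L - 1), -np.ones((1, L - 1))])


class _Term:
    """One parent's age term: design info, prior, and current state."""

    def __init__(self, parent: str, form: str, ages: np.ndarray, spec: ModelSpec):
        self.parent = parent
        self.form = form
        self.ages = ages
        self.is_car = form == "car"
        if self.is_car:
            L = ages.size
            self.A = _sum_zero_basis(L)
            self.p = L - 1
            Q = rw1_structure_matrix(L)
            self.QA = self.A.T @ Q @ self.A  # RW1 structure in the reduced basis
            self.tau = 1.0
            self.tau_min = 1.0 / spec.car_sd_upper**2
            self.grid_design = self.A
        else:
            self.grid_design = design_matrix(form, ages, parent)
            self.p = self.grid_design.shape[1]
            self.prior_prec = 1.0 / spec.fixed_prior.variance
        self.theta = np.zeros(self.p)

    def grid_effects(self, theta=None) -> np.ndarray:
        return self.grid_design @ (self.theta if theta is None else theta)

    def prior_block(self, tau: float | None = None) -> np.ndarray:
        if self.is_car:
            return (self.tau if tau is None else tau) * self.QA
        return self.prior_prec * np.eye(self.p)


class _Posterior:
    """Log target, IWLS mode, and Laplace proposal machinery for one chain.

    Proposals are a defensive mixture: with probability 0.9 a Gaussian
    at the IWLS mode with inverse-Hessian covariance (near-perfect in
    the core, where the huge-count posterior is essentially Gaussian),
    with probability 0.1 a multivariate t with ``_DF`` degrees of
    freedom at the same mode and scale. The binomial-logit target is
    log-concave with near-exponential tails, so a pure Gaussian proposal
    would be lighter-tailed than the target and the independence chain
    could stall at tail points; the t component keeps the importance
    ratio bounded.
    """

    _DF = 5.0
    _W_T = 0.1  # mixture weight of the heavy-tailed component

    def __init__(self, n_grid, y_grid, alpha_prec0, terms, axes, slices):
        # n_grid/y_grid are (D0, D1) count grids; each term acts along one
        # axis, which lets gradients and Hessians be assembled from axis
        # sums of the weight grid instead of per-cell design matrices.
        self.n_grid = n_grid
        self.y_grid = y_grid
        self.alpha_prec0 = alpha_prec0
        self.terms = terms
        self.axes = axes
        self.slices = slices
        self.p_tot = 1 + sum(t.p for t in terms)

    def psi_grid(self, b) -> np.ndarray:
        psi = np.full(self.n_grid.shape, b[0])
        for t, ax, sl in zip(self.terms, self.axes, self.slices):
            v = t.grid_design @ b[sl]
            psi += v[:, None] if ax == 0 else v[None, :]
        return psi

    def loglik(self, b) -> float:
        psi = self.psi_grid(b)
        # cells with n = 0 (hence y = 0) contribute exactly 0
        return float((self.y_grid * psi).sum()
                     - (self.n_grid * np.logaddexp(0.0, psi)).sum())

    def logprior(self, b, taus) -> float:
        out = -0.5 * self.alpha_prec0 * b[0] ** 2
        for t, sl, tau in zip(self.terms, self.slices, taus):
            g = b[sl]
            if t.is_car:
                out += 0.5 * (t.ages.size - 1) * np.log(tau) - 0.5 * tau * float(
                    g @ (t.QA @ g)
                )
            else:
                out += -0.5 * t.prior_prec * float(g @ g)
        return out

    def logpost(self, b, taus) -> float:
        return self.loglik(b) + self.logprior(b, taus)

    def prior_precision(self, taus) -> np.ndarray:
        P0 = np.zeros((self.p_tot, self.p_tot))
        P0[0, 0] = self.alpha_prec0
        for t, sl, tau in zip(self.terms, self.slices, taus):
            P0[sl, sl] += t.prior_block(tau)
        return P0

    def _grad_hess(self, b, P0):
        """Gradient and Hessian of logpost, assembled from axis sums."""
        psi = self.psi_grid(b)
        mu = expit(psi)
        r = self.y_grid - self.n_grid * mu
        w = self.n_grid * mu * (1.0 - mu)
        r_ax = (r.sum(axis=1), r.sum(axis=0))
        w_ax = (w.sum(axis=1), w.sum(axis=0))
        grad = np.empty(self.p_tot)
        grad[0] = r.sum()
        H = np.zeros((self.p_tot, self.p_tot))
        H[0, 0] = w.sum()
        for i, (t, ax, sl) in enumerate(zip(self.terms, self.axes, self.slices)):
            G = t.grid_design
            grad[sl] = G.T @ r_ax[ax]
            v = G.T @ w_ax[ax]
            H[0, sl] = v
            H[sl, 0] = v
            H[sl, sl] = G.T @ (G * w_ax[ax][:, None])
            for t2, ax2, sl2 in zip(self.terms[:i], self.axes[:i], self.slices[:i]):
                if ax2 == ax:
                    continue
                wg = w if ax2 == 0 else w.T  # rows follow t2's axis
                cross = t2.grid_design.T @ (wg @ G)
                H[sl2, sl] = cross
                H[sl, sl2] = cross.T
        grad -= P0 @ b
        H += P0
        return grad, H

    def laplace(self, taus, b0, max_iter: int = 50, tol: float = 1e-8):
        """IWLS mode and Cholesky of the Hessian of -logpost at the mode."""
        P0 = self.prior_precision(taus)
        b = b0.copy()
        fb = self.logpost(b, taus)
        cf = None
        for _ in range(max_iter):
            grad, H = self._grad_hess(b, P0)
            cf = (np.linalg.cholesky(H), True)  # clean factor, upper zeroed
            step = cho_solve(cf, grad)
            if 0.5 * float(grad @ step) < tol:  # Newton decrement: at the mode
                break
            # damped Newton: halve until the target improves
            lam = 1.0
            for _ in range(30):
                b_new = b + lam * step
                f_new = self.logpost(b_new, taus)
                if f_new >= fb - 1e-12:
                    break
                lam *= 0.5
            b, fb = b_new, f_new
        else:
            # iteration cap hit: refresh curvature at the final point
            _, H = self._grad_hess(b, P0)
            cf = (np.linalg.cholesky(H), True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        return b, cf, logdet

    def proposal_logpdf(self, b, mode, cf, logdet) -> float:
        """Log density of the Gaussian/t defensive mixture proposal."""
        p, df = self.p_tot, self._DF
        d = b - mode
        v = cf[0].T @ d  # L^T d, so |v|^2 = d' H d  (cf lower)
        q = float(v @ v)
        log_norm = 0.5 * logdet - 0.5 * p * np.log(2.0 * np.pi) - 0.5 * q
        log_t = (
            gammaln((df + p) / 2.0) - gammaln(df / 2.0) - 0.5 * p * np.log(df * np.pi)
            + 0.5 * logdet - 0.5 * (df + p) * np.log1p(q / df)
        )
        return float(np.logaddexp(np.log1p(-self._W_T) + log_norm,
                                  np.log(self._W_T) + log_t))

    def draw(self, mode, cf, rng) -> np.ndarray:
        z = rng.standard_normal(self.p_tot)
        heavy = rng.random() < self._W_T
        if heavy:
            z = z / np.sqrt(rng.chisquare(self._DF) / self._DF)
        return mode + solve_triangular(cf[0], z, lower=True, trans="T")


def _prepare_cells(tab, spec):
    """Shape the table into (D0, D1) count grids plus per-parent age grids.

    Cross-tabs put maternal on axis 0 and paternal on axis 1; marginal
    tables become single-column grids with their parent on axis 0.
    """
    if isinstance(tab, AgeCrossTab):
        if spec.is_marginal and not (spec.maternal_form == spec.paternal_form == "none"):
            parent = "maternal" if spec.maternal_form != "none" else "paternal"
            tab = marginalize(tab, parent)
    if isinstance(tab, MarginalAgeTab):
        for parent, form in (("maternal", spec.maternal_form), ("paternal", spec.paternal_form)):
            if form != "none" and tab.parent != parent:
                raise ValueError(
                    f"spec has a {parent} term but the marginal table is {tab.parent}"
                )
        n = tab.births.astype(float)[:, None]
        y = tab.cases.astype(float)[:, None]
        grids = {tab.parent: tab.ages}
        axis_of = {tab.parent: 0}
    else:
        n = tab.births.astype(float)
        y = tab.cases.astype(float)
        grids = {"maternal": tab.maternal_ages, "paternal": tab.paternal_ages}
        axis_of = {"maternal": 0, "paternal": 1}
    return tab, n, y, axis_of, grids


def fit_model(
    tab,
    spec: ModelSpec,
    config: MCMCConfig | None = None,
    *,
    _fixed_tau: dict | None = None,
) -> PosteriorDraws:
    """Sample the posterior of ``spec`` on ``tab``.

    A cross-tab passed with a single-parent spec is marginalised onto
    the relevant parent automatically. Results are deterministic given
    (data, spec, config including seed). ``_fixed_tau`` pins named CAR
    precisions (e.g. ``{"maternal": 4.0}``) instead of sampling them —
    used by the sampler-correctness oracles.
    """
    if config is None:
        config = MCMCConfig()
    tab, n, y, axis_of, grids = _prepare_cells(tab, spec)
    if tab.total_cases == 0:
        warnings.warn("table has zero cases; the intercept is only weakly identified")

    occ = n > 0
    loglik_const = float(np.sum(
        gammaln(n[occ] + 1) - gammaln(y[occ] + 1) - gammaln(n[occ] - y[occ] + 1)
    ))

    terms_proto = [
        (parent, spec.form(parent))
        for parent in ("maternal", "paternal")
        if spec.form(parent) != "none"
    ]
    alpha_prec0 = 0.0 if spec.intercept_prior == "flat" else 1.0 / spec.fixed_prior.variance

    total = tab.total_cases or 1
    alpha_center = float(np.log(total / max(tab.total_births - total, 1)))
    offsets = np.linspace(-2.0, 2.0, config.chains) if config.chains > 1 else np.array([0.0])

    n_keep = config.n_retained
    C = config.chains
    store = {"alpha": np.empty((C, n_keep)), "deviance": np.empty((C, n_keep))}
    term_store, coef_store, sd_store = {}, {}, {}
    for parent, form in terms_proto:
        L = grids[parent].size
        term_store[parent] = np.empty((C, n_keep, L))
        if form == "car":
            sd_store[parent] = np.empty((C, n_keep))
        else:
            p = design_matrix(form, grids[parent], parent).shape[1]
            coef_store[parent] = np.empty((C, n_keep, p))
    mu_sum = np.zeros_like(n)
    accept_totals = {"coef": 0.0}
    move_totals = {"coef": 0}

    root = np.random.SeedSequence(config.seed)
    children = root.spawn(C)
    chain_seeds = [int(c.generate_state(1)[0]) for c in children]

    for c in range(C):
        rng = np.random.default_rng(children[c])
        terms = [_Term(parent, form, grids[parent], spec)
                 for parent, form in terms_proto]
        if _fixed_tau:
            for t in terms:
                if t.is_car and t.parent in _fixed_tau:
                    t.tau = float(_fixed_tau[t.parent])
        axes = [axis_of[t.parent] for t in terms]
        slices = []
        pos = 1
        for t in terms:
            slices.append(slice(pos, pos + t.p))
            pos += t.p
        post = _Posterior(n, y, alpha_prec0, terms, axes, slices)

        car_terms = [
            t for t in terms
            if t.is_car and not (_fixed_tau and t.parent in _fixed_tau)
        ]
        prop_sd = {t.parent: 1.0 for t in car_terms}
        acc_count = {t.parent: 0 for t in car_terms}
        for t in car_terms:
            accept_totals.setdefault(f"tau_{t.parent}", 0.0)
            move_totals.setdefault(f"tau_{t.parent}", 0)

        taus = [t.tau if t.is_car else None for t in terms]
        b = np.zeros(post.p_tot)
        b[0] = alpha_center + offsets[c]
        mode, cf, logdet = post.laplace(taus, b)
        f_cur = post.logpost(b, taus)

        total_iter = config.burn_in + config.samples
        kept = 0
        for it in range(total_iter):
            # move 1: independence MH refresh of all coefficients
            b_new = post.draw(mode, cf, rng)
            f_new = post.logpost(b_new, taus)
            log_r = (f_new - f_cur
                     - post.proposal_logpdf(b_new, mode, cf, logdet)
                     + post.proposal_logpdf(b, mode, cf, logdet))
            move_totals["coef"] += 1
            if np.log(rng.random()) < log_r:
                b, f_cur = b_new, f_new
                accept_totals["coef"] += 1
            # move 2: joint (tau, coefficients) for each RW1 precision
            for t in car_terms:
                i = terms.index(t)
                old_tau = t.tau
                new_tau = old_tau * np.exp(prop_sd[t.parent] * rng.standard_normal())
                move_totals[f"tau_{t.parent}"] += 1
                if new_tau > t.tau_min:
                    taus_new = list(taus)
                    taus_new[i] = new_tau
                    mode2, cf2, logdet2 = post.laplace(taus_new, mode, max_iter=25)
                    b2 = post.draw(mode2, cf2, rng)
                    f2 = post.logpost(b2, taus_new)
                    # prior tau^(-3/2) plus log-scale Jacobian tau => -1/2
                    log_r = (f2 - f_cur
                             - 0.5 * (np.log(new_tau) - np.log(old_tau))
                             - post.proposal_logpdf(b2, mode2, cf2, logdet2)
                             + post.proposal_logpdf(b, mode, cf, logdet))
                    if np.log(rng.random()) < log_r:
                        t.tau = new_tau
                        taus = taus_new
                        b, f_cur = b2, f2
                        mode, cf, logdet = mode2, cf2, logdet2
                        acc_count[t.parent] += 1
                        accept_totals[f"tau_{t.parent}"] += 1
                if it < config.burn_in and (it + 1) % config.adapt_every == 0:
                    rate = acc_count[t.parent] / config.adapt_every
                    prop_sd[t.parent] = float(
                        np.clip(prop_sd[t.parent] * np.exp(rate - 0.234), 0.3, 8.0)
                    )
                    acc_count[t.parent] = 0

            if it >= config.burn_in:
                j = it - config.burn_in
                if j % config.thinning == 0:
                    psi = post.psi_grid(b)
                    store["alpha"][c, kept] = b[0]
                    dev = -2.0 * (
                        loglik_const
                        - float(np.sum(y * np.logaddexp(0.0, -psi)
                                       + (n - y) * np.logaddexp(0.0, psi)))
                    )
                    store["deviance"][c, kept] = dev
                    for t, sl in zip(terms, slices):
                        t.theta = b[sl]
                        term_store[t.parent][c, kept] = t.grid_effects()
                        if t.is_car:
                            sd_store[t.parent][c, kept] = 1.0 / np.sqrt(t.tau)
                        else:
                            coef_store[t.parent][c, kept] = t.theta
                    mu_sum += expit(psi)
                    kept += 1

    mu_mean = mu_sum / (C * n_keep)
    if isinstance(tab, MarginalAgeTab):
        mu_mean = mu_mean[:, 0]
    accept_rates = {k: accept_totals[k] / max(move_totals[k], 1) for k in accept_totals}
    return PosteriorDraws(
        spec=spec,
        config=config,
        data=tab,
        alpha=store["alpha"],
        deviance=store["deviance"],
        mu_mean=mu_mean,
        maternal=term_store.get("maternal"),
        paternal=term_store.get("paternal"),
        maternal_coef=coef_store.get("maternal"),
        paternal_coef=coef_store.get("paternal"),
        sd_maternal=sd_store.get("maternal"),
        sd_paternal=sd_store.get("paternal"),
        chain_seeds=chain_seeds,
        accept_rates=accept_rates,
    )


# ---------------------------------------------------------------------------
# diagnostics and model fit


def check_convergence(draws: PosteriorDraws, threshold: float = 1.05) -> ConvergenceReport:
    """Split-R-hat and effective sample size per scalar parameter (via ArviZ)."""
    import arviz as az

    if draws.n_chains < 2:
        raise ValueError("convergence diagnostics need at least 2 chains")
    rhat = {}
    ess = {}
    for name, arr in draws.to_dict().items():
        if name == "deviance":
            continue
        if arr.ndim == 2:
            arr = arr[:, :, None]
        for i in range(arr.shape[2]):
            x = arr[:, :, i]
            if np.ptp(x) == 0:  # constant parameter (e.g. pinned reference)
                continue
            key = name if arr.shape[2] == 1 else f"{name}[{i}]"
            rhat[key] = float(az.rhat(np.asarray(x)))
            ess[key] = float(az.ess(np.asarray(x)))
    passed = all(v <= threshold for v in rhat.values())
    return ConvergenceReport(rhat=rhat, ess=ess, threshold=threshold, passed=passed)


def compute_dic(draws: PosteriorDraws, tab=None, spec=None) -> DICResult:
    """Deviance Information Criterion.

    mean deviance Dbar over retained draws, plug-in deviance Dhat at the
    posterior mean of the per-cell probabilities (the direct stochastic
    parents of the counts), pD = Dbar - Dhat, DIC = Dbar + pD.
    """
    if tab is None:
        tab = draws.data
    else:
        ref = draws.data
        if isinstance(tab, AgeCrossTab) and isinstance(ref, MarginalAgeTab):
            tab = marginalize(tab, ref.parent)
        if np.asarray(tab.births).shape != np.asarray(ref.births).shape or not np.array_equal(
            np.asarray(tab.births), np.asarray(ref.births)
        ):
            raise ValueError("table does not match the one the model was fitted to")
    mean_dev = float(draws.deviance.mean())
    plugin_dev = -2.0 * binomial_loglik(tab, draws.mu_mean)
    p_d = mean_dev - plugin_dev
    return DICResult(mean_deviance=mean_dev, plugin_deviance=plugin_dev, p_d=p_d,
                     dic=mean_dev + p_d)
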