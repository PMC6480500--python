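"""Posterior summaries: age-specific odds ratios, credible intervals,
exceedance probabilities, and comparison plots.

Odds ratios are standardised either to a reference age (default 15
years, zero-width interval at the reference) or to the overall mean
risk (the births-weighted average of the cell log-odds). Intervals are
equal-tailed 2.5/50/97.5 percentiles of the transformed draws —
percentiles of per-draw odds ratios, never transforms of percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crosstab import AgeCrossTab, marginalize
from .mcmc import PosteriorDraws

__all__ = [
    "ORTable",
    "or_vs_reference",
    "or_vs_overall_mean",
    "exceedance_probability",
    "plot_or_curves",
]


@dataclass(frozen=True)
class ORTable:
    """Per-age posterior odds-ratio summary relative to a stated baseline."""

    parent: str
    baseline: str  # 'age15' style reference label or 'overall_mean'
    ages: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    exceedance: np.ndarray
    label: str = ""

    def __post_init__(self):
        if np.any(self.lower > self.median + 1e-12) or np.any(self.median > self.upper + 1e-12):
            raise ValueError("percentile ordering violated: need lower <= median <= upper")
        if np.any(self.lower <= 0):
            raise ValueError("odds ratios must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "median": self.median,
                "lower": self.lower,
                "upper": self.upper,
                "exceedance": self.exceedance,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _summarise(or_draws: np.ndarray, ages, parent, baseline, label="") -> ORTable:
    lo, med, hi = np.percentile(or_draws, [2.5, 50.0, 97.5], axis=0)
    exceed = np.mean(or_draws > 1.0, axis=0)  # strict: ties count as non-exceedance
    return ORTable(
        parent=parent,
        baseline=baseline,
        ages=np.asarray(ages),
        median=med,
        lower=lo,
        upper=hi,
        exceedance=exceed,
        label=label,
    )


def _flat_effects(draws: PosteriorDraws, parent: str) -> tuple[np.ndarray, np.ndarray]:
    eff = draws.effects(parent)  # (chains, draws, L)
    ages = draws.ages(parent)
    return eff.reshape(-1, eff.shape[-1]), ages


def or_vs_reference(draws: PosteriorDraws, parent: str, ref_age: int = 15) -> ORTable:
    """Odds ratios exp(effect_age - effect_ref) per draw, summarised per age.

    At the reference age the odds ratio is exactly 1 with a zero-width
    interval.
    """
    eff, ages = _flat_effects(draws, parent)
    if ref_age < ages[0] or ref_age > ages[-1]:
        raise ValueError(f"reference age {ref_age} outside range [{ages[0]}, {ages[-1]}]")
    ref = eff[:, ref_age - ages[0]]
    or_draws = np.exp(eff - ref[:, None])
    return _summarise(or_draws, ages, parent, f"age{ref_age}", label=draws.spec.outcome)


def or_vs_overall_mean(
    draws: PosteriorDraws, tab: AgeCrossTab, parent: str, weighted: bool = True
) -> ORTable:
    """Odds ratios against the overall mean risk.

    Per draw, the baseline log-odds is the births-weighted mean of the
    cell linear predictors (unweighted across ages if ``weighted`` is
    False); a parent's per-age OR then compares that age, with the other
    term held at its weighted mean, against the baseline — which reduces
    to exp(effect_age - weighted mean of effects).
    """
    eff, ages = _flat_effects(draws, parent)
    fitted = draws.data
    if isinstance(fitted, AgeCrossTab):
        if not np.array_equal(fitted.births, tab.births):
            raise ValueError("table does not match the one the model was fitted to")
        axis = 1 if parent == "maternal" else 0
        w = tab.births.sum(axis=axis).astype(float)
    else:
        marg = marginalize(tab, parent) if isinstance(tab, AgeCrossTab) else tab
        if not np.array_equal(np.asarray(marg.births), np.asarray(fitted.births)):
            raise ValueError("table does not match the one the model was fitted to")
        w = np.asarray(marg.births, dtype=float)
    if not weighted:
        w = np.ones_like(w)
    w = w / w.sum()
    base = eff @ w
    or_draws = np.exp(eff - base[:, None])
    return _summarise(or_draws, ages, parent, "overall_mean", label=draws.spec.outcome)


def exceedance_probability(
    draws: PosteriorDraws, parent: str, age: int, ref_age: int = 15
) -> float:
    """Posterior fraction of draws with OR(age vs ref_age) strictly above 1."""
    eff, ages = _flat_effects(draws, parent)
    for a in (age, ref_age):
        if a < ages[0] or a > ages[-1]:
            raise ValueError(f"age {a} outside range [{ages[0]}, {ages[-1]}]")
    diff = eff[:, age - ages[0]] - eff[:, ref_age - ages[0]]
    return float(np.mean(diff > 0))


def plot_or_curves(tables, path=None, log_scale: bool = True, overlay: bool = False,
                   titles=None):
    """Panel (or overlay) plot of OR medians with 95% credible ribbons.

    Returns the matplotlib figure; writes to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tables = list(tables)
    if not tables:
        raise ValueError("no OR tables to plot")
    if overlay:
        fig, ax = plt.subplots(figsize=(6, 4.5))
        axes = [ax] * len(tables)
        ribbons = False
    else:
        ncol = 2 if len(tables) > 1 else 1
        nrow = int(np.ceil(len(tables) / ncol))
        fig, axarr = plt.subplots(nrow, ncol, figsize=(5.5 * ncol, 4 * nrow), squeeze=False)
        axes = axarr.reshape(-1)[: len(tables)]
        for extra in axarr.reshape(-1)[len(tables):]:
            extra.set_visible(False)
        ribbons = True
    for i, (t, ax) in enumerate(zip(tables, axes)):
        name = t.label or f"{t.parent} vs {t.baseline}"
        ax.plot(t.ages, t.median, lw=1.8, label=name)
        if ribbons:
            ax.fill_between(t.ages, t.lower, t.upper, alpha=0.25)
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        if log_scale:
            ax.set_yscale("log")
        ax.set_xlabel(f"{t.parent} age (years)")
        ax.set_ylabel("odds ratio")
        if not overlay and titles is not None:
            ax.set_title(titles[i])
        elif not overlay:
            ax.set_title(f"{t.parent}, baseline {t.baseline}")
    if overlay:
        axes[0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
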