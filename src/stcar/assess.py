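"""Decision artifacts from posterior draws: WAIC, coverage, percentile maps.

WAIC uses the variance-based effective-parameter penalty computed from
pointwise posterior log-likelihoods,

.. math::

    \\mathrm{lppd} = \\sum_i \\log \\tfrac1S \\sum_s p(y_i \\mid \\theta_s),
    \\quad
    p_\\mathrm{WAIC} = \\sum_i \\mathrm{Var}_s[\\log p(y_i \\mid \\theta_s)],
    \\quad
    \\mathrm{WAIC} = -2(\\mathrm{lppd} - p_\\mathrm{WAIC}),

with the sample variance taken with denominator S - 1.  Lower is better.

Out-of-sample validation follows the 70/30 convention: a seeded random
split of the area-year cells, the model refitted on the training cells
(held-out cells contribute nothing to the likelihood; their latent effects
are drawn from the prior structure conditioned on sampled neighbours), and
the coverage percentage

.. math::

    CP = 100 \\cdot \\tfrac1k \\sum_{i=1}^k I(L_i \\le y_i \\le U_i)

of the 95% posterior-predictive intervals on the held-out counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from .graphs import SpatialGraph
from .mcmc import ChainConfig, PosteriorSamples, run_chain
from .models import ModelSpec
from .panel import PanelData

__all__ = [
    "WAIC",
    "waic",
    "coverage_percentage",
    "rate_ratio_percent",
    "spatial_percentiles",
    "holdout_split",
    "holdout_validate",
    "HoldoutResult",
    "compare_models",
]


class WAIC(NamedTuple):
    waic: float
    lppd: float
    p_waic: float


def waic(pointwise_loglik: np.ndarray) -> WAIC:
    """WAIC from a (draws x observations) pointwise log-likelihood matrix."""
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("expected a (draws, observations) matrix")
    S = ll.shape[0]
    if S < 2:
        raise ValueError("need at least two draws to estimate the WAIC penalty")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihood")
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return WAIC(-2.0 * (lppd - p_waic), lppd, p_waic)


def samples_waic(samples: PosteriorSamples) -> WAIC:
    """WAIC of a fit, over the cells its likelihood actually saw."""
    pw = samples.draws["loglik_pointwise"]
    S = pw.shape[0]
    if samples.mask is not None:
        pw = pw[:, samples.mask]
    else:
        pw = pw.reshape(S, -1)
    return waic(pw)


def coverage_percentage(
    intervals: Sequence[tuple], observed: Sequence[float]
) -> float:
    """Percentage of observations inside their closed intervals [L_i, U_i]."""
    intervals = np.asarray(intervals, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if intervals.size == 0 and observed.size == 0:
        raise ValueError("empty input")
    if intervals.ndim != 2 or intervals.shape[1] != 2:
        raise ValueError("intervals must be a sequence of (L, U) pairs")
    if len(intervals) != len(observed):
        raise ValueError("interval and observation counts differ")
    if len(observed) == 0:
        raise ValueError("empty input")
    L, U = intervals[:, 0], intervals[:, 1]
    if np.any(L > U):
        raise ValueError("found an interval with L > U")
    inside = (L <= observed) & (observed <= U)
    return float(100.0 * inside.mean())


def rate_ratio_percent(coefficient: float, direction: str = "ratio") -> float:
    """Interpret a log-scale coefficient on the percentage scale.

    ``ratio`` returns ``100 * exp(coef)`` (the rate ratio as a percentage);
    ``percent-change`` returns ``100 * (exp(coef) - 1)`` (the percentage
    change in the rate per unit increase of the covariate).
    """
    if direction == "ratio":
        return float(100.0 * np.exp(coefficient))
    if direction == "percent-change":
        return float(100.0 * np.expm1(coefficient))
    raise ValueError("direction must be 'ratio' or 'percent-change'")


def spatial_percentiles(
    fitted: np.ndarray,
    aggregate: str = "sum",
    area_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Per-area percentile ranks of time-aggregated fitted values.

    Aggregates ``fitted`` (n areas x T years) over time, then assigns
    ``100 * (rank - 1) / n`` with average ranks for ties, so the ranks live
    in [0, 100) and exactly the top half of distinct areas sits at or above
    the 50th percentile.
    """
    fitted = np.asarray(fitted, dtype=float)
    if aggregate == "sum":
        agg = fitted.sum(axis=1)
    elif aggregate == "mean":
        agg = fitted.mean(axis=1)
    else:
        raise ValueError("aggregate must be 'sum' or 'mean'")
    n = len(agg)
    ranks = rankdata(agg, method="average")
    pct = 100.0 * (ranks - 1) / n
    if area_ids is None:
        area_ids = list(range(n))
    return pd.DataFrame(
        {"area_id": list(area_ids), "aggregate": agg, "percentile": pct}
    )


# ---------------------------------------------------------------------------
# hold-out validation
# ---------------------------------------------------------------------------

@dataclass
class HoldoutResult:
    cp: float
    intervals: pd.DataFrame       # held-out cells with L, U, observed
    train_mask: np.ndarray        # (n, T) True = training cell
    samples: PosteriorSamples


def holdout_split(
    n: int, T: int, split: float, seed, unit: str = "cell"
) -> np.ndarray:
    """Seeded boolean training mask; True marks training cells.

    ``unit`` chooses what is held out jointly: individual cells (default),
    whole areas, or whole years.
    """
    if not 0.0 < split < 1.0:
        raise ValueError("split must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    mask = np.zeros((n, T), dtype=bool)
    if unit == "cell":
        m = n * T
        k = int(round(split * m))
        idx = rng.permutation(m)[:k]
        mask.reshape(-1)[idx] = True
    elif unit == "area":
        k = int(round(split * n))
        mask[rng.permutation(n)[:k], :] = True
    elif unit == "year":
        k = int(round(split * T))
        mask[:, rng.permutation(T)[:k]] = True
    else:
        raise ValueError("unit must be 'cell', 'area' or 'year'")
    if mask.all() or not mask.any():
        raise ValueError("split leaves an empty training or test set")
    return mask


def predictive_intervals(
    samples: PosteriorSamples,
    cells: np.ndarray,
    y: np.ndarray,
    level: float = 0.95,
    seed=0,
) -> pd.DataFrame:
    """95% posterior-predictive count intervals at the marked cells.

    For each retained draw a Poisson count is generated at that draw's
    cell mean exp(eta); interval endpoints are the equal-tailed predictive
    percentiles.
    """
    rng = np.random.default_rng(seed)
    mu = np.exp(samples.draws["eta"][:, cells])     # (S, k)
    ystar = rng.poisson(mu)
    lo = 100 * (1 - level) / 2
    L, U = np.percentile(ystar, [lo, 100 - lo], axis=0)
    ii, tt = np.nonzero(cells)
    return pd.DataFrame(
        {
            "area_id": [samples.area_ids[i] for i in ii],
            "year": [samples.years[t] for t in tt],
            "observed": y[cells],
            "L": L,
            "U": U,
        }
    )


def holdout_validate(
    panel: PanelData,
    spec: ModelSpec,
    config: ChainConfig,
    graph: SpatialGraph | None = None,
    split: float = 0.7,
    seed: int = 0,
    unit: str = "cell",
) -> HoldoutResult:
    """70/30 out-of-sample validation with predictive-interval coverage."""
    train = holdout_split(panel.n_areas, panel.n_times, split, seed, unit)
    samples = run_chain(panel, spec, config, graph=graph, mask=train)
    table = predictive_intervals(samples, ~train, panel.y, seed=seed + 1)
    cp = coverage_percentage(table[["L", "U"]].to_numpy(), table["observed"])
    return HoldoutResult(cp=cp, intervals=table, train_mask=train, samples=samples)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def compare_models(
    panel: PanelData,
    config: ChainConfig,
    variants: Iterable[str] = ("linear", "anova", "separable", "ar"),
    graph: SpatialGraph | None = None,
    spec_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Fit several variants to one panel and rank them by WAIC (ascending)."""
    spec_kwargs = spec_kwargs or {}
    rows = []
    for variant in variants:
        spec = ModelSpec(
            variant=variant, n_covariates=panel.n_covariates, **spec_kwargs
        )
        samples = run_chain(panel, spec, config, graph=graph)
        w = samples_waic(samples)
        rows.append(
            {"variant": spec.variant, "waic": w.waic, "lppd": w.lppd,
             "p_waic": w.p_waic}
        )
    return (
        pd.DataFrame(rows).sort_values("waic").reset_index(drop=True)
    )
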