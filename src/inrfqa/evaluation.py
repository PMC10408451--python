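"""Correlation protocol and parameter fitting.

Objective metric scores are compared against subjective opinion scores
(MOS/DMOS) by:

* **SRCC** — Spearman rank correlation (average ranks for ties);
* **PLCC** — Pearson correlation computed *after* mapping the objective
  scores through a fitted four-parameter logistic

      y(x) = b2 + (b1 - b2) / (1 + exp(-(x - b3) / |b4|))

  which linearizes the metric-opinion relationship and absorbs its
  orientation (distance metrics anti-correlate with opinion scores).

``grid_search`` exhaustively scans candidate transform parameters and
returns the combination maximizing the chosen correlation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._exceptions import (
    FitFailureError,
    InvalidInputError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from .core import INRFParams
from .iqa import inrf_iqa

__all__ = [
    "ScoredSet",
    "Logistic4Params",
    "GridSpec",
    "GridSearchResult",
    "srcc",
    "logistic4",
    "fit_logistic4",
    "plcc_after_fit",
    "grid_search",
]


@dataclass(frozen=True)
class ScoredSet:
    """Index-paired objective (metric) and subjective (opinion) scores."""

    objective: np.ndarray
    subjective: np.ndarray

    def __post_init__(self):
        obj = np.asarray(self.objective, dtype=np.float64)
        sub = np.asarray(self.subjective, dtype=np.float64)
        if obj.ndim != 1 or sub.ndim != 1 or obj.shape != sub.shape:
            raise InvalidInputError(
                f"objective and subjective must be equal-length 1D vectors, "
                f"got {obj.shape} and {sub.shape}"
            )
        if obj.size < 3:
            raise InvalidInputError(f"need at least 3 scored items, got {obj.size}")
        if not (np.all(np.isfinite(obj)) and np.all(np.isfinite(sub))):
            raise InvalidInputError("scores contain non-finite values")
        object.__setattr__(self, "objective", obj)
        object.__setattr__(self, "subjective", sub)

    def __len__(self) -> int:
        return int(self.objective.size)


def _as_scored(data, subjective=None) -> ScoredSet:
    if isinstance(data, ScoredSet):
        return data
    return ScoredSet(np.asarray(data), np.asarray(subjective))


@dataclass(frozen=True)
class Logistic4Params:
    """Parameters of the four-parameter logistic mapping."""

    beta1: float
    beta2: float
    beta3: float
    beta4: float

    def __post_init__(self):
        if self.beta4 == 0:
            raise InvalidParameterError("beta4 must be nonzero")

    def as_tuple(self):
        return (self.beta1, self.beta2, self.beta3, self.beta4)


@dataclass(frozen=True)
class Logistic4Fit:
    """Fitted logistic parameters plus the residual norm of the fit."""

    params: Logistic4Params
    residual_norm: float


def srcc(data, subjective=None) -> float:
    """Spearman rank correlation between objective and subjective scores."""
    ds = _as_scored(data, subjective)
    if np.ptp(ds.objective) == 0 or np.ptp(ds.subjective) == 0:
        raise UndefinedCorrelationError(
            "rank correlation is undefined for a constant score vector"
        )
    rho = stats.spearmanr(ds.objective, ds.subjective).statistic
    return float(rho)


def logistic4(x, p: Logistic4Params):
    """Evaluate the four-parameter logistic at ``x`` (scalar or array)."""
    return _logistic4_raw(np.asarray(x, dtype=np.float64), *p.as_tuple())


def _logistic4_raw(x, beta1, beta2, beta3, beta4):
    if beta4 == 0:
        raise InvalidParameterError("beta4 must be nonzero")
    return beta2 + (beta1 - beta2) / (1.0 + np.exp(-(x - beta3) / abs(beta4)))


def fit_logistic4(data, subjective=None) -> Logistic4Fit:
    """Nonlinear least-squares fit of the logistic to (objective, subjective).

    Initialization: ``b1 = max(subjective)``, ``b2 = min(subjective)``,
    ``b3 = median(objective)``, ``b4 = std(objective)`` — with ``b1``/``b2``
    swapped when the raw Pearson correlation is negative, so the initial
    curve already has the right orientation.
    """
    ds = _as_scored(data, subjective)
    if len(ds) < 5:
        raise InvalidInputError(f"need at least 5 scored items to fit, got {len(ds)}")
    if np.ptp(ds.objective) == 0:
        raise UndefinedCorrelationError("objective scores are constant; cannot fit")

    b1 = float(np.max(ds.subjective))
    b2 = float(np.min(ds.subjective))
    if np.ptp(ds.subjective) > 0:
        r = stats.pearsonr(ds.objective, ds.subjective).statistic
        if r < 0:
            b1, b2 = b2, b1
    b3 = float(np.median(ds.objective))
    b4 = float(np.std(ds.objective))
    if b4 == 0 or not np.isfinite(b4):
        b4 = 1.0
    init = (b1, b2, b3, b4)

    try:
        popt, _ = optimize.curve_fit(
            _logistic4_raw,
            ds.objective,
            ds.subjective,
            p0=init,
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitFailureError(f"logistic fit did not converge: {exc}", init=init) from exc
    if not np.all(np.isfinite(popt)):
        raise FitFailureError("logistic fit produced non-finite parameters", init=init)
    params = Logistic4Params(*[float(v) for v in popt])
    resid = ds.subjective - _logistic4_raw(ds.objective, *popt)
    return Logistic4Fit(params=params, residual_norm=float(np.linalg.norm(resid)))


def plcc_after_fit(data, subjective=None) -> float:
    """Pearson correlation between logistic-mapped objective and subjective."""
    ds = _as_scored(data, subjective)
    fit = fit_logistic4(ds)
    mapped = logistic4(ds.objective, fit.params)
    if np.ptp(mapped) == 0 or np.ptp(ds.subjective) == 0:
        raise UndefinedCorrelationError(
            "correlation is undefined for a constant vector after mapping"
        )
    r = stats.pearsonr(mapped, ds.subjective).statistic
    return float(r)


@dataclass(frozen=True)
class GridSpec:
    """Candidate values for the exhaustive parameter scan.

    Defaults cover the published optimum so the scan can recover it.
    """

    sigma_m: tuple = (0.5, 1.0, 1.74, 2.5, 4.0)
    sigma_w: tuple = (5.0, 10.0, 25.0, 50.0)
    sigma_g: tuple = (0.5, 1.0, 2.0)
    lam: tuple = (1.0, 2.0, 3.0, 5.0)

    def __post_init__(self):
        for name in ("sigma_m", "sigma_w", "sigma_g", "lam"):
            vals = tuple(getattr(self, name))
            if not vals:
                raise InvalidParameterError(f"grid for {name} is empty")
            object.__setattr__(self, name, vals)

    def points(self):
        """Grid points in lexicographic (sigma_m, sigma_w, sigma_g, lam) order."""
        for sm, sw, sg, lm in itertools.product(
            sorted(self.sigma_m), sorted(self.sigma_w), sorted(self.sigma_g), sorted(self.lam)
        ):
            yield INRFParams(sigma_m=sm, sigma_w=sw, sigma_g=sg, lam=lm)


@dataclass(frozen=True)
class GridSearchResult:
    best: INRFParams
    best_score: float
    log: tuple  # one dict per grid point: params, correlation or error


def grid_search(
    pairs,
    subjective,
    grid: GridSpec | None = None,
    objective_fn: str = "plcc",
    *,
    luminance: str = "luma601",
) -> GridSearchResult:
    """Exhaustive scan of the parameter grid against subjective scores.

    Every grid point is evaluated by computing the image metric on all pairs
    and correlating with the subjective scores — PLCC (after the logistic
    mapping) or |SRCC| (absolute value, since distance metrics anti-correlate
    with opinion scores).  Ties are broken toward the lexicographically
    smallest (sigma_m, sigma_w, sigma_g, lam).  Failures at individual grid
    points are logged and skipped, never silently ignored.
    """
    if objective_fn not in ("plcc", "srcc"):
        raise InvalidParameterError(f"unknown objective_fn {objective_fn!r}")
    pairs = list(pairs)
    subjective = np.asarray(subjective, dtype=np.float64)
    if len(pairs) < 5:
        raise InvalidInputError(f"need at least 5 scored pairs, got {len(pairs)}")
    if subjective.shape != (len(pairs),):
        raise InvalidInputError("subjective scores must match the number of pairs")
    grid = grid or GridSpec()

    best = None
    best_score = -np.inf
    log = []
    for params in grid.points():
        entry = {
            "sigma_m": params.sigma_m,
            "sigma_w": params.sigma_w,
            "sigma_g": params.sigma_g,
            "lam": params.lam,
        }
        try:
            scores = np.array(
                [inrf_iqa(r, d, params, luminance=luminance) for r, d in pairs]
            )
            if objective_fn == "plcc":
                corr = plcc_after_fit(scores, subjective)
            else:
                corr = abs(srcc(scores, subjective))
            entry["correlation"] = corr
        except Exception as exc:  # logged, point skipped
            entry["error"] = f"{type(exc).__name__}: {exc}"
            log.append(entry)
            continue
        log.append(entry)
        if corr > best_score:  # strict: lexicographically first wins ties
            best_score = corr
            best = params
    if best is None:
        raise FitFailureError("every grid point failed; see the scan log")
    return GridSearchResult(best=best, best_score=float(best_score), log=tuple(log))
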