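"""Four-parameter logistic dose–response fitting and potency summaries.

The screen measures percent inhibition (PI) of ATP-proxy viability at five
ten-fold dilutions per compound.  Responses are modeled on a log10-molar
concentration axis with the ascending four-parameter logistic

    y(x) = d + (a - d) / (1 + 10 ** (b * (c - x)))

where ``a`` is the top asymptote (max %-inhibition), ``b > 0`` the Hill
slope, ``c`` the log10 EC50 (inflection) and ``d`` the bottom asymptote,
fixed at 0 by default because the inhibition scale is anchored at the
no-effect level of the DMSO controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .plate_io import DoseSeries

__all__ = [
    "Logistic4P",
    "FitResult",
    "Potency",
    "predict_inhibition",
    "fit_logistic",
    "potency",
    "fit_table",
]

#: PI range (percentage points) below which a series is treated as flat:
#: potency parameters of flatter series are not identifiable from the data.
#: Equal to the DSS minimum-activity threshold.
IDENTIFIABILITY_RANGE = 10.0

_B_STARTS = (0.5, 1.0, 2.0, 5.0)


@dataclass(frozen=True)
class Logistic4P:
    """Parameters of the four-parameter logistic on the log10-molar axis."""

    a: float  # top asymptote, % inhibition
    b: float  # slope, dimensionless, > 0
    c: float  # log10 EC50, log10 molar
    d: float = 0.0  # bottom asymptote, % inhibition

    def __post_init__(self) -> None:
        if not (0.0 <= self.d <= self.a <= 100.0 + 1e-9):
            raise ValueError(f"require 0 <= d <= a <= 100, got a={self.a}, d={self.d}")
        if not (0.0 < self.b <= 10.0):
            raise ValueError(f"require 0 < b <= 10, got b={self.b}")
        if not np.isfinite(self.c):
            raise ValueError("c must be finite")


@dataclass(frozen=True)
class FitResult:
    params: Logistic4P
    rss: float
    r2: float
    converged: bool
    identifiable: bool


@dataclass(frozen=True)
class Potency:
    ec50: float  # molar (relative EC50 = inflection)
    ic50_abs: float | None  # molar; None when the curve never crosses 50 %
    reliable: bool


def predict_inhibition(p: Logistic4P, x) -> np.ndarray | float:
    """Evaluate the 4PL at log10-molar concentration(s) ``x``."""
    x = np.asarray(x, dtype=float)
    y = p.d + (p.a - p.d) / (1.0 + 10.0 ** (p.b * (p.c - x)))
    return float(y) if y.ndim == 0 else y


def _c_starts(x: np.ndarray) -> list[float]:
    mids = ((x[:-1] + x[1:]) / 2.0).tolist()
    return mids + [float(np.median(x))]


def fit_logistic(
    s: DoseSeries,
    *,
    fix_bottom: float | None = 0.0,
    max_slope: float = 10.0,
) -> FitResult:
    """Least-squares 4PL fit with a deterministic multi-start grid.

    Constraints: ``0 <= a <= 100``, ``0 < b <= max_slope``,
    ``c`` within one log-unit of the tested range, ``d`` fixed (default 0).
    Starts span b in {0.5, 1, 2, 5} x c in dose-grid midpoints; the best
    residual sum of squares wins, ties resolved toward the smaller slope.
    A series whose PI range is below 10 points is flagged unidentifiable.
    If every start fails, a flat fallback fit ``a = clip(mean PI, 0, 100)``
    is returned with ``converged=False``.
    """
    x = np.asarray(s.x, dtype=float)
    y = np.asarray(s.pi, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need >= 2 distinct doses to fit")
    d0 = 0.0 if fix_bottom is None else float(fix_bottom)
    identifiable = (y.max() - y.min()) >= IDENTIFIABILITY_RANGE

    c_lo, c_hi = x.min() - 1.0, x.max() + 1.0

    def resid(theta: np.ndarray) -> np.ndarray:
        a, b, c = theta
        return y - (d0 + (a - d0) / (1.0 + 10.0 ** (b * (c - x))))

    def jac(theta: np.ndarray) -> np.ndarray:
        a, b, c = theta
        g = 10.0 ** (b * (c - x))
        denom = 1.0 + g
        da = -1.0 / denom
        common = (a - d0) * g * np.log(10.0) / denom**2
        return np.column_stack([da, common * (c - x), common * b])

    a0 = float(np.clip(y.max(), d0 + 1.0, 100.0))
    best: tuple[float, float, np.ndarray] | None = None  # (rss, b, theta)
    lb = np.array([d0, 1e-3, c_lo])
    ub = np.array([100.0, max_slope, c_hi])
    # rank the deterministic start grid by initial RSS and polish the best
    # few: cheap, and the basin of the global optimum is reliably among them
    starts = [
        np.clip(np.array([a0, b0, c0]), lb, ub)
        for b0 in _B_STARTS for c0 in _c_starts(x)
    ]
    order = np.argsort([float(np.sum(resid(t) ** 2)) for t in starts], kind="stable")
    best_success = False
    for theta0 in (starts[i] for i in order[:4]):
        try:
            sol = least_squares(
                resid, theta0, jac=jac, bounds=(lb, ub),
                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=300,
            )
        except Exception:
            continue
        # an iteration-budget stop still yields a usable (near-)optimum;
        # only a hard optimizer failure is discarded
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-12 or (
            abs(rss - best[0]) <= 1e-12 and sol.x[1] < best[1]
        ):
            best = (rss, float(sol.x[1]), sol.x)
            best_success = bool(sol.success)
        if best is not None and best[0] < 1e-16 * max(len(y), 1):
            break

    # the no-response curve (a = d, exactly flat) is always a candidate: on
    # unresponsive series the optimizer can stall marginally above it
    theta_null = np.clip(np.array([d0, 1.0, float(np.median(x))]), lb, ub)
    null_rss = float(np.sum((y - d0) ** 2))
    if best is not None and null_rss <= best[0] + 1e-12:
        best = (null_rss, 1.0, theta_null)
        best_success = True

    sst = float(np.sum((y - y.mean()) ** 2))
    if best is None:
        a = float(np.clip(y.mean(), 0.0, 100.0))
        params = Logistic4P(a=max(a, d0), b=1.0, c=float(np.median(x)), d=d0)
        rss = float(np.sum((y - predict_inhibition(params, x)) ** 2))
        r2 = 1.0 - rss / sst if sst > 0 else 0.0
        return FitResult(params, rss, r2, converged=False, identifiable=False)

    rss, _, theta = best
    a, b, c = (float(v) for v in theta)
    params = Logistic4P(a=min(a, 100.0), b=min(b, max_slope), c=c, d=d0)
    r2 = 1.0 - rss / sst if sst > 0 else (1.0 if rss < 1e-12 else 0.0)
    return FitResult(params, rss, min(r2, 1.0), converged=best_success,
                     identifiable=bool(identifiable))


def potency(fit: FitResult) -> Potency:
    """EC50 (inflection) and absolute IC50 (50 % inhibition crossing).

    The absolute IC50 solves y(x) = 50 with d = 0:
    ``ic50 = 10 ** (c - log10(a/50 - 1) / b)``; a curve topping out at or
    below 50 % never reaches it.  Values from unidentifiable fits are
    flagged unreliable rather than suppressed.
    """
    if not fit.converged:
        raise ValueError("potency requires a converged fit")
    p = fit.params
    ec50 = 10.0**p.c
    if p.a > 50.0 + 1e-12:
        ic50 = 10.0 ** (p.c - np.log10(p.a / 50.0 - 1.0) / p.b)
    else:
        ic50 = None
    return Potency(ec50=ec50, ic50_abs=ic50, reliable=fit.identifiable)


def fit_table(series: Sequence[DoseSeries], **kwargs):
    """Fit every series and return a tidy per-series table."""
    import pandas as pd

    rows = []
    for s in series:
        fr = fit_logistic(s, **kwargs)
        pot = potency(fr) if fr.converged else None
        rows.append(
            {
                "compound_id": s.compound_id,
                "model_id": s.model_id,
                "a": fr.params.a,
                "b": fr.params.b,
                "c": fr.params.c,
                "d": fr.params.d,
                "rss": fr.rss,
                "r2": fr.r2,
                "converged": fr.converged,
                "identifiable": fr.identifiable,
                "ec50": pot.ec50 if pot else np.nan,
                "ic50_abs": (pot.ic50_abs if pot and pot.ic50_abs is not None else np.nan),
            }
        )
    return pd.DataFrame(rows)
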