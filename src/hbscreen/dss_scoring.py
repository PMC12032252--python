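"""Drug sensitivity scores (DSS/sDSS) and Z'-factor screen QC.

The DSS is the normalized area of the fitted dose-response curve above a
minimum activity threshold ``t`` (default 10 % inhibition) over the tested
log10-concentration window [x_min, x_max].  With bottom fixed at 0 the
curve is y(x) = a / (1 + 10**(b*(c - x))) and the area has a closed form:
the antiderivative of y is (a/b) * log10(1 + 10**(b*(x - c))), so

    x_t = c - (1/b) * log10(a/t - 1)          (where y crosses t)
    x1  = max(x_min, x_t)
    I   = (a/b) * [log10(1 + 10**(b*(x_max - c)))
                   - log10(1 + 10**(b*(x1 - c)))] - t * (x_max - x1)

    DSS1 = 100 * I / ((100 - t) * (x_max - x_min))
    DSS2 = DSS1 / log10(a)

DSS2 (the default variant) divides out the top asymptote's order of
magnitude, keeping scores on the ~0-50 scale on which the DSS >= 10
effectiveness cutoff operates.  The selective score against the healthy
hepatocyte control is a plain difference, sDSS = DSS_tumor - DSS_control.

Z' = 1 - 3*(sd_pos + sd_neg)/|mu_pos - mu_neg| summarizes control
separation per plate; screens with Z' > 0.5 are conventionally usable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dose_response import Logistic4P, predict_inhibition

__all__ = [
    "DssConfig",
    "DssResult",
    "ZPrime",
    "dss_closed_form",
    "dss_numeric",
    "sdss",
    "zfactor",
]


@dataclass(frozen=True)
class DssConfig:
    """Scoring configuration: threshold, integration window, variant."""

    t: float = 10.0  # minimum activity threshold, % inhibition
    x_min: float | None = None  # log10 molar; None -> series' tested min
    x_max: float | None = None  # log10 molar; None -> series' tested max
    variant: str = "DSS2"

    def __post_init__(self) -> None:
        if not (0.0 <= self.t < 100.0):
            raise ValueError(f"threshold t must be in [0, 100), got {self.t}")
        if self.variant not in ("DSS1", "DSS2"):
            raise ValueError(f"unknown DSS variant {self.variant!r}")
        if self.x_min is not None and self.x_max is not None and not (self.x_min < self.x_max):
            raise ValueError("require x_min < x_max")

    def with_window(self, x_min: float, x_max: float) -> "DssConfig":
        return replace(self, x_min=float(x_min), x_max=float(x_max))

    def resolved(self) -> "DssConfig":
        if self.x_min is None or self.x_max is None:
            raise ValueError("integration window unset; call with_window first")
        return self


@dataclass(frozen=True)
class DssResult:
    dss: float  # score units, >= 0
    area: float  # I, %·log10-units above threshold
    x1: float  # lower integration limit actually used
    variant: str
    config: DssConfig


def _check_params(p: Logistic4P) -> None:
    if p.a > 100.0 + 1e-9:
        raise ValueError(f"top asymptote a={p.a} exceeds 100")
    if abs(p.d) > 1e-9:
        raise ValueError("DSS closed form requires bottom d = 0")


def _normalize(area: float, a: float, cfg: DssConfig) -> float:
    dss1 = 100.0 * area / ((100.0 - cfg.t) * (cfg.x_max - cfg.x_min))
    if cfg.variant == "DSS1":
        return max(dss1, 0.0)
    # DSS2: log10(a) <= 0 region is meaningless and always below threshold
    if a <= 1.01:
        return 0.0
    return max(dss1 / np.log10(a), 0.0)


def dss_closed_form(p: Logistic4P, cfg: DssConfig) -> DssResult:
    """Exact DSS from fitted 4PL parameters (bottom fixed at 0)."""
    _check_params(p)
    cfg = cfg.resolved()
    a, b, c, t = p.a, p.b, p.c, cfg.t
    if a <= t:
        return DssResult(0.0, 0.0, cfg.x_max, cfg.variant, cfg)
    x_t = c - np.log10(a / t - 1.0) / b
    x1 = min(max(cfg.x_min, x_t), cfg.x_max)
    area = (a / b) * (
        np.log10(1.0 + 10.0 ** (b * (cfg.x_max - c)))
        - np.log10(1.0 + 10.0 ** (b * (x1 - c)))
    ) - t * (cfg.x_max - x1)
    area = max(float(area), 0.0)
    return DssResult(_normalize(area, a, cfg), area, float(x1), cfg.variant, cfg)


def dss_numeric(p: Logistic4P, cfg: DssConfig, n_grid: int = 100_000) -> float:
    """Trapezoid-rule DSS used as the verification oracle for the closed form."""
    _check_params(p)
    if n_grid < 1_000:
        raise ValueError("n_grid must be >= 1000")
    cfg = cfg.resolved()
    x = np.linspace(cfg.x_min, cfg.x_max, n_grid)
    y = np.maximum(predict_inhibition(p, x) - cfg.t, 0.0)
    area = float(np.trapezoid(y, x))
    return _normalize(area, p.a, cfg)


def sdss(dss_tumor: DssResult, dss_control: DssResult) -> float:
    """Selective DSS: tumor score minus healthy-control score.

    Negative values flag compounds more active in the healthy control
    than in the tumor model.  Both scores must come from an identical
    configuration (threshold, window, variant).
    """
    if dss_tumor.config != dss_control.config:
        raise ValueError(
            "sDSS requires identical DSS configurations for tumor and control"
        )
    return dss_tumor.dss - dss_control.dss


@dataclass(frozen=True)
class ZPrime:
    z: float
    mu_neg: float
    sd_neg: float
    mu_pos: float
    sd_pos: float


def zfactor(neg, pos) -> ZPrime:
    """Z'-factor of a plate from its negative/positive control signals."""
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError("need >= 2 signals in each control group")
    mu_n, mu_p = float(np.mean(neg)), float(np.mean(pos))
    if np.isclose(mu_n, mu_p):
        raise ValueError("Z' undefined: control means are equal")
    sd_n, sd_p = float(np.std(neg, ddof=1)), float(np.std(pos, ddof=1))
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    return ZPrime(z=z, mu_neg=mu_n, sd_neg=sd_n, mu_pos=mu_p, sd_pos=sd_p)
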