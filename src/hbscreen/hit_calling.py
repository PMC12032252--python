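"""Hit selection: effectiveness, tumor selectivity, low-dose toxicity.

A compound is *effective* in a model when DSS >= 10 and *selective* when
sDSS (tumor minus healthy-hepatocyte control) >= 10; both thresholds are
inclusive.  Compounds whose control-cell inhibition already reaches 50 %
below the top tested concentration are additionally flagged as low-dose
toxic — reported as a flag, never silently removed — mirroring the screen
practice of excluding broadly cytotoxic agents from the candidate list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plate_io import DoseSeries

__all__ = [
    "ToxicityRule",
    "HitSummary",
    "call_hits",
    "low_dose_toxicity_flag",
    "summarize",
]

DSS_THRESHOLD = 10.0
SDSS_THRESHOLD = 10.0


@dataclass(frozen=True)
class ToxicityRule:
    control_pi_threshold: float = 50.0  # % inhibition in the control model
    dose_scope: str = "below_top_dose"  # or "any_dose"

    def __post_init__(self) -> None:
        if not (0.0 < self.control_pi_threshold <= 100.0):
            raise ValueError("control_pi_threshold must be in (0, 100]")
        if self.dose_scope not in ("below_top_dose", "any_dose"):
            raise ValueError(f"unknown dose_scope {self.dose_scope!r}")


@dataclass(frozen=True)
class HitSummary:
    effective_counts: dict[str, int]  # per tumor model
    selective_counts: dict[str, int]
    control_toxic: int  # compounds effective in the control model
    selective_any: frozenset[str]
    selective_all: frozenset[str]
    top: dict[str, list[tuple[str, float]]]  # per model: (compound, sdss) desc


def call_hits(
    rows: pd.DataFrame,
    dss_threshold: float = DSS_THRESHOLD,
    sdss_threshold: float = SDSS_THRESHOLD,
) -> pd.DataFrame:
    """Flag effectiveness/selectivity per compound x model (inclusive >=).

    ``rows`` needs columns compound_id, model_id, dss, sdss; a missing
    (NaN) sdss — e.g. no control screen for that compound — marks the row
    unevaluable for selectivity rather than failing.
    """
    out = rows.copy()
    out["effective"] = out["dss"] >= dss_threshold
    has_control = out["sdss"].notna()
    out["selective"] = has_control & (out["sdss"] >= sdss_threshold)
    out["unevaluable"] = ~has_control
    return out


def low_dose_toxicity_flag(control_series: DoseSeries, rule: ToxicityRule = ToxicityRule()) -> bool:
    """True when the healthy-control response reaches the PI threshold
    at any tested dose within scope (default: strictly below the top dose)."""
    if control_series is None:
        raise ValueError("low-dose toxicity is unevaluable without a control series")
    pi = np.asarray(control_series.pi, dtype=float)
    if rule.dose_scope == "below_top_dose":
        pi = pi[:-1]  # x is ascending; last entry is the top concentration
    return bool(len(pi) and np.any(pi >= rule.control_pi_threshold))


def summarize(
    rows: pd.DataFrame,
    tumor_models: list[str],
    control_model: str | None = None,
    n_top: int = 10,
) -> HitSummary:
    """Per-model hit counts, selective-set union/intersection, top-N ranking.

    Top-N is ranked by sDSS descending with ties broken by compound id
    (lexicographic), so rankings are reproducible across runs.
    """
    known = set(rows["model_id"].unique())
    for m in tumor_models:
        if m not in known:
            raise ValueError(f"unknown model {m!r} not present in results")

    eff_counts: dict[str, int] = {}
    sel_counts: dict[str, int] = {}
    sel_sets: dict[str, set[str]] = {}
    top: dict[str, list[tuple[str, float]]] = {}
    for m in tumor_models:
        sub = rows[rows["model_id"] == m]
        eff_counts[m] = int(sub["effective"].sum())
        sel = sub[sub["selective"]]
        sel_counts[m] = len(sel)
        sel_sets[m] = set(sel["compound_id"])
        ranked = sub.dropna(subset=["sdss"]).sort_values(
            ["sdss", "compound_id"], ascending=[False, True]
        )
        top[m] = [
            (str(r.compound_id), float(r.sdss))
            for r in ranked.head(n_top).itertuples()
        ]

    sel_any: set[str] = set().union(*sel_sets.values()) if sel_sets else set()
    sel_all: set[str] = (
        set.intersection(*sel_sets.values()) if sel_sets and all(tumor_models) else set()
    )
    control_toxic = 0
    if control_model is not None:
        if control_model not in known:
            raise ValueError(f"unknown control model {control_model!r}")
        csub = rows[rows["model_id"] == control_model]
        control_toxic = int(csub["effective"].sum())

    return HitSummary(
        effective_counts=eff_counts,
        selective_counts=sel_counts,
        control_toxic=control_toxic,
        selective_any=frozenset(sel_any),
        selective_all=frozenset(sel_all),
        top=top,
    )
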