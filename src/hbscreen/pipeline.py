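"""End-to-end screen scoring: plates in, flagged hit table out."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import plate_io
from .dose_response import fit_logistic
from .dss_scoring import DssConfig, dss_closed_form, sdss, zfactor
from .hit_calling import ToxicityRule, call_hits, low_dose_toxicity_flag
from .plate_io import DoseSeries, PlateMap, RawPlate

__all__ = ["score_screen", "plate_qc"]


def plate_qc(maps: list[PlateMap], raws: list[RawPlate]) -> pd.DataFrame:
    """Per-plate Z'-factor table from each plate's own control wells."""
    raw_by_id = {r.plate_id: r for r in raws}
    rows = []
    for pm in maps:
        raw = raw_by_id[pm.plate_id]
        neg = raw.signals.reindex(pm.wells_of("neg_control").index).to_numpy()
        pos = raw.signals.reindex(pm.wells_of("pos_control").index).to_numpy()
        zp = zfactor(neg, pos)
        rows.append(
            {"plate_id": pm.plate_id, "model_id": pm.model_id, "z_prime": zp.z,
             "mu_neg": zp.mu_neg, "sd_neg": zp.sd_neg,
             "mu_pos": zp.mu_pos, "sd_pos": zp.sd_pos}
        )
    return pd.DataFrame(rows)


def score_screen(
    maps: list[PlateMap],
    raws: list[RawPlate],
    control_model: str,
    dss_config: DssConfig | None = None,
    dss_threshold: float = 10.0,
    sdss_threshold: float = 10.0,
    toxicity_rule: ToxicityRule = ToxicityRule(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize, fit, score and flag a whole screen.

    Returns ``(results, qc)``: one result row per compound x model with
    fitted 4PL parameters, DSS, sDSS against ``control_model``, and
    effectiveness / selectivity / low-dose-toxicity flags; plus the
    per-plate Z' table.  The DSS integration window defaults to each
    series' tested concentration range.
    """
    base_cfg = dss_config or DssConfig()
    raw_by_id = {r.plate_id: r for r in raws}
    pi_tables = []
    for pm in maps:
        pi_tables.append(plate_io.percent_inhibition(pm, raw_by_id[pm.plate_id]))
    pi = pd.concat(pi_tables, ignore_index=True)
    series = plate_io.extract_dose_series(pi)
    by_key: dict[tuple[str, str], DoseSeries] = {
        (s.compound_id, s.model_id): s for s in series
    }

    rows = []
    scores: dict[tuple[str, str], object] = {}
    for (cid, mid), s in sorted(by_key.items()):
        fr = fit_logistic(s)
        cfg = (
            base_cfg if base_cfg.x_min is not None
            else base_cfg.with_window(float(s.x.min()), float(s.x.max()))
        )
        res = dss_closed_form(fr.params, cfg)
        scores[(cid, mid)] = res
        rows.append(
            {"compound_id": cid, "model_id": mid,
             "a": fr.params.a, "b": fr.params.b, "c": fr.params.c,
             "r2": fr.r2, "converged": fr.converged, "identifiable": fr.identifiable,
             "dss": res.dss, "dss_variant": res.variant}
        )
    df = pd.DataFrame(rows)

    sdss_vals, tox = [], []
    for rec in df.itertuples():
        key_ctrl = (rec.compound_id, control_model)
        if rec.model_id == control_model or key_ctrl not in scores:
            sdss_vals.append(np.nan)
            tox.append(False)
            continue
        sdss_vals.append(sdss(scores[(rec.compound_id, rec.model_id)], scores[key_ctrl]))
        tox.append(low_dose_toxicity_flag(by_key[key_ctrl], toxicity_rule))
    df["sdss"] = sdss_vals
    df["low_dose_toxic"] = tox

    df = call_hits(df, dss_threshold=dss_threshold, sdss_threshold=sdss_threshold)
    # the control model itself has no selectivity reading by definition
    df.loc[df["model_id"] == control_model, "unevaluable"] = False
    return df, plate_qc(maps, raws)
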