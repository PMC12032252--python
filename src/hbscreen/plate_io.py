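"""Plate-map / raw-signal I/O and control-based normalization.

384-well plates are addressed with letters A-P for rows and 1-24 for
columns ("A01" ... "P24"); internally rows and columns are 0-based.  Each
plate carries one cell model, DMSO negative-control wells (no-effect
anchor) and benzethonium-chloride positive-control wells (full-kill
anchor).  Raw luminescence is an ATP proxy for viability; percent
inhibition of a well is its position on the negative-to-positive control
axis of its own plate:

    PI(w) = 100 * (mu_neg - S_w) / (mu_neg - mu_pos)

Normalization is strictly per plate — plates are the batch unit and
controls are never pooled across plates.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlateMap",
    "RawPlate",
    "ControlStats",
    "DoseSeries",
    "PlateParseError",
    "read_plate_map",
    "read_raw_plate",
    "write_plate_map",
    "write_raw_plate",
    "control_stats",
    "percent_inhibition",
    "extract_dose_series",
    "well_name",
    "parse_well",
]

N_ROWS, N_COLS = 16, 24
CONTENT_TYPES = {"compound", "neg_control", "pos_control", "empty"}

_WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")


class PlateParseError(ValueError):
    """A plate table violated its schema; the message names row and field."""


def well_name(row: int, col: int) -> str:
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise ValueError(f"well ({row}, {col}) outside 16x24 plate")
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def parse_well(well: str) -> tuple[int, int]:
    m = _WELL_RE.match(str(well).strip().upper())
    if not m:
        raise PlateParseError(f"malformed well address {well!r}")
    row = ord(m.group(1)) - ord("A")
    col = int(m.group(2)) - 1
    if not (0 <= col < N_COLS):
        raise PlateParseError(f"well column out of range in {well!r}")
    return row, col


@dataclass(frozen=True)
class PlateMap:
    plate_id: str
    model_id: str
    wells: pd.DataFrame  # index: well name; columns: row, col, content_type, compound_id, concentration_molar

    def wells_of(self, content_type: str) -> pd.DataFrame:
        return self.wells[self.wells["content_type"] == content_type]


@dataclass(frozen=True)
class RawPlate:
    plate_id: str
    signals: pd.Series  # index: well name -> luminescence


@dataclass(frozen=True)
class ControlStats:
    mu_neg: float
    sd_neg: float
    mu_pos: float
    sd_pos: float
    n_neg: int
    n_pos: int


@dataclass
class DoseSeries:
    """One compound on one model: ascending log10-molar doses and PI."""

    compound_id: str
    model_id: str
    x: np.ndarray  # log10(concentration in molar), strictly increasing
    pi: np.ndarray  # percent inhibition, unclamped

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.x.shape != self.pi.shape:
            raise ValueError("x and pi must have the same length")
        if not np.all(np.isfinite(self.x)) or not np.all(np.isfinite(self.pi)):
            raise ValueError("doses and responses must be finite")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")


_MAP_COLUMNS = ["plate_id", "well", "content_type", "compound_id", "concentration_molar", "model_id"]


def read_plate_map(table: pd.DataFrame | str) -> PlateMap:
    """Validate one plate's map table (columns as in ``_MAP_COLUMNS``)."""
    df = pd.read_csv(table) if isinstance(table, (str, io.IOBase)) else table.copy()
    missing = set(_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise PlateParseError(f"plate map missing columns: {sorted(missing)}")
    plate_ids = df["plate_id"].unique()
    if len(plate_ids) != 1:
        raise PlateParseError(f"expected one plate per table, got {list(plate_ids)}")
    models = df["model_id"].unique()
    if len(models) != 1:
        raise PlateParseError(f"plate {plate_ids[0]}: multiple models {list(models)}")

    seen: set[str] = set()
    rows = []
    for i, rec in df.iterrows():
        well = str(rec["well"]).strip().upper()
        r, c = parse_well(well)
        if well in seen:
            raise PlateParseError(f"row {i}: duplicate well {well!r}")
        seen.add(well)
        ct = str(rec["content_type"])
        if ct not in CONTENT_TYPES:
            raise PlateParseError(f"row {i}: unknown content_type {ct!r}")
        conc = rec["concentration_molar"]
        if ct == "compound":
            if pd.isna(rec["compound_id"]) or str(rec["compound_id"]) == "":
                raise PlateParseError(f"row {i} ({well}): compound well without compound_id")
            if pd.isna(conc) or float(conc) <= 0:
                raise PlateParseError(f"row {i} ({well}): non-positive concentration {conc!r}")
            conc = float(conc)
        else:
            conc = np.nan
        rows.append(
            {
                "well": well, "row": r, "col": c, "content_type": ct,
                "compound_id": (str(rec["compound_id"]) if ct == "compound" else ""),
                "concentration_molar": conc,
            }
        )
    wells = pd.DataFrame(rows).set_index("well")
    return PlateMap(plate_id=str(plate_ids[0]), model_id=str(models[0]), wells=wells)


def read_raw_plate(table: pd.DataFrame | str, plate_map: PlateMap | None = None) -> RawPlate:
    """Validate one plate's raw signal table (plate_id, well, signal)."""
    df = pd.read_csv(table) if isinstance(table, (str, io.IOBase)) else table.copy()
    missing = {"plate_id", "well", "signal"} - set(df.columns)
    if missing:
        raise PlateParseError(f"raw table missing columns: {sorted(missing)}")
    plate_ids = df["plate_id"].unique()
    if len(plate_ids) != 1:
        raise PlateParseError(f"expected one plate per table, got {list(plate_ids)}")

    seen: set[str] = set()
    signals = {}
    for i, rec in df.iterrows():
        well = str(rec["well"]).strip().upper()
        parse_well(well)
        if well in seen:
            raise PlateParseError(f"row {i}: duplicate well {well!r}")
        seen.add(well)
        try:
            s = float(rec["signal"])
        except (TypeError, ValueError):
            raise PlateParseError(f"row {i} ({well}): non-numeric signal {rec['signal']!r}") from None
        if not np.isfinite(s) or s < 0:
            raise PlateParseError(f"row {i} ({well}): negative or non-finite signal {s!r}")
        signals[well] = s

    if plate_map is not None:
        absent = sorted(set(plate_map.wells.index) - set(signals))
        if absent:
            raise PlateParseError(
                f"plate {plate_ids[0]}: missing signals for wells {absent[:8]}"
                + ("..." if len(absent) > 8 else "")
            )
    return RawPlate(plate_id=str(plate_ids[0]), signals=pd.Series(signals, name="signal"))


def write_plate_map(pm: PlateMap) -> pd.DataFrame:
    df = pm.wells.reset_index()[["well", "content_type", "compound_id", "concentration_molar"]].copy()
    df.insert(0, "plate_id", pm.plate_id)
    df["model_id"] = pm.model_id
    return df[_MAP_COLUMNS]


def write_raw_plate(rp: RawPlate) -> pd.DataFrame:
    df = rp.signals.rename_axis("well").reset_index()
    df.insert(0, "plate_id", rp.plate_id)
    return df


def control_stats(pm: PlateMap, raw: RawPlate) -> ControlStats:
    """Means and sample SDs of this plate's own control wells."""
    out = {}
    for ct, tag in (("neg_control", "neg"), ("pos_control", "pos")):
        wells = pm.wells_of(ct).index
        vals = raw.signals.reindex(wells).dropna().to_numpy()
        if len(vals) < 2:
            raise ValueError(
                f"plate {pm.plate_id}: need >= 2 {ct} wells with signal, got {len(vals)}"
            )
        out[f"mu_{tag}"] = float(np.mean(vals))
        out[f"sd_{tag}"] = float(np.std(vals, ddof=1))
        out[f"n_{tag}"] = len(vals)
    return ControlStats(**out)


def percent_inhibition(pm: PlateMap, raw: RawPlate, stats: ControlStats | None = None) -> pd.DataFrame:
    """Per-compound-well percent inhibition on this plate's control axis.

    Control wells are excluded from the output and values are NOT clamped:
    clamping is delegated to the curve-fit constraints downstream.
    """
    if stats is None:
        stats = control_stats(pm, raw)
    if np.isclose(stats.mu_neg, stats.mu_pos):
        raise ValueError(f"plate {pm.plate_id}: degenerate controls (mu_neg == mu_pos)")
    cw = pm.wells_of("compound")
    sig = raw.signals.reindex(cw.index)
    pi = 100.0 * (stats.mu_neg - sig) / (stats.mu_neg - stats.mu_pos)
    out = cw.reset_index()[["well", "compound_id", "concentration_molar"]].copy()
    out.insert(0, "plate_id", pm.plate_id)
    out["model_id"] = pm.model_id
    out["pi"] = pi.to_numpy()
    return out


def extract_dose_series(pi_table: pd.DataFrame) -> list[DoseSeries]:
    """Fold per-well inhibition rows into per-compound-x-model dose series.

    Replicate wells at the same concentration are averaged on the PI scale
    (keeps per-plate normalization coherent).  Series with fewer than two
    distinct concentrations are skipped with a warning.
    """
    import warnings

    series: list[DoseSeries] = []
    for (cid, mid), grp in pi_table.groupby(["compound_id", "model_id"], sort=True):
        agg = grp.groupby("concentration_molar", sort=True)["pi"].mean()
        if len(agg) < 2:
            warnings.warn(
                f"compound {cid} on {mid}: <2 distinct doses, series skipped",
                stacklevel=2,
            )
            continue
        x = np.log10(agg.index.to_numpy(dtype=float))
        series.append(DoseSeries(compound_id=str(cid), model_id=str(mid), x=x, pi=agg.to_numpy()))
    return series
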