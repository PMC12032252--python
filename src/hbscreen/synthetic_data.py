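"""Synthetic screens and microscope fields with planted ground truth.

Every downstream stage (normalization, curve fitting, DSS/sDSS scoring,
hit calling, segmentation, profiling) is exercised against data whose true
answer is known by construction:

* ``simulate_screen`` lays an oncology-library-style screen (five
  ten-fold dilutions per compound) across 384-well plates for several
  tumor models plus one healthy-control model, with DMSO negative and
  full-kill positive control columns, and records each compound's true
  logistic parameters and closed-form DSS per model.
* ``synthesize_image`` renders four-channel fluorescence fields (DNA /
  ER / membrane-actin composite / mitochondria) of ellipse-shaped cells
  whose nuclei are either intact or fragmented into several chromatin
  bodies (the mitotic-catastrophe morphology), with known label masks.

Well signal model: luminescence is positive and right-skewed, so noise is
multiplicative lognormal with unit mean and coefficient of variation
``noise_cv``.  A well at true percent-inhibition PI reads

    S = (floor + (baseline - floor) * (1 - PI/100)) * eps

so that DMSO wells sit at baseline, fully inhibited wells at the
positive-control floor, and the plate's own control axis recovers PI
exactly in the zero-noise limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dose_response import Logistic4P, predict_inhibition
from .dss_scoring import DssConfig, dss_closed_form
from .plate_io import N_COLS, N_ROWS, PlateMap, RawPlate, well_name

__all__ = [
    "ScreenSimConfig",
    "ImageSimConfig",
    "PlantedCompound",
    "ImageTruth",
    "GroundTruth",
    "PlacementError",
    "CONTROL_MODEL_ID",
    "simulate_screen",
    "make_fixture_screen",
    "synthesize_image",
    "planted_hit_sets",
]

CONTROL_MODEL_ID = "CTRL-HEP"  # healthy primary-hepatocyte control model

#: flat "no response" curve used for inactive compound x model pairs
FLAT = Logistic4P(a=0.0, b=1.0, c=-7.0, d=0.0)

# control columns flank the compound area: leftmost column DMSO (negative),
# rightmost column full-kill positive control; 16 wells each
NEG_COL, POS_COL = 0, N_COLS - 1
COMPOUND_COLS = list(range(1, N_COLS - 1))
PLATE_CAPACITY = N_ROWS * len(COMPOUND_COLS)  # 352 compound wells


class PlacementError(RuntimeError):
    """Requested objects could not be placed after bounded retries."""


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions of the simulated screen.

    Defaults mirror the screened library design (five ten-fold dilutions,
    top dose 10 uM, six tumor models) with hit rates on the scale observed
    in practice: a quarter of the library active, of which ~70 % spare the
    healthy control model.
    """

    n_compounds: int = 527
    n_models: int = 6  # tumor models; the healthy control model is always added
    doses_per_compound: int = 5
    dilution_factor: float = 10.0
    top_concentration: float = 1e-5  # molar
    frac_active: float = 0.25
    frac_selective: float = 0.7
    noise_cv: float = 0.05
    baseline_signal: float = 10_000.0  # luminescence units, DMSO level
    floor_signal: float = 400.0  # positive-control level
    seed: int = 0
    row_drift: float = 0.0  # optional linear edge-effect stressors, off by default
    col_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.doses_per_compound < 2:
            raise ValueError("doses_per_compound must be >= 2")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        for name in ("frac_active", "frac_selective"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 <= self.floor_signal < self.baseline_signal):
            raise ValueError("require 0 <= floor_signal < baseline_signal")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.doses_per_compound > PLATE_CAPACITY:
            raise ValueError(
                f"one compound needs {self.doses_per_compound} wells but a plate "
                f"fits only {PLATE_CAPACITY} compound wells"
            )

    @property
    def concentrations(self) -> np.ndarray:
        """Ascending molar dose grid shared by all compounds."""
        k = np.arange(self.doses_per_compound - 1, -1, -1, dtype=float)
        return self.top_concentration / self.dilution_factor**k

    @property
    def log_window(self) -> tuple[float, float]:
        conc = self.concentrations
        return float(np.log10(conc[0])), float(np.log10(conc[-1]))


@dataclass(frozen=True)
class PlantedCompound:
    compound_id: str
    params: dict[str, Logistic4P]  # model_id -> true curve (FLAT if inactive)
    dss: dict[str, float]  # model_id -> true closed-form DSS


@dataclass
class ImageTruth:
    nuclei_mask: np.ndarray  # int labels, 0 background; fragments share the cell label
    cell_mask: np.ndarray
    phenotype: list[str]  # per cell label (index label-1): "normal" | "fragmented"


@dataclass
class GroundTruth:
    screen: list[PlantedCompound] | None = None
    image: ImageTruth | None = None


def _true_dss(params: Logistic4P, cfg: ScreenSimConfig, variant: str = "DSS2") -> float:
    lo, hi = cfg.log_window
    return dss_closed_form(params, DssConfig(variant=variant).with_window(lo, hi)).dss


def _build_plates(
    planted: list[PlantedCompound],
    cfg: ScreenSimConfig,
    model_ids: list[str],
    rng: np.random.Generator,
) -> tuple[list[PlateMap], list[RawPlate]]:
    conc = cfg.concentrations
    x = np.log10(conc)
    sigma = float(np.sqrt(np.log1p(cfg.noise_cv**2)))
    per_plate = PLATE_CAPACITY // cfg.doses_per_compound

    # compound-well visit order: columnwise down the plate
    well_order = [(r, c) for c in COMPOUND_COLS for r in range(N_ROWS)]

    maps: list[PlateMap] = []
    raws: list[RawPlate] = []
    for model in model_ids:
        for p0 in range(0, len(planted), per_plate):
            chunk = planted[p0 : p0 + per_plate]
            plate_id = f"{model}_P{p0 // per_plate + 1:02d}"
            recs, signals = [], {}

            def emit(r: int, c: int, ct: str, cid: str, conc_m: float, pi: float) -> None:
                w = well_name(r, c)
                drift = 1.0 + cfg.row_drift * (r / (N_ROWS - 1) - 0.5) \
                            + cfg.col_drift * (c / (N_COLS - 1) - 0.5)
                eps = (
                    float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
                    if cfg.noise_cv > 0 else 1.0
                )
                base = cfg.floor_signal + (cfg.baseline_signal - cfg.floor_signal) * (
                    1.0 - pi / 100.0
                )
                recs.append(
                    {"plate_id": plate_id, "well": w, "content_type": ct,
                     "compound_id": cid, "concentration_molar": conc_m if ct == "compound" else np.nan,
                     "model_id": model}
                )
                signals[w] = max(base * drift * eps, 0.0)

            for r in range(N_ROWS):
                emit(r, NEG_COL, "neg_control", "", np.nan, 0.0)
            wi = 0
            for pc in chunk:
                pi_true = predict_inhibition(pc.params[model], x)
                for dose_i in range(cfg.doses_per_compound):
                    r, c = well_order[wi]
                    wi += 1
                    emit(r, c, "compound", pc.compound_id, float(conc[dose_i]),
                         float(pi_true[dose_i]))
            for r in range(N_ROWS):
                emit(r, POS_COL, "pos_control", "", np.nan, 100.0)

            from .plate_io import read_plate_map, read_raw_plate

            maps.append(read_plate_map(pd.DataFrame(recs)))
            raws.append(
                read_raw_plate(
                    pd.DataFrame(
                        {"plate_id": plate_id, "well": list(signals),
                         "signal": list(signals.values())}
                    )
                )
            )
    return maps, raws


def simulate_screen(cfg: ScreenSimConfig) -> tuple[list[PlateMap], list[RawPlate], GroundTruth]:
    """Generate plate maps, raw plates, and planted truth for a whole screen.

    Active compounds get a logistic response (top 65-100 %, slope 0.8-2.5,
    EC50 inside the dose window) with small per-tumor-model jitter; the
    selective subset is flat in the healthy control model, the rest keep a
    control response similar to the tumor one.  The single "combination"
    library entry is an ordinary compound with its own id.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.log_window
    n = cfg.n_compounds
    ids = [f"D-{i + 1:04d}" for i in range(n - 1)] + ["COMBO-001"] if n > 1 else ["D-0001"]

    n_active = int(round(cfg.frac_active * n))
    active = set(rng.choice(n, size=n_active, replace=False).tolist())
    n_sel = int(round(cfg.frac_selective * n_active))
    selective = set(
        rng.choice(sorted(active), size=n_sel, replace=False).tolist()
    ) if n_active else set()

    tumor_models = [f"HB-SIM-{m + 1:02d}" for m in range(cfg.n_models)]
    model_ids = tumor_models + [CONTROL_MODEL_ID]

    planted: list[PlantedCompound] = []
    for i, cid in enumerate(ids):
        params: dict[str, Logistic4P] = {}
        if i in active:
            a0 = rng.uniform(65.0, 100.0)
            b0 = rng.uniform(0.8, 2.5)
            c0 = rng.uniform(lo + 0.5, hi - 0.5)
            for m in model_ids:
                if m == CONTROL_MODEL_ID and i in selective:
                    params[m] = FLAT
                    continue
                a = float(np.clip(a0 + rng.normal(0.0, 3.0), 15.0, 100.0))
                c = float(np.clip(c0 + rng.normal(0.0, 0.15), lo + 0.25, hi - 0.25))
                params[m] = Logistic4P(a=a, b=b0, c=c)
        else:
            rng.uniform(); rng.uniform(); rng.uniform()  # keep stream layout stable
            for m in model_ids:
                params[m] = FLAT
        dss = {m: _true_dss(params[m], cfg) for m in model_ids}
        planted.append(PlantedCompound(compound_id=cid, params=params, dss=dss))

    maps, raws = _build_plates(planted, cfg, model_ids, rng)
    return maps, raws, GroundTruth(screen=planted)


def planted_hit_sets(
    truth: GroundTruth,
    tumor_models: list[str],
    control_model: str = CONTROL_MODEL_ID,
    dss_threshold: float = 10.0,
    sdss_threshold: float = 10.0,
) -> dict[str, frozenset[str]]:
    """Truth hit sets implied by the planted closed-form DSS values."""
    eff: dict[str, set[str]] = {m: set() for m in tumor_models}
    sel: dict[str, set[str]] = {m: set() for m in tumor_models}
    for pc in truth.screen:
        for m in tumor_models:
            if pc.dss[m] >= dss_threshold:
                eff[m].add(pc.compound_id)
            if pc.dss[m] - pc.dss[control_model] >= sdss_threshold:
                sel[m].add(pc.compound_id)
    out = {f"effective::{m}": frozenset(eff[m]) for m in tumor_models}
    out |= {f"selective::{m}": frozenset(sel[m]) for m in tumor_models}
    out["selective_any"] = frozenset(set().union(*sel.values())) if sel else frozenset()
    out["selective_all"] = (
        frozenset(set.intersection(*sel.values())) if sel else frozenset()
    )
    return out


FIXTURE_MODELS = ["HB-FIX-T1", "HB-FIX-T2"]


def make_fixture_screen() -> tuple[list[PlateMap], list[RawPlate], GroundTruth]:
    """Deterministic 24-compound, 2-tumor-model + control, zero-noise screen.

    Planted composition (by construction; true DSS from the closed form):
      F01-F06  inactive everywhere
      F07-F12  effective + selective in both tumor models (control flat)
      F13-F15  effective/selective in T1 only
      F16-F18  effective/selective in T2 only
      F19-F21  effective in both tumors but equally active in control
               (non-selective, control-toxic; control PI crosses 50 %
               below the top dose, so the low-dose-toxicity rule also
               flags them)
      F22-F23  potent in tumors, moderately active in control already at
               the lowest doses: still selective, but low-dose toxic
      F24      weakly active (top 25 %): below the DSS >= 10 cutoff
    """
    cfg = ScreenSimConfig(
        n_compounds=24, n_models=2, noise_cv=0.0, frac_active=0.0, seed=0
    )
    t1, t2 = FIXTURE_MODELS
    ctrl = CONTROL_MODEL_ID

    def planted(i: int, p1: Logistic4P, p2: Logistic4P, pc_: Logistic4P) -> PlantedCompound:
        params = {t1: p1, t2: p2, ctrl: pc_}
        return PlantedCompound(
            compound_id=f"F{i:02d}",
            params=params,
            dss={m: _true_dss(p, cfg) for m, p in params.items()},
        )

    strong = Logistic4P(a=95.0, b=1.2, c=-7.0)
    solo = Logistic4P(a=90.0, b=1.0, c=-7.0)
    shared_tox = Logistic4P(a=85.0, b=1.5, c=-7.0)
    potent = Logistic4P(a=100.0, b=2.0, c=-8.5)
    low_dose_ctrl = Logistic4P(a=60.0, b=2.0, c=-8.5)
    weak = Logistic4P(a=25.0, b=1.0, c=-7.0)

    compounds: list[PlantedCompound] = []
    i = 1
    for _ in range(6):
        compounds.append(planted(i, FLAT, FLAT, FLAT)); i += 1
    for _ in range(6):
        compounds.append(planted(i, strong, strong, FLAT)); i += 1
    for _ in range(3):
        compounds.append(planted(i, solo, FLAT, FLAT)); i += 1
    for _ in range(3):
        compounds.append(planted(i, FLAT, solo, FLAT)); i += 1
    for _ in range(3):
        compounds.append(planted(i, shared_tox, shared_tox, shared_tox)); i += 1
    for _ in range(2):
        compounds.append(planted(i, potent, potent, low_dose_ctrl)); i += 1
    compounds.append(planted(i, weak, weak, FLAT))

    rng = np.random.default_rng(0)  # unused at zero noise; keeps the builder signature
    maps, raws = _build_plates(compounds, cfg, [t1, t2, ctrl], rng)
    return maps, raws, GroundTruth(screen=compounds)


# --------------------------------------------------------------------------
# microscope-field synthesis


@dataclass(frozen=True)
class ImageSimConfig:
    """Conditions of one synthetic four-channel field.

    Cells are non-overlapping ellipses; each nucleus is a single ellipse
    (normal) or 3-8 disjoint chromatin fragments (fragmented, the
    mitotic-catastrophe morphology).  The rendered field is blurred by a
    Gaussian point-spread function, then Poisson shot noise and Gaussian
    read noise are applied; truth masks are the pre-blur, pre-noise labels.
    """

    field_shape: tuple[int, int] = (1024, 1024)
    n_cells: int = 10
    nucleus_diameter_range: tuple[float, float] = (50.0, 150.0)
    phenotype: str = "normal"  # or "fragmented"
    fragments_per_nucleus: tuple[int, int] = (3, 8)
    psf_sigma: float = 1.5  # px
    poisson_scale: float = 1.0  # photons per intensity unit
    gaussian_read_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.phenotype not in ("normal", "fragmented"):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        lo, hi = self.nucleus_diameter_range
        if not (0 < lo <= hi):
            raise ValueError("invalid nucleus_diameter_range")


def _ellipse_mask(shape, cy, cx, ry, rx, theta) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


_CELL_SCALE = 1.7  # cell ellipse axes relative to the nucleus ellipse


def synthesize_image(cfg: ImageSimConfig):
    """Render one field; returns (MultiChannelImage, GroundTruth)."""
    from .cell_painting import MultiChannelImage

    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.field_shape
    nuclei = np.zeros((h, w), dtype=np.int32)
    cells = np.zeros((h, w), dtype=np.int32)
    phenos: list[str] = []

    # draw all cell geometries first and place the largest footprints first:
    # greedy non-overlap placement then succeeds whenever the packing is
    # geometrically feasible for realistic densities
    geoms = [
        (rng.uniform(*cfg.nucleus_diameter_range),
         rng.uniform(1.0, 1.25),  # mild elongation: one distance-ridge peak
         rng.uniform(0.0, np.pi))
        for _ in range(cfg.n_cells)
    ]
    order = sorted(range(cfg.n_cells), key=lambda i: -geoms[i][0])

    placed: list[tuple[float, float, float]] = []  # cy, cx, outer radius
    for label, gi in enumerate(order, start=1):
        d, q, theta = geoms[gi]
        ry, rx = d / 2 * np.sqrt(q), d / 2 / np.sqrt(q)
        cry, crx = ry * _CELL_SCALE, rx * _CELL_SCALE
        outer = max(cry, crx)
        ok = False
        for _ in range(2000):
            if h <= 2 * outer + 4 or w <= 2 * outer + 4:
                break
            cy = rng.uniform(outer + 2, h - outer - 2)
            cx = rng.uniform(outer + 2, w - outer - 2)
            if all((cy - py) ** 2 + (cx - px) ** 2 > (outer + pr + 3.0) ** 2
                   for py, px, pr in placed):
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place cell {label} of {cfg.n_cells} in field {cfg.field_shape}"
            )
        placed.append((cy, cx, outer))
        cells[_ellipse_mask((h, w), cy, cx, cry, crx, theta)] = label

        if cfg.phenotype == "normal":
            nuclei[_ellipse_mask((h, w), cy, cx, ry, rx, theta)] = label
            phenos.append("normal")
        else:
            k = int(rng.integers(cfg.fragments_per_nucleus[0],
                                 cfg.fragments_per_nucleus[1] + 1))
            rf = max(0.5 * (d / 2) / np.sqrt(k), 3.0)
            centers: list[tuple[float, float]] = []
            tries = 0
            while len(centers) < k and tries < 5000:
                tries += 1
                # rejection-sample inside the nucleus ellipse shrunk to 80 %
                ang = rng.uniform(0, 2 * np.pi)
                rad = np.sqrt(rng.uniform())
                u = 0.8 * rx * rad * np.cos(ang)
                v = 0.8 * ry * rad * np.sin(ang)
                fy = cy + u * np.sin(theta) + v * np.cos(theta)
                fx = cx + u * np.cos(theta) - v * np.sin(theta)
                if all((fy - oy) ** 2 + (fx - ox) ** 2 > (2 * rf + 2.0) ** 2
                       for oy, ox in centers):
                    centers.append((fy, fx))
            if len(centers) < k:
                raise PlacementError(
                    f"could not place {k} nuclear fragments in a {d:.0f}px nucleus"
                )
            for fy, fx in centers:
                qf = rng.uniform(1.0, 1.3)
                nuclei[_ellipse_mask((h, w), fy, fx, rf * np.sqrt(qf),
                                     rf / np.sqrt(qf), rng.uniform(0, np.pi))] = label
            phenos.append("fragmented")

    truth = ImageTruth(nuclei_mask=nuclei.copy(), cell_mask=cells.copy(), phenotype=phenos)

    # render channels (pre-noise intensities)
    background = 6.0
    chans = {k: np.full((h, w), background) for k in ("DNA", "ER", "AGP", "Mito")}
    nm, cm = nuclei > 0, cells > 0
    chans["DNA"][nm] = 180.0 + rng.normal(0.0, 10.0, int(nm.sum()))
    chans["ER"][cm] = 70.0 + rng.normal(0.0, 8.0, int(cm.sum()))
    chans["AGP"][cm] = 55.0 + rng.normal(0.0, 8.0, int(cm.sum()))
    chans["Mito"][cm] = 18.0
    cy_idx, cx_idx = np.nonzero(cm)
    if len(cy_idx):
        n_dots = max(int(len(cy_idx) / 300), 1)
        pick = rng.choice(len(cy_idx), size=n_dots, replace=len(cy_idx) < n_dots)
        dots = np.zeros((h, w))
        dots[cy_idx[pick], cx_idx[pick]] = 140.0
        from scipy.ndimage import gaussian_filter

        chans["Mito"] += gaussian_filter(dots, 1.5) * 6.0 * cm

    from scipy.ndimage import gaussian_filter

    out = {}
    for name, img in chans.items():
        img = np.clip(img, 0.0, None)
        if cfg.psf_sigma > 0:
            img = gaussian_filter(img, cfg.psf_sigma)
        if cfg.poisson_scale > 0:
            img = rng.poisson(img * cfg.poisson_scale).astype(float) / cfg.poisson_scale
        if cfg.gaussian_read_sd > 0:
            img = img + rng.normal(0.0, cfg.gaussian_read_sd, img.shape)
        out[name] = np.clip(img, 0.0, None)

    return MultiChannelImage(channels=out), GroundTruth(image=truth)
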