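"""Single-cell morphological profiling of four-channel Cell-Painting fields.

Pipeline, per field:

1. The DNA (Hoechst) channel is binarized by minimum-cross-entropy (MCE)
   thresholding; nuclei are labeled by marker-based watershed from the
   local maxima of the Euclidean distance transform, masked with the
   binary, and nuclei outside the 40-240 px equivalent-diameter band are
   discarded.
2. Cells are grown from the nuclei into the MCE-thresholded ER channel by
   geodesic propagation (per-step cost = lambda + |intensity step|).
3. Per cell, intensity, shape and texture features are measured for the
   nucleus, whole-cell and cytoplasm compartments across all channels
   (catalog of 306 named features).
4. Features are standardized plate-wise against the DMSO control cells,
   embedded in 2-D (UMAP), and treatment-level mean profiles are
   hierarchically clustered with Euclidean distance and average linkage.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "MultiChannelImage",
    "SegmentationConfig",
    "ProfileMatrix",
    "DegenerateImageError",
    "CHANNELS",
    "mce_threshold",
    "cross_entropy",
    "segment_nuclei",
    "segment_cells",
    "extract_features",
    "feature_catalog",
    "normalize_platewise",
    "embed_2d",
    "cluster_profiles",
    "save_multichannel",
    "load_multichannel",
]

CHANNELS = ("DNA", "ER", "AGP", "Mito")
COMPARTMENTS = ("nucleus", "cell", "cytoplasm")
_QUANTILES = (5, 10, 25, 50, 75, 90, 95)
_TEXTURE_STATS = ("contrast", "correlation", "energy", "homogeneity", "entropy")
_TEXTURE_OFFSETS = (1, 5)
_TEXTURE_LEVELS = 16  # intensities requantized to 16 gray levels for determinism


class DegenerateImageError(ValueError):
    """Raised when an operation requires >= 2 distinct gray levels."""


@dataclass(frozen=True)
class MultiChannelImage:
    channels: dict[str, np.ndarray]  # {DNA, ER, AGP, Mito} -> 2-D rasters

    def __post_init__(self) -> None:
        shapes = {k: v.shape for k, v in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for k, v in self.channels.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"channel {k} has non-finite intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class SegmentationConfig:
    min_diameter_px: float = 40.0
    max_diameter_px: float = 240.0
    maxima_min_distance: int = 30  # min separation of watershed seed points
    propagation_lambda: float = 0.05  # regularization weight of a unit step

    def __post_init__(self) -> None:
        if not (0 < self.min_diameter_px < self.max_diameter_px):
            raise ValueError("require 0 < min_diameter_px < max_diameter_px")
        if self.propagation_lambda < 0:
            raise ValueError("propagation_lambda must be >= 0")


# --------------------------------------------------------------------------
# minimum-cross-entropy thresholding


def cross_entropy(image: np.ndarray, threshold: float) -> float:
    """Cross-entropy criterion of splitting ``image`` at ``threshold``.

    CE(T) = sum_{g<T} g*h(g)*log(g/mu_b) + sum_{g>=T} g*h(g)*log(g/mu_f),
    with h the gray-level histogram and mu_b/mu_f the below/above-threshold
    mean intensities; zero-intensity terms contribute nothing.
    """
    v = np.asarray(image, dtype=float).ravel()
    lo, hi = v[v < threshold], v[v >= threshold]
    ce = 0.0
    for part in (lo, hi):
        if part.size == 0:
            continue
        mu = part.mean()
        nz = part[part > 0]
        if mu > 0 and nz.size:
            ce += float(np.sum(nz * np.log(nz / mu)))
    return ce


def mce_threshold(image: np.ndarray, max_levels: int = 4096) -> float:
    """Exact minimum-cross-entropy threshold over observed gray levels.

    Evaluates the criterion at every candidate level (each observed level
    above the minimum) via cumulative sums and returns the argmin; pixels
    with intensity >= the returned threshold are foreground.  Images with
    more than ``max_levels`` distinct values are first requantized onto
    that many histogram bins.
    """
    v = np.asarray(image, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("image has non-finite intensities")
    levels, counts = np.unique(v, return_counts=True)
    if levels.size < 2:
        raise DegenerateImageError("constant image: no threshold exists")
    if levels.size > max_levels:
        edges = np.linspace(levels[0], levels[-1], max_levels + 1)
        idx = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, max_levels - 1)
        centers = (edges[:-1] + edges[1:]) / 2.0
        counts = np.bincount(idx, minlength=max_levels)
        keep = counts > 0
        levels, counts = centers[keep], counts[keep]

    gh = levels * counts  # g * h(g)
    glg = np.where(levels > 0, gh * np.log(np.maximum(levels, 1e-300)), 0.0)
    cum_gh = np.cumsum(gh)
    cum_h = np.cumsum(counts)
    cum_glg = np.cumsum(glg)
    tot_gh, tot_h, tot_glg = cum_gh[-1], cum_h[-1], cum_glg[-1]

    # candidate thresholds: levels[1:] (both classes non-empty)
    sb, nb = cum_gh[:-1], cum_h[:-1]
    sf, nf = tot_gh - sb, tot_h - nb
    mu_b = np.where(nb > 0, sb / nb, 0.0)
    mu_f = sf / nf
    glg_b = cum_glg[:-1]
    glg_f = tot_glg - glg_b
    with np.errstate(divide="ignore", invalid="ignore"):
        ce = (
            glg_b - np.where(sb > 0, sb * np.log(np.maximum(mu_b, 1e-300)), 0.0)
            + glg_f - np.where(sf > 0, sf * np.log(np.maximum(mu_f, 1e-300)), 0.0)
        )
    return float(levels[1:][int(np.argmin(ce))])


# --------------------------------------------------------------------------
# segmentation


def _compact_labels(mask: np.ndarray) -> np.ndarray:
    """Relabel to 1..k preserving the order of first appearance of labels."""
    out = np.zeros_like(mask)
    nxt = 1
    for lab in np.unique(mask):
        if lab == 0:
            continue
        out[mask == lab] = nxt
        nxt += 1
    return out


def segment_nuclei(dna: np.ndarray, cfg: SegmentationConfig = SegmentationConfig()) -> np.ndarray:
    """Marker-based watershed nuclei segmentation of the DNA channel.

    MCE binary -> Euclidean distance transform -> local maxima as seeds ->
    watershed on the negated distance restricted to the foreground ->
    equivalent-diameter filter (objects outside [min, max] px discarded).
    An empty foreground yields an empty mask, not an error.
    """
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    try:
        thr = mce_threshold(dna)
    except DegenerateImageError:
        return np.zeros(dna.shape, dtype=np.int32)
    binary = np.asarray(dna, dtype=float) >= thr
    if not binary.any():
        return np.zeros(dna.shape, dtype=np.int32)

    dist = ndi.distance_transform_edt(binary)
    coords = peak_local_max(
        dist, min_distance=cfg.maxima_min_distance, labels=binary, exclude_border=False
    )
    markers = np.zeros(dna.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return np.zeros(dna.shape, dtype=np.int32)
    labels = watershed(-dist, markers, mask=binary)

    min_area = np.pi * (cfg.min_diameter_px / 2.0) ** 2
    max_area = np.pi * (cfg.max_diameter_px / 2.0) ** 2
    ids, areas = np.unique(labels[labels > 0], return_counts=True)
    kill = ids[(areas < min_area) | (areas > max_area)]
    if kill.size:
        labels[np.isin(labels, kill)] = 0
    return _compact_labels(labels)


def segment_cells(
    nuclei: np.ndarray,
    er: np.ndarray,
    cfg: SegmentationConfig = SegmentationConfig(),
) -> np.ndarray:
    """Grow cells from nuclei into the MCE-thresholded ER foreground.

    Each foreground pixel joins the nucleus with the minimal accumulated
    geodesic cost, where one 4-connected step from p to q costs
    ``lambda + |er[q] - er[p]|``; cost ties are broken toward the lower
    nucleus label.  Nucleus pixels always belong to their own cell, so a
    nucleus outside the ER foreground becomes a cell equal to itself.
    """
    if nuclei.shape != er.shape:
        raise ValueError("nuclei mask and ER channel must share a shape")
    try:
        thr = mce_threshold(er)
        fg = np.asarray(er, dtype=float) >= thr
    except DegenerateImageError:
        fg = np.zeros(er.shape, dtype=bool)

    h, w = er.shape
    allowed = (fg | (nuclei > 0)).ravel()
    intens = np.asarray(er, dtype=float).ravel()
    nuc = nuclei.ravel()
    n = h * w

    cost = np.full(n, np.inf)
    label = np.zeros(n, dtype=np.int32)
    settled = np.zeros(n, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for i in np.flatnonzero(nuc > 0):
        cost[i] = 0.0
        heapq.heappush(heap, (0.0, int(nuc[i]), int(i)))

    lam = cfg.propagation_lambda
    while heap:
        c, lab, i = heapq.heappop(heap)
        if settled[i] or c > cost[i]:
            continue
        settled[i] = True
        label[i] = lab
        r, col = divmod(i, w)
        for j in (i - w if r > 0 else -1, i + w if r < h - 1 else -1,
                  i - 1 if col > 0 else -1, i + 1 if col < w - 1 else -1):
            if j < 0 or settled[j] or not allowed[j] or nuc[j] > 0:
                continue
            nc = c + lam + abs(intens[j] - intens[i])
            if nc < cost[j] - 1e-12:
                cost[j] = nc
                heapq.heappush(heap, (nc, lab, j))
            elif nc <= cost[j] + 1e-12:
                # equal-cost path: keep the chance to win the label tie-break
                heapq.heappush(heap, (nc, lab, j))

    out = label.reshape(h, w)
    out[nuclei > 0] = nuclei[nuclei > 0]  # superset guarantee
    return out


# --------------------------------------------------------------------------
# feature extraction

_INTENSITY_STATS = ("mean", "sd", "mad", "min", "max", "integrated") + tuple(
    f"q{q:02d}" for q in _QUANTILES
)
_SHAPE_STATS = (
    "area", "perimeter", "equivalent_diameter", "eccentricity", "solidity",
    "extent", "form_factor", "major_axis", "minor_axis", "n_objects",
)


def feature_catalog() -> list[str]:
    """Ordered names of the shipped per-cell feature set (306 features)."""
    names: list[str] = []
    for comp in COMPARTMENTS:
        for ch in CHANNELS:
            names += [f"{comp}_{ch}_int_{s}" for s in _INTENSITY_STATS]
    for comp in COMPARTMENTS:
        names += [f"{comp}_shape_{s}" for s in _SHAPE_STATS]
    for comp in COMPARTMENTS:
        for ch in CHANNELS:
            for off in _TEXTURE_OFFSETS:
                names += [f"{comp}_{ch}_tex_{s}_o{off}" for s in _TEXTURE_STATS]
    return names


def _intensity_features(vals: np.ndarray) -> list[float]:
    if vals.size == 0:
        return [0.0] * len(_INTENSITY_STATS)
    med = float(np.median(vals))
    qs = np.percentile(vals, _QUANTILES)
    return [
        float(vals.mean()), float(vals.std()), float(np.median(np.abs(vals - med))),
        float(vals.min()), float(vals.max()), float(vals.sum()), *map(float, qs),
    ]


def _shape_features(mask: np.ndarray) -> list[float]:
    from skimage.measure import regionprops

    if not mask.any():
        return [0.0] * len(_SHAPE_STATS)
    props = regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perim = float(props.perimeter)
    form = 4.0 * np.pi * area / perim**2 if perim > 0 else 0.0
    # n_objects separates intact from fragmented (mitotic-catastrophe) nuclei
    n_obj = float(ndi.label(mask)[1])
    return [
        area, perim, float(props.equivalent_diameter_area),
        float(props.eccentricity), float(props.solidity), float(props.extent),
        form, float(props.axis_major_length), float(props.axis_minor_length),
        n_obj,
    ]


def _glcm_features(patch: np.ndarray, mask: np.ndarray) -> list[float]:
    """Direction-averaged co-occurrence stats at offsets {1, 5} px.

    Intensities inside the compartment are requantized to 16 gray levels
    (1..16, background 0); co-occurrence pairs touching background are
    dropped before normalization.
    """
    from skimage.feature import graycomatrix

    out: list[float] = []
    vals = patch[mask]
    if vals.size < 2:
        return [0.0] * (len(_TEXTURE_STATS) * len(_TEXTURE_OFFSETS))
    vmin, vmax = float(vals.min()), float(vals.max())
    q = np.zeros(patch.shape, dtype=np.uint8)
    if vmax > vmin:
        q[mask] = 1 + np.minimum(
            ((patch[mask] - vmin) / (vmax - vmin) * _TEXTURE_LEVELS).astype(int),
            _TEXTURE_LEVELS - 1,
        )
    else:
        q[mask] = 1
    for off in _TEXTURE_OFFSETS:
        glcm = graycomatrix(
            q, distances=[off], angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
            levels=_TEXTURE_LEVELS + 1, symmetric=True, normed=False,
        ).astype(float)
        p = glcm[1:, 1:, 0, :].mean(axis=2)  # drop background row/col, avg directions
        tot = p.sum()
        if tot <= 0:
            out += [0.0] * len(_TEXTURE_STATS)
            continue
        p /= tot
        i, j = np.indices(p.shape, dtype=float)
        contrast = float(np.sum((i - j) ** 2 * p))
        mu_i, mu_j = float(np.sum(i * p)), float(np.sum(j * p))
        sd_i = np.sqrt(float(np.sum((i - mu_i) ** 2 * p)))
        sd_j = np.sqrt(float(np.sum((j - mu_j) ** 2 * p)))
        corr = (
            float(np.sum((i - mu_i) * (j - mu_j) * p) / (sd_i * sd_j))
            if sd_i > 0 and sd_j > 0 else 0.0
        )
        energy = float(np.sum(p**2))
        homog = float(np.sum(p / (1.0 + np.abs(i - j))))
        nz = p[p > 0]
        entropy = float(-np.sum(nz * np.log2(nz)))
        out += [contrast, corr, energy, homog, entropy]
    return out


def extract_features(
    img: MultiChannelImage,
    nuclei: np.ndarray,
    cells: np.ndarray,
    metadata: dict | None = None,
) -> pd.DataFrame:
    """Per-cell feature table over nucleus / cell / cytoplasm compartments.

    Cells whose cytoplasm is empty (cell == nucleus) report zeroed
    cytoplasm features with ``empty_cytoplasm`` set.  Returns one row per
    cell label with metadata columns prepended.
    """
    if nuclei.shape != cells.shape or nuclei.shape != img.shape:
        raise ValueError("image and masks must share a shape")
    catalog = feature_catalog()
    rows = []
    labels = np.unique(cells[cells > 0])
    for lab in labels:
        cell_m = cells == lab
        nuc_m = (nuclei == lab) & cell_m
        cyto_m = cell_m & ~nuc_m
        masks = {"nucleus": nuc_m, "cell": cell_m, "cytoplasm": cyto_m}
        # work in the cell's bounding box for texture/shape speed
        rs, cs = np.nonzero(cell_m)
        sl = (slice(rs.min(), rs.max() + 1), slice(cs.min(), cs.max() + 1))

        feats: list[float] = []
        for comp in COMPARTMENTS:
            m = masks[comp]
            for ch in CHANNELS:
                feats += _intensity_features(img.channels[ch][m])
        for comp in COMPARTMENTS:
            feats += _shape_features(masks[comp][sl])
        for comp in COMPARTMENTS:
            m = masks[comp][sl]
            for ch in CHANNELS:
                feats += _glcm_features(img.channels[ch][sl], m)

        row = dict(metadata or {})
        row["cell_id"] = int(lab)
        row["empty_cytoplasm"] = bool(not cyto_m.any())
        row.update(zip(catalog, feats))
        rows.append(row)

    meta_cols = list((metadata or {}).keys()) + ["cell_id", "empty_cytoplasm"]
    return pd.DataFrame(rows, columns=meta_cols + catalog)


# --------------------------------------------------------------------------
# profiling


def normalize_platewise(
    features: pd.DataFrame,
    plate_col: str = "plate",
    treatment_col: str = "treatment",
    dmso_label: str = "DMSO",
) -> pd.DataFrame:
    """Standard-scale every feature per plate against that plate's DMSO cells.

    z = (f - mu_DMSO) / sd_DMSO per plate per feature; features constant in
    a plate's DMSO cells are set to 0 there and flagged in the
    ``constant_features`` attribute of the result.
    """
    feat_cols = [c for c in feature_catalog() if c in features.columns]
    out = features.copy()
    flagged: dict[str, list[str]] = {}
    for plate, grp in features.groupby(plate_col, sort=True):
        dmso = grp[grp[treatment_col] == dmso_label]
        if len(dmso) < 2:
            raise ValueError(f"plate {plate!r} has fewer than 2 DMSO cells")
        mu = dmso[feat_cols].mean()
        sd = dmso[feat_cols].std(ddof=0)
        z = (grp[feat_cols] - mu) / sd
        const = sd.index[sd == 0.0].tolist()
        if const:
            z[const] = 0.0
            flagged[str(plate)] = const
        out.loc[grp.index, feat_cols] = z
    out.attrs["constant_features"] = flagged
    return out


def embed_2d(features, seed: int, n_neighbors: int = 15) -> np.ndarray:
    """Deterministic 2-D UMAP embedding of per-cell feature rows."""
    X = (
        features[[c for c in feature_catalog() if c in features.columns]].to_numpy()
        if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    )
    if X.shape[0] < n_neighbors + 1:
        raise ValueError(f"need >= {n_neighbors + 1} rows, got {X.shape[0]}")
    import umap

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, random_state=int(seed), n_jobs=1
    )
    return reducer.fit_transform(X)


@dataclass(frozen=True)
class ProfileMatrix:
    profiles: pd.DataFrame  # group-mean normalized features, sorted by group
    linkage: np.ndarray  # scipy average-linkage matrix (Euclidean)
    leaf_order: list[str]


def cluster_profiles(features: pd.DataFrame, group_cols: list[str]) -> ProfileMatrix:
    """Group-mean profiles + Euclidean average-linkage hierarchical clustering.

    Groups are sorted by name before linkage, so equal-distance merges and
    leaf order are reproducible.  Duplicated group profiles merge at
    distance 0.
    """
    feat_cols = [c for c in feature_catalog() if c in features.columns]
    prof = features.groupby(group_cols, sort=True)[feat_cols].mean()
    if len(prof) < 2:
        raise ValueError("need >= 2 groups to cluster")
    Z = linkage(prof.to_numpy(), method="average", metric="euclidean")
    names = ["|".join(map(str, ix)) if isinstance(ix, tuple) else str(ix)
             for ix in prof.index]
    order = [names[i] for i in leaves_list(Z)]
    return ProfileMatrix(profiles=prof, linkage=Z, leaf_order=order)


# --------------------------------------------------------------------------
# TIFF I/O (per-channel files with {DNA, ER, AGP, Mito} suffixes)


def save_multichannel(img: MultiChannelImage, prefix: str) -> list[str]:
    import tifffile

    paths = []
    for ch in CHANNELS:
        path = f"{prefix}_{ch}.tif"
        tifffile.imwrite(path, img.channels[ch].astype(np.float32))
        paths.append(path)
    return paths


def load_multichannel(prefix: str) -> MultiChannelImage:
    import tifffile

    return MultiChannelImage(
        channels={ch: tifffile.imread(f"{prefix}_{ch}.tif").astype(float) for ch in CHANNELS}
    )
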