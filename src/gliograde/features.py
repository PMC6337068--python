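"""Multiparametric feature battery per case.

Three groups, aggregated over the selected ROIs of a case:

* 24 **visual** features — nuclear morphology aggregates (mean and SD of
  area, perimeter, major axis, minor axis, circularity, eccentricity,
  solidity), staining summaries, and spatial-pattern statistics including the
  Clark-Evans aggregation index.
* 171 **sub-visual** features — 13 first-order intensity statistics on each
  of the gray / haematoxylin-OD / eosin-OD channels (39), plus 11 grey-level
  co-occurrence (Haralick-style) properties at 4 angles x 3 pixel distances
  on the quantized gray channel (132).
* 1 **Ki-67** feature — the proliferative index PI = positive/total x 100.

The decomposition into named features is this package's canonical
reconstruction of the published battery: it sums exactly to the printed
counts (24 and 171) and contains every feature the study's case explanations
single out (sd_perimeter, sd_major_axis, nuclei_count, cell-pattern and GLCM
texture features).
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from scipy.stats import kurtosis as _kurtosis, skew as _skew
from skimage.feature import graycomatrix
from skimage.morphology import dilation, disk

from gliograde.roi import DEFAULT_ROI_K, partition_tiles, select_rois, tile_view
from gliograde.segmentation import SegmentationParams, segment_nuclei, separate_stains
from gliograde.synthetic import CohortManifest

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# canonical feature names
# ---------------------------------------------------------------------------

_MORPH_BASE = ("area", "perimeter", "major_axis", "minor_axis",
               "circularity", "eccentricity", "solidity")
_STAIN_NAMES = ("mean_h_od", "mean_sd_intensity", "perinuclear_e_od",
                "nucleus_background_contrast", "chromatin_entropy")
_PATTERN_NAMES = ("nuclei_count", "nuclear_density", "nn_distance_mean",
                  "nn_distance_sd", "clark_evans_index")

VISUAL_FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{agg}_{base}" for base in _MORPH_BASE for agg in ("mean", "sd")]
    + list(_STAIN_NAMES) + list(_PATTERN_NAMES)
)

FIRST_ORDER_STATS = ("mean", "median", "sd", "variance", "skewness", "kurtosis",
                     "min", "max", "range", "p10", "p90", "iqr", "entropy")
CHANNELS = ("gray", "h_od", "e_od")

GLCM_PROPERTIES = ("contrast", "dissimilarity", "homogeneity", "energy",
                   "correlation", "entropy", "cluster_shade", "cluster_prominence",
                   "max_probability", "sum_average", "difference_variance")
GLCM_DISTANCES = (1, 2, 4)
GLCM_ANGLES_DEG = (0, 45, 90, 135)
GLCM_LEVELS = 32

FIRST_ORDER_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"fo_{ch}_{stat}" for ch in CHANNELS for stat in FIRST_ORDER_STATS
)
GLCM_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"glcm_{prop}_d{d}_a{a}"
    for prop in GLCM_PROPERTIES for d in GLCM_DISTANCES for a in GLCM_ANGLES_DEG
)
SUBVISUAL_FEATURE_NAMES: tuple[str, ...] = FIRST_ORDER_FEATURE_NAMES + GLCM_FEATURE_NAMES

KI67_FEATURE_NAME = "ki67_pi"
ALL_FEATURE_NAMES: tuple[str, ...] = (
    VISUAL_FEATURE_NAMES + SUBVISUAL_FEATURE_NAMES + (KI67_FEATURE_NAME,)
)

assert len(VISUAL_FEATURE_NAMES) == 24
assert len(SUBVISUAL_FEATURE_NAMES) == 171
assert len(ALL_FEATURE_NAMES) == 196

#: histogram range per channel for entropy computations
_CHANNEL_RANGE = {"gray": (0.0, 256.0), "h_od": (0.0, 3.0), "e_od": (0.0, 3.0)}


# ---------------------------------------------------------------------------
# Ki-67
# ---------------------------------------------------------------------------

def compute_pi(positive: int, total: int) -> float:
    """Proliferative index PI = positive cells / total cells x 100 (percent)."""
    if total < 1:
        raise ValueError("total cell count must be >= 1")
    if not 0 <= positive <= total:
        raise ValueError(f"positive count {positive} outside [0, {total}]")
    return float(Fraction(positive, total) * 100)


# ---------------------------------------------------------------------------
# first-order statistics
# ---------------------------------------------------------------------------

def first_order_stats(values: np.ndarray, value_range: tuple[float, float],
                      n_bins: int = 64) -> np.ndarray:
    """The 13 first-order statistics of a sample, in canonical order."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty sample")
    sd = float(v.std())
    hist, _ = np.histogram(v, bins=n_bins, range=value_range)
    p = hist[hist > 0] / v.size
    entropy = float(-(p * np.log2(p)).sum())
    skw = float(_skew(v)) if sd > 0 else 0.0
    krt = float(_kurtosis(v)) if sd > 0 else 0.0
    p10, p90 = np.percentile(v, [10, 90])
    q1, q3 = np.percentile(v, [25, 75])
    return np.array([
        v.mean(), np.median(v), sd, v.var(), skw, krt,
        v.min(), v.max(), v.max() - v.min(), p10, p90, q3 - q1, entropy,
    ])


def extract_first_order(channels: dict[str, np.ndarray]) -> np.ndarray:
    """39 first-order values: 13 statistics x channels (gray, h_od, e_od)."""
    out = []
    for ch in CHANNELS:
        out.append(first_order_stats(channels[ch], _CHANNEL_RANGE[ch]))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# GLCM (Haralick-style) texture
# ---------------------------------------------------------------------------

def _glcm_properties(P: np.ndarray) -> dict[str, float]:
    """The 11 co-occurrence properties of one normalized symmetric matrix."""
    L = P.shape[0]
    i = np.arange(L, dtype=np.float64)[:, None]
    j = np.arange(L, dtype=np.float64)[None, :]
    diff = i - j
    psum = i + j

    marg = P.sum(axis=1)            # symmetric: row marginal = col marginal
    mu = float((np.arange(L) * marg).sum())
    var = float(((np.arange(L) - mu) ** 2 * marg).sum())

    nz = P > 0
    entropy = float(-(P[nz] * np.log2(P[nz])).sum())
    if var > 0:
        correlation = float((P * (i - mu) * (j - mu)).sum() / var)
    else:
        correlation = 1.0

    # distance-difference distribution p_{x-y}
    k = np.abs(diff).astype(np.int64)
    p_diff = np.bincount(k.ravel(), weights=P.ravel(), minlength=L)
    kd = np.arange(p_diff.size, dtype=np.float64)
    mu_d = float((kd * p_diff).sum())
    # sum distribution p_{x+y}
    p_sum = np.bincount(psum.astype(np.int64).ravel(), weights=P.ravel(),
                        minlength=2 * L - 1)
    ks = np.arange(p_sum.size, dtype=np.float64)

    return {
        "contrast": float((P * diff**2).sum()),
        "dissimilarity": float((P * np.abs(diff)).sum()),
        "homogeneity": float((P / (1.0 + diff**2)).sum()),
        "energy": float((P**2).sum()),
        "correlation": correlation,
        "entropy": entropy,
        "cluster_shade": float((P * (psum - 2 * mu) ** 3).sum()),
        "cluster_prominence": float((P * (psum - 2 * mu) ** 4).sum()),
        "max_probability": float(P.max()),
        "sum_average": float((ks * p_sum).sum()),
        "difference_variance": float(((kd - mu_d) ** 2 * p_diff).sum()),
    }


def quantize_gray(gray: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Quantize an 8-bit gray image to ``levels`` equal-width bins."""
    g = np.clip(np.asarray(gray), 0, 255).astype(np.uint16)
    return (g * levels // 256).astype(np.uint8)


def extract_glcm(gray_roi: np.ndarray, levels: int = GLCM_LEVELS,
                 distances=GLCM_DISTANCES, angles_deg=GLCM_ANGLES_DEG) -> np.ndarray:
    """132 GLCM values: 11 properties x len(distances) x len(angles).

    Co-occurrence matrices are symmetric and normalized, computed on the gray
    channel quantized to ``levels`` bins.
    """
    gray_roi = np.asarray(gray_roi)
    if gray_roi.ndim != 2:
        raise ValueError("extract_glcm expects a 2-D gray image")
    if min(gray_roi.shape) < 8:
        raise ValueError(f"ROI {gray_roi.shape} smaller than the 8x8 minimum")
    if min(gray_roi.shape) <= max(distances):
        raise ValueError(f"ROI {gray_roi.shape} smaller than the largest GLCM distance")
    quant = quantize_gray(gray_roi, levels)
    P = graycomatrix(quant, distances=list(distances),
                     angles=[np.deg2rad(a) for a in angles_deg],
                     levels=levels, symmetric=True, normed=True)
    values = {prop: [] for prop in GLCM_PROPERTIES}
    for di in range(len(distances)):
        for ai in range(len(angles_deg)):
            props = _glcm_properties(P[:, :, di, ai])
            for prop in GLCM_PROPERTIES:
                values[prop].append(props[prop])
    return np.concatenate([np.asarray(values[prop]) for prop in GLCM_PROPERTIES])


# ---------------------------------------------------------------------------
# visual features
# ---------------------------------------------------------------------------

def _pattern_stats(records_per_roi, roi_area_px2: float):
    """Pooled nearest-neighbour distances and per-ROI Clark-Evans indices."""
    nn_all = []
    ce_values = []
    for records in records_per_roi:
        if len(records) < 2:
            continue
        pts = np.array([r.centroid for r in records])
        tree = cKDTree(pts)
        d, _ = tree.query(pts, k=2)
        nn = d[:, 1]
        nn_all.append(nn)
        density = len(records) / roi_area_px2
        expected = 0.5 / np.sqrt(density)  # CSR expectation
        ce_values.append(float(nn.mean() / expected))
    nn_all = np.concatenate(nn_all) if nn_all else np.array([0.0])
    ce = float(np.mean(ce_values)) if ce_values else 0.0
    return float(nn_all.mean()), float(nn_all.std()), ce


def extract_visual(masks: list[np.ndarray], images: list[np.ndarray],
                   records_per_roi: list[list]) -> pd.Series:
    """The 24 visual features pooled over the selected ROIs of one case.

    Per-nucleus records are pooled across ROIs for the morphology aggregates
    and staining means; spatial-pattern statistics are computed within each
    ROI (nearest-neighbour distances are meaningless across tiles) and then
    pooled or averaged.
    """
    pooled = [r for records in records_per_roi for r in records]
    if len(pooled) < 2:
        raise ValueError(
            "fewer than 2 nuclei across the selected ROIs; aggregate SDs and "
            "nearest-neighbour statistics need >= 2 — lower the detection "
            "threshold or min_nucleus_area_px, or use denser tiles"
        )
    out: dict[str, float] = {}
    attr = {"area": "area_px2", "perimeter": "perimeter_px", "major_axis": "major_axis_px",
            "minor_axis": "minor_axis_px", "circularity": "circularity",
            "eccentricity": "eccentricity", "solidity": "solidity"}
    for base in _MORPH_BASE:
        vals = np.array([getattr(r, attr[base]) for r in pooled])
        out[f"mean_{base}"] = float(vals.mean())
        out[f"sd_{base}"] = float(vals.std())

    # staining summaries
    out["mean_h_od"] = float(np.mean([r.mean_h_od for r in pooled]))
    out["mean_sd_intensity"] = float(np.mean([r.sd_intensity for r in pooled]))
    ring_eod, contrast, chroma_ent = [], [], []
    for mask, image, records in zip(masks, images, records_per_roi):
        if not records:
            continue
        gray = np.asarray(image, dtype=np.float64).mean(axis=-1)
        _, e_od = separate_stains(image)
        fg = mask > 0
        ring = dilation(fg, disk(2)) & ~fg
        if ring.any():
            ring_eod.append(float(e_od[ring].mean()))
        bg = ~fg
        if bg.any():
            contrast.append(float(gray[bg].mean() - gray[fg].mean()))
        for r in records:
            pix = gray[mask == r.label]
            hist, _ = np.histogram(pix, bins=32, range=(0, 256))
            p = hist[hist > 0] / pix.size
            chroma_ent.append(float(-(p * np.log2(p)).sum()))
    out["perinuclear_e_od"] = float(np.mean(ring_eod)) if ring_eod else 0.0
    out["nucleus_background_contrast"] = float(np.mean(contrast)) if contrast else 0.0
    out["chromatin_entropy"] = float(np.mean(chroma_ent)) if chroma_ent else 0.0

    # spatial pattern
    roi_area = float(masks[0].shape[0] * masks[0].shape[1])
    total_area = roi_area * len(masks)
    nn_mean, nn_sd, ce = _pattern_stats(records_per_roi, roi_area)
    out["nuclei_count"] = float(len(pooled))
    out["nuclear_density"] = float(len(pooled) / total_area)
    out["nn_distance_mean"] = nn_mean
    out["nn_distance_sd"] = nn_sd
    out["clark_evans_index"] = ce
    return pd.Series(out, index=list(VISUAL_FEATURE_NAMES), dtype=float)


def extract_subvisual(images: list[np.ndarray]) -> pd.Series:
    """The 171 sub-visual features, averaged across the selected ROIs."""
    per_roi = []
    for image in images:
        gray = np.asarray(image, dtype=np.float64).mean(axis=-1)
        h_od, e_od = separate_stains(image)
        fo = extract_first_order({"gray": gray, "h_od": h_od, "e_od": e_od})
        glcm = extract_glcm(gray)
        per_roi.append(np.concatenate([fo, glcm]))
    mean = np.mean(np.stack(per_roi), axis=0)
    return pd.Series(mean, index=list(SUBVISUAL_FEATURE_NAMES), dtype=float)


# ---------------------------------------------------------------------------
# per-case and cohort assembly
# ---------------------------------------------------------------------------

def extract_case_features(image: np.ndarray,
                          seg_params: SegmentationParams | None = None,
                          tile_size_px: int | None = None,
                          roi_k: int = DEFAULT_ROI_K) -> pd.Series:
    """ROI selection + segmentation + the 195 image features for one image.

    Each tile is segmented once; the same labelled masks serve both the
    density ranking and the feature measurements.
    """
    image = np.asarray(image)
    if tile_size_px is None:
        tile_size_px = min(image.shape[0], image.shape[1])
    grid = partition_tiles(image, tile_size_px)
    seg = {}
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=np.int64)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            labels, records = segment_nuclei(tile_view(image, grid, r, c), seg_params)
            seg[(r, c)] = (labels, records)
            counts[r, c] = len(records)
    # single- or few-tile slides: selecting every tile is the intended result,
    # not a misconfiguration worth warning about per case
    rois = select_rois(counts, k=min(roi_k, grid.n_tiles), tile_size_px=tile_size_px)
    tiles = [tile_view(image, grid, r, c) for r, c in rois.coords()]
    masks = [seg[rc][0] for rc in rois.coords()]
    records = [seg[rc][1] for rc in rois.coords()]
    visual = extract_visual(masks, tiles, records)
    subvisual = extract_subvisual(tiles)
    return pd.concat([visual, subvisual])


def build_feature_table(cohort: CohortManifest,
                        seg_params: SegmentationParams | None = None,
                        tile_size_px: int | None = None,
                        roi_k: int = DEFAULT_ROI_K) -> pd.DataFrame:
    """One row per case: case_id, grade, 24 + 171 + 1 = 196 feature columns.

    Cases whose extraction fails are recorded in ``df.attrs['skipped']`` as
    (case_id, reason) pairs rather than silently dropped.
    """
    rows = []
    skipped: list[tuple[str, str]] = []
    for case in cohort.cases:
        try:
            feats = extract_case_features(case.load_image(), seg_params,
                                          tile_size_px, roi_k)
            feats[KI67_FEATURE_NAME] = compute_pi(case.ki67_positive, case.ki67_total)
            feats["case_id"] = case.case_id
            feats["grade"] = case.grade
            rows.append(feats)
        except Exception as exc:
            logger.warning("skipping case %s: %s", case.case_id, exc)
            skipped.append((case.case_id, str(exc)))
    df = pd.DataFrame(rows).reset_index(drop=True)
    if not df.empty:
        df = df[["case_id", "grade"] + list(ALL_FEATURE_NAMES)]
    df.attrs["skipped"] = skipped
    return df


def feature_ledger() -> list[dict]:
    """Name, category and definition of every one of the 196 feature columns."""
    ledger = []
    defs = {
        "mean_h_od": "mean over nuclei of per-nucleus mean haematoxylin OD",
        "mean_sd_intensity": "mean over nuclei of within-nucleus grayscale SD",
        "perinuclear_e_od": "mean eosin OD in a 2-px ring around the nuclei",
        "nucleus_background_contrast": "mean background gray minus mean nuclear gray",
        "chromatin_entropy": "mean per-nucleus Shannon entropy of a 32-bin gray histogram",
        "nuclei_count": "total nuclei detected across the selected ROIs",
        "nuclear_density": "nuclei per px^2 of selected-ROI area",
        "nn_distance_mean": "mean centroid nearest-neighbour distance (px)",
        "nn_distance_sd": "SD of centroid nearest-neighbour distances (px)",
        "clark_evans_index": "mean NN distance / CSR expectation 0.5/sqrt(density)",
    }
    for name in VISUAL_FEATURE_NAMES:
        if name in defs:
            d = defs[name]
        else:
            agg, base = name.split("_", 1)
            d = f"{'mean' if agg == 'mean' else 'SD'} of per-nucleus {base.replace('_', ' ')}"
        ledger.append({"name": name, "category": "visual", "definition": d})
    for ch in CHANNELS:
        for stat in FIRST_ORDER_STATS:
            ledger.append({"name": f"fo_{ch}_{stat}", "category": "sub-visual/first-order",
                           "definition": f"first-order {stat} of the {ch} channel"})
    for name in GLCM_FEATURE_NAMES:
        body = name[len("glcm_"):]
        prop, d, a = body.rsplit("_", 2)
        ledger.append({"name": name, "category": "sub-visual/GLCM",
                       "definition": f"GLCM {prop.replace('_', ' ')} at distance "
                                     f"{d[1:]} px, angle {a[1:]} deg"})
    ledger.append({"name": KI67_FEATURE_NAME, "category": "IHC",
                   "definition": "Ki-67 proliferative index, percent (positive/total x 100)"})
    return ledger
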