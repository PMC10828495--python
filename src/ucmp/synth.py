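"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate, at known truth:

* PSFG-stained slide regions — green muscle tissue with red fibrosis blob
  clusters, a white empty-slide background, and light-gray debris speckles;
* linear-phase fluorescence kinetics with chosen slope and Gaussian noise;
* 4-arm x 2-timepoint cohorts (sham, CKD, CKD + low-dose treatment,
  CKD + high-dose treatment) with per-arm means/SDs, within-animal
  correlation across timepoints and mid-study dropout;
* labeled cell masks (non-overlapping disks) with analytic per-cell truth;
* qPCR plates with a dilution series and a known fold change.

Every generator takes an explicit seed and is bit-reproducible; no global
RNG state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .colorspace import hsl_to_rgb
from .histo import FilterConfig, PixelClass, classify_pixels

__all__ = [
    "ImageSpec",
    "ImageGroundTruth",
    "CohortEffectSpec",
    "gen_psfg_image",
    "gen_kinetic_trace",
    "gen_cohort",
    "gen_cell_masks",
    "gen_qpcr_plate",
    "ARMS",
    "TIMEPOINTS",
    "ECHO_REFERENCE",
    "ORGAN_REFERENCE",
    "echo_cohort_spec",
]

ARMS = ("Sham", "CKD", "CKD+D1", "CKD+D2")
TIMEPOINTS = ("week5", "endpoint")


# ---------------------------------------------------------------------------
# PSFG slide images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSpec:
    """Parameters of a synthetic PSFG slide region.

    ``target_fibrosis_fraction`` is defined over tissue pixels only (the
    white background and gray debris never count as tissue).  Stain colors
    are given as HSL centers; ``color_jitter_sd`` is the per-channel RGB
    Gaussian jitter, kept small enough by default that no painted pixel
    crosses the default classifier boundary.
    """

    width: int = 512
    height: int = 512
    target_fibrosis_fraction: float = 0.1
    background_fraction: float = 0.2
    debris_density: float = 30.0  # speckles per megapixel
    red_hsl_center: tuple[float, float, float] = (0.0, 0.75, 0.45)
    green_hsl_center: tuple[float, float, float] = (120.0, 0.5, 0.4)
    color_jitter_sd: float = 6.0
    blob_radius: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("image must be at least 8 x 8")
        if not 0.0 <= self.target_fibrosis_fraction <= 1.0:
            raise ValueError("target_fibrosis_fraction must lie in [0, 1]")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must lie in [0, 1)")
        if self.debris_density < 0 or self.color_jitter_sd < 0:
            raise ValueError("densities and jitter must be non-negative")


@dataclass(frozen=True)
class ImageGroundTruth:
    """Per-pixel truth masks and the exact fibrosis fraction of the tissue."""

    fibrosis_mask: np.ndarray
    tissue_mask: np.ndarray
    true_fraction: float


def _paint(rgb: np.ndarray, mask: np.ndarray, color: tuple[float, float, float],
           jitter_sd: float, rng: np.random.Generator) -> None:
    n = int(mask.sum())
    base = np.array(color, dtype=np.float64)
    vals = base[None, :] + rng.normal(0.0, jitter_sd, size=(n, 3))
    rgb[mask] = np.clip(vals, 0, 255)


def gen_psfg_image(spec: ImageSpec) -> tuple[np.ndarray, ImageGroundTruth]:
    """Generate an 8-bit RGB PSFG-like image plus exact ground truth.

    The tissue occupies a centered rectangle (the surrounding frame is white
    background sized to ``background_fraction``); debris speckles are
    painted light gray inside the rectangle and removed from the tissue
    mask; fibrosis is laid down as random disk-shaped blob clusters and then
    trimmed/extended pixelwise so the true fraction matches the target to
    within one pixel.  A post-generation assertion verifies that the default
    classifier reproduces the masks exactly (color jitter must not move any
    pixel across the classification boundary).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # white frame of area ~ background_fraction: solve for margin scale
    scale = math.sqrt(1.0 - spec.background_fraction)
    th, tw = max(2, int(round(h * scale))), max(2, int(round(w * scale)))
    r0, c0 = (h - th) // 2, (w - tw) // 2
    rect = np.zeros((h, w), dtype=bool)
    rect[r0 : r0 + th, c0 : c0 + tw] = True
    if not rect.any():
        raise ValueError("background_fraction leaves no tissue area")

    # debris speckles (small gray disks) inside the rectangle
    debris = np.zeros((h, w), dtype=bool)
    n_debris = rng.poisson(spec.debris_density * h * w / 1e6)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_debris):
        rr = rng.integers(r0, r0 + th)
        cc = rng.integers(c0, c0 + tw)
        rad = rng.uniform(1.5, 4.0)
        debris |= (yy - rr) ** 2 + (xx - cc) ** 2 <= rad**2
    debris &= rect

    tissue = rect & ~debris
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("no tissue pixels left after debris placement")

    target_n = int(round(spec.target_fibrosis_fraction * n_tissue))
    fibrosis = np.zeros((h, w), dtype=bool)
    if target_n > 0:
        tissue_rows, tissue_cols = np.nonzero(tissue)
        rad = spec.blob_radius
        max_iter = 50 * (target_n // max(1, int(math.pi * rad**2)) + 1) + 1000
        it = 0
        while int(fibrosis.sum()) < target_n and it < max_iter:
            it += 1
            k = rng.integers(0, len(tissue_rows))
            rr, cc = tissue_rows[k], tissue_cols[k]
            blob_rad = rng.uniform(0.5 * rad, 1.5 * rad)
            lo_r, hi_r = max(0, int(rr - blob_rad) - 1), min(h, int(rr + blob_rad) + 2)
            lo_c, hi_c = max(0, int(cc - blob_rad) - 1), min(w, int(cc + blob_rad) + 2)
            sub = (yy[lo_r:hi_r, lo_c:hi_c] - rr) ** 2 + (xx[lo_r:hi_r, lo_c:hi_c] - cc) ** 2 <= blob_rad**2
            fibrosis[lo_r:hi_r, lo_c:hi_c] |= sub & tissue[lo_r:hi_r, lo_c:hi_c]
        # trim random excess pixels so the fraction is exact
        excess = int(fibrosis.sum()) - target_n
        if excess > 0:
            fr, fc = np.nonzero(fibrosis)
            drop = rng.choice(len(fr), size=excess, replace=False)
            fibrosis[fr[drop], fc[drop]] = False
        elif excess < 0:
            # blob placement saturated; fill random tissue pixels
            cand = tissue & ~fibrosis
            cr, ccs = np.nonzero(cand)
            add = rng.choice(len(cr), size=-excess, replace=False)
            fibrosis[cr[add], ccs[add]] = True

    rgb = np.full((h, w, 3), 255.0)
    _paint(rgb, tissue & ~fibrosis, hsl_to_rgb(*spec.green_hsl_center),
           spec.color_jitter_sd, rng)
    _paint(rgb, fibrosis, hsl_to_rgb(*spec.red_hsl_center),
           spec.color_jitter_sd, rng)
    gray = rng.uniform(200, 225)
    _paint(rgb, debris, (gray, gray, gray), min(spec.color_jitter_sd, 3.0), rng)
    img = rgb.astype(np.uint8)

    true_fraction = float(fibrosis.sum()) / n_tissue
    truth = ImageGroundTruth(fibrosis_mask=fibrosis, tissue_mask=tissue,
                             true_fraction=true_fraction)

    # jitter must not move painted pixels across the default boundary
    codes = classify_pixels(img, FilterConfig())
    assert np.array_equal(codes == PixelClass.RED, fibrosis), \
        "color jitter crossed the red classification boundary"
    assert np.array_equal(codes != PixelClass.EXCLUDED, tissue), \
        "color jitter crossed the exclusion boundary"
    return img, truth


# ---------------------------------------------------------------------------
# kinetic traces
# ---------------------------------------------------------------------------

def gen_kinetic_trace(slope: float, intercept: float, noise_sd: float,
                      n_points: int = 31, interval: float = 1.0,
                      seed: int = 0):
    """Linear-phase fluorescence trace: intensity = intercept + slope*t + noise.

    Times run 0, interval, ..., (n_points-1)*interval minutes, matching a
    plate reader logging kinetic loops at fixed intervals.
    """
    from .kinetics import KineticTrace  # local import to avoid cycle

    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if interval <= 0:
        raise ValueError("interval must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points, dtype=float) * interval
    y = intercept + slope * t
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_points)
    return KineticTrace(times=tuple(t), intensities=tuple(y))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortEffectSpec:
    """Per-parameter, per-arm means and SDs at both timepoints.

    ``means[param][arm]`` maps timepoint -> (mean, sd).  ``dropout`` removes
    whole animals from an arm (complete-case, as when an animal dies
    mid-study).  ``correlation_across_timepoints`` is the within-animal
    correlation of the two timepoint values.
    """

    means: Mapping[str, Mapping[str, Mapping[str, tuple[float, float]]]]
    n_per_group: int = 8
    dropout: tuple[tuple[str, int], ...] = ()
    correlation_across_timepoints: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.correlation_across_timepoints <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")
        dropped = dict(self.dropout)
        for arm, cnt in dropped.items():
            if self.n_per_group - cnt < 2:
                raise ValueError(f"dropout leaves arm {arm!r} with n < 2")
        tp_sets = set()
        for param, arms in self.means.items():
            for arm, tps in arms.items():
                tp_sets.add(tuple(sorted(tps)))
                for tp, (m, sd) in tps.items():
                    if sd < 0:
                        raise ValueError(
                            f"negative SD for {param}/{arm}/{tp}")
        if len(tp_sets) > 1:
            raise ValueError("inconsistent timepoint lists across parameters/arms")


def gen_cohort(spec: CohortEffectSpec) -> pd.DataFrame:
    """Tidy per-animal cohort table with known group effects.

    Returns columns ``animal``, ``arm``, ``timepoint``, ``parameter``,
    ``value``.  Within an animal the two timepoint values of a parameter
    are bivariate normal with the specified correlation; different
    parameters are sampled independently.
    """
    rng = np.random.default_rng(spec.seed)
    dropped = dict(spec.dropout)
    rho = spec.correlation_across_timepoints
    rows = []
    arms = sorted({arm for p in spec.means.values() for arm in p})
    for arm in arms:
        n = spec.n_per_group - dropped.get(arm, 0)
        for j in range(n):
            animal = f"{arm}-{j + 1:02d}"
            for param, arm_map in spec.means.items():
                tps = sorted(arm_map[arm])
                z = rng.standard_normal(len(tps))
                if len(tps) == 2:
                    z[1] = rho * z[0] + math.sqrt(max(0.0, 1 - rho**2)) * z[1]
                for tp, zz in zip(tps, z):
                    m, sd = arm_map[arm][tp]
                    rows.append((animal, arm, tp, param, m + sd * zz))
    return pd.DataFrame(rows, columns=["animal", "arm", "timepoint",
                                       "parameter", "value"])


# Primary echocardiographic group effects (mean, SEM at n = 8) at the two
# follow-up timepoints, per arm, used as the default synthetic cohort
# conditions.  Derived indices (FS, EF, SV, CO, E/e') are computed, not
# sampled.  Units: diameters/thicknesses mm, volumes uL, velocities m/s,
# HR beats/min.
_E = {  # param -> arm -> {week5: (mean, sem), endpoint: (mean, sem)}
    "AWTs":  {"Sham": ((3.03, 0.14), (3.08, 0.09)), "CKD": ((3.41, 0.14), (3.56, 0.14)),
              "CKD+D1": ((3.52, 0.13), (3.54, 0.10)), "CKD+D2": ((3.50, 0.11), (3.41, 0.16))},
    "PWTs":  {"Sham": ((3.12, 0.10), (2.77, 0.12)), "CKD": ((3.46, 0.11), (3.45, 0.15)),
              "CKD+D1": ((3.56, 0.11), (3.28, 0.17)), "CKD+D2": ((3.61, 0.12), (3.37, 0.17))},
    "SWTs":  {"Sham": ((3.12, 0.14), (3.45, 0.13)), "CKD": ((3.56, 0.18), (3.64, 0.16)),
              "CKD+D1": ((3.98, 0.14), (3.64, 0.10)), "CKD+D2": ((3.92, 0.19), (3.87, 0.18))},
    "SWTd":  {"Sham": ((1.70, 0.09), (1.89, 0.15)), "CKD": ((1.91, 0.09), (2.15, 0.12)),
              "CKD+D1": ((2.06, 0.11), (1.96, 0.12)), "CKD+D2": ((1.88, 0.19), (1.94, 0.16))},
    "LVESD": {"Sham": ((3.46, 0.17), (3.36, 0.14)), "CKD": ((2.16, 0.28), (2.81, 0.26)),
              "CKD+D1": ((2.55, 0.15), (2.66, 0.23)), "CKD+D2": ((2.13, 0.30), (2.94, 0.35))},
    "LVEDD": {"Sham": ((6.75, 0.21), (7.25, 0.32)), "CKD": ((6.35, 0.26), (6.55, 0.20)),
              "CKD+D1": ((6.60, 0.29), (6.54, 0.30)), "CKD+D2": ((6.23, 0.25), (6.58, 0.25))},
    "LVESV": {"Sham": ((81, 7), (104, 6)), "CKD": ((73, 8), (85, 7)),
              "CKD+D1": ((75, 9), (70, 10)), "CKD+D2": ((66, 12), (73, 11))},
    "LVEDV": {"Sham": ((194, 12), (255, 16)), "CKD": ((168, 17), (199, 13)),
              "CKD+D1": ((187, 20), (170, 16)), "CKD+D2": ((159, 24), (176, 18))},
    "HR":    {"Sham": ((408, 12), (406, 10)), "CKD": ((396, 9), (380, 15)),
              "CKD+D1": ((390, 8), (377, 12)), "CKD+D2": ((415, 10), (409, 8))},
    "E":     {"Sham": ((0.89, 0.04), (0.96, 0.04)), "CKD": ((0.91, 0.05), (0.97, 0.05)),
              "CKD+D1": ((0.93, 0.05), (0.98, 0.05)), "CKD+D2": ((0.98, 0.05), (0.98, 0.05))},
    "e_prime": {"Sham": ((0.077, 0.005), (0.086, 0.002)), "CKD": ((0.056, 0.006), (0.065, 0.006)),
                "CKD+D1": ((0.059, 0.004), (0.072, 0.005)), "CKD+D2": ((0.053, 0.004), (0.046, 0.005))},
}

ECHO_REFERENCE: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    param: {arm: {"week5": w5, "endpoint": w12} for arm, (w5, w12) in arms.items()}
    for param, arms in _E.items()
}

# Necropsy reference (single timepoint, mean, SEM at n = 8): body weight g,
# organ weights mg, tibia length cm.
ORGAN_REFERENCE: dict[str, dict[str, tuple[float, float]]] = {
    "body_weight":  {"Sham": (443, 9), "CKD": (443, 19), "CKD+D1": (400, 11), "CKD+D2": (403, 10)},
    "tibia_length": {"Sham": (4.21, 0.04), "CKD": (4.19, 0.06), "CKD+D1": (4.19, 0.04), "CKD+D2": (4.17, 0.03)},
    "heart_weight": {"Sham": (1216, 29), "CKD": (1328, 41), "CKD+D1": (1510, 98), "CKD+D2": (1359, 94)},
    "lv_weight":    {"Sham": (707, 36), "CKD": (852, 43), "CKD+D1": (841, 46), "CKD+D2": (756, 32)},
    "rv_weight":    {"Sham": (194, 8), "CKD": (199, 12), "CKD+D1": (208, 15), "CKD+D2": (210, 18)},
    "lung_weight":  {"Sham": (1477, 52), "CKD": (1635, 81), "CKD+D1": (1385, 29), "CKD+D2": (1407, 29)},
    "kidney_weight": {"Sham": (1186, 44), "CKD": (1487, 126), "CKD+D1": (1379, 106), "CKD+D2": (1343, 79)},
}


def echo_cohort_spec(n_per_group: int = 8,
                     dropout: Sequence[tuple[str, int]] = (("CKD+D2", 1),),
                     correlation: float = 0.6,
                     seed: int = 0,
                     parameters: Optional[Sequence[str]] = None) -> CohortEffectSpec:
    """Default cohort conditions: the echo reference effects, SEM -> SD at n=8.

    One animal is lost from the higher-dose arm by default, giving arm sizes
    8, 8, 8, 7.
    """
    params = list(parameters) if parameters else list(ECHO_REFERENCE)
    means = {
        p: {
            arm: {tp: (m, sem * math.sqrt(8)) for tp, (m, sem) in tps.items()}
            for arm, tps in ECHO_REFERENCE[p].items()
        }
        for p in params
    }
    return CohortEffectSpec(means=means, n_per_group=n_per_group,
                            dropout=tuple(dropout),
                            correlation_across_timepoints=correlation,
                            seed=seed)


# ---------------------------------------------------------------------------
# labeled cell masks
# ---------------------------------------------------------------------------

def gen_cell_masks(n_cells: int, area_mean: float = 350.0, area_sd: float = 60.0,
                   pixel_size: float = 0.5, seed: int = 0,
                   shape: Optional[tuple[int, int]] = None
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Non-overlapping disk 'cells' in a labeled mask, with analytic truth.

    Areas (um^2) are drawn normal(area_mean, area_sd), truncated at a
    minimum radius of 4 px.  Returns the int32 label mask (labels
    1..n_cells) and a truth table with analytic area, perimeter and
    diameter per cell (disk: area = pi r^2, perimeter = 2 pi r,
    diameter = 2 r, in physical units).

    Raises if the requested cells cannot be placed without overlap.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    rng = np.random.default_rng(seed)
    radii_px = []
    for _ in range(n_cells):
        area = max(rng.normal(area_mean, area_sd), math.pi * (4 * pixel_size) ** 2)
        radii_px.append(max(4.0, math.sqrt(area / math.pi) / pixel_size))
    rmax = max(radii_px)
    if shape is None:
        side = int(math.ceil(math.sqrt(n_cells) + 1) * (2 * rmax + 4)) + 8
        shape = (side, side)
    h, w = shape

    mask = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    centers = []
    for lab, r in enumerate(radii_px, start=1):
        placed = False
        for _ in range(2000):
            cy = rng.uniform(r + 1, h - r - 1)
            cx = rng.uniform(r + 1, w - r - 1)
            if all((cy - oy) ** 2 + (cx - ox) ** 2 > (r + orr + 1.5) ** 2
                   for oy, ox, orr in centers):
                placed = True
                break
        if not placed:
            raise ValueError(f"could not place cell {lab} without overlap")
        centers.append((cy, cx, r))
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = lab

    truth = pd.DataFrame({
        "label": np.arange(1, n_cells + 1),
        "area": [math.pi * r**2 * pixel_size**2 for r in radii_px],
        "perimeter": [2 * math.pi * r * pixel_size for r in radii_px],
        "diameter": [2 * r * pixel_size for r in radii_px],
        "center_row": [c[0] for c in centers],
        "center_col": [c[1] for c in centers],
    })
    return mask, truth


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

def gen_qpcr_plate(true_ratio: float, efficiency: float = 1.0,
                   cq_noise_sd: float = 0.0, replicates: int = 2,
                   seed: int = 0, n_standards: int = 5,
                   base_cq_target: float = 26.0, base_cq_hk: float = 20.0
                   ) -> dict[str, pd.DataFrame]:
    """Cq tables for a two-group plate with a known target fold change.

    Returns ``{"samples": ..., "standards": ...}``.  The standards table is
    a 10-fold dilution series for each gene with ideal spacing
    -1/log10(1 + efficiency) cycles per decade (3.3219 at 100% efficiency).
    The samples table holds control and treated samples in technical
    replicates; the treated group's target Cq is shifted by
    -log(true_ratio)/log(1 + efficiency) while the housekeeping gene is
    unchanged, so the encoded fold change is exactly ``true_ratio``.
    """
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must lie in (0, 1]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if true_ratio <= 0:
        raise ValueError("true_ratio must be positive")
    rng = np.random.default_rng(seed)
    slope = -1.0 / math.log10(1.0 + efficiency)

    std_rows = []
    for gene, intercept in (("target", base_cq_target), ("housekeeping", base_cq_hk)):
        for d in range(n_standards):
            log10_q = -float(d)
            cq = intercept + slope * log10_q
            std_rows.append({"target": gene, "log10_quantity": log10_q,
                             "cq": cq + rng.normal(0.0, cq_noise_sd)})
    standards = pd.DataFrame(std_rows)

    shift = -math.log(true_ratio) / math.log(1.0 + efficiency)
    sample_rows = []
    for grp, t_cq in (("control", base_cq_target), ("treated", base_cq_target + shift)):
        for rep in range(1, replicates + 1):
            sample_rows.append({"sample": grp, "group": grp, "target": "target",
                                "replicate": rep,
                                "cq": t_cq + rng.normal(0.0, cq_noise_sd)})
            sample_rows.append({"sample": grp, "group": grp, "target": "housekeeping",
                                "replicate": rep,
                                "cq": base_cq_hk + rng.normal(0.0, cq_noise_sd)})
    samples = pd.DataFrame(sample_rows)
    return {"samples": samples, "standards": standards}
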