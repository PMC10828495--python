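"""Relative transcript quantification from qPCR Cq values.

Two quantification routes, as used for the tissue and cell-culture panels:

* standard-curve analysis — fit Cq against log10(quantity) over a dilution
  series, read each unknown's starting quantity (SQ) off the curve, and
  normalize to a housekeeping gene's SQ;
* the 2^-ddCq method — fold change relative to a control group, normalized
  to a housekeeping gene, assuming ~100% amplification efficiency.

Amplification efficiency E relates to the curve slope by
E = 10^(-1/slope) - 1; a perfect doubling per cycle gives slope
-1/log10(2) = -3.3219 cycles per decade.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "sq_from_cq",
    "normalize_to_housekeeping",
    "combine_housekeeping",
    "ddcq_ratio",
    "collapse_replicates",
]

#: Default QC threshold on technical-replicate Cq spread (cycles).
REPLICATE_SPREAD_THRESHOLD = 0.5


@dataclass(frozen=True)
class StandardCurve:
    """Cq = intercept + slope * log10(quantity); slope < 0 for a valid assay."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("a valid standard curve has negative slope "
                             "(Cq decreases with template quantity)")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 1.0 = perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def summary(self) -> str:
        return (f"Standard curve: slope = {self.slope:.4f} cycles/decade, "
                f"intercept = {self.intercept:.2f}, r^2 = {self.r_squared:.4f}, "
                f"efficiency = {self.efficiency * 100:.1f}%")


def fit_standard_curve(log10_quantities: Sequence[float],
                       mean_cqs: Sequence[float]) -> StandardCurve:
    """Least-squares standard curve from a dilution series (>= 3 points)."""
    x = np.asarray(log10_quantities, dtype=float)
    y = np.asarray(mean_cqs, dtype=float)
    if x.size != y.size:
        raise ValueError("quantity and Cq arrays must have equal length")
    if x.size < 3:
        raise ValueError("a standard curve needs at least 3 dilution points")
    res = stats.linregress(x, y)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue**2))


def sq_from_cq(cq, curve: StandardCurve):
    """Starting quantity interpolated from the standard curve.

    SQ = 10^((Cq - intercept) / slope); arbitrary units of the dilution
    series.  Accepts scalars or arrays.
    """
    cq = np.asarray(cq, dtype=float)
    sq = 10.0 ** ((cq - curve.intercept) / curve.slope)
    return float(sq) if sq.ndim == 0 else sq


def normalize_to_housekeeping(target_sq, hk_sq):
    """Relative expression = target SQ / housekeeping SQ."""
    hk = np.asarray(hk_sq, dtype=float)
    if np.any(hk <= 0):
        raise ValueError("housekeeping SQ must be positive")
    ratio = np.asarray(target_sq, dtype=float) / hk
    return float(ratio) if ratio.ndim == 0 else ratio


def combine_housekeeping(*hk_sqs):
    """Combine several housekeeping genes' SQs by geometric mean.

    Used when two reference genes (e.g. Gapdh and Hgprt) are carried.
    """
    arrs = [np.asarray(a, dtype=float) for a in hk_sqs]
    if not arrs:
        raise ValueError("need at least one housekeeping SQ array")
    stacked = np.stack(np.broadcast_arrays(*arrs))
    if np.any(stacked <= 0):
        raise ValueError("housekeeping SQ must be positive")
    gm = np.exp(np.log(stacked).mean(axis=0))
    return float(gm) if gm.ndim == 0 else gm


def ddcq_ratio(cq_target_sample, cq_hk_sample,
               mean_cq_target_control, mean_cq_hk_control):
    """Fold change by the 2^-ddCq method.

    ddCq = (Cq_target,sample - Cq_hk,sample)
         - (Cq_target,control - Cq_hk,control); returns 2^-ddCq.
    """
    dcq_sample = np.asarray(cq_target_sample, dtype=float) - np.asarray(cq_hk_sample, dtype=float)
    dcq_control = float(mean_cq_target_control) - float(mean_cq_hk_control)
    ratio = 2.0 ** (-(dcq_sample - dcq_control))
    return float(ratio) if ratio.ndim == 0 else ratio


def collapse_replicates(records: pd.DataFrame,
                        spread_threshold: float = REPLICATE_SPREAD_THRESHOLD) -> pd.DataFrame:
    """Mean Cq per (sample, target) over technical replicates, with QC flags.

    Input: long table with columns ``sample``, ``target``, ``cq`` (and
    optionally ``replicate``).  Output: one row per sample x target with
    ``cq`` (mean), ``n_replicates``, ``spread`` (max - min) and ``flag``
    ("" | "singleton" | "high_spread").  Flagged wells are kept, not dropped.
    """
    required = {"sample", "target", "cq"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for (sample, target), grp in records.groupby(["sample", "target"], sort=False):
        cqs = grp["cq"].to_numpy(dtype=float)
        spread = float(cqs.max() - cqs.min())
        if len(cqs) == 1:
            flag = "singleton"
        elif spread > spread_threshold:
            flag = "high_spread"
        else:
            flag = ""
        rows.append({"sample": sample, "target": target,
                     "cq": float(cqs.mean()), "n_replicates": len(cqs),
                     "spread": spread, "flag": flag})
    return pd.DataFrame(rows)
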