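"""ACE activity from fluorogenic-substrate kinetic traces.

The angiotensin-converting-enzyme assay records fluorescence intensity at
fixed intervals (typically 1 min for >= 30 min) while the enzyme cleaves a
quenched substrate.  During the initial linear phase the slope S of the
intensity-vs-time line is proportional to the catalytic rate.  The fit is
ordinary least squares; it passes QC only when r^2 > 0.9 (strictly), and
activity is then

    activity = (S / k) * D / P     [U = pmol min^-1 mg^-1]

where k is the intensity change for complete cleavage of 1 pmol substrate,
D the sample dilution and P the protein concentration in mg/mL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KineticTrace",
    "AceSample",
    "KineticFit",
    "QCRejectionError",
    "R_SQUARED_GATE",
    "fit_slope",
    "ace_activity",
    "batch_activity",
]

#: QC acceptance threshold for the linear fit; r^2 must strictly exceed it.
R_SQUARED_GATE = 0.9


class QCRejectionError(ValueError):
    """Raised when activity is requested from a fit that failed QC."""


@dataclass(frozen=True)
class KineticTrace:
    """Timed fluorescence readings (times in minutes, strictly increasing)."""

    times: tuple[float, ...]
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or t.size != y.size:
            raise ValueError("times and intensities must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("a kinetic trace needs at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", tuple(float(v) for v in t))
        object.__setattr__(self, "intensities", tuple(float(v) for v in y))

    def window(self, start: int, stop: int) -> "KineticTrace":
        """Sub-trace over point indices [start, stop)."""
        return KineticTrace(self.times[start:stop], self.intensities[start:stop])


@dataclass(frozen=True)
class AceSample:
    """Calibration and dilution metadata for one assay well."""

    dilution: float
    protein_mg_per_ml: float
    k: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.dilution <= 0 or self.protein_mg_per_ml <= 0 or self.k <= 0:
            raise ValueError("dilution, protein concentration and k must be positive")


@dataclass(frozen=True)
class KineticFit:
    """OLS fit of a kinetic trace with its QC verdict."""

    slope: float
    intercept: float
    r_squared: float
    accepted: bool
    degenerate: bool = False
    n_points: int = 0

    def summary(self) -> str:
        verdict = "accepted" if self.accepted else "rejected"
        extra = " (degenerate: constant intensities)" if self.degenerate else ""
        return (
            f"Kinetic fit over {self.n_points} points: "
            f"S = {self.slope:.4g} /min, intercept = {self.intercept:.4g}, "
            f"r^2 = {self.r_squared:.4f} -> {verdict}{extra}"
        )


def fit_slope(trace: KineticTrace, window_search: bool = False,
              min_window: int = 10) -> KineticFit:
    """Fit the linear phase of a trace by ordinary least squares.

    By default the full trace is fitted.  With ``window_search=True`` the
    longest contiguous window (>= ``min_window`` points) whose fit passes the
    r^2 gate is used instead; if no window passes, the full-trace fit is
    returned (rejected).  A constant trace has undefined r^2 and is returned
    rejected with ``degenerate=True``.
    """
    if window_search:
        n = len(trace.times)
        best: Optional[tuple[int, KineticFit]] = None
        for size in range(n, max(min_window, 2) - 1, -1):
            for start in range(0, n - size + 1):
                fit = fit_slope(trace.window(start, start + size))
                if fit.accepted:
                    best = (size, fit)
                    break
            if best is not None:
                break
        if best is not None:
            return best[1]
        return fit_slope(trace)

    t = np.asarray(trace.times)
    y = np.asarray(trace.intensities)
    if np.allclose(y, y[0]):
        # zero-variance response: slope 0, r^2 undefined -> QC reject
        return KineticFit(slope=0.0, intercept=float(y[0]), r_squared=float("nan"),
                          accepted=False, degenerate=True, n_points=t.size)
    res = stats.linregress(t, y)
    r2 = float(res.rvalue**2)
    return KineticFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        accepted=bool(r2 > R_SQUARED_GATE),
        n_points=t.size,
    )


def ace_activity(fit: KineticFit, sample: AceSample) -> float:
    """ACE activity in U (pmol substrate cleaved per min per mg protein).

    Refuses to compute past QC: the fit must be accepted.
    """
    if not fit.accepted:
        raise QCRejectionError(
            f"fit rejected (r^2 = {fit.r_squared!r} <= {R_SQUARED_GATE}); "
            "activity is not computed for failed QC"
        )
    return (fit.slope / sample.k) * sample.dilution / sample.protein_mg_per_ml


def batch_activity(traces: Sequence[KineticTrace],
                   samples: Sequence[AceSample],
                   window_search: bool = False) -> pd.DataFrame:
    """Fit and compute activity for matched trace/sample lists.

    Returns a table with one row per sample: slope, r^2, acceptance flag,
    activity (NaN when rejected) and the rejection reason.  The number of
    rejections is stored in ``DataFrame.attrs['n_rejected']``.
    """
    if len(traces) != len(samples):
        raise ValueError("traces and samples must have equal length")
    rows = []
    n_rejected = 0
    for trace, sample in zip(traces, samples):
        fit = fit_slope(trace, window_search=window_search)
        if fit.accepted:
            act = ace_activity(fit, sample)
            reason = ""
        else:
            act = float("nan")
            n_rejected += 1
            reason = ("constant intensities" if fit.degenerate
                      else f"r^2 = {fit.r_squared:.4f} <= {R_SQUARED_GATE}")
        rows.append({
            "sample_id": sample.sample_id,
            "slope": fit.slope,
            "r_squared": fit.r_squared,
            "accepted": fit.accepted,
            "activity_U": act,
            "rejection_reason": reason,
        })
    df = pd.DataFrame(rows, columns=["sample_id", "slope", "r_squared",
                                     "accepted", "activity_U", "rejection_reason"])
    df.attrs["n_rejected"] = n_rejected
    return df
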