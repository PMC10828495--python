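"""Derived cardiac, renal and organ-index quantities.

All formulas are the standard ones used in small-animal echocardiography
and clinical chemistry, at fixed units: diameters in mm, volumes in uL,
velocities in m/s, creatinine in uM, urine volume in mL per 24 h, organ
weights in mg, tibia length in cm.  Conversions (uL -> mL in cardiac
output) are explicit.

- fractional shortening  FS = (LVEDD - LVESD) / LVEDD * 100           [%]
- ejection fraction      EF = (LVEDV - LVESV) / LVEDV * 100           [%]
- stroke volume          SV = LVEDV - LVESV                           [uL]
- cardiac output         CO = SV * HR / 1000                          [mL/min]
- heart rate             HR = 3 / (three-cycle duration) * 60         [BPM]
- diastolic index        E/e' (early mitral inflow / annulus velocity)
- creatinine clearance   (U_crea * V_24h) / (S_crea * 1440 min)       [mL/min]
- organ index            organ weight / tibia length                  [mg/cm]

Also includes the average-mass check for synthesized peptides (e.g. the
C-terminally amidated kisspeptin-13 fragment LPNYNWNSFGLRF).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd
from Bio.SeqUtils import molecular_weight

__all__ = [
    "EchoExam",
    "MetabolicPanel",
    "OrganWeights",
    "fractional_shortening",
    "ejection_fraction",
    "stroke_volume",
    "cardiac_output",
    "heart_rate_from_cycles",
    "e_over_eprime",
    "creatinine_clearance",
    "organ_index",
    "peptide_average_mass",
    "derive_echo_table",
]

#: Average-mass difference between a C-terminal acid (-OH) and amide (-NH2).
_AMIDE_MASS_SHIFT = -0.9847


def fractional_shortening(lvedd: float, lvesd: float) -> float:
    """FS (%) from end-diastolic and end-systolic LV diameters (mm)."""
    if lvedd <= 0:
        raise ValueError("LVEDD must be positive")
    if lvesd < 0 or lvesd > lvedd:
        raise ValueError("LVESD must lie in [0, LVEDD]")
    return (lvedd - lvesd) / lvedd * 100.0


def ejection_fraction(lvedv: float, lvesv: float) -> float:
    """EF (%) from end-diastolic and end-systolic LV volumes (uL)."""
    if lvedv <= 0:
        raise ValueError("LVEDV must be positive")
    if lvesv < 0 or lvesv > lvedv:
        raise ValueError("LVESV must lie in [0, LVEDV]")
    return (lvedv - lvesv) / lvedv * 100.0


def stroke_volume(lvedv: float, lvesv: float) -> float:
    """SV (uL) = LVEDV - LVESV."""
    if lvesv > lvedv:
        raise ValueError("LVESV cannot exceed LVEDV")
    return lvedv - lvesv


def cardiac_output(sv_ul: float, hr_bpm: float) -> float:
    """CO (mL/min) = SV (uL) x HR (beats/min), converted uL -> mL."""
    if sv_ul < 0:
        raise ValueError("stroke volume must be non-negative")
    if hr_bpm <= 0:
        raise ValueError("heart rate must be positive")
    return sv_ul * hr_bpm / 1000.0


def heart_rate_from_cycles(three_cycle_duration_s: float) -> float:
    """HR (BPM) from the duration (s) of three consecutive heart cycles."""
    if three_cycle_duration_s <= 0:
        raise ValueError("cycle duration must be positive")
    return 3.0 / three_cycle_duration_s * 60.0


def e_over_eprime(e: float, e_prime: float) -> float:
    """E/e' diastolic function index (both velocities in m/s)."""
    if e_prime <= 0:
        raise ValueError("e' must be positive")
    return e / e_prime


def creatinine_clearance(urine_creatinine_um: float, urine_volume_24h_ml: float,
                         serum_creatinine_um: float) -> float:
    """Creatinine clearance (mL/min) from a 24-h urine collection."""
    if serum_creatinine_um <= 0:
        raise ValueError("serum creatinine must be positive")
    if urine_creatinine_um < 0 or urine_volume_24h_ml < 0:
        raise ValueError("urine quantities must be non-negative")
    return (urine_creatinine_um * urine_volume_24h_ml) / (serum_creatinine_um * 24 * 60)


def organ_index(weight_mg: float, tibia_cm: float) -> float:
    """Organ weight normalized to tibia length (mg/cm)."""
    if tibia_cm <= 0:
        raise ValueError("tibia length must be positive")
    if weight_mg < 0:
        raise ValueError("weight must be non-negative")
    return weight_mg / tibia_cm


def peptide_average_mass(sequence: str, c_terminal_amide: bool = False) -> float:
    """Average molecular mass (g/mol) of a peptide from one-letter residues.

    Standard average amino-acid masses plus one water; a C-terminal amide
    replaces the terminal -OH with -NH2 (mass shift -0.98).
    """
    if not sequence:
        raise ValueError("empty sequence")
    try:
        mass = molecular_weight(sequence.upper(), seq_type="protein",
                                monoisotopic=False)
    except ValueError as exc:
        raise ValueError(f"invalid residue in {sequence!r}: {exc}") from exc
    if c_terminal_amide:
        mass += _AMIDE_MASS_SHIFT
    return float(mass)


# ---------------------------------------------------------------------------
# per-animal containers + tidy-table deriver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EchoExam:
    """Primary echocardiographic measurements for one animal/timepoint."""

    LVEDD: float
    LVESD: float
    LVEDV: float
    LVESV: float
    E: float
    e_prime: float
    three_cycle_duration: Optional[float] = None
    HR: Optional[float] = None

    def __post_init__(self) -> None:
        if self.LVEDD < self.LVESD:
            raise ValueError("LVEDD must be >= LVESD")
        if self.LVEDV < self.LVESV:
            raise ValueError("LVEDV must be >= LVESV")
        if self.HR is None and self.three_cycle_duration is None:
            raise ValueError("need HR or the three-cycle duration")

    @property
    def heart_rate(self) -> float:
        if self.HR is not None:
            return self.HR
        return heart_rate_from_cycles(self.three_cycle_duration)

    def derived(self) -> dict[str, float]:
        sv = stroke_volume(self.LVEDV, self.LVESV)
        hr = self.heart_rate
        return {
            "FS": fractional_shortening(self.LVEDD, self.LVESD),
            "EF": ejection_fraction(self.LVEDV, self.LVESV),
            "SV": sv,
            "HR": hr,
            "CO": cardiac_output(sv, hr),
            "E_over_e_prime": e_over_eprime(self.E, self.e_prime),
        }


@dataclass(frozen=True)
class MetabolicPanel:
    """Serum/urine chemistry for one animal/timepoint (24-h urine)."""

    serum_creatinine: float
    urine_creatinine: float
    urine_volume_24h: float
    serum_urea: Optional[float] = None
    urine_protein: Optional[float] = None

    def clearance(self) -> float:
        return creatinine_clearance(self.urine_creatinine, self.urine_volume_24h,
                                    self.serum_creatinine)


@dataclass(frozen=True)
class OrganWeights:
    """Necropsy organ weights (mg), body weight (g) and tibia length (cm)."""

    body: float
    heart: float
    lv: float
    rv: float
    lung: float
    kidney: float
    tibia_length: float

    def __post_init__(self) -> None:
        if self.lv + self.rv > self.heart + 1e-9:
            raise ValueError("LV + RV cannot exceed total heart weight")
        for name in ("body", "heart", "lv", "rv", "lung", "kidney", "tibia_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def indices(self) -> dict[str, float]:
        return {
            f"{name}_per_tibia": organ_index(getattr(self, name), self.tibia_length)
            for name in ("heart", "lv", "rv", "lung", "kidney")
        }


_ECHO_PRIMARY = ("LVEDD", "LVESD", "LVEDV", "LVESV", "E", "e_prime", "HR")


def derive_echo_table(df: pd.DataFrame) -> pd.DataFrame:
    """Append derived echo indices to a wide per-animal table.

    Expects columns named as the standard abbreviations (LVEDD, LVESD,
    LVEDV, LVESV, E, e_prime, HR); adds FS, EF, SV, CO and E_over_e_prime.
    """
    missing = [c for c in _ECHO_PRIMARY if c not in df.columns]
    if missing:
        raise ValueError(f"missing primary echo columns: {missing}")
    out = df.copy()
    out["FS"] = (out["LVEDD"] - out["LVESD"]) / out["LVEDD"] * 100.0
    out["EF"] = (out["LVEDV"] - out["LVESV"]) / out["LVEDV"] * 100.0
    out["SV"] = out["LVEDV"] - out["LVESV"]
    out["CO"] = out["SV"] * out["HR"] / 1000.0
    out["E_over_e_prime"] = out["E"] / out["e_prime"]
    return out
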