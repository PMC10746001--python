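"""Derived in-vivo lipid-physiology metrics.

Covers the scalar endpoints of a diet-intervention lipid study: the net
(baseline-corrected) area under a post-gavage triglyceride curve, the
hepatic TG secretion rate from a lipase-blocked linear TG rise, fractional
intestinal cholesterol absorption by the dual-isotope plasma-ratio method,
lipoprotein-lipase activity by decomposition, fecal neutral-sterol
excretion rates, and 2^-ddCt relative gene expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Intravascular distribution volume per body weight, mL per 100 g.
DISTRIBUTION_VOLUME_ML_PER_100G = 3.8


@dataclass
class KineticsSeries:
    """One animal's (time, concentration) curve.

    Times are minutes, strictly increasing from 0; concentrations are mg/mL.
    """

    animal: str
    group: str
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"times not strictly increasing for {self.animal}")
        if self.times[0] != 0:
            raise ValueError(f"first timepoint must be 0 (animal {self.animal})")
        if (self.concentrations < 0).any():
            raise ValueError(f"negative concentrations for {self.animal}")


@dataclass
class IsotopeRecord:
    """Per-animal dual-isotope counts: oral (14C) and intravenous (3H) tracers.

    Dose counts are dpm per administered dose; serum counts are dpm in the
    same assayed aliquot volume for both tracers.
    """

    animal: str
    dose_oral: float
    dose_iv: float
    serum_oral: float
    serum_iv: float
    aliquot_ul: float = 300.0

    def __post_init__(self) -> None:
        if self.dose_oral <= 0 or self.dose_iv <= 0:
            raise ValueError(f"non-positive dose counts for {self.animal}")
        if self.serum_oral < 0 or self.serum_iv < 0:
            raise ValueError(f"negative serum counts for {self.animal}")
        if self.aliquot_ul <= 0:
            raise ValueError("aliquot volume must be positive")


def net_auc(series: KineticsSeries, positive_only: bool = False) -> float:
    """Net area under the curve after baseline (t=0) correction, mg*min/mL.

    Trapezoidal rule on c(t) - c(0) over the full window.  Negative
    excursions are kept by default (net AUC); ``positive_only=True`` clamps
    the corrected curve at zero first (incremental AUC).
    """
    if series.times.size < 2:
        raise ValueError("need at least two timepoints")
    corrected = series.concentrations - series.concentrations[0]
    if positive_only:
        corrected = np.clip(corrected, 0.0, None)
    return float(np.trapezoid(corrected, series.times))


def tg_secretion_rate(series: KineticsSeries, body_weight_g: float) -> dict:
    """Hepatic TG secretion rate from a lipase-blocked linear TG rise.

    The OLS slope of concentration (mg/mL) on time (min) is multiplied by
    the intravascular distribution volume, estimated at 3.8 mL per 100 g
    body weight.  Returns slope (mg/mL/min), volume (mL) and rate (mg/min).
    """
    if series.times.size < 3:
        raise ValueError("need at least three timepoints for a slope")
    if body_weight_g <= 0:
        raise ValueError("body weight must be positive")
    fit = stats.linregress(series.times, series.concentrations)
    slope = float(fit.slope)
    if slope < 0:
        warnings.warn(
            f"negative TG slope for {series.animal}: clearance not fully "
            "blocked or assay problem",
            stacklevel=2,
        )
    volume = DISTRIBUTION_VOLUME_ML_PER_100G * body_weight_g / 100.0
    return {
        "animal": series.animal,
        "slope_mg_per_ml_min": slope,
        "distribution_volume_ml": volume,
        "rate_mg_per_min": slope * volume,
    }


def cholesterol_absorption(rec: IsotopeRecord) -> float:
    """Fractional cholesterol absorption (%) by the dual-isotope plasma ratio.

    absorption = 100 * (serum_oral / dose_oral) / (serum_iv / dose_iv),
    both serum counts taken over the same aliquot.  Values above 150% are
    flagged with a warning but not clipped.
    """
    frac_oral = rec.serum_oral / rec.dose_oral
    frac_iv = rec.serum_iv / rec.dose_iv
    if frac_iv == 0:
        raise ValueError(f"no IV tracer recovery for {rec.animal}")
    pct = 100.0 * frac_oral / frac_iv
    if pct > 150.0:
        warnings.warn(
            f"absorption {pct:.1f}% > 150% for {rec.animal}; check counts",
            stacklevel=2,
        )
    return float(pct)


def lpl_activity(total_lipase: float, hepatic_lipase: float) -> float:
    """Lipoprotein-lipase activity = total lipase - hepatic lipase.

    Both inputs must share units.  A negative difference is returned as-is
    with a warning (assay noise), never clamped.
    """
    if total_lipase < 0 or hepatic_lipase < 0:
        raise ValueError("lipase activities must be non-negative")
    lpl = total_lipase - hepatic_lipase
    if lpl < 0:
        warnings.warn("hepatic lipase exceeds total lipase", stacklevel=2)
    return float(lpl)


def fecal_sterol_excretion(
    conc_ug_per_mg: float, dry_mass_mg: float, days: float, n_animals: int
) -> dict:
    """Fecal sterol excretion per cage and per animal, ug/day.

    `conc_ug_per_mg` is the sterol concentration in dry feces, `dry_mass_mg`
    the total dry fecal mass collected from one cage over `days` days.
    """
    if days <= 0:
        raise ValueError("collection window must be positive")
    if dry_mass_mg < 0 or conc_ug_per_mg < 0:
        raise ValueError("mass and concentration must be non-negative")
    if n_animals <= 0:
        raise ValueError("need at least one animal per cage")
    per_cage = conc_ug_per_mg * dry_mass_mg / days
    return {
        "per_cage_ug_per_day": float(per_cage),
        "per_animal_ug_per_day": float(per_cage / n_animals),
    }


def relative_expression(ct: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Relative quantity Rq = 2^-ddCt per sample (Livak method).

    `ct` needs columns ``sample``, ``group``, ``ct_target``, ``ct_reference``
    (the reference being the housekeeping gene).  dCt = Ct(target) -
    Ct(reference); ddCt = dCt(sample) - mean dCt over the control group.
    Samples with a missing reference Ct are skipped with a warning.
    """
    required = {"sample", "group", "ct_target", "ct_reference"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    ok = ct["ct_reference"].notna() & ct["ct_target"].notna()
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} sample(s) skipped: missing Ct value",
            stacklevel=2,
        )
    df = ct[ok].copy()
    if not (df["group"] == control_group).any():
        raise ValueError(f"control group {control_group!r} is empty")
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    control_mean = df.loc[df["group"] == control_group, "delta_ct"].mean()
    df["delta_delta_ct"] = df["delta_ct"] - control_mean
    df["rq"] = 2.0 ** (-df["delta_delta_ct"])
    return df[["sample", "group", "delta_ct", "delta_delta_ct", "rq"]]


# ---------------------------------------------------------------------------
# Tidy-frame helpers for CSV-level workflows


def kinetics_from_frame(df: pd.DataFrame) -> list[KineticsSeries]:
    """Build KineticsSeries from a tidy frame (animal, group, time_min, concentration)."""
    out = []
    for (animal, group), sub in df.groupby(["animal", "group"], sort=False):
        sub = sub.sort_values("time_min")
        out.append(
            KineticsSeries(
                animal=str(animal),
                group=str(group),
                times=sub["time_min"].to_numpy(),
                concentrations=sub["concentration"].to_numpy(),
            )
        )
    return out


def isotopes_from_frame(df: pd.DataFrame) -> list[IsotopeRecord]:
    """Build IsotopeRecords from a tidy frame with per-animal count columns."""
    return [
        IsotopeRecord(
            animal=str(r.animal),
            dose_oral=float(r.dose_oral_dpm),
            dose_iv=float(r.dose_iv_dpm),
            serum_oral=float(r.serum_oral_dpm),
            serum_iv=float(r.serum_iv_dpm),
            aliquot_ul=float(getattr(r, "aliquot_ul", 300.0)),
        )
        for r in df.itertuples()
    ]
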