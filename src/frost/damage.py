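"""Freezing damage from chlorophyll fluorescence and LT50 estimation.

Damage after a freezing treatment is scored as photoinactivation,
``PhI = 1 − F_fT / F_max``, where ``F_fT`` is the Fv/Fm of a leaf exposed
to temperature T and ``F_max`` the maximum Fv/Fm observed for the species
across all leaves including untreated controls.  PhI is 0 for an
undamaged leaf and 1 for a dead one (Fv/Fm of zero).

LT50 — the temperature at which PhI reaches 50 % — is estimated by linear
interpolation between the treatment temperature with the highest mean
PhI < 50 % and the temperature with the lowest mean PhI > 50 %.  Species
that never reach 50 % damage at the coldest tested temperature are
censored (``below_range``); species already past 50 % at the warmest
tested temperature are censored ``above_range``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError, InputError

logger = logging.getLogger(__name__)

#: treatment temperatures used throughout (°C); controls are held at +4 °C
DEFAULT_TARGET_TEMPS_C = (-5.0, -10.0, -15.0, -19.0)


@dataclass(frozen=True)
class DamageRecord:
    leaf_id: str
    treatment_C: float | None  # None marks an untreated (4 °C dark) control
    fv_fm: float


@dataclass(frozen=True)
class DamageAssay:
    """All Fv/Fm records for one species across control + target temps."""

    species_id: str
    records: tuple[DamageRecord, ...]

    def __post_init__(self) -> None:
        if not any(r.treatment_C is None for r in self.records):
            raise InputError(f"species {self.species_id!r}: assay has no "
                             f"control record")
        for r in self.records:
            if not 0.0 <= r.fv_fm <= 1.0:
                raise InputError(f"species {self.species_id!r} leaf "
                                 f"{r.leaf_id!r}: Fv/Fm {r.fv_fm} outside [0, 1]")

    @property
    def treatment_temps(self) -> list[float]:
        return sorted({r.treatment_C for r in self.records
                       if r.treatment_C is not None}, reverse=True)


@dataclass(frozen=True)
class DamageCurve:
    """Mean photoinactivation per treatment temperature for one species.

    ``points`` are (treatment_temp_C, mean_PhI, n) sorted by descending
    temperature (warmest first).
    """

    species_id: str
    f_max: float
    points: tuple[tuple[float, float, int], ...]


@dataclass(frozen=True)
class LT50Result:
    species_id: str
    lt50_C: float            # NaN when censored
    censored: str            # one of {"none", "below_range", "above_range"}
    bracket: tuple[tuple[float, float], tuple[float, float]] | None


def photoinactivation(fv_fm_treated: float, f_max: float) -> float:
    """PhI = 1 − Fv/Fm(treated) / F_max, clamped to [0, 1]."""
    if f_max <= 0:
        raise InputError(f"f_max must be positive, got {f_max}")
    if fv_fm_treated < 0:
        raise InputError(f"fv_fm_treated must be >= 0, got {fv_fm_treated}")
    return float(min(1.0, max(0.0, 1.0 - fv_fm_treated / f_max)))


def build_damage_curve(assay: DamageAssay) -> DamageCurve:
    """Mean PhI per treatment temperature, with F_max over all records."""
    f_max = max(r.fv_fm for r in assay.records)
    if f_max <= 0:
        raise InputError(f"species {assay.species_id!r}: F_max is zero "
                         f"(all leaves dead including control)")
    points = []
    for temp in assay.treatment_temps:
        phis = [photoinactivation(r.fv_fm, f_max)
                for r in assay.records if r.treatment_C == temp]
        if not phis:
            raise InputError(f"species {assay.species_id!r}: empty treatment "
                             f"level {temp} °C")
        points.append((temp, float(np.mean(phis)), len(phis)))
    if not points:
        raise InputError(f"species {assay.species_id!r}: no treatment records")
    return DamageCurve(assay.species_id, f_max, tuple(points))


def lt50_interpolate(curve: DamageCurve) -> LT50Result:
    """Bracketed linear interpolation of the 50 % damage temperature.

    Scans the curve from warmest to coldest and uses the first bracket
    (T1 with PhI < 0.5, next T2 with PhI > 0.5); an exact PhI = 0.5 at a
    tested temperature returns that temperature.  Censoring: all PhI < 0.5
    → ``below_range``; PhI > 0.5 already at the warmest temperature →
    ``above_range``.
    """
    pts = sorted(curve.points, key=lambda p: -p[0])  # warmest first
    if len(pts) < 2:
        raise InputError(f"species {curve.species_id!r}: need >= 2 damage "
                         f"points, got {len(pts)}")
    for temp, phi, _n in pts:
        if phi == 0.5:
            return LT50Result(curve.species_id, float(temp), "none",
                              ((temp, phi), (temp, phi)))
    if pts[0][1] > 0.5:
        return LT50Result(curve.species_id, float("nan"), "above_range", None)
    for (t1, phi1, _), (t2, phi2, _) in zip(pts, pts[1:]):
        if phi1 < 0.5 < phi2:
            if phi2 <= phi1:  # unreachable with a true crossing; guards ties
                raise EstimationError(
                    f"species {curve.species_id!r}: non-monotone bracket "
                    f"PhI({t1})={phi1:.3f} >= PhI({t2})={phi2:.3f}")
            lt50 = t1 + (0.5 - phi1) * (t2 - t1) / (phi2 - phi1)
            return LT50Result(curve.species_id, float(lt50), "none",
                              ((t1, phi1), (t2, phi2)))
    return LT50Result(curve.species_id, float("nan"), "below_range", None)


def lt50_from_assay(assay: DamageAssay) -> LT50Result:
    """Convenience composition: curve from assay, then interpolation."""
    return lt50_interpolate(build_damage_curve(assay))


def lt50_per_replicate(assay: DamageAssay) -> list[float]:
    """Per-replicate LT50 values for use as a replicate sample.

    Leaves within each treatment are paired by replicate rank (the r-th
    leaf at each temperature forms one pseudo-curve); censored replicates
    are dropped.  This supports the two-sample mechanism comparison; the
    default species-level estimate uses treatment means instead.
    """
    f_max = max(r.fv_fm for r in assay.records)
    by_temp: dict[float, list[DamageRecord]] = {}
    for r in assay.records:
        if r.treatment_C is not None:
            by_temp.setdefault(r.treatment_C, []).append(r)
    n_rep = min(len(v) for v in by_temp.values())
    values = []
    for i in range(n_rep):
        points = tuple(
            (temp, photoinactivation(by_temp[temp][i].fv_fm, f_max), 1)
            for temp in sorted(by_temp, reverse=True))
        res = lt50_interpolate(DamageCurve(assay.species_id, f_max, points))
        if res.censored == "none":
            values.append(res.lt50_C)
    return values


def assays_from_frame(frame: pd.DataFrame) -> list[DamageAssay]:
    """Group a tidy records table (species_id, leaf_id, treatment, fv_fm)
    into per-species assays.  ``treatment`` is 'control' or a temperature."""
    assays = []
    for species_id, grp in frame.groupby("species_id", sort=True):
        records = tuple(
            DamageRecord(
                leaf_id=str(row.leaf_id),
                treatment_C=None if str(row.treatment).lower() == "control"
                else float(row.treatment),
                fv_fm=float(row.fv_fm))
            for row in grp.itertuples())
        assays.append(DamageAssay(str(species_id), records))
    return assays


def damage_results_table(assays: list[DamageAssay]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species LT50 table and per-temperature PhI table."""
    lt_rows, phi_rows = [], []
    for assay in assays:
        curve = build_damage_curve(assay)
        res = lt50_interpolate(curve)
        lt_rows.append({"species_id": assay.species_id, "f_max": curve.f_max,
                        "lt50_C": res.lt50_C, "censored": res.censored})
        for temp, phi, n in curve.points:
            phi_rows.append({"species_id": assay.species_id,
                             "treatment_C": temp, "mean_phi": phi, "n": n})
    return pd.DataFrame(lt_rows), pd.DataFrame(phi_rows)
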