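"""Wing morphology and the flight-performance covariate.

Field measurements are a bird's mass, the area of one spread wing and
the semi-span (photos of a single wing).  Doubling gives the full wing
area S and span b; derived are the mean chord c = S/b, aspect ratio
AR = b^2/S, wing loading N = m g / S (N m^-2) and the weight-normalized
wing area S* = S/(m g) = 1/N, the covariate expected to scale with
in-flight accelerations (thrust ~ S, acceleration ~ thrust / weight).

SI units internally (kg, m); CSV I/O uses field units (g, mm, mm^2)
with conversion at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GRAVITY = 9.81  # m s^-2


@dataclass(frozen=True)
class WingMorphology:
    """Measured and derived wing morphology of one bird (SI units)."""

    mass: float  # kg
    single_wing_area: float  # m^2
    semi_span: float  # m

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.single_wing_area <= 0 or self.semi_span <= 0:
            raise ValueError("mass, wing area and semi-span must all be > 0")

    @property
    def wing_area(self) -> float:
        """S: both wings, m^2."""
        return 2.0 * self.single_wing_area

    @property
    def span(self) -> float:
        """b: full wingspan, m."""
        return 2.0 * self.semi_span

    @property
    def mean_chord(self) -> float:
        """S / b, m."""
        return self.wing_area / self.span

    @property
    def aspect_ratio(self) -> float:
        """AR = b^2 / S, dimensionless."""
        return self.span**2 / self.wing_area

    @property
    def wing_loading(self) -> float:
        """N = m g / S, N m^-2."""
        return self.mass * GRAVITY / self.wing_area

    @property
    def weight_normalized_area(self) -> float:
        """S* = S / (m g) = 1 / N, m^2 N^-1."""
        return self.wing_area / (self.mass * GRAVITY)


def derive_morphology(mass_kg: float, single_wing_area_m2: float, semi_span_m: float) -> WingMorphology:
    """Validate inputs and return the morphology record."""
    return WingMorphology(mass_kg, single_wing_area_m2, semi_span_m)


def from_field_units(mass_g: float, single_wing_area_mm2: float, semi_span_mm: float) -> WingMorphology:
    """Field units (g, mm^2, mm) -> SI."""
    return derive_morphology(mass_g * 1e-3, single_wing_area_mm2 * 1e-6, semi_span_mm * 1e-3)


def percent_difference(group_a_mean: float, group_b_mean: float) -> float:
    """100 * (a - b) / b, the percent excess of group a over reference b."""
    if group_b_mean == 0:
        raise ValueError("reference mean must be nonzero")
    return 100.0 * (group_a_mean - group_b_mean) / group_b_mean


def population_morphology(population: pd.DataFrame) -> pd.DataFrame:
    """Derive per-bird morphology for a population table.

    Expects columns ``bird_id, mass_g, single_wing_area_mm2,
    semi_span_mm``; returns ``bird_id, mass_kg, S_m2, b_m, chord_m, AR,
    N_Nm2, Sstar`` (plus ``sex`` if present).
    """
    rows = []
    for _, rec in population.iterrows():
        m = from_field_units(rec["mass_g"], rec["single_wing_area_mm2"], rec["semi_span_mm"])
        row = {
            "bird_id": rec["bird_id"],
            "mass_kg": m.mass,
            "S_m2": m.wing_area,
            "b_m": m.span,
            "chord_m": m.mean_chord,
            "AR": m.aspect_ratio,
            "N_Nm2": m.wing_loading,
            "Sstar": m.weight_normalized_area,
        }
        if "sex" in rec:
            row["sex"] = rec["sex"]
        rows.append(row)
    return pd.DataFrame(rows)
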