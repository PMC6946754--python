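"""Proton-transfer-reaction kinetic quantification.

In the drift tube an analyte R reacts with the primary ion H3O+ at a
pseudo-first-order rate, so for small conversion the product-ion signal
obeys

    I(RH+) / I(H3O+) = [R] · k · t

with k the ion–molecule rate coefficient (cm³ s⁻¹) and t the reaction
(drift) time.  Solving for the number density [R] and dividing by the
drift-gas number density N = p/(k_B·T) gives the absolute volume mixing
ratio,

    ppbv = I(RH+) / (I(H3O+) · k · t) / N · 1e9 ,

independent of any external calibration gas.  Concentrations are finally
normalized by leaf fresh weight (ppbv · mgFW⁻¹) so that emissions of
different-sized leaves are comparable.

The primary-ion signal is conventionally measured on the H3^18O+
isotopologue at m/z 21.0221 and multiplied by the 16O/18O isotope ratio
(≈487), because the 19.0178 Th peak saturates the detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import monoisotopic_mz

__all__ = [
    "KB",
    "H3O18_MZ",
    "DriftConditions",
    "QuantParams",
    "SampleRecord",
    "EmissionTable",
    "compute_E_over_N",
    "concentration_ppbv",
    "normalize_fw",
    "build_emission_table",
]

KB = 1.380649e-23  # J/K (exact, SI)
TD = 1e-17         # V·cm² per Townsend
H3O18_MZ = monoisotopic_mz("H3O18+")  # 21.0221 Th, primary-ion isotopologue


@dataclass
class DriftConditions:
    """Drift-tube operating point.

    Voltage/pressure/temperature defaults are the screening conditions
    (550 V, 2.3 mbar, 110 °C).  The drift length is instrument geometry
    and must be configured (a PTR-TOF drift tube is ~9–10 cm; the default
    9.3 cm puts E/N at ≈136 Td, consistent with the quoted "about 140").
    The reaction time is the ion residence time in the drift tube
    (~100 µs).  E/N is always derived, never set directly.
    """

    voltage: float = 550.0        # V
    pressure: float = 2.3         # mbar
    temperature: float = 110.0    # °C
    drift_length: float | None = 9.3   # cm
    reaction_time: float = 100e-6      # s

    def __post_init__(self) -> None:
        if self.voltage <= 0 or self.pressure <= 0:
            raise ValueError("voltage and pressure must be positive")
        if self.temperature <= -273.15:
            raise ValueError("temperature below absolute zero")
        if self.reaction_time <= 0:
            raise ValueError("reaction_time must be positive")

    @property
    def temperature_K(self) -> float:
        return self.temperature + 273.15

    @property
    def number_density(self) -> float:
        """Drift-gas number density N in cm⁻³ (ideal gas, p/k_B·T)."""
        p_pa = self.pressure * 100.0
        return p_pa / (KB * self.temperature_K) * 1e-6

    @property
    def E_over_N(self) -> float:
        return compute_E_over_N(self)


def compute_E_over_N(conditions: DriftConditions) -> float:
    """Reduced electric field E/N in Townsend (1 Td = 1e-17 V·cm²)."""
    if conditions.drift_length is None:
        raise ValueError(
            "drift_length is not set; configure the drift-tube geometry "
            "(DriftConditions(drift_length=... cm)) to compute E/N"
        )
    if conditions.drift_length <= 0:
        raise ValueError("drift_length must be positive")
    E = conditions.voltage / conditions.drift_length        # V/cm
    return E / conditions.number_density / TD


@dataclass
class QuantParams:
    """Kinetic quantification settings.

    ``rate_coefficient`` is the default ion–molecule rate coefficient k in
    cm³ s⁻¹ (collision-limited proton transfer is ~2e-9); per-ion values
    can be supplied in ``rate_overrides`` keyed by m/z rounded to 4
    decimals.  ``transmission`` maps m/z to a relative detection
    efficiency (default 1).  With ``primary_isotopologue`` True the
    primary-ion intensity is read at 21.0221 Th and multiplied by
    ``isotope_factor``.
    """

    rate_coefficient: float = 2e-9
    rate_overrides: dict[float, float] = field(default_factory=dict)
    transmission: dict[float, float] = field(default_factory=dict)
    primary_isotopologue: bool = True
    isotope_factor: float = 487.0

    def __post_init__(self) -> None:
        if self.rate_coefficient <= 0:
            raise ValueError("rate coefficient must be positive")
        if any(v <= 0 for v in self.rate_overrides.values()):
            raise ValueError("rate overrides must be positive")
        if any(v <= 0 for v in self.transmission.values()):
            raise ValueError("transmission factors must be positive")

    def k_for(self, mz: float) -> float:
        return self.rate_overrides.get(round(mz, 4), self.rate_coefficient)

    def transmission_for(self, mz: float) -> float:
        return self.transmission.get(round(mz, 4), 1.0)


def concentration_ppbv(
    analyte_intensity: float,
    primary_intensity: float,
    params: QuantParams,
    conditions: DriftConditions,
    analyte_mz: float | None = None,
) -> float:
    """Absolute headspace mixing ratio of one analyte in ppbv.

    Intensities are counts per extraction.  ``primary_intensity`` is the
    H3O+ signal on the direct scale: if the isotopologue convention is in
    use, pass the 21.0221 Th intensity already multiplied by the isotope
    factor (``build_emission_table`` does this).  Transmission correction
    divides the analyte intensity by its relative transmission before the
    ratio.
    """
    if primary_intensity <= 0:
        raise ValueError(
            "primary-ion intensity must be positive (H3O+ peak not detected?)"
        )
    if analyte_intensity < 0:
        raise ValueError("analyte intensity must be non-negative")
    mz = analyte_mz if analyte_mz is not None else -1.0
    k = params.k_for(mz)
    i_r = analyte_intensity / params.transmission_for(mz)
    number_density = i_r / (primary_intensity * k * conditions.reaction_time)
    return number_density / conditions.number_density * 1e9


@dataclass
class SampleRecord:
    """Metadata for one vial: which line, genotype, block and leaf."""

    vial_id: str
    line_id: str
    genotype: str           # e.g. "transgenic" / "Col-0"
    block: int
    fresh_weight: float | None  # mg; None -> excluded from normalized table
    order: int = 0          # measurement order within the run

    def __post_init__(self) -> None:
        if self.fresh_weight is not None and self.fresh_weight <= 0:
            raise ValueError("fresh weight must be positive")


def normalize_fw(ppbv: float, record: SampleRecord) -> float:
    """Fresh-weight normalization: ppbv → ppbv per mg fresh weight."""
    if record.fresh_weight is None:
        raise ValueError(f"vial {record.vial_id}: fresh weight missing")
    return ppbv / record.fresh_weight


@dataclass
class EmissionTable:
    """Samples × ions matrix of headspace concentrations.

    ``ppbv`` holds absolute headspace mixing ratios; ``normalized`` the
    fresh-weight-normalized values (ppbv·mgFW⁻¹, rows with missing weight
    dropped); ``below_lod`` flags entries where no peak was detected (the
    concentration is reported as exactly 0).  Columns are ion m/z values
    in ascending order; rows are indexed by vial ID with line/genotype/
    block metadata alongside.
    """

    ppbv: pd.DataFrame
    normalized: pd.DataFrame
    below_lod: pd.DataFrame
    samples: pd.DataFrame  # vial, line, genotype, block, fw_mg, order

    def per_line(self, mz: float, normalized: bool = True) -> pd.Series:
        """Mean emission per line for one ion column (replicates averaged)."""
        tab = self.normalized if normalized else self.ppbv
        col = _nearest_column(tab, mz)
        joined = tab[[col]].join(self.samples.set_index("vial")["line"])
        return joined.groupby("line")[col].mean()


def _nearest_column(df: pd.DataFrame, mz: float, tol: float = 0.02) -> float:
    cols = np.asarray(df.columns, dtype=float)
    i = int(np.argmin(np.abs(cols - mz)))
    if abs(cols[i] - mz) > tol:
        raise KeyError(f"no ion column within {tol} Th of {mz}")
    return df.columns[i]


def build_emission_table(
    peak_tables: Sequence,
    records: Sequence[SampleRecord],
    target_mzs: Sequence[float],
    params: QuantParams,
    conditions: DriftConditions,
    match_tolerance: float = 0.01,
) -> EmissionTable:
    """Quantify target ions across all vials into an :class:`EmissionTable`.

    Each vial's peak table is searched for the primary ion and every
    target m/z within ``match_tolerance``; missing analyte peaks (below
    the detection limit) become 0 ppbv with a below-LOD flag.  A missing
    primary-ion peak is an error for that vial.  Column order is by m/z;
    duplicate vial IDs are rejected.
    """
    recs = {r.vial_id: r for r in records}
    if len(recs) != len(records):
        raise ValueError("duplicate vial IDs in sample records")
    targets = sorted(float(m) for m in target_mzs)
    primary_mz = H3O18_MZ if params.primary_isotopologue else monoisotopic_mz("H3O+")

    rows_ppbv, rows_lod, idx = [], [], []
    for tab in peak_tables:
        if tab.vial_id in idx:
            raise ValueError(f"duplicate vial ID in peak tables: {tab.vial_id}")
        if tab.vial_id not in recs:
            raise ValueError(f"vial {tab.vial_id} has no sample record")
        prim = tab.area_at(primary_mz, match_tolerance)
        if prim is None or prim <= 0:
            raise ValueError(f"vial {tab.vial_id}: primary ion not detected")
        if params.primary_isotopologue:
            prim = prim * params.isotope_factor
        row, lod = [], []
        for mz in targets:
            area = tab.area_at(mz, match_tolerance)
            if area is None:
                row.append(0.0)
                lod.append(True)
            else:
                row.append(concentration_ppbv(area, prim, params, conditions, analyte_mz=mz))
                lod.append(False)
        rows_ppbv.append(row)
        rows_lod.append(lod)
        idx.append(tab.vial_id)

    ppbv = pd.DataFrame(rows_ppbv, index=idx, columns=targets)
    lod = pd.DataFrame(rows_lod, index=idx, columns=targets)
    sample_cols = ["vial", "line", "genotype", "block", "fw_mg", "order"]
    samples = pd.DataFrame(
        [{
            "vial": r.vial_id, "line": r.line_id, "genotype": r.genotype,
            "block": r.block, "fw_mg": r.fresh_weight, "order": r.order,
        } for r in records if r.vial_id in set(idx)],
        columns=sample_cols,
    )
    fw = samples.set_index("vial")["fw_mg"].reindex(idx)
    keep = fw.notna()
    normalized = ppbv.loc[keep].div(fw[keep], axis=0)
    return EmissionTable(ppbv=ppbv, normalized=normalized, below_lod=lod, samples=samples)
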