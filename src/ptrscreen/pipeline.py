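"""High-level pipeline: spectra → peak tables → emission table → screening.

These functions chain the single-stage operations exactly as the CLI
does, so library users, the command line and the tests all execute the
same code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import monoisotopic_mz
from .config import RunConfig
from .peaks import PeakTable, integrate_table
from .quant import EmissionTable, SampleRecord, build_emission_table
from .screen import (GroupComparison, compare_genotypes, distribution_summary,
                     ols_bootstrap, select_lines)
from .tof import CalibrationModel, RawSpectrum, calibrate

log = logging.getLogger("ptrscreen")

__all__ = ["ScreeningResult", "process_spectrum", "process_run",
           "quantify_run", "screen_emissions"]


def process_spectrum(
    spectrum: RawSpectrum,
    config: RunConfig,
) -> tuple[CalibrationModel, PeakTable]:
    """Dead-time correct, internally calibrate and peak-fit one spectrum.

    The provisional mass axis for locating reference peaks comes from the
    instrument's nominal calibration (stored in the spectrum metadata if
    present, else the configured instrument geometry).
    """
    nominal = CalibrationModel(
        a=spectrum.meta.get("nominal_a", config.instrument.calib_a),
        t0=spectrum.meta.get("nominal_t0", config.instrument.calib_t0),
    )
    model = calibrate(spectrum, config.reference_ions, nominal_model=nominal)
    table = integrate_table(spectrum, model, config.peaks)
    return model, table


def process_run(
    spectra: Sequence[RawSpectrum],
    config: RunConfig,
) -> tuple[dict[str, CalibrationModel], list[PeakTable]]:
    """Process every spectrum of a run; returns calibrations and peak tables."""
    calibs: dict[str, CalibrationModel] = {}
    tables: list[PeakTable] = []
    for s in spectra:
        model, table = process_spectrum(s, config)
        calibs[s.vial_id] = model
        tables.append(table)
    log.info("processed %d spectra (config %s)", len(spectra), config.hash())
    return calibs, tables


def quantify_run(
    peak_tables: Sequence[PeakTable],
    records: Sequence[SampleRecord],
    config: RunConfig,
) -> EmissionTable:
    """Kinetic quantification of the configured target ions for a run."""
    targets = [monoisotopic_mz(f) for f in config.target_ions]
    return build_emission_table(peak_tables, records, targets,
                                config.quant, config.drift)


@dataclass
class ScreeningResult:
    """Bundle of the screening-stage outputs for one target ion."""

    target_mz: float
    per_line: pd.Series                      # mean emission per line, ppbv/mgFW
    ranked: pd.Series
    strata: dict[str, int]
    distribution: "object"
    comparisons: list[GroupComparison] = field(default_factory=list)
    regression: "object | None" = None

    def report(self) -> str:
        """Human-readable summary in the mean ± SD / letters / stars layout."""
        lines = [f"Target ion m/z {self.target_mz:.4f}"]
        d = self.distribution
        lines.append(
            f"  lines: n={d.n}  median={d.median:.3g}  skewness={d.skewness:.2f}"
            f"  excess kurtosis={d.excess_kurtosis:.2f}"
            f"  Shapiro-Wilk p={d.shapiro_p:.3g}")
        for k, v in self.strata.items():
            lines.append(f"  lines with emission {k} ppbv/mgFW: n={v}")
        for gc in self.comparisons:
            cells = "  ".join(
                f"{g}: {gc.means[g]:.3g} ± {gc.sds[g]:.2g} {gc.letters[g]}"
                for g in sorted(gc.means))
            lines.append(f"  m/z {gc.mz:.4f}: {cells}   "
                         f"Welch p={gc.p_value:.2g} {gc.stars}")
        if self.regression is not None:
            r = self.regression
            lines.append(
                f"  emission~expression: R²={r.r_squared:.4f} "
                f"p={r.p_uncorrelated:.3g} (n={r.n}, bootstrap N={r.n_boot})")
        return "\n".join(lines)


def screen_emissions(
    emission_table: EmissionTable,
    config: RunConfig,
    target_mz: float | None = None,
    expression: pd.DataFrame | None = None,
    thresholds: Sequence[tuple[str, float]] = (("<", 10.0), (">", 80.0)),
) -> ScreeningResult:
    """Screening statistics on an emission table.

    Computes per-line mean emissions for the target ion (default: the
    first configured target), distribution diagnostics across transgenic
    lines, genotype comparisons (Welch + Bonferroni + letters) over all
    ion columns, threshold strata and ranking, and — when an expression
    table (line, fold_change) is supplied — the emission–expression
    regression with its bootstrap confidence band.
    """
    if target_mz is None:
        target_mz = monoisotopic_mz(config.target_ions[0])
    per_line_all = emission_table.per_line(target_mz)
    samples = emission_table.samples
    geno_of_line = samples.drop_duplicates("line").set_index("line")["genotype"]
    trans_lines = geno_of_line[geno_of_line != "Col-0"].index
    per_line = per_line_all.loc[per_line_all.index.intersection(trans_lines)]

    dist = distribution_summary(per_line.to_numpy())
    ranked, strata = select_lines(per_line, thresholds=thresholds)

    geno_of_vial = samples.set_index("vial")["genotype"].to_dict()
    comparisons: list[GroupComparison] = []
    counts = samples.groupby("genotype").size()
    if (counts >= 2).sum() >= 2:
        usable = emission_table.normalized.loc[
            [v for v in emission_table.normalized.index
             if counts.get(geno_of_vial[v], 0) >= 2]]
        try:
            comparisons = compare_genotypes(
                usable, geno_of_vial,
                family_size=config.stats.bonferroni_family,
                alpha=config.stats.alpha)
        except ValueError:
            comparisons = []

    regression = None
    if expression is not None and len(expression) >= 3:
        merged = expression.merge(per_line.rename("emission"),
                                  left_on="line", right_index=True)
        if len(merged) >= 3:
            regression = ols_bootstrap(
                merged["fold_change"].to_numpy(),
                merged["emission"].to_numpy(),
                n_boot=config.stats.n_boot,
                seed=config.stats.seed)

    return ScreeningResult(
        target_mz=float(target_mz), per_line=per_line, ranked=ranked,
        strata=strata, distribution=dist, comparisons=comparisons,
        regression=regression,
    )
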