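"""Synthetic ToF spectra and whole screening experiments.

The simulator inverts the toolkit's own forward model so that every
downstream stage can be validated against known truth without any
instrument data:

* concentrations are converted to expected count rates through the same
  proton-transfer kinetics that :mod:`ptrscreen.quant` inverts;
* each ion's counts are spread over flight-time bins as a Gaussian whose
  width is constant in resolving power (FWHM = m/z ÷ resolution), mapped
  through the ToF law t = a·√(m/z) + t0;
* a uniform Poisson baseline is added;
* detector dead time is applied as non-paralyzable censoring: a
  registered count blanks that extraction for the next ``d`` bins.

Censoring is sampled by an exact monotone coupling.  Uncensored
registered counts C(i) ~ Binomial(N_ext, 1 − e^(−λ_i/N_ext)) are drawn
first (the d = 0 spectrum); for d > 0 each bin keeps
A(i) ~ Hypergeometric(live = N_avail(i), blanked = N_ext − N_avail(i),
draws = C(i)), so marginally A(i) ~ Binomial(N_avail(i), p_i) — the
model the Poisson dead-time correction inverts exactly — while
pointwise A(i) ≤ C(i): dead time only ever removes counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .chem import IonFormula, monoisotopic_mz, parse_formula
from .quant import DriftConditions, QuantParams, SampleRecord
from .tof import CalibrationModel, RawSpectrum

__all__ = [
    "InstrumentParams",
    "IonSource",
    "ExperimentDesign",
    "DEFAULT_CALIBRANTS",
    "simulate_spectrum",
    "simulate_experiment",
    "expected_arrivals",
]

FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class InstrumentParams:
    """Geometry and acquisition settings of the simulated ToF.

    ``calib_a``/``calib_t0`` define the true ToF law (bins per √Th and
    bin offset); ``n_bins`` defaults to just covering ``mz_range``.
    ``dead_time_bins`` is the detector blanking window d;
    ``baseline_rate`` is a uniform dark/chemical background in counts
    per bin per extraction.
    """

    calib_a: float = 8000.0
    calib_t0: float = 1200.0
    resolution: float = 7000.0
    mz_range: tuple[float, float] = (15.0, 300.0)
    n_bins: int | None = None
    dead_time_bins: int = 2
    extraction_rate: float = 30000.0   # extractions per second
    baseline_rate: float = 2e-6        # counts / bin / extraction

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.dead_time_bins < 0:
            raise ValueError("dead_time_bins must be >= 0")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ValueError("mz_range must be increasing")
        if self.n_bins is None:
            self.n_bins = int(np.ceil(self.calib_a * np.sqrt(self.mz_range[1])
                                      + self.calib_t0)) + 10

    @property
    def calibration(self) -> CalibrationModel:
        """The true (nominal) ToF law as a calibration model."""
        return CalibrationModel(a=self.calib_a, t0=self.calib_t0)


@dataclass
class IonSource:
    """One ion to place in the spectrum.

    Analytes carry a headspace concentration in ppbv (converted to counts
    through the kinetic forward model); primary and calibrant ions carry
    a detector count rate in counts/s directly.  Exactly one of ``ppbv``
    and ``count_rate`` must be set.  The primary source's ``count_rate``
    is the *direct* H3O+ equivalent rate; its peak is placed at the
    H3^18O+ isotopologue m/z divided by the isotope factor when the
    quantification convention asks for it.
    """

    species: "IonFormula | str | float"
    ppbv: float | None = None
    count_rate: float | None = None
    primary: bool = False

    def __post_init__(self) -> None:
        if (self.ppbv is None) == (self.count_rate is None):
            raise ValueError("set exactly one of ppbv and count_rate")
        if self.ppbv is not None and self.ppbv < 0:
            raise ValueError("concentration must be >= 0")
        if self.count_rate is not None and self.count_rate < 0:
            raise ValueError("count rate must be >= 0")

    @property
    def mz(self) -> float:
        if isinstance(self.species, (int, float)):
            return float(self.species)
        f = parse_formula(self.species) if isinstance(self.species, str) else self.species
        return monoisotopic_mz(f)


def _bin_edges_mz(params: InstrumentParams) -> np.ndarray:
    """m/z of bin boundaries i − 1/2 for i = 0..n_bins (clipped below t0)."""
    edges = np.arange(params.n_bins + 1, dtype=float) - 0.5
    rel = np.maximum(edges - params.calib_t0, 0.0) / params.calib_a
    return rel ** 2


def expected_arrivals(
    ions: Sequence[IonSource],
    params: InstrumentParams,
    duration: float,
    quant_params: QuantParams,
    conditions: DriftConditions,
) -> np.ndarray:
    """Expected arrival counts per bin over the whole acquisition (λ_i).

    This is the noise-free, censoring-free truth that the dead-time
    correction and peak fitting should jointly recover.
    """
    primaries = [s for s in ions if s.primary]
    if len(primaries) > 1:
        raise ValueError("at most one primary ion source")
    n_ext = params.extraction_rate * duration
    lam = np.full(params.n_bins, params.baseline_rate * n_ext, dtype=float)
    edges = _bin_edges_mz(params)

    prim_per_ext = primaries[0].count_rate * duration / n_ext if primaries else None

    def add_peak(mz: float, total_counts: float) -> None:
        if total_counts <= 0:
            return
        sigma = mz / (params.resolution * FWHM_SIGMA)
        lo = np.searchsorted(edges, mz - 8 * sigma)
        hi = np.searchsorted(edges, mz + 8 * sigma) + 1
        lo, hi = max(lo - 1, 0), min(hi, edges.size)
        if hi - lo < 2:
            return
        cdf = norm.cdf(edges[lo:hi], loc=mz, scale=sigma)
        lam[lo:hi - 1] += total_counts * np.diff(cdf)

    for src in ions:
        if src.primary:
            mz = monoisotopic_mz("H3O18+") if quant_params.primary_isotopologue else src.mz
            rate = src.count_rate / (quant_params.isotope_factor
                                     if quant_params.primary_isotopologue else 1.0)
            add_peak(mz, rate * duration)
        elif src.count_rate is not None:
            add_peak(src.mz, src.count_rate * duration)
        else:
            if prim_per_ext is None:
                raise ValueError("ppbv ion sources require a primary ion source")
            mz = src.mz
            i_r = (src.ppbv * 1e-9 * conditions.number_density
                   * quant_params.k_for(round(mz, 4)) * conditions.reaction_time
                   * prim_per_ext * quant_params.transmission_for(round(mz, 4)))
            add_peak(mz, i_r * n_ext)
    return lam


def _censor(C: np.ndarray, n_ext: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """Sequential dead-time thinning of uncensored counts (see module docs)."""
    A = C.copy()
    nz = np.nonzero(C)[0]
    recent: list[tuple[int, int]] = []  # (bin, registered counts) inside window
    blanked = 0
    for i in nz.tolist():
        while recent and recent[0][0] < i - d:
            blanked -= recent[0][1]
            recent.pop(0)
        c = int(C[i])
        if blanked > 0:
            a = int(rng.hypergeometric(n_ext - blanked, blanked, c))
        else:
            a = c
        A[i] = a
        if a and d > 0:
            recent.append((i, a))
            blanked += a
    return A


def simulate_spectrum(
    ions: Sequence[IonSource],
    params: InstrumentParams,
    duration: float = 30.0,
    quant_params: QuantParams | None = None,
    conditions: DriftConditions | None = None,
    seed: "int | np.random.Generator" = 0,
    vial_id: str = "",
) -> RawSpectrum:
    """Draw one raw spectrum from the forward model.

    Requires a primary-ion source whenever any analyte is specified in
    ppbv.  Reproducible: the same seed yields bit-identical counts, and
    the same seed with a larger ``dead_time_bins`` yields pointwise
    smaller-or-equal counts.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    quant_params = quant_params or QuantParams()
    conditions = conditions or DriftConditions()
    if any(s.ppbv is not None for s in ions) and not any(s.primary for s in ions):
        raise ValueError("ppbv analytes given but no primary ion source present")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ext = int(round(params.extraction_rate * duration))
    lam = expected_arrivals(ions, params, duration, quant_params, conditions)
    p = -np.expm1(-lam / n_ext)
    C = rng.binomial(n_ext, p)
    d = params.dead_time_bins
    A = _censor(C, n_ext, d, rng) if d > 0 else C
    return RawSpectrum(
        counts=A.astype(np.int64),
        n_extractions=n_ext,
        dead_time_bins=d,
        duration=duration,
        vial_id=vial_id,
        meta={"nominal_a": params.calib_a, "nominal_t0": params.calib_t0},
    )


# ---------------------------------------------------------------------------
# whole experiments

#: Calibrant ions present in every vial (species, detector count rate in
#: counts/s).  Together with the primary-ion isotopologue they span the
#: mass range for internal calibration.
DEFAULT_CALIBRANTS: tuple[tuple[str, float], ...] = (
    ("C3H7O+", 2000.0),     # protonated acetone, 59.0491 Th
    ("C10H17+", 1500.0),    # protonated monoterpene, 137.1325 Th
)


@dataclass
class ExperimentDesign:
    """Design of a synthetic screening run.

    Defaults mirror the screening study conditions: 116 independent
    transgenic lines, autosampler blocks of 32 vials with one Col-0
    reference each, 30-s measurements in randomized order, strongly
    right-skewed emission across lines (log-normal, median 5
    ppbv·mgFW⁻¹, σ_log = 0.5106 giving population skewness ≈ 1.8) and
    transgene expression only weakly predictive of emission
    (target R² ≈ 0.28 over the top 29 emitters).
    """

    n_lines: int = 116
    block_size: int = 32
    col0_per_block: int = 1
    emission_median: float = 5.0       # ppbv / mg FW
    emission_sigma_log: float = 0.5106
    col0_emission: float = 0.14        # ppbv / mg FW, wild-type background
    analyte: str = "C5H9+"             # protonated isoprene
    fw_mean: float = 25.0              # mg
    fw_sd: float = 5.0
    expression_r2: float = 0.28
    expression_slope: float = 0.1      # fold change per (ppbv/mgFW)
    expression_intercept: float = 1.0
    n_expression_lines: int = 29
    primary_rate: float = 1e6          # counts/s, direct H3O+ equivalent
    duration: float = 30.0             # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")
        if self.block_size < self.col0_per_block + 1:
            raise ValueError("block must hold at least one line besides Col-0")
        for name in ("emission_median", "emission_sigma_log", "fw_mean", "fw_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def simulate_experiment(
    design: ExperimentDesign,
    params: InstrumentParams | None = None,
    quant_params: QuantParams | None = None,
    conditions: DriftConditions | None = None,
    calibrants: Sequence[tuple[str, float]] = DEFAULT_CALIBRANTS,
    render_spectra: bool = True,
) -> tuple[list[RawSpectrum], list[SampleRecord], pd.DataFrame, pd.DataFrame]:
    """Simulate a full screening run.

    Returns ``(spectra, records, expression, truth)``:

    * one raw spectrum per vial, lines packed into blocks sequentially
      with ``col0_per_block`` Col-0 reference vials per block, measured
      order randomized across the run (stored in the records);
    * sample records with fresh weights;
    * an expression table (line, fold_change) for the top emitters, its
      noise calibrated so the expected emission–expression R² matches
      the design;
    * a truth table with each line's true emission (ppbv·mgFW⁻¹).

    Everything is reproducible from ``design.seed``.  With
    ``render_spectra=False`` the spectra list is empty (design-level
    outputs only), while the design, weights, truth and expression draws
    stay identical to the rendered run.
    """
    params = params or InstrumentParams()
    quant_params = quant_params or QuantParams()
    conditions = conditions or DriftConditions()
    rng = np.random.default_rng(design.seed)

    lines = [f"L{i + 1:03d}" for i in range(design.n_lines)]
    emissions = design.emission_median * np.exp(
        design.emission_sigma_log * rng.standard_normal(design.n_lines)
    )

    per_block = design.block_size - design.col0_per_block
    n_blocks = int(np.ceil(design.n_lines / per_block))
    vials: list[tuple[str, str, str, int, float]] = []  # vial, line, genotype, block, emission/mgFW
    vi = 0
    for b in range(n_blocks):
        chunk = lines[b * per_block:(b + 1) * per_block]
        for _ in range(design.col0_per_block):
            vials.append((f"V{vi + 1:03d}", f"Col0_b{b + 1}", "Col-0", b + 1, design.col0_emission))
            vi += 1
        for name in chunk:
            em = emissions[lines.index(name)]
            vials.append((f"V{vi + 1:03d}", name, "transgenic", b + 1, em))
            vi += 1

    order = rng.permutation(len(vials))
    order_of = {i: int(np.nonzero(order == i)[0][0]) for i in range(len(vials))}

    fw = np.clip(rng.normal(design.fw_mean, design.fw_sd, len(vials)), 5.0, None)
    records = [
        SampleRecord(vial_id=v, line_id=ln, genotype=g, block=b,
                     fresh_weight=float(fw[i]), order=order_of[i])
        for i, (v, ln, g, b, _e) in enumerate(vials)
    ]

    analyte_mz = monoisotopic_mz(design.analyte)
    spectra: list[RawSpectrum] = []
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=len(vials))
    if render_spectra:
        for i, (v, _ln, _g, _b, em_per_mg) in enumerate(vials):
            headspace_ppbv = em_per_mg * fw[i]
            ions = [IonSource("H3O+", count_rate=design.primary_rate, primary=True)]
            ions += [IonSource(sp, count_rate=r) for sp, r in calibrants]
            ions.append(IonSource(analyte_mz, ppbv=float(headspace_ppbv)))
            spectra.append(simulate_spectrum(
                ions, params, design.duration, quant_params, conditions,
                seed=int(child_seeds[i]), vial_id=v,
            ))

    truth = pd.DataFrame({
        "line": [ln for _v, ln, _g, _b, _e in vials],
        "genotype": [g for _v, _ln, g, _b, _e in vials],
        "vial": [v for v, _ln, _g, _b, _e in vials],
        "true_emission": [e for _v, _ln, _g, _b, e in vials],
    }).drop_duplicates("line").reset_index(drop=True)

    # expression for the top emitters, noise set from the target R²
    trans = truth[truth.genotype == "transgenic"].sort_values(
        "true_emission", ascending=False)
    top = trans.head(design.n_expression_lines)
    y = top.true_emission.to_numpy()
    signal_sd = design.expression_slope * y.std(ddof=1)
    noise_sd = signal_sd * np.sqrt(1.0 / design.expression_r2 - 1.0)
    fold = (design.expression_intercept + design.expression_slope * y
            + rng.normal(0.0, noise_sd, y.size))
    fold = np.clip(fold, 1e-3, None)
    expression = pd.DataFrame({"line": top.line.to_numpy(), "fold_change": fold})

    return spectra, records, expression, truth
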