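"""Detector dead-time correction and internal mass-axis calibration.

Ion-counting ToF detectors register at most one ion per extraction per
flight-time bin and are blind for a short dead time after each registered
count.  At high count rates the raw histogram is therefore biased low.
The Poisson-statistics correction inverts that censoring exactly in
expectation: for bin *i* with raw counts A(i), extraction count N_ext and
dead-time window of d bins,

    N_avail(i) = N_ext − Σ_{j=i−d}^{i−1} A(j)
    A'(i)      = −N_ext · ln(1 − A(i) / N_avail(i))

N_avail(i) is the number of extractions in which the detector was live at
bin *i* (each registered count in the preceding d bins blanks exactly one
extraction).  With d = 0 this reduces to the pure pile-up inversion
A' = −N_ext·ln(1 − A/N_ext).

Mass calibration uses the first-order ToF law  t = a·√(m/z) + t0  fitted
by least squares to reference ions found within search windows in the
spectrum itself ("internal" calibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import IonFormula, monoisotopic_mz, parse_formula

__all__ = [
    "RawSpectrum",
    "CalibrationModel",
    "SaturationError",
    "correct_dead_time",
    "calibrate",
    "mz_axis",
    "bin_of_mz",
    "centroid_bin",
]


class SaturationError(ValueError):
    """Raised when a bin's counts reach the number of live extractions."""


@dataclass
class RawSpectrum:
    """Per-vial histogram of ion counts versus flight-time bin.

    counts[i] is the number of extractions (out of ``n_extractions``) in
    which an ion was registered in bin *i*; ``dead_time_bins`` is the
    detector blanking window d in bins.
    """

    counts: np.ndarray
    n_extractions: int
    dead_time_bins: int = 0
    duration: float = 30.0  # s
    vial_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.n_extractions <= 0:
            raise ValueError("n_extractions must be positive")
        if self.dead_time_bins < 0:
            raise ValueError("dead_time_bins must be >= 0")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if np.any(self.counts > self.n_extractions):
            raise ValueError("bin counts exceed extraction count")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)


def correct_dead_time(spectrum: RawSpectrum) -> np.ndarray:
    """Invert dead-time censoring; returns real-valued corrected counts.

    Raises :class:`SaturationError`, naming the first offending bin, if any
    bin's raw counts reach the live-extraction count N_avail (the logarithm
    would diverge: the detector was saturated and the true rate is
    unrecoverable).
    """
    A = np.asarray(spectrum.counts, dtype=float)
    n_ext = float(spectrum.n_extractions)
    d = spectrum.dead_time_bins
    if d == 0:
        n_avail = np.full_like(A, n_ext)
    else:
        # window sum of the previous d bins, clipped at the spectrum start
        csum = np.concatenate([[0.0], np.cumsum(A)])
        idx = np.arange(A.size)
        lo = np.maximum(idx - d, 0)
        n_avail = n_ext - (csum[idx] - csum[lo])
    bad = np.nonzero(A >= n_avail)[0]
    if bad.size:
        i = int(bad[0])
        raise SaturationError(
            f"bin {i} saturated: {A[i]:.0f} counts with only "
            f"{n_avail[i]:.0f} live extractions"
        )
    return -n_ext * np.log1p(-A / n_avail)


# ---------------------------------------------------------------------------
# mass axis

@dataclass
class CalibrationModel:
    """Two-parameter ToF mass calibration  t = a·√(m/z) + t0.

    ``achieved_accuracy`` is the maximum absolute leave-one-out m/z
    residual over the reference ions (Th); it estimates the mass accuracy
    on peaks not used in the fit.
    """

    a: float  # bins per sqrt(Th)
    t0: float  # bins
    reference_ions: list[tuple[str, float]] = field(default_factory=list)
    achieved_accuracy: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("calibration slope a must be positive")

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "t0": self.t0,
            "reference_ions": [[n, b] for n, b in self.reference_ions],
            "achieved_accuracy": self.achieved_accuracy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            a=d["a"],
            t0=d["t0"],
            reference_ions=[(n, b) for n, b in d.get("reference_ions", [])],
            achieved_accuracy=d.get("achieved_accuracy", 0.0),
        )


def mz_axis(model: CalibrationModel, bins: np.ndarray | float) -> np.ndarray:
    """m/z of (possibly fractional) bin positions: m/z = ((i − t0)/a)²."""
    b = np.asarray(bins, dtype=float)
    if np.any(b <= model.t0):
        raise ValueError("bin at or before t0 lies in the pre-pulse region")
    return ((b - model.t0) / model.a) ** 2


def bin_of_mz(model: CalibrationModel, mz: np.ndarray | float) -> np.ndarray:
    """Inverse of :func:`mz_axis`: i = a·√(m/z) + t0."""
    m = np.asarray(mz, dtype=float)
    if np.any(m < 0):
        raise ValueError("negative m/z")
    return model.a * np.sqrt(m) + model.t0


def centroid_bin(counts: np.ndarray, lo: int, hi: int,
                 n_top: int | None = None) -> float:
    """Sub-bin peak position inside counts[lo:hi] (fractional bin index).

    Fits a parabola to log-counts over the bins around the local maximum —
    exact for a Gaussian profile — and falls back to the intensity-weighted
    mean when counts are too sparse for the log fit.  By default the fit
    window is the contiguous half-maximum region (so it adapts to the peak
    width in bins); pass ``n_top`` to fix the window size instead.
    """
    seg = np.asarray(counts[lo:hi], dtype=float)
    if seg.size == 0 or seg.max() <= 0:
        raise ValueError("empty or all-zero segment")
    k = int(np.argmax(seg))
    if n_top is None:
        half_max = seg[k] / 2.0
        s = k
        while s > 0 and seg[s - 1] >= half_max:
            s -= 1
        e = k + 1
        while e < seg.size and seg[e] >= half_max:
            e += 1
        if e - s < 3:
            s, e = max(0, k - 1), min(seg.size, k + 2)
    else:
        half = n_top // 2
        s, e = max(0, k - half), min(seg.size, k + half + 1)
    window = seg[s:e]
    x = np.arange(s, e, dtype=float)
    if window.min() > 0 and window.size >= 3:
        coef = np.polyfit(x, np.log(window), 2)
        if coef[0] < 0:
            pos = -coef[1] / (2 * coef[0])
            if s - 1 <= pos <= e:
                return lo + pos
    w = np.clip(window, 0, None)
    return lo + float(np.sum(x * w) / np.sum(w))


def calibrate(
    spectrum: RawSpectrum,
    reference_ions: Sequence["IonFormula | str | float"],
    search_window: float = 0.3,
    initial: CalibrationModel | None = None,
    nominal_model: CalibrationModel | None = None,
) -> CalibrationModel:
    """Internal mass calibration from reference ions found in the spectrum.

    Each reference ion (formula or bare m/z) is located as the highest
    local maximum within ±``search_window`` Th of its theoretical m/z,
    using ``nominal_model`` (or ``initial``) as the provisional axis; its
    sub-bin centroid is paired with the theoretical m/z and the ToF law
    t = a·√(m/z) + t0 is fitted by linear least squares in √(m/z).

    ``achieved_accuracy`` is the maximum |m/z error| over leave-one-out
    refits (with exactly two references the fit is exact and the accuracy
    is reported as 0).
    """
    if nominal_model is None:
        nominal_model = initial
    if nominal_model is None:
        raise ValueError("a provisional calibration (nominal_model=) is required to locate references")
    refs: list[tuple[str, float]] = []
    for ion in reference_ions:
        if isinstance(ion, (int, float)):
            name, mz_th = f"{float(ion):.4f}", float(ion)
        else:
            f = parse_formula(ion) if isinstance(ion, str) else ion
            name, mz_th = f.hill(), monoisotopic_mz(f)
        refs.append((name, mz_th))
    if len(refs) < 2:
        raise ValueError("at least two reference ions are required")
    mzs = [m for _, m in refs]
    if len(set(np.round(mzs, 6))) < len(mzs):
        raise ValueError("degenerate (duplicate) reference ions")

    counts = np.asarray(spectrum.counts, dtype=float)
    matched: list[tuple[str, float, float]] = []  # name, theoretical mz, centroid bin
    for name, mz_th in refs:
        lo = int(np.floor(bin_of_mz(nominal_model, max(mz_th - search_window, 1e-9))))
        hi = int(np.ceil(bin_of_mz(nominal_model, mz_th + search_window))) + 1
        lo, hi = max(lo, 0), min(hi, counts.size)
        if hi - lo < 3 or counts[lo:hi].max() <= 0:
            raise ValueError(f"reference ion {name} not found near {mz_th:.4f} Th")
        seg = counts[lo:hi]
        med = np.median(seg)
        mad = np.median(np.abs(seg - med))
        # a usable reference must tower over the local count noise
        if seg.max() < med + 8.0 * (1.4826 * mad + 1.0):
            raise ValueError(f"reference ion {name} not above noise near {mz_th:.4f} Th")
        matched.append((name, mz_th, centroid_bin(counts, lo, hi)))

    def fit(pairs: list[tuple[float, float]]) -> tuple[float, float]:
        x = np.sqrt([m for m, _ in pairs])
        t = np.array([b for _, b in pairs])
        A = np.vstack([x, np.ones_like(x)]).T
        (a, t0), *_ = np.linalg.lstsq(A, t, rcond=None)
        return float(a), float(t0)

    pairs = [(m, b) for _, m, b in matched]
    a, t0 = fit(pairs)
    # leave-one-out accuracy
    acc = 0.0
    if len(pairs) > 2:
        for k in range(len(pairs)):
            rest = pairs[:k] + pairs[k + 1:]
            ak, t0k = fit(rest)
            m_true, b_obs = pairs[k]
            m_pred = ((b_obs - t0k) / ak) ** 2
            acc = max(acc, abs(m_pred - m_true))
    model = CalibrationModel(a=a, t0=t0, achieved_accuracy=acc)
    model.reference_ions = [(n, b) for (n, _, b) in matched]
    return model
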