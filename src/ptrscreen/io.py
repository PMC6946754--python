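"""Spectrum container formats and tabular readers/writers.

Raw runs are stored one-file-per-run either as HDF5 (the default; bin
counts as integer datasets with per-spectrum metadata and optional
calibration blocks) or as a plain-text directory (a JSON manifest plus
one counts CSV per spectrum) for environments where binary artifacts are
unwanted.  Both round-trip counts and metadata losslessly and are
self-describing (schema version, units).

The supplementary-emissions reader accepts per-genotype VOC emission
workbooks with configurable column names, returning a tidy
(line, ion, emission) frame.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tof import CalibrationModel, RawSpectrum

__all__ = [
    "SCHEMA_VERSION",
    "write_spectra",
    "read_spectra",
    "write_calibration",
    "read_calibration",
    "write_peak_tables",
    "read_peak_tables",
    "write_emissions",
    "read_emissions",
    "write_records",
    "read_records",
    "read_emissions_xlsx",
]

SCHEMA_VERSION = 1


def _atomic_replace(tmp: str, dest: str) -> None:
    os.replace(tmp, dest)


# ---------------------------------------------------------------------------
# HDF5 container

def _write_h5(path: Path, spectra: Sequence[RawSpectrum],
              calibrations: dict[str, CalibrationModel]) -> None:
    import h5py

    fd, tmp = tempfile.mkstemp(dir=str(path.parent), suffix=".h5.part")
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as f:
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.attrs["units"] = "counts per time-of-flight bin"
            f.attrs["n_spectra"] = len(spectra)
            for i, s in enumerate(spectra):
                g = f.create_group(f"spectrum_{i:05d}")
                g.create_dataset("counts", data=np.asarray(s.counts, dtype=np.int64),
                                 compression="gzip", compression_opts=4)
                g.attrs["n_extractions"] = int(s.n_extractions)
                g.attrs["dead_time_bins"] = int(s.dead_time_bins)
                g.attrs["duration"] = float(s.duration)
                g.attrs["vial_id"] = s.vial_id
                g.attrs["meta_json"] = json.dumps(s.meta, sort_keys=True)
                if s.vial_id in calibrations:
                    g.attrs["calibration_json"] = json.dumps(
                        calibrations[s.vial_id].to_dict(), sort_keys=True)
        _atomic_replace(tmp, str(path))
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _read_h5(path: Path) -> tuple[list[RawSpectrum], dict[str, CalibrationModel]]:
    import h5py

    spectra: list[RawSpectrum] = []
    calibs: dict[str, CalibrationModel] = {}
    with h5py.File(path, "r") as f:
        ver = int(f.attrs.get("schema_version", -1))
        if ver != SCHEMA_VERSION:
            raise ValueError(f"unsupported container schema version {ver}")
        n = int(f.attrs["n_spectra"])
        keys = sorted(k for k in f.keys() if k.startswith("spectrum_"))
        if len(keys) != n:
            raise ValueError(f"truncated container: expected {n} spectra, found {len(keys)}")
        for k in keys:
            g = f[k]
            s = RawSpectrum(
                counts=np.asarray(g["counts"][...], dtype=np.int64),
                n_extractions=int(g.attrs["n_extractions"]),
                dead_time_bins=int(g.attrs["dead_time_bins"]),
                duration=float(g.attrs["duration"]),
                vial_id=str(g.attrs["vial_id"]),
                meta=json.loads(g.attrs.get("meta_json", "{}")),
            )
            spectra.append(s)
            if "calibration_json" in g.attrs:
                calibs[s.vial_id] = CalibrationModel.from_dict(
                    json.loads(g.attrs["calibration_json"]))
    return spectra, calibs


# ---------------------------------------------------------------------------
# plain-text directory container

def _write_text(root: Path, spectra: Sequence[RawSpectrum],
                calibrations: dict[str, CalibrationModel]) -> None:
    root.mkdir(parents=True, exist_ok=True)
    manifest = {"schema_version": SCHEMA_VERSION,
                "units": "counts per time-of-flight bin",
                "spectra": []}
    for i, s in enumerate(spectra):
        fname = f"spectrum_{i:05d}.csv"
        entry = {
            "file": fname,
            "n_extractions": int(s.n_extractions),
            "dead_time_bins": int(s.dead_time_bins),
            "duration": float(s.duration),
            "vial_id": s.vial_id,
            "meta": s.meta,
        }
        if s.vial_id in calibrations:
            entry["calibration"] = calibrations[s.vial_id].to_dict()
        manifest["spectra"].append(entry)
        # sparse bin,count rows keep even long spectra compact
        counts = np.asarray(s.counts)
        nz = np.nonzero(counts)[0]
        df = pd.DataFrame({"bin": nz, "count": counts[nz]})
        df.attrs["n_bins"] = counts.size
        entry["n_bins"] = int(counts.size)
        df.to_csv(root / fname, index=False)
    tmp = root / "manifest.json.part"
    tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    _atomic_replace(str(tmp), str(root / "manifest.json"))


def _read_text(root: Path) -> tuple[list[RawSpectrum], dict[str, CalibrationModel]]:
    mpath = root / "manifest.json"
    if not mpath.exists():
        raise ValueError(f"no manifest.json in {root}")
    manifest = json.loads(mpath.read_text())
    ver = manifest.get("schema_version", -1)
    if ver != SCHEMA_VERSION:
        raise ValueError(f"unsupported container schema version {ver}")
    spectra: list[RawSpectrum] = []
    calibs: dict[str, CalibrationModel] = {}
    for entry in manifest["spectra"]:
        fpath = root / entry["file"]
        if not fpath.exists():
            raise ValueError(f"truncated container: missing {entry['file']}")
        df = pd.read_csv(fpath)
        counts = np.zeros(int(entry["n_bins"]), dtype=np.int64)
        counts[df["bin"].to_numpy()] = df["count"].to_numpy()
        s = RawSpectrum(
            counts=counts,
            n_extractions=int(entry["n_extractions"]),
            dead_time_bins=int(entry["dead_time_bins"]),
            duration=float(entry["duration"]),
            vial_id=str(entry["vial_id"]),
            meta=entry.get("meta", {}),
        )
        spectra.append(s)
        if "calibration" in entry:
            calibs[s.vial_id] = CalibrationModel.from_dict(entry["calibration"])
    return spectra, calibs


def write_spectra(path: "str | Path", spectra: Sequence[RawSpectrum],
                  calibrations: dict[str, CalibrationModel] | None = None) -> None:
    """Write a run container; ``.h5`` suffix selects HDF5, else text dir."""
    p = Path(path)
    calibs = calibrations or {}
    if p.suffix in (".h5", ".hdf5"):
        _write_h5(p, spectra, calibs)
    else:
        _write_text(p, spectra, calibs)


def read_spectra(path: "str | Path") -> tuple[list[RawSpectrum], dict[str, CalibrationModel]]:
    """Read a run container written by :func:`write_spectra`."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if p.is_file():
        return _read_h5(p)
    return _read_text(p)


def write_calibration(path: "str | Path", model: CalibrationModel) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1, sort_keys=True))


def read_calibration(path: "str | Path") -> CalibrationModel:
    return CalibrationModel.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# tabular round-trips (CSV)

def write_peak_tables(path: "str | Path", tables) -> None:
    """All peak tables of a run as one CSV, bit-stable row order."""
    frames = [t.to_dataframe() for t in tables]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["vial", "mz", "area_per_extraction", "height", "sigma",
                 "wing_frac", "formula", "delta_mz"])
    df.to_csv(path, index=False)


def read_peak_tables(path: "str | Path"):
    """Rebuild :class:`~ptrscreen.peaks.PeakTable` objects from the CSV."""
    from .peaks import Peak, PeakTable

    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    out = []
    for vial, sub in df.groupby("vial", sort=False):
        peaks = [
            Peak(center_mz=r.mz, area=r.area_per_extraction, height=r.height,
                 width_sigma=r.sigma, wing_frac=r.wing_frac)
            for r in sub.itertuples()
        ]
        out.append(PeakTable(vial_id=str(vial), peaks=peaks))
    return out


def write_records(path: "str | Path", records) -> None:
    pd.DataFrame([{
        "vial": r.vial_id, "line": r.line_id, "genotype": r.genotype,
        "block": r.block, "fw_mg": r.fresh_weight, "order": r.order,
    } for r in records]).to_csv(path, index=False)


def read_records(path: "str | Path"):
    from .quant import SampleRecord

    df = pd.read_csv(path)
    return [SampleRecord(
        vial_id=str(r.vial), line_id=str(r.line), genotype=str(r.genotype),
        block=int(r.block),
        fresh_weight=None if pd.isna(r.fw_mg) else float(r.fw_mg),
        order=int(r.order)) for r in df.itertuples()]


def write_emissions(path: "str | Path", table) -> None:
    """Emission table in long form: vial, mz, ppbv, ppbv_per_mgfw, below_lod."""
    rows = []
    fw = table.samples.set_index("vial")["fw_mg"]
    for vial in table.ppbv.index:
        for mz in table.ppbv.columns:
            norm = (table.normalized.loc[vial, mz]
                    if vial in table.normalized.index else np.nan)
            rows.append({"vial": vial, "mz": mz,
                         "ppbv": table.ppbv.loc[vial, mz],
                         "ppbv_per_mgfw": norm,
                         "below_lod": bool(table.below_lod.loc[vial, mz])})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_emissions(path: "str | Path", records) -> "object":
    """Rebuild an :class:`~ptrscreen.quant.EmissionTable` from the long CSV."""
    from .quant import EmissionTable

    df = pd.read_csv(path)
    ppbv = df.pivot(index="vial", columns="mz", values="ppbv")
    norm = df.pivot(index="vial", columns="mz", values="ppbv_per_mgfw").dropna(how="all")
    lod = df.pivot(index="vial", columns="mz", values="below_lod").astype(bool)
    samples = pd.DataFrame([{
        "vial": r.vial_id, "line": r.line_id, "genotype": r.genotype,
        "block": r.block, "fw_mg": r.fresh_weight, "order": r.order,
    } for r in records])
    order = [r.vial_id for r in records if r.vial_id in ppbv.index]
    return EmissionTable(ppbv=ppbv.loc[order], normalized=norm.loc[[v for v in order if v in norm.index]],
                         below_lod=lod.loc[order], samples=samples)


# ---------------------------------------------------------------------------
# supplementary emissions workbook

def read_emissions_xlsx(
    path: "str | Path",
    column_map: dict[str, str] | None = None,
    sheet: "int | str" = 0,
) -> pd.DataFrame:
    """Read a per-genotype VOC emissions workbook into a tidy frame.

    The layout of such supplements varies, so column names are mapped via
    ``column_map`` with keys ``line``, ``ion`` and ``emission`` (defaults
    try common spellings).  Wide layouts — one row per line, one column
    per ion m/z — are melted automatically: any numeric-named column is
    treated as an ion.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    cmap = {"line": "line", "ion": "ion", "emission": "emission"}
    if column_map:
        cmap.update(column_map)
    lower = {str(c).strip().lower(): c for c in df.columns}

    def find(key: str, *aliases: str):
        for cand in (cmap[key], *aliases):
            if cand.lower() in lower:
                return lower[cand.lower()]
        return None

    line_col = find("line", "line id", "genotype", "sample")
    ion_col = find("ion", "m/z", "mz", "compound")
    em_col = find("emission", "ppbv/mgfw", "value", "concentration")
    if line_col is not None and ion_col is not None and em_col is not None:
        out = df[[line_col, ion_col, em_col]].copy()
        out.columns = ["line", "ion", "emission"]
        return out
    if line_col is not None:
        ion_cols = []
        for c in df.columns:
            if c == line_col:
                continue
            try:
                float(str(c))
                ion_cols.append(c)
            except ValueError:
                continue
        if ion_cols:
            out = df.melt(id_vars=[line_col], value_vars=ion_cols,
                          var_name="ion", value_name="emission")
            out = out.rename(columns={line_col: "line"})
            out["ion"] = out["ion"].astype(float)
            return out
    raise ValueError(
        "could not identify line/ion/emission columns; pass column_map="
        "{'line': ..., 'ion': ..., 'emission': ...}"
    )
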