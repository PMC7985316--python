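"""File formats and run configuration.

DTOF and IRF files are two-column delimited text (time_ps, counts) with a
single commented JSON header line carrying the metadata; spectra are CSV
with a commented JSON header; a Monte Carlo library is a directory of
delimited-text curves plus a JSON manifest.  All round trips are lossless
(counts bit-exact, floats at full precision via %.17g).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .core import SlabGeometry, TimeGrid, TPSF
from .instrument import IRF, DTOFRecord
from .inversion import OpticalSpectrum
from .photon_transport import MCLibrary

__all__ = [
    "read_dtof",
    "write_dtof",
    "read_irf",
    "write_irf",
    "read_spectrum",
    "write_spectrum",
    "save_library",
    "load_library",
    "RunConfig",
    "load_config",
]


def _grid_to_dict(grid: TimeGrid) -> dict:
    return {"t0": grid.t0, "dt": grid.dt, "n_bins": grid.n_bins}


def _grid_from_dict(d: dict) -> TimeGrid:
    return TimeGrid(float(d["t0"]), float(d["dt"]), int(d["n_bins"]))


def _read_header(path: Path) -> dict:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ValueError(f"{path}: line 1: missing commented JSON header")
    try:
        return json.loads(first.lstrip("#").strip())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: line 1: malformed JSON header: {exc}") from exc


def write_dtof(path: Union[str, Path], record: DTOFRecord) -> None:
    path = Path(path)
    header = {
        "wavelength": record.wavelength,
        "acquisition_time": record.acquisition_time,
        "timestamp": record.timestamp,
        "background_rate": record.background_rate,
        "grid": _grid_to_dict(record.grid),
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        for t, c in zip(record.grid.centers, record.counts):
            fh.write(f"{t:.17g}\t{int(c)}\n")


def read_dtof(path: Union[str, Path]) -> DTOFRecord:
    path = Path(path)
    header = _read_header(path)
    for key in ("wavelength", "grid"):
        if key not in header:
            raise ValueError(f"{path}: header missing required key {key!r}")
    grid = _grid_from_dict(header["grid"])
    counts = np.empty(grid.n_bins, dtype=np.int64)
    with open(path) as fh:
        fh.readline()
        n = 0
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            try:
                value = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad count {fields[1]!r}") from exc
            if value < 0:
                raise ValueError(f"{path}: line {lineno}: negative count")
            if n >= grid.n_bins:
                raise ValueError(f"{path}: line {lineno}: more rows than header n_bins")
            counts[n] = value
            n += 1
    if n != grid.n_bins:
        raise ValueError(f"{path}: expected {grid.n_bins} rows, found {n}")
    return DTOFRecord(
        grid=grid,
        counts=counts,
        wavelength=float(header["wavelength"]),
        acquisition_time=float(header.get("acquisition_time", 1.0)),
        timestamp=float(header.get("timestamp", 0.0)),
        background_rate=float(header.get("background_rate", 0.0)),
    )


def write_irf(path: Union[str, Path], irf: IRF) -> None:
    path = Path(path)
    header = {
        "fwhm": irf.fwhm,
        "peak_position": irf.peak_position,
        "wavelength": irf.wavelength,
        "grid": _grid_to_dict(irf.grid),
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        for t, v in zip(irf.grid.centers, irf.values):
            fh.write(f"{t:.17g}\t{v:.17g}\n")


def read_irf(path: Union[str, Path]) -> IRF:
    path = Path(path)
    header = _read_header(path)
    grid = _grid_from_dict(header["grid"])
    values = np.loadtxt(path, comments="#", usecols=1)
    if values.shape != (grid.n_bins,):
        raise ValueError(f"{path}: expected {grid.n_bins} rows")
    return IRF(
        grid=grid,
        values=values,
        fwhm=float(header["fwhm"]),
        peak_position=float(header["peak_position"]),
        wavelength=header.get("wavelength"),
    )


_SPECTRUM_COLUMNS = ["wavelength_nm", "mua_cm1", "musp_cm1", "mua_err", "musp_err"]


def write_spectrum(path: Union[str, Path], spectrum: OpticalSpectrum) -> None:
    path = Path(path)
    n = len(spectrum)
    frame = pd.DataFrame(
        {
            "wavelength_nm": spectrum.wavelengths,
            "mua_cm1": spectrum.mua,
            "musp_cm1": spectrum.mus_prime,
            "mua_err": spectrum.mua_err if spectrum.mua_err is not None else np.full(n, np.nan),
            "musp_err": spectrum.musp_err if spectrum.musp_err is not None else np.full(n, np.nan),
        }
    )
    with open(path, "w") as fh:
        fh.write("# " + json.dumps({"timestamp": spectrum.timestamp}) + "\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_spectrum(path: Union[str, Path]) -> OpticalSpectrum:
    path = Path(path)
    header = _read_header(path)
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in _SPECTRUM_COLUMNS[:3] if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    wl = frame["wavelength_nm"].to_numpy(float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError(f"{path}: wavelengths must be strictly increasing")
    return OpticalSpectrum(
        wavelengths=wl,
        mua=frame["mua_cm1"].to_numpy(float),
        mus_prime=frame["musp_cm1"].to_numpy(float),
        mua_err=frame["mua_err"].to_numpy(float) if "mua_err" in frame else None,
        musp_err=frame["musp_err"].to_numpy(float) if "musp_err" in frame else None,
        timestamp=float(header.get("timestamp", 0.0)),
    )


# ---------------------------------------------------------------------------
# Monte Carlo library persistence (directory of text curves + manifest)


def save_library(library: MCLibrary, directory: Union[str, Path]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    g = library.geometry
    manifest = {
        "geometry": {
            "thickness": g.thickness,
            "n_sample": g.n_sample,
            "n_external": g.n_external,
            "detector_radius": g.detector_radius,
        },
        "grid": _grid_to_dict(library.grid),
        "grid_mus_prime": [float(x) for x in library.grid_mus_prime],
        "n_photons": library.n_photons,
        "seed": library.seed,
        "seeds": [int(s) for s in library.seeds],
        "curves": [f"curve_{i:03d}.tsv" for i in range(len(library.curves))],
        "tallies": [c.tallies for c in library.curves],
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    for name, curve in zip(manifest["curves"], library.curves):
        np.savetxt(
            directory / name,
            np.column_stack([curve.grid.centers, curve.values]),
            fmt="%.17g",
            delimiter="\t",
            header=json.dumps({"mus_prime": curve.mus_prime}),
        )


def load_library(directory: Union[str, Path]) -> MCLibrary:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    g = manifest["geometry"]
    geometry = SlabGeometry(
        thickness=g["thickness"],
        n_sample=g["n_sample"],
        n_external=g["n_external"],
        detector_radius=g["detector_radius"],
    )
    grid = _grid_from_dict(manifest["grid"])
    curves = []
    for name, mus, tallies in zip(
        manifest["curves"], manifest["grid_mus_prime"], manifest["tallies"]
    ):
        values = np.loadtxt(directory / name, usecols=1)
        curves.append(
            TPSF(
                grid=grid,
                values=values,
                mus_prime=float(mus),
                n_sample=geometry.n_sample,
                mua=0.0,
                photons_launched=manifest["n_photons"],
                null_absorption=True,
                tallies=tallies,
            )
        )
    return MCLibrary(
        geometry=geometry,
        grid_mus_prime=np.array(manifest["grid_mus_prime"], dtype=float),
        curves=curves,
        n_photons=int(manifest["n_photons"]),
        seed=int(manifest["seed"]),
        seeds=np.array(manifest["seeds"], dtype=np.uint32),
    )


# ---------------------------------------------------------------------------
# Run configuration (schema-validated; unknown keys rejected)


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    thickness: float = 1.0
    n_sample: float = 1.41
    n_external: float = 1.5
    detector_radius: float = 0.5


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t0: float = 0.0
    dt: float = 2.5
    n_bins: int = 4096


class LibraryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mus_min: float = 1.0
    mus_max: float = 70.0
    n_nodes: int = 25
    n_photons: int = 10**6
    seed: int = 1
    cache_path: Optional[str] = None


class FitBlockConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rise_fraction: float = 0.80
    fall_fraction: float = 0.01
    objective: str = "poisson-deviance"
    max_iterations: int = 400
    background: Union[str, float] = "estimate"
    compute_uncertainties: bool = False


class FeaturesConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 0.05
    lambda0: float = 650.0
    hb_band: tuple = (720.0, 800.0)
    new_peak_band: tuple = (810.0, 870.0)
    water_band: tuple = (940.0, 1010.0)


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    target_temperature: float = 105.0
    ramp_duration: float = 180.0
    hold_duration: float = 600.0
    sampling_mode: str = "broadband"
    cooling: bool = False
    counts_per_curve: float = 1.0e6
    irf_fwhm: float = 80.0
    irf_shape: str = "gaussian"
    irf_peak_position: float = 300.0
    n_samples: int = 1
    seed: int = 1
    # optional overrides of the protocol's acquisition schedule
    timestamps: Optional[list] = None
    wavelengths: Optional[list] = None


class RunConfig(BaseModel):
    """Umbrella configuration for the CLI stages."""

    model_config = ConfigDict(extra="forbid")
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    library: LibraryConfig = Field(default_factory=LibraryConfig)
    fit: FitBlockConfig = Field(default_factory=FitBlockConfig)
    features: FeaturesConfig = Field(default_factory=FeaturesConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    logging_level: str = "INFO"
    output_directory: str = "."

    def slab_geometry(self) -> SlabGeometry:
        return SlabGeometry(**self.geometry.model_dump())

    def time_grid(self) -> TimeGrid:
        return TimeGrid(**self.grid.model_dump())


def load_config(path: Union[str, Path]) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(fh)
        else:
            data = json.load(fh)
    return RunConfig.model_validate(data or {})
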