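"""Domain types and I/O for single-cell Raman spectra (SCRS) and ramanomes.

A *ramanome* is the collection of single-cell Raman spectra sampled from a
cell population.  Spectra are stored as wavenumber/intensity pairs on a
strictly ascending axis in cm^-1; collections may share a common axis
(matrix layout on disk) or keep per-cell axes (one file per cell plus a
manifest).

File dialect: UTF-8 text, comma- or tab-delimited (auto-detected), ``#``
comment lines skipped.  Two layouts are understood:

* two-column: ``wavenumber, intensity`` — one cell per file;
* matrix: first column ``wavenumber``, one additional column per cell,
  with cell ids in the header row.

A manifest CSV (columns ``cell_id, sample_id, timepoint_h, d2o_fraction,
species_label, replicate``) attaches acquisition metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, RamavitError

__all__ = [
    "Band",
    "Spectrum",
    "SpectrumMeta",
    "Ramanome",
    "read_ramanome",
    "write_ramanome",
    "resample",
]

_MANIFEST_COLUMNS = [
    "cell_id",
    "sample_id",
    "timepoint_h",
    "d2o_fraction",
    "species_label",
    "replicate",
]


@dataclass(frozen=True)
class Band:
    """A closed wavenumber interval [lo_cm1, hi_cm1] in cm^-1."""

    name: str
    lo_cm1: float
    hi_cm1: float

    def __post_init__(self):
        if not self.lo_cm1 < self.hi_cm1:
            raise RamavitError(
                f"band {self.name!r}: lo_cm1 ({self.lo_cm1}) must be < hi_cm1 ({self.hi_cm1})"
            )

    def mask(self, wavenumbers: np.ndarray) -> np.ndarray:
        return (wavenumbers >= self.lo_cm1) & (wavenumbers <= self.hi_cm1)


@dataclass
class SpectrumMeta:
    """Per-cell acquisition metadata.

    ``extra`` carries non-persisted bookkeeping (e.g. ground truth attached
    by the synthetic generator); it is not written to manifests.
    """

    cell_id: str = ""
    sample_id: str = ""
    timepoint_h: float = 0.0
    d2o_fraction: float = 0.0
    species_label: str | None = None
    replicate: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.timepoint_h < 0:
            raise RamavitError("timepoint_h must be nonnegative")
        if not 0.0 <= self.d2o_fraction <= 1.0:
            raise RamavitError("d2o_fraction must lie in [0, 1]")


@dataclass
class Spectrum:
    """One cell's wavenumber-intensity trace."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise RamavitError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise RamavitError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.intensities.size} intensities"
            )
        if self.wavenumbers.size < 2:
            raise RamavitError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise RamavitError("axis not ascending")
        if not np.all(np.isfinite(self.intensities)):
            raise RamavitError("intensities must be finite")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def crop(self, lo: float, hi: float) -> "Spectrum":
        m = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        if m.sum() < 2:
            raise RamavitError(f"crop window [{lo}, {hi}] leaves fewer than 2 points")
        return Spectrum(self.wavenumbers[m], self.intensities[m], self.meta)


@dataclass
class Ramanome:
    """A labelled collection of spectra, optionally on a shared axis."""

    spectra: list[Spectrum] = field(default_factory=list)
    axis: np.ndarray | None = None

    def __post_init__(self):
        if self.axis is not None:
            self.axis = np.asarray(self.axis, dtype=float)
            for s in self.spectra:
                if s.wavenumbers.size != self.axis.size or not np.allclose(
                    s.wavenumbers, self.axis
                ):
                    raise RamavitError(
                        f"spectrum {s.meta.cell_id!r} does not conform to the shared axis"
                    )
        ids = [s.meta.cell_id for s in self.spectra if s.meta.cell_id]
        if len(ids) != len(set(ids)):
            raise RamavitError("cell_id values must be unique within a ramanome")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def common_axis(self) -> np.ndarray | None:
        """The shared wavenumber grid, inferred if not set explicitly."""
        if self.axis is not None:
            return self.axis
        if not self.spectra:
            return None
        first = self.spectra[0].wavenumbers
        for s in self.spectra[1:]:
            if s.wavenumbers.size != first.size or not np.array_equal(
                s.wavenumbers, first
            ):
                return None
        return first

    def intensity_matrix(self) -> np.ndarray:
        """(n_cells, n_points) matrix; requires a common axis."""
        if self.common_axis() is None:
            raise RamavitError("ramanome has no common axis")
        return np.vstack([s.intensities for s in self.spectra])


# ---------------------------------------------------------------------------
# resampling

def resample(spectrum: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise RamavitError("grid must be a non-empty 1-D sequence")
    if not np.all(np.diff(grid) > 0):
        raise RamavitError("grid must be strictly ascending")
    w = spectrum.wavenumbers
    if grid[0] < w[0] or grid[-1] > w[-1]:
        raise RamavitError(
            f"grid [{grid[0]}, {grid[-1]}] extends outside data range [{w[0]}, {w[-1]}]"
        )
    vals = np.interp(grid, w, spectrum.intensities)
    return Spectrum(grid.copy(), vals, spectrum.meta)


# ---------------------------------------------------------------------------
# parsing helpers

def _detect_sep(line: str) -> str:
    return "\t" if "\t" in line else ","


def _data_lines(path: Path):
    """Yield (lineno, stripped_line) skipping comments and blanks."""
    with open(path, "r", encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield i, line


def _parse_table(path: Path) -> tuple[list[str] | None, np.ndarray]:
    """Parse a delimited numeric table, returning (header, values)."""
    rows: list[list[float]] = []
    header: list[str] | None = None
    sep = None
    ncol = None
    for lineno, line in _data_lines(path):
        if sep is None:
            sep = _detect_sep(line)
        fields = [f.strip() for f in line.split(sep)]
        if ncol is None:
            ncol = len(fields)
        elif len(fields) != ncol:
            raise ParseError(
                f"malformed row: expected {ncol} fields, got {len(fields)}",
                path=path,
                line=lineno,
            )
        try:
            rows.append([float(f) for f in fields])
        except ValueError:
            if header is None and not rows:
                header = fields
            else:
                raise ParseError("malformed row: non-numeric field", path=path, line=lineno)
    if not rows:
        return header, np.empty((0, ncol or 0))
    return header, np.asarray(rows, dtype=float)


def _read_manifest(path: Path) -> dict[str, SpectrumMeta]:
    try:
        df = pd.read_csv(path, comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read manifest: {exc}", path=path)
    if "cell_id" not in df.columns:
        raise ParseError("manifest lacks a cell_id column", path=path)
    out: dict[str, SpectrumMeta] = {}
    for _, row in df.iterrows():
        def _get(col, default=""):
            v = row.get(col)
            return default if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v) else v

        cid = str(_get("cell_id"))
        out[cid] = SpectrumMeta(
            cell_id=cid,
            sample_id=str(_get("sample_id")),
            timepoint_h=float(_get("timepoint_h", 0.0) or 0.0),
            d2o_fraction=float(_get("d2o_fraction", 0.0) or 0.0),
            species_label=(str(_get("species_label")) or None),
            replicate=(str(_get("replicate")) or None),
        )
    return out


def _spectrum_from_columns(w, y, path, cell_id) -> Spectrum:
    if not np.all(np.diff(w) > 0):
        raise ParseError("axis not ascending", path=path)
    try:
        return Spectrum(w, y, SpectrumMeta(cell_id=cell_id))
    except RamavitError as exc:
        raise ParseError(str(exc), path=path)


# ---------------------------------------------------------------------------
# reading

def read_ramanome(path, manifest=None) -> Ramanome:
    """Read a ramanome from a spectral table, matrix file, or directory.

    ``path`` may be a two-column per-cell file, a matrix file (first column
    wavenumbers, one column per cell), or a directory of per-cell files.
    ``manifest`` (CSV) attaches :class:`SpectrumMeta`; missing fields
    default to empty values.
    """
    path = Path(path)
    meta_map: dict[str, SpectrumMeta] = {}
    if manifest is not None:
        meta_map = _read_manifest(Path(manifest))

    spectra: list[Spectrum] = []
    axis = None
    if path.is_dir():
        files = sorted(
            p
            for p in path.iterdir()
            if p.suffix.lower() in {".csv", ".tsv", ".txt"}
            and "manifest" not in p.name.lower()
        )
        if manifest is None:
            cand = path / "manifest.csv"
            if cand.exists():
                meta_map = _read_manifest(cand)
        for f in files:
            spectra.extend(_read_single_file(f))
    else:
        spectra = _read_single_file(path)
        if len(spectra) > 1:
            axis = spectra[0].wavenumbers

    for s in spectra:
        if s.meta.cell_id in meta_map:
            s.meta = meta_map[s.meta.cell_id]
    return Ramanome(spectra, axis=axis)


def _read_single_file(path: Path) -> list[Spectrum]:
    header, vals = _parse_table(path)
    if vals.size == 0:
        if header is not None:
            return []  # header-only file: empty ramanome
        raise ParseError("no data rows", path=path)
    ncol = vals.shape[1]
    if ncol < 2:
        raise ParseError("need at least 2 columns (wavenumber, intensity)", path=path)
    w = vals[:, 0]
    if ncol == 2:
        cell_id = path.stem
        if header is not None and len(header) == 2 and header[1].lower() not in (
            "intensity",
            "counts",
        ):
            cell_id = header[1]
        return [_spectrum_from_columns(w, vals[:, 1], path, cell_id=cell_id)]
    names = (
        [str(h) for h in header[1:]]
        if header is not None and len(header) == ncol
        else [f"cell{i}" for i in range(1, ncol)]
    )
    return [
        _spectrum_from_columns(w, vals[:, j + 1], path, cell_id=names[j])
        for j in range(ncol - 1)
    ]


# ---------------------------------------------------------------------------
# writing

def _meta_row(m: SpectrumMeta) -> dict:
    return {
        "cell_id": m.cell_id,
        "sample_id": m.sample_id,
        "timepoint_h": m.timepoint_h,
        "d2o_fraction": m.d2o_fraction,
        "species_label": m.species_label or "",
        "replicate": m.replicate or "",
    }


def write_manifest(r: Iterable[Spectrum] | Ramanome, path) -> None:
    rows = [_meta_row(s.meta) for s in r]
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, index=False)


def write_ramanome(r: Ramanome, path) -> None:
    """Write a ramanome; matrix file when a common axis exists, otherwise a
    directory of per-cell two-column files.  A manifest is written alongside
    either layout so that metadata round-trips."""
    path = Path(path)
    axis = r.common_axis()
    if axis is not None or not len(r):
        path.parent.mkdir(parents=True, exist_ok=True)
        cols = {"wavenumber": axis if axis is not None else np.empty(0)}
        for s in r:
            cols[s.meta.cell_id or f"cell{id(s)}"] = s.intensities
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
        write_manifest(r, path.with_suffix(".manifest.csv"))
    else:
        path.mkdir(parents=True, exist_ok=True)
        for s in r:
            pd.DataFrame(
                {"wavenumber": s.wavenumbers, "intensity": s.intensities}
            ).to_csv(path / f"{s.meta.cell_id}.csv", index=False, float_format="%.12g")
        write_manifest(r, path / "manifest.csv")


def read_back(path) -> Ramanome:
    """Convenience: read a ramanome written by :func:`write_ramanome`."""
    path = Path(path)
    if path.is_dir():
        return read_ramanome(path)
    manifest = path.with_suffix(".manifest.csv")
    return read_ramanome(path, manifest if manifest.exists() else None)
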