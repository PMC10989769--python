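"""Viability and vitality statistics from D2O-probed single-cell Raman spectra.

Live cells assimilate heavy water into newly synthesised biomolecules,
which replaces C-H bonds with C-D bonds and raises a C-D band at
2040-2300 cm^-1.  The statistics built on that signal:

* **CDR** (C-D ratio): ``A_CD / (A_CD + A_CH)`` with band areas integrated
  over the C-D (2040-2300 cm^-1) and C-H (2800-3100 cm^-1) bands.  Bounded
  in [0, 1]; a proxy for cumulative metabolic activity.
* **MAL** (metabolic activity level): ``CDR_sample - CDR_0h``, the CDR gain
  over the unlabelled 0-h reference.  ``MAL > 0`` calls a cell live,
  ``MAL <= 0`` dead.
* **rMAL**: MAL under the assayed condition relative to MAL under the
  optimal (log-phase) condition; 1 at the optimum, 0 at the 0-h baseline.
* **HI** (heterogeneity index): the sample standard deviation of MAL across
  cells — the degree of vitality synchronisation in the population.

Counting converts microscopy field counts to absolute concentrations
(CFU/g-equivalent, hemocytometer convention) and splits the live count
across species by their estimated proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import RamavitError
from .preprocess import CH_BAND, SILENT_BAND
from .spectra import Band, Ramanome, Spectrum

__all__ = [
    "CD_BAND",
    "CdrBands",
    "VitalityRecord",
    "VitalitySummary",
    "CountResult",
    "band_area",
    "compute_cdr",
    "compute_mal",
    "compute_rmal",
    "call_viability",
    "summarize_sample",
    "total_count_from_fields",
    "live_count",
    "viable_rate",
    "species_resolved_counts",
    "survival_rate",
    "plateau_time",
    "cdr_of_ramanome",
    "analyze_sample",
]

CD_BAND = Band("C-D", 2040.0, 2300.0)


@dataclass(frozen=True)
class CdrBands:
    cd_band: Band = field(default_factory=lambda: CD_BAND)
    ch_band: Band = field(default_factory=lambda: CH_BAND)

    def __post_init__(self):
        if self.cd_band.hi_cm1 > self.ch_band.lo_cm1:
            raise RamavitError("C-D band must lie entirely below the C-H band")


@dataclass(frozen=True)
class VitalityRecord:
    cell_id: str
    cdr: float
    mal: float
    live: bool


@dataclass(frozen=True)
class VitalitySummary:
    sample_id: str
    n_cells: int
    viable_rate: float
    mal_mean: float
    hi: float | None
    rmal: float | None = None


@dataclass(frozen=True)
class CountResult:
    total_count: float
    live_count: float
    dilution_factor: float
    mass_g: float
    per_species: dict[str, float] | None = None

    def __post_init__(self):
        if self.live_count > self.total_count * (1 + 1e-9):
            raise RamavitError("live_count cannot exceed total_count")
        if self.dilution_factor <= 0 or self.mass_g <= 0:
            raise RamavitError("dilution_factor and mass_g must be positive")
        if self.per_species is not None:
            tot = sum(self.per_species.values())
            if self.live_count > 0 and abs(tot - self.live_count) > 5e-3 * self.live_count:
                raise RamavitError("per-species counts must sum to live_count (0.5%)")


# ---------------------------------------------------------------------------
# per-cell statistics

def band_area(s: Spectrum, b: Band) -> float:
    """Trapezoidal band integral of the (negative-clipped) intensity."""
    w = s.wavenumbers
    if b.lo_cm1 < w[0] or b.hi_cm1 > w[-1]:
        raise RamavitError(
            f"band {b.name!r} [{b.lo_cm1}, {b.hi_cm1}] outside axis [{w[0]}, {w[-1]}]"
        )
    m = b.mask(w)
    if m.sum() < 2:
        raise RamavitError(f"band {b.name!r} covers fewer than 2 grid points")
    y = np.clip(s.intensities[m], 0.0, None)
    return float(np.trapezoid(y, w[m]))


def compute_cdr(
    s: Spectrum, bands: CdrBands | None = None, noise_floor: bool = True
) -> float:
    """C-D ratio A_CD / (A_CD + A_CH); 0 when both areas vanish.

    Because band integration clips negative residual noise, an empty band
    still accumulates a small positive pedestal.  With ``noise_floor``
    (default) the mean clipped level of the cell-silent region
    (1800-2040 cm^-1, which carries no Raman bands) is measured and its
    contribution subtracted from both band areas — exactly zero for a
    noise-free spectrum.  Skipped silently when the spectrum does not
    cover the silent region.
    """
    bands = bands or CdrBands()
    a_cd = band_area(s, bands.cd_band)
    a_ch = band_area(s, bands.ch_band)
    if noise_floor:
        m = SILENT_BAND.mask(s.wavenumbers)
        if m.sum() >= 10:
            pedestal = float(np.mean(np.clip(s.intensities[m], 0.0, None)))
            a_cd = max(0.0, a_cd - pedestal * (bands.cd_band.hi_cm1 - bands.cd_band.lo_cm1))
            a_ch = max(0.0, a_ch - pedestal * (bands.ch_band.hi_cm1 - bands.ch_band.lo_cm1))
    denom = a_cd + a_ch
    if denom == 0.0:
        return 0.0
    return a_cd / denom


def compute_mal(cdr_sample: float, cdr_0h: float) -> float:
    """Metabolic activity level: CDR gain over the 0-h reference."""
    for v in (cdr_sample, cdr_0h):
        if not 0.0 <= v <= 1.0:
            raise RamavitError(f"CDR values must lie in [0, 1], got {v}")
    return cdr_sample - cdr_0h


def compute_rmal(cdr_sample: float, cdr_control: float, cdr_0h: float) -> float:
    """MAL relative to the optimal-condition (log-phase) control."""
    if cdr_control <= cdr_0h:
        raise RamavitError("degenerate control: cdr_control must exceed cdr_0h")
    return (cdr_sample - cdr_0h) / (cdr_control - cdr_0h)


def call_viability(mal: float, margin: float = 0.0) -> bool:
    """Live iff MAL strictly exceeds ``margin`` (default 0)."""
    return mal > margin


# ---------------------------------------------------------------------------
# sample-level statistics

def summarize_sample(
    records: Sequence[VitalityRecord],
    cdr_control: float | None = None,
    cdr_0h: float = 0.0,
    sample_id: str = "",
) -> VitalitySummary:
    """Aggregate per-cell records into the sample-level summary.

    HI is the n-1 (sample) standard deviation of MAL, reported only for
    n >= 2; rMAL is computed from the mean CDR when a log-phase control
    CDR is supplied.
    """
    if not records:
        raise RamavitError("summarize_sample needs at least one record")
    mals = np.array([r.mal for r in records], dtype=float)
    n = len(records)
    live = sum(r.live for r in records)
    hi = float(np.std(mals, ddof=1)) if n >= 2 else None
    rmal = None
    if cdr_control is not None:
        mean_cdr = float(np.mean([r.cdr for r in records]))
        rmal = compute_rmal(mean_cdr, cdr_control, cdr_0h)
    return VitalitySummary(
        sample_id=sample_id,
        n_cells=n,
        viable_rate=live / n,
        mal_mean=float(mals.mean()),
        hi=hi,
        rmal=rmal,
    )


# ---------------------------------------------------------------------------
# counting

def total_count_from_fields(
    cells_per_field: Sequence[float],
    field_factor: float,
    dilution: float,
    mass_g: float,
) -> float:
    """Hemocytometer-style absolute count (CFU/g-equivalent).

    ``field_factor`` encapsulates chamber geometry (cells per field ->
    cells per mL); ``dilution`` and ``mass_g`` refer back to the weighed
    product sample.
    """
    if len(cells_per_field) == 0:
        raise RamavitError("need at least one visual-field count")
    if dilution <= 0 or mass_g <= 0:
        raise RamavitError("dilution and mass_g must be positive")
    if field_factor <= 0:
        raise RamavitError("field_factor must be positive")
    mean = float(np.mean(cells_per_field))
    if mean < 0:
        raise RamavitError("field counts must be nonnegative")
    return mean * field_factor * dilution / mass_g


def live_count(total_count: float, viable_rate: float) -> float:
    if not 0.0 <= viable_rate <= 1.0:
        raise RamavitError("viable_rate must lie in [0, 1]")
    if total_count < 0:
        raise RamavitError("total_count must be nonnegative")
    return total_count * viable_rate


def viable_rate(live: float, total: float) -> float:
    if total <= 0:
        raise RamavitError("total count must be positive")
    return live / total


def species_resolved_counts(
    live_count_total: float, proportions: Mapping[str, float]
) -> dict[str, float]:
    """Split the live count across species; conserves the total exactly."""
    total_p = sum(proportions.values())
    if abs(total_p - 1.0) > 1e-6:
        raise RamavitError(f"proportions must sum to 1 (got {total_p})")
    if live_count_total < 0:
        raise RamavitError("live_count_total must be nonnegative")
    return {sp: live_count_total * p for sp, p in proportions.items()}


def survival_rate(count_after: float, count_before: float) -> float:
    """count_after / count_before; warns when apparent growth exceeds 1."""
    if count_before <= 0:
        raise RamavitError("count_before must be positive")
    rate = count_after / count_before
    if rate > 1.0:
        warnings.warn(
            f"survival rate {rate:.3g} exceeds 1: apparent growth during storage",
            stacklevel=2,
        )
    return rate


def plateau_time(
    times_h: Sequence[float], live_fractions: Sequence[float], epsilon: float
) -> float:
    """Earliest time after which every consecutive increase is < epsilon.

    Mirrors the D2O-uptake time course: the live-cell fraction rises with
    incubation time and saturates; the returned time is the shortest
    incubation that already captures the plateau.  If the series never
    plateaus the last time is returned with a warning.
    """
    t = np.asarray(times_h, dtype=float)
    f = np.asarray(live_fractions, dtype=float)
    if t.size != f.size:
        raise RamavitError("times and fractions must have equal length")
    if t.size < 2:
        raise RamavitError("need at least 2 time points")
    if not np.all(np.diff(t) > 0):
        raise RamavitError("times must be strictly ascending")
    diffs = np.diff(f)
    for i in range(diffs.size):
        if np.all(diffs[i:] < epsilon):
            return float(t[i])
    warnings.warn("live fraction never plateaus; returning the last time", stacklevel=2)
    return float(t[-1])


# ---------------------------------------------------------------------------
# ramanome-level pipeline

def cdr_of_ramanome(r: Ramanome, bands: CdrBands | None = None) -> np.ndarray:
    """Per-cell CDR values of a preprocessed ramanome."""
    return np.array([compute_cdr(s, bands) for s in r], dtype=float)


def analyze_sample(
    sample: Ramanome,
    reference_0h: Ramanome,
    bands: CdrBands | None = None,
    cdr_control: float | None = None,
    margin: float | str = "auto",
    sample_id: str = "",
) -> tuple[list[VitalityRecord], VitalitySummary]:
    """Per-cell viability calls plus the sample summary.

    ``reference_0h`` is a ramanome of unlabelled (0-h) cells; its mean CDR
    is the MAL baseline.  ``margin="auto"`` sets the live/dead threshold at
    3 SD of the reference CDR distribution (a detection-limit convention:
    a cell is called live only when its CDR gain exceeds what measurement
    noise alone produces); pass 0.0 for the strict MAL > 0 rule.
    """
    if not len(sample):
        raise RamavitError("sample ramanome is empty")
    if not len(reference_0h):
        raise RamavitError("0-h reference ramanome is empty")
    bands = bands or CdrBands()
    ref = cdr_of_ramanome(reference_0h, bands)
    cdr_0h = float(ref.mean())
    if margin == "auto":
        margin = 3.0 * float(ref.std(ddof=1)) if ref.size >= 2 else 0.0
    records = []
    for s in sample:
        cdr = compute_cdr(s, bands)
        mal = compute_mal(cdr, cdr_0h)
        records.append(
            VitalityRecord(
                cell_id=s.meta.cell_id,
                cdr=cdr,
                mal=mal,
                live=call_viability(mal, margin=float(margin)),
            )
        )
    summary = summarize_sample(
        records, cdr_control=cdr_control, cdr_0h=cdr_0h, sample_id=sample_id
    )
    return records, summary
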