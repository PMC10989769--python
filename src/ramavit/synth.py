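"""Synthetic ramanomes and cell images for development and validation.

Spectra are built from a physically motivated additive model:

* species-specific *fingerprint* peaks — Gaussians with random centres in
  600-1800 cm^-1, drawn deterministically per (species, seed);
* a C-H stretch band (Gaussian at 2935 cm^-1) and a C-D band (Gaussian at
  2170 cm^-1) sharing a fixed total area ``base_band_area``.  The C-D
  fraction of that area is ``f = cdr_max * vitality * (1 - exp(-k t))``,
  the saturating heavy-water uptake law, so the true (noise-free) C-D
  ratio equals ``f`` exactly;
* a smooth polynomial baseline and white Gaussian noise scaled so the
  high-wavenumber peak height over noise SD matches ``target_snr``.

Dead cells have vitality 0, hence no C-D band — they do not assimilate
heavy water.  Generated cells carry their ground truth (live flag,
vitality, analytic CDR) in ``meta.extra`` for recovery tests.

Cell images emulate bright-field micrographs of rod-shaped bacteria:
rotated ellipses on a dark background, optional small bright impurity
speckles (truth label 2), Gaussian blur and sensor noise.  Truth masks are
exact (pre-blur).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import RamavitError
from .segmentation import SegSample
from .species_id import LabeledRamanome
from .spectra import Ramanome, Spectrum, SpectrumMeta

__all__ = [
    "SpeciesProfile",
    "GeneratorConfig",
    "make_species_profile",
    "reference_profiles",
    "uptake_fraction",
    "simulate_spectrum",
    "simulate_ramanome",
    "simulate_cell_images",
]

GENERATOR_VERSION = "1"


@dataclass(frozen=True)
class SpeciesProfile:
    """Deterministic fingerprint-peak set for one synthetic species."""

    species: str
    peaks: tuple[tuple[float, float, float], ...]  # (center, sigma, amplitude)
    seed: int

    def __post_init__(self):
        if not self.peaks:
            raise RamavitError("a species profile needs at least one peak")
        for c, w, a in self.peaks:
            if not (600.0 <= c <= 1800.0):
                raise RamavitError(f"peak center {c} outside the fingerprint region")
            if a <= 0 or w <= 0:
                raise RamavitError("peak amplitudes and widths must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the spectrum generator.

    ``uptake_rate`` (h^-1) and ``cdr_max`` define the saturating D2O
    uptake law; ``target_snr`` is the C-H peak height over noise SD.
    """

    grid_lo: float = 320.0
    grid_hi: float = 3400.0
    grid_step: float = 1.0
    ch_center: float = 2935.0
    cd_center: float = 2170.0
    band_sigma: float = 35.0
    base_band_area: float = 60.0
    target_snr: float = 50.0
    baseline_mag: float = 0.3
    uptake_rate: float = 1.5
    cdr_max: float = 0.2
    vitality_concentration: float = 10.0

    def __post_init__(self):
        if not 0.0 < self.cdr_max < 1.0:
            raise RamavitError("cdr_max must lie in (0, 1)")
        if self.uptake_rate <= 0:
            raise RamavitError("uptake_rate must be positive")

    def grid(self) -> np.ndarray:
        return np.arange(self.grid_lo, self.grid_hi + self.grid_step / 2, self.grid_step)


def _species_rng(species: str, seed: int) -> np.random.Generator:
    digest = hashlib.blake2s(species.encode("utf-8"), digest_size=4).digest()
    return np.random.default_rng([seed, int.from_bytes(digest, "little")])


def make_species_profile(
    species: str, seed: int = 0, n_peaks: tuple[int, int] = (6, 12)
) -> SpeciesProfile:
    """Draw a deterministic fingerprint-peak set for ``species``."""
    lo, hi = n_peaks
    if lo < 3:
        raise RamavitError("n_peaks must allow at least 3 peaks")
    rng = _species_rng(species, seed)
    k = int(rng.integers(lo, hi + 1))
    centers = rng.uniform(620.0, 1780.0, size=k)
    sigmas = rng.uniform(4.0, 12.0, size=k)
    amps = rng.uniform(0.2, 1.0, size=k)
    peaks = tuple(sorted(zip(centers, sigmas, amps)))
    return SpeciesProfile(species=species, peaks=peaks, seed=seed)


def _fingerprint(profile: SpeciesProfile, grid: np.ndarray) -> np.ndarray:
    y = np.zeros_like(grid)
    for c, w, a in profile.peaks:
        y += a * np.exp(-0.5 * ((grid - c) / w) ** 2)
    return y


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def reference_profiles(
    species: list[str] | int,
    seed: int = 0,
    similarity_cap: float = 0.95,
    cfg: GeneratorConfig | None = None,
    max_tries: int = 50,
) -> list[SpeciesProfile]:
    """Profiles for a reference panel, with pairwise fingerprint cosine
    similarity kept below ``similarity_cap`` (violating profiles are
    redrawn deterministically)."""
    if isinstance(species, int):
        species = [f"species_{i:02d}" for i in range(1, species + 1)]
    cfg = cfg or GeneratorConfig()
    grid = cfg.grid()
    mask = (grid >= 600) & (grid <= 1800)
    profiles: list[SpeciesProfile] = []
    prints: list[np.ndarray] = []
    for sp in species:
        sub = seed
        for _ in range(max_tries):
            prof = make_species_profile(sp, seed=sub)
            fp = _fingerprint(prof, grid)[mask]
            if all(_cosine(fp, q) < similarity_cap for q in prints):
                profiles.append(prof)
                prints.append(fp)
                break
            sub += 1_000_003  # deterministic redraw
        else:
            raise RamavitError(f"could not find a distinct profile for {sp!r}")
    return profiles


def uptake_fraction(t_h: float | np.ndarray, k: float) -> float | np.ndarray:
    """Saturating D2O-uptake kinetics 1 - exp(-k t)."""
    return 1.0 - np.exp(-k * np.asarray(t_h, dtype=float))


def simulate_spectrum(
    profile: SpeciesProfile,
    vitality: float,
    t_h: float,
    cfg: GeneratorConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> Spectrum:
    """One synthetic cell spectrum; its analytic CDR is stored in
    ``meta.extra['true_cdr']``."""
    if not 0.0 <= vitality <= 1.0:
        raise RamavitError("vitality must lie in [0, 1]")
    cfg = cfg or GeneratorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = cfg.grid()
    f = float(cfg.cdr_max * vitality * uptake_fraction(t_h, cfg.uptake_rate))
    norm = 1.0 / (cfg.band_sigma * np.sqrt(2.0 * np.pi))
    cd = np.exp(-0.5 * ((grid - cfg.cd_center) / cfg.band_sigma) ** 2) * norm
    ch = np.exp(-0.5 * ((grid - cfg.ch_center) / cfg.band_sigma) ** 2) * norm
    signal = (
        _fingerprint(profile, grid)
        + cfg.base_band_area * (f * cd + (1.0 - f) * ch)
    )
    # smooth polynomial baseline: positive, slowly varying
    x01 = (grid - grid[0]) / (grid[-1] - grid[0])
    coefs = rng.uniform(0.0, cfg.baseline_mag, size=3)
    baseline = coefs[0] + coefs[1] * x01 + coefs[2] * x01**2
    high = (grid >= 2040) & (grid <= 3100)
    peak_height = float(np.max(signal[high]))
    noise = 0.0
    if np.isfinite(cfg.target_snr) and cfg.target_snr > 0:
        noise = rng.normal(0.0, peak_height / cfg.target_snr, size=grid.size)
    meta = SpectrumMeta(
        cell_id="",
        species_label=profile.species,
        timepoint_h=float(t_h),
        d2o_fraction=1.0,
        extra={
            "true_cdr": f,
            "true_vitality": float(vitality),
            "generator_version": GENERATOR_VERSION,
        },
    )
    return Spectrum(grid, signal + baseline + noise, meta)


def simulate_ramanome(
    composition: dict[str, int],
    vitality_spec: dict[str, tuple[float, float]],
    t_h: float = 3.0,
    cfg: GeneratorConfig | None = None,
    seed: int = 0,
    sample_id: str = "synthetic",
    profiles: dict[str, SpeciesProfile] | None = None,
    profile_seed: int = 0,
) -> LabeledRamanome:
    """A labelled mixed-population ramanome.

    ``composition`` maps species to cell counts; ``vitality_spec`` maps
    species to ``(live_fraction, mean_vitality)``.  Live/dead is drawn
    Bernoulli(live_fraction); live-cell vitality follows a Beta
    distribution with the given mean; dead cells have vitality 0.  Ground
    truth is recorded per cell in ``meta.extra``.

    ``profiles`` (or ``profile_seed``) fixes the fingerprint peak sets
    independently of the sampling ``seed`` so that ramanomes drawn with
    different seeds remain classifiable by one reference model.
    """
    cfg = cfg or GeneratorConfig()
    if any(n < 1 for n in composition.values()):
        raise RamavitError("composition counts must be >= 1")
    rng = np.random.default_rng(seed)
    spectra: list[Spectrum] = []
    idx = 0
    for sp in sorted(composition):
        if profiles is not None:
            profile = profiles[sp]
        else:
            profile = make_species_profile(sp, seed=profile_seed)
        live_frac, mean_vit = vitality_spec.get(sp, (1.0, 0.7))
        for _ in range(composition[sp]):
            alive = bool(rng.random() < live_frac)
            if alive:
                conc = cfg.vitality_concentration
                a = mean_vit * conc
                b = (1.0 - mean_vit) * conc
                vit = float(rng.beta(a, b)) if 0 < mean_vit < 1 else float(mean_vit)
            else:
                vit = 0.0
            s = simulate_spectrum(profile, vit, t_h, cfg, seed=rng)
            s.meta.cell_id = f"{sample_id}_c{idx:05d}"
            s.meta.sample_id = sample_id
            s.meta.extra["true_live"] = alive
            spectra.append(s)
            idx += 1
    ram = Ramanome(spectra, axis=cfg.grid())
    return LabeledRamanome(ram, classes=sorted(composition))


def simulate_cell_images(
    n_images: int,
    cells_per_image: tuple[int, int] = (4, 9),
    impurity_rate: float = 0.002,
    blur_sigma: float = 1.0,
    noise_sigma: float = 0.03,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
) -> list[SegSample]:
    """Synthetic bright rod-shaped cells with exact truth masks.

    Cells are placed by rejection sampling so they never overlap; impurity
    speckles carry truth label 2.
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    out: list[SegSample] = []
    for _ in range(n_images):
        truth = np.zeros(shape, dtype=np.uint8)
        n_cells = int(rng.integers(cells_per_image[0], cells_per_image[1] + 1))
        placed = 0
        for _cell in range(n_cells):
            for _try in range(30):
                cy = rng.uniform(6, H - 6)
                cx = rng.uniform(6, W - 6)
                a = rng.uniform(5.0, 9.0)   # semi-major (rod length / 2)
                b = rng.uniform(1.5, 3.0)   # semi-minor
                theta = rng.uniform(0, np.pi)
                ct, st = np.cos(theta), np.sin(theta)
                u = (xx - cx) * ct + (yy - cy) * st
                v = -(xx - cx) * st + (yy - cy) * ct
                ell = (u / a) ** 2 + (v / b) ** 2 <= 1.0
                # keep a 1-px moat so neighbouring cells never touch
                halo = (u / (a + 2)) ** 2 + (v / (b + 2)) ** 2 <= 1.0
                if not (halo & (truth == 1)).any():
                    truth[ell] = 1
                    placed += 1
                    break
        if impurity_rate > 0:
            n_imp = rng.poisson(impurity_rate * H * W)
            for _ in range(n_imp):
                iy = int(rng.integers(1, H - 1))
                ix = int(rng.integers(1, W - 1))
                r = int(rng.integers(0, 2))
                patch = (np.abs(yy - iy) <= r) & (np.abs(xx - ix) <= r)
                patch &= truth == 0
                truth[patch] = 2
        img = np.full(shape, 0.1)
        img[truth == 1] = 0.7
        img[truth == 2] = 0.95
        if blur_sigma > 0:
            img = gaussian_filter(img, blur_sigma)
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, size=shape)
        img = np.clip(img, 0.0, 1.0)
        out.append(SegSample(image=img, truth_mask=truth, n_cells=placed))
    return out
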