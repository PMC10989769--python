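import numpy as np
import pytest

import ramavit as rv


@pytest.fixture(scope="session")
def profile_a():
    return rv.make_species_profile("A", seed=1)


@pytest.fixture(scope="session")
def two_species_profiles():
    profs = rv.reference_profiles(["A", "B"], seed=3)
    return {p.species: p for p in profs}


@pytest.fixture(scope="session")
def small_ramanome(profile_a):
    """Ten noisy spectra of one species at mixed vitalities."""
    rng = np.random.default_rng(42)
    spectra = []
    for i in range(10):
        s = rv.simulate_spectrum(profile_a, vitality=rng.uniform(0, 1), t_h=3.0, seed=rng)
        s.meta.cell_id = f"cell{i:02d}"
        s.meta.sample_id = "fixture"
        spectra.append(s)
    return rv.Ramanome(spectra, axis=spectra[0].wavenumbers)


def make_flat_spectrum(value=5.0, lo=320.0, hi=3400.0):
    w = np.arange(lo, hi + 0.5)
    return rv.Spectrum(w, np.full(w.size, value))
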