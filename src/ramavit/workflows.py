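"""End-to-end validation workflows on synthetic data.

These functions wire the full pipeline together — generate, preprocess,
measure — and report how well known ground truth is recovered.  They are
what the command-line smoke examples and the self-validation script run.
"""

from __future__ import annotations

import numpy as np

from .preprocess import PreprocessConfig, preprocess_ramanome
from .species_id import ClassifierConfig, LabeledRamanome, estimate_proportions, predict, train_cnn
from .synth import GeneratorConfig, reference_profiles, simulate_ramanome, uptake_fraction
from .vitality import analyze_sample, plateau_time

__all__ = [
    "mock_proportion_recovery",
    "viable_rate_recovery",
    "uptake_plateau_time",
    "MOCK_RATIOS",
]

#: Target-species percentages of the eight standard mock designs.
MOCK_RATIOS = (1, 5, 10, 20, 50, 80, 95, 99)


def _mock_composition(target: str, others: list[str], ratio_pct: int, n_cells: int) -> dict[str, int]:
    n_t = round(n_cells * ratio_pct / 100)
    n_o = n_cells - n_t
    per = [n_o // len(others)] * len(others)
    for j in range(n_o - sum(per)):
        per[j] += 1
    comp = {sp: c for sp, c in zip(others, per) if c}
    if n_t:
        comp[target] = n_t
    return comp


def mock_proportion_recovery(
    seed: int = 0,
    n_species: int = 21,
    n_train_per_class: int = 150,
    n_mock_cells: int = 400,
    ratios: tuple[int, ...] = MOCK_RATIOS,
    classifier_config: ClassifierConfig | None = None,
    generator_config: GeneratorConfig | None = None,
) -> dict:
    """Train the reference CNN and reconstruct mock-community proportions.

    Builds a reference panel of ``n_species`` synthetic species, trains the
    residual CNN on ``n_train_per_class`` spectra per class, then mixes the
    first species (the target) against an equal pool of the rest at each
    design ratio, classifies every cell and compares the estimated target
    proportion with the designed one.

    Returns per-ratio absolute errors (percentage points), their maximum,
    and the classifier's held-out accuracy.
    """
    gcfg = generator_config or GeneratorConfig()
    profiles = {p.species: p for p in reference_profiles(n_species, seed=seed, cfg=gcfg)}
    species = sorted(profiles)
    vit = {sp: (1.0, 0.7) for sp in species}
    pcfg = PreprocessConfig()

    train_set = simulate_ramanome(
        {sp: n_train_per_class for sp in species}, vit,
        t_h=3.0, cfg=gcfg, seed=seed + 1, profiles=profiles, sample_id="ref",
    )
    train_pp = LabeledRamanome(preprocess_ramanome(train_set.ramanome, pcfg), classes=species)
    ccfg = classifier_config or ClassifierConfig(seed=seed)
    model = train_cnn(train_pp, ccfg)

    holdout = simulate_ramanome(
        {sp: 10 for sp in species}, vit, t_h=3.0, cfg=gcfg,
        seed=seed + 2, profiles=profiles, sample_id="holdout",
    )
    ho_pred, _ = predict(model, preprocess_ramanome(holdout.ramanome, pcfg))
    ho_truth = [s.meta.species_label for s in holdout.ramanome]
    holdout_acc = float(np.mean(np.array(ho_pred) == np.array(ho_truth)))

    target, others = species[0], species[1:]
    errors: dict[int, float] = {}
    for i, ratio in enumerate(ratios):
        comp = _mock_composition(target, others, ratio, n_mock_cells)
        mock = simulate_ramanome(
            comp, vit, t_h=3.0, cfg=gcfg, seed=seed + 10 + i,
            profiles=profiles, sample_id=f"mock{ratio}",
        )
        pred, _ = predict(model, preprocess_ramanome(mock.ramanome, pcfg))
        est = estimate_proportions(pred, classes=species)
        true_p = comp.get(target, 0) / n_mock_cells
        errors[ratio] = abs(est.proportions[target] - true_p) * 100.0
    return {
        "target_species": target,
        "per_ratio_error_pts": errors,
        "max_error_pts": max(errors.values()),
        "holdout_accuracy": holdout_acc,
        "n_mock_cells": n_mock_cells,
        "n_train": n_train_per_class * n_species,
    }


def viable_rate_recovery(
    seed: int = 0,
    live_fraction: float = 0.68,
    n_cells: int = 300,
    n_reference: int = 100,
    t_h: float = 3.0,
    mean_vitality: float = 0.7,
    generator_config: GeneratorConfig | None = None,
) -> dict:
    """Simulate a mixed live/dead population and recover its viable rate.

    The sample is probed at ``t_h`` hours; an unlabelled 0-h ramanome of
    the same population provides the MAL baseline.  Returns the realised
    (ground-truth) live fraction and the pipeline estimate.
    """
    gcfg = generator_config or GeneratorConfig()
    vit = {"A": (live_fraction, mean_vitality)}
    sample = simulate_ramanome({"A": n_cells}, vit, t_h=t_h, cfg=gcfg, seed=seed, sample_id="s")
    ref = simulate_ramanome(
        {"A": n_reference}, vit, t_h=0.0, cfg=gcfg, seed=seed + 1, sample_id="r"
    )
    pcfg = PreprocessConfig()
    sample_pp = preprocess_ramanome(sample.ramanome, pcfg)
    ref_pp = preprocess_ramanome(ref.ramanome, pcfg)
    records, summary = analyze_sample(sample_pp, ref_pp, sample_id="s")
    realized = float(np.mean([s.meta.extra["true_live"] for s in sample.ramanome]))
    return {
        "designed_live_fraction": live_fraction,
        "realized_live_fraction": realized,
        "estimated_viable_rate": summary.viable_rate,
        "mal_mean": summary.mal_mean,
        "hi": summary.hi,
        "n_cells": len(records),
    }


def uptake_plateau_time(
    times_h=(1.0, 2.0, 2.5, 3.0, 3.5, 4.0),
    uptake_rate: float = 1.5,
    epsilon: float = 0.01,
) -> float:
    """Plateau time of the saturating uptake curve at the sampled times.

    The generator's kinetics give the live-cell fraction detected at each
    incubation time; the plateau rule picks the earliest time after which
    no consecutive increase reaches ``epsilon``.
    """
    fractions = uptake_fraction(np.asarray(times_h, dtype=float), uptake_rate)
    return plateau_time(list(times_h), list(fractions), epsilon)
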