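# ramavit

**Single-cell Raman viability, vitality and identification toolkit for
live-cell products.**

`ramavit` quantifies the quality of live-cell products (probiotics and
similar preparations) from D₂O-probed single-cell Raman spectra (SCRS),
without culturing. It is aimed at microbiologists and QC engineers who
acquire per-cell Raman spectra and need, per sample:

* the **total and live cell count** (CFU/g-equivalent),
* the **metabolic vitality** of each cell and its population heterogeneity,
* the **species identity** of each cell and the community composition,
* plus **cell segmentation** utilities for automating spectral acquisition.

## The measurements

A live cell incubated in heavy water incorporates deuterium into newly
synthesised biomolecules, which raises a C–D stretch band in its Raman
spectrum at 2040–2300 cm⁻¹ at the expense of the C–H band
(2800–3100 cm⁻¹). The toolkit's core statistics:

- **CDR** (C–D ratio): `CDR = A_CD / (A_CD + A_CH)`, the fraction of the
  combined band area carried by C–D; bounded in [0, 1] and a proxy for
  cumulative metabolic activity.
- **MAL** (metabolic activity level): `MAL = CDR_sample − CDR_0h`, the CDR
  gain over an unlabelled 0-h reference. `MAL > 0` calls a cell live,
  `MAL ≤ 0` dead; the live fraction of the sampled cells is the viable
  rate and scales a hemocytometer-style total count into a live count.
- **rMAL**: `(CDR_sample − CDR_0h) / (CDR_control − CDR_0h)`, vitality
  relative to the same organism under optimal (log-phase) conditions.
- **HI** (heterogeneity index): the sample standard deviation of MAL
  across cells — how synchronised the population's vitality is.

Species identification uses an 18-layer one-dimensional **residual CNN**
(17 convolutional layers plus one fully connected softmax head, wide
kernels, no global average pooling) over the fingerprint region
(600–1800 cm⁻¹), with random-forest and SVM baselines. Estimated
community proportions are tested against expected ones with a χ²
goodness-of-fit statistic (conventional consistency cutoff 11.070).

For automated acquisition, `ramavit.segmentation` provides edge-based
(Sobel/Canny) segmentation, a small dilated-convolution network trained
with impurity down-weighting, watershed-based cell localisation, and the
pixel metric suite ACC / IoU / FPR / FNR / OER.

Because public per-cell spectral databases for this assay are scarce, the
package ships a first-class **synthetic-data generator**
(`ramavit.synth`): species fingerprint profiles, saturating D₂O-uptake
kinetics (`f = cdr_max · vitality · (1 − e^{−kt})`), baseline drift and
shot noise, and synthetic bright-field cell images with exact truth masks.
Every other module is tested end to end against this generator's ground
truth. The neural networks are implemented in numpy with hand-derived,
numerically verified gradients — no deep-learning framework is required.

## Worked example

```python
import ramavit as rv

# a 300-cell product sample: 68% live cells, probed with D2O for 3 h,
# plus an unlabelled 0-h reference of the same population
result = rv.viable_rate_recovery(seed=0, live_fraction=0.68, n_cells=300)
print(result)
```

prints (seed 0; values rounded to 4 digits):

```
{'designed_live_fraction': 0.68, 'realized_live_fraction': 0.6867,
 'estimated_viable_rate': 0.6967, 'mal_mean': 0.0928, 'hi': 0.0665,
 'n_cells': 300}
```

The generator drew 206/300 live cells (realised fraction 0.687); the full
preprocess → CDR → MAL → live-call pipeline estimated a viable rate of
0.697 — within a percentage point of the truth. `mal_mean` is the mean
per-cell CDR gain over the 0-h baseline and `hi` its cell-to-cell
standard deviation.

Scaling into absolute counts:

```python
total = rv.total_count_from_fields([10, 10, 10, 10, 10],
                                   field_factor=1e6, dilution=100, mass_g=1.0)
live = rv.live_count(total, result["estimated_viable_rate"])   # 6.97e8
per_species = rv.species_resolved_counts(live, {"L. plantarum": 0.6, "L. paracasei": 0.4})
```

The command line mirrors the library:

```sh
ramavit simulate spectra --species A --cells 100 --outdir sim/
ramavit vitality --sample sim/sample.csv --reference sim/reference0h.csv \
        --manifest sim/sample.manifest.csv --outdir out/
```

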