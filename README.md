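# camoquant

Quantifies how well a prey animal matches its background *as an avian
receiver sees it*, and relates that to field predation outcomes.  The
package was built around the classic lichen-moth study system — a moth
with high-contrast black-and-white forewings resting on lichen-covered
or bare bark — but every stage takes generic inputs.

It covers the full analysis chain:

* **Receptor-noise-limited (RNL) discrimination.**  For receptor quantum
  catches Q_i = ∫R(λ)I(λ)S_i(λ)dλ (von Kries adapted), log contrasts
  Δf_i = ln(Qa_i/Qb_i) give the chromatic distance

      ΔS² = min_c Σ_i (Δf_i − c)² / ω_i²

  over the chromatic channels, and ΔL = |Δf_D|/ω_D on the double-cone
  (luminance) channel — both in just-noticeable-difference (JND) units,
  where values below ~1 are indiscriminable.  Weber fractions scale with
  cone abundance, ω_i = ν·√(η_max/η_i).
* **Acuity control.**  For a receiver with acuity *A* cycles/degree at
  distance *d*, the minimum resolvable angle (MRA = 1/A degrees) spans
  2d·tan(MRA/2) on the object plane; images are Gaussian-blurred with
  FWHM = 1 MRA and rescaled to 5 px/MRA, removing detail the receiver
  cannot resolve.
* **Granularity pattern analysis.**  FFT bandpass decomposition into
  octave-spaced scales (2, 4, …, ≤1200 px); pattern *energy* per scale is
  the standard deviation of the filtered pixels over a region of
  interest, and the **pattern energy difference** (PED) between the
  animal and background ROIs measures pattern mismatch (low = good
  background pattern matching).
* **Survival analysis** of interval-checked predation experiments:
  Kaplan–Meier product-limit curves with Greenwood errors, pairwise
  log-rank tests (BH-adjusted), and Cox proportional-hazards regression
  (Efron or Breslow ties) with hazard ratios and a Wald test.
* **Synthetic data** for everything: two-tone lichen/moth blotch
  textures, striated bark, composited scenes with ROI masks, Gaussian
  receptor sets, smooth spectra, and exponential-hazard predation tables
  observed at 24/48/72 h checks — so the whole chain runs end to end
  with no downloads.

## Worked example

```
camoquant run-all --out demo --seed 7
```

simulates three replicate scenes per background (a lichen-patterned
moth on lichen and on bark, 22 mm wingspan at 10 px/mm, with a modest
built-in colour/luminance mismatch), analyses them under a 6
cycles/degree receiver at 500 and 1000 mm, and analyses a simulated
300-replicate predation experiment.  `demo/image/image_summary.csv`:

```
background  distance_mm  n  chromatic_jnd_mean  achromatic_jnd_mean  ped_mean
      bark        500.0  3              4.8512               0.8961    0.0403
      bark       1000.0  3              4.4632               0.9209    0.0220
    lichen        500.0  3              4.8556               3.0128    0.0142
    lichen       1000.0  3              4.4877               2.8916    0.0116
```

Colour contrast is far above the 1-JND discrimination threshold on
*both* backgrounds (the moth is a poor colour match everywhere), but
pattern energy difference is ~3× lower on lichen than on bark, and
shrinks with viewing distance — the pattern, not the colour, carries
the camouflage.  The survival chain on the simulated field data
(`demo/survival/`) gives 72-h Kaplan–Meier survival of 0.52 (bark),
0.57 (off-lichen) and 0.68 (lichen), with negative Cox coefficients for
both lichen treatments (being on or near lichen reduces attack hazard).

The same operations are available as a library:

```python
from camoquant import (ViewingGeometry, apply_acuity, gen_scene,
                       pattern_energy_spectrum, ped, roi_jnd, texture_defaults)

img, mask = gen_scene(bg_cfg=texture_defaults("bark"), seed=1)
img, mask = apply_acuity(img, ViewingGeometry(6.0, 500.0), mask=mask)
print(roi_jnd(img, mask))                       # chromatic + achromatic JND
a = pattern_energy_spectrum(img, mask, roi_label=1, normalize=False)
b = pattern_energy_spectrum(img, mask, roi_label=2, normalize=False)
print(ped(a, b, mode="mean").ped)               # pattern energy difference
```

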