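# ehquant

Quantification of **endolymphatic hydrops (EH)** — the distension of the
endolymph-filled membranous labyrinth that is the histopathologic hallmark of
Ménière's disease — on gadolinium-enhanced inner-ear MRI and on
histology-style labeled sections, together with a synthetic inner-ear phantom
generator so that every stage of the pipeline can be validated against known
ground truth without patient data.

## What it computes

**MRI route.** Three co-registered contrasts enter: magnetic resonance
cisternography (MRC, all inner-ear fluid bright), a positive perilymph image
(PPI, enhanced perilymph bright / endolymph dark) and a positive endolymph
image (PEI, reversed contrast). The package composes

```
HYDROPS     = PPI − PEI          (endolymph < 0 < perilymph)
HYDROPS-Mi2 = HYDROPS × MRC      (background suppressed, CNR boosted)
```

selects representative slices by rule — the cochlear slice shows all three
turns (ties broken by the greatest modiolus extent); the vestibular slice is
the lowest one on which the lateral semicircular canal (LSCC) ring is visible
over more than 240° of arc, with the ampulla excluded from the ROI — and
measures

```
EH ratio = (# ROI pixels with HYDROPS-Mi2 < 0) / (# ROI pixels)
```

**Histology route.** On labeled sections it measures the scala-media area of
the basal/middle/apical turns over the whole cochlear fluid area, the saccule
and utricle areas (separately and combined) over the entire vestibule area,
the membranous-duct over canal cross-section area at ampullary and
non-ampullary sites, and calls herniation of an otolithic organ into the
lateral canal from its pixel overlap with the canal territory.

**Statistics.** Group comparisons use a normality-gated branch (Shapiro–Wilk,
then Welch's t-test or Mann–Whitney U, two-sided, α = 0.05), with the branch
taken always recorded.

**Phantom.** A parametric, deliberately stylized inner ear (turn annuli around
a modiolus core, elliptical-segment otolithic organs in a vestibule ellipse,
canal annuli with an elliptical ampulla) whose area fractions are exact by
construction, rendered with 4–8× supersampling; cohorts draw per-ear true
fractions from per-group clipped-normal distributions with mean-compensated
sampling, so cohort means converge to the requested group parameters.

## Worked example

```python
import numpy as np
import ehquant as eq

spec = eq.PhantomSpec(ear_id="demo-001", cochlea_true_fraction=0.314,
                      saccule_true_fraction=0.513, utricle_true_fraction=0.242,
                      noise_sd=20.0, seed=42)
mrc, ppi, pei, labels = eq.render_mr_phantom(spec)
mi2 = eq.compose_mi2(eq.compose_hydrops(ppi, pei), mrc)

roi = eq.cochlea_roi(labels)
m = eq.eh_ratio_mri(mi2, roi, ear_id=spec.ear_id)
print(f"cochlear EH ratio {m.numerator_pixels}/{m.denominator_pixels} = {m.ratio:.3f}")

zv, vroi = eq.select_vestibule_slice(labels)
mv = eq.eh_ratio_mri(mi2, vroi, ear_id=spec.ear_id)
print(vroi.provenance)
print(f"vestibular EH ratio = {mv.ratio:.3f}")

sec = eq.render_histo_section(spec, "vestibule")
comb, sac, utr = eq.histo_vestibule_ratios(sec)
print(f"histology: combined {comb.ratio:.3f} = "
      f"saccular {sac.ratio:.3f} + utricular {utr.ratio:.3f}")

rng = np.random.default_rng(0)
a = np.clip(rng.normal(0.314, 0.118, 54), 0.001, 0.999)   # affected cochleae
b = np.clip(rng.normal(0.064, 0.022, 17), 0.001, 0.999)   # healthy controls
print(eq.compare_groups(a, b, label_a="cochlea/affected",
                        label_b="cochlea/control").summary())
```

prints

```
cochlear EH ratio 852/2715 = 0.314
lowest slice with LSCC arc coverage 265 deg > 240 deg; ampulla excluded
vestibular EH ratio = 0.756
histology: combined 0.755 = saccular 0.510 + utricular 0.245
cochlea/affected (n=54, mean=0.328, SD=0.107) vs cochlea/control (n=17, mean=0.063, SD=0.024)
  normality p: 0.723 / 0.915 -> t_test
  statistic = 16.86, p = 1.53e-25 (significant at alpha = 0.05)
```

The phantom was built with a true cochlear scala-media fraction of 0.314 and a
combined vestibular fraction of 0.755; the negative-pixel counts recover both
to the third decimal even with noise, and the affected-vs-control comparison
is significant at any conventional level.

A command-line interface mirrors the library
(`ehquant simulate | compose | select-roi | measure-mri | measure-histo |
compare`); volumes travel as NIfTI, sections and masks as 16-bit PNG with a
JSON sidecar, tables as CSV.

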