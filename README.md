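# lequant

Quantification of gene expression along the curved **leading edge (LE)** of
the *Drosophila* embryo during dorsal closure (DC), and of the kinematics of
closure itself.

During DC the dorsal-most row of epidermal cells — the leading edge — runs
as a curved path around the amnioserosa. Fluorescent in situ hybridization
(FISH) signal along this path is heterogeneous both along the
anterior–posterior (AP) axis and within each body segment, but standard
box-ROI intensity measurements cannot follow the curvature or compare
segments of unequal length. `lequant` addresses this for image analysts and
developmental biologists who already have traced midlines and contours
(e.g. from FIJI) and need reproducible numbers.

## What it computes

**LE expression profiling.** Given a traced midline (anterior → posterior)
and an amnioserosa background ROI:

1. fit a smooth spline through the midline and re-parameterize it by arc
   length *s* (μm);
2. straighten the ribbon *R(s, t)* of half-width *w* around the curve by
   bilinear resampling (out-of-image samples are masked, not zero-filled)
   and project it to the 1-D profile *I(s)* = mean over *t*;
3. subtract the background (median over the amnioserosa ROI) and clamp
   negative values to 0;
4. split *I(s)* into segments — at annotated boundaries (T1…A7) or into ten
   equal lengths — and length-normalize each segment into **10 equal bins
   ("cells")**: bins 1–7 form the anterior compartment, bins 8–10 the
   posterior (En-expressing) compartment, with the parasegmental boundary
   between bins 7 and 8.

Per segment it reports *d*<sub>LE</sub> (the segment's mean intensity), the
10-bin vector *d*<sub>NS</sub> (the normalized-segment distribution), and
the AP ratio = mean(bins 1–7)/mean(bins 8–10). Profiles pool across embryos
on two axes: per segment over *n* embryos (AP analysis) or per bin over all
segments of all embryos (compartmental analysis), with mean ± s.d. and
s.e.m.

**Closure kinematics.** From annotated pairs of opposing LE contours with
their two canthi: the open length *L*, the fused seam, the closure stage
%DC = 100·seam/*L*₀, height profiles *H(q)* at the 8 subdomains of *L*,
stage-binned closure speeds (−dH/dt, nm/s, least-squares within %DC bins),
the final closure point, zipping-zone lengths and En-matched closure-delay
distances (D-A / D-P).

**Screen bookkeeping.** Inclusive fold-change filtering (|FC| ≥ threshold),
expected false positives from an FDR (n·FDR), and a seeded Monte-Carlo
permutation test for equal means in a one-way layout.

**Synthetic fixtures.** `lequant.synthetic` renders embryo images with a
curved LE band of known per-compartment amplitudes (the 7:3 anterior:
posterior structure) and closure series with programmed zipping rates — the
analytic ground truth behind the whole test suite.

## Worked example

Quantify 15 synthetic embryos (2:1 anterior:posterior amplitude step, 5%
noise) and pool the per-cell signal across all 150 segments:

```python
from lequant import (EmbryoSpec, make_embryo, fit_midline, straighten,
                     project_profile, estimate_background, quantify_profile,
                     compartment_stats, pool)

per_embryo = {}
for k in range(15):
    signal, marker, ann, truth = make_embryo(EmbryoSpec(seed=k))
    curve = fit_midline(ann.midline, pixel_size=ann.pixel_size)
    ribbon = straighten(signal, curve, half_width=3.0)
    profile = project_profile(ribbon, embryo_id=f"embryo{k}")
    background = estimate_background(signal, ann.background_roi)
    per_embryo[f"embryo{k}"] = quantify_profile(
        profile, background, boundaries=ann.boundaries)

seg = per_embryo["embryo0"][0]
print(f"{seg.label}: d_LE = {seg.d_le:.3f}, AP ratio = {compartment_stats(seg).ap_ratio:.2f}")
pooled = pool(per_embryo, axis="compartmental")
print(pooled.data.round(3).to_string(index=False))
```

prints

```
T1: d_LE = 1.695, AP ratio = 1.98
segment  bin  mean    sd   sem   n
    all    1 1.980 0.022 0.002 150
    all    2 2.000 0.012 0.001 150
    all    3 1.998 0.012 0.001 150
    all    4 2.000 0.012 0.001 150
    all    5 2.001 0.013 0.001 150
    all    6 2.000 0.012 0.001 150
    all    7 1.956 0.020 0.002 150
    all    8 1.046 0.019 0.002 150
    all    9 1.001 0.012 0.001 150
    all   10 1.027 0.025 0.002 150
```

T1's *d*<sub>LE</sub> of 1.695 is the background-corrected segment mean
(truth: 0.7·2 + 0.3·1 = 1.7), and the pooled 10-cell profile recovers the
programmed step — anterior bins at 2.0, posterior bins at 1.0, with the
break between cells 7 and 8; residual deviation in the boundary bins comes
from interpolation blur at the compartment edge.

The same workflow is scriptable from a shell (`lequant simulate`,
`lequant straighten`, `lequant quantify`, `lequant pool`,
`lequant dynamics`, `lequant screen`, `lequant oneway`); see
`lequant --help`.

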