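# Methods

## Coordinate and unit conventions

Pixel coordinates are 0-based with `x` = column and `y` = row. All physical
quantities are micrometres (arc length, distances, ribbon offsets) or
arbitrary fluorescence units (intensities). The pixel size is always taken
from the annotation file, never from image metadata, because microscope
TIFF metadata is routinely wrong or missing after conversion; every
annotation file must therefore carry `pixel_size_um`. Arc position `s`
increases anterior → posterior, with T1 at `s = 0`; midline control points
must be supplied in that order.

## Midline fitting and ribbon straightening

The operator-traced midline is interpolated with a parametric cubic
B-spline (`scipy.interpolate.splprep`, degree reduced for < 4 points;
smoothing factor 0 by default so the curve passes through the clicks). The
spline is re-parameterized by arc length numerically: the curve is sampled
densely (≥ 2000 points), chord lengths are accumulated, and `s → u` is
inverted by linear interpolation. This keeps the parameterization
unit-speed to well within 1% everywhere, which is what the downstream
equal-length binning relies on.

The ribbon `R(s, t)` samples the image at `curve(s) + t · n(s)`, `n` the
unit normal, on a grid with step Δs (default: one pixel) in both axes and
`t ∈ [−w, +w]`. Interpolation is bilinear — the standard choice for
intensity quantification, and the tolerance used by the tests (1e-3
relative on the curved-geometry oracle) reflects it. Samples falling
outside the image are masked and excluded from every mean; zero-filling
would bias border profiles downward. Coordinates within 1e-6 px of the
pixel grid are snapped to it so that an axis-aligned straight midline
reproduces pixel values exactly (the identity oracle). When
`w · max-curvature ≥ 1` the normal fan self-intersects and a warning is
raised; results near such folds are not meaningful.

The default half-width is 5 μm — the scale of an LE cell apex. It is a
configurable guess, not an inferred value: no measured ribbon width exists
for this preparation, and users should match it to their band of interest.
The synthetic tests use 3 μm against a 6 μm-half-width painted band so
every ribbon sample lies inside the band.

## Background correction and normalized-segment binning

Background is the **median** intensity over the amnioserosa ROI
(boundary-inclusive point-in-polygon via shapely, ≥ 25 px required). The
median is robust to stray bright pixels in a region whose nominal signal is
flat. Correction is subtraction followed by clamping negatives to zero —
expression below background is reported as 0 — and the clamp is applied to
the profile *before* segment binning, so no negative value ever enters a
bin mean. A division-based "linearization" reading was rejected because it
cannot produce the negative values the zero-clamp rule exists for.

Segments are half-open intervals `[s_i, s_{i+1})`; a sample exactly on an
internal boundary belongs to the posterior-adjacent segment (deterministic
tie-break). The last segment includes its right edge. In `equal-10` mode
the profile extent is split into ten equal lengths labelled S1…S10 — the
mode used when marker-based anatomical boundaries are unavailable.

Length normalization resamples each segment's profile at the centres of
`10·k` equal sub-intervals (linear interpolation, edge-clamped; `k ≥ 4` and
at least one point per original sample). Bin `b` of `d_NS` is the mean of
its `k` points, so all bins have exactly equal length by construction and
the plain mean of the ten bin means equals the segment mean `d_LE`
identically — the conservation property the tests check at 1e-9 relative.
Bins 1–7 are the anterior compartment and bins 8–10 the posterior one
(segments average ten cells, seven anterior and three posterior); the AP
ratio is the ratio of the two compartment means, with a NaN sentinel when
the posterior mean is zero.

Pooling follows the two reporting conventions: per-segment statistics over
embryos (AP analysis; n = embryos, typically 15–20) and per-bin statistics
over all segments of all embryos (compartmental analysis; n = segments,
150–200 for 15–20 embryos × 10 segments). s.e.m. = s.d./√n with the n of
the chosen axis; with n = 1 dispersion is emitted as an empty field, never
as 0.

## Closure kinematics

`L` is the canthus-to-canthus distance projected on the AP axis; the seam
is `L₀ − L` with `L₀` the onset-frame extent, and %DC = 100·seam/L₀. The
denominator choice makes %DC a bounded (0–100), monotone stage variable for
a monotonically closing embryo; normalizing by the current `L` instead
would diverge near closure. Contours are piecewise-linear; `H(q)` is the
vertical separation of the two contours at the station `x_A + q·L`
(defaults q = 1/8 … 7/8, the 8 subdomains of the opening, approximately
one per segment).

Closure speed per station and stage bin is minus the ordinary
least-squares slope of `H(t)` over the frames inside the bin, in nm/s
(positive = closing). Stage bins are half-open on %DC with edge frames
joining the later bin; the default edges are thirds (early/mid/late), with
a quartile preset (25/50/75) available. Whether "closure speed" means
dH/dt or a per-flank dH/dt/2 is a convention; dH/dt is used here, so
comparisons against per-flank numbers need a factor of two.

The final closure point tracks fixed x-stations spanning the onset
opening; a station is open while its height exceeds ε = 1 μm (sub-pixel at
the relevant magnifications). The reported point is the mean open-station
position at the last frame with any open station, as a fraction of `L₀`
(0 = anterior); a series whose last frame still has open stations returns
a "not closed" sentinel (`None`). Zipping-zone length and closure-delay
distances are Euclidean distances between operator-marked point pairs
(contact → first stable junction; matched En compartments across flanks).

## Synthetic generators

`make_embryo` paints a band of half-width 6 μm around a spline midline —
the *same* fitted curve the pipeline later reconstructs from the
annotation control points, so painted and annotated arc lengths agree.
Each of 10 equal-arc-length segments has amplitude `a_i` on its anterior
70% and `p_i` on its posterior 30% (defaults 2.0 and 1.0 a.u.), on a
background of 10 a.u.; the marker channel carries stripes over exactly the
posterior compartments, giving the boundary-suggestion operator an
analytic truth. Noise is additive Gaussian, seeded, clipped at 0 (σ
default 0.1 a.u. = 5% of the anterior signal); Poisson photon statistics,
optical blur, tissue autofluorescence and annotation error are *not*
modelled, so passing recovery tests demonstrates correctness of the
geometry and arithmetic, not robustness to real-microscope artefacts. The
default frame is 512 px at 0.5 μm/px with a sinusoidal midline of 20 μm
amplitude — a desk-scale stand-in for a 2048-px confocal field that keeps
a full 15-embryo recovery run under a few seconds. At this scale a
normalized-segment bin is ~2.5 μm and bilinear blur at the compartment
step leaves a systematic ~4–5% deviation in bins 7/8; all other bins
recover to < 1%.

`make_closure_series` advances the two canthi at programmed rates (nm/s,
optionally functions of %DC, integrated with 20 substeps per frame) and
draws the opening as a sine arch whose apex height shrinks proportionally
to the remaining length: `H(q, t) = h₀·L(t)/L₀·sin(πq)`, linear in time
for constant rates, with closed-form meeting point `r_A/(r_A + r_P)`.
Defaults (250 μm opening, 60 μm apex, 12 + 12 nm/s, 5-min frames) close in
≈ 2.9 h, the scale of a live-imaged closure.

## Statistics

Fold-change filtering uses signed ratios (−1.5 = 1.5-fold down) and an
inclusive threshold (FC ≥ +t or ≤ −t). Expected false positives are
n·FDR with the nearest integer alongside.

The one-way equal-means test permutes group labels: the statistic is the
between-group sum of squares of group means about the grand mean, which is
a monotone function of F under relabelling, so any permutation-exchangeable
F-type statistic gives the same p-value; this one is the cheapest. The
p-value uses the add-one estimator `(1 + #{S* ≥ S}) / (1 + n_resamples)`,
which cannot return 0 and keeps the test valid at any resample count. Ties
with the observed statistic count as exceedances (with a 1e-12 relative
guard against round-off), which makes the test exact-conservative; on a
3-vs-3 complete separation the attainable minimum is the enumerated
2/C(6,3) = 0.1. Dunnett, Kruskal–Wallis and Fisher's exact comparisons are
delegated to standard libraries rather than re-implemented.

## Known limitations

- No automatic LE detection or contour tracking: midlines and contours
  arrive as annotations; the marker-based boundary suggester is advisory
  only and the annotation file always wins.
- "Cells" are equal-length tenths of a segment, not segmented nuclei; real
  cell-size variation within a segment is averaged over.
- The straightening assumes the ribbon does not fold
  (`w · curvature < 1`); it warns, but does not correct, beyond that.
- Output numbers are in arbitrary fluorescence units; nothing calibrates
  across imaging sessions beyond the per-image background subtraction.
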