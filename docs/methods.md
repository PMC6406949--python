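# Methods

`weirtrack` analyses transmitted-light video of a slanted-weir microfluidic
cell sorter and computes the separation-performance statistics of such a
device. This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the tests demonstrate.

## Background model

Each pixel's intensity is modelled as a K-component Gaussian mixture
(weights `w_k`, means `mu_k`, standard deviations `sigma_k`). Per frame and
pixel:

1. components are ranked by `w/sigma` (persistent, low-variance components
   first; ties broken by component index, so the update is deterministic);
2. the first ranked component with `|x - mu_k| <= match_sigma * sigma_k`
   matches the observation;
3. weights decay toward the match indicator, `w_k <- (1-a) w_k + a 1[k]`,
   and the matched component moves toward the observation with the same
   rate (`rho = a`): `mu <- (1-rho) mu + rho x`,
   `sigma^2 <- max(sigma_min^2, (1-rho) sigma^2 + rho (x - mu_new)^2)`;
4. with no match, the lowest-ranked component is replaced by
   `(mu = x, sigma = sigma_0, w = w_init)` and weights renormalise;
5. the background set is the smallest ranked prefix whose cumulative weight
   exceeds `T`; a pixel is foreground iff nothing matched or the match lies
   outside that prefix.

Classification (steps 1, 2, 5) uses the state *before* the frame's update,
so each frame is judged against the model it was observed under; the
alternative (post-update weights) differs only transiently after weight
crossings and was rejected for being harder to reason about. `rho = a` is
the simplest stable choice of second learning rate; density-weighted
variants can be emulated through the config but are not implemented.

Defaults: `K = 5`, `a = 0.01`, `match_sigma = 2.5`, `T = 0.7`,
`sigma_0 = 15`, `sigma_min = 4`, `w_init = 0.05`, 50 burn-in frames. These
are standard adaptive-mixture practice; all are exposed in the
`background:` config block. Two consequences matter for protocol design:

* **Variance settling.** On near-noiseless footage the matched variance
  decays by a factor `(1-a)` per frame, so `sigma` reaches its floor only
  after `ln(sigma_min^2/sigma_0^2)/ln(1-a) ~ 260` frames. Area
  measurements taken before settling are biased low by a slightly
  conservative detection threshold; measurement scenes therefore start
  admitting cells only after the model has settled.
* **Flux limit (absorption).** A pixel that is covered by cells a fraction
  `d` of the time accumulates roughly weight `d` in its cell-level
  component; once `d` approaches `1 - T` the cell intensity joins the
  background prefix and moving cells are eaten by the model. All cells
  funnel along the same weir line, so the per-pixel duty cycle there is
  (cell footprint in frames) / (entry spacing). The synthetic study
  conditions keep this duty below ~0.2, which is also the physically
  relevant regime for rare-cell enumeration.

The vectorised update is verified bit-exactly against an independent scalar
reference implementation on random videos.

## Segmentation and tracking

Foreground masks are cleaned by one 3x3 binary opening (speckle removal)
and one 3x3 closing (hole filling); 8-connected components of at least
`min_blob_area` (default 30 px^2) become blobs. Shape comes from the
moment-equivalent ellipse (second-order central moments); the minor axis is
floored at 1 px for degenerate components. Blobs whose bounding box lies
within 1 px of the frame edge are flagged as border-clipped — the opening's
zero padding erodes the outermost row, so a truly clipped blob can sit one
pixel inside the edge — and excluded from shape statistics, since a clipped
disk masquerades as an elongated object.

Tracking is greedy gated nearest-neighbour association with a
constant-velocity prediction (last centroid plus last displacement).
Candidate pairs within `gate_radius` (default 12 px, ~1.5x the expected
per-frame displacement) are accepted in ascending distance order with
deterministic tie-breaking; unmatched blobs seed new tracks, and tracks
close after `max_misses` (3) consecutive missed frames. Tracks shorter than
`min_track_length` (3) are discarded. Cells ride the flow on near-parallel
paths, so a global assignment solver would change nothing in practice;
on unambiguous configurations the greedy assignment equals the exhaustive
minimum-cost assignment, which the tests check. Touching cells are *not*
split: a merged blob is carried as one object and flagged as a doublet when
its area crosses the doublet threshold.

## Morphometry and outlet enumeration

A track becomes one cell record. Outlet assignment is gate-style
first-entry: the first outlet ROI the centroid enters counts, so a cell
that leaves the field of view after passing the outlet is still enumerated;
a track that somehow enters both ROIs keeps its first label and logs a
warning. Size is the median blob area (um^2, `area = pixels *
pixel_scale^2`) over unclipped observations. Morphology is `elongated` when
the out-of-band median aspect ratio exceeds 1.4, else `spherical`.
Deformability uses the transient aspect-ratio gain during weir contact:
`flexible` if the in-band maximum aspect ratio reaches 1.25x the
out-of-band baseline with at least 3 in-band observations, `stiff` if the
band was visited without such a gain, `undetermined` if the band was never
visited. The deformation index (in-band aspect gain) is this package's
operational definition; it is a reasonable but not unique way to quantify
"differing deformability". Doublets are flagged from 560 um^2, the area
where two touching ~20 um tumor cells become indistinguishable from one
blob. Size histograms use 50 um^2 bins aligned at zero, and the peak bin is
the lowest-index bin attaining the maximal count — the convention under
which a ~20 um tumor population peaks in [300, 350) um^2.

## Separation statistics

For one trial with `n_total` cells enumerated at both outlet ROIs and
`n_waste` of them at the waste ROI, efficiency is
`(n_total - n_waste)/n_total`. Averages over trials are reported to three
decimals under two conventions — the unweighted per-trial mean (default)
and the pooled `1 - sum(waste)/sum(total)`; on the canonical five-trial
example (totals 10/50/100/150/200, waste 0/3/4/7/2) both give 0.969.
Log depletion of a hemocyte class is
`log10(baseline_concentration x volume / observed_separated)`; defaults are
whole-blood baselines 5e9 erythrocytes/mL and 5e6 leukocytes/mL over a
2 mL run, under which 63 escaping erythrocytes are an 8-log and 26
leukocytes a 5.6-log depletion (mixed printed precision, so the rounding
convention is an explicit argument). With zero observed cells the finite
lower bound `log10(baseline x volume)` is reported and flagged. Purity is
the leukocyte share of enumerated hemocytes, as a rounded integer percent.

## Synthetic scene generator

The generator emulates the footage such a device produces: a bright field
(default 200) with dark cells (default 60), a weir line crossing the frame
at a slant, cells entering from the left, per-pixel i.i.d. Gaussian sensor
noise and a slow linear illumination ramp — the two disturbances a
background model must absorb. Motion is piecewise linear: straight along
the channel until weir contact, then along the weir to the separation
outlet or straight across it to the waste outlet, with the route drawn
per cell as a Bernoulli variable (`route_separation_prob`). Deforming cells
ramp their aspect ratio linearly to `deform_gain` x baseline over 4 frames
while inside the weir band, oriented along the weir, and relax after
leaving. Cells render as anti-aliased filled ellipses whose 1-px soft edge
tapers *inside* the true boundary, so the rendered support equals the
ground-truth ellipse and low-threshold detection measures area with only a
small negative bias (about 1-5% depending on the model's current variance).

The weir angle is 45 degrees in the image plane — schematic, chosen so a
compact 120x160 px frame contains the full geometry; the fabricated devices
this emulates use much shallower weirs over a millimetre-scale field of
view, which a simulator need not reproduce to exercise the analysis. Cell
sizes default to ~20 um tumor cells (area ~314 um^2 at 1 um/px, matching
the expected 300-350 um^2 histogram peak), ~10 um leukocytes and ~7 um
erythrocytes; 7 um cells sit at the default detection limit
(~38 px^2 against a 30 px^2 blob cut), so hemocyte-heavy studies should
raise the pixel scale or lower `min_blob_area`.

Entries are evenly spaced in time (constant injection flux) with uniformly
random entry rows, retried so no cell is fully occluded at entry; a
population that cannot be placed, or a video too short for every cell to
finish its run, raises a generation error naming the population. Every
random purpose draws from its own child stream of the scene seed
(`numpy` `SeedSequence` spawn keys), so identical configs give bit-identical
videos and any single stream — e.g. the routing draws — can be replayed in
isolation. Ground truth records the full per-frame pose of every cell.

What the generator does *not* model: cell-fluid coupling, rotation,
out-of-focus blur, fluorescence, overlapping entry streams, or cells
changing route mid-channel. Passing tests therefore demonstrate the
correctness of the analysis chain under controlled conditions, not
performance on real microscope footage.

## Problem sizes used in tests and the acceptance script

Scenes are 120x160 px at 1 um/px. The detection-fidelity scene uses 20
noiseless ~20 um cells; the deformability scene 20 cells with 50% event
probability at noise sigma 5; efficiency recovery uses 20 scenes x 100
cells per routing probability (0.90/0.95/0.97) at noise sigma 5, judged
against the exact central binomial interval of the 2000 route draws; the
size-distribution scene uses 200 cells of 20 +/- 1 um. These sizes keep a
full run deterministic and fast while leaving every statistic
well-resolved.

## Known limitations

* Efficiency estimation counts tracks, not cells: merged doublets count
  once (flagged), and a cell missed by the tracker is simply absent. At the
  fluxes studied here this bias is below the binomial noise floor.
* The background model fails above the documented per-pixel duty cycle;
  this is inherent to adaptive background subtraction, not a bug.
* Aspect-ratio-based deformability requires the weir band to be visited
  with enough observations; fast crossings at low frame rates yield
  `undetermined` or `stiff` labels by default.
* AVI input requires an imageio backend able to decode it; TIFF stacks and
  PNG sequences are the first-class interchange formats.
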