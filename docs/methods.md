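# Methods

## Measurement model

A plate's observations are daily leading-edge radii `r(axis, day)` in mm,
measured from the edge of the 5 mm inoculation plug along three equally
spaced axes, with the first trace at 24 h (day 1); no day-0 point exists.
The radial extension rate is the slope of one ordinary least-squares
regression of radius on day pooling all of the plate's axis points. The
intercept is estimated rather than pinned at zero: although `r(0) = 0` at
the plug edge in the idealized model, plug placement and marker width
introduce small offsets, and pooling "all data" with a free intercept is
the standard practice this package follows. Missing axis/day points are
simply absent (unbalanced OLS); non-monotone radii along an axis warn but
are kept, because real marker traces can wobble and cross. Fewer than two
distinct days is an error; contamination-flagged plates are rejected from
fitting and excluded from all summaries, and the exclusion is recorded.

Rates below 2.0 mm/day (strict `<`; configurable) carry a `below_loq`
flag: daily marker traces cannot resolve slower growth reliably. Flagged
rates are reported, never dropped, and the flag propagates through REU
tables so reports can mark whole groups as at the measurement limit.

## REU normalization

For each lab, the reference rate is the arithmetic mean of that lab's
plate rates for the reference condition (default organism `G_lucidum`,
substrate source `local`; both configurable). Every plate rate the lab
reported is divided by that mean. Computing REU per plate (rather than per
group mean) preserves within-lab spread for plotting and pooled analyses.
The singular "the lab's reported rate" is read as the mean over the lab's
reference replicates; with triplicate plates this is the natural,
lowest-variance reading. A lab with no usable reference plates is a hard
error that names the lab.

Interlab variability is summarized per organism as the CV across labs of
per-lab means (the quantity that measures between-lab agreement); a
`pool_plates` switch pools plates across labs instead. CV uses the sample
SD (n−1). CV reduction `100·(1 − CV_REU/CV_raw)` is returned unclamped —
normalization can worsen variation — and is undefined (error, or NaN in
table outputs) when the raw CV is zero.

## Generative model of an interlab study

The synthetic generator is deliberately minimal and mirrors the structure
the analysis assumes:

    v(plate) = mu_organism · sigma_substrate · sigma_source · lambda_lab · exp(eta_plate)
    r(axis, day) = clip(v·day + epsilon, 0, dish_radius − plug_radius)

with `lambda_lab = exp(omega·z)` lognormal (SD of log = omega),
`eta_plate ~ N(0, tau²)`, and `epsilon ~ N(0, s²)` i.i.d. per axis and
day. Multiplicative lab and plate effects are exactly what a ratio
statistic can remove, so this is the model under which REU's claimed
properties are provable: with `tau = s = 0`, per-lab REUs equal the
analytic `true_reu = (mu_o·sigma_sub)/(mu_ref·sigma_ref)` to float
precision for any omega, and the across-lab CV of raw rates converges to
the lognormal identity `sqrt(exp(omega²) − 1)`.

Defaults are the standard assay conditions: 5-day traces, 3 axes,
triplicate plates, 9 cm dish, 2.5 mm plug radius. The packaged demo study
(`demo_interlab_config`) uses 5 labs, 4 organisms with intrinsic rates
2.5–6.0 mm/day (the range plate assays typically span), one substrate in
`local` and `central` sourcing with identical factors, `omega = 0.2`,
`tau = 0.05`, `s = 0.5 mm`. These values put across-lab raw CVs in the
0.06–0.39 band community studies report while keeping 5-day radii inside a
9 cm dish.

Radii clip at 0 and at the dish rim; rim-clipped plates are flagged
("saturated") in the ground truth, because saturation breaks the linear
growth model and analyses of the generator's multiplicative structure
should exclude such plates (as the acceptance checks do at `omega = 0.4`,
where fast organisms in high-multiplier labs reach the rim). Randomness is
organized as one master seed with sub-streams keyed by (lab, organism,
substrate, source, plate), so enlarging a design never perturbs existing
draws. What the generator does **not** model: lag phases, non-linear
growth, hyphal morphology, substrate chemistry, or lab effects that are
organism-specific — passing tests demonstrate correct behaviour under
multiplicative extrinsic effects, not under arbitrary real-world effects.

## Plate images

The renderer draws a dark dish rim and one dark closed curve per day on a
light background. Ring radius as a function of angle is band-limited
trigonometric interpolation (FFT of the per-axis anchor radii), so the
curve passes exactly through each axis's traced radius and is smooth in
between; a kinked (piecewise-linear) curve was rejected because the kink
would sit exactly on the measurement axes and bias the radial intensity
profile there. Optional waviness uses a cycle count rounded to a multiple
of the axis count so the perturbation vanishes on every axis. Strokes are
anti-aliased (1 px linear coverage ramp); a zero stroke width is an error.
Gray levels live in [0, 1]; seeded Gaussian pixel noise is added last.

Measurement reverses the manual Fiji workflow. Calibration:
`mm_per_pixel = dish_diameter_mm / dish_diameter_px`, with the dish found
by Canny edges + circular Hough over 38–49 % of the image's smaller
dimension (coarse 3 px scan, then 1 px refinement), followed by a radial
centre-of-mass refinement of the rim radius — Canny locks onto one edge of
the rim stroke, and the refinement makes calibration independent of stroke
width. A manual `((cx, cy), diameter_px)` override bypasses detection
entirely. Rays start at the plug edge (2.5 mm from centre along each
axis), are sampled every 0.25 px by bilinear interpolation out to 2 mm
short of the rim (so the rim itself is never counted as a trace), and the
profile is boxcar-smoothed over 3 px. Crossings are minima with prominence
≥ 10 % of the profile's dynamic range; minima closer than one stroke width
(0.8 mm default) merge into a single crossing. The reported position is
the midpoint of the dip's half-prominence width: marker strokes give
flat-bottomed dips whose deepest noisy sample wanders, while the
half-width midpoint is stable to a fraction of a pixel. Traces are assumed
dark-on-light; an `invert` flag handles the opposite polarity.

Day `d` is the d-th crossing. An axis whose crossing count differs from
the expected day count keeps its partial measurements and is flagged;
extraction fails only when *no* axis yields any crossing (a plate with one
missing ring should degrade gracefully, not error).

## Statistics

Paired-mean regression fits OLS of y-group means on x-group means (one
point per organism or per lab×organism, matching how substrate-correlation
analyses are reported); R² is the squared Pearson correlation of the
means, and the 95 % band is the mean-response confidence interval with
n−2 degrees of freedom. Group SDs are carried for error bars only.

One-way ANOVA uses the textbook between/within decomposition. When the
within-group sum of squares is exactly zero the result is the documented
sentinel `F = +inf, p = 0, degenerate=True` rather than an exception, so
constant-group edge cases in automated reports fail soft.

Tukey–Kramer HSD computes `q = |m_i − m_j| / sqrt((MSW/2)(1/n_i + 1/n_j))`
with adjusted p from the studentized range distribution `(k, N−k)`;
`pairwise_q` exposes the statistics so that large null simulations can use
the equivalent critical-value decision (one `ppf` instead of thousands of
slow `sf` evaluations — the decisions are mathematically identical because
the survival function is strictly decreasing). Tests cross-check the table
against statsmodels' `pairwise_tukeyhsd` and a brute-force evaluation of
the formula. Family-wise control is Tukey's only; no extra FDR layer.
Shapiro–Wilk delegates to scipy and is reported only — nothing downstream
is gated on normality.

## Problem sizes and numerical choices

The test suite and acceptance script use: 100 random plates for OLS oracle
equivalence (rel. tol. 1e-10); 200 labs and 24 replicate runs for the
lognormal CV limit (agreement within 3 Monte-Carlo SEs); 200 seeds per
point on the omega grid {0.05, 0.1, 0.2, 0.4}; 100 rendered plates at
0.1 mm/pixel for the image round trip (observed errors ~0.02 mm against a
0.2 mm contract); 10 000 null simulations for type-I calibration (±2
binomial SEs of 0.05) and 1 000 datasets for the k=2 HSD/t equivalence;
11 seeds for the demo-study majority properties. These sizes give stable
Monte-Carlo estimates at interactive runtimes.

Known limitations: dish detection assumes the rim is the dominant circle
in its radius band (38–49 % of image size) and will need the manual
override for unusual framings; automatic plug detection is not attempted
(the origin comes from geometry or the user); crossing detection assumes
trace rings separated by more than one stroke width — days with slower
growth than the marker width merge and flag rather than resolve.
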