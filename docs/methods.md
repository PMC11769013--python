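# Methods

## Allometric normalisation

Linear cardiac dimensions scale with body size. Each raw measurement
(cm) is divided by body weight (kg) raised to a parameter-specific
exponent *b*:

    normalised = value_cm / weight_kg ** b

The exponents are fitted constants from the veterinary allometric-scaling
literature and differ per parameter. They are **mandatory configuration**
(JSON map parameter → b): the package refuses to invent numeric constants
that its reference data do not pin down. Units are fixed — cm for
measurements, kg for weight — with no conversion layer. The reference grid
was derived from dogs under 20 kg; heavier animals are normalised anyway
but their profiles carry a `weight_warning` flag, because the applicability
of the grid outside that range is untested rather than wrong.

## Reference percentiles

Each parameter is summarised at eleven anchor probabilities
(min, 1, 2.5, 5, 25, 50, 75, 95, 97.5, 99, max) over two populations:
HEALTHY (no cardiac or systemic disease) and TOTAL (healthy plus cardiac
pooled). Summaries are always computed on *normalised* values. Missing
per-parameter values (unusable images) are skipped, not imputed, so n can
differ per parameter.

Quantiles use linearly interpolated order statistics (numpy's `linear`
method, the common "type 7" rule). The convention behind the published
reference table is unrecorded; conventions differ at most at the
resolution of single order statistics, which is well inside the rounding
of the published values, and the estimator used is stored on every
summary (`estimator` field) so alternatives can be compared.

The packaged grid (`cardiobox/data/reference_percentiles.csv`) is a
transcription of the published reference percentiles for 802 healthy and
2967 total dogs; the pipeline cannot re-derive it because the underlying
per-animal data are not public.

## Box construction

For one parameter, with healthy percentiles `h` and total percentiles `t`,
the ten continuous boundaries b0..b9 are:

| region | boundaries | rule |
|---|---|---|
| below normal (boxes 1–3) | b0..b3 | three equal thirds of [t.min, h.P1] |
| normal (boxes 4–6) | b3..b6 | three equal thirds of [h.P1, h.P99] |
| above normal (boxes 7–9) | b6..b9 | strategy-dependent, see below |

Two upper-region strategies are exposed because the published limit grid
and its own verbal description disagree:

* `TABLE_CONSISTENT` (default): `b8 = t.P99`, `b7 = (h.P99 + t.P99)/2`,
  box 9 spans `[t.P99, t.max]`. This is the rule the published grid follows
  for all seven parameters (e.g. LVIDSn b7 = (1.06 + 1.58)/2 = 1.32,
  IVSSn b8 = 0.90 = total P99).
* `PROSE_EQUAL_THIRDS`: three equal thirds of `[h.P99, t.max]`, the literal
  reading of the published description. It reproduces none of the published
  upper-region limits; the disagreement is demonstrable with one call per
  strategy and is asserted in the test suite.

Degenerate regions (e.g. `t.min == h.P1`) are hard errors, never silently
collapsed, and under `TABLE_CONSISTENT` the total P99 must lie strictly
inside the upper region.

The published description also says box 5 is centred on the healthy
median. Equal thirds of [P1, P99] do not generally achieve that, and the
published limits are equal thirds, not median-centred — so the builder
does not enforce centring and instead reports `median_offset`
(healthy median minus the centre of box 5) as a diagnostic.

### Displayed bounds

Internally everything is continuous; classification never sees rounding.
For presentation, the boundaries are rendered as nine inclusive
(lower, upper) pairs on a 0.01 grid with a one-grid-step gap between
adjacent boxes. An interior boundary belongs to the box above it,
mirroring the half-open classification convention: the upper box's lower
bound is the boundary rounded *up* to the grid and the lower box's upper
bound is one step below that. The four anchor boundaries (overall min,
healthy P1, healthy P99, overall max) round to nearest, so the printed
normal range starts exactly at P1 and ends exactly at P99. Against the
published grid this reproduces every one of the 126 printed bounds to
within ±0.01; the residual ±0.01 differences are attributable to the
original limits having been computed from unrounded percentiles (the
packaged percentiles are 2-decimal) and to a printing convention that is
not internally consistent at the last digit across parameters.

## Classification

Boxes are half-open `[b_{k-1}, b_k)` against the continuous boundaries,
with box 9 closed at the top, so classification is monotone and every
finite value maps to exactly one box. A value exactly at the healthy P1
is therefore box 4 — the 1st percentile of healthy animals is normal.
Values outside `[b0, b9]` are clamped to box 1 or 9 with an explicit
`BELOW_MIN` / `ABOVE_MAX` flag instead of being rejected; the chart draws
an arrow glyph at the grid edge for them. Because classification uses
continuous boundaries, values falling in the 0.01 display gaps are
handled without any pre-rounding.

## Rendering

SVG 1.1 via the standard-library XML tree: per parameter row, nine box
outlines over a single grey (`#D3D3D3`, configurable) rectangle spanning
cells 4–6, one marker (dot or cross) per assigned parameter, and 1–9
column labels. Markers are centred in their cell by default; proportional
within-cell placement `(value − b_{k−1})/(b_k − b_{k−1})` is opt-in. The
renderer draws the classifier's output verbatim — it never re-derives a
box from a value. A plain-text renderer produces the same grid with
braces delimiting the grey zone, for terminals and logs.

## Synthetic populations

The generator emulates the statistical structure of the reference grid so
the whole pipeline is testable offline:

* **Healthy animals** draw normalised values from the monotone
  piecewise-linear quantile function through the eleven HEALTHY anchors —
  an inverse-CDF sampler, not a parametric family, because the anchors are
  the only distributional information available. Between anchors, linearity
  is an assumption.
* **Cardiac animals** draw from the deconvolved mixture component
  `F_c = (F_t − q·F_h)/(1 − q)` with healthy fraction `q` (802/2967 at the
  default group sizes), evaluated on a dense grid and forced monotone by a
  cumulative maximum where the subtraction locally dips — this happens where
  the healthy density locally exceeds the total density divided by q, e.g.
  at tied healthy anchors (IVSSn P1 = P2.5). The cost of that correction is
  measurable: `pooled_quantile_residuals` reports the anchor-wise error of
  the pooled mixture against the TOTAL targets (≤ 0.014 normalised units on
  the packaged grid, zero for most parameters).
* **Weights** are uniform on the configured range (default 2–20 kg, the
  small-dog demographic of the reference data), and raw centimetre values
  are back-computed as `normalised × weight**b`, so re-normalising a
  generated population reproduces the sampled values to machine precision.
* **Sampling** is Latin-hypercube stratified by default: the n uniforms
  feeding the inverse CDF are one draw per 1/n stratum, randomly permuted.
  Each value is still marginally a draw from the target distribution, but
  the empirical quantiles of a size-n population converge at O(1/n) rather
  than O(1/√n) — appropriate for a generator whose stated purpose is to
  emulate a population with given quantiles. Independent draws are
  available with `sampling="iid"`. All draws flow from one seeded
  generator; the same seed reproduces the population exactly, including
  byte-identical CSV output.
* Parameters are sampled **independently**: the reference grid carries no
  covariance information and none is invented. Synthetic populations
  therefore do not reproduce the strong inter-parameter correlations of
  real dogs (a dilated ventricle in diastole and systole, say), and passing
  recovery tests say nothing about joint distributions — only about each
  parameter's marginal.

Default group sizes are the reference study's (802 healthy, 2165 cardiac).
The recovery tests use 802 and 20,000 healthy animals for the anchor
checks, and 20,000 healthy plus 53,990 cardiac (the same 2165:802 group
ratio) for the end-to-end limit-recovery check; at those sizes the
stratified sampler recovers healthy anchors to about 0.001 and the
rebuilt continuous boundaries to well under 0.01 normalised units.

## Numerical choices

* Display rounding works in integer grid units with a 1e-4 grid-unit guard
  so that boundaries that are exactly on the grid (up to float noise from
  the thirds/midpoint arithmetic) are treated as such.
* Quantile functions validate `u ∈ [0, 1]` and reject non-monotone anchor
  sets; CDF inversion collapses flat runs before interpolation; tied
  anchors become CDF steps of width 1e-9 in value.
* Classification is a bisection over ten boundaries; the brute-force
  interval scan exists only in the test suite as an oracle.
* File writes are atomic (temp file + rename): a failing CLI command never
  leaves a partial output.

## Limitations

* The packaged percentiles are 2-decimal transcriptions; boundaries derived
  from them inherit that precision, hence the ±0.01 comparison band against
  the published limit grid.
* No allometric exponents are shipped; results are only as good as the
  exponents supplied.
* The grid is validated for dogs under 20 kg and for breeds without
  breed-specific reference values; the package flags but does not model
  larger or excluded breeds.
* Box membership carries no diagnostic semantics by itself; the package
  deliberately stops at classification and display.
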