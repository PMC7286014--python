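# Methods

This note documents the models, conventions and numerical choices behind
`sfdose`, and what the synthetic validation does and does not demonstrate
about real measurements.

## Scan processing

**Coordinates and units.** Depth in mm, positive downward from the water
surface; lateral positions in mm with 0 on the beam central axis; field
sizes in cm at the 100 cm isocentre plane unless stated otherwise. Dose
values are relative.

**Smoothing** is local polynomial least squares (Savitzky–Golay), default
window 7 samples, order 2. Commissioning software typically smooths scans
with an unspecified vendor filter; a local polynomial was chosen because it
preserves peak position and reproduces any polynomial up to the fitted
order exactly — a property the test suite asserts directly. Endpoints are
completed by evaluating the polynomial fitted to the terminal window; on
non-uniform grids a per-point windowed polyfit is used instead of the
uniform-grid filter.

**Point queries and level crossings** use linear interpolation between the
bracketing samples, with no further refinement. On the ≤ 0.5 mm grids used
here the residual error is far below the 0.01 cm at which field widths are
reported: near the 50% level an erf-shaped edge is at its inflection point,
so the linear-interpolation error is third order in the grid spacing
(measured worst case ≈ 0.003 mm against a 0.001 mm brute-force search).

**d_max** is refined by a parabola through the maximum sample and its two
neighbours (exact for a locally quadratic peak). A flat plateau of tied
maxima returns the plateau midpoint — symmetric and deterministic. A
maximum on the scan boundary is returned as-is with a warning, since no
interior refinement is possible.

**Degenerate profiles** (monotone, constant) raise shape errors naming the
offending side rather than returning NaN; a silent NaN would propagate into
S_clin and corrupt the k lookup downstream.

**Reporting precision**: field widths 0.01 cm, output factors 3 decimals,
%SD 1 decimal, with round-half-even. All quantities are carried unrounded
internally.

**Chamber effective point of measurement**: no depth shift is applied to
chamber depth-dose scans by default. Scan conventions differ on whether a
shift was already applied by the acquisition software; a user who knows a
shift is needed can offset the depth axis before analysis.

## Field geometry

S_clin is the geometric mean of the cross-plane and in-plane FWHM, both
taken at the measurement plane (e.g. the 110 cm plane for 100 cm SSD and
10 cm depth) and combined at that plane without back-projection to the
isocentre — matching how commissioning tables that list widths at the
measurement plane are constructed. `project_length` handles the purely
divergent scaling between planes.

## Output factors

- Readings are averaged before ratioing (ratio of means); at the ~0.3%
  repeatability of charge measurements the difference from a mean of
  ratios is negligible, and the ratio of accumulated means is what
  electrometer practice produces.
- k(S_clin) is interpolated linearly; protocol tables are dense and slowly
  varying, so higher-order interpolation would change k by far less than
  its stated uncertainty. The table range is strict by default:
  extrapolating k below the smallest tabulated field is exactly the
  failure mode that makes uncorrected small-field commissioning dangerous.
  A `clamp` flag returns the endpoint value with a warning for users who
  accept that risk.
- k tables are input data, never embedded constants. Protocol values
  belong to their publisher; the package ships only generator-implied
  tables.
- The FOF at the msr field is exactly 1 before and after correction, by
  definition.
- Non-monotone corrected FOF sequences warn rather than fail: flat or
  slightly inverted neighbouring values are within measurement uncertainty
  and occur in real commissioning tables.
- The intermediate field method derives the detector's chain correction
  from its msr-referenced table as k(S_clin)/k(S_int); with the
  intermediate field equal to msr and a unit chamber correction the chain
  reduces to the direct method exactly (bit-identical, asserted in tests).

## Comparison statistics

%SD uses the sample standard deviation (n−1 divisor) divided by the mean.
With three detectors the n−1 convention is the one consistent with every
recomputable published %SD cell used in the regression suite, and it is
adopted for MU comparisons as well. SD is forced to exactly 0 for
bit-identical inputs so "SD = 0 iff all values equal" holds despite
floating-point residue. Comparisons against printed values in tests allow
±1 unit in the last printed digit, absorbing the source tables' own
rounding.

## Synthetic generator

The generator emulates the study conditions of a 6 MV flattened-beam
small-field commissioning session. Defaults (all overridable in one YAML
config):

| parameter | default | why |
| --- | --- | --- |
| TPR20,10 | 0.665 | standard 6 MV beam-quality index |
| d_max | 15 mm | typical 6 MV depth of dose maximum |
| μ | 0.0050 /mm | gives PDD(10 cm) ≈ 66.5%, typical 6 MV |
| source blur σ | 3 mm | reproduces 20–80% penumbra of 5–6 mm at 10 cm depth |
| fields | 1, 2, 3, 4, 6, 10 cm | standard small-field commissioning ladder |
| reading noise | 0.3% (3 repeats) | charge-measurement repeatability |
| occlusion onset / scale | 1.2 / 2.0 cm | mild output drop only below ~1 cm |
| FOF plateau c₁, λ | 0.45, 4.0 cm | output-factor curve in the 0.67–1.0 range over 1–10 cm |
| axis width bias | ∓0.5 mm | cross/in-plane collimator asymmetry, S_clin ≠ nominal |

Functional forms — erf-edged profiles, bi-exponential depth dose,
exponential response perturbations — are the simplest smooth families that
reproduce the qualitative small-field phenomenology; they are fixtures, not
physics claims.

**Detector models.** Volume averaging is a 1-D top-hat of the detector's
nominal sensitive length along the scan axis (3.6 mm micro-chamber cavity,
2.0 mm diode diameter, 0.8 mm scan diode); over/under-response is
`1 + β·exp(−S/τ)` with β = +0.10 (shielded diode), −0.06 (unshielded
diode), 0 (chambers), τ = 2 cm. These amplitudes place the uncorrected
cross-detector %SD at the 1 cm field in the 4–6% regime reported for this
detector trio, which is the fixture-calibration target of the generator.
Small depth-linear PDD tilts (+1.0·10⁻⁴/mm micro-chamber, −0.8·10⁻⁴/mm
unshielded diode) emulate the percent-level depth-dose ordering between
detector classes.

**Implied correction factors.** The generator's k is the exact reciprocal
of the normalized response, k(S) = 1/r(S). The emitted k-table knots are
placed at the *dosimetric* S_clin extracted from the generator's own
emitted scan-detector profiles — the same protocol-style index a user
looks up — so a noise-free pipeline run (read → FWHM → S_clin → reading
ratio → k lookup → corrected FOF) recovers the true output factor to
machine precision. This closure is the package's strongest internal check:
any bias in parsing, width extraction, interpolation or the correction
algebra would break it.

**Determinism.** One integer seed drives all randomness; the same seed
produces byte-identical output files (floats are written with shortest
round-trip repr, and the CSV readers parse with round-trip precision).

**What passing tests do not show.** The generator has no head-scatter
model, no MLC leaf-end effects, no energy-dependence of diode response
beyond the single exponential, no angular response, and no measurement
drift. Its detector-perturbed penumbra is broader than the point-detector
penumbra at every field and broadens monotonically with aperture size, but
the *growth* of the chamber–diode penumbra gap toward the smallest fields
seen in real scans is not reproduced below ~2 cm: renormalizing the
volume-averaged profile to its own central-axis value largely cancels the
extra edge broadening in this simple blur model. Likewise, recovering
ground truth here validates the analysis chain, not any claim about how
close a given real detector's k table is to truth.

## Problem sizes

Default scenarios use 6 fields × 4 detectors, profiles on a 0.2 mm grid,
depth doses on a 0.5 mm grid to 310 mm, 3 reading repeats; replicate
studies use 200 seeded repetitions. These sizes keep the full test suite
and the acceptance script in the seconds range while leaving all
grid-dependent errors at least an order of magnitude below the reporting
precisions above.
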