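# Methods

## The model

Haemocyanin oxygenation is described by fixed-PO2 pH–saturation curves: at
each constant oxygen tension the fraction of bound oxygen rises
sigmoidally with pH.  The package's empirical contract is the
five-parameter logistic (5PL)

    S(pH) = c + (d − c) / (1 + exp(b (e − pH)))^f

with steepness `b > 0`, lower/upper asymptotes `c < d`, anchor `e` and
asymmetry `f > 0`.  No mechanistic allosteric (MWC/Hill) model is
implied; the 5PL is a flexible sigmoid whose derived quantities carry the
physiology:

- **pH50** — the pH where `S = 0.5`, found by bracketed root finding
  (xtol 1e−8).  It is reported *undefined* when the fitted asymptotes
  exclude 0.5 (cold pigments can retain > 50 % of oxygen even under pure
  N2) **or** when the crossing falls outside the pH span of the data.
  The second condition matters in practice: at high PO2 the half-
  saturation pH can lie below the end of the CO2 ramp, and an
  extrapolated pH50 from a shoulder-only fit would corrupt everything
  downstream.
- **Bohr coefficient** — each curve's PO2 *is* the P50 at its own pH50,
  so regressing log10 PO2 on pH50 across the curves of one pigment gives
  Δlog10 P50/ΔpH directly.  When curves from several temperatures are
  pooled, the points are first centred within each temperature group
  (temperature shifts the Bohr line without changing its slope); for a
  single temperature this reduces to ordinary least squares.
- **P50 at a stated pH** — the Bohr line evaluated and exponentiated.  A
  temperature with only one defined pH50 still yields a P50 when the
  pooled Bohr slope is supplied (line of that slope through the point);
  this mirrors the cold extreme where only the 1 kPa curve crosses 50 %
  within the ramp.
- **Cooperativity of oxygenation-linked proton binding** — carrying
  capacity × max |dS/dpH| (Δmmol O2 L⁻¹/ΔpH).  The maximiser is numeric
  (bounded Brent) and cross-checked against the closed-form stationary
  point of the 5PL derivative (at `exp(b(e − pH)) = 1/f`); disagreement
  beyond 1e−6 relative raises an error.

### Fitting

Nonlinear least squares (scipy `least_squares`, TRF, bounded) from five
deterministic starts built from data quantiles, because 5PL fits are
initialisation-sensitive.  A start counts as converged when the optimiser
reports success *or* the residual is at machine level (near-flat series
leave the parameters on a ridge where iteration never formally
terminates).  Confidence intervals come from seeded residual resampling
(default 1000 draws, percentile 2.5/97.5, widened to bracket the point
estimate).  Note the raw `e` parameter is only identified jointly with
`b` and `f`; the identifiable location quantities are the inflection pH
`e + ln f / b` and the half-saturation pH, which is why tests and derived
outputs use those.

## In-vivo projection

- **Alpha-stat venous pH**: linear, slope −0.0153 pH/°C.  The line is
  anchored at pH 7.42 / 0 °C, which reproduces the venous pH series
  7.42 / 7.27 / 7.19 / 7.11 at 0/10/15/20 °C to two decimals (an anchor
  of exactly 7.27 at 10 °C gives 7.117 → 7.12 at 20 °C and cannot
  reproduce the last value; 7.42@0 is the same line through the rounded
  anchor 7.27 at 10 °C).  Arterial pH is venous + 0.11.
- **Gas tensions**: arterial 13 kPa; venous 4 kPa (resting) or 1 kPa
  (exercised); held constant across temperature.  Saturation at a PO2
  between the four measured levels is interpolated linearly in log10 PO2
  across the fitted curves; no extrapolation outside 1–21 kPa.
- **Dissolved oxygen**: air-saturated seawater concentration from the
  Garcia–Gordon combined fit to the Benson–Krause data (µmol/kg),
  converted to µmol/L with the EOS-80 surface-density polynomial
  (357.7 µmol/L at 0 °C / 35 psu), then Henry-law scaled by PO2/21 kPa.
  21 kPa (the measured calibration level) is used rather than a
  vapour-corrected air PO2.
- **Budget conventions**: bound release = capacity × (S_a − S_v);
  dissolved release = dissolved(13 kPa) − dissolved(venous PO2); the
  *dissolved fraction of total content* is air-saturated dissolved over
  (dissolved + full capacity) — the only convention consistent with the
  published percentage set (18.5 % at 0 °C for a 1.58 mmol/L pigment,
  17–20 % and 18–21 % for the warm-water species).

## Circulation model

Demand: mass-specific metabolic rate `MO2 = 3.35 M^−0.27` (mass in
grams — with kilograms the scaling constant would imply implausible
~7.5 mmol kg⁻¹ h⁻¹ for a 51 g octopod) scaled across temperature with
Q10 = 2.12.  Supply: haemocyanin-bound oxygen released per litre per
pass (dissolved O2 deliberately excluded unless added by the caller).
Required blood-volume turnover = MO2 / delivery / blood volume fraction
(5.2 % v/w).  With constant supply, the circulation increase over ΔT is
identically `(Q10^(ΔT/10) − 1)·100` = 112.0 % for 10 °C — the package
reports its own arithmetic; published figures derived from unrounded
internal values (e.g. 110.4 %) differ by rounding provenance, not model.

## The synthetic world

The generator emulates the diffusion-chamber protocol: pure-O2 and
pure-N2 calibration segments bracketing a linear pH ramp (8.1 → 6.8 over
30 min, 30 s sampling) at four constant PO2 levels, absorbance
`A = A_min + S·(A_max(t) − A_min)` with `A_max0 = 1.0`, `A_min = 0.1` AU
and a linear drift of the maximum signal (default −0.02 AU/h); raw pH
reads 0.136 above the free scale; i.i.d. Gaussian noise on absorbance
(0.005 AU) and pH (0.005).  Noise magnitudes are fixture choices — no
published values exist — set so that saturation-level noise is well below
the 0.02 sd used in the recovery studies.

Ground truth is a 5PL in pH whose *half-saturation* pH follows the Bohr
line `pH50(PO2, T) = ph_ref + (log10 PO2 − log10 P50(T)) / bohr_slope`
(the half-saturation rather than the raw inflection is anchored because
pH50 is what the downstream chain estimates; for the default symmetric,
zero-floor pigment the two coincide).  Temperature enters only through a
linear P50 shift (`temp_coeff`, kPa/°C) and the lower asymptote
(`lower_asymptote_dT`), reproducing the qualitative cold behaviour —
higher affinity and incomplete deoxygenation — without inventing binding
thermodynamics.  Default steepness 8.0 per pH unit corresponds to a
cooperativity of ~3.2 Δmmol O2 L⁻¹/ΔpH at capacity 1.58 mmol/L.

Respirometry traces are a step change of chamber O2 concentration
(capacity × sample volume / chamber volume) on a linear background flux;
the capacity estimator removes the background with a line fitted to the
pre-injection segment only (the post segment may carry the transient) and
measures the step as a difference of plateau medians (robust to spikes),
subtracting a seawater control to remove the dissolved-O2 share.

What a green test establishes: that the processing, fitting and budget
arithmetic recover a known truth under the stated noise.  What it does
not: real traces have correlated optical noise, pH-optode drift that is
only approximately linear, CO2-equilibration kinetics, and curve shapes
whose steepness varies with temperature — none of which the minimal
generator produces.  In particular, the bundled Antarctic pigment (single
steepness, linear P50 shift) delivers almost no bound oxygen between 13
and 4 kPa at 0 °C, so the illustrative circulation table at the cold end
shows extreme turnover demands; the measured study curves, being
shallower at 0 °C, gave a larger delivery there.  Exact replication of
the study's measured-delivery figures is out of reach without the raw
data and is not claimed.

## Numerical choices

- Saturation clipped to [0, 1] after calibration (noise can push values
  marginally outside); the 5 % minimum-signal uncertainty is propagated
  as a saturation envelope that brackets the point estimate.
- The pH-scale correction *subtracts* 0.136 from raw pH (free-scale pH
  reads lower in high-ionic-strength media); offsets outside
  [0.10, 0.20] are rejected unless zero (identity).
- Degenerate curve sets (identical pH50s, collapsed asymptotes) raise
  explicit errors rather than returning unstable slopes.
- All randomness flows from one root seed through named SHA-256
  substreams (`substream_seed`), so simulation and bootstrap are jointly
  reproducible and every derived seed stays below 2^31.
- ΔP50/°C is the plain difference quotient of P50 between two
  temperatures, each at its own alpha-stat venous pH; no sub-interval
  averaging is attempted.

## Known limitations

- The empirical 5PL carries no subunit mechanism; parameters other than
  the derived location/slope quantities have no physical reading.
- Linear interpolation of saturation in log10 PO2 is accurate to ~0.01
  only for gently sloped curves; for steep pigments mid-range
  interpolation error can reach a few percent saturation.
- The solubility fit and density polynomial are valid for −2–40 °C and
  0–42 psu; inputs outside raise errors rather than extrapolating.
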