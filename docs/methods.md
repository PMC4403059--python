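# Methods

## The analytical problem

Acetaminophen (~25 µg/mL at the working dilution), diphenhydramine
hydrochloride and pseudoephedrine hydrochloride (~1.5–2.25 µg/mL) absorb
with heavily overlapped bands between 200 and 300 nm, so none of the three
can be read directly from a mixture's zero-order spectrum.  The
zero-crossing derivative technique resolves them: because Beer–Lambert
absorbances add and differentiation is linear, the n-th derivative of a
mixture spectrum is the sum of the components' derivatives.  At a
wavelength where the derivative traces of the two *interfering* compounds
are zero, the mixture derivative equals the analyte's derivative alone and
is proportional to its concentration.  One analyte is therefore measured
per (derivative order, Δλ, wavelength) triple — ¹D for the dominant
absorber and ²D/⁴D for the two minor ones in the classical method — and
ordinary single-wavelength calibration does the rest.

## Derivative operator

The instrument-style Δλ derivative is implemented as an iterated centered
difference: order 1 is `D(λ) = [A(λ+Δλ/2) − A(λ−Δλ/2)]/Δλ`, and higher
orders apply the operator repeatedly with the same width.  Δλ is rounded to
the nearest even number of grid steps and the realised width is recorded on
the result (`effective_delta_lambda`); silent interpolation is avoided so
runs are bit-reproducible.  Each application shrinks the usable domain by
Δλ/2 on each side, and no padding is used — padded edges manufacture false
zero crossings.  A Savitzky–Golay variant (window = odd point count closest
to Δλ/step, polynomial order > derivative order, scaled by step⁻ⁿ) is
available when smoothing-differentiation is preferred.  Iterated
differencing has binomial weights, so i.i.d. instrument noise of SD σ maps
to derivative noise `σ·√C(2n,n)/Δλⁿ` — the quantity `derivative_noise_sd`
reports and the default amplitude floor (3× that value) is built from.

A consequence of the iterated-difference reading of Δλ: a fourth-order
derivative with Δλ = 27 nm needs 54 nm of margin on each side and has no
domain inside a 200–300 nm record.  The published triples (¹D Δλ=28.0 at
281.5 nm, ²D Δλ=31.5 at 226.0 nm, ⁴D Δλ=27.0 at 218.0 nm) therefore cannot
be realised under this operator on that range; they are carried as
literature fixtures, and the simulated method uses widths sized for the
synthetic bands (¹D Δλ=8, ²D Δλ=12, ⁴D Δλ=6 on a 0.1 nm grid).

## Zero crossings and working-wavelength selection

Crossings are located by linear interpolation between adjacent
opposite-signed derivative values; runs of exact zeros collapse to their
midpoint; crossings whose flanking amplitudes both fall below the amplitude
floor are discarded as noise.  The published method chose its working
wavelengths by inspection; here the choice is operational: every grid
wavelength where each interferent's |D| is at or below 0.5% of that
interferent's own maximum |D| (at its working concentration) is a
candidate, and among candidates the score
`|analyte D| × r²(mixture D vs analyte concentration)` is maximised, with
ties broken toward larger analyte signal, then lower wavelength.  The
residual tolerance and the floor are method parameters; the defaults above
are used throughout.

## Synthetic spectra

Compounds are modelled as sums of Gaussian absorptivity bands,
`A(λ) = Σ ε_peak·exp(−(λ−c)²/2σ²)·conc·path`, on a 200–300 nm, 0.1 nm grid,
with additive homoscedastic Gaussian noise (default 0.002 AU, always
seeded).  The band set mimics the real system qualitatively: a dominant
mid-UV band with a short-wavelength shoulder for acetaminophen, one strong
~220 nm band for diphenhydramine (peak absorptivity 0.05 AU·mL·µg⁻¹·cm⁻¹,
the realistic magnitude for that band), and a steep end absorption plus a
weak benzenoid triplet for pseudoephedrine.  None of these are calibrated
molar absorptivities of the actual drugs.

The zero-crossing method only works when the real spectra happen to offer
wavelengths where both interferents vanish while the analyte does not — the
published drugs provided such windows at 281.5, 226.0 and 218.0 nm.  A
generic sum of Gaussians does not: near an isolated crossing of the
25 µg/mL dominant absorber, the grid-point residual alone would bias the
minor analytes by several percent.  The synthetic system is therefore
*constructed* to possess the windows the real one had: the acetaminophen
shoulder band was solved (numerically, once) so its ²D has a flat
double-root window around 215 nm and its ⁴D crosses exactly at 216.0 nm,
and the widths of the two minor compounds were solved so pseudoephedrine's
²D crossing and diphenhydramine's ⁴D crossing fall on those same grid
points.  That is why several band parameters carry many digits.  The
automated selection then genuinely *finds* these windows (it is not told
where they are), and picks its own point for acetaminophen in the
257–258 nm region where both minor compounds are spectrally silent.

What the simulator does not emulate: baseline drift, stray light, finite
spectral bandwidth, wavelength-registration error, heteroscedastic shot
noise, and real band shapes (log-normal asymmetry, vibronic structure).
Passing tests therefore demonstrate the correctness of the algorithms and
the internal consistency of the method, not instrument-grade accuracy on
real spectra.

## Calibration and validation statistics

Calibration lines are ordinary least squares of derivative amplitude on
concentration (≥3 points), with standard errors of slope and intercept and
the correlation coefficient.  Replicate curves (six series in the classical
design: the analyte diluted through its range with the other two compounds
fixed at 25/1.5/1.5 µg/mL) are summarised by across-curve mean, SD (n−1),
RSD%, and a 95% confidence half-width `z·SD/√n` with z = 1.96 — the formula
is not stated in the source tables but every printed CI/SD pair satisfies
CI = 0.80·SD = 1.96·SD/√6, so it is adopted (Student's t is available via
`use_t=True`).  Detection limits follow LOD = 3.3σ/s, LOQ = 10σ/s with σ
the across-curve SD of the intercept and s the mean slope magnitude
(derivative responses may be negative).  Rounding to reporting precision
happens only at reporting.

Precision/accuracy use CV% = 100·SD/mean and error% = 100·(mean −
nominal)/nominal with sample SDs; between-day error uses the grand mean.
Standard-addition recovery is 100·(found_spiked − found_base)/added.
Method comparison uses the paired t statistic `mean(d)/(SD(d)/√n)` against
the two-sided critical value, and the variance-ratio F with the *fixed*
test-over-reference convention — the published comparison reports F values
below 1 (0.553, 0.391, 0.354), which only a fixed ratio can produce — at
the upper critical value.  The degrees of freedom behind the printed
critical values (4 for t, (2,2) for F) are inferred from 2.776 and 19.00;
replicate counts are configurable.  A known caveat: the upper F critical
value is monotone decreasing in the denominator df but not, at small
denominator df, in the numerator df; the property tests reflect this.

## Tablet assay and dilution arithmetic

The work-up is powder equivalent to ¼ tablet → 100 mL, 3 mL of filtrate →
100 mL, giving `content [mg] = conc × (final/aliquot) × primary /
mass_fraction / 1000`.  A 500/25/30 mg tablet lands at 37.5/1.875/2.25
µg/mL — acetaminophen near the top of its 5–40 µg/mL range, so the range
check flags rather than fails at boundaries.  The linear range for
acetaminophen is recorded as 5–40 µg/mL (the prepared series), with the
alternative 5–50 µg/mL quotation kept in the literature fixtures.

## Replication protocol and problem sizes

Method development (wavelength selection) is performed once on noiseless
pure-compound standards, as a laboratory would develop a method; assay
replicates then re-measure the calibration series and the tablet solution
(triplicate scans, matching the classical within-day n = 3) with fresh
seeded noise.  The recovery study uses 100 such replicates at 0.002 AU
noise; the type-I-error study uses 2000 simulated same-distribution method
pairs (n = 5 for the paired t, n = 3 per arm for F); the six-curve
linearity summary is averaged over six independent blocks because a single
six-curve RSD estimate has ~30% relative sampling error.  These sizes keep
the full validation under a few seconds while leaving Monte-Carlo error
well inside the tolerances being checked.

## Known limitations

* The Δλ semantics of the original instrument are undocumented; other
  readings (e.g. scan-speed smoothing constants) would shift crossing
  positions and amplitudes.
* Selection assumes interferent identities and pure-compound spectra are
  available; unknown excipient absorption is only addressed indirectly
  (the recovery machinery) and is not simulated.
* Single-wavelength quantification is inherently less robust than
  overdetermined multiwavelength least squares, which is deliberately out
  of scope.
* The published experimental coefficients, recoveries, tablet contents,
  t/F statistics and the 281.5/226.0/218.0 nm wavelengths depend on the
  real instrument spectra, which were never tabulated; they are carried as
  reference fixtures and self-consistency checks only.
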