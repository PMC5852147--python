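# Methods

This note documents the models implemented in `magslice`, their
assumptions, the tunable parameters and defaults, and the numerical
choices that were genuinely open.

## Coordinate and unit conventions

The diamond sensor surface is the plane z = 0; tissue occupies z > 0;
x spans the slice width and y is the somato-dendritic axis of the
pyramidal cells. All quantities are kept in µm, ms, nA, mV, nT and MΩ.
In this system µ0/4π = 0.1 nT·µm/nA exactly, which keeps every
intermediate quantity near unity and avoids the underflow-prone
10⁻⁷–10⁻¹² factors of SI meters and teslas.

## Cell and population model

A CA1 pyramidal cell is represented by a three-branch stand-in: a basal
chain (stratum oriens), a 20 µm soma compartment, and an apical chain
(stratum radiatum), all collinear along +Y, with default extents of
200 µm (basal) and 300 µm (apical) so a cell spans the S.O.–soma–S.R.
depth of the pyramidal layer. The default axial resistance per length is
r_i = 0.12 MΩ/µm, the value for a ~2 µm-radius dendrite at an
intracellular resistivity of 150 Ω·cm. Real morphologies branch and
taper; the stand-in deliberately does not, because everything downstream
of the membrane dynamics depends only on the spatiotemporal distribution
of axial current, which is calibrated (below) rather than derived from
channel biophysics.

Populations place a configurable number of cells (default 1000) in each
50 µm depth layer of the active volume (500 × 500 × 300 µm³ by default,
above a 50 µm dead-cell layer), corresponding to the conservative density
of 100 cells per 50³ µm³. Soma positions are uniform in x and z within
the layer and uniform in a 50 µm band in y; each cell is rotated by a
uniform random angle about its dendritic (+Y) axis. All stages draw from
independent, explicitly seeded generators, and every output records its
seeds and config hash, so runs are bit-reproducible.

Synaptic schedules jitter the base event times (12.5 and 37.5 ms,
emulating 40 Hz paired stimulation) with independent Gaussian offsets
(σ = 1.56 ms default; 0.63 and 3.13 ms are the high- and low-synchrony
conditions). The drive is split between apical and basal dendrites by
region weights (default 50/50; the apical-only variant emulates selective
stratum-radiatum activation).

## Activity templates

The membrane potential of each compartment is a parametric template, not
an integrated conductance model:

* **EPSP** — a double-exponential time course (τ_rise = 0.5 ms,
  τ_decay = 5 ms) whose spatial profile ramps linearly with distance from
  the soma inside each driven region, emulating distally weighted
  excitatory input. Amplitude parameter: mV at the reference distal site.
* **Action potential** (spiking case only) — a biphasic
  difference-of-Gaussians time course with zero net time integral
  (depolarizing lobe FWHM 1.5 ms at 35 °C; a `temperature_scale` knob
  stretches all time constants for colder baths), peaking at the soma
  2 ms after the synaptic event and decaying electrotonically into the
  dendrites with separate space constants (apical 300 µm, basal 100 µm —
  the spike back-propagates preferentially into the apical trunk).

Both templates pass through a one-pole low-pass (τ_m = 1 ms) representing
the local membrane response. Axial currents follow from the
parent-difference cable relation; membrane currents are then obtained by
Kirchhoff's law at each node, which makes ΣIm(t) = 0 exact by telescoping
rather than approximate.

Two consequences of this construction are worth knowing. First, for a
straight uniform-r_i cell the ECD telescopes to
(V_tip,apical − V_tip,basal)/r_i, so the dipole is controlled entirely by
the asymmetry between the two branch profiles — this is why the apical
and basal space constants differ, and why a symmetric template would have
no far field. Second, the polarity of the rendered maps follows the
parent-difference sign convention of the cable relation and is opposite to the
physical current direction; all magnitude and asymmetry properties are
unaffected.

**Calibration.** Template amplitudes (EPSP and AP jointly, ratio fixed)
are scaled so a single spiking event yields a peak single-cell ECD of
0.2 pA·m — the literature anchor for a pyramidal-cell action potential.
After calibration the peak axial current is ≈ 6.6 nA and the somatic
spike ≈ 180 mV, both in the physiological range. By linearity, 200 fully
synchronized cells give exactly 40 pA·m; the conductance-based value
reported for that configuration (≈ 35 pA·m) differs by the morphology
effect that the stand-in cell does not capture.

## Forward model

Magnetic fields use the exact finite-segment Biot–Savart solution per
compartment, validated against 1000-point Gauss–Legendre quadrature of
the line integral to 10⁻⁸ relative accuracy, and against the infinite-wire
limit. Extracellular potentials use the standard line-source
approximation in an infinite homogeneous conductor (σ = 0.3 S/m default;
all potentials scale as 1/σ), with a numerically stabilized log kernel
validated against quadrature. Field points closer than 10⁻³ µm to a
compartment axis raise an error naming the compartment; distances are
always measured from the compartment axis, never from a cell-structure
center.

Pixels average 4 × 4 sub-samples by default (pixel averaging matters for
the planar-cell geometry at 2 µm pixels; it is exact for smooth far
fields). The finite extracellular volume conductor is represented only by
the rational correction s(d) = a1 + a2/(d + c) applied to B_X per
compartment depth; the default is the identity (a1 = 1, a2 = 0) because
no fitted coefficients are built in — they must come from the user's own
finite-element calibration. B_Z and the potential are never corrected.

The population field is the linear superposition of single-cell fields.
Field frames are rendered lazily over a selectable time window to bound
memory.

## Bandwidth analysis

The cumulative power curve is computed from a rectangular-window
periodogram with the DC bin excluded. A rectangular window was chosen
(over tapered windows) so that Parseval's identity — PSD integral equals
time-domain variance — holds exactly, which the test suite asserts at
10⁻⁶ relative; the analyzed signals are compactly supported evoked
transients for which leakage is negligible. The threshold defining "most
of the signal power" is a parameter with default 0.95; the recommended
sampling rate is twice the threshold frequency. Filtering uses
third-order Butterworth sections, causal single-pass by default (matching
a real-time acquisition chain) with a zero-phase option.

## Reconstruction calculus

Spatial frequencies are angular (rad/µm); the usable band for pixel size
Δ is [−π/Δ, π/Δ]², and the field of view is assumed periodic (FFT
convention). The slab transfer function f(k) is evaluated with its
analytic k → 0 limits (the closed-form expression is 0/0 and ∞−∞ there) and
in exponential-difference form for stability at large k. It is validated
against a brute-force oracle: direct depth integration of the real-space
kernel on a 4 mm padded domain followed by a DFT, agreeing within 1%
over the band where f > 10⁻³ f(0) (the DC bin is excluded from the
comparison because the truncated domain misses the 1/ρ³ far tail of the
kernel; the k → 0 limit is checked analytically instead).

σ_j (nA) is the flat-spectrum amplitude of the point source
j_y = σ_j δ(x)δ(y) carried by each depth slice. Source calibration
matches the *continuous* noiseless peak field at the sensor (closed form
(µ0/4π)σ_j(1/z0 − 1/(z0+d)) for the identity correction); the rendered
pixel peak then falls slightly below the target for sharply localized
fields, which is the behaviour of a real pixelated recording. A
pixel-mean calibration mode exists for sensitivity studies.

The Wiener filter uses the point-source regularization η²A_FoV/σ_j², which
depends on spatial frequency only — the filter is pixel-size independent,
asserted to machine precision. The PSF is the band-limited inverse
transform of |f|²/(|f|² + η²A_FoV/σ_j²); FWHM is measured on an axis cut
through the peak (azimuthally averaged profiles are an option and agree
within a few percent for this radially symmetric PSF), linearly
interpolated on a 4× sinc-oversampled grid so sub-pixel widths are
resolved.

**Noise propagation.** White pixel noise of standard deviation η/Δ has a
power spectral density of η² in the continuous convention (variance per
unit k-area over the band equals the pixel variance). The reconstruction
noise variance is therefore (1/(2π)²)∬|f^I|² η² dk. Note this is the PSD
η², not the finite-FoV spectral magnitude s_η = η²A_FoV — conflating the
two overstates the variance by a factor A_FoV and would make every pSNR
figure six orders of magnitude too pessimistic. The analytic propagation
is cross-checked against seeded Monte-Carlo realizations (white pixel
noise through the filter), which agree within 0.5% at 500 realizations;
the acceptance script re-runs this check at every invocation. The
threshold search for "η at which pSNR = 10" bisects on log η to 1%.

With these definitions the slice scenario (z0 = 50 µm, d = 300 µm,
1.5 nT calibration, 1 mm², 7.8 µm pixels) gives pSNR = 9.8 at
η = 10 nT·µm and a threshold of 9.7 nT·µm, and the planar scenario
(z0 = 1 µm, d = 2 µm, 2.5 nT, 2 µm pixels) a threshold of ≈ 0.50 nT·µm.
The slice PSF FWHM evaluates to ≈ 155 µm under the identity
volume-conductor correction. A fitted s(d) with a2 > 0 up-weights shallow
depths and adds E1 terms to f(k) that decay on the scale z0 + c instead
of z0 + d/2; this widens the usable band and narrows the PSF — reported
resolution figures near 100 µm for this geometry are consistent with such
a correction, whose coefficients are not published in a reusable form and
are therefore left as user inputs here.

## Scenario scale and linear density rescaling

Population-level checks in the test suite run density-subsampled
populations (100–300 cells per layer instead of 1000) and rescale the
fields linearly back to the full density — the superposition is linear in
cell count, and density rescaling is the documented way to adapt the
results to other preparations. At these sizes the full property suite
runs in under a minute; the subsampling adds sampling noise to the
thickness-saturation curve, which the tests absorb with a 1%-of-peak
slack on the concavity of its increments.

## Known limitations

* No conductance-based synapses, no threshold spike initiation, no
  propagating action potentials; the nS strength conditions are labels
  mapped to calibrated amplitude factors.
* The stand-in morphology makes the per-cell field pattern more
  stereotyped than a branched cell; population statistics (peak
  magnitudes, sign patterns, saturation) are the meaningful outputs, not
  single-cell map details.
* The volume conductor is an infinite homogeneous medium plus the s(d)
  interface for B_X; no finite-element solver, no anisotropy, no slab
  boundaries.
* Reconstruction is strictly the 2D projection from B_X; no
  depth-resolved (3D) inversion and no joint B_X/B_Z inversion.
* Passing tests demonstrate internal consistency and the stated
  magnitudes under the synthetic conditions; they do not validate channel
  kinetics or real-tissue variability.
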