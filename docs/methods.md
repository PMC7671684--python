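# Methods

## The gating model and what it assumes

The package's core is the three-state allosteric scheme C ⇌ C·L ⇌ O·L with
a single binding step (dissociation constant K_D, µM) and a single
concerted opening step of the liganded channel (equilibrium constant L,
dimensionless). Its equilibrium open probability,

    Po(c) = L (c/K_D) / (1 + (c/K_D)(1 + L)),

is algebraically identical to a Hill function with unit slope,
Po_max = L/(1+L) and EC50 = K_D/(1+L). Assumptions: unliganded openings are
neglected (rare for TRPV1), one effective binding site (the scheme is a
condensation of the four-subunit channel), equilibrium measurements, and a
single open conductance class.

Two estimators are provided. The two-step estimator inverts Po_max and EC50
analytically (`estimate_L`, `estimate_KD`, combined in `decompose`); its
standard errors use the first-order delta method assuming independent
errors in Po_max and EC50 — SE_L = SE_Po/(1−Po_max)², and
SE_KD² = ((1+L)·SE_EC50)² + (EC50·SE_L)². The direct estimator
(`ThreeStateModel.fit`) least-squares fits (log10 K_D, log10 L) to a Po
curve; when the fitted Po_max exceeds 0.98 the data sit on the flat L–K_D
ridge (a shift of the curve can be attributed to either constant) and an
`IdentifiabilityWarning` is raised rather than silently reporting both
numbers. Po_max = 1 exactly raises an error: (1−Po_max) vanishes and L is
undefined. The practical remedy — a background mutation that lowers Po_max
to ≈0.5 — is supported by simply feeding the mutant curve to either
estimator.

A deliberate modelling note recorded in the energy-profile metadata: the
three-state scheme implies a unit Hill slope, while empirical Hill
coefficients on this channel run up to ~2. The decomposition uses only
Po_max and EC50 and is therefore insensitive to the empirical slope; the
Hill fitter reports the slope separately.

## Energy profiles

`eyring_profile` converts (K_D, L) at ligand concentration c into relative
free energies with the unliganded closed state as zero:
G(C·L) = −RT ln(c/K_D), G(O·L) = G(C·L) − RT ln L, with
R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹ and T defaulting to 295.15 K (room
temperature, ~22 °C). Energies are reported in kcal/mol with a k_BT-unit
accessor. When an OFF rate is supplied, the unbinding barrier height uses
transition-state theory, ΔG‡ = RT ln(k_B T/(h·k_off)), with transmission
coefficient 1. Energy *differences* between states are independent of the
concentration-dependent reference shift, which the tests verify.

## Synthetic data: what it emulates and what it does not

The generators reproduce the study's recording conditions so that every
analysis stage can be exercised against known ground truth: 10 kHz
sampling, a 2.9 kHz low-pass corner, +80 mV test potential, 100 pS
single-channel conductance (8 pA unit current), saturating-agonist open
probability 0.94, and the selectivity solutions (140 mM NaCl outside
against 70 mM CaCl₂/MgCl₂ inside, buffers and chloride impermeant).

* **Gating**: a two-state (closed/open) continuous-time Markov chain
  sampled by the Gillespie method, initial state drawn from the stationary
  distribution. Dwell-time constants are not published for these
  recordings; the default mean open dwell of 10 ms is a fixture choice of
  the right order for TRPV1 at saturating capsaicin, not a measured value.
* **Rendering**: dwells are sampled on the acquisition grid with a floor
  convention (a transition at time t belongs to the sample containing t);
  white Gaussian noise is added *before* filtering.
* **Filtering**: the recording chain's corner is emulated by a Gaussian
  kernel with σ_t = 0.1325/f_c, which matches a −3 dB corner at f_c. The
  hardware filter type beyond its corner frequency is not specified; a
  Gaussian is the conventional software stand-in and is what matched-risetime
  analysis tools assume. Baseline drift, capacitance/leak transients, and
  multi-channel patches (discarded experimentally) are not modelled.
* **Dose-response**: Po(c) plus Gaussian noise, proportional to the
  response by default (`noise_sd` is a fraction; the scatter of normalized
  current measurements scales with the signal), with an additive mode.
  Noiseless output equals `predict_po` bit for bit.
* **Ramp I–V**: a linear conductance around the extended-GHK reversal
  potential. Real TRPV1 ramps rectify; the linear form suffices because
  only the zero crossing carries information here.
* **Toy structures**: deterministic helices, atom-ring stacks with
  analytically known pore radii, and rigid-transformed duplicates.

All generators consume one named `numpy.random.Generator` seeded
explicitly, record the seed in output metadata, and are bit-reproducible.
Passing tests on these synthetics demonstrates correctness of the
*analysis* under the stated noise model; they cannot certify behaviour on
artifacts the generators exclude (drift, sub-conductance levels, missed
multi-channel events).

## Single-channel analysis choices

All-point histograms default to Freedman–Diaconis binning (clamped to
[20, 512] bins; binning is not specified by the source protocol). The
double-Gaussian fit is nonlinear least squares on bin counts with
moment-based initial guesses from a midpoint split; noise-free traces whose
level peaks are delta-like are reported from empirical moments directly (a
two-spike nonlinear fit is ill-posed). A fit whose level separation is
below 2 SD is declared degenerate rather than returned.

Idealization uses the half-amplitude threshold — the arithmetic midpoint of
the fitted level means, no hysteresis — followed by dead-time imposition at
0.3 ms: events shorter than the dead time are merged into the enclosing
level, shortest event first with chronological tie-break, re-scanned to a
fixed point (the operation is idempotent and conserves total time). The
merge is implemented as a doubly linked list with a lazy min-heap,
O(n log n), so 200 s recordings idealize in well under a second. Po is open
time over total time; across patches both a per-patch mean ± SEM (default)
and a time-pooled aggregate are available, since the aggregation convention
is not fixed by the protocol.

At the study's operating point (Po 0.94, mean open dwell 10 ms) the mean
closed dwell is ≈0.64 ms, so roughly 8% of closed time falls in
sub-dead-time gaps and is absorbed into open time; the expected upward bias
on Po is ≈0.005, well inside the 0.01 recovery tolerance the tests assert.

## Dose-response fitting

Hill fits run on log-concentration internally (the midpoint parameter is
log10 EC50) with linear-scale parameters and delta-method SEs reported;
initial guesses are the half-range crossing, K = 1 and the maximal
response. Fits are unweighted by default with optional 1/SE² weighting.
Convergence is rejected when the fitted midpoint falls more than 10× outside
the sampled range or the data are flat. Bootstrap SEs (residual resampling
with the √(n/(n−p)) dof inflation) are available on the results object and
agree with the asymptotic SEs to ~10–20% on simulated curves. Tail currents
are fitted as baseline + A·exp(−t/τ) with the OFF rate reported as 1/τ.
Macroscopic-to-Po normalization divides the test current by a unitary
conductance ratio first (the shortened analog's unit current is ~10%
smaller), then scales by the reference ligand's saturating Po, clipping at
1 with a warning.

## Selectivity

Reversal potentials come from a low-order polynomial (default cubic) fitted
within ±10 mV of the ramp's zero crossing; multiple distinct crossings
raise an ambiguity error listing candidates. The GHK conversion uses the
extended constant-field flux sum with integer valences, solved by bisection
in [−200, 200] mV; concentrations are used as activities (no coefficients —
none are specified for these solutions), and Cl⁻/EGTA/HEPES are treated as
impermeant for this cation channel. For the bi-ionic divalent-in /
monovalent-out protocol the closed Fatt–Ginsborg form is used:
P_X/P_M = [M]_o e^(−u)(1 + e^(−u))/(4[X]_i), u = E_rev·F/RT, derived from
the flux equations (at E_rev = 0 with 140 mM Na⁺ out and 70 mM divalent in
it gives exactly 1). The general numeric inverse exploits the linearity of
the flux sum in the unknown permeability; closed form and numeric path
agree to 0.1% across E_rev ∈ [−50, 50] mV in the tests.

## Structural metrics

PDB input is parsed by biotite behind `read_structure`, which first
validates the fixed coordinate columns so malformed records fail with a
line number, keeps the highest-occupancy altloc (ties → 'A'), drops
hydrogens, and warns when extra MODEL blocks are ignored. Superposition is
Kabsch via SVD with the proper-rotation sign correction; a quaternion
(Horn) solver and biotite's superimpose serve as independent cross-checks
in the tests only. Per-residue RMSD superposes once on the anchor segment
(e.g. S4) over the backbone set N, CA, C, O (CA-only available) and then
measures each residue without re-fitting; missing residues are NaN gaps.

Ruler distances default to the minimum over sidechain-oxygen pairs (the
atom pair used in the published figure is not stated; the threonine OG1 /
glutamate OE1/OE2 oxygens are the hydrogen-bonding candidates), computed
per subunit and averaged over the tetramer. Functional residue numbers are
mouse; the rat cryo-EM structures sit one residue lower, so the default
mapping is structure = mouse − 1 (T551/E571 → T550/E570), recorded in the
output.

Pore profiles use the largest-sphere metric with Bondi vdW radii: in
`fixed_axis` mode the radius at z is the minimal atom clearance from the
axis point; `optimized_center` additionally maximizes the clearance over
the slice plane by a coarse grid (±2 Å, 9×9) followed by Nelder–Mead.
Radii above 10 Å (configurable) are flagged unbounded. The default axis is
the laboratory z through the xy centroid, with a principal-axes mode for
tetramers and an explicit two-point override (z is measured from the first
axis point).

## Problem sizes and numerical tolerances

The test suite and the acceptance script use 200 s simulated recordings
(2×10⁶ samples) for Po recovery, ≥10⁴ dwells for distributional checks
(KS at α = 0.01), 100 seeds for parameter-recovery medians, and 20-seed
batches for fit round trips — sizes at which the Monte-Carlo error is a
small fraction of each asserted tolerance while the whole suite runs in a
few minutes on one CPU. Root solving uses `brentq` at xtol 10⁻¹²; GHK flux
terms switch to a series expansion for |zu| < 10⁻⁹; least-squares SEs come
from the Jacobian at the optimum with the residual variance at n − p dof.

## Known limitations

No missed-event correction beyond the fixed dead time; no burst or
dwell-time-histogram analysis; no desensitization kinetics; no
sub-conductance levels; mmCIF is not parsed; docking and electrostatics are
out of scope. The two-step estimator propagates errors to first order and
assumes Po_max and EC50 errors independent, which slightly understates the
K_D uncertainty when both derive from the same patches.
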