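# Methods

`scleromech` re-creates, as a tested computational pipeline, a scleral
biomechanics study design used with the ADAMTS10-mutant canine glaucoma
model: whole-globe infusion testing for ocular rigidity, ultrasound
inflation testing of the posterior sclera, dynamic mechanical analysis
(DMA) and tensile ramp testing of scleral strips, and the cohort-level
age × genotype statistics built on them.  No raw data from such studies
are publicly deposited, so the package is organised around *parameter
recovery*: a synthetic-cohort generator writes latent per-eye mechanical
truth with the published statistical structure, renders raw-modality
records from it, and the analyzers plus the statistics stage must give the
truth back.  What a green test suite shows — and does not show — about
real data is discussed at the end.

## Models per modality

### Infusion — Friedenwald ocular rigidity

The globe is modelled as an exponentially stiffening pressure vessel.
A bolus of volume ΔV = flow × duration (protocol: 15 µL/s × 1 s) injected
from a stable baseline IOP₀ (15 mmHg) gives

    K = ln(IOP_peak / IOP₀) / ΔV          [µL⁻¹]
    k = V₀ · K                            [dimensionless]

with V₀ the ellipsoid globe volume (π/6 · axial · NT · SI, mm³ ≡ µL) from
A-mode biometry.  The forward simulator produces
`IOP(t) = IOP₀·exp(K·flow·t)` during the bolus plus Gaussian sensor noise
(default SD 0.2 mmHg); the estimator takes IOP₀ as the pre-onset window
mean and the peak as a post-bolus plateau mean (1–3 s after the bolus),
and averages the two replicate infusions the protocol prescribes.  Outflow
and the 10-minute re-equilibration are not modelled.  The literature
leaves the units of K unstated; this package uses **per-µL** throughout,
which makes k = V₀K land on the ~10²
scale of the published normalized-rigidity regression.

### Biometry

Pulse-echo time of flight is converted with per-medium sound speeds
(1605 m/s cornea/sclera, 1540 m/s aqueous/vitreous, 1645 m/s lens) as
`d = c·t/2`.  The factor of two is the pulse-echo convention: it is the
only reading under which a 500 MHz RF sampling rate yields the quoted
~1.5 µm per-sample distance resolution (1540/(2·5×10⁸) = 1.54 µm).
Globe dimensions are treated as full diameters, hence π/6 in the
ellipsoid volume.

### DMA — linear viscoelasticity

Strain ε₀·sin(2πft) (ε₀ = 0.15%, below the 0.25% linearity bound) induces
stress σ_pre + E*·ε₀·sin(2πft + δ).  Amplitude and phase of each channel
come from harmonic least squares at the known drive frequency
(`a + b·sin + c·cos`, optional linear-drift column), which is exact for
non-integer cycle counts; an FFT peak-pick is not, which is why it was not
used.  Analysis uses the last 8 of 12 recorded cycles.  Derived
quantities satisfy E′ = E*cos δ, E″ = E*sin δ, tan δ = E″/E′ by
construction.  The 6-frequency × 2-preload sweep (0.1–10 Hz × 0.04/0.1 N)
is analysed per cell; the 1 Hz / 0.04 N cell is the reference condition
used in all cohort statistics.  Preloads map to Laplace-law hoop stress
σ = P·r/(2t) with generic globe geometry r = 12 mm, t = 500 µm (≈0.024 MPa
at 15 mmHg).  Preconditioning and inter-frequency rests are protocol
metadata only — no constitutive evolution is simulated.

### Ramp — exponential stress–strain fit

Engineering stress (force over undeformed thickness × width) versus
engineering strain (grip displacement over post-preload gauge length) from
a 0.1 %/s ramp to 3.5% strain is fit to σ = A(e^{Bε} − 1) by
Levenberg–Marquardt.  A·B is the initial tangent modulus, B the rate of
stiffening with stress.  Initialisation: B₀ from the slope of
log(dσ/dε) vs ε (finite differences), A₀ from the implied initial
tangent; five jittered restarts on non-convergence.  Goodness of fit is
reported as both R² and RMSE.  The small preload stress is not subtracted
from σ; machine-compliance correction of displacement is assumed absent.

### Inflation — RF speckle tracking and strain estimation

A scleral-shell cross-section is imaged at each step of the pressure
schedule (5→20 mmHg in 0.5 mmHg steps, then 22.5–30 in 2.5 mmHg steps,
then 35/40/45) with a 55 MHz transducer sampled at 500 MHz.  The package
implements the full chain on synthetic RF:

*Phantom.*  Uniform random point scatterers (3000/mm², ≥5 per resolution
cell for fully developed speckle) rendered through a separable PSF —
Gaussian axial envelope (30 µm FWHM) modulated at the pulse-echo carrier
(depth wavenumber 2f₀/c), Gaussian lateral profile (62.5 µm FWHM).  The
post frame re-renders the *same* scatterers displaced by the affine field
implied by the prescribed strains (applied about the frame centre), which
is what keeps speckle correlated between pressure steps.  Default frames:
1024 axial samples (1.58 mm) × 192 lines at 15 µm pitch.

*Displacement.*  Per kernel (default 128 samples × 9 lines, 65% overlap),
normalized cross-correlation over integer lags gives the coarse
displacement and the stored correlation value; nodes with peak correlation
below 0.5 are invalid.  The sub-sample residual is then solved
*differentially*: with the post window aligned at the integer peak, the
optical-flow normal equations with symmetric spectral (FFT) gradients of
both frames give the remaining (axial, lateral) offset; one Gauss–Newton
re-warp refines offsets larger than 0.1 sample.  This replaces the
textbook parabolic interpolation of the correlation peak deliberately: the
lateral correlation peak spans several line pitches, and interpolating it
shows a speckle-realisation-dependent gain error of order ±10% for the
deep-sub-pitch lateral motion produced by 0.5 mmHg increments — an error
that compounds coherently over an incremental schedule.  The differential
refinement measured unbiased at per-step scale (gain 1.000 ± 0.003 axial,
1.002 ± 0.016 lateral across phantoms).  Spectral rather than
finite-difference gradients matter: central differences attenuate the RF
carrier's derivative by sin(k)/k ≈ 8%, which propagates one-to-one into
displacement; frames are reflect-padded before the FFT to suppress
wrap-around ringing at the frame edges.

*Strain.*  The least-squares strain estimator: per node, the OLS slope of
displacement versus position over a sliding window of (default 9) nodes
along each axis, excluding invalid nodes; windows with fewer than 3 valid
nodes are missing.  Beam-frame strains rotate into tissue strains by the
2-D tensor rotation ε_t = c²ε_lat + s²ε_ax + 2scε_sh,
ε_r = s²ε_lat + c²ε_ax − 2scε_sh (θ = local surface tangent from the
lateral axis; extension positive).  The inverse mapping used when
prescribing tissue strains to the phantom includes the induced beam-frame
shear sc(ε_t − ε_r).  In `inflation_series` the estimated strains are
converted with zero shear, which is exact for θ = 0 (beam normal to the
surface, the default geometry); arbitrary orientations would need a shear
estimator, which is not implemented.

*Series.*  Consecutive frames are tracked incrementally and per-step mean
strains accumulated, referenced to the 5 mmHg baseline — matching the
rationale that small pressure increments keep speckle correlated.  Tc_15 /
Rc_15 are the cumulative tangential / radial strains at the 15 mmHg step.
An eye with more than 20% invalid nodes at any increment is flagged
"tracking failed" and its Tc/Rc withheld; the 20% threshold is this
package's choice (the source protocol only reports that tracking failed
for some eyes).  Measured accuracy at default settings: single-pair affine
recovery within 1.3×10⁻⁴ strain (lateral) and 4×10⁻⁵ (axial);
accumulated-vs-direct discrepancy over a 5→15 mmHg series ≈ 2×10⁻⁴.
The per-eye Tc_15 noise of the full incremental chain is roughly ±2%
relative at a 1% true strain.

## The synthetic cohort

Each eye carries a latent truth vector (E*, tan δ, A, B, A·B, K, k, Tc_15,
Tm_15, Rc_15, thicknesses, globe diameters).  Ages are uniform on
[5, 131] months in both groups.  Mechanical properties are the published
group-specific age lines evaluated at the eye's age plus Gaussian
residuals:

| property | affected line | normal line |
|---|---|---|
| E* (MPa) | 3.574 + 0.05676·age | 5.361 + 0.04313·age |
| tan δ | 0.11253 − 0.000252·age | 0.12803 − 0.000342·age |
| A·B (MPa) | 0.503 + 0.03196·age | 0.585 + 0.0256·age |

B and posterior thickness have no published lines; their slopes are
derived from the published overall age correlations (−0.44 and −0.827)
together with the group mean ± SD summaries and the group age summaries
(slope = r·SD_prop/SD_age, intercept anchored at the group means), giving
e.g. B_affected ≈ 88.0 − 0.203·age.  A = A·B / B.

*Residual calibration.*  Two modes.  `table_calibrated` (default) sizes
each residual so the *marginal* group SD matches the published summary
given uniform ages: σ_resid = √(SD² − slope²·Var(age)), floored at 10% of
SD.  `correlation_matched(prop, r)` instead solves
r = slope·σ_age/√(slope²σ_age² + σ²) for σ, and is used when a target is a
printed correlation (E*–age 0.857, thickness–age −0.827).  The two modes
cannot hold simultaneously because the published marginal SDs embed the
study's bimodal age distribution, not a uniform one.

*Correlation structure.*  A per-eye latent stiffness factor z ~ N(0,1)
carries part of each property's residual (loadings: E* 0.8, A·B 0.7,
B 0.4, tan δ −0.5, thickness 0.3), inducing cross-property correlations
without a full covariance matrix — parsimonious and sufficient for the
pairwise targets.

*IOP.*  Affected eyes: baseline 15 mmHg until glaucoma onset (10 months,
inside the reported 9–12 month window), then +0.45 mmHg/month with
Gaussian noise (SD 1.5 pre-onset, 8 post-onset), clipped to [5, 90] — this
reproduces the Table-1-like range (≈50–80 mmHg at 90–95 months) and a
positive age–IOP correlation; the two slow-progressor outlier animals are
deliberately not modelled as a class.  Normal eyes: N(12, 2) clipped to
the 8–16 mmHg normotensive band.

*Rigidity.*  Affected eyes lie on the published plane
k = 181.1 + 0.995·age − 2.940·lastIOP plus N(0, 13) (≈10% of the plane
mean).  Normal eyes use k = 165 + 1.1·age with residual SD 18.7, chosen to
give the strong positive normal-group age association (r ≈ 0.9) and a
higher normal-group mean, both qualitative features of the published
scatter; no normal-group equation is printed, so these two constants are
this package's choice.  K = k/V₀ with V₀ from per-eye globe diameters
(affected diameters grow with age — buphthalmia — with slopes interpolated
from the young/old group dimension summaries).

*Inflation links.*  Tc_15 = 0.07/max(E*, 2 MPa) · exp(σ_tc·Z), Tm_15
likewise with its own σ, Rc_15 = −3.0/max(k, 75) · exp(σ_rc·Z), all capped
at |ε| = 4.5% so every latent strain stays inside the RF simulator's
small-strain envelope.  The scale constants put Tc at ~1% and Rc at ~−2.5%
for a typical eye; the floors bound the soft tail.  The σ values (0.308,
0.624, 0.175) are calibrated numerically (`calibrate_link_sigma`, bisection
on a 2×10⁵-draw sample of the same generative model) so the population
correlations equal the published values: Tc–E* −0.744, Tm–E* −0.544,
Rc–k 0.78.

*Raw-record noise* (`RawNoise`): 0.2 mmHg IOP sensor noise, DMA stress
noise 2% of the stress amplitude, 0.005 MPa ramp load noise.  With all
noise at zero, every analyzer recovers its truth parameter to better than
10⁻⁴ relative (machine-level for infusion and DMA; optimizer tolerance for
the ramp fit); the RF strain chain is validated separately at its own
absolute tolerance since correlation-based tracking is not exact.

Where a recovery target is a group mean ± SD (not a line), truth values
are drawn from a lognormal matching the printed mean and SD: the printed
normal-group A·B (1.83 ± 2.05) gives a normal distribution with ~19%
negative mass, and clipping a normal at zero would inflate the recovered
mean by ~12%; the lognormal has exact first two moments on positive
support.

## Statistics stage

OLS via statsmodels: `y ~ age * genotype` (per-group lines derived from the
interaction fit are algebraically identical to separate per-group fits —
tested to machine precision), the age-adjusted genotype contrast from the
additive model, the two-covariate rigidity model `k ~ age + lastIOP`,
Pearson correlations (two-sided p from the t transform), paired t-tests
(identical pairs return t = 0, p = 1 rather than NaN), and a group
mean ± SD summary table with age-adjusted p-values (raw means are
reported; the adjusted model supplies only the p).  p-values are two-sided
with no multiple-testing correction, and a housing-site covariate is
supported but off by default, both matching the study's analysis.  The
mixed-model analysis of preload/frequency effects is out of scope: its
specification was never published and the raw sweep data do not exist.
IOP summaries (lifetime mean; interval-weighted mean over the last 24
months, trapezoidal weights) are provided as small utilities.

## Validation design and what it shows

`tests/test_acceptance.py` checks (a) noise-free forward–inverse closure
per modality, the DMA algebraic identities, and affine-field accuracy of
the strain estimator (0.05 strain-percent); and (b) calibrated recovery:
the uniaxial group means through the raw-signal chain (200 replicate
cohorts at the study's group sizes, within 5%), the regression slopes and
the rigidity IOP coefficient on large cohorts, and the printed
correlations at n = 5000 within ±0.02.  Because a "within 2 SE"
single-cohort check fails 5% of the time for a perfectly unbiased
estimator, the coefficient checks aggregate 12 replicate cohorts and bound
the mean standardized error by 3/√12 ≈ 0.87 — strictly tighter than the
single-cohort 2 SE band — with a 4 SE gross-error guard per cohort.
`scripts/acceptance.py` recomputes the headline quantities from scratch at
a user-supplied seed; problem sizes (200 × 15-eye cohorts, n = 5000 and
n = 2000 cohorts, a 3-eye RF verification subsample) keep the full run
around a minute on one CPU.

What passing does **not** show: the generator emulates published summary
structure, not real tissue.  Real RF data add attenuation, out-of-plane
motion, electronic noise and depth-dependent focusing that the phantom
omits — the reported tracking accuracies are upper bounds for real
acquisitions.  Real residuals need not be Gaussian or lognormal, the true
property covariance is unknown beyond printed pairwise correlations, ramp
tests show rate dependence and preconditioning history the exponential fit
ignores, and infusion neglects outflow.  Recovery here demonstrates that
the *estimators are consistent with their own forward models* under the
published effect sizes and realistic noise — a necessary, not sufficient,
condition for validity on real measurements.

## Known limitations

- Tissue-strain conversion of *estimated* fields assumes beam-normal
  geometry (θ = 0); oblique orientations need a shear estimator.
- One eye per animal; no within-dog or within-site correlation.
- Tm_15 is an independently prescribed truth, not a second acquisition
  plane of the same deformation.
- The IOP trajectory is piecewise-linear-plus-noise; no treatment effects
  or pressure spikes.
- `fit_exponential` degenerates as B → 0 (A·B finite, A unbounded); data
  that are exactly linear can fail to converge rather than return the
  boundary solution.
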