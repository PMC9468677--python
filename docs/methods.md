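# Methods

## Shape model

A magnetically loaded spheroid resting on a non-adhesive slide above a
permanent magnet is treated as an incompressible liquid drop subject to a
uniform downward body force of density f = M_V·grad(B) (N/m³) and a surface
tension γ. Its equilibrium meridional profile satisfies, in arc length *s*
from the apex,

    dx/ds = cos φ
    dz/ds = sin φ
    dφ/ds = 2b + c·z − sin(φ)/x

with apex curvature *b* (1/length) and capillary constant c = f/γ
(1/length²). Coordinates: apex at the origin, *z* increasing toward the
substrate (the direction of the force), *x* radial; φ runs from 0 at the
apex to π at the contact line. The contact condition is taken as φ = π
(contact angle 180°): the slide is treated as perfectly non-adhesive, so the
drop meets it tangentially and sits on a flat contact disk. Only the
equilibrium shape is modelled — no viscoelastic transients, no gravity or
buoyancy correction, and grad(B) is assumed uniform over the aggregate
height.

`sin(φ)/x` has removable singularities at both ends. At the apex the local
solution is a sphere of curvature b (φ ≈ b·s, x ≈ s − b²s³/6,
z ≈ b·s²/2); integration starts from this series at s₀ = 10⁻⁶/b. At
closure the contact radius is positive whenever c > 0, so the φ = π event
is regular; for c = 0 exactly, the profile is returned in closed form as
the sphere of radius 1/b (the ODE is singular at its closure point, and the
closed form is exact).

Integration uses an adaptive eighth-order Runge–Kutta scheme
(`scipy.integrate.solve_ivp`, DOP853) with rtol 10⁻⁹ by default and event
location for φ = π (termination) and φ = π/2 (the equator, giving the
width). The volume is accumulated as a fourth state variable
V' = π·x²·sin φ, so it carries the integrator's accuracy. A guard cap of
50/b on the arc length converts pathological parameter combinations into a
non-closure error. Correctness is pinned by an independent fixed-step RK4
reference (step 10⁻⁵ in 1/b units, Newton-refined terminal point) that the
adaptive integration matches to better than 10⁻⁶ relative.

Observables of the closed profile: h = terminal z, w = 2·x(φ=π/2),
V = π∫x²·sin φ ds. For c ≥ 0 the model only produces oblate shapes
(h ≤ w, equality at c = 0).

## Inverse fit

The measured quantities are (h, w, V) of the flattened aggregate. The fit
works in units of the equivalent radius R_eq = (3V/4π)^(1/3), leaving two
dimensionless unknowns b̃ = b·R_eq, c̃ = c·R_eq², and minimises the sum of
squared *relative* errors on h, w and V; relative errors make the three
observables commensurable (they differ in dimension and magnitude).

Initialisation scans a log-spaced grid of c̃ over [10⁻³, 10²], choosing b̃
at each grid point so the model volume matches the observation (a bracketed
root find; volume is monotone decreasing in b̃). The best grid point seeds a
Levenberg–Marquardt refinement on the three-residual vector in
log-parameter space (the log transform enforces positivity); termination at
xtol 10⁻¹⁰ / ftol 10⁻¹². Damped least squares was chosen over a
direct-search simplex because it reaches the same minima in roughly a fifth
of the forward-model evaluations, and each evaluation is an ODE solve.
Noiseless synthetic observables are recovered to much better than 0.5%
across b̃ ∈ [0.8, 2], c̃ ∈ [0.1, 5].

Tension conversion: γ = M_V·grad(B)/c, reported in mN/m with the c given in
1/µm². Identifiability: as c̃ → 0 the shape tends to a sphere and the
objective becomes flat in c̃ — the data then only bound γ from below. Fits
with c̃ ≤ 10⁻³ (flattening below the measurement resolution at realistic
pixel scales) are flagged `flattened=False` and report the lower bound
implied by the threshold instead of a γ value. Prolate inputs (h > w beyond
0.5% tolerance) are rejected: the model cannot produce them for c ≥ 0.

Volume source: by default V comes from the same side-view image as h and w.
An alternative is incompressibility (V = 4πR₀³/3 from the initial radius
R₀); the synthetic generator uses exactly this to construct its ground
truth, and both conventions agree for the generated data by construction.

## Image extraction

Side-view images are segmented by a global Otsu threshold with polarity
auto-detection (the border is assumed background), keeping the largest
connected component and filling holes — the images are high-contrast dark
objects on a bright background, so nothing more elaborate is warranted. The
substrate row is the lowest populated mask row; the symmetry axis is the
width-weighted mean of per-row midpoints. Conventions: pixel counts include
both edge pixels; h = (substrate − top + 1)·scale; w = max row
width·scale; V sums per-row cylinders of radius equal to the mean of the
two half-widths about the axis. A per-row left/right asymmetry metric is
returned for quality control (≤1% on symmetric renders). Objects touching
the lateral image borders are an error — cropping reflections is the
caller's responsibility.

## AFM detachment force

A force curve has approach/dwell/retract segments. The baseline is a
straight line fitted to the trailing 20% of the retract segment — at the
5 µm/s pull-off speeds used, the tail is guaranteed off-contact — and is
subtracted from the whole retract trace, removing offset and linear drift.
The detachment force is the magnitude of the lowest point of the corrected
retract trace, or zero when that minimum stays above 3× the corrected-tail
standard deviation (no detectable adhesion). The constant-vs-linear
baseline choice and the 20% window are declared defaults; both are
parameters.

## Assay quantification

Wound coverage at time t is 1 − A(t)/A(0), clipped to [0, 1], with areas
from binary masks (or given directly); the t = 0 reference frame is
mandatory. The invasion index of a condition is the ratio of its mean
per-field invading-cell count to the control's, with fields pooled across
replicates — the control's index is exactly 1 by construction. Per-replicate
indices with their SEM are also reported, since whether published
coverage/index figures pool fields or average replicates is ambiguous;
both views are cheap to provide.

## Statistics

Two-group comparisons use the two-sided Mann–Whitney U test: exact null
distribution when the pooled sample is ≤ 12 and tie-free, otherwise the
normal approximation with tie and continuity corrections (both overridable).
The implementation delegates to `scipy.stats.mannwhitneyu`; its exactness is
verified in the tests against full enumeration of group labelings, and its
null calibration by simulation. Boxplot summaries use linear-interpolation
quartiles and the McGill notch 1.57·IQR/√n as an approximate 95% confidence
half-width on the median. Stars: *, **, ***, ****, ***** for p < 0.05,
0.01, 0.001, 10⁻⁴, 10⁻⁵; "ns" otherwise. Conditions are each tested
against the control without multiple-testing correction, mirroring common
practice for these assays; this is deliberate and documented rather than
corrected, so p-values are comparable to published panels.

## Synthetic data

The generator emulates a tensiometry study of an EMT panel in breast-tumour
cells: a no-targeting CRISPR control (NT), two NME1-ablated clones, two
NME2-ablated clones, and normal-like MCF10A cells. Condition means and
standard deviations are the published panel values — surface tension
16 ± 9, 4 ± 3, 7 ± 2, 16 ± 5, 13 ± 5 and 45 ± 18 mN/m; detachment force
1.8 ± 0.8, 1.4 ± 0.5, 1.2 ± 0.4, 2.0 ± 1.0, 1.9 ± 0.8 nN (MCF10A set to
2.5 ± 0.8 nN, the reported range for that line); a 6.5-fold invasion
increase for NME1 loss; wound coverage targets of 78% vs 55% at 24 h and
100% vs 90% at 48 h. Distributions are assumed normal truncated at zero
for tensions and forces and Poisson for counts (no distributional forms are
published). Geometry and magnetics: R₀ = 450 ± 70 µm, grad(B) = 170 T/m,
B = 530 mT. M_V is an instrument-calibration input with no published value;
the synthetic default of 1000 A/m puts control-like tensions at c̃ ≈ 2 —
clearly flattened, well-conditioned shapes.

Aggregate images are rendered at 1 µm/px by default: the true profile (c
from γ, b solved for volume conservation at R₀) is rasterised dark-on-bright,
Gaussian-blurred (σ = 1.5 px) and corrupted with Gaussian intensity noise
(σ = 0.03). What the renders do *not* emulate: uneven illumination, magnet
reflections, partial occlusion, debris, and deviations from axisymmetry —
so passing the image-loop tests demonstrates the geometry pipeline and fit,
not robustness to real-world imaging artifacts. Sample sizes mirror the
experimental design: 10 aggregates per condition (the study used 9–15), 45
AFM curves, 30 wound fields (10 × 3 replicates), 5 invasion fields × 3
replicates. All generators are seed-deterministic.

## Problem sizes and tolerances in the test suite

The forward-model oracle comparison uses 20 random parameter draws; the
noisy-recovery experiment 100 replicates at 2% observable noise; the
Mann–Whitney null calibration 2000 replicates at n = 15 per group; the full
study demo one seed at the default sample sizes. These sizes give stable
pass/fail behaviour for the stated tolerances (e.g. median γ error ≤ 10% at
2% noise) while keeping the default suite fast enough to run routinely.

## Known limitations

- The contact condition φ = π is an idealisation; partial wetting would
  need a contact-angle parameter and is not implemented.
- Tension is not identifiable for sphere-like drops; only a lower bound is
  reported (this is physics, not a solver limitation).
- Automatic scratch segmentation from phase-contrast images is out of
  scope; wound input is masks or areas.
- Per-cell heterogeneity of the magnetic load and viscoelastic approach
  dynamics are not modelled.
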