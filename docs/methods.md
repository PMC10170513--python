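# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `metadrt`, and what the toy-system validations do and
do not establish about real receptor–ligand simulations.

## The estimators

### Conformational flooding

The flooding estimator assumes two-state kinetics: a bound basin A and an
unbound basin B separated by one dominant free-energy barrier.  A
well-tempered metadynamics run confined to A accelerates the escape; the
acceleration factor is the running time-average of the exponentiated bias
at the instantaneous CV point,

    alpha(t) = (1/N_t) * sum_{j <= t} exp(beta * V(s_j, t_j)),

where beta uses the *physical* simulation temperature (300 K), never the
boosted ΔT, and V is the deposited-hill bias only — wall/floor restraint
energies are excluded, since they are part of the definition of the
accessible region rather than flooding potential.  V is recorded at each
deposition instant *before* the new hill is added: alpha measures the bias
the trajectory has experienced, not the hill being placed.

The transition time t\* is taken as the time of the global maximum of
alpha (earliest on ties).  For a unimodal series this is exactly the
abrupt sign change of d(alpha)/dt: while the run stays in the flooded
basin the average grows; once the system leaves, the sampled bias
collapses and the average turns over.  A maximum at the final record
means alpha was still rising — no transition observed — and is flagged
non-converged rather than converted into a number.  Records between the
true transition and the stop frame are left in the running average; they
cannot raise the recorded maximum, so the estimate is unaffected.

The per-replica estimate is RT_calcd = alpha_max × t\*.  Applicability
conditions, checked by the test suite on the shipped fixture:
(i) the CV distinguishes the basins (the double-well coordinate trivially
does); (ii) deposition is slow relative to basin relaxation so little
bias lands on the transition state (stride 1 ps vs ~0.08 ps relaxation);
(iii) the unbiased escape time far exceeds the biased simulation span
(Kramers time ~2 ns vs ~25 ps biased runs; seeded unbiased controls show
no spontaneous escape).

Numerics: alpha is accumulated as a running log-sum-exp, so beta·V up to
~700 per record cannot overflow; when alpha_max itself exceeds the float
range the estimate is carried in log10 form.

### t_META-D

The descriptor is the simulation time of the first deposition record
flagged unbound in a constant-height run (0.25 kcal/mol, no
well-tempering).  Runs that never unbind within `max_time` yield a
censored result.  The descriptor is empirical: it aggregates all barriers
along the exit path and is meaningful for ranking, not as an absolute
time.

### Replica statistics

Campaigns use n = 10 replicas seeded as base_seed + index.  RT_calcd
values are summarised by the geometric mean τ: the mean of log10 values,
with SEM = sample standard deviation (n−1) / √n.  t_META-D is summarised
as the arithmetic mean ± SEM in ns.  Censored or numerically failed
replicas are excluded and reported via n_effective; the summary never
silently imputes them.

The rare-event check is a one-sample Kolmogorov–Smirnov test of the
RT_calcd values against an exponential with rate fitted by the sample
mean.  Because the parameter is estimated from the same sample, the
asymptotic p-value is conservative (it under-rejects); the suite verifies
this bias direction by simulation.  The Poisson comparison curve
P = 1 − exp(−x/θ) is offered in two parameterisations: `standard`
(linear-scale x, θ = τ) and `as_printed` (x and θ both as log10 values,
matching the published figure caption); outputs always state the mode.
The unpaired Student's t-test on log values uses the classic
pooled-variance form with *** < 0.001, ** < 0.01, * < 0.05.

## The metadynamics engine

Hills are multidimensional product Gaussians — the form implied by
per-CV widths.  Deposition parameters default to the published protocol:
stride 1 ps; ω₀ = 0.40 kcal/mol with bias factor k_B·ΔT = 10 kcal/mol
(ΔT ≈ 5000 K) for well-tempered runs; 0.25 kcal/mol constant height
otherwise.  Periodic CVs (dihedrals, period 360°) use wrapped
displacements in both kernels and wall checks.  One-sided harmonic
restraints implement the published floor/wall construct (e.g. a 15 Å
floor on the pulling CV, a 3 Å wall on an RMSD CV); their force constant
is not published and defaults to 10 kcal·mol⁻¹·unit⁻², stiff relative to
hill heights.  Bias forces reach the dynamics through the chain rule: the
analytic hill/wall gradient in CV space contracted with the analytic CV
Jacobian (identity for toy systems whose CVs are the coordinates).

Bound/unbound is decided geometrically where frames exist (no receptor
atom within 5 Å of any ligand atom) and by an absorbing coordinate
threshold for the 1-D/2-D toys — placed at x₀/2, halfway between saddle
and product minimum, and shared with the unbiased oracle so both measure
the same event.

## Toy systems and the oracle

Dynamics are overdamped (Brownian) Euler–Maruyama:
x ← x + F·μ·dt + √(2·k_BT·μ·dt)·η, with mobility μ = 1/(γ·m) in
Å²·mol·kcal⁻¹·ps⁻¹.  The estimators are dynamics-agnostic, and overdamped
dynamics gives cheap reference kinetics with a closed-form Kramers check:

    MFPT ≈ 2π·γ·m / sqrt(U''_min·|U''_saddle|) · exp(ΔG‡ / k_BT).

Units are physical (Å, kcal/mol, ps, K) so the published hill heights and
widths apply verbatim.

The standard recovery fixture is a symmetric quartic double well with
minima at ±1 Å and barrier 8 k_BT at 300 K, friction γ·m = 3
kcal·mol⁻¹·ps·Å⁻², time step 2 fs, CV width 0.2 Å (about one third of the
thermal basin width).  These give an unbiased MFPT near 2 ns — measurable
by a vectorised brute-force ensemble in seconds — while biased runs
escape in tens of ps (acceleration ≳ 50×) and stay safely in the
rare-event regime.  Recovery campaigns use 10 replicas of up to 2 ns
(≈10⁶ Langevin steps each at most, far fewer in practice), minutes on one
CPU.  The ranking fixtures differ by 2 k_BT (8 vs 10).

The pseudo-molecular complex — a fixed 12-particle cage with three anchor
clusters and a rigid 5-particle ligand on a funnel potential along its
exit axis — exists to exercise the geometric CV set (distance, angle,
dihedral, two RMSDs) and the unbound detector on real coordinate frames,
not to model receptor kinetics.  Its only degree of freedom is the exit
displacement, so angular CVs vary weakly; that is deliberate, mirroring
the role of orthogonal CVs as gentle correctors around a dominant pulling
coordinate.

What the toy validations show: that the estimator implementations recover
known kinetics under their stated assumptions, with the published
deposition parameters.  What they do not show: accuracy on systems with
multiple competing pathways, slow orthogonal degrees of freedom hidden
from the CVs, or receptor conformational gating — the regimes where the
published absolute log τ values overshoot experiment by many orders of
magnitude.  The SKR layer exists precisely because the raw estimates are
rank-preserving but not absolute.

## Geometry conventions

Coordinates are Cartesian Å; no minimum-image convention is applied (the
toys are non-periodic; externally supplied trajectories must be
pre-imaged).  Angles are in [0°, 180°]; dihedrals are signed torsions in
(−180°, 180°] under the IUPAC convention (positive when the far bond
rotates clockwise viewed from the second COM towards the third), verified
against an independent cross/dot-product formulation.  RMSD is computed
in the laboratory frame without superposition by default — the scaffold
these protocols restrain (0.6 kcal·mol⁻¹·Å⁻² backbone restraints)
effectively fixes the frame — with an optional Kabsch superposition mode
for unrestrained inputs.  Degenerate geometries (coincident COMs,
collinear dihedral axes) raise errors instead of returning arbitrary
values, so a corrupted bias cannot be deposited silently.

## SKR layer

Ordinary least squares with intercept; r² is the squared Pearson
correlation, reported also as a percentage; RMSE divides the residual sum
of squares by n−2 (the regression standard error) — the convention that
reproduces both published model errors (0.20 and 0.45 log units), where a
denominator of n does not.  Training sets are defined by an explicit
congeneric flag (the eight tiotropium-like compounds for the Tautermann
tables; all four for the Liu tables).  A similarity-threshold filter
(default 0.45) is provided as a configurable alternative but does not
define the shipped training sets, because the printed similarity of one
excluded compound (0.48) straddles the threshold its exclusion was argued
from.  Quantities recomputed from the packaged tables inherit their
3-significant-figure printing, so recomputed statistics can differ from
the published ones by up to ~0.005 in r²; consistency checks therefore
use ±0.02 on predictions/residuals and ±0.01 on r².  The SRT/MRT/LRT
class boundaries (below 1.0 and from 2.5 log₁₀ min) are configuration
chosen to reproduce the published labels, which the source never defines
numerically.

## Known limitations

- Hill lists are summed directly (no grid/spline bias storage); fine at
  desk scale, quadratic in run length for very long runs.
- The exponentiality p-value is approximate under parameter estimation
  (documented above) — adequate for a qualitative rare-event check.
- t_META-D discrimination of nearby barriers is precision-limited: for
  the 2 k_BT ranking fixtures the mean gap (~7 ps) is comparable to the
  per-replica spread (~8 ps), so with n = 10 an occasional mis-ordered
  campaign repetition is expected; τ-based ranking is sharper.
- Censored replicas are excluded rather than treated by survival
  analysis; n_effective makes the exclusion visible.
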