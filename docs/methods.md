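# Methods

`pairsapt` models the intermolecular interaction energy of a molecular
dimer as four atom-pairwise components mirroring a symmetry-adapted
perturbation theory (SAPT) decomposition — electrostatics, exchange–
repulsion, induction, and dispersion — and fits one global parameter per
atomic species and component to reference component energies.  This note
records the model, the conventions the equations leave open, the
numerical design, and what the synthetic studies do and do not show.

## Atom species

Atoms are typed into a fixed 17-label vocabulary that indexes the global
parameters: heavy atoms by element plus *total* bonded-neighbour count
(C4, C3, C2, N3, N2, N1, O2, O1, S2, S1), hydrogens by the heavy element
they bind to (HC, HN, HO, HS), and halogens by element (F, Cl, Br).
Bonds are perceived from geometry: a pair is bonded when its distance is
below 1.2× the sum of single-bond covalent radii.  Under this reading a
methane carbon is C4, a carbonyl oxygen O1, a hydroxyl oxygen O2.
Aromaticity and hybridization beyond neighbour counts are out of scope;
unsupported elements are rejected rather than silently typed.

## Inputs

Per-atom properties are *inputs*, not predictions: net monopole q,
dipole μ, traceless quadrupole Θ, an effective nuclear charge Z, a
density width σ, and a Hirshfeld volume ratio h.  In practice these come
from atoms-in-molecules partitioning of a molecular density (or from
learned predictors of such partitions); the energy model is agnostic to
the source, and the synthetic generator provides them for testing.  A
bundled free-atom table (C6, α, ⟨r²⟩, ⟨r⁴⟩, Z_nuc for the eight supported
elements) carries literature-typical magnitudes; these are configuration
for the synthetic studies, not fitted claims.

## Energy model

All expressions are evaluated in Hartree atomic units internally.  For
each intermolecular atom pair (i ∈ A, j ∈ B) at separation r:

**Electrostatics.**  E = Σ [ Z_i Z_j / r + Z_i·T·M_j f1 + M_i·T·Z_j f1 +
M_i·T·M_j f2 ], where M = (q − Z, μ, Θ) is the electronic multipole set,
T the Cartesian interaction tensors (derivatives of 1/r up to
quadrupole–quadrupole), and f1, f2 charge-penetration damping functions
with per-species exponents K_elst:

    f1(r) = 1 − e^{−K r}
    f2(r) = 1 − K_i²/(K_i²−K_j²) e^{−K_i r} − K_j²/(K_j²−K_i²) e^{−K_j r}

with the analytic limit 1 − e^{−Kr}(1 − Kr/2) when the exponents
coincide (branch threshold 1e−6 relative).  Two conventions had to be
fixed.  First, f1 carries a single species index; we damp each
nucleus–multipole term with the K of the *multipole-bearing* atom, since
the damped object is that atom's electron distribution — this is also
the only one-sided assignment that keeps the total invariant under
swapping the monomer labels.  Second, note that f2 as defined is not
bounded by 1: it peaks at 1 + e⁻³/2 ≈ 1.025 near K r ≈ 3 (visible
directly from the equal-exponent limit).  We keep the function as
defined; the ~2.5 % overshoot is harmless in practice and absorbed by
the fit.

**Exchange–repulsion.**  E = Σ K_ij S_ij with the density-overlap
function S = (⅓(Br)² + Br + 1)e^{−Br}, B = (σ_i σ_j)^{−1/2}.  The
inverse geometric-mean width makes Br dimensionless; S(0) = 1 and S
decays monotonically.

**Dispersion.**  Free-atom inputs are Hirshfeld-rescaled, C6_i =
C6_free h², α_i = α_free h, combined pairwise (sign convention:
C6_ij < 0):

    C6_ij = −2 C6_i C6_j / ((α_j/α_i) C6_i + (α_i/α_j) C6_j)
    C8_ij = 3 C6_ij √(Q_i Q_j),  Q = √Z_nuc ⟨r⁴⟩/⟨r²⟩
    C10_ij = (49/40) C8² / C6

so C10·C6/C8² = 49/40 identically.  Each power law is damped by the
Tang–Toennies function f_n = 1 − e^{−x} Σ_{k≤n} x^k/k! with the
sharpened argument x = Br + r(2B² + 3B)/((Br)² + 3Br + 3).  The C6 term
is parameter-free; K_disp scales the C8/C10 contribution.

**Induction.**  Induced dipoles μ′ solve the Thole-smeared mutual
polarization equations.  The zeroth iterate is α_i times the damped
field of the partner monomer's permanent multipoles (net charge, dipole,
quadrupole); successive substitution with mixing factor ω = 0.7 adds the
mutual induced-dipole coupling over *all* other atoms until the largest
component change falls below `pol_tol`.  Thole smearing (a = 0.39,
reduced distance u = r/(α_i α_j)^{1/6}) multiplies the two radial
structures of the dipole tensor by λ5 = 1 − (1 + au³)e^{−au³} and
λ3 = 1 − e^{−au³}; the charge and quadrupole field terms use λ3 and
(λ5, λ7) analogously.  The polarization energy is −Σ_i μ′_i·F_i summed
over the atoms of both monomers (both polarization directions), with no
½ prefactor — any constant prefactor is absorbed by the fitted K_indu of
the short-range overlap term K_ij S_ij that completes the component.

**Pair parameters.**  The fit determines one positive scalar per species
and component; pair values use the geometric mean K_ij = √(K_i K_j),
which is symmetric, positivity-preserving, and identifiable from
homodimer data alone (homodimers contain all same-species diagonal
pairs).  It is isolated in one function (`energy.pair_parameter`) so the
rule can be swapped.

**Units.**  Electrostatics, dispersion and polarization are computed in
hartree and converted (× 627.509 kcal/mol).  The two overlap terms K·S
yield kcal/mol directly, i.e. K_exch and K_indu are in kcal/mol; with
S ~ 0.01–0.1 at van der Waals contact this puts the fitted values on the
few-unit scale conventional for this model family.  K_elst is in
1/bohr, K_disp dimensionless.

## Loss and optimization

Given reference components per dimer, the multi-target loss is

    L = (1 − γ) MSE(E_total) + γ Σ_c MSE(E_c),    γ = 0.4 by default,

with each MSE averaged over dimers (components summed afterwards, as
written).  Optimization is over log-parameters, so every K stays
positive.  Two numerical facts shaped the optimizer design:

* The damping exponents saturate at van der Waals separations
  (∂E/∂K ∝ r e^{−Kr}), so the Hessian in log-space has eigenvalues
  spanning ten orders of magnitude, with near-degenerate valleys mixing
  the K_elst of co-occurring species.
* The √K pair rule has a flat asymptote at K → 0: a quasi-Newton
  descent that overshoots early can park parameters at K ≈ 0 where the
  gradient vanishes and they never recover.

The fit therefore runs in two stages on identical residuals: a
bound-constrained BFGS descent (box K ∈ [10⁻³, 10²]; the bounds only
prevent collapse onto the flat asymptote) from the K = 1 start, followed
by a Levenberg–Marquardt refinement that resolves the ill-conditioned
tail to machine precision.  Both stages receive complex-step derivatives
of the vectorized pair sums — the loss is holomorphic in the
log-parameters, so gradients are exact to rounding.  Defaults:
`grad_tol` 1e−9, `max_iter` 2000 (per stage); convergence in the
noise-free studies typically takes a few hundred quasi-Newton iterations
plus a few hundred LM residual evaluations.  Species absent from the
training data are left blank and reported, never extrapolated.

For speed, fitting uses a "compiled" representation: every
parameter-independent quantity (multipole contractions, overlaps,
dispersion coefficients, polarization energy) is precomputed per pair,
making one loss evaluation a handful of vectorized array operations.
The readable per-pair implementation in `energy.py` is the reference;
a test asserts the two routes agree to 1e−10.

## Synthetic data

The generator emulates the structure of a homodimer-train /
heterodimer-test study on small organics: a library of 16 idealized
monomers (alkane/alkene/alkyne, alcohol, water, aldehyde, acid, amide,
amine, imine, nitrile, thiol, thiocarbonyl, three halomethanes) whose
union of species covers all 17 labels; homodimers (X,X) and heterodimers
(X,Y) at randomized orientations; per-atom properties with plausible
magnitudes (exactly neutral monomers, σ ∈ [0.5, 1.2] bohr,
h ∈ [0.75, 1.25], small dipoles/quadrupoles, valence Z); ground-truth
parameters drawn from ranges bracketing published-scale magnitudes
(K_elst ∈ [2.5, 5.5], K_exch ∈ [0.5, 7], K_indu ∈ [0.1, 2.5],
K_disp ∈ (0, 1]); and reference components produced by the forward model
itself, optionally with independent per-component Gaussian noise (totals
re-summed after noising).  All randomness flows from one explicit seed;
identical monomers receive identical (content-hashed) properties,
co-rotated with their placement.  A small helper
(`make_class_manifest`) expands a functional-group class → count
composition into a flat manifest of class labels; the bundled default
(`SUPPLEMENT_COMPOSITION`) is the 12-class, 47-dimer composition used
when a homodimer training pool is extended beyond the 8 core classes to
cover nitrogen, sulfur and halogen species.

Centre-of-mass separations default to 4–8 bohr; placements whose
closest intermolecular contact falls below 2.8 bohr (≈1.5 Å) are
resampled, and anything under the 1.5 bohr clash threshold is rejected
outright.  The window deliberately reaches into the repulsive wall:
with equilibrium-only sampling the penetration exponents are nearly
unidentifiable (their damping is saturated), which is the standard
reason force-field fits include compressed geometries.  The contact
floor, conversely, excludes unphysical sub-ångström contacts where
exponential terms would dominate every error measure.  Three
orientations per pair are generated by default: with fewer, a species
pair confined to a single monomer can present near-proportional overlap
equations that admit a second exact solution.

Because the generator uses the model as its own ground truth, parameter
recovery is a *well-specified* inverse problem: passing tests show that
the estimator recovers the generating parameters and transfers from
homodimers to heterodimers of the same monomer pool.  They do not show
that the functional form fits real SAPT surfaces, that learned atomic
properties are accurate, or how the model extrapolates to unseen
chemistry — those require the real reference datasets.

Problem sizes used by the bundled studies: the recovery study trains on
the 48 homodimer records of the full 16-monomer library (three
orientations each) and tests on the 360 heterodimer records.  The noise
study repeats a 6-monomer version (36 homodimer records at six
orientations per pair, 90 heterodimer test records) over 20 seeds with
0.25 kcal/mol per-component noise; six orientations give roughly 4.5
reference equations per fitted parameter, the determinacy regime of the
real training sets — an underdetermined noisy fit would measure
overfitting rather than noise propagation.

## Numerical choices and degenerate inputs

* f2 equal-exponent branch below 1e−6 relative exponent difference.
* Polarization: `pol_tol` 1e−10 a.u. (max dipole-component change), cap
  500 sweeps; the tight tolerance keeps iteration noise in the energy
  below 1e−9 kcal/mol, so rigid-motion invariance holds to that level.
  A dense direct solve of the same linear system is provided as an
  independent oracle.
* Geometry validation rejects interatomic distances below 0.4 Å and
  intermolecular clashes; parsing errors name the offending line.
* Quadrupoles are symmetrized and exactly detraced on input (tolerance
  1e−8 before rejection).
* Parameter tables serialize as CSV with blanks for unset species;
  reading uses round-trip float parsing so save/load is bit-exact.

## Known limitations

* Multipoles truncate at quadrupole; damping enters as scalar
  multipliers per contraction, not re-derived damped kernels.
* No analytic gradients w.r.t. coordinates (no forces), no periodic
  boundary conditions, no three-body dispersion.
* The induction overlap term enters with a positive sign as defined;
  its sign preference is left to the fitted K_indu magnitudes.
* Whether Z is a full or valence nuclear charge is a property of the
  input data, not hard-coded; the synthetic generator uses valence
  charges.
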