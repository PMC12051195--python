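# Methods

## Model

The fluid is an equimolar mixture of polyampholyte cations and anions: linear
chains of `r` charged hard spheres (diameter d, valencies alternating ±1,
both ends the same sign, net charge ±1e; `r` odd by construction).  Bonds
have fixed length b with free rotation.  Water is implicit (ε_r = 78.3,
T = 298 K, Bjerrum length l_B = e²/4πε₀ε_r k_BT ≈ 7.16 Å).  Two hard planar
walls at z = 0 and z = h each carry a smeared surface charge density σ
(default −1/70 e/Å², typical of mica); monomer centers are restricted to
[d/2, h − d/2].  Densities vary only along z; the slit is open to a bulk
reservoir at salt concentration c (chains of each species per volume).

Units: lengths Å, energies k_BT, charges e, densities Å⁻³; molar
concentrations are converted only at the interface layer.

## Free energy functional

**Ideal chains.**  The configurational free energy of flexible
fixed-bond-length chains is treated exactly through transfer-operator
propagators.  Each monomer carries the half Boltzmann weight
w(i, z) = exp(−[Z_i ψ(z) + λ_ex(z) + V_ex(z)]/2); the recursion

    c(1, z) = w(1, z)
    c(i, z) = w(i, z) · T[w(i−1, ·) c(i−1, ·)](z),   i > 1
    (T f)(z) = (1/2b) ∫_{z−b}^{z+b} f(z′) dz′

builds single-sided propagators, and because the alternating charge sequence
is palindromic, the monomer densities are n_i(z) = e^{βμ′} c(i,z) c(r+1−i,z)
with one propagator set per species.  The half-weight convention counts each
monomer's full field weight exactly once; it is fixed unambiguously by the
r = 1 reduction to the Boltzmann monomer density and by the ideal-gas sum
rule n′ = r·n_chain in a field-free system.  The site weight includes the
excluded-volume field λ_ex and the steric wall potential in addition to the
electrostatic term — otherwise the profiles would not minimize the
functional.  The bond kernel is truncated, not renormalized, at the walls:
configurations reaching into a wall are forbidden and their weight is lost.

**Excluded volume.**  A generalized Flory-dimer (GFD) equation of state,
applied as a local-density functional of the *total* monomer density
n(z) = n₊(z) + n₋(z):

    βf_ex(n) = (n/r) ∫₀^η [Z_r(η′) − 1]/η′ dη′,   η = (π/6) d³ n
    Z_r(η) = Z₂(η) + w_r [Z₂(η) − Z₁(η)],
    w_r = (v_e(r) − v_e(2)) / (v_e(2) − v_e(1))

with Z₁ the Carnahan–Starling monomer EOS and Z₂ the Tildesley–Streett
tangent hard-dumbbell EOS (both of the cubic-over-(1−η)³ form, so the
integral is closed-form).  The exclusion volumes v_e are computed
geometrically: sphere-union volumes of a monomer, a bonded dimer (lens
overlap of radius-d exclusion spheres at distance b), and a flexible trimer
whose 1–3 lens is averaged over bond-angle configurations subject to the 1–3
hard core — this is what encodes "end monomers exclude less than free ones,
interior monomers less still".  v_e(r) is linear in r beyond the dimer.  The
construction reduces exactly to Carnahan–Starling at r = 1 and to the dimer
EOS at r = 2, and satisfies n ∂f_ex/∂n − f_ex = (n/r)(Z_r − 1) identically;
for d < b the dimer reference EOS is kept in its tangent form while the
exclusion volumes use the true bond length (a declared approximation).  The
local field is λ_ex(n) = ∂βf_ex/∂n, evaluated analytically.  A strictly
local (LDA) treatment is used throughout; no weighted-density smoothing.

**Electrostatics.**  Mean field with the laterally integrated kernel
βϕ(z, z′) = −2π Z_γ Z_δ l_B |z − z′|.  The reduced potential in the weights
is ψ(z) = Ψ_D + ψ_walls + ∫ K(z,z′) ρ_c(z′) dz′, where ρ_c is the signed
monomer charge density and the two equally charged walls contribute only a
constant inside the slit.  The Donnan offset Ψ_D enforces global
electroneutrality ∫ρ_c dz + 2σ = 0.  No image charges, dielectric contrasts
or ion–ion correlations beyond mean field.

**Grand potential.**  Using the stationarity identity for the ideal term,

    βΩ/A = −(Γ₊+Γ₋) + ∫[f_ex − λ_ex n] dz − ½∫ψ_fl ρ_c dz
           − Ψ_D Q_f − 2π l_B σ² h ,

which is exact up to h-independent constants that cancel in
Δg_s(h) = g_s(h) − g_s(h_ref) with g_s = Ω/A + p_b h.  The bulk pressure is
βp_b = 2 n_chain Z_r(η_b); the normalization chemical potential is
βμ′ = ln n_chain + r λ_ex(n_b) (bulk electrostatics vanish by neutrality).

## Numerical scheme

- Uniform grid on [0, h]; dz (default 0.25 Å) must divide b, d and d/2 so
  kernel supports and the contact plane fall on nodes.  Halving dz changes
  the reported partition ratios by < 10⁻³ (tested).
- All integrals of density-like fields use **window-aware trapezoid rules**:
  profiles jump discontinuously at the contact planes, and restricting
  quadrature cells to the accessible window removes an O(dz) error
  proportional to the contact density (the plain rule would corrupt the
  contact pressure by ~10% at dz = 0.25).  The electrostatic convolution is
  evaluated by prefix sums in O(N), exact for piecewise-linear ρ_c.
- **Picard iteration** (order: fields from current densities → propagator
  prediction → Donnan adjustment → mixing): new densities are mixed with
  fraction α (default 0.05).  Convergence requires max relative density
  change < 10⁻⁷ (with a floor of 10⁻¹² × bulk chain density in the
  denominator so that vacuum regions, tens of decades below bulk, do not
  dominate the metric) and |electroneutrality residual| < 10⁻⁸ e/Å².
- **Donnan offset**: because every chain carries net charge ±1, shifting ψ
  by x multiplies species densities by e^{∓x}, and the electroneutral shift
  solves P e^{−x} − M e^{x} + 2σ = 0 in closed form.  The solver applies
  this exact scalar solve each iteration (in the branch stable under strong
  co-ion exclusion, M → 0), which removes the slow global-neutrality
  relaxation mode of an incremental corrector; a damped corrector
  (`update_donnan`) is provided for step-wise use.  The cold start seeds
  Ψ_D to cancel the constant wall potential −2π l_B σ h, so the first
  iteration sees a bulk-like interior.
- **Stability**: long-wavelength charge relaxation limits the stable α at
  large κh (gain ≈ (κh/π)²).  Divergence is detected by a physical tripwire
  (an iterate whose packing fraction exceeds η = 0.6, far above any
  equilibrium in scope) or a non-finite metric; limit cycles by a stall
  window without improvement.  Either restores the best iterate and halves
  α (floor 5×10⁻⁴).  Propagator slices are rescaled to unit maximum with
  log-scale bookkeeping, and weight exponents are capped at ±250, so
  arbitrarily violent transients remain finite; neither cap binds at
  convergence.  The iteration is fully deterministic.
- **Net pressure routes.**  Derivative route: centered differences of
  −∂Δg_s/∂h.  Contact route: βp_net = n(d/2) + βp_ex(n(d/2)) − 2πl_Bσ² −
  βp_b, where βp_ex(n) = (n/r)(Z_r − 1) is the local GFD excess pressure.
  The excess term is required by the soft-wall limit of a local-density
  functional (the wall force integral picks up ∫n dλ_ex across the wall
  region); with it the two routes agree to 1% at dz = 0.0625 and converge
  to each other as O(dz²).
- Δg_s references the largest separation of a scan; the default reference
  is min(40 λ_D, 300 Å) or farther, and tests use references where the
  residual tail is negligible relative to the quantity under study.

## Verification strategy

- Propagator assembly is checked against a brute-force sum over all
  discretized 3-monomer configurations with nonuniform fields (agreement at
  machine precision), uniform-weight power laws against dense operator
  composition, and the ideal-gas sum rule.
- The r = 1 point-ion limit (d = b = 0.25 Å) is compared with an
  independent nonlinear Poisson–Boltzmann boundary-value oracle
  (`scipy.solve_bvp`) and with the analytic Gouy–Chapman single-wall
  solution; density profiles agree to < 1%.
- GFD reductions (r = 1, r = 2), thermodynamic consistency identities, and
  a finite-difference check of λ_ex pin the equation of state.
- Grand-canonical consistency: wide neutral slits recover bulk densities at
  mid-slit to 10⁻⁷ relative for interacting pentamers.

## Problem sizes

Default production grids use dz = 0.25 Å (e.g. 433 nodes at h = 108 Å);
reported ratios are grid-converged at that spacing (halving dz moves them by
< 10⁻³ relative).  Scans for decay-length fits use h up to ~300–400 Å.  The
route-consistency check runs at dz = 0.0625 Å, where the wall-quadrature
error falls below 1% of the net pressure even far out on the repulsive tail.

## Known limitations

- The strictly local excluded-volume functional cannot resolve packing
  oscillations at the walls, and the partition ratio of strongly adsorbing
  long chains is exponentially sensitive to how the first adsorbed monolayer
  is treated; with the defaults (d = b = 4 Å) the 15-mer slit ratio comes
  out two to three decades below the reported reference value even though
  every qualitative feature (linear apparent-charge profile, near-total
  co-ion exclusion, giant ratio) is reproduced.  A weighted-density
  refinement is deliberately out of scope.
- The bond length b and diameter d of the reference calculations are not
  fully specified upstream; d = b = 4 Å is a declared assumption, and
  results that depend exponentially on brush structure inherit that
  uncertainty.
- Monodisperse chains only; no added simple salt, no asymmetric walls, no
  branched architectures, no electrostatic correlation corrections.
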