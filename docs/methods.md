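# Methods

## Model and assumptions

The package implements mass-action dynamics for `N_S` consumers and `N_R`
substitutable abiotic resources. Resources enter at constant influx `ρ_i`
(resource · time⁻¹), optionally leach at rate `η_i` (time⁻¹, default 0),
and are removed bilinearly at per-consumer, per-resource rates `C_ij ≥ 0`.
Consumers convert uptake into biomass with efficiency `ε > 0` and die at
rate `μ_i > 0`. Crossfeeding adds production terms `P_ij ≥ 0` (per unit
consumer · time⁻¹): consumer `j` leaks resource `i` at rate `P_ij S_j`
regardless of what it is itself consuming, and pays the corresponding
biomass cost `S_j Σ_i P_ij` in its own equation — substrate-independent
leakage (or, equivalently, partial recycling of biomass on mortality).
The cost term carries no `ε` factor and no resource dependence; that exact
form is deliberate and is what the equilibrium formulas and Jacobians
differentiate. Functional responses are linear throughout: no saturating
(Monod) uptake, no colimitation, no stochasticity.

Matrix orientation is fixed as rows = resources, columns = consumers; the
transpose in formulas is always the transpose of this stored matrix. Time
units are arbitrary; only shape consistency is enforced.

## Equilibria and inverse design

With invertible `C` (square case) the interior equilibrium is unique:
`R* = (Cᵀ)⁻¹ μ/ε`, `S* = [diag(R*) C]⁻¹ ρ`, and with production
`R* = (Cᵀ)⁻¹ (Pᵀ1 + μ)/ε`, `S* = [diag(R*) C − P]⁻¹ ρ`. Matrices with
condition number above 10¹² are treated as singular (the framework's
guarantees assume sufficiently distinct preference vectors; near-singular
`C` is a degenerate community). Feasibility is strict positivity with no
tolerance; feasible equilibria with densities below 10⁻⁹ are logged as
nearly degenerate.

The inverse problem is solved for arbitrary shape as
`μ = ε Cᵀ R* − Pᵀ1`, `ρ = diag(R*) C S* − P S*`. For uniform specialist
targets this reduces to `μ = crε1 − Pᵀ1`, `ρ = s[crI − P]1`; for
non-uniform targets with `P ≠ 0` the general expression is the natural
extension (it is exactly the equilibrium condition of the crossfeeding
ODE), and positivity is then *checked*, not guaranteed — violations emit a
`FeasibilityWarning` naming the offending indices rather than failing
silently. Forward solving is restricted to square `C`; with more resources
than consumers the resource equations alone do not pin down `S*`, while the
inverse design remains well posed and is the supported route.

## Stability machinery

The Jacobian blocks at `(R*, S*)` are
`[−diag(CS*) − diag(η), P − diag(R*)C; ε diag(S*)Cᵀ, diag(εCᵀR* − Pᵀ1 − μ)]`.
The bottom-right diagonal vanishes at an interior equilibrium and carries
the invasion growth rate for an extirpated consumer, so one assembler
covers interior and boundary equilibria. The blocks are validated against
central finite differences of the right-hand side (relative tolerance
10⁻⁵, step 10⁻⁶) in the test suite, including `P ≠ 0` and `η ≠ 0`.

Stability verdicts use a tolerance band: stable means
`max Re λ < −10⁻¹⁰`, and `|max Re λ| ≤ 10⁻¹⁰` is reported as marginal.
These spectra characteristically pile up real eigenvalues near zero (slow
relaxation), so a strict sign test would be numerically fragile.
Eigenvalues are reported sorted by descending real part, ties by ascending
imaginary part; multiset comparisons in tests pair eigenvalues by optimal
assignment because sort order under 10⁻¹⁶ real-part ties is unstable.

For specialists the quadratic map between production eigenvalues `γ` and
Jacobian eigenvalues `λ` is evaluated with both complex square-root
branches, no principal-branch pruning; the union over `γ` reproduces the
full `2N` spectrum to 10⁻⁸. The Hermitian certificate forms
`H(√D1 Cᵀ D2 C √D1)` with `D1 = ε diag(S*)`,
`D2 = [−diag(CS*) − λI]⁻¹(−diag(R*))` and declares positive definiteness
when the smallest eigenvalue of the Hermitian part exceeds
`10⁻¹² · max(1, ‖H‖)`; rank-deficient `C` correctly fails the certificate.

## Structural-stability volumes

Feasible mortality vectors form the cone spanned by the columns of `Cᵀ`;
feasible influx vectors the cone spanned by the columns of `diag(R*) C`
(hence `V_ρ` depends on the choice of `μ` through `R*`). Volumes are
normalized so that `V = 2 ×` (fraction of the unit sphere inside the
cone): orthogonal generators at `n = 3` give exactly 1/4. Three routes are
implemented and cross-checked:

* `gaussian_mc` — importance sampling of `∫_{ℝ₊ⁿ} e^{−ξᵀMξ} dξ` with a
  product-of-half-normals proposal matched to `diag(M)`, scaled by
  `2√(det M)/π^{n/2}`; the reported standard error is the sample standard
  error of the weights, scaled accordingly.
* `cone_mc` — twice the fraction of standard-normal directions whose
  coordinates in the Cholesky-factor basis of `M` are all nonnegative
  (isotropic directions, so this is the literal solid-angle fraction),
  with a binomial standard error.
* `lhuilier3` — for `n = 3`, twice the spherical-triangle solid angle from
  L'Huilier's theorem over `4π`; exact, zero standard error.

Default sample count is 10⁶, giving ≲1% relative error at `V ≈ 0.04`. The
seed is a required argument of the API (defaulted and logged in the CLI).
For the uniform-similarity family the determinant
`(1 − a)^{n−1}(1 + (n−1)a)` is monotone in the common cosine `a`, so
uniformly less similar consumers always enlarge the volume; the packaged
3-species pair shows the general case is not monotone in any single angle.

## Ensemble generators

Generators emulate communities at a designed equilibrium, not fitted data.
One consumption matrix is fixed per configuration: `diag_strength` on the
diagonal with i.i.d. `U(0, offdiag_scale)` off-diagonals (specialist:
weak; generalist: strong), or a Gaussian kernel
`offdiag_scale · exp(−d²/2w²)` in circular resource distance `d` for the
ordered variants (the kernel family is a modelling choice; any smooth
decaying preference profile would serve), or `c·I`. Equilibrium densities
are drawn per draw from `U(0.1, 1)` by default — bounded away from zero so
`diag(R*)` stays well conditioned — and rates are designed by the inverse
formulas, so every draw is exactly at equilibrium by construction.
Rank-deficient consumption draws are rejected and logged.

Production matrices are i.i.d. `U(0, production_scale)`, optionally
symmetrized as `(P + Pᵀ)/2`, then rescaled by a single scalar (preserving
symmetry and relative structure) only as far as needed for the feasibility
constraints `crε > Σᵢ Pᵢⱼ` (column sums) and `cr > Σⱼ Pᵢⱼ` (row sums) to be
satisfiable at the top of the density band; individual `(r, s)` draws are
then rejection-sampled subject to those constraints, so every pooled draw
is feasible.

Instability under asymmetric production is a rare-consumer phenomenon in
this ensemble: the sharp condition fails only when
`ε Im(γ)² ≥ cs(cr − Re γ)`, and feasibility caps the row sums (hence
`Re γ` and the Gershgorin radii), so with the default density band and
i.i.d. uniform `P` unstable feasible draws essentially never occur. The
demonstration configuration therefore lowers the consumer-abundance floor
to `density_low = 10⁻³` (consumers near extinction damp oscillatory
exchange modes only weakly) with `N = 5`, `production_scale = 0.2`,
`ε = 1`; at those settings a few percent of feasible draws are unstable.
Symmetric production never destabilizes a feasible draw at any setting, in
line with the reciprocity theorem.

What the generators do **not** emulate: saturating uptake, environmental
fluctuations, demographic noise, measurement error, or empirically
structured (sparse, modular, phylogenetically correlated) preference
matrices. Passing tests therefore certify the mathematical claims for the
linear model at designed equilibria, not predictions for any particular
real community.

## Numerical choices

* Integration: `scipy.integrate.solve_ivp` with LSODA (stiff-capable),
  `rtol = 10⁻⁸`, `atol = 10⁻¹⁰`. Negative densities of magnitude below
  10⁻¹² are clamped to zero and logged; anything worse raises with the
  last valid state attached.
* Problem sizes: randomized theorem checks use 200 systems up to 30
  species (square and rectangular), 500 reciprocity draws up to 12
  species, 1000 draws for the sharp-condition equivalence, and 10⁶ Monte
  Carlo samples per volume; these sizes give clear margins for every
  assertion while keeping the full suite around a few seconds.
* All randomness flows through `numpy.random.default_rng` seeds; identical
  configuration and seed reproduce matrices bitwise and eigenvalue
  multisets exactly.

## Known limitations

Forward equilibria for rectangular `C` are not solved (inverse design
only). No bifurcation/continuation analysis: the model has a unique
interior equilibrium. No global stability results — all verdicts are
local. Spherical-simplex volumes beyond `n = 3` have no closed form here;
Monte Carlo is the route. The `V_ρ` volume has only property-level checks
(no external reference value exists for it).
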