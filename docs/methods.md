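# Methods

## Physical model and conventions

The solver computes the TM-polarized (out-of-plane electric) field of an
electric line source in a 2D dielectric map, the forward problem of
ring-array microwave tomography. All quantities are SI; frequency enters
as the angular `ω = 2πf`.

* **Time convention** `e^{+jωt}`. Outgoing waves are Hankel functions of
  the second kind; the complex relative permittivity is
  `ε_c = ε_r − jσ/(ωε₀)` and wavenumbers `k = ω√(μ₀ε₀ε_c)` are taken on
  the branch `Im k ≤ 0` so fields decay in lossy media. (The alternative
  sign, `k² = ω²μ₀ε₀ε_r + jωμ₀σ`, would grow under `H₀⁽²⁾` and is
  rejected; see the sign check in the wavenumber tests.)
* **Green's function** `G(ρ,ρ′) = −(j/4)H₀⁽²⁾(k_bk|ρ−ρ′|)`, evaluated only
  at strictly positive distances — the singular self term never passes
  through this kernel; the system diagonal is `1/α` instead.
* **Constants** `μ₀ = 4π×10⁻⁷ H/m`, `ε₀ = 8.8541878128×10⁻¹² F/m`, fixed.

## Polarizability: two schemes

The per-dipole polarizability couples the moment to the local field,
`P_i = α_i E_tot(ρ_i)`. Two forms are implemented
(`polarizability.scheme` in the config):

* **`calibrated`** (default): `α_i = h²(k_i² − k_bk²)
  = ω²μ₀ε₀ h²(ε_c,i − ε_c,bk)` with `h` the lattice spacing. This is the
  midpoint-rule (weak-form) discretization of the 2D Lippmann–Schwinger
  volume integral `E = E_inc + ∫ G (k² − k_bk²) E dΩ`, so the dipole
  system converges to the continuous scattering solution as `h → 0`. The
  self-patch integral of `G` over a cell is neglected (its relative
  contribution to an inclusion diagonal is `O(α)` and vanishes with
  `h²`); the measured receiver-field error against the analytic cylinder
  series is 3.8% / 1.0% / 0.37% at 17/33/65 dipoles per side for the
  default scenario, comfortably first-order convergent.
* **`maxwell-garnett`**: the dimensionless 2D contrast
  `α = (ε_t − ε_b)/(ε_t + ε_b)` (single component), or the
  concentration-weighted mixture sum `Σ c_k (ε_k − ε_b)/(ε_k + ε_b)` with
  area-fraction concentrations supplied by the user. A
  `dimension_factor` option multiplies by 2, the m-dimensional
  Clausius–Mossotti prefactor for m = 2, for users who prefer that
  normalization. This form is kept because it is the classical
  effective-medium expression, but it carries no cell-area scale: used as
  the coupling coefficient it mis-scales the scattered field by roughly
  `ε_b/(k_bk²h²(ε_t+ε_b))` and does **not** converge under refinement
  (the denominator `ε_t + ε_b` encodes the depolarization of a
  perpendicular-field (TE) inclusion, which does not apply to the TM
  out-of-plane field). It is therefore not the default for quantitative
  field prediction; all structural, solver and conditioning behaviour is
  scheme-independent.

## The bath/background offset

Dipoles whose permittivity exactly equals the background have `α = 0` and
an infinite diagonal, so the bath assigned to the grid (ε_bath = 22) is
offset from the Green's-function background (ε_bk = 21.99 by default;
conductivities equal). Consequences, reproduced by the sweep experiment:

* the `1/α`-diagonal system's condition number scales like
  `1/(ε_bath − ε_bk)` — one decade per decade of offset;
* multiplying each row by `α_i` (unit diagonal, `−α_iG_ij` off-diagonal)
  keeps the condition number essentially flat (~4 on the 17 × 17 case)
  but destroys the Toeplitz structure of the off-diagonal part, which is
  what the FFT acceleration needs; the package therefore solves the
  `1/α` form and uses the α-multiplied form only as the conditioning /
  consistency reference;
* the sweep's `relative_error` column is the total-field discrepancy
  between the two formulations solved directly at the same ε_bk — the
  reference for this error is a deliberate design choice of this package
  (no canonical definition exists) and is documented here prominently;
* field maps are insensitive to the offset until it reaches ~1
  permittivity unit: maps for ε_bk ∈ {21.9, 21.99, 21.999} agree pairwise
  within 5% while ε_bk = 21 visibly deviates. The default 21.99 balances
  a modest condition number (~3.4×10³ at 17 × 17) against offset error.

## Fast operator

On the uniform grid the off-diagonal kernel depends only on the index
displacement, so `G` is block Toeplitz with symmetric Toeplitz blocks.
A symmetric `n × n` block embeds into a circulant of size `2n − 2`
(first row followed by its reversed interior: 81 → 160, i.e. 79 added
columns), and FFT lengths are rounded up to the next power of two by
default (160 → 256); when padding beyond `2n − 2`, the negative
displacements are wrapped to the tail of the kernel so the cyclic
convolution stays exact on the leading `n` coordinates. Two equivalent
strategies are exposed and tested against the dense oracle:

* `full2d` — one 2D block-circulant embedding of the whole kernel
  (two 2D FFTs + one inverse per application);
* `block1d` — per-block 1D circulant products with the `2n − 1` distinct
  block spectra (`T_Δ = T_{−Δ}`) reused across block rows.

Both store O(N) complex values (diagonal + kernel spectra), never the
dense matrix. Spectra are computed once per operator and reused across
iterations and right-hand sides (per-antenna solves).

## Solvers

* **direct** — LAPACK LU via `scipy.linalg.lu_factor`.
* **COCG** — van der Vorst–Melissen recurrence on the unconjugated
  bilinear form `⟨x,y⟩ = Σ xᵢyᵢ`; one operator application per iteration.
* **COCR** — Sogabe–Zhang recurrence (residuals orthogonal in the
  A-weighted bilinear form); one application per iteration after the
  initial `A r₀`.

Convergence is the relative residual `‖b − Ax‖/‖b‖ ≤ tol` (default 1e−5,
scale-free), declared on the recursion residual and confirmed by a single
true-residual evaluation. The initial guess is zero — there is no RNG
anywhere in the solve path, so runs are bit-reproducible. Breakdown of the
unconjugated products (`|rᵀr| < 10⁻³⁰‖r‖²`, and the analogous pivot
products) returns a flagged non-convergent report, never a silent wrong
answer. Residuals are not monotone for COCG and are not asserted to be.
On the default scenario the bath-dominated diagonal makes the system
strongly diagonally clustered and COCG converges in ~20 iterations at
N = 4225 without preconditioning (none is implemented).

## Analytic validation oracle

The independent reference is the classical cylindrical-harmonic series for
a line source near a homogeneous dielectric cylinder: the incident
`H₀⁽²⁾` field is expanded about the cylinder axis by the addition theorem,
and continuity of `E_z` and `∂E_z/∂r` at `r = a` fixes per-mode reflection
coefficients (module docstring of `dda2d.validation` gives the closed
form). Truncation defaults to `max(20, ⌈2|k_e a|⌉ + 15)` (Wiscombe-style);
self-convergence under order doubling is < 1e−8 in the test scenario. At
zero contrast the series reduces exactly to the line-source field of the
physics module, pinning the two modules to the same convention. The
comparison quantity is the *total* receiver field (what an antenna
measures); the scattered-only discrepancy is also reported but is
intrinsically larger since the scattered part is ~1.6% of the total in
the heavily lossy bath.

Because the DDA scene carries the ε_bath/ε_bk offset, its continuous limit
differs from the pure cylinder-in-bath problem by that offset (~0.1% at
the default 0.01); the analytic exterior uses the bath properties and the
offset contribution is part of the measured discrepancy envelope.

## Defaults and their provenance

| parameter | default | note |
|---|---|---|
| grid | 81 × 81 over 40 cm (h = 5.0 mm) | bench scenario; 65 × 65 over 35.2 cm (h = 5.5 mm) is the power-of-two-friendly alternative |
| antenna ring | 16 antennas, ⌀ 15.2 cm, start 0° (east), CCW | the antenna count of the physical array is not documented; 16 is typical of these monopole rings and is explicit in the config |
| bath / background | ε 22 / 21.99, σ = 1.0 S/m | offset rationale above |
| phantom | 6 cm cylinder, ε_r 40, σ 1.0 S/m at origin | imaging circle radius 7.6 cm (the antenna ring) |
| frequency, source | 1.3 GHz, I₀ = 1 A | line-source model |
| solver | COCG, FFT backend, tol 1e−5, max 5000 iterations | 1e−3 is a usable fast setting; iterations shrink accordingly |

## Limitations

* Uniform node-centered grids only — the FFT fast path requires the
  translation-invariant kernel; no adaptive meshes, no metallic scatterers
  (extra boundary dipoles would break uniformity).
* Ideal line-source antennas; no mutual coupling or monopole feed model.
* The grid boundary is open: boundary reflections are only controlled by
  bath loss, so very low-loss backgrounds will show truncation artifacts.
* No preconditioning; convergence degrades as the bath/background offset
  shrinks (condition number `∝ 1/Δε`).
* 2D TM only; no 3D polarizabilities or out-of-plane propagation. The
  inverse/reconstruction problem is out of scope.
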