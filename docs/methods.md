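# Methods

## Model

A feed-forward network `Z = W Φ(U X + B)` with `Nx` inputs, `Ny`
representation neurons, and an `Nz`-dimensional linear readout must realize
`P` input→readout mappings exactly. The readout `W` and bias `B` are fixed;
only `U` is plastic. `Φ` is clipped-threshold-linear with activity threshold
0 and saturation threshold `α` (defaults: `Nx=15`, `Ny=12`, `Nz=1`, `P=8`,
`α=5`). Tasks are generated by a teacher: `X ~ N(0,1)`, `W ~ N(0,10)`,
`T ~ N(0,1)` entrywise (all second arguments are standard deviations
throughout the package), and `Z = W Φ(T X + B)`, so an exact solution always
exists. The construction requires `P ≤ Nx` and `X` of full column rank.

## η-coordinates

`Xext = [X | Q]` extends the inputs with a deterministic orthonormal basis
`Q` of the orthogonal complement of `col(X)` (SVD null space of `Xᵀ`, each
column's largest-magnitude entry made positive so the construction is
reproducible). Then `η = U·Xext` acts independently per postsynaptic neuron:
columns `1..P` are the input currents, columns `P+1..Nx` are invisible to
all stored conditions. The per-column noise scales are
`s_μ = 1 / ‖row μ of Xext⁻¹‖₂`. This choice makes the pooled variance of the
induced weight noise exact: for independent `δη_{i,μ} ~ N(0, (σ s_μ)²)`,
`δU = δη·Xext⁻¹` has `Σ_j Var(δU_{ij}) = σ² Σ_μ (Xinv_{μj})² / ‖row μ‖²`,
which sums over `j` to `Nx·σ²` — i.e. pooled SD exactly σ. The printed form
of this scale factor admits several readings; the package pins the
implementation to the equal-variance contract (pooled drift-induced δU has
mean 0 and SD ≈ σ), which is verified by Monte Carlo in the test suite and
holds within a few percent even with clamping and kernel rescaling active.

## Drift step

Per step, with step scale σ (default 0.05):

1. **Unconstrained** columns (`μ > P` and any condition column not yet
   learned) receive i.i.d. `N(0, (σ s_μ)²)` increments. Unlearned condition
   columns drift freely because their error surface does not exist yet.
2. **Semiconstrained** coordinates of learned conditions (inactive neurons:
   current ≤ 0; saturated: ≥ α) receive the same proposals; a proposal that
   would cross the threshold is clamped *exactly* onto it (`η = −b` or
   `α − b`) and the neuron joins the engaged set.
3. **Engaged** coordinates of a learned condition move by `K·c`,
   `c ~ N(0, (σ s_μ)²)` per coefficient, where `K` is a column-orthonormal
   basis of `ker(Wμ)` (`Wμ` = readout columns of the engaged set). If the
   move would push any engaged current outside `[0, α]`, the whole move is
   rescaled by the largest `γ ∈ [0,1]` keeping all currents inside; the
   neurons sitting exactly on a bound at `γ` (ties included) transition to
   the adjacent disengaged set. `γ` is clamped at 0, which also self-heals
   the (measure-zero) case of a current marginally outside the band.
4. **Norm bound**: rows of `U = η·Xext⁻¹` whose norm would exceed `Umax` are
   fully reverted for this step, including their set transitions (a
   reflecting/rejection boundary). Because a kernel increment preserves the
   readout only as a whole, the engaged-block increment of every condition
   in which a reverted row was engaged is reverted across all of its rows as
   well, iterated to a fixed point. Without this coupling, a partial revert
   would leak readout error at every rejection; with it, conservation is
   exact. Rows that start outside the bound are frozen rather than ejected.

Transitions take effect on the next step (no same-step re-entry). Kernel
bases are recomputed from scratch whenever an engaged set changes —
correctness over speed at these sizes; for `Nz = 1` the basis is obtained
from a Householder reflector rather than an SVD, which is exact and much
cheaper. All threshold placements are exact assignments, so set membership
uses strict comparisons with no epsilon bands; at initialization a current
exactly on a threshold is classified into the adjacent disengaged set.

Numerical tolerances: linear-algebra identities (frame inversion, kernel
orthonormality) are held to 1e-10; per-step readout conservation to 1e-8
relative; a run aborts if the stored readouts move beyond 1e-6 (relative to
the readout scale), which in practice sits many orders of magnitude above
the observed float-level drift (~1e-12 over 10⁴ steps).

## Learning and allocation

Learning minimizes the squared readout error over target conditions with the
hand-coded gradient, holding `W` and `b` fixed. `Φ′` is 1 strictly inside
`(0, α)` and 0 elsewhere — including exactly at the thresholds, so clamped
neurons contribute no gradient. Plain gradient descent (lr 0.001 default) is
used for the two-neuron worked example, where the curvature is O(1). At
simulation scale the readout weights `~N(0,10)` put the plain-GD stability
limit near 5e-5, so the protocols use the Adam-style adaptive optimizer
(lr 0.001), which is also the standard choice for this kind of fit.
Convergence is declared when the RMS readout error over the targets falls
below `tol` (default: 1e-3 × RMS of the target readouts); runs abort on
divergence. The weight-norm bound is *not* enforced during learning — it is
a property of the drift dynamics only.

Allocation resamples a new condition's η column as `N(α/2, 0.1)` (SD),
centering every current in the engaged regime; all other columns are bitwise
untouched. η-gradient learning of condition μ updates only column μ, so the
change to every other column is exactly zero by construction — the package's
continual-learning guarantee is structural, not approximate.

## Protocols and problem sizes

- **Solution finding** (`learn_solution`): `U ~ N(0, 0.1)`, allocate all P
  columns, batch-Adam over all conditions.
- **Sparsification / conservation**: learned state, σ=0.05, `Umax=350`,
  runs of 10⁴–5×10⁴ steps, recording every 100–1000 steps. These durations
  are enough for the engaged fraction to fall from ~1.0 to its ~0.2 plateau.
- **Robustness**: n=100 perturbations `ΔU ~ N(0, 1)` entrywise, identical
  draws before and after drift (paired substreams). Scaled improvement
  `(RMS_before − RMS_after)/RMS_before` is swept over `Umax ∈ {1, 8, 350}`
  with 10 paired seeds. The middle point sits where the bound actually binds
  within a 10⁴-step run (free diffusion reaches row norms ~20 in that time);
  bounds much larger than that are equivalent to unbounded drift at this
  duration and reproduce the large-bound plateau.
- **Learnability**: mappings added sequentially up to `Nx` (task generated
  with `P = Nx = 15`); without allocation each addition refits `U` jointly
  over all stored mappings (Adam) and the protocol stops at the first
  failure of the stored-RMS tolerance; with allocation each new column is
  allocated and learned in η. Initial weight SDs `{1/√Nx, 1, 4, 15}` span
  per-row norms ~1 to ~58. With the strict tolerance and stop-at-failure
  rule the no-allocation counts are conservative (a few mappings at small
  init); failures are genuine vanished-gradient optima, and the qualitative
  ordering (monotone decrease with init scale; allocation reaching `Nx`)
  is robust to the success convention. Drift between additions is available
  but off by default there: η-drift preserves stored readouts exactly, so it
  cannot change the learned count, only the state's sparsity.
- **Continual learning**: `U ~ N(0, 15)` init, memories added by allocation
  plus U-gradient descent on the new memory only; the drift arm runs 10⁴
  constrained steps (`Umax=350`) between additions; 10 paired seeds.

Randomness is fanned out from one user seed into named substreams (task,
init, allocation, drift, perturbations) so paired arms consume identical
draws wherever the protocol requires matching.

## What the generator emulates — and what it does not

Generated tasks are Gaussian and unstructured: independent input conditions,
i.i.d. readout weights, exact teacher-realizable targets, zero bias. Real
neural data have correlated inputs, structured readouts, nonzero biases,
noise in the targets, and far more neurons than conditions in a different
ratio. Passing tests therefore demonstrate the *mechanisms* — exact readout
conservation under restricted diffusion, entropic sparsification, the
robustness/learnability trade-off, allocation's rescue of learnability —
under the stated statistical conditions, not quantitative predictions for
any particular circuit. Biases and thresholds are exposed so sparsely-active
(rather than sparsely-engaged) regimes can be explored, but no claims about
those regimes are tested here.

## Known limitations

- The construction requires `P ≤ Nx` and exact-error solution spaces;
  near-capacity networks and soft-error manifolds are out of scope.
- Readout weights are fixed; drifting readouts and stable subpopulations are
  not modeled.
- The rejection boundary for the norm bound is one of several defensible
  mechanisms (e.g. projection back onto the sphere); it was chosen because
  it keeps readout conservation exact and produces norms that fluctuate just
  below the bound.
- Engagement rasters recomputed from snapshots use strict inequalities, so a
  neuron recorded exactly on a threshold mid-transition counts as disengaged
  there even though the stateful labels may briefly say otherwise.
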