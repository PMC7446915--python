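# Methods

## Model

`empj` synthesizes recurrent rate networks of the form

    dx/dt = (1/τ) (−x + Wᵀ tanh(x) + I),          x ∈ ℝᴺ

whose activity is confined to a prescribed low-dimensional manifold and whose
slow dynamics on that manifold follow a prescribed drift function. The method
works entirely through local linear constraints: at a set of states on the
target manifold ("setpoints"), the network Jacobian

    J(x) = (1/τ) (−I_N + Wᵀ Φ(x)),   Φ = diag(1 − tanh²(x))

is required to have given eigenvectors and eigenvalues. For d constrained
modes collected in an orthonormal N×d matrix U with eigenvalues Σ this is the
linear condition

    Uᵀ Φ(x_j) W = τ (Σ + I_d/τ) Uᵀ,

and stacking these d-row blocks over m setpoints gives a single system
A W = B that is solved by least squares after perturbing A with i.i.d.
Gaussian noise of standard deviation `sigma_reg` (a regularizer that
decouples the solution from the particular setpoints chosen). Constraints can
also be placed on the dynamics directly: at a state x_f that should be an
equilibrium, the row tanh(x_f)ᵀ W = x_fᵀ forces dx/dt = 0 there. These
fixed-point rows are what allow drift functions with non-zero baseline, which
Jacobians alone cannot express (derivatives are blind to baselines).

## Manifolds

Ring manifolds are parametrized by latent tuning functions: a sine/cosine
pair plus `n_dim − 2` von Mises bumps

    c_j(θ) = A · exp(κ (cos(θ − 2πj/(n_dim−2)) − 1)),   A = 0.5 by default,

with the sinusoid amplitude rescaled pointwise to s(θ) = √(r² − Σ_j c_j²) so
that every point lies on a hypersphere of radius r. The latent curve is
mapped into the N-dimensional state space through a random orthonormal basis
drawn by QR from a seeded standard-normal matrix. Bases are *nested*: the
raw matrix is drawn column-by-column, so the basis for `n_dim` is always a
prefix of the basis for `n_dim+1` with the same seed. This lets an input
direction be appended to an existing ring subspace without redrawing it.
Tangents are computed analytically from the latent derivative; the remaining
frame directions come from a deterministic Gram–Schmidt pass over the basis
columns.

Default radii follow the study conditions: 10 for the 400-unit planar-ring
demonstrations, 12 for high-dimensional rings and for the end-state
statistics protocol, 8 for input control. Larger radii push more units
toward tanh saturation, which both slows the realizable dynamics and — we
find — stabilizes the ring against in-plane escape (at radius 10 with 300
units, roughly half of random embeddings have an escape barrier within ~2
units of an 8-fixed-point ring; at radius 12 the protocol is stable across
embedding seeds).

## Target dynamics

The drift function over the ring is G(θ) = b − a·cos(ωθ) (rad/s); its zero
crossings are fixed points, stable where G′ < 0, and ω equals the number of
stable fixed points at zero baseline. At each setpoint the tangential
eigenvalue is set to G′(θ) = aω·sin(ωθ); the within-subspace normal
directions get a negative constant `lambda_normal` (default −1/τ) and all
remaining directions are left to the leak. The time constant τ is not
dictated by the method; we use τ = 0.1 s throughout and express every
eigenvalue in s⁻¹, so results are τ-invariant except where noise scaling
involves τ explicitly.

## Two solver modes

The Jacobian system constrains only d directions per setpoint, so the
solution is selected by a rule, and the rule matters:

* `minimum_norm` (default): rank deficiency is resolved by the minimum-norm
  least-squares solution. W then has rank equal to the ring's embedding
  dimension, its row space is exactly the embedding subspace, and the
  realized drift reproduces the target to ~0.01 rad/s. This mode is used for
  all dynamical-accuracy results. Its W is maximally asymmetric (the column
  space lies along Φ-modulated directions), which matters only for
  connectivity analyses.
* `explicit`: zero-target rows are added for the entire orthogonal
  complement at every setpoint. Because the per-setpoint block then becomes
  the diagonal matrix equation Φ(x_j) W = S_j with the symmetric rank-d
  target S_j = Σ_k (τλ_k + 1) u_k u_kᵀ, the stacked least-squares problem
  decouples by rows of W and has the closed form
  W[i,:] = Σ_j φ′_i(x_j) S_j[i,:] / Σ_j φ′_i(x_j)². The system is
  over-determined and inconsistent across setpoints, so drift accuracy
  degrades to ~0.1–0.2 rad/s, but W is near-symmetric with bounded gain:
  this is the mode whose coupling structure mirrors classical ring-attractor
  connectivity, and it is used for the connectivity-structure analyses.

The two modes realize the same on-manifold eigenstructure; they differ in
everything the constraints leave free. We regard the choice as part of the
experiment definition and record it in each network's metadata.

## Noise and the reference drift-diffusion model

The behavioral reference model is dθ = G(θ)dt + σ·dW on the circle,
integrated by Euler–Maruyama at dt = 50 ms for 15 s. The network is driven
by "external" noise confined to the ring plane: at every Euler step a fresh
Gaussian sample per projection vector is added inside the rate equation,
with per-direction standard deviation

    σ_RNN = σ_DDM · r · τ / √dt.

Each step then adds (dt/τ)·σ_RNN = σ_DDM·r·√dt of in-plane displacement,
i.e. σ_DDM·√dt radians, so the decoded angle diffuses with variance σ_DDM²·t
for any dt — verified by Monte Carlo against the reference model. Internal
(per-unit) noise is supported for robustness checks but is deliberately not
calibrated to the reference model; its dominant effect is indirect, through
off-manifold excursions feeding back into the planar flow.

## Decoding and error metrics

A linear decoder D (2×N) maps tanh(x) to (cos θ̂, sin θ̂), fitted by least
squares on n_train = 360 evenly spaced on-ring states; θ̂ = atan2 of the two
outputs. For end-state statistics each trial's *desired* end state is its
initial angle (a veridical memory): per initial condition, bias is the
wrapped difference between the circular mean of end angles and the initial
angle, and variance is the circular variance −2·ln R̄ from the mean
resultant length R̄, which is exactly σ² for wrapped-normal data (the
small-angle form 2(1−R̄) is available but underestimates the dispersion at
the σ√t ≈ 0.78 operating point of the 15-s protocol). BIAS is the RMS of
per-init biases, VAR the mean of per-init variances, and RMSE = √(BIAS²+VAR)
by construction. Realized drift is measured by decoding short (0.5 s)
noiseless runs from a grid of on-ring starts; decoding both endpoints
cancels static decoder bias. The stability metric "deviation" is the mean
Euclidean distance between each visited state and the on-ring state implied
by its decoded angle, averaged over timepoints (every 0.1 s) and initial
conditions.

## Input control

A one-dimensional input subspace orthogonal to the ring plane carries a
tonic input. The input-direction eigenvalue defaults to the leak rate
−1/τ, which makes the input direction decay through the leak alone; the
equilibrium under tonic input I·v̂ is then exactly y* = I/(τ·|λ_input|) = I
state units. Copies of the ring are constrained at offsets k·(6 units) along
the input direction with tangential eigenvalues scaled by the level label
(0, 0.5, 1, 1.5, 2), so drift speed is proportional to the selected level.
Because the zero-input, zero-drift ring consists of true fixed points, it is
pinned with fixed-point rows; Jacobian rows alone leave the baseline of the
input-direction dynamics free and the ring family would float. Exact
satisfiability requires the network dimension to exceed the total constraint
row count; the packaged experiment uses 800 units with 40 setpoints per ring
(5·40·3 + 40 = 640 rows).

## Connectivity analyses

Unit tuning curves are by default the pre-nonlinearity states x_i(θ) — the
weighted sums of the latent tuning functions — with the saturated outputs
available as an option. Under the Wᵀtanh(x) convention the input weights
into unit i are the i-th column of W, so the input coupling matrix is WᵀW
and the output coupling W Wᵀ; the tuning similarity matrix is the covariance
of tuning curves over the angle. Correlations between matrices are Pearson
correlations over the upper off-diagonal triangle (diagonals are
self-similarities and would inflate r); partial correlations use the
standard three-variable formula; chance levels come from jointly permuting
the rows and columns of the first matrix of each pair (500 draws). For these
analyses `lambda_normal` is set to −1.3/τ: the value is not dictated by the
constraints (any negative constant contracts), and it was calibrated once so
that the normal modes carry enough weight in the explicit solve for the
decline of tuning–coupling correlations with embedding dimension to be
expressed; it is then held fixed for all connectivity results. At −1/τ the
normal modes drop out of the explicit solution entirely and all correlations
sit near 1 at every dimension.

## Numerical choices

Forward Euler with dt = 10 ms at τ = 100 ms (dt ≤ τ/5 enforced); angles live
in [0, 2π), differences are wrapped to (−π, π]; the basis QR fixes column
signs from the R diagonal for cross-platform determinism; rank uses the
singular-value threshold 10⁻⁶·σ_max; Jacobian verification uses central
differences with step 10⁻⁵ and Rayleigh quotients along the target
eigenvectors; drift zero crossings are located by sign change plus linear
interpolation on a 128-point grid. All random draws flow through
`numpy.random.default_rng` with explicit seeds; experiment outputs are
deterministic given (experiment, seed, scale).

## Problem sizes

The packaged experiments run at the native scales of the study they
replicate (400- or 300-unit networks, 64 setpoints, 18×30 trials, 15-s
noisy runs, 500-draw nulls); `scale="reduced"` shrinks replicate counts
(networks per condition, trials, shuffle draws), never the protocol. The
capacity sweeps default to 5 networks per condition in reduced mode and 30
in full mode.

## What the synthetic conditions do and do not show

All inputs are generated: there is no recorded neural data anywhere in the
pipeline. Passing tests therefore demonstrate the internal consistency of
the method — that the linear system realizes the requested eigenstructure,
that the resulting networks emulate the reference drift-diffusion behavior,
and that the connectivity structure behaves as analyzed — not that cortical
circuits implement these dynamics. Two further limitations are worth
stating plainly. First, quantities the constraints leave free (global
stability far from the manifold, weight symmetry, capacity limits) depend on
the solver's selection rule; our minimum-norm networks are uniformly *more*
stable across the capacity grid (deviation ≈ 0.03 of radius for 100–500
units) than the degradation trends reported for the original implementation,
so those trends are not reproduced here and the capacity experiment should
be read accordingly. Second, only real eigenvalues and orthonormal
eigenvectors are supported: oscillatory (complex-eigenvalue) target dynamics
are out of scope, as are Jacobians estimated from spiking data.
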