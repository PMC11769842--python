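# Methods

This note records the scientific and numerical choices behind `equiace`:
what is computed, which conventions were fixed where the field admits
several, and what the synthetic benchmarks do and do not demonstrate.

## Symmetry kernel

**Spherical harmonics.** Real, orthonormal, without the Condon–Shortley
phase, ordered m = −l…+l with sine components at negative m; for a unit
vector (x, y, z) the l = 1 block is √(3/4π)·(y, z, x). They are evaluated
by a Cartesian recursion (azimuthal complex-multiplication recursion ×
associated Legendre recursion with the sin^m θ factor removed), which is
polynomial in (x, y, z) and therefore free of pole singularities and
differentiable everywhere on the sphere. The same code runs on plain
arrays and on autodiff tensors.

**Wigner-D matrices.** Defined functionally: D_L(Q) is the unique matrix
with Y_L(Qv) = D_L(Q)·Y_L(v), computed by least squares over a fixed set
of generic sample directions (cached per L). This construction is exact
to ~1e-14 and is automatically consistent with the harmonic convention
above. O(3) is handled through parity labels: a feature of parity p
transforms under an improper operation Q as p·D_L(−Q); spherical
harmonics carry parity (−1)^l, and parities multiply under coupling.

**Clebsch–Gordan coupling.** Ordinary real-basis coupling tensors are
obtained from exact (sympy, rational) complex CG coefficients transformed
with the analytic complex↔real change of basis, phase-fixed to be real,
and normalized to unit Frobenius norm. They satisfy
(D_l1 ⊗ D_l2)·C = C·D_L to ~1e-15 and vanish when the triangle rule
fails. Generalized coupling for ν degrees couples left-to-right through a
sequential binary tree; η enumerates the admissible intermediate-degree
sequences in lexicographic order. Paths are mutually orthonormal (a
consequence of the recoupling tree), which the Monte-Carlo symmetrization
oracle relies on. The degenerate ν = 1 path is kept as the exact identity
on m (so B = A holds exactly) rather than unit-Frobenius rescaled; ν ≥ 2
paths are unit-Frobenius. Any fixed normalization only rescales learned
weights. Tensors are cached in memory and optionally on disk
(`o3.set_cache_dir`; layout `<dir>/v1/gc_<degrees>_L<L>_p<±>.npz`).

## Differentiation engine

No array-autodiff framework ships with the environment this package
targets, so it carries a small reverse-mode engine (`equiace.autodiff`)
over numpy arrays. Every primitive's vector-Jacobian product is itself
expressed in primitives, so gradients can be differentiated again:
forces are exact reverse-mode gradients of the energy, and training on a
force loss differentiates *through* the force computation
(second-order reverse mode). The engine supports exactly the operations
an atom-centred potential needs — elementwise arithmetic and
activations, a restricted einsum, reductions/broadcasts, gather/scatter
along the atom/edge axis, slicing and concatenation.

## Radial basis and cutoff

R_n(r) = √(2/r_cut)·sin(nπr/r_cut)/r with fixed frequencies, orthonormal
on [0, r_cut] with weight r²; the smooth envelope is the standard
polynomial cutoff with p = 6 by default (value 1 at r = 0, vanishing with
two derivatives at r_cut). The envelope multiplies the Bessel features
*before* any learnable map and no learnable radial map carries an output
bias, so every radial variant is exactly zero beyond the cutoff and C¹ in
r. Two learnable variants exist: an element-agnostic MLP (default widths
64×64×64, sharing the model's scalar nonlinearity) and an
element-dependent linear map with one weight block per sender element,
the k multi-index running over embedding × element channels. A published
description of this cutoff states that it vanishes as r → 0; that is
inconsistent with its own smoothness role and with the standard form, so
the envelope here vanishes at r_cut and equals 1 at r = 0.

## Layers, coupling modes, and weights

Features are dictionaries {(L, parity) → array [n_atoms, channels,
2L+1]}. In *uncoupled* mode (the message-passing presets) the channel
index k never enters tensor products and is mixed only by the
block-diagonal linear update W[k, k', L] (structurally incapable of
mixing L or M); at ν = 1 the pool → product → symmetrize ladder is
evaluated as a single Clebsch–Gordan convolution over edges, which the
tests verify to be algebraically identical to the generic engine. In
*full coupling* (delta) mode the element and radial indices are coupled
through the products, reproducing classic linear ACE; tuples are bounded
by a maximum total polynomial degree Σ(n_ξ + l_ξ) ≤ 12 by default.

The central-equation weights w_{i,kηL} are realized as element-conditioned
shared weights w_{kηL}(z_i): genuinely per-atom weights cannot generalize
across configurations, and conditioning on the central element recovers
the classic per-element linear-ACE parameterization in delta mode.

The pooling normalization λ is one fixed constant per model, taken from
training-set statistics: the mean neighbour count (`avg`) or its square
root (`sqrt_avg`), with λ = 1 as the fallback for gases of isolated
atoms. The self-connection is an element-conditioned residual linear map
per (L, parity) block. Weight initialization is Gaussian scaled by
1/√fan-in from the config seed. The final layer emits only invariant
(L = 0) blocks by default, since all readouts consume scalars; set
`final_invariant_only=False` to propagate equivariant blocks to the last
layer (the equivariance certificates do this).

Nonlinearities are gated: scalars pass through the pointwise function
(SiLU, tanh, or square); every other block is multiplied by a scalar gate
(sigmoid of a linear map of the scalars, or the linear map itself for
`square`). `square` is the finite-Taylor option: it doubles the body
order instead of making it infinite, which the body-order certificate
demonstrates.

## Energies, forces, body order

Site energies are per-layer linear readouts of the invariant channels
(plus, in the BOTNet-style preset, a final SiLU MLP readout that carries
the body-order remainder), shifted by per-element reference energies E0
estimated by least squares on training compositions. The energy result
reports each term separately so body order is auditable; forces are
reverse-mode gradients (never finite differences — those serve as the
independent oracle in tests, agreeing to ≤1e-6 eV/Å at step 1e-4 Å).

A T-layer, ν = 1 model with linear updates and readouts has total energy
body order T + 1. The certificate is the inclusion–exclusion functional
u(S) = Σ_{A⊆S} (−1)^{|S∖A|} E_centre(centre ∪ A) over neighbour subsets,
which must vanish (≤1e-9 eV) for |S| ≥ T + 1 and not before. The
testbench also *fails* deliberately broken variants — corrupted coupling
tensors, order-dependent pooling, hard cutoffs, SiLU readouts — so the
certificates are known to detect the defects they claim to.

## Monte-Carlo symmetrization oracle

The symmetrized basis is, by definition, the projection of the product
basis onto an irreducible O(3) component, expressible as an integral over
the group. The oracle samples Haar-uniform rotations (QR of a Gaussian
matrix with sign correction) and reflections (composition with a fixed
mirror), projects the product basis of the rotated environment onto each
η path and rotates back with D_L(Q)⁻¹; by Schur orthogonality the sample
mean estimates B_{η,LM}. Because the η paths are complete and orthonormal
on the product space, the estimator has (near-)zero variance when the
input is exactly a product basis — the comparison "within 3 standard
errors" then becomes a sharp float-precision identity; genuinely
statistical behaviour appears for inputs outside the span (e.g. the
parity-mismatch test, which averages to zero at finite SE).

## Synthetic data

The generator emulates small molecular clusters (or periodic boxes) of a
single or a few elements, labelled by analytic potentials of *exact* low
body order: a Morse pair term D(1−e^{−a(r−r0)})²−D (defaults D = 0.5 eV,
a = 1.5 Å⁻¹, r0 = 2.0 Å) and an angular three-body term
ε·cos²θ_jik·g(r_ij)·g(r_ik) (ε = 0.15 eV), both enveloped by the models'
own polynomial cutoff at r_cut = 4 Å so labels share the models'
smoothness assumptions. Forces are hand-derived analytic gradients,
checked against finite differences to ≤1e-8 eV/Å, and the labels
themselves pass the body-order certificate at their declared orders (2
and 3) — the benchmark ground truth is certified before any model sees
it. Default geometry: clusters of 8 atoms in a ball of radius 3 Å with
minimum separation 1.6 Å; the standard learning run uses 500 frames
split 80/10/10.

What this emulates — and what it does not: the datasets probe geometric
learning (radial shape, angular structure, body order, smoothness) under
exactly known ground truth. They contain no quantum-mechanical
electronic-structure effects, no label noise, no long-range
interactions, and a single element by default, so passing the learning
test demonstrates correctness and optimizability of the architecture,
not accuracy on ab initio data.

## Training

The loss is energy_weight·MSE(E/n_atoms) + force_weight·MSE(F), defaults
1.0 and 10.0 — a conventional, admittedly arbitrary weighting. Fitting is
deterministic given the seed: minibatch Adam (default lr 0.02) with an
optional full-batch L-BFGS refinement (exact gradients through the force
computation) and a closing exact least-squares solve of the readout
weights and E0, which are linear in both energies and forces.

One-body constants deserve care. Site energies are defined as *binding
energies*: each layer's readout (and the final MLP) is evaluated once on
a virtual isolated atom of every element and that baseline is subtracted
inside the model, so a free atom's energy is exactly its E0 and the
per-layer contributions are pure interaction terms. Without this, the
readout constants of different layers span exactly energy-flat parameter
directions along which quasi-Newton steps drift unboundedly (observed:
mutually cancelling ±1e5 eV constants that left the total energy intact
but made the decomposition meaningless). Two further small guards: the
closing least-squares solve truncates near-null singular directions
(rcond 1e-8), and the training objective carries a negligible L2 tether
(1e-10, configurable) on the parameters. For models
whose only free parameters are linear (teacher–student recovery) the
convex solve alone reaches numerical zero. Best-validation parameters are
retained. The standard learning run fits the BOTNet-style preset
(8 channels, 8 Bessel functions, l_max = L_max = 2, r_cut = 4 Å) to the
500-frame Morse+three-body dataset; these sizes keep a full fit within
minutes on one CPU core while leaving the target comfortably inside the
model class (the pair term and the cos²θ three-body term are exactly
representable at l ≤ 2).

## Known limitations

* Brute-force O(n²) neighbour search with explicit cell replication —
  exact, but not for thousands of atoms.
* The generic product-basis engine is exponential in ν; it is meant for
  ν ≤ 3–4 at cluster scale (the combinatorial guards refuse more).
* No stress/virial outputs, no MD integrator, no long-range
  electrostatics, no GPU path.
* Wigner-D matrices and coupling tensors are built for moderate degrees
  (l ≤ ~6); the sample-direction construction loses accuracy slowly with
  growing L.
* The attention-based extension of the one-particle basis and Cartesian
  (vector-feature) architectures are out of scope; Cartesian models
  correspond to the (L = 1, parity −1) corner of this framework by a
  change of basis.
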