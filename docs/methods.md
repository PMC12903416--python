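# Methods

## Model

Each cell contributes a UMI count vector x ∈ ℕ^G and a categorical batch
vector y. Marker-gene lists partition the genes into blocks x¹, …, xᵏ;
any two blocks must be identical or disjoint, and the final block
implicitly owns every unclaimed gene. Identical blocks are modelled once
(a latent component per list, one decoded block). The latent z = (z¹, …,
zᵏ) lives on a product of constant-curvature spaces:

* Euclidean E^d (K = 0), points stored as d-vectors;
* hypersphere S_K^d = {x : ⟨x,x⟩₂ = 1/K}, K > 0, ambient ℝ^{d+1};
* hyperbolic H_K^d = {x : ⟨x,x⟩_L = 1/K, x₀ > 0}, K < 0, in the Lorentz
  model with ⟨x,y⟩_L = −x₀y₀ + Σ_{i≥1} xᵢyᵢ.

The generative side factorises as p(x, y, z) = p(y) p(z) p(x | y, z) with
a wrapped-normal prior at each component's origin (unit tangent scales)
and a negative-binomial observation model: block j's decoder consumes the
designated latent components (its own for non-final blocks; all of them
for the final block — earlier signals may inform the remaining genes) in
ambient coordinates, plus the one-hot batch covariates declared
applicable to that component. A softmax over the block's genes times the
cell's **total** UMI count gives the NB means — so each block's means sum
to the full library size, a deliberate convention kept from the model's
definition; its main consequence (a constant per-block inflation soaked
up unevenly by the most dispersion-tolerant genes) is documented and does
not affect within-block contrasts, which is what downstream procedures
use. Dispersions are free positive parameters per gene, and per level of
the first batch covariate when one exists.

The variational posterior factorises per component; each component's
encoder sees only its own gene block, log1p-transformed (masking the
rest), runs a GELU MLP (128–64–32) and emits an unconstrained location
(lifted onto curved manifolds through the exponential map at the origin)
and a softplus scale floored at 1e-4. Decoders are 64–128 MLPs. The ELBO
uses one reparameterised sample per cell per step; curved components
estimate their KL term by single-sample Monte Carlo (log q − log p at the
drawn point), Euclidean components use the closed-form Gaussian KL (a
deterministic, strictly tighter estimate; the Monte-Carlo estimator is
also provided and tested for all three geometries).

### Wrapped normal and RoWN

Sampling WN(μ, Σ): draw ṽ ~ N(0, Σ) in ℝ^d, prepend 0 (curved cases) so
v is tangent at the origin μ₀ = (1/√|K|, 0, …, 0), parallel-transport to
μ, apply the exponential map. The density runs the construction
backwards and subtracts the wrapping Jacobian, log det = (d−1)
log(sinh(√|K| r)/(√|K| r)) on the Lorentz model (sin on the sphere, 0 in
flat space), with r the tangent norm of log_μ(z). The log-determinant is
not taken on faith: a polar-quadrature test integrates exp(log density)
over H² and requires 1 ± 1e-2.

RoWN rotates a diagonal Σ so its leading axis points radially: with
y the normalised spatial part of μ, x = [s, 0, …, 0] where s is the sign
of μ's first *spatial* coordinate (the literal "first element of μ" is
the Lorentz time-like coordinate, which is always positive and would
make the ± rule vacuous; the spatial reading also keeps 1 + ⟨x,y⟩ ≥ 1,
avoiding the antiparallel blow-up), A = yᵀx − xᵀy, and R = I + A +
A²/(1 + ⟨x,y⟩); Σ̂ = RΣRᵀ. The rotation is applied for hyperbolic
components of dimension ≥ 2 and skipped (identity) otherwise, and at
μ = μ₀ (zero spatial part) R = I by convention. R is smooth in μ away
from that guard and is differentiated through during training.

### Stop-gradient

Reconstruction of block j can be prevented, for the first
`stop_grad_epochs[j]` epochs, from backpropagating into other
components' latents (the latents are detached in that decoder's input).
Default 0 everywhere: with small marker lists the non-marker
reconstruction is a useful gradient source for the remaining components,
and the signal latent stabilises early anyway; the switch exists for
datasets whose marker genes partially carry a second strong signal.

## Training

AdamW (decoupled weight decay) with learning rate 1e-3, weight decay
0.01, minibatch 128, 500 epochs by default, no schedule, no early
stopping. The layers emitting the signal component's posterior
parameters are Xavier-normal initialised; all other dense layers use the
uniform ±1/√fan_in default. Raw dispersions start at 2 (θ ≈ 2.1, a
typical droplet-data scale): starting near zero lets early mean misfits
hide behind heavy tails and stall the means' gradients. Everything runs
in float64 on a tape-based numpy autodiff layer (gradients are tested
against central finite differences), single-threaded and therefore
bit-deterministic for a given seed.

## Downstream procedures

**Pseudotime.** For a 2-D hyperbolic component, project Lorentz
coordinates to the Poincaré disk, p = (z₁, z₂)/(1 + √|K| z₀), and take
the angle against the (0,0)→(1,0) edge, in [0, 2π). When the cycling
cells hug one side of the disk instead of surrounding the origin, the
origin is recentered by Möbius addition: left-translation by the negated
new origin, which maps the chosen origin to 0 and is an isometry. The
cycling-cell centre is estimated as the midpoint of their bounding box,
and the advisory new origin is placed diagonally across from it at 0.9
of the disk radius; an automatic rule (recenter only when the cells'
angular coverage around the current origin is below 95% of a 36-bin
circle) decides whether recentering is needed at all. Estimated and
reference pseudotimes are compared after a grid search over 720
rotations × flip maximising Pearson r, with the sine-transformed
correlation reported alongside as a wraparound-robust companion.

**Selective and counterfactual decoding.** Reconstruct expression with a
subset of components at their posterior locations and the others pinned
to their origin (or a user override in latent coordinates, e.g. a low
dissociation-score point); or overwrite a single latent coordinate for
every cell (e.g. ±2.6 on the zonation axis) and decode. Counterfactual
central/portal expression yields the ratio c/(c+p) per gene, classified
by the fixed thresholds ratio < 0.2 ("central") and ratio > 0.8
("portal"), applied exactly as printed.

**k-NN identity.** One Euclidean k-NN classifier per k in {5, 11, …, 73};
a query keeps a label only under unanimity, otherwise "uncertain".

**Upregulated-gene discovery.** PCA (centred, unscaled) on the designated
component's posterior locations; the two groups' separating direction is
computed on the designated PC axes (the others zeroed); the 100 most
extreme cells per group along it are taken, their latents reconstructed
from the retained PCs, the other components filled (origin by default),
all cells decoded at a common depth, the groups paired by rank along the
separating direction, and each pair's top-50 genes by positive decoded
difference tallied after removing excluded (marker) genes. The
cell-selection and pairing rules are genuinely open design points;
most-extreme selection and rank pairing are this package's documented,
configurable choices.

## Synthetic data

The generator produces the structure the model assumes, with ground
truth: a cycling fraction of cells with phase φ ~ U[0, 2π); marker gene
g with baseline a_g ~ N(0, 0.7), amplitude b_g ~ U(0.8, 1.6) and phase
offset ψ_g ~ U[0, 2π) has log-rate a_g + b_g cos(φ − ψ_g) in cycling
cells (b_g = 0 otherwise); non-marker genes carry per-cell-type log
effects ~ N(0, 1); batches act as per-gene multiplicative log-normal
factors (sd 0.3, reference batch fixed); rates are normalised per cell
and scaled to a log-normal library size (meanlog 9, sdlog 0.3, ≈ 8k
UMIs — a typical droplet depth); counts are gamma-Poisson (negative
binomial) with per-gene dispersions ~ U(2, 10). A linear-gradient kind
replaces the harmonic with β_g(position − ½) to emulate zonation, and a
categorical kind drives the markers with discrete programs. The
canonical fixture has 1,500 cells (1,000 cycling; 3 cell types), 120
marker and 280 other genes, 2 batches — small enough that a full
training run takes ~2 minutes on one CPU, which is why validation uses
300 epochs there. A built-in oracle check guarantees the fixture is
solvable before the model is judged against it: the polar angle of the
first two marker-gene principal components must track the true phase
(aligned |r| > 0.8).

What the generator does **not** emulate: gene–gene correlation beyond
the planted programs, doublets, ambient RNA, zero inflation, or
continuous batch effects. Passing tests therefore demonstrate correct
inference under the model's own assumptions plus NB noise — not
robustness to the full messiness of real tissue data.

## Numerical choices and degenerate inputs

Manifold-constraint residuals below 1e-6 are treated as exact; residuals
up to 1e-4 are silently re-projected (float drift over long runs);
larger ones raise. Tangent norms and arccosh/arccos arguments are
clamped away from their singular points with series-safe factors (the
sinh θ/θ-type coefficients tend to 1). The hyperspherical logarithm
raises on antipodal pairs (no unique geodesic). All-zero cells are legal:
encoders see log1p(0), the library size is floored at 1e-8 and the NB
log-likelihood stays finite. Pseudotime at the exact origin is 0 with a
warning. Identical discovery groups yield a degenerate separating
direction and are flagged rather than guessed at.

## Limitations

Curvatures are fixed hyperparameters, not learned; product-manifold
geodesics are not needed (components are independent); covariances are
diagonal up to the RoWN rotation; likelihoods are plain NB (no zero
inflation); covariates must be categorical. The numpy training loop is
single-core — datasets beyond ~10⁵ cells will want fewer epochs (the
epoch count is exposed in the config) or an accelerator-backed port.
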