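# curvae

Disentangling a known, marker-defined biological signal from everything
else in single-cell RNA-seq counts, with a variational autoencoder whose
latent space is a product of constant-curvature subspaces.

## The problem

Strong transcriptional programs — the cell cycle above all, but also
tissue zonation, stimulation responses or dissociation stress — overlay
the signals a study actually cares about (cell identity, differentiation,
disease state). Regressing such programs out gene-by-gene discards
information; ignoring them confounds clustering and trajectory analysis.

`curvae` instead *factorises* the latent representation. The UMI count
vector **x** of each cell is split by user-supplied marker-gene lists into
blocks **x¹**, …, **xᵏ** (the final block holds every unclaimed gene), and
each block gets its own latent component **zʲ** with a geometry matched to
the signal:

* a 2-D hyperbolic component (Lorentz model, curvature K = −2) for cyclic
  signals — after projection to the Poincaré disk, cycling cells arrange
  on a circle whose angle is a pseudotime;
* Euclidean components for cell type, zonation gradients or stimulation;
* hyperspherical components where a closed manifold fits better.

Each component has its own encoder that sees only its own gene block
(all other genes masked), and each block is decoded only from the latents
designated for it (the final block sees all of them). Decoded block means
are a softmax over the block's genes times the cell's total UMI count, and
counts follow a negative binomial with free per-gene (and per-batch-level)
dispersions. Categorical batch covariates are appended to the decoders on
a per-component basis. The posterior on curved components is a wrapped
normal — a tangent-space Gaussian pushed through parallel transport and the
exponential map — optionally rotated (RoWN) so that its leading covariance
axis points radially on the disk, keeping angular position (phase) tight
while letting off-circle noise escape radially. Training maximises the
usual ELBO

L = E_q[log p(x | y, z)] − KL(q(z | x) ∥ p(z)),

with AdamW (500 epochs, minibatch 128, learning rate 1e-3, weight decay
0.01 by default), and an optional stop-gradient that blocks, for an
initial number of epochs, the gradients a block's reconstruction would
send into *other* components' latents.

Because no GPU frameworks are assumed, the networks run on a small
reverse-mode autodiff engine over numpy (`curvae.autodiff`), verified
against finite differences.

## Worked example

```python
import numpy as np
from curvae import MixedCurvatureVAE
from curvae.simulate import fixture_small
from curvae import analysis as an, manifolds as mf

counts, genes, truth, _ = fixture_small(0)   # 1,500 cells x 400 genes
markers = np.flatnonzero(genes["is_marker"]) # 120 cycle marker genes

est = MixedCurvatureVAE(
    components=(
        {"name": "cycle", "genes": markers, "geometry": "hyperbolic",
         "curvature": -2.0, "dim": 2, "distribution": "rown"},
        {"name": "rest", "geometry": "euclidean", "dim": 10},
    ),
    epochs=300, random_state=0,
).fit(counts, batches=truth["batch"].astype(str))

z = est.encode_components(counts)
sp = mf.hyperbolic(2, -2.0)
angles = an.pseudotime(z["cycle"], sp)
cyc = truth["cycling"]
_, _, r, sin_r = an.align_pseudotime(angles[cyc], truth["phase"][cyc])
acc = an.knn_accuracy(z["rest"], truth["cell_type"], k=15)
print(f"phase alignment r = {r:.3f} (sin r = {sin_r:.3f})")
print(f"cell-type 15-NN accuracy from the non-cycle component = {acc:.3f}")
```

Output:

```
phase alignment r = 0.953 (sin r = 0.995)
cell-type 15-NN accuracy from the non-cycle component = 1.000
```

So the hyperbolic component recovers the simulated cell-cycle phase
(Pearson r of 0.95 after the rotation/flip alignment), while cell-type
identity is read off the Euclidean component at 100% 15-NN accuracy — the
two signals, entangled in the raw counts, come apart cleanly.

Downstream procedures live in `curvae.analysis`: pseudotime with optional
Möbius recentering of the disk origin, selective decoding (reconstruct
expression from a subset of components to remove or enhance one signal),
counterfactual decoding (pin one latent coordinate, e.g. to a "central" or
"portal" zonation value, and classify genes by their central/(central +
portal) expression ratio), k-NN identity transfer with an unanimity rule
across many k, and the paired decode-and-rank discovery of genes
upregulated in one condition.

A thin CLI mirrors the library:

```bash
curvae --seed 1 simulate --preset small --out data/
curvae --seed 1 train --counts data/ --markers cycle=data/markers.txt \
       --batch-key batch --epochs 300 --out model.zip
curvae embed --counts data/ --checkpoint model.zip --out emb
curvae pseudotime --embeddings emb.signal.tsv --out pt.tsv
```

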