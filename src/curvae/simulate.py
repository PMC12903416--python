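"""Synthetic entangled-signal scRNA-seq counts with ground truth.

The generator emulates the data structure the model assumes: a subset
of cells carries a latent signal expressed only through marker genes
(cyclic phase, linear gradient, or a categorical program), all cells
carry discrete cell-type programs on the non-marker genes, counts are
negative-binomial around cell-specific means with log-normal library
sizes, and batches act multiplicatively per gene.

For a cycling cell ``c`` with phase ``phi_c`` and marker gene ``g``:

    rate_gc = exp(a_g + b_g * cos(phi_c - psi_g)),  psi_g ~ U[0, 2pi)

(b_g = 0 for non-cycling cells); the NB mean is ``s_c * rate_gc`` where
``s_c`` scales each cell's rates so the expected total equals its drawn
library size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse as sps


@dataclass
class SimConfig:
    n_cells: int = 2000
    fraction_cycling: float = 0.5
    n_cycle_genes: int = 100
    n_other_genes: int = 300
    n_cell_types: int = 3
    signal: str = "cyclic"  # cyclic | linear-gradient | categorical
    amplitude_range: tuple[float, float] = (0.8, 1.6)
    cell_type_effect: float = 1.0
    n_batches: int = 1
    batch_effect_scale: float = 0.3
    library_meanlog: float = 9.0
    library_sdlog: float = 0.3
    dispersion_range: tuple[float, float] = (2.0, 10.0)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction_cycling <= 1.0:
            raise ValueError("fraction_cycling must be in [0, 1]")
        for v in (self.n_cells, self.n_cycle_genes, self.n_other_genes,
                  self.n_cell_types, self.n_batches):
            if v < 1:
                raise ValueError("counts must be positive")
        if self.signal not in ("cyclic", "linear-gradient", "categorical"):
            raise ValueError(f"unknown signal kind {self.signal!r}")


@dataclass
class SimTruth:
    """Per-cell ground truth: phase/position, cycling flag, type, batch, library."""

    table: pd.DataFrame

    def __getitem__(self, col):
        return self.table[col].to_numpy()


def expected_means(config: SimConfig, rng: np.random.Generator | None = None):
    """The generator's structural draws, before count noise.

    Returns ``(mean, genes, truth, batch_fx)`` where ``mean[c, g]`` is the
    NB mean ``s_c * rate_gc`` of gene g in cell c, ``genes`` carries the
    marker flags and dispersions, and ``batch_fx`` the injected per-gene
    log batch factors.  ``simulate`` is exactly NB noise around this.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, gm, go = config.n_cells, config.n_cycle_genes, config.n_other_genes
    G = gm + go

    cycling = np.zeros(n, dtype=bool)
    cycling[: int(round(n * config.fraction_cycling))] = True
    cell_type = rng.integers(0, config.n_cell_types, size=n)
    batch = rng.integers(0, config.n_batches, size=n)
    phase = np.where(cycling, rng.uniform(0, 2 * np.pi, size=n), np.nan)
    position = rng.uniform(0, 1, size=n)  # used by the gradient kind

    # marker-gene signal
    a = rng.normal(0.0, 0.7, size=gm)             # baseline log-rate
    lo, hi = config.amplitude_range
    b = rng.uniform(lo, hi, size=gm)
    psi = rng.uniform(0, 2 * np.pi, size=gm)
    log_rate_m = np.tile(a, (n, 1))
    if config.signal == "cyclic":
        ph = np.where(cycling, phase, 0.0)
        log_rate_m += np.where(cycling[:, None],
                               b * np.cos(ph[:, None] - psi), 0.0)
    elif config.signal == "linear-gradient":
        beta = rng.uniform(lo, hi, size=gm) * rng.choice([-1.0, 1.0], size=gm)
        log_rate_m += beta * (position[:, None] - 0.5) * 2.0
    else:  # categorical program on the markers
        prog = rng.normal(0.0, config.cell_type_effect,
                          size=(config.n_cell_types, gm))
        log_rate_m += prog[cell_type]

    # cell-type programs on the non-marker genes
    a_o = rng.normal(0.0, 0.7, size=go)
    type_fx = rng.normal(0.0, config.cell_type_effect,
                         size=(config.n_cell_types, go))
    log_rate_o = a_o + type_fx[cell_type]

    log_rate = np.concatenate([log_rate_m, log_rate_o], axis=1)
    # multiplicative per-gene batch factor (log-normal)
    batch_fx = rng.normal(0.0, config.batch_effect_scale,
                          size=(config.n_batches, G))
    batch_fx[0] = 0.0  # reference batch
    log_rate += batch_fx[batch]

    rate = np.exp(log_rate)
    library = rng.lognormal(config.library_meanlog, config.library_sdlog, size=n)
    s = library / rate.sum(axis=1)
    mean = s[:, None] * rate

    theta = rng.uniform(*config.dispersion_range, size=G)

    genes = pd.DataFrame({
        "gene": [f"M{i:04d}" for i in range(gm)] + [f"O{i:04d}" for i in range(go)],
        "is_marker": [True] * gm + [False] * go,
        "dispersion": theta,
    })
    truth = SimTruth(pd.DataFrame({
        "cell": [f"C{i:05d}" for i in range(n)],
        "phase": phase,
        "position": position,
        "cycling": cycling,
        "cell_type": cell_type,
        "batch": batch,
        "library": library,
        "expected_total": library,
    }))
    return mean, genes, truth, batch_fx


def simulate(config: SimConfig, rng: np.random.Generator | None = None):
    """Returns (counts csr int matrix, gene table, SimTruth)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mean, genes, truth, _ = expected_means(config, rng)
    theta = genes["dispersion"].to_numpy()
    counts = rng.poisson(rng.gamma(theta, mean / theta))  # NB(mean, theta)
    return sps.csr_matrix(counts.astype(np.int64)), genes, truth


def fixture_small(seed: int = 0):
    """Canonical deterministic test fixture.

    1,500 cells (1,000 cycling + 500 non-cycling, 3 cell types across
    both groups), 120 cycle-marker genes, 280 other genes, 2 batches.
    """
    cfg = SimConfig(n_cells=1500, fraction_cycling=1000 / 1500,
                    n_cycle_genes=120, n_other_genes=280, n_cell_types=3,
                    n_batches=2, seed=seed)
    return (*simulate(cfg, np.random.default_rng(seed)), cfg)


def fixture_gradient(seed: int = 0):
    """Linear-gradient (zonation-like) fixture: 1,000 cells, 50 marker genes."""
    cfg = SimConfig(n_cells=1000, fraction_cycling=1.0, n_cycle_genes=50,
                    n_other_genes=150, n_cell_types=2,
                    signal="linear-gradient", seed=seed)
    return (*simulate(cfg, np.random.default_rng(seed)), cfg)


def fixture_spiked(seed: int = 0, n_spiked: int = 10, spike: float = 1.5):
    """Two-condition fixture for the upregulated-gene discovery test.

    600 cells in two equal groups ("ctrl"/"stim"); 60 cell-type marker
    genes carry a categorical program; of the remaining 140 genes,
    ``n_spiked`` well-expressed ones are upregulated by ``spike`` (log
    scale) in the stim group.  Returns (counts, genes, truth) with a
    "group" truth column and a "spiked" gene flag.
    """
    rng = np.random.default_rng(seed)
    n, gm, go, n_types = 600, 60, 140, 3
    group = np.zeros(n, dtype=int)
    group[n // 2:] = 1
    cell_type = rng.integers(0, n_types, size=n)

    a_m = rng.normal(0.0, 0.7, size=gm)
    prog = rng.normal(0.0, 1.2, size=(n_types, gm))
    a_o = rng.normal(0.0, 0.7, size=go)
    type_fx = rng.normal(0.0, 1.0, size=(n_types, go))
    # spike genes with solid baseline so the planted signal is detectable
    expressed = np.argsort(a_o)[::-1][:3 * n_spiked]
    spiked = np.sort(rng.choice(expressed, size=n_spiked, replace=False)) + gm

    log_rate = np.concatenate(
        [a_m + prog[cell_type], a_o + type_fx[cell_type]], axis=1)
    log_rate[:, spiked] += spike * group[:, None]
    rate = np.exp(log_rate)
    library = rng.lognormal(9.0, 0.3, size=n)
    mean = (library / rate.sum(axis=1))[:, None] * rate
    theta = rng.uniform(2.0, 10.0, size=gm + go)
    counts = rng.poisson(rng.gamma(theta, mean / theta))

    genes = pd.DataFrame({
        "gene": [f"M{i:04d}" for i in range(gm)] + [f"O{i:04d}" for i in range(go)],
        "is_marker": [True] * gm + [False] * go,
        "dispersion": theta,
        "spiked": np.isin(np.arange(gm + go), spiked),
    })
    truth = SimTruth(pd.DataFrame({
        "cell": [f"C{i:05d}" for i in range(n)],
        "phase": np.nan,
        "position": np.nan,
        "cycling": False,
        "cell_type": cell_type,
        "batch": 0,
        "library": library,
        "group": np.where(group == 0, "ctrl", "stim"),
    }))
    return sps.csr_matrix(counts.astype(np.int64)), genes, truth


def write_dataset(prefix, counts, genes: pd.DataFrame, truth: SimTruth):
    """Write MTX + id files + marker list + gene metadata + truth table.

    Layout: ``matrix.mtx``, ``genes.tsv`` (headerless ids),
    ``cells.tsv`` (truth table; cell id first), ``gene_meta.tsv``
    (flags/dispersions) and ``markers.txt`` (one marker symbol per line).
    """
    from pathlib import Path

    from scipy.io import mmwrite

    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    mmwrite(str(prefix / "matrix.mtx"), sps.coo_matrix(counts), field="integer")
    (prefix / "genes.tsv").write_text("\n".join(genes["gene"]) + "\n")
    genes.to_csv(prefix / "gene_meta.tsv", sep="\t", index=False)
    (prefix / "markers.txt").write_text(
        "\n".join(genes.loc[genes["is_marker"], "gene"]) + "\n")
    truth.table.to_csv(prefix / "cells.tsv", sep="\t", index=False)
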