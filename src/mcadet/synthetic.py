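"""Synthetic scRNA-seq benchmark generator with planted informative genes.

Emulates a standard simulation design for benchmarking highly-variable-gene
selection: a fixed number of cell populations with prescribed abundances,
*driver* genes upregulated in exactly one population, *DE* genes up- or
down-regulated in two to four populations, and 24 graded intensity levels
whose fold-change ranges come in a "fine" (subtle differences) and a
"coarse" (strong differences) flavour.  Counts follow a Gamma-Poisson
recipe: a log-normal per-gene baseline rate, a log-normal per-cell library
factor, and population-specific fold-change multipliers, giving integer
matrices with realistic sparsity.  Binomial count splitting is provided for
consistency experiments.

Defaults reproduce the benchmark's study conditions: 6,000 cells x 15,000
genes, 10 populations at abundances 25/20/16/10/8/7/6/4/3/1%, 200 driver
genes (20 per population) and 1,800 DE genes (2,000 informative in total),
with driver fold-change ranges boosted by a factor 1.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .preprocess import CountMatrix

__all__ = [
    "SyntheticDesign",
    "SyntheticDataset",
    "DEFAULT_ABUNDANCES",
    "make_design",
    "scaled_design",
    "simulate_counts",
    "count_split",
    "write_dataset",
]

DEFAULT_ABUNDANCES = (0.25, 0.20, 0.16, 0.10, 0.08, 0.07, 0.06, 0.04, 0.03, 0.01)

#: fold-change parameter ranges (a_up, b_up, a_down, b_down) per mode
_MODE_RANGES = {
    "fine": ((1.5, 2.0), (2.0, 2.5), (0.4, 0.6), (0.6, 0.8)),
    "coarse": ((2.0, 3.0), (2.5, 3.5), (0.1, 0.3), (0.3, 0.5)),
}
N_LEVELS = 24
DRIVER_BOOST = 1.2


@dataclass
class SyntheticDesign:
    """Fully resolved simulation design (deterministic given mode/level/seed)."""

    n_cells: int
    n_genes: int
    abundances: tuple[float, ...]
    pop_sizes: np.ndarray            # per-population cell counts, sums to n_cells
    driver_genes: np.ndarray         # (n_pops, drivers_per_pop) gene indices
    de_genes: np.ndarray             # (n_de,) gene indices, disjoint from drivers
    fold_changes: np.ndarray         # (n_pops, n_genes) multipliers, 1 = no DE
    mode: str
    level: int
    seed: int
    baseline_median: float = 0.3     # median baseline rate, counts/cell
    baseline_sigma: float = 1.5      # log-sd of the baseline rate
    library_sigma: float = 0.3       # log-sd of per-cell library factors
    params: dict = field(default_factory=dict)  # (a_up, b_up, a_down, b_down) used

    @property
    def n_pops(self) -> int:
        return len(self.abundances)

    @property
    def informative_genes(self) -> np.ndarray:
        """Sorted union of driver and DE gene indices."""
        return np.sort(np.concatenate([self.driver_genes.ravel(), self.de_genes]))


@dataclass
class SyntheticDataset:
    """Simulated counts plus ground truth."""

    counts: CountMatrix
    labels: np.ndarray               # (n_cells,) population ids 1..n_pops
    truth_hvgs: set[str]             # informative gene ids (drivers + DE)
    minority_truth: set[str]         # informative gene ids for population 1


def _level_params(mode: str, level: int) -> tuple[float, float, float, float]:
    """Equally spaced fold-change parameters for one of the 24 intensity levels.

    Higher levels mean stronger differential expression: the "up" parameters
    increase and the "down" parameters decrease along the grid, which stays
    strictly inside the stated open ranges.
    """
    (au_lo, au_hi), (bu_lo, bu_hi), (ad_lo, ad_hi), (bd_lo, bd_hi) = _MODE_RANGES[mode]
    f = level / (N_LEVELS + 1)
    a_up = au_lo + (au_hi - au_lo) * f
    b_up = bu_lo + (bu_hi - bu_lo) * f
    a_down = ad_hi - (ad_hi - ad_lo) * f
    b_down = bd_hi - (bd_hi - bd_lo) * f
    return a_up, b_up, a_down, b_down


def _population_sizes(n_cells: int, abundances: tuple[float, ...]) -> np.ndarray:
    sizes = np.array([int(round(a * n_cells)) for a in abundances])
    sizes[np.argmax(sizes)] += n_cells - sizes.sum()  # absorb rounding drift
    if np.any(sizes <= 0):
        raise ValueError("a population received no cells; increase n_cells")
    return sizes


def make_design(
    mode: str = "fine",
    level: int = 12,
    seed: int = 1,
    n_cells: int = 6000,
    n_genes: int = 15000,
    abundances: tuple[float, ...] = DEFAULT_ABUNDANCES,
    drivers_per_pop: int = 20,
    n_de: int = 1800,
) -> SyntheticDesign:
    """Build a deterministic simulation design.

    Driver genes get a fold change drawn from ``Unif(1.2 a_up, 1.2 b_up)``
    in exactly one population each; every DE gene is assigned a direction
    (up or down) and 2-4 populations, with its multiplier drawn per
    population from ``Unif(a_up, b_up)`` or ``Unif(a_down, b_down)``.
    """
    if mode not in _MODE_RANGES:
        raise ValueError(f"mode must be one of {sorted(_MODE_RANGES)}, got {mode!r}")
    if not (1 <= level <= N_LEVELS):
        raise ValueError(f"level must be in 1..{N_LEVELS}, got {level}")
    if abs(sum(abundances) - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    n_pops = len(abundances)
    n_drivers = n_pops * drivers_per_pop
    if n_drivers + n_de > n_genes:
        raise ValueError("more informative genes than genes in the design")

    a_up, b_up, a_down, b_down = _level_params(mode, level)
    rng = np.random.default_rng(seed)
    pop_sizes = _population_sizes(n_cells, abundances)

    informative = rng.choice(n_genes, size=n_drivers + n_de, replace=False)
    driver_genes = informative[:n_drivers].reshape(n_pops, drivers_per_pop)
    de_genes = np.sort(informative[n_drivers:])

    fold = np.ones((n_pops, n_genes))
    for pop in range(n_pops):
        idx = driver_genes[pop]
        fold[pop, idx] = rng.uniform(DRIVER_BOOST * a_up, DRIVER_BOOST * b_up, size=idx.size)
    n_affected = rng.integers(2, min(4, n_pops) + 1, size=de_genes.size)
    directions = rng.random(de_genes.size) < 0.5  # True = up
    for g, n_aff, up in zip(de_genes, n_affected, directions):
        pops = rng.choice(n_pops, size=n_aff, replace=False)
        if up:
            fold[pops, g] = rng.uniform(a_up, b_up, size=n_aff)
        else:
            fold[pops, g] = rng.uniform(a_down, b_down, size=n_aff)

    return SyntheticDesign(
        n_cells=n_cells,
        n_genes=n_genes,
        abundances=tuple(abundances),
        pop_sizes=pop_sizes,
        driver_genes=driver_genes,
        de_genes=de_genes,
        fold_changes=fold,
        mode=mode,
        level=level,
        seed=seed,
        params={"a_up": a_up, "b_up": b_up, "a_down": a_down, "b_down": b_down},
    )


def scaled_design(
    mode: str = "coarse",
    level: int = 12,
    seed: int = 1,
    n_cells: int = 1000,
    n_genes: int = 2000,
) -> SyntheticDesign:
    """A small five-population design (20 drivers + 180 DE genes) for fast runs."""
    return make_design(
        mode=mode,
        level=level,
        seed=seed,
        n_cells=n_cells,
        n_genes=n_genes,
        abundances=(0.30, 0.25, 0.20, 0.15, 0.10),
        drivers_per_pop=4,
        n_de=180,
    )


def simulate_counts(design: SyntheticDesign) -> SyntheticDataset:
    """Draw a count matrix from the Gamma-Poisson model of the design.

    Per-gene baseline rates are log-normal (median ``baseline_median``
    counts/cell, log-sd ``baseline_sigma``); per-cell library factors are
    log-normal with unit median; counts are Poisson with rate
    ``library_i * baseline_j * fold_change[pop(i), j]``.
    """
    rng = np.random.default_rng([design.seed, 7])
    n, p = design.n_cells, design.n_genes
    baseline = np.exp(rng.normal(np.log(design.baseline_median), design.baseline_sigma, size=p))
    library = np.exp(rng.normal(0.0, design.library_sigma, size=n))

    labels = np.repeat(np.arange(1, design.n_pops + 1), design.pop_sizes)
    counts = np.empty((n, p), dtype=np.int32)
    start = 0
    for pop in range(design.n_pops):
        stop = start + int(design.pop_sizes[pop])
        rate = np.outer(library[start:stop], baseline * design.fold_changes[pop])
        counts[start:stop] = rng.poisson(rate)
        start = stop

    gene_ids = [f"gene_{j:05d}" for j in range(p)]
    cell_ids = [f"cell_{i:05d}" for i in range(n)]
    cm = CountMatrix(values=counts, gene_ids=gene_ids, cell_ids=cell_ids)

    truth = {gene_ids[j] for j in design.informative_genes}
    minority = set(gene_ids[j] for j in design.driver_genes[0])
    minority.update(
        gene_ids[g] for g in design.de_genes if design.fold_changes[0, g] != 1.0
    )
    return SyntheticDataset(counts=cm, labels=labels, truth_hvgs=truth, minority_truth=minority)


def count_split(
    counts: CountMatrix, epsilon: float = 0.5, seed: int = 1
) -> tuple[CountMatrix, CountMatrix]:
    """Binomial thinning of a count matrix into two matrices summing to it.

    Each entry of the first split is ``Binom(Y_ij, epsilon)``; the second
    split is the exact remainder.
    """
    if not (0.0 < epsilon < 1.0):
        raise ValueError(f"epsilon must be in (0, 1), got {epsilon}")
    rng = np.random.default_rng(seed)
    Y = counts.values.toarray() if sp.issparse(counts.values) else np.asarray(counts.values)
    Y = Y.astype(np.int64)
    first = rng.binomial(Y, epsilon)
    second = Y - first
    mk = lambda v: CountMatrix(values=v, gene_ids=list(counts.gene_ids), cell_ids=list(counts.cell_ids))
    return mk(first), mk(second)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write a dataset as Matrix Market + sidecars (10x-style, genes x cells).

    Files: ``matrix.mtx``, ``genes.tsv``, ``barcodes.tsv``, ``labels.tsv``
    (cell_id <tab> population) and ``truth_hvgs.txt`` (one gene id per line).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm = dataset.counts
    mat = cm.values if sp.issparse(cm.values) else sp.csc_matrix(cm.values)
    scipy.io.mmwrite(outdir / "matrix.mtx", mat.T.astype(np.int64))
    (outdir / "genes.tsv").write_text("\n".join(cm.gene_ids) + "\n")
    (outdir / "barcodes.tsv").write_text("\n".join(cm.cell_ids) + "\n")
    with open(outdir / "labels.tsv", "w") as fh:
        for cell, lab in zip(cm.cell_ids, dataset.labels):
            fh.write(f"{cell}\t{lab}\n")
    (outdir / "truth_hvgs.txt").write_text("\n".join(sorted(dataset.truth_hvgs)) + "\n")
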