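"""Synthetic single-nucleus multiome (RNA + ATAC) with planted effects.

RNA counts are negative-binomial per gene/cell-type/condition with planted
log2 effects on a subset of genes; ATAC counts are sparse
Bernoulli(detection rate) * (1 + Poisson) events with planted detection-rate
shifts on differential peaks.

Cells carry a low-dimensional continuous state (a D-dimensional Gaussian
latent vector, the in-silico analogue of graded cell-state variation within
a type). A block of "structural" background peaks loads on this state so
that TF-IDF + LSI recovers it and kNN aggregation pools cells of similar
state. Each linked peak-gene pair is driven by a couple of state dimensions:
the gene log-mean loads on one dimension and the peak logit-rate on a
rho-mixture of that dimension and an independent one, so the correlation of
the underlying signals — and, once count noise is averaged out over
aggregates, the observable aggregate-level Pearson r — targets
``latent_corr``. Decoy peaks placed inside the linkage window of linked
genes carry no state loading, giving the unlinked pass rate something real
to measure; all remaining unlinked peaks sit >= 300 kb from every gene
start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ..multiome import CellFeatureMatrix
from ._rng import substream

__all__ = ["MultiomeDesign", "MultiomeTruth", "simulate_multiome"]

_N_STATE_DIMS = 8  # latent cell-state dimensionality (couples of 2 per pair)


@dataclass(frozen=True)
class MultiomeDesign:
    """Cell-type x condition layout of the simulated experiment."""

    cell_types: tuple[str, ...] = ("skeletal MN",)
    conditions: tuple[str, ...] = ("Ctrl", "KO")
    cells_per_group: int = 200
    n_samples_per_condition: int = 1

    def __post_init__(self) -> None:
        if len(self.conditions) < 2 or len(self.cell_types) < 1:
            raise ValueError("design needs >= 2 conditions and >= 1 cell type")


@dataclass
class MultiomeTruth:
    """Planted effects; sufficient to score DE/DA and linkage recovery."""

    de_genes: dict[str, float]          # gene_id -> log2 effect (KO vs Ctrl)
    da_peaks: dict[str, float]          # peak_id -> detection-rate shift
    linked_pairs: list[tuple[str, str, float]]  # (peak_id, gene_id, latent r)
    decoy_pairs: list[tuple[str, str]]  # in-window but unlinked (peak, gene)
    design: MultiomeDesign


def _toy_coordinates(
    n_genes: int,
    n_peaks: int,
    n_linked: int,
    n_decoy: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[int, int]], list[tuple[int, int]]]:
    """Gene starts 1 Mb apart. Linked peaks (and decoys) within +-200 kb of
    their gene; all other peaks are >= 300 kb from every gene start."""
    gene_starts = pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "chrom": "chrM1",
            "gene_start": [i * 1_000_000 + 500_000 for i in range(n_genes)],
            "strand": "+",
        }
    )
    rows = []
    linked_idx: list[tuple[int, int]] = []
    decoy_idx: list[tuple[int, int]] = []
    for p in range(n_peaks):
        if p < n_linked + n_decoy:
            # pair with genes from the top of the index range so linked
            # genes never coincide with planted DE genes (bottom of range)
            gi = n_genes - 1 - (p % n_genes)
            offset = int(rng.integers(-200_000, 200_001))
            center = gene_starts["gene_start"][gi] + offset
            (linked_idx if p < n_linked else decoy_idx).append((p, gi))
        else:
            # midway between gene starts: 500 kb from the two flanking genes
            slot = p % max(n_genes - 1, 1)
            center = slot * 1_000_000 + 1_000_000
        rows.append(
            {
                "feature_id": f"peak{p:05d}",
                "chrom": "chrM1",
                "start": int(center - 250),
                "end": int(center + 250),
            }
        )
    return gene_starts, pd.DataFrame(rows), linked_idx, decoy_idx


def simulate_multiome(
    design: MultiomeDesign | None = None,
    n_genes: int = 500,
    n_peaks: int = 1500,
    nb_dispersion: float = 0.3,
    n_de_genes: int = 50,
    de_log2fc: float = 1.5,
    n_da_peaks: int = 100,
    da_rate_shift: float = 0.3,
    n_linked_pairs: int = 50,
    latent_corr: float = 0.7,
    n_decoy_pairs: int | None = None,
    n_structural_peaks: int = 200,
    seed: int = 0,
) -> tuple[CellFeatureMatrix, CellFeatureMatrix, pd.DataFrame, MultiomeTruth]:
    """Generate matched RNA/ATAC matrices, gene-start table, and truth.

    Planted effects apply to the second condition (KO): the first
    ``n_de_genes`` genes get the log2 effect (alternating sign) and
    ``n_da_peaks`` far-from-gene peaks get the detection-rate shift
    (alternating sign). ``n_linked_pairs`` peak-gene pairs are driven by the
    latent cell state to an aggregate-level Pearson correlation near
    ``latent_corr``; ``n_decoy_pairs`` (default: same number) peaks sit in
    linked genes' windows without any state loading. ``n_structural_peaks``
    far-from-gene peaks expose the latent state to LSI.
    """
    design = design or MultiomeDesign()
    if n_decoy_pairs is None:
        n_decoy_pairs = n_linked_pairs
    n_special = n_linked_pairs + n_decoy_pairs + n_da_peaks + n_structural_peaks
    if n_de_genes + n_linked_pairs + n_decoy_pairs > n_genes or n_special > n_peaks:
        raise ValueError("inconsistent design: planted features exceed totals")
    if not 0.0 <= latent_corr <= 1.0:
        raise ValueError("latent_corr must lie in [0, 1]")

    rng_coord = substream(seed, "multiome/coords")
    rng_base = substream(seed, "multiome/baseline")
    rng_rna = substream(seed, "multiome/rna")
    rng_atac = substream(seed, "multiome/atac")
    rng_latent = substream(seed, "multiome/latent")

    gene_starts, peak_meta, linked_idx, decoy_idx = _toy_coordinates(
        n_genes, n_peaks, n_linked_pairs, n_decoy_pairs, rng_coord
    )
    gene_ids = gene_starts["gene_id"].to_numpy()
    peak_ids = peak_meta["feature_id"].to_numpy()

    # Cell layout.
    cells = []
    for ct_i, ct in enumerate(design.cell_types):
        for cond in design.conditions:
            for c in range(design.cells_per_group):
                sample = f"{cond}_s{c % design.n_samples_per_condition + 1}"
                cells.append((ct, cond, sample, ct_i))
    cell_meta = pd.DataFrame(cells, columns=["cell_type", "condition",
                                             "sample_id", "_ct_index"])
    n_cells = len(cell_meta)
    is_ko = (cell_meta["condition"] == design.conditions[1]).to_numpy()
    ct_index = cell_meta.pop("_ct_index").to_numpy()

    # Latent cell state and the per-pair gene/peak factors.
    state = rng_latent.normal(size=(n_cells, _N_STATE_DIMS))
    rho = latent_corr
    gene_factor = np.zeros((n_cells, max(n_linked_pairs, 1)))
    peak_factor = np.zeros((n_cells, max(n_linked_pairs, 1)))
    for i in range(n_linked_pairs):
        d = (2 * i) % _N_STATE_DIMS
        gene_factor[:, i] = state[:, d]
        peak_factor[:, i] = rho * state[:, d] + np.sqrt(1 - rho**2) * state[:, d + 1]

    # Baseline RNA means; log2 DE effects on the KO condition.
    base_mean = rng_base.lognormal(mean=0.7, sigma=0.8, size=n_genes)
    ct_factor = rng_base.lognormal(0.0, 0.4, size=(len(design.cell_types), n_genes))
    de_effect = np.zeros(n_genes)
    de_truth: dict[str, float] = {}
    for i in range(n_de_genes):
        eff = de_log2fc if i % 2 == 0 else -de_log2fc
        de_effect[i] = eff
        de_truth[str(gene_ids[i])] = eff

    # Baseline ATAC detection rates; planted shifts on far-from-gene peaks.
    base_rate = rng_base.uniform(0.05, 0.45, size=n_peaks)
    ct_rate = rng_base.uniform(0.8, 1.2, size=(len(design.cell_types), n_peaks))
    da_effect = np.zeros(n_peaks)
    da_truth: dict[str, float] = {}
    da_offset = n_linked_pairs + n_decoy_pairs
    for j in range(n_da_peaks):
        p = da_offset + j  # keep linked/decoy peaks free of condition effects
        shift = da_rate_shift if j % 2 == 0 else -da_rate_shift
        base_rate[p] = np.clip(base_rate[p], 0.05 + max(0.0, -shift),
                               0.95 - max(0.0, shift))
        da_effect[p] = shift
        da_truth[str(peak_ids[p])] = shift

    # RNA counts.
    gene_log_mean = (
        np.log(base_mean)[None, :]
        + np.log(ct_factor)[ct_index, :]
        + np.log(2.0) * de_effect[None, :] * is_ko[:, None]
    )
    gene_loading = 1.2
    for i, (p, gi) in enumerate(linked_idx):
        gene_log_mean[:, gi] += gene_loading * gene_factor[:, i]
    mean = np.exp(gene_log_mean)
    r = 1.0 / nb_dispersion
    rna_counts = rng_rna.negative_binomial(r, r / (r + mean))

    # ATAC counts: Bernoulli(rate) * (1 + Poisson).
    logit = np.log(base_rate / (1 - base_rate))[None, :] + np.log(
        ct_rate[ct_index, :]
    )
    rate = 1.0 / (1.0 + np.exp(-logit))
    shift_term = np.zeros((n_cells, n_peaks))
    shift_term[is_ko] = da_effect[None, :]
    rate = np.clip(rate + shift_term, 0.01, 0.98)

    rate_loading = 1.8
    logit_rate = np.log(rate / (1 - rate))
    for i, (p, gi) in enumerate(linked_idx):
        logit_rate[:, p] += rate_loading * peak_factor[:, i]
    # Structural peaks: expose each latent dimension to the ATAC embedding.
    struct_offset = da_offset + n_da_peaks
    for s in range(n_structural_peaks):
        p = struct_offset + s
        d = s % _N_STATE_DIMS
        logit_rate[:, p] += 1.2 * state[:, d]
    rate = 1.0 / (1.0 + np.exp(-logit_rate))
    detected = rng_atac.random((n_cells, n_peaks)) < rate
    atac_counts = detected * (1 + rng_atac.poisson(0.5, size=(n_cells, n_peaks)))

    rna = CellFeatureMatrix(
        counts=sp.csr_matrix(rna_counts),
        modality="RNA",
        cell_meta=cell_meta.copy(),
        feature_meta=pd.DataFrame({"gene_id": gene_ids}),
    )
    atac = CellFeatureMatrix(
        counts=sp.csr_matrix(atac_counts),
        modality="ATAC",
        cell_meta=cell_meta.copy(),
        feature_meta=peak_meta,
    )
    truth = MultiomeTruth(
        de_genes=de_truth,
        da_peaks=da_truth,
        linked_pairs=[
            (str(peak_ids[p]), str(gene_ids[gi]), latent_corr)
            for p, gi in linked_idx
        ],
        decoy_pairs=[
            (str(peak_ids[p]), str(gene_ids[gi])) for p, gi in decoy_idx
        ],
        design=design,
    )
    return rna, atac, gene_starts, truth
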