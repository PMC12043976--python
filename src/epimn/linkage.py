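"""Aggregate-based peak-to-gene linkage.

Sparse single-cell chromatin data is smoothed by pooling each sampled seed
cell with its k-1 nearest neighbors in LSI space; near-duplicate aggregates
(> 80% member overlap with an earlier one) are discarded. Candidate pairs
are all peaks whose midpoint lies within +-250 kb of a gene start; for each
pair the Pearson correlation across aggregates is computed, its p-value from
the t-transform with m-2 degrees of freedom, BH-adjusted over all pairs.
A pair passes when r >= 0.45 and adjusted p <= 1e-4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .enrichment import adjust_bh
from .genome import GenomicInterval
from .multiome import CellFeatureMatrix, EmbeddingMatrix, _row_normalize_log

logger = logging.getLogger(__name__)

__all__ = [
    "AggregateSet",
    "LinkageRecord",
    "make_aggregates",
    "filter_overlapping_aggregates",
    "aggregate_and_normalize",
    "candidate_pairs",
    "correlate_pairs",
    "link_peaks_to_genes",
    "linkage_records_to_frame",
]


@dataclass
class AggregateSet:
    """kNN cell aggregates: each member set is a seed cell plus neighbors."""

    members: list[np.ndarray]  # arrays of cell indices, each of size k
    k: int

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class LinkageRecord:
    """One peak-gene candidate with its correlation evidence."""

    peak: GenomicInterval
    gene_id: str
    distance_bp: int  # strand-oriented: positive = downstream of gene start
    r: float
    p: float
    p_adj: float
    passes: bool
    degenerate: bool = False


def make_aggregates(
    embedding: EmbeddingMatrix | np.ndarray,
    k: int,
    n_aggregates: int,
    seed: int = 0,
) -> AggregateSet:
    """Sample seed cells and pool each with its k-1 nearest LSI neighbors.

    Seeds are drawn without replacement with a seeded RNG; neighbor distance
    ties are broken by lower cell index, so the output is deterministic given
    the seed.
    """
    coords = embedding.selected() if isinstance(embedding, EmbeddingMatrix) else np.asarray(embedding)
    n_cells = coords.shape[0]
    if k < 1 or k > n_cells:
        raise ValueError(f"k={k} outside [1, n_cells={n_cells}]")
    if n_aggregates > n_cells:
        raise ValueError(f"n_aggregates={n_aggregates} > n_cells={n_cells}")
    rng = np.random.default_rng(seed)
    seeds = rng.choice(n_cells, size=n_aggregates, replace=False)
    members: list[np.ndarray] = []
    idx = np.arange(n_cells)
    for s in seeds:
        d = np.linalg.norm(coords - coords[s], axis=1)
        # stable tie-break: sort by (distance, cell index)
        order = np.lexsort((idx, d))
        members.append(np.sort(order[:k]))
    return AggregateSet(members=members, k=k)


def filter_overlapping_aggregates(
    aggs: AggregateSet, max_overlap: float = 0.8
) -> AggregateSet:
    """Greedy scan dropping aggregates overlapping a kept one by > max_overlap.

    Overlap(A, B) = |A intersect B| / k; the comparison is strict, so exactly
    80% overlap is kept.
    """
    kept: list[np.ndarray] = []
    kept_sets: list[set[int]] = []
    for m in aggs.members:
        mset = set(m.tolist())
        if any(len(mset & ks) / aggs.k > max_overlap for ks in kept_sets):
            continue
        kept.append(m)
        kept_sets.append(mset)
    if len(kept) < len(aggs.members):
        logger.info(
            "dropped %d/%d aggregates with > %.0f%% overlap",
            len(aggs.members) - len(kept), len(aggs.members), 100 * max_overlap,
        )
    return AggregateSet(members=kept, k=aggs.k)


def aggregate_and_normalize(
    counts: sp.spmatrix | CellFeatureMatrix, aggs: AggregateSet
) -> np.ndarray:
    """Per-aggregate feature sums, log-normalized (ln(1 + 1e4 x / total))."""
    if isinstance(counts, CellFeatureMatrix):
        counts = counts.counts
    counts = sp.csr_matrix(counts)
    if not len(aggs):
        raise ValueError("empty aggregate set")
    n_agg = len(aggs)
    pooled = sp.lil_matrix((n_agg, counts.shape[1]))
    for i, m in enumerate(aggs.members):
        pooled[i] = counts[m].sum(axis=0)
    return np.asarray(_row_normalize_log(sp.csr_matrix(pooled),
                                         what="aggregate").todense())


def candidate_pairs(
    peaks: Sequence[GenomicInterval],
    gene_starts: pd.DataFrame,
    window: int = 250_000,
) -> list[tuple[int, str, int]]:
    """All (peak index, gene_id, distance) pairs within the linkage window.

    ``gene_starts`` needs columns gene_id, chrom, gene_start, strand. A pair
    is emitted iff the peak midpoint lies in [gene_start - window,
    gene_start + window] (closed at both ends). Distance is strand-oriented:
    positive means the peak midpoint is downstream of the gene start.
    """
    required = {"gene_id", "chrom", "gene_start", "strand"}
    if not required <= set(gene_starts.columns):
        raise ValueError(f"gene_starts needs columns {sorted(required)}")
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): g for c, g in gene_starts.groupby("chrom")
    }
    pairs: list[tuple[int, str, int]] = []
    for pi, peak in enumerate(peaks):
        genes = by_chrom.get(peak.chrom)
        if genes is None:
            continue
        mid = peak.midpoint
        near = genes[(genes["gene_start"] - window <= mid)
                     & (mid <= genes["gene_start"] + window)]
        for row in near.itertuples(index=False):
            raw = mid - int(row.gene_start)
            dist = raw if row.strand == "+" else -raw
            pairs.append((pi, str(row.gene_id), int(dist)))
    return pairs


def correlate_pairs(
    agg_peak: np.ndarray,
    agg_gene: np.ndarray,
    pairs: Sequence[tuple[int, str, int]],
    peaks: Sequence[GenomicInterval],
    gene_index: dict[str, int],
    r_min: float = 0.45,
    padj_max: float = 1e-4,
) -> list[LinkageRecord]:
    """Pearson r per candidate pair across aggregates with BH-adjusted p.

    p comes from t = r * sqrt((m - 2) / (1 - r^2)) on m - 2 df (two-sided);
    passes iff r >= r_min and p_adj <= padj_max (both inclusive). A pair with
    a zero-variance side is emitted with r = 0, p = 1 and flagged degenerate.
    """
    m = agg_peak.shape[0]
    if m < 3:
        raise ValueError("need >= 3 aggregates for a correlation test")
    if agg_gene.shape[0] != m:
        raise ValueError("aggregate matrices disagree on the number of rows")
    rs = np.empty(len(pairs))
    degenerate = np.zeros(len(pairs), dtype=bool)
    for i, (pi, gid, _) in enumerate(pairs):
        x = agg_peak[:, pi]
        y = agg_gene[:, gene_index[gid]]
        if np.std(x) == 0 or np.std(y) == 0:
            rs[i] = 0.0
            degenerate[i] = True
        else:
            rs[i] = float(np.corrcoef(x, y)[0, 1])
    with np.errstate(divide="ignore"):
        t = rs * np.sqrt((m - 2) / np.maximum(1.0 - rs**2, 1e-300))
    pvals = 2.0 * stats.t.sf(np.abs(t), df=m - 2)
    pvals[degenerate] = 1.0
    padj = adjust_bh(pvals) if len(pairs) else np.array([])
    records = []
    for i, (pi, gid, dist) in enumerate(pairs):
        records.append(
            LinkageRecord(
                peak=peaks[pi],
                gene_id=gid,
                distance_bp=dist,
                r=float(rs[i]),
                p=float(pvals[i]),
                p_adj=float(padj[i]),
                passes=bool(rs[i] >= r_min and padj[i] <= padj_max
                            and not degenerate[i]),
                degenerate=bool(degenerate[i]),
            )
        )
    return records


def link_peaks_to_genes(
    rna: CellFeatureMatrix,
    atac: CellFeatureMatrix,
    embedding: EmbeddingMatrix | np.ndarray,
    gene_starts: pd.DataFrame,
    k: int = 50,
    n_aggregates: int = 500,
    window: int = 250_000,
    r_min: float = 0.45,
    padj_max: float = 1e-4,
    max_overlap: float = 0.8,
    seed: int = 0,
) -> list[LinkageRecord]:
    """Full linkage pipeline on matched RNA/ATAC matrices.

    ``n_aggregates`` is capped at the cell count. Peak coordinates are taken
    from the ATAC feature_meta (columns chrom, start, end, with optional
    strand ignored — peaks are unstranded).
    """
    if rna.n_cells != atac.n_cells:
        raise ValueError("RNA and ATAC matrices must share cells")
    n_aggregates = min(n_aggregates, rna.n_cells)
    aggs = filter_overlapping_aggregates(
        make_aggregates(embedding, k=k, n_aggregates=n_aggregates, seed=seed),
        max_overlap=max_overlap,
    )
    agg_gene = aggregate_and_normalize(rna, aggs)
    agg_peak = aggregate_and_normalize(atac, aggs)
    peaks = [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        for r in atac.feature_meta.itertuples(index=False)
    ]
    pairs = candidate_pairs(peaks, gene_starts, window=window)
    gene_index = {g: i for i, g in enumerate(rna.feature_ids())}
    pairs = [p for p in pairs if p[1] in gene_index]
    return correlate_pairs(
        agg_peak, agg_gene, pairs, peaks, gene_index,
        r_min=r_min, padj_max=padj_max,
    )


def write_links_bedpe(records: Sequence[LinkageRecord],
                      gene_starts: pd.DataFrame, path,
                      passing_only: bool = True) -> None:
    """BEDPE-style pairs file: peak interval vs gene-start anchor, score = r."""
    starts = {str(r.gene_id): (str(r.chrom), int(r.gene_start))
              for r in gene_starts.itertuples(index=False)}
    with open(path, "w") as fh:
        for rec in records:
            if passing_only and not rec.passes:
                continue
            chrom_g, gs = starts[rec.gene_id]
            fh.write(
                f"{rec.peak.chrom}\t{rec.peak.start}\t{rec.peak.end}\t"
                f"{chrom_g}\t{gs}\t{gs + 1}\t"
                f"{rec.gene_id}\t{rec.r:.4f}\n"
            )


def linkage_records_to_frame(records: Sequence[LinkageRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.peak.chrom for r in records],
            "peak_start": [r.peak.start for r in records],
            "peak_end": [r.peak.end for r in records],
            "gene_id": [r.gene_id for r in records],
            "distance_bp": [r.distance_bp for r in records],
            "r": [r.r for r in records],
            "p": [r.p for r in records],
            "p_adj": [r.p_adj for r in records],
            "passes": [r.passes for r in records],
        }
    )
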