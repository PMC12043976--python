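"""Single-nucleus multiome normalization, reduction, and differential tests.

RNA counts are log-normalized (ln(1 + 1e4 * x / cell_total)); ATAC counts get
log-TF-IDF followed by truncated SVD (LSI), of which components 2-10 feed
downstream consumers. Differential expression between conditions within a
cell type uses a two-part ("bimodal") likelihood-ratio test: each group is
modeled by a detection probability plus a Gaussian on the detected
(log-normalized, nonzero) values with a pooled standard deviation; the LRT
statistic is referred to chi-squared with 2 degrees of freedom and genes are
called at Bonferroni-adjusted p < 0.05. Differential accessibility uses the
Wilcoxon rank-sum test with the Gaussian (normal) approximation — midranks
for ties, tie-corrected variance, continuity correction — BH adjustment, and
the open/closed/neutral rule: open in the first condition iff adjusted
p < 0.01, log2 fold-change > 0.1, and more than 5 percent of that
condition's cells are nonzero; the symmetric run with conditions swapped
yields the closed set; everything else is neutral.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import TruncatedSVD

from .enrichment import adjust_bh, adjust_bonferroni

logger = logging.getLogger(__name__)

__all__ = [
    "CellFeatureMatrix",
    "EmbeddingMatrix",
    "DiffRecord",
    "lognormalize_rna",
    "tfidf_atac",
    "lsi",
    "bimodal_lrt",
    "wilcoxon_gaussian",
    "differential_expression",
    "differential_accessibility",
]

_SIGMA_FLOOR = 1e-8  # shared with the test-suite oracle; keeps degenerate
                     # Gaussian terms equal in full and null models


@dataclass
class CellFeatureMatrix:
    """Cells x features nonnegative integer counts with annotations.

    ``cell_meta`` carries condition, cell_type, and sample_id per cell;
    ``feature_meta`` carries gene_id (RNA) or peak coordinates (ATAC).
    Counts are stored sparse (CSR) and never densified by the operations in
    this module.
    """

    counts: sp.csr_matrix
    modality: str  # "RNA" | "ATAC"
    cell_meta: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.modality not in ("RNA", "ATAC"):
            raise ValueError(f"modality must be RNA or ATAC, got {self.modality!r}")
        if self.counts.shape[0] != len(self.cell_meta):
            raise ValueError("cell_meta length != n_cells")
        if self.counts.shape[1] != len(self.feature_meta):
            raise ValueError("feature_meta length != n_features")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def feature_ids(self) -> np.ndarray:
        col = "gene_id" if "gene_id" in self.feature_meta.columns else "feature_id"
        return self.feature_meta[col].to_numpy()

    def subset_cells(self, mask: np.ndarray) -> "CellFeatureMatrix":
        return CellFeatureMatrix(
            counts=self.counts[mask],
            modality=self.modality,
            cell_meta=self.cell_meta.loc[mask].reset_index(drop=True),
            feature_meta=self.feature_meta,
        )

    def to_anndata(self):
        """Optional AnnData view (anndata is imported lazily)."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(),
            obs=self.cell_meta.copy(),
            var=self.feature_meta.copy(),
        )


@dataclass
class EmbeddingMatrix:
    """Cells x components scores from a truncated SVD/PCA.

    ``component_range_used`` is 1-based inclusive; :meth:`selected` returns
    only those columns (the chromatin convention of dropping the depth-driven
    first LSI component corresponds to (2, 10)).
    """

    scores: np.ndarray
    singular_values: np.ndarray
    component_range_used: tuple[int, int]

    def selected(self) -> np.ndarray:
        lo, hi = self.component_range_used
        return self.scores[:, lo - 1 : hi]


@dataclass
class DiffRecord:
    """Per-feature differential statistics with a class label.

    ``pct_1``/``pct_2`` are the percent of cells with a nonzero value in each
    group. RNA classes: up/down/not_significant; ATAC: open/closed/neutral.
    """

    feature_id: str
    log2fc: float
    pct_1: float
    pct_2: float
    p: float
    p_adj: float
    klass: str


def _row_normalize_log(counts: sp.spmatrix, scale: float = 1e4,
                       what: str = "cell") -> sp.csr_matrix:
    counts = sp.csr_matrix(counts, dtype=float)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"zero-total {what}(s) at index {zero[:5].tolist()}")
    out = counts.multiply(scale / totals[:, None]).tocsr()
    out.data = np.log1p(out.data)
    return out


def lognormalize_rna(counts: sp.spmatrix | CellFeatureMatrix) -> sp.csr_matrix:
    """ln(1 + 1e4 * x / cell_total); zeros stay zero (sparse-safe)."""
    if isinstance(counts, CellFeatureMatrix):
        counts = counts.counts
    return _row_normalize_log(counts)


def tfidf_atac(
    counts: sp.spmatrix | CellFeatureMatrix,
    scale: float = 1e4,
    log_variant: bool = True,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Log-TF-IDF normalization of an ATAC count matrix.

    value = ln(1 + scale * tf * idf) with tf = x / cell_total and
    idf = n_cells / n_cells_with_feature. All-zero features are dropped with
    a warning; the returned index array maps kept columns back to the input.
    With ``log_variant=False`` the plain tf*idf product is returned instead.
    """
    if isinstance(counts, CellFeatureMatrix):
        counts = counts.counts
    counts = sp.csr_matrix(counts, dtype=float)
    n_cells = counts.shape[0]
    doc_freq = np.asarray((counts > 0).sum(axis=0)).ravel()
    keep = np.flatnonzero(doc_freq > 0)
    if keep.size < counts.shape[1]:
        warnings.warn(
            f"dropping {counts.shape[1] - keep.size} all-zero feature(s)",
            stacklevel=2,
        )
        counts = counts[:, keep]
        doc_freq = doc_freq[keep]
    totals = np.asarray(counts.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"zero-total cell(s) at index {zero[:5].tolist()}")
    tf = counts.multiply(1.0 / totals[:, None])
    idf = n_cells / doc_freq
    out = tf.multiply(idf[None, :]).tocsr()
    if log_variant:
        out.data = np.log1p(scale * out.data)
    return out, keep


def lsi(
    normalized: sp.spmatrix,
    n_components: int = 10,
    use_range: tuple[int, int] = (2, 10),
    seed: int = 0,
) -> EmbeddingMatrix:
    """Truncated SVD of a normalized matrix (LSI scores).

    ``use_range`` is 1-based inclusive and must fit within ``n_components``.
    The randomized solver is seeded for reproducibility.
    """
    normalized = sp.csr_matrix(normalized)
    lo, hi = use_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid use_range {use_range}")
    if n_components < hi:
        raise ValueError(f"n_components={n_components} < use_range hi={hi}")
    if n_components > min(normalized.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_cells, n_features)="
            f"{min(normalized.shape)}"
        )
    svd = TruncatedSVD(n_components=n_components, random_state=seed)
    scores = svd.fit_transform(normalized)
    return EmbeddingMatrix(
        scores=scores,
        singular_values=svd.singular_values_,
        component_range_used=use_range,
    )


def _two_part_loglik(values: np.ndarray, pi: float, mu: float, sigma: float) -> float:
    """Log-likelihood of the detection + Gaussian-on-nonzeros model."""
    nz = values[values != 0]
    n0 = values.size - nz.size
    ll = 0.0
    if n0:
        ll += n0 * (np.log(1 - pi) if pi < 1 else -np.inf)
    if nz.size:
        ll += nz.size * np.log(pi) if pi > 0 else -np.inf
        ll += float(np.sum(stats.norm.logpdf(nz, mu, sigma)))
    return ll


def bimodal_lrt(group1: np.ndarray, group2: np.ndarray) -> float:
    """Two-part likelihood-ratio p-value for a difference between groups.

    Per group: detection probability pi (fraction nonzero) and a Gaussian on
    the nonzero values; the standard deviation is pooled across groups within
    each model. The statistic 2(l_full - l_null) is referred to chi-squared
    with 2 df. All-zero input in both groups carries no information (p = 1).
    When the pooled nonzero variance is 0 a small floor keeps the Gaussian
    terms finite and equal across models, so the detection part drives the
    statistic.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 3 or g2.size < 3:
        raise ValueError("each group needs >= 3 cells")
    nz1, nz2 = g1[g1 != 0], g2[g2 != 0]
    if nz1.size == 0 and nz2.size == 0:
        logger.debug("all values zero in both groups; p = 1")
        return 1.0

    all_vals = np.concatenate([g1, g2])
    all_nz = np.concatenate([nz1, nz2])

    # Full model: per-group pi and mu, pooled sigma over both groups' nonzeros.
    pi1, pi2 = nz1.size / g1.size, nz2.size / g2.size
    mu1 = float(nz1.mean()) if nz1.size else 0.0
    mu2 = float(nz2.mean()) if nz2.size else 0.0
    sse_full = 0.0
    if nz1.size:
        sse_full += float(np.sum((nz1 - mu1) ** 2))
    if nz2.size:
        sse_full += float(np.sum((nz2 - mu2) ** 2))
    sigma_full = max(np.sqrt(sse_full / all_nz.size), _SIGMA_FLOOR)

    # Null model: common pi, mu, sigma.
    pi0 = all_nz.size / all_vals.size
    mu0 = float(all_nz.mean())
    sigma0 = max(np.sqrt(float(np.sum((all_nz - mu0) ** 2)) / all_nz.size),
                 _SIGMA_FLOOR)

    ll_full = (_two_part_loglik(g1, pi1, mu1, sigma_full)
               + _two_part_loglik(g2, pi2, mu2, sigma_full))
    ll_null = (_two_part_loglik(g1, pi0, mu0, sigma0)
               + _two_part_loglik(g2, pi0, mu0, sigma0))
    stat = max(0.0, 2.0 * (ll_full - ll_null))
    return float(stats.chi2.sf(stat, df=2)) if stat > 0 else 1.0


def wilcoxon_gaussian(group1: np.ndarray, group2: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum z and two-sided p via the Gaussian approximation.

    Midranks for ties, tie-corrected variance, continuity correction. If ties
    make the variance 0 (all values identical) the comparison is
    uninformative and (0, 1) is returned.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 values")
    pooled = np.concatenate([g1, g2])
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        logger.debug("zero rank variance (all values tied); p = 1")
        return 0.0, 1.0
    diff = u1 - mean_u
    z = (diff - np.sign(diff) * 0.5) / np.sqrt(var_u) if diff != 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def _log2fc(norm1: np.ndarray, norm2: np.ndarray) -> float:
    """log2((mean(expm1(n1)) + 1) / (mean(expm1(n2)) + 1)); pseudocount 1."""
    m1 = float(np.mean(np.expm1(norm1)))
    m2 = float(np.mean(np.expm1(norm2)))
    return float(np.log2((m1 + 1.0) / (m2 + 1.0)))


def _split_groups(
    matrix: CellFeatureMatrix,
    cell_type: str,
    condition_1: str,
    condition_2: str,
) -> tuple[np.ndarray, np.ndarray]:
    meta = matrix.cell_meta
    if cell_type not in set(meta["cell_type"]):
        raise ValueError(f"cell_type {cell_type!r} absent from cell_meta")
    in_type = (meta["cell_type"] == cell_type).to_numpy()
    m1 = in_type & (meta["condition"] == condition_1).to_numpy()
    m2 = in_type & (meta["condition"] == condition_2).to_numpy()
    if not m1.any() or not m2.any():
        raise ValueError(
            f"both conditions ({condition_1!r}, {condition_2!r}) must be present "
            f"within cell_type {cell_type!r}"
        )
    return m1, m2


def _min_detection_filter(
    x1: sp.csr_matrix, x2: sp.csr_matrix, min_cells: int
) -> np.ndarray:
    det1 = np.asarray((x1 > 0).sum(axis=0)).ravel()
    det2 = np.asarray((x2 > 0).sum(axis=0)).ravel()
    return (det1 >= min_cells) & (det2 >= min_cells)


def differential_expression(
    matrix: CellFeatureMatrix,
    cell_type: str,
    condition_1: str,
    condition_2: str,
    alpha: float = 0.05,
    min_cells: int = 3,
    adjust: str = "bonferroni",
) -> list[DiffRecord]:
    """Two-part LRT differential expression within one cell type.

    Genes detected in fewer than ``min_cells`` cells in either condition are
    not tested (the filter is logged). Adjustment is Bonferroni by default
    (BH available); class is up/down by the sign of log2fc when
    p_adj < alpha, else not_significant. log2fc is condition_1 over
    condition_2.
    """
    if matrix.modality != "RNA":
        raise ValueError("differential_expression expects an RNA matrix")
    m1, m2 = _split_groups(matrix, cell_type, condition_1, condition_2)
    norm = lognormalize_rna(matrix.counts)
    x1, x2 = norm[m1], norm[m2]
    tested = np.flatnonzero(_min_detection_filter(x1, x2, min_cells))
    logger.info(
        "%s: testing %d/%d genes (>= %d detected cells per condition)",
        cell_type, tested.size, matrix.n_features, min_cells,
    )
    ids = matrix.feature_ids()
    records: list[DiffRecord] = []
    pvals = np.empty(tested.size)
    x1, x2 = x1.tocsc(), x2.tocsc()  # fast column access
    for i, j in enumerate(tested):
        v1 = x1[:, j].toarray().ravel()
        v2 = x2[:, j].toarray().ravel()
        pvals[i] = bimodal_lrt(v1, v2)
        records.append(
            DiffRecord(
                feature_id=str(ids[j]),
                log2fc=_log2fc(v1, v2),
                pct_1=100.0 * np.count_nonzero(v1) / v1.size,
                pct_2=100.0 * np.count_nonzero(v2) / v2.size,
                p=pvals[i],
                p_adj=np.nan,
                klass="not_significant",
            )
        )
    adjusted = (adjust_bonferroni(pvals) if adjust == "bonferroni"
                else adjust_bh(pvals))
    for rec, padj in zip(records, adjusted):
        rec.p_adj = float(padj)
        if padj < alpha:
            rec.klass = "up" if rec.log2fc > 0 else "down"
    return records


def differential_accessibility(
    matrix: CellFeatureMatrix,
    cell_type: str,
    condition_1: str,
    condition_2: str,
    alpha: float = 0.01,
    min_log2fc: float = 0.1,
    min_pct: float = 5.0,
    min_cells: int = 3,
) -> list[DiffRecord]:
    """Wilcoxon/Gaussian differential accessibility with open/closed classes.

    A peak is open in condition_1 iff BH-adjusted p < alpha, log2fc >
    min_log2fc, and pct_1 > min_pct (percent of condition_1 cells nonzero);
    closed iff the same holds with the conditions swapped; neutral otherwise.
    p-values are shared between the two directions, so swapping the condition
    labels exactly exchanges open and closed.
    """
    if matrix.modality != "ATAC":
        raise ValueError("differential_accessibility expects an ATAC matrix")
    m1, m2 = _split_groups(matrix, cell_type, condition_1, condition_2)
    sub = m1 | m2
    norm, keep = tfidf_atac(matrix.counts[sub])
    m1s, m2s = m1[sub], m2[sub]
    x1, x2 = norm[m1s], norm[m2s]
    tested_local = np.flatnonzero(_min_detection_filter(x1, x2, min_cells))
    ids = matrix.feature_ids()[keep]
    logger.info(
        "%s: testing %d/%d peaks (>= %d accessible cells per condition)",
        cell_type, tested_local.size, matrix.n_features, min_cells,
    )
    records: list[DiffRecord] = []
    pvals = np.empty(tested_local.size)
    x1, x2 = x1.tocsc(), x2.tocsc()  # fast column access
    for i, j in enumerate(tested_local):
        v1 = x1[:, j].toarray().ravel()
        v2 = x2[:, j].toarray().ravel()
        _, pvals[i] = wilcoxon_gaussian(v1, v2)
        records.append(
            DiffRecord(
                feature_id=str(ids[j]),
                log2fc=_log2fc(v1, v2),
                pct_1=100.0 * np.count_nonzero(v1) / v1.size,
                pct_2=100.0 * np.count_nonzero(v2) / v2.size,
                p=pvals[i],
                p_adj=np.nan,
                klass="neutral",
            )
        )
    adjusted = adjust_bh(pvals)
    for rec, padj in zip(records, adjusted):
        rec.p_adj = float(padj)
        if padj < alpha and rec.log2fc > min_log2fc and rec.pct_1 > min_pct:
            rec.klass = "open"
        elif padj < alpha and -rec.log2fc > min_log2fc and rec.pct_2 > min_pct:
            rec.klass = "closed"
    return records


def diff_records_to_frame(records: Sequence[DiffRecord]) -> pd.DataFrame:
    """Tabular view of differential results."""
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "pct_1": [r.pct_1 for r in records],
            "pct_2": [r.pct_2 for r in records],
            "p": [r.p for r in records],
            "p_adj": [r.p_adj for r in records],
            "class": [r.klass for r in records],
        }
    )
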