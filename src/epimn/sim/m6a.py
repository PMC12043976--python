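"""Synthetic per-tool m6A site-prediction tables with planted ground truth.

The generator emulates what two nanopore m6A predictors emit on a motor-
neuron transcriptome: a toy genome of single-transcript genes, true sites
drawn per gene with positions concentrated near the stop codon (a mixture of
a uniform-over-CDS component and a Gaussian at the CDS/3'UTR boundary), a
DRACH 5-mer context for every true site, and per-tool, per-sample detection
noise. A designated risk-gene subset is modified at base_rate *
enrichment_factor (capped at 1), so downstream gene-set enrichment has a
known effect to recover.

Detection scores: a tool's threshold is strict, so a detected true site's
reported probability is drawn as threshold + (1 - threshold) * Beta(a, b) —
the Beta shapes control the above-threshold score distribution while the
sensitivity parameter alone controls detection. False sites arise at fp_rate
per kb of transcript per tool/sample with low above-threshold scores. With
sensitivity 1 and fp_rate 0 both consensus policies recover the planted
truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..consensus import SitePrediction, TOOL_THRESHOLDS
from ..genome import GeneSet, GenomicInterval, TranscriptModel
from ._rng import substream

__all__ = ["M6aTruth", "simulate_m6a_predictions"]

_DRACH_KMERS = [
    d + r + "AC" + h for d in "ATG" for r in "AG" for h in "ATC"
]


@dataclass
class M6aTruth:
    """Planted truth for the m6A simulation."""

    sites: list[tuple[str, int, float]]  # (transcript_id, position, stoichiometry)
    modified_genes: GeneSet
    risk_genes: GeneSet
    enrichment_factor: float


def _toy_transcriptome(
    n_genes: int, rng: np.random.Generator
) -> list[TranscriptModel]:
    """Single-exon, plus-strand transcripts spaced 100 kb apart on one chrom."""
    models = []
    for g in range(n_genes):
        utr5 = int(rng.integers(80, 300))
        cds = int(rng.integers(300, 1800))
        utr3 = int(rng.integers(200, 800))
        total = utr5 + cds + utr3
        start = g * 100_000 + 10_000
        exon = GenomicInterval("chrT", start, start + total, "+")
        models.append(
            TranscriptModel(
                transcript_id=f"tx{g:05d}",
                gene_id=f"gene{g:05d}",
                exons=[exon],
                utr5_len=utr5,
                cds_len=cds,
                utr3_len=utr3,
            )
        )
    return models


def _draw_positions(
    model: TranscriptModel, n: int, stop_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Mixture of Uniform(CDS) and Normal(stop boundary, 5% of CDS length)."""
    u5, cds = model.utr5_len, model.cds_len
    stop = u5 + cds  # transcript coordinate of the CDS/3'UTR boundary
    out = np.empty(n, dtype=int)
    for i in range(n):
        if rng.random() < stop_fraction:
            pos = int(round(rng.normal(stop, 0.05 * cds)))
        else:
            pos = int(rng.integers(u5, u5 + cds))
        out[i] = min(max(pos, 0), model.length - 1)
    return out


def simulate_m6a_predictions(
    n_genes: int = 2000,
    n_samples: int = 3,
    sensitivity: dict[str, float] | None = None,
    fp_rate_per_kb: dict[str, float] | None = None,
    stop_fraction: float = 0.5,
    base_rate: float = 0.35,
    enrichment_factor: float = 1.2,
    n_risk_genes: int = 200,
    sites_per_gene: float = 3.0,
    seed: int = 0,
) -> tuple[list[TranscriptModel], list[SitePrediction], M6aTruth]:
    """Generate transcript models, per-tool prediction tables, and truth.

    Defaults: 2,000 single-transcript genes, 3 biological samples, ~35% of
    genes modified (the fraction reported for a motor-neuron transcriptome),
    risk genes modified at base_rate * enrichment_factor, and positions split
    50/50 between Uniform(CDS) and a stop-codon-centered Gaussian.
    """
    sensitivity = dict(sensitivity or {"epinano": 0.8, "m6anet": 0.85})
    fp_rate_per_kb = dict(fp_rate_per_kb or {"epinano": 0.02, "m6anet": 0.01})
    for name, table in (("sensitivity", sensitivity), ("fp_rate", fp_rate_per_kb)):
        for tool, v in table.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}[{tool}]={v} outside [0,1]")
    if n_risk_genes > n_genes:
        raise ValueError("n_risk_genes cannot exceed n_genes")

    rng_genome = substream(seed, "m6a/genome")
    rng_truth = substream(seed, "m6a/truth")
    rng_detect = substream(seed, "m6a/detect")
    rng_fp = substream(seed, "m6a/falsepos")

    models = _toy_transcriptome(n_genes, rng_genome)
    risk_ids = frozenset(m.gene_id for m in models[:n_risk_genes])
    samples = [f"R{i + 1}" for i in range(n_samples)]

    # Plant the truth: per-gene modification, then site positions and
    # stoichiometries, with a DRACH context for every true site.
    true_sites: list[tuple[str, int, float, str]] = []
    modified: set[str] = set()
    p_risk = min(1.0, base_rate * enrichment_factor)
    for m in models:
        p_mod = p_risk if m.gene_id in risk_ids else base_rate
        if rng_truth.random() >= p_mod:
            continue
        n_sites = 1 + rng_truth.poisson(max(sites_per_gene - 1, 0.0))
        positions = np.unique(_draw_positions(m, n_sites, stop_fraction, rng_truth))
        for pos in positions:
            stoich = float(rng_truth.beta(4, 2))
            kmer = _DRACH_KMERS[rng_truth.integers(len(_DRACH_KMERS))]
            true_sites.append((m.transcript_id, int(pos), stoich, kmer))
        modified.add(m.gene_id)

    beta_shapes = {"epinano": (8.0, 2.0), "m6anet": (12.0, 1.5)}
    preds: list[SitePrediction] = []
    for tool in sorted(sensitivity):
        thr = TOOL_THRESHOLDS[tool]
        a, b = beta_shapes.get(tool, (8.0, 2.0))
        sens = sensitivity[tool]
        for sample in samples:
            for tid, pos, stoich, kmer in true_sites:
                if rng_detect.random() >= sens:
                    continue
                prob = thr + (1.0 - thr) * rng_detect.beta(a, b)
                mod_ratio = None
                if tool == "m6anet":
                    c = 50.0
                    mod_ratio = float(
                        rng_detect.beta(c * stoich + 1e-3, c * (1 - stoich) + 1e-3)
                    )
                preds.append(
                    SitePrediction(tool, sample, tid, pos,
                                   float(min(prob, 1.0)), kmer, mod_ratio)
                )
            # False positives at fp_rate per kb of transcript.
            fp = fp_rate_per_kb[tool]
            if fp > 0:
                for m in models:
                    n_fp = rng_fp.poisson(fp * m.length / 1000.0)
                    for _ in range(n_fp):
                        pos = int(rng_fp.integers(0, m.length))
                        prob = thr + (1.0 - thr) * rng_fp.beta(2, 8)
                        kmer = _DRACH_KMERS[rng_fp.integers(len(_DRACH_KMERS))]
                        mr = float(rng_fp.beta(2, 8)) if tool == "m6anet" else None
                        preds.append(
                            SitePrediction(tool, sample, m.transcript_id, pos,
                                           float(min(prob, 1.0)), kmer, mr)
                        )

    truth = M6aTruth(
        sites=[(tid, pos, stoich) for tid, pos, stoich, _ in true_sites],
        modified_genes=GeneSet("planted_modified", frozenset(modified)),
        risk_genes=GeneSet("planted_risk", risk_ids),
        enrichment_factor=enrichment_factor,
    )
    return models, preds, truth
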