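"""Consensus m6A epitranscriptome calling from per-tool site predictions.

Two nanopore m6A predictors are consumed as tabular output: EpiNano-style
tables (modification probability in a 'ProbM'-like column, kept at
probability > 0.5) and m6Anet-style tables ('probability_modified', kept at
probability > 0.9, carrying a per-site mod_ratio stoichiometry estimate).
Candidate sites are filtered on the DRACH motif and the per-tool threshold,
then combined into a consensus set under one of two policies:

``replicated_either_tool``
    a (transcript, position) is consensus iff a single tool predicts it in at
    least two distinct samples;
``shared_across_tools_per_sample``
    consensus iff both tools predict it within the same sample, for at least
    one sample.

The consensus set is summarized by stoichiometry, genomic region, metagene
profile (stop-codon-proximal enrichment), and a position-frequency matrix of
the site 5-mers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    GeneSet,
    RegionCategory,
    TranscriptIndex,
    TranscriptModel,
    is_drach,
    metagene_coordinate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TOOL_THRESHOLDS",
    "SitePrediction",
    "ConsensusSite",
    "EpitranscriptomeSummary",
    "read_predictions",
    "write_predictions",
    "filter_predictions",
    "call_consensus",
    "summarize_stoichiometry",
    "epitranscriptome_summary",
    "modified_gene_set",
    "write_consensus_bed",
    "write_consensus_tsv",
]

#: Strict per-tool probability thresholds (kept iff probability > threshold).
TOOL_THRESHOLDS: dict[str, float] = {"epinano": 0.5, "m6anet": 0.9}

PRED_COLUMNS = ["tool", "sample_id", "transcript_id", "position", "probability",
                "kmer", "mod_ratio"]


@dataclass(frozen=True)
class SitePrediction:
    """One per-tool, per-sample m6A site call (transcript coordinates)."""

    tool: str
    sample_id: str
    transcript_id: str
    position: int
    probability: float
    kmer: str
    mod_ratio: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0,1]")
        if self.mod_ratio is not None and not 0.0 <= self.mod_ratio <= 1.0:
            raise ValueError(f"mod_ratio {self.mod_ratio} outside [0,1]")


@dataclass
class ConsensusSite:
    """A consensus m6A site with its supporting evidence and stoichiometry."""

    transcript_id: str
    position: int
    kmer: str
    supporting: dict[str, set[str]]  # tool -> sample_ids
    stoichiometry_mean: float | None = None
    stoichiometry_min: float | None = None
    stoichiometry_max: float | None = None
    region: RegionCategory | None = None
    metagene_coord: float | None = None
    mean_probability: float = 0.0

    @property
    def n_supporting_samples(self) -> dict[str, int]:
        return {tool: len(samples) for tool, samples in self.supporting.items()}


@dataclass
class EpitranscriptomeSummary:
    """Dataset-level view of a consensus epitranscriptome."""

    n_sites: int
    n_genes: int
    region_counts: dict[RegionCategory, int]
    metagene_histogram: np.ndarray
    metagene_bin_edges: np.ndarray
    motif_pfm: np.ndarray  # 4 x 5, rows A/C/G/T

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_sites": self.n_sites,
                "n_genes": self.n_genes,
                "region_counts": {k.value: v for k, v in self.region_counts.items()},
                "metagene_histogram": self.metagene_histogram.tolist(),
                "metagene_bin_edges": self.metagene_bin_edges.tolist(),
                "motif_pfm": self.motif_pfm.tolist(),
            },
            indent=2,
        )


def read_predictions(path_or_buf) -> list[SitePrediction]:
    """Read a per-tool prediction TSV.

    Header: tool, sample, transcript, position, probability, kmer, mod_ratio
    (mod_ratio may be empty/NA for tools that do not report it).
    """
    df = pd.read_csv(path_or_buf, sep="\t")
    expected = {"tool", "sample", "transcript", "position", "probability", "kmer"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    if "mod_ratio" not in df.columns:
        df["mod_ratio"] = np.nan
    out = []
    for row in df.itertuples(index=False):
        mr = None if pd.isna(row.mod_ratio) else float(row.mod_ratio)
        out.append(
            SitePrediction(
                tool=str(row.tool),
                sample_id=str(row.sample),
                transcript_id=str(row.transcript),
                position=int(row.position),
                probability=float(row.probability),
                kmer=str(row.kmer),
                mod_ratio=mr,
            )
        )
    return out


def write_predictions(preds: Sequence[SitePrediction], path) -> None:
    """Write a prediction table in the dialect :func:`read_predictions` reads."""
    pd.DataFrame(
        {
            "tool": [p.tool for p in preds],
            "sample": [p.sample_id for p in preds],
            "transcript": [p.transcript_id for p in preds],
            "position": [p.position for p in preds],
            "probability": [p.probability for p in preds],
            "kmer": [p.kmer for p in preds],
            "mod_ratio": [p.mod_ratio for p in preds],
        }
    ).to_csv(path, sep="\t", index=False)


def filter_predictions(
    preds: Sequence[SitePrediction],
    require_drach: bool = True,
    thresholds: Mapping[str, float] | None = None,
) -> list[SitePrediction]:
    """Keep predictions with probability strictly above the per-tool threshold.

    With ``require_drach`` the site 5-mer must also match the DRACH consensus.
    Order-stable; a prediction whose tool has no threshold is an error.
    """
    thresholds = dict(TOOL_THRESHOLDS if thresholds is None else thresholds)
    unknown = {p.tool for p in preds} - set(thresholds)
    if unknown:
        raise ValueError(f"no threshold for tool(s): {sorted(unknown)}")
    kept = []
    for p in preds:
        if p.probability <= thresholds[p.tool]:
            continue
        if require_drach and not is_drach(p.kmer):
            continue
        kept.append(p)
    return kept


def call_consensus(
    preds: Sequence[SitePrediction],
    policy: str = "replicated_either_tool",
    position_tolerance: int = 0,
) -> list[ConsensusSite]:
    """Combine filtered predictions into consensus sites under a policy.

    Site identity across tools is exact (transcript_id, position) equality by
    default; ``position_tolerance`` > 0 merges calls within +-k nt onto the
    position most supported (lowest position on ties).
    """
    if policy not in ("replicated_either_tool", "shared_across_tools_per_sample"):
        raise ValueError(f"unknown policy {policy!r}")

    by_site: dict[tuple[str, int], list[SitePrediction]] = {}
    for p in preds:
        by_site.setdefault((p.transcript_id, p.position), []).append(p)

    if position_tolerance > 0:
        by_site = _merge_nearby(by_site, position_tolerance)

    sites: list[ConsensusSite] = []
    for (tid, pos), plist in sorted(by_site.items()):
        supporting: dict[str, set[str]] = {}
        for p in plist:
            supporting.setdefault(p.tool, set()).add(p.sample_id)
        if policy == "replicated_either_tool":
            ok = any(len(samples) >= 2 for samples in supporting.values())
        else:
            per_sample: dict[str, set[str]] = {}
            for p in plist:
                per_sample.setdefault(p.sample_id, set()).add(p.tool)
            ok = any(len(tools) >= 2 for tools in per_sample.values())
        if not ok:
            continue
        site = ConsensusSite(
            transcript_id=tid,
            position=pos,
            kmer=plist[0].kmer,
            supporting=supporting,
            mean_probability=float(np.mean([p.probability for p in plist])),
        )
        summarize_stoichiometry(site, plist)
        sites.append(site)
    return sites


def _merge_nearby(
    by_site: dict[tuple[str, int], list[SitePrediction]], tol: int
) -> dict[tuple[str, int], list[SitePrediction]]:
    merged: dict[tuple[str, int], list[SitePrediction]] = {}
    for tid in sorted({t for t, _ in by_site}):
        positions = sorted(p for t, p in by_site if t == tid)
        cluster: list[int] = []
        for pos in positions:
            if cluster and pos - cluster[-1] > tol:
                _flush(merged, by_site, tid, cluster)
                cluster = []
            cluster.append(pos)
        if cluster:
            _flush(merged, by_site, tid, cluster)
    return merged


def _flush(merged, by_site, tid, cluster) -> None:
    anchor = max(cluster, key=lambda p: (len(by_site[(tid, p)]), -p))
    merged[(tid, anchor)] = [p for pos in cluster for p in by_site[(tid, pos)]]


def summarize_stoichiometry(
    site: ConsensusSite, preds: Iterable[SitePrediction]
) -> ConsensusSite:
    """Fill mean/min/max stoichiometry from supporting mod_ratio values.

    Predictions without a mod_ratio contribute nothing; with no mod_ratio at
    all the fields stay absent (None).
    """
    ratios = [p.mod_ratio for p in preds if p.mod_ratio is not None]
    if ratios:
        site.stoichiometry_mean = float(np.mean(ratios))
        site.stoichiometry_min = float(min(ratios))
        site.stoichiometry_max = float(max(ratios))
    return site


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def epitranscriptome_summary(
    sites: Sequence[ConsensusSite],
    models: Sequence[TranscriptModel],
    n_bins: int = 30,
    tss_window: int = 1000,
    tts_window: int = 1000,
) -> EpitranscriptomeSummary:
    """Region distribution, metagene histogram, and motif PFM of a site set.

    ``n_bins`` must be divisible by 3 so each transcript segment gets an equal
    number of bins. Sites on transcripts absent from the models count toward
    n_sites but are excluded from the histogram (logged).
    """
    if n_bins < 3 or n_bins % 3 != 0:
        raise ValueError("n_bins must be >= 3 and divisible by 3")
    model_index = {m.transcript_id: m for m in models}
    region_index = TranscriptIndex(models, tss_window, tts_window)
    edges = np.linspace(0.0, 3.0, n_bins + 1)
    hist = np.zeros(n_bins, dtype=int)
    region_counts: dict[RegionCategory, int] = {c: 0 for c in RegionCategory}
    pfm = np.zeros((4, 5), dtype=int)
    genes: set[str] = set()
    n_missing = 0

    for site in sites:
        kmer = site.kmer.upper().replace("U", "T")
        for j, base in enumerate(kmer):
            pfm[_BASE_INDEX[base], j] += 1
        model = model_index.get(site.transcript_id)
        if model is None:
            n_missing += 1
            region_counts[RegionCategory.INTERGENIC] += 1
            continue
        genes.add(model.gene_id)
        coord = metagene_coordinate(site.position, model)
        site.metagene_coord = coord
        b = min(int(coord / 3.0 * n_bins), n_bins - 1)
        hist[b] += 1
        gpos = model.to_genomic(site.position)
        site.region = region_index.annotate(model.chrom, gpos)
        region_counts[site.region] += 1

    if n_missing:
        logger.warning("%d site(s) on transcripts absent from models", n_missing)
    return EpitranscriptomeSummary(
        n_sites=len(sites),
        n_genes=len(genes),
        region_counts={c: n for c, n in region_counts.items() if n > 0},
        metagene_histogram=hist,
        metagene_bin_edges=edges,
        motif_pfm=pfm,
    )


def modified_gene_set(
    sites: Sequence[ConsensusSite],
    models: Sequence[TranscriptModel],
    name: str = "m6a_modified",
) -> GeneSet:
    """Genes carrying at least one consensus site."""
    model_index = {m.transcript_id: m.gene_id for m in models}
    genes = {
        model_index[s.transcript_id] for s in sites if s.transcript_id in model_index
    }
    if not genes:
        raise ValueError("no consensus site maps to a known gene")
    return GeneSet(name, frozenset(genes))


def write_consensus_bed(sites: Sequence[ConsensusSite],
                        models: Sequence[TranscriptModel], path) -> None:
    """BED6 of consensus sites in genomic coordinates.

    name = transcript:position, score = round(1000 * mean probability).
    """
    model_index = {m.transcript_id: m for m in models}
    with open(path, "w") as fh:
        for s in sites:
            m = model_index.get(s.transcript_id)
            if m is None:
                continue
            g = m.to_genomic(s.position)
            fh.write(
                f"{m.chrom}\t{g}\t{g + 1}\t{s.transcript_id}:{s.position}\t"
                f"{round(1000 * s.mean_probability)}\t{m.strand}\n"
            )


def write_consensus_tsv(sites: Sequence[ConsensusSite], path) -> None:
    rows = []
    for s in sites:
        rows.append(
            {
                "transcript_id": s.transcript_id,
                "position": s.position,
                "kmer": s.kmer,
                "supporting": ";".join(
                    f"{tool}:{','.join(sorted(samples))}"
                    for tool, samples in sorted(s.supporting.items())
                ),
                "stoichiometry_mean": s.stoichiometry_mean,
                "stoichiometry_min": s.stoichiometry_min,
                "stoichiometry_max": s.stoichiometry_max,
                "region": s.region.value if s.region else None,
                "metagene_coord": s.metagene_coord,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
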