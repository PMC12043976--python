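"""Transcript models, genomic coordinates, region annotation, and the DRACH motif.

All coordinates are 0-based, half-open internally. Transcript coordinates run
5'->3' along the spliced mRNA; the mapping between transcript and genomic
position is a strand-aware bijection over the exon union.

The metagene coordinate rescales each transcript so that the 5'UTR, CDS, and
3'UTR occupy [0,1), [1,2), and [2,3) respectively; the stop codon therefore
sits at coordinate 2.0, which is where m6A sites cluster in mammalian mRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "RegionCategory",
    "GeneSet",
    "load_transcript_models",
    "read_gene_set",
    "annotate_feature",
    "metagene_coordinate",
    "is_drach",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a stranded chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class RegionCategory(str, Enum):
    """Genomic region classes used for peak and m6A-site annotation.

    Precedence when several apply (promoter-first convention):
    TSS > TTS > 5UTR_Exon > 3UTR_Exon > Exon(CDS) > Intronic > Intergenic.
    """

    TSS = "TSS"
    TTS = "TTS"
    UTR5_EXON = "5UTR_Exon"
    UTR3_EXON = "3UTR_Exon"
    EXON_CDS = "Exon(CDS)"
    INTRONIC = "Intronic"
    INTERGENIC = "Intergenic"


_PRECEDENCE = {
    RegionCategory.TSS: 0,
    RegionCategory.TTS: 1,
    RegionCategory.UTR5_EXON: 2,
    RegionCategory.UTR3_EXON: 3,
    RegionCategory.EXON_CDS: 4,
    RegionCategory.INTRONIC: 5,
    RegionCategory.INTERGENIC: 6,
}


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members


@dataclass
class TranscriptModel:
    """Exon architecture plus the 5'UTR/CDS/3'UTR partition of a transcript.

    ``exons`` are ordered 5'->3' (descending genomic coordinate on the minus
    strand). ``utr5_len + cds_len + utr3_len`` must equal the summed exon
    length, and transcript<->genomic mapping is a bijection over
    [0, total length).
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: exons span chrom/strand")
        for a, b in zip(self.exons, self.exons[1:]):
            ordered = a.end <= b.start if self.strand == "+" else b.end <= a.start
            if not ordered:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are not 5'->3' ordered"
                )
        if min(self.utr5_len, self.cds_len, self.utr3_len) < 0:
            raise ValueError(f"{self.transcript_id}: negative segment length")
        if self.utr5_len + self.cds_len + self.utr3_len != self.length:
            raise ValueError(
                f"{self.transcript_id}: UTR/CDS partition "
                f"({self.utr5_len}+{self.cds_len}+{self.utr3_len}) does not sum "
                f"to exon length {self.length}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        """Genomic footprint from first to last exonic base."""
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def gene_start(self) -> int:
        """Genomic position of the transcription start (strand-aware)."""
        first = self.exons[0]
        return first.start if self.strand == "+" else first.end - 1

    @property
    def gene_end(self) -> int:
        """Genomic position of the transcription termination site."""
        last = self.exons[-1]
        return last.end - 1 if self.strand == "+" else last.start

    def to_genomic(self, transcript_pos: int) -> int:
        """Map a transcript coordinate to its genomic position."""
        if not 0 <= transcript_pos < self.length:
            raise ValueError(
                f"{self.transcript_id}: transcript position {transcript_pos} "
                f"outside [0, {self.length})"
            )
        remaining = transcript_pos
        for exon in self.exons:
            if remaining < len(exon):
                if self.strand == "+":
                    return exon.start + remaining
                return exon.end - 1 - remaining
            remaining -= len(exon)
        raise AssertionError("unreachable")

    def to_transcript(self, genomic_pos: int) -> int:
        """Inverse of :meth:`to_genomic`; raises if the base is not exonic."""
        offset = 0
        for exon in self.exons:
            if exon.start <= genomic_pos < exon.end:
                if self.strand == "+":
                    return offset + (genomic_pos - exon.start)
                return offset + (exon.end - 1 - genomic_pos)
            offset += len(exon)
        raise ValueError(
            f"{self.transcript_id}: genomic position {genomic_pos} is not exonic"
        )


def is_drach(kmer: str) -> bool:
    """True iff the 5-mer matches the DRACH consensus.

    D = A/T/G, R = A/G, the central base is the candidate A, the fourth base
    is C, and H = A/T/C. U is treated as T. Exactly 18 of the 1,024 5-mers
    match.
    """
    if len(kmer) != 5:
        raise ValueError(f"kmer must have length 5, got {kmer!r}")
    k = kmer.upper().replace("U", "T")
    if any(b not in "ACGT" for b in k):
        raise ValueError(f"kmer contains non-ACGT(U) characters: {kmer!r}")
    return (
        k[0] in "ATG"
        and k[1] in "AG"
        and k[2] == "A"
        and k[3] == "C"
        and k[4] in "ATC"
    )


def metagene_coordinate(transcript_pos: int, model: TranscriptModel) -> float:
    """Rescale a transcript position onto the 3-unit metagene axis.

    5'UTR -> [0,1), CDS -> [1,2), 3'UTR -> [2,3); the stop-codon boundary is
    exactly 2.0.
    """
    if model.cds_len <= 0:
        raise ValueError(f"{model.transcript_id}: non-coding model (cds_len=0)")
    if not 0 <= transcript_pos < model.length:
        raise ValueError(
            f"transcript position {transcript_pos} outside [0, {model.length})"
        )
    u5, cds, u3 = model.utr5_len, model.cds_len, model.utr3_len
    if transcript_pos < u5:
        return transcript_pos / u5
    if transcript_pos < u5 + cds:
        return 1.0 + (transcript_pos - u5) / cds
    return 2.0 + (transcript_pos - u5 - cds) / u3


def _category_for_transcript(
    point: int, model: TranscriptModel, tss_window: int, tts_window: int
) -> tuple[RegionCategory, int]:
    """Category of one point against one transcript, plus feature distance.

    Distance is 0 when the point is inside the transcript span or a TSS/TTS
    window, otherwise the gap to the nearest such position.
    """
    if abs(point - model.gene_start) <= tss_window:
        return RegionCategory.TSS, 0
    if abs(point - model.gene_end) <= tts_window:
        return RegionCategory.TTS, 0
    span = model.span
    if span.start <= point < span.end:
        try:
            tpos = model.to_transcript(point)
        except ValueError:
            return RegionCategory.INTRONIC, 0
        if tpos < model.utr5_len:
            return RegionCategory.UTR5_EXON, 0
        if tpos < model.utr5_len + model.cds_len:
            return RegionCategory.EXON_CDS, 0
        return RegionCategory.UTR3_EXON, 0
    dist = span.start - point if point < span.start else point - (span.end - 1)
    dist = max(0, dist - max(tss_window, tts_window))
    return RegionCategory.INTERGENIC, dist


def annotate_feature(
    feature: GenomicInterval | tuple[str, int],
    models: Sequence[TranscriptModel],
    tss_window: int = 1000,
    tts_window: int = 1000,
) -> RegionCategory:
    """Assign exactly one region category to a point or interval midpoint.

    Intervals are annotated by their midpoint. Among transcripts at minimal
    feature distance the highest-precedence category wins (TSS > TTS > 5'UTR >
    3'UTR > CDS > Intronic > Intergenic); remaining ties are broken by
    lexicographic transcript_id, making the output deterministic. A chromosome
    absent from the models yields Intergenic.
    """
    if tss_window < 0 or tts_window < 0:
        raise ValueError("windows must be >= 0")
    if isinstance(feature, GenomicInterval):
        chrom, point = feature.chrom, feature.midpoint
    else:
        chrom, point = feature
    candidates = [m for m in models if m.chrom == chrom]
    if not candidates:
        logger.debug("chromosome %s absent from models; Intergenic", chrom)
        return RegionCategory.INTERGENIC
    scored = sorted(
        (
            (dist, _PRECEDENCE[cat], m.transcript_id, cat)
            for m in candidates
            for cat, dist in [_category_for_transcript(point, m, tss_window, tts_window)]
        )
    )
    return scored[0][3]


class TranscriptIndex:
    """Per-chromosome interval index for repeated region annotation.

    Produces the same categories as :func:`annotate_feature` but restricts
    the scan to transcripts whose (window-padded) span can contain the query
    point, which matters when annotating thousands of sites against
    thousands of models.
    """

    def __init__(
        self,
        models: Sequence[TranscriptModel],
        tss_window: int = 1000,
        tts_window: int = 1000,
    ) -> None:
        if tss_window < 0 or tts_window < 0:
            raise ValueError("windows must be >= 0")
        self.tss_window = tss_window
        self.tts_window = tts_window
        self._pad = max(tss_window, tts_window)
        self._by_chrom: dict[str, tuple[list[int], list[int], list[TranscriptModel]]] = {}
        grouped: dict[str, list[TranscriptModel]] = {}
        for m in models:
            grouped.setdefault(m.chrom, []).append(m)
        for chrom, ms in grouped.items():
            ms.sort(key=lambda m: m.span.start)
            starts = [m.span.start for m in ms]
            cummax_end: list[int] = []
            cur = 0
            for m in ms:
                cur = max(cur, m.span.end)
                cummax_end.append(cur)
            self._by_chrom[chrom] = (starts, cummax_end, ms)

    def annotate(self, chrom: str, point: int) -> RegionCategory:
        import bisect

        entry = self._by_chrom.get(chrom)
        if entry is None:
            return RegionCategory.INTERGENIC
        starts, cummax_end, ms = entry
        hi = bisect.bisect_right(starts, point + self._pad)
        best: tuple[int, int, str, RegionCategory] | None = None
        for i in range(hi - 1, -1, -1):
            if cummax_end[i] + self._pad < point:
                break  # no earlier span can reach the point
            m = ms[i]
            cat, dist = _category_for_transcript(
                point, m, self.tss_window, self.tts_window
            )
            key = (dist, _PRECEDENCE[cat], m.transcript_id, cat)
            if best is None or key < best:
                best = key
        if best is None or best[0] > 0:
            # nothing overlaps: Intergenic regardless of nearest-gene distance
            return RegionCategory.INTERGENIC if best is None else best[3]
        return best[3]


def _parse_int_list(text: str) -> list[int]:
    return [int(tok) for tok in text.strip().rstrip(",").split(",") if tok.strip()]


def load_transcript_models(path_or_lines) -> list[TranscriptModel]:
    """Read transcript models from a tab-delimited table.

    Columns: transcript_id, gene_id, chrom, strand, exonStarts, exonEnds,
    cdsStart, cdsEnd (exon lists comma-separated, UCSC style; coordinates
    0-based half-open). Duplicate transcript_ids are rejected; a CDS outside
    the exon union is a validation error.
    """
    if hasattr(path_or_lines, "read"):
        lines = path_or_lines.read().splitlines()
    elif isinstance(path_or_lines, (list, tuple)):
        lines = list(path_or_lines)
    else:
        with open(path_or_lines) as fh:
            lines = fh.read().splitlines()

    models: list[TranscriptModel] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0] == "transcript_id":  # header
            continue
        if len(fields) < 8:
            raise ValueError(f"row {lineno}: expected 8 columns, got {len(fields)}")
        tid, gid, chrom, strand = fields[:4]
        if tid in seen:
            raise ValueError(f"row {lineno}: duplicate transcript_id {tid!r}")
        seen.add(tid)
        try:
            starts = _parse_int_list(fields[4])
            ends = _parse_int_list(fields[5])
            cds_start, cds_end = int(fields[6]), int(fields[7])
        except ValueError as exc:
            raise ValueError(f"row {lineno} ({tid}): malformed exon blocks: {exc}")
        if len(starts) != len(ends):
            raise ValueError(
                f"row {lineno} ({tid}): exonStarts/exonEnds length mismatch"
            )
        try:
            genomic_order = [
                GenomicInterval(chrom, s, e, strand) for s, e in zip(starts, ends)
            ]
        except ValueError as exc:
            raise ValueError(f"row {lineno} ({tid}): {exc}")
        exons = genomic_order if strand == "+" else list(reversed(genomic_order))

        # Map genomic CDS span into transcript coordinates to get the partition.
        total = sum(len(e) for e in exons)
        if cds_end <= cds_start:
            raise ValueError(f"row {lineno} ({tid}): empty CDS span")
        probe = TranscriptModel(tid, gid, exons, 0, total, 0)
        try:
            t_a = probe.to_transcript(cds_start)
            t_b = probe.to_transcript(cds_end - 1)
        except ValueError:
            raise ValueError(
                f"row {lineno} ({tid}): CDS [{cds_start},{cds_end}) outside exon union"
            )
        t_first, t_last = min(t_a, t_b), max(t_a, t_b)
        utr5 = t_first
        cds = t_last - t_first + 1
        utr3 = total - utr5 - cds
        models.append(TranscriptModel(tid, gid, exons, utr5, cds, utr3))
    return models


def load_transcript_models_bed12(path_or_lines) -> list[TranscriptModel]:
    """Read transcript models from BED12.

    The name field supplies both ids as ``transcript_id|gene_id`` (a bare
    name is used for both). thickStart/thickEnd give the CDS span; block
    offsets are relative to chromStart, per the BED specification.
    """
    if isinstance(path_or_lines, (list, tuple)):
        lines = list(path_or_lines)
    else:
        with open(path_or_lines) as fh:
            lines = fh.read().splitlines()
    rows = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 12:
            raise ValueError(f"row {lineno}: BED12 needs 12 columns, got {len(f)}")
        chrom, start, _end, name, _score, strand = f[:6]
        thick_start, thick_end = int(f[6]), int(f[7])
        sizes = _parse_int_list(f[10])
        offsets = _parse_int_list(f[11])
        if len(sizes) != len(offsets) or len(sizes) != int(f[9]):
            raise ValueError(f"row {lineno} ({name}): inconsistent block lists")
        tid, _, gid = name.partition("|")
        gid = gid or tid
        starts = [int(start) + o for o in offsets]
        ends = [s + z for s, z in zip(starts, sizes)]
        rows.append(
            "\t".join(
                [tid, gid, chrom, strand,
                 ",".join(map(str, starts)), ",".join(map(str, ends)),
                 str(thick_start), str(thick_end)]
            )
        )
    return load_transcript_models(rows)


def packaged_risk_gene_set() -> GeneSet:
    """Synthetic 81-name stand-in for a curated ALS risk-gene panel.

    Useful for tests and demos where only the set size matters; real
    analyses should load their own curated list with :func:`read_gene_set`.
    """
    from importlib import resources

    text = (
        resources.files("epimn.data")
        .joinpath("als_risk_genes_synthetic.txt")
        .read_text()
    )
    return read_gene_set(text.splitlines(), name="als_risk_synthetic")


def read_gene_set(path_or_lines, name: str = "gene_set") -> GeneSet:
    """Read one gene_id per line; '#' starts a comment."""
    if isinstance(path_or_lines, (list, tuple)):
        lines = list(path_or_lines)
    else:
        with open(path_or_lines) as fh:
            lines = fh.read().splitlines()
    members = {
        line.strip() for line in lines if line.strip() and not line.startswith("#")
    }
    return GeneSet(name, frozenset(members))
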