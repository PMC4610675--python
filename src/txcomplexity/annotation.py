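"""In-memory transcript annotation model.

Parses GTF and UCSC refFlat/refGene tables into a locus -> transcript ->
exon hierarchy.  All coordinates are 0-based half-open internally; GTF's
1-based closed convention is converted at the parsing boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "AnnotationError",
    "ParseError",
    "ExonInterval",
    "TranscriptModel",
    "Locus",
    "GenomeAnnotation",
    "GeneList",
    "build_annotation",
    "read_gtf",
    "write_gtf",
    "read_refflat",
    "write_refflat",
    "locus_length",
    "filter_loci",
    "load_gene_list",
]


class AnnotationError(ValueError):
    """Invalid annotation content or request."""


class ParseError(AnnotationError):
    """Malformed input file; carries a line number where possible."""


@dataclass(frozen=True, order=True)
class ExonInterval:
    """A genomic exon as a 0-based half-open interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise AnnotationError(f"negative exon start {self.start}")
        if self.end <= self.start:
            raise AnnotationError(
                f"exon end must exceed start: [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """An ordered, non-overlapping chain of exons on one strand.

    ``exons`` are stored in genomic (ascending-start) order regardless of
    strand; transcript orientation is derived from ``strand`` where needed.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: tuple[ExonInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        prev_end = -1
        for e in exons:
            if e.chrom != self.chrom:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon on {e.chrom}, "
                    f"transcript on {self.chrom}"
                )
            if e.start < prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            prev_end = e.end

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def mature_length(self) -> int:
        """Summed exon length (mRNA length)."""
        return sum(e.length for e in self.exons)

    def structure_key(self) -> tuple:
        """Strand- and coordinate-level identity of the exon chain."""
        return (self.chrom, self.strand, tuple((e.start, e.end) for e in self.exons))


@dataclass
class Locus:
    """All transcripts sharing one gene symbol, with their genomic span."""

    gene_symbol: str
    chrom: str
    strand: str
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    @property
    def span_start(self) -> int:
        return min(t.start for t in self.transcripts.values())

    @property
    def span_end(self) -> int:
        return max(t.end for t in self.transcripts.values())

    @property
    def length(self) -> int:
        return self.span_end - self.span_start

    @property
    def transcript_count(self) -> int:
        return len(self.transcripts)

    def add(self, transcript: TranscriptModel) -> None:
        if transcript.gene_symbol != self.gene_symbol:
            raise AnnotationError("gene symbol mismatch")
        if transcript.transcript_id in self.transcripts:
            existing = self.transcripts[transcript.transcript_id]
            if existing.structure_key() != transcript.structure_key():
                log.warning(
                    "duplicate transcript id %s with different structure; "
                    "keeping first",
                    transcript.transcript_id,
                )
            return
        self.transcripts[transcript.transcript_id] = transcript

    def sorted_transcripts(self) -> list[TranscriptModel]:
        return [self.transcripts[k] for k in sorted(self.transcripts)]


@dataclass
class GenomeAnnotation:
    """Mapping of gene symbol to :class:`Locus`."""

    loci: dict[str, Locus] = field(default_factory=dict)
    source_tag: str = "unknown"

    def __len__(self) -> int:
        return len(self.loci)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.loci

    def __getitem__(self, symbol: str) -> Locus:
        return self.loci[symbol]

    def symbols(self) -> list[str]:
        return sorted(self.loci)

    def transcript_count(self, symbol: str) -> int:
        return self.loci[symbol].transcript_count

    def transcript_counts(self) -> dict[str, int]:
        return {s: l.transcript_count for s, l in self.loci.items()}

    def locus_lengths(self) -> dict[str, int]:
        return {s: l.length for s, l in self.loci.items()}


def build_annotation(
    transcripts: Iterable[TranscriptModel], source_tag: str = "unknown"
) -> GenomeAnnotation:
    """Group transcripts into loci, applying the tie-break conventions.

    Duplicate transcript ids keep the first occurrence.  A symbol annotated
    on several chromosomes keeps the chromosome with the most transcripts
    (ties: lexicographically smallest chromosome); the rest is dropped with
    a warning.
    """
    by_gene: dict[str, dict[str, dict[str, TranscriptModel]]] = {}
    for t in transcripts:
        chroms = by_gene.setdefault(t.gene_symbol, {})
        txs = chroms.setdefault(t.chrom, {})
        if t.transcript_id in txs:
            if txs[t.transcript_id].structure_key() != t.structure_key():
                log.warning(
                    "duplicate transcript id %s with different structure; "
                    "keeping first",
                    t.transcript_id,
                )
            continue
        txs[t.transcript_id] = t

    loci: dict[str, Locus] = {}
    for symbol, chroms in by_gene.items():
        if len(chroms) > 1:
            chosen = sorted(chroms, key=lambda c: (-len(chroms[c]), c))[0]
            log.warning(
                "gene %s annotated on %d chromosomes; keeping %s",
                symbol,
                len(chroms),
                chosen,
            )
        else:
            (chosen,) = chroms
        txs = chroms[chosen]
        strand = next(iter(txs.values())).strand
        locus = Locus(gene_symbol=symbol, chrom=chosen, strand=strand)
        for t in txs.values():
            locus.add(t)
        loci[symbol] = locus
    return GenomeAnnotation(loci=loci, source_tag=source_tag)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(raw: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(raw))


def read_gtf(path: str | Path, source_tag: str = "gtf") -> GenomeAnnotation:
    """Read exon features from a GTF file into a :class:`GenomeAnnotation`.

    Gene symbols come from the ``gene_name`` attribute, falling back to
    ``gene_id``.  1-based closed GTF coordinates are converted to 0-based
    half-open.
    """
    exons: dict[str, list[ExonInterval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = (
                fields[:9]
            )
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start1 > end1:
                raise ParseError(
                    f"{path}:{lineno}: rejected record, exon start > end"
                )
            attr = _parse_gtf_attributes(attrs)
            tid = attr.get("transcript_id")
            gene = attr.get("gene_name") or attr.get("gene_id")
            if not tid or not gene:
                raise ParseError(
                    f"{path}:{lineno}: exon lacks transcript_id/gene attribute"
                )
            key = tid
            if key in meta and meta[key][0] != gene:
                raise ParseError(
                    f"{path}:{lineno}: transcript {tid} assigned to several genes"
                )
            meta.setdefault(key, (gene, chrom, strand))
            exons.setdefault(key, []).append(
                ExonInterval(chrom=chrom, start=start1 - 1, end=end1)
            )
    transcripts = []
    for tid, (gene, chrom, strand) in meta.items():
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_symbol=gene,
                chrom=chrom,
                strand=strand,
                exons=tuple(exons[tid]),
            )
        )
    return build_annotation(transcripts, source_tag=source_tag)


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write exon features (1-based closed coordinates) for round-tripping."""
    with open(path, "w") as fh:
        for symbol in sorted(annotation.loci):
            locus = annotation.loci[symbol]
            for t in locus.sorted_transcripts():
                for e in t.exons:
                    attrs = (
                        f'gene_id "{symbol}"; gene_name "{symbol}"; '
                        f'transcript_id "{t.transcript_id}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                t.chrom,
                                "txc",
                                "exon",
                                str(e.start + 1),
                                str(e.end),
                                ".",
                                t.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# refFlat / refGene
# ---------------------------------------------------------------------------


def read_refflat(path: str | Path, source_tag: str = "refflat") -> GenomeAnnotation:
    """Read a UCSC refFlat table (0-based half-open, taken verbatim)."""
    transcripts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ParseError(f"{path}:{lineno}: expected 11 fields")
            gene, tid, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            try:
                exon_count = int(fields[8])
                starts = [int(x) for x in fields[9].rstrip(",").split(",")]
                ends = [int(x) for x in fields[10].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer exon fields") from exc
            if len(starts) != exon_count or len(ends) != exon_count:
                raise ParseError(
                    f"{path}:{lineno}: rejected record, exonCount={exon_count} "
                    f"does not match exon lists"
                )
            exons = tuple(
                ExonInterval(chrom=chrom, start=s, end=e)
                for s, e in zip(starts, ends)
            )
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_symbol=gene,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                )
            )
    return build_annotation(transcripts, source_tag=source_tag)


def write_refflat(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for symbol in sorted(annotation.loci):
            for t in annotation.loci[symbol].sorted_transcripts():
                starts = ",".join(str(e.start) for e in t.exons) + ","
                ends = ",".join(str(e.end) for e in t.exons) + ","
                fh.write(
                    "\t".join(
                        [
                            symbol,
                            t.transcript_id,
                            t.chrom,
                            t.strand,
                            str(t.start),
                            str(t.end),
                            str(t.start),
                            str(t.end),
                            str(t.n_exons),
                            starts,
                            ends,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Locus-level helpers
# ---------------------------------------------------------------------------


def locus_length(locus: Locus) -> int:
    """Length of the maximal span covering every transcript of the locus."""
    return locus.length


def filter_loci(
    annotation: GenomeAnnotation,
    max_length: int = 1_000_000,
    min_length: int = 0,
    *,
    return_removed: bool = False,
):
    """Drop loci whose span is strictly above ``max_length`` or strictly
    below ``min_length``.  The boundary values themselves are retained."""
    kept: dict[str, Locus] = {}
    removed: list[str] = []
    for symbol, locus in annotation.loci.items():
        n = locus.length
        if n > max_length or n < min_length:
            removed.append(symbol)
        else:
            kept[symbol] = locus
    if removed:
        log.info("filter_loci removed %d loci: %s", len(removed), sorted(removed)[:20])
    out = GenomeAnnotation(loci=kept, source_tag=annotation.source_tag)
    if return_removed:
        return out, sorted(removed)
    return out


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------


@dataclass
class GeneList:
    """An ordered, duplicate-free list of gene symbols with optional
    per-symbol study-evidence counts (n_positive, n_negative)."""

    name: str
    symbols: tuple[str, ...]
    evidence: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise AnnotationError(f"gene list {self.name} has duplicate symbols")
        if self.evidence is not None:
            for sym, (pos, neg) in self.evidence.items():
                if pos < 0 or neg < 0:
                    raise AnnotationError(f"negative evidence count for {sym}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.symbols)

    def missing_from(self, annotation: GenomeAnnotation) -> list[str]:
        """Symbols absent from the annotation (reported, then skipped by
        downstream statistics)."""
        return [s for s in self.symbols if s not in annotation]

    def present_in(self, annotation: GenomeAnnotation) -> list[str]:
        return [s for s in self.symbols if s in annotation]


def load_gene_list(
    path: str | Path,
    alias_map: Mapping[str, str] | None = None,
    name: str | None = None,
) -> GeneList:
    """Load a plain-text gene list: one symbol per line, optionally followed
    by tab-separated n_positive / n_negative evidence columns.

    Symbols are trimmed, uppercased, alias-mapped and deduplicated (first
    occurrence wins).
    """
    symbols: list[str] = []
    seen: set[str] = set()
    evidence: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            sym = parts[0].strip().upper()
            if alias_map:
                sym = alias_map.get(sym, sym)
            if sym in seen:
                log.warning("%s:%d: duplicate symbol %s kept once", path, lineno, sym)
                continue
            seen.add(sym)
            symbols.append(sym)
            if len(parts) >= 3:
                try:
                    evidence[sym] = (int(parts[1]), int(parts[2]))
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer evidence columns"
                    ) from exc
    if not symbols:
        raise AnnotationError(f"gene list file {path} contains no symbols")
    return GeneList(
        name=name or Path(path).stem,
        symbols=tuple(symbols),
        evidence=evidence or None,
    )
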