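"""GC-content windows at transcript boundaries and canonical splice motifs.

Five boundary classes are profiled: the transcription start site (TSS), the
first donor and first acceptor splice sites (Donor / Accept) and all
subsequent internal donors and acceptors (DonorMid / AcceptMid).  Windows
are centred on the boundary, half upstream and half downstream, and are
reported in transcript (sense-strand) orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .annotation import GeneList, GenomeAnnotation, TranscriptModel

log = logging.getLogger(__name__)

__all__ = [
    "TSS",
    "DONOR",
    "ACCEPT",
    "DONOR_MID",
    "ACCEPT_MID",
    "REGION_CLASSES",
    "DONOR_MOTIFS",
    "ACCEPTOR_MOTIFS",
    "GCProfile",
    "DictGenome",
    "FastaGenome",
    "as_genome",
    "reverse_complement",
    "boundary_centers",
    "boundary_windows",
    "junction_windows",
    "gc_percent",
    "gc_profile",
    "donor_acceptor_gap",
    "canonical_site_fractions",
]

TSS = "TSS"
DONOR = "Donor"
ACCEPT = "Accept"
DONOR_MID = "DonorMid"
ACCEPT_MID = "AcceptMid"
REGION_CLASSES = (TSS, DONOR, ACCEPT, DONOR_MID, ACCEPT_MID)

DONOR_MOTIFS = ("GGTAA", "GGTGA")
ACCEPTOR_MOTIFS = ("CAGGT", "TAGGT")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class DictGenome:
    """Genome accessor over an in-memory chrom -> sequence mapping."""

    def __init__(self, sequences: Mapping[str, str]) -> None:
        self._seq = dict(sequences)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self._seq[chrom][start:end].upper()

    def length(self, chrom: str) -> int:
        return len(self._seq[chrom])

    def chroms(self) -> list[str]:
        return sorted(self._seq)


class FastaGenome:
    """Genome accessor over an indexed FASTA file (via pyfaidx)."""

    def __init__(self, path: str | Path) -> None:
        import pyfaidx

        self._fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self._fa[chrom][start:end])

    def length(self, chrom: str) -> int:
        return len(self._fa[chrom])


def as_genome(obj):
    if hasattr(obj, "fetch") and hasattr(obj, "length"):
        return obj
    if isinstance(obj, Mapping):
        return DictGenome(obj)
    return FastaGenome(obj)


@dataclass
class GCProfile:
    """Per-region mean GC percent and pooled window counts."""

    mean_gc: dict
    n_windows: dict

    def __post_init__(self) -> None:
        for cls, gc in self.mean_gc.items():
            if not (0.0 <= gc <= 100.0):
                raise ValueError(f"mean GC out of range for {cls}: {gc}")


# ---------------------------------------------------------------------------
# Boundary geometry
# ---------------------------------------------------------------------------


def boundary_centers(transcript: TranscriptModel) -> dict[str, list[int]]:
    """Genomic coordinates of each boundary class, in transcript order.

    Donors are exon 3' (transcript-orientation) boundaries, acceptors exon
    5' boundaries.  Single-exon transcripts yield only a TSS.  The last
    exon's acceptor is excluded from AcceptMid.
    """
    ex = transcript.exons
    n = len(ex)
    if transcript.strand == "+":
        tss = ex[0].start
        donors = [e.end for e in ex[:-1]]
        acceptors = [e.start for e in ex[1:]]
    else:
        tss = ex[-1].end
        donors = [e.start for e in reversed(ex[1:])]
        acceptors = [e.end for e in reversed(ex[:-1])]
    centers: dict[str, list[int]] = {
        TSS: [tss],
        DONOR: [],
        ACCEPT: [],
        DONOR_MID: [],
        ACCEPT_MID: [],
    }
    if n >= 2:
        centers[DONOR] = donors[:1]
        centers[ACCEPT] = acceptors[:1]
        centers[DONOR_MID] = donors[1:]
        centers[ACCEPT_MID] = acceptors[1:-1] if n >= 3 else []
    return centers


def _extract(genome, transcript: TranscriptModel, center: int, window: int) -> str | None:
    half = window // 2
    lo, hi = center - half, center + half
    if lo < 0 or hi > genome.length(transcript.chrom):
        log.warning(
            "window at %s:%d within %d nt of contig edge; dropped",
            transcript.chrom,
            center,
            half,
        )
        return None
    seq = genome.fetch(transcript.chrom, lo, hi)
    return seq if transcript.strand == "+" else reverse_complement(seq)


def boundary_windows(
    transcript: TranscriptModel, genome, window: int = 60
) -> dict[str, list[str]]:
    """Sense-orientation sequence windows centred on each boundary class."""
    if window % 2:
        raise ValueError("window size must be even")
    genome = as_genome(genome)
    out: dict[str, list[str]] = {}
    for cls, centers in boundary_centers(transcript).items():
        seqs = []
        for c in centers:
            s = _extract(genome, transcript, c, window)
            if s is not None:
                seqs.append(s)
        out[cls] = seqs
    return out


def junction_windows(
    transcript: TranscriptModel, genome, window: int = 60
) -> tuple[list[str], list[str]]:
    """All donor-side and acceptor-side junction windows of a transcript
    (the first exon's 5' and the last exon's 3' regions carry no junction
    and are excluded by construction)."""
    genome = as_genome(genome)
    centers = boundary_centers(transcript)
    donors = centers[DONOR] + centers[DONOR_MID]
    ex = transcript.exons
    if transcript.strand == "+":
        acceptors = [e.start for e in ex[1:]]
    else:
        acceptors = [e.end for e in reversed(ex[:-1])]
    d = [s for c in donors if (s := _extract(genome, transcript, c, window))]
    a = [s for c in acceptors if (s := _extract(genome, transcript, c, window))]
    return d, a


# ---------------------------------------------------------------------------
# GC statistics
# ---------------------------------------------------------------------------


def gc_percent(seq: str) -> float:
    """GC percent with N bases excluded from numerator and denominator."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    denom = len(s) - s.count("N")
    if denom == 0:
        raise ValueError("all-N sequence has undefined GC content")
    return 100.0 * (s.count("G") + s.count("C")) / denom


def gc_profile(
    gene_list: GeneList | Sequence[str],
    annotation: GenomeAnnotation,
    genome,
    window: int = 60,
) -> GCProfile:
    """Pool boundary windows across every transcript of every list locus
    and average GC per region class."""
    genome = as_genome(genome)
    sums = {cls: 0.0 for cls in REGION_CLASSES}
    counts = {cls: 0 for cls in REGION_CLASSES}
    for symbol in gene_list:
        if symbol not in annotation:
            continue
        for t in annotation.loci[symbol].sorted_transcripts():
            for cls, seqs in boundary_windows(t, genome, window=window).items():
                for s in seqs:
                    try:
                        g = gc_percent(s)
                    except ValueError:
                        continue
                    sums[cls] += g
                    counts[cls] += 1
    mean_gc = {
        cls: (sums[cls] / counts[cls]) for cls in REGION_CLASSES if counts[cls]
    }
    return GCProfile(mean_gc=mean_gc, n_windows=counts)


def donor_acceptor_gap(profile: GCProfile, mode: str = "donor_accept") -> float:
    """Signed GC gap across the first intron.

    ``donor_accept`` (default): mean GC(Donor) - mean GC(Accept).
    ``tss_accept``: mean GC(TSS) - mean GC(Accept) (alternative reading).
    """
    first = TSS if mode == "tss_accept" else DONOR
    for cls in (first, ACCEPT):
        if cls not in profile.mean_gc:
            raise ValueError(f"profile lacks region class {cls}")
    return profile.mean_gc[first] - profile.mean_gc[ACCEPT]


# ---------------------------------------------------------------------------
# Canonical splice motifs
# ---------------------------------------------------------------------------


def _contains_any(seq: str, motifs: Sequence[str]) -> bool:
    return any(m in seq for m in motifs)


def canonical_site_fractions(
    gene_list: GeneList | Sequence[str],
    annotation: GenomeAnnotation,
    genome,
    window: int = 60,
) -> tuple[float, float]:
    """Percent of donor-side and acceptor-side junction windows containing
    a canonical motif (GGTAA/GGTGA donors, CAGGT/TAGGT acceptors)."""
    genome = as_genome(genome)
    donor_hits = donor_total = 0
    acc_hits = acc_total = 0
    for symbol in gene_list:
        if symbol not in annotation:
            continue
        for t in annotation.loci[symbol].sorted_transcripts():
            d, a = junction_windows(t, genome, window=window)
            donor_total += len(d)
            acc_total += len(a)
            donor_hits += sum(_contains_any(s, DONOR_MOTIFS) for s in d)
            acc_hits += sum(_contains_any(s, ACCEPTOR_MOTIFS) for s in a)
    donor_pct = 100.0 * donor_hits / donor_total if donor_total else float("nan")
    acc_pct = 100.0 * acc_hits / acc_total if acc_total else float("nan")
    return donor_pct, acc_pct


# statistic registration ----------------------------------------------------

from .enrichment import register_statistic  # noqa: E402


@register_statistic("donor_acceptor_gap")
def _gap_factory(annotation: GenomeAnnotation, genome, window: int = 60, mode: str = "donor_accept", **_):
    genome = as_genome(genome)

    def stat(symbols: Sequence[str]) -> float:
        return donor_acceptor_gap(
            gc_profile(symbols, annotation, genome, window=window), mode=mode
        )

    return stat
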