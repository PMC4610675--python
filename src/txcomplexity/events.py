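"""Pairwise splice-event enumeration and classification.

Each transcript is reduced to its chain of internal splice sites (donor =
exon 3' boundary, acceptor = exon 5' boundary, strand-aware).  For every
transcript pair, within the genomic interval where both overlap, each
maximal run of sites present in exactly one chain — flanked by sites common
to both — is a single event, classified as skipped_exon, alt_donor,
alt_acceptor, or other.  Events are deduplicated locus-wide by coordinate
signature.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .annotation import GeneList, GenomeAnnotation, Locus, TranscriptModel
from .enrichment import (
    BootstrapResult,
    bootstrap_enrichment,
    register_statistic,
)

log = logging.getLogger(__name__)

__all__ = [
    "EVENT_TYPES",
    "SpliceEvent",
    "EventProportions",
    "internal_splice_sites",
    "enumerate_events",
    "event_proportions",
    "proportion_enrichment",
]

SKIPPED_EXON = "skipped_exon"
ALT_DONOR = "alt_donor"
ALT_ACCEPTOR = "alt_acceptor"
OTHER = "other"
EVENT_TYPES = (SKIPPED_EXON, ALT_DONOR, ALT_ACCEPTOR, OTHER)

Site = tuple  # (genomic position, 'D' | 'A')


@dataclass(frozen=True)
class SpliceEvent:
    gene_symbol: str
    event_type: str
    signature: tuple  # (differing sites..., left flank, right flank)
    transcript_pair_witness: tuple


@dataclass
class EventProportions:
    fractions: dict
    total_events: int

    def __post_init__(self) -> None:
        if self.total_events > 0:
            s = sum(self.fractions.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"event fractions sum to {s}")


def internal_splice_sites(transcript: TranscriptModel) -> list[Site]:
    """Internal splice sites sorted by (position, role); transcript termini
    are not sites."""
    ex = transcript.exons
    if transcript.strand == "+":
        sites = [(e.end, "D") for e in ex[:-1]] + [(e.start, "A") for e in ex[1:]]
    else:
        sites = [(e.start, "D") for e in ex[1:]] + [(e.end, "A") for e in ex[:-1]]
    return sorted(sites)


def _exon_coord_set(t: TranscriptModel) -> set[tuple[int, int]]:
    return {(e.start, e.end) for e in t.exons}


def _classify_block(
    block: list[Site],
    only1: set[Site],
    strand: str,
    t1: TranscriptModel,
    t2: TranscriptModel,
    terminal: bool,
) -> str:
    if terminal:
        return OTHER
    a_sites = [s for s in block if s in only1]
    b_sites = [s for s in block if s not in only1]
    # skipped exon: one transcript contributes a complete exon, the other none
    for extra, witness in ((a_sites, t1), (b_sites, t2)):
        partner = b_sites if witness is t1 else a_sites
        if partner or len(extra) != 2:
            continue
        (p1, r1), (p2, r2) = sorted(extra)
        expected = ("A", "D") if strand == "+" else ("D", "A")
        if (r1, r2) == expected and (p1, p2) in _exon_coord_set(witness):
            return SKIPPED_EXON
    if len(a_sites) == 1 and len(b_sites) == 1:
        r1, r2 = a_sites[0][1], b_sites[0][1]
        if r1 == r2 == "D":
            return ALT_DONOR
        if r1 == r2 == "A":
            return ALT_ACCEPTOR
    return OTHER


def enumerate_events(
    locus: Locus, include_terminal: bool = True
) -> list[SpliceEvent]:
    """All deduplicated splice events of a locus.

    Structurally identical transcripts are collapsed first, so duplicating
    a transcript never changes the event set.  Blocks that touch the edge
    of the pairwise overlap interval (terminal variations: alternative
    first/last exons, TSS shifts) are classified ``other`` when
    ``include_terminal`` is true, and dropped otherwise.
    """
    uniq: dict[tuple, TranscriptModel] = {}
    for t in locus.sorted_transcripts():
        uniq.setdefault(t.structure_key(), t)
    transcripts = list(uniq.values())
    events: dict[tuple, SpliceEvent] = {}
    for t1, t2 in combinations(transcripts, 2):
        lo = max(t1.start, t2.start)
        hi = min(t1.end, t2.end)
        if lo >= hi:
            continue
        set1 = {s for s in internal_splice_sites(t1) if lo <= s[0] <= hi}
        set2 = {s for s in internal_splice_sites(t2) if lo <= s[0] <= hi}
        common = set1 & set2
        only1 = set1 - set2
        merged = sorted(set1 | set2)
        # shared transcript termini act as flanking sites
        left_flank = ("start", lo) if t1.start == t2.start else None
        right_flank = ("end", hi) if t1.end == t2.end else None
        block: list[Site] = []
        prev: Site | None = left_flank
        for site in merged + [None]:
            if site is None or site in common:
                right = right_flank if site is None else site
                if block:
                    terminal = prev is None or right is None
                    if terminal and not include_terminal:
                        block = []
                        prev = site
                        continue
                    etype = _classify_block(
                        block, only1, locus.strand, t1, t2, terminal
                    )
                    signature = (tuple(block), prev, right)
                    if signature not in events:
                        events[signature] = SpliceEvent(
                            gene_symbol=locus.gene_symbol,
                            event_type=etype,
                            signature=signature,
                            transcript_pair_witness=(
                                t1.transcript_id,
                                t2.transcript_id,
                            ),
                        )
                block = []
                prev = site
            else:
                block.append(site)
    return list(events.values())


def locus_event_counts(
    annotation: GenomeAnnotation,
    symbols: Sequence[str] | None = None,
    include_terminal: bool = True,
) -> dict[str, Counter]:
    """Per-locus event-type counts (cache for bootstrap statistics)."""
    out: dict[str, Counter] = {}
    for s in symbols if symbols is not None else annotation.symbols():
        if s not in annotation:
            continue
        counts = Counter()
        for ev in enumerate_events(annotation.loci[s], include_terminal=include_terminal):
            counts[ev.event_type] += 1
        out[s] = counts
    return out


def event_proportions(
    gene_list: GeneList | Sequence[str],
    annotation: GenomeAnnotation,
    exclude: set[str] | frozenset = frozenset(),
    outlier_event_cap: int | None = None,
    include_terminal: bool = True,
) -> EventProportions:
    """Pool deduplicated events over list loci and normalise per type.

    ``exclude`` drops named loci; ``outlier_event_cap`` drops any locus
    whose total event count exceeds the cap (generalising single-gene
    outlier removal to a reproducible rule).
    """
    totals: Counter = Counter()
    for symbol in gene_list:
        if symbol in exclude or symbol not in annotation:
            continue
        counts = Counter()
        for ev in enumerate_events(
            annotation.loci[symbol], include_terminal=include_terminal
        ):
            counts[ev.event_type] += 1
        n = sum(counts.values())
        if outlier_event_cap is not None and n > outlier_event_cap:
            log.info(
                "locus %s dropped: %d events exceed cap %d",
                symbol,
                n,
                outlier_event_cap,
            )
            continue
        totals.update(counts)
    total = sum(totals.values())
    if total == 0:
        raise ValueError("no splice events among the list loci")
    return EventProportions(
        fractions={t: totals.get(t, 0) / total for t in EVENT_TYPES},
        total_events=total,
    )


@register_statistic("event_fraction")
def _event_fraction_factory(
    annotation: GenomeAnnotation,
    event_type: str,
    include_terminal: bool = True,
    event_counts: Mapping[str, Counter] | None = None,
    **_,
):
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    cache = (
        dict(event_counts)
        if event_counts is not None
        else locus_event_counts(annotation, include_terminal=include_terminal)
    )

    def stat(symbols: Sequence[str]) -> float:
        hits = total = 0
        for s in symbols:
            c = cache.get(s)
            if not c:
                continue
            hits += c.get(event_type, 0)
            total += sum(c.values())
        return hits / total if total else 0.0

    return stat


def proportion_enrichment(
    gene_list: GeneList | Sequence[str],
    pool: GeneList | Sequence[str],
    annotation: GenomeAnnotation,
    event_type: str,
    *,
    n_lists: int = 1000,
    direction: str = "greater",
    tolerance: float = 0.10,
    rng: np.random.Generator | int | None = None,
    include_terminal: bool = True,
    exclude_list_from_pool: bool = True,
) -> BootstrapResult:
    """Length-matched bootstrap of one event type's share of all events."""
    relevant = set(gene_list) | set(pool)
    cache = locus_event_counts(
        annotation,
        [s for s in annotation.symbols() if s in relevant],
        include_terminal=include_terminal,
    )
    return bootstrap_enrichment(
        gene_list,
        pool,
        annotation,
        "event_fraction",
        n_lists=n_lists,
        direction=direction,
        tolerance=tolerance,
        rng=rng,
        exclude_list_from_pool=exclude_list_from_pool,
        statistic_context={
            "event_type": event_type,
            "include_terminal": include_terminal,
            "event_counts": cache,
        },
    )
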