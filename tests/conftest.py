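"""Shared builders and fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from txcomplexity.annotation import (
    ExonInterval,
    GeneList,
    GenomeAnnotation,
    TranscriptModel,
    build_annotation,
)


def make_transcript(tid, gene, exons, strand="+", chrom="chr1"):
    """exons: iterable of (start, end) pairs."""
    return TranscriptModel(
        transcript_id=tid,
        gene_symbol=gene,
        chrom=chrom,
        strand=strand,
        exons=tuple(ExonInterval(chrom=chrom, start=s, end=e) for s, e in exons),
    )


def make_annotation(spec, source_tag="test"):
    """spec: list of (gene, tid, strand, chrom, exon-pairs)."""
    transcripts = [
        make_transcript(tid, gene, exons, strand=strand, chrom=chrom)
        for gene, tid, strand, chrom, exons in spec
    ]
    return build_annotation(transcripts, source_tag=source_tag)


def mirror_transcript(t, contig_len):
    """The same transcript on the opposite strand of the reversed contig."""
    flipped = [(contig_len - e.end, contig_len - e.start) for e in t.exons]
    return make_transcript(
        t.transcript_id,
        t.gene_symbol,
        sorted(flipped),
        strand="-" if t.strand == "+" else "+",
        chrom=t.chrom,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_annotation():
    return make_annotation(
        [
            ("GA", "GA.t0", "+", "chr1", [(100, 200), (300, 400), (500, 600)]),
            ("GA", "GA.t1", "+", "chr1", [(100, 200), (500, 600)]),
            ("GB", "GB.t0", "-", "chr2", [(50, 150), (250, 350)]),
            ("GC", "GC.t0", "+", "chr3", [(0, 1000)]),
        ]
    )


@pytest.fixture
def toy_list():
    return GeneList(name="toy", symbols=("GA", "GB", "GC"))
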