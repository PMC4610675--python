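import bisect
from itertools import combinations

import numpy as np
import pytest

from txcomplexity.annotation import Locus, build_annotation
from txcomplexity.events import (
    ALT_ACCEPTOR,
    ALT_DONOR,
    EVENT_TYPES,
    OTHER,
    SKIPPED_EXON,
    enumerate_events,
    event_proportions,
    proportion_enrichment,
)
from txcomplexity.synth import SyntheticParams, generate_annotation, generate_disease_list

from conftest import make_annotation, make_transcript, mirror_transcript


# ---------------------------------------------------------------------------
# Independent brute-force oracle: enumerate site-set differences directly by
# clustering the symmetric difference between common sites located by bisect.
# ---------------------------------------------------------------------------


def _oracle_sites(t):
    out = set()
    ex = t.exons
    n = len(ex)
    for i, e in enumerate(ex):
        if t.strand == "+":
            if i < n - 1:
                out.add((e.end, "D"))
            if i > 0:
                out.add((e.start, "A"))
        else:
            if i > 0:
                out.add((e.start, "D"))
            if i < n - 1:
                out.add((e.end, "A"))
    return out


def _oracle_classify(cluster, from1, t1, t2, strand):
    a = sorted(s for s in cluster if s in from1)
    b = sorted(s for s in cluster if s not in from1)
    exon_pairs = lambda t: {(e.start, e.end) for e in t.exons}
    for extra, partner, witness in ((a, b, t1), (b, a, t2)):
        if partner:
            continue
        if len(extra) == 2:
            (p1, r1), (p2, r2) = extra
            want = ("A", "D") if strand == "+" else ("D", "A")
            if (r1, r2) == want and (p1, p2) in exon_pairs(witness):
                return SKIPPED_EXON
    if len(a) == 1 and len(b) == 1:
        if a[0][1] == b[0][1] == "D":
            return ALT_DONOR
        if a[0][1] == b[0][1] == "A":
            return ALT_ACCEPTOR
    return OTHER


def oracle_events(locus, include_terminal=True):
    """Returns {(cluster, left, right): type} over all transcript pairs."""
    uniq = {}
    for tid in sorted(locus.transcripts):
        t = locus.transcripts[tid]
        uniq.setdefault((t.chrom, t.strand, tuple((e.start, e.end) for e in t.exons)), t)
    out = {}
    for t1, t2 in combinations(uniq.values(), 2):
        lo, hi = max(t1.start, t2.start), min(t1.end, t2.end)
        if lo >= hi:
            continue
        s1 = {s for s in _oracle_sites(t1) if lo <= s[0] <= hi}
        s2 = {s for s in _oracle_sites(t2) if lo <= s[0] <= hi}
        common = sorted(s1 & s2)
        diff = sorted(s1 ^ s2)
        if not diff:
            continue
        # cluster diff sites: same cluster iff no common site lies between
        clusters = [[diff[0]]]
        for prev, cur in zip(diff, diff[1:]):
            i = bisect.bisect_right(common, prev)
            sep = i < len(common) and common[i] < cur
            if sep:
                clusters.append([cur])
            else:
                clusters[-1].append(cur)
        for cluster in clusters:
            i = bisect.bisect_left(common, cluster[0])
            left = common[i - 1] if i > 0 else (
                ("start", lo) if t1.start == t2.start else None
            )
            j = bisect.bisect_right(common, cluster[-1])
            right = common[j] if j < len(common) else (
                ("end", hi) if t1.end == t2.end else None
            )
            if (left is None or right is None) and not include_terminal:
                continue
            if left is None or right is None:
                etype = OTHER
            else:
                etype = _oracle_classify(cluster, s1, t1, t2, locus.strand)
            out[(tuple(cluster), left, right)] = etype
    return out


def classifier_events(locus, include_terminal=True):
    return {
        ev.signature: ev.event_type
        for ev in enumerate_events(locus, include_terminal=include_terminal)
    }


def random_structural_locus(rng, strand):
    """Adversarial random exon chains over a small coordinate grid."""
    grid = np.arange(0, 400, 10)
    transcripts = []
    for k in range(int(rng.integers(2, 4))):
        n_ex = int(rng.integers(1, 5))
        cuts = sorted(rng.choice(grid, size=2 * n_ex, replace=False))
        exons = [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_ex)]
        transcripts.append(
            make_transcript(f"T{k}", "G", exons, strand=strand, chrom="chr1")
        )
    locus = Locus(gene_symbol="G", chrom="chr1", strand=strand)
    for t in transcripts:
        locus.add(t)
    return locus


# ---------------------------------------------------------------------------


class TestClassifierBasics:
    def test_simple_skipped_exon(self):
        ann = make_annotation(
            [
                ("G", "T1", "+", "chr1", [(0, 100), (200, 300), (400, 500)]),
                ("G", "T2", "+", "chr1", [(0, 100), (400, 500)]),
            ]
        )
        evs = enumerate_events(ann.loci["G"])
        assert [e.event_type for e in evs] == [SKIPPED_EXON]

    def test_alt_donor_first_exon(self):
        ann = make_annotation(
            [
                ("G", "T1", "+", "chr1", [(0, 100), (200, 300)]),
                ("G", "T2", "+", "chr1", [(0, 80), (200, 300)]),
            ]
        )
        evs = enumerate_events(ann.loci["G"])
        assert [e.event_type for e in evs] == [ALT_DONOR]

    def test_alt_acceptor(self):
        ann = make_annotation(
            [
                ("G", "T1", "+", "chr1", [(0, 100), (200, 300)]),
                ("G", "T2", "+", "chr1", [(0, 100), (230, 300)]),
            ]
        )
        evs = enumerate_events(ann.loci["G"])
        assert [e.event_type for e in evs] == [ALT_ACCEPTOR]

    def test_minus_strand_roles(self):
        # same coordinates on the minus strand: the shifted start of the
        # *second* exon is now a donor shift
        ann = make_annotation(
            [
                ("G", "T1", "-", "chr1", [(0, 100), (200, 300)]),
                ("G", "T2", "-", "chr1", [(0, 100), (230, 300)]),
            ]
        )
        evs = enumerate_events(ann.loci["G"])
        assert [e.event_type for e in evs] == [ALT_DONOR]

    def test_single_transcript_no_events(self):
        ann = make_annotation([("G", "T1", "+", "chr1", [(0, 100), (200, 300)])])
        assert enumerate_events(ann.loci["G"]) == []

    def test_terminal_variation_other_or_dropped(self):
        # alternative first exon: differing TSS plus a differing donor with
        # no shared site to the left -> terminal variation
        ann = make_annotation(
            [
                ("G", "T1", "+", "chr1", [(0, 100), (200, 300)]),
                ("G", "T2", "+", "chr1", [(40, 120), (200, 300)]),
            ]
        )
        included = enumerate_events(ann.loci["G"], include_terminal=True)
        assert {e.event_type for e in included} == {OTHER}
        assert enumerate_events(ann.loci["G"], include_terminal=False) == []

    def test_shared_termini_act_as_flanks(self):
        # differing first-exon starts but shared sites elsewhere: the
        # acceptor shift is still a flanked alt_acceptor event
        ann = make_annotation(
            [
                ("G", "T1", "+", "chr1", [(0, 100), (200, 300)]),
                ("G", "T2", "+", "chr1", [(50, 100), (250, 300)]),
            ]
        )
        evs = enumerate_events(ann.loci["G"])
        assert [e.event_type for e in evs] == [ALT_ACCEPTOR]

    def test_dedup_idempotent_under_duplicate_transcript(self):
        base = [
            ("G", "T1", "+", "chr1", [(0, 100), (200, 300), (400, 500)]),
            ("G", "T2", "+", "chr1", [(0, 100), (400, 500)]),
        ]
        with_dup = base + [("G", "T3", "+", "chr1", [(0, 100), (400, 500)])]
        a = classifier_events(make_annotation(base).loci["G"])
        b = classifier_events(make_annotation(with_dup).loci["G"])
        assert a == b

    def test_transcript_order_invariance(self):
        spec = [
            ("G", "T1", "+", "chr1", [(0, 100), (200, 300), (400, 500)]),
            ("G", "T2", "+", "chr1", [(0, 100), (400, 500)]),
            ("G", "T3", "+", "chr1", [(0, 100), (200, 280), (400, 500)]),
        ]
        a = classifier_events(make_annotation(spec).loci["G"])
        b = classifier_events(make_annotation(spec[::-1]).loci["G"])
        assert a == b

    def test_three_transcripts_match_oracle(self):
        spec = [
            ("G", "T1", "+", "chr1", [(0, 100), (200, 300), (400, 500)]),
            ("G", "T2", "+", "chr1", [(0, 100), (400, 500)]),
            ("G", "T3", "+", "chr1", [(0, 100), (200, 280), (400, 500)]),
        ]
        locus = make_annotation(spec).loci["G"]
        assert classifier_events(locus) == oracle_events(locus)

    def test_strand_mirror_keeps_classification(self):
        spec = [
            ("G", "T1", "+", "chr1", [(0, 100), (200, 300), (400, 500)]),
            ("G", "T2", "+", "chr1", [(0, 100), (400, 500)]),
            ("G", "T3", "+", "chr1", [(0, 100), (230, 300), (400, 500)]),
        ]
        locus = make_annotation(spec).loci["G"]
        mirrored = build_annotation(
            [mirror_transcript(t, 600) for t in locus.transcripts.values()]
        ).loci["G"]
        from collections import Counter

        a = Counter(e.event_type for e in enumerate_events(locus))
        b = Counter(e.event_type for e in enumerate_events(mirrored))
        assert a == b


class TestOracleEquivalence:
    def test_generated_corpus(self):
        params = SyntheticParams(
            n_loci=150,
            transcript_count_histogram={1: 0.2, 2: 0.5, 3: 0.3},
            exon_count_range=(3, 6),
            seed=67,
        )
        ann, _, _ = generate_annotation(params, rng=67, with_sequence=False)
        for s in ann.symbols():
            locus = ann.loci[s]
            assert classifier_events(locus) == oracle_events(locus), s

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_adversarial_random_structures(self, strand):
        rng = np.random.default_rng(71 if strand == "+" else 73)
        for _ in range(150):
            locus = random_structural_locus(rng, strand)
            for inc in (True, False):
                assert classifier_events(locus, inc) == oracle_events(locus, inc)


class TestEventProportions:
    def test_fractions_sum_to_one(self):
        params = SyntheticParams(n_loci=120, seed=79)
        ann, _, _ = generate_annotation(params, rng=79, with_sequence=False)
        props = event_proportions(ann.symbols(), ann)
        assert sum(props.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_events_errors(self):
        ann = make_annotation([("G", "T", "+", "chr1", [(0, 100)])])
        with pytest.raises(ValueError):
            event_proportions(["G"], ann)

    def test_exclusion_list(self):
        spec = [
            ("G", "T1", "+", "chr1", [(0, 100), (200, 300), (400, 500)]),
            ("G", "T2", "+", "chr1", [(0, 100), (400, 500)]),
            ("H", "U1", "+", "chr2", [(0, 100), (200, 300)]),
            ("H", "U2", "+", "chr2", [(0, 80), (200, 300)]),
        ]
        ann = make_annotation(spec)
        props = event_proportions(["G", "H"], ann, exclude={"G"})
        assert props.total_events == 1
        assert props.fractions[ALT_DONOR] == 1.0

    def test_outlier_cap_drops_busy_locus(self):
        spec = [
            ("G", "T1", "+", "chr1", [(0, 100), (200, 300), (400, 500), (600, 700)]),
            ("G", "T2", "+", "chr1", [(0, 100), (400, 500), (600, 700)]),
            ("G", "T3", "+", "chr1", [(0, 100), (200, 300), (600, 700)]),
            ("H", "U1", "+", "chr2", [(0, 100), (200, 300)]),
            ("H", "U2", "+", "chr2", [(0, 80), (200, 300)]),
        ]
        ann = make_annotation(spec)
        props = event_proportions(["G", "H"], ann, outlier_event_cap=1)
        assert props.total_events == 1

    def test_recovers_generator_mix(self):
        params = SyntheticParams(
            n_loci=300,
            transcript_count_histogram={2: 0.6, 3: 0.4},
            exon_count_range=(8, 12),
            event_mix=(0.5, 0.2, 0.2, 0.1),
            seed=83,
        )
        ann, _, truth = generate_annotation(params, rng=83, with_sequence=False)
        props = event_proportions(ann.symbols(), ann)
        assert props.fractions[SKIPPED_EXON] == pytest.approx(0.5, abs=0.05)
        assert props.fractions[ALT_DONOR] == pytest.approx(0.2, abs=0.05)
        assert props.fractions[ALT_ACCEPTOR] == pytest.approx(0.2, abs=0.05)
        assert props.fractions[OTHER] == pytest.approx(0.1, abs=0.05)

    def test_single_operator_loci_match_truth_exactly(self):
        params = SyntheticParams(
            n_loci=120,
            transcript_count_histogram={1: 0.2, 2: 0.5, 3: 0.3},
            exon_count_range=(6, 10),
            seed=89,
        )
        ann, _, truth = generate_annotation(params, rng=89, with_sequence=False)
        checked = 0
        for s in ann.symbols():
            rec = truth.per_locus[s]
            if not rec["events_exact"]:
                continue
            got = {
                (e.event_type, tuple(sorted(e.signature[0])))
                for e in enumerate_events(ann.loci[s])
            }
            want = {
                (e["type"], tuple((int(p), r) for p, r in e["sites"]))
                for e in rec["events"]
            }
            assert got == want, s
            checked += 1
        assert checked >= 100


@pytest.fixture(scope="module")
def corpus():
    params = SyntheticParams(
        n_loci=500,
        transcript_count_histogram={1: 0.3, 2: 0.4, 3: 0.3},
        exon_count_range=(6, 10),
        event_mix=(0.45, 0.2, 0.25, 0.1),
        seed=97,
    )
    ann, _, _ = generate_annotation(params, rng=97, with_sequence=False)
    return ann


class TestProportionEnrichment:
    def test_null_list_not_extreme(self, corpus):
        lst = generate_disease_list(corpus, 80, 0.0, rng=3)
        res = proportion_enrichment(
            lst, corpus.symbols(), corpus, ALT_ACCEPTOR, n_lists=100, rng=3
        )
        assert 0.01 < res.p_value <= 1.0

    def test_below_all_nulls_p_one(self, corpus):
        # a list made only of zero-event (single transcript) loci
        singles = [s for s in corpus.symbols() if corpus.transcript_count(s) == 1][:40]
        res = proportion_enrichment(
            singles, corpus.symbols(), corpus, ALT_ACCEPTOR, n_lists=100, rng=4
        )
        assert res.observed == 0.0
        assert res.p_value == 1.0
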