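"""Synthetic annotation / genome / expression generator with truth records.

Every emitted artifact is reparseable by the package's own readers, and a
:class:`TruthRecord` keeps the planted ground truth (transcript counts,
splice events, window GC targets, canonical-motif flags, dominant tissues)
so downstream statistics can be checked against construction.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    ExonInterval,
    GeneList,
    GenomeAnnotation,
    TranscriptModel,
    build_annotation,
    write_gtf,
)
from .expression import ExpressionMatrix, GENE_COL, write_expression
from .seqfeatures import (
    ACCEPT,
    ACCEPT_MID,
    ACCEPTOR_MOTIFS,
    DONOR,
    DONOR_MID,
    DONOR_MOTIFS,
    TSS,
    DictGenome,
    reverse_complement,
)

log = logging.getLogger(__name__)

__all__ = [
    "SyntheticParams",
    "TruthRecord",
    "generate_annotation",
    "generate_disease_list",
    "generate_expression",
    "generate_disease_db",
    "write_fasta",
    "emit_bundle",
]

DEFAULT_TISSUES = (
    "adipose",
    "adrenal",
    "brain",
    "breast",
    "colon",
    "heart",
    "kidney",
    "liver",
    "lung",
    "lymph_node",
    "ovary",
    "prostate",
    "skeletal_muscle",
    "testes",
    "thyroid",
    "white_blood_cells",
)

DEFAULT_HISTOGRAM = {1: 0.557, 2: 0.20, 3: 0.10, 4: 0.05, 5: 0.043, "6+": 0.05}

_OP_NAMES = ("skipped_exon", "alt_donor", "alt_acceptor", "other")


@dataclass
class SyntheticParams:
    """Knobs of the generator; see module docstring."""

    n_loci: int = 500
    transcript_count_histogram: Mapping = field(
        default_factory=lambda: dict(DEFAULT_HISTOGRAM)
    )
    transcript_count_geometric_q: float | None = None
    locus_length_log_mean: float = math.log(20_000.0)
    locus_length_log_sd: float = 0.8
    outlier_fraction_over_1mb: float = 0.0
    exon_count_range: tuple = (3, 9)
    exon_length_range: tuple = (80, 300)
    min_intron_length: int = 100
    event_mix: tuple = (0.45, 0.20, 0.25, 0.10)  # skip, alt donor, alt acceptor, other
    p_canonical_motif: float = 0.8
    region_gc: Mapping = field(
        default_factory=lambda: {
            TSS: 65.0,
            DONOR: 60.0,
            ACCEPT: 45.0,
            DONOR_MID: 55.0,
            ACCEPT_MID: 50.0,
        }
    )
    background_gc: float = 42.0
    tissues: tuple = DEFAULT_TISSUES
    dirichlet_concentration: float = 1.0
    lung_dominance_excess: float = 1.0
    minus_strand_fraction: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.transcript_count_geometric_q is None:
            total = sum(self.transcript_count_histogram.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"count histogram sums to {total}")
        elif not (0.0 < self.transcript_count_geometric_q < 1.0):
            raise ValueError("geometric q must be in (0, 1)")
        if abs(sum(self.event_mix) - 1.0) > 1e-6:
            raise ValueError("event_mix must sum to 1")
        if not (0.0 <= self.p_canonical_motif <= 1.0):
            raise ValueError("p_canonical_motif must be a probability")
        if self.locus_length_log_sd <= 0:
            raise ValueError("locus_length_log_sd must be positive")
        if len(self.tissues) < 1:
            raise ValueError("need at least one tissue")


@dataclass
class TruthRecord:
    """Planted per-locus ground truth, keyed by gene symbol."""

    per_locus: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.per_locus, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# Transcript-count and layout sampling
# ---------------------------------------------------------------------------


def _sample_count(params: SyntheticParams, rng: np.random.Generator) -> int:
    if params.transcript_count_geometric_q is not None:
        return int(rng.geometric(params.transcript_count_geometric_q))
    bins = list(params.transcript_count_histogram.keys())
    probs = np.array([params.transcript_count_histogram[b] for b in bins], float)
    probs /= probs.sum()
    b = bins[int(rng.choice(len(bins), p=probs))]
    if b == "6+":
        return 6 + int(rng.geometric(0.5)) - 1
    return int(b)


def _sample_locus_length(params: SyntheticParams, rng: np.random.Generator) -> int:
    if rng.random() < params.outlier_fraction_over_1mb:
        return int(rng.integers(1_000_001, 2_000_000))
    return max(300, int(rng.lognormal(params.locus_length_log_mean, params.locus_length_log_sd)))


def _base_exons(
    params: SyntheticParams, rng: np.random.Generator, count: int, target_len: int
) -> list[list[int]]:
    """Exon [start, end) pairs (locus-relative) for the base transcript."""
    lo, hi = params.exon_count_range
    n = int(rng.integers(lo, hi + 1))
    if count > 1:
        n = max(n, 3)
    elo, ehi = params.exon_length_range
    if n == 1:
        return [[0, max(200, min(target_len, 1_500_000))]]
    exon_lens = rng.integers(elo, ehi + 1, size=n)
    e_total = int(exon_lens.sum())
    min_introns = params.min_intron_length * (n - 1)
    extra = max(0, target_len - e_total - min_introns)
    weights = rng.dirichlet(np.ones(n - 1))
    introns = params.min_intron_length + np.floor(weights * extra).astype(int)
    exons = []
    pos = 0
    for i in range(n):
        exons.append([pos, pos + int(exon_lens[i])])
        pos += int(exon_lens[i])
        if i < n - 1:
            pos += int(introns[i])
    return exons


# ---------------------------------------------------------------------------
# Event operators
# ---------------------------------------------------------------------------


def _donor_exons(n: int, strand: str) -> range:
    return range(0, n - 1) if strand == "+" else range(1, n)


def _acceptor_exons(n: int, strand: str) -> range:
    return range(1, n) if strand == "+" else range(0, n - 1)


def _site(exon: Sequence[int], role: str, strand: str) -> tuple[int, str]:
    """Genomic coordinate of a donor/acceptor boundary of an exon."""
    start, end = exon
    if role == "D":
        return (end, "D") if strand == "+" else (start, "D")
    return (start, "A") if strand == "+" else (end, "A")


def _shift_boundary(
    exon: list[int], role: str, strand: str, d: int
) -> tuple[list[int], tuple[int, str], tuple[int, str]]:
    """Move a donor/acceptor boundary ``d`` bp into the exon; returns the
    modified exon plus (old site, new site)."""
    old = _site(exon, role, strand)
    new_exon = list(exon)
    if (role == "D") == (strand == "+"):  # boundary is the exon end
        new_exon[1] -= d
    else:
        new_exon[0] += d
    new = _site(new_exon, role, strand)
    return new_exon, old, new


def _separated(idx: int, used: set[int]) -> bool:
    return all(abs(idx - u) >= 2 for u in used)


def _apply_operator(
    op: str,
    base: list[list[int]],
    strand: str,
    used_exons: set[int],
    rng: np.random.Generator,
) -> tuple[list[list[int]], list[dict], list[int]] | None:
    """Derive one alternative exon chain from the base transcript.

    Returns (exons, planted event dicts, affected exon indices), or None
    when the operator is infeasible under the separation constraint.
    """
    n = len(base)
    min_len = 50

    def shiftable(i: int, role: str) -> bool:
        return base[i][1] - base[i][0] - 46 >= min_len

    if op == "skipped_exon":
        cands = [i for i in range(1, n - 1) if _separated(i, used_exons)]
        if not cands:
            return None
        i = int(cands[int(rng.integers(len(cands)))])
        exons = [e for j, e in enumerate(base) if j != i]
        a = _site(base[i], "A", strand)
        d = _site(base[i], "D", strand)
        return exons, [{"type": "skipped_exon", "sites": sorted([a, d])}], [i]

    if op in ("alt_donor", "alt_acceptor"):
        role = "D" if op == "alt_donor" else "A"
        pool = _donor_exons(n, strand) if role == "D" else _acceptor_exons(n, strand)
        cands = [i for i in pool if _separated(i, used_exons) and shiftable(i, role)]
        if not cands:
            return None
        i = int(cands[int(rng.integers(len(cands)))])
        d = int(rng.integers(6, 41))
        exons = [list(e) for e in base]
        exons[i], old, new = _shift_boundary(exons[i], role, strand, d)
        return exons, [{"type": op, "sites": sorted([old, new])}], [i]

    if op == "other":
        # shift both ends of one intron: donor and acceptor differ together
        cands = [
            j
            for j in range(n - 1)
            if _separated(j, used_exons) and _separated(j + 1, used_exons)
        ]
        d_role_exon = lambda j: j if strand == "+" else j + 1
        a_role_exon = lambda j: j + 1 if strand == "+" else j
        cands = [
            j
            for j in cands
            if shiftable(d_role_exon(j), "D") and shiftable(a_role_exon(j), "A")
        ]
        if not cands:
            return None
        j = int(cands[int(rng.integers(len(cands)))])
        exons = [list(e) for e in base]
        dd, da = int(rng.integers(6, 41)), int(rng.integers(6, 41))
        di, ai = d_role_exon(j), a_role_exon(j)
        exons[di], d_old, d_new = _shift_boundary(exons[di], "D", strand, dd)
        exons[ai], a_old, a_new = _shift_boundary(exons[ai], "A", strand, da)
        sites = sorted([d_old, d_new, a_old, a_new])
        return exons, [{"type": "other", "sites": sites}], [j, j + 1]

    raise ValueError(f"unknown operator {op!r}")


def _fallback_alt_donor(
    base: list[list[int]],
    strand: str,
    used_offsets: dict,
    rng: np.random.Generator,
) -> tuple[list[list[int]], list[dict], list[int]] | None:
    """Guarantee a structurally distinct transcript when the separation
    constraint is exhausted: reuse a donor junction with a fresh offset."""
    n = len(base)
    for i in _donor_exons(n, strand):
        taken = used_offsets.setdefault(i, set())
        free = [d for d in range(6, 41) if d not in taken]
        if not free or base[i][1] - base[i][0] - 46 < 50:
            continue
        d = int(free[int(rng.integers(len(free)))])
        taken.add(d)
        exons = [list(e) for e in base]
        exons[i], old, new = _shift_boundary(exons[i], "D", strand, d)
        return exons, [{"type": "alt_donor", "sites": sorted([old, new])}], [i]
    return None


# ---------------------------------------------------------------------------
# Sequence planting
# ---------------------------------------------------------------------------

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _background(rng: np.random.Generator, length: int, gc: float) -> bytearray:
    p = gc / 100.0
    probs = [(1 - p) / 2, p / 2, p / 2, (1 - p) / 2]
    idx = rng.choice(4, size=length, p=probs)
    return bytearray(_BASE_BYTES[idx].tobytes())


def _window_content(
    rng: np.random.Generator,
    target_gc: float,
    window: int,
    side: str | None = None,
    canonical: bool = False,
) -> str:
    """A window hitting the GC target within rounding, with the side's
    canonical motif planted (or provably absent)."""
    bi = window // 2
    motifs = {"D": DONOR_MOTIFS, "A": ACCEPTOR_MOTIFS}.get(side, ())
    need = round(target_gc / 100.0 * window)
    for _ in range(500):
        fixed: dict[int, str] = {}
        if canonical:
            m = motifs[int(rng.integers(len(motifs)))]
            start = bi - 1 if side == "D" else bi - 3
            for k, ch in enumerate(m):
                fixed[start + k] = ch
        gc_fixed = sum(ch in "GC" for ch in fixed.values())
        free = [i for i in range(window) if i not in fixed]
        need_rem = min(max(need - gc_fixed, 0), len(free))
        order = rng.permutation(len(free))
        chars = list(rng.choice(["G", "C"], size=need_rem)) + list(
            rng.choice(["A", "T"], size=len(free) - need_rem)
        )
        out = [""] * window
        for i, ch in fixed.items():
            out[i] = ch
        for slot, ch in zip(order, chars):
            out[free[slot]] = ch
        seq = "".join(out)
        if side and not canonical and any(m in seq for m in motifs):
            continue
        return seq
    raise RuntimeError("could not construct a motif-free window")


def _plant_windows(
    seq: bytearray,
    transcript: TranscriptModel,
    params: SyntheticParams,
    rng: np.random.Generator,
    window: int = 60,
) -> dict:
    """Overwrite boundary windows with GC-targeted content; returns
    planted canonical flags per side."""
    ex = transcript.exons
    n = len(ex)
    strand = transcript.strand
    half = window // 2
    gc = params.region_gc

    jobs: list[tuple[int, str, str | None]] = []  # (center, gc-class, side)
    if strand == "+":
        jobs.append((ex[0].start, TSS, None))
        donors = [e.end for e in ex[:-1]]
        acceptors = [e.start for e in ex[1:]]
    else:
        jobs.append((ex[-1].end, TSS, None))
        donors = [e.start for e in reversed(ex[1:])]
        acceptors = [e.end for e in reversed(ex[:-1])]
    for k, c in enumerate(donors):
        jobs.append((c, DONOR if k == 0 else DONOR_MID, "D"))
    for k, c in enumerate(acceptors):
        jobs.append((c, ACCEPT if k == 0 else ACCEPT_MID, "A"))

    flags = {"donor": [], "acceptor": []}
    for center, cls, side in jobs:
        canonical = bool(rng.random() < params.p_canonical_motif) if side else False
        content = _window_content(
            rng, float(gc[cls]), window, side=side, canonical=canonical
        )
        if strand == "-":
            content = reverse_complement(content)
        lo = center - half
        seq[lo : lo + window] = content.encode()
        if side == "D":
            flags["donor"].append(canonical)
        elif side == "A":
            flags["acceptor"].append(canonical)
    return flags


# ---------------------------------------------------------------------------
# Main generators
# ---------------------------------------------------------------------------


def generate_annotation(
    params: SyntheticParams,
    rng: np.random.Generator | int | None = None,
    with_sequence: bool = True,
) -> tuple[GenomeAnnotation, DictGenome | None, TruthRecord]:
    """Generate loci (one per chromosome), optional genome sequence, and
    the planted truth.

    Alternative transcripts are derived from the base transcript (star
    topology) by event operators drawn from ``event_mix``; operators are
    kept one untouched exon apart so that pairwise enumeration recovers
    exactly the planted events.  When separation is infeasible the locus
    falls back to extra alternative-donor offsets and its ``events_exact``
    truth flag is cleared.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rng = np.random.default_rng(rng)
    pad = 100
    truth = TruthRecord()
    transcripts: list[TranscriptModel] = []
    sequences: dict[str, str] = {}
    op_probs = np.asarray(params.event_mix, float)

    for i in range(params.n_loci):
        gene = f"G{i:05d}"
        chrom = f"chr{i + 1}"
        strand = "+" if rng.random() >= params.minus_strand_fraction else "-"
        count = _sample_count(params, rng)
        target_len = _sample_locus_length(params, rng)
        base = _base_exons(params, rng, count, target_len)

        chains: list[list[list[int]]] = [base]
        seen = {tuple(map(tuple, base))}
        planted_events: list[dict] = []
        used_exons: set[int] = set()
        used_offsets: dict[int, set[int]] = {}
        events_exact = True
        for _ in range(count - 1):
            derived = None
            for _attempt in range(12):
                op = _OP_NAMES[int(rng.choice(4, p=op_probs))]
                result = _apply_operator(op, base, strand, used_exons, rng)
                if result is None:
                    continue
                exons, evs, touched = result
                if tuple(map(tuple, exons)) in seen:
                    continue
                derived = (exons, evs, touched)
                break
            if derived is None:
                fb = _fallback_alt_donor(base, strand, used_offsets, rng)
                if fb is None:
                    log.warning("%s: could not derive another transcript", gene)
                    break
                derived = fb
                events_exact = False
                log.debug("%s: fallback operator used", gene)
            exons, evs, touched = derived
            seen.add(tuple(map(tuple, exons)))
            chains.append(exons)
            planted_events.extend(evs)
            used_exons.update(touched)

        span = max(e[1] for e in base)
        shift = pad
        locus_transcripts = []
        for j, chain in enumerate(chains):
            tid = f"{gene}.t{j}"
            exons = tuple(
                ExonInterval(chrom=chrom, start=s + shift, end=e + shift)
                for s, e in chain
            )
            locus_transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_symbol=gene,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                )
            )
        transcripts.extend(locus_transcripts)

        shifted_events = [
            {
                "type": ev["type"],
                "sites": sorted((int(p) + shift, r) for p, r in ev["sites"]),
            }
            for ev in planted_events
        ]
        rec = {
            "transcript_count": len(chains),
            "strand": strand,
            "events": shifted_events,
            "events_exact": events_exact,
            "gc_exact": len(chains) == 1,
            "region_gc": {k: float(v) for k, v in params.region_gc.items()},
        }

        if with_sequence:
            length = span + 2 * pad
            seq = _background(rng, length, params.background_gc)
            flags_all = {"donor": [], "acceptor": []}
            for t in locus_transcripts:
                flags = _plant_windows(seq, t, params, rng)
                flags_all["donor"].extend(flags["donor"])
                flags_all["acceptor"].extend(flags["acceptor"])
            sequences[chrom] = seq.decode("ascii")
            rec["canonical"] = flags_all
        truth.per_locus[gene] = rec

    annotation = build_annotation(transcripts, source_tag="synthetic")
    genome = DictGenome(sequences) if with_sequence else None
    return annotation, genome, truth


def generate_disease_list(
    annotation: GenomeAnnotation,
    size: int,
    complexity_shift: float,
    rng: np.random.Generator | int | None = None,
    name: str = "synthetic_disease",
) -> GeneList:
    """Sample genes with selection weight increasing in transcript count so
    the list's expected mean count exceeds the pool mean by
    ``complexity_shift``; locus lengths are left untouched."""
    rng = np.random.default_rng(rng)
    symbols = np.array(annotation.symbols(), dtype=object)
    counts = np.array(
        [annotation.transcript_count(s) for s in symbols], dtype=np.float64
    )
    if size > symbols.size:
        raise ValueError("size exceeds pool")
    if size == symbols.size:
        if complexity_shift != 0:
            raise ValueError("whole-pool list requires complexity_shift = 0")
        return GeneList(name=name, symbols=tuple(symbols))
    if complexity_shift == 0:
        pick = rng.choice(symbols.size, size=size, replace=False)
        return GeneList(name=name, symbols=tuple(sorted(symbols[pick])))

    target = counts.mean() + complexity_shift
    top_mean = np.sort(counts)[-size:].mean()
    if target > top_mean - 0.05:
        raise ValueError(
            f"complexity shift {complexity_shift} infeasible for this pool "
            f"(max achievable mean {top_mean:.2f})"
        )

    def weighted_mean(beta: float) -> float:
        w = np.exp(beta * (counts - counts.max()))
        return float((w * counts).sum() / w.sum())

    lo, hi = 0.0, 20.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if weighted_mean(mid) < target:
            lo = mid
        else:
            hi = mid
    beta = (lo + hi) / 2

    # correct for without-replacement depletion by stochastic approximation
    for _ in range(8):
        w = np.exp(beta * (counts - counts.max()))
        p = w / w.sum()
        realized = np.mean(
            [
                counts[rng.choice(counts.size, size=size, replace=False, p=p)].mean()
                for _ in range(4)
            ]
        )
        err = target - realized
        if abs(err) < 0.03:
            break
        beta += err / max(np.var(counts), 0.5)
        beta = min(max(beta, 0.0), 30.0)

    w = np.exp(beta * (counts - counts.max()))
    p = w / w.sum()
    pick = rng.choice(symbols.size, size=size, replace=False, p=p)
    return GeneList(name=name, symbols=tuple(sorted(symbols[pick])))


def generate_expression(
    annotation: GenomeAnnotation,
    params: SyntheticParams,
    flagged_list: GeneList | Sequence[str] = (),
    rng: np.random.Generator | int | None = None,
    lung_tissue: str = "lung",
) -> tuple[ExpressionMatrix, dict]:
    """Dirichlet tissue profiles with one planted dominant tissue per gene.

    Genes in ``flagged_list`` receive ``lung_tissue`` as dominant with
    probability ``lung_dominance_excess / n_tissues`` (excess 1.0 gives the
    uniform rate); other genes draw their dominant tissue uniformly.
    Returns the matrix plus the planted gene -> dominant-tissue map.
    """
    rng = np.random.default_rng(rng)
    tissues = list(params.tissues)
    T = len(tissues)
    if lung_tissue not in tissues:
        raise ValueError(f"{lung_tissue!r} not among tissues")
    lung_idx = tissues.index(lung_tissue)
    excess = params.lung_dominance_excess
    p_lung = min(excess / T, 1.0)
    flagged = set(flagged_list)

    rows = []
    index = []
    genes_col = []
    dominance: dict[str, str] = {}
    for gene in annotation.symbols():
        tids = sorted(annotation.loci[gene].transcripts)
        if gene in flagged:
            if rng.random() < p_lung:
                dom_idx = lung_idx
            else:
                others = [k for k in range(T) if k != lung_idx]
                dom_idx = others[int(rng.integers(T - 1))]
        else:
            dom_idx = int(rng.integers(T))
        dominance[gene] = tissues[dom_idx]
        for rank, tid in enumerate(tids):
            w = rng.dirichlet(np.full(T, params.dirichlet_concentration))
            if rank == 0:
                j = int(np.argmax(w))
                w[j], w[dom_idx] = w[dom_idx], w[j]
                w = w * 100.0
            else:
                w = w * 10.0
            rows.append(w)
            index.append(tid)
            genes_col.append(gene)
    df = pd.DataFrame(np.array(rows), columns=tissues, index=pd.Index(index, name="transcript_id"))
    df.insert(0, GENE_COL, genes_col)
    return ExpressionMatrix(data=df), dominance


def generate_disease_db(
    annotation: GenomeAnnotation,
    base_rate: float,
    complexity_odds: float,
    rng: np.random.Generator | int | None = None,
    threshold: int = 5,
    name: str = "synthetic_disease_db",
) -> GeneList:
    """Bernoulli database membership; odds are multiplied by
    ``complexity_odds`` for loci with more than ``threshold`` transcripts."""
    if not (0.0 <= base_rate <= 1.0):
        raise ValueError("base_rate must be a probability")
    rng = np.random.default_rng(rng)
    if base_rate == 0.0:
        return GeneList(name=name, symbols=())
    odds = base_rate / (1.0 - base_rate) if base_rate < 1.0 else math.inf
    high_odds = odds * complexity_odds
    p_high = high_odds / (1.0 + high_odds) if math.isfinite(high_odds) else 1.0
    members = []
    for s in annotation.symbols():
        p = p_high if annotation.transcript_count(s) > threshold else base_rate
        if rng.random() < p:
            members.append(s)
    return GeneList(name=name, symbols=tuple(members))


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------


def write_fasta(genome: DictGenome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chroms():
            fh.write(f">{chrom}\n")
            seq = genome.fetch(chrom, 0, genome.length(chrom))
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def emit_bundle(
    outdir: str | Path,
    params: SyntheticParams,
    rng: np.random.Generator | int | None = None,
    list_size: int | None = None,
    complexity_shift: float = 0.0,
) -> dict:
    """Generate and write a complete analysis bundle; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed if rng is None else rng)
    annotation, genome, truth = generate_annotation(params, rng)
    size = list_size or max(10, params.n_loci // 10)
    gene_list = generate_disease_list(annotation, size, complexity_shift, rng)
    matrix, dominance = generate_expression(annotation, params, gene_list, rng)
    for gene, tissue in dominance.items():
        truth.per_locus[gene]["dominant_tissue"] = tissue

    paths = {
        "annotation": outdir / "annotation.gtf",
        "genome": outdir / "genome.fa",
        "expression": outdir / "expression.tsv",
        "gene_list": outdir / "gene_list.txt",
        "pool": outdir / "pool.txt",
        "truth": outdir / "truth.json",
    }
    write_gtf(annotation, paths["annotation"])
    if genome is not None:
        write_fasta(genome, paths["genome"])
    write_expression(matrix, paths["expression"])
    paths["gene_list"].write_text("\n".join(gene_list.symbols) + "\n")
    paths["pool"].write_text("\n".join(annotation.symbols()) + "\n")
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
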