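"""Transcript-complexity statistics and length-matched bootstrap resampling.

The null model draws control gene lists from a reference pool such that the
i-th control gene's locus length is within a relative tolerance (default
10%) of the i-th test gene's locus length, sampling without replacement
within each control list.  Empirical p-values are floored at ``1/n_lists``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .annotation import AnnotationError, GeneList, GenomeAnnotation

log = logging.getLogger(__name__)

__all__ = [
    "BootstrapResult",
    "ComplexityHistogram",
    "MatchingError",
    "LengthMatchedSampler",
    "mean_transcripts_per_locus",
    "complexity_histogram",
    "sample_length_matched_list",
    "bootstrap_enrichment",
    "leave_top_k_out",
    "filter_by_evidence",
    "transcript_length_stats",
    "diverse_gene_disease_enrichment",
    "make_statistic",
    "STATISTIC_FACTORIES",
]

HISTOGRAM_BINS: tuple = (1, 2, 3, 4, 5, "6+")


class MatchingError(RuntimeError):
    """No length-matched candidate available for a target, even relaxed."""


@dataclass
class BootstrapResult:
    """Observed statistic, its bootstrap null distribution, and p-value."""

    statistic_name: str
    observed: float
    null_values: list[float]
    p_value: float
    direction: str
    n_lists: int
    seed: int | None = None

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1)) if len(self.null_values) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_value": self.p_value,
            "direction": self.direction,
            "n_lists": self.n_lists,
            "seed": self.seed,
        }


@dataclass
class ComplexityHistogram:
    """Proportion of loci producing 1..5 or 6+ transcripts."""

    proportions: dict

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"histogram proportions sum to {total}, expected 1")


def _found_symbols(gene_list: GeneList | Sequence[str], annotation: GenomeAnnotation) -> list[str]:
    symbols = list(gene_list)
    found = [s for s in symbols if s in annotation]
    if not found:
        raise AnnotationError("no list symbols found in the annotation")
    missing = len(symbols) - len(found)
    if missing:
        log.info("%d list symbols absent from annotation; skipped", missing)
    return found


def mean_transcripts_per_locus(
    gene_list: GeneList | Sequence[str], annotation: GenomeAnnotation
) -> float:
    """Arithmetic mean transcript count over list symbols found in the
    annotation; absent symbols are skipped."""
    found = _found_symbols(gene_list, annotation)
    return sum(annotation.transcript_count(s) for s in found) / len(found)


def complexity_histogram(
    gene_list: GeneList | Sequence[str], annotation: GenomeAnnotation
) -> ComplexityHistogram:
    """Bin list loci by transcript count into 1..5 and 6+."""
    found = _found_symbols(gene_list, annotation)
    counts = {b: 0 for b in HISTOGRAM_BINS}
    for s in found:
        n = annotation.transcript_count(s)
        counts[n if n < 6 else "6+"] += 1
    return ComplexityHistogram(
        proportions={b: c / len(found) for b, c in counts.items()}
    )


# ---------------------------------------------------------------------------
# Length-matched sampling
# ---------------------------------------------------------------------------


class LengthMatchedSampler:
    """Samples control gene lists matched per-gene on locus length.

    Candidate lookup is by binary search over pool lengths sorted
    ascending.  If a target has no candidate at the base tolerance the
    window is widened stepwise through ``relaxation`` (with a warning);
    a target that still cannot be matched raises :class:`MatchingError`.
    """

    def __init__(
        self,
        pool_lengths: Mapping[str, int],
        tolerance: float = 0.10,
        relaxation: Sequence[float] = (0.15, 0.20),
    ) -> None:
        if not pool_lengths:
            raise MatchingError("empty pool")
        items = sorted(pool_lengths.items(), key=lambda kv: (kv[1], kv[0]))
        self.symbols = np.array([k for k, _ in items], dtype=object)
        self.lengths = np.array([v for _, v in items], dtype=np.float64)
        self.tolerance = float(tolerance)
        self.relaxation = tuple(relaxation)
        self._warned_relax = False

    def _window(self, targets: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.lengths, targets * (1.0 - tol), side="left")
        hi = np.searchsorted(self.lengths, targets * (1.0 + tol), side="right")
        return lo, hi

    def _note_relax(self, n_targets: int, tol: float) -> None:
        if self._warned_relax:
            log.debug("%d targets relaxed to tolerance %.2f", n_targets, tol)
        else:
            log.warning(
                "%d targets relaxed to tolerance %.2f (further relaxations "
                "logged at DEBUG)",
                n_targets,
                tol,
            )
            self._warned_relax = True

    def sample_indices(self, target_lengths: Sequence[int], rng: np.random.Generator) -> np.ndarray:
        targets = np.asarray(target_lengths, dtype=np.float64)
        n = targets.size
        lo, hi = self._window(targets, self.tolerance)
        empty = np.flatnonzero(hi <= lo)
        if empty.size:
            for tol in self.relaxation:
                lo2, hi2 = self._window(targets[empty], tol)
                self._note_relax(int(empty.size), tol)
                lo[empty], hi[empty] = lo2, hi2
                empty = empty[hi2 <= lo2]
                if not empty.size:
                    break
            if empty.size:
                raise MatchingError(
                    f"no pool candidate for target lengths "
                    f"{targets[empty][:5].tolist()} even at relaxed tolerance"
                )
        width = hi - lo
        idx = lo + (rng.random(n) * width).astype(np.int64)
        # resolve within-list duplicates (sampling without replacement)
        for _ in range(60):
            order = np.argsort(idx, kind="stable")
            sorted_idx = idx[order]
            dup_mask_sorted = np.zeros(n, dtype=bool)
            dup_mask_sorted[1:] = sorted_idx[1:] == sorted_idx[:-1]
            dups = order[dup_mask_sorted]
            if not dups.size:
                return idx
            idx[dups] = lo[dups] + (rng.random(dups.size) * width[dups]).astype(np.int64)
        # Deterministic fallback for stubborn collisions: classic
        # earliest-deadline interval matching (process windows by right
        # edge, take the smallest free candidate), which finds a perfect
        # assignment whenever one exists.  Free-slot lookup via union-find.
        parent = list(range(self.lengths.size + 1))

        def find(j: int) -> int:
            root = j
            while parent[root] != root:
                root = parent[root]
            while parent[j] != root:
                parent[j], j = root, parent[j]
            return root

        out = np.empty(n, dtype=np.int64)
        for pos in np.argsort(hi, kind="stable"):
            pos = int(pos)
            j = find(int(lo[pos]))
            if j >= int(hi[pos]):
                for tol in self.relaxation:
                    l2, h2 = self._window(targets[pos : pos + 1], tol)
                    self._note_relax(1, tol)
                    j = find(int(l2[0]))
                    if j < int(h2[0]):
                        break
                else:
                    raise MatchingError(
                        f"pool exhausted for target length {target_lengths[pos]}"
                    )
            out[pos] = j
            parent[j] = j + 1
        return out

    def sample(self, target_lengths: Sequence[int], rng: np.random.Generator) -> list[str]:
        idx = self.sample_indices(target_lengths, rng)
        return [self.symbols[i] for i in idx]


def sample_length_matched_list(
    target_lengths: Sequence[int],
    pool_lengths: Mapping[str, int],
    tolerance: float = 0.10,
    rng: np.random.Generator | int | None = None,
    name: str = "control",
) -> GeneList:
    """Draw one control list: the i-th sampled gene's locus length is within
    ``tolerance`` of ``target_lengths[i]`` (pairing preserved in order)."""
    rng = np.random.default_rng(rng)
    sampler = LengthMatchedSampler(pool_lengths, tolerance=tolerance)
    return GeneList(name=name, symbols=tuple(sampler.sample(target_lengths, rng)))


# ---------------------------------------------------------------------------
# Named statistics
# ---------------------------------------------------------------------------

STATISTIC_FACTORIES: dict[str, Callable] = {}


def register_statistic(name: str):
    def deco(factory: Callable) -> Callable:
        STATISTIC_FACTORIES[name] = factory
        return factory

    return deco


def make_statistic(name: str, **context) -> Callable[[Sequence[str]], float]:
    """Build a named statistic closure from context (annotation, genome,
    expression matrix, ...).  The closure maps a symbol list to a float."""
    try:
        factory = STATISTIC_FACTORIES[name]
    except KeyError:
        raise KeyError(
            f"unknown statistic {name!r}; known: {sorted(STATISTIC_FACTORIES)}"
        ) from None
    return factory(**context)


@register_statistic("mean_transcripts")
def _mean_transcripts_factory(annotation: GenomeAnnotation, **_) -> Callable:
    counts = annotation.transcript_counts()

    def stat(symbols: Sequence[str]) -> float:
        vals = [counts[s] for s in symbols if s in counts]
        return sum(vals) / len(vals)

    return stat


@register_statistic("bin_proportion")
def _bin_proportion_factory(annotation: GenomeAnnotation, bin, **_) -> Callable:
    counts = annotation.transcript_counts()

    def in_bin(n: int) -> bool:
        return n >= 6 if bin == "6+" else n == bin

    def stat(symbols: Sequence[str]) -> float:
        vals = [in_bin(counts[s]) for s in symbols if s in counts]
        return sum(vals) / len(vals)

    return stat


@register_statistic("mean_mrna_length")
def _mean_mrna_length_factory(annotation: GenomeAnnotation, **_) -> Callable:
    per_gene = {
        s: [t.mature_length for t in l.transcripts.values()]
        for s, l in annotation.loci.items()
    }

    def stat(symbols: Sequence[str]) -> float:
        vals = [v for s in symbols for v in per_gene.get(s, ())]
        return sum(vals) / len(vals)

    return stat


@register_statistic("mean_large_exon_count")
def _mean_large_exon_factory(
    annotation: GenomeAnnotation, large_exon_bp: int = 200, **_
) -> Callable:
    per_gene = {
        s: [
            sum(1 for e in t.exons if e.length > large_exon_bp)
            for t in l.transcripts.values()
        ]
        for s, l in annotation.loci.items()
    }

    def stat(symbols: Sequence[str]) -> float:
        vals = [v for s in symbols for v in per_gene.get(s, ())]
        return sum(vals) / len(vals)

    return stat


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def empirical_p(
    observed: float, null_values: Sequence[float], direction: str, n_lists: int
) -> float:
    """#{null as-or-more-extreme}/N, floored at 1/N; two_sided doubles the
    smaller tail (capped at 1)."""
    arr = np.asarray(null_values, dtype=np.float64)
    ge = int(np.sum(arr >= observed))
    le = int(np.sum(arr <= observed))
    if direction == "greater":
        count = ge
    elif direction == "less":
        count = le
    elif direction == "two_sided":
        return min(1.0, 2.0 * max(min(ge, le), 1) / n_lists)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return max(count, 1) / n_lists


def bootstrap_enrichment(
    gene_list: GeneList | Sequence[str],
    pool: GeneList | Sequence[str],
    annotation: GenomeAnnotation,
    statistic: str | Callable[[Sequence[str]], float],
    *,
    n_lists: int = 1000,
    direction: str = "greater",
    tolerance: float = 0.10,
    rng: np.random.Generator | int | None = None,
    exclude_list_from_pool: bool = True,
    statistic_context: Mapping | None = None,
) -> BootstrapResult:
    """Length-matched bootstrap enrichment of a named or callable statistic.

    The observed value is the statistic on the test list; the null
    distribution is the statistic on ``n_lists`` control lists matched
    per-gene on locus length (the test list's own symbols are excluded from
    the pool by default).
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    if isinstance(statistic, str):
        name = statistic
        statistic = make_statistic(name, annotation=annotation, **(statistic_context or {}))
    else:
        name = getattr(statistic, "__name__", "custom")

    list_symbols = _found_symbols(gene_list, annotation)
    lengths = annotation.locus_lengths()
    targets = [lengths[s] for s in list_symbols]

    list_set = set(gene_list) if exclude_list_from_pool else set()
    pool_lengths = {
        s: lengths[s] for s in pool if s in lengths and s not in list_set
    }
    sampler = LengthMatchedSampler(pool_lengths, tolerance=tolerance)

    observed = float(statistic(list_symbols))
    null_values = [
        float(statistic(sampler.sample(targets, rng))) for _ in range(n_lists)
    ]
    p = empirical_p(observed, null_values, direction, n_lists)
    return BootstrapResult(
        statistic_name=name,
        observed=observed,
        null_values=null_values,
        p_value=p,
        direction=direction,
        n_lists=n_lists,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Robustness helpers
# ---------------------------------------------------------------------------


def leave_top_k_out(
    gene_list: GeneList, annotation: GenomeAnnotation, k: int
) -> GeneList:
    """Remove the ``k`` list genes with the largest transcript counts (ties
    broken by list order)."""
    if k >= len(gene_list):
        raise ValueError(f"k={k} must be smaller than the list ({len(gene_list)})")
    if k == 0:
        return gene_list
    counts = annotation.transcript_counts()
    ranked = sorted(
        range(len(gene_list.symbols)),
        key=lambda i: (-counts.get(gene_list.symbols[i], 0), i),
    )
    drop = {gene_list.symbols[i] for i in ranked[:k]}
    return GeneList(
        name=f"{gene_list.name}_minus_top{k}",
        symbols=tuple(s for s in gene_list.symbols if s not in drop),
        evidence=gene_list.evidence,
    )


def filter_by_evidence(gene_list: GeneList) -> GeneList:
    """Keep symbols with strictly more positive than negative studies.
    Symbols lacking evidence records are kept with a warning."""
    if gene_list.evidence is None:
        raise AnnotationError(f"gene list {gene_list.name} carries no evidence")
    kept = []
    for s in gene_list.symbols:
        if s not in gene_list.evidence:
            log.warning("no evidence for %s; kept", s)
            kept.append(s)
            continue
        pos, neg = gene_list.evidence[s]
        if pos > neg:
            kept.append(s)
    return GeneList(
        name=f"{gene_list.name}_supported",
        symbols=tuple(kept),
        evidence=gene_list.evidence,
    )


def transcript_length_stats(
    gene_list: GeneList | Sequence[str],
    annotation: GenomeAnnotation,
    large_exon_bp: int = 200,
) -> tuple[float, float]:
    """(mean mRNA length, mean count of exons strictly larger than
    ``large_exon_bp``) over all transcripts of all list loci."""
    found = _found_symbols(gene_list, annotation)
    lengths: list[int] = []
    large: list[int] = []
    for s in found:
        for t in annotation.loci[s].transcripts.values():
            lengths.append(t.mature_length)
            large.append(sum(1 for e in t.exons if e.length > large_exon_bp))
    return sum(lengths) / len(lengths), sum(large) / len(large)


def diverse_gene_disease_enrichment(
    annotation: GenomeAnnotation,
    disease_db: GeneList | Sequence[str],
    *,
    n_lists: int = 1000,
    threshold: int = 5,
    rng: np.random.Generator | int | None = None,
) -> BootstrapResult:
    """Is disease-database membership enriched among loci with more than
    ``threshold`` transcripts, versus equal-size draws from the 1..threshold
    set?"""
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    counts = annotation.transcript_counts()
    high = sorted(s for s, n in counts.items() if n > threshold)
    low = sorted(s for s, n in counts.items() if 1 <= n <= threshold)
    if not high:
        raise AnnotationError(f"no loci with more than {threshold} transcripts")
    db = set(disease_db)
    observed = float(sum(1 for s in high if s in db))
    member = np.array([s in db for s in low], dtype=np.float64)
    null_values = []
    for _ in range(n_lists):
        pick = rng.choice(member.size, size=len(high), replace=False)
        null_values.append(float(member[pick].sum()))
    p = empirical_p(observed, null_values, "greater", n_lists)
    return BootstrapResult(
        statistic_name=f"disease_members_gt{threshold}_transcripts",
        observed=observed,
        null_values=null_values,
        p_value=p,
        direction="greater",
        n_lists=n_lists,
        seed=seed,
    )
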