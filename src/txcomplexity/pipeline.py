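"""End-to-end orchestration from a declarative YAML/dict config.

All randomness fans out from one root seed via named substreams, so adding
or toggling a stage never perturbs another stage's draws.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import annotation as ann
from . import enrichment, events, expression, seqfeatures

log = logging.getLogger(__name__)

__all__ = ["PipelineError", "ConfigError", "StageError", "load_config", "run_pipeline"]

# fixed substream labels: stage order never shifts stream assignment
_STAGE_STREAMS = {
    "complexity": 1,
    "gc": 2,
    "events": 3,
    "tissue": 4,
}


class PipelineError(RuntimeError):
    pass


class ConfigError(PipelineError):
    pass


class StageError(PipelineError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def _stage_rng(root_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(root_seed), _STAGE_STREAMS[stage]])


def _require(cfg: dict, key: str) -> str:
    if key not in cfg:
        raise ConfigError(f"config lacks required key {key!r}")
    p = Path(cfg[key])
    if not p.exists():
        raise ConfigError(f"{key} path does not exist: {p}")
    return str(p)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured stages and write per-stage TSVs plus a JSON
    summary.  Returns the summary dict.

    Config keys: ``annotation`` (path), ``annotation_format`` (gtf|refflat),
    ``gene_list``, ``pool``, optional ``genome`` (FASTA), ``expression``
    (TSV), ``stages`` (list among complexity/gc/events/tissue), ``n_lists``,
    ``tolerance``, ``window``, ``seed``, ``max_locus_length``, ``out_dir``.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    out_dir = Path(cfg.get("out_dir", "txc_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    n_lists = int(cfg.get("n_lists", 1000))
    if n_lists < 1:
        raise ConfigError("n_lists must be >= 1")
    tolerance = float(cfg.get("tolerance", 0.10))
    window = int(cfg.get("window", 60))
    stages = list(cfg.get("stages", []))
    unknown = [s for s in stages if s not in _STAGE_STREAMS]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")

    fmt = cfg.get("annotation_format", "gtf")
    reader = {"gtf": ann.read_gtf, "refflat": ann.read_refflat}.get(fmt)
    if reader is None:
        raise ConfigError(f"unknown annotation_format {fmt!r}")
    annotation = reader(_require(cfg, "annotation"))
    annotation = ann.filter_loci(
        annotation,
        max_length=int(cfg.get("max_locus_length", 1_000_000)),
        min_length=int(cfg.get("min_locus_length", 0)),
    )
    gene_list = ann.load_gene_list(_require(cfg, "gene_list"))
    pool = ann.load_gene_list(_require(cfg, "pool"))
    genome = (
        seqfeatures.as_genome(_require(cfg, "genome")) if cfg.get("genome") else None
    )
    matrix = (
        expression.read_expression(_require(cfg, "expression"))
        if cfg.get("expression")
        else None
    )

    summary: dict = {
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "n_lists": n_lists,
        "tolerance": tolerance,
        "stages": {},
    }

    def record(stage: str, payload: dict) -> None:
        summary["stages"][stage] = payload

    for stage in stages:
        rng = _stage_rng(seed, stage)
        try:
            if stage == "complexity":
                res = enrichment.bootstrap_enrichment(
                    gene_list,
                    pool,
                    annotation,
                    "mean_transcripts",
                    n_lists=n_lists,
                    tolerance=tolerance,
                    rng=rng,
                )
                hist = enrichment.complexity_histogram(gene_list, annotation)
                payload = {
                    "bootstrap": res.summary(),
                    "histogram": {str(k): v for k, v in hist.proportions.items()},
                }
                _write_tsv(
                    out_dir / "complexity.tsv",
                    ["statistic", "observed", "null_mean", "null_sd", "p_value"],
                    [
                        [
                            res.statistic_name,
                            res.observed,
                            res.null_mean,
                            res.null_sd,
                            res.p_value,
                        ]
                    ],
                )
            elif stage == "gc":
                if genome is None:
                    raise ConfigError("gc stage requires a genome path")
                profile = seqfeatures.gc_profile(
                    gene_list, annotation, genome, window=window
                )
                gap = seqfeatures.donor_acceptor_gap(profile)
                donor_pct, acc_pct = seqfeatures.canonical_site_fractions(
                    gene_list, annotation, genome, window=window
                )
                payload = {
                    "mean_gc": profile.mean_gc,
                    "n_windows": profile.n_windows,
                    "donor_acceptor_gap": gap,
                    "canonical_donor_pct": donor_pct,
                    "canonical_acceptor_pct": acc_pct,
                }
                _write_tsv(
                    out_dir / "gc_profile.tsv",
                    ["region", "mean_gc", "n_windows"],
                    [
                        [cls, profile.mean_gc.get(cls, ""), profile.n_windows[cls]]
                        for cls in seqfeatures.REGION_CLASSES
                    ],
                )
            elif stage == "events":
                props = events.event_proportions(gene_list, annotation)
                res = events.proportion_enrichment(
                    gene_list,
                    pool,
                    annotation,
                    "alt_acceptor",
                    n_lists=n_lists,
                    tolerance=tolerance,
                    rng=rng,
                )
                payload = {
                    "fractions": props.fractions,
                    "total_events": props.total_events,
                    "alt_acceptor_bootstrap": res.summary(),
                }
                _write_tsv(
                    out_dir / "event_proportions.tsv",
                    ["event_type", "fraction"],
                    [[t, props.fractions[t]] for t in events.EVENT_TYPES],
                )
            elif stage == "tissue":
                if matrix is None:
                    raise ConfigError("tissue stage requires an expression path")
                dom = expression.tissue_dominance(gene_list, matrix)
                res = expression.lung_enrichment(
                    gene_list,
                    pool,
                    matrix,
                    annotation,
                    tissue=cfg.get("tissue", "lung"),
                    n_lists=n_lists,
                    tolerance=tolerance,
                    rng=rng,
                )
                payload = {
                    "fractions": dom.fractions,
                    "n_scored": dom.n_scored,
                    "lung_bootstrap": res.summary(),
                }
                _write_tsv(
                    out_dir / "tissue_dominance.tsv",
                    ["tissue", "fraction"],
                    [[t, f] for t, f in sorted(dom.fractions.items())],
                )
            record(stage, payload)
        except PipelineError:
            _dump_summary(summary, out_dir)
            raise
        except Exception as exc:  # partial results preserved on failure
            _dump_summary(summary, out_dir)
            raise StageError(stage, exc) from exc

    _dump_summary(summary, out_dir)
    return summary


def _write_tsv(path: Path, header: list, rows: list) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, header)) + "\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def _dump_summary(summary: dict, out_dir: Path) -> None:
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
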