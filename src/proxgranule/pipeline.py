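"""End-to-end orchestration: enrichment -> Venn -> recovery -> disorder -> ROI.

A :class:`PipelineConfig` (usually loaded from YAML) names the input files
for two bait experiments, the curated reference lists, the per-protein
disorder summaries, and the ROI measurements, plus the statistical
settings and a master seed.  :func:`run_pipeline` runs every stage,
writes per-stage outputs plus one machine-readable ``summary.json`` with
the headline counts, and is fully deterministic given the config and
inputs.  GO enrichment and PPI-network construction are deliberately not
stages; the exported candidate lists are the hand-off to those external
tools.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .disorder import compare_to_random, load_summary_table
from .enrichment import (
    EnrichmentConfig,
    call_enrichment,
    enriched_ids,
    intersect_enrichment,
    load_count_matrix,
    write_enrichment_table,
)
from .imaging import load_roi_measurements, ratio_summary, ratio_table
from .reference import harmonize_ids, load_alias_map, load_reference_sets, recovery

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "load_pipeline_config"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage label."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    counts_a: str
    samples_a: str
    counts_b: str
    samples_b: str
    reference: str
    disorder_summary: str
    roi: str
    alias: str | None = None
    seed: int = 0
    bait_a_name: str = "bait_a"
    bait_b_name: str = "bait_b"
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    disorder_alternative: str = "two-sided"
    disorder_n_draws: int = 1
    disorder_exclude_targets: bool = True
    disorder_target: str = "both"  # "both" or "either" bait's enriched set
    roi_mode: str = "symmetric"

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config; file paths are resolved relative to it."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    enr = EnrichmentConfig(**raw.pop("enrichment", {}))
    base = path.parent

    def resolve(v):
        return str((base / v)) if v and not Path(v).is_absolute() else v

    for key in ("counts_a", "samples_a", "counts_b", "samples_b", "reference",
                "disorder_summary", "roi", "alias"):
        if raw.get(key):
            raw[key] = resolve(raw[key])
    try:
        return PipelineConfig(enrichment=enr, **raw)
    except TypeError as exc:
        raise ValueError(f"invalid pipeline config: {exc}") from exc


def _json_dump(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Run every stage and write the report bundle into ``outdir``.

    Returns the summary dictionary also written to ``summary.json``.  A
    failing stage raises :class:`StageError`; outputs of completed stages
    are retained.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: config hash %s, version %s", config.config_hash(), __version__)

    # --- enrichment per bait -------------------------------------------------
    stage = "enrichment"
    try:
        tables = {}
        for tag, name, cpath, spath in (
            ("a", config.bait_a_name, config.counts_a, config.samples_a),
            ("b", config.bait_b_name, config.counts_b, config.samples_b),
        ):
            matrix = load_count_matrix(cpath, spath)
            table = call_enrichment(matrix, config.enrichment)
            write_enrichment_table(table, out / f"enrichment_{tag}.tsv")
            tables[tag] = table
            logger.info("%s: %d/%d proteins enriched", name, int(table["enriched"].sum()), len(table))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    set_a, set_b = enriched_ids(tables["a"]), enriched_ids(tables["b"])

    # --- dual-bait intersection ----------------------------------------------
    stage = "venn"
    try:
        venn = intersect_enrichment(set_a, set_b)
        _json_dump(venn.to_dict(), out / "venn.json")
        both = sorted(set_a & set_b)
        either = sorted(set_a | set_b)
        (out / "candidates_both.txt").write_text("\n".join(both) + "\n")
        (out / "candidates_either.txt").write_text("\n".join(either) + "\n")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- curated-set recovery ------------------------------------------------
    stage = "recovery"
    try:
        refs = load_reference_sets(config.reference)
        alias = load_alias_map(config.alias) if config.alias else None
        candidates, refs_h = harmonize_ids(either, refs, alias_map=alias)
        report = recovery(candidates, refs_h)
        _json_dump(report.to_dict(), out / "recovery.json")
        report.to_frame().to_csv(out / "recovery.tsv", sep="\t", index=False)
        per_bait = {}
        for tag, ids in (("a", set_a), ("b", set_b)):
            cand_t, _ = harmonize_ids(ids, refs, alias_map=alias)
            per_bait[tag] = recovery(cand_t, refs_h).to_dict()
        _json_dump(per_bait, out / "recovery_per_bait.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- disorder comparison -------------------------------------------------
    stage = "disorder"
    try:
        summaries = load_summary_table(config.disorder_summary)
        target = both if config.disorder_target == "both" else either
        comparison = compare_to_random(
            target,
            summaries,
            seed=config.seed,
            n_draws=config.disorder_n_draws,
            alternative=config.disorder_alternative,
            exclude_targets=config.disorder_exclude_targets,
        )
        _json_dump(comparison.to_dict(), out / "disorder_comparison.json")
        # boxplot-ready long table: targets vs the rest of the proteome
        target_set = set(target)
        rows = ["protein_id\tgroup\tmean_disorder"]
        for pid in summaries.index:
            grp = "target" if pid in target_set else "population"
            rows.append(f"{pid}\t{grp}\t{summaries.loc[pid, 'mean']:.10g}")
        (out / "disorder_long.tsv").write_text("\n".join(rows) + "\n")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- ROI ratios ----------------------------------------------------------
    stage = "roi"
    try:
        records, group_of = load_roi_measurements(config.roi)
        table = ratio_table(records, group_of=group_of, mode=config.roi_mode)
        table.to_csv(out / "roi_ratios.tsv", sep="\t", index=False, float_format="%.10g")
        roi = ratio_summary(records, group_of, mode=config.roi_mode)
        _json_dump(roi, out / "roi_summary.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- combined summary ----------------------------------------------------
    summary = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "enriched_a": len(set_a),
        "enriched_b": len(set_b),
        "only_a": venn.only_a,
        "only_b": venn.only_b,
        "both": venn.both,
        "union": venn.union,
        "recovery": {
            g: {"n_known": e["n_known"], "n_recovered": e["n_recovered"], "fraction": e["fraction"]}
            for g, e in report.to_dict().items()
        },
        "disorder_p": comparison.p_value,
        "disorder_median_target": comparison.median_target,
        "disorder_median_control": comparison.median_control,
        "roi_group_means": {g: v["mean"] for g, v in roi["groups"].items()},
        "roi_pairwise_p": roi["pairwise_p"],
    }
    _json_dump(summary, out / "summary.json")
    logger.info("pipeline done: %s", out / "summary.json")
    return summary
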