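"""End-to-end orchestration: preprocess -> discover -> score -> evaluate -> validate.

A single :class:`RunConfig` drives the run; every stage's artifact is
written under the output directory, stamped with a hash of the config and
the seeds, so an identical config reproduces byte-identical JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import reference, simulate
from .discovery import discover_signature
from .evaluation import evaluate_scores
from .preprocess import preprocess, read_count_table, write_abundance_table, write_count_table
from .score import group_summary, score_cohort
from .tables import TaxaCountTable
from .validation import validate

log = logging.getLogger("wci")


@dataclass
class RunConfig:
    # inputs: either file paths or a synthetic preset
    counts_path: str | None = None
    metadata_path: str | None = None
    blacklist_path: str | None = None
    synthetic_preset: str | None = None  # "table1" | "null"
    level: str = "genus"
    case_label: str = "BCa"
    # preprocessing (defaults = the published run)
    use_default_blacklist: bool = True
    min_count: int = 20
    min_prevalence: float = 0.10
    variance_percentile: float = 10.0
    # discovery
    ntree: int = 1500
    mtry: int | str = "auto"
    mda_threshold: float = 5.0
    # validation
    k: int = 5
    repeats: int = 10
    permutations: int = 1000
    cv_mode: str = "fixed"
    # seeds and output
    seed: int = 20240101
    out_dir: str = "wci_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _round_floats(obj, digits: int = 10):
    if isinstance(obj, float):
        return round(obj, digits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    return obj


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(_round_floats(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_input(config: RunConfig) -> TaxaCountTable:
    if config.synthetic_preset:
        maker = {"table1": simulate.table1_spec, "null": simulate.null_spec}
        if config.synthetic_preset not in maker:
            raise ValueError(f"unknown synthetic preset {config.synthetic_preset!r}")
        spec = maker[config.synthetic_preset](level=config.level, seed=config.seed)
        return simulate.with_ages(simulate.make_cohort(spec), seed=config.seed + 1)
    if not (config.counts_path and config.metadata_path):
        raise ValueError("either file inputs or a synthetic preset is required")
    return read_count_table(
        config.counts_path,
        config.metadata_path,
        level=config.level,
        case_label=config.case_label,
    )


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns a report of artifact paths and summaries."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    report: dict = {"config": asdict(config), **stamp, "artifacts": {}, "stages": {}}
    stage = "load"
    try:
        table = _load_input(config)
        if config.synthetic_preset:
            write_count_table(table, out / "counts.tsv", out / "metadata.tsv")
            report["artifacts"]["counts"] = str(out / "counts.tsv")
            report["artifacts"]["metadata"] = str(out / "metadata.tsv")
        log.info("load: %d samples x %d taxa", *table.counts.shape)

        stage = "preprocess"
        blacklist = list(reference.DEFAULT_CONTAMINANT_BLACKLIST) if config.use_default_blacklist else []
        if config.blacklist_path:
            blacklist += [
                line.strip()
                for line in Path(config.blacklist_path).read_text().splitlines()
                if line.strip()
            ]
        ab, filter_reports = preprocess(
            table,
            blacklist=blacklist,
            min_count=config.min_count,
            min_prevalence=config.min_prevalence,
            variance_percentile=config.variance_percentile,
        )
        for rep in filter_reports:
            log.info(
                "filter %s: %d taxa in -> %d kept",
                rep.stage,
                len(rep.kept_taxa) + len(rep.removed_taxa),
                len(rep.kept_taxa),
            )
        _write_json(out / "filter_reports.json", [r.to_dict() for r in filter_reports])
        write_abundance_table(ab, out / "ra.tsv")
        report["artifacts"]["filter_reports"] = str(out / "filter_reports.json")
        report["artifacts"]["ra"] = str(out / "ra.tsv")
        report["stages"]["preprocess"] = {
            "n_taxa_final": len(ab.taxon_ids),
            "n_samples": len(ab.sample_ids),
        }

        stage = "discover"
        signature, imp = discover_signature(
            ab,
            ntree=config.ntree,
            mtry=config.mtry,
            mda_threshold=config.mda_threshold,
            seed=config.seed,
        )
        signature.to_json(out / "signature.json")
        report["artifacts"]["signature"] = str(out / "signature.json")
        report["stages"]["discover"] = {
            "oob_error": imp.oob_error,
            "n_selected": len(signature.taxa),
        }
        log.info(
            "discover: OOB error %.3f, %d taxa selected",
            imp.oob_error,
            len(signature.taxa),
        )

        stage = "score"
        scores = score_cohort(signature, ab)
        scores.to_csv(out / "scores.tsv", sep="\t", index_label="sample_id", float_format="%.12g")
        report["artifacts"]["scores"] = str(out / "scores.tsv")
        summary = group_summary(scores)
        report["stages"]["score"] = {
            g: {"mean": float(r["mean"]), "sd": float(r["std"]), "n": int(r["count"])}
            for g, r in summary.iterrows()
        }
        log.info("score:\n%s", summary)

        stage = "evaluate"
        age = ab.covariates["age"] if ab.covariates is not None and "age" in ab.covariates else None
        eval_report = evaluate_scores(scores, case_label=ab.case_label, age=age)
        _write_json(out / "report.json", eval_report)
        report["artifacts"]["report"] = str(out / "report.json")
        report["stages"]["evaluate"] = {"auc": eval_report["roc"]["auc"]}

        stage = "validate"
        cv, perm = validate(
            ab,
            signature,
            k=config.k,
            repeats=config.repeats,
            permutations=config.permutations,
            seed=config.seed,
            mode=config.cv_mode,
        )
        _write_json(
            out / "validation.json",
            {"cv": cv.to_dict(), "permutation": perm.to_dict()},
        )
        report["artifacts"]["validation"] = str(out / "validation.json")
        report["stages"]["validate"] = {
            "cv_mean_auc": cv.means["auc"],
            "permutation_p": perm.p,
        }
    except Exception as exc:
        _write_json(out / "run_report.json", {**report, "failed_stage": stage, "error": str(exc)})
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    _write_json(out / "run_report.json", report)
    return report
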