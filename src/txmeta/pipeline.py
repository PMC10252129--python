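"""End-to-end orchestration: simulate -> DGE -> meta-analysis -> ORA -> survival.

Each stage consumes the previous stage's files under the output directory;
a JSON run manifest records every threshold used, per-stage row counts and
the files produced, so that the report (and the tests) can recount
everything without hidden defaults.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import DGEResult, ValidationError
from .enrichment import ora, read_gmt, write_gmt
from .io import read_study, write_fixtures
from .meta import MetaConfig, MetaResult, run_meta
from .preprocess import fit_dge, normalize_study
from .survival import SurvivalCohort, signature_score, cooccurrence_groups
from .synthetic import (
    SimulationConfig,
    make_gene_sets,
    simulate_multistudy,
    simulate_survival_cohort,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml`` for the schema)."""

    out_dir: str
    seed: int = 0
    simulate: dict | None = None
    study_dir: str | None = None
    meta: MetaConfig = dataclasses.field(default_factory=MetaConfig)
    ora: dict = dataclasses.field(default_factory=dict)
    survival: dict = dataclasses.field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base_dir=os.path.dirname(os.path.abspath(path)))

    @classmethod
    def from_dict(cls, raw: dict, base_dir: str = ".") -> "PipelineConfig":
        if "out_dir" not in raw:
            raise ConfigError("config requires out_dir")
        meta_cfg = MetaConfig(**raw.get("meta", {}))
        study_dir = raw.get("study_dir")
        if study_dir is not None:
            study_dir = os.path.join(base_dir, study_dir)
            if not os.path.isdir(study_dir):
                raise ConfigError(f"study_dir does not exist: {study_dir}")
        if study_dir is None and raw.get("simulate") is None:
            raise ConfigError("config needs either simulate: or study_dir:")
        ora_cfg = dict(raw.get("ora", {}))
        if "gmt" in ora_cfg:
            ora_cfg["gmt"] = os.path.join(base_dir, ora_cfg["gmt"])
            if not os.path.exists(ora_cfg["gmt"]):
                raise ConfigError(f"GMT file does not exist: {ora_cfg['gmt']}")
        return cls(
            out_dir=os.path.join(base_dir, raw["out_dir"]),
            seed=int(raw.get("seed", 0)),
            simulate=raw.get("simulate"),
            study_dir=study_dir,
            meta=meta_cfg,
            ora=ora_cfg,
            survival=dict(raw.get("survival", {})),
            log_level=raw.get("log_level", "INFO"),
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and return the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "thresholds": {
            "meta": dataclasses.asdict(config.meta),
            "ora": {
                "min_overlap": int(config.ora.get("min_overlap", 10)),
                "fdr_max": float(config.ora.get("fdr_max", 0.05)),
            },
        },
    }

    studies, truth, cohort, collection = _stage_inputs(config, manifest)
    dge_results = _stage_dge(config, studies, manifest)
    meta_result = _stage_meta(config, dge_results, manifest)
    _stage_ora(config, meta_result, collection, manifest)
    _stage_survival(config, cohort, truth, meta_result, manifest)

    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _stage_inputs(config: PipelineConfig, manifest: dict):
    try:
        collection = None
        if "gmt" in config.ora:
            collection = read_gmt(config.ora["gmt"])
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            surv_kwargs = sim_kwargs.pop("survival", {})
            gene_sets_kwargs = sim_kwargs.pop("gene_sets", {})
            sim_kwargs.setdefault("seed", config.seed)
            sim = SimulationConfig(**sim_kwargs)
            studies, truth = simulate_multistudy(sim)
            surv_kwargs.setdefault("seed", config.seed)
            cohort, surv_truth = simulate_survival_cohort(**surv_kwargs)
            truth.survival = surv_truth.survival
            data_dir = os.path.join(config.out_dir, "data")
            files = write_fixtures(studies, cohort, data_dir, truth=truth)
            if collection is None:
                collection = make_gene_sets(truth, seed=config.seed, **gene_sets_kwargs)
                write_gmt(collection, os.path.join(data_dir, "sets.gmt"))
            manifest["stages"]["simulate"] = {
                "n_studies": len(studies),
                "n_genes": sim.n_genes,
                "n_files": len(files["files"]),
                "dir": data_dir,
            }
        else:
            sheets = [
                f for f in sorted(os.listdir(config.study_dir)) if f.endswith(".samples.csv")
            ]
            ids = [f[: -len(".samples.csv")] for f in sheets]
            if not ids:
                raise ConfigError(f"no studies found in {config.study_dir}")
            studies = [read_study(config.study_dir, sid) for sid in ids]
            truth, cohort = None, None
            if os.path.exists(os.path.join(config.study_dir, "survival.csv")):
                from .io import read_survival

                cohort = read_survival(config.study_dir)
            manifest["stages"]["inputs"] = {"n_studies": len(studies)}
        return studies, truth, cohort, collection
    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'inputs' failed: {exc}") from exc


def _stage_dge(config: PipelineConfig, studies, manifest: dict) -> list[DGEResult]:
    try:
        dge_dir = os.path.join(config.out_dir, "dge")
        os.makedirs(dge_dir, exist_ok=True)
        results = []
        for study in studies:
            norm = normalize_study(study)
            res = fit_dge(norm)
            res.to_tsv(os.path.join(dge_dir, f"{study.study_id}.dge.tsv"))
            results.append(res)
        manifest["stages"]["dge"] = {
            "n_studies": len(results),
            "genes_per_study": {r.study_id: int(len(r.table)) for r in results},
            "dir": dge_dir,
        }
        return results
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'dge' failed: {exc}") from exc


def _stage_meta(config: PipelineConfig, dge_results, manifest: dict) -> MetaResult:
    try:
        result = run_meta(dge_results, config.meta)
        path = os.path.join(config.out_dir, "meta.tsv")
        result.to_tsv(path)
        manifest["stages"]["meta"] = {
            "genes_evaluated": int(len(result.table)),
            "genes_significant": int(result.table["significant"].sum()),
            "genes_loo_stable": int(result.table["loo_stable"].sum()),
            "file": path,
        }
        return result
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'meta' failed: {exc}") from exc


def _stage_ora(config: PipelineConfig, meta_result: MetaResult, collection, manifest: dict):
    try:
        if collection is None:
            manifest["stages"]["ora"] = {"skipped": "no gene-set collection configured"}
            return None
        universe = set(meta_result.table.index)
        collection = collection.with_universe(
            universe & collection.effective_universe()
            if config.ora.get("intersect_universe", True)
            else universe
        )
        sig_up = set(
            meta_result.table.index[
                meta_result.table["significant"] & (meta_result.table["log2fc"] > 0)
            ]
        )
        sig_down = set(
            meta_result.table.index[
                meta_result.table["significant"] & (meta_result.table["log2fc"] < 0)
            ]
        )
        min_overlap = int(config.ora.get("min_overlap", 10))
        fdr_max = float(config.ora.get("fdr_max", 0.05))
        frames = []
        for direction, sig in (("up", sig_up), ("down", sig_down)):
            if not sig:
                continue
            res = ora(sig, collection, min_overlap=min_overlap, fdr_max=fdr_max)
            res.insert(0, "direction", direction)
            frames.append(res)
        out = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(
                columns=["direction", "term", "description", "k", "K", "n", "N", "p", "fdr", "genes"]
            )
        )
        path = os.path.join(config.out_dir, "ora.tsv")
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest["stages"]["ora"] = {
            "terms_reported": int(len(out)),
            "n_up": len(sig_up),
            "n_down": len(sig_down),
            "file": path,
        }
        return out
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'ora' failed: {exc}") from exc


def _stage_survival(config: PipelineConfig, cohort, truth, meta_result, manifest: dict):
    try:
        if cohort is None:
            manifest["stages"]["survival"] = {"skipped": "no survival cohort configured"}
            return None
        genes = config.survival.get("signature")
        if genes is None and truth is not None and truth.survival:
            genes = truth.survival.get("signature_genes")
        if genes is None:
            manifest["stages"]["survival"] = {"skipped": "no signature configured"}
            return None
        result = signature_score(cohort, genes, cox=True)
        surv_dir = os.path.join(config.out_dir, "survival")
        os.makedirs(surv_dir, exist_ok=True)

        assign = pd.DataFrame(
            {"count": result.counts, "risk": result.risk}
        )
        assign.index.name = "sample_id"
        assign_path = os.path.join(surv_dir, "signature_assignment.csv")
        assign.to_csv(assign_path)

        km_frames = []
        for label, curve in result.km.items():
            c = curve.copy()
            c.insert(0, "group", label)
            km_frames.append(c)
        km_path = os.path.join(surv_dir, "km_curves.tsv")
        pd.concat(km_frames, ignore_index=True).to_csv(
            km_path, sep="\t", index=False, float_format="%.10g"
        )

        cooc = cooccurrence_groups(result.indicator)
        summary = {
            "signature_size": len(result.genes),
            "cutoff": result.cutoff,
            "n_high": int((result.risk == "high").sum()),
            "n_low": int((result.risk == "low").sum()),
            "logrank_chi2": result.logrank[0] if result.logrank else None,
            "logrank_p": result.logrank[2] if result.logrank else None,
            "cox_hr": float(result.cox.summary.loc["high_risk", "hr"]) if result.cox else None,
            "cox_p": float(result.cox.summary.loc["high_risk", "p"]) if result.cox else None,
            "cooccurrence_clusters": {
                str(g): int(c) for g, c in cooc["clusters"].items()
            },
        }
        summary_path = os.path.join(surv_dir, "summary.json")
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        manifest["stages"]["survival"] = {
            "n_samples": int(len(cohort.table)),
            "files": [assign_path, km_path, summary_path],
            "cutoff": result.cutoff,
            "logrank_p": summary["logrank_p"],
        }
        return result
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'survival' failed: {exc}") from exc


# ---------------------------------------------------------------------------
# Static report
# ---------------------------------------------------------------------------

def export_report(manifest: dict, out_path: str | None = None, top_n: int = 20) -> str:
    """Render a static HTML summary of a completed run.

    The report shows the per-stage counts, the top genes of the meta-analysis
    table and the enrichment/survival summaries; every number is read back
    from the TSV/JSON files the run produced.
    """
    stages = manifest.get("stages", {})
    missing = [s for s in ("dge", "meta") if s not in stages]
    if missing:
        raise StageError(f"incomplete run; missing stages: {missing}")
    meta_path = stages["meta"]["file"]
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    n_sig = int(meta["significant"].sum())

    parts = [
        "<html><head><meta charset='utf-8'><title>txmeta report</title></head><body>",
        "<h1>Transcriptomic meta-analysis report</h1>",
        f"<p>txmeta version {manifest.get('version', '?')}, seed {manifest.get('seed')}.</p>",
        "<h2>Stage summary</h2>",
        "<pre>" + json.dumps({k: v for k, v in stages.items()}, indent=1, sort_keys=True) + "</pre>",
        "<h2>Thresholds</h2>",
        "<pre>" + json.dumps(manifest.get("thresholds", {}), indent=1, sort_keys=True) + "</pre>",
        f"<h2>Meta-analysis</h2><p>{len(meta)} genes evaluated; "
        f"{n_sig} significant genes.</p>",
        meta.head(top_n).to_html(float_format=lambda v: f"{v:.4g}"),
    ]
    if "ora" in stages and "file" in stages["ora"]:
        ora_table = pd.read_csv(stages["ora"]["file"], sep="\t")
        parts.append(
            f"<h2>Over-representation</h2><p>{len(ora_table)} reported terms.</p>"
        )
        if len(ora_table):
            parts.append(ora_table.head(top_n).to_html(index=False))
    if "survival" in stages and "files" in stages["survival"]:
        with open(stages["survival"]["files"][-1]) as fh:
            surv = json.load(fh)
        parts.append("<h2>Survival signature</h2><pre>" + json.dumps(surv, indent=1, sort_keys=True) + "</pre>")
    parts.append("</body></html>")
    html = "\n".join(parts)
    if out_path is None:
        out_dir = os.path.dirname(meta_path)
        out_path = os.path.join(out_dir, "report.html")
    with open(out_path, "w") as fh:
        fh.write(html)
    return out_path
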