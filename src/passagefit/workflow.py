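"""Reproducible workflows with config validation, seeds, and provenance.

A run is described by a single YAML config with a versioned schema;
unknown keys are errors. One global seed expands deterministically into
per-stage seeds by hashing the stage name, so adding a stage never
shifts the random stream of an earlier one. Every run writes a manifest
recording the config snapshot, seeds, and a checksum for each output
file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import amplicon, copynum, model, simulate
from .design import (
    CovariateSetting,
    SimulationDesign,
    TrueParameters,
    exponential_design,
    saturation_design,
)
from .errors import PassagefitError, StageError, ValidationError

logger = logging.getLogger("passagefit")

SCHEMA_VERSION = 1

_SCHEMAS: dict[str, dict] = {
    "simulate_fit": {
        "workflow": None,
        "schema_version": None,
        "design": {
            "preset", "n_replicates", "read_depth", "bottleneck_cells",
            "conditions", "days",
        },
        "params": {
            "w_base", "beta_mat", "beta_cocl2", "beta_glucose",
            "beta_tf_null", "p0",
        },
        "model": {
            "recursion_variant", "likelihood", "active_betas", "fixed_p0",
            "walkers", "warmup", "steps", "hpdi_prob",
        },
    },
    "count_fit": {
        "workflow": None,
        "schema_version": None,
        "fastq": None,
        "samples": None,
        "alleles": None,
        "model": {
            "recursion_variant", "likelihood", "active_betas", "fixed_p0",
            "walkers", "warmup", "steps", "hpdi_prob",
        },
    },
    "copynum": {
        "workflow": None,
        "schema_version": None,
        "reads": None,
        "te": None,
        "panel": None,
        "k": None,
        "max_mismatch_per_100": None,
    },
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def params_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def validate_config(config: dict, workflow: str | None = None) -> str:
    """Check a workflow config against its schema; returns the workflow name."""
    if not isinstance(config, dict):
        raise ValidationError("config must be a mapping")
    workflow = workflow or config.get("workflow")
    if workflow not in _SCHEMAS:
        raise ValidationError(
            f"unknown workflow {workflow!r}; expected one of {sorted(_SCHEMAS)}"
        )
    schema = _SCHEMAS[workflow]
    offending = sorted(set(config) - set(schema))
    if offending:
        raise ValidationError(f"unknown config keys: {offending}")
    version = config.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValidationError(f"unsupported schema_version {version}")
    for key, allowed in schema.items():
        if allowed is not None and key in config and config[key] is not None:
            sub = config[key]
            if not isinstance(sub, dict):
                raise ValidationError(f"config section {key!r} must be a mapping")
            bad = sorted(set(sub) - allowed)
            if bad:
                raise ValidationError(f"unknown config keys in {key!r}: {bad}")
    required = {
        "count_fit": ("fastq", "samples", "alleles"),
        "copynum": ("reads", "te", "panel"),
    }.get(workflow, ())
    missing = [key for key in required if key not in config]
    if missing:
        raise ValidationError(f"workflow {workflow!r} missing config keys: {missing}")
    return workflow


def design_from_config(cfg: dict, seed: int) -> SimulationDesign:
    cfg = dict(cfg or {})
    preset = cfg.pop("preset", "exponential")
    if "conditions" in cfg:
        cfg["conditions"] = tuple(
            CovariateSetting(**c) for c in cfg["conditions"]
        )
    if "bottleneck_cells" in cfg and cfg["bottleneck_cells"] in ("inf", None):
        cfg["bottleneck_cells"] = math.inf
    cfg.pop("days", None)
    if preset == "exponential":
        return exponential_design(seed=seed, **cfg)
    if preset == "saturation":
        return saturation_design(seed=seed, **cfg)
    raise ValidationError(f"unknown design preset {preset!r}")


def model_spec_from_config(cfg: dict, seed: int) -> model.ModelSpec:
    cfg = dict(cfg or {})
    if "active_betas" in cfg:
        cfg["active_betas"] = tuple(cfg["active_betas"])
    return model.ModelSpec(seed=seed, **cfg)


@dataclass
class RunManifest:
    workflow: str
    config: dict
    seed: int
    stage_seeds: dict[str, int] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    status: str = "running"
    started: str = ""
    finished: str = ""

    def record_output(self, path: Path) -> None:
        self.outputs[str(path)] = _sha256(path)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def validate_manifest(manifest_path: str | Path) -> bool:
    """Re-checksum every output listed in a manifest; False on any mismatch."""
    data = json.loads(Path(manifest_path).read_text())
    for path, digest in data.get("outputs", {}).items():
        p = Path(path)
        if not p.exists() or _sha256(p) != digest:
            return False
    return True


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def run_workflow(
    config: dict | str | Path,
    outdir: str | Path,
    seed: int = 0,
    workflow: str | None = None,
) -> RunManifest:
    """Execute a workflow end to end and write its manifest.

    Re-running with the same config and seed reproduces identical numeric
    outputs. Raises :class:`ValidationError` for bad configs and
    :class:`StageError` (with the failed stage recorded in the manifest)
    for runtime failures.
    """
    if not isinstance(config, dict):
        config_path = Path(config)
        config = yaml.safe_load(config_path.read_text())
    workflow = validate_config(config, workflow)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        workflow=workflow, config=config, seed=seed, started=_now()
    )
    for path_key in ("fastq", "samples", "alleles", "reads", "te", "panel"):
        if path_key in config:
            p = Path(config[path_key])
            if p.exists():
                manifest.inputs[str(p)] = _sha256(p)

    def run_stage(name: str, fn):
        s = stage_seed(seed, name)
        manifest.stage_seeds[name] = s
        logger.info(
            "stage=%s seed=%d params_hash=%s", name, s, params_hash(config)
        )
        try:
            out = fn(s)
        except PassagefitError:
            manifest.stages.append({"name": name, "status": "failed"})
            manifest.status = "failed"
            manifest.finished = _now()
            manifest.save(outdir / "manifest.json")
            raise
        except Exception as exc:
            manifest.stages.append({"name": name, "status": "failed"})
            manifest.status = "failed"
            manifest.finished = _now()
            manifest.save(outdir / "manifest.json")
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest.stages.append({"name": name, "status": "ok"})
        return out

    if workflow == "simulate_fit":
        def _simulate(s):
            design = design_from_config(config.get("design"), seed=s)
            params = TrueParameters(**(config.get("params") or {}))
            ds = simulate.simulate_experiment(design, params)
            counts_path = outdir / "counts.tsv"
            truth_path = outdir / "truth.json"
            ds.write_counts(counts_path)
            ds.write_truth(truth_path)
            manifest.record_output(counts_path)
            manifest.record_output(truth_path)
            return ds

        ds = run_stage("simulate", _simulate)

        def _fit(s):
            spec = model_spec_from_config(config.get("model"), seed=s)
            dataset = model.CompetitionDataset.from_table(ds.counts)
            summary = model.sample_posterior(dataset, spec)
            summary.save(outdir / "posterior")
            manifest.record_output(outdir / "posterior" / "posterior_summary.tsv")
            manifest.record_output(outdir / "posterior" / "posterior_draws.tsv")
            return summary

        run_stage("fit", _fit)

    elif workflow == "count_fit":
        def _count(s):
            sheet = amplicon.read_sample_sheet(config["samples"])
            alleles = amplicon.load_alleles(config["alleles"])
            table, log = amplicon.count_reads(config["fastq"], sheet, alleles)
            counts_path = outdir / "counts.tsv"
            table.to_csv(counts_path, sep="\t", index=False)
            (outdir / "processing_log.json").write_text(
                json.dumps(asdict(log), indent=2) + "\n"
            )
            manifest.record_output(counts_path)
            manifest.record_output(outdir / "processing_log.json")
            return table

        table = run_stage("count", _count)

        def _fit(s):
            spec = model_spec_from_config(config.get("model"), seed=s)
            dataset = model.CompetitionDataset.from_table(table)
            summary = model.sample_posterior(dataset, spec)
            summary.save(outdir / "posterior")
            manifest.record_output(outdir / "posterior" / "posterior_summary.tsv")
            manifest.record_output(outdir / "posterior" / "posterior_draws.tsv")
            return summary

        run_stage("fit", _fit)

    elif workflow == "copynum":
        def _estimate(s):
            te = copynum._read_seqs(config["te"])
            panel = copynum._read_seqs(config["panel"])
            targets = te + panel
            result = copynum.assign_reads(
                config["reads"],
                targets,
                k=int(config.get("k", 21)),
                max_mismatch_per_100=float(config.get("max_mismatch_per_100", 3.0)),
            )
            estimates = copynum.estimate_copy_number(
                result.coverage,
                families=[n for n, _ in te],
                panel_genes=[n for n, _ in panel],
            )
            est_path = outdir / "copynum.tsv"
            copynum.estimates_to_frame(estimates).to_csv(est_path, sep="\t", index=False)
            manifest.record_output(est_path)
            return estimates

        run_stage("estimate", _estimate)

    manifest.status = "ok"
    manifest.finished = _now()
    manifest.save(outdir / "manifest.json")
    return manifest
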