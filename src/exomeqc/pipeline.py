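"""The two-stage calling workflow, end to end.

Stage 1 (cohort curation): simulate or load a cohort's intensities,
build per-variant cluster models, call genotypes, compute metrics, flag
variants under a ruleset, recluster the flagged variants, re-call, run
the QC cascade, and write the curated cluster model out as a JSON
cluster file.

Stage 2 (transfer): call an independent cohort on the same variant
panel twice — once with the stage-1 custom cluster file and once with
models built from the new cohort's own data (the "default" clustering)
— run QC on both call sets, and compare the surviving variant sets
(shared / unique-to-custom / unique-to-default).

All artifacts are deterministic functions of the configuration and
seed; a run log records every threshold used.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from . import io_formats
from .caller import CallerConfig, build_cluster_models, call_genotypes, recluster_flagged
from .concord import compare_variant_sets
from .containers import GenotypeMatrix
from .metrics import metrics_table
from .qc import QCConfig, run_qc
from .rules import apply_ruleset, builtin_ruleset, summarize_flags
from .simdata import SimConfig, simulate_dataset

__all__ = ["run_stage1", "run_stage2", "run_pipeline"]


def _write_json(path: Path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def _log(out: Path, stage: str, sim: SimConfig, caller: CallerConfig,
         qc: QCConfig, ruleset_name: str) -> None:
    _write_json(out / "run_log.json", {
        "stage": stage,
        "seed": sim.seed,
        "sim": {k: v for k, v in dataclasses.asdict(sim).items()
                if k != "cluster_geometry"},
        "cluster_geometry": dataclasses.asdict(sim.cluster_geometry),
        "caller": dataclasses.asdict(caller),
        "qc": dataclasses.asdict(qc),
        "ruleset": ruleset_name,
    })


def run_stage1(
    sim: SimConfig,
    out_dir: str | Path,
    caller: CallerConfig = CallerConfig(),
    qc: QCConfig = QCConfig(),
    ruleset_name: str = "adjusted",
) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = simulate_dataset(sim)
    shrink = set(bundle.error_variants("short_boundary"))
    model = build_cluster_models(bundle.intensities, caller, shrink_variants=shrink)
    calls = call_genotypes(bundle.intensities, model, caller)
    table = metrics_table(calls, bundle.intensities, model)
    ruleset = builtin_ruleset(ruleset_name)
    report = apply_ruleset(table, ruleset)
    revised, status = recluster_flagged(bundle.intensities, model, report, caller, ruleset)
    # zeroed variants leave the dataset at curation time, like variants
    # dropped during manual review; QC sees only callable variants
    callable_ids = set(revised.callable_variants())
    keep = [v for v in bundle.intensities.variant_ids if v in callable_ids]
    final_calls = call_genotypes(bundle.intensities.subset(variant_ids=keep),
                                 revised, caller)
    qc_report = run_qc(final_calls, bundle.variant_meta,
                       dict(zip(bundle.sample_meta["sample_id"],
                                bundle.sample_meta["declared_sex"])), qc)

    io_formats.write_final_report(out / "intensities.tsv", bundle.intensities)
    bundle.sample_meta.to_csv(out / "sample_meta.tsv", sep="\t", index=False)
    bundle.variant_meta.to_csv(out / "variant_meta.tsv", sep="\t", index=False)
    bundle.error_registry.to_csv(out / "error_registry.tsv", sep="\t", index=False)
    table.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.6g")
    report.hits.to_csv(out / "flags.tsv", sep="\t", index=False)
    summarize_flags(report).to_frame().to_csv(out / "flag_summary.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(status.items()), columns=["variant_id", "status"]).to_csv(
        out / "recluster_status.tsv", sep="\t", index=False)
    io_formats.write_cluster_json(out / "cluster_model.json", revised)
    qc_report.excluded_samples.to_csv(out / "qc_excluded_samples.tsv", sep="\t", index=False)
    qc_report.excluded_variants.to_csv(out / "qc_excluded_variants.tsv", sep="\t", index=False)
    io_formats.write_ped_map(out / "calls", final_calls, bundle.variant_meta,
                             bundle.sample_meta)
    _write_json(out / "qc_summary.json", {
        "excluded_samples": qc_report.sample_counts(),
        "excluded_variants": qc_report.variant_counts(),
        "n_samples_out": len(qc_report.surviving_samples),
        "n_variants_out": len(qc_report.surviving_variants),
    })
    _log(out, "stage1", sim, caller, qc, ruleset_name)
    return {
        "bundle": bundle, "model": revised, "calls": final_calls,
        "flag_report": report, "recluster_status": status, "qc": qc_report,
    }


def run_stage2(
    sim: SimConfig,
    cluster_file: str | Path,
    out_dir: str | Path,
    caller: CallerConfig = CallerConfig(),
    qc: QCConfig = QCConfig(),
) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    custom = io_formats.read_cluster_json(cluster_file)
    bundle = simulate_dataset(sim)
    missing = [v for v in bundle.intensities.variant_ids if v not in custom]
    if missing:
        raise ValueError(
            f"{len(missing)} cohort variants absent from the cluster file; "
            "stage-2 cohorts must share the stage-1 variant panel")
    sexes = dict(zip(bundle.sample_meta["sample_id"], bundle.sample_meta["declared_sex"]))

    default_model = build_cluster_models(bundle.intensities, caller)
    results = {}
    for label, model in (("custom", custom), ("default", default_model)):
        callable_ids = set(model.callable_variants())
        keep = [v for v in bundle.intensities.variant_ids if v in callable_ids]
        calls = call_genotypes(bundle.intensities.subset(variant_ids=keep),
                               model, caller)
        report = run_qc(calls, bundle.variant_meta, sexes, qc)
        results[label] = report
        report.excluded_variants.to_csv(out / f"qc_excluded_variants_{label}.tsv",
                                        sep="\t", index=False)
    shared, only_custom, only_default = compare_variant_sets(
        results["custom"].surviving_variants, results["default"].surviving_variants)
    venn = {"shared": shared, "unique_custom": only_custom,
            "unique_default": only_default}
    _write_json(out / "venn.json", venn)
    _log(out, "stage2", sim, caller, qc, "-")
    return {"bundle": bundle, "qc": results, "venn": venn}


def run_pipeline(config: dict) -> dict:
    """Dispatch a stage config (e.g. parsed from YAML).

    Keys: ``stage`` (1 or 2), ``out_dir``, optional ``sim`` /
    ``caller`` / ``qc`` override mappings, ``ruleset`` (stage 1),
    ``cluster_file`` (stage 2, required)."""
    stage = config.get("stage")
    sim_kwargs = dict(config.get("sim", {}))
    if "error_mode_rates" in sim_kwargs:
        rates = sim_kwargs["error_mode_rates"]
        if isinstance(rates, dict):
            sim_kwargs["error_mode_rates"] = tuple(rates.items())
        else:
            sim_kwargs["error_mode_rates"] = tuple(tuple(x) for x in rates)
    sim = SimConfig(**sim_kwargs)
    caller = CallerConfig(**config.get("caller", {}))
    qc = QCConfig(**config.get("qc", {}))
    out_dir = config["out_dir"]
    if stage == 1:
        return run_stage1(sim, out_dir, caller, qc, config.get("ruleset", "adjusted"))
    if stage == 2:
        if "cluster_file" not in config:
            raise ValueError("stage-2 configuration needs a cluster_file")
        return run_stage2(sim, config["cluster_file"], out_dir, caller, qc)
    raise ValueError("config['stage'] must be 1 or 2")
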