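"""Config-driven orchestration of the full analysis.

One YAML config describes the inputs and decision constants for every
stage; validation reports all problems at once before any computation.
Stages are independent except that the differential screen consumes the
two conservation profiles and the conformational call consumes the
geometry report; a failing stage halts only its dependents.  Runs are
deterministic given the config (all seeds explicit) and the consolidated
JSON report embeds versions, thresholds and method tags, never timestamps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .binding import fit_dose_response, fit_total_binding, load_curve
from .classify import SpatialThresholds, classify, load_cluster_library
from .conservation import METHOD_TAG, compute_profile, read_msa
from .differential import assign_regions, coverage_difference, deltas_to_tsv, grade_delta, load_region_spans
from .panel import classify_groups, load_panel_table, overlap
from .structure import AMPK_ALPHA2_ANCHORS, KinaseAnchors, geometry_report, read_structure

logger = logging.getLogger("kinprof")

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_anchors", "run"]


class ConfigError(ValueError):
    """Aggregated configuration problems; message lists every issue."""


@dataclass
class RunConfig:
    output_dir: Path
    stages: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({"output_dir": str(self.output_dir), "stages": self.stages},
                           sort_keys=True)
        )


def load_anchors(source: str | Path | dict | None) -> KinaseAnchors:
    """Anchor residues from a YAML file/dict; defaults to AMPKalpha2."""
    if source is None:
        return AMPK_ALPHA2_ANCHORS
    raw = source if isinstance(source, dict) else yaml.safe_load(Path(source).read_text())
    kwargs = dict(raw)
    for key in ("xdfgx_span", "spine_residues"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "disulfide_candidates" in kwargs:
        kwargs["disulfide_candidates"] = tuple(tuple(p) for p in kwargs["disulfide_candidates"])
    return KinaseAnchors(**kwargs)


def validate_config(source: str | Path | dict) -> RunConfig:
    """Parse and validate a run config, aggregating all errors."""
    if isinstance(source, dict):
        raw = source
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    errors: list[str] = []
    stages = raw.get("stages", {}) or {}
    if not stages:
        errors.append("config defines no stages")

    def need_file(stage: str, key: str, required: bool = True) -> None:
        val = stages.get(stage, {}).get(key)
        if val is None:
            if required:
                errors.append(f"{stage}: missing required path {key!r}")
            return
        if not Path(val).exists():
            errors.append(f"{stage}: file not found: {val}")

    if "panel" in stages:
        need_file("panel", "table")
        if not stages["panel"].get("compound"):
            errors.append("panel: missing 'compound'")
        lo = stages["panel"].get("inhibited_cutoff", 50)
        hi = stages["panel"].get("noninhibited_cutoff", 99)
        if not lo < hi:
            errors.append(f"panel: inhibited_cutoff ({lo}) must be < noninhibited_cutoff ({hi})")
    if "conservation" in stages:
        need_file("conservation", "inhibited_msa")
        need_file("conservation", "noninhibited_msa")
        for key in ("reference_id", "first_residue", "seed"):
            if stages["conservation"].get(key) is None:
                errors.append(f"conservation: missing {key!r}")
    if "differential" in stages and "conservation" not in stages:
        errors.append("differential: requires the conservation stage")
    if "geometry" in stages:
        need_file("geometry", "structure")
        need_file("geometry", "anchors", required=False)
    if "classification" in stages:
        if "geometry" not in stages:
            errors.append("classification: requires the geometry stage")
        need_file("classification", "cluster_library", required=False)
    if "binding" in stages:
        need_file("binding", "curve")
        model = stages["binding"].get("model", "total-binding")
        if model not in ("total-binding", "dose-response"):
            errors.append(f"binding: unknown model {model!r}")

    if errors:
        raise ConfigError("invalid config:\n  - " + "\n  - ".join(errors))
    return RunConfig(output_dir=Path(raw.get("output_dir", "kinprof-out")), stages=stages)


def run(config: RunConfig) -> dict:
    """Execute all configured stages; returns the consolidated report.

    The report (also written to ``<output_dir>/report.json``) contains one
    entry per stage with either its results or its error; dependent stages
    are skipped when their inputs failed.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": 1,
        "kinprof_version": __version__,
        "stages": {},
    }
    stages = config.stages
    state: dict = {}

    def run_stage(name, fn):
        if name not in stages:
            return
        try:
            logger.info("[%s] running", name)
            report["stages"][name] = {"status": "ok", **fn(stages[name])}
        except Exception as exc:  # failure must not silence other stages
            logger.error("[%s] failed: %s", name, exc)
            report["stages"][name] = {"status": "error", "error": str(exc)}

    def stage_panel(cfg):
        kwargs = {
            k.replace("-", "_"): v
            for k, v in cfg.items()
            if k in ("kinase_col", "compound_col", "activity_col")
        }
        records = load_panel_table(cfg["table"], **kwargs)
        groups = classify_groups(
            records, cfg["compound"],
            inhibited_cutoff=cfg.get("inhibited_cutoff", 50),
            noninhibited_cutoff=cfg.get("noninhibited_cutoff", 99),
        )
        groups.to_json(out / "panel_groups.json")
        result = {
            "compound": groups.compound_id,
            "n_inhibited": len(groups.inhibited),
            "n_noninhibited": len(groups.noninhibited),
            "n_unclassified": len(groups.unclassified),
            "inhibited_cutoff": groups.inhibited_cutoff,
            "noninhibited_cutoff": groups.noninhibited_cutoff,
        }
        if cfg.get("compound_b"):
            groups_b = classify_groups(
                records, cfg["compound_b"],
                inhibited_cutoff=cfg.get("inhibited_cutoff", 50),
                noninhibited_cutoff=cfg.get("noninhibited_cutoff", 99),
            )
            venn = overlap(groups, groups_b)
            result["overlap"] = {
                "compound_b": cfg["compound_b"],
                **venn.counts,
                "both": sorted(venn.both),
            }
        return result

    def stage_conservation(cfg):
        profiles = {}
        for group in ("inhibited", "noninhibited"):
            aln = read_msa(cfg[f"{group}_msa"])
            prof = compute_profile(
                aln,
                reference_id=cfg["reference_id"],
                first_residue_number=int(cfg["first_residue"]),
                seed=int(cfg["seed"]),
                msa_id=group,
                n_bootstrap=int(cfg.get("n_bootstrap", 200)),
            )
            prof.to_tsv(out / f"conservation_{group}.tsv")
            profiles[group] = prof
        state["profiles"] = profiles
        return {
            "method_tag": METHOD_TAG,
            "n_columns": {g: len(p.columns) for g, p in profiles.items()},
            "n_low_confidence": {
                g: sum(c.low_confidence for c in p.columns) for g, p in profiles.items()
            },
        }

    def stage_differential(cfg):
        if "profiles" not in state:
            raise RuntimeError("conservation stage did not complete")
        prof = state["profiles"]
        deltas = grade_delta(
            prof["inhibited"], prof["noninhibited"],
            min_delta=int(cfg.get("min_delta", 3)),
            omit_low_confidence=bool(cfg.get("omit_low_confidence", True)),
        )
        spans = load_region_spans(cfg.get("region_spans"))
        assign_regions(deltas, spans)
        deltas_to_tsv(deltas, out / "differential.tsv")
        cov = coverage_difference(prof["inhibited"], prof["noninhibited"])
        regions: dict[str, int] = {}
        for d in deltas:
            regions[d.region] = regions.get(d.region, 0) + 1
        return {
            "n_retained": len(deltas),
            "by_region": regions,
            "coverage_only_one_group": {k: len(v) for k, v in cov.items()},
        }

    def stage_geometry(cfg):
        model = read_structure(cfg["structure"])
        anchors = load_anchors(cfg.get("anchors"))
        if cfg.get("chain"):
            anchors = KinaseAnchors(**{**anchors.__dict__, "chain_id": cfg["chain"]})
        missing = anchors.validate(model)
        if missing:
            raise RuntimeError(f"anchor residues missing from structure: {missing}")
        rep = geometry_report(model, anchors)
        rep.to_json(out / "geometry.json")
        state["geometry"] = (model, anchors, rep)
        return rep.to_dict()

    def stage_classification(cfg):
        if "geometry" not in state:
            raise RuntimeError("geometry stage did not complete")
        model, anchors, _ = state["geometry"]
        thresholds = SpatialThresholds(
            dfg_out_d2_max=float(cfg.get("dfg_out_d2_max", 11.0)),
            dfg_in_min_separation=float(cfg.get("dfg_in_min_separation", 2.0)),
            alphac_out_min=float(cfg.get("alphac_out_min", 10.0)),
        )
        library = load_cluster_library(cfg.get("cluster_library"))
        call = classify(model, anchors, library, thresholds)
        call.to_json(out / "conformation.json")
        d = call.to_dict()
        d.pop("geometry", None)
        return d

    def stage_binding(cfg):
        curve = load_curve(cfg["curve"])
        model = cfg.get("model", "total-binding")
        if model == "total-binding":
            fit = fit_total_binding(curve)
            params = {
                "bmax": fit.bmax, "kd": fit.kd, "ns": fit.ns, "background": fit.background,
            }
        else:
            fit = fit_dose_response(curve)
            params = {
                "top": fit.top, "bottom": fit.bottom,
                "ic50": fit.ic50, "hill_slope": fit.hill_slope,
            }
        result = {
            "model": model,
            "parameters": params,
            "standard_errors": fit.se,
            "rss": fit.rss,
            "converged": fit.converged,
        }
        (out / "binding_fit.json").write_text(json.dumps(result, indent=2, sort_keys=True) + "\n")
        return result

    run_stage("panel", stage_panel)
    run_stage("conservation", stage_conservation)
    run_stage("differential", stage_differential)
    run_stage("geometry", stage_geometry)
    run_stage("classification", stage_classification)
    run_stage("binding", stage_binding)

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
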