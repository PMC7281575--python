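"""End-to-end orchestration: trim -> optimize -> pick -> correct -> enrich.

A pipeline run is driven by a single structured config (dict or YAML file),
executes the enabled stages in order on disk artifacts, and records a
manifest with parameters, seeds, wall-clock times and output hashes so that
identical config + seed reproduces identical deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import batch as _batch
from . import mummichog as _mm
from .optimize import optimize_params, platform_defaults
from .peaks import detect_isotopes, group_and_align, pick_peaks
from .spectra import read_spectra, write_spectra
from .trim import TrimSpec, select_rois, trim_run

__all__ = ["PipelineError", "validate_config", "run_pipeline"]

STAGE_ORDER = ("trim", "optimize", "pick", "correct", "enrich")


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_config(config: Mapping) -> dict:
    """Validate stage wiring and referenced files; return a normalized copy."""
    cfg = {k: dict(v) if isinstance(v, Mapping) else v for k, v in config.items()}
    cfg.setdefault("seed", 0)
    cfg.setdefault("out_dir", "metaboflow_out")
    stages = cfg.setdefault("stages", {})
    for name in STAGE_ORDER:
        stages.setdefault(name, False)
    enabled = [s for s in STAGE_ORDER if stages[s]]
    if not enabled:
        raise PipelineError("config enables no stages")
    if (stages["trim"] or stages["pick"] or stages["optimize"]) and not cfg.get("inputs"):
        raise PipelineError("trim/optimize/pick enabled but no 'inputs' spectra listed")
    for path in cfg.get("inputs", []):
        if not Path(path).exists():
            raise PipelineError(f"input file missing: {path}")
    if stages["pick"] and not (stages["optimize"] or cfg.get("params")):
        cfg["params"] = {}
    if stages["correct"] and not (stages["pick"] or cfg.get("table")):
        raise PipelineError("correct enabled without an upstream peak table ('table')")
    if stages["enrich"]:
        if not (stages["pick"] or cfg.get("peak_list")):
            raise PipelineError("enrich enabled without an upstream peak list ('peak_list')")
        if not cfg.get("library"):
            raise PipelineError("enrich requires a 'library' file (pathway -> compounds)")
        if not cfg.get("compounds"):
            raise PipelineError("enrich requires a 'compounds' file (id, mass)")
    return cfg


def run_pipeline(config: Mapping) -> dict:
    """Execute the enabled stages in order and return the manifest."""
    cfg = validate_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg["seed"], "stages": [], "config": json.loads(json.dumps(cfg, default=str))}
    runs = None
    params = None
    feature_table = None

    def record(stage: str, started: float, outputs: dict) -> None:
        rec = {
            "stage": stage,
            "wall_seconds": round(time.time() - started, 3),
            "outputs": {},
        }
        for name, path in outputs.items():
            p = Path(path)
            rec["outputs"][name] = {"path": str(p), "sha256": _sha256(p)}
        manifest["stages"].append(rec)

    stages = cfg["stages"]
    try:
        if stages["trim"]:
            t0 = time.time()
            spec = TrimSpec(**cfg.get("trim", {}))
            runs = []
            outputs = {}
            for path in cfg["inputs"]:
                run = read_spectra(path)
                rois = select_rois(run, spec) if spec.strategy == "ssm" else None
                trimmed = trim_run(run, spec, rois)
                out = out_dir / f"trimmed_{Path(path).stem}.mzML"
                write_spectra(trimmed, out)
                runs.append(trimmed)
                outputs[Path(path).stem] = out
            record("trim", t0, outputs)
        if stages["optimize"]:
            t0 = time.time()
            if runs is None:
                runs = [read_spectra(p) for p in cfg["inputs"]]
            opt_cfg = cfg.get("optimize", {})
            init = platform_defaults(opt_cfg.get("platform", "generic"))
            result = optimize_params(
                runs,
                init=init,
                max_rounds=int(opt_cfg.get("max_rounds", 3)),
                rel_tol=float(opt_cfg.get("rel_tol", 0.05)),
            )
            params = result.best_params
            out = out_dir / "best_params.yaml"
            import yaml

            out.write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))
            hist = out_dir / "history.json"
            hist.write_text(json.dumps(result.history, indent=1, default=float))
            record("optimize", t0, {"best_params": out, "history": hist})
        if stages["pick"]:
            t0 = time.time()
            if runs is None:
                runs = [read_spectra(p) for p in cfg["inputs"]]
            if params is None:
                base = platform_defaults(cfg.get("pick", {}).get("platform", "generic"))
                params = replace(base, **cfg.get("params", {}))
            peaks_by_sample = [pick_peaks(r, params) for r in runs]
            fs = group_and_align(peaks_by_sample, params)
            detect_isotopes(fs, ppm=max(params.ppm, 5.0))
            rows = []
            for i, f in enumerate(fs.features):
                row = {"feature": f"F{i + 1}", "mz": f.mz, "rt": f.rt}
                for s, run in enumerate(runs):
                    peak = f.members.get(s)
                    row[run.sample_id] = peak.area if peak else np.nan
                rows.append(row)
            feature_table = pd.DataFrame(rows)
            out = out_dir / "feature_table.tsv"
            feature_table.to_csv(out, sep="\t", index=False)
            record("pick", t0, {"feature_table": out})
        if stages["correct"]:
            t0 = time.time()
            if cfg.get("table"):
                table = pd.read_csv(cfg["table"], sep="\t", index_col=0)
            elif feature_table is not None:
                table = feature_table.set_index("feature").drop(columns=["mz", "rt"])
            else:
                raise PipelineError("correct: no feature table available")
            design = _batch.BatchDesign.from_frame(pd.read_csv(cfg["design"], sep="\t"))
            methods = cfg.get("correct", {}).get(
                "methods", ("eigenms", "combat", "qc_rlsc", "none")
            )
            result = _batch.select_best_correction(table.fillna(0.0), design, methods)
            out = out_dir / "corrected.tsv"
            result.corrected.to_csv(out, sep="\t")
            report = out_dir / "correction_report.json"
            report.write_text(
                json.dumps(
                    {
                        "method": result.method,
                        "score": result.score,
                        "ordination": result.ordination_used,
                        "gradient_length": result.gradient_length,
                        "log": result.log,
                    },
                    indent=1,
                )
            )
            record("correct", t0, {"corrected": out, "report": report})
        if stages["enrich"]:
            t0 = time.time()
            if cfg.get("peak_list"):
                peak_list = pd.read_csv(cfg["peak_list"], sep="\t")
            else:
                raise PipelineError("enrich: provide 'peak_list' (mz, rt, p columns)")
            library = {
                k: set(v) for k, v in json.loads(Path(cfg["library"]).read_text()).items()
            }
            compounds = pd.read_csv(cfg["compounds"], sep="\t")
            mm_params = _mm.MummichogParams(
                seed=int(cfg["seed"]), **cfg.get("enrich", {})
            )
            rows = _mm.enrich_mummichog(peak_list, library, compounds, mm_params)
            out = out_dir / "pathways.tsv"
            pd.DataFrame(
                [
                    {
                        "pathway": r.pathway,
                        "total_ecs": r.total_ecs,
                        "hits_sig": r.hits_sig,
                        "p_raw": r.p_raw,
                        "p_gamma": r.p_gamma,
                    }
                    for r in rows
                ]
            ).to_csv(out, sep="\t", index=False)
            record("enrich", t0, {"pathways": out})
    except PipelineError:
        raise
    except Exception as exc:
        stage = manifest["stages"][-1]["stage"] if manifest["stages"] else "setup"
        raise PipelineError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
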