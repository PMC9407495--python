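"""Pipeline orchestration: staged runs, a deterministic manifest, reports.

A run is described by a :class:`RunConfig` (input table or synthetic
cohort, stage list, per-stage parameters, output directory, seed). Stages
execute in dependency order and each writes its outputs under the run
directory; the manifest records parameters, input checksum and every
produced file, so rerunning an identical config and seed reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .assoc import pearson_matrix
from .colorreg import regression_table
from .mva import altitude_split_labels, export_newick, run_hca, run_oplsda, run_pca
from .pathcoef import path_decompose, stepwise_select
from .sample_io import (
    ANALYTE_CODES,
    CLIMATE_CODES,
    COLOR_CODES,
    SampleTable,
    load_table1_fixture,
    read_sample_table,
    summarize_ranges,
    write_sample_table,
)
from .semfit import SemSpec, effects_decomposition, fit_sem, parse_spec
from .synth import default_config, generate

__all__ = ["RunConfig", "run_pipeline", "make_report", "ALL_STAGES"]

log = logging.getLogger("flavopath")

ALL_STAGES = ("simulate", "summary", "correlate", "pca", "hca", "oplsda",
              "path", "regress", "sem")

#: Stage execution order (io implicit first; report generated on demand).
_ORDER = {name: i for i, name in enumerate(ALL_STAGES)}


@dataclass
class RunConfig:
    """Configuration of a pipeline run; loadable from YAML/JSON."""

    input_path: str | None = None      # CSV/TSV sample table
    use_fixture: bool = False          # load the bundled content table
    synthetic: bool = False            # generate the default synthetic cohort
    stages: Sequence[str] = ("summary",)
    out_dir: str = "flavopath_run"
    seed: int = 0
    pca_scaling: str = "unit_variance"
    hca_linkage: str = "complete"
    stepwise_p_enter: float = 0.05
    stepwise_p_remove: float = 0.10
    sem_spec_path: str | None = None
    sem_thresholds: tuple[float, float, float] = (1.0, 0.08, 0.9)
    variables: Sequence[str] | None = None   # analysis variable subset
    log_level: str = "info"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        sources = sum(map(bool, (self.input_path, self.use_fixture, self.synthetic)))
        if sources != 1:
            raise ValueError(
                "exactly one of input_path / use_fixture / synthetic required")
        if self.input_path and not Path(self.input_path).exists():
            raise FileNotFoundError(self.input_path)
        if self.sem_spec_path and not Path(self.sem_spec_path).exists():
            raise FileNotFoundError(self.sem_spec_path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _default_sem_specs(table: SampleTable) -> dict[str, SemSpec]:
    """One model per color axis, mirroring the fitted color models:
    two climate drivers, one mediating pigment, direct + mediated edges."""
    mediator = {"L": "Y_PG", "a": "Y_CGC", "b": "Y_QI"}
    drivers = {"L": ("X_AMAT", "X_MAW"), "a": ("X_AMAT", "X_MAW"),
               "b": ("X_AMT", "X_MW")}
    specs = {}
    for axis in COLOR_CODES:
        d1, d2 = drivers[axis]
        med = mediator[axis]
        specs[axis] = SemSpec(
            variables=(d1, d2, med, axis),
            regressions=((d1, med), (d2, med), (med, axis), (d2, axis)),
            exogenous_covariances=((d1, d2),),
        )
    return specs


def _load_input(config: RunConfig) -> tuple[SampleTable, object, dict]:
    meta: dict = {}
    truth = None
    if config.synthetic:
        synth_cfg = default_config()
        table, truth = generate(synth_cfg, seed=config.seed)
        meta["input"] = {"kind": "synthetic", "seed": config.seed,
                         "n": len(table)}
    elif config.use_fixture:
        table = load_table1_fixture()
        meta["input"] = {"kind": "fixture", "n": len(table)}
    else:
        path = Path(config.input_path)
        table = read_sample_table(path)
        meta["input"] = {"kind": "file", "path": str(path),
                         "sha256": _sha256(path), "n": len(table)}
    return table, truth, meta


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the manifest dict."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper()))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth, meta = _load_input(config)
    frame = table.to_frame()

    analytes = [c for c in ANALYTE_CODES if c in frame.columns
                and frame[c].notna().all()]
    have_climate = all(c in frame.columns for c in CLIMATE_CODES)
    have_color = all(c in frame.columns for c in COLOR_CODES)
    selected = list(config.variables) if config.variables else analytes

    stages = sorted(set(config.stages), key=_ORDER.get)
    outputs: dict[str, list[str]] = {}
    completed: list[str] = []

    def emit(stage: str, name: str, path: Path) -> None:
        outputs.setdefault(stage, []).append(str(path.relative_to(out)))

    for stage in stages:
        log.info("stage %s", stage)
        if stage == "simulate":
            if not config.synthetic:
                raise ValueError("simulate stage requires synthetic input")
            p = out / "synthetic_table.csv"
            write_sample_table(table, p)
            emit(stage, "table", p)
            p2 = out / "synthetic_truth.json"
            truth.to_json(p2)
            emit(stage, "truth", p2)
        elif stage == "summary":
            p = out / "summary_ranges.csv"
            summarize_ranges(table, selected).to_csv(p)
            emit(stage, "ranges", p)
        elif stage == "correlate":
            variables = list(selected)
            if have_color:
                variables += list(COLOR_CODES)
            if have_climate:
                variables += list(CLIMATE_CODES)
            res = pearson_matrix(table, variables)
            res.write_csv(out / "correlations_long.csv",
                          out / "correlations_matrix.csv")
            emit(stage, "long", out / "correlations_long.csv")
            emit(stage, "matrix", out / "correlations_matrix.csv")
        elif stage == "pca":
            res = run_pca(table, selected, scaling=config.pca_scaling)
            res.scores.to_csv(out / "pca_scores.csv")
            res.loadings.to_csv(out / "pca_loadings.csv")
            pd_explained(res).to_csv(out / "pca_explained.csv")
            for name in ("pca_scores", "pca_loadings", "pca_explained"):
                emit(stage, name, out / f"{name}.csv")
        elif stage == "hca":
            res = run_hca(table, selected, linkage=config.hca_linkage)
            p = out / "hca_dendrogram.nwk"
            p.write_text(export_newick(res) + "\n")
            emit(stage, "newick", p)
            p2 = out / "hca_order.csv"
            p2.write_text("sample_id\n" + "\n".join(res.order) + "\n")
            emit(stage, "order", p2)
        elif stage == "oplsda":
            labels = altitude_split_labels(table)
            res = run_oplsda(table, selected, labels, seed=config.seed)
            p = out / "oplsda_scores.csv"
            scores = res.predictive_scores.to_frame()
            scores["class"] = res.classes
            scores.to_csv(p)
            emit(stage, "scores", p)
            p2 = out / "oplsda_summary.json"
            p2.write_text(json.dumps(
                {"r2x": res.r2x, "r2y": res.r2y, "q2": res.q2},
                indent=1, sort_keys=True))
            emit(stage, "summary", p2)
        elif stage == "path":
            if not have_climate:
                raise ValueError(
                    "path stage needs climate columns "
                    f"{list(CLIMATE_CODES)}; input table lacks them")
            rows = []
            responses = list(selected) + (list(COLOR_CODES) if have_color else [])
            for resp in responses:
                trace = stepwise_select(
                    table, resp, CLIMATE_CODES,
                    p_enter=config.stepwise_p_enter,
                    p_remove=config.stepwise_p_remove)
                if not trace.final_set:
                    continue
                res = path_decompose(frame, resp, trace.final_set)
                rows.append(res.to_frame().reset_index(names="factor"))
            p = out / "path_analysis.csv"
            if rows:
                import pandas as pd
                pd.concat(rows, ignore_index=True).to_csv(p, index=False)
            else:
                p.write_text("response,factor\n")
            emit(stage, "table", p)
        elif stage == "regress":
            if not have_color:
                raise ValueError(
                    "regress stage needs color columns L, a, b")
            p = out / "color_regressions.csv"
            regression_table(table, selected).to_csv(p, index=False)
            emit(stage, "table", p)
        elif stage == "sem":
            if not (have_climate and have_color):
                raise ValueError(
                    "sem stage needs both climate and color columns")
            if config.sem_spec_path:
                spec = parse_spec(Path(config.sem_spec_path).read_text())
                specs = {"custom": spec}
            else:
                specs = _default_sem_specs(table)
            report = {}
            for name, spec in specs.items():
                fit = fit_sem(table, spec)
                effects = effects_decomposition(fit)
                fit.edge_frame().to_csv(out / f"sem_edges_{name}.csv",
                                        index=False)
                emit(stage, f"edges_{name}", out / f"sem_edges_{name}.csv")
                report[name] = {
                    "chi2": fit.chi2, "df": fit.df, "cmin_df": fit.cmin_df,
                    "rmsea": fit.rmsea, "gfi": fit.gfi, "agfi": fit.agfi,
                    "r2": fit.r2, "converged": fit.converged,
                    "effects": effects.to_frame().to_dict("records"),
                }
            p = out / "sem_fit.json"
            p.write_text(json.dumps(report, indent=1, sort_keys=True,
                                    default=float))
            emit(stage, "fits", p)
        completed.append(stage)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "pca_scaling": config.pca_scaling,
            "hca_linkage": config.hca_linkage,
            "stepwise": [config.stepwise_p_enter, config.stepwise_p_remove],
            "sem_thresholds": list(config.sem_thresholds),
            "variables": selected,
        },
        **meta,
        "stages_completed": completed,
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def pd_explained(res) -> "object":
    import pandas as pd
    return pd.DataFrame({
        "component": [f"PC{i+1}" for i in range(len(res.explained_pct))],
        "explained_pct": res.explained_pct,
        "cumulative_pct": res.cumulative_pct,
    }).set_index("component")


_SECTION_FILES = {
    "summary": ["summary_ranges.csv"],
    "correlate": ["correlations_matrix.csv"],
    "pca": ["pca_explained.csv"],
    "hca": ["hca_order.csv"],
    "oplsda": ["oplsda_summary.json"],
    "path": ["path_analysis.csv"],
    "regress": ["color_regressions.csv"],
    "sem": ["sem_fit.json"],
}


def make_report(run_dir: str | Path) -> Path:
    """Assemble a single human-readable markdown report from a finished run
    directory; stages missing from the manifest are noted as gaps."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    lines = ["# flavopath run report", "",
             f"- package version: {manifest['version']}",
             f"- seed: {manifest['seed']}",
             f"- input: {json.dumps(manifest['input'], sort_keys=True)}", ""]
    completed = set(manifest["stages_completed"])
    for stage in ALL_STAGES:
        if stage == "simulate":
            continue
        lines.append(f"## {stage}")
        if stage not in completed:
            lines.append("_not run in this pipeline invocation_")
            lines.append("")
            continue
        for fname in _SECTION_FILES.get(stage, []):
            fpath = run_dir / fname
            lines.append(f"### {fname}")
            lines.append("```")
            lines.append(fpath.read_text().rstrip())
            lines.append("```")
        lines.append("")
    out = run_dir / "report.md"
    out.write_text("\n".join(lines) + "\n")
    return out
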