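"""End-to-end orchestration of the analysis stages.

One YAML-configurable run executes: simulate (optional) -> factor scores ->
correlation tables -> whole-brain PLSR -> subnetwork resampling -> graph
metrics -> mediation, writing CSV/JSON artifacts per stage plus run.log and
manifest.json.  A single master seed deterministically spawns per-stage
seeds so stages are individually rerunnable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, factors, graphs, io, mediation, plsr, resampling, synth

__all__ = ["PipelineConfig", "run", "load_config"]

_STAGES = ("simulate", "factors", "assoc", "plsr", "resample", "graph", "mediate")


@dataclass
class PipelineConfig:
    out_dir: str = "results/run"
    phenotypes: str | None = None      # existing CSV; None -> simulate
    connectome_dir: str | None = None
    atlas: str | None = None
    master_seed: int = 0
    wmh_k: str = "k07"                 # WMH threshold series: k05 or k07
    stages: tuple[str, ...] = _STAGES
    cohort_sizes: tuple[int, int, int] = (28, 20, 20)
    n_iter: int = 5000
    n_boot: int = 10000
    kfolds: int = 5
    a_max: int = 10
    gammas: tuple[float, ...] = (1.0, 1.25, 1.5)
    consensus_runs: int = 100
    consensus: bool = True
    masks: tuple[str, ...] = ()        # empty -> all 8

    def __post_init__(self):
        if self.wmh_k not in ("k05", "k07"):
            raise ValueError("wmh_k must be 'k05' or 'k07'")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("stages", "cohort_sizes", "gammas", "masks"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _stage_seeds(master_seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(master_seed).generate_state(len(_STAGES), dtype=np.uint32)
    return {stage: int(s % (2**31)) for stage, s in zip(_STAGES, state)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("wmhnet.pipeline")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seeds = _stage_seeds(config.master_seed)
    log.info("stage seeds: %s", seeds)
    (out / "config_resolved.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))

    timings: dict[str, float] = {}
    artifacts: list[Path] = [out / "config_resolved.yaml"]

    def stage_enabled(name: str) -> bool:
        return name in config.stages

    try:
        t0 = time.time()
        if stage_enabled("simulate") and config.phenotypes is None:
            sim = synth.SimConfig(cohort_sizes=tuple(config.cohort_sizes), seed=seeds["simulate"])
            pheno = synth.simulate_phenotypes(sim)
            atlas = synth.make_atlas(seeds["simulate"])
            conn = synth.simulate_connectomes(pheno, atlas, sim)
            synth.write_dataset(out / "data", pheno, atlas, conn, sim)
            artifacts += [out / "data" / "phenotypes.csv", out / "data" / "atlas.tsv"]
        else:
            if config.phenotypes is None or config.atlas is None or config.connectome_dir is None:
                raise ValueError("simulate disabled: phenotypes, atlas and connectome_dir required")
            pheno = io.read_phenotypes(config.phenotypes)
            atlas = io.read_atlas(config.atlas)
            conn = io.read_connectome_dir(
                config.connectome_dir, list(pheno["participant_id"]), n_nodes=len(atlas)
            )
        timings["simulate"] = time.time() - t0
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    wmh_col = f"wmh_global_{config.wmh_k}"

    def _run_stage(name, fn):
        if not stage_enabled(name):
            return None
        t = time.time()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        timings[name] = time.time() - t
        log.info("stage %s done in %.1fs", name, timings[name])
        return result

    def do_factors():
        scored = factors.fluid_factor(pheno)
        scored.to_csv(out / "factors.csv", index=False)
        artifacts.append(out / "factors.csv")
        return scored

    scored = _run_stage("factors", do_factors)
    if scored is None:
        scored = pheno

    def do_assoc():
        data = scored.copy()
        data["log_wmh"] = assoc.log_wmh(data[wmh_col])
        pairs = [
            {"x": a, "y": b, "family": "age_cog_wmh"}
            for a, b in [
                ("age_years", "fluid"),
                ("age_years", "log_wmh"),
                ("fluid", "log_wmh"),
            ]
        ]
        table = assoc.correlation_table(data, pairs)
        r_part, p_part = assoc.partial_correlation(
            data["log_wmh"], data["fluid"], data[["age_years"]].to_numpy()
        )
        table = pd.concat(
            [
                table,
                pd.DataFrame(
                    [
                        {
                            "x_name": "log_wmh",
                            "y_name": "fluid|age",
                            "n": len(data),
                            "r": r_part,
                            "p": p_part,
                            "p_fdr": np.nan,
                            "family_id": "partial",
                        }
                    ]
                ),
            ]
        )
        table.to_csv(out / "correlations.csv", index=False)
        artifacts.append(out / "correlations.csv")
        return table

    _run_stage("assoc", do_assoc)

    emap = plsr.EdgeMap(len(atlas))
    X = emap.stack(conn.matrices)
    Y = np.column_stack(
        [
            scored["age_years"].to_numpy(dtype=float),
            scored["fluid"].to_numpy(dtype=float)
            if "fluid" in scored
            else scored["latent_g"].to_numpy(dtype=float),
            assoc.log_wmh(scored[wmh_col].to_numpy()),
        ]
    )

    def do_plsr():
        cv = plsr.select_components_cv(X, Y, k=config.kfolds, a_max=config.a_max, seed=seeds["plsr"])
        models = plsr.fit_fold_models(X, Y, cv.chosen_a, cv.fold_labels)
        imp = plsr.feature_importance(models, emap, atlas)
        pdir = out / "plsr"
        pdir.mkdir(exist_ok=True)
        (pdir / "cv_result.json").write_text(
            json.dumps(
                {
                    "chosen_components": cv.chosen_a,
                    "cv_msep": cv.cv_msep.tolist(),
                    "cv_pctvar": cv.cv_pctvar.tolist(),
                    "baseline_mse": cv.baseline_mse,
                    "per_outcome_r2": cv.per_outcome_r2.tolist(),
                },
                indent=2,
            )
        )
        imp.edges.to_csv(pdir / "edge_importance.csv", index=False)
        imp.rois.to_csv(pdir / "roi_importance.csv", index=False)
        artifacts.extend([pdir / "cv_result.json", pdir / "edge_importance.csv", pdir / "roi_importance.csv"])
        return cv

    _run_stage("plsr", do_plsr)

    def do_resample():
        masks = resampling.build_masks(atlas, emap)
        wanted = config.masks or tuple(masks)
        summaries = []
        for name in wanted:
            res = resampling.resample_evaluate(
                X, Y, masks[name], n_iter=config.n_iter, seed=seeds["resample"], name=name
            )
            summaries.append(res.summary())
        df = pd.DataFrame(summaries)
        df["ks_p_fdr"] = assoc.bh_fdr(df["ks_p"].to_numpy())
        df.to_csv(out / "resample.csv", index=False)
        artifacts.append(out / "resample.csv")
        return df

    _run_stage("resample", do_resample)

    def do_graph():
        metrics = graphs.compute_metrics(
            conn,
            atlas,
            gammas=tuple(config.gammas),
            consensus=config.consensus,
            consensus_runs=config.consensus_runs,
            seed=seeds["graph"],
        )
        metrics.to_csv(out / "metrics.csv", index=False)
        corr = graphs.metrics_correlations(metrics, scored)
        corr.to_csv(out / "metrics_correlations.csv", index=False)
        reg = graphs.metrics_regressions(metrics, scored, wmh_col=wmh_col)
        reg.to_csv(out / "metrics_regressions.csv", index=False)
        artifacts.extend(
            [out / "metrics.csv", out / "metrics_correlations.csv", out / "metrics_regressions.csv"]
        )
        return metrics

    _run_stage("graph", do_graph)

    def do_mediate():
        y = scored["fluid"].to_numpy(dtype=float)
        x = scored["age_years"].to_numpy(dtype=float)
        simple = mediation.mediate(
            x,
            assoc.log_wmh(scored[wmh_col].to_numpy()),
            y,
            n_boot=config.n_boot,
            seed=seeds["mediate"],
            mediator_names=["log_wmh_global"],
        )
        tract_cols = [f"tract_{t}" for t in synth.TRACTS]
        parallel = mediation.mediate(
            x,
            np.column_stack([assoc.log_wmh(scored[c].to_numpy()) for c in tract_cols]),
            y,
            n_boot=config.n_boot,
            seed=seeds["mediate"] + 1,
            mediator_names=list(synth.TRACTS),
        )
        payload = {
            "simple": dataclasses.asdict(simple),
            "parallel": dataclasses.asdict(parallel),
        }
        for model in payload.values():
            model.pop("seed", None)
        (out / "mediation.json").write_text(json.dumps(payload, indent=2, default=float))
        artifacts.append(out / "mediation.json")
        return simple

    _run_stage("mediate", do_mediate)

    manifest = {
        "seeds": seeds,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts if p.exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete")
    log.removeHandler(handler)
    handler.close()
    return manifest
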