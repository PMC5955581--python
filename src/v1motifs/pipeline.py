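"""End-to-end orchestration: simulate -> preprocess -> tune -> graph -> motifs
-> reconstruct -> report, with a single JSON-serializable configuration.

Every output file is stamped with a hash of the configuration so downstream
artifacts can be traced to their exact settings; identical configurations
(seeds included) reproduce byte-identical numerical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import funcnet, motifs, preprocessing, reconstruction, synthetic, tuning

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("v1motifs")

STAGES = ("simulate", "preprocess", "tune", "graph", "motifs", "reconstruct", "report")


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    input_path: Optional[str] = None  # load instead of simulating
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    schedule: dict = field(
        default_factory=lambda: dict(
            n_blocks=8, n_directions=12, reps_per_block=3,
            grating_dur_s=5.0, grey_dur_s=3.0, frame_rate_hz=30.0,
        )
    )
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    preprocess: dict = field(
        default_factory=lambda: dict(sg_order=4, sg_window=81, transient_sd=3.0)
    )
    tune: dict = field(
        default_factory=lambda: dict(
            alpha_responsive=0.01, alpha_tuning=0.05, n_perm=1000, n_restarts=20
        )
    )
    graph: dict = field(
        default_factory=lambda: dict(
            frame_filter="all", cutoff_s=0.5, max_search_lag_s=1.5, weight_floor=0.0
        )
    )
    motifs: dict = field(default_factory=lambda: dict(n_null_graphs=50, n_ve_bins=5))
    reconstruct: dict = field(
        default_factory=lambda: dict(lasso=True, lasso_folds=5, crossval=True)
    )

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output path is excluded:
        the same analysis written elsewhere is the same analysis)."""
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as f:
        f.write(f"# config_hash={config_hash}\n")
        df.to_csv(f, index=False, float_format="%.10g", lineterminator="\n")


def _write_json(obj: dict, path: Path, config_hash: str) -> None:
    obj = dict(obj)
    obj["config_hash"] = config_hash
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order and return the report dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    fh = logging.FileHandler(out / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    config.to_json(out / "config.json")

    report: dict = {}
    ctx: dict = {}
    enabled = {s: config.stages.get(s, True) for s in STAGES}
    try:
        for stage in STAGES:
            if not enabled[stage]:
                log.info("stage %s disabled", stage)
                continue
            t0 = time.perf_counter()
            _STAGE_FUNCS[stage](config, ctx, report, out, h)
            log.info("stage %s done in %.1f s", stage, time.perf_counter() - t0)
    finally:
        log.removeHandler(fh)
        fh.close()
    return report


def _require(ctx: dict, key: str, stage: str, needed_by: str):
    if key not in ctx:
        raise RuntimeError(
            f"stage '{needed_by}' needs the output of stage '{stage}'; "
            f"enable it or provide an input recording"
        )
    return ctx[key]


def _stage_simulate(config, ctx, report, out, h):
    if config.input_path:
        rec = synthetic.load_recording(config.input_path)
        log.info("loaded recording from %s", config.input_path)
    else:
        schedule = synthetic.make_schedule(seed=config.seed, **config.schedule)
        sim = synthetic.SimConfig(**config.simulate)
        _, rec = synthetic.simulate_population(sim, schedule, seed=config.seed + 1)
        synthetic.save_recording(rec, str(out / "recording.h5"))
        import h5py

        with h5py.File(out / "recording.h5", "r+") as f:
            f.attrs["config_hash"] = h
    ctx["recording"] = rec
    report["n_neurons"] = rec.n_neurons
    report["n_frames"] = rec.n_frames
    log.info("recording: %d neurons, %d frames", rec.n_neurons, rec.n_frames)


def _stage_preprocess(config, ctx, report, out, h):
    rec = _require(ctx, "recording", "simulate", "preprocess")
    dff = preprocessing.preprocess(rec, **config.preprocess)
    tr = preprocessing.trial_means(dff, rec.schedule)
    ctx["dff"] = dff
    ctx["trial_responses"] = tr
    long = tr.trial_meta.copy()
    rows = []
    for j in range(tr.n_neurons):
        d = long.copy()
        d.insert(0, "neuron", j)
        d["response"] = tr.responses[j]
        rows.append(d)
    _write_csv(pd.concat(rows, ignore_index=True), out / "trial_responses.csv", h)
    report["n_trials"] = tr.responses.shape[1]


def _stage_tune(config, ctx, report, out, h):
    tr = _require(ctx, "trial_responses", "preprocess", "tune")
    results = tuning.analyze_tuning(
        tr,
        alpha_responsive=config.tune["alpha_responsive"],
        alpha_tuning=config.tune["alpha_tuning"],
        n_perm=config.tune["n_perm"],
        n_restarts=config.tune["n_restarts"],
        seed=config.seed + 10,
    )
    ctx["tuning"] = results
    ctx["classes"] = tuning.class_labels(results)
    table = tuning.results_table(results)
    _write_csv(table, out / "tuning.csv", h)
    fits = {
        str(i): dict(
            baseline=r.fit.baseline, amp1=r.fit.amp1, amp2=r.fit.amp2,
            sigma_deg=r.fit.sigma_deg, theta_pref_deg=r.fit.theta_pref_deg,
            r_squared=r.fit.r_squared,
        )
        for i, r in enumerate(results) if r.fit is not None
    }
    _write_json({"fits": fits}, out / "tuning_fits.json", h)
    report["n_responsive"] = int(sum(r.responsive for r in results))
    report["n_direction_tuned"] = int(sum(r.tuning_class == tuning.DIRECTION for r in results))
    report["n_orientation_tuned"] = int(
        sum(r.tuning_class == tuning.ORIENTATION for r in results)
    )
    ve = tuning.tuning_variance_explained(tr)
    report["mean_tuning_ve"] = float(np.nanmean(ve))
    log.info(
        "responsive %d/%d; dir %d, ori %d",
        report["n_responsive"], len(results),
        report["n_direction_tuned"], report["n_orientation_tuned"],
    )


def _stage_graph(config, ctx, report, out, h):
    rec = _require(ctx, "recording", "simulate", "graph")
    dff = _require(ctx, "dff", "preprocess", "graph")
    g = funcnet.build_functional_graph(
        dff,
        rec.schedule,
        frame_filter=config.graph["frame_filter"],
        positions_um=rec.positions_um,
        classes=ctx.get("classes"),
        max_search_lag_s=config.graph["max_search_lag_s"],
        cutoff_s=config.graph["cutoff_s"],
        weight_floor=config.graph["weight_floor"],
    )
    ctx["graph"] = g
    _write_csv(g.edge_table(), out / "graph_edges.csv", h)
    _write_csv(pd.DataFrame(g.W), out / "graph_weights.csv", h)
    import networkx as nx

    gx = g.to_networkx()
    gx.graph["config_hash"] = h
    nx.write_graphml(gx, out / "graph.graphml")
    n = g.n_neurons
    n_pairs = n * (n - 1) // 2
    iu, ju = np.triu_indices(n, k=1)
    connected = (g.W[iu, ju] != 0) | (g.W[ju, iu] != 0)
    report["edge_density"] = float(connected.mean())
    report["zero_edge_fraction"] = float(1.0 - connected.mean())
    bi = g.bidirectional_mask()[iu, ju]
    report["bidirectional_fraction_of_edges"] = (
        float(bi.sum() / connected.sum()) if connected.any() else np.nan
    )
    stats = funcnet.graph_stats(g)
    report["lag_speed_mm_s"] = stats.get("lag_speed_mm_s", np.nan)
    log.info("graph: %d/%d pairs connected", int(connected.sum()), n_pairs)


def _stage_motifs(config, ctx, report, out, h):
    g = _require(ctx, "graph", "graph", "motifs")
    prof = motifs.normalized_clustering(
        g.W, n_graphs=config.motifs["n_null_graphs"], seed=config.seed + 20
    )
    ctx["clustering"] = prof
    df = pd.DataFrame({"neuron": np.arange(g.n_neurons)})
    for m in motifs.MOTIFS:
        df[m] = prof.coefficients[m]
    df["in_degree"] = prof.in_degree
    df["out_degree"] = prof.out_degree
    df["bidirectional_degree"] = prof.bidirectional_degree
    _write_csv(df, out / "clustering.csv", h)
    means = prof.node_means()
    _write_json(
        {
            "data_mean": means,
            "null_mean": prof.null_mean,
            "null_sd": prof.null_sd,
            "normalized": {
                m: (means[m] / prof.null_mean[m]) if prof.null_mean[m] else np.nan
                for m in motifs.MOTIFS
            },
        },
        out / "clustering_null.json",
        h,
    )
    report["clustering_normalized"] = {
        m: (means[m] / prof.null_mean[m]) if prof.null_mean[m] else np.nan
        for m in motifs.MOTIFS
    }


def _stage_reconstruct(config, ctx, report, out, h):
    rec = _require(ctx, "recording", "simulate", "reconstruct")
    dff = _require(ctx, "dff", "preprocess", "reconstruct")
    g = _require(ctx, "graph", "graph", "reconstruct")
    res = reconstruction.reconstruct_population(g, dff)
    ctx["reconstruction"] = res
    report["population_ve_partial_corr"] = res.population_variance_explained
    report["mean_ve_partial_corr"] = float(np.nanmean(res.ve_array()))

    df = pd.DataFrame(
        {
            "neuron": [p.neuron for p in res.per_neuron],
            "gain": [p.gain for p in res.per_neuron],
            "offset": [p.offset for p in res.per_neuron],
            "mse": [p.mse for p in res.per_neuron],
            "variance_explained": [p.variance_explained for p in res.per_neuron],
            "n_inputs": [p.n_inputs for p in res.per_neuron],
        }
    )
    if "classes" in ctx:
        df["class"] = ctx["classes"]
        for cls in np.unique(ctx["classes"]):
            sel = ctx["classes"] == cls
            report[f"mean_ve_{cls}"] = float(np.nanmean(res.ve_array()[sel]))

    if config.reconstruct.get("lasso", True):
        lres = reconstruction.lasso_reconstruction(
            g, dff, n_folds=config.reconstruct["lasso_folds"], seed=config.seed + 30
        )
        report["population_ve_lasso"] = lres.population_variance_explained
        df["variance_explained_lasso"] = lres.ve_array()
        ctx["lasso_reconstruction"] = lres
    if config.reconstruct.get("crossval", True):
        cv = reconstruction.crossval_reconstruction(
            dff,
            rec.schedule,
            frame_filter=config.graph["frame_filter"],
            weight_floor=config.graph["weight_floor"],
            cutoff_s=config.graph["cutoff_s"],
        )
        report["population_ve_crossval"] = float(np.nanmean(cv["fold_population_ve"]))
        df["variance_explained_crossval"] = cv["per_neuron_ve"]
        ctx["crossval"] = cv
    if "tuning" in ctx:
        sim = reconstruction.model_tuning_similarity(res, dff, rec.schedule, ctx["tuning"])
        df["model_tuning_similarity"] = sim
        report["mean_model_tuning_similarity"] = (
            float(np.nanmean(sim)) if np.isfinite(sim).any() else float("nan")
        )
    if "clustering" in ctx:
        cvp = motifs.clustering_vs_performance(
            ctx["clustering"], res.ve_array(), n_bins=config.motifs["n_ve_bins"]
        )
        report["clustering_vs_ve"] = {m: v for m, v in cvp["motifs"].items()}
    _write_csv(df, out / "reconstruction.csv", h)
    log.info("population VE (pc weights) = %.3f", res.population_variance_explained)


def _stage_report(config, ctx, report, out, h):
    _write_json(report, out / "report.json", h)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "tune": _stage_tune,
    "graph": _stage_graph,
    "motifs": _stage_motifs,
    "reconstruct": _stage_reconstruct,
    "report": _stage_report,
}
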