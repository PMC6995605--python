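"""End-to-end pipeline driver: config, staged execution, manifest, caching.

The pipeline runs the analysis in the order the method requires:
input (synthetic or loaded) → structural metrics → features (alignment to
the first frame, pairwise distances, PCA) → k-means microstates → MSM
estimation and implied-timescale scan → Chapman–Kolmogorov validation →
PCCA+ lumping → coarse-grained TPT pathways → state-conditional DCCMs and
a free-energy surface. Every stage writes its artifacts under the output
directory and registers them in a machine-readable run manifest (config
hash, seed, package version); a rerun with an unchanged config consumes
cached artifacts where possible.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dccm import state_conditional_dccm
from .discretize import kmeans_fit
from .features import fit_pca, pairwise_ca_distances
from .io import read_structure, read_trajectory, write_array, write_dtrajs_csv, write_trajectory
from .lumping import (
    free_energy_surface,
    macrostate_dtrajs,
    macrostate_populations,
    pcca_plus,
    representative_frames,
)
from .msm import ck_test, estimate_msm, its_scan
from .structure import Trajectory, radius_of_gyration, rmsd_series, superpose_trajectory
from .synthetic import basin_labels, double_well_spec, embed_path_as_structure, random_template, simulate_brownian
from .tpt import transition_pathways

__all__ = ["SyntheticSpec", "PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class SyntheticSpec:
    """Double-well Brownian input specification (the built-in test system)."""

    delta_kT: float = 1.0
    n_steps: int = 400_000
    dt: float = 0.01
    stride: int = 10
    n_particles: int = 30
    amplitude: float = 2.0
    noise_sigma: float = 0.1
    frame_interval: float = 0.1        # ns equivalent of one strided frame


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run.

    Either ``synthetic`` is set, or ``topology``+``trajectory`` paths are.
    ``lag`` may be given in frames (``lag_frames``) or physical time
    (``lag_time``, converted with ``frame_interval`` by exact integer
    rounding).
    """

    output_dir: str = "msmpath_output"
    seed: int = 0
    synthetic: SyntheticSpec | None = field(default_factory=SyntheticSpec)
    topology: str | None = None
    trajectories: list[str] = field(default_factory=list)
    frame_interval: float | None = None       # ns, for loaded trajectories
    residue_first: int | None = None          # e.g. 10
    residue_last: int | None = None           # e.g. 124
    pca_components: int | None = None         # None = 90%-variance rule
    n_microstates: int = 50
    lags: list[int] = field(default_factory=lambda: [1, 2, 5, 10, 20, 50])
    lag_frames: int | None = None
    lag_time: float | None = None
    n_macrostates: int = 2
    source_macrostate: int | None = None
    sink_macrostate: int | None = None
    ck_steps: int = 5
    n_representative: int = 100
    fes_bins: int = 40

    def resolve_lag(self, frame_interval: float) -> int:
        if self.lag_frames is not None:
            return int(self.lag_frames)
        if self.lag_time is not None:
            frames = self.lag_time / frame_interval
            if abs(frames - round(frames)) > 1e-6:
                raise ValueError(
                    f"lag_time {self.lag_time} is not an integer number of frames "
                    f"at frame_interval {frame_interval}"
                )
            return int(round(frames))
        return 10

    def validate(self) -> None:
        if self.synthetic is None and not self.trajectories:
            raise ValueError("config needs either a synthetic spec or trajectory paths")
        if self.n_microstates < 1:
            raise ValueError("n_microstates must be >= 1")
        if self.n_macrostates < 2:
            raise ValueError("n_macrostates must be >= 2")
        if any(l < 1 for l in self.lags):
            raise ValueError("lags must be >= 1 frame")
        if self.trajectories and (self.frame_interval is None or self.frame_interval <= 0):
            raise ValueError("frame_interval > 0 required for loaded trajectories")


def load_config(path) -> PipelineConfig:
    """Load a YAML or JSON config file."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    syn = data.pop("synthetic", None)
    cfg = PipelineConfig(**data)
    if syn is not None:
        cfg.synthetic = SyntheticSpec(**syn) if isinstance(syn, dict) else None
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class _Manifest:
    def __init__(self, out: Path, cfg: PipelineConfig):
        self.path = out / "manifest.json"
        self.data = {
            "config": asdict(cfg),
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
            "version": __version__,
            "stages": {},
        }
        if self.path.exists():
            try:
                old = json.loads(self.path.read_text())
                if old.get("config_hash") == self.data["config_hash"]:
                    self.data["stages"] = old.get("stages", {})
            except (json.JSONDecodeError, OSError):
                pass

    def cached(self, stage: str) -> bool:
        entry = self.data["stages"].get(stage)
        if not entry:
            return False
        return all(Path(p).exists() for p in entry["outputs"])

    def record(self, stage: str, outputs: list, cached: bool = False) -> None:
        self.data["stages"][stage] = {
            "outputs": [str(p) for p in outputs],
            "cached": cached,
        }
        self.path.write_text(json.dumps(self.data, indent=2, default=str))


def run_pipeline(cfg: PipelineConfig, verbose: bool = True) -> dict:
    """Execute all stages; returns the in-memory result bundle.

    Artifacts land under ``cfg.output_dir``; a stage failure raises with
    the stage name while earlier artifacts remain on disk.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, cfg)
    results: dict = {}

    def log(msg: str) -> None:
        if verbose:
            print(f"[msmpath] {msg}")

    def run_stage(name: str, fn, cached_fn=None):
        try:
            if cached_fn is not None and manifest.cached(name):
                log(f"stage {name} (cached)")
                outputs = cached_fn()
                manifest.record(name, outputs, cached=True)
                return
            log(f"stage {name} ...")
            outputs = fn()
            manifest.record(name, outputs)
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err

    # ---- input -----------------------------------------------------------
    if cfg.synthetic is not None:
        syn = cfg.synthetic
        potential = double_well_spec(syn.delta_kT)

        def stage_input():
            path = simulate_brownian(
                potential, n_steps=syn.n_steps, dt=syn.dt,
                x0=potential.well_centers[0], seed=cfg.seed, stride=syn.stride,
            )
            labels = basin_labels(potential, path)
            template = random_template(syn.n_particles, seed=cfg.seed + 1)
            emb = embed_path_as_structure(
                path, template, labels=labels, amplitude=syn.amplitude,
                noise_sigma=syn.noise_sigma, frame_interval=syn.frame_interval,
                seed=cfg.seed + 2,
            )
            traj = Trajectory(emb.coordinates, frame_interval=syn.frame_interval)
            results["trajectories"] = [traj]
            results["latent_labels"] = [emb.latent_state_labels]
            results["potential"] = potential
            p1 = write_trajectory(out / "synthetic_trajectory", traj)
            df = pd.DataFrame({"frame": np.arange(len(labels)), "label": labels})
            p2 = out / "latent_labels.csv"
            df.to_csv(p2, index=False)
            return [p1, p2]

        def stage_input_cached():
            traj = read_trajectory(out / "synthetic_trajectory")
            labels = pd.read_csv(out / "latent_labels.csv")["label"].to_numpy()
            results["trajectories"] = [traj]
            results["latent_labels"] = [labels]
            results["potential"] = potential
            return [out / "synthetic_trajectory.npy", out / "latent_labels.csv"]

        run_stage("input", stage_input, stage_input_cached)
    else:

        def stage_input():
            mask_range = None
            reference = None
            if cfg.topology:
                ref_coords, resnum = read_structure(
                    cfg.topology,
                    residue_range=(cfg.residue_first, cfg.residue_last)
                    if cfg.residue_first is not None else None,
                )
                reference = ref_coords
            trajs = [
                read_trajectory(p, topology=cfg.topology, frame_interval=cfg.frame_interval)
                for p in cfg.trajectories
            ]
            results["trajectories"] = trajs
            results["latent_labels"] = None
            results["reference"] = reference
            return [Path(p) for p in cfg.trajectories]

        run_stage("input", stage_input)

    trajs: list[Trajectory] = results["trajectories"]
    frame_interval = trajs[0].frame_interval

    # selection mask (residue range on labelled trajectories)
    mask = None
    if cfg.residue_first is not None and cfg.residue_last is not None:
        mask = trajs[0].select_residues(cfg.residue_first, cfg.residue_last)

    # ---- metrics ---------------------------------------------------------
    def stage_metrics():
        ref = results.get("reference")
        outputs = []
        for i, tr in enumerate(trajs):
            r = rmsd_series(tr, reference=ref, mask=mask)
            rg = radius_of_gyration(tr, mask=mask)
            df = pd.DataFrame({
                "frame": np.arange(tr.n_frames),
                "time_ns": np.arange(tr.n_frames) * tr.frame_interval,
                "rmsd_A": r,
                "rg_A": rg,
            })
            p = out / f"metrics_traj{i}.csv"
            df.to_csv(p, index=False)
            outputs.append(p)
        results["metrics"] = outputs
        return outputs

    run_stage("metrics", stage_metrics)

    # ---- features --------------------------------------------------------
    def stage_features():
        aligned = [superpose_trajectory(tr, mask=mask) for tr in trajs]
        results["aligned"] = aligned
        feats = [pairwise_ca_distances(tr, mask=mask) for tr in aligned]
        pooled = np.vstack([f.values for f in feats])
        from .features import FeatureMatrix

        pca = fit_pca(FeatureMatrix(pooled, feats[0].descriptors), n_components=cfg.pca_components)
        projected = [pca.transform(f) for f in feats]
        results["features"] = feats
        results["pca"] = pca
        results["projected"] = projected
        p = write_array(
            out / "pca_projection",
            np.vstack([pf.values for pf in projected]),
            axes=["frame", "component"], units=["frame", "angstrom"],
            explained_variance_ratio=pca.explained_variance_ratio.tolist(),
        )
        return [p]

    run_stage("features", stage_features)

    # ---- clustering ------------------------------------------------------
    def stage_cluster():
        states = kmeans_fit(results["projected"], k=cfg.n_microstates, seed=cfg.seed)
        results["microstates"] = states
        results["dtrajs"] = states.assignments
        p1 = write_dtrajs_csv(out / "dtrajs.csv", states.assignments)
        p2 = write_array(out / "cluster_centers", states.centers,
                         axes=["microstate", "component"], units=["index", "angstrom"])
        return [p1, p2]

    run_stage("cluster", stage_cluster)

    # ---- MSM -------------------------------------------------------------
    lag = cfg.resolve_lag(frame_interval)

    def stage_msm():
        table = its_scan(
            results["dtrajs"], cfg.lags, n_timescales=min(4, cfg.n_microstates - 1),
            frame_interval=frame_interval,
        )
        results["its"] = table
        model = estimate_msm(
            results["dtrajs"], lag=lag, reversible=True, frame_interval=frame_interval,
        )
        results["model"] = model
        p1 = out / "implied_timescales.csv"
        table.to_csv(p1, index=False)
        p2 = write_array(out / "transition_matrix", model.T,
                         axes=["state_from", "state_to"], units=["index", "probability"],
                         lag_frames=model.lag, lag_time_ns=model.lag_time,
                         active_set=model.active_set.tolist())
        p3 = out / "stationary_distribution.csv"
        pd.DataFrame({"microstate": model.active_set, "pi": model.stationary}).to_csv(p3, index=False)
        from .plots import plot_implied_timescales

        p4 = out / "implied_timescales.png"
        plot_implied_timescales(table, p4)
        return [p1, p2, p3, p4]

    run_stage("msm", stage_msm)
    model = results["model"]

    # ---- lumping (needed by CK groups and TPT) ---------------------------
    def stage_lump():
        lumping = pcca_plus(model, cfg.n_macrostates)
        results["lumping"] = lumping
        pops = macrostate_populations(lumping, model)
        results["macro_populations"] = pops
        df = pd.DataFrame({
            "microstate": lumping.active_set,
            "macrostate": lumping.crisp_map,
            **{f"membership_{a}": lumping.memberships[:, a] for a in range(cfg.n_macrostates)},
        })
        p1 = out / "lumping.csv"
        df.to_csv(p1, index=False)
        p2 = out / "macrostate_populations.csv"
        pd.DataFrame({"macrostate": np.arange(len(pops)), "probability": pops}).to_csv(p2, index=False)
        reps = representative_frames(
            lumping, results["dtrajs"], np.vstack([f.values for f in results["projected"]]),
            model, n_samples=cfg.n_representative, seed=cfg.seed,
        )
        results["representatives"] = reps
        p3 = out / "representative_frames.json"
        p3.write_text(json.dumps(
            {str(a): {"frames": v["frames"].tolist(), "medoid": v["medoid"]}
             for a, v in reps.items()}, indent=2))
        return [p1, p2, p3]

    run_stage("lumping", stage_lump)
    lumping = results["lumping"]

    # ---- CK validation ---------------------------------------------------
    def stage_ck():
        sets = [lumping.active_set[lumping.crisp_map == a] for a in range(cfg.n_macrostates)]
        report = ck_test(results["dtrajs"], model, sets=sets, n_steps=cfg.ck_steps)
        results["ck"] = report
        df = pd.DataFrame({
            "group": np.repeat(np.arange(len(sets)), len(report.steps)),
            "n": np.tile(report.steps, len(sets)),
            "predicted": report.predicted.ravel(),
            "estimated": report.estimated.ravel(),
            "std_err": report.std_err.ravel(),
        })
        p1 = out / "ck_test.csv"
        df.to_csv(p1, index=False)
        from .plots import plot_ck_panels

        p2 = out / "ck_test.png"
        plot_ck_panels(report, p2)
        return [p1, p2]

    run_stage("ck", stage_ck)

    # ---- TPT -------------------------------------------------------------
    def stage_tpt():
        res = transition_pathways(
            model, lumping,
            source_macro=cfg.source_macrostate, sink_macro=cfg.sink_macrostate,
        )
        results["tpt"] = res
        rows = [
            {"path": "->".join(f"S{s}" for s in p["path"]),
             "flux": p["flux"], "fraction": p["fraction"], "percent": p["percent"]}
            for p in res["pathways"]
        ]
        p1 = out / "pathways.csv"
        pd.DataFrame(rows).to_csv(p1, index=False)
        p2 = out / "committors.csv"
        pd.DataFrame({
            "microstate": model.active_set,
            "q_forward": res["tpt"].forward_committor,
            "q_backward": res["tpt"].backward_committor,
        }).to_csv(p2, index=False)
        from .plots import plot_pathway_network

        p3 = out / "pathway_network.png"
        plot_pathway_network(res["macro_net_flux"], results["macro_populations"],
                             res["source"], res["sink"], p3)
        return [p1, p2, p3]

    run_stage("tpt", stage_tpt)

    # ---- DCCM + free-energy surface -------------------------------------
    def stage_dccm():
        aligned = results["aligned"]
        coords = np.concatenate([tr.coordinates for tr in aligned], axis=0)
        full = Trajectory(coords, frame_interval)
        macro = np.concatenate(macrostate_dtrajs(lumping, results["dtrajs"]))
        outputs = []
        results["dccm"] = {}
        from .plots import plot_dccm

        for a in (results["tpt"]["source"], results["tpt"]["sink"]):
            frames = np.nonzero(macro == a)[0]
            if frames.size < 2:
                warnings.warn(f"macrostate S{a} has too few frames for a DCCM")
                continue
            d = state_conditional_dccm(full, frames, mask=mask, subset_name=f"macrostate S{a}")
            results["dccm"][a] = d
            p = out / f"dccm_S{a}.csv"
            pd.DataFrame(d.values).to_csv(p, index=False)
            outputs.append(p)
            pimg = out / f"dccm_S{a}.png"
            plot_dccm(d, pimg)
            outputs.append(pimg)
        # free-energy surface over the first two PCs, equilibrium-reweighted
        proj = np.vstack([pf.values for pf in results["projected"]])
        micro = np.concatenate(results["dtrajs"])
        counts = np.bincount(micro, minlength=int(lumping.active_set.max()) + 1).astype(float)
        pi_full = np.zeros_like(counts)
        pi_full[lumping.active_set] = model.stationary
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(counts[micro] > 0, pi_full[micro] / counts[micro], 0.0)
        if proj.shape[1] >= 2:
            fes = free_energy_surface(proj[:, :2], weights=w, bins=cfg.fes_bins,
                                      macrostate_labels=macro)
        else:
            pad = np.c_[proj[:, 0], np.zeros(len(proj))]
            fes = free_energy_surface(pad, weights=w, bins=(cfg.fes_bins, 2),
                                      macrostate_labels=macro)
        results["fes"] = fes
        p = write_array(out / "free_energy_surface", fes.free_energy,
                        axes=["x_bin", "y_bin"], units=["PC1", "PC2"])
        outputs.append(p)
        from .plots import plot_free_energy_surface

        pimg = out / "free_energy_surface.png"
        plot_free_energy_surface(fes, pimg)
        outputs.append(pimg)
        return outputs

    run_stage("dccm", stage_dccm)
    log("pipeline complete")
    return results
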