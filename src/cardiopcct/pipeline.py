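"""End-to-end pipeline orchestration: configuration, staging, provenance.

``run_pipeline`` executes the stages in acquisition order --

    phantom -> acquisition -> gating -> reconstruction -> decomposition
            -> segmentation -> metrics -> statistics

-- writing every stage's artifacts under the configured output directory and
recording a run manifest (config hash, package version, per-stage seeds,
timings and output checksums).  A re-run with an unchanged config resumes
from cached stage outputs; any config change invalidates the cache (the
config hash no longer matches).

Configuration is YAML with nested sections mirroring each stage's
parameters; every parameter left at its default is logged at INFO when the
pipeline starts (no silent defaults).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .cohort import CohortSpec, generate_cohort
from .decomposition import decompose, sensitivity_from_model
from .gating import assign_phases, extract_intrinsic_signal
from .metrics import metrics_from_labels
from .phantom import (AcquisitionSpec, PhantomSpec, bin_effective_energies,
                      build_phantom, simulate_acquisition)
from .projector import ParallelProjector
from .reconstruction import ReconConfig, bin_projections, iterative_reconstruct
from .segmentation import SeedSet, region_grow_segment, seeds_from_labels
from .stats import (assumption_gate, run_factorial_anova, run_gamma_glm,
                    run_kruskal_dunn, stratified_mannwhitney)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES", "default_config_yaml"]

logger = logging.getLogger("cardiopcct.pipeline")

STAGES = ("phantom", "acquisition", "gating", "reconstruction",
          "decomposition", "segmentation", "metrics", "statistics")

_DEFAULTS = {
    "phantom": {
        "grid": 64,
        "voxel_size": 0.125,
        "target_EF_lv": 50.0,
        "target_EF_rv": 45.0,
        "heart_rate": 480.0,
        "n_phases": 10,
        "blood_iodine": 10.0,
    },
    "acquisition": {
        "n_projections": 1200,
        "exposure": 10.0,
        "thresholds": [25.0, 34.0, 50.0, 60.0],
        "e_max": 80.0,
        "flux": 300000.0,
        "total_rotation": 1260.0,
        "noise": True,
    },
    "gating": {"band": [5.0, 12.0]},
    "reconstruction": {
        "lam": 0.0,
        "max_iters": 1,
        "inner_iters": 6,
        "reg_blend": 0.3,
        "svt_frac": 0.05,
        "patch": 4,
        "init": "fbp",
        "nonneg": False,
    },
    "decomposition": {"preset": "auto"},
    "segmentation": {"engine": "region_grow", "tolerance_frac": 0.2,
                     "closing_radius": 1},
    "metrics": {"body_mass_g": 30.0},
    "statistics": {"metrics": ["EF", "CI"], "enabled": True},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-backed).

    Nested sections mirror the stage parameters; unknown keys are rejected
    at validation time, and every key absent from the file keeps (and logs)
    its default.  ``seed`` feeds a seed sequence from which each stochastic
    stage draws its own sub-seed, all recorded in the manifest.
    """

    seed: int
    output_dir: str
    verbosity: str = "INFO"
    sections: dict = field(default_factory=dict)
    defaulted: list = field(default_factory=list)

    def __post_init__(self):
        if not (0 <= int(self.seed) < 2 ** 31):
            raise ValueError("seed must lie in [0, 2^31)")
        merged = {}
        defaulted = []
        user = self.sections or {}
        unknown = set(user) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config section(s) {sorted(unknown)}")
        for section, defaults in _DEFAULTS.items():
            given = dict(user.get(section, {}) or {})
            bad = set(given) - set(defaults)
            if bad:
                raise ValueError(
                    f"unknown key(s) {sorted(bad)} in config section {section!r}")
            merged[section] = {**defaults, **given}
            defaulted.extend(f"{section}.{k}" for k in defaults if k not in given)
        self.sections = merged
        self.defaulted = defaulted
        self.validate()

    # -- construction --------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file {path} not found")
        raw = yaml.safe_load(path.read_text()) or {}
        if "seed" not in raw or "output_dir" not in raw:
            raise ValueError("config must provide 'seed' and 'output_dir'")
        sections = {k: v for k, v in raw.items()
                    if k not in ("seed", "output_dir", "verbosity")}
        return cls(seed=int(raw["seed"]), output_dir=str(raw["output_dir"]),
                   verbosity=str(raw.get("verbosity", "INFO")), sections=sections)

    def to_dict(self) -> dict:
        return {"seed": int(self.seed), "output_dir": str(self.output_dir),
                "verbosity": self.verbosity, **self.sections}

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @property
    def config_hash(self) -> str:
        # the hash covers the science parameters, not where outputs land
        payload = {k: v for k, v in self.to_dict().items()
                   if k not in ("output_dir", "verbosity")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        """Construct every stage's spec object so bad values fail up front."""
        self.phantom_spec()  # raises on e.g. n_phases = 1
        self.acquisition_spec(noise_seed=0)
        r = self.sections["reconstruction"]
        ReconConfig(lam=r["lam"], max_iters=r["max_iters"],
                    inner_iters=r["inner_iters"], reg_blend=r["reg_blend"],
                    svt_frac=r["svt_frac"], patch=r["patch"], init=r["init"],
                    nonneg=r["nonneg"])
        band = self.sections["gating"]["band"]
        if not (len(band) == 2 and 0 < band[0] < band[1]):
            raise ValueError(f"gating band {band} must be (low, high) with 0 < low < high")
        seg = self.sections["segmentation"]
        if seg["engine"] not in ("region_grow",):
            raise ValueError(f"unknown segmentation engine {seg['engine']!r}")
        if not (0 < seg["tolerance_frac"] <= 1):
            raise ValueError("segmentation tolerance_frac must lie in (0, 1]")
        if self.sections["metrics"]["body_mass_g"] <= 0:
            raise ValueError("body_mass_g must be > 0")
        target = Path(self.output_dir)
        if target.exists() and not target.is_dir():
            raise ValueError(f"output path {target} exists and is not a directory")

    def phantom_spec(self) -> PhantomSpec:
        p = self.sections["phantom"]
        g = int(p["grid"])
        return PhantomSpec(grid_shape=(g, g, g), voxel_size=p["voxel_size"],
                           target_EF_lv=p["target_EF_lv"],
                           target_EF_rv=p["target_EF_rv"],
                           heart_rate=p["heart_rate"], n_phases=p["n_phases"],
                           blood_iodine=p["blood_iodine"])

    def acquisition_spec(self, noise_seed: int) -> AcquisitionSpec:
        a = self.sections["acquisition"]
        return AcquisitionSpec(n_projections=int(a["n_projections"]),
                               exposure=a["exposure"],
                               thresholds=tuple(a["thresholds"]),
                               e_max=a["e_max"], flux=a["flux"],
                               total_rotation=a["total_rotation"],
                               noise=bool(a["noise"]), noise_seed=noise_seed)

    def stage_seeds(self) -> dict:
        """One sub-seed (< 2^31) per stochastic stage, derived from the seed."""
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(STAGES))
        return {name: int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
                for name, child in zip(STAGES, children)}


def default_config_yaml() -> str:
    """The canonical example configuration as a YAML string."""
    cfg = {"seed": 1, "output_dir": "runs/example", "verbosity": "INFO",
           **_DEFAULTS}
    return yaml.safe_dump(cfg, sort_keys=True)


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _checksum_outputs(out_dir: Path, paths: list) -> dict:
    result = {}
    for p in paths:
        p = Path(p)
        if p.is_dir():
            for f in sorted(p.rglob("*")):
                if f.is_file():
                    result[str(f.relative_to(out_dir))] = _sha256(f)
        else:
            result[str(p.relative_to(out_dir))] = _sha256(p)
    return result


class _Run:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.seeds = config.stage_seeds()
        self.cache: dict = {}
        self.manifest = {
            "config_hash": config.config_hash,
            "seed": int(config.seed),
            "stage_seeds": self.seeds,
            "package_version": _package_version(),
            "stages": {},
            "status": "running",
        }
        prev_path = self.out / "manifest.json"
        self.previous = None
        if prev_path.exists():
            try:
                prev = json.loads(prev_path.read_text())
            except json.JSONDecodeError:
                prev = None
            if prev and prev.get("config_hash") == config.config_hash:
                self.previous = prev

    def stage_dir(self, name: str) -> Path:
        d = self.out / name
        d.mkdir(exist_ok=True)
        return d

    def cached_complete(self, name: str) -> bool:
        if self.previous is None:
            return False
        rec = self.previous.get("stages", {}).get(name)
        if not rec or rec.get("status") != "complete":
            return False
        for rel, digest in rec.get("outputs", {}).items():
            f = self.out / rel
            if not f.exists() or _sha256(f) != digest:
                return False
        return True

    def record(self, name: str, seconds: float, outputs: dict, params: dict,
               cached: bool = False) -> None:
        self.manifest["stages"][name] = {
            "status": "complete", "seconds": round(seconds, 3),
            "outputs": outputs, "params": params, "cached": cached,
        }

    def write_manifest(self) -> Path:
        path = self.out / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return path


def _package_version() -> str:
    from . import __version__
    return __version__


# -- stage implementations ---------------------------------------------------


def _stage_phantom(run: _Run):
    spec = run.config.phantom_spec()
    phantom = build_phantom(spec)
    d = run.stage_dir("phantom")
    pio.save_labels(phantom.labels, phantom.voxel_size, d / "truth_labels.nii.gz")
    truth = pd.DataFrame({name: v for name, v in phantom.truth_volumes.items()})
    truth.insert(0, "phase", np.arange(phantom.n_phases))
    pio.save_table(truth, d / "truth_volumes.csv")
    (d / "phantom.json").write_text(json.dumps(
        {"truth_HR": phantom.truth_HR, "voxel_size": phantom.voxel_size,
         "truth_EF_lv": phantom.truth_ef("LV"),
         "truth_EF_rv": phantom.truth_ef("RV")}, indent=2))
    run.cache["phantom"] = phantom
    return [d], dict(run.config.sections["phantom"])


def _load_phantom(run: _Run):
    if "phantom" not in run.cache:
        spec = run.config.phantom_spec()
        run.cache["phantom"] = build_phantom(spec)
    return run.cache["phantom"]


def _stage_acquisition(run: _Run):
    phantom = _load_phantom(run)
    acq = run.config.acquisition_spec(noise_seed=run.seeds["acquisition"])
    stream = simulate_acquisition(phantom, acq, projector=_projector(run))
    d = run.stage_dir("acquisition")
    pio.save_stream(stream, d / "stream")
    run.cache["stream"] = stream
    return [d], dict(run.config.sections["acquisition"])


def _projector(run: _Run) -> ParallelProjector:
    if "projector" not in run.cache:
        g = int(run.config.sections["phantom"]["grid"])
        run.cache["projector"] = ParallelProjector(g)
    return run.cache["projector"]


def _load_stream(run: _Run):
    if "stream" not in run.cache:
        run.cache["stream"] = pio.load_stream(run.out / "acquisition" / "stream")
    return run.cache["stream"]


def _stage_gating(run: _Run):
    stream = _load_stream(run)
    band = tuple(run.config.sections["gating"]["band"])
    n_phases = int(run.config.sections["phantom"]["n_phases"])
    sig = extract_intrinsic_signal(stream, band=band)
    assignment = assign_phases(sig, n_phases=n_phases)
    d = run.stage_dir("gating")
    table = pd.DataFrame({"exposure": np.arange(len(assignment.phase_index)),
                          "timestamp_s": stream.timestamps,
                          "phase": assignment.phase_index})
    pio.save_table(table, d / "gating.csv")
    (d / "gating.json").write_text(json.dumps(
        {"estimated_HR": sig.estimated_HR, "band": list(band),
         "n_phases": n_phases, "n_dropped": int(len(assignment.dropped)),
         "nonstationary": bool(sig.nonstationary)}, indent=2))
    run.cache["gating"] = (sig, assignment)
    return [d], {"band": list(band), "n_phases": n_phases}


def _load_gating(run: _Run):
    if "gating" not in run.cache:
        stream = _load_stream(run)
        meta = json.loads((run.out / "gating" / "gating.json").read_text())
        table = pio.load_table(run.out / "gating" / "gating.csv")
        from .gating import GatingSignal, PhaseAssignment
        phase = table["phase"].to_numpy(int)
        sig = GatingSignal(values=np.zeros(len(phase)),
                           timestamps=stream.timestamps,
                           band=tuple(meta["band"]),
                           estimated_HR=meta["estimated_HR"],
                           nonstationary=meta["nonstationary"])
        assignment = PhaseAssignment(phase_index=phase,
                                     n_phases=int(meta["n_phases"]),
                                     dropped=np.nonzero(phase < 0)[0])
        run.cache["gating"] = (sig, assignment)
    return run.cache["gating"]


def _stage_reconstruction(run: _Run):
    stream = _load_stream(run)
    _, assignment = _load_gating(run)
    r = run.config.sections["reconstruction"]
    cfg = ReconConfig(lam=r["lam"], max_iters=r["max_iters"],
                      inner_iters=r["inner_iters"], reg_blend=r["reg_blend"],
                      svt_frac=r["svt_frac"], patch=r["patch"], init=r["init"],
                      nonneg=r["nonneg"])
    sino = bin_projections(stream, assignment)
    vol = iterative_reconstruct(sino, cfg, projector=_projector(run))
    d = run.stage_dir("reconstruction")
    pio.save_volume5d(vol, d / "volume5d.nii.gz")
    (d / "recon.json").write_text(json.dumps(
        {"objective_log": list(getattr(vol, "objective_log", []))}, indent=2))
    run.cache["volume5d"] = vol
    return [d], dict(r)


def _load_volume5d(run: _Run):
    if "volume5d" not in run.cache:
        run.cache["volume5d"] = pio.load_volume5d(
            run.out / "reconstruction" / "volume5d.nii.gz")
    return run.cache["volume5d"]


def _stage_decomposition(run: _Run):
    vol = _load_volume5d(run)
    preset = run.config.sections["decomposition"]["preset"]
    thresholds = np.asarray(run.config.sections["acquisition"]["thresholds"], float)
    e_max = run.config.sections["acquisition"]["e_max"]
    energies = bin_effective_energies(thresholds, e_max)
    M = sensitivity_from_model(energies, preset=preset,
                               voxel_size=vol.voxel_size)
    maps = decompose(vol, M)
    d = run.stage_dir("decomposition")
    import nibabel as nib
    for m in maps.materials:
        arr = maps.map_for(m)  # (t, z, y, x) -> NIfTI (x, y, z, t)
        data = np.transpose(arr, (3, 2, 1, 0))
        img = nib.Nifti1Image(np.ascontiguousarray(data),
                              np.diag([vol.voxel_size] * 3 + [1.0]))
        nib.save(img, str(d / f"{m}.nii.gz"))
    (d / "decomposition.json").write_text(json.dumps(
        {"materials": list(maps.materials), "units": list(maps.units),
         "condition_number": M.condition_number,
         "energies_kev": [float(e) for e in energies]}, indent=2))
    run.cache["materials"] = maps
    return [d], {"preset": preset}


def _stage_segmentation(run: _Run):
    vol = _load_volume5d(run)
    phantom = _load_phantom(run)
    seg = run.config.sections["segmentation"]
    # segment the lowest-energy-bin volume (highest iodine contrast)
    labels = []
    for t in range(vol.n_phases):
        v = vol.values[t, 0]
        lo, hi = np.percentile(v, [1.0, 99.0])
        tol = seg["tolerance_frac"] * max(hi - lo, 1e-12)
        seeds = SeedSet(seeds=seeds_from_labels(phantom.labels[t]),
                        default_tolerance=tol)
        labels.append(region_grow_segment(
            v, seeds, closing_radius=int(seg["closing_radius"])))
    labels = np.stack(labels)
    d = run.stage_dir("segmentation")
    pio.save_labels(labels, vol.voxel_size, d / "labels.nii.gz")
    run.cache["seg_labels"] = labels
    return [d], dict(seg)


def _load_seg_labels(run: _Run):
    if "seg_labels" not in run.cache:
        lab, _, _ = pio.load_labels(run.out / "segmentation" / "labels.nii.gz")
        run.cache["seg_labels"] = lab
    return run.cache["seg_labels"]


def _stage_metrics(run: _Run):
    labels = _load_seg_labels(run)
    meta = json.loads((run.out / "gating" / "gating.json").read_text())
    mass = float(run.config.sections["metrics"]["body_mass_g"])
    voxel = float(run.config.sections["phantom"]["voxel_size"])
    m = metrics_from_labels(labels, voxel, HR=float(meta["estimated_HR"]),
                            mass=mass)
    d = run.stage_dir("metrics")
    row = {k: getattr(m, k) for k in ("EDV", "ESV", "SV", "EF", "CO", "CI",
                                      "MM", "RVSV", "RVEF", "HR", "mass",
                                      "ed_phase", "es_phase")}
    pio.save_table(pd.DataFrame([row]), d / "metrics.csv")
    run.cache["metrics"] = m
    return [d], {"body_mass_g": mass}


def _stage_statistics(run: _Run):
    cfg = run.config.sections["statistics"]
    d = run.stage_dir("statistics")
    if not cfg["enabled"]:
        (d / "skipped.json").write_text(json.dumps({"enabled": False}))
        return [d], dict(cfg)
    cohort = generate_cohort(CohortSpec(seed=run.seeds["statistics"]))
    pio.save_table(cohort, d / "cohort.csv")
    gate_rows, routed = [], {}
    for metric in cfg["metrics"]:
        rep = assumption_gate(cohort, metric)
        gate_rows.append({"metric": metric, "shapiro_p": rep.shapiro_p,
                          "levene_p": rep.levene_p, "route": rep.route})
        if rep.route == "ANOVA":
            routed[metric] = run_factorial_anova(cohort, metric)
        elif rep.route == "GLM_gamma_log":
            routed[metric] = run_gamma_glm(cohort, metric)
        else:
            res = run_kruskal_dunn(cohort, metric, "genotype")
            routed[metric] = res["pairs"].assign(H=res["H"], p_kw=res["p"])
    pio.save_table(pd.DataFrame(gate_rows), d / "assumptions.csv")
    for metric, table in routed.items():
        pio.save_table(table, d / f"analysis_{metric}.csv")
    strat = stratified_mannwhitney(cohort, metrics=tuple(cfg["metrics"]))
    pio.save_table(strat, d / "stratified.csv")
    return [d], dict(cfg)


_STAGE_FUNCS = {
    "phantom": _stage_phantom,
    "acquisition": _stage_acquisition,
    "gating": _stage_gating,
    "reconstruction": _stage_reconstruction,
    "decomposition": _stage_decomposition,
    "segmentation": _stage_segmentation,
    "metrics": _stage_metrics,
    "statistics": _stage_statistics,
}


def run_pipeline(config: PipelineConfig, through: str | None = None,
                 resume: bool = True) -> dict:
    """Execute the pipeline (optionally only up to stage ``through``).

    Returns the run manifest (also written as ``manifest.json`` in the output
    directory).  With ``resume=True`` stages whose outputs are present,
    checksum-intact and produced under the same config hash are skipped.
    A stage failure writes a manifest recording the partial completion and
    re-raises the stage's exception.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    run = _Run(config)
    if config.defaulted:
        logger.info("defaulted parameters: %s", ", ".join(config.defaulted))
    if through is not None and through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; stages are {STAGES}")
    last = len(STAGES) if through is None else STAGES.index(through) + 1
    for name in STAGES[:last]:
        t0 = time.perf_counter()
        if resume and run.cached_complete(name):
            rec = dict(run.previous["stages"][name])
            rec["cached"] = True
            run.manifest["stages"][name] = rec
            logger.info("stage %-14s cached (outputs intact)", name)
            continue
        logger.info("stage %-14s params: %s", name,
                    json.dumps(run.config.sections.get(name, {}), sort_keys=True))
        try:
            outputs, params = _STAGE_FUNCS[name](run)
        except Exception:
            run.manifest["status"] = f"failed at {name}"
            run.write_manifest()
            raise
        seconds = time.perf_counter() - t0
        run.record(name, seconds, _checksum_outputs(run.out, outputs), params)
        logger.info("stage %-14s done in %.1f s", name, seconds)
    run.manifest["status"] = "complete"
    run.write_manifest()
    return run.manifest
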