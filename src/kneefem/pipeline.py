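"""File-based orchestration of the full pipeline.

Stages communicate only through files inside the run directory, so any stage
can be re-run in isolation:

    synth/          phantom volume (NIfTI), ground-truth density, knee model,
                    gait fixture CSVs
    calibrate/      HU→density calibration JSON
    materials/      per-element density/modulus table (CSV) + VTK field map
    model/          posed model JSON + case configuration echo
    solve/          displacement/stress VTK, result JSON (tensions, reactions,
                    contact state, convergence log)
    post/           contact summaries, compartment split, equivalent-stress VTK
    gait/           stance events, knee/tibia angles, EMG envelopes,
                    activation similarity
    manifest.json   config echo, file hashes, per-stage status

A fixed seed makes every stage — and therefore every output hash —
reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from kneefem import __version__
from kneefem.volume import CTVolume
from kneefem.mesh import Mesh
from kneefem.io import write_vtk
from kneefem.materials import (
    MaterialField,
    DensityCalibration,
    calibrate_hu_density,
    assign_element_materials,
)
from kneefem.model import (
    KneeModel,
    PosePrescription,
    apply_pose,
    build_constraints,
    calibrate_forced_displacement,
    build_external_forces,
)
from kneefem.solver import solve_static, SolveResult
from kneefem.post import equivalent_stress, summarize_contact, combine_contact, compartment_split
from kneefem.gait import (
    GaitRecording,
    detect_stance,
    knee_angles_jcs,
    tibia_floor_angles,
    emg_envelope,
    activation_similarity,
    resample_percent_cycle,
    EMG_CHANNELS,
)
from kneefem.synthetic import (
    PhantomSpec,
    GaitFixtureSpec,
    make_ct_phantom,
    make_knee_mesh,
    make_gait_fixture,
    rod_samples,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"stage {stage!r}: {msg}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All tunable stage parameters, with the defaults used throughout."""

    seed: int = 0
    out_dir: str = "runs/knee"
    resolution: float = 3.0  # mm, target element edge
    phantom_noise_sd: float = 5.0  # HU
    marker_noise_sd: float = 0.0  # mm
    stance_duration: float = 0.6  # s
    grf_peak: float = 808.95  # N
    grf_threshold: float = 20.0  # N, stance detection
    reseat_clearance: float = 0.1  # mm
    forced_displacement: float = 3.0  # mm
    dp_alpha: float = 0.0  # Drucker–Prager pressure sensitivity
    solver_max_iter: int = 200
    solver_step_limit: float = 0.5  # mm
    verbosity: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1))


# ------------------------------------------------------------------ stages

def stage_synth(cfg: PipelineConfig, out: Path) -> dict:
    d = out / "synth"
    d.mkdir(parents=True, exist_ok=True)
    spec = PhantomSpec(noise_sd=cfg.phantom_noise_sd, seed=cfg.seed)
    vol, density = make_ct_phantom(spec)
    vol.to_nifti(d / "volume.nii")
    CTVolume(density, vol.spacing, vol.origin).to_nifti(d / "density_gt.nii")
    _dump_json(d / "phantom.json", {
        "rod_densities": list(spec.rod_densities),
        "rod_samples": rod_samples(spec, vol),
        "true_calibration": list(spec.true_calibration),
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    })
    model = make_knee_mesh(cfg.resolution)
    model.save_json(d / "model.json")
    mesh = model.mesh
    write_vtk(d / "mesh.vtk", mesh.points, [mesh.tets, mesh.tris, mesh.trusses])
    gspec = GaitFixtureSpec(
        stance_duration=cfg.stance_duration,
        grf_peak=cfg.grf_peak,
        marker_noise_sd=cfg.marker_noise_sd,
        seed=cfg.seed,
    )
    rec = make_gait_fixture(gspec)
    rec.save_csv(d / "gait")
    return {"n_tets": int(len(mesh.tets)), "n_nodes": int(mesh.n_nodes)}


def stage_calibrate(cfg: PipelineConfig, out: Path) -> dict:
    d = out / "calibrate"
    d.mkdir(parents=True, exist_ok=True)
    phantom = json.loads((out / "synth" / "phantom.json").read_text())
    cal = calibrate_hu_density(phantom["rod_samples"])
    _dump_json(d / "calibration.json", cal.to_dict())
    return {"a": cal.a, "b": cal.b, "residual_sd": cal.residual_sd}


def stage_map_materials(cfg: PipelineConfig, out: Path) -> dict:
    d = out / "materials"
    d.mkdir(parents=True, exist_ok=True)
    vol = CTVolume.from_nifti(out / "synth" / "volume.nii")
    cal = DensityCalibration.from_dict(
        json.loads((out / "calibrate" / "calibration.json").read_text())
    )
    model = KneeModel.load_json(out / "synth" / "model.json")
    mats = assign_element_materials(model.mesh, vol, cal)
    pd.DataFrame(
        {"part": mats.part.astype(str), "rho": mats.rho, "E": mats.E, "nu": mats.nu}
    ).to_csv(d / "materials.csv", index=False)
    write_vtk(
        d / "materials.vtk",
        model.mesh.points,
        [model.mesh.tets],
        cell_data={"density": mats.rho, "youngs_modulus": mats.E},
    )
    bone = np.isin(mats.part.astype(str), ("femur", "tibia"))
    return {"bone_E_min": float(mats.E[bone].min()), "bone_E_max": float(mats.E[bone].max())}


def _load_materials(out: Path, mesh: Mesh) -> MaterialField:
    df = pd.read_csv(out / "materials" / "materials.csv")
    return MaterialField(
        rho=df["rho"].to_numpy(),
        E=df["E"].to_numpy(),
        nu=df["nu"].to_numpy(),
        part=np.array(df["part"], dtype=object),
    )


def stage_build_model(cfg: PipelineConfig, out: Path) -> dict:
    d = out / "model"
    d.mkdir(parents=True, exist_ok=True)
    model = KneeModel.load_json(out / "synth" / "model.json")
    pose = PosePrescription()
    posed = apply_pose(model, pose, reseat_clearance=cfg.reseat_clearance)
    act = calibrate_forced_displacement(
        posed, target_traction=posed.load_case.quadriceps, displacement=cfg.forced_displacement
    )
    posed.save_json(d / "model_posed.json")
    case = {
        "pose": pose.to_dict(),
        "load_case": posed.load_case.to_dict(),
        "actuation": {
            "node": act["node"],
            "vector": [float(v) for v in np.asarray(act["vector"], float)],
            "strain": float(act["strain"]),
            "tension": float(act["tension"]),
        },
        "contact_pairs": [p.to_dict() for p in posed.contact_pairs],
        "reseat_clearance": cfg.reseat_clearance,
    }
    (d / "case.yaml").write_text(yaml.safe_dump(case, sort_keys=True))
    return {"quadriceps_strain": act["strain"], "quadriceps_tension": act["tension"]}


def stage_solve(cfg: PipelineConfig, out: Path) -> dict:
    d = out / "solve"
    d.mkdir(parents=True, exist_ok=True)
    posed = KneeModel.load_json(out / "model" / "model_posed.json")
    case = yaml.safe_load((out / "model" / "case.yaml").read_text())
    mats = _load_materials(out, posed.mesh)
    bcs = build_constraints(posed)
    act = case["actuation"]
    if act["node"] is not None:
        bcs.prescribe(int(act["node"]), np.array(act["vector"], float))
    loads = build_external_forces(posed)
    result = solve_static(
        posed, mats, bcs, loads=loads,
        max_iter=cfg.solver_max_iter, step_limit=cfg.solver_step_limit,
    )
    _save_result(d, posed, mats, result)
    return {
        "iterations": result.iterations,
        "equilibrium_residual": result.equilibrium_residual(),
        "truss_tension": dict(
            zip(posed.mesh.truss_names, [float(t) for t in result.truss_tension])
        ),
    }


def _save_result(d: Path, model: KneeModel, mats: MaterialField, result: SolveResult) -> None:
    mesh = model.mesh
    write_vtk(
        d / "result.vtk",
        mesh.points,
        [mesh.tets],
        cell_data={"stress": result.tet_stress},
        point_data={"displacement": result.u, "reaction": result.reactions},
    )
    contact = [
        {
            "pair_index": s.pair_index,
            "tied": s.tied,
            "slave_nodes": s.slave_nodes.tolist(),
            "active": s.active.tolist(),
            "gap": s.gap.tolist(),
            "normal": s.normal.tolist(),
            "normal_force": s.normal_force.tolist(),
            "tangential_force": s.tangential_force.tolist(),
            "area": s.area.tolist(),
        }
        for s in result.contact
    ]
    _dump_json(d / "result.json", {
        "converged": result.converged,
        "iterations": result.iterations,
        "residual": result.residual,
        "equilibrium_residual": result.equilibrium_residual(),
        "truss_tension": result.truss_tension.tolist(),
        "truss_strain": result.truss_strain.tolist(),
        "contact": contact,
    })
    with (d / "convergence.jsonl").open("w") as fh:
        for entry in result.log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")


def _load_result(out: Path, model: KneeModel, mats: MaterialField) -> SolveResult:
    from kneefem.io import read_vtk
    from kneefem.solver import ContactState

    vtk = read_vtk(out / "solve" / "result.vtk")
    meta = json.loads((out / "solve" / "result.json").read_text())
    contact = [
        ContactState(
            pair_index=c["pair_index"],
            slave_nodes=np.array(c["slave_nodes"], dtype=int),
            active=np.array(c["active"], dtype=bool),
            gap=np.array(c["gap"]),
            normal=np.array(c["normal"]),
            normal_force=np.array(c["normal_force"]),
            tangential_force=np.array(c["tangential_force"]),
            area=np.array(c["area"]),
            tied=c["tied"],
        )
        for c in meta["contact"]
    ]
    return SolveResult(
        u=vtk["point_data"]["displacement"],
        tet_stress=vtk["cell_data"]["stress"],
        tri_stress=np.zeros((len(model.mesh.tris), 3, 3)),
        truss_tension=np.array(meta["truss_tension"]),
        truss_strain=np.array(meta["truss_strain"]),
        contact=contact,
        reactions=vtk["point_data"]["reaction"],
        applied_forces=build_external_forces(model),
        iterations=meta["iterations"],
        converged=meta["converged"],
        residual=meta["residual"],
    )


def stage_post(cfg: PipelineConfig, out: Path) -> dict:
    d = out / "post"
    d.mkdir(parents=True, exist_ok=True)
    posed = KneeModel.load_json(out / "model" / "model_posed.json")
    mats = _load_materials(out, posed.mesh)
    result = _load_result(out, posed, mats)
    eq = equivalent_stress(result.tet_stress, mats.part, alpha=cfg.dp_alpha)
    write_vtk(
        d / "equivalent_stress.vtk",
        posed.mesh.points,
        [posed.mesh.tets],
        cell_data={"equivalent_stress": eq},
    )
    summaries = {}
    for s in result.contact:
        if s.tied:
            continue
        summaries[f"pair_{s.pair_index}"] = summarize_contact(result, s.pair_index).to_dict()
    joint = combine_contact(result)
    medial, lateral = compartment_split(result, posed.mesh.points)
    report = {
        "pairs": summaries,
        "joint": joint.to_dict(),
        "compartment_force": {"medial": medial, "lateral": lateral},
        "dp_alpha": cfg.dp_alpha,
    }
    _dump_json(d / "contact_summary.json", report)
    rows = [dict(pair=k, **v) for k, v in summaries.items()]
    pd.DataFrame(rows).to_csv(d / "contact_summary.csv", index=False)
    _render_surface_maps(d, posed, result, eq)
    return report


def _render_surface_maps(d: Path, posed: KneeModel, result, eq: np.ndarray) -> None:
    """Top-view maps of the tibial joint surface: contact pressure and
    equivalent stress (0–5 MPa default colour range)."""
    from kneefem.post import plot_surface_field

    mesh = posed.mesh
    faces = mesh.facet_sets["cartilage_superior_facets"]
    # per-node contact traction on the tibial cartilage surface
    traction = np.zeros(mesh.n_nodes)
    for s in result.contact:
        if s.tied:
            continue
        fn = np.linalg.norm(s.normal_force, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            tr = np.where(s.area > 0, fn / s.area, 0.0)
        traction[s.slave_nodes] = np.maximum(traction[s.slave_nodes], tr)
    plot_surface_field(
        mesh.points, faces, traction[faces].mean(axis=1), d / "contact_pressure_map.png",
        title="Tibial surface contact pressure", label="N/mm²",
    )
    # equivalent stress of the tet adjacent to each surface face
    owner = {}
    for eid, tet in enumerate(mesh.tets):
        for tri in ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)):
            owner[tuple(sorted(tet[list(tri)]))] = eid
    face_eq = np.array([eq[owner[tuple(sorted(f))]] for f in faces])
    plot_surface_field(
        mesh.points, faces, face_eq, d / "equivalent_stress_map.png",
        title="Tibial surface equivalent stress",
    )


def stage_gait(cfg: PipelineConfig, out: Path) -> dict:
    d = out / "gait"
    d.mkdir(parents=True, exist_ok=True)
    rec = GaitRecording.load_csv(out / "synth" / "gait")
    events = detect_stance(rec.grf, threshold=cfg.grf_threshold)
    _dump_json(d / "events.json", events.to_dict())
    lr = events.times["LR"]
    markers = rec.frame_at_time(lr)
    flexion, varus, internal = knee_angles_jcs(markers)
    inv, bend, inw = tibia_floor_angles(markers)
    pd.DataFrame(
        [
            {"quantity": "knee_flexion", "deg": flexion},
            {"quantity": "knee_varus", "deg": varus},
            {"quantity": "knee_internal", "deg": internal},
            {"quantity": "tibia_inversion", "deg": inv},
            {"quantity": "tibia_bending", "deg": bend},
            {"quantity": "tibia_inward", "deg": inw},
        ]
    ).to_csv(d / "angles_lr.csv", index=False)

    t = rec.emg["time"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    T = rec.meta["cycle_duration"]
    pct = {}
    sims = {}
    for ch in EMG_CHANNELS:
        env = emg_envelope(rec.emg[ch].to_numpy(), fs)
        env_pct = resample_percent_cycle(t, env, 0.0, T)
        pct[ch] = env_pct
        a = rec.meta["activations"][ch]
        x = np.linspace(0, 1, 101)
        simulated = np.exp(-0.5 * ((x - a["center"]) / a["width"]) ** 2)
        sims[ch] = activation_similarity(simulated, env_pct)
    df = pd.DataFrame({"percent_cycle": np.arange(101)} | {ch: pct[ch] for ch in EMG_CHANNELS})
    df.to_csv(d / "envelopes.csv", index=False)
    _dump_json(d / "activation_similarity.json", sims)
    return {"events": events.to_dict(), "activation_similarity": sims}


STAGES = [
    ("synth", stage_synth),
    ("calibrate", stage_calibrate),
    ("map_materials", stage_map_materials),
    ("build_model", stage_build_model),
    ("solve", stage_solve),
    ("post", stage_post),
    ("gait", stage_gait),
]


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage and write ``manifest.json`` into the run directory.

    Returns the manifest dict (config echo, per-stage status, output file
    hashes). A stage failure raises :class:`PipelineError` naming the stage;
    artifacts of completed stages are preserved.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    manifest = {"version": __version__, "config": cfg.to_dict(), "stages": {}, "files": {}}
    for name, fn in STAGES:
        try:
            summary = fn(cfg, out)
        except Exception as exc:  # noqa: BLE001 - stage name must be attached
            raise PipelineError(name, str(exc)) from exc
        manifest["stages"][name] = {"status": "ok", "summary": _jsonable(summary)}
        if cfg.verbosity:
            print(f"[kneefem] stage {name}: ok")
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    _dump_json(out / "manifest.json", manifest)
    return manifest


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=lambda o: float(o) if np.isscalar(o) else str(o)))
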