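"""Config-driven orchestration of the full flexibility-analysis chain.

A single structured YAML config describes inputs, selections, trajectory
windows and per-stage parameters; :func:`run_pipeline` executes the stages

    load → window/union → rmsd → rmsf/hinges → pca/pmf → elasticity → wlc

writing per-stage CSV/JSON outputs plus a machine-readable ``report.json``.
A failing stage is recorded and later independent stages still run; stages
whose inputs are not configured are marked ``skipped``.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .coarse_grain import (
    bead_trajectory,
    internal_coordinates,
    load_bead_map,
    spring_constants,
)
from .core import (
    MDFlexError,
    Trajectory,
    WindowSpec,
    concat_windows,
    read_structure,
    read_trajectory,
    select,
)
from .pca import fit_pca, pmf_2d, project, variance_fractions
from .persistence import estimate_lp
from .superpose import detect_hinges, rmsd_series, rmsf_profile

__all__ = ["RunConfig", "Report", "run_pipeline", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1

log = logging.getLogger("mdflex.pipeline")


@dataclass
class RunConfig:
    """Validated pipeline configuration. See ``RunConfig.from_yaml``."""

    structure: str
    trajectories: list[dict]  # {id, path, format?, timestep?}
    output_dir: str
    windows: list[dict] = field(default_factory=list)  # {source, start, end}
    selection: str = "name CA"
    exclude: str | None = None
    references: list[dict] = field(default_factory=list)  # {label, path}
    hinge: dict = field(default_factory=dict)
    pca: dict = field(default_factory=dict)  # {k, pmf_bins}
    bead_map: str | None = None
    bead_weighting: str = "mass"
    temperature: float = 310.0
    persistence: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise MDFlexError(f"unknown config keys: {sorted(unknown)}")
        missing = {"structure", "trajectories", "output_dir"} - set(raw)
        if missing:
            raise MDFlexError(f"missing required config keys: {sorted(missing)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.temperature <= 0:
            raise MDFlexError("temperature must be positive")
        if not Path(self.structure).exists():
            raise MDFlexError(f"structure file not found: {self.structure}")
        if not self.trajectories:
            raise MDFlexError("at least one trajectory is required")
        for tr in self.trajectories:
            if "path" not in tr:
                raise MDFlexError("each trajectory entry needs a 'path'")
            if not Path(tr["path"]).exists():
                raise MDFlexError(f"trajectory file not found: {tr['path']}")
        for ref in self.references:
            if not Path(ref["path"]).exists():
                raise MDFlexError(f"reference file not found: {ref['path']}")
        if self.bead_map is not None and not Path(self.bead_map).exists():
            raise MDFlexError(f"bead map file not found: {self.bead_map}")

    def canonical(self) -> dict:
        return {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)}

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class Report:
    """Per-stage outputs and provenance of one pipeline run."""

    stages: dict[str, dict]
    provenance: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "schema_version": REPORT_SCHEMA_VERSION,
                    "provenance": self.provenance,
                    "stages": self.stages,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def _file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _round(x: float, nd: int = 10) -> float:
    return float(np.round(float(x), nd))


def run_pipeline(config: RunConfig) -> Report:
    """Execute every configured stage; see module docstring."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}

    def record(name: str, status: str, **info) -> None:
        stages[name] = {"status": status, **info}
        log.info("stage %s: %s", name, status)

    # ----- load -------------------------------------------------------
    structure = read_structure(config.structure)
    sources = []
    for tr in config.trajectories:
        sources.append(
            read_trajectory(
                tr["path"],
                structure,
                format=tr.get("format"),
                timestep=tr.get("timestep"),
            )
        )
        sources[-1].label = tr.get("id", sources[-1].label)
    record(
        "load",
        "ok",
        structure=config.structure,
        structure_sha=_file_hash(config.structure),
        n_atoms=structure.n_atoms,
        trajectories=[
            {"id": s.label, "n_frames": s.n_frames, "sha": _file_hash(t["path"])}
            for s, t in zip(sources, config.trajectories)
        ],
    )

    # ----- window union ----------------------------------------------
    if config.windows:
        specs = [WindowSpec(w["source"], w["start"], w["end"]) for w in config.windows]
        traj = concat_windows(sources, specs)
        record(
            "union",
            "ok",
            n_frames=traj.n_frames,
            duration_ns=_round(traj.duration_ns),
        )
    else:
        traj = sources[0]
        record("union", "skipped", reason="no windows configured")

    sel = select(structure, config.selection)
    excl = select(structure, config.exclude) if config.exclude else None

    # ----- rmsd -------------------------------------------------------
    refs = config.references or [{"label": "frame0", "path": None}]
    rmsd_summary = []
    try:
        for ref in refs:
            ref_struct = read_structure(ref["path"]) if ref["path"] else structure
            series = rmsd_series(
                traj, ref_struct, sel, excl, reference_label=ref["label"]
            )
            csv_path = out / f"rmsd_{ref['label']}.csv"
            series.to_csv(csv_path)
            rmsd_summary.append(
                {
                    "reference": ref["label"],
                    "path": str(csv_path),
                    "mean_A": _round(series.rmsd.mean()),
                    "max_A": _round(series.rmsd.max()),
                }
            )
        record("rmsd", "ok", references=rmsd_summary)
    except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
        record("rmsd", "failed", error=str(exc))

    # ----- rmsf / hinges ---------------------------------------------
    profile = None
    try:
        profile = rmsf_profile(traj, sel)
        hinges = detect_hinges(
            profile,
            smooth_window=config.hinge.get("smooth_window", 5),
            percentile=config.hinge.get("percentile", 25.0),
            min_len=config.hinge.get("min_len", 4),
            interior_only=config.hinge.get("interior_only", True),
        )
        rmsf_path = out / "rmsf.csv"
        hinge_path = out / "hinges.tsv"
        profile.to_csv(rmsf_path)
        profile.hinges_to_tsv(hinge_path)
        record(
            "rmsf",
            "ok",
            path=str(rmsf_path),
            hinges_path=str(hinge_path),
            max_rmsf_A=_round(profile.rmsf.max()),
            hinges=[[h.chain, h.start, h.end] for h in hinges],
        )
    except Exception as exc:  # noqa: BLE001
        record("rmsf", "failed", error=str(exc))

    # ----- pca --------------------------------------------------------
    try:
        k = int(config.pca.get("k", 3))
        bins = int(config.pca.get("pmf_bins", 50))
        modes, aligned = fit_pca(traj, sel)
        k_eff = min(k, modes.n_modes)
        proj = project(aligned, modes, k=k_eff, selection=sel)
        proj_path = out / "projections.csv"
        proj.to_csv(proj_path)
        info: dict[str, Any] = {
            "path": str(proj_path),
            "variance_fraction_k": _round(variance_fractions(modes, k_eff)),
            "eigenvalues_A2": [_round(v) for v in modes.eigenvalues[:k_eff]],
        }
        if k_eff >= 2:
            grid = pmf_2d(proj, axes=(0, 1), bins=bins)
            pmf_path = out / "pmf_pc1_pc2.json"
            grid.to_json(pmf_path)
            info["pmf_path"] = str(pmf_path)
        record("pca", "ok", **info)
    except Exception as exc:  # noqa: BLE001
        record("pca", "failed", error=str(exc))

    # ----- coarse-grain elasticity -----------------------------------
    btraj = None
    if config.bead_map is None:
        record("elasticity", "skipped", reason="no bead map configured")
    else:
        try:
            bead_map = load_bead_map(config.bead_map)
            btraj = bead_trajectory(traj, bead_map, weighting=config.bead_weighting)
            series = internal_coordinates(btraj)
            prof = spring_constants(
                series, temperature=config.temperature, domains=bead_map.domains
            )
            csv_path = out / "elasticity.csv"
            json_path = out / "elasticity.json"
            prof.to_csv(csv_path)
            prof.to_json(json_path)
            record(
                "elasticity",
                "ok",
                path=str(csv_path),
                json_path=str(json_path),
                n_angles=int((prof.table["kind"] == "angle").sum()),
                n_dihedrals=int((prof.table["kind"] == "dihedral").sum()),
                k_min=_round(prof.k.min()),
                k_max=_round(prof.k.max()),
            )
        except Exception as exc:  # noqa: BLE001
            record("elasticity", "failed", error=str(exc))

    # ----- persistence length ----------------------------------------
    if btraj is None:
        record("persistence", "skipped", reason="coarse-grain stage did not run")
    else:
        try:
            p = config.persistence
            endpoints = tuple(p.get("endpoints", ("P6", "P15")))
            tail = p.get("tail_beads")
            est = estimate_lp(
                btraj,
                endpoints,
                tail_beads=tail,
                block_length=int(p.get("block_length", 50)),
                n_boot=int(p.get("n_boot", 1000)),
                seed=config.seed,
            )
            wlc_path = out / "wlc.json"
            est.to_json(wlc_path)
            record(
                "persistence",
                "ok",
                path=str(wlc_path),
                lp_nm=_round(est.lp),
                lp_std_nm=_round(est.lp_std),
                contour_nm=_round(est.contour_length),
            )
        except Exception as exc:  # noqa: BLE001
            record("persistence", "failed", error=str(exc))

    report = Report(
        stages=stages,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "mdflex_version": __version__,
            "schema_version": REPORT_SCHEMA_VERSION,
        },
    )
    report.to_json(out / "report.json")
    return report
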