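"""Configuration-driven end-to-end analysis workflow.

A run analyses a dehydration series — either synthetic (planted-bond
systems generated per hydration step, with the planted bond count ramping
up as water is removed) or user-supplied coordinate files — and writes, per
step, the classified bond list (CSV), the pre-polymer summary (JSON) and
the C3' RDF with detected peaks (CSV); plus a lattice match for the driest
step, an optional surface map, a droplet-model summary, and a manifest
recording the package version, seed and config hash.  Outputs are a pure
function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .hbonds import HBondCriteria, bonds_to_dataframe, count_by_category, detect_hbonds
from .rdf import compute_rdf, find_peaks, match_lattice
from .stats import ProximityRule, prepolymer_summary, proximity_partition
from .synthetic import (
    LatticeSpec,
    PlantedSystemSpec,
    make_dehydration_schedule,
    make_planted_hbond_system,
    make_slab_system,
)
from .system import annotate, read_configuration
from . import droplet as droplet_model
from .surface import potential_map

log = logging.getLogger("prepolymer")


class SyntheticSpec(BaseModel):
    n_nucleotides: int = 200
    box: tuple[float, float, float] = (85.0, 85.0, 85.0)
    bonds_wet: int = 2
    bonds_dry: int = 50
    bond_distance: float = 2.8
    bond_angle: float = 10.0
    initial_waters: int = 12500
    final_waters: int = 600
    n_steps: int = 10


class InputStep(BaseModel):
    hydration_percent: float
    path: str


class CriteriaSpec(BaseModel):
    da_cutoff: float = 3.0
    angle_cutoff: float = 20.0


class ProximitySpec(BaseModel):
    cutoff: float = 7.0
    mode: Literal["any_atom", "reference_atom"] = "any_atom"


class RdfSpec(BaseModel):
    selection: str = "C3'"
    bin_width: float = 0.1
    r_max: float = 12.0
    smoothing_window: int = 3
    min_prominence: float = 0.5


class LatticeCandidate(BaseModel):
    a: float
    b: float
    alpha: float = 90.0


class SurfaceMapSpec(BaseModel):
    enabled: bool = False
    mode: Literal["charge", "donor_acceptor"] = "donor_acceptor"
    grid_spacing: float = 1.0
    probe_offset: float = 1.4
    slab_dims: tuple[float, float, float] = (40.0, 50.0, 30.0)
    lattice_const: float = 2.0


class DropletSpec(BaseModel):
    r: float = 100.0
    H: float = 5.0
    delta_T: float = 6.1
    q0: float = 89.84


class RunConfig(BaseModel):
    """Validated run configuration (YAML-loadable)."""

    synthetic: Optional[SyntheticSpec] = None
    inputs: Optional[list[InputStep]] = None
    criteria: CriteriaSpec = Field(default_factory=CriteriaSpec)
    proximity: ProximitySpec = Field(default_factory=ProximitySpec)
    rdf: RdfSpec = Field(default_factory=RdfSpec)
    lattice_candidates: list[LatticeCandidate] = Field(
        default_factory=lambda: [
            LatticeCandidate(a=6.8, b=4.3, alpha=120.0),
            LatticeCandidate(a=5.7, b=4.5, alpha=90.0),
        ]
    )
    surface_map: SurfaceMapSpec = Field(default_factory=SurfaceMapSpec)
    droplet: DropletSpec = Field(default_factory=DropletSpec)
    output_dir: str = "prepolymer_run"
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _one_source(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' or 'inputs' must be given")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _build_series(config: RunConfig):
    """(hydration_percent, Configuration) list, decreasing hydration."""
    if config.inputs is not None:
        steps = sorted(config.inputs, key=lambda s: -s.hydration_percent)
        return [(s.hydration_percent, read_configuration(s.path)) for s in steps]

    syn = config.synthetic
    schedule = make_dehydration_schedule(
        initial_waters=syn.initial_waters,
        final_waters=syn.final_waters,
        n_steps=syn.n_steps,
        n_nucleotides=syn.n_nucleotides,
    )
    series = []
    n_steps = len(schedule.steps)
    for k, step in enumerate(schedule.steps):
        frac = k / (n_steps - 1)
        n_bonds = round(syn.bonds_wet + frac * (syn.bonds_dry - syn.bonds_wet))
        spec = PlantedSystemSpec(
            n_nucleotides=syn.n_nucleotides,
            n_planted_bonds=n_bonds,
            bond_distance=syn.bond_distance,
            bond_angle=syn.bond_angle,
            box=syn.box,
            seed=(config.seed * 1009 + k) % (2**31 - 1),
        )
        cfg, _truth = make_planted_hbond_system(spec)
        series.append((step.hydration_percent, cfg))
    return series


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    criteria = HBondCriteria(config.criteria.da_cutoff, config.criteria.angle_cutoff)
    rule = ProximityRule(config.proximity.cutoff, config.proximity.mode)

    try:
        series = _build_series(config)
    except Exception as e:  # noqa: BLE001 - report the stage
        raise StageError("build_series", str(e)) from e

    summary_rows = []
    last_rdf_peaks = None
    for hydration, cfg in series:
        tag = f"h{hydration:06.2f}"
        try:
            topo = annotate(cfg)
            bonds = detect_hbonds(cfg, topo, criteria)
            partition = proximity_partition(cfg, rule)
            n_nuc = len(cfg.nucleotide_residue_ids())
            summary = prepolymer_summary(bonds, partition, n_nuc, cfg)
        except Exception as e:
            raise StageError("hbond_analysis", f"step {tag}: {e}") from e

        bonds_to_dataframe(bonds).to_csv(out / f"bonds_{tag}.csv", index=False)
        with open(out / f"summary_{tag}.json", "w") as fh:
            json.dump(
                {**dataclasses.asdict(summary), "hydration_percent": hydration,
                 "counts": count_by_category(bonds)},
                fh,
                indent=2,
            )

        try:
            r_max = min(config.rdf.r_max, min(cfg.box) / 2) if cfg.box else config.rdf.r_max
            rdf = compute_rdf(cfg, config.rdf.selection, config.rdf.bin_width, r_max)
            peaks = find_peaks(rdf, config.rdf.smoothing_window, config.rdf.min_prominence)
        except Exception as e:
            raise StageError("rdf", f"step {tag}: {e}") from e
        rdf.to_dataframe().to_csv(out / f"rdf_{tag}.csv", index=False)
        last_rdf_peaks = peaks

        summary_rows.append(
            {
                "hydration_percent": hydration,
                "n_c3c5_total": summary.n_c3c5_total,
                "n_c3c5_near": summary.n_c3c5_near,
                "n_nucleotides_near": summary.n_nucleotides_near,
                "bonded_percent": summary.bonded_percent,
            }
        )
        log.info("step %s: %d pre-polymer bonds", tag, summary.n_c3c5_total)

    import pandas as pd

    pd.DataFrame(summary_rows).to_csv(out / "trace.csv", index=False)

    lattice_result = None
    if last_rdf_peaks is not None and len(last_rdf_peaks.positions) > 0:
        cands = [LatticeSpec(c.a, c.b, c.alpha) for c in config.lattice_candidates]
        m = match_lattice(last_rdf_peaks, cands)
        lattice_result = {
            "matched": m.matched,
            "rms_residual": None if not m.matched else m.rms_residual,
            "candidate": None
            if m.candidate is None
            else {"a": m.candidate.a, "b": m.candidate.b, "alpha": m.candidate.alpha},
        }
    with open(out / "lattice_match.json", "w") as fh:
        json.dump(lattice_result, fh, indent=2)

    if config.surface_map.enabled:
        try:
            slab = make_slab_system(
                slab_dims=config.surface_map.slab_dims,
                lattice_const=config.surface_map.lattice_const,
                seed=config.seed,
            )
            topo = annotate(slab)
            pm = potential_map(
                slab,
                topo,
                mode=config.surface_map.mode,
                grid_spacing=config.surface_map.grid_spacing,
                probe_offset=config.surface_map.probe_offset,
            )
            pm.to_dataframe().to_csv(out / "surface_map.csv", index=False)
        except Exception as e:
            raise StageError("surface_map", str(e)) from e

    d = config.droplet
    params = droplet_model.DropletParams(r=d.r, H=d.H, delta_T=d.delta_T, q0=d.q0)
    r_star, t_cross = droplet_model.optimal_radius(params)
    res = droplet_model.summarize(params)
    droplet_summary = {
        "r_um": d.r,
        "v_t_m_per_s": res.v_t,
        "t_fall_s": res.t_fall,
        "t_life_s": res.t_life,
        "volume_uL": res.volume,
        "r_star_um": r_star,
        "t_at_crossing_s": t_cross,
        "volume_at_r_star_uL": droplet_model.droplet_volume(r_star),
    }
    with open(out / "droplet.json", "w") as fh:
        json.dump(droplet_summary, fh, indent=2)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "n_steps": len(series),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
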