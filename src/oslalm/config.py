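"""Run configuration: one structured YAML/JSON document per run.

A :class:`RunConfig` gathers the phantom, geometry, noise, regularizer and
solver sections; it round-trips losslessly through YAML (JSON-compatible),
and every CLI run writes its resolved config next to its outputs so any
artifact can be reproduced from the config alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .geometry import ScanGeometry, make_geometry
from .phantoms import PhantomSpec
from .regularization import RegularizerSpec
from .simulate import NoiseModel
from .solvers import SolverConfig

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    phantom: PhantomSpec
    geometry: ScanGeometry
    noise: NoiseModel
    regularizer: RegularizerSpec
    solver: SolverConfig
    outdir: str = "runs"
    seed: int = 0

    @classmethod
    def default(cls) -> "RunConfig":
        return cls(
            phantom=PhantomSpec(),
            geometry=make_geometry(128, 128, 1.0, 120, 185, 1.0),
            noise=NoiseModel(),
            regularizer=RegularizerSpec(),
            solver=SolverConfig(checkpoints=(5, 20, 40)),
        )

    def to_dict(self) -> dict:
        g = self.geometry
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "phantom": {
                "kind": self.phantom.kind,
                "n": self.phantom.n,
                "pixel_size": self.phantom.pixel_size,
                "ellipses": [list(e) for e in self.phantom.ellipses],
                "outer_radius": self.phantom.outer_radius,
                "wall_thickness": self.phantom.wall_thickness,
                "wall_value": self.phantom.wall_value,
                "background_value": self.phantom.background_value,
                "spots": [list(s) for s in self.phantom.spots],
            },
            "geometry": {
                "n_x": g.n_x,
                "n_y": g.n_y,
                "pixel_size": g.pixel_size,
                "n_views": g.n_views,
                "n_bins": g.n_bins,
                "bin_spacing": g.bin_spacing,
                "detector_offset": g.detector_offset,
            },
            "noise": {
                "incident_count": self.noise.incident_count,
                "electronic_variance": self.noise.electronic_variance,
                "seed": self.noise.seed,
            },
            "regularizer": self.regularizer.to_dict(),
            "solver": self.solver.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        for section in ("phantom", "geometry", "noise", "regularizer", "solver"):
            if section not in d:
                raise ConfigError(f"missing required config section: {section!r}")
        ph = dict(d["phantom"])
        for key in ("kind", "n"):
            if key not in ph:
                raise ConfigError(f"missing required field: phantom.{key}")
        ph["ellipses"] = tuple(tuple(e) for e in ph.get("ellipses", ()))
        ph["spots"] = tuple(tuple(s) for s in ph.get("spots", ()))
        gd = dict(d["geometry"])
        for key in ("n_x", "n_y", "pixel_size", "n_views", "n_bins", "bin_spacing"):
            if key not in gd:
                raise ConfigError(f"missing required field: geometry.{key}")
        geom = make_geometry(
            gd["n_x"],
            gd["n_y"],
            gd["pixel_size"],
            gd["n_views"],
            gd["n_bins"],
            gd["bin_spacing"],
            gd.get("detector_offset", 0.0),
        )
        noise_d = dict(d["noise"])
        if "incident_count" not in noise_d:
            raise ConfigError("missing required field: noise.incident_count")
        inc = noise_d["incident_count"]
        noise_d["incident_count"] = float("inf") if inc in ("inf", None) else float(inc)
        return cls(
            phantom=PhantomSpec(**ph),
            geometry=geom,
            noise=NoiseModel(**noise_d),
            regularizer=RegularizerSpec.from_dict(d["regularizer"]),
            solver=SolverConfig.from_dict(d["solver"]),
            outdir=d.get("outdir", "runs"),
            seed=int(d.get("seed", 0)),
        )

    def save(self, path) -> None:
        d = self.to_dict()
        if d["noise"]["incident_count"] == float("inf"):
            d["noise"]["incident_count"] = "inf"
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        try:
            d = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as e:
            raise ConfigError(f"unreadable config {path}: {e}") from e
        if not isinstance(d, dict):
            raise ConfigError(f"config {path} is not a mapping")
        return cls.from_dict(d)

    def hash(self) -> str:
        d = self.to_dict()
        if d["noise"]["incident_count"] == float("inf"):
            d["noise"]["incident_count"] = "inf"
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
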