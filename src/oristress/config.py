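"""Analysis configuration and the run manifest.

One :class:`AnalysisConfig` carries every tunable the pipeline honors;
command-line flags override config-file values.  The manifest written to
each output directory records the exact configuration, seeds and input
digests that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .core import ValidationError

__all__ = ["AnalysisConfig", "RunManifest"]


@dataclass
class AnalysisConfig:
    """Every threshold and default the pipeline uses, in one place.

    The headline constants: peaks need a derivative-sign persistence of more
    than 3 kb; an origin counts as fired at >= 20% of cells; origins split
    early/late at T_rep 27.5 min; QFA hits come from the top 25% of |GIS|
    at q < 0.05.
    """

    bin_size: int = 1000
    fourier_cutoff_kb: float = 20.0
    persistence_bp: int = 3000
    fired_threshold: float = 0.20
    trep_cutoff_min: float = 27.5
    match_tol_bp: int = 5000
    fired_window_bp: int = 9000
    fired_source: str = "raw"
    anchor: str = "modal"
    g1_reference: str = "binwise"
    min_g1: float = 1.0
    damage_window_bp: int = 2000
    min_replication: float = 0.05
    meta_half_window_bp: int = 10_000
    trep_bin_edges: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0, 35.0, 40.0)
    qfa_top_fraction: float = 0.25
    qfa_q_max: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.bin_size > 0, "bin_size must be > 0"),
            (self.fourier_cutoff_kb * 1000 >= 2 * self.bin_size,
             "fourier cutoff must be >= 2 bins"),
            (self.persistence_bp > 0, "persistence_bp must be > 0"),
            (0 < self.fired_threshold <= 1, "fired_threshold must be in (0,1]"),
            (self.trep_cutoff_min > 0, "trep_cutoff_min must be > 0"),
            (0 < self.qfa_top_fraction <= 1, "qfa_top_fraction must be in (0,1]"),
            (0 < self.qfa_q_max < 1, "qfa_q_max must be in (0,1)"),
            (self.min_replication > 0, "min_replication must be > 0"),
            (self.anchor in ("none", "total", "modal"), "unknown anchor mode"),
            (self.g1_reference in ("binwise", "smoothed", "flat"),
             "unknown g1_reference mode"),
            (self.fired_source in ("raw", "smoothed"), "unknown fired_source"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(msg)

    @classmethod
    def for_simulation(cls, **overrides) -> "AnalysisConfig":
        """Defaults for analyzing the built-in simulator's output.

        Simulated G1/S libraries are depth-matched with uniform G1 coverage
        by construction, so no ratio anchoring is needed and the flat G1
        reference is the minimum-variance denominator.
        """
        params = {"anchor": "none", "g1_reference": "flat"}
        params.update(overrides)
        return cls(**params)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trep_bin_edges"] = list(d["trep_bin_edges"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "trep_bin_edges" in d:
            d["trep_bin_edges"] = tuple(d["trep_bin_edges"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunManifest:
    """Provenance record written once per output directory."""

    config: dict
    seed: Optional[int]
    input_digests: dict = field(default_factory=dict)
    package_version: str = ""
    mode: str = ""

    @staticmethod
    def digest(path: Union[str, Path]) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 16), b""):
                h.update(chunk)
        return h.hexdigest()

    def write(self, outdir: Union[str, Path]) -> Path:
        path = Path(outdir) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path
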