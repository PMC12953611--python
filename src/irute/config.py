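"""Structured-text experiment configuration for the command-line interface.

A single YAML file drives every subcommand; unknown keys are rejected with
the offending key named, defaults are filled in, and the fully resolved
config is echoed to the output directory so any run can be reproduced
exactly.  All randomness flows from the single top-level ``seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .recon import GriddingParams
from .sequence import SequenceParams, preset

__all__ = ["ExperimentConfig", "load_config"]

_TOP_KEYS = {"seed", "output_dir", "phantom", "sequence", "ordering",
             "gating", "gridding", "metrics"}
_PHANTOM_KEYS = {"size", "seed", "n_lesions", "pixel_size"}
_GATING_KEYS = {"mode", "fraction", "window", "event_segment", "shift_mm",
                "noise_frac"}
_GRIDDING_KEYS = {"kernel_width", "oversampling", "beta"}
_METRICS_KEYS = {"core_radius"}
_SEQ_KEYS = {"preset"} | {f.name for f in dataclasses.fields(SequenceParams)}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    for key in section:
        if key not in allowed:
            raise ValueError(f"invalid config key {key!r} in {where}")


@dataclass
class ExperimentConfig:
    seed: int = 0
    output_dir: str = "irute_out"
    phantom_size: int = 220
    phantom_seed: int | None = None   # defaults to top-level seed
    n_lesions: int = 4
    pixel_size: float = 1.0
    sequence: SequenceParams = field(default_factory=SequenceParams)
    ordering: str = "bit_reversed"
    gating_mode: str = "fraction"     # 'fraction' | 'navigator'
    gating_fraction: float = 0.10
    gating_window: float | None = None
    event_segment: int = 29
    shift_mm: float = 8.0
    noise_frac: float = 0.01
    gridding: GriddingParams = field(default_factory=GriddingParams)
    core_radius: float = 3.0

    def __post_init__(self) -> None:
        if self.ordering not in ("sequential", "bit_reversed"):
            raise ValueError(f"invalid config key value ordering={self.ordering!r}")
        if self.gating_mode not in ("fraction", "navigator"):
            raise ValueError(f"invalid config key value gating.mode={self.gating_mode!r}")
        if self.phantom_seed is None:
            self.phantom_seed = self.seed

    def resolved(self) -> dict:
        """Fully resolved config as a plain dict (echoed next to outputs)."""
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "phantom": {"size": self.phantom_size, "seed": self.phantom_seed,
                        "n_lesions": self.n_lesions, "pixel_size": self.pixel_size},
            "sequence": self.sequence.to_dict(),
            "ordering": self.ordering,
            "gating": {"mode": self.gating_mode, "fraction": self.gating_fraction,
                       "window": self.gating_window,
                       "event_segment": self.event_segment,
                       "shift_mm": self.shift_mm, "noise_frac": self.noise_frac},
            "gridding": {"kernel_width": self.gridding.kernel_width,
                         "oversampling": self.gridding.oversampling,
                         "beta": self.gridding.beta},
            "metrics": {"core_radius": self.core_radius},
        }

    def echo_to(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "resolved_config.yaml").write_text(
            yaml.safe_dump(self.resolved(), sort_keys=False)
        )


def load_config(path: str | Path | None = None, **overrides) -> ExperimentConfig:
    """Load and validate a YAML config; CLI flags override file keys."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")

    ph = raw.get("phantom", {}) or {}
    _check_keys(ph, _PHANTOM_KEYS, "phantom")
    gk = raw.get("gating", {}) or {}
    _check_keys(gk, _GATING_KEYS, "gating")
    gr = raw.get("gridding", {}) or {}
    _check_keys(gr, _GRIDDING_KEYS, "gridding")
    mk = raw.get("metrics", {}) or {}
    _check_keys(mk, _METRICS_KEYS, "metrics")

    sq = raw.get("sequence", {}) or {}
    _check_keys(sq, _SEQ_KEYS, "sequence")
    if "preset" in sq:
        params = preset(sq["preset"])
        extra = {k: v for k, v in sq.items() if k != "preset"}
        if extra:
            params = dataclasses.replace(params, **extra)
    elif sq:
        params = SequenceParams(**sq)
    else:
        params = SequenceParams()

    beta = gr.get("beta")
    if beta in ("auto", "beatty"):
        beta = None
    gridding = GriddingParams(
        kernel_width=gr.get("kernel_width", 3.0),
        oversampling=gr.get("oversampling", 2.0),
        beta=beta,
    )

    cfg = ExperimentConfig(
        seed=raw.get("seed", 0),
        output_dir=raw.get("output_dir", "irute_out"),
        phantom_size=ph.get("size", 220),
        phantom_seed=ph.get("seed"),
        n_lesions=ph.get("n_lesions", 4),
        pixel_size=ph.get("pixel_size", 1.0),
        sequence=params,
        ordering=raw.get("ordering", "bit_reversed"),
        gating_mode=gk.get("mode", "fraction"),
        gating_fraction=gk.get("fraction", 0.10),
        gating_window=gk.get("window"),
        event_segment=gk.get("event_segment", 29),
        shift_mm=gk.get("shift_mm", 8.0),
        noise_frac=gk.get("noise_frac", 0.01),
        gridding=gridding,
        core_radius=mk.get("core_radius", 3.0),
    )
    for key, val in overrides.items():
        if val is not None:
            setattr(cfg, key, val)
    return cfg
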