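"""Pipeline configuration: a single validated YAML document drives every stage.

Unknown keys are rejected (``extra="forbid"``), so typos fail before any
compute.  Command-line flags override config values; the effective, fully
resolved configuration is logged and stamped (as a hash) on every artifact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Strict):
    shell_radii_mm: tuple[float, float, float, float] = (92.0, 86.0, 80.0, 78.0)
    white_core_radius_mm: float = 55.0
    voxel_size_mm: float = 4.0
    with_eyes: bool = True
    with_air_cavity: bool = True


class MontageSection(_Strict):
    n_channels: int = 128
    scalp_radius_mm: float = 92.0


class SourceSpaceSection(_Strict):
    # every gray voxel by default, so ROI node counts track ROI volumes
    spacing_mm: float = 4.0
    include_eyes: bool = False


class ForwardSection(_Strict):
    engine: str = "sphere"  # "sphere" | "fdm"
    conductivities: dict[str, float] = Field(default_factory=dict)
    fdm_solver: str = "direct"


class InverseSection(_Strict):
    alpha: float | None = None
    snr: float = 10.0
    standardized: bool = True


class DesignSection(_Strict):
    trials_per_cell: int = 40
    procedures: tuple[str, ...] = ("mixed", "blocked")
    cues: tuple[str, ...] = ("cued", "uncued")
    # sessions per simulated dataset; the analysis unit for statistics
    n_sessions: int = 8


class NoiseSection(_Strict):
    sd_uv: float = 5.0
    error_rate: float = 0.03
    blink_rate: float = 0.02


class ErpSection(_Strict):
    window_mode: str = "integral"  # "integral" | "samples"


class PipelineConfig(_Strict):
    seed: int = 7
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    montage: MontageSection = Field(default_factory=MontageSection)
    source_space: SourceSpaceSection = Field(default_factory=SourceSpaceSection)
    forward: ForwardSection = Field(default_factory=ForwardSection)
    inverse: InverseSection = Field(default_factory=InverseSection)
    design: DesignSection = Field(default_factory=DesignSection)
    noise: NoiseSection = Field(default_factory=NoiseSection)
    erp: ErpSection = Field(default_factory=ErpSection)
    roi_recipes: str | None = None  # path; None = shipped phantom recipes
    output_dir: str = "presaccade_out"

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a pipeline config; raises :class:`ConfigError`."""
    doc: dict = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        doc = _deep_merge(doc, overrides)
    try:
        return PipelineConfig(**doc)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out
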