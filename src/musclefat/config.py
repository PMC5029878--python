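"""Pipeline configuration: validated YAML in, resolved YAML out.

The configuration nests the phantom, field, cohort, reconstruction and
statistics settings under one seeded document.  Unknown keys are rejected
on load so typos cannot silently fall back to defaults, and every run
writes the fully resolved configuration beside its outputs together with
a short hash that is stamped into each CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .labels import MUSCLE_LABELS
from .phantom import CohortSpec, FieldSpec, PhantomSpec

__all__ = ["ReconOptions", "StatsOptions", "PipelineConfig", "load_config"]


@dataclass
class ReconOptions:
    """Dixon reconstruction flags."""

    signal_threshold: float = 0.05  # fraction of the 99th-percentile |S1|
    inphase_average: bool = True
    resolve_swap: bool = True
    snr: float | None = 50.0  # in-phase magnitude SNR; None = noiseless
    noise_sd: float | None = None  # overrides snr when set

    def __post_init__(self) -> None:
        if not 0 <= self.signal_threshold < 1:
            raise ValueError("signal_threshold must be a fraction in [0, 1)")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class StatsOptions:
    """Longitudinal analysis settings."""

    outcome: str = "total_ff_central"
    covariate: str = "time_non_ambulant"
    exclude_no_steroid: bool = False
    ci_level: float = 0.95


def _build(cls, data: dict, path: str):
    """Construct a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        if dataclasses.is_dataclass(_SUBSPECS.get(name)):
            value = _build(_SUBSPECS[name], value, f"{path}.{name}")
        elif name in ("muscle_ff_true", "true_mean_change") and isinstance(value, dict):
            value = {int(k): float(v) for k, v in value.items()}
        elif isinstance(value, list):
            leaf = value[0] if value else None
            if isinstance(leaf, list):
                value = np.asarray(value, dtype=float)
            else:
                value = tuple(value)
        del ftype
        kwargs[name] = value
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    """Top-level configuration for an end-to-end run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    fieldmap: FieldSpec = field(default_factory=FieldSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    recon: ReconOptions = field(default_factory=ReconOptions)
    stats: StatsOptions = field(default_factory=StatsOptions)
    roi_labels: dict = field(default_factory=lambda: dict(MUSCLE_LABELS))
    central_slice_index: int | None = None  # None -> middle of the stack
    slice_offset_mm: float = 74.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sorted(self.roi_labels.values()) != list(range(1, 11)):
            raise ValueError("roi_labels must map names onto labels 1..10 exactly")
        if self.central_slice_index is not None and not (
            0 <= self.central_slice_index < self.phantom.n_slices
        ):
            raise ValueError("central_slice_index outside the slice stack")

    def resolved_yaml(self) -> str:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: plain(getattr(obj, f.name)) for f in fields(obj)}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return yaml.safe_dump(plain(self), sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()[:12]


_SUBSPECS = {
    "phantom": PhantomSpec,
    "fieldmap": FieldSpec,
    "cohort": CohortSpec,
    "recon": ReconOptions,
    "stats": StatsOptions,
}


def load_config(path: str | Path | None = None, text: str | None = None) -> PipelineConfig:
    """Load and validate a YAML configuration file (or literal text)."""
    if (path is None) == (text is None):
        raise ValueError("pass exactly one of path or text")
    if path is not None:
        text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return _build(PipelineConfig, data, "config")
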