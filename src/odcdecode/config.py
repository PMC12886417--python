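"""Pipeline configuration: YAML round-trip, validation, defaults.

Defaults reproduce the reference analysis constants: high-pass cutoff
1/270 Hz, 200 features, SVM C = 1, nine intermediate surfaces (11 layers),
10,000 permutations, 1,000 bootstrap resamples, alpha = 0.05.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # data layout (unused when simulate=True generates everything itself)
    data_dir: str | None = None
    out_dir: str = "odcdecode_out"
    contrast: str = "GE-BOLD"  # GE-BOLD | SE-BOLD | VASO

    # simulation
    simulate: bool = True
    n_sessions: int = 1
    sheet_nx: int = 48
    sheet_ny: int = 48
    sheet_spacing_mm: float = 0.4
    thickness_mm: float = 2.5
    column_frequency_cpm: float = 0.5  # cycles/mm
    column_bandwidth_cpm: float = 0.1
    pattern_sharpness: float = 3.0
    base_amplitude_pct: float = 2.0
    noise_sd_pct: float = 5.0
    drain_lambda: float | None = None  # per-contrast default when None
    drift_amplitude_pct: float = 1.0
    write_volumes: bool = False

    # design constants
    tr_s: float = 3.0
    n_volumes: int = 90
    baseline_s: float = 15.0
    block_s: float = 30.0
    n_runs: int = 10

    # analysis constants
    highpass_cutoff_hz: float = 1.0 / 270.0
    n_intermediate_layers: int = 9
    k_features: int = 200
    svm_c: float = 1.0
    selection_policy: str = "depth-averaged"
    n_perm: int = 10_000
    n_boot: int = 1_000
    alpha: float = 0.05

    # reproducibility / reporting
    seed: int = 0
    make_plots: bool = True

    def validate(self) -> "PipelineConfig":
        if self.contrast not in ("GE-BOLD", "SE-BOLD", "VASO"):
            raise ValueError(f"contrast: unknown value {self.contrast!r}")
        positive = ["sheet_spacing_mm", "thickness_mm",
                    "column_frequency_cpm", "column_bandwidth_cpm",
                    "pattern_sharpness", "noise_sd_pct", "tr_s", "block_s",
                    "highpass_cutoff_hz", "k_features", "svm_c", "n_perm",
                    "n_boot", "alpha", "n_runs", "n_volumes", "n_sessions"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name}: must be positive")
        if self.highpass_cutoff_hz >= 1.0 / (2.0 * self.tr_s):
            raise ValueError("highpass_cutoff_hz: at or above Nyquist for "
                             f"TR {self.tr_s} s")
        if self.n_intermediate_layers < 0:
            raise ValueError("n_intermediate_layers: must be >= 0")
        if not self.simulate:
            if self.data_dir is None:
                raise ValueError("data_dir: required when simulate is false")
            if not Path(self.data_dir).exists():
                raise ValueError(f"data_dir: path {self.data_dir} not found")
        return self

    @property
    def n_layers(self) -> int:
        return self.n_intermediate_layers + 2

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def validate_and_load(path) -> PipelineConfig:
    """Read a YAML config file, fill defaults, validate every field."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return PipelineConfig(**raw).validate()
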