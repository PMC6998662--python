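"""Study configuration and seed plumbing.

The defaults encode the analysis design this package implements: a 120-month
(10-year) prediagnostic span split into seven fixed windows of ~17 months for
the time-resolved phases, 17-month sliding windows advanced in 2.5-month
steps for the trajectory phase, 1:5 case-control matching, stage-specific
case quotas, 20 bootstrap iterations, and the ``>= 5 reads in >= 20% of
samples`` count filter.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["StudyConfig", "load_config", "child_seed"]

#: Stage labels used for case samples throughout the package.
STAGES = ("early", "locally_advanced", "advanced", "unknown")


@dataclass
class StudyConfig:
    """Tunable parameters of the windowed case-control analysis.

    Attributes
    ----------
    span_months:
        Length of the prediagnostic follow-up span covered by the analysis,
        in months before diagnosis.
    n_fixed_windows:
        Number of contiguous fixed windows the span is divided into for the
        time-resolved phases (2 and 3).
    sliding_width_months, sliding_step_months:
        Width and step of the overlapping windows of the sliding-window
        (trajectory) phase.
    phase2_cases_per_window:
        Case samples drawn per fixed window when all stages are pooled.
    control_ratio:
        Matched controls per case (1:k matching).
    phase3_cases:
        Case quota per window for the stage-specific phase, keyed by stage.
    n_bootstrap:
        Resampling iterations used to bootstrap the per-window signal.
    filter_min_reads, filter_min_fraction:
        An RNA is retained when it has at least ``filter_min_reads`` reads in
        at least ``filter_min_fraction`` of the samples.
    alpha:
        BH-adjusted significance cutoff defining a differentially expressed
        RNA.
    target_score_cutoff:
        Minimum (strict) target-prediction score for a miRNA/isomiR target
        to enter pathway enrichment.
    rng_seed:
        Master seed; per-module streams are derived via :func:`child_seed`.
    """

    span_months: float = 120.0
    n_fixed_windows: int = 7
    sliding_width_months: float = 17.0
    sliding_step_months: float = 2.5
    phase2_cases_per_window: int = 27
    control_ratio: int = 5
    phase3_cases: dict[str, int] = field(
        default_factory=lambda: {"early": 9, "locally_advanced": 14, "advanced": 18}
    )
    n_bootstrap: int = 20
    filter_min_reads: int = 5
    filter_min_fraction: float = 0.20
    alpha: float = 0.05
    target_score_cutoff: float = 60.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "span_months",
            "n_fixed_windows",
            "sliding_width_months",
            "sliding_step_months",
            "phase2_cases_per_window",
            "control_ratio",
            "n_bootstrap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.filter_min_reads < 0:
            raise ValueError("filter_min_reads must be >= 0")
        if not 0 < self.filter_min_fraction <= 1:
            raise ValueError("filter_min_fraction must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sliding_step_months > self.sliding_width_months:
            raise ValueError("sliding_step_months must not exceed sliding_width_months")
        for stage, n in self.phase3_cases.items():
            if n <= 0:
                raise ValueError(f"phase3_cases[{stage!r}] must be positive")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None) -> StudyConfig:
    """Load a :class:`StudyConfig` from a YAML or JSON mapping.

    Unspecified keys take the defaults; unknown keys raise ``ValueError``.
    ``None`` or an empty file yields the full default configuration.
    """
    if path is None:
        return StudyConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ValueError(f"config file {path} must contain a mapping, got {type(data).__name__}")
    valid = {f.name: f for f in dataclasses.fields(StudyConfig)}
    unknown = sorted(set(data) - set(valid))
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        fld = valid[key]
        if fld.name == "phase3_cases":
            if not isinstance(value, Mapping):
                raise ValueError("config key 'phase3_cases' must be a mapping stage -> count")
            value = {str(k): int(v) for k, v in value.items()}
        elif fld.type.startswith("int") and not isinstance(value, int):
            raise ValueError(f"config key {key!r} must be an integer, got {value!r}")
        elif fld.type.startswith("float"):
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ValueError(f"config key {key!r} must be a number, got {value!r}")
            value = float(value)
        kwargs[key] = value
    return StudyConfig(**kwargs)


def child_seed(seed: int, name: str) -> int:
    """Derive a reproducible per-module seed from a master seed.

    The derivation hashes the module name so each pipeline stage consumes an
    independent stream; the result always fits in a signed 32-bit integer.
    """
    return (int(seed) * 1_000_003 + zlib.crc32(name.encode("utf-8"))) % (2**31)


def config_digest(cfg: StudyConfig) -> str:
    """Stable short digest of a configuration (used in run manifests)."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return f"{zlib.crc32(blob):08x}"
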