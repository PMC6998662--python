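"""Prediagnostic time windows and per-window sample selection.

Windows are half-open month intervals ``[start, end)`` measured backward from
diagnosis, so the fixed windows partition the follow-up span without double
counting.  Within a window, cases are drawn stage-balanced by a
largest-remainder rule (equal proportions across the stages present, clipped
to availability with backfill) and controls are attached by exact optimal 1:k
age matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import SampleRecord
from .matching import MatchResult, MatchSpec, optimal_match

__all__ = [
    "WindowSpec",
    "WindowSelection",
    "make_fixed_windows",
    "make_sliding_windows",
    "select_window_samples",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Half-open prediagnostic time interval [start, end) in months."""

    start_months: float
    end_months: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start_months < self.end_months:
            raise ValueError(f"invalid window [{self.start_months}, {self.end_months})")

    def contains(self, t: float) -> bool:
        return self.start_months <= t < self.end_months

    @property
    def center_months(self) -> float:
        return 0.5 * (self.start_months + self.end_months)

    @property
    def label_years(self) -> str:
        return f"{self.start_months / 12:.1f}-{self.end_months / 12:.1f}y"


@dataclass
class WindowSelection:
    """Selected case and matched control sample ids for one window."""

    window: WindowSpec
    case_ids: list[str]
    control_ids: list[str]
    stage_composition: dict[str, int] = field(default_factory=dict)
    histology_composition: dict[str, int] = field(default_factory=dict)
    match_result: MatchResult | None = None


def make_fixed_windows(span_months: float, n_windows: int) -> list[WindowSpec]:
    """Contiguous equal-width windows partitioning [0, span)."""
    if n_windows <= 0:
        raise ValueError("n_windows must be >= 1")
    if span_months <= 0:
        raise ValueError("span_months must be > 0")
    width = span_months / n_windows
    return [
        WindowSpec(k * width, (k + 1) * width, label=f"fw{k}")
        for k in range(n_windows)
    ]


def make_sliding_windows(
    width_months: float, step_months: float, span_months: float
) -> list[WindowSpec]:
    """Overlapping windows [i*step, i*step + width) fully inside [0, span]."""
    if step_months <= 0:
        raise ValueError("step_months must be > 0")
    if not step_months <= width_months <= span_months:
        raise ValueError("need 0 < step <= width <= span")
    n = int(np.floor((span_months - width_months) / step_months + 1e-9)) + 1
    return [
        WindowSpec(i * step_months, i * step_months + width_months, label=f"sw{i}")
        for i in range(n)
    ]


def _balanced_allocation(
    available: dict[str, int], n_cases: int
) -> dict[str, int]:
    """Allocate ``n_cases`` across strata as equally as availability allows.

    Repeatedly gives one slot to the non-exhausted stratum with the fewest
    slots (ties broken lexicographically), which equals largest-remainder
    allocation toward equal proportions and backfills short strata from the
    others.
    """
    quota = {k: 0 for k in available}
    for _ in range(n_cases):
        active = [k for k in quota if quota[k] < available[k]]
        if not active:
            raise ValueError("not enough cases across strata")
        pick = min(active, key=lambda k: (quota[k], k))
        quota[pick] += 1
    return quota


def select_window_samples(
    samples: Sequence[SampleRecord],
    window: WindowSpec,
    n_cases: int,
    ratio_k: int = 5,
    balance_var: str = "stage",
    match_spec: MatchSpec | None = None,
    seed: int = 0,
) -> WindowSelection:
    """Draw a stage-balanced case set in ``window`` and match controls 1:k.

    Eligible cases are those whose time to diagnosis falls in the window;
    controls (no prediagnostic time) are all eligible for every window.
    Raises ``ValueError`` when the window holds fewer than ``n_cases``
    eligible cases; matching infeasibility propagates as ``MatchingError``.
    """
    rng = np.random.default_rng(seed)
    cases = [
        s
        for s in samples
        if s.group == "case" and s.time_to_diagnosis is not None and window.contains(s.time_to_diagnosis)
    ]
    controls = [s for s in samples if s.group == "control"]
    if len(cases) < n_cases:
        raise ValueError(
            f"window {window.label or window.label_years}: {len(cases)} eligible cases,"
            f" need {n_cases}"
        )
    strata: dict[str, list[SampleRecord]] = {}
    for c in sorted(cases, key=lambda s: s.sample_id):
        strata.setdefault(getattr(c, balance_var), []).append(c)
    quota = _balanced_allocation({k: len(v) for k, v in strata.items()}, n_cases)
    if max(quota.values()) - min(quota.values()) > 1:
        log.warning(
            "window %s: exact %s balance impossible, allocation %s",
            window.label or window.label_years,
            balance_var,
            quota,
        )
    chosen: list[SampleRecord] = []
    for key in sorted(strata):
        members = strata[key]
        take = quota[key]
        idx = rng.choice(len(members), size=take, replace=False)
        chosen += [members[i] for i in sorted(idx)]

    spec = match_spec or MatchSpec(ratio_k=ratio_k)
    if spec.ratio_k != ratio_k:
        spec = MatchSpec(
            exact_vars=spec.exact_vars,
            distance_var=spec.distance_var,
            ratio_k=ratio_k,
            caliper_years=spec.caliper_years,
        )
    match = optimal_match(chosen, controls, spec)

    stage_comp: dict[str, int] = {}
    hist_comp: dict[str, int] = {}
    for c in chosen:
        stage_comp[c.stage] = stage_comp.get(c.stage, 0) + 1
        hist_comp[c.histology] = hist_comp.get(c.histology, 0) + 1
    return WindowSelection(
        window=window,
        case_ids=[c.sample_id for c in chosen],
        control_ids=match.control_ids,
        stage_composition=stage_comp,
        histology_composition=hist_comp,
        match_result=match,
    )
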