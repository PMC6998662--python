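"""End-to-end analysis phases, bootstrap robustness, and signal trajectories.

Four phases of increasing homogeneity:

1. all cases vs all controls in a single covariate-adjusted analysis
   (samples with missing smoking keep an explicit ``unknown`` level);
2. seven fixed prediagnostic windows, stage-balanced case quota per window,
   1:5 matched controls, one DE analysis per window;
3. as phase 2 but restricted to one stage with a stage-specific quota, with
   an optional repeated-resampling (bootstrap) variant and a 2-year-window
   robustness variant;
4. overlapping sliding windows producing a quasi-continuous signal
   trajectory, optionally restricted by stage and histology.

The per-window "signal" is the number of RNAs with BH-adjusted p below the
significance cutoff; trajectories tabulate it per RNA class over window
centers, and peaks are local maxima kept greedily under a minimum-separation
constraint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .cohort import CountMatrix, SampleRecord, filter_low_counts
from .config import StudyConfig, child_seed
from .de import DEResult, run_de
from .matching import MatchingError, MatchSpec
from .windows import WindowSpec, make_fixed_windows, make_sliding_windows, select_window_samples

__all__ = [
    "WindowSummary",
    "Trajectory",
    "BootstrapWindow",
    "BootstrapSummary",
    "run_phase",
    "bootstrap_phase3",
    "build_trajectory",
    "detect_peaks",
    "recurrent_rnas",
]

log = logging.getLogger(__name__)


@dataclass
class WindowSummary:
    """Differential-expression summary of one analysis window."""

    window: WindowSpec
    n_de: int = 0
    n_de_by_class: dict[str, int] = field(default_factory=dict)
    de_rna_ids: list[str] = field(default_factory=list)
    direction: dict[str, int] = field(default_factory=dict)
    n_tested: int = 0
    n_cases: int = 0
    n_controls: int = 0
    skipped: bool = False
    reason: str = ""
    results: list[DEResult] = field(default_factory=list)
    #: effect-weighted signal: sum of |log2fc| over the DE RNAs
    weighted: float = 0.0
    #: per-iteration DE counts when the window was resampled (>= 1 entries)
    n_de_values: list[int] = field(default_factory=list)
    weighted_values: list[float] = field(default_factory=list)
    #: per-class DE counts averaged over resampling iterations
    n_de_by_class_mean: dict[str, float] = field(default_factory=dict)

    @property
    def n_de_mean(self) -> float:
        if self.n_de_values:
            return float(np.mean(self.n_de_values))
        return float(self.n_de)

    @property
    def weighted_mean(self) -> float:
        if self.weighted_values:
            return float(np.mean(self.weighted_values))
        return float(self.weighted)


@dataclass
class Trajectory:
    """Per-class DE-count series over ordered window centers (months)."""

    centers: np.ndarray
    total: np.ndarray
    per_class: dict[str, np.ndarray]


@dataclass
class BootstrapWindow:
    window: WindowSpec
    n_iter: int
    n_de_values: list[int]
    mean: float
    sd: float
    min: int
    max: int


@dataclass
class BootstrapSummary:
    """Dispersion of the per-window signal across resampling iterations."""

    windows: list[BootstrapWindow]
    n_iter: int


def _smoker_subset(samples: Sequence[SampleRecord]) -> list[SampleRecord]:
    """Restriction used by phases 2-4: current or former smokers only."""
    return [s for s in samples if s.is_ever_smoker]


def _summarize(window: WindowSpec, results: Sequence[DEResult], alpha: float,
               n_cases: int, n_controls: int) -> WindowSummary:
    de = [r for r in results if np.isfinite(r.padj) and r.padj < alpha]
    by_class: dict[str, int] = {}
    for r in de:
        by_class[r.rna_class] = by_class.get(r.rna_class, 0) + 1
    return WindowSummary(
        window=window,
        n_de=len(de),
        n_de_by_class=by_class,
        de_rna_ids=[r.rna_id for r in de],
        direction={r.rna_id: (1 if r.log2fc > 0 else -1) for r in de},
        n_tested=len(results),
        n_cases=n_cases,
        n_controls=n_controls,
        results=list(results),
        weighted=float(sum(abs(r.log2fc) for r in de)),
    )


def _window_de(
    samples: Sequence[SampleRecord],
    counts: CountMatrix,
    window: WindowSpec,
    n_cases: int,
    cfg: StudyConfig,
    match_spec: MatchSpec | None,
    seed: int,
) -> WindowSummary:
    try:
        sel = select_window_samples(
            samples,
            window,
            n_cases=n_cases,
            ratio_k=cfg.control_ratio,
            match_spec=match_spec,
            seed=seed,
        )
    except (ValueError, MatchingError) as exc:
        log.warning("window %s skipped: %s", window.label or window.label_years, exc)
        return WindowSummary(window=window, skipped=True, reason=str(exc))
    by_id = {s.sample_id: s for s in samples}
    selected = [by_id[i] for i in sel.case_ids + sel.control_ids]
    # smoking is constant by design in phases 2-4 (ever-smokers only), so it
    # drops out of the model via the constant-column rule in build_design
    results = run_de(counts, selected)
    summary = _summarize(window, results, cfg.alpha, len(sel.case_ids), len(sel.control_ids))
    log.info(
        "window %s: %d cases, %d controls, %d DE RNAs",
        window.label or window.label_years,
        summary.n_cases,
        summary.n_controls,
        summary.n_de,
    )
    return summary


def run_phase(
    samples: Sequence[SampleRecord],
    counts: CountMatrix,
    phase: int,
    cfg: StudyConfig | None = None,
    stage_filter: str | None = None,
    histology_filter: str | None = None,
    seed: int = 0,
    match_spec: MatchSpec | None = None,
    windows: Sequence[WindowSpec] | None = None,
    n_resample: int = 1,
) -> list[WindowSummary]:
    """Run one analysis phase; returns one :class:`WindowSummary` per window.

    ``stage_filter`` is required for phase 3 (it sets the case quota);
    ``histology_filter`` additionally restricts cases in phases 3-4.  A
    window that cannot be filled (too few cases, infeasible matching) is
    returned flagged ``skipped`` and the run continues.  ``windows``
    overrides the default window layout (used by the 2-year robustness
    variant).

    ``n_resample`` redraws each window's case set (and rematches controls)
    that many times, mirroring the replication used in the stage-specific
    phase; the summary then reports the first draw's DE set plus the
    per-iteration counts, and trajectories use the mean signal.
    """
    cfg = cfg or StudyConfig()
    if phase not in (1, 2, 3, 4):
        raise ValueError("phase must be 1, 2, 3, or 4")
    if phase == 3 and stage_filter is None:
        raise ValueError("phase 3 requires stage_filter")
    counts = filter_low_counts(counts, cfg.filter_min_reads, cfg.filter_min_fraction)

    if phase == 1:
        sel = list(samples)
        results = run_de(counts.subset_samples([s.sample_id for s in sel]), sel)
        window = WindowSpec(0.0, cfg.span_months, label="all")
        summary = _summarize(
            window,
            results,
            cfg.alpha,
            sum(s.group == "case" for s in sel),
            sum(s.group == "control" for s in sel),
        )
        return [summary]

    pool = _smoker_subset(samples)
    if stage_filter is not None:
        pool = [s for s in pool if s.group == "control" or s.stage == stage_filter]
    if histology_filter is not None:
        pool = [s for s in pool if s.group == "control" or s.histology == histology_filter]

    if stage_filter is not None:
        if stage_filter not in cfg.phase3_cases:
            raise ValueError(f"no case quota configured for stage {stage_filter!r}")
        n_cases = cfg.phase3_cases[stage_filter]
    else:
        n_cases = cfg.phase2_cases_per_window

    if windows is None:
        if phase in (2, 3):
            windows = make_fixed_windows(cfg.span_months, cfg.n_fixed_windows)
        else:
            windows = make_sliding_windows(
                cfg.sliding_width_months, cfg.sliding_step_months, cfg.span_months
            )

    if n_resample < 1:
        raise ValueError("n_resample must be >= 1")
    summaries = []
    for wi, window in enumerate(windows):
        draws = [
            _window_de(
                pool, counts, window, n_cases, cfg, match_spec,
                child_seed(seed, f"phase{phase}:{wi}:{it}"),
            )
            for it in range(n_resample)
        ]
        base = draws[0]
        filled = [d for d in draws if not d.skipped]
        if filled:
            base = filled[0]
            base.n_de_values = [d.n_de for d in filled]
            base.weighted_values = [d.weighted for d in filled]
            classes = {c for d in filled for c in d.n_de_by_class}
            base.n_de_by_class_mean = {
                c: float(np.mean([d.n_de_by_class.get(c, 0) for d in filled]))
                for c in classes
            }
        summaries.append(base)
    return summaries


def bootstrap_phase3(
    samples: Sequence[SampleRecord],
    counts: CountMatrix,
    stage: str,
    cfg: StudyConfig | None = None,
    seed: int = 0,
    match_spec: MatchSpec | None = None,
    window_months: float | None = None,
) -> BootstrapSummary:
    """Repeated resampling of the stage-specific windowed analysis.

    Each iteration independently redraws the window's case set (without
    replacement within the iteration) and rematches controls, then reruns
    DE; the per-window signal dispersion (mean/sd/min/max of the DE count)
    quantifies its stability.  ``window_months`` switches to fixed windows
    of that width (e.g. 24 for the 2-year robustness variant).
    """
    cfg = cfg or StudyConfig()
    counts = filter_low_counts(counts, cfg.filter_min_reads, cfg.filter_min_fraction)
    pool = _smoker_subset(samples)
    pool = [s for s in pool if s.group == "control" or s.stage == stage]
    n_cases = cfg.phase3_cases[stage]
    if window_months is None:
        windows = make_fixed_windows(cfg.span_months, cfg.n_fixed_windows)
    else:
        windows = make_fixed_windows(cfg.span_months, int(round(cfg.span_months / window_months)))

    out = []
    for wi, window in enumerate(windows):
        values: list[int] = []
        for it in range(cfg.n_bootstrap):
            wseed = child_seed(seed, f"boot:{wi}:{it}")
            summary = _window_de(pool, counts, window, n_cases, cfg, match_spec, wseed)
            if summary.skipped:
                log.warning(
                    "bootstrap window %s iteration %d infeasible: %s",
                    window.label, it, summary.reason,
                )
                break
            values.append(summary.n_de)
        arr = np.asarray(values, dtype=float)
        out.append(
            BootstrapWindow(
                window=window,
                n_iter=len(values),
                n_de_values=values,
                mean=float(arr.mean()) if values else float("nan"),
                sd=float(arr.std(ddof=1)) if len(values) > 1 else float("nan"),
                min=int(arr.min()) if values else 0,
                max=int(arr.max()) if values else 0,
            )
        )
    return BootstrapSummary(windows=out, n_iter=cfg.n_bootstrap)


def build_trajectory(
    summaries: Sequence[WindowSummary], signal: str = "count"
) -> Trajectory:
    """Tabulate per-class DE counts over window centers (skipped windows drop).

    ``signal`` selects the total series: ``"count"`` (default) is the number
    of DE RNAs per window; ``"effect"`` weights each DE RNA by |log2fc|,
    which keeps curvature when detection saturates near a strong peak.
    Per-class series are always counts.
    """
    kept = [s for s in summaries if not s.skipped]
    if not kept:
        raise ValueError("no non-skipped window summaries")
    if signal not in ("count", "effect"):
        raise ValueError("signal must be 'count' or 'effect'")
    kept = sorted(kept, key=lambda s: s.window.center_months)
    centers = np.array([s.window.center_months for s in kept])
    if signal == "effect":
        total = np.array([s.weighted_mean for s in kept])
    else:
        total = np.array([s.n_de_mean for s in kept])
    classes = sorted(
        {c for s in kept for c in (s.n_de_by_class_mean or s.n_de_by_class)}
    )
    per_class = {
        cls: np.array(
            [
                (s.n_de_by_class_mean or s.n_de_by_class).get(cls, 0)
                for s in kept
            ],
            dtype=float,
        )
        for cls in classes
    }
    return Trajectory(centers=centers, total=total, per_class=per_class)


def detect_peaks(
    traj: Trajectory, min_height: float = 1.0, min_separation_months: float = 12.0
) -> list[float]:
    """Local maxima of the total series, greedily thinned by separation.

    Candidate peaks (interior local maxima with value >= ``min_height``,
    plateau midpoints included) are kept in decreasing height order subject
    to pairwise center separation >= ``min_separation_months``.  Returns the
    window-center times of the kept peaks, in time order.
    """
    if len(traj.total) < 3:
        raise ValueError("trajectory needs >= 3 windows for peak detection")
    idx, props = find_peaks(traj.total.astype(float), height=min_height, plateau_size=1)
    heights = props["peak_heights"]
    order = sorted(range(len(idx)), key=lambda i: (-heights[i], traj.centers[idx[i]]))
    kept: list[float] = []
    for i in order:
        t = float(traj.centers[idx[i]])
        if all(abs(t - k) >= min_separation_months for k in kept):
            kept.append(t)
    return sorted(kept)


def recurrent_rnas(
    summaries: Sequence[WindowSummary], min_windows: int = 2
) -> list[tuple[str, list[str], list[int]]]:
    """RNAs differentially expressed in >= ``min_windows`` windows.

    Returns ``(rna_id, window labels, per-window signs)`` sorted by rna_id.
    """
    hits: dict[str, list[tuple[str, int]]] = {}
    for s in summaries:
        if s.skipped:
            continue
        for rid in s.de_rna_ids:
            hits.setdefault(rid, []).append((s.window.label or s.window.label_years, s.direction[rid]))
    out = []
    for rid in sorted(hits):
        if len(hits[rid]) >= min_windows:
            labels = [w for w, _ in hits[rid]]
            signs = [g for _, g in hits[rid]]
            out.append((rid, labels, signs))
    return out
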