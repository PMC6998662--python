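"""Synthetic serum RNA cohort generator with full ground truth.

The generator emulates the structure the downstream analysis assumes: a
case-control serum biobank cohort of smokers followed up to 10 years before
a lung-cancer diagnosis.  Case margins (stage x histology, sex by stage,
smokers by stage), control counts, and age distributions default to the
published cohort summary; counts are negative-binomial with per-RNA
dispersion, log-normal library size factors, batch (blood-donor-group) and
sex covariate shifts, and time-to-diagnosis-dependent case effects shaped as
Gaussian bumps in log2 space.

Everything injected is recorded in a :class:`SimulationTruth` so tests can
score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CASE_STAGES,
    RNA_CLASSES,
    CountMatrix,
    SampleRecord,
    write_count_matrix,
    write_sample_table,
)
from .config import StudyConfig

__all__ = [
    "EffectProfile",
    "SimulationTruth",
    "CohortMargins",
    "effect_at_time",
    "generate_cohort",
    "make_rna_features",
    "make_signal_profiles",
    "write_cohort",
]


@dataclass(frozen=True)
class EffectProfile:
    """Gaussian-bump log2 effect trajectory for one RNA.

    The case effect for a sample at ``t`` months before diagnosis is
    ``amplitude_log2 * exp(-(t - center)^2 / (2 width^2))`` applied when the
    sample's stage and histology fall in ``stages`` / ``histologies``
    (``None`` means all).
    """

    rna_id: str
    center_months: float
    width_months: float
    amplitude_log2: float
    stages: tuple[str, ...] | None = None
    histologies: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.width_months <= 0:
            raise ValueError("width_months must be > 0")
        if not 0 <= self.center_months <= 120:
            raise ValueError("center_months must lie in [0, 120]")

    def applies_to(self, stage: str, histology: str) -> bool:
        ok_stage = self.stages is None or stage in self.stages
        ok_hist = self.histologies is None or histology in self.histologies
        return ok_stage and ok_hist


def effect_at_time(profile: EffectProfile, t: float) -> float:
    """Log2 fold change of ``profile`` at ``t`` months before diagnosis."""
    if t < 0:
        raise ValueError("t must be >= 0")
    z = (t - profile.center_months) / profile.width_months
    return profile.amplitude_log2 * float(np.exp(-0.5 * z * z))


@dataclass
class SimulationTruth:
    """Everything injected into a synthetic cohort."""

    profiles: list[EffectProfile]
    baseline_log2_means: dict[str, float]
    dispersions: dict[str, float]
    library_size_factors: dict[str, float]
    #: (covariate, level) -> per-RNA log2 shift array aligned to rna order
    covariate_effects: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, a in self.dispersions.items():
            if a <= 0:
                raise ValueError(f"dispersion for {rid} must be > 0")
        for p in self.profiles:
            if p.rna_id not in self.baseline_log2_means:
                raise ValueError(f"profile RNA {p.rna_id} not in count matrix")


# Cohort margins of the emulated serum biobank study.  Cases are serum
# samples donated up to 10 years before a lung-cancer diagnosis; stage is the
# TNM-derived extent at diagnosis, histology NSCLC/SCLC/other.
_CASE_HISTOLOGY_STAGE = {
    "NSCLC": {"early": 84, "locally_advanced": 101, "advanced": 171, "unknown": 11},
    "SCLC": {"early": 9, "locally_advanced": 35, "advanced": 76, "unknown": 4},
    "other": {"early": 10, "locally_advanced": 5, "advanced": 32, "unknown": 4},
}
_CASE_MALE_BY_STAGE = {"early": 78, "locally_advanced": 104, "advanced": 180, "unknown": 12}
_CASE_SMOKERS_BY_STAGE = {"early": 102, "locally_advanced": 139, "advanced": 271, "unknown": 19}
_CASE_AGE_BY_STAGE = {
    "early": (54.3, 7.33),
    "locally_advanced": (55.0, 9.04),
    "advanced": (53.4, 8.26),
    "unknown": (51.8, 6.53),
}
_CASE_TIME_YEARS_BY_STAGE = {
    "early": (5.52, 2.81),
    "locally_advanced": (5.63, 2.78),
    "advanced": (5.89, 2.66),
    "unknown": (6.75, 2.18),
}


@dataclass
class CohortMargins:
    """Requested sample counts; defaults reproduce the study cohort summary.

    ``case_histology_stage`` gives case sample counts per histology x stage;
    ``case_male_by_stage`` and ``case_smokers_by_stage`` the male and
    ever-smoker case counts per stage; controls are given as totals.
    """

    case_histology_stage: dict[str, dict[str, int]] = field(
        default_factory=lambda: {h: dict(d) for h, d in _CASE_HISTOLOGY_STAGE.items()}
    )
    case_male_by_stage: dict[str, int] = field(
        default_factory=lambda: dict(_CASE_MALE_BY_STAGE)
    )
    case_smokers_by_stage: dict[str, int] = field(
        default_factory=lambda: dict(_CASE_SMOKERS_BY_STAGE)
    )
    n_controls: int = 519
    n_control_males: int = 350
    n_control_smokers: int = 189
    n_case_subjects: int = 391
    n_control_subjects: int = 518

    def stage_totals(self) -> dict[str, int]:
        totals = {s: 0 for s in CASE_STAGES}
        for counts in self.case_histology_stage.values():
            for s, n in counts.items():
                totals[s] += n
        return totals

    def n_cases(self) -> int:
        return sum(self.stage_totals().values())

    def validate(self) -> None:
        totals = self.stage_totals()
        for s, n_male in self.case_male_by_stage.items():
            if n_male > totals.get(s, 0):
                raise ValueError(f"male count exceeds stage total in stage {s!r}")
        for s, n_smoke in self.case_smokers_by_stage.items():
            if n_smoke > totals.get(s, 0):
                raise ValueError(f"smoker count exceeds stage total in stage {s!r}")
        if self.n_control_males > self.n_controls:
            raise ValueError("control male count exceeds control total")
        if self.n_control_smokers > self.n_controls:
            raise ValueError("control smoker count exceeds control total")
        if not 0 < self.n_case_subjects <= self.n_cases():
            raise ValueError("n_case_subjects must be in (0, n_cases]")
        if not 0 < self.n_control_subjects <= self.n_controls:
            raise ValueError("n_control_subjects must be in (0, n_controls]")

    def scaled(self, factor: float) -> "CohortMargins":
        """Proportionally smaller cohort with the same structure (>=1 per cell)."""

        def sc(n: int) -> int:
            return max(1, round(n * factor))

        hist_stage = {
            h: {s: sc(n) for s, n in d.items()} for h, d in self.case_histology_stage.items()
        }
        stage_totals: dict[str, int] = {}
        for d in hist_stage.values():
            for s, n in d.items():
                stage_totals[s] = stage_totals.get(s, 0) + n
        n_controls = sc(self.n_controls)
        out = CohortMargins(
            case_histology_stage=hist_stage,
            case_male_by_stage={
                s: min(sc(n), stage_totals.get(s, 0)) for s, n in self.case_male_by_stage.items()
            },
            case_smokers_by_stage={
                s: min(sc(n), stage_totals.get(s, 0)) for s, n in self.case_smokers_by_stage.items()
            },
            n_controls=n_controls,
            n_control_males=min(sc(self.n_control_males), n_controls),
            n_control_smokers=min(sc(self.n_control_smokers), n_controls),
            n_case_subjects=min(sc(self.n_case_subjects), sum(stage_totals.values())),
            n_control_subjects=min(sc(self.n_control_subjects), n_controls),
        )
        return out


_CONTROL_AGE = (49.9, 11.2)
_BDG_LEVELS = ("BDg_A", "BDg_B", "BDg_C")

# RNA id prefixes per class; mRNA ids double as gene ids for enrichment.
_CLASS_PREFIX = {
    "miRNA": "miR",
    "miRNA_hairpin": "mir-hp",
    "isomiR": "iso",
    "piRNA": "piR",
    "tRNA": "tRNA",
    "tRF": "tRF",
    "snoRNA": "SNORD",
    "miscRNA": "misc",
    "lncRNA": "LINC",
    "mRNA": "GENE",
}

# Serum small-RNA class mix: small RNAs dominate, mRNA/lncRNA fragments rarer.
_CLASS_WEIGHTS = {
    "miRNA": 0.14,
    "miRNA_hairpin": 0.04,
    "isomiR": 0.14,
    "piRNA": 0.16,
    "tRNA": 0.10,
    "tRF": 0.16,
    "snoRNA": 0.05,
    "miscRNA": 0.05,
    "lncRNA": 0.06,
    "mRNA": 0.10,
}


def _allocate(n: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder integer allocation of ``n`` by ``weights``."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base.tolist()


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def make_signal_profiles(
    rna_ids: Sequence[str],
    fraction: float,
    amplitude_log2: float,
    center_months: float,
    width_months: float,
    stages: Sequence[str] | None = None,
    histologies: Sequence[str] | None = None,
    seed: int = 0,
) -> list[EffectProfile]:
    """Assign one Gaussian-bump profile to a random fraction of RNAs.

    Signs alternate so roughly half the affected RNAs go up and half down,
    as in observed serum signals.
    """
    rng = np.random.default_rng(seed)
    n_affected = int(round(fraction * len(rna_ids)))
    chosen = rng.choice(len(rna_ids), size=n_affected, replace=False)
    profiles = []
    for k, i in enumerate(sorted(chosen)):
        sign = 1.0 if k % 2 == 0 else -1.0
        profiles.append(
            EffectProfile(
                rna_id=rna_ids[i],
                center_months=center_months,
                width_months=width_months,
                amplitude_log2=sign * amplitude_log2,
                stages=tuple(stages) if stages is not None else None,
                histologies=tuple(histologies) if histologies is not None else None,
            )
        )
    return profiles


def make_rna_features(n_rnas: int) -> tuple[list[str], list[str]]:
    """Deterministic RNA ids and class labels for a cohort of ``n_rnas``.

    The class mix follows the serum small-RNA weights; ids are sorted
    lexicographically, matching the ids :func:`generate_cohort` produces.
    """
    class_counts = _allocate(n_rnas, [_CLASS_WEIGHTS[c] for c in RNA_CLASSES])
    rna_ids: list[str] = []
    rna_class: list[str] = []
    for cls, k in zip(RNA_CLASSES, class_counts):
        for j in range(k):
            rna_ids.append(f"{_CLASS_PREFIX[cls]}{j + 1:04d}")
            rna_class.append(cls)
    order = np.argsort(np.asarray(rna_ids, dtype=object))
    return [rna_ids[i] for i in order], [rna_class[i] for i in order]


def _make_case_samples(margins: CohortMargins, rng: np.random.Generator,
                       time_mode: str, span_months: float) -> list[dict]:
    rows: list[dict] = []
    stage_totals = margins.stage_totals()
    for stage in CASE_STAGES:
        total = stage_totals.get(stage, 0)
        if total == 0:
            continue
        hists: list[str] = []
        for hist in sorted(margins.case_histology_stage):
            hists += [hist] * margins.case_histology_stage[hist].get(stage, 0)
        n_male = margins.case_male_by_stage.get(stage, 0)
        sexes = ["male"] * n_male + ["female"] * (total - n_male)
        n_smoke = margins.case_smokers_by_stage.get(stage, total)
        current = rng.integers(0, 2, size=n_smoke)
        smoking = ["current" if c else "former" for c in current] + ["never"] * (total - n_smoke)
        rng.shuffle(hists)
        rng.shuffle(sexes)
        rng.shuffle(smoking)
        mean, sd = _CASE_AGE_BY_STAGE.get(stage, (54.0, 8.0))
        ages = np.round(_truncated_normal(rng, mean, sd, 25.0, 75.0, total), 1)
        if time_mode == "empirical":
            tmean, tsd = _CASE_TIME_YEARS_BY_STAGE.get(stage, (5.7, 2.7))
            times = _truncated_normal(rng, tmean * 12, tsd * 12, 0.0, span_months, total)
        else:
            times = rng.uniform(0.0, span_months, size=total)
        times = np.round(times, 2)
        for i in range(total):
            rows.append(
                dict(
                    group="case",
                    stage=stage,
                    histology=hists[i],
                    sex=sexes[i],
                    smoking=smoking[i],
                    age_at_donation=float(ages[i]),
                    time_to_diagnosis=float(times[i]),
                )
            )
    return rows


def _make_control_samples(margins: CohortMargins, rng: np.random.Generator) -> list[dict]:
    n = margins.n_controls
    sexes = ["male"] * margins.n_control_males + ["female"] * (n - margins.n_control_males)
    n_smoke = margins.n_control_smokers
    current = rng.integers(0, 2, size=n_smoke)
    smoking = ["current" if c else "former" for c in current] + ["never"] * (n - n_smoke)
    rng.shuffle(sexes)
    rng.shuffle(smoking)
    ages = np.round(_truncated_normal(rng, *_CONTROL_AGE, 20.0, 75.0, n), 1)
    return [
        dict(
            group="control",
            stage="not_applicable",
            histology="not_applicable",
            sex=sexes[i],
            smoking=smoking[i],
            age_at_donation=float(ages[i]),
            time_to_diagnosis=None,
        )
        for i in range(n)
    ]


def _assign_subjects(rows: list[dict], n_subjects: int, prefix: str,
                     rng: np.random.Generator) -> list[str]:
    """Group samples into subjects; repeat samples share stage/histology/sex."""
    n = len(rows)
    n_extra = n - n_subjects
    cells: dict[tuple, list[int]] = {}
    for i, r in enumerate(rows):
        cells.setdefault((r["group"], r["stage"], r["histology"], r["sex"]), []).append(i)
    # choose samples that will reuse the previous subject in their cell
    eligible = [idx for members in cells.values() for idx in members[1:]]
    reuse = set(rng.choice(eligible, size=n_extra, replace=False)) if n_extra else set()
    subject_of: list[str] = [""] * n
    counter = 0
    last_in_cell: dict[tuple, str] = {}
    for key in sorted(cells, key=repr):
        for idx in cells[key]:
            if idx in reuse and key in last_in_cell:
                subject_of[idx] = last_in_cell[key]
            else:
                counter += 1
                subject_of[idx] = f"{prefix}{counter:05d}"
                last_in_cell[key] = subject_of[idx]
    return subject_of


def generate_cohort(
    cfg: StudyConfig,
    margins: CohortMargins | None = None,
    n_rnas: int = 500,
    signal_spec: Sequence[EffectProfile] = (),
    seed: int = 0,
    time_mode: str = "uniform",
    bdg_levels: Sequence[str] = _BDG_LEVELS,
    dispersion_range: tuple[float, float] = (0.05, 1.0),
    library_sigma: float = 0.3,
    covariate_sd: float = 0.2,
    count_seed: int | None = None,
) -> tuple[list[SampleRecord], CountMatrix, SimulationTruth]:
    """Generate a synthetic cohort with the requested margins and ground truth.

    Parameters default to the emulated study conditions: published cohort
    margins, prediagnostic times uniform on ``[0, span_months]`` (an
    ``"empirical"`` mode instead draws per-stage truncated normals), per-RNA
    dispersions log-uniform on ``dispersion_range``, log-normal library size
    factors (``sigma=library_sigma``), and small per-RNA batch/sex shifts
    (normal with sd ``covariate_sd``, clipped to |log2| <= 0.5).

    ``seed`` fixes the cohort structure and all model parameters;
    ``count_seed`` (derived from ``seed`` when omitted) fixes only the
    negative-binomial count noise, so two ``count_seed`` values give
    independent count draws from identical underlying means.
    """
    if margins is None:
        margins = CohortMargins()
    margins.validate()
    if n_rnas < 10:
        raise ValueError("n_rnas must be >= 10 (one per RNA class)")
    profiled = {p.rna_id for p in signal_spec}
    if len(profiled) > n_rnas:
        raise ValueError("more profiled RNAs than n_rnas")

    ss = np.random.SeedSequence(seed)
    s_param, s_count = ss.spawn(2)
    rng = np.random.default_rng(s_param)
    rng_counts = np.random.default_rng(
        s_count if count_seed is None else np.random.SeedSequence(count_seed)
    )

    # --- samples -----------------------------------------------------------
    case_rows = _make_case_samples(margins, rng, time_mode, cfg.span_months)
    control_rows = _make_control_samples(margins, rng)
    case_subjects = _assign_subjects(case_rows, margins.n_case_subjects, "P", rng)
    control_subjects = _assign_subjects(control_rows, margins.n_control_subjects, "C", rng)
    rows = case_rows + control_rows
    subjects = case_subjects + control_subjects
    bdg_levels = tuple(bdg_levels)
    bdgs = rng.choice(bdg_levels, size=len(rows))
    samples = []
    for i, (r, subj) in enumerate(zip(rows, subjects)):
        samples.append(
            SampleRecord(
                sample_id=f"S{i + 1:05d}",
                subject_id=subj,
                bdg=str(bdgs[i]),
                **r,
            )
        )

    # --- RNA features ------------------------------------------------------
    rna_ids, rna_class = make_rna_features(n_rnas)
    missing = profiled - set(rna_ids)
    if missing:
        raise ValueError(f"signal_spec names unknown RNAs: {sorted(missing)[:5]}")

    # long-tailed baseline so a minority of RNAs dominates reads, as in serum
    base_log2 = np.clip(rng.exponential(scale=2.5, size=n_rnas) + 1.0, None, 14.0)
    lo, hi = dispersion_range
    disp = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_rnas))
    size_f = rng.lognormal(mean=0.0, sigma=library_sigma, size=len(samples))

    cov_effects: dict[tuple[str, str], np.ndarray] = {}
    for level in bdg_levels[1:]:
        cov_effects[("bdg", level)] = np.clip(
            rng.normal(0.0, covariate_sd, size=n_rnas), -0.5, 0.5
        )
    cov_effects[("sex", "male")] = np.clip(
        rng.normal(0.0, covariate_sd / 2, size=n_rnas), -0.5, 0.5
    )

    # --- counts ------------------------------------------------------------
    rna_index = {rid: i for i, rid in enumerate(rna_ids)}
    log2_mu = np.tile(base_log2[:, None], (1, len(samples)))
    for j, s in enumerate(samples):
        for (var, level), shift in cov_effects.items():
            if getattr(s, var) == level:
                log2_mu[:, j] += shift
        if s.group == "case":
            for p in signal_spec:
                if p.applies_to(s.stage, s.histology):
                    log2_mu[rna_index[p.rna_id], j] += effect_at_time(p, s.time_to_diagnosis)
    mean = size_f[None, :] * np.exp2(log2_mu)
    r = 1.0 / disp[:, None]
    counts = rng_counts.negative_binomial(r, r / (r + mean))

    matrix = CountMatrix(
        rna_ids=rna_ids,
        rna_class=rna_class,
        sample_ids=[s.sample_id for s in samples],
        counts=counts.astype(np.int64),
    )
    truth = SimulationTruth(
        profiles=list(signal_spec),
        baseline_log2_means=dict(zip(rna_ids, base_log2.tolist())),
        dispersions=dict(zip(rna_ids, disp.tolist())),
        library_size_factors={s.sample_id: float(f) for s, f in zip(samples, size_f)},
        covariate_effects=cov_effects,
    )
    return samples, matrix, truth


def write_cohort(
    samples: Sequence[SampleRecord],
    counts: CountMatrix,
    truth: SimulationTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Write samples.tsv, counts.tsv, and truth.tsv (injected effect profiles).

    The truth file tabulates the effect profiles; per-RNA baselines and
    dispersions live on the in-memory :class:`SimulationTruth` object.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": directory / "samples.tsv",
        "counts": directory / "counts.tsv",
        "truth": directory / "truth.tsv",
    }
    write_sample_table(list(samples), paths["samples"])
    write_count_matrix(counts, paths["counts"])
    prof = pd.DataFrame(
        [
            {
                "rna_id": p.rna_id,
                "center_months": p.center_months,
                "width_months": p.width_months,
                "amplitude_log2": p.amplitude_log2,
                "stages": "|".join(p.stages) if p.stages else "",
                "histologies": "|".join(p.histologies) if p.histologies else "",
            }
            for p in sorted(truth.profiles, key=lambda p: p.rna_id)
        ],
        columns=["rna_id", "center_months", "width_months", "amplitude_log2", "stages", "histologies"],
    )
    prof.to_csv(paths["truth"], sep="\t", index=False)
    return paths
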