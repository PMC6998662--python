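"""Covariate-adjusted negative-binomial Wald differential expression.

The engine follows the standard count-based DE recipe: per-sample size
factors by the median-of-ratios method, per-RNA NB2 dispersions by a
trend-shrunken method-of-moments estimate, a per-RNA negative-binomial
log-link regression with the size factors as offsets (iteratively reweighted
least squares at fixed dispersion), a Wald test of the case/control
coefficient against the standard normal, and Benjamini-Hochberg adjustment.

It is a deliberately simplified analogue of the full DESeq2 machinery: no
Cox-Reid adjustment, dispersion-outlier refitting, fold-change shrinkage,
independent filtering, or outlier-count handling.  The IRLS is vectorised
across RNAs (one batched p x p solve per iteration) so that sliding-window
analyses with dozens of windows stay fast.

Model: for RNA i and sample j, ``y_ij ~ NB(mu_ij, alpha_i)`` with
``log mu_ij = log s_j + x_j' beta_i`` and ``Var = mu + alpha mu^2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .cohort import CountMatrix, SampleRecord

__all__ = [
    "DEResult",
    "build_design",
    "size_factors",
    "estimate_dispersions",
    "wald_test",
    "adjust_bh",
    "run_de",
]

LN2 = float(np.log(2.0))
_ALPHA_FLOOR = 1e-8
_MU_MIN = 1e-10


@dataclass
class DEResult:
    """Per-RNA differential-expression result for one analysis."""

    rna_id: str
    rna_class: str
    base_mean: float
    log2fc: float
    se: float
    wald: float
    pvalue: float
    padj: float
    converged: bool = True

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.padj) and self.padj < 0.05)


def results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rna_id": r.rna_id,
                "rna_class": r.rna_class,
                "base_mean": r.base_mean,
                "log2fc": r.log2fc,
                "se": r.se,
                "wald": r.wald,
                "pvalue": r.pvalue,
                "padj": r.padj,
                "converged": r.converged,
            }
            for r in results
        ]
    )


def build_design(
    samples: Sequence[SampleRecord],
    covariates: Sequence[str] = ("age_at_donation", "sex", "smoking", "bdg"),
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, case indicator, and confounder encodings.

    Age is z-scored; sex, smoking, and blood-donor group enter as
    reference-coded indicators (reference levels: female, former smoker, and
    the alphabetically first bdg label).  Indicator columns constant across
    the samples are dropped; a rank-deficient design raises ``ValueError``.
    """
    n = len(samples)
    cols = [np.ones(n), np.array([1.0 if s.group == "case" else 0.0 for s in samples])]
    names = ["intercept", "group_case"]
    for var in covariates:
        if var == "age_at_donation":
            age = np.array([s.age_at_donation for s in samples], dtype=float)
            sd = age.std()
            z = (age - age.mean()) / sd if sd > 0 else np.zeros(n)
            cols.append(z)
            names.append("age_z")
            continue
        levels = sorted({getattr(s, var) for s in samples})
        ref = {"sex": "female", "smoking": "former"}.get(var, levels[0])
        for lev in levels:
            if lev == ref:
                continue
            ind = np.array([1.0 if getattr(s, var) == lev else 0.0 for s in samples])
            if 0 < ind.sum() < n:
                cols.append(ind)
                names.append(f"{var}_{lev}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


def size_factors(counts: np.ndarray | CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors (the standard count-DE default).

    ``s_j = exp(median_i(log c_ij - log geomean_i))`` over RNAs whose
    geometric mean is positive (i.e. no zero count).  Factors are not
    rescaled afterwards.
    """
    c = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    c = c.astype(float)
    with np.errstate(divide="ignore"):
        logc = np.log(c)
    log_geo = logc.mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no RNA has all-positive counts; size factors undefined")
    ratios = logc[usable, :] - log_geo[usable, None]
    if not np.all(np.isfinite(ratios).any(axis=0)):
        raise ValueError("a sample shares no positive RNA with the reference")
    return np.exp(np.median(ratios, axis=0))


def estimate_dispersions(
    counts: np.ndarray | CountMatrix,
    sf: np.ndarray,
    design: np.ndarray,
    alpha_floor: float = _ALPHA_FLOOR,
) -> np.ndarray:
    """Trend-shrunken method-of-moments NB2 dispersions, one per RNA.

    Raw estimate on normalized counts q = y/s: ``alpha = (var - mean)/mean^2``
    floored at ``alpha_floor``; a mean-dispersion trend ``a0/mean + a1`` is
    fitted by non-negative least squares across RNAs and the raw estimates
    are shrunk 50/50 toward it in log space.
    """
    c = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    n, p = design.shape[0], design.shape[1]
    if n - p < 2:
        raise ValueError("need >= 2 residual degrees of freedom")
    q = c / sf[None, :]
    m = q.mean(axis=1)
    v = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, alpha_floor)
    raw = np.maximum(raw, alpha_floor)

    informative = (m > 0) & (raw > alpha_floor)
    if informative.sum() >= 10:
        from scipy.optimize import nnls

        A = np.column_stack([1.0 / m[informative], np.ones(int(informative.sum()))])
        coef, _ = nnls(A, raw[informative])
        a0, a1 = coef
    else:
        a0, a1 = 0.0, float(np.median(raw))
    with np.errstate(divide="ignore"):
        trend = np.where(m > 0, a0 / np.maximum(m, 1e-300) + a1, a1)
    trend = np.maximum(trend, alpha_floor)
    shrunk = np.exp(0.5 * np.log(raw) + 0.5 * np.log(trend))
    return np.maximum(shrunk, alpha_floor)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, r: np.ndarray) -> np.ndarray:
    """NB2 log-likelihood summed over samples, per RNA (y, mu: R x S)."""
    mu = np.maximum(mu, _MU_MIN)
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    ).sum(axis=1)


def _irls_fit(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised IRLS for NB log-link regression at fixed dispersion.

    Returns (beta [R x p], cov diagonal se [R x p], converged [R]).
    """
    n_rna, n = y.shape
    p = X.shape[1]
    r = 1.0 / np.maximum(alpha, _ALPHA_FLOOR)
    beta = np.zeros((n_rna, p))
    q0 = (y / np.exp(offset)[None, :]).mean(axis=1)
    beta[:, 0] = np.log(np.maximum(q0, 1e-8))
    eta = beta @ X.T + offset[None, :]
    mu = np.maximum(np.exp(eta), _MU_MIN)
    ll = _nb_loglik(y, mu, r[:, None])
    converged = np.zeros(n_rna, dtype=bool)
    active = np.ones(n_rna, dtype=bool)

    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        mu_a = mu[idx]
        w = mu_a / (1.0 + alpha[idx, None] * mu_a)  # Fisher weights
        z = (eta[idx] - offset[None, :]) + (y[idx] - mu_a) / mu_a
        A = np.einsum("jp,ij,jq->ipq", X, w, X)
        b = np.einsum("jp,ij,ij->ip", X, w, z)
        try:
            new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_beta = np.einsum("ipq,iq->ip", np.linalg.pinv(A), b)
        # step-halving if the likelihood decreases (rare, keeps IRLS safe)
        step = new_beta - beta[idx]
        scale = np.ones(idx.size)
        for _half in range(12):
            cand = beta[idx] + scale[:, None] * step
            eta_c = cand @ X.T + offset[None, :]
            eta_c = np.clip(eta_c, -40.0, 40.0)
            mu_c = np.maximum(np.exp(eta_c), _MU_MIN)
            ll_c = _nb_loglik(y[idx], mu_c, r[idx, None])
            worse = ll_c < ll[idx] - 1e-10
            if not worse.any():
                break
            scale[worse] *= 0.5
        beta[idx] = cand
        eta[idx] = eta_c
        mu[idx] = mu_c
        delta = np.abs(ll_c - ll[idx]) / (np.abs(ll[idx]) + 0.1)
        ll[idx] = ll_c
        done = delta < tol
        converged[idx[done]] = True
        active[idx[done]] = False

    # standard errors from the final Fisher information
    w = mu / (1.0 + alpha[:, None] * mu)
    A = np.einsum("jp,ij,jq->ipq", X, w, X)
    se = np.full((n_rna, p), np.nan)
    for i in range(n_rna):
        try:
            cov = np.linalg.inv(A[i])
            d = np.diag(cov)
            if np.all(d > 0):
                se[i] = np.sqrt(d)
            else:
                converged[i] = False
        except np.linalg.LinAlgError:
            converged[i] = False
    return beta, se, converged


def wald_test(
    counts: CountMatrix,
    design: np.ndarray,
    sf: np.ndarray,
    dispersions: np.ndarray,
    design_names: Sequence[str] | None = None,
    group_col: int = 1,
) -> list[DEResult]:
    """Per-RNA NB Wald test of the case/control coefficient.

    Non-convergent or degenerate RNAs (for example all-zero counts) are
    flagged with missing p-values and excluded from BH adjustment, never
    raised as errors.
    """
    X = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if design_names is not None:
        group_col = list(design_names).index("group_case")
    y = counts.counts.astype(float)
    offset = np.log(sf)
    nonzero = y.sum(axis=1) > 0

    beta = np.full((y.shape[0], X.shape[1]), np.nan)
    se = np.full_like(beta, np.nan)
    conv = np.zeros(y.shape[0], dtype=bool)
    if nonzero.any():
        b, s, c = _irls_fit(y[nonzero], X, offset, np.asarray(dispersions)[nonzero])
        beta[nonzero] = b
        se[nonzero] = s
        conv[nonzero] = c

    base_mean = (y / sf[None, :]).mean(axis=1)
    log2fc = beta[:, group_col] / LN2
    se2 = se[:, group_col] / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / se2
    ok = conv & np.isfinite(wald)
    pvals = np.where(ok, 2.0 * norm.sf(np.abs(wald)), np.nan)
    padj = adjust_bh(pvals)

    results = []
    for i, rid in enumerate(counts.rna_ids):
        results.append(
            DEResult(
                rna_id=rid,
                rna_class=counts.rna_class[i],
                base_mean=float(base_mean[i]),
                log2fc=float(log2fc[i]) if np.isfinite(log2fc[i]) else np.nan,
                se=float(se2[i]) if np.isfinite(se2[i]) else np.nan,
                wald=float(wald[i]) if np.isfinite(wald[i]) else np.nan,
                pvalue=float(pvals[i]) if np.isfinite(pvals[i]) else np.nan,
                padj=float(padj[i]) if np.isfinite(padj[i]) else np.nan,
                converged=bool(ok[i]),
            )
        )
    return results


def adjust_bh(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs are excluded with warning
    (the number of tests m is reduced accordingly) and returned as NaN."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.sum() < p.size:
        warnings.warn(
            f"adjust_bh: excluding {p.size - int(mask.sum())} missing p-values",
            stacklevel=2,
        )
    if not mask.any():
        return out
    if p[mask].min() < 0 or p[mask].max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def run_de(
    counts: CountMatrix,
    samples: Sequence[SampleRecord],
    covariates: Sequence[str] = ("age_at_donation", "sex", "smoking", "bdg"),
) -> list[DEResult]:
    """Convenience wrapper: design + size factors + dispersions + Wald test."""
    sub = counts.subset_samples([s.sample_id for s in samples])
    X, names = build_design(samples, covariates)
    sf = size_factors(sub)
    disp = estimate_dispersions(sub, sf, X)
    return wald_test(sub, X, sf, disp, design_names=names)
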