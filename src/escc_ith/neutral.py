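"""Neutral tumor-growth model fit on the subclonal VAF spectrum.

Under neutral growth the cumulative number of subclonal mutations
with frequency at least f follows

    M(f) = (mu / beta) * (1/f - f/f_max)

where mu/beta is the mutation rate per effective cell division and
f_max the expected VAF of clonal mutations (purity/2 in a diploid
region).  The slope is fitted by least squares through the origin on
x = 1/f - f/f_max over the open VAF window (0.12, 0.24); R^2 >= 0.98
calls the sample neutral.  Samples failing that fit fall back to a
contamination-corrected model in which observed VAFs are deflated by
normal-cell dilution: f_true = f_obs * (1 + eps), eps >= 0, fitted
jointly with the slope.

Eligibility for the cohort summary: purity > 0.5 and at least 12
SNVs inside the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

R2_NEUTRAL = 0.98
WINDOW = (0.12, 0.24)
MIN_WINDOW_SNVS = 12
MIN_PURITY = 0.5


@dataclass
class NeutralFitResult:
    sample_id: str
    mu_over_beta: float
    epsilon: float
    f_max: float
    r_squared: float
    r_squared_adjusted: float | None
    n_snvs_in_window: int
    neutral: bool
    eligible: bool
    model: str  # "eq1" or "eq2"


def cumulative_curve(
    vafs: np.ndarray, window: tuple[float, float] = WINDOW
) -> tuple[np.ndarray, np.ndarray]:
    """Ordered (f, M(f)) pairs over the open VAF window.

    M(f) is the cumulative count of ALL input mutations with VAF >= f
    (the clonal peak above the window contributes, as the model
    requires: M(f_max) = (mu/beta)(1/f_max - 1) > 0), evaluated at
    each observed VAF inside the open window.  Returned with f
    descending, so M is nondecreasing along the output.
    """
    vafs = np.asarray(vafs, dtype=float)
    if np.any((vafs <= 0) | (vafs >= 1)):
        raise ValueError("VAFs must lie in (0, 1)")
    lo, hi = window
    inside = vafs[(vafs > lo) & (vafs < hi)]
    if inside.size == 0:
        raise ValueError("empty_window")
    asc_all = np.sort(vafs)
    f = np.sort(inside)[::-1].copy()
    # exact count of mutations with VAF >= f (ties handled)
    m = (vafs.size - np.searchsorted(asc_all, f, side="left")).astype(float)
    return f, m


def _r_squared(m: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((m - fitted) ** 2))
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_neutral(
    f: np.ndarray,
    m: np.ndarray,
    f_max: float,
    sample_id: str = "",
    min_points: int = MIN_WINDOW_SNVS,
) -> NeutralFitResult:
    """One-parameter origin-constrained fit of M(f) (Eq-1-style model)."""
    f, m = np.asarray(f, float), np.asarray(m, float)
    if f.size < min_points:
        raise ValueError(f"need >= {min_points} points, got {f.size}")
    if f_max <= f.max():
        raise ValueError(f"f_max={f_max} must exceed the largest window VAF")
    x = 1.0 / f - f / f_max
    slope = float(np.dot(x, m) / np.dot(x, x))
    r2 = _r_squared(m, slope * x)
    return NeutralFitResult(
        sample_id=sample_id,
        mu_over_beta=max(slope, 0.0),
        epsilon=0.0,
        f_max=f_max,
        r_squared=r2,
        r_squared_adjusted=None,
        n_snvs_in_window=int(f.size),
        neutral=r2 >= R2_NEUTRAL,
        eligible=True,
        model="eq1",
    )


def fit_neutral_corrected(
    f: np.ndarray,
    m: np.ndarray,
    f_max: float,
    sample_id: str = "",
    eps_max: float = 2.0,
) -> NeutralFitResult:
    """Two-parameter contamination-corrected fit (fallback model).

    Observed VAFs are rescaled as g = f*(1+eps) with eps >= 0 (normal
    contamination) and M is refitted on x = 1/g - g/f_max.  Intended
    as the fallback when the plain fit is rejected.
    """
    f, m = np.asarray(f, float), np.asarray(m, float)
    if f.size < MIN_WINDOW_SNVS:
        raise ValueError(f"need >= {MIN_WINDOW_SNVS} points")

    # rescaled VAFs must stay below f_max, otherwise extreme eps can
    # compress the window and "fit" arbitrary curves
    eps_cap = max(min(eps_max, f_max * 0.999 / float(f.max()) - 1.0), 1e-9)

    def residuals(params):
        slope, eps = params
        g = f * (1.0 + eps)
        return slope * (1.0 / g - g / f_max) - m

    x0 = 1.0 / f - f / f_max
    slope0 = float(np.dot(x0, m) / np.dot(x0, x0))
    result = scipy.optimize.least_squares(
        residuals, x0=[max(slope0, 1e-6), 0.0],
        bounds=([0.0, 0.0], [np.inf, eps_cap]),
    )
    slope, eps = result.x
    # an eps pinned at its bound is not a credible contamination estimate
    converged = bool(result.success and eps < eps_cap - 1e-6)
    r2_adj = _r_squared(m, m + result.fun)
    return NeutralFitResult(
        sample_id=sample_id,
        mu_over_beta=float(slope),
        epsilon=float(eps),
        f_max=f_max,
        r_squared=r2_adj,
        r_squared_adjusted=r2_adj,
        n_snvs_in_window=int(f.size),
        neutral=bool(converged and r2_adj >= R2_NEUTRAL),
        eligible=True,
        model="eq2",
    )


def fit_sample(
    vafs: np.ndarray,
    purity: float | None,
    sample_id: str = "",
    f_max: float | None = None,
    window: tuple[float, float] = WINDOW,
) -> NeutralFitResult:
    """Full per-sample procedure: eligibility, plain fit, corrected fallback.

    f_max defaults to purity/2, the expected clonal heterozygous VAF
    in a diploid region.
    """
    vafs = np.asarray(vafs, dtype=float)
    lo, hi = window
    n_window = int(np.sum((vafs > lo) & (vafs < hi)))
    eligible = purity is not None and purity > MIN_PURITY and n_window >= MIN_WINDOW_SNVS
    if not eligible:
        return NeutralFitResult(sample_id, 0.0, 0.0, f_max or 0.0, -np.inf, None,
                                n_window, neutral=False, eligible=False, model="none")
    if f_max is None:
        f_max = purity / 2.0
    f_max = max(f_max, hi * 1.0001)  # the model needs f_max beyond the window
    f, m = cumulative_curve(vafs, window)
    fit = fit_neutral(f, m, f_max, sample_id)
    if fit.neutral:
        return fit
    fit2 = fit_neutral_corrected(f, m, f_max, sample_id)
    fit2.r_squared = fit.r_squared  # keep the plain-model R^2 alongside
    return fit2


@dataclass
class CohortNeutrality:
    n_samples: int
    n_eligible: int
    n_neutral: int

    @property
    def fraction_neutral(self) -> float:
        return self.n_neutral / self.n_eligible if self.n_eligible else 0.0


def classify_cohort(
    sample_vafs: dict[str, np.ndarray],
    purities: dict[str, float | None],
    f_max: dict[str, float] | None = None,
) -> tuple[CohortNeutrality, list[NeutralFitResult]]:
    """Apply the per-sample procedure across a cohort and tally neutrality."""
    fits = []
    for sid, vafs in sample_vafs.items():
        fm = f_max.get(sid) if f_max else None
        fits.append(fit_sample(np.asarray(vafs), purities.get(sid), sid, f_max=fm))
    n_eligible = sum(f.eligible for f in fits)
    n_neutral = sum(f.neutral for f in fits)
    return CohortNeutrality(len(fits), n_eligible, n_neutral), fits
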