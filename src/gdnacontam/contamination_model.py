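"""Spike-in regression and intercept decomposition.

The intergenic mapping ratio of a library is modelled as linear in the spiked
gDNA mass fraction DNA_a:

    mapping_ratio_IR = (a c p_IR) DNA_a + (a c p_IR) DNA_r + a cDNA_IR + e

where c is the method's DNA capture coefficient, p_IR the intergenic genome
fraction, DNA_r the residual post-DNase gDNA, and cDNA_IR the intergenic
unannotated-transcript background (a is an overall scale).  The procedure is
sequential:

1. fit the poly(A) series; its intercept estimates the PA cDNA background
   (the PA slope is recorded but typically not significant — gDNA is barely
   captured by oligo-dT);
2. scale the PA background by 1 + n_noncoding/n_coding to the rRNA-depletion
   (RZ) background, since ribosomal depletion additionally retains
   non-polyadenylated unannotated transcripts;
3. decompose the RZ intercept: DNA_r = (intercept - cDNA term) / slope;
4. invert the fitted line to score any RZ library:
   gDNA_total = (mapping_ratio - cDNA term) / slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats


class DegenerateDesignError(ValueError):
    """The regression design is singular (fewer than two distinct DNA_a)."""


class NonIdentifiableError(ValueError):
    """The slope is non-positive; DNA_r cannot be recovered."""


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares fit of mapping ratio against DNA_a.

    ``f_statistic`` is the slope F test (equal to the squared slope t
    statistic) on (1, n-2) degrees of freedom with two-sided p-value.
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    f_statistic: float
    f_df: tuple[int, int]
    p_value: float
    residuals: np.ndarray
    n_points: int


class CdnaTermPA(NamedTuple):
    value: float
    pa_slope_significant: bool
    clamped: bool


class GdnaPrediction(NamedTuple):
    value: float
    below_detection: bool


@dataclass(frozen=True)
class ContaminationEstimate:
    """Full decomposition of the two-method fit."""

    fit_pa: RegressionFit
    fit_rz: RegressionFit
    slope_rz: float
    cdna_term_pa: float
    cdna_term_rz: float
    coding_noncoding_ratio: float
    dna_r_hat: float
    pa_slope_significant: bool
    pa_intercept_clamped: bool

    @property
    def dna_r_negative(self) -> bool:
        return self.dna_r_hat < 0


def fit_series(
    dna_a: Sequence[float], mapping_ratio: Sequence[float]
) -> RegressionFit:
    """Closed-form simple OLS of mapping ratio on DNA_a.

    Requires >= 3 points with >= 2 distinct DNA_a values.  Libraries with
    unknown DNA_a (no-DNase) must be excluded by the caller.
    """
    x = np.asarray(dna_a, dtype=float)
    y = np.asarray(mapping_ratio, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("dna_a and mapping_ratio must be equal-length 1-D")
    n = len(x)
    if n < 3:
        raise DegenerateDesignError(f"need >= 3 points, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise DegenerateDesignError("all DNA_a values identical")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    residuals = y - (intercept + slope * x)
    sse = float(np.sum(residuals**2))
    df = n - 2
    sigma2 = sse / df
    slope_se = float(np.sqrt(sigma2 / sxx))
    intercept_se = float(np.sqrt(sigma2 * (1.0 / n + x.mean() ** 2 / sxx)))
    r_squared = 1.0 - sse / syy if syy > 0 else (1.0 if sse == 0 else 0.0)
    if sigma2 > 0:
        f_stat = slope**2 * sxx / sigma2
        p_value = float(stats.f.sf(f_stat, 1, df))
    else:  # perfect fit
        f_stat = np.inf if slope != 0 else 0.0
        p_value = 0.0 if slope != 0 else 1.0
    return RegressionFit(
        slope=float(slope),
        intercept=intercept,
        slope_se=slope_se,
        intercept_se=intercept_se,
        r_squared=float(r_squared),
        f_statistic=float(f_stat),
        f_df=(1, df),
        p_value=p_value,
        residuals=residuals,
        n_points=n,
    )


def estimate_cdna_term_pa(
    fit_pa: RegressionFit, alpha_level: float = 0.05
) -> CdnaTermPA:
    """PA intercept as the unannotated-transcript background term.

    A negative intercept is clamped to zero with a flag.  Whether the PA slope
    is significant at *alpha_level* is recorded but does not change the
    computation: the intercept is always used.
    """
    value = fit_pa.intercept
    clamped = value < 0
    if clamped:
        value = 0.0
    return CdnaTermPA(
        value=value,
        pa_slope_significant=bool(fit_pa.p_value < alpha_level),
        clamped=clamped,
    )


def infer_cdna_term_rz(
    cdna_term_pa: float, n_coding: int, n_noncoding: int
) -> float:
    """Scale the PA background to RZ by the noncoding/coding gene-count ratio."""
    if n_coding <= 0:
        raise ZeroDivisionError("n_coding must be positive")
    if n_noncoding < 0:
        raise ValueError("n_noncoding must be >= 0")
    return (1.0 + n_noncoding / n_coding) * cdna_term_pa


def estimate_residual_dna(fit_rz: RegressionFit, cdna_term_rz: float) -> float:
    """DNA_r = (RZ intercept - RZ cDNA term) / RZ slope.

    Negative estimates are returned as-is (the caller flags them); a
    non-positive slope makes DNA_r non-identifiable.
    """
    if fit_rz.slope <= 0:
        raise NonIdentifiableError(
            f"RZ slope {fit_rz.slope} <= 0: residual DNA not identifiable"
        )
    return (fit_rz.intercept - cdna_term_rz) / fit_rz.slope


def predict_gdna(
    mapping_ratio_ir: float, slope_rz: float, cdna_term_rz: float
) -> GdnaPrediction:
    """Total gDNA mass fraction of one RZ library by inverting the fit."""
    if not 0.0 <= mapping_ratio_ir <= 1.0:
        raise ValueError(f"mapping ratio {mapping_ratio_ir} outside [0, 1]")
    if slope_rz <= 0:
        raise NonIdentifiableError("slope must be positive to invert")
    value = (mapping_ratio_ir - cdna_term_rz) / slope_rz
    return GdnaPrediction(value=value, below_detection=value < 0)


def estimate_contamination(
    pa_points: tuple[Sequence[float], Sequence[float]],
    rz_points: tuple[Sequence[float], Sequence[float]],
    n_coding: int,
    n_noncoding: int,
    alpha_level: float = 0.05,
) -> ContaminationEstimate:
    """Run the full sequential procedure on (DNA_a, ratio) point sets."""
    fit_pa = fit_series(*pa_points)
    fit_rz = fit_series(*rz_points)
    cdna_pa = estimate_cdna_term_pa(fit_pa, alpha_level=alpha_level)
    cdna_rz = infer_cdna_term_rz(cdna_pa.value, n_coding, n_noncoding)
    dna_r_hat = estimate_residual_dna(fit_rz, cdna_rz)
    return ContaminationEstimate(
        fit_pa=fit_pa,
        fit_rz=fit_rz,
        slope_rz=fit_rz.slope,
        cdna_term_pa=cdna_pa.value,
        cdna_term_rz=cdna_rz,
        coding_noncoding_ratio=n_noncoding / n_coding,
        dna_r_hat=dna_r_hat,
        pa_slope_significant=cdna_pa.pa_slope_significant,
        pa_intercept_clamped=cdna_pa.clamped,
    )
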