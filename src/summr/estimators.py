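"""Summary-data Mendelian randomization estimators.

Given per-SNP exposure effects ``beta_X`` (with SEs ``se_X``) and allele-
aligned outcome effects ``beta_Y`` (with SEs ``se_Y``), the causal effect of
one exposure unit on the outcome is estimated by combining the per-SNP Wald
ratios ``theta_j = beta_Yj / beta_Xj``:

* :class:`IVWEstimator` — fixed-effect inverse-variance weighting, identical
  to weighted least squares of beta_Y on beta_X through the origin with
  weights se_Y^-2;
* :class:`CorrelatedGLSEstimator` — the same regression generalized to
  correlated instruments, with weight matrix Omega^-1 where
  Omega_jk = se_Yj se_Yk rho_jk and rho is the LD correlation matrix;
* :class:`WeightedMedianEstimator` — the weighted median of the ratio
  distribution, consistent when instruments carrying at least half the
  weight are valid; SE by parametric bootstrap;
* :class:`EggerRegression` — weighted regression *with* an intercept; a
  nonzero intercept indicates directional horizontal pleiotropy and the slope
  is a pleiotropy-adjusted estimate. Fitted with the I2_GX statistic
  quantifying violation of the no-measurement-error (NOME) assumption.

All estimators follow the scikit-learn protocol: hyper-parameters in
``__init__``, data in ``fit(X, y, ...)``, results in trailing-underscore
attributes, and they compose with ``sklearn.base.clone``/``get_params``.
``X`` is the exposure-effect vector (shape ``(K,)`` or ``(K, 1)``) and ``y``
the outcome-effect vector. The module-level functions (:func:`ivw`,
:func:`gls_correlated`, :func:`weighted_median`, :func:`egger`) are thin
wrappers consuming a :class:`~summr.records.HarmonizedInstrumentSet`.

Standard errors are fixed-effect throughout: the outcome SEs are treated as
known, and no residual overdispersion scaling is applied. Confidence
intervals are normal-theory, estimate +/- z_{1-alpha/2} * SE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    NumericalError,
    UndefinedRatioError,
)
from .records import HarmonizedInstrumentSet


@dataclass(frozen=True)
class RatioEstimate:
    """A single SNP's Wald ratio with its first-order SE and IV weight."""

    snp_id: str
    theta: float
    se_theta: float

    @property
    def weight(self) -> float:
        return self.se_theta ** -2


@dataclass
class MRResult:
    """A causal estimate on the exposure's unit scale.

    ``beta`` is the effect of one exposure unit (e.g. 1 mg/dl serum calcium)
    on the outcome; when ``outcome_scale`` is ``"log-odds"`` the exponentiated
    view (odds ratio with CI) is available via :meth:`odds_ratio`.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    n_snps: int
    outcome_scale: str = "raw"
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None

    def odds_ratio(self) -> Tuple[float, float, float]:
        """(OR, CI low, CI high); only defined for log-odds outcomes."""
        if self.outcome_scale != "log-odds":
            raise ValueError(
                f"odds ratio undefined for outcome scale {self.outcome_scale!r}"
            )
        return (float(np.exp(self.beta)), float(np.exp(self.ci_low)),
                float(np.exp(self.ci_high)))


@dataclass(frozen=True)
class EggerDiagnostics:
    """NOME-violation diagnostic for MR-Egger.

    ``q_gx`` is the heterogeneity statistic of the SNP-exposure effects about
    their precision-weighted mean; ``i2_gx = max(0, (Q - (K-1)) / Q)`` is the
    fraction of their dispersion not attributable to sampling error. Values
    near 1 mean exposure effects are estimated precisely relative to their
    spread (NOME approximately holds); low values warn that the Egger slope
    is attenuated.
    """

    q_gx: float
    i2_gx: float


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float,
               snp_id: str = "", second_order: bool = False) -> RatioEstimate:
    """Single-SNP causal estimate theta = beta_y / beta_x.

    The default SE is the first-order delta-method value se_y / |beta_x|,
    which ignores the uncertainty in beta_x; ``second_order=True`` adds the
    beta_x sampling-variance term
    sqrt(se_y^2 / beta_x^2 + beta_y^2 se_x^2 / beta_x^4).
    """
    if beta_x == 0:
        raise UndefinedRatioError(f"{snp_id or 'SNP'}: beta_x is zero, ratio undefined")
    if se_y <= 0:
        raise ValueError("se_y must be positive")
    theta = beta_y / beta_x
    if second_order:
        se = np.sqrt(se_y ** 2 / beta_x ** 2 + beta_y ** 2 * se_x ** 2 / beta_x ** 4)
    else:
        se = se_y / abs(beta_x)
    return RatioEstimate(snp_id=snp_id, theta=float(theta), se_theta=float(se))


def _as_vector(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError(f"expected a vector or (K, 1) array, got shape {X.shape}")
    return X


class _BaseMREstimator(RegressorMixin, BaseEstimator):
    """Shared plumbing: CI construction, prediction, result export."""

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    _method = "base"

    def _finalize(self, beta: float, se: float, n_snps: int) -> None:
        z = stats.norm.ppf(1.0 - self.alpha / 2.0)
        self.beta_ = float(beta)
        self.se_ = float(se)
        self.ci_low_ = self.beta_ - z * self.se_
        self.ci_high_ = self.beta_ + z * self.se_
        self.n_snps_ = int(n_snps)

    def predict(self, X) -> np.ndarray:
        """Predicted outcome effects beta_ * beta_X (+ intercept if any)."""
        x = _as_vector(X)
        return getattr(self, "intercept_", 0.0) + self.beta_ * x

    def to_result(self, outcome_scale: str = "raw") -> MRResult:
        return MRResult(
            method=self._method,
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            n_snps=self.n_snps_,
            outcome_scale=outcome_scale,
            intercept=getattr(self, "intercept_", None),
            intercept_se=getattr(self, "intercept_se_", None),
            intercept_p=getattr(self, "intercept_p_", None),
        )


class IVWEstimator(_BaseMREstimator):
    """Fixed-effect inverse-variance-weighted estimator.

    beta = sum_j bX_j bY_j / sY_j^2  /  sum_j bX_j^2 / sY_j^2,
    SE = (sum_j bX_j^2 / sY_j^2)^(-1/2).

    With a single SNP this reduces exactly to the Wald ratio.
    """

    _method = "ivw"

    def fit(self, X, y, se_y=None):
        bx = _as_vector(X)
        by = _as_vector(y)
        sy = np.ones_like(bx) if se_y is None else _as_vector(se_y)
        if not (bx.shape == by.shape == sy.shape):
            raise ValueError("beta_X, beta_Y and se_Y must have equal length")
        if np.any(sy <= 0):
            raise ValueError("se_y must be strictly positive")
        w = sy ** -2.0
        denom = float(np.sum(bx ** 2 * w))
        if denom == 0.0:
            raise DegenerateInstrumentError("all SNP-exposure effects are zero")
        self._finalize(np.sum(bx * by * w) / denom, denom ** -0.5, bx.size)
        return self


class CorrelatedGLSEstimator(_BaseMREstimator):
    """IVW generalized to correlated instruments.

    With Omega_jk = sY_j sY_k rho_jk (rho the signed LD correlation matrix):
    beta = (bX' Omega^-1 bX)^-1 bX' Omega^-1 bY,
    SE = (bX' Omega^-1 bX)^(-1/2).

    Reduces exactly to IVW when rho is the identity. Omega must be positive
    definite; perfectly correlated pairs (|rho| = 1) are rejected with advice
    to LD-prune first.
    """

    _method = "gls"

    def fit(self, X, y, se_y=None, ld=None):
        bx = _as_vector(X)
        by = _as_vector(y)
        sy = np.ones_like(bx) if se_y is None else _as_vector(se_y)
        K = bx.size
        rho = np.eye(K) if ld is None else np.asarray(ld, dtype=float)
        if rho.shape != (K, K):
            raise ValueError(f"LD matrix shape {rho.shape} does not match K = {K}")
        off = ~np.eye(K, dtype=bool)
        if K > 1 and np.any(np.abs(rho[off]) >= 1.0 - 1e-12):
            raise NumericalError(
                "instrument pair with |rho| = 1; prune perfectly correlated "
                "SNPs before the GLS fit"
            )
        if np.any(sy <= 0):
            raise ValueError("se_y must be strictly positive")
        omega = np.outer(sy, sy) * rho
        eigmin = float(np.linalg.eigvalsh(omega)[0])
        if eigmin <= 0.0:
            raise NumericalError(
                f"Omega is not positive definite (smallest eigenvalue {eigmin:.3g})"
            )
        oinv_bx = np.linalg.solve(omega, bx)
        denom = float(bx @ oinv_bx)
        if denom == 0.0:
            raise DegenerateInstrumentError("all SNP-exposure effects are zero")
        self._finalize(float(oinv_bx @ by) / denom, denom ** -0.5, K)
        return self


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Weighted median by interpolation of the cumulative-weight midpoints.

    Order theta ascending with normalized weights w (sum 1); the cumulative
    midpoint of the j-th is p_j = sum_{k<=j} w_k - w_j / 2; the estimate
    interpolates theta against p at p = 0.5, clamping to the extreme theta
    when 0.5 falls outside [p_1, p_K].
    """
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    ww = w[order] / np.sum(w)
    p = np.cumsum(ww) - 0.5 * ww
    return float(np.interp(0.5, p, th))


def _weighted_median_rows(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median for (B, K) arrays (vectorized bootstrap)."""
    order = np.argsort(theta, axis=1, kind="stable")
    th = np.take_along_axis(theta, order, axis=1)
    ww = np.take_along_axis(w, order, axis=1)
    ww = ww / ww.sum(axis=1, keepdims=True)
    p = np.cumsum(ww, axis=1) - 0.5 * ww
    B, K = th.shape
    # np.interp per row; with p strictly increasing within each row
    below = p >= 0.5
    j = np.argmax(below, axis=1)  # first index with p >= 0.5
    out = np.empty(B)
    at_edge_low = j == 0
    out[at_edge_low] = th[at_edge_low, 0]
    rows = ~at_edge_low
    jj = j[rows]
    r = np.flatnonzero(rows)
    p_hi = p[r, jj]
    p_lo = p[r, jj - 1]
    t_hi = th[r, jj]
    t_lo = th[r, jj - 1]
    out[r] = t_lo + (t_hi - t_lo) * (0.5 - p_lo) / (p_hi - p_lo)
    # rows where even the last midpoint is below 0.5 clamp to the largest theta
    none_above = ~below.any(axis=1)
    out[none_above] = th[none_above, -1]
    return out


class WeightedMedianEstimator(_BaseMREstimator):
    """Weighted median of the Wald-ratio distribution.

    Consistent when instruments contributing at least 50% of the weight are
    valid, making it robust to a minority of pleiotropic SNPs. Weights are
    the normalized inverse variances of the first-order ratio SEs. The SE is
    the standard deviation of the estimate over ``n_boot`` parametric
    bootstrap replicates, drawing beta_X* and beta_Y* independently from
    normal(beta, se) with a fixed seed. Defined for uncorrelated SNPs
    (K >= 3); any LD between them is deliberately ignored.
    """

    _method = "weighted_median"

    def __init__(self, alpha: float = 0.05, n_boot: int = 10000,
                 seed: Optional[int] = None):
        super().__init__(alpha=alpha)
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y, se_x=None, se_y=None):
        bx = _as_vector(X)
        by = _as_vector(y)
        if bx.size < 3:
            raise InsufficientInstrumentsError(
                f"weighted median needs K >= 3 SNPs, got {bx.size}"
            )
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        sx = np.zeros_like(bx) if se_x is None else _as_vector(se_x)
        sy = np.ones_like(bx) if se_y is None else _as_vector(se_y)
        if np.any(bx == 0):
            raise UndefinedRatioError("zero SNP-exposure effect; ratio undefined")
        theta = by / bx
        w = (np.abs(bx) / sy) ** 2  # inverse variance of the first-order ratio SE
        est = _weighted_median(theta, w)

        rng = np.random.default_rng(self.seed)
        bxs = rng.normal(bx, sx, size=(self.n_boot, bx.size))
        bys = rng.normal(by, sy, size=(self.n_boot, bx.size))
        bxs = np.where(bxs == 0.0, np.finfo(float).tiny, bxs)
        boots = _weighted_median_rows(bys / bxs, (bxs / sy) ** 2)
        self._finalize(est, float(np.std(boots, ddof=1)), bx.size)
        return self


class EggerRegression(_BaseMREstimator):
    """MR-Egger: weighted regression of outcome on exposure effects with a
    free intercept.

    Each SNP pair is first oriented so its exposure effect is positive (the
    fit is otherwise not invariant to allele coding). The intercept estimates
    the average directional pleiotropic effect; its two-sided normal p-value
    tests the exclusion restriction. With the intercept constrained to zero
    (``fix_intercept=True``) the slope is algebraically identical to IVW.

    When exposure SEs are supplied, ``q_gx_``/``i2_gx_`` quantify how far the
    NOME assumption (exposure effects measured without error) is violated.
    """

    _method = "egger"

    def __init__(self, alpha: float = 0.05, fix_intercept: bool = False):
        super().__init__(alpha=alpha)
        self.fix_intercept = fix_intercept

    def fit(self, X, y, se_x=None, se_y=None):
        bx = _as_vector(X)
        by = _as_vector(y)
        sy = np.ones_like(bx) if se_y is None else _as_vector(se_y)
        if not self.fix_intercept and bx.size < 3:
            raise InsufficientInstrumentsError(
                f"MR-Egger needs K >= 3 SNPs, got {bx.size}"
            )
        sign = np.where(bx < 0, -1.0, 1.0)
        bx_o = bx * sign
        by_o = by * sign
        w = sy ** -2.0

        if self.fix_intercept:
            design = bx_o[:, None]
        else:
            design = sm.add_constant(bx_o)
        fit = sm.WLS(by_o, design, weights=w).fit()
        # fixed-effect covariance: statsmodels scales (X'WX)^-1 by the
        # residual variance estimate; divide the scale back out since the
        # outcome SEs are treated as known
        cov = np.asarray(fit.normalized_cov_params)
        if self.fix_intercept:
            slope = float(fit.params[0])
            slope_se = float(np.sqrt(cov[0, 0]))
            self.intercept_ = 0.0
            self.intercept_se_ = None
            self.intercept_p_ = None
        else:
            slope = float(fit.params[1])
            slope_se = float(np.sqrt(cov[1, 1]))
            self.intercept_ = float(fit.params[0])
            self.intercept_se_ = float(np.sqrt(cov[0, 0]))
            z = self.intercept_ / self.intercept_se_
            self.intercept_p_ = float(2.0 * stats.norm.sf(abs(z)))
        self._finalize(slope, slope_se, bx.size)

        self.q_gx_ = None
        self.i2_gx_ = None
        if se_x is not None:
            sx = _as_vector(se_x)
            wx = sx ** -2.0
            mu = float(np.sum(wx * bx_o) / np.sum(wx))
            q = float(np.sum(wx * (bx_o - mu) ** 2))
            self.q_gx_ = q
            self.i2_gx_ = max(0.0, (q - (bx.size - 1)) / q) if q > 0 else 0.0
        return self

    def diagnostics(self) -> EggerDiagnostics:
        if self.q_gx_ is None:
            raise ValueError("fit with se_x to obtain I2_GX diagnostics")
        return EggerDiagnostics(q_gx=self.q_gx_, i2_gx=self.i2_gx_)


# ---------------------------------------------------------------------------
# HarmonizedInstrumentSet-level wrappers


def ivw(hset: HarmonizedInstrumentSet, alpha: float = 0.05) -> MRResult:
    """Fixed-effect IVW estimate from a harmonized instrument set."""
    est = IVWEstimator(alpha=alpha).fit(
        hset.beta_exposure, hset.beta_outcome, se_y=hset.se_outcome
    )
    return est.to_result(hset.outcome_scale)


def gls_correlated(hset: HarmonizedInstrumentSet, alpha: float = 0.05) -> MRResult:
    """LD-aware GLS estimate using the set's correlation matrix."""
    est = CorrelatedGLSEstimator(alpha=alpha).fit(
        hset.beta_exposure, hset.beta_outcome, se_y=hset.se_outcome, ld=hset.ld.r
    )
    return est.to_result(hset.outcome_scale)


def weighted_median(hset: HarmonizedInstrumentSet, n_boot: int = 10000,
                    seed: Optional[int] = None, alpha: float = 0.05) -> MRResult:
    """Weighted-median estimate with parametric-bootstrap SE."""
    est = WeightedMedianEstimator(alpha=alpha, n_boot=n_boot, seed=seed).fit(
        hset.beta_exposure, hset.beta_outcome,
        se_x=hset.se_exposure, se_y=hset.se_outcome,
    )
    return est.to_result(hset.outcome_scale)


def egger(hset: HarmonizedInstrumentSet,
          alpha: float = 0.05) -> Tuple[MRResult, EggerDiagnostics]:
    """MR-Egger estimate plus its NOME diagnostic."""
    est = EggerRegression(alpha=alpha).fit(
        hset.beta_exposure, hset.beta_outcome,
        se_x=hset.se_exposure, se_y=hset.se_outcome,
    )
    return est.to_result(hset.outcome_scale), est.diagnostics()
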