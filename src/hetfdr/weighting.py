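"""Step II: data-adaptive weighting of heterogeneity p-values.

The prior encoded here is that, across a phenome, heterogeneous effects
almost always occur at phenotypes whose *pooled* effect is non-zero.  The
pooled z-statistic is asymptotically independent of the heterogeneity
statistic (see :mod:`hetfdr.core_stats`), so it can be used as an auxiliary
covariate to re-weight the heterogeneity p-values without invalidating them.

Weight estimation is regression-based: a logit-link regression of the
exceedance indicator ``1{p_het <= tau}`` on a basis of ``|z_mean|`` gives a
fitted exceedance propensity ``pi_hat(z)``.  Null heterogeneity p-values
fall below ``tau`` with the same probability regardless of ``z``, so the
excess of ``pi_hat`` over its own fitted floor, scaled by ``1 - tau``,
estimates the local fraction of truly heterogeneous phenotypes at each
value of the mean-effect statistic.  (Subtracting the fitted floor rather
than the nominal ``tau`` removes the null exceedance level as actually
estimated, which keeps near-null phenotypes close to the lower weight
clamp instead of inheriting intercept noise.)  Only excess larger than its
own sampling noise (one standard error) is retained, so weight flows to
regions of genuine enrichment rather than to fit noise.
Weights proportional to that fraction concentrate the FDR budget on the
small active set, which is what drives the power gain when one stratum is
much smaller than the other.  Two safeguards keep the procedure honest when
there is nothing to learn:

* the soft-thresholding itself acts as an informativeness gate: when the
  exceedance rate does not depend on ``|z_mean|`` every excess is zeroed
  and the model falls back to unit weights;
* a monotonicity check falls back to unit weights if the fitted propensity
  *decreases* with mean-effect significance, which contradicts the prior.

Because each phenotype's own exceedance indicator enters the regression,
its fitted propensity — and hence its weight — is mildly correlated with
its own p-value, which inflates the realized FDR.  The model therefore
carries a one-step leave-one-out correction for the phenotypes it was
trained on: when weights are computed for a training phenotype, its own
contribution to the fit is removed analytically (working-residual /
leverage form), so no hypothesis is weighted by a function of its own
p-value.

Final weights are clamped to ``[w_min, w_max]`` and iteratively
re-normalized to mean 1, the standard validity condition for weighted FDR
procedures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .core_stats import HetStatRecord

__all__ = ["WeightModel", "fit_weight_model", "compute_weights", "apply_weights"]

_MIN_RECORDS = 20
#: the regressor is min(|z_mean|, _Z_CAP): the prior concerns the
#: *presence* of a mean effect, so once |z| is unambiguous (|z| = 5 is
#: p ~ 6e-7) further magnitude should not raise the weight any further.
_Z_CAP = 5.0
#: propensity excess below this many delta-method standard errors of the
#: fitted propensity is treated as noise and zeroed.
_EXCESS_SE_MULT = 1.0


@dataclass(frozen=True)
class WeightModel:
    """Fitted weighting function from mean-effect significance to weights."""

    tau: float = 0.01
    basis: str = "quadratic"  # "linear" -> [1, |z|]; "quadratic" -> [1, |z|, z^2]
    coefficients: np.ndarray | None = None
    #: coefficient covariance of the fitted regression, used to
    #: soft-threshold the propensity excess at one standard error.
    cov: np.ndarray | None = None
    w_min: float = 0.05
    w_max: float = 20.0
    #: fitted null floor of the exceedance propensity over the training
    #: range of |z_mean|; subtracted before weights are formed.
    pi_floor: float = 0.0
    normalizer: float = 1.0
    #: leave-one-out raw weights for the training phenotypes, keyed by
    #: their |z_mean| (an unseen |z| gets the plain model evaluation,
    #: which needs no correction).
    loo_raw: dict | None = None
    informative: bool = False
    reason: str | None = None

    @property
    def is_unit(self) -> bool:
        return not self.informative


def _design(abs_z: np.ndarray, basis: str) -> np.ndarray:
    u = np.minimum(abs_z, _Z_CAP)
    if basis == "linear":
        return np.column_stack([np.ones_like(u), u])
    if basis == "quadratic":
        return np.column_stack([np.ones_like(u), u, u**2])
    raise ValueError(f"unknown basis {basis!r}")


def _unit_model(tau: float, basis: str, w_min: float, w_max: float, reason: str) -> WeightModel:
    warnings.warn(f"weight model degenerates to unit weights: {reason}", stacklevel=3)
    return WeightModel(tau=tau, basis=basis, w_min=w_min, w_max=w_max, reason=reason)


def fit_weight_model(
    stats_table: Sequence[HetStatRecord],
    tau: float = 0.01,
    basis: str = "quadratic",
    w_min: float = 0.05,
    w_max: float = 20.0,
) -> WeightModel:
    """Fit the exceedance regression and return the weighting function.

    Falls back to a unit-weight model (with a warning and a ``reason``) on
    any fitting pathology: fewer than 20 phenotypes, an all-zero or all-one
    training response, non-convergence, an uninformative covariate, or a
    propensity that decreases with ``|z_mean|``.
    """
    if not (0.0 < tau <= 0.5):
        raise ValueError(f"tau must be in (0, 0.5], got {tau!r}")
    stats_table = list(stats_table)
    if len(stats_table) < _MIN_RECORDS:
        return _unit_model(tau, basis, w_min, w_max, f"fewer than {_MIN_RECORDS} phenotypes")

    abs_z = np.abs(np.array([t.z_mean for t in stats_table]))
    y = (np.array([t.p_het for t in stats_table]) <= tau).astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        return _unit_model(tau, basis, w_min, w_max, "degenerate training response")

    X = _design(abs_z, basis)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        if not np.all(np.isfinite(fit.params)):
            raise ValueError("non-finite coefficients")
    except Exception as exc:  # non-convergence, separation, singular design
        return _unit_model(tau, basis, w_min, w_max, f"fit failed: {exc}")

    # Monotonicity: propensity at the largest observed |z| must not fall
    # below |z| = 0, else weights would punish mean significance.
    hi = float(min(abs_z.max(), _Z_CAP))
    pi_lo, pi_hi = _propensity(np.array([0.0, hi]), fit.params, basis)
    if pi_hi < pi_lo:
        return _unit_model(tau, basis, w_min, w_max, "propensity decreases with |z_mean|")

    pi_floor = _propensity_floor(fit.params, basis, hi)
    cov = np.asarray(fit.cov_params())
    raw = _raw_weights(abs_z, fit.params, cov, basis, tau, pi_floor)
    if raw.max() == 0.0:
        return _unit_model(tau, basis, w_min, w_max, "no significant propensity excess")
    loo = _loo_raw_weights(abs_z, y, fit.params, cov, basis, tau, pi_floor)
    return WeightModel(
        tau=tau,
        basis=basis,
        coefficients=np.asarray(fit.params),
        cov=cov,
        w_min=w_min,
        w_max=w_max,
        pi_floor=pi_floor,
        normalizer=float(raw.mean()),
        loo_raw=dict(zip(abs_z.tolist(), loo.tolist())),
        informative=True,
    )


def _propensity(abs_z: np.ndarray, coef: np.ndarray, basis: str) -> np.ndarray:
    eta = _design(abs_z, basis) @ coef
    return 1.0 / (1.0 + np.exp(-eta))


def _propensity_floor(coef: np.ndarray, basis: str, z_max: float) -> float:
    """Minimum fitted propensity over the training range [0, z_max].

    The linear predictor is linear or quadratic in |z|, so the minimum is
    attained at an endpoint or at the vertex of the parabola.
    """
    candidates = [0.0, z_max]
    if basis == "quadratic" and coef[2] > 0:
        vertex = -coef[1] / (2.0 * coef[2])
        if 0.0 < vertex < z_max:
            candidates.append(vertex)
    return float(_propensity(np.array(candidates), coef, basis).min())


def _raw_weights(
    abs_z: np.ndarray,
    coef: np.ndarray,
    cov: np.ndarray | None,
    basis: str,
    tau: float,
    pi_floor: float,
) -> np.ndarray:
    X = _design(abs_z, basis)
    pi_hat = 1.0 / (1.0 + np.exp(-(X @ coef)))
    excess = pi_hat - pi_floor
    if cov is not None:
        # delta-method SE of pi_hat; keep only excess beyond the noise band
        se_eta = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, cov, X), 0.0))
        excess = excess - _EXCESS_SE_MULT * pi_hat * (1.0 - pi_hat) * se_eta
    return np.clip(excess / (1.0 - tau), 0.0, None)


def _loo_raw_weights(
    abs_z: np.ndarray,
    y: np.ndarray,
    coef: np.ndarray,
    cov: np.ndarray,
    basis: str,
    tau: float,
    pi_floor: float,
) -> np.ndarray:
    """Raw weights with each training point's self-influence removed.

    One-step leave-one-out for an IRLS fit: with hat value
    ``h_j = W_j x_j' (X'WX)^-1 x_j`` and working weight
    ``W_j = pi_j (1 - pi_j)``, the linear predictor refit without point j
    is approximately ``eta_j - h_j / (1 - h_j) * (y_j - pi_j) / W_j``.
    """
    X = _design(abs_z, basis)
    eta = X @ coef
    pi_hat = 1.0 / (1.0 + np.exp(-eta))
    w_irls = np.clip(pi_hat * (1.0 - pi_hat), 1e-12, None)
    h = w_irls * np.einsum("ij,jk,ik->i", X, cov, X)
    h = np.clip(h, 0.0, 0.99)
    eta_loo = eta - (h / (1.0 - h)) * (y - pi_hat) / w_irls
    pi_loo = 1.0 / (1.0 + np.exp(-eta_loo))
    excess = pi_loo - pi_floor
    se_eta = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, cov, X), 0.0))
    excess = excess - _EXCESS_SE_MULT * pi_loo * (1.0 - pi_loo) * se_eta
    return np.clip(excess / (1.0 - tau), 0.0, None)


def _clamp_normalize(raw: np.ndarray, w_min: float, w_max: float, tol: float = 1e-6) -> np.ndarray:
    """Scale to mean 1, then iterate clamp/re-scale until the mean is stable."""
    w = raw / raw.mean()
    for _ in range(100):
        w = np.clip(w, w_min, w_max)
        mean = w.mean()
        if abs(mean - 1.0) < tol:
            return w
        w = w / mean
    return np.clip(w, w_min, w_max)


def compute_weights(model: WeightModel, stats_table: Sequence[HetStatRecord]) -> np.ndarray:
    """Evaluate the fitted weighting function; mean-1, clamped, deterministic."""
    stats_table = list(stats_table)
    if not stats_table:
        return np.empty(0)
    if model.is_unit:
        return np.ones(len(stats_table))
    abs_z = np.abs(np.array([t.z_mean for t in stats_table]))
    raw = _raw_weights(
        abs_z, model.coefficients, model.cov, model.basis, model.tau, model.pi_floor
    )
    if model.loo_raw is not None:
        # training phenotypes get their leave-one-out weight (keyed by |z|)
        raw = np.array([model.loo_raw.get(z, r) for z, r in zip(abs_z.tolist(), raw)])
    if raw.mean() == 0.0:
        return np.ones(len(stats_table))
    return _clamp_normalize(raw, model.w_min, model.w_max)


def apply_weights(p_het: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted p-values ``min(p / w, 1)``."""
    p_het = np.asarray(p_het, dtype=float)
    w = np.asarray(w, dtype=float)
    if p_het.shape != w.shape:
        raise ValueError(f"length mismatch: {p_het.shape} p-values vs {w.shape} weights")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return np.minimum(p_het / w, 1.0)
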