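"""FDR-controlled multiple-testing procedures and the hetFDR orchestrator.

Implements the Benjamini–Hochberg step-up (BHq), Storey's adaptive variant
with a pi0 estimate, their weighted counterparts over mean-1 weighted
p-values, and ``hetfdr`` — the three-step pipeline: Step-I statistics,
Step-II adaptive weights, Step-III FDR-controlled testing of the weighted
heterogeneity p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_stats import PhenotypeRecord, compute_stat_table, stat_table_to_frame
from .weighting import WeightModel, apply_weights, compute_weights, fit_weight_model

__all__ = [
    "RejectionResult",
    "bh_adjust",
    "bh_reject",
    "storey_pi0",
    "storey_reject",
    "weighted_fdr_reject",
    "hetfdr",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RejectionResult:
    """Outcome of an FDR procedure at nominal level ``alpha``."""

    alpha: float
    rejected: np.ndarray
    adjusted_p: np.ndarray
    pi0: float | None
    procedure: str

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in original order.

    Sort ascending, scale ``p_(i) * m / i``, enforce monotonicity by a
    cumulative minimum from the largest, cap at 1.  Rejecting where the
    adjusted value is <= alpha reproduces the BHq rejection set.
    """
    p = _check_p(p)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def bh_reject(p: np.ndarray, alpha: float = 0.1) -> RejectionResult:
    """BHq at level ``alpha``."""
    adjusted = bh_adjust(p)
    return RejectionResult(alpha, adjusted <= alpha, adjusted, None, "bh")


def storey_pi0(p: np.ndarray, lam: float = 0.5) -> float:
    """Storey's estimate of the null proportion at tuning point ``lam``.

    ``pi0 = #{p > lam} / (m * (1 - lam))``, capped at 1 and floored at 1/m.
    """
    if not (0.0 < lam < 1.0):
        raise ValueError(f"lambda must be in (0, 1), got {lam!r}")
    p = _check_p(p)
    m = p.size
    if m == 0:
        return 1.0
    pi0 = np.sum(p > lam) / (m * (1.0 - lam))
    return float(min(1.0, max(pi0, 1.0 / m)))


def storey_reject(p: np.ndarray, alpha: float = 0.1, lam: float = 0.5) -> RejectionResult:
    """Storey-adaptive BH: BHq applied at the pi0-inflated level.

    Equivalent to rejecting where ``bh_adjust(p) * pi0 <= alpha``; the
    reported adjusted p-values are the pi0-scaled ones (q-value style).
    """
    p = _check_p(p)
    pi0 = storey_pi0(p, lam)
    adjusted = np.minimum(bh_adjust(p) * pi0, 1.0)
    return RejectionResult(alpha, adjusted <= alpha, adjusted, pi0, "storey")


_BASES = {"bh": bh_reject, "storey": storey_reject}


def weighted_fdr_reject(
    p: np.ndarray, w: np.ndarray, alpha: float = 0.1, base: str = "storey"
) -> RejectionResult:
    """Apply the chosen base procedure to the weighted p-values ``min(p/w, 1)``.

    Weights must be positive with mean 1 (the weighted-FDR validity
    condition); unit weights reduce exactly to the unweighted base.
    """
    if base not in _BASES:
        raise ValueError(f"base must be one of {sorted(_BASES)}, got {base!r}")
    w = np.asarray(w, dtype=float)
    if w.size and abs(w.mean() - 1.0) > 1e-3:
        raise ValueError(f"weights must average 1, got mean {w.mean():.6f}")
    q = apply_weights(_check_p(p), w)
    result = _BASES[base](q, alpha)
    return RejectionResult(alpha, result.rejected, result.adjusted_p, result.pi0,
                           f"weighted-{base}")


def hetfdr(
    records: Sequence[PhenotypeRecord],
    alpha: float = 0.1,
    tau: float = 0.01,
    basis: str = "quadratic",
    base: str = "storey",
    w_min: float = 0.05,
    w_max: float = 20.0,
    unit_weights: bool = False,
) -> pd.DataFrame:
    """Run the three-step hetFDR procedure on paired two-group records.

    Steps: (I) pooled-mean and heterogeneity statistics per phenotype;
    (II) adaptive weights from the mean-effect statistics (skipped when
    ``unit_weights`` is set, which reduces the procedure exactly to the
    unweighted base); (III) the base FDR procedure on the weighted
    heterogeneity p-values at level ``alpha``.

    Returns a DataFrame with one row per input phenotype, in input order,
    with Step-I columns plus ``weight``, ``p_weighted``, ``rejected``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")
    table = compute_stat_table(records)
    frame = stat_table_to_frame(table)
    if frame.empty:
        frame["weight"] = pd.Series(dtype=float)
        frame["p_weighted"] = pd.Series(dtype=float)
        frame["rejected"] = pd.Series(dtype=bool)
        return frame

    if unit_weights:
        model = WeightModel(tau=tau, basis=basis, w_min=w_min, w_max=w_max,
                            reason="unit weights requested")
    else:
        model = fit_weight_model(table, tau=tau, basis=basis, w_min=w_min, w_max=w_max)
    w = compute_weights(model, table)
    p_het = frame["p_het"].to_numpy()

    # Stable tie-break on (weighted p, phenotype_id) so output is
    # byte-reproducible whatever the input order of tied phenotypes.
    q = apply_weights(p_het, w)
    order = np.lexsort((frame["phenotype_id"].to_numpy(), q))
    result = weighted_fdr_reject(p_het[order], w[order], alpha=alpha, base=base)
    rejected = np.empty(len(frame), dtype=bool)
    rejected[order] = result.rejected
    adjusted = np.empty(len(frame))
    adjusted[order] = result.adjusted_p

    frame["weight"] = w
    frame["p_weighted"] = q
    frame["p_adjusted"] = adjusted
    frame["rejected"] = rejected
    logger.info(
        "hetfdr: %d phenotypes, weights %s, %d rejected at alpha=%g",
        len(frame), "unit" if model.is_unit else "adaptive", int(rejected.sum()), alpha,
    )
    return frame
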