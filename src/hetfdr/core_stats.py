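"""Step I: pooled mean-effect and heterogeneity statistics per phenotype.

For each phenotype tested in two ancestry strata we reduce the pair of
regression coefficients (beta_a, se_a), (beta_b, se_b) to two asymptotically
independent statistics:

* the inverse-variance weighted pooled effect and its standardized z
  (``z_mean``), testing whether the phenotype has any association at all;
* a 1-df chi-square on the standardized between-group difference
  (``q_het``), testing whether the association differs between strata.

Independence of the two follows from the inverse-variance weights: with
``w_g = se_g**-2`` the pooled mean and the difference ``beta_a - beta_b``
have zero covariance under independent strata, so the heterogeneity p-value
can later be re-weighted by any function of ``z_mean`` without distorting
its null distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "P_FLOOR",
    "GroupAssociation",
    "PhenotypeRecord",
    "HetStatRecord",
    "pooled_mean_effect",
    "heterogeneity_stat",
    "compute_stat_table",
    "stat_table_to_frame",
]

#: p-values are floored here so that later division by weights cannot
#: underflow to exact zero.
P_FLOOR = 1e-300


@dataclass(frozen=True)
class GroupAssociation:
    """One stratum's effect estimate for one phenotype.

    ``beta`` is the per-minor-allele-copy effect: a log odds ratio for
    binary traits, a change in log lab value for continuous traits.
    """

    group_id: str
    beta: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta):
            raise ValueError(f"beta must be finite, got {self.beta!r}")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"se must be positive and finite, got {self.se!r}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n!r}")


@dataclass(frozen=True)
class PhenotypeRecord:
    """A phenotype's paired two-group associations.

    ``phenotype_id`` is a PheCode string such as ``"250.2"`` or a lab name;
    ``trait_kind`` is ``"binary"`` or ``"continuous"``.  Both strata must be
    present — phenotypes surviving filters in only one stratum are excluded
    upstream, not imputed.
    """

    phenotype_id: str
    trait_kind: str
    assoc_a: GroupAssociation
    assoc_b: GroupAssociation

    def __post_init__(self) -> None:
        if self.trait_kind not in ("binary", "continuous"):
            raise ValueError(f"trait_kind must be 'binary' or 'continuous', got {self.trait_kind!r}")
        if self.assoc_a.group_id == self.assoc_b.group_id:
            raise ValueError(
                f"phenotype {self.phenotype_id!r}: the two associations share "
                f"group_id {self.assoc_a.group_id!r}"
            )


@dataclass(frozen=True)
class HetStatRecord:
    """Step-I outputs for one phenotype."""

    phenotype_id: str
    beta_pooled: float
    se_pooled: float
    z_mean: float
    p_mean: float
    q_het: float
    p_het: float


class PooledEffect(NamedTuple):
    beta_pooled: float
    se_pooled: float
    z_mean: float
    p_mean: float


def pooled_mean_effect(a: GroupAssociation, b: GroupAssociation) -> PooledEffect:
    """Inverse-variance weighted pooled effect across the two strata.

    With weights ``w_g = se_g**-2``::

        beta_pooled = (w_a * beta_a + w_b * beta_b) / (w_a + w_b)
        se_pooled   = (w_a + w_b) ** -0.5

    and ``p_mean`` is the two-sided standard-normal tail probability of
    ``z_mean = beta_pooled / se_pooled``.
    """
    w_a = a.se**-2
    w_b = b.se**-2
    beta_pooled = (w_a * a.beta + w_b * b.beta) / (w_a + w_b)
    se_pooled = (w_a + w_b) ** -0.5
    z_mean = beta_pooled / se_pooled
    p_mean = float(np.clip(2.0 * stats.norm.sf(abs(z_mean)), P_FLOOR, 1.0))
    return PooledEffect(beta_pooled, se_pooled, z_mean, p_mean)


def heterogeneity_stat(a: GroupAssociation, b: GroupAssociation) -> tuple[float, float]:
    """1-df chi-square on the standardized between-group difference.

    ``q_het = (beta_a - beta_b)**2 / (se_a**2 + se_b**2)``; ``p_het`` is the
    upper-tail chi-square probability.  Symmetric in the two groups and
    invariant to adding a constant to both betas.
    """
    q_het = (a.beta - b.beta) ** 2 / (a.se**2 + b.se**2)
    p_het = float(np.clip(stats.chi2.sf(q_het, df=1), P_FLOOR, 1.0))
    return q_het, p_het


def compute_stat_table(records: Sequence[PhenotypeRecord]) -> list[HetStatRecord]:
    """Step I over a collection of phenotypes, order-preserving.

    Raises ``ValueError`` naming the first duplicated ``phenotype_id``.
    Vectorized internally; equivalent to applying the two scalar operations
    row by row.
    """
    records = list(records)
    seen: set[str] = set()
    for rec in records:
        if rec.phenotype_id in seen:
            raise ValueError(f"duplicate phenotype_id: {rec.phenotype_id!r}")
        seen.add(rec.phenotype_id)
    if not records:
        return []

    beta_a = np.array([r.assoc_a.beta for r in records])
    beta_b = np.array([r.assoc_b.beta for r in records])
    se_a = np.array([r.assoc_a.se for r in records])
    se_b = np.array([r.assoc_b.se for r in records])

    w_a = se_a**-2
    w_b = se_b**-2
    beta_pooled = (w_a * beta_a + w_b * beta_b) / (w_a + w_b)
    se_pooled = (w_a + w_b) ** -0.5
    z_mean = beta_pooled / se_pooled
    p_mean = np.clip(2.0 * stats.norm.sf(np.abs(z_mean)), P_FLOOR, 1.0)
    q_het = (beta_a - beta_b) ** 2 / (se_a**2 + se_b**2)
    p_het = np.clip(stats.chi2.sf(q_het, df=1), P_FLOOR, 1.0)

    return [
        HetStatRecord(
            phenotype_id=rec.phenotype_id,
            beta_pooled=float(beta_pooled[i]),
            se_pooled=float(se_pooled[i]),
            z_mean=float(z_mean[i]),
            p_mean=float(p_mean[i]),
            q_het=float(q_het[i]),
            p_het=float(p_het[i]),
        )
        for i, rec in enumerate(records)
    ]


def stat_table_to_frame(table: Iterable[HetStatRecord]) -> pd.DataFrame:
    """Stat records as a DataFrame, one row per phenotype."""
    return pd.DataFrame(
        [
            (t.phenotype_id, t.beta_pooled, t.se_pooled, t.z_mean, t.p_mean, t.q_het, t.p_het)
            for t in table
        ],
        columns=["phenotype_id", "beta_pooled", "se_pooled", "z_mean", "p_mean", "q_het", "p_het"],
    )
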