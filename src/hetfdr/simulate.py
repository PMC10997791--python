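"""Synthetic data: summary-statistics simulations, cohort generator, evaluation.

Two generators:

* :func:`simulate_summary_stats` draws per-phenotype two-group summary
  statistics directly — the benchmark workhorse.  Each phenotype is
  inactive (both true betas zero), active-homogeneous (equal non-zero
  betas) or active-heterogeneous (betas split symmetrically around a
  non-zero mean, so heterogeneous phenotypes also carry mean signal — the
  prior hetFDR exploits).  Observed betas are the truth plus normal noise
  with ``se_g = sigma / sqrt(n_g)``; the minority stratum has ``ratio``
  times the majority's sample size.

* :func:`simulate_cohort` draws an individual-level cohort (genotype
  dosages under Hardy–Weinberg with stratum-specific allele frequencies,
  demographics matching a large veteran biobank, billing-code counts and
  lab measurements from planted logistic / log-normal models) for
  end-to-end tests through the PheWAS engine.

:func:`empirical_fdr_power` scores a rejection set against the simulation
truth, and :func:`benchmark` runs hetFDR against the BHq and Storey
baselines over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_stats import GroupAssociation, PhenotypeRecord
from .fdr import bh_reject, hetfdr, storey_reject
from .phewas import CohortTable

__all__ = [
    "SimConfig",
    "simulate_summary_stats",
    "PlannedPhenotype",
    "make_effect_plan",
    "plan_truth",
    "simulate_cohort",
    "empirical_fdr_power",
    "benchmark",
]

SE_FLOOR = 1e-8

LABELS = ("inactive", "active_homogeneous", "active_heterogeneous")


@dataclass(frozen=True)
class SimConfig:
    """Design of one summary-statistics simulation scenario.

    Defaults follow the benchmark setting: 1000 phenotypes of which 50 are
    active and 10 of those heterogeneous, with the minority stratum at 25%
    of the majority's sample size.  ``mu`` and ``delta`` (common and
    heterogeneous effect magnitudes) were fixed by ``scripts/calibrate.py``
    so that the unweighted BH baseline operates at intermediate power
    (~0.3) at alpha = 0.1; ``sigma`` maps sample size to standard error via
    ``se_g = sigma / sqrt(n_g)``.
    """

    m: int = 1000
    n_active: int = 50
    n_het: int = 10
    n_major: int = 8000
    ratio: float = 0.25
    mu: float = 0.08
    delta: float = 0.075
    sigma: float = 1.0
    seed: int = 0
    group_minor: str = "AFR"
    group_major: str = "EUR"

    def __post_init__(self) -> None:
        if not (0 <= self.n_het <= self.n_active <= self.m):
            raise ValueError("require n_het <= n_active <= m")
        if not (0.0 < self.ratio <= 1.0):
            raise ValueError(f"ratio must be in (0, 1], got {self.ratio!r}")
        if min(self.mu, self.delta) < 0 or self.sigma <= 0 or self.n_major < 1:
            raise ValueError("scales must be positive")

    @property
    def n_minor(self) -> int:
        return max(1, round(self.ratio * self.n_major))


def simulate_summary_stats(config: SimConfig) -> tuple[list[PhenotypeRecord], pd.DataFrame]:
    """Draw one replicate of two-group summary statistics plus its truth.

    Returns ``(records, truth)`` where ``truth`` has one row per phenotype
    (aligned with ``records``) with columns ``phenotype_id``, ``label``,
    ``beta_minor``, ``beta_major``.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    m, n_active, n_het = config.m, config.n_active, config.n_het

    labels = np.array(["inactive"] * m, dtype=object)
    active_idx = rng.choice(m, size=n_active, replace=False)
    het_idx = rng.choice(active_idx, size=n_het, replace=False)
    labels[active_idx] = "active_homogeneous"
    labels[het_idx] = "active_heterogeneous"

    mu_j = np.zeros(m)
    mu_j[active_idx] = config.mu * rng.choice([-1.0, 1.0], size=n_active)
    delta_j = np.zeros(m)
    delta_j[het_idx] = config.delta * rng.choice([-1.0, 1.0], size=n_het)

    beta_minor = mu_j + delta_j / 2.0
    beta_major = mu_j - delta_j / 2.0

    n_minor, n_major = config.n_minor, config.n_major
    se_minor = max(config.sigma / np.sqrt(n_minor), SE_FLOOR)
    se_major = max(config.sigma / np.sqrt(n_major), SE_FLOOR)
    obs_minor = rng.normal(beta_minor, se_minor)
    obs_major = rng.normal(beta_major, se_major)

    width = len(str(m - 1))
    ids = [f"pheno_{i:0{width}d}" for i in range(m)]
    records = [
        PhenotypeRecord(
            phenotype_id=ids[i],
            trait_kind="continuous",
            assoc_a=GroupAssociation(config.group_minor, float(obs_minor[i]), se_minor, n_minor),
            assoc_b=GroupAssociation(config.group_major, float(obs_major[i]), se_major, n_major),
        )
        for i in range(m)
    ]
    truth = pd.DataFrame(
        {"phenotype_id": ids, "label": labels, "beta_minor": beta_minor, "beta_major": beta_major}
    )
    return records, truth


# ---------------------------------------------------------------------------
# Individual-level cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlannedPhenotype:
    """Generating model for one phenotype in the cohort simulator.

    For binary phenotypes ``base`` is the control-scale intercept on the
    logit scale and ``beta`` the per-allele log odds ratio per stratum; for
    labs ``base`` is the mean log value and ``beta`` the per-allele change
    in log value.  ``label`` is the ground-truth class for scoring.
    """

    name: str
    kind: str  # "binary" | "continuous"
    base: float
    beta: Mapping[str, float]
    label: str
    lab_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"kind must be binary/continuous, got {self.kind!r}")
        if self.label not in LABELS:
            raise ValueError(f"unknown truth label {self.label!r}")


def make_effect_plan(
    strata: Sequence[str] = ("AFR", "EUR"),
    n_binary: int = 220,
    n_lab: int = 60,
    n_active_binary: int = 24,
    n_het_binary: int = 8,
    n_active_lab: int = 8,
    n_het_lab: int = 4,
    mu_binary: float = 0.18,
    delta_binary: float = 0.5,
    mu_lab: float = 0.02,
    delta_lab: float = 0.04,
    n_rare: int = 5,
    seed: int = 0,
) -> list[PlannedPhenotype]:
    """Default phenotype plan for the cohort simulator.

    Binary phenotypes get control prevalences mostly in 2–15% (plus
    ``n_rare`` codes below the 0.5% prevalence floor, to exercise the
    filter); labs are log-normal around clinically plausible log means.
    Heterogeneous phenotypes split ``delta`` symmetrically around ``mu``
    across the two strata, so they retain mean signal.  The binary name
    space includes a parent/descendant pair ("250" with "250.1"/"250.2")
    to exercise the hierarchy filter.
    """
    rng = np.random.default_rng(seed)
    a, b = strata
    plan: list[PlannedPhenotype] = []

    def split(mu: float, delta: float, het: bool) -> dict[str, float]:
        s_mu = float(rng.choice([-1.0, 1.0]))
        if not het:
            return {a: s_mu * mu, b: s_mu * mu}
        s_d = float(rng.choice([-1.0, 1.0]))
        return {a: s_mu * mu + s_d * delta / 2.0, b: s_mu * mu - s_d * delta / 2.0}

    # Binary phenotypes, PheCode-style names.  008.* codes carry the
    # signal; the 250 family exercises parent exclusion.
    names = ["250", "250.1", "250.2"] + [f"{100 + i}.{i % 9 + 1}" for i in range(n_binary - 3)]
    n_common = n_binary - n_rare
    order = ["active_heterogeneous"] * n_het_binary
    order += ["active_homogeneous"] * (n_active_binary - n_het_binary)
    order += ["inactive"] * (n_common - n_active_binary)
    rng.shuffle(order)
    # signal is never planted on the rare (below-floor) codes
    order += ["inactive"] * n_rare
    for i, (name, label) in enumerate(zip(names, order)):
        if i >= n_common:
            prevalence = 0.002  # below the 0.5% floor -> filtered out
        else:
            prevalence = float(rng.uniform(0.03, 0.15))
        base = float(np.log(prevalence / (1 - prevalence)))
        beta = split(
            mu_binary, delta_binary, het=label == "active_heterogeneous"
        ) if label != "inactive" else {a: 0.0, b: 0.0}
        plan.append(PlannedPhenotype(name, "binary", base, beta, label))

    lab_order = ["active_heterogeneous"] * n_het_lab
    lab_order += ["active_homogeneous"] * (n_active_lab - n_het_lab)
    lab_order += ["inactive"] * (n_lab - n_active_lab)
    rng.shuffle(lab_order)
    for i, label in enumerate(lab_order):
        base = float(rng.uniform(0.5, 5.0))
        beta = split(
            mu_lab, delta_lab, het=label == "active_heterogeneous"
        ) if label != "inactive" else {a: 0.0, b: 0.0}
        plan.append(PlannedPhenotype(f"lab_{i:02d}", "continuous", base, beta, label))
    return plan


def plan_truth(plan: Iterable[PlannedPhenotype]) -> pd.DataFrame:
    """Ground-truth table for a phenotype plan."""
    return pd.DataFrame(
        [(p.name, p.kind, p.label) for p in plan], columns=["phenotype_id", "kind", "label"]
    )


def simulate_cohort(
    n_per_stratum: Mapping[str, int],
    maf_per_stratum: Mapping[str, float] | None = None,
    plan: Sequence[PlannedPhenotype] | None = None,
    seed: int = 0,
) -> CohortTable:
    """Draw an individual-level two-stratum cohort.

    Dosages are Binomial(2, MAF) per stratum (Hardy–Weinberg; defaults
    0.14 AFR / 0.40 EUR), age ~ N(62.1, 13.9^2) truncated to [18, 100],
    follow-up ~ N(12.5, 5.7^2) truncated positive, sex skewed male, and
    utilization (total PheCode count) log-normal.  Binary phenotypes are
    Bernoulli under a logistic model in dosage plus mild covariate effects;
    cases receive 2+ code occurrences while a small fraction of controls
    receive a single occurrence (so the at-least-2-codes case rule is
    load-bearing).  Labs are log-normal with planted per-allele log
    effects, 1–3 repeated measurements per subject.
    """
    if maf_per_stratum is None:
        maf_per_stratum = {"AFR": 0.14, "EUR": 0.40}
    strata = list(n_per_stratum)
    if len(strata) != 2:
        raise ValueError("exactly two strata required")
    for s in strata:
        if not (0.0 < maf_per_stratum[s] <= 0.5):
            raise ValueError(f"MAF for {s!r} must be in (0, 0.5]")
        if n_per_stratum[s] < 100:
            raise ValueError("need at least 100 subjects per stratum")
    if plan is None:
        plan = make_effect_plan(strata=tuple(strata), seed=seed)

    rng = np.random.default_rng(seed)
    frames = []
    for s in strata:
        n = n_per_stratum[s]
        age = rng.normal(62.1, 13.9, size=n)
        age = np.clip(age, 18.0, 100.0)
        followup = rng.normal(12.5, 5.7, size=n)
        followup = np.abs(followup) + 0.1
        frames.append(
            pd.DataFrame(
                {
                    "ancestry": s,
                    "dosage": rng.binomial(2, maf_per_stratum[s], size=n),
                    "age": age,
                    "sex": rng.binomial(1, 0.913, size=n),
                    "followup": followup,
                    "code_total": np.maximum(
                        1, np.round(np.exp(rng.normal(3.5, 0.6, size=n)))
                    ).astype(int),
                }
            )
        )
    subjects = pd.concat(frames, ignore_index=True)
    n_all = len(subjects)
    subjects.insert(0, "subject_id", [f"S{i:06d}" for i in range(n_all)])

    # Standardized covariates feed mild effects into every phenotype so the
    # engine's covariate adjustment is doing real work.
    age_z = (subjects["age"].to_numpy() - 62.1) / 13.9
    fu_z = (subjects["followup"].to_numpy() - 12.5) / 5.7
    util_z = np.log(subjects["code_total"].to_numpy()) - 3.5
    sex = subjects["sex"].to_numpy()
    dosage = subjects["dosage"].to_numpy().astype(float)
    beta_vec = {  # per-subject planted genetic effect lookup by stratum
        s: (subjects["ancestry"].to_numpy() == s) for s in strata
    }

    code_rows = []
    lab_rows = []
    for pheno in plan:
        g_effect = np.zeros(n_all)
        for s in strata:
            g_effect[beta_vec[s]] = pheno.beta[s]
        if pheno.kind == "binary":
            eta = pheno.base + g_effect * dosage + 0.25 * age_z + 0.1 * sex + 0.15 * util_z
            case = rng.random(n_all) < 1.0 / (1.0 + np.exp(-eta))
            counts = np.zeros(n_all, dtype=int)
            counts[case] = 2 + rng.poisson(2.0, size=int(case.sum()))
            # some controls get a single passing mention of the code
            single = (~case) & (rng.random(n_all) < 0.03)
            counts[single] = 1
            idx = np.nonzero(counts)[0]
            code_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": subjects["subject_id"].to_numpy()[idx],
                        "phecode": pheno.name,
                        "count": counts[idx],
                    }
                )
            )
        else:
            log_mean = (
                pheno.base + g_effect * dosage + 0.05 * age_z - 0.03 * sex + 0.02 * fu_z
            )
            n_meas = rng.integers(1, 4, size=n_all)
            reps = np.repeat(np.arange(n_all), n_meas)
            values = np.exp(
                log_mean[reps] + rng.normal(0.0, pheno.lab_sd, size=reps.size)
            )
            lab_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": subjects["subject_id"].to_numpy()[reps],
                        "lab": pheno.name,
                        "value": values,
                    }
                )
            )

    phecode_counts = (
        pd.concat(code_rows, ignore_index=True)
        if code_rows
        else pd.DataFrame(columns=["subject_id", "phecode", "count"])
    )
    labs = (
        pd.concat(lab_rows, ignore_index=True)
        if lab_rows
        else pd.DataFrame(columns=["subject_id", "lab", "value"])
    )
    return CohortTable(subjects=subjects, phecode_counts=phecode_counts, labs=labs)


# ---------------------------------------------------------------------------
# Evaluation and benchmarking
# ---------------------------------------------------------------------------

def empirical_fdr_power(
    rejected: np.ndarray, truth: pd.DataFrame
) -> tuple[float, float | None]:
    """False-discovery proportion and power of one rejection set.

    ``FDP = #(rejected and not heterogeneous) / max(#rejected, 1)``;
    ``power = #(rejected and heterogeneous) / #heterogeneous`` or ``None``
    when the truth contains no heterogeneous phenotype.  Averaging FDP over
    replicates estimates FDR.
    """
    rejected = np.asarray(rejected, dtype=bool)
    het = (truth["label"].to_numpy() == "active_heterogeneous")
    if rejected.shape != het.shape:
        raise ValueError("rejection indicator and truth lengths differ")
    n_rej = int(rejected.sum())
    fdp = float((rejected & ~het).sum() / max(n_rej, 1))
    n_het = int(het.sum())
    power = float((rejected & het).sum() / n_het) if n_het else None
    return fdp, power


def _rejections(records, truth, alpha, procedure, **het_kwargs):
    from .core_stats import compute_stat_table

    if procedure == "hetfdr":
        frame = hetfdr(records, alpha=alpha, **het_kwargs)
        return frame["rejected"].to_numpy()
    p_het = np.array([t.p_het for t in compute_stat_table(records)])
    if procedure == "bh":
        return bh_reject(p_het, alpha).rejected
    if procedure == "storey":
        return storey_reject(p_het, alpha).rejected
    raise ValueError(f"unknown procedure {procedure!r}")


def benchmark(
    configs: Sequence[SimConfig] | SimConfig,
    n_reps: int = 200,
    alpha: float = 0.1,
    procedures: Sequence[str] = ("hetfdr", "bh", "storey"),
    seed: int = 1,
    **het_kwargs,
) -> pd.DataFrame:
    """Empirical FDR and average power per procedure and scenario.

    Each replicate draws a fresh summary-statistics dataset (seeds derived
    from ``seed``), runs every procedure on the same draw, and scores it
    against the truth.  Returns one row per (scenario, procedure) with
    columns ``fdr``, ``power``, ``fdr_se``, ``power_se`` (Monte-Carlo
    standard errors of the means) and ``n_reps``.
    """
    if isinstance(configs, SimConfig):
        configs = [configs]
    root = np.random.default_rng(seed)
    rows = []
    for scenario, config in enumerate(configs):
        rep_seeds = root.integers(0, 2**31 - 1, size=n_reps)
        fdp = {proc: [] for proc in procedures}
        power = {proc: [] for proc in procedures}
        for rep_seed in rep_seeds:
            records, truth = simulate_summary_stats(replace(config, seed=int(rep_seed)))
            for proc in procedures:
                rej = _rejections(records, truth, alpha, proc, **het_kwargs)
                f, pw = empirical_fdr_power(rej, truth)
                fdp[proc].append(f)
                if pw is not None:
                    power[proc].append(pw)
        for proc in procedures:
            f = np.array(fdp[proc])
            pw = np.array(power[proc]) if power[proc] else np.array([np.nan])
            rows.append(
                {
                    "scenario": scenario,
                    "m": config.m,
                    "n_active": config.n_active,
                    "n_het": config.n_het,
                    "ratio": config.ratio,
                    "mu": config.mu,
                    "delta": config.delta,
                    "procedure": proc,
                    "fdr": f.mean(),
                    "fdr_se": f.std(ddof=1) / np.sqrt(len(f)) if len(f) > 1 else 0.0,
                    "power": pw.mean(),
                    "power_se": pw.std(ddof=1) / np.sqrt(len(pw)) if len(pw) > 1 else 0.0,
                    "n_reps": n_reps,
                }
            )
    return pd.DataFrame(rows)
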