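"""Clustering-robustness protocol: retrain the map under different seeds
and quantify how consistently components co-cluster.

The protocol retrains the map several times with identical hyperparameters,
varying only the codebook initialization and sample presentation order.
Agreement between two runs is measured on co-membership indicators — for
every unordered component pair, whether the two components share a cluster
— which makes the statistics invariant to arbitrary cluster-id relabeling:

* Cohen's kappa on the paired co-membership series, with an asymptotic
  95% CI and a test of kappa = 0;
* a per-component consistency fraction: how many of a component's
  cluster-mates in one run are still its cluster-mates in the other
  (components with no mates in the first run count as fully consistent);
* ICC(2,1) — two-way random-effects, absolute-agreement, single-measure
  intraclass correlation — over per-component, per-run consistency values
  relative to a baseline run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .clusters import ClusterMap, SOMClusterer, assign_clusters, delineate_clusters, umatrix
from .som import SelfOrganizingMap


# ---------------------------------------------------------------------------
# Ensemble retraining
# ---------------------------------------------------------------------------

def retrain_ensemble(train_data: np.ndarray,
                     config: dict,
                     seeds: Sequence[int],
                     assign_data: np.ndarray | None = None
                     ) -> list[tuple[SelfOrganizingMap, ClusterMap, np.ndarray]]:
    """Train one map per seed with identical hyperparameters; only the
    initialization and presentation order differ.  Returns per-seed
    (model, clustermap, assignments) triples; assignments cover
    ``assign_data`` (default: the training data)."""
    if len(seeds) < 2:
        raise ValueError("robustness needs at least 2 retraining seeds")
    if assign_data is None:
        assign_data = train_data
    out = []
    for seed in seeds:
        clst = SOMClusterer(**config, random_state=int(seed)).fit(train_data)
        out.append((clst.som_, clst.clustermap_, clst.predict(assign_data)))
    return out


# ---------------------------------------------------------------------------
# Co-membership and consistency
# ---------------------------------------------------------------------------

def comembership(assignments: Sequence[int]) -> np.ndarray:
    """Indicator over unordered component pairs (i < j, lexicographic):
    1 if the two components share a cluster."""
    a = np.asarray(assignments)
    n = len(a)
    iu, ju = np.triu_indices(n, k=1)
    return (a[iu] == a[ju]).astype(int)


def consistency_fraction(run_a: Sequence[int], run_b: Sequence[int]
                         ) -> tuple[np.ndarray, float, float]:
    """Per-component fraction of run-a cluster-mates retained in run-b.

    Components with no cluster-mates in run a contribute 1 by convention.
    Returns (per-component fractions, mean, SD).
    """
    a = np.asarray(run_a)
    b = np.asarray(run_b)
    if a.shape != b.shape:
        raise ValueError("runs must cover the same component set")
    n = len(a)
    fractions = np.empty(n)
    for i in range(n):
        mates = np.flatnonzero((a == a[i]) & (np.arange(n) != i))
        if mates.size == 0:
            fractions[i] = 1.0
        else:
            fractions[i] = float(np.mean(b[mates] == b[i]))
    return fractions, float(fractions.mean()), float(fractions.std(ddof=1) if n > 1 else 0.0)


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementResult:
    """Chance-corrected agreement between two binary series."""

    kappa: float
    ci_low: float
    ci_high: float
    p_value: float
    p_observed: float
    p_expected: float
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.kappa <= self.ci_high):
            raise ValueError("kappa must lie inside its confidence interval")


def cohens_kappa(indicators_a: Sequence[int], indicators_b: Sequence[int],
                 alpha: float = 0.05) -> AgreementResult:
    """Cohen's kappa between two equal-length binary series.

    kappa = (p_o - p_e) / (1 - p_e) with the chance agreement p_e from the
    marginals.  The CI uses the large-sample standard error
    sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)); the p-value tests kappa = 0
    with the null standard error sqrt(p_e / (n (1 - p_e))).
    """
    a = np.asarray(indicators_a).astype(int)
    b = np.asarray(indicators_b).astype(int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("indicator series must be equal-length 1-D")
    n = len(a)
    if n == 0:
        raise ValueError("empty indicator series")
    # 2x2 contingency: rows = a, cols = b
    n11 = int(((a == 1) & (b == 1)).sum())
    n00 = int(((a == 0) & (b == 0)).sum())
    p_o = (n11 + n00) / n
    pa1, pb1 = a.mean(), b.mean()
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if p_e >= 1.0:
        raise ZeroDivisionError(
            "kappa undefined: both series are constant and equal (p_e = 1)")
    kappa = (p_o - p_e) / (1 - p_e)
    se = np.sqrt(max(p_o * (1 - p_o), 0.0) / n) / (1 - p_e)
    z = stats.norm.ppf(1 - alpha / 2)
    se0 = np.sqrt(p_e / (n * (1 - p_e)))
    p_value = 2 * stats.norm.sf(abs(kappa) / se0) if se0 > 0 else np.nan
    return AgreementResult(
        kappa=float(kappa),
        ci_low=float(kappa - z * se),
        ci_high=float(kappa + z * se),
        p_value=float(p_value),
        p_observed=float(p_o),
        p_expected=float(p_e),
        n=n,
    )


def ensemble_kappa(run_assignments: Sequence[Sequence[int]]
                   ) -> tuple[float, tuple[float, float], list[AgreementResult]]:
    """Mean pairwise kappa over all run pairs, with its range and the
    per-pair results."""
    runs = [np.asarray(r) for r in run_assignments]
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    results = [cohens_kappa(comembership(x), comembership(y))
               for x, y in combinations(runs, 2)]
    ks = [r.kappa for r in results]
    return float(np.mean(ks)), (float(min(ks)), float(max(ks))), results


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def icc_absolute(ratings: np.ndarray, alpha: float = 0.05
                 ) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an (n_subjects, k_raters) numeric table.  Computed from
    the classical mean-squares decomposition,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n),

    with an F-based confidence interval.
    """
    Y = np.asarray(ratings, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2 or Y.shape[1] < 2:
        raise ValueError("ratings must be (>=2 subjects) x (>=2 runs)")
    n, k = Y.shape
    grand = Y.mean()
    row_m = Y.mean(axis=1)
    col_m = Y.mean(axis=0)
    ss_total = ((Y - grand) ** 2).sum()
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise ZeroDivisionError("ICC undefined: ratings have zero variance")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ZeroDivisionError("ICC undefined: zero denominator")
    icc = (msr - mse) / denom

    # F-based CI (Shrout & Fleiss / McGraw & Wong, two-way random single)
    if mse > 0 and icc < 1:
        fj = msc / mse
        a_ = (k * icc) / (n * (1 - icc))
        b_ = 1 + (k * icc * (n - 1)) / (n * (1 - icc))
        v = ((a_ * msc + b_ * mse) ** 2 /
             ((a_ * msc) ** 2 / (k - 1)
              + (b_ * mse) ** 2 / ((n - 1) * (k - 1))))
        f_star = stats.f.ppf(1 - alpha / 2, n - 1, v)
        fl = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = (n * (msr - f_star * mse)
              / (f_star * (k * msc + (k * n - k - n) * mse) + n * msr))
        hi = (n * (fl * msr - mse)
              / (k * msc + (k * n - k - n) * mse + n * fl * msr))
        ci = (float(min(lo, icc)), float(max(hi, icc)))
    else:
        ci = (float(icc), float(icc))
    return float(icc), ci


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def robustness_report(run_assignments: Sequence[Sequence[int]]) -> dict:
    """Summary of an ensemble: mean pairwise kappa (+range, CI of the first
    pair), mean +/- SD per-component consistency vs the first (baseline)
    run, and ICC(2,1) over consistency values."""
    runs = [np.asarray(r) for r in run_assignments]
    mean_k, k_range, pair_results = ensemble_kappa(runs)
    base = runs[0]
    per_run_fracs = []
    for other in runs[1:]:
        fr, _, _ = consistency_fraction(base, other)
        per_run_fracs.append(fr)
    frac_mat = np.column_stack(per_run_fracs) if per_run_fracs else np.empty((len(base), 0))
    all_fracs = frac_mat.ravel()
    try:
        icc, icc_ci = (icc_absolute(frac_mat) if frac_mat.shape[1] >= 2
                       else (np.nan, (np.nan, np.nan)))
    except ZeroDivisionError:
        icc, icc_ci = 1.0, (1.0, 1.0)  # zero variance = perfect agreement
    first = pair_results[0]
    return {
        "kappa_mean": mean_k,
        "kappa_range": list(k_range),
        "kappa_first_pair": first.kappa,
        "kappa_first_pair_ci": [first.ci_low, first.ci_high],
        "kappa_first_pair_p": first.p_value,
        "consistency_mean": float(all_fracs.mean()) if all_fracs.size else 1.0,
        "consistency_sd": float(all_fracs.std(ddof=1)) if all_fracs.size > 1 else 0.0,
        "icc": float(icc),
        "icc_ci": [float(icc_ci[0]), float(icc_ci[1])],
        "n_runs": len(runs),
        "n_components": int(len(base)),
    }
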