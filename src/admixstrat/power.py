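"""Analytic power for variance-explained effects and nested-model R² accounting.

A 1-df association test of an effect explaining a fraction q of phenotypic
variance has noncentrality lambda = n*q/(1-q); power is the noncentral
chi-square tail beyond the central critical value.  The minimum detectable
q at given power is the inverse, solved by bisection.  Variance explained
by groups of predictors is reported as the difference of unadjusted R²
between nested OLS models fit on the identical individual set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .association import ols_fit

__all__ = [
    "VariancePartition",
    "power_at_variance",
    "min_detectable_variance",
    "delta_r2",
    "variance_partition_report",
]


@dataclass(frozen=True)
class VariancePartition:
    component: str
    r2_full: float
    r2_reduced: float

    @property
    def delta_r2(self) -> float:
        return self.r2_full - self.r2_reduced


def power_at_variance(n: int, alpha: float, q: float) -> float:
    """Power of a 1-df test for an effect explaining fraction q of variance."""
    if n < 10:
        raise ValueError("n must be >= 10")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if not (0 <= q < 1):
        raise ValueError("q must lie in [0, 1)")
    crit = stats.chi2.isf(alpha, df=1)
    lam = n * q / (1 - q)
    return float(stats.ncx2.sf(crit, df=1, nc=lam)) if lam > 0 else alpha


def min_detectable_variance(n: int, alpha: float, power: float) -> float:
    """Smallest variance fraction q detectable with the target power.

    Solved by bisection on the monotone power curve to 1e-10.  Target power
    must exceed alpha (otherwise q=0 suffices) and be attainable (< 1).
    """
    if not (0 < power < 1):
        raise ValueError("target power must lie in (0, 1)")
    if power <= alpha:
        return 0.0
    f = lambda q: power_at_variance(n, alpha, q) - power
    hi = 1 - 1e-9
    if f(hi) < 0:
        raise ValueError("target power unattainable at this sample size")
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-10))


def _as_design(X, names):
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


def delta_r2(y, full, reduced, full_names=None, reduced_names=None) -> VariancePartition:
    """Unadjusted R² difference between nested OLS models.

    The reduced design's columns must be a subset of the full design's
    (matched by name when names are given, by exact column content
    otherwise); both models are fit on the complete cases of the full
    design so the comparison is on one individual set.
    """
    Xf, nf = _as_design(full, full_names)
    Xr, nr = _as_design(reduced, reduced_names)
    if full_names is not None and reduced_names is not None:
        if not set(nr) <= set(nf):
            raise ValueError("reduced model is not nested in the full model")
    else:
        for j in range(Xr.shape[1]):
            if not np.any([np.array_equal(Xr[:, j], Xf[:, i]) for i in range(Xf.shape[1])]):
                raise ValueError("reduced model is not nested in the full model")
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y) & np.all(np.isfinite(Xf), axis=1) & np.all(np.isfinite(Xr), axis=1)
    fit_full = ols_fit(y[ok], Xf[ok], nf)
    fit_red = ols_fit(y[ok], Xr[ok], nr)
    return VariancePartition(component="delta", r2_full=fit_full.r2, r2_reduced=fit_red.r2)


def _stratum_interactions(g: np.ndarray, local: np.ndarray) -> list[np.ndarray]:
    """Genotype-within-stratum columns: g * 1[local == s] for each stratum."""
    cols = []
    for s in (0, 1, 2):
        col = g * (local == s)
        if np.nanstd(col) > 0:
            cols.append(col)
    return cols


def variance_partition_report(
    y,
    age,
    sex,
    theta,
    snp_dosages: dict[str, np.ndarray],
    snp_local: dict[str, np.ndarray] | None = None,
    conditional_dosages: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Sequential variance-explained accounting against the covariate baseline.

    Components, each an R² increment over the age + sex + theta baseline:

    - ``genotype``: all hit-SNP dosages jointly, uncorrected for local
      ancestry;
    - ``genotype_stratified``: genotype-within-stratum interaction columns
      (how the stratified analysis aggregates genotype signal);
    - ``local_ancestry``: the per-hit local ancestry columns, added on top
      of the stratified genotype terms;
    - ``conditional``: secondary-signal dosages, added on top of everything.

    Returns a tidy frame (component, delta_r2, percent).
    """
    y = np.asarray(y, dtype=float)
    base = [np.ones_like(y), np.asarray(age, float), np.asarray(sex, float), np.asarray(theta, float)]
    g_cols = [np.asarray(v, float) for v in snp_dosages.values()]
    rows = []

    def _fit(cols):
        X = np.column_stack(cols)
        ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
        return ols_fit(y[ok], X[ok]).r2

    r2_base = _fit(base)
    r2_geno = _fit(base + g_cols)
    rows.append(("genotype", r2_geno, r2_base))

    strat_cols = list(g_cols)
    if snp_local:
        strat_cols = []
        for sid, g in snp_dosages.items():
            strat_cols.extend(
                _stratum_interactions(np.asarray(g, float), np.asarray(snp_local[sid], float))
            )
        r2_strat = _fit(base + strat_cols)
        rows.append(("genotype_stratified", r2_strat, r2_base))
        l_cols = [np.asarray(v, float) for v in snp_local.values() if np.nanstd(v) > 0]
        r2_local = _fit(base + strat_cols + l_cols)
        rows.append(("local_ancestry", r2_local, r2_strat))
    if conditional_dosages:
        c_cols = [np.asarray(v, float) for v in conditional_dosages.values()]
        prev = base + strat_cols + (
            [np.asarray(v, float) for v in snp_local.values()] if snp_local else []
        )
        r2_prev = _fit(prev)
        r2_cond = _fit(prev + c_cols)
        rows.append(("conditional", r2_cond, r2_prev))

    df = pd.DataFrame(rows, columns=["component", "r2_full", "r2_reduced"])
    df["delta_r2"] = df["r2_full"] - df["r2_reduced"]
    df["percent"] = 100.0 * df["delta_r2"]
    return df
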