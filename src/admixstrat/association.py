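"""Local-ancestry-stratified association testing.

The central idea: within a stratum of individuals carrying the same number
of African-ancestry chromosomes at a marker (0, 1 or 2), genotype cannot be
confounded by local ancestry.  Each SNP is therefore tested by ordinary
least squares within every usable stratum — phenotype on coded genotype,
adjusted for age, sex and global ancestry theta — and the per-stratum
estimates are combined with inverse-variance-weighted (IVW) fixed-effects
meta-analysis.  The fixed-effects model is the appropriate one here because
the three local-ancestry strata exhaust the possible strata.

Also provided: the conditional (secondary-signal) scan, the 0-vs-2-stratum
effect-heterogeneity and allele-differentiation tests, the excess-ancestry
(admixture) effect test, and an exact Hardy-Weinberg equilibrium test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
import statsmodels.api as sm

__all__ = [
    "StratumFit",
    "StratifiedFit",
    "OlsResult",
    "HeterogeneityResult",
    "encode_genotype",
    "ols_fit",
    "meta_fixed",
    "stratified_assoc",
    "conditional_scan",
    "stratum_heterogeneity_test",
    "admixture_effect_test",
    "allele_diff_test",
    "hwe_exact_test",
]

STRATA = (0, 1, 2)


class AllStrataDegenerateError(ValueError):
    """No local-ancestry stratum satisfied the size/polymorphism rules."""


@dataclass(frozen=True)
class StratumFit:
    stratum: int  # copies of African ancestry
    beta: float
    se: float
    n: int


@dataclass
class StratifiedFit:
    """Per-stratum estimates plus the IVW-combined estimate for one SNP."""

    snp_id: str
    coded_allele: str
    model: str  # additive | recessive
    strata: list[StratumFit]
    beta_meta: float
    se_meta: float
    z: float
    p: float
    skipped: dict[int, str] = field(default_factory=dict)

    @property
    def stratum(self) -> dict[int, StratumFit]:
        return {s.stratum: s for s in self.strata}


@dataclass(frozen=True)
class OlsResult:
    names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    resid_var: float
    r2: float
    n: int
    df_resid: int

    def __getitem__(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.beta[i]), float(self.se[i])


@dataclass(frozen=True)
class HeterogeneityResult:
    z: float
    p: float
    testable: bool = True
    reason: str = ""


def encode_genotype(dosage, model: str = "additive", flip: bool = False):
    """Code dosages for regression.

    ``flip`` re-orients to the other allele (d -> 2-d) before coding;
    additive returns the (oriented) dosage, recessive returns 1 for
    homozygous carriers of the coded allele, else 0.  NaN passes through.
    """
    d = np.asarray(dosage, dtype=float)
    ok = ~np.isnan(d)
    if not np.isin(d[ok], (0, 1, 2)).all():
        raise ValueError("dosages must be 0, 1, 2 or missing")
    if flip:
        d = 2.0 - d
    if model == "additive":
        return d
    if model == "recessive":
        out = np.where(np.isnan(d), np.nan, (d == 2).astype(float))
        return out
    raise ValueError(f"unknown genetic model {model!r}")


def ols_fit(y, design, names=None) -> OlsResult:
    """OLS with classical (homoskedastic) standard errors and unadjusted R².

    Rows with any missing value are excluded (complete-case).  A rank
    deficient design raises with the name of the first offending column.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("design must be n x k aligned with y")
    if names is None:
        names = tuple(f"x{j}" for j in range(X.shape[1]))
    names = tuple(names)
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[ok], X[ok]
    n, k = X.shape
    if n - k < 1:
        raise ValueError("residual degrees of freedom < 1")
    # locate the first column not increasing the rank, for the error message
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        for j in range(1, k + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                raise np.linalg.LinAlgError(
                    f"singular design: column {names[j - 1]!r} is collinear"
                )
    fit = sm.OLS(y, X).fit()
    return OlsResult(
        names=names, beta=np.asarray(fit.params), se=np.asarray(fit.bse),
        resid_var=float(fit.mse_resid), r2=float(fit.rsquared),
        n=n, df_resid=int(fit.df_resid),
    )


def meta_fixed(betas, ses) -> tuple[float, float, float, float]:
    """Inverse-variance-weighted fixed-effects combination.

    weights w_s = se_s^-2; beta = sum(w b)/sum(w); se = sum(w)^-1/2;
    z = beta/se with a two-sided standard-normal p-value.
    """
    b = np.atleast_1d(np.asarray(betas, dtype=float))
    s = np.atleast_1d(np.asarray(ses, dtype=float))
    if b.size == 0 or b.shape != s.shape:
        raise ValueError("need >= 1 aligned (beta, se) pair")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = s ** -2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return beta, se, z, max(float(p), np.finfo(float).tiny)


def _stratum_design(g_enc, covars, names):
    """Assemble [const, genotype, covariates]; constant covariates dropped."""
    cols = [np.ones_like(g_enc), g_enc]
    kept_names = ["const", "genotype"]
    for c, nm in zip(covars, names):
        if np.nanstd(c) > 0:
            cols.append(c)
            kept_names.append(nm)
    return np.column_stack(cols), tuple(kept_names)


def stratified_assoc(
    y,
    g,
    local,
    age,
    sex,
    theta,
    model: str = "additive",
    flip: bool = False,
    min_stratum_n: int = 10,
    min_mac: int = 3,
    extra_covariates: dict[str, np.ndarray] | None = None,
    snp_id: str = "",
    coded_allele: str = "",
) -> StratifiedFit:
    """Test one SNP within local-ancestry strata and combine by IVW meta.

    Within each stratum with at least ``min_stratum_n`` complete cases,
    minor-allele count >= ``min_mac`` and a polymorphic genotype, fit
    y ~ 1 + genotype + age + sex + theta (+ extras); strata failing these
    rules are recorded in ``skipped`` with a reason, not pooled.  Covariate
    columns that are constant within a stratum are dropped from that
    stratum's design; a genotype collinear with an extra covariate skips
    the stratum.
    """
    y = np.asarray(y, dtype=float)
    g_enc = encode_genotype(g, model=model, flip=flip)
    local = np.asarray(local, dtype=float)
    extra_covariates = extra_covariates or {}

    fits: list[StratumFit] = []
    skipped: dict[int, str] = {}
    for s in STRATA:
        mask = local == s
        ysub = y[mask]
        gsub = g_enc[mask]
        covars = [np.asarray(c, dtype=float)[mask] for c in (age, sex, theta)]
        extras = {nm: np.asarray(v, dtype=float)[mask] for nm, v in extra_covariates.items()}
        ok = np.isfinite(ysub) & np.isfinite(gsub)
        for c in list(covars) + list(extras.values()):
            ok &= np.isfinite(c)
        n_s = int(ok.sum())
        if n_s < min_stratum_n:
            skipped[s] = f"n={n_s} < {min_stratum_n}"
            continue
        d_raw = np.asarray(g, dtype=float)[mask][ok]
        mac = float(np.minimum(d_raw, 2 - d_raw).sum())
        if mac < min_mac:
            skipped[s] = f"minor allele count {mac:g} < {min_mac}"
            continue
        if np.std(gsub[ok]) == 0:
            skipped[s] = "monomorphic coded genotype"
            continue
        X, names = _stratum_design(
            gsub[ok],
            [c[ok] for c in covars] + [v[ok] for v in extras.values()],
            ["age", "sex", "theta"] + list(extras),
        )
        try:
            res = ols_fit(ysub[ok], X, names)
        except np.linalg.LinAlgError as err:
            skipped[s] = f"singular design ({err})"
            continue
        beta, se = res["genotype"]
        fits.append(StratumFit(stratum=s, beta=beta, se=se, n=res.n))

    if not fits:
        raise AllStrataDegenerateError(
            f"no usable local-ancestry stratum for {snp_id or 'SNP'}: {skipped}"
        )
    beta, se, z, p = meta_fixed([f.beta for f in fits], [f.se for f in fits])
    return StratifiedFit(
        snp_id=snp_id, coded_allele=coded_allele, model=model,
        strata=fits, beta_meta=beta, se_meta=se, z=z, p=p, skipped=skipped,
    )


def conditional_scan(
    y,
    genotypes,
    snp_ids,
    top_snp: str,
    local,
    age,
    sex,
    theta,
    model: str = "additive",
    **kwargs,
) -> dict[str, StratifiedFit | None]:
    """Re-test every locus SNP with the top SNP's dosage as a covariate.

    ``genotypes``/``local`` are n x K matrices over the locus members in
    ``snp_ids`` order.  The top SNP itself, and any SNP whose genotype is
    collinear with it in every stratum, is reported as None (non-testable).
    """
    snp_ids = list(snp_ids)
    if top_snp not in snp_ids:
        raise ValueError(f"top SNP {top_snp!r} not in locus")
    G = np.asarray(genotypes, dtype=float)
    L = np.asarray(local, dtype=float)
    top = G[:, snp_ids.index(top_snp)]
    out: dict[str, StratifiedFit | None] = {}
    for j, sid in enumerate(snp_ids):
        if sid == top_snp:
            out[sid] = None
            continue
        try:
            out[sid] = stratified_assoc(
                y, G[:, j], L[:, j], age, sex, theta, model=model,
                extra_covariates={"top_snp": top}, snp_id=sid, **kwargs,
            )
        except AllStrataDegenerateError:
            out[sid] = None
    return out


def stratum_heterogeneity_test(fit: StratifiedFit) -> HeterogeneityResult:
    """Compare effect sizes between the 0- and 2-African-ancestry strata.

    z = (beta_0 - beta_2) / sqrt(se_0^2 + se_2^2), two-sided normal p.
    """
    by = fit.stratum
    if 0 not in by or 2 not in by:
        missing = [s for s in (0, 2) if s not in by]
        return HeterogeneityResult(
            z=np.nan, p=np.nan, testable=False,
            reason=f"stratum {missing} not fitted",
        )
    f0, f2 = by[0], by[2]
    z = (f0.beta - f2.beta) / np.hypot(f0.se, f2.se)
    return HeterogeneityResult(z=float(z), p=float(2 * stats.norm.sf(abs(z))))


def admixture_effect_test(y, local_at_snp, age, sex, theta) -> tuple[float, float, float]:
    """Effect of excess ancestry: y ~ 1 + local + age + sex + theta.

    With global ancestry theta in the model, the coefficient on local
    ancestry measures ancestry at the marker beyond its genome-wide
    expectation — the admixture-mapping signal.  Returns (beta, se, p).
    """
    l = np.asarray(local_at_snp, dtype=float)
    ok = ~np.isnan(l)
    if np.nanstd(l) == 0:
        raise ValueError("local ancestry is constant: admixture effect untestable")
    X = np.column_stack([
        np.ones(ok.sum()),
        l[ok],
        np.asarray(age, float)[ok],
        np.asarray(sex, float)[ok],
        np.asarray(theta, float)[ok],
    ])
    res = ols_fit(np.asarray(y, float)[ok], X, ("const", "local", "age", "sex", "theta"))
    beta, se = res["local"]
    t = beta / se
    p = 2 * stats.t.sf(abs(t), res.df_resid)
    return beta, se, float(p)


def allele_diff_test(count_a, n_a, count_b, n_b):
    """Two-sample test of allele proportions (1-df chi-square, no continuity
    correction) on coded-allele chromosome counts.  Vectorized; returns
    (chi2, p).  Individuals in the 0/2 ancestry strata contribute 2
    chromosomes each."""
    xa = np.asarray(count_a, dtype=float)
    xb = np.asarray(count_b, dtype=float)
    na = np.asarray(n_a, dtype=float)
    nb = np.asarray(n_b, dtype=float)
    if np.any(na < 1) or np.any(nb < 1):
        raise ValueError("each group needs at least one chromosome")
    if np.any(xa < 0) or np.any(xb < 0) or np.any(xa > na) or np.any(xb > nb):
        raise ValueError("allele counts must lie in [0, n chromosomes]")
    pa, pb = xa / na, xb / nb
    pooled = (xa + xb) / (na + nb)
    denom = pooled * (1 - pooled) * (1 / na + 1 / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, (pa - pb) ** 2 / denom, 0.0)
    p = stats.chi2.sf(chi2, df=1)
    if chi2.ndim == 0:
        return float(chi2), float(p)
    return chi2, p


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, bool]:
    """Exact conditional Hardy-Weinberg test; returns (p, heterozygote excess).

    Conditional on the observed allele counts, heterozygote counts follow
    P(h) ∝ n! / (n_hom1! h! n_hom2!) * 2^h over h with the parity of the
    minor-allele count; the p-value sums probabilities of all outcomes no
    more probable than the observed one.  The flag is set when the observed
    heterozygote count exceeds its conditional expectation.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts) or not all(float(c).is_integer() for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n_AA, n_Aa, n_aa = (int(c) for c in counts)
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_A = 2 * n_AA + n_Aa
    n_minor = min(n_A, 2 * n - n_A)
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(h) up to a constant: -log(hom1!)-log(h)!-log(hom2)! + h log 2
    hom1 = (n_A - hs) // 2
    hom2 = (2 * n - n_A - hs) // 2
    logp = hs * np.log(2.0) - special.gammaln(hom1 + 1) - special.gammaln(hs + 1) - special.gammaln(hom2 + 1)
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = np.flatnonzero(hs == n_Aa)
    if obs.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p_obs = prob[obs[0]]
    p = float(prob[prob <= p_obs * (1 + 1e-12)].sum())
    expected_het = float(np.sum(hs * prob))
    return min(p, 1.0), n_Aa > expected_het
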