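"""Synthetic admixed cohorts with ancestry structure, LD, and a skewed trait.

Emulates a two-way admixed population (African/European, mean African
ancestry ~0.8) under the Balding-Nichols allele-frequency divergence model:
ancestral frequency pairs are Beta deviates around a shared base frequency
with variance F_ST * p * (1 - p).  Local ancestry is laid down per chromosome
as a two-state Markov segment process with stationary probability equal to
the individual's global ancestry theta, so genotype and local ancestry
covary exactly as they do in real admixed samples — the confounding the
stratified association analysis exists to remove.

Every cohort carries a :class:`SimTruth` record of the generating parameters
so downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "AncestralPanel",
    "SimConfig",
    "AdmixedCohort",
    "SimTruth",
    "sample_ancestral_freqs",
    "sample_cohort",
    "sample_ld_block",
    "pool_r2",
]


@dataclass(frozen=True)
class AncestralPanel:
    """Per-SNP allele frequencies and counts in two ancestral populations.

    Plays the role of a reference panel of ancestral allele counts (e.g.
    HapMap CEU/YRI): ``freq_afr``/``freq_eur`` are the (true or estimated)
    coded-allele frequencies, ``count_afr``/``count_eur`` are coded-allele
    chromosome counts out of ``n_chrom_afr``/``n_chrom_eur`` sampled
    chromosomes.
    """

    snp_id: np.ndarray
    pos: np.ndarray
    freq_afr: np.ndarray
    freq_eur: np.ndarray
    count_afr: np.ndarray | None = None
    count_eur: np.ndarray | None = None
    n_chrom_afr: int | None = None
    n_chrom_eur: int | None = None

    def __post_init__(self) -> None:
        for name in ("snp_id", "pos", "freq_afr", "freq_eur"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if len(np.unique(self.snp_id)) != self.m:
            raise ValueError("snp_ids must be unique")
        for name in ("freq_afr", "freq_eur"):
            f = getattr(self, name)
            if np.any((f < 0) | (f > 1)):
                raise ValueError(f"{name} outside [0, 1]")
        for cname, nname in (("count_afr", "n_chrom_afr"), ("count_eur", "n_chrom_eur")):
            c = getattr(self, cname)
            if c is not None:
                c = np.asarray(c)
                object.__setattr__(self, cname, c)
                n = getattr(self, nname)
                if n is None:
                    raise ValueError(f"{cname} given without {nname}")
                if np.any((c < 0) | (c > n)):
                    raise ValueError(f"{cname} outside [0, {nname}]")

    @property
    def m(self) -> int:
        return len(self.snp_id)


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one synthetic cohort.

    Defaults emulate the study conditions of an admixed African-American
    cohort: n=1018 unrelated individuals, mean African ancestry 0.80,
    ancestral differentiation F_ST=0.15 (CEU/YRI scale), and a right-skewed
    residual (skewness ~2.4) so the Box-Cox stage has work to do.

    ``causal_effects`` maps snp_id -> phenotype units per coded allele;
    ``ancestry_effect`` is phenotype units per copy of African ancestry at
    ``ancestry_marker`` (admixture-mapping-style direct ancestry effect).
    ``ld_switch_rate`` is the per-marker probability that a chromosome's
    ancestry state is redrawn from its stationary distribution; 1.0 gives
    independent-per-marker local ancestry (useful in unit tests).
    """

    n: int = 1018
    m: int = 1000
    fst: float = 0.15
    theta_mean: float = 0.80
    theta_conc: float = 15.0
    causal_effects: Mapping[str, float] = field(default_factory=dict)
    ancestry_effect: float = 0.0
    ancestry_marker: str | None = None
    age_effect: float = -0.02
    sex_effect: float = 0.3
    noise_sd: float = 1.0
    noise_skew: float = 2.4
    ld_switch_rate: float = 0.01
    make_creatinine: bool = False
    egfr_base: float = 100.0
    egfr_scale: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("n and m must be >= 1")
        if not (0 <= self.fst < 1):
            raise ValueError("fst must lie in [0, 1)")
        if not (0 < self.theta_mean <= 1):
            raise ValueError("theta_mean must lie in (0, 1]")
        if self.theta_mean < 1 and self.theta_conc <= 0:
            raise ValueError("theta_conc must be positive")
        if not (0 < self.ld_switch_rate <= 1):
            raise ValueError("ld_switch_rate must lie in (0, 1]")
        if self.noise_sd < 0 or self.noise_skew < 0:
            raise ValueError("noise_sd and noise_skew must be non-negative")


@dataclass
class AdmixedCohort:
    """Genotypes, local/global ancestry, covariates and trait for n x m."""

    snp_id: np.ndarray
    pos: np.ndarray
    genotypes: np.ndarray  # n x m float, entries in {0,1,2} or NaN
    local: np.ndarray  # n x m, copies of African ancestry in {0,1,2}
    global_anc: np.ndarray  # length n, in [0,1]
    age: np.ndarray
    sex: np.ndarray  # 1 = female
    creatinine: np.ndarray | None = None  # mg/dL
    phenotype: np.ndarray | None = None  # analysis-ready transformed trait
    sample_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if self.local.shape != (n, m):
            raise ValueError("local ancestry shape mismatch")
        if len(self.global_anc) != n or len(self.age) != n or len(self.sex) != n:
            raise ValueError("per-individual vector length mismatch")
        if len(self.snp_id) != m or len(self.pos) != m:
            raise ValueError("marker metadata length mismatch")
        loc = self.local[~np.isnan(np.asarray(self.local, dtype=float))]
        if loc.size and not np.isin(loc, (0, 1, 2)).all():
            raise ValueError("local ancestry entries must be 0, 1 or 2")
        if self.sample_id is None:
            self.sample_id = np.array([f"ind{i:05d}" for i in range(n)])

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]

    def dosage(self, snp_id: str) -> np.ndarray:
        return self.genotypes[:, self._col(snp_id)]

    def local_at(self, snp_id: str) -> np.ndarray:
        return self.local[:, self._col(snp_id)]

    def _col(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snp_id == snp_id)
        if idx.size == 0:
            raise KeyError(f"unknown snp_id {snp_id!r}")
        return int(idx[0])


@dataclass(frozen=True)
class SimTruth:
    """Immutable record of the realized generating process."""

    config: SimConfig
    freq_afr: np.ndarray
    freq_eur: np.ndarray
    theta: np.ndarray
    snp_id: np.ndarray


def _default_base_dist(rng: np.random.Generator, size: int) -> np.ndarray:
    # base allele frequencies of the shared ancestral population
    return rng.uniform(0.1, 0.9, size=size)


def sample_ancestral_freqs(
    m: int,
    fst: float,
    base_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int | np.random.Generator | None = None,
    freq_floor: float = 0.01,
    n_chrom: int = 120,
    sample_counts: bool = True,
    pos_spacing: int = 5_000,
) -> AncestralPanel:
    """Draw ancestral frequency pairs under the Balding-Nichols model.

    For each marker a base frequency p is drawn from ``base_dist`` and the
    two ancestral frequencies are independent Beta(p(1-F)/F, (1-p)(1-F)/F)
    deviates, so that E[freq] = p and Var[freq] = F_ST * p(1-p).  At
    ``fst=0`` both populations share p exactly.  Frequencies are clamped to
    [freq_floor, 1-freq_floor] to avoid monomorphic markers.

    When ``sample_counts`` is true, per-population allele counts are drawn
    binomially from ``n_chrom`` chromosomes, mimicking a finite reference
    panel such as HapMap CEU/YRI.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    if not (0 <= fst < 1):
        raise ValueError("fst must lie in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    base_dist = base_dist or _default_base_dist
    p = np.asarray(base_dist(rng, m), dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("base_dist must yield frequencies strictly inside (0, 1)")
    if fst == 0:
        fa = p.copy()
        fe = p.copy()
    else:
        a = p * (1 - fst) / fst
        b = (1 - p) * (1 - fst) / fst
        fa = rng.beta(a, b)
        fe = rng.beta(a, b)
    fa = np.clip(fa, freq_floor, 1 - freq_floor)
    fe = np.clip(fe, freq_floor, 1 - freq_floor)
    snp_id = np.array([f"snp{i:06d}" for i in range(m)])
    pos = np.arange(1, m + 1, dtype=int) * pos_spacing
    ca = ce = None
    if sample_counts:
        ca = rng.binomial(n_chrom, fa)
        ce = rng.binomial(n_chrom, fe)
    return AncestralPanel(
        snp_id=snp_id, pos=pos, freq_afr=fa, freq_eur=fe,
        count_afr=ca, count_eur=ce,
        n_chrom_afr=n_chrom if sample_counts else None,
        n_chrom_eur=n_chrom if sample_counts else None,
    )


def _sample_local_chromosome(
    rng: np.random.Generator, theta: np.ndarray, m: int, switch_rate: float
) -> np.ndarray:
    """One haploid ancestry track per individual: n x m boolean (True=African).

    Two-state Markov chain along markers with stationary probability theta_i:
    at each marker the state is redrawn from Bernoulli(theta_i) with
    probability ``switch_rate``, else copied from the previous marker.
    """
    n = len(theta)
    out = np.empty((n, m), dtype=bool)
    out[:, 0] = rng.random(n) < theta
    if m == 1:
        return out
    redraw = rng.random((n, m - 1)) < switch_rate
    fresh = rng.random((n, m - 1)) < theta[:, None]
    for j in range(1, m):
        out[:, j] = np.where(redraw[:, j - 1], fresh[:, j - 1], out[:, j - 1])
    return out


def _skewed_noise(rng: np.random.Generator, n: int, sd: float, skew: float) -> np.ndarray:
    """Zero-mean residuals with target SD and (moment) skewness.

    Shifted-gamma construction: gamma(k) has skewness 2/sqrt(k), so k is set
    from the target; standardized to mean 0, variance sd^2.  skew=0 falls
    back to a normal draw.
    """
    if sd == 0:
        return np.zeros(n)
    if skew == 0:
        return rng.normal(0.0, sd, size=n)
    k = (2.0 / skew) ** 2
    g = rng.gamma(k, 1.0, size=n)
    return (g - k) / np.sqrt(k) * sd


def sample_cohort(cfg: SimConfig, panel: AncestralPanel) -> tuple[AdmixedCohort, SimTruth]:
    """Simulate one admixed cohort from a config and an ancestral panel.

    Per individual: theta ~ Beta(mean*conc, (1-mean)*conc); two haploid
    ancestry tracks from the Markov segment process; each chromosome's
    allele Bernoulli(freq of its ancestry at that marker); genotype is the
    chromosome sum and local ancestry the African-track sum.  The trait is

        y = sum_k beta_k g_k + gamma * l_anc + b_age (age-50) + b_sex sex + e

    with e the skewed residual.  With ``make_creatinine`` the trait is
    embedded into an eGFR scale (egfr_base + egfr_scale * y) and serum
    creatinine is back-computed by inverting the MDRD equation, so the
    phenotype-construction pipeline can be exercised end to end.
    """
    if panel.m < cfg.m:
        raise ValueError(f"panel has {panel.m} markers, config needs {cfg.m}")
    for sid in cfg.causal_effects:
        if sid not in panel.snp_id[: cfg.m]:
            raise ValueError(f"causal snp_id {sid!r} not in the first {cfg.m} panel markers")
    if cfg.ancestry_effect != 0:
        marker = cfg.ancestry_marker
        if marker is None:
            raise ValueError("ancestry_effect set but no ancestry_marker given")
        if marker not in panel.snp_id[: cfg.m]:
            raise ValueError(f"ancestry_marker {marker!r} not in the first {cfg.m} panel markers")

    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n, cfg.m
    fa = panel.freq_afr[:m]
    fe = panel.freq_eur[:m]

    if cfg.theta_mean == 1.0:
        theta = np.ones(n)
    else:
        theta = rng.beta(cfg.theta_mean * cfg.theta_conc, (1 - cfg.theta_mean) * cfg.theta_conc, size=n)

    anc1 = _sample_local_chromosome(rng, theta, m, cfg.ld_switch_rate)
    anc2 = _sample_local_chromosome(rng, theta, m, cfg.ld_switch_rate)
    freq1 = np.where(anc1, fa[None, :], fe[None, :])
    freq2 = np.where(anc2, fa[None, :], fe[None, :])
    allele1 = rng.random((n, m)) < freq1
    allele2 = rng.random((n, m)) < freq2
    genotypes = (allele1.astype(np.int8) + allele2.astype(np.int8)).astype(float)
    local = anc1.astype(np.int8) + anc2.astype(np.int8)

    age = rng.uniform(30, 70, size=n)
    sex = (rng.random(n) < 0.5).astype(int)  # 1 = female

    snp_id = panel.snp_id[:m]
    y = np.zeros(n)
    for sid, beta in cfg.causal_effects.items():
        j = int(np.flatnonzero(snp_id == sid)[0])
        y += beta * genotypes[:, j]
    if cfg.ancestry_effect != 0:
        j = int(np.flatnonzero(snp_id == cfg.ancestry_marker)[0])
        y += cfg.ancestry_effect * local[:, j]
    y += cfg.age_effect * (age - 50.0) + cfg.sex_effect * sex
    y += _skewed_noise(rng, n, cfg.noise_sd, cfg.noise_skew)

    creatinine = None
    if cfg.make_creatinine:
        egfr = np.clip(cfg.egfr_base + cfg.egfr_scale * y, 5.0, None)
        # invert MDRD (black=True for the emulated cohort): solve for creatinine
        denom = 186.0 * age ** (-0.203) * np.where(sex == 1, 0.742, 1.0) * 1.210
        creatinine = (egfr / denom) ** (-1.0 / 1.154)

    cohort = AdmixedCohort(
        snp_id=snp_id.copy(), pos=panel.pos[:m].copy(), genotypes=genotypes,
        local=local, global_anc=local.mean(axis=1) / 2.0, age=age, sex=sex,
        creatinine=creatinine, phenotype=y,
    )
    truth = SimTruth(
        config=dataclasses.replace(cfg), freq_afr=fa.copy(), freq_eur=fe.copy(),
        theta=theta, snp_id=snp_id.copy(),
    )
    return cohort, truth


def sample_ld_block(
    n: int,
    K: int,
    pool_size: int,
    seed: int | np.random.Generator | None = None,
    pool: np.ndarray | None = None,
    freq: float = 0.5,
) -> np.ndarray:
    """Genotypes for one LD block drawn from a finite haplotype pool.

    Each individual's two chromosomes are drawn uniformly (with replacement)
    from a pool of ``pool_size`` haplotypes over K biallelic markers; the
    genotype is the chromosome sum.  Small pools induce strong LD (pool of 2
    complementary haplotypes -> all markers perfectly correlated), large
    pools with independent marker states approach linkage equilibrium.

    A haplotype ``pool`` (pool_size x K in {0,1}) may be supplied; otherwise
    one is drawn with independent Bernoulli(freq) entries.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if pool_size < 2:
        raise ValueError("pool_size must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if pool is None:
        pool = (rng.random((pool_size, K)) < freq).astype(np.int8)
    else:
        pool = np.asarray(pool, dtype=np.int8)
        if pool.shape != (pool_size, K):
            raise ValueError("pool shape must be (pool_size, K)")
    idx1 = rng.integers(pool_size, size=n)
    idx2 = rng.integers(pool_size, size=n)
    return (pool[idx1] + pool[idx2]).astype(float)


def pool_r2(pool: np.ndarray) -> np.ndarray:
    """Pool-implied pairwise haplotype r^2 matrix (equal haplotype weights)."""
    h = np.asarray(pool, dtype=float)
    p = h.mean(axis=0)
    d = h.T @ h / h.shape[0] - np.outer(p, p)
    denom = np.sqrt(np.outer(p * (1 - p), p * (1 - p)))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, d / denom, 0.0)
    np.fill_diagonal(r, 1.0)
    return r ** 2
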