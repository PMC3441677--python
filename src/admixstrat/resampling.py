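"""Permutation test for excess ancestral differentiation among hit loci.

Observing allelic differentiation between ancestral populations at (say)
10 of 11 associated loci only means something relative to the genome-wide
level of differentiation.  The test draws k SNPs at random without
replacement from the full panel, applies the two-population allele
proportion test to each, counts how many are significant, and reports the
fraction of replicates in which the count reaches the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import allele_diff_test
from .simulate import AncestralPanel

__all__ = ["PermutationResult", "differentiation_permutation"]


@dataclass(frozen=True)
class PermutationResult:
    reps: int
    hits_per_rep: np.ndarray
    p_value: float
    alpha_per_snp: float
    observed_hits: int
    k: int
    seed: int | None

    def __str__(self) -> str:
        return (
            "differentiation permutation test\n"
            f"  replicates              {self.reps}\n"
            f"  draw size / observed    {self.k} / >= {self.observed_hits}\n"
            f"  per-SNP alpha           {self.alpha_per_snp}\n"
            f"  mean hits per draw      {self.hits_per_rep.mean():.3f}\n"
            f"  p-value                 {self.p_value:.6g}"
        )


def differentiation_permutation(
    panel: AncestralPanel,
    k: int = 11,
    observed_hits: int = 10,
    reps: int = 10_000,
    alpha_per_snp: float = 0.05,
    seed: int | np.random.Generator | None = None,
    plus_one: bool = False,
) -> PermutationResult:
    """Permutation distribution of the per-draw differentiated-SNP count.

    Per replicate, ``k`` SNPs are sampled without replacement from the
    panel and tested for allele-frequency difference between the two
    ancestral populations (chi-square on allele counts at
    ``alpha_per_snp``); the p-value is the fraction of replicates with at
    least ``observed_hits`` significant SNPs (``plus_one`` applies the
    (r+1)/(reps+1) correction).
    """
    if panel.count_afr is None or panel.count_eur is None:
        raise ValueError("panel must carry allele counts for both populations")
    if k > panel.m:
        raise ValueError(f"draw size {k} exceeds panel size {panel.m}")
    if not (0 <= observed_hits <= k):
        raise ValueError("observed_hits must lie in [0, k]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    # the per-SNP test depends only on the SNP: precompute once
    _, p = allele_diff_test(
        panel.count_afr, panel.n_chrom_afr, panel.count_eur, panel.n_chrom_eur
    )
    sig = np.asarray(p) < alpha_per_snp

    hits = np.empty(reps, dtype=int)
    for r in range(reps):
        idx = rng.choice(panel.m, size=k, replace=False)
        hits[r] = int(sig[idx].sum())
    r_ge = int(np.sum(hits >= observed_hits))
    p_value = (r_ge + 1) / (reps + 1) if plus_one else r_ge / reps
    return PermutationResult(
        reps=reps, hits_per_rep=hits, p_value=float(p_value),
        alpha_per_snp=alpha_per_snp, observed_hits=observed_hits, k=k,
        seed=seed if isinstance(seed, int) else None,
    )
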