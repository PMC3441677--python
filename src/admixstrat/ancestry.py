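"""Global ancestry, population-structure checks, and F_ST annotation.

Global ancestry theta is the marker-average of local ancestry / 2.  The
structure check mirrors standard GWAS practice: LD-prune, randomly thin,
run PCA on standardized genotypes, and decide the number of meaningful
components with Velicer's minimum-average-partial (MAP) test.  Allele
frequency differentiation between ancestral panels is annotated with
Hudson's F_ST estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StructureReport",
    "global_from_local",
    "ld_prune",
    "thin_random",
    "pca_genotypes",
    "map_test",
    "hudson_fst",
]


@dataclass(frozen=True)
class StructureReport:
    """Outcome of the PCA + minimum-average-partial structure check."""

    n_significant_pcs: int
    pc_variance_fractions: np.ndarray
    map_values: np.ndarray  # average squared partial correlation, index = k

    def __str__(self) -> str:
        top = ", ".join(f"{v:.3f}" for v in self.pc_variance_fractions[:5])
        return (
            "structure report\n"
            f"  significant components  {self.n_significant_pcs}\n"
            f"  leading variance fracs  {top}\n"
            f"  MAP minimum             f({self.n_significant_pcs}) = "
            f"{self.map_values[self.n_significant_pcs]:.5f}"
        )


def global_from_local(local: np.ndarray) -> np.ndarray:
    """theta_i = mean over non-missing markers of local_ij / 2."""
    local = np.asarray(local, dtype=float)
    if local.ndim != 2:
        raise ValueError("local ancestry must be an n x m matrix")
    ok = ~np.isnan(local)
    vals = local[ok]
    if vals.size and not np.isin(vals, (0, 1, 2)).all():
        raise ValueError("local ancestry entries must be 0, 1 or 2")
    counts = ok.sum(axis=1)
    if np.any(counts == 0):
        bad = np.flatnonzero(counts == 0)
        raise ValueError(f"individuals with all-missing local ancestry: {bad.tolist()}")
    return np.nansum(local, axis=1) / counts / 2.0


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def ld_prune(genotypes: np.ndarray, r2_max: float = 0.2, window: int = 50) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns retained column indices.

    A marker is dropped if its squared Pearson correlation with any retained
    marker within the preceding ``window`` markers reaches ``r2_max``.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must lie in (0, 1]")
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.shape[1] == 0:
        raise ValueError("empty genotype matrix")
    kept: list[int] = []
    for j in range(G.shape[1]):
        drop = False
        for i in reversed(kept):
            if j - i > window:
                break
            if _pairwise_r2(G[:, i], G[:, j]) >= r2_max:
                drop = True
                break
        if not drop:
            kept.append(j)
    return np.asarray(kept, dtype=int)


def thin_random(markers, target: int, seed=None) -> np.ndarray:
    """Uniform sample of ``target`` markers without replacement (seeded)."""
    markers = np.asarray(markers)
    if target > len(markers):
        raise ValueError(f"target {target} exceeds available {len(markers)}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = np.sort(rng.choice(len(markers), size=target, replace=False))
    return markers[idx]


def pca_genotypes(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCA of standardized genotypes: (scores n x r, variance fractions).

    Markers are standardized to mean 0 / unit variance (zero-variance
    markers dropped); the decomposition is the SVD of the standardized
    matrix, equivalent to the eigendecomposition of the individual by
    individual covariance.  Scores are mutually orthogonal; variance
    fractions sum to 1.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2 or G.shape[1] < 2:
        raise ValueError("need at least 2 individuals and 2 markers")
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), col_mean[None, :], G)
    sd = G.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all markers have zero variance")
    X = (G[:, keep] - G[:, keep].mean(axis=0)) / sd[keep]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    return U * s, var / var.sum()


def map_test(matrix: np.ndarray, k_max: int | None = None) -> StructureReport:
    """Velicer's minimum-average-partial test for the number of components.

    For k = 0, 1, 2, ... the first k principal components are partialled out
    of the marker correlation matrix and the average squared off-diagonal
    partial correlation f(k) is recorded; the number of meaningful
    components is the k minimizing f.  Squared (not fourth-power) partial
    correlations, following Velicer's original criterion.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need at least 3 rows and 2 columns")
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean[None, :], X)
    X = X[:, X.std(axis=0) > 0]
    p = X.shape[1]
    if p < 2:
        raise ValueError("fewer than 2 variable columns with variance")
    R = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if k_max is None:
        k_max = min(p - 2, X.shape[0] - 2, int(np.sum(eigval > 1e-10)) - 1)
    k_max = max(k_max, 0)
    off = ~np.eye(p, dtype=bool)
    fks = []
    C = R.copy()
    for k in range(k_max + 1):
        if k > 0:
            lam, v = eigval[k - 1], eigvec[:, k - 1]
            C = C - lam * np.outer(v, v)
        d = np.diag(C).copy()
        if np.any(d < 1e-12):
            break
        P = C / np.sqrt(np.outer(d, d))
        fks.append(float(np.mean(P[off] ** 2)))
    map_values = np.asarray(fks)
    n_sig = int(np.argmin(map_values))
    _, fractions = pca_genotypes(X) if p >= 2 else (None, np.ones(1))
    return StructureReport(
        n_significant_pcs=n_sig, pc_variance_fractions=fractions, map_values=map_values
    )


def hudson_fst(freq_a, freq_b, n_a, n_b):
    """Hudson's F_ST estimator for one or more markers, clamped to [0, 1].

    numerator (p_a-p_b)^2 - p_a(1-p_a)/(n_a-1) - p_b(1-p_b)/(n_b-1),
    denominator p_a(1-p_b) + p_b(1-p_a); n_a, n_b are chromosome counts.
    """
    pa = np.asarray(freq_a, dtype=float)
    pb = np.asarray(freq_b, dtype=float)
    na = np.asarray(n_a, dtype=float)
    nb = np.asarray(n_b, dtype=float)
    if np.any((pa < 0) | (pa > 1) | (pb < 0) | (pb > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if np.any(na <= 1) or np.any(nb <= 1):
        raise ValueError("sample sizes must exceed 1 chromosome")
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(den > 0, num / den, 0.0)
    out = np.clip(fst, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def hudson_fst_panel(freq_a, freq_b, n_a, n_b) -> float:
    """Multi-marker Hudson F_ST as a ratio of averages.

    Summing numerators and denominators over markers before dividing gives
    an (essentially) unbiased genome-wide estimate — the per-marker ratios
    of :func:`hudson_fst` are individually noisy and their plain mean is
    downward biased by Jensen's inequality.
    """
    pa = np.asarray(freq_a, dtype=float)
    pb = np.asarray(freq_b, dtype=float)
    na = np.asarray(n_a, dtype=float)
    nb = np.asarray(n_b, dtype=float)
    if np.any(na <= 1) or np.any(nb <= 1):
        raise ValueError("sample sizes must exceed 1 chromosome")
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    return float(np.sum(num) / np.sum(den))
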