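"""Kernel (un)conditional independence screening of legacy-effect drivers.

Per-event driver variables are tested against the legacy-effect magnitude
with three kernel methods — an HSIC permutation test, the HSIC gamma
approximation, and a kernel-based conditional independence test (KCIT, run
unconditionally when the conditioning set is empty).  A driver becomes a
candidate when at least two of the three p-values fall below 0.05; with two
or more candidates, conditional KCIT runs among them to resolve which
dependence survives conditioning on the others.  Kernel tests are used
because driver–legacy relationships are expected to be nonlinear; no
multiple-testing correction is applied across drivers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def _is_binary(x: np.ndarray) -> bool:
    return np.unique(x[np.isfinite(x)]).size <= 2


def median_bandwidth(x: np.ndarray) -> float:
    """Median of non-zero pairwise distances (the median heuristic)."""
    d = pdist(np.atleast_2d(x.reshape(len(x), -1)))
    d = d[d > 0]
    return float(np.median(d)) if d.size else 1.0


def gram_matrix(x: np.ndarray, kernel: str | None = None) -> np.ndarray:
    """Gaussian Gram matrix with the median-heuristic bandwidth.

    Binary variables (e.g. forest vs non-forest) use a delta kernel unless a
    kernel is forced explicitly.
    """
    x = np.asarray(x, float)
    if kernel is None:
        kernel = "delta" if _is_binary(x) else "gaussian"
    if kernel == "delta":
        return (x[:, None] == x[None, :]).astype(float)
    sigma = median_bandwidth(x)
    d2 = squareform(pdist(np.atleast_2d(x.reshape(len(x), -1)))) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def _center(k: np.ndarray) -> np.ndarray:
    return k - k.mean(axis=0) - k.mean(axis=1)[:, None] + k.mean()


# ---------------------------------------------------------------------------
# HSIC
# ---------------------------------------------------------------------------

def hsic_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Biased V-statistic HSIC = tr(KHLH)/n² with Gaussian/delta kernels.

    Symmetric in its arguments; zero-variance input yields 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.ptp(x[np.isfinite(x)]) == 0 or np.ptp(y[np.isfinite(y)]) == 0:
        return 0.0
    k = gram_matrix(x)
    l = gram_matrix(y)
    n = x.size
    return float(np.sum(_center(k) * _center(l)) / n**2)


def hsic_permutation_test(
    x: np.ndarray, y: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> float:
    """Permutation p-value for HSIC with the add-one convention.

    y is shuffled ``n_perm`` times; p = (1 + #{permuted ≥ observed}) /
    (1 + n_perm), so p is never below 1/(1+n_perm).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    kc = _center(gram_matrix(x))
    l = gram_matrix(y)
    lc = _center(l)
    observed = float(np.sum(kc * lc) / n**2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        stat = float(np.sum(kc * lc[np.ix_(perm, perm)]) / n**2)
        if stat >= observed:
            count += 1
    return (1 + count) / (1 + n_perm)


def hsic_gamma_test(x: np.ndarray, y: np.ndarray) -> float:
    """Gamma approximation to the HSIC null (moment-matched mean/variance).

    Follows the standard two-moment approximation of the permutation null of
    m·HSIC_b; a non-positive variance estimate falls back to the permutation
    test.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m = x.size
    if m < 6:
        raise ValueError("gamma approximation needs n >= 6")
    k = gram_matrix(x)
    l = gram_matrix(y)
    kc, lc = _center(k), _center(l)
    test_stat = np.sum(kc * lc) / m  # = m * HSIC_b

    var = (kc * lc / 6.0) ** 2
    var = (var.sum() - np.trace(var)) / m / (m - 1)
    var = var * 72.0 * (m - 4) * (m - 5) / m / (m - 1) / (m - 2) / (m - 3)

    k_od = k - np.diag(np.diag(k))
    l_od = l - np.diag(np.diag(l))
    mu_x = k_od.sum() / m / (m - 1)
    mu_y = l_od.sum() / m / (m - 1)
    mean = (1.0 + mu_x * mu_y - mu_x - mu_y) / m

    if var <= 0 or mean <= 0:
        return hsic_permutation_test(x, y)
    # mean/var are moments of HSIC_b; the statistic is m·HSIC_b, so the
    # gamma scale carries the extra factor of m (shape is scale-free)
    shape = mean**2 / var
    scale = var * m / mean
    return float(stats.gamma.sf(test_stat, a=shape, scale=scale))


# ---------------------------------------------------------------------------
# KCIT
# ---------------------------------------------------------------------------

def kcit(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray | None = None,
    ridge: float = 1e-3,
    null: str = "spectral",
    n_null: int = 5000,
    seed: int = 0,
) -> float:
    """Kernel-based (conditional) independence test.

    Unconditional (z empty): the statistic is tr(K̃x K̃y) on centered kernels.
    Conditional: kernels are residualized with R_z = ε(K̈z + εI)⁻¹ (K̈x built
    on the augmented (x, z) so that dependence through z is removed), then
    the same statistic applies.  The null is approximated spectrally — the
    statistic is distributed like Σᵢⱼ λᵢμⱼ zᵢⱼ²/n over products of kernel
    eigenvalues, sampled ``n_null`` times — or, with ``null="gamma"``, by a
    two-moment gamma fit.  A singular conditioning kernel raises the ridge.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size

    if z is None or (hasattr(z, "size") and np.asarray(z).size == 0):
        kx = _center(gram_matrix(x))
        ky = _center(gram_matrix(y))
    else:
        z = np.asarray(z, float)
        if z.ndim == 1:
            z = z[:, None]
        xz = np.column_stack([_standardize(x), 0.5 * _standardize_cols(z)])
        kz = _center(_gram_multi(_standardize_cols(z)))
        eps = ridge * n
        for _ in range(4):
            try:
                rz = eps * np.linalg.inv(kz + eps * np.eye(n))
                break
            except np.linalg.LinAlgError:
                eps *= 10
        kx = rz @ _center(_gram_multi(xz)) @ rz.T
        ky = rz @ _center(gram_matrix(y)) @ rz.T

    stat = float(np.sum(kx * ky.T))

    if null == "spectral":
        lam = np.linalg.eigvalsh((kx + kx.T) / 2)
        mu = np.linalg.eigvalsh((ky + ky.T) / 2)
        lam = lam[lam > 1e-10 * lam.max()]
        mu = mu[mu > 1e-10 * mu.max()]
        prod = np.outer(lam, mu).ravel() / n
        # keep the dominant eigenvalue products; the tail is negligible
        prod = np.sort(prod)[::-1][: min(prod.size, 2000)]
        rng = np.random.default_rng(seed)
        draws = prod @ rng.chisquare(1.0, size=(prod.size, n_null))
        return float((1 + np.sum(draws >= stat)) / (1 + n_null))

    mean = np.trace(kx) * np.trace(ky) / n
    var = 2.0 * float(np.sum(kx * kx.T)) * float(np.sum(ky * ky.T)) / n**2
    if mean <= 0 or var <= 0:
        return 1.0
    shape = mean**2 / var
    scale = var / mean
    return float(stats.gamma.sf(stat, a=shape, scale=scale))


def _standardize(x: np.ndarray) -> np.ndarray:
    s = np.std(x)
    return (x - np.mean(x)) / (s if s > 0 else 1.0)


def _standardize_cols(z: np.ndarray) -> np.ndarray:
    if z.ndim == 1:
        z = z[:, None]
    return np.column_stack([_standardize(z[:, j]) for j in range(z.shape[1])])


def _gram_multi(x: np.ndarray) -> np.ndarray:
    """Gaussian Gram matrix for multivariate rows, median-heuristic bandwidth."""
    d = squareform(pdist(np.atleast_2d(x)))
    pos = d[d > 0]
    sigma = float(np.median(pos)) if pos.size else 1.0
    return np.exp(-(d**2) / (2.0 * sigma**2))


# ---------------------------------------------------------------------------
# Driver screening
# ---------------------------------------------------------------------------

@dataclass
class IndependenceResult:
    """Three p-values and the 2-of-3 candidate decision for one driver."""

    driver: str
    p_hsic_perm: float
    p_hsic_gamma: float
    p_kcit: float
    candidate: bool


def test_driver(
    x: np.ndarray, y: np.ndarray, name: str = "",
    n_perm: int = 1000, seed: int = 0, alpha: float = 0.05,
) -> IndependenceResult:
    """Run all three kernel tests for one driver against the legacy effect."""
    p_perm = hsic_permutation_test(x, y, n_perm=n_perm, seed=seed)
    p_gamma = hsic_gamma_test(x, y)
    p_k = kcit(x, y)
    n_sig = sum(p < alpha for p in (p_perm, p_gamma, p_k))
    return IndependenceResult(
        driver=name, p_hsic_perm=p_perm, p_hsic_gamma=p_gamma, p_kcit=p_k,
        candidate=n_sig >= 2,
    )


def select_candidates(results: list[IndependenceResult]) -> list[str]:
    """Drivers where at least two of the three tests reject independence."""
    return [r.driver for r in results if r.candidate]


def screen_drivers(
    table, legacy_col: str = "legacy_effect",
    n_perm: int = 1000, seed: int = 0, alpha: float = 0.05,
) -> tuple[list[IndependenceResult], list[str], dict[str, float]]:
    """Screen every driver column of a per-event table with the 2-of-3 rule.

    Rows with missing values in tested columns are dropped.  If two or more
    candidates emerge, each is re-tested conditionally on the others (KCIT)
    to resolve the structure; with exactly one candidate it stands as the
    causal driver.  Returns (per-driver results, candidates, conditional
    p-values).
    """
    table = table.dropna()
    y = table[legacy_col].to_numpy(float)
    drivers = [c for c in table.columns if c != legacy_col]
    results = []
    for i, name in enumerate(drivers):
        results.append(
            test_driver(table[name].to_numpy(float), y, name=name,
                        n_perm=n_perm, seed=seed + i, alpha=alpha)
        )
    candidates = select_candidates(results)
    conditional: dict[str, float] = {}
    if len(candidates) >= 2:
        for name in candidates:
            others = [c for c in candidates if c != name]
            z = table[others].to_numpy(float)
            conditional[name] = kcit(table[name].to_numpy(float), y, z)
    return results, candidates, conditional
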