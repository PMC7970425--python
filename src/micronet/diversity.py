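"""Alpha diversity, Bray-Curtis dissimilarity, NMDS ordination and PERMANOVA.

The estimators are implemented from their definitions (they are the unit of
analysis here, and the test suite cross-checks them against scikit-bio and
scipy); the NMDS is a Kruskal stress-1 SMACOF with monotone (isotonic)
regression, and the PERMANOVA supports restricted permutation within subject
strata for the paired crossover design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: np.ndarray  # sample x k, centred at the origin
    stress: float
    n_iterations: int
    converged: bool
    stress_history: tuple[float, ...]


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts, base: float = np.e) -> float:
    """Shannon-Wiener index H' = -sum p_i log p_i (natural log by default)."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(base))


def richness(counts) -> int:
    """Number of strictly positive entries (observed OTUs)."""
    return int((np.asarray(counts) > 0).sum())


def chao1(counts) -> float:
    """Chao-1 richness estimator from singleton/doubleton counts.

    ``S_obs + F1^2 / (2 F2)`` when doubletons exist, otherwise the
    bias-corrected ``S_obs + F1 (F1 - 1) / 2``.
    """
    c = np.asarray(counts)
    if not np.issubdtype(c.dtype, np.integer):
        if not np.allclose(c, np.round(c)):
            raise ValueError("chao1 requires integer counts")
        c = np.round(c).astype(np.int64)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("entries must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(abund: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis matrix for rows of ``abund`` (samples x OTUs)."""
    return squareform(pdist(np.asarray(abund, dtype=float), metric="braycurtis"))


# ---------------------------------------------------------------------------
# NMDS (Kruskal stress-1 via SMACOF with isotonic regression)
# ---------------------------------------------------------------------------

def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = len(d)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(vals)


def _smacof_nonmetric(d, init, max_iter, tol):
    n = len(d)
    iu = np.triu_indices(n, 1)
    diss = d[iu]
    x = init.copy()
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    history = []
    converged = False
    prev = np.inf
    for it in range(1, max_iter + 1):
        dist = squareform(pdist(x))[iu]
        dhat = iso.fit_transform(diss, dist)
        denom = (dist**2).sum()
        stress = np.sqrt(((dist - dhat) ** 2).sum() / denom) if denom > 0 else 0.0
        history.append(float(stress))
        if prev - stress < tol:
            converged = True
            break
        prev = stress
        # Guttman transform with the fitted disparities
        full_dist = squareform(dist)
        full_dhat = squareform(dhat)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(full_dist > 0, full_dhat / full_dist, 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = b @ x / n
    return x, history[-1], len(history), converged, tuple(history)


def nmds(
    d,
    k: int = 2,
    n_starts: int = 8,
    max_iter: int = 300,
    seed: int = 0,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Non-metric multidimensional scaling minimising Kruskal stress-1.

    Runs one start initialised from classical MDS plus ``n_starts`` random
    starts and returns the configuration with the lowest stress. Deterministic
    for a fixed seed.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    rng = np.random.default_rng(seed)
    scale = d.max() or 1.0
    inits = [_classical_mds(d, k)]
    inits += [rng.normal(scale=scale, size=(len(d), k)) for _ in range(n_starts)]
    best = None
    for init in inits:
        x, stress, n_it, conv, hist = _smacof_nonmetric(d, init, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, n_it, conv, hist)
    x, stress, n_it, conv, hist = best
    x = x - x.mean(axis=0)
    return OrdinationResult(
        coordinates=x, stress=float(stress), n_iterations=n_it, converged=conv,
        stress_history=hist,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _pseudo_f(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    n = len(groups)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    labels = np.unique(groups)
    for g in labels:
        idx = np.where(groups == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(labels)
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def permanova(
    d,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    strata=None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA (ADONIS) on a dissimilarity matrix.

    When ``strata`` is given (e.g. subject ids in a paired design), group
    labels are permuted only within each stratum, which is the exchangeability
    unit for a crossover.
    """
    d = np.asarray(d, dtype=float)
    groups = np.asarray(groups)
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 groups with at least 2 samples each")
    d2 = d**2
    f_obs, r2 = _pseudo_f(d2, groups)
    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray(strata)
        blocks = [np.where(strata == s)[0] for s in np.unique(strata)]
    hits = 0
    for _ in range(n_perm):
        perm = groups.copy()
        if strata is None:
            perm = groups[rng.permutation(len(groups))]
        else:
            for idx in blocks:
                perm[idx] = groups[idx[rng.permutation(len(idx))]]
        f_perm, _ = _pseudo_f(d2, perm)
        if f_perm >= f_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermanovaResult(pseudo_F=float(f_obs), R2=float(r2), p_value=float(p), n_permutations=n_perm)
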