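"""Signed weighted co-occurrence network core.

Builds signed adjacencies from correlations of log-transformed relative
abundances, smooths them into topological overlap matrices (TOM), reduces two
conditions to a consensus TOM, and identifies modules of positively
co-varying OTUs from the TOM dendrogram. Modules are summarised by
eigengenes (first principal component of the member profiles).

Module identification uses a validated-cut scan: flat cuts of the
average-linkage dendrogram are scored by how many clusters pass a cohesion
test against the TOM background (mean within-cluster overlap must clearly
exceed the cluster's overlap with the rest of the network), the best cut is
kept, and modules whose eigengenes are highly correlated in every condition
are merged. Clusters that fail validation, and all leftover OTUs, are
unassigned (module id 0, "grey").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

__all__ = [
    "CooccurrenceNetwork",
    "ModuleSet",
    "ScaleFreeFit",
    "signed_adjacency",
    "connectivity",
    "scale_free_fit",
    "pick_soft_threshold",
    "tom",
    "consensus_tom",
    "detect_modules",
    "module_eigengene",
    "kme",
    "MODULE_COLORS",
]

# WGCNA-style colour names for module labels (index 0 = unassigned).
MODULE_COLORS = (
    "grey", "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
)


@dataclass
class CooccurrenceNetwork:
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    beta: int
    condition: str


@dataclass(frozen=True)
class ScaleFreeFit:
    power: int
    fit_r2_signed: float
    mean_connectivity: float


@dataclass
class ModuleSet:
    """OTU -> module assignment plus per-condition eigengenes and kME."""

    labels: pd.Series  # otu -> int, 0 = unassigned
    dendrogram: np.ndarray | None = None
    eigengenes: dict[str, pd.DataFrame] = field(default_factory=dict)
    kme: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def module_sizes(self) -> dict[int, int]:
        vc = self.labels[self.labels > 0].value_counts().sort_index()
        return {int(k): int(v) for k, v in vc.items()}

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0

    @property
    def n_unassigned(self) -> int:
        return int((self.labels == 0).sum())

    def color_names(self) -> pd.Series:
        def name(i):
            return MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i}"
        return self.labels.map(name)

    def members(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]


# ---------------------------------------------------------------------------
# Adjacency and soft threshold
# ---------------------------------------------------------------------------

def _correlation(x: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        x = np.apply_along_axis(rankdata, 0, x)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = x.std(axis=0)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance column(s); correlations set to 0")
        x = x.copy()
        x[:, zero_var] = np.nan
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(x, rowvar=False)
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    return c


def signed_adjacency(x, beta: int = 6, method: str = "pearson") -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + cor(x_i, x_j)) / 2)^beta.

    ``x`` is samples x OTUs (observations in rows). The mapping sends
    correlation -1 to 0 and +1 to 1, so only positive co-occurrence
    contributes topological weight. The diagonal is 1 by convention and is
    excluded from connectivity sums.
    """
    if beta < 1 or int(beta) != beta:
        raise ValueError("beta must be a positive integer")
    cols = x.columns if isinstance(x, pd.DataFrame) else None
    arr = np.asarray(x, dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    c = _correlation(arr, method)
    a = ((1.0 + c) / 2.0) ** int(beta)
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=cols, columns=cols) if cols is not None else pd.DataFrame(a)


def connectivity(adjacency) -> np.ndarray:
    """Per-node connectivity k_i = sum_{j != i} a_ij."""
    a = np.asarray(adjacency, dtype=float)
    return a.sum(axis=1) - np.diag(a)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of the log-log regression of the binned degree distribution.

    Returns ``(signed_r2, slope)`` where signed R^2 = -sign(slope) * R^2, so a
    decreasing p(k) (scale-free-like) scores positively. NaN when fewer than
    3 non-empty bins remain.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size == 0:
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    dk, pk = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        dk.append(k[sel].mean())
        pk.append(sel.mean())
    if len(dk) < 3:
        return float("nan"), float("nan")
    lx, ly = np.log10(dk), np.log10(pk)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = ((ly - ly.mean()) ** 2).sum()
    r2 = 1 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), float(slope)


def pick_soft_threshold(
    x_by_condition: dict[str, pd.DataFrame],
    powers=range(1, 21),
    r2_target: float = 0.8,
    method: str = "pearson",
    min_mean_connectivity: float | str = "auto",
) -> tuple[int, pd.DataFrame]:
    """Choose the smallest soft power whose scale-free fit reaches
    ``r2_target`` in every condition.

    High powers trivially improve the scale-free fit while collapsing the
    network, so candidate powers are restricted to those whose mean
    connectivity stays above ``min_mean_connectivity`` in every condition
    (``"auto"`` = max(5, n_nodes / 50)). If no candidate passes the R^2
    target, the candidate maximising the minimum-across-conditions signed
    R^2 is returned with a warning.
    """
    powers = list(powers)
    if not powers:
        raise ValueError("powers must be non-empty")
    rows = []
    n_nodes = None
    for cond, x in x_by_condition.items():
        n_nodes = np.asarray(x).shape[1]
        for p in powers:
            a = signed_adjacency(x, beta=p, method=method).to_numpy()
            k = connectivity(a)
            r2, slope = scale_free_fit(k)
            rows.append(
                {"condition": cond, "power": p, "fit_r2_signed": r2,
                 "slope": slope, "mean_connectivity": float(k.mean())}
            )
    fits = pd.DataFrame(rows)
    if min_mean_connectivity == "auto":
        min_mean_connectivity = max(5.0, n_nodes / 50.0)
    pivot = fits.pivot(index="power", columns="condition", values="fit_r2_signed")
    kmin = fits.pivot(index="power", columns="condition", values="mean_connectivity").min(axis=1)
    eligible = kmin.index[kmin >= min_mean_connectivity]
    if len(eligible) == 0:
        eligible = kmin.index
    min_r2 = pivot.loc[eligible].min(axis=1)
    passing = min_r2[min_r2 >= r2_target]
    if len(passing):
        beta = int(passing.index.min())
    else:
        beta = int(min_r2.idxmax())
        warnings.warn(
            f"no power reaches signed R^2 >= {r2_target} in all conditions "
            f"(mean connectivity floor {min_mean_connectivity:.1f}); "
            f"using power {beta} (min R^2 = {min_r2.max():.3f})"
        )
    return beta, fits


# ---------------------------------------------------------------------------
# Topological overlap
# ---------------------------------------------------------------------------

def tom(adjacency) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; TOM_ii = 1.
    """
    cols = adjacency.columns if isinstance(adjacency, pd.DataFrame) else None
    a = np.asarray(adjacency, dtype=float).copy()
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # with zero diagonal this is exactly sum over u != i, j
    t = (l + a) / (np.minimum.outer(k, k) + 1.0 - a)
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=cols, columns=cols) if cols is not None else pd.DataFrame(t)


def consensus_tom(
    tom_pl, tom_br, scale_quantile: float = 0.95
) -> pd.DataFrame:
    """Quantile-scaled element-wise minimum of two TOMs.

    The second TOM is power-transformed so that its ``scale_quantile`` matches
    the first's (removing scale differences between conditions), then the
    element-wise minimum is taken, keeping only overlap supported by both
    conditions.
    """
    cols = tom_pl.columns if isinstance(tom_pl, pd.DataFrame) else None
    t1 = np.asarray(tom_pl, dtype=float)
    t2 = np.asarray(tom_br, dtype=float)
    if t1.shape != t2.shape:
        raise ValueError("TOM matrices must have the same shape")
    off = ~np.eye(len(t1), dtype=bool)
    q1 = np.quantile(t1[off], scale_quantile)
    q2 = np.quantile(t2[off], scale_quantile)
    if 0 < q1 < 1 and 0 < q2 < 1:
        t2 = t2 ** (np.log(q1) / np.log(q2))
    cons = np.minimum(t1, t2)
    np.fill_diagonal(cons, 1.0)
    return pd.DataFrame(cons, index=cols, columns=cols) if cols is not None else pd.DataFrame(cons)


# ---------------------------------------------------------------------------
# Eigengenes
# ---------------------------------------------------------------------------

def _eigengene_vector(x: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component of column-standardised profiles.

    Returns the unit-variance eigengene (sign-oriented to correlate
    positively with the mean member profile) and the fraction of variance it
    explains.
    """
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    e = u[:, 0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    mean_profile = z.mean(axis=1)
    if np.corrcoef(e, mean_profile)[0, 1] < 0:
        e = -e
    e = e / e.std(ddof=1)
    return e, var_explained


def module_eigengene(x, labels) -> pd.DataFrame:
    """Per-module eigengenes (samples x modules, unit variance).

    ``x`` is samples x OTUs; ``labels`` maps each OTU to a module id
    (0 = unassigned, skipped). A single-member module returns that OTU's
    standardised profile with a warning.
    """
    xdf = x if isinstance(x, pd.DataFrame) else pd.DataFrame(x)
    labels = pd.Series(labels, index=xdf.columns) if not isinstance(labels, pd.Series) else labels
    cols = {}
    var_expl = {}
    for m in sorted(set(labels) - {0}):
        members = labels.index[labels == m]
        sub = xdf.loc[:, members].to_numpy(dtype=float)
        if sub.shape[1] == 1:
            warnings.warn(f"module {m} has a single member; returning its standardised profile")
            prof = sub[:, 0]
            e = (prof - prof.mean()) / prof.std(ddof=1)
            cols[f"MM{m}"] = e
            var_expl[f"MM{m}"] = 1.0
            continue
        e, ve = _eigengene_vector(sub)
        cols[f"MM{m}"] = e
        var_expl[f"MM{m}"] = ve
    out = pd.DataFrame(cols, index=xdf.index)
    out.attrs["variance_explained"] = var_expl
    return out


def kme(x, eigengenes) -> pd.DataFrame:
    """Module membership: correlation of each OTU profile with each eigengene."""
    xdf = x if isinstance(x, pd.DataFrame) else pd.DataFrame(x)
    eg = eigengenes if isinstance(eigengenes, pd.DataFrame) else pd.DataFrame(eigengenes)
    xa = xdf.to_numpy(dtype=float)
    ea = eg.to_numpy(dtype=float)
    xz = xa - xa.mean(axis=0)
    ez = ea - ea.mean(axis=0)
    xsd = xz.std(axis=0)
    esd = ez.std(axis=0)
    xsd[xsd == 0] = np.nan
    with np.errstate(invalid="ignore"):
        c = (xz / xsd).T @ (ez / esd) / len(xa)
    return pd.DataFrame(np.clip(np.nan_to_num(c), -1, 1), index=xdf.columns, columns=eg.columns)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def _validated_clusters(t, cl, min_size, cohesion_ratio, margin, bg):
    """Clusters of ``cl`` passing the size and TOM-cohesion tests."""
    n = len(t)
    mods = []
    for c in np.unique(cl):
        idx = np.where(cl == c)[0]
        if len(idx) < min_size:
            continue
        sub = t[np.ix_(idx, idx)]
        within = sub[~np.eye(len(idx), dtype=bool)].mean()
        rest = np.setdiff1d(np.arange(n), idx)
        between = t[np.ix_(idx, rest)].mean() if len(rest) else 0.0
        if within >= cohesion_ratio * between and within >= bg + margin:
            mods.append(idx)
    return mods


def _merge_by_eigengene(mods, x_by_condition, merge_height):
    """Iteratively merge the most-correlated module pair (consensus across
    conditions) while the smallest cross-condition eigengene correlation
    exceeds 1 - merge_height."""
    mods = [list(m) for m in mods]
    while len(mods) > 1:
        egs = []
        for x in x_by_condition.values():
            arr = np.asarray(x, dtype=float)
            egs.append(np.column_stack([_eigengene_vector(arr[:, m])[0] for m in mods]))
        best = None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                c = min(float(np.corrcoef(e[:, i], e[:, j])[0, 1]) for e in egs)
                if c > 1 - merge_height and (best is None or c > best[0]):
                    best = (c, i, j)
        if best is None:
            break
        _, i, j = best
        mods[i] = mods[i] + mods[j]
        del mods[j]
    return mods


def detect_modules(
    tom_matrix,
    x_by_condition: dict[str, pd.DataFrame] | None = None,
    min_module_size: int = 20,
    deep_split: int = 2,
    merge_height: float = 0.25,
    cut_grid: int = 50,
    cohesion_margin: float = 0.02,
) -> ModuleSet:
    """Identify modules from a TOM by a validated-cut scan of the dendrogram.

    Average-linkage clustering is run on dissimilarity 1 - TOM. Flat cuts over
    a grid of merge-height quantiles are scored by the number (then total
    size) of clusters that pass a cohesion validation: mean within-cluster
    TOM at least ``cohesion_ratio`` times the cluster-to-rest TOM and above
    the network background. ``deep_split`` (0..4) maps to the cohesion ratio
    3 - 0.5 * deep_split, so larger values admit more, weaker modules. When
    ``x_by_condition`` is provided, modules whose eigengenes correlate above
    1 - merge_height in every condition are merged, and per-condition
    eigengenes and kME tables are attached to the result. Detection is fully
    deterministic.
    """
    if min_module_size < 3:
        raise ValueError("min_module_size must be at least 3")
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    cohesion_ratio = 3.0 - 0.5 * deep_split
    cols = tom_matrix.columns if isinstance(tom_matrix, pd.DataFrame) else None
    t = np.asarray(tom_matrix, dtype=float)
    n = len(t)
    d = 1.0 - t
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    off = ~np.eye(n, dtype=bool)
    bg = float(np.median(t[off]))
    heights = z[:, 2]
    grid = np.unique(np.quantile(heights, np.linspace(0.30, 0.999, cut_grid)))
    best_score, best_mods = (-1, -1), []
    for h in grid:
        cl = fcluster(z, t=h, criterion="distance")
        mods = _validated_clusters(t, cl, min_module_size, cohesion_ratio, cohesion_margin, bg)
        score = (len(mods), sum(len(m) for m in mods))
        if score > best_score:
            best_score, best_mods = score, mods
    if x_by_condition and merge_height > 0 and len(best_mods) > 1:
        best_mods = _merge_by_eigengene(best_mods, x_by_condition, merge_height)
    labels_arr = np.zeros(n, dtype=int)
    for i, idx in enumerate(sorted(best_mods, key=len, reverse=True), start=1):
        labels_arr[np.asarray(idx)] = i
    labels = pd.Series(labels_arr, index=cols if cols is not None else range(n), name="module")
    modules = ModuleSet(labels=labels, dendrogram=z)
    if x_by_condition and labels.max() > 0:
        for cond, x in x_by_condition.items():
            eg = module_eigengene(x, labels)
            modules.eigengenes[cond] = eg
            modules.kme[cond] = kme(x, eg)
    return modules
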