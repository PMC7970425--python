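"""Module eigengene / host trait correlation networks and their cross-condition
consensus.

The consensus screen is the stability filter of the analysis: a module-trait
relationship is retained only when it has the same sign in both dietary
conditions, its consensus magnitude is the weaker of the two, and its
consensus p-value is the larger of the two. Baseline-only traits (measured
once, e.g. ACE-III cognitive subscores) are analysed as part of the placebo
network only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import TraitTable
from .diffabund import bh_adjust


@dataclass
class ModuleTraitNetwork:
    r: pd.DataFrame  # module x trait
    p: pd.DataFrame
    n: pd.DataFrame  # complete pairs per cell
    condition: str   # "PL", "BR" or "consensus"


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 4:
        return np.nan, np.nan, n
    r = float(np.corrcoef(x[mask], y[mask])[0, 1])
    if np.isnan(r):
        return np.nan, np.nan, n
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return r, p, n


def eigengene_trait_correlation(
    eigengenes: pd.DataFrame,
    traits: TraitTable,
    condition: str,
    include_baseline: bool | None = None,
) -> ModuleTraitNetwork:
    """Pearson r and two-sided Student p per (module, trait).

    ``eigengenes`` is samples x modules with the subject id as index; trait
    values are aligned on subjects and handled pairwise-complete. Cells with
    fewer than 4 complete pairs are set missing with a warning. Baseline-only
    traits are appended when ``condition == 'PL'`` (overridable).
    """
    if include_baseline is None:
        include_baseline = condition == "PL"
    tr = traits.values[condition].copy()
    if include_baseline and len(traits.baseline.columns):
        tr = tr.join(traits.baseline, how="left")
    common = [s for s in eigengenes.index if s in tr.index]
    if not common:
        raise ValueError("no subjects shared between eigengenes and traits")
    eg = eigengenes.loc[common]
    tr = tr.loc[common]
    r = pd.DataFrame(index=eg.columns, columns=tr.columns, dtype=float)
    p = r.copy()
    n = r.copy()
    sparse_cells = 0
    for m in eg.columns:
        ev = eg[m].to_numpy(dtype=float)
        for t in tr.columns:
            rv, pv, nv = _pearson_with_p(ev, tr[t].to_numpy(dtype=float))
            if nv < 4:
                sparse_cells += 1
            r.loc[m, t], p.loc[m, t], n.loc[m, t] = rv, pv, nv
    if sparse_cells:
        warnings.warn(f"{sparse_cells} module-trait cell(s) with < 4 complete pairs set missing")
    return ModuleTraitNetwork(r=r, p=p, n=n, condition=condition)


def consensus_correlation(
    net_pl: ModuleTraitNetwork, net_br: ModuleTraitNetwork
) -> ModuleTraitNetwork:
    """Cross-condition consensus of two module-trait networks.

    Concordant signs: consensus r = sign * min(|r_PL|, |r_BR|), consensus
    p = max(p_PL, p_BR). Discordant signs: r = 0, p = 1. Traits present in
    only one network (e.g. baseline-only traits) are dropped.
    """
    common_traits = [t for t in net_pl.r.columns if t in net_br.r.columns]
    if list(net_pl.r.index) != list(net_br.r.index):
        raise ValueError("module sets differ between conditions")
    r1 = net_pl.r[common_traits].to_numpy(dtype=float)
    r2 = net_br.r[common_traits].to_numpy(dtype=float)
    p1 = net_pl.p[common_traits].to_numpy(dtype=float)
    p2 = net_br.p[common_traits].to_numpy(dtype=float)
    concordant = np.sign(r1) == np.sign(r2)
    mag = np.minimum(np.abs(r1), np.abs(r2))
    r = np.where(concordant, np.sign(r1) * mag, 0.0)
    p = np.where(concordant, np.maximum(p1, p2), 1.0)
    missing = np.isnan(r1) | np.isnan(r2)
    r[missing] = np.nan
    p[missing] = np.nan
    n = np.minimum(
        net_pl.n[common_traits].to_numpy(dtype=float),
        net_br.n[common_traits].to_numpy(dtype=float),
    )
    idx = net_pl.r.index
    return ModuleTraitNetwork(
        r=pd.DataFrame(r, index=idx, columns=common_traits),
        p=pd.DataFrame(p, index=idx, columns=common_traits),
        n=pd.DataFrame(n, index=idx, columns=common_traits),
        condition="consensus",
    )


def significant_cells(
    net: ModuleTraitNetwork, alpha: float = 0.05, bh: bool = False
) -> pd.DataFrame:
    """Cells with p <= alpha, sorted by |r| descending.

    ``bh=True`` applies Benjamini-Hochberg across all non-missing cells first
    (off by default: the analysis reports raw per-cell p-values).
    """
    long = (
        net.p.stack(future_stack=True)
        .rename("p")
        .to_frame()
        .join(net.r.stack(future_stack=True).rename("r"))
        .join(net.n.stack(future_stack=True).rename("n"))
        .dropna(subset=["p"])
    )
    long.index.names = ["module", "trait"]
    if bh and len(long):
        long["p"] = bh_adjust(long["p"].to_numpy())
    hits = long[long["p"] <= alpha].copy()
    hits["abs_r"] = hits["r"].abs()
    hits = hits.sort_values("abs_r", ascending=False).drop(columns="abs_r")
    return hits.reset_index()


def network_to_long(net: ModuleTraitNetwork) -> pd.DataFrame:
    """Heatmap-ready long format: module, trait, r, p, n."""
    out = (
        net.r.stack(future_stack=True).rename("r").to_frame()
        .join(net.p.stack(future_stack=True).rename("p"))
        .join(net.n.stack(future_stack=True).rename("n"))
    )
    out.index.names = ["module", "trait"]
    out = out.reset_index()
    out.insert(0, "condition", net.condition)
    return out
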