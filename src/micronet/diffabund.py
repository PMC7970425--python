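"""Paired differential abundance testing with BH correction and percent-change
reporting.

Tests operate on relative abundances. Taxa below a prevalence threshold
(default: mean relative abundance across all samples must exceed 0.01%) are
excluded from testing but kept in the report with ``tested = False``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CONDITIONS, TAXONOMIC_RANKS, RelAbundanceTable


def prevalence_threshold(
    rel: RelAbundanceTable | pd.DataFrame, min_frac_of_total: float = 1e-4
) -> pd.Index:
    """Taxa whose mean relative abundance across all samples strictly exceeds
    ``min_frac_of_total``."""
    frac = rel.fractions if isinstance(rel, RelAbundanceTable) else rel
    mean = frac.mean(axis=1)
    return frac.index[mean > min_frac_of_total]


def paired_t(x_pl, x_br) -> tuple[float, float]:
    """Two-sided paired t-test on per-subject differences.

    Degenerate inputs are resolved by the limit of the statistic: all-zero
    differences give (0, 1); zero-variance differences with a non-zero mean
    give p = 0 with a warning.
    """
    x_pl = np.asarray(x_pl, dtype=float)
    x_br = np.asarray(x_br, dtype=float)
    if x_pl.shape != x_br.shape or x_pl.size < 3:
        raise ValueError("paired vectors must have equal length >= 3")
    d = x_br - x_pl
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        warnings.warn("zero-variance differences with non-zero mean: degenerate p = 0")
        return float(np.sign(d.mean()) * np.inf), 0.0
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return float(t), float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def percent_change(mean_pl: float, mean_br: float) -> float:
    """Percent change from PL to BR: 100 (BR - PL) / PL; NaN when PL is zero."""
    if mean_pl == 0:
        return float("nan")
    return 100.0 * (mean_br - mean_pl) / mean_pl


def rollup_by_rank(rel: RelAbundanceTable, rank: str) -> pd.DataFrame:
    """Sum fractions within each lineage prefix truncated at ``rank``.

    Taxonomy strings are semicolon-delimited, ordered kingdom..species.
    """
    if rank not in TAXONOMIC_RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    tax = rel.taxonomy
    if tax is None:
        raise ValueError("relative abundance table has no taxonomy attached")
    depth = TAXONOMIC_RANKS.index(rank) + 1
    keys = tax.str.split(";").str[:depth].str.join(";")
    return rel.fractions.groupby(keys).sum()


def differential_abundance(
    rel: RelAbundanceTable,
    rank: str | None = None,
    alpha: float = 0.05,
    min_frac_of_total: float = 1e-4,
    log_scale: bool = True,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Table-2-style paired differential abundance report.

    One row per taxon (OTU, or lineage rollup when ``rank`` is given) with
    per-condition mean relative abundance, percent change, paired-t statistics
    and BH q-values over the tested taxa. Because condition effects on
    relative abundances are multiplicative and abundances are roughly
    log-normal across subjects, the paired t-test is computed on
    log10(fraction + pseudocount) by default (``log_scale=False`` tests raw
    fractions); means and percent change are always reported on the raw
    fraction scale.
    """
    if rank is None:
        frac = rel.fractions
    else:
        frac = rollup_by_rank(rel, rank)
    meta = rel.sample_meta
    per_cond = {}
    for cond in CONDITIONS:
        cols = meta.index[meta["condition"] == cond]
        sub = frac.loc[:, cols]
        sub.columns = meta.loc[cols, "subject_id"]
        per_cond[cond] = sub
    subjects = [s for s in per_cond["PL"].columns if s in per_cond["BR"].columns]
    pl = per_cond["PL"].loc[:, subjects]
    br = per_cond["BR"].loc[:, subjects]
    if log_scale:
        arr = frac.to_numpy()
        nz = arr[arr > 0]
        pc = (float(nz.min()) / 2.0) if pseudocount is None else pseudocount
        pl_t, br_t = np.log10(pl + pc), np.log10(br + pc)
    else:
        pl_t, br_t = pl, br

    tested_idx = prevalence_threshold(frac, min_frac_of_total)
    rows = []
    for taxon in frac.index:
        mean_pl = float(pl.loc[taxon].mean())
        mean_br = float(br.loc[taxon].mean())
        tested = taxon in tested_idx
        if tested:
            t, p = paired_t(pl_t.loc[taxon], br_t.loc[taxon])
        else:
            t, p = np.nan, np.nan
        rows.append(
            {
                "taxon": taxon,
                "mean_PL": mean_pl,
                "mean_BR": mean_br,
                "percent_change": percent_change(mean_pl, mean_br),
                "t_statistic": t,
                "p_raw": p,
                "tested": tested,
            }
        )
    out = pd.DataFrame(rows).set_index("taxon")
    out["q_bh"] = np.nan
    mask = out["tested"]
    if mask.any():
        out.loc[mask, "q_bh"] = bh_adjust(out.loc[mask, "p_raw"].to_numpy())
    out["significant"] = out["q_bh"] <= alpha
    return out
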