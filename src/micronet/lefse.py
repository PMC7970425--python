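"""Per-module biomarker screening with Kruskal-Wallis + LDA effect size.

This is the two-class (PL vs BR) LDA-effect-size procedure: features are
first screened by a Kruskal-Wallis rank test, surviving features receive an
effect size from bootstrapped linear discriminant analysis combined with the
raw between-class difference, reported on a log10 scale after scaling
abundances to parts-per-million. Features with |log10 effect| at or above the
threshold (default 2) and a significant KW p are the module drivers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

PER_MILLION = 1e6


@dataclass
class LefseResult:
    table: pd.DataFrame  # columns: module, feature, kw_p, lda_effect, enriched_class, passes
    threshold: float
    alpha: float


def kruskal_wallis(values, classes) -> float:
    """Tie-corrected Kruskal-Wallis p-value across >= 2 classes."""
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    labels = np.unique(classes)
    if len(labels) < 2:
        raise ValueError("need at least 2 classes")
    groups = [values[classes == g] for g in labels]
    if min(len(g) for g in groups) < 2:
        raise ValueError("each class needs at least 2 observations")
    if np.all(values == values[0]):
        return 1.0  # constant feature: H = 0
    try:
        return float(stats.kruskal(*groups).pvalue)
    except ValueError:
        # identical values within the test's tolerance
        return 1.0


def _subsample_indices(rng, classes, frac, max_retries=20):
    """Per-class subsample (without replacement) keeping every class present."""
    classes = np.asarray(classes)
    for _ in range(max_retries):
        idx = []
        for g in np.unique(classes):
            members = np.where(classes == g)[0]
            take = max(2, int(np.ceil(frac * len(members))))
            take = min(take, len(members))
            idx.append(rng.choice(members, size=take, replace=False))
        idx = np.concatenate(idx)
        if len(np.unique(classes[idx])) == len(np.unique(classes)):
            return idx
    raise RuntimeError("could not draw a subsample containing every class")


def lda_effect_size(
    x,
    classes,
    n_boot: int = 30,
    subsample_frac: float = 2.0 / 3.0,
    seed: int = 0,
    positive_class=None,
) -> pd.DataFrame:
    """Bootstrapped LDA effect sizes for a samples x features matrix.

    Features are scaled to parts-per-million (the conventional scale putting
    log10 effects in the familiar 2-6 range). Per bootstrap, a linear
    discriminant is fitted on a per-class 2/3 subsample; a feature's effect is
    the average of (a) its share of the class separation along the
    discriminant axis and (b) the raw class-mean difference. The reported
    ``lda_effect`` is log10 of the bootstrap-mean effect, signed by the
    enriched class: positive when the feature is enriched in
    ``positive_class`` (default ``"BR"`` when present), negative otherwise.
    ``enriched_class`` carries the explicit label.
    """
    cols = x.columns if isinstance(x, pd.DataFrame) else None
    arr = np.asarray(x, dtype=float)
    classes = np.asarray(classes)
    labels = np.unique(classes)
    if len(labels) != 2:
        raise ValueError("lda_effect_size supports exactly 2 classes")
    arr = arr * PER_MILLION
    rng = np.random.default_rng(seed)
    n_feat = arr.shape[1]
    effects = np.zeros(n_feat)
    n_ok = 0
    for _ in range(n_boot):
        idx = _subsample_indices(rng, classes, subsample_frac)
        xb, yb = arr[idx], classes[idx]
        means = {g: xb[yb == g].mean(axis=0) for g in labels}
        raw_diff = np.abs(means[labels[0]] - means[labels[1]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lda = LinearDiscriminantAnalysis(solver="svd")
                lda.fit(xb, yb)
            w = lda.scalings_[:, 0]
            norm = np.linalg.norm(w)
            if norm == 0 or not np.isfinite(norm):
                raise np.linalg.LinAlgError
            w_unit = w / norm
            proj = xb @ w_unit
            delta_proj = abs(proj[yb == labels[0]].mean() - proj[yb == labels[1]].mean())
            lda_part = np.abs(w_unit) * delta_proj
        except (np.linalg.LinAlgError, ValueError, IndexError):
            lda_part = raw_diff  # fall back to raw differences for this draw
        effects += (lda_part + raw_diff) / 2.0
        n_ok += 1
    effects /= max(n_ok, 1)
    full_means = {g: arr[classes == g].mean(axis=0) for g in labels}
    enriched = np.where(full_means[labels[1]] >= full_means[labels[0]], labels[1], labels[0])
    if positive_class is None:
        positive_class = "BR" if "BR" in labels else labels[-1]
    sign = np.where(enriched == positive_class, 1.0, -1.0)
    # effects below 1 ppm are below the resolution of the score scale; clamp
    # to log10 = 0 so the magnitude is monotone in the effect.
    score = sign * np.log10(np.maximum(effects, 1.0))
    out = pd.DataFrame(
        {
            "lda_effect": score,
            "enriched_class": enriched,
            "mean_" + str(labels[0]): full_means[labels[0]] / PER_MILLION,
            "mean_" + str(labels[1]): full_means[labels[1]] / PER_MILLION,
        },
        index=cols if cols is not None else pd.RangeIndex(n_feat),
    )
    return out


def lefse_modules(
    rel_by_sample: pd.DataFrame,
    classes,
    module_labels: pd.Series,
    alpha: float = 0.05,
    threshold: float = 2.0,
    n_boot: int = 30,
    subsample_frac: float = 2.0 / 3.0,
    seed: int = 0,
) -> LefseResult:
    """Run the KW + LDA-effect-size screen within each module.

    ``rel_by_sample`` is samples x OTUs relative abundance; ``classes`` the
    per-sample condition labels; ``module_labels`` the OTU -> module map
    (0 = unassigned, skipped).
    """
    classes = np.asarray(classes)
    rows = []
    rng = np.random.default_rng(seed)
    for m in sorted(set(module_labels) - {0}):
        members = module_labels.index[module_labels == m]
        sub = rel_by_sample.loc[:, members]
        kw_p = pd.Series(
            [kruskal_wallis(sub[c].to_numpy(), classes) for c in sub.columns],
            index=sub.columns,
        )
        survivors = kw_p.index[kw_p <= alpha]
        if len(survivors):
            eff = lda_effect_size(
                sub.loc[:, survivors],
                classes,
                n_boot=n_boot,
                subsample_frac=subsample_frac,
                seed=int(rng.integers(2**31 - 1)),
            )
        else:
            eff = pd.DataFrame(columns=["lda_effect", "enriched_class"])
        for feat in sub.columns:
            tested = feat in eff.index
            effect = float(eff.loc[feat, "lda_effect"]) if tested else np.nan
            enriched = str(eff.loc[feat, "enriched_class"]) if tested else ""
            passes = bool(tested and abs(effect) >= threshold and kw_p[feat] <= alpha)
            rows.append(
                {
                    "module": m,
                    "feature": feat,
                    "kw_p": float(kw_p[feat]),
                    "lda_effect": effect,
                    "enriched_class": enriched,
                    "passes": passes,
                }
            )
    return LefseResult(table=pd.DataFrame(rows), threshold=threshold, alpha=alpha)


def module_drivers(result: LefseResult, threshold: float | None = None) -> dict[int, pd.DataFrame]:
    """Per-module driver features with |lda_effect| >= threshold, ranked.

    Modules without any passing feature map to an empty frame.
    """
    thr = result.threshold if threshold is None else threshold
    t = result.table
    out: dict[int, pd.DataFrame] = {}
    for m in sorted(t["module"].unique()):
        sub = t[(t["module"] == m) & (t["kw_p"] <= result.alpha)].copy()
        sub = sub[sub["lda_effect"].abs() >= thr]
        sub["abs_effect"] = sub["lda_effect"].abs()
        out[int(m)] = (
            sub.sort_values("abs_effect", ascending=False)
            .drop(columns="abs_effect")
            .reset_index(drop=True)
        )
    return out
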