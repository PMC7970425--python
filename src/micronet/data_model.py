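"""Core data containers and I/O for paired microbiome count and host-trait tables.

The study design throughout the package is a two-condition crossover: every
subject contributes one sample under a placebo condition (``PL``) and one under
a nitrate-rich condition (``BR``). Sample identifiers encode this pairing as
``<subject>_<condition>`` (e.g. ``S07_PL``).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The two dietary conditions of the crossover design.
CONDITIONS = ("PL", "BR")

#: Molar mass of the nitrate anion (g/mol), used for mg -> mmol conversion.
NITRATE_MOLAR_MASS_G_PER_MOL = 62.004

TAXONOMIC_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class FormatError(ValueError):
    """Raised when an input table violates the expected on-disk format."""


def split_sample_id(sample_id: str) -> tuple[str, str]:
    """Split ``<subject>_<condition>`` into its parts.

    The condition is the trailing token after the last underscore and must be
    one of :data:`CONDITIONS`.
    """
    subject, _, condition = str(sample_id).rpartition("_")
    if not subject or condition not in CONDITIONS:
        raise FormatError(
            f"sample id {sample_id!r} does not match '<subject>_<PL|BR>'"
        )
    return subject, condition


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for the two-stage rare-OTU filter."""

    n_input_otus: int
    n_removed_rule1: int
    n_removed_rule2: int
    n_removed_samples: int
    surviving_otu_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_input_otus != (
            len(self.surviving_otu_ids) + self.n_removed_rule1 + self.n_removed_rule2
        ):
            raise ValueError("filter report does not account for every OTU exactly once")


@dataclass
class OtuTable:
    """Paired OTU counts with taxonomy.

    Parameters
    ----------
    counts
        Non-negative integer matrix, rows = OTUs, columns = samples named
        ``<subject>_<condition>``.
    taxonomy
        Per-OTU semicolon-delimited lineage string, indexed like ``counts``.

    Subjects that are present in only one condition are dropped at
    construction (with a logged warning); the count of removed sample columns
    is kept in :attr:`n_dropped_samples`.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    n_dropped_samples: int = 0

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate OTU ids: {dupes}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("counts must be integers")
            c = c.round().astype(np.int64)
        if (c.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")
        # enforce paired design: subjects need both conditions exactly once
        meta = pd.DataFrame(
            [split_sample_id(s) for s in c.columns],
            index=c.columns,
            columns=["subject_id", "condition"],
        )
        ok_subjects = []
        for subj, grp in meta.groupby("subject_id", sort=False):
            if sorted(grp["condition"]) == sorted(CONDITIONS):
                ok_subjects.append(subj)
            else:
                logger.warning(
                    "dropping subject %s: present in %s only",
                    subj,
                    list(grp["condition"]),
                )
        keep = meta["subject_id"].isin(ok_subjects)
        self.n_dropped_samples += int((~keep).sum())
        c = c.loc[:, keep[keep].index]
        if c.shape[1] < 2:
            raise FormatError("need at least one complete subject (2 sample columns)")
        self.counts = c
        self.taxonomy = self.taxonomy.reindex(c.index)

    # -- convenience views ------------------------------------------------
    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_meta(self) -> pd.DataFrame:
        """Per-sample (subject_id, condition) frame, indexed by sample id."""
        return pd.DataFrame(
            [split_sample_id(s) for s in self.counts.columns],
            index=self.counts.columns,
            columns=["subject_id", "condition"],
        )

    @property
    def subjects(self) -> list[str]:
        meta = self.sample_meta
        return list(dict.fromkeys(meta["subject_id"]))

    def samples_for(self, condition: str) -> pd.DataFrame:
        """Counts restricted to one condition, columns reindexed to subjects."""
        meta = self.sample_meta
        cols = meta.index[meta["condition"] == condition]
        sub = self.counts.loc[:, cols]
        sub.columns = meta.loc[cols, "subject_id"]
        return sub.loc[:, self.subjects]


@dataclass
class RelAbundanceTable:
    """Column-normalised relative abundances derived from an :class:`OtuTable`."""

    fractions: pd.DataFrame
    derived_from: OtuTable | None = None

    def __post_init__(self) -> None:
        sums = self.fractions.sum(axis=0)
        if not np.allclose(sums.to_numpy(), 1.0, atol=1e-9):
            raise ValueError("relative abundance columns must sum to 1")

    @property
    def sample_meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            [split_sample_id(s) for s in self.fractions.columns],
            index=self.fractions.columns,
            columns=["subject_id", "condition"],
        )

    @property
    def taxonomy(self) -> pd.Series | None:
        return self.derived_from.taxonomy if self.derived_from is not None else None

    def condition_frame(self, condition: str) -> pd.DataFrame:
        meta = self.sample_meta
        cols = meta.index[meta["condition"] == condition]
        sub = self.fractions.loc[:, cols]
        sub.columns = meta.loc[cols, "subject_id"]
        return sub


@dataclass
class TraitTable:
    """Host traits measured per subject.

    ``values`` maps each condition to a subject x trait frame (the same traits
    in both conditions); ``baseline`` holds traits measured once at baseline
    (the ACE-III cognitive subscores), which downstream analysis attaches to
    the placebo network only. Missing values are NaN.
    """

    values: dict[str, pd.DataFrame]
    baseline: pd.DataFrame = field(default_factory=pd.DataFrame)
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond in self.values:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
        traits = {cond: tuple(df.columns) for cond, df in self.values.items()}
        if len(set(traits.values())) > 1:
            raise ValueError("trait columns differ between conditions")
        n_traits = len(next(iter(self.values.values())).columns) if self.values else 0
        if n_traits > 32:
            raise ValueError("at most 32 traits per condition are supported")

    @property
    def subjects(self) -> pd.Index:
        return next(iter(self.values.values())).index

    @property
    def trait_names(self) -> list[str]:
        return list(next(iter(self.values.values())).columns)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(path, format: str = "tsv") -> OtuTable:
    """Read an OTU count table.

    ``tsv``: first column ``otu_id``, last column ``taxonomy``, remaining
    columns one sample each. ``biom-json``: BIOM v1.0 JSON, read-only; the
    per-row ``taxonomy`` metadata (string or list of ranks) is used if present.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        if df.columns[0] != "otu_id" or df.columns[-1] != "taxonomy":
            raise FormatError("expected first column 'otu_id' and last column 'taxonomy'")
        df = df.set_index("otu_id")
        taxonomy = df.pop("taxonomy").astype(str)
        counts = df
        try:
            counts = counts.astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-integer count in {path}: {exc}") from exc
        return OtuTable(counts=counts, taxonomy=taxonomy)
    if format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mat = np.zeros(shape)
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
        else:
            mat = np.asarray(doc["data"], dtype=float)
        tax = []
        for r in doc["rows"]:
            md = r.get("metadata") or {}
            t = md.get("taxonomy", "")
            tax.append(";".join(t) if isinstance(t, (list, tuple)) else str(t))
        counts = pd.DataFrame(mat, index=pd.Index(otu_ids, name="otu_id"), columns=sample_ids)
        return OtuTable(counts=counts, taxonomy=pd.Series(tax, index=counts.index))
    raise ValueError(f"unknown format {format!r}")


def write_otu_table(table: OtuTable, path) -> None:
    out = table.counts.copy()
    out.insert(len(out.columns), "taxonomy", table.taxonomy)
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")


def read_trait_table(path) -> TraitTable:
    """Read a wide trait TSV with columns ``trait@PL`` / ``trait@BR`` / ``trait@BASE``."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}).set_index("subject_id")
    per_cond: dict[str, dict[str, pd.Series]] = {c: {} for c in CONDITIONS}
    baseline: dict[str, pd.Series] = {}
    for col in df.columns:
        name, _, tag = col.rpartition("@")
        if not name:
            raise FormatError(f"trait column {col!r} lacks '@PL/@BR/@BASE' suffix")
        if tag == "BASE":
            baseline[name] = df[col].astype(float)
        elif tag in CONDITIONS:
            per_cond[tag][name] = df[col].astype(float)
        else:
            raise FormatError(f"unknown condition tag in column {col!r}")
    values = {c: pd.DataFrame(cols) for c, cols in per_cond.items() if cols}
    return TraitTable(values=values, baseline=pd.DataFrame(baseline))


def write_trait_table(traits: TraitTable, path) -> None:
    frames = []
    for cond, df in traits.values.items():
        renamed = df.rename(columns={c: f"{c}@{cond}" for c in df.columns})
        frames.append(renamed)
    if len(traits.baseline.columns):
        frames.append(traits.baseline.rename(columns={c: f"{c}@BASE" for c in traits.baseline.columns}))
    out = pd.concat(frames, axis=1)
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Filtering and transforms
# ---------------------------------------------------------------------------

def filter_rare_otus(
    table: OtuTable,
    min_count_everywhere: int = 10,
    min_count_prevalence: int = 5,
    prevalence_frac: float = 0.5,
) -> tuple[OtuTable, FilterReport]:
    """Apply the two-stage rare-OTU filter.

    Rule 1 removes an OTU iff its count is below ``min_count_everywhere`` in
    *every* sample of both conditions. Rule 2 then removes an OTU iff its
    count is below ``min_count_prevalence`` in at least ``prevalence_frac`` of
    the samples. Rules are applied sequentially, so each removed OTU is
    attributed to exactly one rule. Filtering is idempotent.
    """
    counts = table.counts
    rule1 = counts.max(axis=1) < min_count_everywhere
    frac_low = (counts < min_count_prevalence).mean(axis=1)
    rule2 = (frac_low >= prevalence_frac) & ~rule1
    keep = ~(rule1 | rule2)
    if not keep.any():
        raise ValueError("all OTUs filtered")
    filtered = OtuTable(
        counts=counts.loc[keep].copy(),
        taxonomy=table.taxonomy.loc[keep].copy(),
        n_dropped_samples=table.n_dropped_samples,
    )
    report = FilterReport(
        n_input_otus=len(counts),
        n_removed_rule1=int(rule1.sum()),
        n_removed_rule2=int(rule2.sum()),
        n_removed_samples=table.n_dropped_samples,
        surviving_otu_ids=tuple(counts.index[keep]),
    )
    return filtered, report


def to_relative_abundance(table: OtuTable) -> RelAbundanceTable:
    """Column-normalise counts to fractions; an all-zero sample is an error."""
    sums = table.counts.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return RelAbundanceTable(fractions=table.counts / sums, derived_from=table)


def transform_for_network(
    rel: RelAbundanceTable, pseudocount: float | None = None
) -> pd.DataFrame:
    """log10(fraction + pseudocount), transposed to samples x OTUs.

    The default pseudocount is half the smallest non-zero fraction in the
    table. Zero-variance OTU columns are flagged via a warning and listed in
    ``result.attrs['zero_variance_otus']``.
    """
    frac = rel.fractions.to_numpy()
    if pseudocount is None:
        nz = frac[frac > 0]
        if nz.size == 0:
            raise ValueError("table contains no non-zero fraction")
        pseudocount = float(nz.min()) / 2.0
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = pd.DataFrame(
        np.log10(frac + pseudocount).T,
        index=rel.fractions.columns,
        columns=rel.fractions.index,
    )
    zero_var = x.columns[x.std(axis=0, ddof=1).to_numpy() == 0].tolist()
    if zero_var:
        warnings.warn(f"{len(zero_var)} zero-variance OTU column(s): {zero_var[:5]}...")
    x.attrs["zero_variance_otus"] = zero_var
    x.attrs["pseudocount"] = pseudocount
    return x


def condition_network_inputs(
    rel: RelAbundanceTable, pseudocount: float | None = None
) -> dict[str, pd.DataFrame]:
    """Per-condition network input matrices (subjects x OTUs, log10 transformed).

    Splits the relative abundance table by condition, relabels sample columns
    by subject so the two matrices align row-wise, and applies
    :func:`transform_for_network` with a pseudocount shared across conditions
    (half the smallest non-zero fraction of the full table by default).
    """
    if pseudocount is None:
        arr = rel.fractions.to_numpy()
        nz = arr[arr > 0]
        if nz.size == 0:
            raise ValueError("table contains no non-zero fraction")
        pseudocount = float(nz.min()) / 2.0
    out = {}
    for cond in CONDITIONS:
        sub = rel.condition_frame(cond)
        cond_rel = RelAbundanceTable(fractions=sub, derived_from=rel.derived_from)
        out[cond] = transform_for_network(cond_rel, pseudocount=pseudocount)
    return out


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report display convention)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def compute_relative_dose(dose_mg_per_day: float, body_mass_kg: float) -> float:
    """Daily nitrate dose relative to body mass, in mmol/kg/day.

    ``dose_mg / 62.004`` converts milligrams of nitrate to millimoles.
    """
    if body_mass_kg <= 0:
        raise ValueError("body mass must be positive")
    return (dose_mg_per_day / NITRATE_MOLAR_MASS_G_PER_MOL) / body_mass_kg
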