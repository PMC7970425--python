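"""End-to-end orchestration: configuration, seeded stage execution, and the
report bundle (module table, driver table, consensus heatmap data, manifest).

Every stage output is a pure function of (inputs, config, seed); reruns with
the same manifest produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conetwork, diffabund, diversity, lefse, module_traits, synthdata
from .data_model import (
    CONDITIONS,
    OtuTable,
    TraitTable,
    condition_network_inputs,
    filter_rare_otus,
    read_otu_table,
    read_trait_table,
    to_relative_abundance,
)

logger = logging.getLogger("micronet")

FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All knobs of a pipeline run, serialisable to/from YAML."""

    otu_table: str = ""
    trait_table: str = ""
    output_dir: str = "micronet_out"
    seed: int = 0
    # filtering
    min_count_everywhere: int = 10
    min_count_prevalence: int = 5
    prevalence_frac: float = 0.5
    # transform
    pseudocount: float | None = None
    # diversity
    nmds_k: int = 2
    n_permutations: int = 999
    # differential abundance
    diffabund_rank: str | None = "species"
    min_frac_of_total: float = 1e-4
    alpha: float = 0.05
    # network
    powers: tuple[int, ...] = tuple(range(1, 21))
    r2_target: float = 0.8
    correlation: str = "pearson"
    min_module_size: int = 20
    deep_split: int = 2
    merge_height: float = 0.25
    scale_quantile: float = 0.95
    write_tom: bool = False
    # lefse
    lda_threshold: float = 2.0
    n_boot: int = 30
    subsample_frac: float = 2.0 / 3.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "powers" in raw:
            raw["powers"] = tuple(raw["powers"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["powers"] = list(self.powers)
        return d


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(
    config: RunConfig,
    otus: OtuTable | None = None,
    traits: TraitTable | None = None,
) -> dict:
    """Execute filter -> diversity -> diffabund -> network -> module-traits ->
    lefse, writing all stage TSVs plus ``manifest.json`` and ``report.md``
    into ``config.output_dir``.

    ``otus``/``traits`` may be passed in memory (e.g. straight from the
    synthetic generator); otherwise they are read from the configured paths.
    Any stage failure raises :class:`PipelineError` naming the stage; files
    already written are left in place.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict()}

    stage = "load"
    try:
        if otus is None:
            otus = read_otu_table(config.otu_table)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    try:
        stage = "filter"
        logger.info("filtering %d OTUs x %d samples", *otus.counts.shape)
        filtered, report = filter_rare_otus(
            otus,
            min_count_everywhere=config.min_count_everywhere,
            min_count_prevalence=config.min_count_prevalence,
            prevalence_frac=config.prevalence_frac,
        )
        pd.DataFrame(
            {
                "n_input_otus": [report.n_input_otus],
                "n_removed_rule1": [report.n_removed_rule1],
                "n_removed_rule2": [report.n_removed_rule2],
                "n_removed_samples": [report.n_removed_samples],
                "n_surviving": [len(report.surviving_otu_ids)],
            }
        ).to_csv(out / "filter_report.tsv", sep="\t", index=False)
        rel = to_relative_abundance(filtered)

        stage = "diversity"
        meta = filtered.sample_meta
        counts_t = filtered.counts.T  # samples x otus
        alpha_div = pd.DataFrame(
            {
                "shannon": [diversity.shannon(row) for row in counts_t.to_numpy()],
                "chao1": [diversity.chao1(row) for row in counts_t.to_numpy()],
                "richness": [diversity.richness(row) for row in counts_t.to_numpy()],
            },
            index=counts_t.index,
        ).join(meta)
        _write_tsv(alpha_div, out / "alpha_diversity.tsv")
        dmat = diversity.bray_curtis_matrix(rel.fractions.T.to_numpy())
        ord_res = diversity.nmds(dmat, k=config.nmds_k, seed=config.seed)
        coords = pd.DataFrame(
            ord_res.coordinates,
            index=counts_t.index,
            columns=[f"NMDS{i+1}" for i in range(config.nmds_k)],
        ).join(meta)
        coords.attrs["stress"] = ord_res.stress
        _write_tsv(coords, out / "nmds_coordinates.tsv")
        perm = diversity.permanova(
            dmat,
            meta["condition"].to_numpy(),
            n_perm=config.n_permutations,
            seed=config.seed,
            strata=meta["subject_id"].to_numpy(),
        )
        pd.DataFrame(
            {
                "pseudo_F": [perm.pseudo_F], "R2": [perm.R2],
                "p_value": [perm.p_value], "n_permutations": [perm.n_permutations],
                "nmds_stress": [ord_res.stress],
            }
        ).to_csv(out / "permanova.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

        stage = "diffabund"
        da = diffabund.differential_abundance(
            rel,
            rank=config.diffabund_rank,
            alpha=config.alpha,
            min_frac_of_total=config.min_frac_of_total,
        )
        _write_tsv(da, out / "differential_abundance.tsv")

        stage = "network"
        x_by_cond = condition_network_inputs(rel, pseudocount=config.pseudocount)
        beta, fits = conetwork.pick_soft_threshold(
            x_by_cond, powers=config.powers, r2_target=config.r2_target,
            method=config.correlation,
        )
        _write_tsv(fits, out / "scale_free_fit.tsv", index=False)
        toms = {}
        for cond, x in x_by_cond.items():
            adj = conetwork.signed_adjacency(x, beta=beta, method=config.correlation)
            toms[cond] = conetwork.tom(adj)
            if config.write_tom:
                np.save(out / f"tom_{cond}.npy", toms[cond].to_numpy())
                _write_tsv(toms[cond], out / f"tom_{cond}.tsv")
        cons = conetwork.consensus_tom(
            toms["PL"], toms["BR"], scale_quantile=config.scale_quantile
        )
        if config.write_tom:
            np.save(out / "tom_consensus.npy", cons.to_numpy())
            _write_tsv(cons, out / "tom_consensus.tsv")
        modules = conetwork.detect_modules(
            cons,
            x_by_condition=x_by_cond,
            min_module_size=config.min_module_size,
            deep_split=config.deep_split,
            merge_height=config.merge_height,
        )
        module_table = pd.DataFrame(
            {"module": modules.labels, "color": modules.color_names()}
        )
        for cond in CONDITIONS:
            if cond in modules.kme:
                km = modules.kme[cond]
                own = [
                    km.loc[o, f"MM{m}"] if m > 0 and f"MM{m}" in km.columns else np.nan
                    for o, m in modules.labels.items()
                ]
                module_table[f"kme_{cond}"] = own
        module_table["taxonomy"] = filtered.taxonomy
        _write_tsv(module_table, out / "modules.tsv")
        for cond, eg in modules.eigengenes.items():
            _write_tsv(eg, out / f"eigengenes_{cond}.tsv")
        summary["beta"] = beta
        summary["n_modules"] = modules.n_modules
        summary["n_unassigned"] = modules.n_unassigned
        summary["module_sizes"] = modules.module_sizes

        stage = "module_traits"
        nets = {}
        consensus = None
        if traits is None and config.trait_table:
            traits = read_trait_table(config.trait_table)
        if traits is not None and modules.n_modules > 0:
            for cond in CONDITIONS:
                nets[cond] = module_traits.eigengene_trait_correlation(
                    modules.eigengenes[cond], traits, condition=cond
                )
                _write_tsv(
                    module_traits.network_to_long(nets[cond]),
                    out / f"module_traits_{cond}.tsv",
                    index=False,
                )
            consensus = module_traits.consensus_correlation(nets["PL"], nets["BR"])
            _write_tsv(
                module_traits.network_to_long(consensus),
                out / "module_traits_consensus.tsv",
                index=False,
            )
            sig = module_traits.significant_cells(consensus, alpha=config.alpha)
            _write_tsv(sig, out / "consensus_significant.tsv", index=False)
            summary["n_consensus_significant"] = int(len(sig))

        stage = "lefse"
        lefse_res = None
        if modules.n_modules > 0:
            rel_by_sample = rel.fractions.T  # samples x otus
            lefse_res = lefse.lefse_modules(
                rel_by_sample,
                classes=meta["condition"].to_numpy(),
                module_labels=modules.labels,
                alpha=config.alpha,
                threshold=config.lda_threshold,
                n_boot=config.n_boot,
                subsample_frac=config.subsample_frac,
                seed=config.seed,
            )
            _write_tsv(lefse_res.table, out / "lefse.tsv", index=False)
            drivers = lefse.module_drivers(lefse_res)
            driver_rows = [df for df in drivers.values() if len(df)]
            driver_table = (
                pd.concat(driver_rows, ignore_index=True)
                if driver_rows
                else lefse_res.table.iloc[0:0]
            )
            _write_tsv(driver_table, out / "module_drivers.tsv", index=False)
            summary["n_drivers"] = int(len(driver_table))

        stage = "report"
        _write_report(out, summary, modules, consensus, lefse_res, perm, ord_res, da, config)
        manifest = {
            "config": config.to_dict(),
            "versions": _versions(),
            "checksums": {
                p.name: _sha256(p)
                for p in sorted(out.iterdir())
                if p.suffix in {".tsv", ".md"} and p.name != "manifest.json"
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    summary["output_dir"] = str(out)
    return summary


def _versions() -> dict:
    import scipy
    import sklearn

    from . import __version__

    return {
        "micronet": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }


def _write_report(out, summary, modules, consensus, lefse_res, perm, ord_res, da, config):
    lines = ["# micronet run report", ""]
    lines += [
        "## Community comparison",
        "",
        f"- NMDS stress: {ord_res.stress:.4f}",
        f"- PERMANOVA (condition, strata = subject): pseudo-F = {perm.pseudo_F:.3f}, "
        f"R2 = {perm.R2:.3f}, p = {perm.p_value:.4g} ({perm.n_permutations} permutations)",
        "",
        "## Differential abundance",
        "",
        f"- taxa tested: {int(da['tested'].sum())} of {len(da)}",
        f"- significant at BH q <= {config.alpha}: {int(da['significant'].sum())}",
        "",
        "## Modules",
        "",
        f"- soft power: {summary.get('beta')}",
        f"- modules detected: {summary.get('n_modules')} "
        f"(sizes: {summary.get('module_sizes')}), unassigned: {summary.get('n_unassigned')}",
        "",
    ]
    if consensus is not None:
        sig = module_traits.significant_cells(consensus, alpha=config.alpha)
        lines += ["## Consensus module-trait relationships", ""]
        if len(sig):
            for _, row in sig.iterrows():
                lines.append(
                    f"- {row['module']} ~ {row['trait']}: r = {row['r']:.2f}, p = {row['p']:.3g}"
                )
        else:
            lines.append("- none at alpha")
        lines.append("")
    if lefse_res is not None:
        drivers = lefse.module_drivers(lefse_res)
        lines += ["## Module drivers (|log10 LDA effect| >= " f"{lefse_res.threshold})", ""]
        for m, df in drivers.items():
            if len(df):
                feats = ", ".join(
                    f"{r.feature} ({r.enriched_class}, {r.lda_effect:+.2f})"
                    for r in df.itertuples()
                )
                lines.append(f"- MM{m}: {feats}")
            else:
                lines.append(f"- MM{m}: no feature exceeded the threshold")
        lines.append("")
    (Path(out) / "report.md").write_text("\n".join(lines))


def simulate_to_dir(params: synthdata.SyntheticParams | None, seed: int, out_dir) -> dict:
    """Generate a synthetic dataset and write otus.tsv / traits.tsv / truth.tsv."""
    from .data_model import write_otu_table, write_trait_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = synthdata.generate(params, seed=seed)
    write_otu_table(ds.otus, out / "otus.tsv")
    write_trait_table(ds.traits, out / "traits.tsv")
    synthdata.export_truth(ds, out / "truth.tsv")
    return {
        "otus": str(out / "otus.tsv"),
        "traits": str(out / "traits.tsv"),
        "truth": str(out / "truth.tsv"),
        "n_otus": int(ds.otus.counts.shape[0]),
        "n_samples": int(ds.otus.counts.shape[1]),
    }
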