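"""Synthetic paired-microbiome generator with planted ground truth.

The generator emulates a two-condition crossover 16S study: each subject
contributes one sample per dietary condition (placebo ``PL`` and nitrate-rich
``BR``). OTUs are organised into planted co-occurrence modules driven by
per-subject latent factors shared across conditions; selected OTUs carry
condition-dependent fold changes; host traits are linear in the module
factors with calibrated target correlations. Counts are drawn from a
Dirichlet-multinomial, so samples are compositional, overdispersed and close
to a fixed sequencing depth.

All randomness flows from a single seed; a dataset is byte-identical given
``(params, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conetwork import module_eigengene
from .data_model import (
    CONDITIONS,
    OtuTable,
    TraitTable,
    condition_network_inputs,
    to_relative_abundance,
)

__all__ = [
    "ConditionEffect",
    "TraitCoupling",
    "SyntheticParams",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate",
    "export_truth",
    "read_truth",
    "DEFAULT_CONDITION_EFFECTS",
    "DEFAULT_TRAIT_COUPLINGS",
    "TRAIT_NAMES",
    "BASELINE_TRAIT_NAMES",
]


@dataclass(frozen=True)
class ConditionEffect:
    """A planted BR-vs-PL fold change on one OTU.

    ``percent_change`` is on the relative-abundance scale (e.g. +259 means
    the BR mean is 3.59x the PL mean); internally applied as a log fold
    change on the OTU's latent abundance.
    """

    species: str
    module: int  # 0 = unassigned/background OTU
    percent_change: float
    phylum: str = "Firmicutes"
    genus: str = ""

    @property
    def log_fc(self) -> float:
        return float(np.log1p(self.percent_change / 100.0))


@dataclass(frozen=True)
class TraitCoupling:
    """A planted linear coupling between a trait and a module factor.

    ``condition`` is ``"both"`` (stable across diets), ``"PL"`` / ``"BR"``
    (loads in that condition only; the other condition's measurement is pure
    noise) or ``"BASE"`` (baseline-only trait, measured once).
    """

    trait: str
    module: int
    target_r: float
    condition: str = "both"


# Nitrate-sensitive species planted by default: module placement and percent
# change follow the reported distribution of diet-sensitive oral taxa across
# eight co-occurrence modules (module 0 = unassigned).
DEFAULT_CONDITION_EFFECTS = (
    ConditionEffect("Bacillus amyloliquefaciens", 1, -37, "Firmicutes", "Bacillus"),
    ConditionEffect("Phycisphaera mikurensis", 1, +118, "Planctomycetota", "Phycisphaera"),
    ConditionEffect("Ruminococcus bromii", 1, -56, "Firmicutes", "Ruminococcus"),
    ConditionEffect("Spirochaeta africana", 1, -66, "Spirochaetes", "Spirochaeta"),
    ConditionEffect("Atopobium parvulum", 2, -60, "Actinobacteria", "Atopobium"),
    ConditionEffect("Clostridium difficile", 2, -79, "Firmicutes", "Clostridium"),
    ConditionEffect("Megasphaera elsdenii", 2, -80, "Firmicutes", "Megasphaera"),
    ConditionEffect("Prevotella intermedia", 2, -46, "Bacteroidetes", "Prevotella"),
    ConditionEffect("Prevotella melaninogenica", 2, -56, "Bacteroidetes", "Prevotella"),
    ConditionEffect("Ruminococcus torques", 2, -78, "Firmicutes", "Ruminococcus"),
    ConditionEffect("Veillonella parvula", 2, -63, "Firmicutes", "Veillonella"),
    ConditionEffect("Tetragenococcus halophilus", 3, -30, "Firmicutes", "Tetragenococcus"),
    ConditionEffect("Butyrivibrio proteoclasticus", 4, -41, "Firmicutes", "Butyrivibrio"),
    ConditionEffect("Clostridium phytofermentans", 4, -47, "Firmicutes", "Clostridium"),
    ConditionEffect("Roseburia hominis", 4, -52, "Firmicutes", "Roseburia"),
    ConditionEffect("Capnocytophaga ochracea", 5, +96, "Bacteroidetes", "Capnocytophaga"),
    ConditionEffect("Flavobacterium indicum", 5, +183, "Bacteroidetes", "Flavobacterium"),
    ConditionEffect("Neisseria lactamica", 5, +175, "Proteobacteria", "Neisseria"),
    ConditionEffect("Neisseria meningitidis", 5, +305, "Proteobacteria", "Neisseria"),
    ConditionEffect("Nitrosococcus halophilus", 5, +115, "Proteobacteria", "Nitrosococcus"),
    ConditionEffect("Ornithobacterium rhinotracheale", 5, +109, "Bacteroidetes", "Ornithobacterium"),
    ConditionEffect("Rothia mucilaginosa", 6, +259, "Actinobacteria", "Rothia"),
    ConditionEffect("Leptothrix cholodnii", 0, +628, "Proteobacteria", "Leptothrix"),
    ConditionEffect("Variovorax paradoxus", 0, +544, "Proteobacteria", "Variovorax"),
)

TRAIT_NAMES = (
    "plasma_nitrate", "plasma_nitrite", "nitrite_nitrate_ratio",
    "SBP", "DBP", "MAP", "heart_rate",
    "body_mass", "BMI",
    "VO2_rest", "VO2_walk", "O2_cost_walking",
    "sit_to_stand_time", "six_min_walk_distance",
    "Qmax", "pcr_recovery_tau",
    "RVP_errors", "RVP_latency", "number_recall_score",
    "stroop_time", "stroop_errors", "reaction_time", "serial_subtraction_score",
    "brain_NAA_gm", "brain_Cho_gm", "brain_Cr_gm", "brain_mI_gm",
    "brain_NAA_wm", "brain_Cho_wm", "brain_Cr_wm", "brain_mI_wm",
    "salivary_flow_score",
)

BASELINE_TRAIT_NAMES = ("ace_total", "ace_attention", "ace_memory", "ace_fluency", "ace_language")

# Three stable couplings (the consensus-screen positives), four couplings per
# single condition (the spurious relationships the consensus screen should
# reject), and baseline cognitive couplings analysed in the PL network.
DEFAULT_TRAIT_COUPLINGS = (
    TraitCoupling("MAP", 6, -0.44, "both"),
    TraitCoupling("reaction_time", 5, -0.39, "both"),
    TraitCoupling("VO2_rest", 7, +0.48, "both"),
    TraitCoupling("plasma_nitrate", 5, +0.45, "BR"),
    TraitCoupling("SBP", 2, +0.45, "BR"),
    TraitCoupling("RVP_errors", 2, +0.45, "BR"),
    TraitCoupling("brain_Cho_wm", 6, +0.45, "BR"),
    TraitCoupling("plasma_nitrite", 1, +0.45, "PL"),
    TraitCoupling("stroop_time", 3, -0.45, "PL"),
    TraitCoupling("brain_NAA_gm", 2, +0.45, "PL"),
    TraitCoupling("six_min_walk_distance", 8, +0.45, "PL"),
    TraitCoupling("ace_total", 6, +0.45, "BASE"),
    TraitCoupling("ace_fluency", 6, +0.42, "BASE"),
    TraitCoupling("ace_language", 4, +0.51, "BASE"),
    TraitCoupling("ace_language", 6, +0.41, "BASE"),
    TraitCoupling("ace_memory", 1, -0.40, "BASE"),
)


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings; defaults reproduce the study scale."""

    n_subjects: int = 26
    module_sizes: tuple[int, ...] = (243, 48, 24, 71, 57, 71, 46, 24)
    n_background_otus: int = 26
    sequencing_depth: int = 100_000
    dirichlet_concentration: float = 3000.0
    baseline_sd: float = 1.0
    effect_otu_baseline_mean: float = 0.5
    effect_otu_baseline_sd: float = 0.75
    loading_range: tuple[float, float] = (1.0, 1.5)
    sigma_subject: float = 0.8
    sigma_condition: float = 0.3
    condition_effects: tuple[ConditionEffect, ...] = DEFAULT_CONDITION_EFFECTS
    trait_couplings: tuple[TraitCoupling, ...] = DEFAULT_TRAIT_COUPLINGS
    trait_names: tuple[str, ...] = TRAIT_NAMES
    baseline_trait_names: tuple[str, ...] = BASELINE_TRAIT_NAMES

    @property
    def n_otus(self) -> int:
        return sum(self.module_sizes) + self.n_background_otus

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)


@dataclass
class SyntheticTruth:
    module_of: pd.Series            # otu -> planted module (0 = background)
    condition_log_fc: pd.Series     # otu -> log fold change BR vs PL
    trait_loadings: tuple[TraitCoupling, ...]
    seed: int
    params: SyntheticParams
    factors: pd.DataFrame | None = None  # subject x module latent factors


@dataclass
class SyntheticDataset:
    otus: OtuTable
    traits: TraitTable
    truth: SyntheticTruth


def _plausible_phyla(rng, n):
    pool = np.array(
        ["Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria",
         "Fusobacteria", "Spirochaetes"]
    )
    probs = np.array([0.38, 0.22, 0.2, 0.12, 0.05, 0.03])
    return pool[rng.choice(len(pool), size=n, p=probs)]


def generate(params: SyntheticParams | None = None, seed: int = 0) -> SyntheticDataset:
    """Draw one synthetic paired dataset with exported ground truth.

    Latent model per OTU i, subject s, condition c:

        log a_isc = baseline_i + lambda_i * f_{s, module(i)}
                    + log_fc_i * [c = BR] + u_is + eps_isc

    with f and u shared across conditions (the crossover pairing) and eps
    condition-specific. Counts per sample are Dirichlet-multinomial at the
    configured depth and concentration. A trait coupled to module m at target
    correlation r is r * e_m + sqrt(1 - sum r^2) * noise, where e_m is the
    module's standardised eigengene computed from the generated counts (with
    the planted labels), so the population correlation between the trait and
    the module eigengene equals the target. Baseline-only traits couple to the
    placebo-condition eigengene, matching how they are analysed.
    """
    p = params or SyntheticParams()
    rng = np.random.default_rng(seed)
    n, k = p.n_otus, p.n_modules

    labels = np.concatenate(
        [np.full(s, m + 1, dtype=int) for m, s in enumerate(p.module_sizes)]
        + [np.zeros(p.n_background_otus, dtype=int)]
    )
    otu_ids = pd.Index([f"OTU_{i+1:04d}" for i in range(n)], name="otu_id")

    # place the named condition effects at the head of their module's block
    log_fc = np.zeros(n)
    species_name = [""] * n
    genus_name = [""] * n
    phyla = _plausible_phyla(rng, n)
    # labels is ordered blocks 1..k then background zeros
    block_start = {}
    pos = 0
    for m, size in enumerate(p.module_sizes, start=1):
        block_start[m] = pos
        pos += size
    block_start[0] = pos
    cursor = dict(block_start)
    for eff in p.condition_effects:
        if eff.module > k:
            raise ValueError(f"effect {eff.species!r} targets module {eff.module} > {k}")
        i = cursor[eff.module]
        limit = block_start[eff.module] + (
            p.module_sizes[eff.module - 1] if eff.module > 0 else p.n_background_otus
        )
        if i >= limit:
            raise ValueError(f"too many condition effects for module {eff.module}")
        cursor[eff.module] = i + 1
        log_fc[i] = eff.log_fc
        species_name[i] = eff.species
        genus_name[i] = eff.genus or eff.species.split()[0]
        phyla[i] = eff.phylum

    taxonomy = pd.Series(
        [
            ";".join(
                [
                    "Bacteria",
                    phyla[i],
                    f"Class_{labels[i]}",
                    f"Order_{labels[i]}",
                    f"Family_{labels[i]}",
                    genus_name[i] or f"Genus_{i+1:04d}",
                    species_name[i] or f"Species_{i+1:04d}",
                ]
            )
            for i in range(n)
        ],
        index=otu_ids,
        name="taxonomy",
    )

    baseline = rng.normal(0.0, p.baseline_sd, n)
    effect_mask = log_fc != 0
    baseline[effect_mask] = rng.normal(
        p.effect_otu_baseline_mean, p.effect_otu_baseline_sd, int(effect_mask.sum())
    )
    lam = rng.uniform(*p.loading_range, n) * (labels > 0)
    factors = rng.normal(size=(p.n_subjects, k))            # shared across conditions
    subj_effect = rng.normal(0.0, p.sigma_subject, (p.n_subjects, n))

    subjects = [f"S{j+1:02d}" for j in range(p.n_subjects)]
    fmat = np.zeros((p.n_subjects, n))
    for m in range(1, k + 1):
        fmat[:, labels == m] = factors[:, m - 1][:, None]

    count_cols = {}
    for cond in CONDITIONS:
        eps = rng.normal(0.0, p.sigma_condition, (p.n_subjects, n))
        shift = log_fc if cond == "BR" else 0.0
        log_ab = baseline + lam * fmat + shift + subj_effect + eps
        alpha = np.exp(log_ab)
        alpha = alpha / alpha.sum(axis=1, keepdims=True) * p.dirichlet_concentration
        for s, subj in enumerate(subjects):
            prob = rng.dirichlet(alpha[s])
            count_cols[f"{subj}_{cond}"] = rng.multinomial(p.sequencing_depth, prob)

    counts = pd.DataFrame(count_cols, index=otu_ids, dtype=np.int64)
    # interleave columns subject-major so the table reads pairwise
    ordered = [f"{s}_{c}" for s in subjects for c in CONDITIONS]
    otus = OtuTable(counts=counts.loc[:, ordered], taxonomy=taxonomy)

    # ---- traits -----------------------------------------------------------
    # eigengenes of the planted modules, from the generated counts
    labels_series = pd.Series(labels, index=otu_ids, name="module")
    xs = condition_network_inputs(to_relative_abundance(otus))
    eigengene_by_cond = {}
    for cond in CONDITIONS:
        eg = module_eigengene(xs[cond], labels_series)
        z = (eg - eg.mean()) / eg.std(ddof=0)
        eigengene_by_cond[cond] = z
    eigengene_by_cond["BASE"] = eigengene_by_cond["PL"]

    loadings: dict[tuple[str, str], list[tuple[int, float]]] = {}
    for tc in p.trait_couplings:
        if not abs(tc.target_r) < 1:
            raise ValueError(f"target_r for trait {tc.trait!r} must satisfy |r| < 1")
        if tc.condition == "both":
            tags = list(CONDITIONS)
        else:
            tags = [tc.condition]
        for tag in tags:
            loadings.setdefault((tc.trait, tag), []).append((tc.module, tc.target_r))
    for (trait, tag), ld in loadings.items():
        ssq = sum(r * r for _, r in ld)
        if ssq >= 1:
            raise ValueError(
                f"infeasible couplings for trait {trait!r} ({tag}): sum of squared target_r = {ssq:.3f} >= 1"
            )

    def draw_trait(name: str, tag: str) -> np.ndarray:
        ld = loadings.get((name, tag), [])
        signal = np.zeros(p.n_subjects)
        ssq = 0.0
        for module, r in ld:
            col = f"MM{module}"
            if col not in eigengene_by_cond[tag].columns:
                raise ValueError(f"trait {name!r} couples to unknown module {module}")
            signal += r * eigengene_by_cond[tag][col].to_numpy()
            ssq += r * r
        return signal + np.sqrt(1.0 - ssq) * rng.normal(size=p.n_subjects)

    values = {
        cond: pd.DataFrame(
            {name: draw_trait(name, cond) for name in p.trait_names},
            index=pd.Index(subjects, name="subject_id"),
        )
        for cond in CONDITIONS
    }
    baseline_traits = pd.DataFrame(
        {name: draw_trait(name, "BASE") for name in p.baseline_trait_names},
        index=pd.Index(subjects, name="subject_id"),
    )
    traits = TraitTable(
        values=values,
        baseline=baseline_traits,
        units={name: "z-score" for name in (*p.trait_names, *p.baseline_trait_names)},
    )

    truth = SyntheticTruth(
        module_of=pd.Series(labels, index=otu_ids, name="module"),
        condition_log_fc=pd.Series(log_fc, index=otu_ids, name="log_fc"),
        trait_loadings=p.trait_couplings,
        seed=seed,
        params=p,
        factors=pd.DataFrame(
            factors, index=pd.Index(subjects, name="subject_id"),
            columns=[f"MM{m}" for m in range(1, k + 1)],
        ),
    )
    return SyntheticDataset(otus=otus, traits=traits, truth=truth)


def export_truth(dataset: SyntheticDataset, path) -> None:
    """Write the per-OTU ground truth (module, log fold change, percent change)."""
    truth = dataset.truth
    out = pd.DataFrame(
        {
            "module": truth.module_of,
            "log_fc": truth.condition_log_fc,
            "percent_change": 100.0 * np.expm1(truth.condition_log_fc),
        }
    )
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="otu_id")
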