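"""Seeded synthetic datasets with the structure the analysis assumes.

The generator emulates a paired two-region (CA1/CA3), two-condition
(control/AD) brain expression study: every subject contributes one CA1 and
one CA3 array; cell-type co-expression modules ride on latent cell
proportions that shift with diagnosis, age, or early tau (Braak) pathology;
and dedicated gene sets are planted with region-enriched, disease-altered,
vulnerability, or protection fold-change patterns. Expression is simulated
on the log2 scale and exported as linear intensities (2^x) with
intensity-dependent detection p-values, mirroring Illumina-style arrays.

Every draw flows from ``SimulationConfig.seed``; identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_phenotypes

__all__ = [
    "PlantedModule",
    "SimulationConfig",
    "GroundTruth",
    "default_modules",
    "generate_dataset",
    "plant_vulnerability_protection",
]

#: Canonical cell-type marker symbols used when a module's cell type is known.
MARKER_SYMBOLS = {
    "neuron": "SYT1",
    "astrocyte": "AQP4",
    "oligodendrocyte": "MOG",
    "microglia": "TYROBP",
}

CELL_TYPES = ("neuron", "astrocyte", "oligodendrocyte", "microglia", "none")
TRAIT_LINKS = (
    "down_with_AD",
    "up_with_AD",
    "up_with_age",
    "up_with_braak_in_controls",
    "none",
)


@dataclass(frozen=True)
class PlantedModule:
    """One co-expression module driven by a latent cell-type abundance."""

    label: str
    size: int
    cell_type: str = "none"
    trait_link: str = "none"
    loading: float = 0.45  # log2 units per unit (standardized) latent

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ValueError(f"module {self.label!r}: size must be >= 3")
        if self.loading <= 0:
            raise ValueError(f"module {self.label!r}: loading must be > 0")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"module {self.label!r}: unknown cell_type {self.cell_type!r}")
        if self.trait_link not in TRAIT_LINKS:
            raise ValueError(f"module {self.label!r}: unknown trait_link {self.trait_link!r}")


def default_modules() -> list[PlantedModule]:
    """Four cell-type modules with the trait links seen in AD hippocampus:
    neurons depleted in AD, astrocytes increased, oligodendrocytes tracking
    age, microglia tracking early tau pathology in controls."""
    return [
        PlantedModule("neuron", 120, "neuron", "down_with_AD", loading=0.45),
        PlantedModule("astrocyte", 80, "astrocyte", "up_with_AD", loading=0.45),
        PlantedModule("oligodendrocyte", 60, "oligodendrocyte", "up_with_age", loading=0.45),
        PlantedModule("microglia", 60, "microglia", "up_with_braak_in_controls", loading=0.45),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the real study's design: 16 control and 17 AD subjects,
    each contributing paired CA1/CA3 samples; planted fold changes of 1.5
    (strong) and 1.05 (weak); residual noise of 0.35 log2 units.
    """

    n_control: int = 16
    n_ad: int = 17
    n_genes: int = 2000
    modules: tuple[PlantedModule, ...] = field(default_factory=lambda: tuple(default_modules()))
    n_region_enriched: int = 30  # per direction (CA1-enriched and CA3-enriched)
    n_disease_altered: int = 30  # per direction (up and down with AD)
    n_vulnerability: int = 4
    n_protection: int = 3
    noise_sd: float = 0.35
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    planted_fc: float = 1.5  # strong planted linear fold change
    weak_fc: float = 1.05  # the "lesser degree" disease response
    classifier_fc: float = 1.8  # vulnerability/protection pattern fold change
    latent_sd: float = 0.6  # per-sample noise on each module latent
    latent_shift: float = 1.0  # trait-linked shift of a latent, in raw units
    marker_loading: float = 1.5  # loading of each module's designated marker
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_control": self.n_control,
            "n_ad": self.n_ad,
            "n_genes": self.n_genes,
            "n_region_enriched": self.n_region_enriched,
            "n_disease_altered": self.n_disease_altered,
            "n_vulnerability": self.n_vulnerability,
            "n_protection": self.n_protection,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        labels = [m.label for m in self.modules]
        if len(set(labels)) != len(labels):
            raise ValueError("module labels must be unique")
        n_planted = (
            sum(m.size for m in self.modules)
            + 2 * self.n_region_enriched
            + 2 * self.n_disease_altered
            + self.n_vulnerability
            + self.n_protection
        )
        if n_planted > self.n_genes:
            raise ValueError(
                f"planted gene sets need {n_planted} genes but n_genes={self.n_genes}"
            )

    @property
    def n_subjects(self) -> int:
        return self.n_control + self.n_ad

    @property
    def n_samples(self) -> int:
        return 2 * self.n_subjects


@dataclass
class GroundTruth:
    """Planted labels and latents backing one simulated dataset.

    ``genes`` is indexed by probe id with columns: gene_symbol, role,
    module, is_marker, baseline_log2, region_effect (log2; positive =
    higher in CA1), disease_ca1, disease_ca3 (log2 shifts in AD).
    ``latents`` holds the standardized per-sample module latents;
    ``cell_proportions`` the simplex-normalized abundances they derive from.
    ``markers`` maps module label -> (marker probe, runner-up probe).
    """

    genes: pd.DataFrame
    latents: pd.DataFrame
    cell_proportions: pd.DataFrame
    markers: dict[str, tuple[str, str]]
    config: SimulationConfig

    def genes_with_role(self, role: str) -> list[str]:
        return list(self.genes.index[self.genes["role"] == role])


# ---------------------------------------------------------------------------
# phenotype construction
# ---------------------------------------------------------------------------

def _balanced_levels(n: int, levels: list, proportions: list[float], rng) -> np.ndarray:
    """Deterministic counts closest to the target proportions, shuffled."""
    counts = [int(round(p * n)) for p in proportions]
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n:
        counts[int(np.argmin(counts))] += 1
    out = np.repeat(levels, counts)
    rng.shuffle(out)
    return out


def _make_phenotypes(config: SimulationConfig, rng) -> pd.DataFrame:
    n_c, n_a = config.n_control, config.n_ad
    subjects = [f"S{i + 1:03d}" for i in range(config.n_subjects)]
    diagnosis = np.array(["control"] * n_c + ["AD"] * n_a)

    # Braak/plaque distributions reproduce the study's group means
    # (Braak 1.50 vs 5.33; plaques 0.58 vs 2.59).
    braak = np.concatenate(
        [
            _balanced_levels(n_c, [1, 2], [0.5, 0.5], rng),
            _balanced_levels(n_a, [4, 5, 6], [1 / 6, 1 / 3, 1 / 2], rng),
        ]
    )
    plaque = np.concatenate(
        [
            _balanced_levels(n_c, [0, 1], [0.42, 0.58], rng),
            _balanced_levels(n_a, [2, 3], [0.41, 0.59], rng),
        ]
    )
    sex = np.concatenate(
        [
            _balanced_levels(n_c, ["M", "F"], [11 / 16, 5 / 16], rng),
            _balanced_levels(n_a, ["M", "F"], [9 / 17, 8 / 17], rng),
        ]
    )
    age = np.clip(rng.normal(80.0, 8.0, size=config.n_subjects), 60.0, 95.0).round(1)
    pmi = np.clip(rng.normal(11.0, 6.0, size=config.n_subjects), 1.0, 30.0).round(1)
    batch = rng.choice([f"batch{i}" for i in range(1, 7)], size=config.n_subjects)
    bank = rng.choice(["bankA", "bankB"], size=config.n_subjects)

    rows = []
    for i, subj in enumerate(subjects):
        for region in ("CA1", "CA3"):
            rows.append(
                {
                    "sample_id": f"{subj}_{region}",
                    "subject_id": subj,
                    "region": region,
                    "diagnosis": diagnosis[i],
                    "braak": int(braak[i]),
                    "plaque": int(plaque[i]),
                    "age": float(age[i]),
                    "sex": sex[i],
                    "pmi": float(pmi[i]),
                    "batch": batch[i],
                    "brain_bank": bank[i],
                }
            )
    return validate_phenotypes(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# latent cell abundances
# ---------------------------------------------------------------------------

def _module_latents(config: SimulationConfig, ph: pd.DataFrame, rng):
    """Standardized latents plus the simplex proportions they came from.

    Raw abundances a_m = exp(eta_m + noise) for each module are normalized
    (with a constant residual pool) to per-sample proportions; the
    standardized proportion is the latent that scales module loadings.
    """
    n = len(ph)
    is_ad = (ph["diagnosis"] == "AD").to_numpy(float)
    age_z = (ph["age"].to_numpy(float) - 80.0) / 8.0
    braak = ph["braak"].to_numpy(float)

    raw = {}
    for mod in config.modules:
        if mod.trait_link == "down_with_AD":
            eta = -config.latent_shift * is_ad
        elif mod.trait_link == "up_with_AD":
            eta = config.latent_shift * is_ad
        elif mod.trait_link == "up_with_age":
            eta = config.latent_shift * age_z
        elif mod.trait_link == "up_with_braak_in_controls":
            # rises over Braak 1->2 in controls; saturated in AD
            eta = config.latent_shift * (np.minimum(braak, 2.0) - 1.5)
        else:
            eta = np.zeros(n)
        raw[mod.label] = np.exp(0.5 * (eta + rng.normal(0.0, config.latent_sd, size=n)))

    if not raw:
        empty = pd.DataFrame(index=ph.index)
        return empty, empty
    abundance = pd.DataFrame(raw, index=ph.index)
    total = abundance.sum(axis=1) + 2.0  # constant pool of unmodeled cell types
    proportions = abundance.div(total, axis=0)
    latents = (proportions - proportions.mean()) / proportions.std(ddof=0)
    return latents, proportions


# ---------------------------------------------------------------------------
# planted effect tables
# ---------------------------------------------------------------------------

def _blank_truth_genes(config: SimulationConfig, rng) -> pd.DataFrame:
    probes = [f"ILMN_{i + 1:06d}" for i in range(config.n_genes)]
    symbols = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]
    genes = pd.DataFrame(
        {
            "gene_symbol": symbols,
            "role": "null",
            "module": "",
            "is_marker": False,
            "baseline_log2": rng.normal(
                config.baseline_log2_mean, config.baseline_log2_sd, size=config.n_genes
            ),
            "region_effect": 0.0,
            "disease_ca1": 0.0,
            "disease_ca3": 0.0,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return genes


def plant_vulnerability_protection(
    truth: GroundTruth, config: SimulationConfig
) -> GroundTruth:
    """Write the vulnerability/protection fold-change patterns into the truth.

    Vulnerability genes are CA1-enriched at baseline (FC =
    ``classifier_fc``) and rise with AD more in CA1 (CA1 FC =
    ``classifier_fc``, CA3 FC = ``weak_fc``); protection genes are
    CA3-enriched at baseline, rise with AD in CA3 and drift slightly down
    in CA1 (FC = -``weak_fc``). ``classifier_fc`` defaults to 1.8 so every
    criterion of the downstream rule clears its 1.2 cutoff by several
    standard errors of a group median at the default noise level and
    sample size. Candidates are drawn from the 50th-90th percentile band
    of baselines: high enough that detection filtering cannot remove them,
    below the extreme upper tail where quantile normalization pins values
    to the shared reference and erases group differences.
    """
    genes = truth.genes
    need = config.n_vulnerability + config.n_protection
    if need == 0:
        return truth
    lo, hi = genes["baseline_log2"].quantile([0.5, 0.9])
    free = genes.index[
        (genes["role"] == "null")
        & genes["baseline_log2"].between(lo, hi)
    ]
    if len(free) < need:
        raise ValueError("not enough unplanted genes for vulnerability/protection sets")
    rng = np.random.default_rng(config.seed + 104729)
    chosen = rng.choice(free.to_numpy(), size=need, replace=False)
    strong = math.log2(config.classifier_fc)
    weak = math.log2(config.weak_fc)
    vul = chosen[: config.n_vulnerability]
    pro = chosen[config.n_vulnerability :]
    genes.loc[vul, ["role", "region_effect", "disease_ca1", "disease_ca3"]] = [
        "vulnerability",
        strong,
        strong,
        weak,
    ]
    genes.loc[pro, ["role", "region_effect", "disease_ca1", "disease_ca3"]] = [
        "protection",
        -strong,
        -weak,
        strong,
    ]
    return truth


def _assign_roles(genes: pd.DataFrame, config: SimulationConfig, rng) -> dict:
    """Assign module membership and region/disease planted sets; returns
    the module loading matrix info."""
    strong = math.log2(config.planted_fc)
    order = rng.permutation(genes.index.to_numpy())
    cursor = 0
    member_loadings: dict[str, pd.Series] = {}
    markers: dict[str, tuple[str, str]] = {}

    for mod in config.modules:
        members = order[cursor : cursor + mod.size]
        cursor += mod.size
        genes.loc[members, "module"] = mod.label
        genes.loc[members, "role"] = "module"
        loadings = pd.Series(
            rng.uniform(0.75 * mod.loading, 1.25 * mod.loading, size=mod.size),
            index=members,
        )
        # designated marker gets the highest loading; the runner-up is a
        # comparable alternate marker (real cell types have several)
        loadings.iloc[0] = config.marker_loading
        loadings.iloc[1] = 0.9 * config.marker_loading
        marker = members[0]
        runner_up = members[1]
        genes.loc[marker, "is_marker"] = True
        if mod.cell_type in MARKER_SYMBOLS:
            genes.loc[marker, "gene_symbol"] = MARKER_SYMBOLS[mod.cell_type]
        markers[mod.label] = (marker, runner_up)
        member_loadings[mod.label] = loadings

    def take(n):
        nonlocal cursor
        block = order[cursor : cursor + n]
        cursor += n
        return block

    genes.loc[take(config.n_region_enriched), ["role", "region_effect"]] = ["region_ca1", strong]
    genes.loc[take(config.n_region_enriched), ["role", "region_effect"]] = ["region_ca3", -strong]
    up = take(config.n_disease_altered)
    genes.loc[up, "role"] = "disease_up"
    genes.loc[up, ["disease_ca1", "disease_ca3"]] = strong
    down = take(config.n_disease_altered)
    genes.loc[down, "role"] = "disease_down"
    genes.loc[down, ["disease_ca1", "disease_ca3"]] = -strong
    return {"loadings": member_loadings, "markers": markers}


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------

def generate_dataset(config: SimulationConfig):
    """Simulate one dataset; returns ``(ExpressionMatrix, phenotypes, GroundTruth)``.

    The log2 signal for gene g in sample s is::

        x_gs = baseline_g + region_g·[CA1] + disease_g(region)·[AD]
               + sum_m loading_gm · z_m(s) + Normal(0, noise_sd)

    exported as linear intensities 2^x with detection p-values that decay
    monotonically with intensity relative to a low-intensity noise floor.
    """
    rng = np.random.default_rng(config.seed)
    ph = _make_phenotypes(config, rng)
    genes = _blank_truth_genes(config, rng)
    planted = _assign_roles(genes, config, rng)
    latents, proportions = _module_latents(config, ph, rng)

    truth = GroundTruth(
        genes=genes,
        latents=latents,
        cell_proportions=proportions,
        markers=planted["markers"],
        config=config,
    )
    truth = plant_vulnerability_protection(truth, config)
    genes = truth.genes

    is_ca1 = (ph["region"] == "CA1").to_numpy(float)
    is_ad = (ph["diagnosis"] == "AD").to_numpy(float)

    base = genes["baseline_log2"].to_numpy()[:, None]
    region = np.outer(genes["region_effect"].to_numpy(), is_ca1)
    disease = np.outer(genes["disease_ca1"].to_numpy(), is_ad * is_ca1) + np.outer(
        genes["disease_ca3"].to_numpy(), is_ad * (1.0 - is_ca1)
    )
    x = base + region + disease

    for mod in config.modules:
        loadings = planted["loadings"][mod.label]
        z = latents[mod.label].to_numpy()
        x[genes.index.get_indexer(loadings.index)] += np.outer(loadings.to_numpy(), z)

    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=x.shape)

    values = pd.DataFrame(
        np.exp2(x), index=genes.index, columns=ph.index.copy()
    )

    # Detection: p = 1 / (1 + (intensity/floor)^3) with the floor at the 1st
    # percentile of all intensities -> monotone non-increasing in intensity.
    floor = max(np.percentile(values.to_numpy(), 1.0), 1e-12)
    detection = 1.0 / (1.0 + (values / floor) ** 3)

    matrix = ExpressionMatrix(
        values=values,
        detection_p=detection,
        gene_symbols=genes["gene_symbol"].copy(),
    )
    return matrix, ph, truth


def write_dataset(matrix, ph, truth, outdir) -> None:
    """Write the simulated dataset and its ground truth as TSV/YAML files."""
    from pathlib import Path

    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.to_tsv(
        outdir / "expression.tsv", outdir / "detection.tsv", outdir / "annotation.tsv"
    )
    ph.reset_index().to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t")
    truth.latents.to_csv(outdir / "truth_latents.tsv", sep="\t")
    truth.cell_proportions.to_csv(outdir / "truth_proportions.tsv", sep="\t")
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(truth.config).items()
        if k != "modules"
    }
    cfg["modules"] = [vars(m) for m in truth.config.modules]
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
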