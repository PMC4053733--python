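"""Synthetic multi-dataset methylation data with planted co-methylation modules.

The generator emulates the structure of a multi-cohort methylation study:
several independent datasets ("cohorts") drawn from at least two tissues,
each a probe x sample beta matrix, with

* a planted *consensus aging module* whose probes rise in methylation with
  age in every dataset,
* a *sex module* of X-chromosome probes driven by sex,
* *dataset-specific* modules that co-vary in a single dataset only (and so
  must not survive consensus analysis),
* background probes with no planted structure, and
* optional corrupted samples whose whole column is independent noise
  (the target of the inter-array-connectivity QC rule).

Generative model.  Each probe p has a baseline level mu_p (shared across
datasets, giving realistic cross-dataset concordance of probe means).  A
module m carries a per-sample latent factor F_m; for the aging module
F = e * z(age) + sqrt(1 - e^2) * eta, for the sex module the standardized
covariate is sex, and for dataset-specific modules F is pure shared noise
in the home dataset only.  A member probe's latent value is

    x_pi = mu_p + sqrt(rho) * F_mi + sqrt(1 - rho) * noise_sd * eps_pi

so that at noise_sd = 1 the within-module correlation is rho, and larger
noise_sd monotonically dilutes it.  Betas are the inverse-logit of x,
hence strictly inside (0, 1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import Dialect, write_beta_matrix, write_probe_table, write_sample_table

__all__ = [
    "PlantedModule",
    "SimulationDesign",
    "default_design",
    "generate_consensus_datasets",
    "generate_probe_annotation",
    "write_design",
    "read_design",
]

MODULE_KINDS = ("consensus_aging", "sex_X", "dataset_specific", "background")
GREY = "grey"


@dataclass
class PlantedModule:
    """One planted block of correlated probes.

    effect_size is the latent-scale correlation between the module factor
    and the standardized driving covariate (age for ``consensus_aging``,
    sex for ``sex_X``); within_module_cor is the target pairwise
    correlation of member probes at noise_sd = 1.
    """

    name: str
    size: int
    kind: str
    effect_size: float = 0.0
    within_module_cor: float = 0.8
    home_dataset: int = 0  # only used for kind == "dataset_specific"
    member_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in MODULE_KINDS:
            raise ValueError(f"unknown module kind {self.kind!r}")
        if self.size < 1:
            raise ValueError("module size must be positive")
        if not (0.0 < self.within_module_cor <= 1.0):
            raise ValueError("within_module_cor must be in (0, 1]")
        if self.kind == "consensus_aging" and self.effect_size <= 0:
            raise ValueError("consensus_aging modules must have effect_size > 0")
        if abs(self.effect_size) > 1:
            raise ValueError("effect_size is a latent correlation, |e| <= 1")


@dataclass
class SimulationDesign:
    """Study layout: datasets, cohort sizes, age ranges and planted modules."""

    n_datasets: int
    n_samples_per_dataset: list[int]
    n_probes: int
    age_ranges: list[tuple[float, float]]
    planted_modules: list[PlantedModule]
    tissues: list[str] = field(default_factory=list)
    single_sex: list[str | None] = field(default_factory=list)
    noise_sd: float = 1.0
    baseline_sd: float = 1.5
    outlier_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_datasets < 1:
            raise ValueError("need at least one dataset")
        if len(self.n_samples_per_dataset) != self.n_datasets:
            raise ValueError("n_samples_per_dataset length mismatch")
        if len(self.age_ranges) != self.n_datasets:
            raise ValueError("age_ranges length mismatch")
        if any(n < 1 for n in self.n_samples_per_dataset):
            raise ValueError("empty dataset in design")
        for lo, hi in self.age_ranges:
            if not hi > lo:
                raise ValueError("age range must have positive width")
        if not (0.0 <= self.outlier_fraction <= 1.0):
            raise ValueError("outlier_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        total = sum(m.size for m in self.planted_modules)
        if total > self.n_probes:
            raise ValueError(
                f"planted module sizes ({total}) exceed n_probes ({self.n_probes})"
            )
        if not self.tissues:
            self.tissues = [f"tissue{s + 1}" for s in range(self.n_datasets)]
        if not self.single_sex:
            self.single_sex = [None] * self.n_datasets
        # assign member probe ids: planted modules occupy the leading probes
        start = 0
        for m in self.planted_modules:
            m.member_ids = tuple(f"cg{p:05d}" for p in range(start, start + m.size))
            start += m.size

    @property
    def probe_ids(self) -> list[str]:
        return [f"cg{p:05d}" for p in range(self.n_probes)]

    @property
    def dataset_names(self) -> list[str]:
        return [f"ds{s + 1}" for s in range(self.n_datasets)]

    def planted_labels(self) -> pd.Series:
        """probe -> planted module name; background probes labelled 'grey'."""
        labels = pd.Series(GREY, index=pd.Index(self.probe_ids, name="probe_id"))
        for m in self.planted_modules:
            if m.kind != "background":
                labels.loc[list(m.member_ids)] = m.name
        return labels


def default_design(seed: int = 0, **overrides) -> SimulationDesign:
    """The default study conditions: 4 datasets (2 blood + 2 brain cohorts),
    80 samples each, 2,000 probes; one consensus aging module of 60 probes,
    one sex-driven X module, one dataset-specific module."""
    kwargs = dict(
        n_datasets=4,
        n_samples_per_dataset=[80, 80, 80, 80],
        n_probes=2000,
        age_ranges=[(16.0, 88.0), (24.0, 74.0), (15.0, 101.0), (20.0, 96.0)],
        tissues=["blood", "blood", "brain", "brain"],
        planted_modules=[
            PlantedModule("aging", 60, "consensus_aging", effect_size=0.7),
            PlantedModule("sexX", 50, "sex_X", effect_size=0.9),
            PlantedModule("ds1only", 50, "dataset_specific", home_dataset=0),
        ],
        noise_sd=1.0,
        outlier_fraction=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationDesign(**kwargs)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_consensus_datasets(
    design: SimulationDesign,
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Generate one (beta matrix, sample table) pair per dataset.

    Deterministic given ``design.seed``; per-dataset random streams are
    spawned from one seed sequence so datasets are independent but the
    whole collection is reproducible.
    """
    root = np.random.SeedSequence(design.seed)
    base_ss, *ds_ss = root.spawn(design.n_datasets + 1)
    base_rng = np.random.default_rng(base_ss)
    # probe baselines shared across datasets
    mu = base_rng.normal(0.0, design.baseline_sd, size=design.n_probes)

    out = []
    for s in range(design.n_datasets):
        rng = np.random.default_rng(ds_ss[s])
        n = design.n_samples_per_dataset[s]
        lo, hi = design.age_ranges[s]
        age = rng.uniform(lo, hi, size=n)
        z_age = (age - (lo + hi) / 2.0) / ((hi - lo) / np.sqrt(12.0))
        forced = design.single_sex[s]
        if forced is None:
            sex = np.where(rng.random(n) < 0.5, "female", "male")
        else:
            sex = np.full(n, forced)
        sex_code = np.where(sex == "female", 1.0, -1.0)

        latent = np.empty((design.n_probes, n))
        latent[:] = mu[:, None] + design.noise_sd * rng.normal(size=(design.n_probes, n))

        for m in design.planted_modules:
            if m.kind == "background":
                continue
            factor = None
            if m.kind == "consensus_aging":
                e = m.effect_size
                factor = e * z_age + np.sqrt(max(0.0, 1 - e**2)) * rng.normal(size=n)
            elif m.kind == "sex_X":
                e = m.effect_size
                factor = e * sex_code + np.sqrt(max(0.0, 1 - e**2)) * rng.normal(size=n)
            elif m.kind == "dataset_specific" and s == m.home_dataset:
                factor = rng.normal(size=n)
            if factor is None:
                continue  # members behave as background in this dataset
            rho = m.within_module_cor
            idx = slice(
                design.probe_ids.index(m.member_ids[0]),
                design.probe_ids.index(m.member_ids[-1]) + 1,
            )
            eps = rng.normal(size=(m.size, n))
            latent[idx] = (
                mu[idx][:, None]
                + np.sqrt(rho) * factor[None, :]
                + np.sqrt(1 - rho) * design.noise_sd * eps
            )

        # corrupted samples: full-column replacement with independent noise
        is_outlier = rng.random(n) < design.outlier_fraction
        if is_outlier.any():
            k = int(is_outlier.sum())
            sd = np.sqrt(design.baseline_sd**2 + design.noise_sd**2)
            latent[:, is_outlier] = rng.normal(0.0, sd, size=(design.n_probes, k))

        beta = pd.DataFrame(
            _expit(latent),
            index=pd.Index(design.probe_ids, name="probe_id"),
            columns=[f"{design.dataset_names[s]}_s{i:03d}" for i in range(n)],
        )
        samples = pd.DataFrame(
            {
                "sample_id": beta.columns,
                "age": age,
                "sex": sex,
                "disease": "control",
                "tissue": design.tissues[s],
                "dataset": design.dataset_names[s],
                "outlier": is_outlier,
            }
        )
        out.append((beta, samples))
    return out


def generate_probe_annotation(
    design: SimulationDesign,
    enrichment_odds: float = 3.0,
    island_odds: float = 3.0,
    polymorphic_rate: float = 0.03,
    cross_reactive_rate: float = 0.06,
) -> pd.DataFrame:
    """Probe annotations with configurable enrichment in the aging module.

    Aging-module members are enriched for high Polycomb occupancy counts
    (weights multiplied by enrichment_odds**count) and for CpG-island
    location (island weight multiplied by island_odds); odds of 1 give
    annotations independent of membership.  Sex-module probes are placed
    on chromosome X by construction.  Polymorphic / cross-reactive flags
    are independent Bernoulli draws at the given rates.
    """
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 977)))
    labels = design.planted_labels()
    n = design.n_probes
    aging = np.zeros(n, dtype=bool)
    on_x = np.zeros(n, dtype=bool)
    for m in design.planted_modules:
        pos = [design.probe_ids.index(p) for p in (m.member_ids[0], m.member_ids[-1])]
        sl = slice(pos[0], pos[1] + 1)
        if m.kind == "consensus_aging":
            aging[sl] = True
        elif m.kind == "sex_X":
            on_x[sl] = True

    chrom = rng.choice([str(c) for c in range(1, 23)], size=n)
    chrom[rng.random(n) < 0.04] = "X"
    chrom[on_x] = "X"

    island_base = np.array([0.40, 0.25, 0.35])  # island, shore, outside
    pcg_base = np.array([0.55, 0.20, 0.15, 0.10])  # counts 0..3
    island_en = island_base * np.array([island_odds, 1.0, 1.0])
    island_en /= island_en.sum()
    pcg_en = pcg_base * enrichment_odds ** np.arange(4)
    pcg_en /= pcg_en.sum()

    island = np.empty(n, dtype=object)
    pcg = np.empty(n, dtype=int)
    levels = np.array(["island", "shore", "outside"], dtype=object)
    island[~aging] = rng.choice(levels, size=(~aging).sum(), p=island_base)
    island[aging] = rng.choice(levels, size=aging.sum(), p=island_en)
    pcg[~aging] = rng.choice(4, size=(~aging).sum(), p=pcg_base)
    pcg[aging] = rng.choice(4, size=aging.sum(), p=pcg_en)

    return pd.DataFrame(
        {
            "probe_id": design.probe_ids,
            "gene_symbol": [f"GENE{p:05d}" for p in range(n)],
            "chromosome": chrom,
            "island_status": island,
            "pcg_occupancy": pcg,
            "distance_to_tss": rng.integers(0, 1500, size=n),
            "polymorphic": rng.random(n) < polymorphic_rate,
            "cross_reactive": rng.random(n) < cross_reactive_rate,
            "planted_module": labels.to_numpy(),
        }
    )


# -- plain-text design round trip -------------------------------------------

def write_design(design: SimulationDesign, path) -> None:
    d = dataclasses.asdict(design)
    d["age_ranges"] = [list(r) for r in design.age_ranges]
    for m in d["planted_modules"]:
        m.pop("member_ids")
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_design(path) -> SimulationDesign:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["age_ranges"] = [tuple(r) for r in d["age_ranges"]]
    d["planted_modules"] = [PlantedModule(**m) for m in d["planted_modules"]]
    return SimulationDesign(**d)


def write_dataset_files(design: SimulationDesign, outdir, dialect: Dialect = Dialect()):
    """Materialize the design as the delimited files the pipeline consumes."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs = generate_consensus_datasets(design)
    paths = []
    all_samples = []
    for (beta, samples), name in zip(pairs, design.dataset_names):
        p = outdir / f"{name}_beta.tsv"
        write_beta_matrix(beta, p, dialect)
        all_samples.append(samples)
        paths.append(p)
    write_sample_table(pd.concat(all_samples, ignore_index=True), outdir / "samples.tsv", dialect)
    write_probe_table(generate_probe_annotation(design), outdir / "probes.tsv", dialect)
    write_design(design, outdir / "design.yaml")
    return paths
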