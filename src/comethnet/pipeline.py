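"""End-to-end orchestration: data -> QC -> meta-analysis -> consensus
network -> modules -> preservation -> annotation.

The in-memory entry point is :func:`run_consensus`, which takes per-
dataset beta matrices and sample tables and returns all intermediate
objects; :func:`run_pipeline` drives a whole run from a YAML config
(simulating data when the config embeds a design), writes delimited
artifacts, figures and a manifest into the output directory.
Reference (consensus-building) and validation datasets are kept strictly
separate: validation sets never enter consensus construction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import assoc, modules as mods, network, preservation, qc as qcmod, simulate
from .io import Dialect, align_samples, intersect_probes, read_beta_matrix, read_sample_table

log = logging.getLogger("comethnet")

__all__ = ["ConsensusResult", "run_consensus", "run_pipeline", "load_config"]


@dataclass
class ConsensusResult:
    betas: dict[str, pd.DataFrame]
    sample_tables: dict[str, pd.DataFrame]
    qc_reports: dict[str, qcmod.QCReport]
    assoc_results: dict[str, pd.DataFrame]
    meta_tables: dict[str, pd.DataFrame]
    calibration_exponents: np.ndarray
    consensus_tom: np.ndarray
    module_set: mods.ModuleSet
    eigengenes: dict[str, pd.DataFrame]
    prop_var_explained: pd.DataFrame
    consensus_kme: pd.DataFrame
    trait_table: pd.DataFrame

    def module_probe_map(self) -> dict[int, list[str]]:
        return {l: self.module_set.module_probes(l) for l in self.module_set.module_labels}


def run_consensus(
    betas: dict[str, pd.DataFrame],
    sample_tables: dict[str, pd.DataFrame],
    net_cfg: network.NetworkConfig = network.NetworkConfig(),
    sd_multiplier: float = 2.0,
    qc_max_iter: int = 2,
    min_module_size: int = 30,
    cut_height: float | None = None,
    deep_split: int = 1,
    selections: dict[str, list[str]] | None = None,
    run_qc: bool = True,
) -> ConsensusResult:
    """Consensus co-methylation analysis over the reference datasets."""
    names = list(betas)
    betas = {n: b for n, b in betas.items()}
    if len(names) >= 2:
        aligned = intersect_probes([betas[n] for n in names])
        betas = dict(zip(names, aligned))

    qc_reports = {}
    if run_qc:
        for n in names:
            betas[n], qc_reports[n] = qcmod.remove_outlier_samples(
                betas[n], sd_multiplier=sd_multiplier, max_iter=qc_max_iter
            )
            if qc_reports[n].removed_sample_ids:
                log.info("QC %s: removed %s", n, qc_reports[n].removed_sample_ids)

    assoc_results = {
        n: assoc.cor_test_age(betas[n], sample_tables[n], method=net_cfg.correlation)
        for n in names
    }
    if selections is None:
        selections = {"all": names}
    meta_tables = assoc.meta_by_selection(assoc_results, selections)

    toms = []
    for n in names:
        adjm = network.signed_adjacency(betas[n], net_cfg)
        toms.append(network.tom(adjm))
        log.info("network %s: adjacency and TOM done", n)
    if len(toms) > 1:
        calibrated, exps = network.calibrate_toms_with_exponents(toms, net_cfg)
        ctom = network.consensus_tom(calibrated, net_cfg)
    else:
        calibrated, exps = toms, np.array([1.0])
        ctom = calibrated[0]

    link = mods.cluster_dissimilarity(1.0 - ctom)
    module_set = mods.cut_tree_adaptive(
        link, list(betas[names[0]].index),
        min_module_size=min_module_size, cut_height=cut_height, deep_split=deep_split,
    )
    log.info("modules: %s", dict(module_set.sizes()))

    eigengenes, pve = mods.eigengene_set(betas, module_set)
    kmes = {n: mods.kme(betas[n], eigengenes[n]) for n in names}
    ckme = mods.consensus_kme(kmes, {n: betas[n].shape[1] for n in names})
    trait = mods.module_trait_table(eigengenes, sample_tables, "age")

    return ConsensusResult(
        betas=betas,
        sample_tables=sample_tables,
        qc_reports=qc_reports,
        assoc_results=assoc_results,
        meta_tables=meta_tables,
        calibration_exponents=exps,
        consensus_tom=ctom,
        module_set=module_set,
        eigengenes=eigengenes,
        prop_var_explained=pve,
        consensus_kme=ckme,
        trait_table=trait,
    )


# -- config-driven run ------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "qc": {"sd_multiplier": 2.0, "max_iter": 2},
    "network": {},
    "modules": {"min_module_size": 30, "cut_height": None, "deep_split": 1},
    "preservation": {"n_perm": 200},
    "top_k": 100,
    "selections": None,
    "figures": True,
}


def _merge_defaults(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge_defaults(user)


def _load_datasets(cfg, dialect: Dialect):
    """Return (reference betas, reference samples, validation betas,
    validation samples, probe table or None)."""
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        n_val = int(sim.pop("n_validation", 1))
        modules_spec = sim.pop("planted_modules", None)
        kwargs = dict(sim)
        if modules_spec is not None:
            kwargs["planted_modules"] = [simulate.PlantedModule(**m) for m in modules_spec]
        design = simulate.default_design(seed=int(cfg["seed"]), **kwargs)
        # validation sets: extra datasets drawn from a shifted seed, sharing
        # the planted consensus/sex modules but not dataset-specific ones
        val_design = dataclasses.replace(
            design,
            seed=design.seed + 10_000,
            planted_modules=[
                dataclasses.replace(m, member_ids=())
                for m in design.planted_modules
                if m.kind != "dataset_specific"
            ],
            n_datasets=max(1, n_val),
            n_samples_per_dataset=design.n_samples_per_dataset[:1] * max(1, n_val),
            age_ranges=design.age_ranges[:1] * max(1, n_val),
            tissues=design.tissues[:1] * max(1, n_val),
            single_sex=[None] * max(1, n_val),
        )
        ref_pairs = simulate.generate_consensus_datasets(design)
        val_pairs = simulate.generate_consensus_datasets(val_design)
        refs = {n: b for n, (b, _) in zip(design.dataset_names, ref_pairs)}
        ref_samples = {n: s for n, (_, s) in zip(design.dataset_names, ref_pairs)}
        vals = {f"val{i+1}": b for i, (b, _) in enumerate(val_pairs)}
        val_samples = {f"val{i+1}": s for i, (_, s) in enumerate(val_pairs)}
        probes = simulate.generate_probe_annotation(design)
        return refs, ref_samples, vals, val_samples, probes, design
    # file-backed datasets
    refs, ref_samples, vals, val_samples = {}, {}, {}, {}
    sample_table = read_sample_table(cfg["sample_table"], dialect)
    for name, spec in cfg["datasets"].items():
        beta = read_beta_matrix(spec["beta"], dialect)
        table = align_samples(beta, sample_table)
        if spec.get("role", "reference") == "validation":
            vals[name], val_samples[name] = beta, table
        else:
            refs[name], ref_samples[name] = beta, table
    probes = None
    if cfg.get("probe_table"):
        from .io import read_probe_table

        probes = read_probe_table(cfg["probe_table"], dialect)
    return refs, ref_samples, vals, val_samples, probes, None


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> Path:
    """Run every stage from a config mapping or YAML path; returns outdir."""
    t0 = time.time()
    cfg = _merge_defaults(config) if isinstance(config, dict) else load_config(config)
    outdir = Path(output_dir or cfg.get("output_dir", "comethnet_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    dialect = Dialect()
    seed = int(cfg["seed"])

    refs, ref_samples, vals, val_samples, probes, design = _load_datasets(cfg, dialect)

    net_cfg = network.NetworkConfig(**cfg["network"])
    result = run_consensus(
        refs,
        ref_samples,
        net_cfg=net_cfg,
        sd_multiplier=cfg["qc"]["sd_multiplier"],
        qc_max_iter=cfg["qc"]["max_iter"],
        selections=cfg.get("selections"),
        **{k: cfg["modules"][k] for k in ("min_module_size", "cut_height", "deep_split")},
    )

    # --- artifacts ---
    qc_dir = outdir / "qc"
    qc_dir.mkdir(exist_ok=True)
    for n, rep in result.qc_reports.items():
        rep.to_frame().to_csv(qc_dir / f"{n}_qc.tsv", sep="\t", index=False)

    meta_dir = outdir / "meta"
    meta_dir.mkdir(exist_ok=True)
    for sel, table in result.meta_tables.items():
        table.to_csv(meta_dir / f"meta_{sel}.tsv", sep="\t", index_label="probe_id")

    mod_dir = outdir / "modules"
    mod_dir.mkdir(exist_ok=True)
    result.module_set.to_frame().to_csv(mod_dir / "module_assignment.tsv", sep="\t")
    pd.DataFrame(
        result.module_set.linkage_matrix,
        columns=["left", "right", "height", "size"],
    ).to_csv(mod_dir / "dendrogram_merges.tsv", sep="\t", index=False)
    result.consensus_kme.to_csv(mod_dir / "consensus_kme.tsv", sep="\t", index_label="probe_id")
    result.trait_table.to_csv(mod_dir / "module_trait_reference.tsv", sep="\t", index=False)
    result.prop_var_explained.to_csv(mod_dir / "prop_var_explained.tsv", sep="\t")

    labels = result.module_set.module_labels
    if labels:
        largest = labels[0]
        top = mods.top_module_probes(result.consensus_kme, largest, int(cfg["top_k"]))
        top.to_csv(mod_dir / f"top_module{largest}_probes.tsv", sep="\t", index_label="probe_id")

    # --- validation: module-trait and preservation ---
    pres_dir = outdir / "preservation"
    pres_dir.mkdir(exist_ok=True)
    module_map = result.module_probe_map()
    preservation_summaries = {}
    if vals and module_map:
        val_eg = {}
        for n, beta in vals.items():
            shared = [p for p in result.betas[list(refs)[0]].index if p in beta.index]
            beta = beta.loc[shared]
            eg_cols, pv = {}, {}
            for label in labels:
                probes_l = [p for p in module_map[label] if p in beta.index]
                if len(probes_l) >= 2:
                    eg_cols[label], pv[label] = mods.module_eigengene(beta, probes_l)
            if eg_cols:
                val_eg[n] = pd.DataFrame(eg_cols)
            rep = preservation.multi_reference_preservation(
                result.betas, module_map, beta,
                cfg=net_cfg, n_perm=int(cfg["preservation"]["n_perm"]), seed=seed,
            )
            preservation_summaries[n] = rep
            rep.per_reference.to_csv(pres_dir / f"{n}_per_reference.tsv", sep="\t", index=False)
            rep.summary.to_csv(pres_dir / f"{n}_summary.tsv", sep="\t", index_label="module")
        if val_eg:
            val_trait = mods.module_trait_table(val_eg, val_samples, "age")
            val_trait.to_csv(mod_dir / "module_trait_validation.tsv", sep="\t", index=False)

    # --- annotation analyses ---
    ann_dir = outdir / "annotation"
    ann_dir.mkdir(exist_ok=True)
    if probes is not None and labels:
        aging_label = _aging_module_label(result)
        kme_col = f"kME{aging_label}"
        ptab = probes.set_index("probe_id").loc[result.consensus_kme.index]
        values = result.consensus_kme[kme_col]
        for factor in ("pcg_occupancy", "island_status"):
            summ = ann.grouped_membership_summary(values, ptab[factor])
            h, p = ann.kruskal_wallis(values, ptab[factor])
            summ.to_csv(ann_dir / f"kme_by_{factor}.tsv", sep="\t", index=False)
            with open(ann_dir / f"kruskal_{factor}.json", "w") as fh:
                json.dump({"H": h, "p": p}, fh)
        factors = pd.DataFrame(
            {
                "pcg_occupancy": ptab["pcg_occupancy"].astype(float),
                "island_status": ptab["island_status"],
                "x_chromosome": (ptab["chromosome"] == "X").astype(float),
                "distance_to_tss": ptab["distance_to_tss"].astype(float),
            }
        )
        for response_name, response in (
            ("consensus_kme", values),
            ("signed_log_p", result.meta_tables[list(result.meta_tables)[0]]["signed_log_p"]),
        ):
            table = ann.anova_decomposition(
                response, factors, categorical=("island_status",)
            )
            table.to_csv(ann_dir / f"anova_{response_name}.tsv", sep="\t", index_label="source")
        flags, _ = ann.flag_filter_probes(
            probes, module_map[aging_label], ("polymorphic", "cross_reactive")
        )
        flags.to_csv(ann_dir / "flag_counts.tsv", sep="\t", index=False)
        if cfg.get("gene_lists"):
            lists = ann.read_gene_lists(cfg["gene_lists"])
            universe = set(probes["gene_symbol"])
            module_genes = set(
                probes.set_index("probe_id").loc[module_map[aging_label], "gene_symbol"]
            )
            enr = ann.hypergeometric_enrichment(module_genes, lists, universe, "over")
            enr.to_csv(ann_dir / "gene_list_enrichment.tsv", sep="\t", index=False)

    if cfg.get("figures", True):
        _figures(outdir, result, preservation_summaries)

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "n_reference_datasets": len(refs),
        "n_validation_datasets": len(vals),
        "modules": {str(k): len(v) for k, v in module_map.items()},
        "elapsed_s": round(time.time() - t0, 2),
        "versions": _versions(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def _aging_module_label(result: ConsensusResult) -> int:
    """The module whose eigengene-age correlation is most consistently
    positive across reference datasets (minimum r across datasets)."""
    grid = result.trait_table.pivot(index="module", columns="dataset", values="r")
    return int(grid.min(axis=1).idxmax())


def _versions() -> dict:
    import matplotlib
    import scipy
    import statsmodels

    from . import __version__

    return {
        "comethnet": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.version.version
        if hasattr(statsmodels, "version")
        else statsmodels.__version__,
        "matplotlib": matplotlib.__version__,
    }


def _figures(outdir: Path, result: ConsensusResult, preservation_summaries: dict):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = outdir / "figures"
    fig_dir.mkdir(exist_ok=True)

    # module-trait grid (module x dataset correlation heatmap)
    grid = result.trait_table.pivot(index="module", columns="dataset", values="r")
    pgrid = result.trait_table.pivot(index="module", columns="dataset", values="p")
    fig, ax = plt.subplots(figsize=(1.2 * grid.shape[1] + 2, 0.6 * grid.shape[0] + 2))
    im = ax.pcolormesh(grid.to_numpy(), cmap="RdYlGn_r", vmin=-1, vmax=1)
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            ax.text(
                j + 0.5, i + 0.5,
                f"{grid.iloc[i, j]:.2f}\n{pgrid.iloc[i, j]:.1e}",
                ha="center", va="center", fontsize=7,
            )
    ax.set_xticks(np.arange(grid.shape[1]) + 0.5, grid.columns)
    ax.set_yticks(
        np.arange(grid.shape[0]) + 0.5,
        [mods.color_name(l) for l in grid.index],
    )
    ax.set_title("Module eigengene - age correlations")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(fig_dir / "module_trait_grid.png", dpi=120)
    plt.close(fig)

    # preservation panels: Zdensity and medianRank vs module size
    sizes = result.module_set.sizes()
    for n, rep in preservation_summaries.items():
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        s = rep.summary
        x = [sizes[m] for m in s.index]
        axes[0].scatter(x, s["Zdensity"])
        for m, xi, yi in zip(s.index, x, s["Zdensity"]):
            axes[0].annotate(mods.color_name(m), (xi, yi), fontsize=7)
        axes[0].axhline(2, color="grey", ls="--")
        axes[0].axhline(10, color="grey", ls=":")
        axes[0].set_xlabel("module size")
        axes[0].set_ylabel("Zdensity")
        axes[1].scatter(x, s["medianRank"])
        axes[1].invert_yaxis()
        axes[1].set_xlabel("module size")
        axes[1].set_ylabel("medianRank")
        fig.suptitle(f"Module preservation in {n}")
        fig.tight_layout()
        fig.savefig(fig_dir / f"preservation_{n}.png", dpi=120)
        plt.close(fig)
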