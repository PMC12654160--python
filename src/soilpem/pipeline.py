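"""End-to-end pipeline: simulate/load -> enzymes -> group stats ->
diversity -> network -> association -> latent models, from one config.

Every stochastic stage gets its own seed derived from the global seed by a
fixed per-stage offset (stage order never shifts another stage's stream).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (ENZYME_COLUMNS, P_FRACTION_COLUMNS, StudyDataset,
                   ValidationError)
from .simulate import GeneratorConfig, generate_dataset
from .enzymes import stoichiometry_table, vector_summary
from .stats import treatment_summary
from .diversity import alpha_diversity_table, bray_curtis_matrix, nmds
from .network import (build_network, correlation_screen, detect_modules,
                      domain_node_percentages, extract_subnetwork,
                      keystone_report, topology_metrics, write_edge_list,
                      zi_pi)
from .association import (correlation_panel, environment_distance, mantel,
                          yield_glm)
from .latent import default_plspm_spec, plspm_bootstrap, plspm_fit, rf_importance

log = logging.getLogger(__name__)

#: fixed per-stage seed offsets
STAGE_SEEDS = {"simulate": 1, "network": 2, "nmds": 3, "mantel": 4,
               "rf": 5, "plspm": 6}


def stage_seed(global_seed: int, stage: str) -> int:
    return (global_seed * 1000 + STAGE_SEEDS[stage]) % (2 ** 31 - 1)


@dataclass
class PipelineConfig:
    input_dir: str | None = None        # read a study from disk; else simulate
    outdir: str = "soilpem_report"
    seed: int = 0
    r_min: float = 0.75
    p_max: float = 0.01
    prevalence_min: float = 0.2
    alpha: float = 0.05
    n_perm: int = 999
    bootstrap_n: int = 199
    rf_trees: int = 200
    rf_perm: int = 99
    stages: dict[str, bool] = field(default_factory=lambda: {
        "enzymes": True, "group_stats": True, "community": True,
        "network": True, "association": True, "latent": True})
    generator: GeneratorConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "stages"})
        if "stages" in raw:
            cfg.stages.update(raw["stages"])
        if gen:
            cfg.generator = GeneratorConfig(**gen)
        return cfg


def run_all(config: PipelineConfig) -> Path:
    """Run every enabled stage; returns the report directory.

    Raises :class:`ValidationError` on fatal dataset findings; a failing
    stage aborts with the stage name while retaining earlier outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "thresholds": {"r_min": config.r_min,
                                     "p_max": config.p_max,
                                     "alpha": config.alpha,
                                     "n_perm": config.n_perm,
                                     "bootstrap_n": config.bootstrap_n},
                      "stages": []}

    if config.input_dir:
        dataset = StudyDataset.read(config.input_dir)
    else:
        gen = config.generator or GeneratorConfig()
        gen.seed = stage_seed(config.seed, "simulate")
        dataset = generate_dataset(gen)
        dataset.write(outdir / "dataset")
        manifest["stages"].append("simulate")

    report = dataset.validate()
    report.raise_on_fatal()
    for f in report.advisory:
        log.warning("advisory: %s", f.message)

    meta = dataset.metadata
    treatments = meta.treatments.to_numpy()

    def _stage(name):
        return config.stages.get(name, True)

    try:
        if _stage("enzymes"):
            stoich = stoichiometry_table(dataset.enzymes)
            stoich.to_csv(outdir / "enzyme_stoichiometry.tsv", sep="\t",
                          index_label="sample_id")
            vs = vector_summary(dataset.enzymes, meta, alpha=config.alpha)
            vs["vector_length"].to_csv(outdir / "vector_length_summary.tsv",
                                       sep="\t")
            vs["vector_angle"].to_csv(outdir / "vector_angle_summary.tsv",
                                      sep="\t")
            manifest["stages"].append("enzymes")

        if _stage("group_stats"):
            frames = []
            chem = dataset.soil_chemistry.data
            for col in chem.columns:
                tab = treatment_summary(chem[col].to_numpy(), treatments,
                                        alpha=config.alpha)
                tab.insert(0, "variable", col)
                frames.append(tab)
            for col in P_FRACTION_COLUMNS:
                tab = treatment_summary(
                    dataset.p_fractions.data[col].to_numpy(), treatments,
                    alpha=config.alpha)
                tab.insert(0, "variable", col)
                frames.append(tab)
            for col in ENZYME_COLUMNS:
                tab = treatment_summary(
                    dataset.enzymes.data[col].to_numpy(), treatments,
                    alpha=config.alpha)
                tab.insert(0, "variable", col)
                frames.append(tab)
            pd.concat(frames).to_csv(outdir / "treatment_contrasts.tsv",
                                     sep="\t", index_label="treatment")
            manifest["stages"].append("group_stats")

        ordinations = {}
        if _stage("community"):
            for dom, table in dataset.features.items():
                alpha_diversity_table(table).to_csv(
                    outdir / f"alpha_diversity_{dom}.tsv", sep="\t",
                    index_label="sample_id")
                dist = bray_curtis_matrix(table)
                ord_res = nmds(dist, seed=stage_seed(config.seed, "nmds"))
                ord_res.coordinates.to_csv(outdir / f"nmds_{dom}.tsv",
                                           sep="\t", index_label="sample_id")
                log.info("NMDS %s stress = %.4f", dom, ord_res.stress)
                ordinations[dom] = ord_res
            manifest["stages"].append("community")

        if _stage("network"):
            pooled = dataset.pooled_features()
            edges = correlation_screen(pooled, r_min=config.r_min,
                                       p_max=config.p_max,
                                       prevalence_min=config.prevalence_min)
            net = build_network(edges, pooled)
            if net.n_edges > 0:
                net = detect_modules(net,
                                     seed=stage_seed(config.seed, "network"))
                write_edge_list(net, outdir / "network_edges.tsv")
                metrics = topology_metrics(net)
                metrics["domain_pct"] = domain_node_percentages(net)
                topo = zi_pi(net)
                topo.to_csv(outdir / "node_topology.tsv", sep="\t",
                            index_label="feature_id")
                keystone_report(topo, pooled.taxonomy, pooled.domain).to_csv(
                    outdir / "keystone_taxa.tsv", sep="\t",
                    index_label="feature_id")
                sub_rows = {}
                for t in meta.data["treatment"].unique():
                    sub = extract_subnetwork(net, pooled, meta, t)
                    sub_rows[t] = topology_metrics(sub)
                pd.DataFrame(sub_rows).T.to_csv(
                    outdir / "subnetwork_metrics.tsv", sep="\t",
                    index_label="treatment")
                (outdir / "network_metrics.json").write_text(
                    json.dumps(metrics, indent=2, default=float))
            else:
                log.warning("no edges passed the correlation screen")
            manifest["stages"].append("network")

        if _stage("association"):
            chem = dataset.soil_chemistry.data
            env = chem.join(dataset.p_fractions.data)
            env_dist = environment_distance(env.drop(columns="yield"))
            mantel_rows = {}
            for dom, table in dataset.features.items():
                dist = bray_curtis_matrix(table)
                res = mantel(dist, env_dist, n_perm=config.n_perm,
                             seed=stage_seed(config.seed, "mantel"),
                             exhaustive=False)
                mantel_rows[dom] = {"r": res.r, "p": res.p,
                                    "n_perm": res.n_perm}
            pd.DataFrame(mantel_rows).T.to_csv(outdir / "mantel.tsv",
                                               sep="\t", index_label="domain")
            phyla = {}
            for dom, table in dataset.features.items():
                by_phylum = table.counts.groupby(table.phylum()).sum()
                rel = by_phylum / by_phylum.sum()
                for ph in rel.index:
                    phyla[f"{dom}:{ph}"] = rel.loc[ph]
            panel = correlation_panel(pd.DataFrame(phyla), env)
            panel.to_csv(outdir / "correlation_panel.tsv", sep="\t",
                         index=False)
            glm = yield_glm(chem["yield"], chem["SOM"], chem["AP"])
            glm.to_csv(outdir / "yield_glm.tsv", sep="\t", index_label="term")
            manifest["stages"].append("association")

        if _stage("latent"):
            data = _latent_indicator_table(dataset, ordinations)
            spec = default_plspm_spec()
            spec.bootstrap_n = config.bootstrap_n
            spec.seed = stage_seed(config.seed, "plspm")
            boot = plspm_bootstrap(data, spec)
            boot.paths.to_csv(outdir / "plspm_paths.tsv", sep="\t",
                              index=False)
            model = plspm_fit(data, spec)
            model.loadings.to_frame("loading").to_csv(
                outdir / "plspm_loadings.tsv", sep="\t",
                index_label="indicator")
            predictors = data.drop(columns=["yield"])
            rf = rf_importance(predictors, data["yield"],
                               n_trees=config.rf_trees, n_perm=config.rf_perm,
                               seed=stage_seed(config.seed, "rf"))
            rf.table.to_csv(outdir / "rf_importance.tsv", sep="\t",
                            index_label="predictor")
            manifest["stages"].append("latent")
    except ValidationError as err:
        manifest["error"] = str(err)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


_FERT_DOSE = {"CK": 0.0, "OPT": 1.0, "OPTN": 1.5, "OPTP": 1.5, "OPTM": 2.0}


def _latent_indicator_table(dataset: StudyDataset, ordinations: dict
                            ) -> pd.DataFrame:
    """Assemble the default PLS-PM indicator table from a study dataset."""
    meta = dataset.metadata
    chem = dataset.soil_chemistry.data
    bact = dataset.features["bacteria"]
    div = alpha_diversity_table(bact)["shannon"]
    if "bacteria" in ordinations:
        nmds1 = ordinations["bacteria"].coordinates["NMDS1"]
    else:
        ord_res = nmds(bray_curtis_matrix(bact), seed=0)
        nmds1 = ord_res.coordinates["NMDS1"]
    out = pd.DataFrame({
        "fert_dose": meta.treatments.map(_FERT_DOSE),
        "Citrate_P": dataset.p_fractions.data["Citrate_P"],
        "Enzyme_P": dataset.p_fractions.data["Enzyme_P"],
        "HCl_P": dataset.p_fractions.data["HCl_P"],
        "BG": dataset.enzymes.data["BG"],
        "CBH": dataset.enzymes.data["CBH"],
        "NAG": dataset.enzymes.data["NAG"],
        "shannon": div,
        "NMDS1": nmds1,
        "yield": chem["yield"],
    })
    return out
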