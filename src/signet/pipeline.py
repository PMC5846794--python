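"""End-to-end workflow: simulate (or load) inputs, optimize short and long
panels, covariate screens, enrichment, network analysis and proximity, with a
machine-readable run report.

Every stage writes its artifacts to the output directory so each step is
independently re-runnable, and the report records every threshold and seed
actually used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier, covariates, enrichment, network, synthetic
from .io_formats import (
    ExpressionDataset,
    GeneSetCollection,
    InteractionNetwork,
    read_expression,
    read_gmt,
    read_network,
    read_tissue_table,
    write_expression,
    write_gmt,
    write_network,
    write_tissue_table,
)

logger = logging.getLogger("signet")


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulateBlock:
    """Synthetic-input parameters (cohort defaults live in CohortConfig)."""

    cohort: dict = field(default_factory=dict)
    network_nodes: int = 500
    network_tfs: int = 20
    network_mean_degree: float = 4.0
    network_de_intermediates: int = 12
    n_gene_sets: int = 30
    set_size_range: tuple[int, int] = (10, 40)
    tissues: tuple[str, ...] = (
        "skeletal_muscle", "heart", "liver", "brain", "kidney",
        "lung", "pancreas", "spleen", "testis", "skin",
    )
    tissue_quota: dict = field(default_factory=lambda: {
        "tissue_enriched": 8, "group_enriched": 6, "tissue_enhanced": 6,
        "expressed_in_all": 10, "not_detected": 5, "mixed": 10,
    })
    n_tissue_genes: int = 80


@dataclass
class InputsBlock:
    """Paths to user-supplied input files."""

    matrix: str = ""
    phenotype: str = ""
    annotation: str = ""
    gmt: str = ""
    signaling_edges: str = ""
    ppi_edges: str = ""
    tf_list: str = ""
    tissue_table: str = ""
    proximity_seed_gene: str = "DMD"


@dataclass
class GABlock:
    population_size: int = 40
    generations: int = 60
    tournament_size: int = 3
    crossover_rate: float = 0.8
    mutation_rate: float = 0.15
    n_min: int = 1
    n_max: int = 40
    accuracy_floor: float = 0.98


@dataclass
class RunConfig:
    out_dir: str = "signet_run"
    seed: int = 0
    simulate: SimulateBlock | None = None
    inputs: InputsBlock | None = None
    ga: GABlock = field(default_factory=GABlock)
    cv_folds: int = 5
    permutations: int = 1000
    n_random: int = 1000
    de_alpha: float = 0.05
    weight_exponent: float = 1.0
    run_permutation: bool = True

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must contain exactly one of 'simulate' or 'inputs'")
        if self.inputs is not None:
            for name in ("matrix", "phenotype", "annotation", "gmt",
                         "signaling_edges", "ppi_edges", "tf_list", "tissue_table"):
                path = getattr(self.inputs, name)
                if not path:
                    raise ValueError(f"inputs block missing required path {name!r}")
                if not Path(path).exists():
                    raise ValueError(f"input file does not exist: {path} (key {name!r})")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.permutations < 1 or self.n_random < 1:
            raise ValueError("permutations and n_random must be >= 1")


def _from_dict(cls, data: dict, context: str):
    """Build a dataclass from a dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"{context}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{context}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            val = data[f.name]
            if isinstance(val, list):
                val = tuple(val)
            kwargs[f.name] = val
    return cls(**kwargs)


def validate_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a YAML mapping")
    names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - names
    if unknown:
        raise ValueError(f"run config: unknown key(s) {sorted(unknown)}")
    cfg = RunConfig()
    for key, val in raw.items():
        if key == "simulate":
            cfg.simulate = _from_dict(SimulateBlock, val or {}, "simulate")
            if cfg.simulate.cohort:
                synthetic.CohortConfig(**cfg.simulate.cohort).validate()
        elif key == "inputs":
            cfg.inputs = _from_dict(InputsBlock, val or {}, "inputs")
        elif key == "ga":
            cfg.ga = _from_dict(GABlock, val or {}, "ga")
        else:
            setattr(cfg, key, val)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Simulation stage (writes all input files + truth.json)
# ---------------------------------------------------------------------------


def simulate_inputs(
    block: SimulateBlock, out_dir: str | Path, seed: int
) -> tuple[ExpressionDataset, synthetic.SyntheticTruth, GeneSetCollection,
           InteractionNetwork, InteractionNetwork, "object"]:
    """Generate every pipeline input with planted ground truth and write the
    files in the formats the readers expect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_cohort, s_net, s_sets, s_tissue = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(4)]

    cohort_cfg = synthetic.CohortConfig(**{**block.cohort, "seed": s_cohort})
    dataset, truth = synthetic.generate_cohort(cohort_cfg)
    write_expression(dataset, out / "matrix.tsv", out / "phenotype.tsv", out / "annotation.tsv")

    universe = dataset.mapped_genes()
    signaling, physical, truth = synthetic.generate_network(
        n_nodes=block.network_nodes,
        n_tfs=block.network_tfs,
        mean_degree=block.network_mean_degree,
        truth_markers=truth.marker_genes,
        n_de_intermediates=block.network_de_intermediates,
        seed=s_net,
        truth=truth,
        universe=universe,
    )
    write_network(signaling, out / "signaling_edges.tsv", out / "tf_list.txt")
    write_network(physical, out / "ppi_edges.tsv")

    geneset_universe = sorted(set(universe) | signaling.nodes)
    collection = synthetic.generate_genesets(
        n_sets=block.n_gene_sets,
        set_size_range=tuple(block.set_size_range),
        universe=geneset_universe,
        planted_set=truth.planted_pathway_genes,
        seed=s_sets,
    )
    truth.planted_pathway_name = "PLANTED_PATHWAY"
    write_gmt(collection, out / "gene_sets.gmt")

    tissue_table, tissue_truth = synthetic.generate_tissue_table(
        n_genes=block.n_tissue_genes,
        tissues=list(block.tissues),
        category_quota=dict(block.tissue_quota),
        seed=s_tissue,
    )
    # tissue-table genes alias panel genes so the tissue stage has a real join
    alias = {tg: universe[i % len(universe)] for i, tg in enumerate(tissue_table.genes)}
    tissue_table.genes = [alias[g] for g in tissue_table.genes]
    write_tissue_table(tissue_table, out / "tissue_table.tsv")

    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    return dataset, truth, collection, signaling, physical, tissue_table


# ---------------------------------------------------------------------------
# Full workflow
# ---------------------------------------------------------------------------


def run_workflow(config: RunConfig) -> dict:
    """Execute the full workflow and return (and write) the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(c.generate_state(1)[0] % (2**31 - 1))
        for name, c in zip(
            ["simulate", "ga_short", "ga_long", "permutation", "proximity"], ss.spawn(5)
        )
    }
    report: dict = {"seed": config.seed, "stage_seeds": seeds, "thresholds": {
        "de_alpha": config.de_alpha,
        "accuracy_floor": config.ga.accuracy_floor,
        "cv_folds": config.cv_folds,
        "permutations": config.permutations,
        "n_random": config.n_random,
        "weight_exponent": config.weight_exponent,
    }}

    stage = "inputs"
    try:
        if config.simulate is not None:
            stage = "simulate"
            logger.info("stage %s: generating synthetic inputs", stage)
            sim_dir = out / "inputs"
            dataset, truth, collection, signaling, physical, tissue_table = simulate_inputs(
                config.simulate, sim_dir, seeds["simulate"]
            )
            seed_gene = truth.planted_seed_gene or "DMD"
            report["inputs"] = {"simulated": True, "dir": sim_dir.name}
        else:
            inp = config.inputs
            assert inp is not None
            logger.info("stage %s: loading user inputs", stage)
            dataset = read_expression(inp.matrix, inp.phenotype, inp.annotation)
            collection = read_gmt(inp.gmt)
            signaling = read_network(inp.signaling_edges, directed=True, tf_list_path=inp.tf_list)
            physical = read_network(inp.ppi_edges, directed=False)
            tissue_table = read_tissue_table(inp.tissue_table)
            truth = None
            seed_gene = inp.proximity_seed_gene
            report["inputs"] = {
                "simulated": False,
                "manifest": {
                    k: _sha256(getattr(inp, k))
                    for k in ("matrix", "phenotype", "annotation", "gmt",
                              "signaling_edges", "ppi_edges", "tf_list", "tissue_table")
                },
            }

        report["cohort"] = {
            "n_subjects": dataset.n_subjects,
            "n_proteins": dataset.n_proteins,
            "n_control": int(dataset.class_mask("control").sum()),
            "n_affected": int(dataset.class_mask("affected").sum()),
        }

        panels: dict[str, classifier.BiomarkerPanel] = {}
        for mode in ("short", "long"):
            stage = f"optimize_{mode}"
            logger.info("stage %s: genetic optimization (%s mode)", stage, mode)
            ga = classifier.GAConfig(
                population_size=config.ga.population_size,
                generations=config.ga.generations,
                tournament_size=config.ga.tournament_size,
                crossover_rate=config.ga.crossover_rate,
                mutation_rate=config.ga.mutation_rate,
                n_min=config.ga.n_min,
                n_max=config.ga.n_max,
                mode=mode,
                accuracy_floor=config.ga.accuracy_floor,
                seed=seeds[f"ga_{mode}"],
                cv_folds=config.cv_folds,
            )
            params, panel, cv = classifier.optimize_parameters(dataset, ga)
            panels[mode] = panel
            _write_panel(panel, dataset, out / f"panel_{mode}.tsv")
            with open(out / f"cv_result_{mode}.json", "w") as fh:
                json.dump(
                    {
                        "params": dataclasses.asdict(params),
                        "fold_accuracies": cv.fold_accuracies,
                        "mean_accuracy": cv.mean_accuracy,
                        "fold_assignment": cv.fold_assignment,
                        "predicted": cv.predicted,
                    },
                    fh,
                    indent=1,
                )
            report[f"panel_{mode}"] = {
                "size": len(panel),
                "params": dataclasses.asdict(params),
                "mean_cv_accuracy": cv.mean_accuracy,
            }
            dm = classifier.compute_distance_matrix(dataset, params)
            pd.DataFrame(dm.values, index=dm.subject_ids, columns=dm.subject_ids).to_csv(
                out / f"distance_matrix_{mode}.tsv", sep="\t"
            )
            if mode == "long":
                long_params = params

        if config.run_permutation:
            stage = "permutation"
            logger.info("stage %s: %d label permutations", stage, config.permutations)
            perm = classifier.permutation_test(
                dataset, long_params, k=config.cv_folds,
                B=config.permutations, seed=seeds["permutation"],
            )
            with open(out / "permutation.json", "w") as fh:
                json.dump(
                    {
                        "B": perm.B,
                        "observed": perm.observed,
                        "p_value": perm.p_value,
                        "null_mean": float(perm.null_accuracies.mean()),
                        "null_max": float(perm.null_accuracies.max()),
                    },
                    fh,
                    indent=1,
                )
            report["permutation"] = {"B": perm.B, "observed": perm.observed, "p_value": perm.p_value}

        stage = "covariates"
        logger.info("stage %s: age and treatment screens on the long panel", stage)
        panel_ids = panels["long"].protein_ids
        age_tab = covariates.age_association(dataset, "both-separately", proteins=panel_ids)
        age_tab.to_csv(out / "age_association.tsv", sep="\t", index=False)
        trt_tab = covariates.treatment_association(dataset, proteins=panel_ids)
        trt_tab.to_csv(out / "treatment_association.tsv", sep="\t", index=False)
        D, ks_p = covariates.ks_age_compare(
            dataset.ages[dataset.class_mask("affected")],
            dataset.ages[dataset.class_mask("control")],
        )
        with open(out / "ks_age.json", "w") as fh:
            json.dump({"D": D, "p_value": ks_p}, fh, indent=1)
        aff_age = age_tab[age_tab["group"] == "affected"]
        report["covariates"] = {
            "n_age_associated": int((aff_age["q_value"] < 0.05).sum()),
            "n_treatment_associated": int((trt_tab["q_value"] < 0.05).sum()),
            "ks_age_p": ks_p,
        }

        stage = "enrichment"
        logger.info("stage %s: ORA and tissue specificity of the long panel", stage)
        panel_genes = dataset.genes_for(panel_ids)
        background = dataset.mapped_genes()
        ora = enrichment.ora_hypergeometric(panel_genes, collection, background)
        ora.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        categories = enrichment.classify_tissue_specificity(tissue_table)
        tissue_bg = [g for g in background if g in categories]
        tissue_panel = [g for g in panel_genes if g in categories]
        fisher = enrichment.fisher_tissue_enrichment(tissue_panel, tissue_bg, categories)
        fisher.to_csv(out / "tissue_enrichment.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "gene": list(categories),
                "category": [c.category for c in categories.values()],
                "tissues": [",".join(c.tissues) for c in categories.values()],
            }
        ).to_csv(out / "tissue_categories.tsv", sep="\t", index=False)
        report["enrichment"] = {
            "n_significant_sets": int((ora["q_value"] < 0.05).sum()) if len(ora) else 0,
            "top_set": str(ora.iloc[0]["set_name"]) if len(ora) else None,
        }

        stage = "network"
        logger.info("stage %s: TF sub-networks and regulator ranking", stage)
        de_set, de_table = network.differential_proteins(dataset, alpha=config.de_alpha)
        de_table.to_csv(out / "differential_proteins.tsv", sep="\t", index=False)
        regulators = network.rank_regulators(
            signaling, sorted(signaling.is_tf), panel_genes, de_set, collection
        )
        regulators.to_csv(out / "regulators.tsv", sep="\t", index=False)
        sub_dir = out / "subnetworks"
        sub_dir.mkdir(exist_ok=True)
        sig_pathways = list(regulators["pathway"]) if len(regulators) else []
        for tf in sorted(set(regulators["regulator"])) if len(regulators) else []:
            sn = network.tf_subnetwork(signaling, tf, panel_genes, de_set)
            with open(sub_dir / f"{tf}.tsv", "w") as fh:
                for u, v in sorted(sn.edges):
                    fh.write(f"{u}\t{v}\n")
        overlap_rows = []
        for i, a in enumerate(sig_pathways):
            for b in sig_pathways[i + 1:]:
                coef, shared = network.pathway_overlap_coefficient(collection[a], collection[b])
                overlap_rows.append({"pathway_a": a, "pathway_b": b,
                                     "overlap_coefficient": coef, "shared_genes": shared})
        pd.DataFrame(overlap_rows, columns=["pathway_a", "pathway_b", "overlap_coefficient", "shared_genes"]).to_csv(
            out / "overlap_map.tsv", sep="\t", index=False
        )
        report["network"] = {
            "n_de_genes": len(de_set),
            "n_significant_pathways": len(regulators),
            "regulators": sorted(set(regulators["regulator"])) if len(regulators) else [],
        }

        stage = "proximity"
        logger.info("stage %s: seed-gene proximity", stage)
        prox_results = []
        for name in (sig_pathways or ([truth.planted_pathway_name] if truth else [])):
            if name not in collection.sets:
                continue
            pw = collection[name] & physical.nodes
            if not pw or seed_gene not in physical.nodes:
                continue
            res = network.proximity_empirical_p(
                physical, seed_gene, pw, n_random=config.n_random,
                rng_seed=seeds["proximity"], pathway_name=name,
            )
            prox_results.append(
                {"pathway": name, "observed_distance": res.observed_distance, "p_value": res.p_value}
            )
        with open(out / "proximity.json", "w") as fh:
            json.dump({"seed_gene": seed_gene, "results": prox_results}, fh, indent=1)
        report["proximity"] = {"seed_gene": seed_gene, "results": prox_results}

    except Exception as exc:
        raise RuntimeError(
            f"stage {stage!r} failed: {exc}; reproduce with "
            f"`signet run --config <config>` after fixing the stage inputs"
        ) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    logger.info("workflow complete; report at %s", out / "report.json")
    return report


def _write_panel(panel: classifier.BiomarkerPanel, dataset: ExpressionDataset, path: Path) -> None:
    pd.DataFrame(
        {
            "assay_id": panel.protein_ids,
            "gene_symbols": [";".join(dataset.gene_map.get(p, [])) for p in panel.protein_ids],
            "n_contributing_subjects": [len(panel.contributing[p]) for p in panel.protein_ids],
        }
    ).to_csv(path, sep="\t", index=False)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
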