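"""End-to-end pipeline: enrichment loop -> aggregation -> consensus -> hubs ->
pathway landscape -> variant prioritization, with a JSON run manifest.

Every stage writes plain files into the output directory, so stages are
resumable and independently inspectable; the manifest records parameters,
seeds and per-stage output paths, and the iterations table mirrors the loop's
per-iteration statistics (seed size, overlapping pathways, new candidates).
All randomness flows from the single master seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Tuple

import yaml

from . import __version__
from .enrichment import (
    aggregate_iterations,
    fisher_enrichment,
    iteration_stratification,
    run_until_saturation,
)
from .inference import InferenceParams
from .io import (
    read_expression,
    read_gmt,
    read_seed,
    read_variants,
    write_network,
    write_seed,
)
from .topology import consensus_network, hub_genes, pathway_landscape
from .variants import prioritize


@dataclass
class RunConfig:
    """Paths and parameters of a full pipeline run (YAML-loadable)."""

    datasets: Dict[str, Tuple[str, str]]  # id -> (expression TSV, phenotype TSV)
    seed_path: str
    gmt_path: str
    outdir: str
    variants_path: Optional[str] = None
    curated_path: Optional[str] = None
    params: InferenceParams = field(default_factory=InferenceParams)
    tau: float = 0.5
    tau_mode: str = "gt"
    alpha: float = 0.05
    hub_quantile: float = 0.95
    category_cutoff: str = "3a"
    max_iterations: int = 25

    def validate(self) -> None:
        paths = [self.seed_path, self.gmt_path]
        for expr, phen in self.datasets.values():
            paths += [expr, phen]
        if self.variants_path:
            paths.append(self.variants_path)
        if self.curated_path:
            paths.append(self.curated_path)
        missing = [p for p in paths if not os.path.exists(p)]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        if not self.datasets:
            raise ValueError("at least one dataset is required")


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    params = InferenceParams(**raw.pop("params", {}))
    datasets = {k: (v["expression"], v["phenotype"]) for k, v in raw.pop("datasets").items()}
    return RunConfig(datasets=datasets, params=params, **raw)


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "params": asdict(config.params),
        "tau": config.tau,
        "alpha": config.alpha,
        "hub_quantile": config.hub_quantile,
        "category_cutoff": config.category_cutoff,
        "stages": {},
    }

    def _stage(name: str):
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    # --- load inputs -------------------------------------------------------
    datasets = {
        ds_id: read_expression(expr, phen)
        for ds_id, (expr, phen) in config.datasets.items()
    }
    seed = read_seed(config.seed_path)
    catalog = read_gmt(config.gmt_path)

    # --- enrichment loop ---------------------------------------------------
    stage = _stage("loop")
    records = run_until_saturation(
        datasets, seed, catalog, config.params,
        tau=config.tau, alpha=config.alpha,
        max_iterations=config.max_iterations, tau_mode=config.tau_mode,
    )
    iterations_path = os.path.join(config.outdir, "iterations.tsv")
    with open(iterations_path, "w") as fh:
        fh.write("iteration\tseed_size_in\tn_overlapping_pathways\toverlapping_pathways\tn_new_candidates\n")
        for r in records:
            fh.write(
                f"{r.index}\t{r.seed_size_in}\t{len(r.overlapping_pathways)}\t"
                f"{','.join(sorted(r.overlapping_pathways))}\t{len(r.new_candidates)}\n"
            )
    stage["iterations_table"] = iterations_path
    stage["n_iterations"] = len(records)
    stage["networks"] = {}
    for r in records:
        for ds_id, net in sorted(r.per_dataset_networks.items()):
            path = os.path.join(config.outdir, f"network_{ds_id}_iter{r.index}.tsv")
            write_network(net, path)
            stage["networks"].setdefault(ds_id, []).append(path)
    final_seed_path = os.path.join(config.outdir, "final_seed.txt")
    write_seed(records[-1].seed_out, final_seed_path)
    stage["final_seed"] = final_seed_path

    # --- aggregation and consensus ----------------------------------------
    stage = _stage("aggregate")
    aggregated = {}
    for ds_id in sorted(datasets):
        agg = aggregate_iterations(records, ds_id)
        aggregated[ds_id] = agg
        path = os.path.join(config.outdir, f"aggregated_{ds_id}.tsv")
        write_network(agg, path)
        stage[ds_id] = path
        strat = iteration_stratification(records, ds_id)
        strat_path = os.path.join(config.outdir, f"stratification_{ds_id}.tsv")
        with open(strat_path, "w") as fh:
            fh.write("iteration\tnode_fraction\tedge_fraction\n")
            for it in sorted(strat):
                fn, fe = strat[it]
                fh.write(f"{it}\t{fn!r}\t{fe!r}\n")

    stage = _stage("consensus")
    if len(aggregated) >= 2:
        consensus = consensus_network(aggregated)
    else:
        consensus = next(iter(aggregated.values())).copy()
    consensus_path = os.path.join(config.outdir, "consensus.tsv")
    write_network(consensus, consensus_path)
    stage["network"] = consensus_path

    # --- hubs ---------------------------------------------------------------
    stage = _stage("hubs")
    hubs_path = os.path.join(config.outdir, "hubs.tsv")
    all_hub_genes: set = set()
    with open(hubs_path, "w") as fh:
        fh.write("dataset\tgene\tdegree\tquantile_threshold\n")
        for ds_id, net in sorted(aggregated.items()):
            if not net.nodes:
                continue
            report = hub_genes(net, config.hub_quantile, dataset_id=ds_id)
            for gene, degree in report.hubs:
                fh.write(f"{ds_id}\t{gene}\t{degree}\t{report.quantile_threshold!r}\n")
                all_hub_genes.add(gene)
    stage["table"] = hubs_path

    # --- pathway landscape --------------------------------------------------
    stage = _stage("landscape")
    enrichments = {}
    universes = {}
    for ds_id, matrix in datasets.items():
        universes[ds_id] = catalog.universe & set(matrix.gene_ids)
        enrichments[ds_id] = fisher_enrichment(
            set(aggregated[ds_id].nodes), catalog, universes[ds_id], config.alpha
        )
    # consensus mixes platforms; its background is the union of the universes
    consensus_universe = set.union(*universes.values())
    enrichments["consensus"] = fisher_enrichment(
        set(consensus.nodes), catalog, consensus_universe, config.alpha
    )
    common = set.intersection(
        *[
            {r.pathway_id for r in results if r.significant}
            for ds_id, results in enrichments.items()
            if ds_id != "consensus"
        ]
    )
    landscape = pathway_landscape(enrichments, sorted(common))
    landscape_path = os.path.join(config.outdir, "landscape.tsv")
    landscape.to_csv(landscape_path, sep="\t", index=False)
    stage["table"] = landscape_path
    stage["common_pathways"] = sorted(common)

    # --- variant prioritization --------------------------------------------
    if config.variants_path:
        stage = _stage("prioritize")
        table = read_variants(config.variants_path)
        curated = set(read_seed(config.curated_path).genes) if config.curated_path else set()
        pathway_genes: set = set()
        for pid in common:
            pathway_genes |= set(catalog.members(pid))
        candidates = (pathway_genes & consensus.nodes) | all_hub_genes | curated
        ranked = prioritize(candidates, table, config.category_cutoff, curated)
        ranked_path = os.path.join(config.outdir, "ranked_genes.tsv")
        ranked.frame.to_csv(ranked_path, sep="\t", index=False)
        stage["table"] = ranked_path
        stage["n_candidates"] = len(candidates)
        stage["n_ranked"] = len(ranked.frame)

    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest_path"] = manifest_path
    return manifest
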