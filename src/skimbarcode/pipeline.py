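"""End-to-end orchestration: simulate (or load) data, then run every stage.

The pipeline bundles the full analysis: data-set assembly, variability
summaries and ranking, divergence-hotspot detection, K2P matrices, NJ trees
with bootstrap supports, the three delimitation methods with a
discrimination-rate table, ASAP-style candidate partitions, median-joining
haplotype networks for the organellar data sets, PCoA of the hotspot data
set, and population-level divergence tables.  All stochastic stages draw
their seeds deterministically from the single pipeline seed, so a rerun
with the same configuration reproduces every numeric table byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import asap as asap_mod
from . import haplonet, ordination, trees, variability
from .delimit import (
    DelimitationResult,
    TaxonVerdict,
    distance_delimitation,
    summarize_discrimination,
    verdict_table,
)
from .distances import (
    combined_population_table,
    pairwise_matrix,
    population_divergence,
    population_matrix,
)
from .errors import ConfigError
from .seqio import (
    RegionAlignment,
    build_datasets,
    read_dataset_definitions,
    read_fasta_alignment,
    read_metadata,
)
from .simulate import SimulationConfig, config_to_yaml, default_config, simulate_dataset
from .trees import FAILURE, taxon_monophyly

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    mode: str = "synthetic"  # "synthetic" | "user"
    simulation: SimulationConfig | None = None  # synthetic mode; default design if None
    data_dir: Path | None = None  # user mode: regions/, metadata.tsv, ...
    dataset_definitions: dict | None = None
    support_threshold: float = 50.0
    bootstrap: int = 1000
    permutations: int = 999
    epsilon: float = 0.0
    k_axes: int = 2
    pad_missing: bool = False
    network_sets: tuple[str, ...] = ("A", "B")
    ordination_set: str = "G"
    population_sets: tuple[str, ...] = ("C", "G")
    log_level: str = "INFO"


@dataclass
class PipelineBundle:
    """In-memory handles to everything the pipeline produced."""

    outdir: Path
    datasets: dict
    variability_reports: dict
    ranking: list[str]
    hotspots: variability.HotspotCall | None
    matrices: dict
    trees: dict
    delimitation: list[DelimitationResult]
    discrimination: pd.DataFrame
    asap_candidates: dict
    networks: dict
    pcoa: ordination.PCoAResult | None
    population_divergence: dict
    metadata: pd.DataFrame
    truth: dict | None = None


def load_user_data(data_dir: Path):
    """Load a data directory (one FASTA per region + metadata + config files)."""
    data_dir = Path(data_dir)
    meta = read_metadata(data_dir / "metadata.tsv")
    comp_path = data_dir / "compartments.json"
    compartments = json.loads(comp_path.read_text()) if comp_path.exists() else {}
    regions = []
    for fasta in sorted((data_dir / "regions").glob("*.fasta")):
        name = fasta.stem
        regions.append(
            read_fasta_alignment(fasta, region_name=name, compartment=compartments.get(name, ""))
        )
    if not regions:
        raise ConfigError(f"{data_dir}/regions contains no FASTA files")
    defs_path = data_dir / "datasets.yaml"
    definitions = read_dataset_definitions(defs_path) if defs_path.exists() else None
    truth_path = data_dir / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    return regions, meta, definitions, truth


def _stage_seeds(seed: int, n: int = 12) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def run_pipeline(config: PipelineConfig) -> PipelineBundle:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    seeds = _stage_seeds(config.seed)

    # ---- inputs -----------------------------------------------------------
    truth = None
    if config.mode == "synthetic":
        sim_config = config.simulation or default_config(seed=config.seed)
        dataset = simulate_dataset(sim_config)
        dataset.write(outdir / "data")
        config_to_yaml(sim_config, outdir / "data" / "simulation_config.yaml")
        regions, metadata, truth = dataset.regions, dataset.metadata, dataset.truth
        definitions = config.dataset_definitions
    elif config.mode == "user":
        if config.data_dir is None:
            raise ConfigError("user mode needs data_dir")
        regions, metadata, definitions, truth = load_user_data(config.data_dir)
        if config.dataset_definitions is not None:
            definitions = config.dataset_definitions
    else:
        raise ConfigError(f"unknown mode {config.mode!r}")

    datasets = build_datasets(regions, definitions, pad_missing=config.pad_missing)
    taxa = sorted(metadata["taxon"].unique())
    logger.info("datasets: %s; %d samples, %d taxa", sorted(datasets), len(metadata), len(taxa))

    # ---- variability and hotspots ----------------------------------------
    reports = {code: variability.summarize(ds) for code, ds in sorted(datasets.items())}
    var_table = pd.DataFrame(
        [
            {
                "data_set": r.code,
                "length_bp": r.length,
                "variable_sites": r.n_variable,
                "pct_variable": f"{r.pct_variable:.3f}",
                "parsimony_informative_sites": r.n_parsimony_informative,
                "pct_parsimony_informative": f"{r.pct_parsimony_informative:.3f}",
            }
            for r in reports.values()
        ]
    )
    var_table.to_csv(outdir / "variability.tsv", sep="\t", index=False)
    ranking = variability.rank_datasets(list(reports.values()))
    (outdir / "ranking.txt").write_text(" > ".join(ranking) + "\n")

    per_region = variability.per_region_variability(regions)
    hotspots = None
    if len(per_region) >= 2:
        hotspots = variability.detect_hotspots(per_region)
        compartment_of = {r.region_name: r.compartment for r in regions}
        pd.DataFrame(
            [
                {
                    "region": name,
                    "compartment": compartment_of.get(name, ""),
                    "pct_variable": value,
                    "threshold": hotspots.threshold,
                    "flagged": name in hotspots.flagged,
                }
                for name, value in per_region.items()
            ]
        ).to_csv(outdir / "hotspots.tsv", sep="\t", index=False)
    else:
        logger.info("fewer than 2 regions: hotspot scan skipped")

    # ---- per data set: distances, trees, delimitation, partitioning ------
    matrices, built_trees, asap_candidates = {}, {}, {}
    delimitation: list[DelimitationResult] = []
    (outdir / "trees").mkdir(exist_ok=True)
    (outdir / "matrices").mkdir(exist_ok=True)
    (outdir / "asap").mkdir(exist_ok=True)
    for k, (code, ds) in enumerate(sorted(datasets.items())):
        matrix = pairwise_matrix(ds)
        matrices[code] = matrix
        matrix.to_dataframe().to_csv(outdir / "matrices" / f"k2p_{code}.tsv", sep="\t")

        tree = trees.bootstrap_supports(ds, B=config.bootstrap, seed=seeds[0] + k)
        built_trees[code] = tree
        trees.write_tree(tree, outdir / "trees" / f"nj_{code}.nwk")
        mono = [
            taxon_monophyly(tree, metadata, t, config.support_threshold) for t in taxa
        ]
        delimitation.append(
            DelimitationResult(
                code=code,
                method="tree",
                verdicts=[
                    TaxonVerdict(m.taxon, m.status, support=m.support) for m in mono
                ],
            )
        )
        delimitation.append(distance_delimitation(matrix, metadata, code))

        ladder = asap_mod.build_partition_ladder(matrix)
        ranked = asap_mod.score_partitions(
            ladder, matrix, n_permutations=config.permutations, seed=seeds[1] + k
        )
        asap_candidates[code] = ranked
        asap_mod.candidate_table(ranked).to_csv(
            outdir / "asap" / f"asap_{code}.tsv", sep="\t", index=False
        )
        asap_mod.partition_table(ranked).to_csv(
            outdir / "asap" / f"asap_{code}_partitions.tsv", sep="\t", index=False
        )
        if ranked:
            delimitation.append(asap_mod.asap_taxon_verdicts(ranked[0], metadata, code))
        else:
            delimitation.append(
                DelimitationResult(
                    code=code,
                    method="asap",
                    verdicts=[TaxonVerdict(t, FAILURE, matching_group=False) for t in taxa],
                )
            )

    discrimination = summarize_discrimination(delimitation)
    discrimination.to_csv(outdir / "discrimination.tsv", sep="\t")
    verdict_table(delimitation).to_csv(outdir / "verdicts.tsv", sep="\t", index=False)

    # ---- haplotype networks ----------------------------------------------
    networks = {}
    (outdir / "networks").mkdir(exist_ok=True)
    for code in config.network_sets:
        if code not in datasets:
            continue
        hapset = haplonet.collapse_haplotypes(datasets[code])
        if hapset.n_haplotypes < 2:
            logger.info("data set %s collapses to one haplotype; no network", code)
            continue
        network = haplonet.median_joining_network(hapset, epsilon=config.epsilon)
        networks[code] = (hapset, network)
        haplonet.write_network(network, outdir / "networks" / f"mjn_{code}.gml")
        node_table, edge_table = haplonet.network_tables(network, metadata)
        node_table.to_csv(outdir / "networks" / f"mjn_{code}_nodes.tsv", sep="\t", index=False)
        edge_table.to_csv(outdir / "networks" / f"mjn_{code}_edges.tsv", sep="\t", index=False)

    # ---- ordination -------------------------------------------------------
    pcoa_result = None
    if config.ordination_set in datasets:
        pcoa_result = ordination.pcoa(matrices[config.ordination_set], k=config.k_axes)
        ordination.coordinates_table(pcoa_result, metadata).to_csv(
            outdir / f"pcoa_{config.ordination_set}.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {
                "eigenvalue": pcoa_result.eigenvalues,
            }
        ).to_csv(outdir / f"pcoa_{config.ordination_set}_eigenvalues.tsv", sep="\t", index=False)

    # ---- population divergence -------------------------------------------
    pop_div = {}
    for k, code in enumerate(config.population_sets):
        if code not in datasets:
            continue
        divs = population_divergence(
            datasets[code], metadata, B=min(config.bootstrap, 1000), seed=seeds[2] + k
        )
        pop_div[code] = divs
        pd.DataFrame(
            [
                {
                    "population_a": d.population_a,
                    "population_b": d.population_b,
                    "mean_k2p": d.mean,
                    "bootstrap_se": d.se,
                    "n_pairs": d.n_pairs,
                }
                for d in divs
            ]
        ).to_csv(outdir / f"population_divergence_{code}.tsv", sep="\t", index=False)
        population_matrix(divs).to_csv(outdir / f"population_matrix_{code}.tsv", sep="\t")
    if len(config.population_sets) >= 2 and all(c in pop_div for c in config.population_sets[:2]):
        lower, upper = config.population_sets[0], config.population_sets[1]
        combined_population_table(pop_div[lower], pop_div[upper]).to_csv(
            outdir / f"population_heatmap_{lower}_{upper}.tsv", sep="\t"
        )

    # ---- provenance -------------------------------------------------------
    with open(outdir / "pipeline_config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "seed": config.seed,
                "mode": config.mode,
                "support_threshold": config.support_threshold,
                "bootstrap": config.bootstrap,
                "permutations": config.permutations,
                "epsilon": config.epsilon,
                "k_axes": config.k_axes,
                "pad_missing": config.pad_missing,
                "ranking": ranking,
            },
            fh,
            sort_keys=False,
        )

    return PipelineBundle(
        outdir=outdir,
        datasets=datasets,
        variability_reports=reports,
        ranking=ranking,
        hotspots=hotspots,
        matrices=matrices,
        trees=built_trees,
        delimitation=delimitation,
        discrimination=discrimination,
        asap_candidates=asap_candidates,
        networks=networks,
        pcoa=pcoa_result,
        population_divergence=pop_div,
        metadata=metadata,
        truth=truth,
    )
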