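"""Synthetic multi-compartment, multi-region alignment generator.

Sequences evolve along a user-supplied species tree (newick, branch lengths
in expected substitutions per site) under the Kimura two-parameter model:
per site, the number of substitution events on a branch of length ``d`` is
Poisson(d * rate_multiplier); each event is a transition with probability
kappa/(kappa+2) and otherwise one of the two transversions, uniformly.
Every event is recorded in a per-region event log (transition vs
transversion per site), so substitution-type statistics are testable.

Below the species tree, population structure is modelled without coalescent
machinery: each population receives founder mutations at half the
configured between-population divergence, and each sample receives private
tip mutations at half the within-population diversity theta (so expected
pairwise diversity within a population is ~theta).  Both are scaled by the
region's rate multiplier, like the tree branches.

A hybrid taxon is a fixed mosaic: each genome compartment's ancestral
sequence is copied wholesale from a designated parent lineage (no per-site
recombination), after which the hybrid's populations and samples vary like
any other taxon's.

Organellar compartments carry exactly one haplotype per sample; there is no
heterozygosity representation anywhere (nrDNA is treated as a single
concerted-evolution sequence per sample).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .errors import ConfigError
from .seqio import (
    COMPARTMENTS,
    DEFAULT_DATASET_DEFINITIONS,
    RegionAlignment,
    write_fasta_alignment,
    write_metadata,
)


@dataclass(frozen=True)
class RegionSpec:
    name: str
    compartment: str
    length: int
    rate_multiplier: float = 1.0


@dataclass(frozen=True)
class HybridSpec:
    """A fixed-mosaic hybrid: whole compartments from one parent each."""

    taxon: str
    parent_a: str
    parent_b: str
    compartment_origin: dict[str, str] = field(default_factory=dict)

    def origin(self, compartment: str) -> str:
        try:
            return self.compartment_origin[compartment]
        except KeyError:
            raise ConfigError(
                f"hybrid {self.taxon}: no parental origin for compartment {compartment}"
            ) from None


@dataclass
class SimulationConfig:
    species_tree: str
    samples_per_population: int
    populations_per_taxon: dict[str, int]
    region_plan: list[RegionSpec]
    kappa: float = 2.0
    within_population_theta: float = 0.001
    between_population_divergence: float = 0.002
    hybrid_spec: HybridSpec | None = None
    missingness: float = 0.0
    seed: int = 0

    def validate(self) -> TreeNode:
        """Validate the config; returns the parsed species tree."""
        if self.samples_per_population < 1:
            raise ConfigError("samples_per_population must be >= 1")
        if self.kappa <= 0:
            raise ConfigError("kappa must be positive")
        if self.within_population_theta < 0 or self.between_population_divergence < 0:
            raise ConfigError("divergence parameters must be >= 0")
        if not 0 <= self.missingness < 1:
            raise ConfigError("missingness must be in [0, 1)")
        if not self.region_plan:
            raise ConfigError("region plan is empty")
        seen = set()
        for r in self.region_plan:
            if r.length < 1:
                raise ConfigError(f"region {r.name}: length must be >= 1")
            if r.rate_multiplier < 0:
                raise ConfigError(f"region {r.name}: rate_multiplier must be >= 0")
            if r.compartment not in COMPARTMENTS:
                raise ConfigError(
                    f"region {r.name}: unknown compartment {r.compartment!r}"
                )
            if r.name in seen:
                raise ConfigError(f"duplicate region name {r.name}")
            seen.add(r.name)
        tree = parse_species_tree(self.species_tree)
        leaves = {t.name for t in tree.tips()}
        hybrid_taxon = self.hybrid_spec.taxon if self.hybrid_spec else None
        if self.hybrid_spec:
            for parent in (self.hybrid_spec.parent_a, self.hybrid_spec.parent_b):
                if parent not in leaves:
                    raise ConfigError(
                        f"hybrid parent {parent!r} is not a leaf of the species tree"
                    )
            bad = set(self.hybrid_spec.compartment_origin.values()) - {
                self.hybrid_spec.parent_a,
                self.hybrid_spec.parent_b,
            }
            if bad:
                raise ConfigError(f"hybrid compartment origins must be a parent: {bad}")
        for taxon, n_pops in self.populations_per_taxon.items():
            if n_pops < 1:
                raise ConfigError(f"taxon {taxon}: populations must be >= 1")
            if taxon != hybrid_taxon and taxon not in leaves:
                raise ConfigError(f"taxon {taxon!r} is not a leaf of the species tree")
        return tree


@dataclass
class SyntheticDataset:
    regions: list[RegionAlignment]
    metadata: pd.DataFrame
    truth: dict
    event_log: dict

    @property
    def region_by_name(self) -> dict[str, RegionAlignment]:
        return {r.region_name: r for r in self.regions}

    def write(self, directory: str | Path) -> None:
        """Write one FASTA per region, metadata TSV, truth JSON, data-set YAML."""
        directory = Path(directory)
        (directory / "regions").mkdir(parents=True, exist_ok=True)
        for region in self.regions:
            write_fasta_alignment(region, directory / "regions" / f"{region.region_name}.fasta")
        write_metadata(self.metadata, directory / "metadata.tsv")
        compartments = {r.region_name: r.compartment for r in self.regions}
        with open(directory / "compartments.json", "w") as fh:
            json.dump(compartments, fh, indent=1)
        with open(directory / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)
        with open(directory / "datasets.yaml", "w") as fh:
            yaml.safe_dump(DEFAULT_DATASET_DEFINITIONS, fh, sort_keys=False)
        totals = {
            name: {
                "transitions": int(log["per_site_transitions"].sum()),
                "transversions": int(log["per_site_transversions"].sum()),
            }
            for name, log in self.event_log.items()
        }
        with open(directory / "event_log.json", "w") as fh:
            json.dump(totals, fh, indent=1)


def parse_species_tree(newick: str) -> TreeNode:
    """Parse and check the species tree: binary, named leaves, lengths >= 0."""
    try:
        tree = TreeNode.read(io.StringIO(newick), convert_underscores=False)
    except Exception as exc:  # skbio raises several parser error types
        raise ConfigError(f"unreadable newick species tree: {exc}") from exc
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ConfigError("species tree needs at least 2 leaves")
    names = [t.name for t in tips]
    if None in names or len(set(names)) != len(names):
        raise ConfigError("species tree leaves must carry unique names")
    for node in tree.non_tips(include_self=True):
        n_children = len(node.children)
        limit = 3 if node is tree else 2  # unrooted trees may have a trifurcating root
        if not 2 <= n_children <= limit:
            raise ConfigError("species tree must be binary")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ConfigError("species tree branch lengths must be >= 0")
    return tree


_P_TS_CACHE = {}


def _evolve(
    seq: np.ndarray,
    d: float,
    kappa: float,
    rng: np.random.Generator,
    log_ts: np.ndarray | None = None,
    log_tv: np.ndarray | None = None,
) -> np.ndarray:
    """Evolve an encoded sequence over branch length d (expected subs/site)."""
    out = seq.copy()
    if d <= 0:
        return out
    n_events = rng.poisson(d, seq.size)
    p_ts = kappa / (kappa + 2.0)
    for round_ in range(int(n_events.max())):
        idx = np.nonzero(n_events > round_)[0]
        cur = out[idx]
        is_ts = rng.random(idx.size) < p_ts
        tv_choice = rng.integers(0, 2, idx.size)
        # purines (even codes) transvert to {C,T}; pyrimidines to {A,G}
        tv_target = np.where(cur % 2 == 0, 1 + 2 * tv_choice, 2 * tv_choice).astype(np.uint8)
        out[idx] = np.where(is_ts, cur ^ 2, tv_target)
        if log_ts is not None:
            np.add.at(log_ts, idx[is_ts], 1)
            np.add.at(log_tv, idx[~is_ts], 1)
    return out


def _decode_rows(matrix: np.ndarray) -> list[str]:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    full = np.full(256, ord("N"), dtype=np.uint8)
    full[:4] = lut
    return [full[row].tobytes().decode("ascii") for row in matrix]


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Simulate all regions; same seed and config give byte-identical output."""
    tree = config.validate()
    rng = np.random.default_rng(config.seed)

    samples: list[tuple[str, str, str]] = []  # (sample_id, taxon, population)
    for taxon, n_pops in config.populations_per_taxon.items():
        for p in range(1, n_pops + 1):
            pop = f"{taxon}-p{p}"
            for k in range(1, config.samples_per_population + 1):
                samples.append((f"{taxon}-p{p}-{k}", taxon, pop))
    sample_ids = [s[0] for s in samples]

    mean_path = _mean_tip_path(tree)
    regions: list[RegionAlignment] = []
    event_log: dict[str, dict] = {}
    for region in config.region_plan:
        L = region.length
        log_ts = np.zeros(L, dtype=np.int64)
        log_tv = np.zeros(L, dtype=np.int64)
        root_seq = rng.integers(0, 4, L, dtype=np.uint8)
        taxon_seq: dict[str, np.ndarray] = {}

        def walk(node: TreeNode, seq: np.ndarray) -> None:
            for child in node.children:
                d = (child.length or 0.0) * region.rate_multiplier
                child_seq = _evolve(seq, d, config.kappa, rng, log_ts, log_tv)
                if child.is_tip():
                    taxon_seq[child.name] = child_seq
                else:
                    walk(child, child_seq)

        walk(tree, root_seq)
        if config.hybrid_spec:
            taxon_seq[config.hybrid_spec.taxon] = taxon_seq[
                config.hybrid_spec.origin(region.compartment)
            ]

        rows = np.empty((len(samples), L), dtype=np.uint8)
        d_pop = 0.5 * config.between_population_divergence * region.rate_multiplier
        d_tip = 0.5 * config.within_population_theta * region.rate_multiplier
        row = 0
        for taxon, n_pops in config.populations_per_taxon.items():
            base = taxon_seq[taxon]
            for _p in range(n_pops):
                pop_seq = _evolve(base, d_pop, config.kappa, rng, log_ts, log_tv)
                for _k in range(config.samples_per_population):
                    rows[row] = _evolve(pop_seq, d_tip, config.kappa, rng, log_ts, log_tv)
                    row += 1
        if config.missingness > 0:
            masked = rng.random(rows.shape) < config.missingness
            rows[masked] = 255
        regions.append(
            RegionAlignment(
                region_name=region.name,
                compartment=region.compartment,
                samples=list(sample_ids),
                sequences=_decode_rows(rows),
            )
        )
        event_log[region.name] = {
            "per_site_transitions": log_ts,
            "per_site_transversions": log_tv,
        }

    multipliers = {r.name: r.rate_multiplier for r in config.region_plan}
    median_rate = float(np.median(list(multipliers.values())))
    planted = [
        name
        for name, m in multipliers.items()
        if median_rate > 0 and m >= 10.0 * median_rate
    ]
    extra = config.between_population_divergence + config.within_population_theta
    truth = {
        "taxon_partition": {sid: taxon for sid, taxon, _ in samples},
        "population_of": {sid: pop for sid, _, pop in samples},
        "region_rate_multipliers": multipliers,
        "planted_hotspots": planted,
        "per_region_expected_divergence": {
            name: m * (mean_path + extra) for name, m in multipliers.items()
        },
        "seed": config.seed,
    }
    metadata = pd.DataFrame(samples, columns=["sample_id", "taxon", "population"])
    return SyntheticDataset(regions=regions, metadata=metadata, truth=truth, event_log=event_log)


def _mean_tip_path(tree: TreeNode) -> float:
    """Mean pairwise path length between species-tree leaves."""
    work = tree.copy()
    for node in work.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    dm = work.tip_tip_distances()
    iu = np.triu_indices(dm.shape[0], k=1)
    return float(np.asarray(dm.data)[iu].mean())


# ---------------------------------------------------------------------------
# Default study design
# ---------------------------------------------------------------------------

#: Species tree for the default design: four closely related mountain-pine
#: taxa plus an outgroup-like congener on a long branch; lengths in expected
#: substitutions/site, of the order seen between closely related conifers.
DEFAULT_SPECIES_TREE = (
    "(((mugo:0.002,(uliginosa:0.001,rotundata:0.001):0.001):0.002,"
    "uncinata:0.004):0.004,sylvestris:0.008);"
)

#: Relative substitution-rate multipliers by compartment role.  Divergence
#: hotspot regions are planted at 18x the plastid-gene baseline, matching the
#: roughly twenty-fold variability contrast the method is designed to detect.
DEFAULT_RATES = {
    "plastid_gene": 1.0,
    "plastid_spacer": 2.0,
    "mito_gene": 6.0,
    "nrDNA_part": 0.7,
    "hotspot": 18.0,
}


def default_region_plan() -> list[RegionSpec]:
    """Scaled-down region inventory: 57 plastid genes, 18 spacers, 15
    mitochondrial genes and the 5 nrDNA cistron parts at ~1/10 real length."""
    plan: list[RegionSpec] = []
    plan.append(RegionSpec("matK", "plastid_gene", 152, DEFAULT_RATES["plastid_gene"]))
    plan.append(RegionSpec("rbcL", "plastid_gene", 143, DEFAULT_RATES["plastid_gene"]))
    for name in ("rps1", "rps2", "rps14"):
        plan.append(RegionSpec(name, "plastid_gene", 80, DEFAULT_RATES["hotspot"]))
    for i in range(1, 53):
        plan.append(RegionSpec(f"cpgene{i:02d}", "plastid_gene", 80, DEFAULT_RATES["plastid_gene"]))
    for name in ("ycf3-psaA", "trnE-clpP"):
        plan.append(RegionSpec(name, "plastid_spacer", 80, DEFAULT_RATES["hotspot"]))
    for i in range(1, 17):
        plan.append(RegionSpec(f"spacer{i:02d}", "plastid_spacer", 39, DEFAULT_RATES["plastid_spacer"]))
    for i in range(1, 16):
        plan.append(RegionSpec(f"mtgene{i:02d}", "mito_gene", 56, DEFAULT_RATES["mito_gene"]))
    for name, length in (("18S", 181), ("ITS1", 248), ("5.8S", 16), ("ITS2", 24), ("26S", 316)):
        plan.append(RegionSpec(name, "nrDNA_part", length, DEFAULT_RATES["nrDNA_part"]))
    return plan


def default_config(seed: int = 0) -> SimulationConfig:
    """The default study design: 32 samples, 6 taxa (4 complex members, one
    congener, one fixed-mosaic hybrid), 16 populations, 95 regions across
    three genome compartments with planted divergence hotspots."""
    return SimulationConfig(
        species_tree=DEFAULT_SPECIES_TREE,
        samples_per_population=2,
        populations_per_taxon={
            "mugo": 3,
            "uncinata": 3,
            "uliginosa": 2,
            "rotundata": 4,
            "sylvestris": 2,
            "rhaetica": 2,
        },
        region_plan=default_region_plan(),
        kappa=2.0,
        within_population_theta=0.001,
        between_population_divergence=0.002,
        hybrid_spec=HybridSpec(
            taxon="rhaetica",
            parent_a="sylvestris",
            parent_b="mugo",
            compartment_origin={
                "plastid_gene": "sylvestris",
                "plastid_spacer": "sylvestris",
                "mito_gene": "mugo",
                "nrDNA_part": "sylvestris",
            },
        ),
        seed=seed,
    )


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    doc = {
        "species_tree": config.species_tree,
        "samples_per_population": config.samples_per_population,
        "populations_per_taxon": dict(config.populations_per_taxon),
        "region_plan": [
            [r.name, r.compartment, r.length, r.rate_multiplier] for r in config.region_plan
        ],
        "kappa": config.kappa,
        "within_population_theta": config.within_population_theta,
        "between_population_divergence": config.between_population_divergence,
        "missingness": config.missingness,
        "seed": config.seed,
    }
    if config.hybrid_spec:
        doc["hybrid_spec"] = {
            "taxon": config.hybrid_spec.taxon,
            "parent_a": config.hybrid_spec.parent_a,
            "parent_b": config.hybrid_spec.parent_b,
            "compartment_origin": dict(config.hybrid_spec.compartment_origin),
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    hybrid = None
    if doc.get("hybrid_spec"):
        h = doc["hybrid_spec"]
        hybrid = HybridSpec(
            taxon=h["taxon"],
            parent_a=h["parent_a"],
            parent_b=h["parent_b"],
            compartment_origin=dict(h.get("compartment_origin", {})),
        )
    return SimulationConfig(
        species_tree=doc["species_tree"],
        samples_per_population=int(doc["samples_per_population"]),
        populations_per_taxon={k: int(v) for k, v in doc["populations_per_taxon"].items()},
        region_plan=[RegionSpec(n, c, int(l), float(m)) for n, c, l, m in doc["region_plan"]],
        kappa=float(doc.get("kappa", 2.0)),
        within_population_theta=float(doc.get("within_population_theta", 0.001)),
        between_population_divergence=float(doc.get("between_population_divergence", 0.002)),
        hybrid_spec=hybrid,
        missingness=float(doc.get("missingness", 0.0)),
        seed=int(doc.get("seed", 0)),
    )
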