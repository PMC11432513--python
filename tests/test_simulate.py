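import numpy as np
import pytest

from skimbarcode.distances import k2p_distance
from skimbarcode.errors import ConfigError
from skimbarcode.simulate import (
    HybridSpec,
    RegionSpec,
    SimulationConfig,
    config_from_yaml,
    config_to_yaml,
    default_config,
    simulate_dataset,
)


def two_taxon_config(seed, length=10000, path_length=0.01, theta=0.0, kappa=2.0):
    half = path_length / 2
    return SimulationConfig(
        species_tree=f"(x:{half},y:{half});",
        samples_per_population=1,
        populations_per_taxon={"x": 1, "y": 1},
        region_plan=[RegionSpec("locus", "plastid_gene", length, 1.0)],
        kappa=kappa,
        within_population_theta=theta,
        between_population_divergence=0.0,
        seed=seed,
    )


def test_same_seed_byte_identical_output(tmp_path):
    a = simulate_dataset(default_config(seed=7))
    b = simulate_dataset(default_config(seed=7))
    for ra, rb in zip(a.regions, b.regions):
        assert ra.sequences == rb.sequences
    a.write(tmp_path / "a")
    b.write(tmp_path / "b")
    fa = (tmp_path / "a" / "regions" / "matK.fasta").read_bytes()
    fb = (tmp_path / "b" / "regions" / "matK.fasta").read_bytes()
    assert fa == fb
    c = simulate_dataset(default_config(seed=8))
    assert c.regions[0].sequences != a.regions[0].sequences


def test_zero_divergence_all_identical():
    config = SimulationConfig(
        species_tree="(x:0.0,y:0.0);",
        samples_per_population=3,
        populations_per_taxon={"x": 2, "y": 2},
        region_plan=[RegionSpec("locus", "plastid_gene", 500, 1.0)],
        within_population_theta=0.0,
        between_population_divergence=0.0,
        seed=0,
    )
    ds = simulate_dataset(config)
    assert len(set(ds.regions[0].sequences)) == 1


def test_k2p_estimate_recovers_true_divergence():
    """Mean pairwise K2P across 20 seeds ~ true path length 0.01."""
    estimates = []
    for seed in range(20):
        ds = simulate_dataset(two_taxon_config(seed))
        a, b = ds.regions[0].sequences
        estimates.append(k2p_distance(a, b))
    mean = float(np.mean(estimates))
    se = float(np.std(estimates, ddof=1) / np.sqrt(len(estimates)))
    assert abs(mean - 0.01) <= 3 * se


def test_event_log_transition_bias_under_high_kappa():
    """kappa=8: transitions outnumber transversions (binomial test, 5%)."""
    from scipy.stats import binomtest

    ds = simulate_dataset(two_taxon_config(seed=2, length=20000, path_length=0.05, kappa=8.0))
    log = ds.event_log["locus"]
    n_ts = int(log["per_site_transitions"].sum())
    n_tv = int(log["per_site_transversions"].sum())
    assert n_ts + n_tv > 100
    # under kappa=8 the transition fraction is 8/10; reject 50:50 decisively
    assert binomtest(n_ts, n_ts + n_tv, 0.5, alternative="greater").pvalue < 0.05
    assert n_ts > n_tv


def test_event_log_matches_observed_differences():
    ds = simulate_dataset(two_taxon_config(seed=3, length=5000, path_length=0.02))
    from skimbarcode.alphabet import encode

    a, b = (encode(s) for s in ds.regions[0].sequences)
    diff_sites = int((a != b).sum())
    log = ds.event_log["locus"]
    n_events = int(log["per_site_transitions"].sum() + log["per_site_transversions"].sum())
    # every observed difference requires at least one logged event
    assert n_events >= diff_sites > 0


def test_hybrid_compartments_copy_designated_parent():
    config = SimulationConfig(
        species_tree="(p1:0.05,p2:0.05);",
        samples_per_population=2,
        populations_per_taxon={"p1": 1, "p2": 1, "hyb": 1},
        region_plan=[
            RegionSpec("cp", "plastid_gene", 400, 1.0),
            RegionSpec("mt", "mito_gene", 400, 1.0),
        ],
        within_population_theta=0.0,
        between_population_divergence=0.0,
        hybrid_spec=HybridSpec(
            taxon="hyb",
            parent_a="p1",
            parent_b="p2",
            compartment_origin={"plastid_gene": "p1", "mito_gene": "p2"},
        ),
        seed=4,
    )
    ds = simulate_dataset(config)
    by_name = ds.region_by_name
    cp, mt = by_name["cp"], by_name["mt"]
    assert cp.sequence_of("hyb-p1-1") == cp.sequence_of("p1-p1-1")
    assert mt.sequence_of("hyb-p1-1") == mt.sequence_of("p2-p1-1")
    assert cp.sequence_of("hyb-p1-1") != cp.sequence_of("p2-p1-1")


def test_default_design_shape(default_dataset):
    assert len(default_dataset.metadata) == 32
    assert default_dataset.metadata["taxon"].nunique() == 6
    assert len(default_dataset.regions) == 95
    by_comp = {}
    for r in default_dataset.regions:
        by_comp[r.compartment] = by_comp.get(r.compartment, 0) + 1
    assert by_comp == {
        "plastid_gene": 57,
        "plastid_spacer": 18,
        "mito_gene": 15,
        "nrDNA_part": 5,
    }
    # organellar regions: exactly one sequence (haplotype) per sample
    for r in default_dataset.regions:
        assert len(r.sequences) == 32
    assert set(default_dataset.truth["planted_hotspots"]) == {
        "rps1",
        "rps2",
        "rps14",
        "trnE-clpP",
        "ycf3-psaA",
    }


def test_missingness_masks_sites():
    config = two_taxon_config(seed=5, length=2000)
    config.missingness = 0.1
    ds = simulate_dataset(config)
    seq = ds.regions[0].sequences[0]
    frac = seq.count("N") / len(seq)
    assert 0.05 < frac < 0.15


def _with_bad_hybrid(c):
    c.populations_per_taxon = {"x": 1, "y": 1, "hyb": 1}
    c.hybrid_spec = HybridSpec("hyb", "nope", "y", {"plastid_gene": "nope"})


@pytest.mark.parametrize(
    "mutate",
    [
        lambda c: setattr(c, "species_tree", "not a tree"),
        lambda c: setattr(c, "species_tree", "((a:1,b:1,c:1):1,d:1);"),  # non-binary
        _with_bad_hybrid,  # hybrid parent absent from the tree
        lambda c: setattr(c, "region_plan", [RegionSpec("r", "plastid_gene", 0, 1.0)]),
        lambda c: setattr(c, "region_plan", [RegionSpec("r", "plastid_gene", 10, -1.0)]),
        lambda c: setattr(c, "populations_per_taxon", {"x": 1, "zz": 1}),
    ],
)
def test_config_validation_errors(mutate):
    config = two_taxon_config(seed=0)
    mutate(config)
    with pytest.raises(ConfigError):
        simulate_dataset(config)


def test_config_yaml_roundtrip(tmp_path):
    config = default_config(seed=9)
    config_to_yaml(config, tmp_path / "c.yaml")
    back = config_from_yaml(tmp_path / "c.yaml")
    assert back == config
    assert simulate_dataset(back).regions[0].sequences == simulate_dataset(config).regions[0].sequences
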