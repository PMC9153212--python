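"""The cohort generator: determinism, conservation, forward-model limits."""

import numpy as np
import pytest

from clonescape import (
    SimulationConfig,
    simulate_baf_segments,
    simulate_contaminated_normals,
    simulate_read_counts,
    simulate_truth,
)
from clonescape.errors import InvalidConfigError
from clonescape.synthetic import CNVEventSpec


def test_invalid_configs_rejected():
    with pytest.raises(InvalidConfigError):
        SimulationConfig(n_clusters=0).validate()
    with pytest.raises(InvalidConfigError):
        SimulationConfig(base_error_rate=0.0).validate()
    with pytest.raises(InvalidConfigError):
        SimulationConfig(contamination_fractions=[1.0, 0.0]).validate()
    with pytest.raises(InvalidConfigError):
        SimulationConfig(
            n_clusters=3,
            cnv_events=[CNVEventSpec(5, "1", 2, 1)],
        ).validate()


def test_single_cluster_degenerate_case():
    cfg = SimulationConfig(n_clusters=1, cnv_events=[],
                           n_normals=1, contamination_fractions=[0.0])
    truth = simulate_truth(cfg, seed=2)
    assert set(truth.tree.nodes) == {"N0"}
    assert set(truth.variant_assignments.values()) == {"N0"}


def test_convergent_driver_contract():
    cfg = SimulationConfig(n_clusters=5, convergent_driver="PIK3CA")
    truth = simulate_truth(cfg, seed=3)
    drivers = [v for v in truth.variants if v.gene == "PIK3CA"]
    assert len(drivers) >= 2
    assert len({v.pos for v in drivers}) == len(drivers)
    branches = {truth.variant_assignments[v.variant_id] for v in drivers}
    assert len(branches) >= 2 and "N0" not in branches


def test_truth_determinism_byte_identical():
    cfg = SimulationConfig()
    a = simulate_truth(cfg, seed=9).to_json()
    b = simulate_truth(SimulationConfig(), seed=9).to_json()
    assert a == b


def test_observation_determinism():
    cfg = SimulationConfig(n_regions=3, n_clusters=3)
    truth = simulate_truth(cfg, seed=5)
    c1 = simulate_read_counts(truth, cfg, seed=6)
    c2 = simulate_read_counts(truth, cfg, seed=6)
    assert c1.alt.equals(c2.alt) and c1.ref.equals(c2.ref)
    s1 = simulate_baf_segments(truth, cfg, seed=7)
    s2 = simulate_baf_segments(truth, cfg, seed=7)
    assert s1.equals(s2)
    n1 = simulate_contaminated_normals(truth, cfg, seed=8)
    n2 = simulate_contaminated_normals(truth, cfg, seed=8)
    assert n1.alt.equals(n2.alt)


def test_fraction_conservation_and_ccf_monotone():
    cfg = SimulationConfig(n_regions=6, n_clusters=8)
    truth = simulate_truth(cfg, seed=13)
    for rc in truth.region_compositions:
        assert sum(rc.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(f >= 0 for f in rc.fractions.values())
    for s in truth.tumor_samples:
        for nid, node in truth.tree.nodes.items():
            if node.parent_id is None:
                continue
            assert (
                truth.node_ccf(node.parent_id, s)
                >= truth.node_ccf(nid, s) - 1e-12
            )


def test_forward_model_monte_carlo_mean():
    """Founder VAF: t=0.8 diploid gives v=0.4; empirical mean within 5e-3."""
    cfg = SimulationConfig(
        n_regions=1, n_clusters=1, cnv_events=[], base_error_rate=1e-12,
        n_normals=1, contamination_fractions=[0.0], deep_depth=2500,
    )
    truth = simulate_truth(cfg, seed=21)
    truth.purities["R1"] = 0.8
    founder = truth.variants[0].variant_id
    assert truth.expected_vaf(founder, "R1") == pytest.approx(0.4)
    rng_seeds = range(100)
    vafs = []
    for sd in rng_seeds:
        counts = simulate_read_counts(truth, cfg, seed=1000 + sd)
        sub = counts.vaf.loc[[v.variant_id for v in truth.variants]]
        vafs.extend(sub["R1"].tolist())
    assert np.mean(vafs) == pytest.approx(0.4, abs=5e-3)


def test_error_floor_mean_alt_count():
    """Absent variant at depth 2500, e=1e-3: mean alt ~ 2.5 (binomial mean)."""
    cfg = SimulationConfig(
        n_regions=2, n_clusters=3, cnv_events=[], base_error_rate=1e-3,
        n_normals=1, contamination_fractions=[0.0],
    )
    truth = simulate_truth(cfg, seed=31)
    # zero out one branch everywhere: its variants become pure error
    victim = "N2"
    for rc in truth.region_compositions:
        mass = sum(rc.fractions[n] for n in truth.tree.subtree(victim))
        for n in truth.tree.subtree(victim):
            rc.fractions[n] = 0.0
        rc.fractions["N0"] += mass
    absent = [v for v, n in truth.variant_assignments.items() if n == victim]
    alts = []
    for sd in range(60):
        counts = simulate_read_counts(truth, cfg, seed=2000 + sd)
        alts.extend(counts.alt.loc[absent].to_numpy().ravel().tolist())
    assert np.mean(alts) == pytest.approx(2.5, rel=0.1)


def test_depth_floor_never_zero():
    cfg = SimulationConfig(n_regions=2, n_clusters=2, deep_depth=1.0,
                           cnv_events=[])
    truth = simulate_truth(cfg, seed=41)
    counts = simulate_read_counts(truth, cfg, seed=42)
    assert (counts.depth.to_numpy() >= 1).all()


def test_forward_model_convergence_at_extreme_depth():
    """Empirical VAF converges to the model VAF (depth 1e6, tol 1e-3)."""
    cfg = SimulationConfig(
        n_regions=2, n_clusters=3, base_error_rate=1e-12, deep_depth=1e6,
    )
    truth = simulate_truth(cfg, seed=51)
    counts = simulate_read_counts(truth, cfg, seed=52)
    for v in truth.variants[::5]:
        for s in truth.tumor_samples:
            exp = truth.expected_vaf(v.variant_id, s)
            obs = float(counts.vaf.loc[v.variant_id, s])
            assert obs == pytest.approx(exp, abs=1e-3)


class TestBafSegments:
    def test_null_segment_shrinks_to_zero(self):
        cfg = SimulationConfig(
            n_regions=1, n_clusters=3, snps_per_segment=5000,
            cnv_events=[CNVEventSpec(2, "17", 1, 0)],
        )
        truth = simulate_truth(cfg, seed=61)
        # remove the CNV-bearing lineage from the region
        for rc in truth.region_compositions:
            mass = sum(rc.fractions[n] for n in truth.tree.subtree("N2"))
            for n in truth.tree.subtree("N2"):
                rc.fractions[n] = 0.0
            rc.fractions["N0"] += mass
        segs = simulate_baf_segments(truth, cfg, seed=62)
        assert segs.baf_dev.abs().max() < 0.01

    def test_biallelic_duplication_ai_invisible(self):
        cfg = SimulationConfig(
            n_regions=1, n_clusters=1, snps_per_segment=2000,
            cnv_events=[CNVEventSpec(0, "7", 2, 2)],
        )
        truth = simulate_truth(cfg, seed=63)
        truth.purities["R1"] = 0.6
        for seg in truth.segments:
            seg.cp["R1"] = 0.6
            seg.c["R1"] = 3.2
        segs = simulate_baf_segments(truth, cfg, seed=64)
        row = segs.iloc[0]
        assert row.baf_dev < 0.01  # balanced gain leaves BAF centered
        assert row.c == pytest.approx(2 + 2 * 0.6, abs=0.15)


class TestContaminatedNormals:
    def _truth(self, fractions, seed=71):
        cfg = SimulationConfig(
            n_regions=3, n_clusters=4, cnv_events=[], base_error_rate=1e-12,
            n_normals=len(fractions), contamination_fractions=fractions,
        )
        return cfg, simulate_truth(cfg, seed)

    def test_zero_contamination_zero_alt(self):
        cfg, truth = self._truth([0.0])
        counts = simulate_contaminated_normals(truth, cfg, seed=72)
        assert counts.alt["G1"].sum() == 0

    def test_founder_vaf_scale(self):
        """phi=0.02 at a diploid founder gives expected VAF 0.01."""
        cfg, truth = self._truth([0.02])
        founder = truth.variants[0].variant_id
        assert truth.expected_vaf(founder, "G1") == pytest.approx(0.01)

    def test_clone_subset_contract(self):
        cfg, truth = self._truth([0.12])
        phi, fractions = truth.contamination["G1"]
        inside = {n for n, f in fractions.items() if f > 0}
        outside = [
            v for v, n in truth.variant_assignments.items()
            if n not in inside and n not in
            {d for i in inside for d in truth.tree.ancestors(i)}
        ]
        present = [
            v for v, n in truth.variant_assignments.items() if n in inside
        ]
        assert any(truth.expected_vaf(v, "G1") > 0 for v in present)
        for v in outside[:10]:
            node = truth.variant_assignments[v]
            if all(i not in truth.tree.subtree(node) for i in inside):
                assert truth.expected_vaf(v, "G1") == 0.0
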