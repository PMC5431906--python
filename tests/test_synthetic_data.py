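"""Ground-truth generators: determinism, planted structure, sampling oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from cgsplice.annotations import consecutive_gene_pairs, intergenic_distance, write_annotation
from cgsplice.synthetic_data import (
    ConfigurationError,
    GroundTruth,
    MotifPlantSpec,
    SimulationConfig,
    plant_motifs,
    simulate_annotation,
    simulate_cg_readthrough,
    simulate_dose_response_profiles,
    simulate_junction_counts,
    simulate_sirna_counts,
)


class TestAnnotationGeometry:
    def test_pair_construction(self):
        ann, genome = simulate_annotation(SimulationConfig(n_gene_pairs=10, seed=7))
        assert len(ann.genes) == 20
        pairs = consecutive_gene_pairs(ann, same_strand_only=True)
        intra = [(a, b) for a, b in pairs if a.id[:-1] == b.id[:-1]]
        assert len(intra) == 10
        assert all(a.strand == b.strand for a, b in intra)

    def test_determinism_byte_identical_gtf(self, tmp_path):
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        for p in (p1, p2):
            ann, _ = simulate_annotation(SimulationConfig(n_gene_pairs=5, seed=99))
            write_annotation(ann, p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_fixed_intergenic_distance_round_trips(self):
        cfg = SimulationConfig(n_gene_pairs=6, intergenic_len=(5000, 5000), seed=3)
        ann, _ = simulate_annotation(cfg)
        for p in range(6):
            a, b = ann.genes[f"G{p:03d}A"], ann.genes[f"G{p:03d}B"]
            assert intergenic_distance(a, b).distance == 5000

    def test_sequence_covers_features_and_is_canonical(self):
        ann, genome = simulate_annotation(SimulationConfig(n_gene_pairs=3, seed=5))
        seq = genome["chr1"]
        assert len(seq) >= max(g.end for g in ann.genes.values())
        for g in ann.genes.values():
            for lo, hi in g.longest_transcript().introns():
                assert seq[lo : lo + 2] == "GT" and seq[hi - 2 : hi] == "AG"

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_gene_pairs=0).validate()
        with pytest.raises(ConfigurationError):
            SimulationConfig(dose_grid=(0.0, 0.1, 0.1, 1.0)).validate()
        with pytest.raises(ConfigurationError):
            SimulationConfig(exon_len=(0, 10)).validate()


class TestDoseResponseProfiles:
    def test_zero_effect_means_flat(self):
        cfg = SimulationConfig(
            psi_shape_proportions={"flat": 1.0}, noise_sd=0.0, seed=1
        )
        truth = simulate_dose_response_profiles(cfg, n_events=20)
        m = truth.psi_matrix.to_numpy()
        assert (truth.cluster_labels == "flat").all()
        assert np.allclose(m, m[:, [0]])

    def test_noiseless_down_is_non_increasing(self):
        cfg = SimulationConfig(
            psi_shape_proportions={"down": 1.0}, noise_sd=0.0, seed=2
        )
        truth = simulate_dose_response_profiles(cfg, n_events=15)
        m = truth.psi_matrix.to_numpy()
        assert (np.diff(m, axis=1) <= 0).all()

    def test_noise_magnitude_matches_folded_normal(self):
        # E|N(0, sigma)| = sigma * sqrt(2/pi) ~= 0.0399 for sigma = 0.05
        cfg = SimulationConfig(noise_sd=0.05, seed=4)
        truth = simulate_dose_response_profiles(cfg, n_events=2000)
        mad = float(
            np.abs(truth.psi_matrix.to_numpy() - truth.noiseless_psi.to_numpy()).mean()
        )
        expected = 0.05 * math.sqrt(2 / math.pi)
        assert abs(mad - expected) / expected < 0.10

    def test_values_clipped_to_unit_interval(self):
        cfg = SimulationConfig(noise_sd=0.3, seed=6)
        truth = simulate_dose_response_profiles(cfg, n_events=200)
        m = truth.psi_matrix.to_numpy()
        assert m.min() >= 0.0 and m.max() <= 1.0


def constant_truth(psi, n_events, doses=tuple("d%d" % i for i in range(7))):
    idx = [f"e{i}" for i in range(n_events)]
    m = pd.DataFrame(psi, index=idx, columns=list(doses), dtype=float)
    return GroundTruth(dose_labels=list(doses), psi_matrix=m)


class TestJunctionCounts:
    def test_psi_one_gives_zero_exclusion(self):
        t = constant_truth(1.0, 5)
        df = simulate_junction_counts(t, depth=100, seed=0)
        assert (df["k_exc"] == 0).all()

    def test_zero_depth_gives_zero_counts(self):
        t = constant_truth(0.5, 5)
        df = simulate_junction_counts(t, depth=0, seed=0)
        assert (df[["k_inc", "k_exc"]] == 0).all().all()

    def test_pooled_fraction_within_binomial_error(self):
        t = constant_truth(0.5, 500)
        df = simulate_junction_counts(t, depth=1000, seed=1)
        n = int((df["k_inc"] + df["k_exc"]).sum())
        frac = df["k_inc"].sum() / n
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_reproducible_by_seed(self):
        t = constant_truth(0.3, 10)
        a = simulate_junction_counts(t, depth=50, seed=9)
        b = simulate_junction_counts(t, depth=50, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestCGReadthrough:
    def test_zero_rate_curve_emits_no_cg_junctions(self):
        cfg = SimulationConfig(
            n_gene_pairs=4, cg_rate_curve=(0.0,) * 7, seed=8
        )
        ann, _ = simulate_annotation(cfg)
        jx, _, planted = simulate_cg_readthrough(cfg, ann, seed=9)
        keys = {(p.donor, p.acceptor) for p in planted}
        emitted = set(map(tuple, jx[["donor", "acceptor"]].itertuples(index=False)))
        assert not keys & emitted

    def test_every_cg_junction_is_planted(self, small_study):
        ann = small_study["ann"]
        jx, _, planted = (
            small_study["junctions"],
            small_study["coverage"],
            small_study["planted"],
        )
        planted_keys = {(p.donor, p.acceptor) for p in planted}
        gene_junctions = set()
        for g in ann.genes.values():
            gene_junctions |= g.junctions()
        for row in jx.itertuples(index=False):
            key = (row.donor, row.acceptor)
            assert key in gene_junctions or key in planted_keys

    def test_monotone_rate_curve_gives_monotone_mean_counts(self):
        cfg = SimulationConfig(n_gene_pairs=5, seed=0)
        ann, _ = simulate_annotation(cfg)
        rhos = []
        for seed in range(20):
            jx, _, planted = simulate_cg_readthrough(cfg, ann, seed=seed)
            keys = {(p.donor, p.acceptor) for p in planted}
            cg_rows = jx[
                [tuple(t) in keys for t in jx[["donor", "acceptor"]].itertuples(index=False)]
            ]
            mean_by_dose = (
                cg_rows.groupby("sample")["count"].sum()
                .reindex(cfg.dose_labels, fill_value=0)
            )
            rhos.append(spearmanr(np.arange(7), mean_by_dose.to_numpy()).statistic)
        assert np.mean(rhos) >= 0.9

    def test_readthrough_steals_terminal_junction_reads(self):
        # total terminal-junction depth is conserved: wild-type + CG counts
        # at the top dose stay near the configured depth
        cfg = SimulationConfig(n_gene_pairs=30, seed=12)
        ann, _ = simulate_annotation(cfg)
        jx, _, planted = simulate_cg_readthrough(
            cfg, ann, seed=13, cg_pair_fraction=1.0
        )
        top = jx[jx["sample"] == cfg.dose_labels[-1]]
        totals = []
        for p in planted:
            term = ann.genes[p.upstream_gene].longest_transcript().introns()[-1]
            wt = top[(top["donor"] == term[0]) & (top["acceptor"] == term[1])]["count"].sum()
            cg = top[(top["donor"] == p.donor) & (top["acceptor"] == p.acceptor)]["count"].sum()
            totals.append(wt + cg)
        mean_total = float(np.mean(totals))
        assert abs(mean_total - cfg.depth) < 4 * math.sqrt(cfg.depth / len(planted))


class TestPlantMotifs:
    def test_zero_density_leaves_sequence_unchanged(self):
        genome = {"chr1": "ACGT" * 500}
        spec = MotifPlantSpec(intervals=(("chr1", 0, 600),), consensus="TGCATG", density=0.0)
        assert plant_motifs(genome, spec, seed=0) == genome

    def test_achieved_density_in_600bp_regions(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 6000))
        genome = {"chr1": seq}
        intervals = tuple(("chr1", i * 600, (i + 1) * 600) for i in range(10))
        spec = MotifPlantSpec(intervals=intervals, consensus="TGCATG", density=0.01)
        planted = plant_motifs(genome, spec, seed=1)
        for _, s, e in intervals:
            region = planted["chr1"][s:e]
            count = sum(
                region[i : i + 6] == "TGCATG" for i in range(len(region) - 5)
            )
            assert 5 <= count <= 7  # 6 requested; +/-1 for chance hits/overlaps

    def test_impossible_occupancy_rejected(self):
        genome = {"chr1": "A" * 100}
        spec = MotifPlantSpec(intervals=(("chr1", 0, 60),), consensus="TGCATG", density=0.5)
        with pytest.raises(ConfigurationError):
            plant_motifs(genome, spec, seed=0)

    def test_non_target_regions_untouched(self):
        genome = {"chr1": "ACGT" * 300}
        spec = MotifPlantSpec(intervals=(("chr1", 0, 400),), consensus="TGCATG", density=0.01)
        planted = plant_motifs(genome, spec, seed=2)
        assert planted["chr1"][400:] == genome["chr1"][400:]


class TestSirnaCounts:
    def test_same_seed_identical(self):
        _, t1 = simulate_sirna_counts(seed=5)
        _, t2 = simulate_sirna_counts(seed=5)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)

    def test_planted_fold_shift_recovered(self):
        from cgsplice.sirna_screen import SirnaScreen

        affected = [f"CG{i:03d}" for i in range(10)]
        hits = []
        for seed in range(20):
            _, table = simulate_sirna_counts(
                effects={"siRNA_00": affected}, fold=5.0, seed=seed
            )
            res = SirnaScreen(table).fit()
            kept = set(
                res.retained[res.retained["treatment"] == "siRNA_00"]["cg_id"]
            )
            hits.append(len(kept & set(affected)))
        assert np.mean([h >= 9 for h in hits]) >= 0.95

    def test_null_retention_rate_near_gaussian_tail(self):
        # with no planted effects, each (CG, treatment) cell exceeds the
        # control mean + 2 SD threshold at roughly the normal-tail rate
        # (inflated by the t-like spread of the estimated control moments)
        from cgsplice.sirna_screen import SirnaScreen

        rates = []
        for seed in range(10):
            _, table = simulate_sirna_counts(n_cgs=100, seed=100 + seed)
            res = SirnaScreen(table).fit()
            n_cells = 100 * len(table.treatment_libraries)
            rates.append(len(res.retained) / n_cells)
        rate = float(np.mean(rates))
        assert 0.01 < rate < 0.10

    def test_zero_control_group_populated(self):
        _, table = simulate_sirna_counts(n_control_undetected=5, seed=3)
        from cgsplice.sirna_screen import group_cg_by_control_detection

        groups = group_cg_by_control_detection(table)
        assert len(groups["in_zero_controls"]) == 5


class TestTruthRoundTrip:
    def test_write_read_identity(self, tmp_path):
        cfg = SimulationConfig(seed=21)
        truth = simulate_dose_response_profiles(cfg, n_events=12)
        truth.planted_cgs = [
            # synthetic stand-in record
        ]
        truth.sirna_effects = {"siRNA_00": ["CG001"]}
        truth.write(tmp_path)
        back = GroundTruth.read(tmp_path, cfg.dose_labels)
        pd.testing.assert_frame_equal(
            back.psi_matrix, truth.psi_matrix, check_exact=False, rtol=0, atol=1e-12
        )
        assert (back.cluster_labels == truth.cluster_labels).all()
        assert back.sirna_effects == truth.sirna_effects
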