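"""Generator contracts: planted truth must be exact and deterministic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnidomir.core_io import GeneSet, derive_rng
from cnidomir.deg_filtering import call_degs, cpm_filter
from cnidomir.synthetic_data import (
    DEFAULT_CLUSTER_SIZES,
    EnrichmentSpec,
    SiteSpec,
    UniverseSpec,
    plant_enrichment,
    random_mirna,
    simulate_de_tables,
    simulate_marker_table,
    simulate_qpcr,
    simulate_transcripts_with_sites,
    simulate_universe,
)


class TestUniverse:
    def test_zero_fraction_zero_retains_all(self, rng):
        spec = UniverseSpec(B=200, zero_gene_fraction=0.0)
        universe, truth = simulate_universe(spec, rng)
        bg, _ = cpm_filter(universe)
        assert len(bg) == 200
        assert truth.in_background.all()

    def test_planted_fraction_fails_filter_exactly(self, rng):
        spec = UniverseSpec(B=1000, zero_gene_fraction=0.1)
        universe, truth = simulate_universe(spec, rng)
        bg, _ = cpm_filter(universe)
        assert len(bg) == 900
        assert bg.members == frozenset(truth.gene[truth.in_background])

    def test_determinism(self):
        spec = UniverseSpec(B=100)
        u1, _ = simulate_universe(spec, derive_rng(3, "u"))
        u2, _ = simulate_universe(spec, derive_rng(3, "u"))
        assert np.array_equal(u1.counts, u2.counts)

    def test_size_guard(self, rng):
        with pytest.raises(ValueError, match="1e8"):
            simulate_universe(UniverseSpec(B=10**8, libraries=6), rng)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            UniverseSpec(zero_gene_fraction=1.0)
        with pytest.raises(ValueError):
            UniverseSpec(nb_dispersion=0.0)


class TestPlantEnrichment:
    def test_study_configuration_overlap_is_exact(self, rng):
        genes = [f"g{i}" for i in range(22_500)]
        spec = EnrichmentSpec(K=2615, n=944, x_target=268)
        target, degs, truth = plant_enrichment(genes, spec, rng)
        assert len(target) == 2615 and len(degs) == 944
        assert len(target.members & degs.members) == 268

    def test_degenerate_full_overlap(self, rng):
        genes = [f"g{i}" for i in range(50)]
        spec = EnrichmentSpec(K=50, n=50, x_target=50)
        target, degs, _ = plant_enrichment(genes, spec, rng)
        assert target.members == degs.members == frozenset(genes)

    def test_small_case_brute_force_recount(self, rng):
        genes = [f"g{i}" for i in range(20)]
        target, degs, _ = plant_enrichment(genes, EnrichmentSpec(K=5, n=4, x_target=1), rng)
        assert sum(1 for g in degs if g in target.members) == 1

    def test_infeasible_overlap_quotes_range(self, rng):
        genes = [f"g{i}" for i in range(20)]
        with pytest.raises(ValueError, match=r"\[0, 4\]"):
            plant_enrichment(genes, EnrichmentSpec(K=5, n=4, x_target=5), rng)

    @settings(derandomize=True, max_examples=50)
    @given(data=st.data())
    def test_planted_overlap_exactness_property(self, data):
        B = data.draw(st.integers(5, 60))
        K = data.draw(st.integers(0, B))
        n = data.draw(st.integers(0, B))
        x = data.draw(st.integers(max(0, n + K - B), min(n, K)))
        genes = [f"g{i}" for i in range(B)]
        rng = np.random.default_rng(data.draw(st.integers(0, 2**20)))
        target, degs, _ = plant_enrichment(genes, EnrichmentSpec(K=K, n=n, x_target=x), rng)
        assert len(target.members & degs.members) == x


class TestMarkerTable:
    def test_default_catalogue_shape(self, rng):
        genes = [f"g{i}" for i in range(5000)]
        table, truth = simulate_marker_table(genes, rng)
        assert len(table) == sum(DEFAULT_CLUSTER_SIZES) == 2168
        assert table.cluster.nunique() == 12

    def test_markers_are_cluster_unique(self, rng):
        genes = [f"g{i}" for i in range(3000)]
        table, _ = simulate_marker_table(genes, rng)
        assert not table.gene.duplicated().any()

    def test_zero_size_cluster_gives_empty_rows(self, rng):
        table, _ = simulate_marker_table([f"g{i}" for i in range(10)], rng, n_clusters=1, sizes=[0])
        assert len(table) == 0
        assert list(table.columns) == ["gene", "cluster"]

    def test_oversubscription_rejected(self, rng):
        with pytest.raises(ValueError, match="background holds only"):
            simulate_marker_table([f"g{i}" for i in range(100)], rng)

    def test_fixed_seed_reproducible(self):
        genes = [f"g{i}" for i in range(3000)]
        t1, _ = simulate_marker_table(genes, derive_rng(1, "m"))
        t2, _ = simulate_marker_table(genes, derive_rng(1, "m"))
        pd.testing.assert_frame_equal(t1, t2)


class TestTranscriptsWithSites:
    def test_class_scores_and_decoy_absence(self):
        from cnidomir.target_scan import scan_targets

        rng = derive_rng(21, "sites")
        mir = random_mirna(rng)
        recs, truth = simulate_transcripts_with_sites(mir, SiteSpec(), rng)
        hits = scan_targets([mir], recs)
        planted = truth.dropna(subset=["expected_expectation"])
        assert sorted(h.expectation for h in hits) == sorted(planted.expected_expectation)
        decoy_txs = set(truth[truth.expected_expectation.isna()].transcript)
        assert all(h.transcript_id not in decoy_txs for h in hits)

    def test_transcript_too_short_rejected(self, rng):
        mir = random_mirna(rng)
        with pytest.raises(ValueError, match="too short"):
            simulate_transcripts_with_sites(
                mir, SiteSpec(n_transcripts=1, transcript_length=30), rng
            )

    def test_mirna_length_bounds(self, rng):
        with pytest.raises(ValueError, match="19-24"):
            simulate_transcripts_with_sites(("m", "ACGU" * 10), SiteSpec(), rng)

    def test_determinism(self):
        mir = random_mirna(derive_rng(2, "mir"))
        r1, t1 = simulate_transcripts_with_sites(mir, SiteSpec(), derive_rng(2, "tx"))
        r2, t2 = simulate_transcripts_with_sites(mir, SiteSpec(), derive_rng(2, "tx"))
        assert r1 == r2
        pd.testing.assert_frame_equal(t1, t2)


class TestDeTables:
    def test_truth_matches_call_degs(self, small_background, rng):
        tables, truth = simulate_de_tables(small_background, rng, n_degs=40)
        calls, summary = call_degs(tables)
        assert {c.gene for c in calls} == set(truth.gene[truth.is_deg])
        directions = dict(zip(truth.gene, truth.direction))
        assert all(c.direction == directions[c.gene] for c in calls)
        assert summary["n_discordant_excluded"] >= 1

    def test_boundary_categories_present(self, small_background, rng):
        _, truth = simulate_de_tables(small_background, rng, n_degs=40)
        assert {"boundary_fdr", "discordant", "one_method_only", "missing"} <= set(
            truth.category
        )


class TestQpcr:
    def test_null_effect_noiseless_gives_unity(self, rng):
        from cnidomir.quantification import ddct

        table, _ = simulate_qpcr(effect=1.0, noise_sd=0.0, rng=rng)
        res = ddct(table, "5sRNA", "control")["mir-target"]
        assert np.allclose(res.per_replicate.rq, 1.0)

    def test_planted_knockdown_recovered_exactly(self, rng):
        from cnidomir.quantification import ddct

        table, _ = simulate_qpcr(effect=0.25, noise_sd=0.0, rng=rng)
        res = ddct(table, "5sRNA", "control")["mir-target"]
        assert np.allclose(res.rq_values("treatment"), 0.25)

    def test_invalid_args_rejected(self, rng):
        with pytest.raises(ValueError, match="replicates"):
            simulate_qpcr(effect=0.5, noise_sd=0.1, rng=rng, replicates=1)
        with pytest.raises(ValueError, match="> 0"):
            simulate_qpcr(effect=0.0, noise_sd=0.1, rng=rng)
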