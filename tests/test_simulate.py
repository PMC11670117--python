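"""Ground-truth guarantees of the synthetic-experiment generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import endokit as ek
from endokit.motifs import PHI
from endokit.simulate import GroundTruth, substream


def _cfg(**kw) -> ek.SimConfig:
    base = dict(n_proteins=200, seed=11)
    base.update(kw)
    return ek.SimConfig(**base)


class TestConfigValidation:
    def test_fractions_over_one_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            ek.SimConfig(compartment_fractions={"lysosome": 0.7, "endosome": 0.5})

    @pytest.mark.parametrize(
        "kw",
        [
            {"noise_sd": 0.0},
            {"n_replicates_per_group": 1},
            {"seq_length_range": (10, 50)},
            {"motif_plant_rate_snx27": 1.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            ek.SimConfig(**kw)


class TestCatalog:
    def test_deterministic_under_seed(self):
        c1 = ek.generate_catalog(_cfg())
        c2 = ek.generate_catalog(_cfg())
        pd.testing.assert_frame_equal(c1.table, c2.table)
        pd.testing.assert_frame_equal(c1.terms, c2.terms)

    def test_zero_pm_fraction_yields_no_pm_proteins(self):
        cfg = _cfg(compartment_fractions={"lysosome": 0.2, "plasma_membrane": 0.0})
        catalog = ek.generate_catalog(cfg)
        assert (catalog.table["compartment"] != "plasma_membrane").all()

    def test_lysosome_count_within_binomial_bounds(self):
        # Binomial(1000, 0.1): P(outside [60, 140]) < 1e-4
        cfg = ek.SimConfig(
            n_proteins=1000, seed=5, compartment_fractions={"lysosome": 0.1}
        )
        catalog = ek.generate_catalog(cfg)
        count = (catalog.table["compartment"] == "lysosome").sum()
        assert 60 <= count <= 140

    def test_pm_proteins_are_flagged_membrane_with_tm(self):
        catalog = ek.generate_catalog(_cfg())
        pm = catalog.table[catalog.table["compartment"] == "plasma_membrane"]
        assert (pm["tm_count"] >= 1).all()
        assert pm["cell_membrane"].all()

    def test_terms_reference_synaptic_catalog_members(self):
        catalog = ek.generate_catalog(_cfg())
        members = set(catalog.terms["protein_id"])
        assert members <= set(catalog.ids)
        assert catalog.table.loc[sorted(members), "synaptic"].all()


class TestSequences:
    def test_full_plant_rate_all_end_in_snx27_motif(self):
        cfg = _cfg(n_proteins=10, motif_plant_rate_snx27=1.0, motif_plant_rate_snx17=0)
        seqs, truth = ek.generate_sequences(ek.generate_catalog(cfg), cfg)
        assert len(truth.motif_ids_snx27) == 10
        for seq in seqs.values():
            assert seq[-3] in "ST" and seq[-1] in PHI

    def test_zero_plant_rate_no_cterminal_matches(self):
        cfg = _cfg(motif_plant_rate_snx27=0.0, motif_plant_rate_snx17=0.0)
        seqs, truth = ek.generate_sequences(ek.generate_catalog(cfg), cfg)
        assert not truth.motif_ids_snx27
        for seq in seqs.values():
            assert not (seq[-3] in "ST" and seq[-1] in PHI)

    def test_planted_snx17_windows_match_pattern(self):
        cfg = _cfg(motif_plant_rate_snx17=0.5, motif_plant_rate_snx27=0.0)
        seqs, truth = ek.generate_sequences(ek.generate_catalog(cfg), cfg)
        assert truth.snx17_positions
        for pid, starts in truth.snx17_positions.items():
            for start in starts:
                window = seqs[pid][start : start + 6]
                assert window[0] in PHI and window[2] == "N" and window[5] in "FY"

    def test_background_snx17_rate_matches_analytic_window_probability(self):
        # per-window p = P(Phi) * P(N) * P(F/Y) = 0.4 * 0.05 * 0.1 = 0.002
        cfg = ek.SimConfig(
            n_proteins=300, seed=23, motif_plant_rate_snx27=0.0,
            motif_plant_rate_snx17=0.0, seq_length_range=(200, 200),
        )
        seqs, truth = ek.generate_sequences(ek.generate_catalog(cfg), cfg)
        n_hits = sum(len(v) for v in truth.incidental_snx17.values())
        n_windows = sum(len(s) - 5 for s in seqs.values())
        expected = 0.002 * n_windows
        sd = np.sqrt(n_windows * 0.002 * 0.998)
        assert abs(n_hits - expected) < 4.5 * sd

    def test_suppressed_background_leaves_only_planted_motifs(self):
        cfg = _cfg(
            n_proteins=60, motif_plant_rate_snx17=0.5, motif_plant_rate_snx27=0.2,
            suppress_background_snx17=True,
        )
        seqs, truth = ek.generate_sequences(ek.generate_catalog(cfg), cfg)
        assert not truth.incidental_snx17
        table = ek.scan_proteome(seqs)
        assert table.summary["proteins_with_snx17"] == len(truth.motif_ids_snx17)
        assert table.summary["total_snx17_motifs"] == sum(
            len(v) for v in truth.snx17_positions.values()
        )

    def test_deterministic_under_seed(self):
        cfg = _cfg()
        s1, _ = ek.generate_sequences(ek.generate_catalog(cfg), cfg)
        s2, _ = ek.generate_sequences(ek.generate_catalog(cfg), cfg)
        assert s1 == s2


class TestQuant:
    def test_null_effect_mean_log2fc_near_zero(self):
        cfg = _cfg(n_proteins=500, enrichment_effect=0.0)
        catalog = ek.generate_catalog(cfg)
        q = ek.generate_quant(catalog, GroundTruth(), cfg)
        res = ek.EnrichmentModel(q).fit("genotype:tagged/untagged")
        assert abs(res.table["log2fc"].mean()) < 0.1

    def test_noise_free_recovery_of_planted_effect(self):
        # with zero noise and zero channel offsets the raw log2 group
        # difference equals the planted effect exactly
        cfg = ek.SimConfig(
            n_proteins=100, seed=3, noise_sd=1e-12, channel_offset_sd=1e-12,
            enrichment_effect=2.0,
        )
        catalog = ek.generate_catalog(cfg)
        truth = GroundTruth()
        q = ek.generate_quant(catalog, truth, cfg)
        log2 = np.log2(q.intensities)
        tagged = q.samples_where("genotype", "tagged")
        untagged = q.samples_where("genotype", "untagged")
        fc = log2[tagged].mean(axis=1) - log2[untagged].mean(axis=1)
        np.testing.assert_allclose(fc.loc[sorted(truth.enriched_ids)], 2.0, atol=1e-6)
        null_ids = sorted(set(q.protein_ids) - truth.enriched_ids)
        np.testing.assert_allclose(fc.loc[null_ids], 0.0, atol=1e-6)

    def test_log2fc_sampling_distribution_mean_and_sd(self):
        # closed form: sd of a 3-vs-3 difference of means = 0.3 * sqrt(2/3)
        cfg = ek.SimConfig(
            n_proteins=1000, seed=17, noise_sd=0.3, n_replicates_per_group=3,
            compartment_fractions={"lysosome": 0.10}, enrichment_effect=2.0,
        )
        catalog = ek.generate_catalog(cfg)
        truth = GroundTruth()
        q = ek.generate_quant(catalog, truth, cfg)
        res = ek.EnrichmentModel(q).fit("genotype:tagged/untagged")
        planted = res.table.loc[sorted(truth.enriched_ids), "log2fc"]
        null_ids = sorted(set(res.table.index) - truth.enriched_ids)
        # the planted-vs-background contrast cancels the (small) shift that
        # median centring introduces when 10% of proteins carry the effect
        assert abs((planted.mean() - res.table.loc[null_ids, "log2fc"].mean()) - 2.0) < 0.1
        assert abs(planted.std(ddof=1) - 0.3 * np.sqrt(2 / 3)) < 0.06

    def test_linear_scale_positive_and_missing_mechanism(self):
        cfg = _cfg(missing_below_quantile=0.1)
        catalog = ek.generate_catalog(cfg)
        q = ek.generate_quant(catalog, GroundTruth(), cfg)
        values = q.intensities.to_numpy()
        assert np.nanmin(values) > 0
        frac_missing = np.isnan(values).mean()
        assert 0.05 < frac_missing < 0.15


class TestTimecourse:
    def test_zero_noise_members_share_zscored_profile(self):
        cfg = _cfg(timecourse_noise_sd=1e-9, n_clusters=3)
        catalog = ek.generate_catalog(cfg)
        matrix, assignment = ek.generate_timecourse(catalog, cfg)
        z, _ = ek.zscore(matrix)
        for cluster in set(assignment.values()):
            members = [pid for pid, c in assignment.items() if c == cluster]
            profiles = z.loc[members].to_numpy()
            assert np.allclose(profiles, profiles[0], atol=1e-6)

    def test_two_clusters_separated_by_trajectory_sign(self):
        cfg = _cfg(timecourse_noise_sd=1e-9, n_clusters=2)
        catalog = ek.generate_catalog(cfg)
        matrix, assignment = ek.generate_timecourse(catalog, cfg)
        z, _ = ek.zscore(matrix)
        slope_sign = np.sign(z.iloc[:, -1] - z.iloc[:, 0])
        labels = pd.Series(assignment)
        by_sign = labels.groupby(slope_sign).nunique()
        assert (by_sign == 1).all()

    def test_too_high_noise_rejected(self):
        cfg = _cfg(timecourse_noise_sd=2.0)
        with pytest.raises(ValueError, match="3 x noise"):
            ek.generate_timecourse(ek.generate_catalog(cfg), cfg)


class TestIptm:
    def test_values_in_unit_interval(self, small_experiment):
        iptm = small_experiment.iptm["iptm"]
        assert ((iptm >= 0) & (iptm <= 1)).all()

    def test_degenerate_modes_triage_perfectly(self):
        # nearly-degenerate Beta modes at ~0.9 and ~0.3
        cfg = _cfg(
            iptm_high_params=(9000.0, 1000.0), iptm_low_params=(3000.0, 7000.0),
            motif_plant_rate_snx27=0.3, motif_plant_rate_snx17=0.2,
        )
        catalog = ek.generate_catalog(cfg)
        seqs, truth = ek.generate_sequences(catalog, cfg)
        records = ek.generate_iptm(truth, seqs, cfg)
        passed, failed = ek.triage(records, threshold=0.6)
        assert set(passed["planted"]) == {True}
        assert set(failed["planted"]) == {False}

    def test_control_pass_rate_matches_beta_tail(self):
        # low-mode Beta(2.5, 8): P(X > 0.6) is the analytic control pass rate
        cfg = ek.SimConfig(
            n_proteins=600, seed=29, motif_plant_rate_snx27=0.0,
            motif_plant_rate_snx17=0.0, n_iptm_controls=600,
        )
        catalog = ek.generate_catalog(cfg)
        seqs, truth = ek.generate_sequences(catalog, cfg)
        records = ek.generate_iptm(truth, seqs, cfg)
        passed, _ = ek.triage(records, threshold=0.6)
        rate = len(passed) / len(records)
        p = stats.beta.sf(0.6, *cfg.iptm_low_params)
        sd = np.sqrt(p * (1 - p) / len(records))
        assert abs(rate - p) < 4.5 * sd


class TestDeterminism:
    def test_full_experiment_reproducible(self):
        e1 = ek.simulate_experiment(_cfg(n_proteins=80))
        e2 = ek.simulate_experiment(_cfg(n_proteins=80))
        assert e1.sequences == e2.sequences
        pd.testing.assert_frame_equal(e1.quant.intensities, e2.quant.intensities)
        pd.testing.assert_frame_equal(e1.timecourse, e2.timecourse)
        pd.testing.assert_frame_equal(e1.iptm, e2.iptm)
        assert e1.truth.cluster_assignment == e2.truth.cluster_assignment

    def test_named_substreams_are_independent(self):
        a = substream(1, "catalog").random(3)
        b = substream(1, "quant").random(3)
        assert not np.allclose(a, b)
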