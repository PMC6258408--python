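"""Cohort simulator: panel handling, multinomial sampling, spike-in."""

import numpy as np
import pandas as pd
import pytest

from burdenrank.scores import normalize_score
from burdenrank.simulate import (
    FrequencyPanel,
    PathogenicVariant,
    SimulationSpec,
    default_pathogenic_variants,
    filter_panel,
    make_synthetic_panel,
    simulate_cohort,
    simulate_individual,
    simulate_one_replicate,
    simulate_replicates,
    spike_pathogenic,
    validate_pathogenic_variants,
)


class TestFrequencyPanel:
    def test_invalid_frequencies_rejected(self):
        df = pd.DataFrame(
            [("1", 100, "A", "T", "G1", 10.0, 1.2)],
            columns=["chrom", "pos", "ref", "alt", "gene", "score", "adjusted"],
        )
        with pytest.raises(ValueError):
            FrequencyPanel(df, ["adjusted"])

    def test_site_frequency_sum_over_one_rejected(self):
        df = pd.DataFrame(
            [
                ("1", 100, "A", "T", "G1", 10.0, 0.6),
                ("1", 100, "A", "G", "G1", 10.0, 0.6),
            ],
            columns=["chrom", "pos", "ref", "alt", "gene", "score", "adjusted"],
        )
        with pytest.raises(ValueError, match="exceed 1"):
            FrequencyPanel(df, ["adjusted"])

    def test_tsv_round_trip(self, tiny_panel, tmp_path):
        p = tmp_path / "panel.tsv"
        tiny_panel.to_tsv(p)
        back = FrequencyPanel.from_tsv(p)
        pd.testing.assert_frame_equal(back.df, tiny_panel.df)
        assert back.populations == tiny_panel.populations

    def test_filter_panel(self, tiny_panel):
        kept = filter_panel(tiny_panel, 0.005)
        assert len(kept) == 5  # the 0.02 allele dropped
        assert filter_panel(tiny_panel, 1.0).df.shape == tiny_panel.df.shape
        with pytest.raises(ValueError):
            filter_panel(tiny_panel, 0.0)


class TestSimulateIndividual:
    def test_zero_frequency_panel_emits_nothing(self, rng):
        df = pd.DataFrame(
            [("1", 100, "A", "T", "G1", 10.0, 0.0)],
            columns=["chrom", "pos", "ref", "alt", "gene", "score", "adjusted"],
        )
        panel = FrequencyPanel(df, ["adjusted"])
        assert simulate_individual(panel, {"adjusted": 1.0}, rng) == []

    def test_multinomial_emission_fractions(self):
        """Worked example: alt freqs 0.2% / 0.5% at one site emit at those
        rates (within 3 binomial SDs) and never both in one individual."""
        df = pd.DataFrame(
            [
                ("1", 10000, "A", "T", "G1", 10.0, 0.002),
                ("1", 10000, "A", "G", "G1", 10.0, 0.005),
            ],
            columns=["chrom", "pos", "ref", "alt", "gene", "score", "adjusted"],
        )
        panel = FrequencyPanel(df, ["adjusted"])
        rng = np.random.default_rng(5)
        n = 40000
        cohort = simulate_cohort(panel, n, {"adjusted": 1.0}, rng)
        alts = cohort.allele_idx
        per_ind = np.bincount(cohort.ind_idx, minlength=n)
        assert per_ind.max() <= 1  # at most one alt per site per individual
        for allele, freq in [(0, 0.002), (1, 0.005)]:
            count = int((alts == allele).sum())
            sd = np.sqrt(n * freq * (1 - freq))
            assert abs(count - n * freq) < 3 * sd

    def test_fixed_seed_reproducible(self, tiny_panel):
        a = simulate_individual(tiny_panel, {"adjusted": 1.0}, np.random.default_rng(3))
        b = simulate_individual(tiny_panel, {"adjusted": 1.0}, np.random.default_rng(3))
        assert a == b

    def test_normalized_scores_attached(self, tiny_panel):
        rng = np.random.default_rng(12)
        cohort = simulate_cohort(tiny_panel, 500, {"adjusted": 1.0}, rng)
        calls = cohort.to_calls()
        assert calls, "expected some background calls at these frequencies"
        table = {
            (r.chrom, r.pos, r.ref, r.alt): r.score
            for r in tiny_panel.df.itertuples()
        }
        for c in calls[:50]:
            assert c.s == pytest.approx(normalize_score(table[c.key]))


class TestAdmixture:
    def test_population_assignment_fraction(self):
        panel = make_synthetic_panel(n_genes=5, populations=["A", "B"], seed=3)
        rng = np.random.default_rng(7)
        n = 5000
        cohort = simulate_cohort(panel, n, {"A": 0.6, "B": 0.4}, rng)
        frac_a = cohort.populations_drawn.count("A") / n
        assert abs(frac_a - 0.6) < 3 * np.sqrt(0.6 * 0.4 / n)

    def test_invalid_weights_rejected(self, tiny_panel, rng):
        with pytest.raises(ValueError):
            simulate_cohort(tiny_panel, 5, {"adjusted": 0.7}, rng)

    def test_private_alleles_create_population_excess(self):
        """Disjoint private alleles: a cohort drawn from population A
        carries A-private alleles; one drawn from B carries none of them."""
        panel = make_synthetic_panel(
            n_genes=20, populations=["A", "B"], seed=11, private_allele_fraction=1.0
        )
        a_private = np.flatnonzero(
            (panel.df["A"].to_numpy() > 0) & (panel.df["B"].to_numpy() == 0)
        )
        assert len(a_private) > 0
        rng = np.random.default_rng(2)
        from_a = simulate_cohort(panel, 2000, {"A": 1.0}, rng)
        from_b = simulate_cohort(panel, 2000, {"B": 1.0}, rng)
        assert np.isin(from_a.allele_idx, a_private).sum() > 0
        assert np.isin(from_b.allele_idx, a_private).sum() == 0


class TestSpike:
    def _spec(self, **kw):
        defaults = dict(
            n_cases=600,
            n_controls=100,
            model="AR",
            spike_gene="G1",
            spike_proportion=0.02,
            pathogenic_variants=[
                PathogenicVariant("1", 1500, "A", "T", "G1", 30.0),
                PathogenicVariant("1", 1600, "C", "G", "G1", 35.0),
            ],
            n_replicates=1,
            seed=5,
        )
        defaults.update(kw)
        return SimulationSpec(**defaults)

    def test_exact_spike_count(self, tiny_panel, rng):
        cohort = simulate_cohort(tiny_panel, 600, {"adjusted": 1.0}, rng, cohort="case")
        spiked = spike_pathogenic(cohort, self._spec(), rng)
        assert len(spiked.spiked_individuals) == 12  # 2% of 600
        # recessive: two draws per selected case
        assert len(spiked.spiked_calls) == 24

    def test_dominant_single_draw(self, tiny_panel, rng):
        cohort = simulate_cohort(tiny_panel, 200, {"adjusted": 1.0}, rng, cohort="case")
        spiked = spike_pathogenic(cohort, self._spec(model="AD", n_cases=200), rng)
        assert len(spiked.spiked_individuals) == 4
        assert len(spiked.spiked_calls) == 4

    def test_zero_proportion_unchanged(self, tiny_panel, rng):
        cohort = simulate_cohort(tiny_panel, 50, {"adjusted": 1.0}, rng)
        assert spike_pathogenic(cohort, self._spec(spike_proportion=0.0), rng) is cohort

    def test_subone_selection_warns_and_skips(self, tiny_panel, rng, caplog):
        cohort = simulate_cohort(tiny_panel, 20, {"adjusted": 1.0}, rng)
        with caplog.at_level("WARNING"):
            out = spike_pathogenic(cohort, self._spec(spike_proportion=0.01), rng)
        assert out.spiked_individuals == []

    def test_homozygous_spike_scores_double(self, tiny_panel, rng):
        pv = PathogenicVariant("1", 1500, "A", "T", "G1", 30.0)
        spec = self._spec(pathogenic_variants=[pv], spike_proportion=1.0, n_cases=10)
        cohort = simulate_cohort(
            filter_panel(tiny_panel, 1e-9), 10, {"adjusted": 1.0}, rng, cohort="case"
        )
        spiked = spike_pathogenic(cohort, spec, rng)
        m = spiked.gene_score_matrix("AR")
        for ind in m.individuals:
            assert m.score("G1", ind) == pytest.approx(2 * pv.s)

    def test_spiked_gene_score_is_sum_of_drawn_pair(self, rng):
        panel = make_synthetic_panel(n_genes=30, seed=4)
        pvs = default_pathogenic_variants(panel, "GENE00003", n=10, seed=4)
        spec = SimulationSpec(
            n_cases=100,
            n_controls=10,
            model="AR",
            spike_gene="GENE00003",
            spike_proportion=0.1,
            pathogenic_variants=pvs,
            seed=9,
        )
        cases, _ = simulate_one_replicate(spec, panel, 0)
        m = cases.gene_score_matrix("AR")
        by_ind = {}
        for i, pv in cases.spiked_calls:
            by_ind.setdefault(cases.individual_ids[i], []).append(pv.s)
        assert len(by_ind) == 10
        for ind, ss in by_ind.items():
            # background variants in the gene can only raise the top-two sum
            assert m.score("GENE00003", ind) >= sum(ss) - 1e-9
            assert m.score("GENE00003", ind) <= 2.0

    def test_common_spike_variant_rejected(self, tiny_panel):
        common = PathogenicVariant("2", 6000, "T", "C", "G2", 25.0)  # freq 0.02
        with pytest.raises(ValueError, match="frequency"):
            validate_pathogenic_variants([common], tiny_panel)

    def test_fixed_pair_mode(self, tiny_panel, rng):
        spec = self._spec(spike_mode="fixed-pair", spike_proportion=0.5, n_cases=10)
        cohort = simulate_cohort(
            filter_panel(tiny_panel, 1e-9), 10, {"adjusted": 1.0}, rng, cohort="case"
        )
        spiked = spike_pathogenic(cohort, spec, rng)
        pair = {pv.pos for _, pv in spiked.spiked_calls}
        assert pair == {1500, 1600}
        per_ind = {}
        for i, pv in spiked.spiked_calls:
            per_ind.setdefault(i, set()).add(pv.pos)
        assert all(v == {1500, 1600} for v in per_ind.values())


class TestReplicates:
    def test_replicate_count_and_determinism(self, tiny_panel):
        spec = SimulationSpec(n_cases=5, n_controls=10, n_replicates=3, seed=42)
        reps_a = simulate_replicates(spec, tiny_panel)
        reps_b = simulate_replicates(spec, tiny_panel)
        assert len(reps_a) == 3
        for (ca, ka), (cb, kb) in zip(reps_a, reps_b):
            np.testing.assert_array_equal(ca.allele_idx, cb.allele_idx)
            np.testing.assert_array_equal(ca.ind_idx, cb.ind_idx)
            np.testing.assert_array_equal(ka.allele_idx, kb.allele_idx)

    def test_zero_replicates(self, tiny_panel):
        spec = SimulationSpec(n_cases=5, n_controls=10, n_replicates=0, seed=42)
        assert simulate_replicates(spec, tiny_panel) == []

    def test_replicates_differ_from_each_other(self):
        panel = make_synthetic_panel(n_genes=20, seed=8)
        spec = SimulationSpec(n_cases=200, n_controls=200, n_replicates=2, seed=42)
        (c0, _), (c1, _) = simulate_replicates(spec, panel)
        same = len(c0.allele_idx) == len(c1.allele_idx) and np.array_equal(
            c0.allele_idx, c1.allele_idx
        ) and np.array_equal(c0.ind_idx, c1.ind_idx)
        assert not same

    def test_default_maf_cutoff_by_model(self):
        ar = SimulationSpec(n_cases=1, n_controls=1, model="AR")
        ad = SimulationSpec(n_cases=1, n_controls=1, model="AD")
        assert ar.maf_cutoff == 0.005
        assert ad.maf_cutoff == 0.0001


class TestSyntheticPanel:
    def test_reproducible_and_gene_count(self):
        a = make_synthetic_panel(n_genes=100, seed=7)
        b = make_synthetic_panel(n_genes=100, seed=7)
        pd.testing.assert_frame_equal(a.df, b.df)
        assert len(a.gene_ids) == 100
        assert len(set(a.gene_ids)) == 100

    def test_autosomal_layout_and_rarity(self):
        panel = make_synthetic_panel(n_genes=50, seed=1)
        assert set(panel.df["chrom"]).issubset({str(i) for i in range(1, 23)})
        assert panel.max_freq().max() <= 0.005

    def test_optional_x_block(self):
        panel = make_synthetic_panel(n_genes=46, seed=1, include_x=True)
        assert "X" in set(panel.df["chrom"])

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            make_synthetic_panel(n_genes=0)
        with pytest.raises(ValueError):
            make_synthetic_panel(n_genes=5, private_allele_fraction=1.5)


class TestFrequencyRecovery:
    def test_empirical_frequencies_match_panel(self):
        """Empirical allele frequencies over 20,000 individuals fall
        within 4 SDs of the panel values for alleles with f >= 1e-4."""
        panel = make_synthetic_panel(n_genes=10, seed=13)
        rng = np.random.default_rng(17)
        n = 20000
        cohort = simulate_cohort(panel, n, {"adjusted": 1.0}, rng)
        counts = np.bincount(cohort.allele_idx, minlength=len(panel))
        freqs = panel.df["adjusted"].to_numpy()
        check = freqs >= 1e-4
        assert check.sum() > 50
        sd = np.sqrt(n * freqs * (1 - freqs))
        dev = np.abs(counts - n * freqs)
        assert np.all(dev[check] <= 4 * sd[check])
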