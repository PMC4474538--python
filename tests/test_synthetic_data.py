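"""Statistical structure of the synthetic study generator."""

import numpy as np
import pytest
from scipy import stats

from nbspanel.clinical_assoc import logrank_test
from nbspanel.synthetic_data import (
    cohort_to_mutation_table,
    gen_clinical,
    gen_cohort,
    gen_network,
    gen_panel,
    write_simulation,
)


class TestGenNetwork:
    def test_zero_between_probability_isolates_modules(self):
        net, truth = gen_network(40, 4, p_in=0.4, p_out=0.0, seed=0)
        module = np.array([truth.module_of[g] for g in net.genes])
        across = net.weights[module[:, None] != module[None, :]]
        assert not across.any()

    def test_within_module_edge_count_matches_binomial(self):
        net, truth = gen_network(100, 4, p_in=0.3, p_out=0.02, seed=1)
        module = np.array([truth.module_of[g] for g in net.genes])
        for mod in range(4):
            idx = np.flatnonzero(module == mod)
            block = net.weights[np.ix_(idx, idx)]
            observed = np.count_nonzero(np.triu(block, 1))
            n_pairs = len(idx) * (len(idx) - 1) // 2  # C(25,2) = 300
            mean = 0.3 * n_pairs
            sd = np.sqrt(n_pairs * 0.3 * 0.7)
            assert abs(observed - mean) <= 3 * sd

    def test_weight_ranges_separate_within_and_between(self):
        net, truth = gen_network(60, 3, seed=2)
        module = np.array([truth.module_of[g] for g in net.genes])
        same = module[:, None] == module[None, :]
        within = net.weights[same & (net.weights > 0)]
        across = net.weights[~same & (net.weights > 0)]
        assert within.min() >= 0.5 and across.max() <= 0.5

    def test_same_seed_identical(self):
        a, _ = gen_network(30, 3, seed=7)
        b, _ = gen_network(30, 3, seed=7)
        assert (a.weights == b.weights).all()

    def test_bad_probabilities_raise(self):
        with pytest.raises(ValueError):
            gen_network(20, 2, p_in=0.1, p_out=0.3)


class TestGenCohort:
    def test_zero_background_confines_mutations_to_modules(self):
        net, truth = gen_network(40, 4, seed=3)
        cohort, truth = gen_cohort(net, truth, 20, 4, driver_rate=0.5, background_rate=0.0, seed=4)
        module = np.array([truth.module_of[g] for g in cohort.genes])
        for j, s in enumerate(cohort.samples):
            mutated = module[cohort.values[:, j] > 0]
            assert set(mutated) == {truth.subtype_of[s]}

    def test_driver_mutation_count_matches_binomial(self):
        net, truth = gen_network(100, 4, seed=5)  # modules of 25 genes
        cohort, truth = gen_cohort(
            net, truth, 200, 4, driver_rate=0.2, background_rate=0.01, seed=6, min_mutations=0
        )
        module = np.array([truth.module_of[g] for g in cohort.genes])
        counts = [
            cohort.values[module == truth.subtype_of[s], j].sum()
            for j, s in enumerate(cohort.samples)
        ]
        mean = np.mean(counts)  # expectation 0.2 * 25 = 5
        sd = np.sqrt(25 * 0.2 * 0.8) / np.sqrt(200)
        assert abs(mean - 5.0) <= 3 * sd

    def test_same_subtype_samples_share_more_genes(self):
        net, truth = gen_network(100, 4, seed=7)
        cohort, truth = gen_cohort(net, truth, 100, 4, seed=8)
        planted = truth.subtype_labels(cohort.samples)
        overlap = cohort.values.T.astype(int) @ cohort.values.astype(int)
        same = planted[:, None] == planted[None, :]
        off = ~np.eye(len(planted), dtype=bool)
        assert np.median(overlap[same & off]) > np.median(overlap[~same & off])

    def test_min_mutation_guarantee_keeps_full_filter_happy(self):
        net, truth = gen_network(60, 3, seed=9)
        cohort, _ = gen_cohort(net, truth, 30, 3, driver_rate=0.15, background_rate=0.005, seed=10)
        assert (cohort.values.sum(axis=0) >= 6).all()

    def test_bad_rates_raise(self):
        net, truth = gen_network(20, 2, seed=0)
        with pytest.raises(ValueError):
            gen_cohort(net, truth, 5, 2, driver_rate=0.1, background_rate=0.2)


class TestGenPanel:
    def test_full_coverage_no_decoys_is_module_union(self):
        _, truth = gen_network(40, 4, seed=11)
        panel = gen_panel(truth, coverage=1.0, decoys=0, seed=12)
        assert panel.genes == frozenset(truth.module_of)

    def test_half_coverage_takes_floor_per_module(self):
        _, truth = gen_network(100, 4, seed=13)  # 4 modules of 25
        panel = gen_panel(truth, coverage=0.5, decoys=0, seed=14)
        assert len(panel) == 4 * 12  # floor(0.5 * 25) per module

    def test_module_targeting_excludes_other_modules(self):
        _, truth = gen_network(80, 4, seed=15)
        panel = gen_panel(truth, coverage=1.0, decoys=0, seed=16, modules=[0, 1])
        modules_hit = {truth.module_of[g] for g in panel.genes}
        assert modules_hit == {0, 1}

    def test_same_seed_same_panel(self):
        _, truth = gen_network(40, 4, seed=17)
        a = gen_panel(truth, 0.6, decoys=3, seed=18)
        b = gen_panel(truth, 0.6, decoys=3, seed=18)
        assert a.genes == b.genes

    def test_zero_coverage_raises(self):
        _, truth = gen_network(20, 2, seed=0)
        with pytest.raises(ValueError):
            gen_panel(truth, coverage=0.0)


class TestGenClinical:
    def test_null_hazards_give_uniform_logrank_p(self):
        """All hazard ratios 1: log-rank p on planted subtypes is uniform
        (KS test over 500 simulations does not reject)."""
        _, truth0 = gen_network(30, 3, seed=19)
        pvals = []
        for sim in range(500):
            net, truth = gen_network(30, 3, seed=19)
            cohort, truth = gen_cohort(net, truth, 45, 3, seed=sim)
            clinical, _ = gen_clinical(truth, cohort.samples, seed=10_000 + sim)
            res = logrank_test(
                clinical["time"], clinical["event"],
                truth.subtype_labels(list(clinical["sample_id"])),
            )
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_hazard_ratio_reflected_in_median_times(self):
        net, truth = gen_network(100, 2, seed=20)
        cohort, truth = gen_cohort(net, truth, 200, 2, seed=21)
        clinical, truth = gen_clinical(
            truth, cohort.samples, hazard_ratios={0: 1.0, 1: 4.0}, censor_rate=0.0, seed=22
        )
        planted = truth.subtype_labels(list(clinical["sample_id"]))
        med0 = clinical.loc[planted == 0, "time"].median()
        med1 = clinical.loc[planted == 1, "time"].median()
        assert med0 / med1 == pytest.approx(4.0, rel=0.5)  # exponential median ~ ln2/rate

    def test_zero_censor_rate_gives_all_events(self):
        net, truth = gen_network(20, 2, seed=23)
        cohort, truth = gen_cohort(net, truth, 30, 2, seed=24)
        clinical, _ = gen_clinical(truth, cohort.samples, censor_rate=0.0, seed=25)
        assert (clinical["event"] == 1).all()

    def test_censor_rate_calibrated(self):
        net, truth = gen_network(100, 2, seed=26)
        cohort, truth = gen_cohort(net, truth, 400, 2, seed=27)
        clinical, _ = gen_clinical(truth, cohort.samples, censor_rate=0.3, seed=28)
        censored = 1 - clinical["event"].mean()
        assert abs(censored - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 400)


def test_mutation_table_round_trips_through_binarization():
    from nbspanel.data_io import MutationRecord, binarize

    net, truth = gen_network(30, 3, seed=29)
    cohort, _ = gen_cohort(net, truth, 12, 3, seed=30)
    table = cohort_to_mutation_table(cohort, seed=31)
    records = [
        MutationRecord(r.Tumor_Sample_Barcode, r.Hugo_Symbol, r.Variant_Classification)
        for r in table.itertuples()
    ]
    rebuilt = binarize(records, cohort.genes)
    rb = rebuilt.to_frame().reindex(columns=cohort.samples, fill_value=0)
    assert (rb.to_numpy() == cohort.values).all()


def test_write_simulation_produces_consistent_files(tmp_path):
    paths = write_simulation(tmp_path, m=40, n_modules=4, n_samples=16, n_subtypes=4, seed=1)
    assert all(p.exists() for p in paths.values())
    from nbspanel.data_io import read_clinical, read_mutations, read_panel
    from nbspanel.network_ops import read_network

    records = read_mutations(paths["mutations"])
    net = read_network(paths["network"])
    clinical = read_clinical(paths["clinical"])
    panel = read_panel(paths["panel"])
    assert {r.sample_id for r in records} <= set(clinical["sample_id"])
    assert set(net.genes) <= {f"G{i:04d}" for i in range(40)}
    assert len(panel) > 0
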