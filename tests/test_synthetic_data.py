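import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, spearmanr

from solshift import (
    GeneSetCollection,
    call_significant,
    cross_classify,
    delta_delta_ct,
    enrich,
    gen_cells,
    gen_coip,
    gen_ct,
    gen_de_pair,
    gen_flow,
    gen_image,
    index_table,
    score_nuclear,
    tof_normalize,
    top_fraction,
)
from solshift.synthetic_data import SPEARMAN_DI_BOUND


class TestDeterminism:
    @pytest.mark.parametrize("gen", [
        lambda s: gen_coip(n_proteins=30, n_planted=3, seed=s)[0].records,
        lambda s: gen_de_pair(n_genes=50, n_sig_A=10, seed=s)[0].rows,
        lambda s: gen_cells(n_animals=5, seed=s)[0].rows,
        lambda s: gen_flow(n_events=40, seed=s)[1].rows,
        lambda s: pd.DataFrame(gen_image(width=32, height=32, n_discs=2,
                                         disc_radius=4, seed=s)[0]),
        lambda s: gen_ct(seed=s)[0].rows,
    ])
    def test_same_seed_identical_output(self, gen):
        pd.testing.assert_frame_equal(gen(7), gen(7))
        assert not gen(7).equals(gen(8))


class TestCoip:
    def test_planted_ids_exist_in_table(self):
        table, truth = gen_coip(n_proteins=40, n_planted=5, seed=1)
        assert truth.planted_sets["destabilized"] <= set(table.protein_ids())

    def test_null_generator_gives_indistinguishable_di(self):
        # with no planted shift the planted/background DI distributions
        # should look identical; derandomized over 20 seeds
        n_significant = 0
        for seed in range(20):
            table, truth = gen_coip(n_proteins=60, n_planted=10, sr_base=0.5,
                                    sr_shifted=0.5, seed=seed)
            res = index_table(table).dropna(subset=["destab_index"])
            planted = res["protein_id"].isin(truth.planted_sets["destabilized"])
            p = mannwhitneyu(res.loc[planted, "destab_index"],
                             res.loc[~planted & (res["protein_id"] != "BAIT"),
                                     "destab_index"]).pvalue
            n_significant += p < 0.01
        assert n_significant <= 1

    def test_all_planted_low_dispersion_di_near_expectation(self):
        table, truth = gen_coip(n_proteins=100, n_planted=100, sr_base=0.9,
                                sr_shifted=0.1, dispersion=0.01,
                                mean_depth=200, seed=3)
        res = index_table(table)
        di = res.loc[res["protein_id"] != "BAIT", "destab_index"].dropna()
        assert abs(di.mean() - 0.8) < 0.05

    def test_truth_versus_di_spearman_meets_pinned_bound(self):
        table, truth = gen_coip(seed=0)
        res = index_table(table).dropna(subset=["destab_index"])
        true_mag = res["protein_id"].isin(
            truth.planted_sets["destabilized"]).astype(float) * 0.8
        rho = spearmanr(true_mag, res["destab_index"]).statistic
        assert rho >= SPEARMAN_DI_BOUND

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_coip(sr_base=1.5)
        with pytest.raises(ValueError):
            gen_coip(n_proteins=5, n_planted=10)


class TestDePair:
    def test_composition_planted_exactly(self):
        a, b, truth = gen_de_pair(n_genes=200, n_sig_A=37, frac_inverse=7 / 37,
                                  frac_unchanged=25 / 37, seed=11)
        assert len(truth.planted_sets["inverse"]) == 7
        assert len(truth.planted_sets["unchanged"]) == 25

    def test_zero_inverse_fraction_yields_no_inverse_calls(self):
        for seed in range(5):
            a, b, _ = gen_de_pair(n_genes=100, n_sig_A=20, frac_inverse=0.0,
                                  frac_unchanged=0.5, seed=seed)
            _, summary = cross_classify(call_significant(a), b)
            assert summary["n_inverse"] == 0

    def test_classification_recovers_planted_labels(self):
        agreements = []
        for seed in range(50):
            a, b, truth = gen_de_pair(n_genes=150, n_sig_A=30, frac_inverse=0.3,
                                      frac_unchanged=0.4, effect_size=2.0,
                                      seed=seed)
            records, _ = cross_classify(call_significant(a), b)
            cls = records.set_index("gene_id")["cls"]
            correct = sum(
                cls[g] == label
                for label, key in (("inverse", "inverse"),
                                   ("unchanged", "unchanged"),
                                   ("concordant", "concordant"))
                for g in truth.planted_sets[key]
            )
            agreements.append(correct / 30)
        assert np.mean(agreements) >= 0.99

    def test_infeasible_composition_rejected(self):
        with pytest.raises(ValueError):
            gen_de_pair(frac_inverse=0.7, frac_unchanged=0.7)


class TestCells:
    def test_no_shift_positives_only_from_noise(self):
        rates = []
        for seed in range(5):
            table, _ = gen_cells(n_animals=10, frac_nuclear_animals=0.5,
                                 fold_shift=1.0, noise_cv=0.2, seed=seed)
            res = score_nuclear(table)
            rates.append(res["percent_nuclear"].mean())
        # a 2-fold call against ~28% relative noise is a rare false positive
        assert np.mean(rates) < 5.0

    def test_planted_animals_exceed_background(self):
        table, truth = gen_cells(n_animals=20, frac_nuclear_animals=0.5,
                                 fold_shift=4.0, noise_cv=0.1, seed=9)
        res = score_nuclear(table).set_index("animal_id")
        planted = truth.planted_sets["nuclear_shifted"]
        med_planted = res.loc[sorted(planted), "percent_nuclear"].median()
        background = [a for a in res.index if a not in planted]
        med_bg = res.loc[background, "percent_nuclear"].median()
        assert med_planted > med_bg
        assert med_planted >= 40.0


class TestFlow:
    @pytest.mark.parametrize("ratio", [1.0, 2.0])
    def test_relative_fluorescence_estimates_expression_ratio(self, ratio):
        control, sample, _ = gen_flow(n_events=2000, expression_ratio=ratio,
                                      seed=13)
        res = tof_normalize(sample, control).set_index("group_label")
        assert res.loc["sample", "relative_to_control"] == pytest.approx(
            ratio, rel=0.05)


class TestImage:
    def test_zero_discs_zero_fraction(self):
        img, truth = gen_image(n_discs=0, seed=0)
        assert truth.expected["dark_fraction"] == 0.0
        assert (img == 255).all()

    def test_truth_fraction_matches_pixel_count(self):
        img, truth = gen_image(width=64, height=64, n_discs=4, disc_radius=6,
                               noise_sd=0.0, seed=2)
        assert truth.expected["dark_fraction"] == (img == 0).mean()


class TestCt:
    def test_planted_fold_change_recovered(self):
        table, truth = gen_ct(fold_changes={"tgtA": 2.0, "tgtB": 0.25},
                              noise_sd=0.0, seed=4)
        res = delta_delta_ct(table, "control").set_index(
            ["sample_label", "gene_id"])
        assert res.loc[("treatment", "tgtA"),
                       "relative_abundance"] == pytest.approx(2.0)
        assert res.loc[("treatment", "tgtB"),
                       "relative_abundance"] == pytest.approx(0.25)


class TestEndToEndRecovery:
    def test_single_seed_pipeline_recovers_planted_set(self):
        table, truth = gen_coip(seed=0)
        res = index_table(table)
        selected = top_fraction(res, 0.10)
        planted = truth.planted_sets["destabilized"]
        assert len(selected & planted) / len(planted) >= 0.9

        universe = set(res.dropna(subset=["destab_index"])["protein_id"])
        rng = np.random.default_rng(99)
        sets = {"planted_set": frozenset(planted)}
        pool = sorted(universe)
        for i in range(5):
            sets[f"decoy{i}"] = frozenset(
                map(str, rng.choice(pool, size=20, replace=False)))
        enr = enrich(selected & universe, GeneSetCollection(sets=sets),
                     universe=universe)
        assert enr.iloc[0]["set_name"] == "planted_set"
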