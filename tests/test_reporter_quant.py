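import numpy as np
import pandas as pd
import pytest

from solshift import (
    CellTable,
    CtTable,
    EventTable,
    absorption_impairment,
    delta_delta_ct,
    oro_density,
    score_nuclear,
    tem_black_fraction,
    tem_relative_density,
    tof_normalize,
)
from solshift.reporter_quant import oro_density_per_sample
from solshift.synthetic_data import gen_image


def cells(rows):
    return CellTable(pd.DataFrame(
        rows, columns=["animal_id", "cell_id", "nucleus_intensity",
                       "cytosol_intensity"]))


def events(pairs, group="sample"):
    return EventTable(pd.DataFrame(
        [(i, t, f) for i, (t, f) in enumerate(pairs)],
        columns=["event_id", "tof", "fluor_integral"]), group_label=group)


class TestNuclearScoring:
    def test_two_fold_rule_boundaries(self):
        table = cells([
            ("w1", 1, 250, 100),   # 2.5x -> positive
            ("w1", 2, 199, 100),   # 1.99x -> negative
            ("w1", 3, 200, 100),   # exactly 2x -> positive ("at least")
        ])
        res = score_nuclear(table).set_index("animal_id")
        assert res.loc["w1", "positive_nuclei"] == 2

    def test_percent_uses_fixed_denominator_20(self):
        table = cells([("w1", i, 300 if i <= 4 else 100, 100)
                       for i in range(1, 13)])
        res = score_nuclear(table).set_index("animal_id")
        assert res.loc["w1", "percent_nuclear"] == 20.0  # 4 / 20

    def test_zero_cytosol_cell_unscorable_denominator_unchanged(self):
        table = cells([("w1", 1, 300, 0), ("w1", 2, 300, 100)])
        res = score_nuclear(table).set_index("animal_id")
        assert res.loc["w1", "positive_nuclei"] == 1
        assert res.loc["w1", "percent_nuclear"] == 5.0

    def test_percent_is_always_multiple_of_five(self):
        rng = np.random.default_rng(2)
        rows = [(f"w{a}", c, float(rng.uniform(0, 400)), float(rng.uniform(1, 200)))
                for a in range(10) for c in range(1, 21)]
        res = score_nuclear(cells(rows))
        assert set(res["percent_nuclear"] % 5) == {0.0}


class TestTofNormalize:
    def test_per_event_ratio_then_group_mean(self):
        ctrl = events([(200, 1000)], group="control")   # normalized 5
        samp = events([(100, 1000)], group="sample")    # normalized 10
        res = tof_normalize(samp, ctrl).set_index("group_label")
        assert res.loc["sample", "relative_to_control"] == pytest.approx(2.0)
        assert res.loc["control", "relative_to_control"] == pytest.approx(1.0)

    def test_simultaneous_doubling_is_invariant(self):
        ctrl = events([(100, 300), (150, 600)], group="control")
        samp = events([(120, 700), (90, 200)], group="sample")
        doubled = events([(240, 1400), (180, 400)], group="sample")
        r1 = tof_normalize(samp, ctrl).set_index("group_label")
        r2 = tof_normalize(doubled, ctrl).set_index("group_label")
        assert r1.loc["sample", "relative_to_control"] == pytest.approx(
            r2.loc["sample", "relative_to_control"])

    def test_empty_control_rejected(self):
        samp = events([(100, 100)])
        with pytest.raises(Exception):
            tof_normalize(samp, EventTable(pd.DataFrame(
                columns=["event_id", "tof", "fluor_integral"]), "control"))


class TestOroDensity:
    def test_sample_equal_to_control_is_one(self):
        res = oro_density([4.0, 4.0], [4.0, 4.0]).set_index("group_label")
        assert res.loc["sample", "relative_to_control"] == pytest.approx(1.0)
        assert res.loc["control", "relative_to_control"] == pytest.approx(1.0)

    def test_half_brightness_doubles_density(self):
        res = oro_density([2.0], [4.0, 4.0]).set_index("group_label")
        assert res.loc["sample", "relative_to_control"] == pytest.approx(2.0)

    def test_hand_worked_mean_of_inverses(self):
        # control {2, 4}: mean inverse brightness = (1/2 + 1/4)/2 = 3/8
        # sample 2: (1/2) / (3/8) = 4/3
        rel = oro_density_per_sample([2.0], [2.0, 4.0])
        assert rel[0] == pytest.approx(4 / 3)

    def test_zero_brightness_rejected(self):
        with pytest.raises(ValueError):
            oro_density([0.0], [1.0])


class TestTemBlackFraction:
    def test_uniform_images(self):
        assert tem_black_fraction(np.full((4, 4), 255)) == 0.0
        assert tem_black_fraction(np.zeros((4, 4))) == 1.0

    def test_synthetic_disc_fraction_exact(self):
        img, truth = gen_image(width=96, height=96, n_discs=3, disc_radius=9,
                               noise_sd=0.0, seed=5)
        assert tem_black_fraction(img) == truth.expected["dark_fraction"]

    def test_double_inversion_idempotent(self):
        rng = np.random.default_rng(8)
        img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        double_inverted = 255 - (255 - img)
        assert tem_black_fraction(double_inverted) == tem_black_fraction(img)

    def test_relative_density_normalizes_to_control_mean(self):
        dark = np.zeros((8, 8))
        half = np.zeros((8, 8)); half[:4] = 255
        res = tem_relative_density([dark], [half, half]).set_index("group_label")
        assert res.loc["sample", "relative_to_control"].item() == pytest.approx(2.0)

    def test_empty_image_rejected(self):
        with pytest.raises(Exception):
            tem_black_fraction(np.zeros((0, 4)))


class TestDeltaDeltaCt:
    def ct_table(self, rows, hk=("hk1",)):
        return CtTable(pd.DataFrame(
            rows, columns=["sample_label", "gene_id", "ct", "replicate"]),
            housekeeping_ids=hk)

    def test_identical_cts_give_one(self):
        rows = [(s, g, ct, 1) for s in ("control", "mut")
                for g, ct in (("hk1", 15.0), ("tgt", 20.0))]
        res = delta_delta_ct(self.ct_table(rows), "control")
        res = res.set_index("sample_label")
        assert res.loc["mut", "relative_abundance"] == pytest.approx(1.0)

    def test_one_cycle_lower_doubles_abundance(self):
        rows = [("control", "hk1", 15.0, 1), ("control", "tgt", 20.0, 1),
                ("mut", "hk1", 15.0, 1), ("mut", "tgt", 19.0, 1)]
        res = delta_delta_ct(self.ct_table(rows), "control").set_index("sample_label")
        assert res.loc["mut", "relative_abundance"] == pytest.approx(2.0)

    def test_hand_worked_example(self):
        # ddCt = (20 - 15) - (22 - 16) = -1  ->  2^1 = 2
        rows = [("control", "hk1", 16.0, 1), ("control", "tgt", 22.0, 1),
                ("mut", "hk1", 15.0, 1), ("mut", "tgt", 20.0, 1)]
        res = delta_delta_ct(self.ct_table(rows), "control").set_index("sample_label")
        assert res.loc["mut", "delta_delta_ct"] == pytest.approx(-1.0)
        assert res.loc["mut", "relative_abundance"] == pytest.approx(2.0)

    def test_replicates_averaged_before_delta(self):
        rows = [("control", "hk1", 15.0, 1), ("control", "hk1", 17.0, 2),
                ("control", "tgt", 20.0, 1), ("control", "tgt", 22.0, 2),
                ("mut", "hk1", 16.0, 1), ("mut", "tgt", 20.0, 1)]
        res = delta_delta_ct(self.ct_table(rows), "control").set_index("sample_label")
        # control dCt = 21 - 16 = 5; mut dCt = 20 - 16 = 4 -> 2^1
        assert res.loc["mut", "relative_abundance"] == pytest.approx(2.0)

    def test_batch_shift_cancels_only_when_applied_to_all_genes(self):
        base = [("control", "hk1", 15.0, 1), ("control", "tgt", 20.0, 1),
                ("mut", "hk1", 15.0, 1), ("mut", "tgt", 20.0, 1)]
        shifted_all = [(s, g, ct + 3.0 if s == "mut" else ct, r)
                       for s, g, ct, r in base]
        res_all = delta_delta_ct(self.ct_table(shifted_all), "control")
        assert res_all.set_index("sample_label").loc[
            "mut", "relative_abundance"] == pytest.approx(1.0)
        shifted_target_only = [(s, g, ct + 3.0 if (s, g) == ("mut", "tgt") else ct, r)
                               for s, g, ct, r in base]
        res_tgt = delta_delta_ct(self.ct_table(shifted_target_only), "control")
        assert res_tgt.set_index("sample_label").loc[
            "mut", "relative_abundance"] == pytest.approx(2.0 ** -3)

    def test_geometric_mean_equivalence_two_housekeepers(self):
        # arithmetic mean of hk Cts == log2 of geometric mean of linear levels
        rows = [("control", "hk1", 14.0, 1), ("control", "hk2", 18.0, 1),
                ("control", "tgt", 20.0, 1),
                ("mut", "hk1", 14.0, 1), ("mut", "hk2", 18.0, 1),
                ("mut", "tgt", 19.0, 1)]
        res = delta_delta_ct(self.ct_table(rows, hk=("hk1", "hk2")),
                             "control").set_index("sample_label")
        assert res.loc["mut", "relative_abundance"] == pytest.approx(2.0)


class TestAbsorption:
    def test_strict_less_than_cutoff(self):
        assert absorption_impairment([0.9, 0.8, 0.2]) == pytest.approx(100 / 3)
        assert absorption_impairment([0.5, 0.5, 0.5]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            absorption_impairment([])
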