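"""ddCt folds, luciferase fold induction, in-silico PCR and the t-test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nrescan.assays import (
    CtMeasurement,
    LuciferaseWell,
    PcrProduct,
    PrimerPair,
    ddct_fold,
    insilico_pcr,
    rla_fold,
    stars_for,
    unpaired_t,
)
from nrescan.motifs import reverse_complement


def _ct_rows(rows):
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])


class TestDdctFold:
    def test_identical_cts_give_fold_one(self):
        rows = [
            (f"s{i}", grp, gene, 20.0 if gene == "NDRG2" else 15.0)
            for i, grp in enumerate(["DMSO"] * 3 + ["agonist"] * 3)
            for gene in ("NDRG2", "TBP")
        ]
        per, summary = ddct_fold(_ct_rows(rows), "NDRG2", "TBP", "DMSO")
        assert np.allclose(per["fold"], 1.0)
        assert np.allclose(summary["mean_fold"], 1.0)

    def test_one_cycle_earlier_doubles_expression(self):
        rows = []
        for i in range(3):
            rows += [(f"c{i}", "DMSO", "NDRG2", 20.0), (f"c{i}", "DMSO", "TBP", 15.0)]
            rows += [(f"t{i}", "agonist", "NDRG2", 19.0), (f"t{i}", "agonist", "TBP", 15.0)]
        per, summary = ddct_fold(_ct_rows(rows), "NDRG2", "TBP", "DMSO")
        treated = summary.set_index("group").loc["agonist", "mean_fold"]
        assert treated == pytest.approx(2.0, abs=1e-12)

    def test_matches_spreadsheet_oracle_on_random_table(self):
        rng = np.random.default_rng(8)
        rows, oracle_dct = [], {}
        for i, grp in enumerate(["ctl"] * 4 + ["trt"] * 5):
            sid = f"s{i}"
            tgt, hk = rng.uniform(18, 30), rng.uniform(14, 18)
            rows += [(sid, grp, "GENE", tgt), (sid, grp, "HK", hk)]
            oracle_dct[sid] = (grp, tgt - hk)
        per, _ = ddct_fold(_ct_rows(rows), "GENE", "HK", "ctl")
        ctl_mean = np.mean([d for g, d in oracle_dct.values() if g == "ctl"])
        for _, r in per.iterrows():
            expected = 2.0 ** (-(oracle_dct[r["sample_id"]][1] - ctl_mean))
            assert r["fold"] == pytest.approx(expected, abs=1e-12)

    def test_shift_invariance_per_sample(self):
        """Adding a constant to both Cts of a sample leaves every fold unchanged."""
        rng = np.random.default_rng(9)
        rows, shifted = [], []
        for i, grp in enumerate(["ctl"] * 3 + ["trt"] * 3):
            sid, tgt, hk = f"s{i}", rng.uniform(18, 30), rng.uniform(14, 18)
            c = rng.uniform(-3, 3)
            rows += [(sid, grp, "G", tgt), (sid, grp, "H", hk)]
            shifted += [(sid, grp, "G", tgt + c), (sid, grp, "H", hk + c)]
        f1, _ = ddct_fold(_ct_rows(rows), "G", "H", "ctl")
        f2, _ = ddct_fold(_ct_rows(shifted), "G", "H", "ctl")
        assert np.allclose(f1["fold"], f2["fold"], atol=1e-12)

    def test_missing_housekeeping_names_the_sample(self):
        rows = [("s0", "ctl", "G", 20.0), ("s0", "ctl", "H", 15.0), ("s1", "ctl", "G", 21.0)]
        with pytest.raises(ValueError, match="s1"):
            ddct_fold(_ct_rows(rows), "G", "H", "ctl")

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError):
            CtMeasurement("s", "g", "G", 0.0)


class TestRlaFold:
    def test_identical_conditions_fold_one(self):
        wells = [LuciferaseWell(f"w{i}", c, 300.0, 100.0)
                 for i, c in enumerate(["DMSO", "DMSO", "Px", "Px"])]
        assert rla_fold(wells, "Px", "DMSO") == pytest.approx(1.0)

    def test_threefold_activation(self):
        wells = [LuciferaseWell("c1", "DMSO", 100.0, 50.0),
                 LuciferaseWell("c2", "DMSO", 200.0, 100.0),
                 LuciferaseWell("t1", "Px", 300.0, 50.0),
                 LuciferaseWell("t2", "Px", 600.0, 100.0)]
        assert rla_fold(wells, "Px", "DMSO") == pytest.approx(3.0, abs=1e-12)

    def test_unbalanced_replicates_match_hand_oracle(self):
        rng = np.random.default_rng(14)
        ctl = [LuciferaseWell(f"c{i}", "D", rng.uniform(50, 500), rng.uniform(20, 200))
               for i in range(3)]
        trt = [LuciferaseWell(f"t{i}", "P", rng.uniform(50, 500), rng.uniform(20, 200))
               for i in range(5)]
        expected = (sum(w.firefly / w.renilla for w in trt) / 5) / (
            sum(w.firefly / w.renilla for w in ctl) / 3
        )
        assert rla_fold(ctl + trt, "P", "D") == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance_per_condition(self):
        rng = np.random.default_rng(15)
        wells = [LuciferaseWell(f"w{i}", c, rng.uniform(50, 500), rng.uniform(20, 200))
                 for i, c in enumerate(["D", "D", "P", "P", "P"])]
        scaled = [LuciferaseWell(w.well_id, w.condition, w.firefly * 7.5, w.renilla * 7.5)
                  for w in wells]
        assert rla_fold(scaled, "P", "D") == pytest.approx(rla_fold(wells, "P", "D"), rel=1e-12)

    def test_zero_renilla_rejected_at_construction(self):
        with pytest.raises(ValueError):
            LuciferaseWell("w", "D", 100.0, 0.0)


class TestInsilicoPcr:
    PRIMERS = PrimerPair("GAACTGATGCCCTTGTAGCC", "CAACGAGGTGAATGACATGG")

    def test_constructed_product_length(self):
        template = self.PRIMERS.forward + "A" * 10 + reverse_complement(self.PRIMERS.reverse)
        (prod,) = insilico_pcr(template, self.PRIMERS)
        assert prod.length == 20 + 10 + 20

    def test_missing_primer_gives_no_product(self):
        assert insilico_pcr("ACGT" * 50, self.PRIMERS) == []
        assert insilico_pcr(self.PRIMERS.forward + "A" * 30, self.PRIMERS) == []

    def test_two_reverse_sites_two_products(self):
        rc = reverse_complement(self.PRIMERS.reverse)
        template = self.PRIMERS.forward + "A" * 5 + rc + "C" * 7 + rc
        prods = insilico_pcr(template, self.PRIMERS)
        assert [p.length for p in prods] == [45, 72]

    def test_flanking_sequence_invariance(self):
        template = self.PRIMERS.forward + "ACGTACGT" + reverse_complement(self.PRIMERS.reverse)
        bare = insilico_pcr(template, self.PRIMERS)
        flanked = insilico_pcr("TTTT" + template + "GGGG", self.PRIMERS)
        assert [p.length for p in bare] == [p.length for p in flanked]

    def test_invalid_primers_rejected(self):
        with pytest.raises(ValueError):
            PrimerPair("", "ACGT")
        with pytest.raises(ValueError):
            PrimerPair("ACGT", "ACXT")


class TestUnpairedT:
    def test_identical_groups(self):
        res = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)
        assert res.stars == "ns"

    def test_large_shift_reaches_three_stars(self):
        res = unpaired_t([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert res.stars == "***"

    def test_matches_closed_form(self):
        a, b = [4.2, 5.1, 3.9, 4.8], [6.0, 6.4, 5.7]
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t_hand = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        p_hand = 2 * stats.t.sf(abs(t_hand), na + nb - 2)
        res = unpaired_t(a, b)
        assert res.t == pytest.approx(t_hand, abs=1e-9)
        assert res.p == pytest.approx(p_hand, abs=1e-9)

    def test_group_swap_negates_t_preserves_p(self):
        rng = np.random.default_rng(21)
        a, b = rng.normal(0, 1, 6), rng.normal(0.8, 1, 7)
        r1, r2 = unpaired_t(a, b), unpaired_t(b, a)
        assert r1.t == pytest.approx(-r2.t, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_zero_variance_equal_means(self):
        res = unpaired_t([2.0, 2.0], [2.0, 2.0])
        assert (res.t, res.p, res.stars) == (0.0, 1.0, "ns")

    def test_zero_variance_unequal_means_undefined(self):
        with pytest.raises(ValueError):
            unpaired_t([2.0, 2.0], [3.0, 3.0])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t([1.0], [2.0, 3.0])

    @pytest.mark.parametrize(
        "p,expected",
        [(0.2, "ns"), (0.049, "*"), (0.009, "**"), (0.0009, "***"), (0.05, "ns")],
    )
    def test_star_thresholds(self, p, expected):
        assert stars_for(p) == expected
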