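import math

import numpy as np
import pandas as pd
import pytest

from promdir.directionality import (
    LOG2_10,
    change_table,
    directionality_change,
    directionality_score,
    directionality_table,
    log2fc,
    spikein_size_factors,
    stratify_quintiles,
)


class TestDirectionalityScore:
    def test_hand_computed_goldens(self):
        assert directionality_score([9, 9, 9], [0, 0, 0]) == pytest.approx(
            1.0, abs=1e-12)
        assert directionality_score([4], [4]) == 0.0
        assert directionality_score([10, 20], [3, 1]) == pytest.approx(
            math.log10(16 / 3), abs=1e-12)

    def test_antisymmetry(self, rng):
        for _ in range(25):
            s = rng.poisson(20, 3).tolist()
            a = rng.poisson(5, 3).tolist()
            assert directionality_score(s, a) == pytest.approx(
                -directionality_score(a, s), abs=1e-12)

    def test_monotonicity_in_each_replicate(self):
        base_s, base_a = [10, 20, 15], [3, 1, 2]
        d0 = directionality_score(base_s, base_a)
        for i in range(3):
            s_up = list(base_s); s_up[i] += 5
            assert directionality_score(s_up, base_a) > d0
            a_up = list(base_a); a_up[i] += 5
            assert directionality_score(base_s, a_up) < d0

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            directionality_score([], [])

    def test_mismatched_replicates_rejected(self):
        with pytest.raises(ValueError):
            directionality_score([1, 2], [1])


class TestSizeFactors:
    def test_hand_median_of_ratios(self):
        counts = pd.DataFrame([[10, 20], [20, 40]], index=["s1", "s2"],
                              columns=["A", "B"])
        sf = spikein_size_factors(counts, ["s1", "s2"])
        assert sf.factors["A"] == pytest.approx(1 / math.sqrt(2), abs=1e-9)
        assert sf.factors["B"] == pytest.approx(math.sqrt(2), abs=1e-9)

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"A": [5, 9, 30], "B": [5, 9, 30]},
                              index=["s1", "s2", "s3"])
        sf = spikein_size_factors(counts, ["s1", "s2", "s3"])
        assert np.allclose(sf.factors, 1.0)

    def test_scale_equivariance(self, rng):
        counts = pd.DataFrame(rng.poisson(50, (20, 3)) + 1,
                              index=[f"s{i}" for i in range(20)],
                              columns=["A", "B", "C"])
        base = spikein_size_factors(counts, counts.index)
        scaled = counts.copy()
        scaled["B"] = scaled["B"] * 3
        out = spikein_size_factors(scaled, counts.index)
        # gene-wise geometric means shift by 3**(1/3); sample B's ratio
        # gains the remaining factor relative to the others
        ratio = out.factors / base.factors
        assert ratio["B"] / ratio["A"] == pytest.approx(3.0, rel=1e-9)

    def test_gene_order_invariance(self, rng):
        counts = pd.DataFrame(rng.poisson(30, (10, 2)) + 1,
                              index=[f"s{i}" for i in range(10)],
                              columns=["A", "B"])
        sf1 = spikein_size_factors(counts, counts.index)
        shuffled = counts.sample(frac=1.0, random_state=7)
        sf2 = spikein_size_factors(shuffled, shuffled.index)
        assert np.allclose(sf1.factors, sf2.factors)

    def test_requires_one_all_nonzero_spikein(self):
        counts = pd.DataFrame({"A": [0, 3], "B": [4, 0]},
                              index=["s1", "s2"])
        with pytest.raises(ValueError, match="nonzero"):
            spikein_size_factors(counts, ["s1", "s2"])


class TestLog2fcAndChange:
    def test_fold_change_goldens(self):
        assert log2fc(31, 15) == pytest.approx(1.0, abs=1e-12)
        assert log2fc(20, 20) == 0.0
        assert log2fc(15, 31) == pytest.approx(-1.0, abs=1e-12)

    def test_size_factor_normalization(self):
        # doubling the count and the size factor together changes nothing
        assert log2fc(62, 15, sf_t=2.0) == pytest.approx(1.0, abs=1e-12)

    def test_directionality_change_unit_conversion(self):
        assert directionality_change(2.0, 1.0) == pytest.approx(
            math.log2(10), abs=1e-9)
        assert directionality_change(1.3, 1.3) == 0.0

    def test_change_equals_sense_minus_divergent_fold_change(self, rng):
        """delta_directionality decomposes exactly into the two fold changes
        when everything shares pseudocounted means and unit size factors."""
        for _ in range(20):
            s_t, a_t = rng.poisson(30, 3), rng.poisson(6, 3)
            s_c, a_c = rng.poisson(25, 3), rng.poisson(8, 3)
            S_t, A_t = (s_t + 1).mean(), (a_t + 1).mean()
            S_c, A_c = (s_c + 1).mean(), (a_c + 1).mean()
            D_t = directionality_score(s_t, a_t)
            D_c = directionality_score(s_c, a_c)
            delta = directionality_change(D_t, D_c)
            assert delta == pytest.approx(
                math.log2(S_t / S_c) - math.log2(A_t / A_c), abs=1e-9)


class TestQuintiles:
    def test_ten_genes_split_evenly(self):
        scores = pd.Series(range(1, 11),
                           index=[f"g{i}" for i in range(1, 11)],
                           dtype=float)
        q = stratify_quintiles(scores)
        assert list(q.summary["size"]) == [2, 2, 2, 2, 2]
        q5 = q.summary.set_index("quintile").loc["Q5"]
        assert (q5["min_score"], q5["max_score"]) == (9.0, 10.0)
        assert q.labels["g1"] == "Q1" and q.labels["g10"] == "Q5"

    def test_eleven_genes_remainder_goes_low(self):
        scores = pd.Series(range(11), index=[f"g{i:02d}" for i in range(11)],
                           dtype=float)
        q = stratify_quintiles(scores)
        assert list(q.summary["size"]) == [3, 2, 2, 2, 2]

    def test_all_equal_scores_tie_break_by_gene_id(self):
        scores = pd.Series(1.0, index=[f"g{i:02d}" for i in range(10)])
        q = stratify_quintiles(scores)
        assert q.labels["g00"] == "Q1" and q.labels["g09"] == "Q5"

    def test_permutation_invariance(self, rng):
        scores = pd.Series(rng.normal(size=37),
                           index=[f"g{i:02d}" for i in range(37)])
        q1 = stratify_quintiles(scores)
        q2 = stratify_quintiles(scores.sample(frac=1.0, random_state=3))
        assert q1.labels.sort_index().equals(q2.labels.sort_index())

    def test_partition_is_disjoint_and_exhaustive(self, rng):
        scores = pd.Series(rng.normal(size=53),
                           index=[f"g{i:02d}" for i in range(53)])
        q = stratify_quintiles(scores)
        assert len(q.labels) == 53
        assert q.summary["size"].sum() == 53
        # ranges ordered and non-overlapping
        s = q.summary
        assert (s["min_score"] <= s["max_score"]).all()
        assert (s["max_score"].iloc[:-1].values
                <= s["min_score"].iloc[1:].values).all()

    def test_fewer_than_five_genes_rejected(self):
        with pytest.raises(ValueError):
            stratify_quintiles(pd.Series([1.0, 2.0], index=["a", "b"]))


class TestTables:
    def make_inputs(self, rng):
        sheet = pd.DataFrame({
            "sample_id": ["c1", "c2", "t1", "t2"],
            "condition": ["control", "control", "treated", "treated"],
            "replicate": [1, 2, 1, 2],
        })
        rows = []
        for gid in ["gA", "gB", "gC"]:
            for s in sheet["sample_id"]:
                rows.append({"gene_id": gid, "sample_id": s,
                             "sense": int(rng.poisson(40)),
                             "antisense": int(rng.poisson(5))})
        return pd.DataFrame(rows), sheet

    def test_directionality_table_matches_scalar_formula(self, rng):
        wc, sheet = self.make_inputs(rng)
        table = directionality_table(wc, sheet, "control")
        for gid in table.index:
            sub = wc[(wc["gene_id"] == gid)
                     & (wc["sample_id"].isin(["c1", "c2"]))]
            expected = directionality_score(sub["sense"].tolist(),
                                            sub["antisense"].tolist())
            assert table.loc[gid, "D"] == pytest.approx(expected, abs=1e-12)
        assert (table["replicate_count"] == 2).all()

    def test_change_table_identity(self, rng):
        wc, sheet = self.make_inputs(rng)
        t = directionality_table(wc, sheet, "treated")
        c = directionality_table(wc, sheet, "control")
        ch = change_table(t, c)
        lhs = ch["delta_directionality"]
        rhs = ch["log2FC_sense"] - ch["log2FC_divergent"]
        assert np.allclose(lhs, rhs)
        assert np.allclose(ch["delta_directionality"],
                           (t["D"] - c["D"]) * LOG2_10)

    def test_missing_condition_rejected(self, rng):
        wc, sheet = self.make_inputs(rng)
        with pytest.raises(ValueError):
            directionality_table(wc, sheet, "ghost")
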