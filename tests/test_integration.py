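import numpy as np
import pandas as pd
import pytest

from omicshub import integration as integ
from omicshub.containers import OmicsMatrix, TargetMap

from oracles import pearson_r_p


def _de_table(status: dict) -> pd.DataFrame:
    ids = list(status)
    return pd.DataFrame(
        {"log2fc": [1.5 if s == "up" else -1.5 if s == "down" else 0.0 for s in status.values()],
         "p_adj": [0.001 if s != "ns" else 0.5 for s in status.values()],
         "status": list(status.values())},
        index=pd.Index(ids, name="feature_id"),
    )


def _targets(rows):
    return TargetMap(pd.DataFrame(rows, columns=["mirna_id", "gene_id", "n_algorithms"]))


class TestTargetFilter:
    def test_boundary_at_three_algorithms(self):
        tm = _targets([("m1", "g1", 3), ("m2", "g2", 2), ("m3", "g3", 5)])
        kept = integ.filter_targets(tm).df
        assert set(zip(kept["mirna_id"], kept["gene_id"])) == {("m1", "g1"), ("m3", "g3")}

    def test_random_map_matches_elementwise_oracle(self):
        rng = np.random.default_rng(21)
        rows = [(f"m{i}", f"g{i}", int(rng.integers(1, 6))) for i in range(100)]
        kept = integ.filter_targets(_targets(rows), min_algorithms=4).df
        expected = {(m, g) for m, g, n in rows if n >= 4}
        assert set(zip(kept["mirna_id"], kept["gene_id"])) == expected


class TestMirnaBimodal:
    def test_direction_truth_table(self):
        gene_de = _de_table({"gU": "up", "gD": "down", "gN": "ns"})
        mirna_de = _de_table({"mU": "up", "mD": "down", "mN": "ns"})
        tm = _targets([
            ("mU", "gD", 5),   # up miRNA, down gene -> kept
            ("mU", "gU", 5),   # concordant -> dropped
            ("mD", "gU", 5),   # down miRNA, up gene -> kept
            ("mD", "gD", 5),   # concordant -> dropped
            ("mN", "gD", 5),   # miRNA not DE -> dropped
            ("mU", "gN", 5),   # gene not DE -> dropped
        ])
        pairs, genes = integ.mirna_bimodal_filter(gene_de, mirna_de, tm)
        assert set(zip(pairs["mirna_id"], pairs["gene_id"])) == {("mU", "gD"), ("mD", "gU")}
        assert genes == {"gD", "gU"}

    def test_candidates_are_degs(self, small_cohort):
        from omicshub import differential as diff
        gde = diff.paired_moderated_test(small_cohort.expression)
        mde = diff.paired_moderated_test(small_cohort.mirna)
        tm = integ.filter_targets(small_cohort.targets)
        _, genes = integ.mirna_bimodal_filter(gde, mde, tm)
        degs = set(gde.index[gde["status"] != "ns"])
        assert genes <= degs


class TestCorrelate:
    def _matrices(self, a_rows, b_rows):
        n = a_rows.shape[1]
        samples = [f"P{i}-T" for i in range(n)]
        meta = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)], "tissue": ["tumor"] * n},
                            index=pd.Index(samples, name="sample_id"))
        ma = OmicsMatrix(pd.DataFrame(a_rows, index=[f"a{i}" for i in range(len(a_rows))], columns=samples), meta)
        mb = OmicsMatrix(pd.DataFrame(b_rows, index=[f"b{i}" for i in range(len(b_rows))], columns=samples), meta)
        return ma, mb

    def test_perfect_linear_and_inverse(self):
        ma, mb = self._matrices(np.array([[1.0, 2, 3]]), np.array([[2.0, 4, 6], [6.0, 4, 2]]))
        pairs = pd.DataFrame({"mirna_id": ["a0", "a0"], "gene_id": ["b0", "b1"]})
        rec = integ.correlate(pairs, ma, mb, log_transform=False)
        assert rec["r"].iloc[0] == pytest.approx(1.0)
        assert rec["r"].iloc[1] == pytest.approx(-1.0)

    def test_random_vectors_match_formula_oracle(self):
        rng = np.random.default_rng(22)
        a = rng.uniform(1, 50, size=(5, 20))
        b = rng.uniform(1, 50, size=(5, 20))
        ma, mb = self._matrices(a, b)
        pairs = pd.DataFrame({"mirna_id": [f"a{i}" for i in range(5)], "gene_id": [f"b{i}" for i in range(5)]})
        rec = integ.correlate(pairs, ma, mb, log_transform=False)
        for i in range(5):
            r, p = pearson_r_p(a[i], b[i])
            assert rec["r"].iloc[i] == pytest.approx(r, abs=1e-12)
            assert rec["p"].iloc[i] == pytest.approx(p, abs=1e-12)

    def test_zero_variance_yields_nan_record(self):
        ma, mb = self._matrices(np.array([[3.0, 3, 3]]), np.array([[1.0, 2, 3]]))
        pairs = pd.DataFrame({"mirna_id": ["a0"], "gene_id": ["b0"]})
        rec = integ.correlate(pairs, ma, mb, log_transform=False)
        assert np.isnan(rec["r"].iloc[0])
        # and the downstream gate excludes it
        assert len(integ.functional_pairs(rec)) == 0

    def test_requires_three_common_samples(self):
        ma, mb = self._matrices(np.ones((1, 2)), np.ones((1, 2)))
        pairs = pd.DataFrame({"mirna_id": ["a0"], "gene_id": ["b0"]})
        with pytest.raises(ValueError, match="common"):
            integ.correlate(pairs, ma, mb)


class TestFunctionalPairs:
    @pytest.mark.parametrize(
        "r,p,kept",
        [
            (-0.05, 0.01, False),  # r not below -0.1
            (-0.5, 0.001, True),
            (-0.5, 0.2, False),    # P gate fails
            (-0.1, 0.01, False),   # boundary r = -0.1 excluded (strict <)
            (0.5, 0.001, False),
        ],
    )
    def test_gates(self, r, p, kept):
        rec = pd.DataFrame({"id_a": ["m"], "id_b": ["g"], "r": [r], "p": [p], "n": [30]})
        assert (len(integ.functional_pairs(rec)) == 1) is kept

    def test_threshold_relaxation_is_monotone(self):
        rng = np.random.default_rng(23)
        rec = pd.DataFrame({"id_a": "m", "id_b": [f"g{i}" for i in range(200)],
                            "r": rng.uniform(-1, 1, 200), "p": rng.uniform(0, 1, 200), "n": 30})
        strict = set(integ.functional_pairs(rec, r_max=-0.3, p_max=0.01)["id_b"])
        loose = set(integ.functional_pairs(rec, r_max=-0.1, p_max=0.05)["id_b"])
        assert strict <= loose


class TestMethylationBimodal:
    def test_direction_truth_table(self):
        gene_de = _de_table({"g1": "up", "g2": "up", "g3": "down", "g4": "down", "g5": "ns"})
        meth_de = _de_table({"g1": "down", "g2": "up", "g3": "up", "g4": "down", "g5": "down"})
        ann, genes = integ.methylation_bimodal_filter(gene_de, meth_de)
        assert genes == {"g1", "g3"}
        lookup = ann.set_index("gene_id")["methylation"]
        assert lookup["g1"] == "hypo"   # over-expressed & hypomethylated
        assert lookup["g3"] == "hyper"  # under-expressed & hypermethylated


class TestCnaBimodal:
    def _cohort_pieces(self):
        rng = np.random.default_rng(24)
        n = 30
        samples = [f"P{i}-T" for i in range(n)]
        meta = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)], "tissue": ["tumor"] * n},
                            index=pd.Index(samples, name="sample_id"))
        dose = rng.normal(1.2, 0.4, n)
        expr = pd.DataFrame(
            {
                "gAmpGood": np.power(2.0, 6 + dose + rng.normal(0, 0.1, n)),
                "gAmpNoCorr": np.power(2.0, 6 + rng.normal(0, 0.5, n)),
                "gDel": np.power(2.0, 4 + rng.normal(0, 0.3, n)),
            },
            index=samples,
        ).T
        ratios = pd.DataFrame(
            {"gAmpGood": dose, "gAmpNoCorr": rng.normal(1.2, 0.4, n), "gDel": rng.normal(-1.8, 0.3, n)},
            index=samples,
        ).T
        return OmicsMatrix(expr, meta), ratios

    def test_concordance_and_correlation_gates(self):
        expr, ratios = self._cohort_pieces()
        gene_de = _de_table({"gAmpGood": "up", "gAmpNoCorr": "up", "gDel": "down"})
        ann, genes = integ.cna_bimodal_filter(
            gene_de, amplified={"gAmpGood", "gAmpNoCorr"}, deleted=set(), expr=expr, ratios=ratios
        )
        assert genes == {"gAmpGood"}  # dosage-correlated amp gene only
        assert ann.set_index("gene_id").loc["gAmpGood", "r"] > 0.5
        # down gene recurrently amplified (discordant) is never admitted
        gene_de2 = _de_table({"gAmpGood": "down", "gAmpNoCorr": "ns", "gDel": "down"})
        _, genes2 = integ.cna_bimodal_filter(
            gene_de2, amplified={"gAmpGood"}, deleted=set(), expr=expr, ratios=ratios
        )
        assert genes2 == set()


class TestOverlap:
    def test_enumerable_example(self):
        sets = integ.CandidateGeneSets(mirna_set={"g1", "g2"}, meth_set={"g2", "g3"}, cna_set={"g2"})
        out = integ.overlap_analysis(sets)
        assert out["triple_intersection"] == ["g2"]
        assert out["genes_in_two_or_more"] == ["g2"]
        assert out["regions"]["mirna_only"] == 1 and out["regions"]["meth_only"] == 1

    def test_disjoint_sets(self):
        sets = integ.CandidateGeneSets(mirna_set={"a"}, meth_set={"b"}, cna_set={"c"})
        out = integ.overlap_analysis(sets)
        assert out["triple_intersection"] == [] and out["genes_in_two_or_more"] == []

    def test_random_sets_match_bruteforce_enumeration(self):
        rng = np.random.default_rng(25)
        universe = [f"g{i}" for i in range(120)]
        a, b, c = (set(rng.choice(universe, 50, replace=False)) for _ in range(3))
        out = integ.overlap_analysis(integ.CandidateGeneSets(mirna_set=a, meth_set=b, cna_set=c))
        counts = {k: 0 for k in out["regions"]}
        for g in universe:
            key = (g in a, g in b, g in c)
            name = {
                (True, False, False): "mirna_only", (False, True, False): "meth_only",
                (False, False, True): "cna_only", (True, True, False): "mirna_meth",
                (True, False, True): "mirna_cna", (False, True, True): "meth_cna",
                (True, True, True): "triple",
            }.get(key)
            if name:
                counts[name] += 1
        assert out["regions"] == counts
        assert set(out["genes_in_two_or_more"]) == {g for g in universe if (g in a) + (g in b) + (g in c) >= 2}
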