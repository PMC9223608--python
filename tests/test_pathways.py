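"""Pathway enrichment, z-scores, correlation, clustering, regression."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pdgbo import pathways as pw
from pdgbo import simulate as sim


def brute_force_ssgsea(expression: pd.Series, gene_set, alpha: float) -> float:
    """Independent running-sum oracle, coded step by step from the formula.

    Ranks are computed by explicit counting (average on ties), the walk
    order by an explicit sort on (-value, name), and the running sums by a
    plain loop.
    """
    genes = list(expression.index)
    values = [float(expression[g]) for g in genes]
    n = len(genes)
    # average rank of each gene, 1 = lowest value
    ranks = {}
    for g, v in zip(genes, values):
        below = sum(1 for u in values if u < v)
        ties = sum(1 for u in values if u == v)
        ranks[g] = below + (ties + 1) / 2.0
    walk = sorted(genes, key=lambda g: (-expression[g], g))
    in_set = set(gene_set)
    w_total = sum((ranks[g] / n) ** alpha for g in walk if g in in_set)
    n_out = n - sum(1 for g in walk if g in in_set)
    es = 0.0
    p_in = p_out = 0.0
    for g in walk:
        if g in in_set:
            p_in += (ranks[g] / n) ** alpha / w_total
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es


@pytest.fixture()
def toy_expression():
    return pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=[f"g{i}" for i in range(1, 6)])


class TestGmt:
    def test_roundtrip_and_dedup(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("P1\tdesc\tA\tB\nP2\tdesc\tA\tA\tC\n")
        coll = pw.read_gmt(str(p))
        assert coll["P1"] == ["A", "B"]
        assert coll["P2"] == ["A", "C"]  # duplicate collapsed
        out = tmp_path / "out.gmt"
        pw.write_gmt(coll, str(out))
        assert pw.read_gmt(str(out)).sets == coll.sets

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("P1\tdesc\tA\nP2\tonlytwo\n")
        with pytest.raises(ValueError, match=":2:"):
            pw.read_gmt(str(p))

    def test_empty_set_rejected(self, tmp_path):
        p = tmp_path / "empty.gmt"
        p.write_text("P1\tdesc\t\t\n")
        with pytest.raises(ValueError, match="no genes"):
            pw.read_gmt(str(p))


class TestSsgsea:
    def test_top_set_positive_and_matches_oracle(self, toy_expression):
        es = pw.ssgsea_score(toy_expression, ["g1", "g2"])
        assert es > 0
        assert es == pytest.approx(
            brute_force_ssgsea(toy_expression, ["g1", "g2"], 0.25), abs=1e-12
        )

    def test_bottom_set_negative(self, toy_expression):
        assert pw.ssgsea_score(toy_expression, ["g4", "g5"]) < 0

    def test_unweighted_walk_is_sign_symmetric(self, toy_expression):
        # with alpha=0 the running sum reduces to the classic KS walk, which
        # is exactly antisymmetric between a top-k and bottom-k set
        top = pw.ssgsea_score(toy_expression, ["g1", "g2"], alpha=0.0)
        bottom = pw.ssgsea_score(toy_expression, ["g4", "g5"], alpha=0.0)
        assert top == pytest.approx(-bottom, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_all_admissible_subsets_match_oracle_exactly(
        self, toy_expression, alpha
    ):
        genes = list(toy_expression.index)
        for k in range(1, 5):
            for subset in itertools.combinations(genes, k):
                if len(subset) < 2:
                    continue
                assert pw.ssgsea_score(
                    toy_expression, list(subset), alpha=alpha
                ) == pytest.approx(
                    brute_force_ssgsea(toy_expression, subset, alpha), abs=1e-12
                )

    def test_rank_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        expr = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        gene_set = [f"g{i}" for i in range(0, 10, 2)]
        es = pw.ssgsea_score(expr, gene_set)
        assert pw.ssgsea_score(np.exp(expr), gene_set) == pytest.approx(es, abs=1e-12)
        assert pw.ssgsea_score(expr * 100 + 7, gene_set) == pytest.approx(
            es, abs=1e-12
        )

    def test_input_file_order_irrelevant(self, toy_expression):
        shuffled = toy_expression.sample(frac=1.0, random_state=1)
        assert pw.ssgsea_score(shuffled, ["g1", "g3"]) == pytest.approx(
            pw.ssgsea_score(toy_expression, ["g1", "g3"]), abs=1e-12
        )

    def test_degenerate_overlap_rejected(self, toy_expression):
        with pytest.raises(ValueError, match="overlap"):
            pw.ssgsea_score(toy_expression, ["g1"])
        with pytest.raises(ValueError, match="complement"):
            pw.ssgsea_score(toy_expression, list(toy_expression.index))


class TestZscoreEnrichment:
    def test_hand_row(self):
        es = pd.DataFrame([[1.0, 2.0, 3.0]], index=["P"], columns=list("abc"))
        z, flags = pw.zscore_enrichment(es)
        assert z.loc["P"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert flags == []

    def test_constant_row_zeroed_and_flagged(self):
        es = pd.DataFrame(
            [[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]], index=["flat", "ok"],
            columns=list("abc"),
        )
        z, flags = pw.zscore_enrichment(es)
        assert (z.loc["flat"] == 0).all()
        assert flags == ["flat"]

    def test_rows_standardized(self):
        rng = np.random.default_rng(1)
        es = pd.DataFrame(rng.normal(size=(5, 8)))
        z, _ = pw.zscore_enrichment(es)
        assert z.mean(axis=1).to_numpy() == pytest.approx(np.zeros(5), abs=1e-9)
        assert z.std(axis=1, ddof=1).to_numpy() == pytest.approx(
            np.ones(5), abs=1e-9
        )

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pw.zscore_enrichment(pd.DataFrame([[1.0]], columns=["s"]))


class TestCorrelation:
    def test_identical_and_negated_vectors(self):
        e = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["P"], columns=list("abcd"))
        r_pos, n, flags = pw.correlate_drug_pathway(
            e, pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["d"], columns=list("abcd"))
        )
        r_neg, _, _ = pw.correlate_drug_pathway(
            e, pd.DataFrame([[-1.0, -2.0, -3.0, -4.0]], index=["d"],
                            columns=list("abcd"))
        )
        assert r_pos.loc["P", "d"] == pytest.approx(1.0)
        assert r_neg.loc["P", "d"] == pytest.approx(-1.0)
        assert n == 4 and flags == ["low_n"]

    def test_too_few_samples_rejected(self):
        e = pd.DataFrame([[1.0, 2.0]], index=["P"], columns=list("ab"))
        with pytest.raises(ValueError, match="shared samples"):
            pw.correlate_drug_pathway(e, e.rename(index={"P": "d"}))

    def test_planted_negative_link_recovered(self, small_gene_sets):
        rs = []
        for seed in range(10):
            truth = sim.make_expression_truth(
                small_gene_sets, n_samples=20,
                neg_pathways=["NEG_1"], pos_pathways=["POS_1"], seed=seed,
            )
            expr, resp = sim.simulate_expression(truth, small_gene_sets, seed=seed)
            es = pw.ssgsea_matrix(
                expr, {k: small_gene_sets[k] for k in ("NEG_1", "POS_1")}
            )
            r, _, _ = pw.correlate_drug_pathway(es, resp)
            rs.append(r.loc["NEG_1"].mean())
        assert np.mean(rs) < -0.5


class TestClustering:
    def test_sign_blocks_get_canonical_labels(self):
        r = pd.DataFrame(
            {
                "d1": [-0.9, 0.8, 0.05],
                "d2": [-0.8, 0.9, -0.1],
                "d3": [-0.85, 0.85, 0.1],
            },
            index=["neg", "pos", "mixed"],
        )
        order, labels = pw.cluster_pathways(r)
        assert labels["neg"] == "C1"
        assert labels["pos"] == "C2"
        assert labels["mixed"] == "C3"
        assert sorted(order) == sorted(r.index)

    def test_duplicated_rows_co_cluster(self):
        rows = [[-0.9, -0.8], [-0.9, -0.8], [0.9, 0.8], [0.0, 0.1]]
        r = pd.DataFrame(rows, index=["a", "a2", "b", "c"], columns=["d1", "d2"])
        _, labels = pw.cluster_pathways(r)
        assert labels["a"] == labels["a2"]

    def test_fewer_than_three_pathways_rejected(self):
        r = pd.DataFrame([[0.1, 0.2], [0.3, 0.4]], columns=["d1", "d2"])
        with pytest.raises(ValueError):
            pw.cluster_pathways(r)


class TestRegression:
    def test_exact_linear_relationship(self):
        es = pd.DataFrame(
            [[0.0, 1.0, 2.0, 3.0]], index=["P"], columns=list("abcd")
        )
        resp = pd.DataFrame(
            [[1.0, 3.0, 5.0, 7.0]], index=["drug"], columns=list("abcd")
        )
        rec = pw.regress_drug_on_target_pathways(es, resp, {"drug": "P"})
        row = rec.iloc[0]
        assert row["slope"] == pytest.approx(2.0)
        assert row["intercept"] == pytest.approx(1.0)
        assert row["r"] == pytest.approx(1.0)
        assert row["flags"] == "low_n"

    def test_null_pvalues_are_uniform(self, small_gene_sets):
        # independent response: p-values should be ~U(0,1)
        from scipy.stats import kstest

        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            x = pd.DataFrame(
                rng.normal(size=(1, 20)), index=["P"],
                columns=[f"s{i}" for i in range(20)],
            )
            y = pd.DataFrame(
                rng.normal(size=(1, 20)), index=["d"],
                columns=[f"s{i}" for i in range(20)],
            )
            rec = pw.regress_drug_on_target_pathways(x, y, {"d": "P"})
            pvals.append(rec["p"].iloc[0])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_missing_mapping_warns_and_skips(self):
        es = pd.DataFrame(
            [[0.0, 1.0, 2.0]], index=["P"], columns=list("abc")
        )
        resp = pd.DataFrame([[1.0, 2.0, 3.0]], index=["drug"], columns=list("abc"))
        with pytest.warns(UserWarning, match="skipped"):
            rec = pw.regress_drug_on_target_pathways(
                es, resp, {"drug": "P", "ghost": "P", "drug2": "missing"}
            )
        assert len(rec) == 1
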