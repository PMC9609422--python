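import math

import numpy as np
import networkx as nx
import pytest
from scipy.stats import kstest

from netpharm import GeneSet, SyntheticConfig, generate_annotations
from netpharm.enrichment import (
    AnnotationCollection,
    adjust_pvalues,
    associated_percent,
    hypergeometric_enrich,
    read_gmt,
    write_gmt,
)
from netpharm.graph_core import PPINetwork

from _oracles import hypergeom_tail_by_enumeration


def collection(terms, background=None):
    return AnnotationCollection.from_terms(
        {tid: (tid.lower(), members) for tid, members in terms.items()},
        background,
    )


def nodes_only_net(n):
    g = nx.Graph()
    g.add_nodes_from(f"G{i:04d}" for i in range(n))
    return PPINetwork(g)


class TestAssociatedPercent:
    def test_extremes_and_fraction(self):
        assert associated_percent(5, 5) == 100.0
        assert associated_percent(0, 7) == 0.0
        assert associated_percent(3, 42) == pytest.approx(100 * 3 / 42)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            associated_percent(1, 0)
        with pytest.raises(ValueError):
            associated_percent(6, 5)


class TestAdjust:
    def test_single_p_unchanged_under_all_methods(self):
        for method in ("holm", "bonferroni", "bh"):
            assert adjust_pvalues([0.04], method)[0] == pytest.approx(0.04)

    def test_holm_hand_example(self):
        # step-down: 0.01*3=0.03; 0.02*2=0.04; max(0.03*1, previous)=0.04
        got = adjust_pvalues([0.01, 0.02, 0.03], "holm")
        assert np.allclose(got, [0.03, 0.04, 0.04])

    def test_dominance_bonferroni_holm_raw(self, rng):
        p = rng.uniform(1e-6, 1, 50)
        holm = adjust_pvalues(p, "holm")
        bonf = adjust_pvalues(p, "bonferroni")
        bh = adjust_pvalues(p, "bh")
        assert np.all(bonf >= holm - 1e-15)
        assert np.all(holm >= p - 1e-15)
        assert np.all(bh >= p - 1e-15)
        assert np.all(bonf <= 1.0) and np.all(holm <= 1.0)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], method="hochberg-ish")


class TestHypergeom:
    def test_closed_form_full_overlap_tail(self):
        # query of 5 hitting all 5 members of a term in a 20-gene universe:
        # P[X >= 5] = 1/C(20,5)
        ann = collection(
            {"T1": frozenset(f"G{i}" for i in range(5))},
            background=[f"G{i}" for i in range(20)],
        )
        q = GeneSet.from_strings("q", [f"G{i}" for i in range(5)])
        row = hypergeometric_enrich(q, ann, min_overlap=1).iloc[0]
        assert row["p_raw"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)
        assert row["associated_percent"] == 100.0

    def test_degenerate_query_equals_background(self):
        members = frozenset(f"G{i}" for i in range(8))
        ann = collection({"T1": members}, background=members)
        row = hypergeometric_enrich(
            GeneSet.from_strings("q", members), ann, min_overlap=1
        ).iloc[0]
        assert row["p_raw"] == pytest.approx(1.0)
        assert row["k"] == row["K"] == row["n"] == row["N"] == 8

    @pytest.mark.parametrize("N,K,n", [(12, 4, 5), (14, 6, 6), (16, 5, 4)])
    def test_matches_exhaustive_enumeration(self, N, K, n):
        universe = [f"G{i}" for i in range(N)]
        ann = collection({"T1": frozenset(universe[:K])}, background=universe)
        for k in range(1, min(K, n) + 1):
            query = universe[:k] + universe[K:K + (n - k)]
            row = hypergeometric_enrich(
                GeneSet.from_strings("q", query), ann, min_overlap=1
            ).iloc[0]
            assert row["p_raw"] == pytest.approx(
                hypergeom_tail_by_enumeration(N, K, n, k), rel=1e-9
            )

    def test_p_raw_monotone_decreasing_in_overlap(self):
        universe = [f"G{i}" for i in range(100)]
        ann = collection({"T1": frozenset(universe[:20])}, background=universe)
        ps = []
        for k in range(1, 11):
            q = universe[:k] + universe[20:20 + (10 - k)]
            ps.append(
                hypergeometric_enrich(
                    GeneSet.from_strings("q", q), ann, min_overlap=1
                ).iloc[0]["p_raw"]
            )
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_min_overlap_filters_rows(self):
        universe = [f"G{i}" for i in range(30)]
        ann = collection(
            {"T1": frozenset(universe[:6]), "T2": frozenset(universe[10:20])},
            background=universe,
        )
        q = GeneSet.from_strings("q", universe[:2] + universe[10:16])
        out = hypergeometric_enrich(q, ann, min_overlap=3)
        assert out["term_id"].tolist() == ["T2"]

    def test_query_outside_background_dropped_and_counted(self):
        universe = [f"G{i}" for i in range(20)]
        ann = collection({"T1": frozenset(universe[:8])}, background=universe)
        q = GeneSet.from_strings("q", universe[:5] + ["ALIEN1", "ALIEN2"])
        out = hypergeometric_enrich(q, ann, min_overlap=1)
        assert out.attrs["n_query_dropped"] == 2
        assert out.iloc[0]["n"] == 5

    def test_sorted_by_adjusted_pvalue_and_invariants(self, rng):
        universe = [f"G{i}" for i in range(200)]
        terms = {
            f"T{j}": frozenset(
                universe[int(i)] for i in rng.choice(200, 30, replace=False)
            )
            for j in range(8)
        }
        ann = collection(terms, background=universe)
        q = GeneSet.from_strings(
            "q", [universe[int(i)] for i in rng.choice(200, 40, replace=False)]
        )
        out = hypergeometric_enrich(q, ann, min_overlap=1)
        assert out["p_adjusted"].is_monotonic_increasing
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-15).all()
        assert (out["k"] <= out[["K", "n"]].min(axis=1)).all()
        assert np.allclose(out["associated_percent"], 100 * out["k"] / out["K"])

    def test_empty_inputs_rejected(self):
        universe = [f"G{i}" for i in range(10)]
        ann = collection({"T1": frozenset(universe[:4])}, background=universe)
        with pytest.raises(ValueError):
            hypergeometric_enrich(GeneSet.from_strings("q", []), ann)
        with pytest.raises(ValueError):
            hypergeometric_enrich(GeneSet.from_strings("q", ["ALIEN"]), ann)


class TestGMT:
    def test_round_trip(self, tmp_path):
        ann = collection(
            {"T1": frozenset(["A", "B", "C"]), "T2": frozenset(["B", "D"])}
        )
        write_gmt(ann, tmp_path / "a.gmt")
        back = read_gmt(tmp_path / "a.gmt")
        assert back.terms == ann.terms
        assert back.background == ann.background

    def test_short_rows_rejected(self, tmp_path):
        (tmp_path / "bad.gmt").write_text("T1\tdesc-only\n")
        with pytest.raises(ValueError, match="GMT row"):
            read_gmt(tmp_path / "bad.gmt")

    def test_empty_terms_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            collection({"T1": frozenset()})


class TestCalibrationAndRecovery:
    def test_null_pvalues_are_not_anticonservative(self):
        """Uniform queries must give super-uniform (valid) raw p-values.

        The hypergeometric statistic is discrete, so its p-values are
        stochastically *larger* than uniform; the calibration check is the
        one-sided KS test against anti-conservatism.
        """
        rng = np.random.default_rng(77)
        universe = [f"G{i}" for i in range(600)]
        terms = {
            f"T{j}": frozenset(
                universe[int(i)]
                for i in rng.choice(600, int(rng.integers(40, 120)), replace=False)
            )
            for j in range(10)
        }
        ann = collection(terms, background=universe)
        ps = []
        for _ in range(120):
            q = [universe[int(i)] for i in rng.choice(600, 60, replace=False)]
            out = hypergeometric_enrich(
                GeneSet.from_strings("q", q), ann, min_overlap=1
            )
            ps.extend(out["p_raw"].tolist())
        stat = kstest(ps, "uniform", alternative="greater")
        assert stat.pvalue > 0.01

    def test_oversampled_term_ranks_first(self):
        cfg = SyntheticConfig(
            seed=123, n_terms=25, term_size_range=(30, 80), query_size=80,
            enriched_terms=[(0, 5.0)],
        )
        net = nodes_only_net(800)
        ann, query, truth = generate_annotations(net, cfg)
        out = hypergeometric_enrich(query, ann, min_overlap=1)
        assert out.iloc[0]["term_id"] == truth["enriched_terms"][0]["term_id"]
        assert out.iloc[0]["p_adjusted"] < 0.05
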