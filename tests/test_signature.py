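"""Biomarker cascade, per-strain response sets, Venn, response correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nitrosig import preprocess, rankprod, signature, simulate
from nitrosig.rankprod import RPResult


def _fake_rp(genes, p_up=None, p_down=None):
    n = len(genes)
    table = pd.DataFrame(
        {
            "rp_up": np.arange(1, n + 1, dtype=float),
            "rp_down": np.arange(n, 0, -1, dtype=float),
            "p_up": p_up if p_up is not None else np.ones(n),
            "p_down": p_down if p_down is not None else np.ones(n),
            "pfp_up": np.ones(n),
            "pfp_down": np.ones(n),
        },
        index=genes,
    )
    return RPResult(table=table, n_comparisons=2, n_permutations=100, seed=0)


class TestFoldChange:
    def test_large_up_fold_magnitude(self):
        mat = pd.DataFrame({"a1": [23.5], "a2": [23.5], "b1": [1.0], "b2": [1.0]})
        fold = signature.fold_change(mat, ["a1", "a2"], ["b1", "b2"])
        assert fold.iloc[0] == pytest.approx(23.5)

    def test_equal_means_fold_one(self):
        mat = pd.DataFrame({"a": [5.0], "b": [5.0]})
        assert signature.fold_change(mat, ["a"], ["b"]).iloc[0] == 1.0

    def test_down_fold_magnitude(self):
        mat = pd.DataFrame({"a": [1.0], "b": [6.4]})
        fold = signature.fold_change(mat, ["a"], ["b"])
        assert 1.0 / fold.iloc[0] == pytest.approx(6.4)

    def test_empty_group_rejected(self):
        mat = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValueError):
            signature.fold_change(mat, [], ["a"])


class TestConditionDESets:
    def test_identical_regime_columns_give_empty_sets(self, rng):
        vals = rng.normal(8, 1, (80, 2))
        cols = ["S_LN_12h_m1", "S_LN_12h_m2", "S_HN_12h_m1", "S_HN_12h_m2"]
        mat = pd.DataFrame(np.hstack([vals, vals]), columns=cols)
        design = pd.DataFrame(
            {
                "sample_id": cols,
                "strain": "S",
                "regime": ["LN", "LN", "HN", "HN"],
                "time_h": 12,
                "replicate": [1, 2, 1, 2],
            }
        )
        up, down = signature.condition_de_sets(mat, design, "S", 12, n_perm=200, seed=0)
        assert up == set() and down == set()

    def test_recovers_planted_ln_up_genes(self):
        hits = []
        for seed in range(10):
            local = np.random.default_rng(100 + seed)
            n = 400
            vals = local.normal(8, 0.25, (n, 4))
            vals[:30, :2] += np.log2(5.0)  # 5-fold up in LN
            cols = ["S_LN_24h_m1", "S_LN_24h_m2", "S_HN_24h_m1", "S_HN_24h_m2"]
            mat = pd.DataFrame(vals, columns=cols)
            design = pd.DataFrame(
                {
                    "sample_id": cols,
                    "strain": "S",
                    "regime": ["LN", "LN", "HN", "HN"],
                    "time_h": 24,
                    "replicate": [1, 2, 1, 2],
                }
            )
            up, _ = signature.condition_de_sets(mat, design, "S", 24, n_perm=300, seed=seed)
            hits.append(len(up & set(range(30))))
        assert np.mean(hits) >= 27

    def test_missing_regime_rejected(self, rng):
        cols = ["S_LN_12h_m1", "S_LN_12h_m2"]
        mat = pd.DataFrame(rng.normal(0, 1, (10, 2)), columns=cols)
        design = pd.DataFrame(
            {
                "sample_id": cols,
                "strain": "S",
                "regime": "LN",
                "time_h": 12,
                "replicate": [1, 2],
            }
        )
        with pytest.raises(ValueError, match="missing regime"):
            signature.condition_de_sets(mat, design, "S", 12)


class TestOverlapReport:
    def test_disjoint_and_identical_sets(self):
        rep = signature.overlap_report({"A": {"a"}, "B": {"b"}})
        assert rep.intersections[("A", "B")] == 0
        rep2 = signature.overlap_report({"A": {"x", "y"}, "B": {"x", "y"}, "C": {"x", "y"}})
        assert rep2.regions[("A", "B", "C")] == 2
        assert rep2.regions[("A",)] == 0

    def test_inclusion_exclusion_on_random_sets(self, rng):
        universe = [f"g{i}" for i in range(300)]
        for _ in range(10):
            sets = {
                name: set(rng.choice(universe, size=rng.integers(10, 150), replace=False))
                for name in ("A", "B", "C")
            }
            rep = signature.overlap_report(sets)
            assert rep.check_inclusion_exclusion()
            assert sum(rep.regions.values()) == len(sets["A"] | sets["B"] | sets["C"])

    def test_random_set_intersection_matches_hypergeometric_interval(self, rng):
        universe = np.arange(5000)
        a = set(rng.choice(universe, 240, replace=False))
        b = set(rng.choice(universe, 300, replace=False))
        k = len(a & b)
        lo, hi = stats.hypergeom.interval(0.99, 5000, 240, 300)
        assert lo <= k <= hi


class TestResponseCorrelationMatrix:
    def _make(self, rng, responses):
        genes = [f"g{i}" for i in range(len(next(iter(responses.values()))))]
        cols = {}
        for (strain, t), resp in responses.items():
            base = rng.normal(8, 1, len(genes))
            cols[f"{strain}_HN_{t:02d}h"] = base
            cols[f"{strain}_LN_{t:02d}h"] = base + resp
        avg = pd.DataFrame(cols, index=genes)
        design = pd.DataFrame(
            {
                "sample_id": [f"{s}_{r}_{t:02d}h_m1" for (s, t) in responses for r in ("LN", "HN")],
                "strain": [s for (s, t) in responses for _ in range(2)],
                "regime": ["LN", "HN"] * len(responses),
                "time_h": [t for (s, t) in responses for _ in range(2)],
                "replicate": 1,
            }
        )
        return avg, design

    def test_identical_and_negated_responses(self, rng):
        resp = rng.normal(0, 1, 50)
        avg, design = self._make(
            rng, {("A", 12): resp, ("B", 12): resp.copy(), ("C", 12): -resp}
        )
        M = signature.response_correlation_matrix(avg, design)
        assert M.loc["A_12h", "B_12h"] == pytest.approx(1.0)
        assert M.loc["A_12h", "C_12h"] == pytest.approx(-1.0)

    def test_matches_direct_genewise_formula(self, rng):
        responses = {
            (s, t): rng.normal(0, 1, 40) for s in "ABC" for t in (12, 24, 96)
        }
        avg, design = self._make(rng, responses)
        M = signature.response_correlation_matrix(avg, design)
        assert M.shape == (9, 9)
        r1 = responses[("A", 12)]
        r2 = responses[("B", 24)]
        ref = np.corrcoef(r1, r2)[0, 1]
        assert M.loc["A_12h", "B_24h"] == pytest.approx(ref, abs=1e-12)


class TestCascade:
    def test_threshold_logic_and_nesting(self):
        genes = ["car1_like", "mid", "weak", "hn_resp", "down1"]
        p_up = np.array([0.01, 0.01, 0.01, 0.01, 1.0])
        p_down = np.array([1.0, 1.0, 1.0, 1.0, 0.01])
        rp = _fake_rp(genes, p_up, p_down)
        folds = pd.Series([23.5, 3.5, 2.0, 10.0, 1 / 6.4], index=genes)
        panel = signature.nitrogen_signature(
            rp, hn_responders={"hn_resp"}, ln_induced=set(genes), folds=folds
        )
        assert "car1_like" in panel.final_up
        assert "mid" in panel.candidate_up and "mid" not in panel.final_up
        assert "weak" not in panel.candidate_up
        assert "hn_resp" not in panel.candidate_up
        assert panel.final_up <= panel.candidate_up <= panel.rp_up
        assert panel.final_down == panel.candidate_down == {"down1"}
        table = panel.fold_table()
        assert table.loc[table["gene_id"] == "down1", "fold"].iloc[0] == pytest.approx(6.4)

    def test_raising_thresholds_never_grows_panels(self):
        genes = [f"g{i}" for i in range(20)]
        rp = _fake_rp(genes, p_up=np.full(20, 0.01))
        folds = pd.Series(np.linspace(1.5, 30, 20), index=genes)
        sizes = []
        for cand in (2.0, 3.0, 5.0, 8.0):
            panel = signature.nitrogen_signature(
                rp, set(), set(genes), folds, thresholds=(cand, cand + 1)
            )
            sizes.append((len(panel.candidate_up), len(panel.final_up)))
        assert sorted(sizes, reverse=True) == sizes

    def test_cascade_excludes_all_planted_hn_responders(self):
        matrix, design, roles = simulate.simulate_signature_scenario(
            n_genes=800, n_true=25, n_decoy=25, seed=13
        )
        linear, log2 = preprocess.run(matrix)
        panel = signature.nitrogen_signature_pipeline(
            linear, log2, design, n_perm=200, seed=13
        )
        decoys = set(roles.index[roles["role"] == "decoy"])
        assert panel.candidate_up.isdisjoint(decoys)
        assert panel.final_up <= panel.candidate_up <= panel.rp_up
        true = set(roles.index[roles["role"] == "true"])
        assert len(panel.final_up & true) / len(true) >= 0.85

    def test_invalid_thresholds_rejected(self):
        rp = _fake_rp(["a"])
        with pytest.raises(ValueError):
            signature.nitrogen_signature(rp, set(), set(), pd.Series([1.0], index=["a"]), thresholds=(4, 3))
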