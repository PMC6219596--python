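"""Library construction, hypergeometric screening and FDR adjustment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plastox import (
    ChemicalGeneTable,
    DirectionalSignature,
    GeneSetLibrary,
    Universe,
    build_composite_library,
    build_universe,
    composite_screen,
    fdr_adjust,
    fisher_overlap,
    fisher_overlap_counts,
    hypergeom_overlap,
    library_enrichment,
    reversal_screen,
    split_library,
)
from plastox.synthetic import SimConfig, gen_chem_table


def chem_table(rows):
    return ChemicalGeneTable(records=pd.DataFrame(rows, columns=["chemical", "gene", "direction"]))


def enumeration_tail(n, a, b, k):
    """Brute-force P(overlap >= k): enumerate every size-b draw from n."""
    hits = total = 0
    targets = set(range(a))
    for draw in itertools.combinations(range(n), b):
        total += 1
        hits += len(targets & set(draw)) >= k
    return hits / total


class TestHypergeomOverlap:
    def test_small_case_matches_enumeration(self):
        u = Universe(frozenset(f"g{i}" for i in range(10)))
        res = hypergeom_overlap([f"g{i}" for i in range(5)],
                                ["g0", "g1", "g2", "g3"], u)
        assert res.k == 4
        assert res.p == pytest.approx(5 / 210)
        assert res.p == pytest.approx(enumeration_tail(10, 5, 4, 4))

    def test_zero_overlap_p_is_one(self):
        u = Universe(frozenset(f"g{i}" for i in range(10)))
        res = hypergeom_overlap(["g0", "g1"], ["g5", "g6"], u)
        assert res.k == 0 and res.p == 1.0

    def test_forced_full_overlap_p_is_one(self):
        u = Universe(frozenset("abcd"))
        res = hypergeom_overlap("abcd", "abcd", u)
        assert res.k == 4 and res.p == pytest.approx(1.0)

    def test_genes_outside_universe_dropped(self):
        u = Universe(frozenset("abc"))
        res = hypergeom_overlap(["a", "b", "zzz"], ["b", "c", "yyy"], u)
        assert res.size_a == 2 and res.size_b == 2 and res.k == 1

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        relabel = dict(zip(genes, rng.permutation(genes)))
        a = genes[:12]
        b = genes[8:25]
        u = Universe(frozenset(genes))
        p1 = hypergeom_overlap(a, b, u).p
        p2 = hypergeom_overlap([relabel[g] for g in a], [relabel[g] for g in b],
                               Universe(frozenset(relabel.values()))).p
        assert p1 == pytest.approx(p2)

    def test_empty_after_restriction_errors(self):
        u = Universe(frozenset("abc"))
        with pytest.raises(ValueError, match="empty"):
            hypergeom_overlap(["zzz"], ["a"], u)


class TestUniverse:
    def test_intersection(self):
        table = chem_table([("c1", "b", "increased"), ("c1", "c", "decreased"),
                            ("c2", "d", "increased")])
        assert build_universe({"a", "b", "c"}, table).genes == {"b", "c"}

    def test_disjoint_errors(self):
        table = chem_table([("c1", "x", "increased")])
        with pytest.raises(ValueError, match="disjoint"):
            build_universe({"a"}, table)

    def test_identity(self):
        table = chem_table([("c1", "a", "increased"), ("c1", "b", "decreased")])
        assert build_universe({"a", "b"}, table).genes == {"a", "b"}


class TestLibraryConstruction:
    def test_composite_is_union(self):
        table = chem_table([("c", "g1", "increased"), ("c", "g2", "increased"),
                            ("c", "g2", "decreased"), ("c", "g3", "decreased")])
        lib = build_composite_library(table)
        assert lib.sets["c"] == {"g1", "g2", "g3"}

    def test_size_filter_bounds(self):
        rows = [("small", "g1", "increased"), ("small", "g2", "decreased")]
        rows += [("big", f"g{i}", "increased") for i in range(2501)]
        rows += [("ok", f"g{i}", "increased") for i in range(10)]
        lib = build_composite_library(chem_table(rows))
        assert set(lib.sets) == {"ok"}

    def test_neurotoxicant_filter_case_insensitive(self):
        rows = [("Lead", f"g{i}", "increased") for i in range(5)]
        rows += [("other", f"g{i}", "increased") for i in range(5)]
        lib = build_composite_library(chem_table(rows), neurotoxicant_filter=["lead"])
        assert set(lib.sets) == {"Lead"}

    def test_split_drops_chemical_undersized_on_both_sides(self):
        # composite size 4 passes, but 2 up + 2 down both miss min=3
        rows = [("c", "g1", "increased"), ("c", "g2", "increased"),
                ("c", "g3", "decreased"), ("c", "g4", "decreased")]
        up, down = split_library(chem_table(rows), ["c"])
        assert "c" not in up and "c" not in down

    def test_split_one_sided_survival(self):
        rows = [("c", f"g{i}", "increased") for i in range(5)]
        up, down = split_library(chem_table(rows), ["c"])
        assert "c" in up and "c" not in down

    def test_split_counts_drop(self):
        # 28 chemicals in; 3 have undersized down-sets -> 25 down sets remain
        rows = []
        for i in range(28):
            rows += [(f"c{i}", f"u{i}_{j}", "increased") for j in range(5)]
            n_down = 2 if i < 3 else 5
            rows += [(f"c{i}", f"d{i}_{j}", "decreased") for j in range(n_down)]
        up, down = split_library(chem_table(rows), [f"c{i}" for i in range(28)])
        assert len(up) == 28 and len(down) == 25

    def test_direction_vocabulary_enforced(self):
        with pytest.raises(ValueError, match="direction"):
            chem_table([("c", "g", "upregulated")])

    def test_library_size_invariant(self):
        with pytest.raises(ValueError, match="outside"):
            GeneSetLibrary(sets={"tiny": {"g1"}}, min_size=3, max_size=10)


class TestFisher:
    def test_printed_marginals_reproduce_odds_ratio(self):
        res = fisher_overlap_counts(k=185, size_a=1125, size_b=1485, n=11_582)
        assert res.odds_ratio == pytest.approx((185 * 9157) / (940 * 1300))
        assert round(res.odds_ratio, 1) == 1.4
        assert res.p < 0.001

    def test_independent_sets_or_near_one(self):
        rng = np.random.default_rng(2)
        genes = np.array([f"g{i}" for i in range(2000)])
        u = Universe(frozenset(genes))
        ors = []
        for _ in range(300):
            a = genes[rng.choice(2000, 200, replace=False)]
            b = genes[rng.choice(2000, 200, replace=False)]
            ors.append(fisher_overlap(a, b, u).odds_ratio)
        assert np.mean(ors) == pytest.approx(1.0, abs=0.1)

    def test_complete_overlap_flagged_infinite(self):
        u = Universe(frozenset(f"g{i}" for i in range(20)))
        res = fisher_overlap([f"g{i}" for i in range(5)], [f"g{i}" for i in range(5)], u)
        assert math.isinf(res.odds_ratio)


class TestFdrAdjust:
    def test_bh_step_up_hand_computed(self):
        assert fdr_adjust([0.01, 0.02, 0.03], "BH") == pytest.approx([0.03, 0.03, 0.03])

    def test_holm_step_down_hand_computed(self):
        assert fdr_adjust([0.001, 0.02, 0.04], "holm") == pytest.approx([0.003, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_stay_equal(self):
        out = fdr_adjust([0.04] * 5)
        assert np.allclose(out, out[0])

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [np.nan]])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            fdr_adjust(bad)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_bh_dominates_raw_and_preserves_order(self, ps):
        adj = fdr_adjust(ps, "BH")
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestReversalScreen:
    def test_planted_reverser_ranks_first(self):
        cfg = SimConfig(seed=5, planted_reversers=(("plumbum", 0.5),))
        table, cp, genes, _ = gen_chem_table(cfg)
        universe = build_universe(genes, table)
        composite = build_composite_library(table)
        up, down = split_library(table, list(composite.sets))
        res = reversal_screen(up, down, cp, universe)
        top = res.iloc[0]
        assert top["set_a"] == "plumbum"
        assert top["p_adj"] < 0.05
        assert top["p"] < 1e-20

    def test_global_null_controls_fdr(self):
        sig = 0
        n_rep = 20
        for seed in range(n_rep):
            cfg = SimConfig(seed=seed, n_chemicals=50)
            table, cp, genes, _ = gen_chem_table(cfg)
            universe = build_universe(genes, table)
            composite = build_composite_library(table)
            up, down = split_library(table, list(composite.sets))
            res = reversal_screen(up, down, cp, universe)
            sig += int(res["significant"].sum() > 0)
        # few if any replicates show a false discovery
        assert sig / n_rep <= 0.1

    def test_empty_up_signature_runs_one_family(self):
        rows = [("c", f"g{i}", "increased") for i in range(5)]
        rows += [("c", f"g{i}", "decreased") for i in range(5, 10)]
        table = chem_table(rows)
        u = Universe(frozenset(f"g{i}" for i in range(20)))
        cp = DirectionalSignature(name="CP", up=frozenset(),
                                  down=frozenset({"g1", "g2", "g3"}))
        up, down = split_library(table, ["c"])
        res = reversal_screen(up, down, cp, u)
        assert len(res) == 1
        assert res.iloc[0]["set_b"] == "CP_down"

    def test_tie_break_alphabetical(self):
        rows = []
        for name in ("zeta", "alpha"):
            rows += [(name, f"g{i}", "decreased") for i in range(3)]
        table = chem_table(rows)
        u = Universe(frozenset(f"g{i}" for i in range(30)))
        cp = DirectionalSignature(name="CP", up=frozenset({"g0", "g1", "g2"}),
                                  down=frozenset())
        up, down = split_library(table, ["zeta", "alpha"])
        res = reversal_screen(up, down, cp, u)
        assert res["set_a"].tolist() == ["alpha", "zeta"]

    def test_screen_p_uniform_under_null(self):
        # the screen's hypergeometric p is discrete, hence super-uniform;
        # its randomized counterpart P(X > k) + U * P(X = k) is exactly
        # uniform under the null, which pins the screen's counts and sizes
        from scipy.stats import hypergeom, kstest
        rng = np.random.default_rng(55)
        ps = []
        for seed in range(10):
            cfg = SimConfig(seed=100 + seed, n_chemicals=50)
            table, cp, genes, _ = gen_chem_table(cfg)
            universe = build_universe(genes, table)
            composite = build_composite_library(table)
            up, down = split_library(table, list(composite.sets))
            res = reversal_screen(up, down, cp, universe)
            tail_above = hypergeom.sf(res["k"], res["N"], res["size_a"], res["size_b"])
            atom = hypergeom.pmf(res["k"], res["N"], res["size_a"], res["size_b"])
            # the reported upper tail is P(X >= k) = tail_above + atom
            assert np.allclose(res["p"], tail_above + atom, atol=1e-12)
            ps.extend(tail_above + rng.uniform(size=len(res)) * atom)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestCompositeAndLibraryEnrichment:
    def test_self_enrichment_dominates(self):
        genes = [f"g{i}" for i in range(200)]
        u = Universe(frozenset(genes))
        shared = frozenset(genes[:20])
        lib = GeneSetLibrary(sets={"self": shared,
                                   "other": frozenset(genes[100:150])})
        res = library_enrichment(shared, lib, u)
        assert res.iloc[0]["set_a"] == "self"

    def test_disjoint_shared_genes_all_p_one(self):
        genes = [f"g{i}" for i in range(100)]
        u = Universe(frozenset(genes))
        lib = GeneSetLibrary(sets={"a": frozenset(genes[:10]),
                                   "b": frozenset(genes[10:20])})
        res = library_enrichment(genes[50:60], lib, u)
        assert (res["p"] == 1.0).all()

    def test_planted_enrichment_detected(self):
        genes = [f"g{i}" for i in range(10_000)]
        u = Universe(frozenset(genes))
        target = frozenset(genes[:200])
        shared = frozenset(genes[:20]) | frozenset(genes[5000:5020])  # 20 of 40 inside
        lib = GeneSetLibrary(sets={"target": target,
                                   "decoy": frozenset(genes[8000:8200])})
        res = library_enrichment(shared, lib, u)
        row = res[res["set_a"] == "target"].iloc[0]
        assert row["p_adj"] < 0.05 and row["k"] == 20

    def test_composite_screen_restriction_never_increases_overlap(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(300)]
        a = set(rng.choice(genes, 50, replace=False))
        b = set(rng.choice(genes, 60, replace=False))
        full_u = Universe(frozenset(genes))
        small_u = Universe(frozenset(genes[:150]))
        k_full = hypergeom_overlap(a, b, full_u).k
        restricted = (a & small_u.genes, b & small_u.genes)
        if restricted[0] and restricted[1]:
            k_small = hypergeom_overlap(*restricted, small_u).k
            assert k_small <= k_full

    def test_composite_screen_runs(self):
        cfg = SimConfig(seed=1, n_chemicals=20)
        table, cp, genes, _ = gen_chem_table(cfg)
        universe = build_universe(genes, table)
        lib = build_composite_library(table)
        res = composite_screen(lib, cp.all_genes, universe, "CP")
        assert len(res) == len(lib.sets)
        assert (res["p_adj"] >= res["p"] - 1e-12).all()
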