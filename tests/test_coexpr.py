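"""Soft threshold, TOM, module detection, eigengenes, module-trait, hubs."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from thermolnc import coexpr
from thermolnc.coexpr import (CoexprModule, adjacency, detect_modules,
                              eigengene, hubs_and_trans_targets, module_trait,
                              pick_beta, tom_similarity)
from thermolnc.types import TraitVector, make_design, sample_name

from conftest import make_matrix, stage_profile_matrix


def _block_matrix(block_sizes, n_noise=0, seed=0, n_samples=15):
    """Expression with perfectly correlated blocks plus independent noise."""
    rng = np.random.default_rng(seed)
    rows = {}
    truth = {}
    for b_idx, size in enumerate(block_sizes):
        base = rng.uniform(1, 10, n_samples)
        for j in range(size):
            tid = f"b{b_idx}_{j}"
            rows[tid] = list(base * rng.uniform(0.5, 2.0))
            truth[tid] = b_idx
    for j in range(n_noise):
        rows[f"n{j}"] = list(rng.uniform(1, 10, n_samples))
    return make_matrix(rows), truth


class TestAdjacency:
    def test_beta_one_on_perfect_correlation_is_one(self):
        cor = np.ones((3, 3))
        a = adjacency(cor, 1, "unsigned")
        off = a[~np.eye(3, dtype=bool)]
        assert off == pytest.approx(np.ones(6))

    def test_increasing_beta_weakly_decreases_adjacency(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 15))
        cor = np.corrcoef(x)
        prev = adjacency(cor, 1, "unsigned")
        for beta in range(2, 12):
            cur = adjacency(cor, beta, "unsigned")
            mask = ~np.eye(8, dtype=bool)
            assert np.all(cur[mask] <= prev[mask] + 1e-12)
            prev = cur

    def test_signed_adjacency_separates_anticorrelated_profiles(self):
        x = np.vstack([np.linspace(1, 15, 15), -np.linspace(1, 15, 15)])
        cor = np.corrcoef(x)
        a_signed = adjacency(cor, 6, "signed")
        a_unsigned = adjacency(cor, 6, "unsigned")
        assert a_signed[0, 1] == pytest.approx(0.0)
        assert a_unsigned[0, 1] == pytest.approx(1.0)


class TestTom:
    def test_three_node_worked_example(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        tom = tom_similarity(a)
        # omega_12 = (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert tom[0, 1] == pytest.approx(0.5)
        assert np.diag(tom) == pytest.approx(np.ones(3))

    def test_zero_adjacency_gives_identity(self):
        tom = tom_similarity(np.zeros((4, 4)))
        assert tom == pytest.approx(np.eye(4))

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            n = 20
            m = rng.uniform(0, 1, (n, n))
            a = (m + m.T) / 2.0
            np.fill_diagonal(a, 0.0)
            tom = tom_similarity(a)
            k = a.sum(axis=1)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    l_ij = sum(a[i, u] * a[u, j] for u in range(n)
                               if u not in (i, j))
                    expect = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                    assert tom[i, j] == pytest.approx(expect, abs=1e-12)

    def test_asymmetric_input_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)


class TestDetectModules:
    def _tom_for(self, expr):
        cor, ids = coexpr.correlation_matrix(expr)
        return tom_similarity(adjacency(cor, 6, "signed")), ids

    def test_two_perfect_blocks_recovered(self):
        # two internally perfectly correlated blocks with opposite profiles
        rng = np.random.default_rng(0)
        base0 = np.array([8.0, 9, 10, 9, 8, 1, 1, 2, 1, 1, 8, 9, 10, 9, 8])
        base1 = base0.max() + base0.min() - base0  # anti-phased
        rows, truth = {}, {}
        for b_idx, base in enumerate((base0, base1)):
            for j in range(15):
                tid = f"b{b_idx}_{j}"
                rows[tid] = list(base * rng.uniform(0.5, 2.0))
                truth[tid] = b_idx
        expr = make_matrix(rows)
        tom, ids = self._tom_for(expr)
        assign = detect_modules(tom, ids, min_size=10)
        labels = {}
        for tid, color in assign.items():
            labels.setdefault(color, set()).add(tid)
        non_grey = {c: m for c, m in labels.items() if c != "grey"}
        assert len(non_grey) == 2
        blocks = [{t for t, b in truth.items() if b == i} for i in (0, 1)]
        assert sorted(map(frozenset, non_grey.values())) == \
               sorted(map(frozenset, blocks))

    def test_independent_noise_is_mostly_grey(self):
        import warnings
        rng = np.random.default_rng(21)
        rows = {f"n{j}": list(rng.uniform(1, 10, 15)) for j in range(200)}
        expr = make_matrix(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            st = coexpr.pick_beta(expr)  # default soft-threshold selection
        cor, ids = coexpr.correlation_matrix(expr)
        tom = tom_similarity(adjacency(cor, st.beta, "signed"))
        assign = detect_modules(tom, ids)
        grey_frac = sum(1 for c in assign.values() if c == "grey") / len(assign)
        assert grey_frac >= 0.95

    def test_min_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            detect_modules(np.eye(3), ["a", "b", "c"], min_size=1)

    def test_membership_invariant_to_input_order(self):
        expr, _ = _block_matrix([12, 14], n_noise=10)
        tom, ids = self._tom_for(expr)
        assign1 = detect_modules(tom, ids)
        perm = np.random.default_rng(3).permutation(len(ids))
        tom2 = tom[np.ix_(perm, perm)]
        ids2 = [ids[i] for i in perm]
        assign2 = detect_modules(tom2, ids2)
        assert assign1 == assign2

    def test_colors_follow_canonical_sequence_by_size(self):
        rng = np.random.default_rng(1)
        base0 = np.array([8.0, 9, 10, 9, 8, 1, 1, 2, 1, 1, 8, 9, 10, 9, 8])
        base1 = base0.max() + base0.min() - base0
        rows = {}
        for b_idx, (base, size) in enumerate(((base0, 20), (base1, 12))):
            for j in range(size):
                rows[f"b{b_idx}_{j}"] = list(base * rng.uniform(0.5, 2.0))
        expr = make_matrix(rows)
        tom, ids = self._tom_for(expr)
        assign = detect_modules(tom, ids, min_size=10)
        sizes = {}
        for color in assign.values():
            sizes[color] = sizes.get(color, 0) + 1
        sizes.pop("grey", None)
        assert len(sizes) == 2
        ordered = sorted(sizes, key=lambda c: -sizes[c])
        assert ordered == list(coexpr.COLOR_SEQUENCE[:len(ordered)])


class TestEigengene:
    def test_identical_profiles_give_shared_standardized_profile(self):
        base = np.linspace(1, 15, 15)
        expr = make_matrix({f"t{i}": list(base) for i in range(5)})
        eg = eigengene(expr, [f"t{i}" for i in range(5)])
        logged = np.log2(base + 1)
        expect = (logged - logged.mean()) / logged.std(ddof=1)
        assert eg == pytest.approx(expect)

    def test_unit_variance(self):
        expr, _ = _block_matrix([10])
        eg = eigengene(expr, [f"b0_{j}" for j in range(10)])
        assert np.var(eg, ddof=1) == pytest.approx(1.0)

    def test_flipping_all_member_profiles_flips_the_eigengene(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(1, 10, 15)
        rows = {f"t{i}": list(base * rng.uniform(0.5, 2)) for i in range(6)}
        expr = make_matrix(rows)
        eg = eigengene(expr, sorted(rows))
        # mirror each profile in the log2(x+1) working space: the member
        # z-profiles flip sign exactly, so the eigengene must flip too
        flipped = make_matrix(
            {t: list(2.0 ** (10.0 - np.log2(np.array(v) + 1)) - 1.0)
             for t, v in rows.items()})
        eg_f = eigengene(flipped, sorted(rows))
        assert eg_f == pytest.approx(-eg, abs=1e-8)

    def test_pc1_explains_at_least_as_much_as_pc2(self):
        expr, _ = _block_matrix([12], seed=4)
        mat, kept = coexpr._standardized(expr, [f"b0_{j}" for j in range(12)])
        u, s, vt = np.linalg.svd(mat.T, full_matrices=False)
        assert s[0] >= s[1]

    def test_single_member_module_returns_standardized_profile(self):
        base = np.linspace(2, 30, 15)
        expr = make_matrix({"t1": list(base), "t2": list(base[::-1])})
        eg = eigengene(expr, ["t1"])
        logged = np.log2(base + 1)
        expect = (logged - logged.mean()) / logged.std(ddof=1)
        assert eg == pytest.approx(expect)


class TestModuleTrait:
    def _design(self):
        return make_design(5, 3)

    def _samples(self):
        return [sample_name(s, r) for s in range(1, 6) for r in range(1, 4)]

    def test_trait_equal_to_eigengene_has_correlation_one(self):
        eg = np.tile(np.array([1.0, 2.0, 5.0, 2.0, 1.0]), (3, 1)).T.ravel()
        mod = CoexprModule("turquoise", ("t1",), eigengene=eg)
        trait = TraitVector(values=np.array([1.0, 2.0, 5.0, 2.0, 1.0]), stages=5)
        module_trait([mod], trait, self._design(), self._samples())
        assert mod.trait_cor == pytest.approx(1.0)
        assert mod.trait_p < 1e-10

    def test_orthogonal_trait_has_near_zero_correlation(self):
        eg = np.tile(np.array([1.0, -1.0, 1.0, -1.0, 0.0]), (3, 1)).T.ravel()
        mod = CoexprModule("turquoise", ("t1",), eigengene=eg)
        trait = TraitVector(values=np.array([1.0, 1.0, -1.0, -1.0, 0.0]),
                            stages=5)
        module_trait([mod], trait, self._design(), self._samples())
        assert abs(mod.trait_cor) < 1e-10
        assert mod.trait_p > 0.99

    def test_constant_trait_rejected(self):
        eg = np.arange(15, dtype=float)
        mod = CoexprModule("turquoise", ("t1",), eigengene=eg)
        trait = TraitVector(values=np.full(5, 3.0), stages=5)
        with pytest.raises(ValueError, match="constant"):
            module_trait([mod], trait, self._design(), self._samples())


class TestHubsAndTransTargets:
    def test_member_tracking_eigengene_is_a_hub(self):
        expr, _ = _block_matrix([8])
        members = tuple(sorted(f"b0_{j}" for j in range(8)))
        mod = CoexprModule("turquoise", members,
                           eigengene=eigengene(expr, members))
        hubs, _ = hubs_and_trans_targets(
            expr, mod, {m: "mRNA" for m in members})
        assert hubs, "perfectly correlated block must yield hubs"
        assert hubs[0][1] == pytest.approx(1.0, abs=1e-6)

    def test_module_without_lncrnas_has_no_trans_pairs(self):
        expr, _ = _block_matrix([8])
        members = tuple(sorted(f"b0_{j}" for j in range(8)))
        mod = CoexprModule("turquoise", members,
                           eigengene=eigengene(expr, members))
        _, pairs = hubs_and_trans_targets(
            expr, mod, {m: "mRNA" for m in members})
        assert pairs == []

    def test_lncrna_and_mrna_hubs_form_trans_pairs(self):
        expr, _ = _block_matrix([8])
        members = tuple(sorted(f"b0_{j}" for j in range(8)))
        biotype = {m: ("lncRNA" if i < 2 else "mRNA")
                   for i, m in enumerate(members)}
        mod = CoexprModule("turquoise", members,
                           eigengene=eigengene(expr, members))
        _, pairs = hubs_and_trans_targets(expr, mod, biotype)
        assert len(pairs) == 2 * 6
        assert all(biotype[l] == "lncRNA" and biotype[m] == "mRNA"
                   for l, m in pairs)


class TestPickBetaAndRecovery:
    def test_too_few_transcripts_rejected(self):
        expr = make_matrix({"t1": list(range(15)), "t2": list(range(15))})
        with pytest.raises(ValueError):
            pick_beta(expr)

    def test_planted_modules_recovered_with_correct_trait_signs(self, synth_default):
        import warnings
        truth = synth_default["truth"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wg = coexpr.run_wgcna(synth_default["fpkm"],
                                  trait=synth_default["trait"],
                                  biotype=truth.biotype_by_transcript)
        planted = truth.module_membership
        in_both = [t for t in planted if t in wg["assignment"]]
        ari = adjusted_rand_score([planted[t] for t in in_both],
                                  [wg["assignment"][t] for t in in_both])
        assert ari >= 0.8
        # trait-correlation signs of the planted +trait / -trait modules
        color_of = {}
        for t, mid in planted.items():
            color = wg["assignment"].get(t)
            if color and color != "grey":
                color_of.setdefault(mid, {}).setdefault(color, 0)
                color_of[mid][color] += 1
        trait_cor = {m.module_id: m.trait_cor for m in wg["modules"]}
        for mid, sign in truth.module_trait_sign.items():
            if sign == 0:
                continue
            dominant = max(color_of[mid], key=color_of[mid].get)
            assert np.sign(trait_cor[dominant]) == sign
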