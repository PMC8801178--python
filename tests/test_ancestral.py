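"""Translation, gap filtering, parsimony and ML reconstruction."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from chloroconv.ancestral import (
    CodonModelM0,
    TreeIndex,
    f3x4_frequencies,
    filter_gap_sites,
    fit_model,
    fitch_asr,
    fitch_min_changes,
    generic_log_likelihood,
    generic_marginal_posteriors,
    log_likelihood,
    marginal_asr,
    translate_codons,
)
from chloroconv.genetics import N_SENSE, SENSE_CODONS, SENSE_INDEX
from chloroconv.io_phylo import (
    AlignmentError,
    MultipleSequenceAlignment,
    TraitLabeledTree,
    _Node,
    parse_newick,
)
from chloroconv.simulate import SimulationConfig, random_labeled_tree, simulate_dataset

from conftest import random_binary_tree


def msa(records, molecule="protein", gene="g"):
    return MultipleSequenceAlignment(gene, tuple(records), molecule)


# ---------------------------------------------------------------------------
# translation / filtering


class TestTranslation:
    def test_standard_translation(self):
        out = translate_codons(msa([("a", "ATGGCT"), ("b", "ATGGCA")], "codon"))
        assert out.sequence("a") == "MA"

    def test_gap_codon_rule(self):
        out = translate_codons(msa([("a", "---GCT"), ("b", "ATGGCA")], "codon"))
        assert out.sequence("a") == "-A"

    def test_internal_stop_is_error(self):
        with pytest.raises(AlignmentError, match="stop"):
            translate_codons(msa([("a", "TAAGCT"), ("b", "ATGGCA")], "codon"))

    def test_partial_gap_codon_is_error(self):
        with pytest.raises(AlignmentError, match="gapped"):
            translate_codons(msa([("a", "A--GCT"), ("b", "ATGGCA")], "codon"))


class TestFilterGapSites:
    def test_ingroup_gap_dropped_outgroup_gap_kept(self):
        m = msa([("i1", "AV-K"), ("i2", "AVLK"), ("out", "A-LK")])
        filtered, smap = filter_gap_sites(m, ["i1", "i2"])
        assert filtered.sequence("i1") == "AVK"
        assert smap.columns == (0, 1, 3)

    def test_all_species_flag(self):
        m = msa([("i1", "AVLK"), ("out", "A-LK")])
        filtered, _ = filter_gap_sites(m, ["i1"], all_species=True)
        assert filtered.length == 3

    def test_gap_free_identity_sitemap(self):
        m = msa([("i1", "AVLK"), ("i2", "AVLK")])
        filtered, smap = filter_gap_sites(m, ["i1", "i2"], ref_species="i1")
        assert filtered.length == 4
        assert smap.columns == (0, 1, 2, 3)
        assert [smap.label(i) for i in range(4)] == [1, 2, 3, 4]

    def test_reference_coordinates_skip_reference_gaps(self):
        # reference has a gap at column 2: later sites shift, gap column
        # falls back to a column label
        m = msa([("ref", "A-LK"), ("i2", "AVLK"), ("i3", "AVLK")])
        filtered, smap = filter_gap_sites(m, ["i2", "i3"], ref_species="ref")
        assert [smap.label(i) for i in range(len(smap))] == [1, "col:2", 2, 3]


# ---------------------------------------------------------------------------
# Fitch parsimony


class TestFitch:
    def test_invariant_column_unambiguous(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        anc = fitch_asr(msa([(s, "K") for s in "abcd"]), t)
        for nid in t.node_ids:
            assert anc.best[nid][0] == "K"
            assert not anc.ambiguous[nid][0]

    def test_textbook_root_ambiguity(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        anc = fitch_asr(msa([("a", "V"), ("b", "V"), ("c", "I"), ("d", "I")]), t)
        assert anc.ambiguous[t.root_id][0]
        # alphabetical tie-break among the optimal states {I, V}
        assert anc.best[t.root_id][0] == "I"

    def test_tips_reproduce_observed(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        m = msa([("a", "VKL"), ("b", "VRL"), ("c", "IK-"), ("d", "IKL")])
        anc = fitch_asr(m, t)
        for name, seq in m.records:
            assert anc.states(name) == seq

    def test_min_changes_match_brute_force(self, rng):
        """Bottom-up counts equal exhaustive internal labelings (8 tips)."""
        names = [f"t{i}" for i in range(8)]
        for _ in range(5):
            tree = parse_newick(random_binary_tree(names, rng))
            tidx = TreeIndex(tree)
            n_sites = 20
            alphabet = list("ACD")
            seqs = {
                n: "".join(rng.choice(alphabet, size=n_sites)) for n in names
            }
            m = msa(sorted(seqs.items()))
            mine = fitch_min_changes(m, tree)
            internals = [v for v in range(tidx.n_nodes) if not tidx.is_tip[v]]
            for s in range(n_sites):
                best = None
                for assign in itertools.product(alphabet, repeat=len(internals)):
                    state = dict(zip(internals, assign))
                    for v in range(tidx.n_nodes):
                        if tidx.is_tip[v]:
                            state[v] = seqs[tidx.ids[v]][s]
                    changes = sum(
                        state[v] != state[tidx.parent[v]]
                        for v in range(tidx.n_nodes) if v != tidx.root
                    )
                    best = changes if best is None else min(best, changes)
                assert mine[s] == best


# ---------------------------------------------------------------------------
# generic pruning machinery (2-state fixtures with brute-force oracles)


def two_state_setup(newick, tip_states, pi=(0.3, 0.7), rate=1.0):
    tree = parse_newick(newick)
    tidx = TreeIndex(tree)
    pi = np.asarray(pi)
    Q = rate * np.array([[-pi[1], pi[1]], [pi[0], -pi[0]]])
    P = np.zeros((tidx.n_nodes, 2, 2))
    for v in range(tidx.n_nodes):
        t = tidx.lengths[v]
        P[v] = expm(Q * (0.0 if np.isnan(t) else t))
    tips = np.zeros((tidx.n_nodes, 1, 2))
    for v in range(tidx.n_nodes):
        if tidx.is_tip[v]:
            tips[v, 0, tip_states[tidx.ids[v]]] = 1.0
    return tree, tidx, P, tips, pi


def brute_force_likelihood(tidx, P, tip_states, pi):
    internals = [v for v in range(tidx.n_nodes) if not tidx.is_tip[v]]
    total = 0.0
    for assign in itertools.product(range(2), repeat=len(internals)):
        state = dict(zip(internals, assign))
        for v in range(tidx.n_nodes):
            if tidx.is_tip[v]:
                state[v] = tip_states[tidx.ids[v]]
        pr = pi[state[tidx.root]]
        for v in range(tidx.n_nodes):
            if v != tidx.root:
                pr *= P[v][state[tidx.parent[v]], state[v]]
        total += pr
    return total


class TestPruning:
    def test_single_tip_closed_form(self):
        # a one-tip tree: likelihood is just the root prior of the state
        nodes = {
            "r": _Node("r", None, ["a"], None),
            "a": _Node("a", "r", [], 0.0),
        }
        tree = TraitLabeledTree(nodes, "r")
        tidx = TreeIndex(tree)
        pi = np.array([0.3, 0.7])
        P = np.tile(np.eye(2), (tidx.n_nodes, 1, 1))
        tips = np.zeros((tidx.n_nodes, 1, 2))
        tips[tidx.index["a"], 0, 1] = 1.0
        ll = generic_log_likelihood(tidx, P, tips, pi)
        assert ll == pytest.approx(np.log(0.7), abs=1e-12)

    @pytest.mark.parametrize("newick", [
        "((a:0.1,b:0.2):0.3,(c:0.4,d:0.5):0.6);",
        "(((a:0.2,b:0.1):0.2,c:0.3):0.1,(d:0.2,e:0.4):0.3);",
        "((a:0.5,b:0.5):0.5,c:0.5);",
    ])
    def test_likelihood_matches_exhaustive_summation(self, newick, rng):
        names = sorted(set("abcde") & set(newick))
        tip_states = {n: int(rng.integers(0, 2)) for n in names}
        tree, tidx, P, tips, pi = two_state_setup(newick, tip_states)
        ll = generic_log_likelihood(tidx, P, tips, pi)
        oracle = np.log(brute_force_likelihood(tidx, P, tip_states, pi))
        assert abs(ll - oracle) / abs(oracle) <= 1e-8

    def test_marginal_posteriors_match_bayes_enumeration(self, rng):
        newick = "((a:0.15,b:0.25):0.2,(c:0.35,d:0.45):0.3);"
        tip_states = {"a": 0, "b": 1, "c": 1, "d": 0}
        tree, tidx, P, tips, pi = two_state_setup(newick, tip_states)
        post = generic_marginal_posteriors(tidx, P, tips, pi)
        internals = [v for v in range(tidx.n_nodes) if not tidx.is_tip[v]]
        for node in internals:
            num = np.zeros(2)
            for assign in itertools.product(range(2), repeat=len(internals)):
                state = dict(zip(internals, assign))
                for v in range(tidx.n_nodes):
                    if tidx.is_tip[v]:
                        state[v] = tip_states[tidx.ids[v]]
                pr = pi[state[tidx.root]]
                for v in range(tidx.n_nodes):
                    if v != tidx.root:
                        pr *= P[v][state[tidx.parent[v]], state[v]]
                num[state[node]] += pr
            assert np.allclose(post[node, 0], num / num.sum(), atol=1e-10)

    def test_posteriors_sum_to_one(self, rng):
        newick = "((a:0.1,b:0.2):0.3,(c:0.4,d:0.5):0.6);"
        tip_states = {"a": 0, "b": 1, "c": 1, "d": 0}
        _, tidx, P, tips, pi = two_state_setup(newick, tip_states)
        post = generic_marginal_posteriors(tidx, P, tips, pi)
        assert np.abs(post.sum(axis=2) - 1).max() < 1e-9


# ---------------------------------------------------------------------------
# M0 codon model


class TestCodonModel:
    def test_rate_matrix_structure(self):
        m = CodonModelM0(kappa=2.5, omega=0.3)
        Q = m.rate_matrix()
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        assert -(m.codon_frequencies @ np.diag(Q)) == pytest.approx(1.0)
        pi = m.codon_frequencies
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12  # reversibility

    def test_transition_matrices_are_stochastic(self):
        m = CodonModelM0()
        P = m.transition_matrices(np.array([0.0, 0.01, 1.0, 10.0]))
        assert np.abs(P.sum(axis=2) - 1).max() < 1e-10
        assert P.min() >= 0.0
        assert np.allclose(P[0], np.eye(N_SENSE), atol=1e-10)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            CodonModelM0(kappa=-1.0)

    def test_likelihood_invariant_under_site_reordering(self):
        t = parse_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
        m1 = msa([("a", "ATGAAA"), ("b", "ATGAAG"), ("c", "ATGAAA"),
                  ("d", "ACGAAA")], "codon")
        m2 = msa([("a", "AAAATG"), ("b", "AAGATG"), ("c", "AAAATG"),
                  ("d", "AAAACG")], "codon")
        model = CodonModelM0()
        assert log_likelihood(m1, t, model) == pytest.approx(
            log_likelihood(m2, t, model), rel=1e-12
        )

    def test_f3x4_ignores_gap_codons(self):
        m = msa([("a", "ATG---"), ("b", "ATGAAA")], "codon")
        f = f3x4_frequencies(m)
        assert f.shape == (N_SENSE,)
        assert f.sum() == pytest.approx(1.0)


class TestMarginalASR:
    def test_invariant_column_dominant_posterior(self):
        t = parse_newick("((a:0.05,b:0.05):0.05,(c:0.05,d:0.05):0.05);")
        m = msa([(s, "ATG") for s in "abcd"], "codon")
        anc = marginal_asr(m, t, CodonModelM0())
        for nid in t.node_ids:
            assert anc.best[nid][0] == "M"

    def test_short_branch_limit_recovers_consensus(self):
        t = parse_newick("((a:1e-6,b:1e-6):1e-6,(c:1e-6,d:1e-6):1e-6);")
        m = msa([(s, "TGGAAA") for s in "abcd"], "codon")
        anc = marginal_asr(m, t, CodonModelM0())
        for nid in t.node_ids:
            if not t.is_tip(nid):
                assert anc.states(nid) == "WK"
                assert anc.posterior[nid].min() > 0.999

    def test_tips_reproduce_observed(self):
        t = parse_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
        m = msa([("a", "ATGAAA"), ("b", "ATGAAG"), ("c", "ATG---"),
                 ("d", "ACGAAA")], "codon")
        anc = marginal_asr(m, t, CodonModelM0())
        assert anc.states("a") == "MK"
        assert anc.states("c") == "M-"

    def test_codon_collapse_flag(self):
        t = parse_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
        m = msa([(s, "CTGAAA") for s in "abcd"], "codon")
        by_aa = marginal_asr(m, t, CodonModelM0(), collapse="amino_acid")
        by_codon = marginal_asr(m, t, CodonModelM0(), collapse="codon")
        assert by_aa.states(t.root_id) == by_codon.states(t.root_id) == "LK"

    def test_agreement_with_parsimony_low_divergence(self):
        """Parsimony and marginal ML agree on >= 95% of internal states."""
        tree = random_labeled_tree(3, 2, 3, seed=11)
        ds = simulate_dataset(
            SimulationConfig(tree=tree, n_codons=200, seed=12)
        )
        ml = marginal_asr(ds.alignment, tree, ds.config.model)
        pars = fitch_asr(translate_codons(ds.alignment), tree)
        agree = total = 0
        for nid in tree.node_ids:
            if tree.is_tip(nid):
                continue
            a, b = ml.best[nid], pars.best[nid]
            total += len(a)
            agree += int((a == b).sum())
        assert agree / total >= 0.95


@pytest.fixture(scope="module")
def small_sim():
    tree = random_labeled_tree(3, 2, 3, seed=21,
                               mean_backbone_length=0.08,
                               mean_tip_length=0.05)
    model = CodonModelM0(kappa=3.0, omega=0.3)
    ds = simulate_dataset(
        SimulationConfig(tree=tree, model=model, n_codons=150, seed=22)
    )
    return tree, model, ds


class TestFitModel:
    def test_fit_does_not_undershoot_true_parameters(self, small_sim):
        # ML property within the fitted family: the optimum is at least
        # as good as the generating kappa/omega under the same
        # (empirical) codon frequencies and unscaled lengths
        tree, model, ds = small_sim
        fit = fit_model(ds.alignment, tree, estimate_lengths="scale")
        same_family = CodonModelM0(
            kappa=model.kappa, omega=model.omega,
            codon_frequencies=fit.model.codon_frequencies,
        )
        truth_ll = log_likelihood(ds.alignment, tree, same_family)
        assert fit.log_likelihood >= truth_ll - 1e-6

    def test_multistart_agreement(self, small_sim):
        tree, model, ds = small_sim
        lo = fit_model(ds.alignment, tree, estimate_lengths="scale",
                       init=CodonModelM0(kappa=1.0, omega=0.1))
        hi = fit_model(ds.alignment, tree, estimate_lengths="scale",
                       init=CodonModelM0(kappa=8.0, omega=2.0))
        assert lo.model.kappa == pytest.approx(hi.model.kappa, rel=1e-2)
        assert lo.model.omega == pytest.approx(hi.model.omega, rel=1e-2)

    def test_cladogram_branch_estimation(self):
        # strip lengths: fit must estimate them (codeml guide-tree mode)
        tree = random_labeled_tree(2, 1, 2, seed=31, mean_backbone_length=0.1,
                                   mean_tip_length=0.08)
        ds = simulate_dataset(
            SimulationConfig(tree=tree, n_codons=120, seed=32)
        )
        bare = tree.copy()
        for nid in bare.node_ids:
            bare.node(nid).length = None
        fit = fit_model(ds.alignment, bare, estimate_lengths="branch",
                        max_sweeps=4)
        total_true = sum(tree.branch_length(n) or 0 for n in tree.node_ids)
        total_fit = sum(fit.tree.branch_length(n) or 0 for n in fit.tree.node_ids)
        assert total_fit == pytest.approx(total_true, rel=0.5)
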