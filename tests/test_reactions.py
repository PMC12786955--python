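"""Mapped-reaction parsing, condensed reaction graphs, fragments, PCA."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condvae.reactions import (FragmentTable, ReactionParseError,
                               apply_compressor, build_cgr,
                               enumerate_fragments, fit_compressor,
                               parse_mapped_reaction)

ETHENE_TO_ETHANE = "[CH2:1]=[CH2:2].[H][H]>>[CH3:1][CH3:2]"


# ----------------------------------------------------------------------
# parsing
# ----------------------------------------------------------------------
class TestParsing:
    def test_ethene_hydrogenation(self):
        rxn = parse_mapped_reaction(ETHENE_TO_ETHANE)
        assert len(rxn.reactants) == 1 and len(rxn.products) == 1
        r, p = rxn.reactants[0], rxn.products[0]
        assert r.number_of_nodes() == 2 and p.number_of_nodes() == 2
        assert list(r.edges(data="order"))[0][2] == 2.0
        assert list(p.edges(data="order"))[0][2] == 1.0
        # unmapped H2 is kept as reagent metadata, not a graph
        assert rxn.reagents == ["[H][H]"]

    def test_identity_reaction(self):
        rxn = parse_mapped_reaction("[CH4:1]>>[CH4:1]")
        assert rxn.reactants[0].number_of_nodes() == 1
        assert rxn.products[0].number_of_nodes() == 1

    @pytest.mark.parametrize("bad", [
        "C>>",                                  # no mapped product
        "not_a_smiles>>[CH4:1]",                # unparsable
        "[CH3:1][CH3:1]>>[CH4:1]",              # duplicated map number
        "plain text with no separator",
    ])
    def test_malformed_inputs_raise(self, bad):
        with pytest.raises(ReactionParseError):
            parse_mapped_reaction(bad)


# ----------------------------------------------------------------------
# condensed graph of reaction, with a brute-force bond-difference oracle
# ----------------------------------------------------------------------
def bond_difference_oracle(rxn):
    """Dynamic bonds = symmetric difference of (pair, order) mapped bond sets."""
    r = rxn.mapped_bonds("reactant")
    p = rxn.mapped_bonds("product")
    dynamic = {pair for pair in set(r) | set(p) if r.get(pair) != p.get(pair)}
    return dynamic


class TestCGR:
    def test_identity_reaction_has_no_dynamics(self):
        cgr = build_cgr(parse_mapped_reaction("[CH3:1][OH:2]>>[CH3:1][OH:2]"))
        assert not any(d for *_, d in cgr.edges(data="dynamic"))
        assert not any(d for _, d in cgr.nodes(data="dynamic"))

    @pytest.mark.parametrize("smiles", [
        ETHENE_TO_ETHANE,
        "[CH3:1][N+:2](=[O:3])[O-:4]>>[CH3:1][NH2:2]",          # nitro→amine
        "[CH3:1][O:2][CH2:3][c:4]1[cH:5][cH:6][cH:7][cH:8][cH:9]1"
        ">>[CH3:1][OH:2].[CH3:3][c:4]1[cH:5][cH:6][cH:7][cH:8][cH:9]1",
        "[CH:1]#[CH:2]>>[CH2:1]=[CH2:2]",
    ])
    def test_dynamic_bonds_match_brute_force(self, smiles):
        rxn = parse_mapped_reaction(smiles)
        cgr = build_cgr(rxn)
        got = {frozenset((a, b)) for a, b, d in cgr.edges(data="dynamic") if d}
        assert got == bond_difference_oracle(rxn)

    def test_nitro_reduction_dynamics(self):
        cgr = build_cgr(parse_mapped_reaction(
            "[CH3:1][N+:2](=[O:3])[O-:4]>>[CH3:1][NH2:2]"))
        dynamic_bonds = {frozenset((a, b)) for a, b, d in cgr.edges(data="dynamic") if d}
        assert dynamic_bonds == {frozenset((2, 3)), frozenset((2, 4))}
        # N loses its + charge → dynamic atom; O atoms vanish → one-sided
        assert cgr.nodes[2]["dynamic"]
        assert cgr.nodes[3]["charge_p"] is None


# ----------------------------------------------------------------------
# fragment enumeration
# ----------------------------------------------------------------------
def brute_force_paths(graph, length):
    """All undirected simple paths with `length` atoms, as node tuples."""
    found = set()
    for nodes in itertools.permutations(graph.nodes, length):
        if all(graph.has_edge(a, b) for a, b in zip(nodes, nodes[1:])):
            found.add(min(nodes, nodes[::-1]))
    return found


class TestFragments:
    def test_single_atom_no_len2_paths(self):
        g = nx.Graph()
        g.add_node(1, element="C", charge_r=0, charge_p=0, dynamic=False)
        assert enumerate_fragments(g, 2, 4).counts == {}

    def test_linear_chain_hand_counts(self):
        cgr = build_cgr(parse_mapped_reaction(
            "[CH3:1][CH2:2][OH:3]>>[CH3:1][CH2:2][OH:3]"))
        table = enumerate_fragments(cgr, 2, 3)
        assert table.counts == {"C-C": 1, "C-O": 1, "C-C-O": 1}

    def test_dynamic_bond_label_encodes_both_orders(self):
        cgr = build_cgr(parse_mapped_reaction(ETHENE_TO_ETHANE))
        table = enumerate_fragments(cgr, 2, 2)
        assert table.counts == {"C=>-C": 1}

    def test_min_len_below_one_rejected(self):
        g = nx.Graph()
        g.add_node(1, element="C", charge_r=0, charge_p=0, dynamic=False)
        with pytest.raises(ValueError):
            enumerate_fragments(g, 0, 2)

    @given(st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None)
    def test_counts_invariant_under_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        g = nx.gnp_random_graph(n, 0.6, seed=int(rng.integers(2**31)))
        elements = rng.choice(["C", "N", "O"], size=n)
        for i in g.nodes:
            g.nodes[i].update(element=str(elements[i]), charge_r=0,
                              charge_p=0, dynamic=False)
        for a, b in g.edges:
            g.edges[a, b].update(order_r=1.0, order_p=1.0, dynamic=False)
        perm = rng.permutation(n)
        h = nx.relabel_nodes(g, {i: int(perm[i]) + 100 for i in g.nodes})
        assert (enumerate_fragments(g, 2, 4).counts
                == enumerate_fragments(h, 2, 4).counts)

    @given(st.integers(0, 10**6), st.integers(2, 4))
    @settings(max_examples=20, deadline=None)
    def test_total_path_count_matches_brute_force(self, seed, length):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
        for i in g.nodes:
            g.nodes[i].update(element="C", charge_r=0, charge_p=0, dynamic=False)
        for a, b in g.edges:
            g.edges[a, b].update(order_r=1.0, order_p=1.0, dynamic=False)
        table = enumerate_fragments(g, length, length)
        assert sum(table.counts.values()) == len(brute_force_paths(g, length))


# ----------------------------------------------------------------------
# descriptor compression
# ----------------------------------------------------------------------
def random_corpus(rng, n=40, vocab=12):
    keys = [f"f{k}" for k in range(vocab)]
    return [FragmentTable({k: int(c) for k, c in
                           zip(keys, rng.integers(0, 9, size=vocab)) if c > 0},
                          2, 4) for _ in range(n)]


class TestCompressor:
    def test_rank2_corpus_needs_at_most_two_dims(self):
        base1 = {"a": 2, "b": 1}
        base2 = {"b": 3, "c": 5}
        tables = []
        for i in range(12):
            mix = {k: (i % 3) * base1.get(k, 0) + (i % 4) * base2.get(k, 0)
                   for k in "abc"}
            tables.append(FragmentTable({k: v for k, v in mix.items() if v}, 2, 4))
        comp = fit_compressor(tables, target_variance=0.95, whiten=False)
        assert comp.dim <= 2
        assert comp.explained_variance_ratio.sum() >= 0.99

    def test_matches_full_svd_oracle(self):
        rng = np.random.default_rng(5)
        tables = random_corpus(rng)
        comp = fit_compressor(tables, target_variance=0.95, whiten=False)
        X = np.stack([t.vector(comp.vocabulary) for t in tables])
        Xc = X - X.mean(axis=0)
        # full eigendecomposition oracle
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        var = s**2 / (len(X) - 1)
        ratio = np.cumsum(var) / var.sum()
        d_oracle = int(np.searchsorted(ratio, 0.95) + 1)
        assert comp.dim == d_oracle
        assert comp.explained_variance_ratio.sum() >= 0.95
        # projection of a fit-corpus member matches the oracle projection
        proj = apply_compressor(comp, tables[0])
        oracle = Xc[0] @ vt[:comp.dim].T
        # columns may differ by sign
        assert np.allclose(np.abs(proj), np.abs(oracle), atol=1e-6)

    def test_mean_profile_maps_to_zero(self):
        rng = np.random.default_rng(7)
        tables = random_corpus(rng)
        comp = fit_compressor(tables, whiten=False)
        X = np.stack([t.vector(comp.vocabulary) for t in tables])
        mean_counts = {k: float(v) for k, v in
                       zip(comp.vocabulary, X.mean(axis=0))}
        table = FragmentTable(mean_counts, 2, 4)
        assert np.allclose(comp.transform(table), 0.0, atol=1e-9)

    def test_unseen_keys_ignored(self):
        rng = np.random.default_rng(9)
        tables = random_corpus(rng)
        comp = fit_compressor(tables)
        t = FragmentTable({"zz_never_seen": 5}, 2, 4)
        x = apply_compressor(comp, t)
        assert x.shape == (comp.dim,) and np.all(np.isfinite(x))

    def test_reconstruction_error_nonincreasing_in_dim(self):
        rng = np.random.default_rng(3)
        tables = random_corpus(rng)
        errs = []
        for d in (1, 2, 4, 8):
            comp = fit_compressor(tables, target_variance=1.1, max_dim=d,
                                  whiten=False)
            X = np.stack([t.vector(comp.vocabulary) for t in tables])
            Xc = X - comp.mean
            recon = (Xc @ comp.components.T) @ comp.components
            errs.append(np.linalg.norm(Xc - recon))
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit_compressor([])
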