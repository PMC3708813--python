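"""Tree loading, taxon alignment, character filtering and trait recoding."""

import numpy as np
import pandas as pd
import pytest

import coevoscan as cs
from coevoscan.data import DEFAULT_TRAIT_VOCAB, TraitTable
from coevoscan.errors import (
    FormatError,
    InsufficientDataError,
    ValidationError,
)


def branch_lengths(tree):
    return [
        nd.edge.length
        for nd in tree.tree.preorder_node_iter()
        if nd.parent_node is not None
    ]


class TestLoadTree:
    def test_zero_branch_replaced_by_epsilon(self):
        tree = cs.load_tree("((a:0.1,b:0):0.2,c:0.3);", epsilon=1e-5)
        b = next(
            nd for nd in tree.tree.leaf_node_iter() if nd.taxon.label == "b"
        )
        assert b.edge.length == 1e-5
        assert min(branch_lengths(tree)) >= 1e-5

    def test_positive_lengths_unchanged(self):
        newick = "((a:0.1,b:0.2):0.3,c:0.4);"
        tree = cs.load_tree(newick)
        assert sorted(branch_lengths(tree)) == [0.1, 0.2, 0.3, 0.4]

    def test_all_zero_branches_replaced(self):
        """Three zero-length branches in, exactly three epsilons out."""
        tree = cs.load_tree("((a:0,b:0.2):0,(c:0.3,d:0):0.1);", epsilon=1e-5)
        lengths = branch_lengths(tree)
        assert sum(1 for l in lengths if l == 1e-5) == 3
        assert all(l > 0 for l in lengths)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValidationError):
            cs.load_tree("((a:0.1,b:-0.2):0.3,c:0.4);")

    def test_unparseable_newick(self):
        with pytest.raises(FormatError):
            cs.load_tree("((a:0.1,b:0.2;")

    def test_missing_branch_length(self):
        with pytest.raises(FormatError):
            cs.load_tree("((a:0.1,b):0.3,c:0.4);")


def make_matrix(taxa, data):
    return cs.CharacterMatrix(pd.DataFrame(data, index=taxa))


class TestAlign:
    def test_prunes_to_intersection(self):
        tree = cs.load_tree("((a:0.1,b:0.2):0.3,(c:0.4,d:0.2):0.1);")
        matrix = make_matrix(["a", "b", "c"], {"g1": [0, 1, 1]})
        ptree, pmat = cs.align_tree_and_matrix(tree, matrix)
        assert set(ptree.taxon_labels) == {"a", "b", "c"}
        assert pmat.taxa == ptree.taxon_labels

    def test_disjoint_taxa_error(self):
        tree = cs.load_tree("((a:0.1,b:0.2):0.3,c:0.4);")
        matrix = make_matrix(["x", "y", "z"], {"g1": [0, 1, 1]})
        with pytest.raises(InsufficientDataError):
            cs.align_tree_and_matrix(tree, matrix)

    def test_partial_overlap_counts(self):
        """10 tree taxa, 3 tree-only and 2 matrix-only -> 7 shared."""
        leaves = ",".join(f"t{i}:0.{i + 1}" for i in range(10))
        tree = cs.load_tree(f"({leaves});")
        taxa = [f"t{i}" for i in range(3, 10)] + ["m1", "m2"]
        matrix = make_matrix(taxa, {"g1": [0, 1] * 4 + [1]})
        ptree, pmat = cs.align_tree_and_matrix(tree, matrix)
        assert ptree.n_leaves == 7
        assert len(pmat.taxa) == 7


class TestFilterCharacters:
    def test_universal_character_dropped(self):
        m = make_matrix(list("abcdefghij"), {"g1": [1] * 10, "g2": [0, 1] * 5})
        kept, dropped = cs.filter_characters(m)
        assert dropped == ["g1"]
        assert kept.characters == ["g2"]

    def test_boundary_five_five_retained(self):
        m = make_matrix(list("abcdefghij"), {"g1": [1] * 5 + [0] * 5})
        kept, dropped = cs.filter_characters(m, 5, 5)
        assert kept.characters == ["g1"] and not dropped

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(17)
        states = rng.integers(0, 2, size=(20, 40))
        m = cs.CharacterMatrix(
            pd.DataFrame(states, index=[f"t{i}" for i in range(20)],
                         columns=[f"g{j}" for j in range(40)])
        )
        kept, dropped = cs.filter_characters(m, 5, 5)
        expected = [
            f"g{j}" for j in range(40)
            if states[:, j].sum() >= 5 and (20 - states[:, j].sum()) >= 5
        ]
        assert kept.characters == expected
        assert len(dropped) == 40 - len(expected)

    def test_idempotent(self):
        rng = np.random.default_rng(23)
        m = make_matrix(
            [f"t{i}" for i in range(12)],
            {f"g{j}": rng.integers(0, 2, 12) for j in range(10)},
        )
        once, _ = cs.filter_characters(m)
        twice, dropped = cs.filter_characters(once)
        assert twice.characters == once.characters and not dropped

    def test_align_then_filter_commutes(self):
        """Filtering after pruning equals pruning after filtering when the
        filter is evaluated on the shared taxa."""
        rng = np.random.default_rng(31)
        leaves = ",".join(f"t{i}:0.{i + 1}" for i in range(12))
        tree = cs.load_tree(f"({leaves});")
        taxa = [f"t{i}" for i in range(10)]  # 2 tree-only taxa
        m = make_matrix(taxa, {f"g{j}": rng.integers(0, 2, 10) for j in range(15)})
        t1, m1 = cs.align_tree_and_matrix(tree, m)
        f1, _ = cs.filter_characters(m1, 3, 3)
        f0, _ = cs.filter_characters(m, 3, 3)  # matrix taxa == shared taxa
        _, m2 = cs.align_tree_and_matrix(tree, f0)
        assert f1.characters == m2.characters
        pd.testing.assert_frame_equal(f1.states, m2.states)


class TestRecodeTraits:
    def make_raw(self, **cols):
        taxa = ["s1", "s2", "s3", "s4"]
        return TraitTable(raw=pd.DataFrame(cols, index=taxa))

    def test_thermophilicity(self):
        raw = self.make_raw(
            thermophilicity=["hyperthermophilic", "thermophilic",
                             "mesophilic", None]
        )
        out = cs.recode_traits(raw)
        assert list(out.binary["thermophilicity"][:3]) == [1, 1, 0]
        assert pd.isna(out.binary["thermophilicity"].iloc[3])

    def test_aerobicity(self):
        raw = self.make_raw(
            aerobicity=["anaerobic", "aerobic", "facultative", "microaerophilic"]
        )
        out = cs.recode_traits(raw)
        assert list(out.binary["aerobicity"]) == [0, 1, 1, 1]

    def test_multiple_habitat(self):
        raw = self.make_raw(
            habitat=["soil,host", "aquatic", "soil, aquatic ,host", None]
        )
        out = cs.recode_traits(raw)
        col = out.binary["multiple_habitat"]
        assert list(col[:3]) == [1, 0, 1]
        assert pd.isna(col.iloc[3])

    def test_pathogenicity(self):
        raw = self.make_raw(
            pathogenicity=["pathogenic", "nonpathogenic", None, "pathogenic"]
        )
        out = cs.recode_traits(raw)
        assert list(out.binary["pathogenicity"].dropna()) == [1, 0, 1]

    def test_unknown_token_listed(self):
        raw = self.make_raw(aerobicity=["anaerobic", "vacuum", None, None])
        with pytest.raises(ValidationError, match="vacuum"):
            cs.recode_traits(raw)

    def test_rules_recorded(self):
        raw = self.make_raw(aerobicity=["anaerobic"] * 4)
        out = cs.recode_traits(raw)
        assert "aerobicity" in out.rules

    def test_sidecar_vocabulary(self):
        vocab = cs.load_trait_vocab(
            "motility:\n  motile: 1\n  nonmotile: 0\n"
        )
        raw = self.make_raw(motility=["motile", "nonmotile", "motile", None])
        out = cs.recode_traits(raw, vocab=vocab)
        assert list(out.binary["motility"].dropna()) == [1, 0, 1]

    def test_sidecar_vocabulary_rejects_non_binary(self):
        with pytest.raises(ValidationError):
            cs.load_trait_vocab("motility:\n  motile: 2\n")


class TestPruneToTrait:
    def _tree10(self):
        leaves = ",".join(f"s{i}:0.{i + 1}" for i in range(10))
        return cs.load_tree(f"({leaves});")

    def test_prunes_to_annotated(self):
        tree = self._tree10()
        raw = pd.DataFrame(
            {"aerobicity": ["aerobic"] * 6 + [None] * 4},
            index=[f"s{i}" for i in range(10)],
        )
        traits = cs.recode_traits(TraitTable(raw=raw))
        sub, states = cs.prune_to_trait(tree, traits, "aerobicity")
        assert sub.n_leaves == 6
        assert states.shape == (6,)

    def test_all_annotated_unchanged(self):
        tree = self._tree10()
        raw = pd.DataFrame(
            {"aerobicity": ["anaerobic"] * 10}, index=[f"s{i}" for i in range(10)]
        )
        traits = cs.recode_traits(TraitTable(raw=raw))
        sub, states = cs.prune_to_trait(tree, traits, "aerobicity")
        assert sub.n_leaves == 10
        assert (states == 0).all()

    def test_per_trait_missingness_counts(self):
        tree = self._tree10()
        rng = np.random.default_rng(2)
        cols = {}
        expected = {}
        for trait in ("aerobicity", "thermophilicity"):
            vocab = list(DEFAULT_TRAIT_VOCAB[trait])
            annotated = rng.integers(0, 2, 10).astype(bool)
            # ensure at least 3 annotated
            annotated[:3] = True
            cols[trait] = [
                rng.choice(vocab) if a else None for a in annotated
            ]
            expected[trait] = int(annotated.sum())
        raw = pd.DataFrame(cols, index=[f"s{i}" for i in range(10)])
        traits = cs.recode_traits(TraitTable(raw=raw))
        for trait, n in expected.items():
            sub, states = cs.prune_to_trait(tree, traits, trait)
            assert sub.n_leaves == n == len(states)

    def test_too_few_annotated(self):
        tree = self._tree10()
        raw = pd.DataFrame(
            {"aerobicity": ["aerobic", "aerobic"] + [None] * 8},
            index=[f"s{i}" for i in range(10)],
        )
        traits = cs.recode_traits(TraitTable(raw=raw))
        with pytest.raises(InsufficientDataError):
            cs.prune_to_trait(tree, traits, "aerobicity")


class TestMatrixIO:
    def test_round_trip(self):
        tsv = "taxon\tg1\tg2\ns1\t0\t1\ns2\t1\t0\ns3\t1\t1\n"
        m = cs.load_matrix(tsv)
        assert m.taxa == ["s1", "s2", "s3"]
        assert m.characters == ["g1", "g2"]

    def test_missing_cell_rejected(self):
        tsv = "taxon\tg1\ns1\t0\ns2\t\ns3\t1\n"
        with pytest.raises(ValidationError):
            cs.load_matrix(tsv)

    def test_non_binary_rejected(self):
        tsv = "taxon\tg1\ns1\t0\ns2\t2\ns3\t1\n"
        with pytest.raises(ValidationError):
            cs.load_matrix(tsv)
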