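import math

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from nbscensus import classify, phylo
from nbscensus.models import NBSType

from _oracles import random_additive_tree
from conftest import make_gene, make_hit


def rec(gene_id, nbs_type):
    gene = make_gene(gene_id)
    return classify.NBSRecord(gene, [make_hit(gene_id, "NBARC", 1, 300)], nbs_type.value, nbs_type)


class TestSelect:
    def test_tn_and_tnl_selected(self):
        records = [rec("a", NBSType.TNL), rec("b", NBSType.CNL), rec("c", NBSType.TN)]
        assert [r.gene_id for r in phylo.select_tir_nbs(records)] == ["a", "c"]

    def test_published_tir_total(self):
        """The four species' TN+TNL counts sum to the reported TIR-NBS total."""
        tn = [2, 14, 0, 11]
        tnl = [5, 50, 5, 44]
        assert sum(tn) + sum(tnl) == 131


class TestPDistance:
    def test_direct_cases(self):
        assert phylo.p_distance("MKV", "MKV") == 0.0
        assert phylo.p_distance("MKV", "MRV") == pytest.approx(1 / 3)
        assert phylo.p_distance("M-KV", "MAKV") == 0.0  # gap column not counted

    def test_column_scan_oracle(self, rng):
        chars = list("ACDE-")
        for _ in range(50):
            n = int(rng.integers(4, 40))
            a = "".join(rng.choice(chars, n))
            b = "".join(rng.choice(chars, n))
            counted = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not counted:
                with pytest.raises(ValueError):
                    phylo.p_distance(a, b)
                continue
            expected = sum(1 for x, y in counted if x != y) / len(counted)
            assert phylo.p_distance(a, b) == pytest.approx(expected)

    def test_no_counted_columns_raises(self):
        with pytest.raises(ValueError):
            phylo.p_distance("M-", "-M")


class TestKimura:
    def test_closed_form_values(self):
        assert phylo.kimura_correct(0.0) == 0.0
        assert phylo.kimura_correct(0.2) == pytest.approx(-math.log(0.792))

    def test_correction_expands_distances(self):
        for p in np.linspace(0.01, 0.5, 25):
            assert phylo.kimura_correct(float(p)) >= p

    def test_saturation_capped(self):
        assert phylo.kimura_correct(0.99999 * (math.sqrt(1.8) - 1) / 0.4 + 0.01) <= phylo.SATURATION_CAP
        assert phylo.kimura_correct(0.9) == phylo.SATURATION_CAP

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            phylo.kimura_correct(-0.1)
        with pytest.raises(ValueError):
            phylo.kimura_correct(1.0)


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]], ["a", "b", "c"])
        tree = nj_tree = phylo.nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_four_taxon_split_recovered(self):
        # ((A,B),(C,D)) with unit internal edge, leaf edges 1
        D = [
            [0, 2, 3, 3],
            [2, 0, 3, 3],
            [3, 3, 0, 2],
            [3, 3, 2, 0],
        ]
        tree = phylo.nj_tree(DistanceMatrix(D, ["A", "B", "C", "D"]))
        assert frozenset({"C", "D"}) in phylo.bipartitions(tree) or frozenset(
            {"A", "B"}
        ) in phylo.bipartitions(tree)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            phylo.nj_tree(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))

    @pytest.mark.parametrize("seed", range(15))
    def test_additive_matrix_topology_recovery(self, seed):
        rng = np.random.default_rng(seed)
        D, labels, true_bips = random_additive_tree(rng, int(rng.integers(5, 13)))
        dm = DistanceMatrix([[D[a][b] for b in labels] for a in labels], labels)
        tree = phylo.nj_tree(dm)
        assert phylo.bipartitions(tree) == true_bips

    def test_matches_scikit_bio_nj(self, rng):
        """Independent library cross-check on additive matrices."""
        for seed in range(5):
            r = np.random.default_rng(seed + 100)
            D, labels, _ = random_additive_tree(r, 8)
            dm = DistanceMatrix([[D[a][b] for b in labels] for a in labels], labels)
            ours = phylo.bipartitions(phylo.nj_tree(dm))
            theirs = phylo.bipartitions(skbio_nj(dm))
            assert ours == theirs


def duplicated_clade_alignment():
    a = "MKVLWAALLVTFLAGCQAKVEQAVETEPEPELRQQTEW" * 6
    b = "".join("A" if c == "M" else c for c in a)
    rows = [a, a, b[:20] + "W" + b[21:], b, b[:50] + "Y" + b[51:], a[:10] + "C" + a[11:]]
    labels = [f"s{i}" for i in range(6)]
    return rows, labels


class TestBootstrap:
    def test_invariant_split_gets_full_support(self):
        rows, labels = duplicated_clade_alignment()
        _, supports = phylo.bootstrap_nj(rows, labels, n_replicates=50, seed=1)
        clade_b = frozenset({"s2", "s3", "s4"})
        assert supports[clade_b] == 100

    def test_single_replicate_supports_are_binary(self):
        rows, labels = duplicated_clade_alignment()
        _, supports = phylo.bootstrap_nj(rows, labels, n_replicates=1, seed=3)
        assert set(supports.values()) <= {0, 100}

    def test_fixed_seed_is_deterministic(self):
        rows, labels = duplicated_clade_alignment()
        _, s1 = phylo.bootstrap_nj(rows, labels, n_replicates=30, seed=9)
        _, s2 = phylo.bootstrap_nj(rows, labels, n_replicates=30, seed=9)
        assert s1 == s2

    def test_row_order_invariance_of_supports(self, rng):
        """With a tie-free distance matrix, supports do not depend on row order."""
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200))
        from nbscensus.synthetic_data import mutate_protein

        rows = [mutate_protein(base, r, np.random.default_rng(i)) for i, r in
                enumerate([0.05, 0.1, 0.15, 0.2, 0.3, 0.35])]
        labels = [f"s{i}" for i in range(6)]
        _, s1 = phylo.bootstrap_nj(rows, labels, n_replicates=40, seed=5)
        order = [3, 1, 5, 0, 4, 2]
        _, s2 = phylo.bootstrap_nj([rows[i] for i in order], [labels[i] for i in order],
                                   n_replicates=40, seed=5)
        assert s1 == s2

    def test_bad_replicate_count(self):
        rows, labels = duplicated_clade_alignment()
        with pytest.raises(ValueError):
            phylo.bootstrap_nj(rows, labels, n_replicates=0)


class TestStarAlignment:
    def test_identical_sequences_no_gaps(self):
        rows = phylo.star_alignment(["MKVL", "MKVL", "MKVL"])
        assert rows == ["MKVL", "MKVL", "MKVL"]

    def test_rows_equal_length_and_ungap_to_inputs(self, small_records):
        seqs = [r.gene.protein for r in small_records[:5]]
        rows = phylo.star_alignment(seqs)
        assert len({len(r) for r in rows}) == 1
        assert [r.replace("-", "") for r in rows] == seqs


def test_divergence_monotonicity_of_distances(rng):
    """Generator mutation model: larger configured divergence, larger distance."""
    from nbscensus.synthetic_data import mutate_protein

    base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 400))
    rates = [0.05, 0.15, 0.3, 0.45]
    dists = [phylo.p_distance(base, mutate_protein(base, r, np.random.default_rng(1))) for r in rates]
    assert dists == sorted(dists)
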