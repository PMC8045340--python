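import numpy as np
import pytest

from negeseek import (IdentityMatrix, build_identity_matrix, global_align,
                      nj_tree, nucleotide_scheme, parse_identity_table,
                      percent_identity, protein_scheme, smallest_clade_with)
from negeseek.identity import ScoringScheme

import pandas as pd


def nw_linear_gap_score(a, b, match, mismatch, gap):
    """Plain Needleman-Wunsch with a per-symbol gap cost (test oracle)."""
    n, m = len(a), len(b)
    D = np.zeros((n + 1, m + 1))
    D[:, 0] = -gap * np.arange(n + 1)
    D[0, :] = -gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            D[i, j] = max(D[i - 1, j - 1] + sub,
                          D[i - 1, j] - gap, D[i, j - 1] - gap)
    return D[n, m]


def test_self_alignment_is_identity():
    aln = global_align("ACGT", "ACGT", nucleotide_scheme())
    assert aln.n_identical == aln.n_aligned_cols == 4
    assert percent_identity(aln) == 100.0


def test_hand_computed_mismatch_alignment():
    # gap cost (10 + 0.5) exceeds the mismatch penalty: ungapped optimum
    aln = global_align("ACGT", "ACGA", nucleotide_scheme())
    assert "-" not in aln.aligned_a + aln.aligned_b
    assert aln.score == 5 + 5 + 5 - 4
    assert (aln.n_identical, aln.n_aligned_cols) == (3, 4)
    assert percent_identity(aln) == 75.0


def test_score_symmetry_random_pairs():
    rng = np.random.default_rng(1)
    scheme = nucleotide_scheme()
    for _ in range(100):
        a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 30))))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 30))))
        assert global_align(a, b, scheme).score == \
            global_align(b, a, scheme).score


def test_affine_aligner_matches_linear_dp_oracle_when_open_equals_extend():
    rng = np.random.default_rng(2)
    gap = 4.0
    scheme = ScoringScheme("nucleotide", (5.0, -4.0), gap, gap)
    for _ in range(200):
        a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 31))))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 31))))
        got = global_align(a, b, scheme).score
        assert got == pytest.approx(nw_linear_gap_score(a, b, 5.0, -4.0, gap))


def test_percent_identity_denominators():
    aln = global_align("ACGTACGT", "ACGT", nucleotide_scheme())
    assert percent_identity(aln, "nogap") == 100.0
    assert percent_identity(aln, "shorter") == 100.0
    assert percent_identity(aln, "alignment") == 50.0


def test_identity_100_iff_equal_sequences():
    scheme = protein_scheme()
    aln = global_align("MKVLW", "MKVLW", scheme)
    assert percent_identity(aln) == 100.0
    aln2 = global_align("MKVLW", "MKVLF", scheme)
    assert percent_identity(aln2) < 100.0


def test_build_identity_matrix_symmetry_and_permutation_invariance():
    seqs = {"a": "MKVLWAAL", "b": "MKVLWAAV", "c": "MKLLWGAL"}
    m1 = build_identity_matrix(aa_seqs=seqs)
    m1.validate()
    assert m1.aa.loc["a", "a"] == 100.0
    perm = {"c": seqs["c"], "a": seqs["a"], "b": seqs["b"]}
    m2 = build_identity_matrix(aa_seqs=perm)
    for x in "abc":
        for y in "abc":
            assert m1.aa.loc[x, y] == m2.aa.loc[x, y]


def test_build_identity_matrix_identical_pair():
    m = build_identity_matrix(aa_seqs={"a": "MKVLW", "b": "MKVLW"})
    assert m.aa.loc["a", "b"] == 100.0


def test_build_identity_matrix_missing_label_listed():
    with pytest.raises(ValueError, match="missing"):
        build_identity_matrix(aa_seqs={"a": "MKV", "b": "MKL"},
                              nt_seqs={"a": "ATG"})


def test_packaged_table_values_and_invariants():
    m = parse_identity_table()
    m.validate()
    assert m.labels[0] == "INLV1"
    assert len(m.labels) == 18
    assert m.aa.loc["INLV1", "BARV-1"] == 77.2
    assert m.nt.loc["INLV1", "BARV-1"] == 69.2
    assert m.aa.loc["INLV1", "HVLV-4"] == 76.3
    assert m.nt.loc["INLV1", "HVLV-4"] == 69.0
    assert m.aa.loc["TANAV", "BUSV"] == 66.9
    assert m.aa.loc["INLV1", "INLV1"] == 100.0


def test_parse_identity_table_rejects_bad_table(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("label\ta\tb\na\t*\t\nb\t50.0\t*\n")
    with pytest.raises(ValueError, match="missing value"):
        parse_identity_table(p)


def _random_additive_instance(rng, n_leaves):
    """Random tree -> exact leaf-to-leaf distances (independent oracle)."""
    clusters = [(f"T{i}", {f"T{i}": 0.0}) for i in range(n_leaves)]
    dist = {}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (na, da) = clusters[j]
        (nb, db) = clusters[i]
        la, lb = rng.uniform(0.01, 0.05, size=2)
        for x, dx in da.items():
            for y, dy in db.items():
                dist[frozenset((x, y))] = dx + la + dy + lb
        merged = {x: d + la for x, d in da.items()}
        merged.update({y: d + lb for y, d in db.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(("join", merged))
    return dist


def test_nj_three_taxa_star():
    labels = ["a", "b", "c"]
    ident = pd.DataFrame(
        [[100.0, 90.0, 80.0], [90.0, 100.0, 82.0], [80.0, 82.0, 100.0]],
        index=labels, columns=labels)
    t = nj_tree(IdentityMatrix(labels, aa=ident), "aa")
    tips = {x.name for x in t.tree.tips()}
    assert tips == set(labels)
    d = t.tree.tip_tip_distances(labels).data
    assert d[0, 1] == pytest.approx(0.10, abs=1e-9)


def test_nj_exact_on_additive_matrices():
    """NJ recovers the generating tree's leaf distances exactly."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        n = int(rng.integers(4, 11))
        dist = _random_additive_instance(rng, n)
        labels = [f"T{i}" for i in range(n)]
        ident = pd.DataFrame(100.0, index=labels, columns=labels)
        for i, x in enumerate(labels):
            for y in labels[i + 1:]:
                ident.loc[x, y] = ident.loc[y, x] = \
                    100.0 * (1.0 - dist[frozenset((x, y))])
        t = nj_tree(IdentityMatrix(labels, aa=ident), "aa")
        got = t.tree.tip_tip_distances(labels).data
        for i, x in enumerate(labels):
            for j in range(i + 1, n):
                assert got[i, j] == pytest.approx(
                    dist[frozenset((x, labels[j]))], abs=1e-6)


def test_nj_on_published_table_groups_inlv1_with_centivirus_partners():
    m = parse_identity_table()
    t = nj_tree(m, "aa")
    clade = smallest_clade_with(t, "INLV1")
    assert clade & {"BARV-1", "HVLV-4"}


def test_newick_output_has_branch_lengths():
    m = parse_identity_table()
    nwk = nj_tree(m, "aa").to_newick()
    assert nwk.endswith(";") and ":" in nwk and "INLV1" in nwk
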