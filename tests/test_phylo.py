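"""Distance models, neighbor joining, bootstrap, and lineage assignment."""

import itertools
import math

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table

from lilrseq import phylo
from lilrseq.phylo import (
    DistanceMatrix,
    SaturatedDistanceError,
    assign_lineages,
    bootstrap_support,
    build_nj_tree,
    codon_path_differences,
    codon_syn_sites,
    distance_matrix,
    jc_distance,
    nei_gojobori_ns,
    tamura_nei_distance,
)

# frozen cross-check: ape::dist.dna(model="TN93", pairwise.deletion=TRUE) on
# the three pairs generated by _tn_pairs() below
APE_TN93 = [0.1073438607, 0.1073701802, 0.1075179642]


def _tn_pairs():
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    pairs = []
    for _ in range(3):
        n = 600
        a = rng.choice(bases, n)
        b = a.copy()
        idx = rng.choice(n, 60, replace=False)
        for i in idx:
            b[i] = rng.choice([x for x in "ACGT" if x != a[i]])
        pairs.append(("".join(a), "".join(b)))
    return pairs


class TestJukesCantor:
    def test_identical_sequences_give_zero(self):
        assert jc_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_at_p_ten_percent(self):
        a = "A" * 90 + "C" * 10
        b = "A" * 90 + "G" * 10
        assert jc_distance(a, b) == pytest.approx(-0.75 * math.log(1 - 0.4 / 3),
                                                  abs=1e-12)

    def test_saturation_at_three_quarters(self):
        with pytest.raises(SaturatedDistanceError):
            jc_distance("A" * 25 + "C" * 75, "A" * 25 + "G" * 75)

    def test_gapped_columns_excluded(self):
        assert jc_distance("AC-T", "AG-T") == jc_distance("ACT", "AGT")


class TestTamuraNei:
    def test_identical_sequences_give_zero(self):
        assert tamura_nei_distance("ACGT" * 10, "ACGT" * 10) == 0.0

    def test_matches_frozen_reference_implementation(self):
        for (a, b), expect in zip(_tn_pairs(), APE_TN93):
            assert tamura_nei_distance(a, b) == pytest.approx(expect, abs=1e-9)

    def test_transversion_only_equals_k2p_transversion_term(self):
        # uniform composition, 20 transversions in 200 sites (Q = 0.1),
        # composition-balanced so empirical frequencies stay uniform
        a = list("ACGT" * 50)
        b = a.copy()
        swaps = [("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")]
        done = {s: 0 for s in swaps}
        for i, x in enumerate(a):
            for s in swaps:
                if x == s[0] and done[s] < 5:
                    b[i] = s[1]
                    done[s] += 1
                    break
        q = sum(x != y for x, y in zip(a, b)) / len(a)
        assert q == 0.1
        expect = -0.5 * math.log(1 - q) - 0.25 * math.log(1 - 2 * q)
        assert tamura_nei_distance("".join(a), "".join(b)) == pytest.approx(
            expect, abs=1e-12
        )

    def test_transition_rich_pairs_exceed_jc(self):
        # balanced composition, 10 A<->G transitions in 100 sites
        a = list("ACGT" * 25)
        b = a.copy()
        swapped = {"A": 0, "G": 0}
        for i, x in enumerate(a):
            if x in swapped and swapped[x] < 5:
                b[i] = "G" if x == "A" else "A"
                swapped[x] += 1
        a, b = "".join(a), "".join(b)
        assert tamura_nei_distance(a, b) >= jc_distance(a, b)

    def test_first_order_agreement_at_small_p(self):
        n = 10000
        a = "ACGT" * (n // 4)
        b = "GCGT" + a[4:]  # one A->G transition
        p = 1 / n
        assert abs(jc_distance(a, b) - p) < 1e-6
        assert abs(tamura_nei_distance(a, b) - p) < 1e-6


def _oracle_path_diffs(c1, c2):
    """Independent pathway enumeration using Biopython's codon table."""
    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in stops:
                ok = False
                break
            sd += table[cur] == table[nxt]
            nd += table[cur] != table[nxt]
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        results = [(0, len(diffs))]
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


class TestNeiGojobori:
    def test_identical_cds_gives_zero(self):
        assert nei_gojobori_ns("ATGGCTAAA", "ATGGCTAAA") == 0.0

    def test_phe_to_leu_is_one_nonsynonymous_difference(self):
        assert codon_path_differences("TTT", "TTA") == (0.0, 1.0)

    def test_known_synonymous_site_fractions(self):
        assert codon_syn_sites("TTT") == pytest.approx(1 / 3)
        assert codon_syn_sites("CTG") == pytest.approx(4 / 3)  # L, 4-fold + wobble
        assert codon_syn_sites("ATG") == 0.0  # Met: no synonymous change

    def test_pathway_counts_match_exhaustive_oracle(self):
        codons = [c for c in map("".join, itertools.product("ACGT", repeat=3))
                  if c not in ("TAA", "TAG", "TGA")]
        rng = np.random.default_rng(0)
        checked = 0
        for c1 in codons:
            for c2 in rng.choice(codons, 8, replace=False):
                if c2 in ("TAA", "TAG", "TGA"):
                    continue
                ndiff = sum(x != y for x, y in zip(c1, c2))
                if ndiff > 2:
                    continue
                assert codon_path_differences(c1, c2) == pytest.approx(
                    _oracle_path_diffs(c1, c2)
                )
                checked += 1
        assert checked > 100

    def test_multi_codon_alignment_matches_manual_count(self):
        a = "TTTGCTATG"  # F A M
        b = "TTAGCCATG"  # L A M : 1 nonsyn (TTT->TTA), 1 syn (GCT->GCC)
        S = (codon_syn_sites("TTT") + codon_syn_sites("TTA")) / 2
        S += (codon_syn_sites("GCT") + codon_syn_sites("GCC")) / 2
        S += codon_syn_sites("ATG")
        N = 9 - S
        pN = 1 / N
        expect = -0.75 * math.log(1 - 4 * pN / 3)
        assert nei_gojobori_ns(a, b) == pytest.approx(expect, abs=1e-12)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            nei_gojobori_ns("ATGTAAAAA", "ATGTAAAAA")


def _ls_best_topology(labels, d):
    """Brute-force least-squares fit of all three unrooted 4-taxon topologies."""
    best = None
    idx = {l: i for i, l in enumerate(labels)}
    a, b, c, e = labels
    for split in ((a, b, c, e), (a, c, b, e), (a, e, b, c)):
        p, q, r, s = split
        # branch lengths: p,q on one cherry, r,s on the other, m = middle
        A = []
        y = []
        pairs = list(itertools.combinations(labels, 2))
        for (u, v) in pairs:
            row = {p: 0, q: 0, r: 0, s: 0, "m": 0}
            row[u] += 1
            row[v] += 1
            same_cherry = {u, v} in ({p, q}, {r, s})
            if not same_cherry:
                row["m"] = 1
            A.append([row[p], row[q], row[r], row[s], row["m"]])
            y.append(d[idx[u], idx[v]])
        coef, res, *_ = np.linalg.lstsq(np.array(A, float), np.array(y), rcond=None)
        rss = float(res[0]) if len(res) else float(
            np.sum((np.array(A) @ coef - y) ** 2)
        )
        if best is None or rss < best[0]:
            best = (rss, frozenset((p, q)))
    return best[1]


class TestNeighborJoining:
    @pytest.mark.parametrize("seed", range(6))
    def test_additive_four_taxon_matrices_recover_ls_topology(self, seed):
        rng = np.random.default_rng(seed)
        labels = ["A", "B", "C", "D"]
        # generate an additive matrix from a random 4-taxon tree
        bl = rng.uniform(0.05, 1.0, size=5)  # a, b, c, d, middle
        pairing = [("A", "B"), ("A", "C"), ("A", "D")][seed % 3]
        other = [l for l in labels if l not in pairing]
        L = {pairing[0]: bl[0], pairing[1]: bl[1], other[0]: bl[2],
             other[1]: bl[3]}
        d = np.zeros((4, 4))
        for i, u in enumerate(labels):
            for j, v in enumerate(labels):
                if i < j:
                    m = 0 if {u, v} in ({*pairing}, {*other}) and False else None
                    same = {u, v} == set(pairing) or {u, v} == set(other)
                    dist = L[u] + L[v] + (0 if same else bl[4])
                    d[i, j] = d[j, i] = dist
        newick = build_nj_tree(DistanceMatrix(labels, d, "JC"))
        got = phylo._bipartitions(newick)
        expect_split = _ls_best_topology(labels, d)
        anchor = min(labels)
        canon = (expect_split if anchor not in expect_split
                 else frozenset(set(labels) - expect_split))
        assert got == {canon}

    def test_three_taxa_unique_resolution(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        newick = build_nj_tree(DistanceMatrix(["A", "B", "C"], d, "JC"))
        assert phylo._bipartitions(newick) == set()
        for leaf in "ABC":
            assert leaf in newick

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(3)
        labels = ["w", "x", "y", "z", "v"]
        pts = rng.uniform(size=(5, 6))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0)
        ref = phylo._bipartitions(build_nj_tree(DistanceMatrix(labels, d, "JC")))
        order = [3, 1, 4, 0, 2]
        d2 = d[np.ix_(order, order)]
        lab2 = [labels[i] for i in order]
        assert phylo._bipartitions(
            build_nj_tree(DistanceMatrix(lab2, d2, "JC"))
        ) == ref

    def test_agrees_with_skbio_on_random_matrices(self):
        import skbio

        rng = np.random.default_rng(8)
        labels = [f"t{i}" for i in range(6)]
        pts = rng.uniform(size=(6, 8))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0)
        mine = phylo._bipartitions(build_nj_tree(DistanceMatrix(labels, d, "JC")))
        ref_tree = skbio.tree.nj(skbio.DistanceMatrix(d, labels))
        theirs = phylo._bipartitions(str(ref_tree).strip())
        assert mine == theirs

    def test_saturated_matrix_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(SaturatedDistanceError):
            build_nj_tree(DistanceMatrix(["A", "B", "C"], d, "JC"))


@pytest.fixture(scope="module")
def sim_alignment(small_sim):
    _, truth, _ = small_sim
    return truth


class TestBootstrapAndLineages:
    def test_well_separated_lineages_get_full_support(self, sim_alignment):
        aln = sim_alignment.cds_alignment
        newick, support = bootstrap_support(aln, 200, seed=4)
        true_of = {r.name: r.lineage for r in sim_alignment.alleles}
        leaves = set(aln)
        anchor = min(leaves)
        for lid in sorted(set(true_of.values())):
            side = frozenset(n for n, l in true_of.items() if l == lid)
            key = side if anchor not in side else frozenset(leaves - side)
            if len(key) < 2 or len(leaves - key) < 2:
                continue
            assert support[key] >= 0.99

    def test_bootstrap_deterministic_and_zero_reps_empty(self, sim_alignment):
        aln = sim_alignment.cds_alignment
        _, s1 = bootstrap_support(aln, 50, seed=6)
        _, s2 = bootstrap_support(aln, 50, seed=6)
        assert s1 == s2
        _, s0 = bootstrap_support(aln, 0, seed=6)
        assert s0 == {}

    def test_lineage_assignment_recovers_truth(self, sim_alignment):
        aln = sim_alignment.cds_alignment
        dm = distance_matrix(aln, "JC")
        newick, support = bootstrap_support(aln, 200, seed=4)
        asn = assign_lineages(newick, dm, support)
        true_of = {r.name: r.lineage for r in sim_alignment.alleles}
        # bijective agreement between assigned and true lineages
        mapping = {}
        for allele, lid in asn.lineage_of.items():
            mapping.setdefault(lid, set()).add(true_of[allele])
        assert all(len(v) == 1 for v in mapping.values())
        assert len(mapping) == len(set(true_of.values()))

    def test_single_allele_is_singleton_lineage(self):
        dm = DistanceMatrix(["X"], np.zeros((1, 1)), "JC")
        asn = assign_lineages("(X:0.0);", dm)
        assert asn.lineage_of == {"X": "001"}

    def test_legacy_map_pins_lineage_ids(self, sim_alignment):
        aln = sim_alignment.cds_alignment
        dm = distance_matrix(aln, "JC")
        newick, support = bootstrap_support(aln, 50, seed=4)
        pinned_allele = sim_alignment.alleles[0].name
        asn = assign_lineages(newick, dm, support,
                              legacy_map={pinned_allele: "007"})
        assert asn.lineage_of[pinned_allele] == "007"
        assert len(set(asn.lineage_of.values())) == 3


def test_all_distances_zero_on_identity_and_symmetric():
    a = "ATGGCTAAACGTTTGGCTCAT"
    b = "ATGGCAAAACGTCTGGCTCAC"
    for func in (jc_distance, tamura_nei_distance, nei_gojobori_ns):
        assert func(a, a) == 0.0
        assert func(a, b) == pytest.approx(func(b, a), abs=1e-15)
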