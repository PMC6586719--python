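"""Population-genetics statistics against independent oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from Bio.Seq import Seq

from crisprkit.popgen import (
    CodingAlignment,
    DistanceMatrix,
    InsufficientSamplesError,
    SaturationError,
    codon_sites,
    domain_scan,
    jc_corrected_distance,
    k2p_distance,
    k2p_matrix,
    mean_pairwise_differences,
    neighbor_joining,
    nei_gojobori,
    nucleotide_diversity,
    segregating_sites,
    tajima_constants,
    tajimas_d,
    tajimas_d_from_stats,
)

SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if str(Seq(a + b + c).translate()) != "*"
]


# ---------------------------------------------------------------------------
# Jukes-Cantor

class TestJukesCantor:
    def test_identity(self):
        assert jc_corrected_distance(0.0) == 0.0

    def test_known_value(self):
        # -0.75 * ln(0.6), evaluated independently
        assert jc_corrected_distance(0.3) == pytest.approx(0.38312, abs=1e-4)

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            jc_corrected_distance(0.75)

    def test_negative_p_rejected(self):
        with pytest.raises(ValueError):
            jc_corrected_distance(-0.01)

    @pytest.mark.parametrize("p", [0.01, 0.1, 0.3, 0.5, 0.7])
    def test_correction_inflates(self, p):
        assert jc_corrected_distance(p) >= p


# ---------------------------------------------------------------------------
# nucleotide diversity

def _brute_force_pi(seqs):
    """Oracle: direct pairwise enumeration with pairwise gap/N deletion."""
    vals = []
    for s1, s2 in itertools.combinations(seqs, 2):
        pairs = [(a, b) for a, b in zip(s1, s2) if a not in "N-" and b not in "N-"]
        vals.append(sum(a != b for a, b in pairs) / len(pairs))
    return sum(vals) / len(vals)


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        aln = CodingAlignment(["a", "b"], ["ACGT" * 25] * 2)
        assert nucleotide_diversity(aln) == 0.0

    def test_single_difference(self):
        s = "ACGT" * 25
        aln = CodingAlignment(["a", "b"], [s, "T" + s[1:]])
        assert nucleotide_diversity(aln) == pytest.approx(0.01)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        base = "".join(rng.choice(list("ACGT"), 60))
        seqs = []
        for _ in range(3):
            s = list(base)
            for pos in rng.choice(60, size=5, replace=False):
                s[pos] = rng.choice([c for c in "ACGT" if c != s[pos]])
            seqs.append("".join(s))
        aln = CodingAlignment(["a", "b", "c"], seqs)
        assert nucleotide_diversity(aln) == pytest.approx(_brute_force_pi(seqs))

    def test_jc_at_least_raw(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            base = "".join(rng.choice(list("ACGT"), 90))
            seqs = []
            for _ in range(4):
                s = list(base)
                for pos in rng.choice(90, size=int(rng.integers(0, 12)), replace=False):
                    s[pos] = rng.choice([c for c in "ACGT" if c != s[pos]])
                seqs.append("".join(s))
            aln = CodingAlignment([f"s{i}" for i in range(4)], seqs)
            raw = nucleotide_diversity(aln)
            jc = nucleotide_diversity(aln, corrected=True)
            assert jc >= raw
            if raw > 0:
                assert jc > raw

    def test_needs_two_samples(self):
        with pytest.raises(InsufficientSamplesError):
            nucleotide_diversity(CodingAlignment(["a"], ["ACG"]))

    def test_all_masked_is_undefined(self):
        aln = CodingAlignment(["a", "b"], ["NNN", "ACG"])
        assert math.isnan(nucleotide_diversity(aln))

    def test_gap_sites_excluded_pairwise(self):
        aln = CodingAlignment(["a", "b"], ["AC-T", "ACGT"])
        assert nucleotide_diversity(aln) == 0.0


# ---------------------------------------------------------------------------
# Tajima's D

def _tajima_constants_oracle(n):
    """Independent transcription of the 1989 constants using Fractions."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


class TestTajimasD:
    @pytest.mark.parametrize("n", range(4, 21))
    def test_constants_match_literal_transcription(self, n):
        got = tajima_constants(n)
        want = _tajima_constants_oracle(n)
        for key, val in want.items():
            assert got[key] == pytest.approx(float(val), rel=1e-12), key

    @pytest.mark.parametrize("n", [4, 8, 15, 20])
    @pytest.mark.parametrize("S", [1, 5, 17, 30])
    def test_statistic_from_stats_matches_formula(self, n, S):
        c = _tajima_constants_oracle(n)
        khat = 1.7 * S / float(c["a1"])  # arbitrary positive k-hat
        want = (khat - S / float(c["a1"])) / math.sqrt(
            float(c["e1"]) * S + float(c["e2"]) * S * (S - 1)
        )
        assert tajimas_d_from_stats(n, S, khat) == pytest.approx(want, rel=1e-12)

    def test_no_segregating_sites_is_undefined(self):
        aln = CodingAlignment([f"s{i}" for i in range(4)], ["ACGTAA"] * 4)
        assert math.isnan(tajimas_d(aln))

    def test_hand_built_alignment(self):
        # n=4, S=3; pairwise difference counts enumerable by eye
        seqs = [
            "AAAAAAAAAA",
            "TAAAAAAAAA",
            "TCAAAAAAAA",
            "TCGAAAAAAA",
        ]
        aln = CodingAlignment(list("abcd"), seqs)
        assert segregating_sites(aln) == 3
        # pairs: ab=1 ac=2 ad=3 bc=1 bd=2 cd=1 -> mean 10/6
        assert mean_pairwise_differences(aln) == pytest.approx(10 / 6)
        c = _tajima_constants_oracle(4)
        S = 3
        want = (10 / 6 - S / float(c["a1"])) / math.sqrt(
            float(c["e1"]) * S + float(c["e2"]) * S * 2
        )
        assert tajimas_d(aln) == pytest.approx(want, rel=1e-12)

    def test_complete_deletion_drops_gapped_columns(self):
        seqs = ["A-GT", "ACGT", "ACGT", "TCGT"]
        aln = CodingAlignment(list("abcd"), seqs)
        assert segregating_sites(aln) == 1  # column 2 removed entirely


# ---------------------------------------------------------------------------
# Nei-Gojobori

def _ng_site_oracle(codon):
    """Synonymous site fraction by enumeration of all 9 single-base
    neighbours, changes to stop counted nonsynonymous."""
    aa = str(Seq(codon).translate())
    syn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if str(Seq(alt).translate()) == aa:
                syn += 1 / 3
    return syn


def _ng_pathway_oracle(c1, c2):
    """Independent pathway enumerator using Biopython translation."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results, blocked = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd, stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if str(Seq(nxt).translate()) == "*" and nxt != c2:
                stop = True
            if (str(Seq(cur).translate()) == str(Seq(nxt).translate())
                    and str(Seq(nxt).translate()) != "*"):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if stop else results).append((sd, nd))
    use = results or blocked
    return (sum(r[0] for r in use) / len(use), sum(r[1] for r in use) / len(use))


class TestNeiGojobori:
    def test_identical_sequences(self):
        cds = "ATGAAACCCGGGTTT" * 6  # 30 codons
        ka, ks, ratio = nei_gojobori(cds, cds)
        assert ka == 0 and ks == 0 and math.isnan(ratio)

    @pytest.mark.parametrize("codon", SENSE_CODONS)
    def test_sites_sum_to_three(self, codon):
        s, n = codon_sites(codon)
        assert s + n == pytest.approx(3.0)
        assert s == pytest.approx(_ng_site_oracle(codon))

    def test_single_nonsynonymous_difference(self):
        cds1 = "ATGAAACCCGGGTTTCTGCAG" + "GCT" * 23  # 30 codons
        cds2 = "ATGAAACCCGGGTTTCTGCAG" + "CCT" + "GCT" * 22  # Ala->Pro
        ka, ks, _ = nei_gojobori(cds1, cds2)
        assert ks == 0.0
        n_sites = sum(codon_sites(cds1[i:i+3])[1] for i in range(0, len(cds1), 3))
        n_sites2 = sum(codon_sites(cds2[i:i+3])[1] for i in range(0, len(cds2), 3))
        from crisprkit.popgen import jc_corrected_distance
        assert ka == pytest.approx(jc_corrected_distance(1 / ((n_sites + n_sites2) / 2)))

    def test_pathway_counts_match_independent_enumerator(self):
        rng = np.random.default_rng(23)
        for trial in range(5):
            c1 = "".join(rng.choice(list("ACGT"), 150))
            c2 = list(c1)
            for pos in rng.choice(150, size=18, replace=False):
                c2[pos] = rng.choice([b for b in "ACGT" if b != c2[pos]])
            c2 = "".join(c2)
            # drop codon pairs involving stops (precondition of the method)
            keep1, keep2 = [], []
            for i in range(0, 150, 3):
                a, b = c1[i:i+3], c2[i:i+3]
                if str(Seq(a).translate()) != "*" and str(Seq(b).translate()) != "*":
                    keep1.append(a)
                    keep2.append(b)
            s1, s2 = "".join(keep1), "".join(keep2)
            sd = nd = 0.0
            for i in range(0, len(s1), 3):
                d_s, d_n = _ng_pathway_oracle(s1[i:i+3], s2[i:i+3])
                sd += d_s
                nd += d_n
            S_sites = sum(
                (_ng_site_oracle(s1[i:i+3]) + _ng_site_oracle(s2[i:i+3])) / 2
                for i in range(0, len(s1), 3)
            )
            N_sites = len(s1) - S_sites
            from crisprkit.popgen import jc_corrected_distance
            ka, ks, _ = nei_gojobori(s1, s2)
            assert ks == pytest.approx(jc_corrected_distance(sd / S_sites))
            assert ka == pytest.approx(jc_corrected_distance(nd / N_sites))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nei_gojobori("ATGATG", "ATG")


# ---------------------------------------------------------------------------
# K2P

class TestK2P:
    def test_identical(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_known_value(self):
        # 20 sites: 2 transitions (A<->G), 1 transversion (A<->C)
        s1 = "A" * 20
        s2 = "G" * 2 + "C" + "A" * 17
        want = -0.5 * math.log(1 - 0.2 - 0.05) - 0.25 * math.log(1 - 0.1)
        assert k2p_distance(s1, s2) == pytest.approx(want)
        assert k2p_distance(s1, s2) == pytest.approx(0.17018, abs=1e-4)

    def test_saturation(self):
        s1 = "A" * 10
        s2 = "G" * 5 + "A" * 5  # P=0.5, Q=0
        with pytest.raises(SaturationError):
            k2p_distance(s1, s2)

    def test_pairwise_deletion(self):
        assert k2p_distance("ACN-", "ACGT") == 0.0


# ---------------------------------------------------------------------------
# neighbor joining

def _random_additive_tree(rng, n_leaves=5):
    """Random binary tree with positive branch lengths and its leaf
    distance matrix (additivity holds exactly)."""
    import random

    import dendropy

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_leaves)])
    tree = dendropy.simulate.treesim.pure_kingman_tree(
        taxon_namespace=taxa, pop_size=1, rng=random.Random(int(rng.integers(2**31)))
    )
    # replace coalescent branch lengths with fresh positive ones
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in taxa]
    mat = np.zeros((n_leaves, n_leaves))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            if i != j:
                mat[i, j] = pdm.distance(ti, tj)
    return tree, labels, mat


def _rf_distance(newick, ref_tree, labels):
    import dendropy

    tns = ref_tree.taxon_namespace
    tree2 = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
    tree2.encode_bipartitions()
    ref_tree.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ref_tree, tree2)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # three-point formulas: la = (dab + dac - dbc)/2, etc.
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        dm = DistanceMatrix(labels=["A", "B", "C"], values=d)
        nwk = neighbor_joining(dm)
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        lens = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
        # la=2, lb=3, lc=7 up to the placement of the root edge
        pdm = tree.phylogenetic_distance_matrix()
        t = {x.label: x for x in tree.taxon_namespace}
        assert pdm.distance(t["A"], t["B"]) == pytest.approx(5, abs=1e-4)
        assert pdm.distance(t["A"], t["C"]) == pytest.approx(9, abs=1e-4)
        assert pdm.distance(t["B"], t["C"]) == pytest.approx(10, abs=1e-4)

    def test_four_taxon_additive_recovery(self):
        # distances from tree ((A:1,B:2):1,(C:3,D:4)) with internal edge 1
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        nwk = neighbor_joining(DistanceMatrix(labels=labels, values=d))
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        t = {x.label: x for x in tree.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm.distance(t[a], t[b]) == pytest.approx(d[i, j], abs=1e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_random_five_leaf_additive_trees(self, seed):
        rng = np.random.default_rng(100 + seed)
        ref, labels, mat = _random_additive_tree(rng, 5)
        nwk = neighbor_joining(DistanceMatrix(labels=labels, values=mat))
        assert _rf_distance(nwk, ref, labels) == 0

    def test_agrees_with_skbio_on_random_matrix(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        import dendropy

        rng = np.random.default_rng(42)
        ref, labels, mat = _random_additive_tree(rng, 6)
        ours = neighbor_joining(DistanceMatrix(labels=labels, values=mat))
        theirs = str(skbio_nj(SkbioDM(mat, ids=labels)))
        tns = dendropy.TaxonNamespace(labels)
        t1 = dendropy.Tree.get(data=ours, schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=theirs, schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"], values=np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"], values=np.array([[0, -1], [-1, 0]]))

    def test_tie_break_is_lexicographic(self):
        # perfectly symmetric matrix: every Q entry ties, so the first
        # (deepest-nested) join must be the lexicographically smallest pair
        labels = ["d", "c", "b", "a"]
        mat = np.ones((4, 4)) - np.eye(4)
        nwk = neighbor_joining(DistanceMatrix(labels=labels, values=mat))
        innermost = nwk.rsplit("(", 1)[1].split(")")[0]
        joined = {part.split(":")[0] for part in innermost.split(",")}
        assert joined == {"a", "b"}


# ---------------------------------------------------------------------------
# domain scan

class TestDomainScan:
    def _aln(self, seqs, domains):
        return CodingAlignment([f"s{i}" for i in range(len(seqs))], seqs,
                               domains=domains)

    def test_single_domain_covering_everything(self):
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACGT"), 60))
        seqs = []
        for _ in range(4):
            s = list(base)
            for pos in rng.choice(60, size=4, replace=False):
                s[pos] = rng.choice([c for c in "ACGT" if c != s[pos]])
            seqs.append("".join(s))
        aln = self._aln(seqs, [("all", 1, 60)])
        rows = domain_scan(aln)
        assert [r.region_name for r in rows] == ["CDS", "all"]
        assert rows[0].pi_raw == pytest.approx(rows[1].pi_raw)
        assert rows[0].S == rows[1].S

    def test_no_domains_gives_single_row(self):
        aln = self._aln(["ACGTAA"] * 2, [])
        rows = domain_scan(aln)
        assert len(rows) == 1 and rows[0].region_name == "CDS"

    def test_elevated_domain_diversity(self):
        rng = np.random.default_rng(9)
        base = "".join(rng.choice(list("ACGT"), 300))
        seqs = []
        for _ in range(6):
            s = list(base)
            # dense differences inside positions 121..180, sparse elsewhere
            for pos in rng.choice(np.arange(120, 180), size=12, replace=False):
                s[pos] = rng.choice([c for c in "ACGT" if c != s[pos]])
            for pos in rng.choice(np.arange(0, 120), size=2, replace=False):
                s[pos] = rng.choice([c for c in "ACGT" if c != s[pos]])
            seqs.append("".join(s))
        aln = self._aln(seqs, [("Domain II", 121, 180)])
        rows = {r.region_name: r for r in domain_scan(aln)}
        assert rows["Domain II"].pi_raw > rows["CDS"].pi_raw
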