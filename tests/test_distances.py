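"""p-distances, threshold delimitation, and BSC concordance scoring."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossri import datasets
from crossri.distances import (Alignment, DistanceMatrix, bsc_partition,
                               clade_mean_distance, compare_delimitations,
                               distance_matrix, p_distance, read_alignment,
                               threshold_delimit, write_alignment)

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


class TestPDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACGT", "ACGT", 0.0),
        ("ACGT", "ACGA", 0.25),
        ("ACGT", "AC-T", 0.0),      # gap excluded, 0 over 3 sites
        ("ACGT", "ANGT", 0.0),      # ambiguity excluded
        ("AAAA", "TTTT", 1.0),
        ("acgt", "ACGA", 0.25),     # case-insensitive
    ])
    def test_known_values(self, a, b, expected):
        assert p_distance(a, b) == pytest.approx(expected)

    def test_no_comparable_sites_flagged(self):
        assert math.isnan(p_distance("--NN", "AC--"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            p_distance("ACGT", "ACG")

    def test_metric_axioms_by_enumeration(self):
        """Identity, symmetry, triangle inequality on all gap-free
        length-3 sequences over a two-letter alphabet."""
        seqs = ["".join(p) for p in itertools.product("AC", repeat=3)]
        for a, b, c in itertools.product(seqs, repeat=3):
            dab, dba = p_distance(a, b), p_distance(b, a)
            assert dab == dba
            assert (dab == 0) == (a == b)
            assert dab <= p_distance(a, c) + p_distance(c, b) + 1e-12

    def test_matches_scikit_bio_on_gapfree(self):
        from skbio.sequence import DNA
        from skbio.sequence.distance import hamming
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), 60))
            b = "".join(rng.choice(list("ACGT"), 60))
            assert p_distance(a, b) == pytest.approx(
                float(hamming(DNA(a), DNA(b))), abs=1e-12)


class TestDistanceMatrix:
    def test_matrix_matches_pairwise_calls(self):
        aln = Alignment(taxa=["x", "y", "z"],
                        sequences=["ACGTACGT", "ACGAACGA", "TCG-ACGT"])
        dm = distance_matrix(aln)
        for i, j in itertools.combinations(range(3), 2):
            expected = p_distance(aln.sequences[i], aln.sequences[j])
            assert dm.d[i, j] == pytest.approx(expected)

    def test_complete_deletion_drops_gapped_columns(self):
        aln = Alignment(taxa=["x", "y", "z"],
                        sequences=["ACGT", "AC-T", "ACGA"])
        dm = distance_matrix(aln, policy="complete")
        # column 3 removed for everyone: x vs z compare A,C,T vs A,C,A
        assert dm.get("x", "z") == pytest.approx(1 / 3)

    def test_phylip_and_fasta_round_trip(self, tmp_path):
        aln = Alignment(taxa=["x", "y"], sequences=["ACGT", "ACGA"])
        fasta = tmp_path / "aln.fasta"
        write_alignment(aln, fasta)
        again = read_alignment(fasta)
        assert again.taxa == aln.taxa and again.sequences == aln.sequences
        dm = distance_matrix(aln)
        phy = tmp_path / "d.phy"
        dm.write_phylip(phy)
        lines = phy.read_text().splitlines()
        assert lines[0].strip() == "2"
        assert float(lines[1].split()[2]) == pytest.approx(0.25)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(taxa=["a", "b"], d=np.array([[0, 0.5], [0.4, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(taxa=["a", "b"], d=np.array([[0, 1.5], [1.5, 0]]))


class TestCladeMeans:
    def test_homogeneous_two_clade_case(self):
        # identical within, 10% between by construction
        a = "A" * 90 + "C" * 10
        b = "A" * 100
        aln = Alignment(taxa=["a1", "a2", "b1", "b2"],
                        sequences=[a, a, b, b],
                        clade_of={"a1": "A", "a2": "A",
                                  "b1": "B", "b2": "B"})
        dm = distance_matrix(aln)
        assert clade_mean_distance(dm, "A", "B") == pytest.approx(0.10)
        assert clade_mean_distance(dm, "A") == 0.0

    def test_singleton_within_clade_flagged(self):
        aln = Alignment(taxa=["a1", "b1"], sequences=["ACGT", "ACGA"],
                        clade_of={"a1": "A", "b1": "B"})
        dm = distance_matrix(aln)
        assert math.isnan(clade_mean_distance(dm, "A"))

    def test_simulated_divergence_recovered(self):
        from crossri.simulate import simulate_alignment
        target = 0.072
        aln = simulate_alignment(8, length=658, between_divergence=target,
                                 within_divergence=0.0, seed=12)
        dm = distance_matrix(aln)
        # dominant noise: site flips along the two ancestor branches
        se = math.sqrt(target * (1 - target) / 658)
        assert clade_mean_distance(dm, "A", "B") == pytest.approx(
            target, abs=2 * se)


class TestThresholdDelimit:
    def _dm(self, dab=0.028, dac=0.072, dbc=0.072):
        d = np.array([[0, dab, dac], [dab, 0, dbc], [dac, dbc, 0]])
        return DistanceMatrix(taxa=["A", "B", "C"], d=d)

    def test_barcode_threshold_splits_all(self):
        assert threshold_delimit(self._dm(), 0.02) == {"A": 0, "B": 1, "C": 2}

    def test_intermediate_threshold_by_chain_oracle(self):
        clusters = threshold_delimit(self._dm(), 0.03)
        assert clusters["A"] == clusters["B"] != clusters["C"]

    def test_threshold_above_max_gives_one_cluster(self):
        assert set(threshold_delimit(self._dm(), 0.5).values()) == {0}

    def test_invariant_to_taxon_order(self):
        dm = self._dm()
        perm = [2, 0, 1]
        dm2 = DistanceMatrix(taxa=[dm.taxa[i] for i in perm],
                             d=dm.d[np.ix_(perm, perm)])
        a = threshold_delimit(dm, 0.03)
        b = threshold_delimit(dm2, 0.03)
        partition_a = {frozenset(t for t in a if a[t] == v)
                       for v in set(a.values())}
        partition_b = {frozenset(t for t in b if b[t] == v)
                       for v in set(b.values())}
        assert partition_a == partition_b

    @given(st.lists(st.floats(0.0, 0.3, allow_nan=False), min_size=6,
                    max_size=6),
           st.floats(0.01, 0.3), st.floats(0.0, 0.2))
    @settings(derandomize=True, max_examples=100)
    def test_raising_threshold_never_splits(self, dists, thr, bump):
        n = 4
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = dists
        d += d.T
        dm = DistanceMatrix(taxa=list("WXYZ"), d=d)
        lo = threshold_delimit(dm, thr)
        hi = threshold_delimit(dm, min(0.999, thr + bump))
        assert len(set(hi.values())) <= len(set(lo.values()))


class TestConcordance:
    def test_study_conflict_pattern(self):
        """Strains 2.8% apart in the barcode but freely interbreeding are
        split by the 2% rule yet lumped by the BSC; a 7.2% pair with
        near-complete isolation is split by both."""
        taxa = ["BIR", "STU", "CAN"]
        iso = {("BIR", "STU"): -0.2785, ("STU", "BIR"): 0.1436,
               ("CAN", "STU"): 0.8319, ("STU", "CAN"): 0.9651}
        bsc = bsc_partition(taxa, iso, threshold=0.8)
        assert bsc["BIR"] == bsc["STU"] != bsc["CAN"]
        d = np.array([[0, 0.028, 0.08], [0.028, 0, 0.072], [0.08, 0.072, 0]])
        dm = DistanceMatrix(taxa=taxa, d=d)
        for thr in (0.02, 0.022):
            rep = compare_delimitations(threshold_delimit(dm, thr), bsc)
            assert rep.barcode_split_bsc_lumped == [("BIR", "STU")]
            assert rep.barcode_lumped_bsc_split == []

    def test_identical_partitions_fully_concordant(self):
        part = {"a": 0, "b": 0, "c": 1}
        rep = compare_delimitations(part, dict(part))
        assert rep.concordant and rep.rand_index == 1.0

    def test_rand_index_matches_sklearn(self):
        from sklearn.metrics import rand_score
        bc = {"a": 0, "b": 0, "c": 1, "d": 2, "e": 2}
        bsc = {"a": 0, "b": 1, "c": 1, "d": 2, "e": 2}
        rep = compare_delimitations(bc, bsc)
        taxa = sorted(bc)
        ref = rand_score([bc[t] for t in taxa], [bsc[t] for t in taxa])
        assert rep.rand_index == pytest.approx(ref)

    def test_domain_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_delimitations({"a": 0}, {"b": 0})

    def test_pairs_without_isolation_data_stay_split(self):
        bsc = bsc_partition(["X", "Y"], {}, threshold=0.8)
        assert bsc["X"] != bsc["Y"]

    def test_one_direction_above_threshold_splits(self):
        iso = {("X", "Y"): 0.1, ("Y", "X"): 0.95}
        bsc = bsc_partition(["X", "Y"], iso, threshold=0.8)
        assert bsc["X"] != bsc["Y"]
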