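import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from moadecon import chemtarget as ct


class TestFingerprint:
    def test_deterministic_for_identical_smiles(self):
        a = ct.fingerprint("CCO")
        b = ct.fingerprint("CCO")
        assert a.bits == b.bits and a.nbits == 2048
        assert a.source == "structure"

    def test_canonicalisation_invariance(self):
        """Different SMILES spellings of one molecule give identical bits."""
        for smi1, smi2 in [("OCC", "CCO"), ("c1ccccc1C", "Cc1ccccc1"),
                           ("C(=O)(O)C", "CC(O)=O")]:
            assert ct.fingerprint(smi1).bits == ct.fingerprint(smi2).bits

    def test_different_molecules_differ(self):
        assert ct.fingerprint("C").bits != ct.fingerprint("CCO").bits

    def test_unparseable_smiles_raises(self):
        with pytest.raises(ct.SmilesParseError, match="position"):
            ct.fingerprint("C1CC")  # unclosed ring

    def test_hex_round_trip(self):
        fp = ct.fingerprint("c1ccccc1O", nbits=512)
        again = ct.Fingerprint.from_hex(fp.to_hex())
        assert again.bits == fp.bits and again.nbits == 512


class TestTanimoto:
    def fp(self, bits, nbits=64):
        return ct.Fingerprint(bits=frozenset(bits), nbits=nbits, source="synthetic")

    def test_worked_example(self):
        assert ct.tanimoto(self.fp({1, 2}), self.fp({2, 3, 4})) == 0.25

    def test_identical_fingerprints(self):
        assert ct.tanimoto(self.fp({1, 5, 9}), self.fp({1, 5, 9})) == 1.0

    def test_both_empty_defined_as_zero(self):
        assert ct.tanimoto(self.fp(set()), self.fp(set())) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ct.tanimoto(self.fp({1}), self.fp({1}, nbits=128))

    @settings(derandomize=True, max_examples=100)
    @given(
        st.sets(st.integers(0, 63), max_size=64),
        st.sets(st.integers(0, 63), max_size=64),
    )
    def test_matches_bit_loop_oracle(self, a_bits, b_bits):
        a, b = self.fp(a_bits), self.fp(b_bits)
        inter = union = 0
        for i in range(64):
            ai, bi = i in a_bits, i in b_bits
            inter += ai and bi
            union += ai or bi
        expected = inter / union if union else 0.0
        assert ct.tanimoto(a, b) == pytest.approx(expected)
        assert ct.tanimoto(b, a) == ct.tanimoto(a, b)


def corpus(rows):
    return pd.DataFrame(
        rows, columns=["compound_id", "fingerprint_hex", "target_id", "activity_uM"]
    )


class TestPredictTargets:
    def make_neighbours(self):
        """Query with 63 bits; neighbours at exact Tanimoto 0.8/0.4/0.2."""
        rng = np.random.default_rng(0)
        query = ct.Fingerprint(bits=frozenset(range(63)), nbits=512, source="synthetic")
        sims = {"nbr_a": 0.8, "nbr_b": 0.4, "nbr_c": 0.2}
        fps = {cid: ct.neighbour_fingerprint(query, s, rng=rng) for cid, s in sims.items()}
        for cid, s in sims.items():
            assert ct.tanimoto(query, fps[cid]) == pytest.approx(s)
        return query, fps

    def test_similarity_weighted_vote(self):
        query, fps = self.make_neighbours()
        c = corpus(
            [
                ("nbr_a", fps["nbr_a"].to_hex(), "T1", 0.5),    # active at 1 uM
                ("nbr_b", fps["nbr_b"].to_hex(), "T1", 50.0),   # inactive at 1 uM
                ("nbr_c", fps["nbr_c"].to_hex(), "T1", 0.5),    # active at 1 uM
            ]
        )
        out = ct.predict_targets(query, c, thresholds=(1.0,), k=3)
        assert out.loc[0, "probability"] == pytest.approx(1.0 / 1.4)
        assert out.loc[0, "nn_id"] == "nbr_a"
        assert out.loc[0, "nn_similarity"] == pytest.approx(0.8)

    def test_all_inactive_neighbours_give_zero(self):
        query, fps = self.make_neighbours()
        c = corpus(
            [(cid, fp.to_hex(), "T1", 500.0) for cid, fp in fps.items()]
        )
        out = ct.predict_targets(query, c, thresholds=(1.0,), k=3)
        assert out.loc[0, "probability"] == 0.0

    def test_query_duplicate_in_corpus_dominates(self):
        query, fps = self.make_neighbours()
        c = corpus(
            [
                ("twin", query.to_hex(), "T1", 0.1),
                ("nbr_c", fps["nbr_c"].to_hex(), "T1", 500.0),
            ]
        )
        out = ct.predict_targets(query, c, thresholds=(1.0,), k=2)
        assert out.loc[0, "nn_id"] == "twin"
        assert out.loc[0, "nn_similarity"] == 1.0
        assert out.loc[0, "probability"] == pytest.approx(1.0 / 1.2)

    def test_invariant_to_duplicating_the_corpus(self):
        query, fps = self.make_neighbours()
        rows = [
            ("nbr_a", fps["nbr_a"].to_hex(), "T1", 0.5),
            ("nbr_b", fps["nbr_b"].to_hex(), "T1", 50.0),
        ]
        once = ct.predict_targets(query, corpus(rows), thresholds=(1.0,), k=5)
        twice = ct.predict_targets(query, corpus(rows * 2), thresholds=(1.0,), k=5)
        pd.testing.assert_frame_equal(once, twice)

    def test_activity_threshold_direction(self):
        """Active means potency at most the threshold: a 5 uM record is
        active at 10 and 100 uM but not at 0.1 or 1 uM."""
        query, fps = self.make_neighbours()
        c = corpus([("nbr_a", fps["nbr_a"].to_hex(), "T1", 5.0)])
        out = ct.predict_targets(query, c, k=1).set_index("threshold_uM")
        assert out.loc[0.1, "probability"] == 0.0
        assert out.loc[1.0, "probability"] == 0.0
        assert out.loc[10.0, "probability"] == 1.0
        assert out.loc[100.0, "probability"] == 1.0

    def test_empty_corpus_rejected(self):
        query, _ = self.make_neighbours()
        with pytest.raises(ValueError):
            ct.predict_targets(query, corpus([]))

    def test_planted_target_recovered_top1_across_seeds(self):
        """On synthetic corpora with actives planted among high-similarity
        neighbours, the planted target ranks first by probability."""
        from moadecon import synth

        net = synth.simulate_network(20, 3, 0.3, seed=0)
        hits = 0
        for seed in range(20):
            ann = synth.simulate_annotations(net, {"G0001": 1}, seed=seed)
            out = ct.predict_targets(ann.query_fingerprint, ann.bioactivity)
            best = out.groupby("target_id")["probability"].max().idxmax()
            hits += best == ann.planted_target
        assert hits >= 18


class TestApplicabilityPercentile:
    def test_matches_direct_reimplementation(self):
        rng = np.random.default_rng(9)
        train = [ct.random_fingerprint(128, density=0.15, rng=rng) for _ in range(12)]
        query = ct.random_fingerprint(128, density=0.15, rng=rng)
        k = 4

        def stat(fp, others):
            sims = sorted((ct.tanimoto(fp, o) for o in others), reverse=True)
            return float(np.mean(sims[:k]))

        ref = [stat(t, train[:i] + train[i + 1:]) for i, t in enumerate(train)]
        qstat = stat(query, train)
        expected = 100.0 * np.mean([r <= qstat for r in ref])
        assert ct.applicability_percentile(query, train, k=k) == pytest.approx(expected)

    def test_member_of_tight_cluster_scores_high(self):
        rng = np.random.default_rng(1)
        centre = ct.random_fingerprint(256, density=0.15, rng=rng)
        train = [ct.neighbour_fingerprint(centre, 0.85, rng=rng) for _ in range(8)]
        assert ct.applicability_percentile(centre, train, k=3) >= 50.0

    def test_orthogonal_query_scores_zero(self):
        """A query sharing no bits with a self-similar training set sits
        below every reference statistic."""
        rng = np.random.default_rng(2)
        centre = ct.Fingerprint(bits=frozenset(range(30)), nbits=256, source="synthetic")
        train = [ct.neighbour_fingerprint(centre, 0.6, rng=rng) for _ in range(8)]
        used = frozenset().union(*(t.bits for t in train))
        query = ct.Fingerprint(
            bits=frozenset(range(200, 220)) - used, nbits=256, source="synthetic"
        )
        assert query.bits and not (query.bits & used)
        assert ct.applicability_percentile(query, train, k=3) == 0.0


class TestUnboundCmax:
    def test_worked_pharmacokinetic_example(self):
        assert ct.unbound_cmax(125.0, 0.08) == pytest.approx(10.0)

    def test_fully_unbound_identity(self):
        assert ct.unbound_cmax(42.0, 1.0) == 42.0

    def test_zero_concentration(self):
        assert ct.unbound_cmax(0.0, 0.5) == 0.0

    @pytest.mark.parametrize("cmax,fu", [(-1.0, 0.5), (10.0, -0.1), (10.0, 1.5)])
    def test_invalid_inputs(self, cmax, fu):
        with pytest.raises(ValueError):
            ct.unbound_cmax(cmax, fu)
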