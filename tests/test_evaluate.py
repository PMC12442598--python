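"""Sequence statistics against brute-force oracles on enumerable fixtures."""

import math

import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from prolatent import evaluate as ev
from prolatent.seqdata import Alphabet

LOG20 = math.log(20.0)


class TestMSAProfile:
    def test_gap_filter_removes_high_gap_columns(self):
        rows = ["A-KV", "A--V", "A--V", "A-KV"]       # col 1: 100% gap, col 2: 50%
        msa = ev.MSAProfile(rows)
        assert msa.kept_columns.tolist() == [0, 2, 3]

    def test_ragged_rows_rejected(self):
        with pytest.raises(ev.MetricError):
            ev.MSAProfile(["MKV", "MK"])
        with pytest.raises(ev.MetricError):
            ev.MSAProfile([])


class TestEntropyProfile:
    def test_closed_forms(self):
        """Fully conserved -> 0; uniform over 20 -> 1; 50/50 -> log20(2)."""
        conserved = ev.MSAProfile(["A", "A", "A"])
        se, _ = ev.entropy_profile(conserved)
        assert se[0] == pytest.approx(0.0, abs=1e-9)

        uniform = ev.MSAProfile(list("ACDEFGHIKLMNPQRSTVWY"))
        se, _ = ev.entropy_profile(uniform)
        assert se[0] == pytest.approx(1.0, abs=1e-9)

        half = ev.MSAProfile(["A", "A", "C", "C"])
        se, _ = ev.entropy_profile(half)
        assert se[0] == pytest.approx(math.log(2) / LOG20, abs=1e-9)

    def test_brute_force_oracle_on_random_alignment(self, rng):
        residues = Alphabet().residues
        rows = ["".join(rng.choice(list(residues), 5)) for _ in range(4)]
        se, _ = ev.entropy_profile(ev.MSAProfile(rows))
        for j in range(5):
            col = [r[j] for r in rows]
            expected = -sum((col.count(a) / 4) * math.log(col.count(a) / 4) / LOG20
                            for a in set(col))
            assert se[j] == pytest.approx(expected, abs=1e-9)

    def test_gaps_excluded_and_renormalized(self):
        # threshold 1.0 keeps even the all-gap column, exercising the flag
        msa = ev.MSAProfile(["A-", "A-", "C-", "--"], gap_threshold=1.0)
        se, empty = ev.entropy_profile(msa)
        # column 0: A,A,C over non-gaps -> entropy of (2/3, 1/3)
        expected = -(2 / 3 * math.log(2 / 3) + 1 / 3 * math.log(1 / 3)) / LOG20
        assert se[0] == pytest.approx(expected, abs=1e-9)
        assert empty.tolist() == [False, True] and se[1] == 0.0

    def test_bounds_hold(self, rng):
        rows = ["".join(rng.choice(list(Alphabet().residues), 8))
                for _ in range(6)]
        se, _ = ev.entropy_profile(ev.MSAProfile(rows))
        assert ((se >= 0) & (se <= 1)).all()


class TestEntropyCompare:
    def test_identical_profiles(self):
        mse, r = ev.entropy_compare([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert mse == 0.0 and r == pytest.approx(1.0)

    def test_constant_offset(self):
        a = np.array([0.1, 0.5, 0.9])
        mse, r = ev.entropy_compare(a, a + 0.2)
        assert mse == pytest.approx(0.04)
        assert r == pytest.approx(1.0)

    def test_hand_profile(self):
        mse, _ = ev.entropy_compare([0.0, 0.5, 1.0], [0.0, 1.0, 0.5])
        assert mse == pytest.approx(1 / 6)

    def test_constant_profile_gives_nan_r(self):
        mse, r = ev.entropy_compare([0.5, 0.5], [0.5, 0.5])
        assert mse == 0.0 and math.isnan(r)

    def test_length_mismatch(self):
        with pytest.raises(ev.MetricError):
            ev.entropy_compare([0.1], [0.1, 0.2])


class TestLogoMatrix:
    def test_single_sequence_one_hot(self):
        logo = ev.logo_matrix(ev.MSAProfile(["MKV"]))
        assert logo.shape == (3, 20)
        assert (logo.max(axis=1) == 1.0).all()
        assert np.allclose(logo.sum(axis=1), 1.0)

    def test_rows_normalized(self, rng):
        rows = ["".join(rng.choice(list(Alphabet().residues), 6))
                for _ in range(5)]
        logo = ev.logo_matrix(ev.MSAProfile(rows))
        np.testing.assert_allclose(logo.sum(axis=1), 1.0, atol=1e-9)

    def test_consistent_with_entropy_profile(self, rng):
        """Recomputing entropy from the logo matrix reproduces the profile."""
        rows = ["".join(rng.choice(list("ACDE"), 7)) for _ in range(6)]
        msa = ev.MSAProfile(rows)
        logo = ev.logo_matrix(msa)
        se, _ = ev.entropy_profile(msa)
        p = np.where(logo > 0, logo, 1.0)
        recomputed = -(logo * np.log(p) / LOG20).sum(axis=1)
        np.testing.assert_allclose(se, recomputed, atol=1e-12)


class TestPairFreq:
    def test_identical_alignments_correlate_perfectly(self, rng):
        rows = ["".join(rng.choice(list("ACDEF"), 4)) for _ in range(5)]
        a, b = ev.MSAProfile(rows), ev.MSAProfile(list(rows))
        assert ev.pairfreq_correlation(a, b) == pytest.approx(1.0)

    def test_brute_force_oracle_two_sequences(self):
        """Direct enumeration over all position pairs of two length-3
        alignments."""
        rows_a = ["MKV", "MKA"]
        rows_b = ["MAV", "MKV"]

        def stack(rows):
            n, L = len(rows), len(rows[0])
            out = np.zeros((n, L * L))
            for s, seq in enumerate(rows):
                for i in range(L):
                    for j in range(L):
                        pair = (seq[i], seq[j])
                        count = sum((r[i], r[j]) == pair for r in rows)
                        out[s, i * L + j] = count / n
            return out

        expected = np.corrcoef(stack(rows_a).mean(axis=0),
                               stack(rows_b).mean(axis=0))[0, 1]
        got = ev.pairfreq_correlation(ev.MSAProfile(rows_a),
                                      ev.MSAProfile(rows_b))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_bounded_and_length_checked(self, rng):
        rows_a = ["".join(rng.choice(list("ACD"), 3)) for _ in range(4)]
        rows_b = ["".join(rng.choice(list("ACD"), 3)) for _ in range(4)]
        r = ev.pairfreq_correlation(ev.MSAProfile(rows_a), ev.MSAProfile(rows_b))
        assert -1.0 <= r <= 1.0
        with pytest.raises(ev.MetricError):
            ev.pairfreq_correlation(ev.MSAProfile(["MK"]), ev.MSAProfile(["MKV"]))


class TestIdentity:
    def test_identical_and_disjoint(self):
        assert ev.sequence_identity("MKV", "MKV") == 100.0
        assert ev.sequence_identity("MKV", "ACD") == 0.0

    def test_two_thirds(self):
        assert ev.sequence_identity("MKV", "MRV") == pytest.approx(200 / 3)

    def test_pads_ignored_in_aligned_mode(self):
        assert ev.sequence_identity("MK..", "MK..") == 100.0
        assert ev.sequence_identity("MKV.", "MKA.") == pytest.approx(200 / 3)

    def test_global_mode_handles_length_difference(self):
        assert ev.sequence_identity("MKVA", "MKA", mode="global") > 0
        assert ev.sequence_identity("MKV", "MKV", mode="global") == 100.0

    def test_errors(self):
        with pytest.raises(ev.MetricError):
            ev.sequence_identity("", "MK")
        with pytest.raises(ev.MetricError):
            ev.sequence_identity("MK", "MKV", mode="aligned")


class TestMinHamming:
    def test_subset_gives_zero(self):
        mean, sd, d = ev.min_hamming(["MKV", "ACD"], ["MKV", "ACD", "WWW"])
        assert mean == 0.0 and sd == 0.0

    def test_disjoint_alphabets_give_one(self):
        mean, _, _ = ev.min_hamming(["AAA"], ["WWW", "YYY"])
        assert mean == 1.0

    def test_hand_case(self):
        mean, _, d = ev.min_hamming(["AAAA"], ["AAAT", "CCCC"])
        assert mean == pytest.approx(0.25)

    def test_pads_compared_as_symbols(self):
        # "MK" padded to length 3 differs from "MKV" at the pad position
        mean, _, _ = ev.min_hamming(["MK"], ["MKV"])
        assert mean == pytest.approx(1 / 3)

    def test_empty_reference_rejected(self):
        with pytest.raises(ev.MetricError):
            ev.min_hamming(["MK"], [])


class TestReconKL:
    def test_identical_composition_zero(self):
        assert ev.recon_kl(["MKV"], ["KVM"]) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative(self, rng):
        res = list(Alphabet().residues)
        gen = ["".join(rng.choice(res, 6)) for _ in range(4)]
        ref = ["".join(rng.choice(res, 6)) for _ in range(4)]
        assert ev.recon_kl(gen, ref) >= 0.0

    def test_hand_computed_smoothed_value(self):
        """All-A generated (n=100, L=10) vs uniform reference, pseudocount 1:
        direct summation over the smoothed 20-symbol distributions."""
        gen = ["A" * 10] * 100
        ref = [Alphabet().residues] * 50          # 50 copies of all 20 residues
        p = np.ones(20)
        p[0] += 1000.0
        q = np.ones(20) + 50.0
        p /= p.sum()
        q /= q.sum()
        expected = float(np.sum(p * np.log(p / q)))
        assert ev.recon_kl(gen, ref) == pytest.approx(expected, abs=1e-12)

    def test_asymmetry_guard(self):
        """KL is directional; a constructed pair must not be symmetrized."""
        gen = ["AAAAC"]
        ref = ["ACDEF"]
        assert ev.recon_kl(gen, ref) != pytest.approx(ev.recon_kl(ref, gen))

    def test_empty_rejected(self):
        with pytest.raises(ev.MetricError):
            ev.recon_kl([], ["MK"])


class TestDiversity:
    def test_identical_sequences_one_cluster(self):
        curve = ev.diversity_curve(["MKV"] * 5, [50.0, 90.0])
        assert curve == {50.0: 1, 90.0: 1}

    def test_disjoint_sequences_all_singletons(self):
        seqs = ["AAA", "CCC", "DDD"]
        assert ev.diversity_curve(seqs, [50.0]) == {50.0: 3}

    def test_brute_force_three_sequences_at_60(self):
        """Hand-checkable: MKVA joins MKVV (75% identity >= 60), WWWW founds
        its own cluster."""
        seqs = ["MKVV", "MKVA", "WWWW"]
        clusters = ev.greedy_identity_clusters(seqs, 60.0)
        assert len(clusters) == 2
        sizes = sorted(len(c) for c in clusters)
        assert sizes == [1, 2]

    def test_count_monotone_in_threshold(self, rng):
        res = list(Alphabet().residues)
        seqs = ["".join(rng.choice(res, 10)) for _ in range(15)]
        curve = ev.diversity_curve(seqs, [20.0, 50.0, 80.0])
        assert curve[20.0] <= curve[50.0] <= curve[80.0]

    def test_invalid_inputs(self):
        with pytest.raises(ev.MetricError):
            ev.diversity_curve([], [50.0])
        with pytest.raises(ev.MetricError):
            ev.diversity_curve(["MK"], [0.0])


class TestInstabilityIndex:
    def test_homopolymer_closed_form(self):
        from prolatent._diwv import DIWV
        for r in "AW":
            L = 12
            expected = 10.0 * (L - 1) / L * DIWV[r][r]
            assert ev.instability_index(r * L) == pytest.approx(expected)

    def test_stability_flag_threshold(self):
        assert ev.is_stable("A" * 20)                 # DIWV[A][A]=1 -> index ~9.5
        assert not ev.is_stable("P" * 20)             # DIWV[P][P]=20.26 -> ~192

    def test_matches_reference_implementation(self, rng):
        """100 random sequences agree with Biopython's instability index."""
        res = list(Alphabet().residues)
        for _ in range(100):
            seq = "".join(rng.choice(res, rng.integers(5, 40)))
            ours = ev.instability_index(seq)
            ref = ProteinAnalysis(seq).instability_index()
            assert ours == pytest.approx(ref, abs=1e-6)

    def test_errors(self):
        with pytest.raises(ev.MetricError):
            ev.instability_index("A")
        with pytest.raises(ev.MetricError):
            ev.instability_index("AXA")


class TestAAEmbedding:
    def test_shapes_and_symmetry(self, trained_desk):
        corr, proj = ev.aa_embedding_correlation(
            trained_desk["ckpt"], trained_desk["train"], n_sample=32, seed=0)
        assert corr.shape == (20, 20) and proj.shape == (20, 2)
        np.testing.assert_allclose(corr, corr.T, atol=1e-10)
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-10)

    def test_interchangeable_residues_correlate(self):
        """Constructed-family oracle: when two residues substitute freely at
        every variable column, the decoder should treat them alike, so their
        embedding correlation exceeds the median off-diagonal value."""
        from prolatent.diffusion import DiffusionConfig
        from prolatent.generate import TrainConfig, train
        from prolatent.jtae import JTAEConfig
        from prolatent.synthetic import make_family_spec, sample_family

        spec = make_family_spec(length=10, n_conserved=4, seed=8)
        alpha = Alphabet()
        iK, iR = alpha.index_of("K"), alpha.index_of("R")
        for pos in range(10):
            if pos not in spec.conserved_positions:
                col = np.zeros(20)
                col[iK] = col[iR] = 0.5
                spec.pwm[pos] = col
        ds = sample_family(spec, 80, seed=8)
        jtae = JTAEConfig(embed_dim=8, model_dim=16, n_heads=2, n_layers=1,
                          latent_dim=8, decoder_layers=2, decoder_channels=8,
                          decoder_hidden=16, regressor_hidden=8)
        diff = DiffusionConfig(T=10, base_channels=4, n_levels=1, cond_dim=8)
        ckpt = train(ds, jtae, diff,
                     TrainConfig(epochs=40, batch_size=40, lr=3e-3, seed=8,
                                 detach_latents=True, val_fraction=0.0))
        corr, _ = ev.aa_embedding_correlation(ckpt, ds, n_sample=40, seed=0)
        off = corr[~np.eye(20, dtype=bool)]
        assert corr[iK, iR] > np.median(off)
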