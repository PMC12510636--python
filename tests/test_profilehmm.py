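"""Profile construction, forward/Viterbi scoring, and E-value calibration."""

import math

import numpy as np
import pytest
from scipy import stats

import coconserve as cc
from coconserve.profilehmm import (
    UNIFORM_BACKGROUND,
    _score_tables,
    default_length_sampler,
    sample_background_sequence,
)

from conftest import random_peptide, random_tiny_profile
from oracles import brute_force_forward_bits, brute_force_viterbi_bits


def single_seq_profile(seq: str, pseudocount: float = 0.0) -> cc.ProfileHMM:
    return cc.build_profile([("s0", seq)], pseudocount=pseudocount, name="single")


class TestBuildProfile:
    def test_single_ungapped_sequence_zero_pseudocount_is_indicator(self):
        seq = "MKVLYA"
        profile = single_seq_profile(seq)
        assert profile.L == len(seq)
        for k, ch in enumerate(seq):
            row = profile.match_emissions[k]
            assert row.sum() == pytest.approx(1.0)
            assert row.max() == pytest.approx(1.0)
            assert row[cc.profilehmm._AA_TO_IDX[ch]] == pytest.approx(1.0)

    def test_rows_are_distributions(self, rng):
        for _ in range(5):
            profile = random_tiny_profile(rng)
            profile.validate()  # raises on any non-normalised row

    def test_gap_heavy_column_excluded_at_half_cutoff(self):
        rows = [("a", "MKV"), ("b", "M-V"), ("c", "M-V"), ("d", "MAV")]
        profile = cc.build_profile(rows, gap_fraction_cutoff=0.5)
        # middle column has gap fraction 0.5, not < 0.5: excluded
        assert profile.L == 2

    def test_all_columns_gapped_raises(self):
        rows = [("a", "M-"), ("b", "-K")]
        with pytest.raises(ValueError, match="gap-fraction"):
            cc.build_profile(rows, gap_fraction_cutoff=0.4)

    def test_negative_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            cc.build_profile([("a", "MKV")], pseudocount=-1.0)

    def test_inconsistent_row_lengths_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            cc.build_profile([("a", "MKV"), ("b", "MK")])


class TestScoringOracle:
    def test_forward_and_viterbi_match_exhaustive_enumeration(self, rng):
        for _ in range(40):
            profile = random_tiny_profile(rng)
            for _ in range(3):
                seq = random_peptide(rng, int(rng.integers(1, 5)))
                f = cc.forward_bits(profile, seq)
                v = cc.viterbi_bits(profile, seq)
                bf = brute_force_forward_bits(profile, seq)
                bv = brute_force_viterbi_bits(profile, seq)
                assert f == pytest.approx(bf, rel=1e-9, abs=1e-9)
                assert v == pytest.approx(bv, rel=1e-9, abs=1e-9)

    def test_viterbi_never_exceeds_forward(self, rng):
        fam = cc.generate_family(
            cc.FamilySpec(gene_name="ubiG", master_length=60, n_members=6, seed=9)
        )
        profile = cc.build_profile(fam.msa[1:], name="ubiG")
        for _ in range(20):
            seq = random_peptide(rng, int(rng.integers(30, 90)))
            assert cc.viterbi_bits(profile, seq) <= cc.forward_bits(profile, seq) + 1e-6

    def test_single_path_profile_forward_equals_viterbi(self):
        # a single ungapped training sequence with zero pseudocount leaves
        # only the all-match path with nonzero probability
        seq = "MKVLYAANNG"
        profile = single_seq_profile(seq)
        f = cc.forward_bits(profile, seq)
        v = cc.viterbi_bits(profile, seq)
        assert f == pytest.approx(v, abs=1e-9)
        # and the score is the exact log-odds of that path
        assert f == pytest.approx(len(seq) * math.log2(20.0), abs=1e-9)

    def test_viterbi_alignment_path_is_all_match_on_training_sequence(self):
        seq = "MKVLYA"
        profile = single_seq_profile(seq)
        bits, path = cc.viterbi_alignment(profile, seq)
        assert bits == pytest.approx(cc.viterbi_bits(profile, seq), abs=1e-9)
        assert path == [("M", k) for k in range(1, len(seq) + 1)]

    def test_x_residue_scores_as_background(self):
        seq = "MKVLYAANNG"
        profile = single_seq_profile(seq)
        with_x = "X" + seq[1:]
        # single path: replacing a matched residue by X removes exactly its
        # log-odds contribution log2(1 / (1/20))
        assert cc.forward_bits(profile, with_x) == pytest.approx(
            cc.forward_bits(profile, seq) - math.log2(20.0), abs=1e-9
        )

    def test_mean_score_of_background_shuffles_is_negative(self, rng):
        profile = single_seq_profile("MKVLYAANNGEILDPRTQWS" * 3)
        scores = [
            cc.forward_bits(profile, random_peptide(rng, 60)) for _ in range(100)
        ]
        assert np.mean(scores) < 0.0

    def test_empty_sequence_rejected(self):
        profile = single_seq_profile("MKVLYA")
        with pytest.raises(ValueError):
            cc.forward_bits(profile, "")
        with pytest.raises(ValueError):
            cc.viterbi_bits(profile, "")

    def test_null_model_shift_changes_bits_by_predicted_constant(self):
        # log-odds linearity: with a single-path profile, swapping the null
        # (and matching insert emissions) shifts the bit score by exactly
        # sum_i log2(q(x_i) / q'(x_i))
        seq = "MKVLYAANNG"
        profile = single_seq_profile(seq)
        new_null = np.linspace(1.0, 2.0, 20)
        new_null /= new_null.sum()
        shifted = cc.ProfileHMM(
            name="shifted",
            match_emissions=profile.match_emissions.copy(),
            insert_emissions=new_null.copy(),
            transitions={k: v.copy() for k, v in profile.transitions.items()},
            null_model=new_null,
        )
        idx = [cc.profilehmm._AA_TO_IDX[ch] for ch in seq]
        predicted_shift = sum(
            math.log2(UNIFORM_BACKGROUND[i] / new_null[i]) for i in idx
        )
        assert cc.forward_bits(shifted, seq) - cc.forward_bits(profile, seq) == pytest.approx(
            predicted_shift, abs=1e-9
        )


class TestProbabilityConservation:
    def test_total_sequence_probability_matches_path_mass(self, rng):
        """Sum of P(seq | model) over every sequence of length <= 3 equals
        the total transition-path mass emitting <= 3 residues.

        Emissions are concentrated on a 4-letter sub-alphabet so the sum
        over sequence space is tractable; the path mass is enumerated over
        the transition graph alone, independent of the scoring code.
        """
        sub = "ACDE"
        conc = np.full(20, 1e-12)
        for ch in sub:
            conc[cc.profilehmm._AA_TO_IDX[ch]] = 0.25 - 4e-12
        conc /= conc.sum()
        base = random_tiny_profile(rng, max_L=2)
        profile = cc.ProfileHMM(
            name="conc",
            match_emissions=np.tile(conc, (base.L, 1)),
            insert_emissions=conc.copy(),
            transitions={k: v.copy() for k, v in base.transitions.items()},
            null_model=conc.copy(),
        )

        # path mass: enumerate transition paths with <= 3 emissions
        t = profile.transitions
        L = profile.L
        total_mass = 0.0

        def walk(state, k, emitted, prob):
            nonlocal total_mass
            if emitted > 3 or prob == 0.0:
                return
            if state == "M":
                nxt = [("M", k + 1, t["MM"][k]), ("I", k, t["MI"][k])]
                if k < L:
                    nxt.append(("D", k + 1, t["MD"][k]))
            elif state == "I":
                nxt = [("M", k + 1, t["IM"][k]), ("I", k, t["II"][k])]
                if k < L:
                    nxt.append(("D", k + 1, t["ID"][k]))
            else:
                nxt = [("M", k + 1, t["DM"][k - 1]), ("I", k, t["DI"][k - 1])]
                if k < L:
                    nxt.append(("D", k + 1, t["DD"][k - 1]))
            for s2, k2, p in nxt:
                if s2 == "M" and k2 == L + 1:
                    total_mass += prob * p
                elif s2 in ("M", "I"):
                    walk(s2, k2, emitted + 1, prob * p)
                else:
                    walk(s2, k2, emitted, prob * p)

        walk("M", 0, 0, 1.0)

        # sequence mass: forward log-odds converted back to P(seq | model)
        seq_mass = 0.0
        q = 0.25
        from itertools import product

        for length in (1, 2, 3):
            for combo in product(sub, repeat=length):
                seq = "".join(combo)
                bits = cc.forward_bits(profile, seq)
                seq_mass += (2.0**bits) * (q**length)
        # length-0 sequences cannot be scored; their only path is the
        # all-delete chain B -> D_1 -> ... -> D_L -> E
        zero_mass = t["MD"][0] * t["DM"][L - 1]
        for k in range(1, L):
            zero_mass *= t["DD"][k - 1]
        assert seq_mass + zero_mass == pytest.approx(total_mass, rel=1e-6)


class TestCalibration:
    def test_evalue_at_gumbel_location(self, calibrated_panel):
        profile = calibrated_panel["ndh"]
        c = profile.calibration
        e = cc.evalue(profile, c.gumbel_mu, db_size=1000)
        assert e == pytest.approx(1000 * (1 - math.exp(-1)), rel=1e-6)

    def test_evalue_strictly_decreasing_in_score(self, calibrated_panel):
        profile = calibrated_panel["menB"]
        c = profile.calibration
        # span the representable range of the fitted survival function
        scores = np.linspace(
            c.gumbel_mu - 3.0 / c.gumbel_lambda,
            c.gumbel_mu + 30.0 / c.gumbel_lambda,
            40,
        )
        evals = [cc.evalue(profile, s) for s in scores]
        assert all(a > b for a, b in zip(evals, evals[1:]))

    def test_calibration_reproducible_under_fixed_seed(self, marker_families):
        fam = marker_families["ubiC"]
        p1 = cc.build_profile(fam.msa[1:], name="ubiC")
        p2 = cc.build_profile(fam.msa[1:], name="ubiC")
        cc.calibrate_evalue(p1, n_random=200, seed=7)
        cc.calibrate_evalue(p2, n_random=200, seed=7)
        assert p1.calibration.gumbel_mu == p2.calibration.gumbel_mu
        assert p1.calibration.gumbel_lambda == p2.calibration.gumbel_lambda

    def test_degenerate_score_distribution_raises(self):
        # match emissions equal to the background make every residue score
        # zero log-odds; with a constant-length sampler all calibration
        # scores coincide
        profile = cc.ProfileHMM(
            name="flat",
            match_emissions=np.tile(UNIFORM_BACKGROUND, (3, 1)),
            insert_emissions=UNIFORM_BACKGROUND.copy(),
            transitions=single_seq_profile("MKV", pseudocount=0.0).transitions,
            null_model=UNIFORM_BACKGROUND.copy(),
        )
        with pytest.raises(ValueError, match="degenerate"):
            cc.calibrate_evalue(
                profile, n_random=100, length_sampler=lambda rng: 3, seed=0
            )

    def test_minimum_sample_size_enforced(self, calibrated_panel):
        profile = calibrated_panel["ndh"]
        with pytest.raises(ValueError):
            cc.calibrate_evalue(profile, n_random=50)

    def test_uncalibrated_profile_has_no_evalue(self):
        profile = single_seq_profile("MKVLYA")
        with pytest.raises(ValueError, match="not calibrated"):
            cc.evalue(profile, 10.0)


class TestSerialization:
    def test_text_round_trip_preserves_scores_and_calibration(
        self, calibrated_panel, tmp_path, rng
    ):
        profile = calibrated_panel["nuoJ"]
        path = tmp_path / "nuoJ.hmm"
        profile.to_text(path)
        back = cc.ProfileHMM.from_text(path)
        assert back.name == profile.name
        assert back.L == profile.L
        seq = random_peptide(rng, 100)
        assert cc.forward_bits(back, seq) == pytest.approx(
            cc.forward_bits(profile, seq), rel=1e-9
        )
        assert back.calibration.gumbel_mu == pytest.approx(
            profile.calibration.gumbel_mu
        )
        assert back.calibration.db_size == profile.calibration.db_size
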