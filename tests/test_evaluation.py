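"""Metric suite: mass-based residue matching, alignment identity, summaries
and the target-decoy threshold table — each checked against an independent
naive implementation."""

import itertools

import numpy as np
import pytest

from pepflow import (
    EvaluationRecord,
    Peptide,
    identity_fraction,
    match_residues,
    summarize,
    target_decoy_report,
)
from pepflow.evaluation import MatchResult, score_histogram

RESIDUES = tuple("GASPVTLINDQKEMHFRYW")


def naive_mass_match(pred, truth, vocab, residue_tol=0.1, prefix_tol=0.5):
    """Independent two-pointer re-implementation used as an oracle."""
    pm = [vocab.mass_of(t) for t in pred.tokens]
    tm = [vocab.mass_of(t) for t in truth.tokens]
    i = j = n = 0
    cp = ct = 0.0  # prefix masses before i / j
    while i < len(pm) and j < len(tm):
        if abs(pm[i] - tm[j]) < residue_tol and abs(cp - ct) <= prefix_tol:
            n += 1
            cp += pm[i]
            ct += tm[j]
            i += 1
            j += 1
        elif cp + pm[i] < ct + tm[j]:
            cp += pm[i]
            i += 1
        else:
            ct += tm[j]
            j += 1
    return n


def brute_force_identity(pred, truth):
    """Exhaustive alignment oracle: maximum number of identical residues in
    any order-preserving pairing (gap-free scoring, zero penalties)."""
    a, b = pred.tokens, truth.tokens
    best = 0
    for k in range(min(len(a), len(b)), 0, -1):
        for ia in itertools.combinations(range(len(a)), k):
            for ib in itertools.combinations(range(len(b)), k):
                if all(a[x] == b[y] for x, y in zip(ia, ib)):
                    return k / len(b)
        best = 0
    return best


def random_peptide(rng, lo=3, hi=12):
    n = int(rng.integers(lo, hi + 1))
    return Peptide(tuple(rng.choice(RESIDUES, size=n)))


class TestMatchResidues:
    def test_exact_match(self, vocab):
        p = Peptide.from_string("PEPTIDEK")
        res = match_residues(p, p, vocab)
        assert res.n_matched == 8 and res.peptide_correct

    def test_isoleucine_leucine_substitution_still_correct(self, vocab):
        pred = Peptide.from_string("PEPTIDE")
        truth = Peptide.from_string("PEPTLDE")
        res = match_residues(pred, truth, vocab)
        assert res.n_matched == 7 and res.peptide_correct

    def test_lysine_glutamine_masses_within_tolerance(self, vocab):
        # K and Q differ by 0.03638 Da < 0.1 with aligned prefixes
        pred = Peptide.from_string("PEPKIDE")
        truth = Peptide.from_string("PEPQIDE")
        res = match_residues(pred, truth, vocab)
        assert res.n_matched == 7

    def test_prefix_shift_blocks_downstream_matches(self, vocab):
        # a missing residue shifts every later prefix mass by > 0.5 Da
        pred = Peptide.from_string("PETIDE")
        truth = Peptide.from_string("PEPTIDE")
        res = match_residues(pred, truth, vocab)
        assert res.n_matched == 2
        assert not res.peptide_correct

    def test_agrees_with_naive_reference_on_random_pairs(self, vocab):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            a, b = random_peptide(rng), random_peptide(rng)
            got = match_residues(a, b, vocab)
            assert got.n_matched == naive_mass_match(a, b, vocab)
            assert got.n_matched <= min(len(a), len(b))

    def test_positional_mode_matches_index_by_index(self, vocab):
        pred = Peptide.from_string("AGAG")
        truth = Peptide.from_string("AGGA")
        res = match_residues(pred, truth, vocab, mode="position")
        assert res.n_matched == 2

    def test_match_result_invariants(self):
        with pytest.raises(ValueError):
            MatchResult(5, 3, 4)
        assert MatchResult(3, 3, 3).peptide_correct
        assert not MatchResult(3, 3, 4).peptide_correct


class TestIdentityFraction:
    def test_identical_sequences(self):
        p = Peptide.from_string("PEPTIDEK")
        assert identity_fraction(p, p) == 1.0

    def test_disjoint_alphabets(self):
        assert identity_fraction(
            Peptide.from_string("GGG"), Peptide.from_string("AAA")
        ) == 0.0

    def test_single_deletion(self):
        assert identity_fraction(
            Peptide.from_string("PEPTIE"), Peptide.from_string("PEPTIDE")
        ) == pytest.approx(6 / 7)

    def test_agrees_with_exhaustive_alignment(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            a, b = random_peptide(rng, 2, 7), random_peptide(rng, 2, 7)
            assert identity_fraction(a, b) == pytest.approx(
                brute_force_identity(a, b)
            )


class TestSummarize:
    @staticmethod
    def record(matched, predicted, true, identity, score=0.5):
        return EvaluationRecord(
            match=MatchResult(matched, predicted, true),
            identity=identity,
            score=score,
        )

    def test_all_correct_stream(self):
        recs = [self.record(7, 7, 7, 1.0) for _ in range(5)]
        rep = summarize(recs)
        assert rep["aa_precision"] == 1.0
        assert rep["peptide_precision"] == 1.0
        assert all(v == 1.0 for v in rep["identity_proportions"].values())

    def test_mixed_stream_arithmetic(self):
        recs = [
            self.record(7, 7, 7, 1.0),
            self.record(0, 7, 7, 0.0),
            self.record(7, 7, 7, 1.0),
        ]
        rep = summarize(recs)
        assert rep["aa_precision"] == pytest.approx(14 / 21)
        assert rep["peptide_precision"] == pytest.approx(2 / 3)

    def test_identity_curve_monotone_non_increasing(self, rng):
        recs = [
            self.record(3, 5, 5, float(rng.random())) for _ in range(50)
        ]
        rep = summarize(recs, thresholds=(0.9, 0.7, 0.5, 0.3, 0.1))
        values = list(rep["identity_proportions"].values())
        assert all(a <= b for a, b in zip(values, values[1:]))

    def test_peptide_precision_bounded_by_identity_proportions(self, rng):
        recs = []
        for _ in range(40):
            ok = rng.random() < 0.5
            recs.append(
                self.record(5 if ok else 2, 5, 5, 1.0 if ok else 0.4)
            )
        rep = summarize(recs, thresholds=(0.9,))
        assert rep["peptide_precision"] <= rep["identity_proportions"][0.9] + 1e-12

    def test_precision_coverage_curve_shape(self, rng):
        recs = [
            self.record(int(rng.integers(0, 6)), 5, 5, 0.5, float(rng.random()))
            for _ in range(30)
        ]
        rep = summarize(recs)
        curve = rep["precision_coverage"]
        assert curve.shape[0] == 30
        assert curve["coverage"].iloc[-1] == 1.0
        assert (curve["score_threshold"].diff().dropna() <= 1e-12).all()

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestTargetDecoy:
    def test_identical_distributions_give_half_decoy_fraction(self, rng):
        s = rng.random(2000)
        table = target_decoy_report(s, s, thresholds=(0.5, 0.2))
        np.testing.assert_allclose(table["decoy_fraction"], 0.5, atol=1e-12)

    def test_separated_distributions(self):
        table = target_decoy_report(
            np.ones(100), np.zeros(100), thresholds=(0.5,)
        )
        assert table.loc[0, "decoy_fraction"] == 0.0
        assert table.loc[0, "n_target"] == 100

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            target_decoy_report(np.array([1.5]), np.array([0.5]))

    def test_histogram_covers_unit_interval(self, rng):
        h = score_histogram(rng.random(500), n_bins=10)
        assert h["count"].sum() == 500
        assert h["bin_left"].iloc[0] == 0.0
        assert h["bin_right"].iloc[-1] == 1.0
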