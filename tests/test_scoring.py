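"""Consensus-value arithmetic, cryptic acceptor scanning and ranking."""

import dataclasses

import numpy as np
import pytest

from pcpa_screen.polya import ScreenParams
from pcpa_screen.scoring import (
    CrypticAcceptor,
    FrequencyMatrix,
    consensus_value,
    rank_cryptic_sites,
    scan_cryptic_acceptors,
)
from pcpa_screen.synthetic import sample_motif_with_cv
from reference_impl import naive_cv

TOY = FrequencyMatrix(
    name="toy2",
    freqs=(
        {"A": 0.7, "C": 0.1, "G": 0.1, "T": 0.1},
        {"A": 0.4, "C": 0.3, "G": 0.2, "T": 0.1},
    ),
)


class TestConsensusValue:
    def test_hand_computed_toy_value(self):
        # S("AG") = 0.7 + 0.2 = 0.9; S_min = 0.1 + 0.1; S_max = 0.7 + 0.4
        assert consensus_value("AG", TOY) == pytest.approx(
            100 * (0.9 - 0.2) / (1.1 - 0.2)
        )

    def test_consensus_and_anti_consensus_bounds(self, matrices):
        for m in matrices:
            assert consensus_value(m.consensus_window(), m) == pytest.approx(100.0)
            assert consensus_value(m.anti_consensus_window(), m) == pytest.approx(0.0)

    def test_range_on_random_windows(self, matrices):
        rng = np.random.default_rng(2)
        for m in matrices:
            for _ in range(500):
                w = "".join(rng.choice(list("ACGT"), size=m.width))
                cv = consensus_value(w, m)
                assert 0.0 <= cv <= 100.0
                assert cv == pytest.approx(naive_cv(w, [dict(r) for r in m.freqs]))

    def test_monotone_in_observed_base_frequency(self, matrices):
        """Raising the frequency of the observed base at any position never
        decreases the window's consensus value."""
        _, m = matrices
        rng = np.random.default_rng(3)
        w = "".join(rng.choice(list("ACGT"), size=m.width))
        base_cv = consensus_value(w, m)
        for pos in range(m.width):
            rows = [dict(r) for r in m.freqs]
            obs = w[pos]
            bump = 0.05
            others = [b for b in "ACGT" if b != obs and rows[pos][b] >= bump / 3]
            if not others or rows[pos][obs] > 0.9:
                continue
            for b in others:
                rows[pos][b] -= bump / len(others)
            rows[pos][obs] += bump
            bumped = FrequencyMatrix("bumped", tuple(rows))
            assert consensus_value(w, bumped) >= base_cv - 1e-9

    def test_invariant_under_joint_position_permutation(self, matrices):
        bm, _ = matrices
        rng = np.random.default_rng(4)
        perm = rng.permutation(bm.width)
        shuffled = FrequencyMatrix("perm", tuple(bm.freqs[i] for i in perm))
        w = "".join(rng.choice(list("ACGT"), size=bm.width))
        wp = "".join(w[i] for i in perm)
        assert consensus_value(w, bm) == pytest.approx(consensus_value(wp, shuffled))

    def test_window_with_n_rejected(self, matrices):
        bm, _ = matrices
        with pytest.raises(ValueError):
            consensus_value("N" * bm.width, bm)

    def test_wrong_width_rejected(self, matrices):
        bm, _ = matrices
        with pytest.raises(ValueError):
            consensus_value("A" * (bm.width + 1), bm)


def planted_intron(matrices, rng, dists=(30,), polya_offset=400, length=1200,
                   acceptor_band=(100.0, 100.0), branch_band=(100.0, 100.0)):
    """An intron with consensus motif pairs planted upstream of a hexamer."""
    bm, am = matrices
    seq = list("".join(rng.choice(list("CT"), size=length)))
    seq[polya_offset : polya_offset + 6] = "AATAAA"
    for dist in dists:
        j = polya_offset - dist
        a_win = sample_motif_with_cv(am, acceptor_band, rng)
        seq[j - 13 : j + 1] = a_win
        b_start = j - 30 - bm.width
        b_win = sample_motif_with_cv(bm, branch_band, rng)
        seq[b_start : b_start + bm.width] = b_win
    return "".join(seq)


class TestScanCrypticAcceptors:
    def test_planted_consensus_pair_called_at_full_score(self, matrices, params):
        rng = np.random.default_rng(8)
        bm, am = matrices
        iseq = planted_intron(matrices, rng)
        calls = scan_cryptic_acceptors(iseq, 400, params, bm, am)
        assert len(calls) == 1
        (call,) = calls
        assert call.acceptor.cv == pytest.approx(100.0)
        assert call.branch.cv == pytest.approx(100.0)
        assert call.junction_offset == 370
        assert call.dist_to_polya == 30

    def test_mutating_invariant_ag_abolishes_call(self, matrices, params):
        rng = np.random.default_rng(8)
        bm, am = matrices
        iseq = list(planted_intron(matrices, rng))
        iseq[369] = "T"  # the invariant G of the planted acceptor -> AT
        assert scan_cryptic_acceptors("".join(iseq), 400, params, bm, am) == []

    def test_region_shorter_than_matrix_width(self, matrices, params):
        bm, am = matrices
        assert scan_cryptic_acceptors("ACGT", 4, params, bm, am) == []

    def test_thresholds_act_as_pure_filters(self, matrices, params):
        rng = np.random.default_rng(9)
        bm, am = matrices
        iseq = planted_intron(
            matrices, rng, dists=(30, 120),
            acceptor_band=(55.0, 90.0), branch_band=(60.0, 95.0),
        )
        base = scan_cryptic_acceptors(iseq, 400, params, bm, am)
        strict = dataclasses.replace(
            params, acceptor_cv_threshold=70.0, branch_cv_threshold=80.0
        )
        subset = scan_cryptic_acceptors(iseq, 400, strict, bm, am)
        base_keys = {(c.junction_offset, c.acceptor.window) for c in base}
        assert {(c.junction_offset, c.acceptor.window) for c in subset} <= base_keys

    def test_matches_exhaustive_pair_scoring_on_random_sequence(
        self, matrices, params
    ):
        """Production scan equals a nested-loop rescoring of every
        (branch, acceptor) window pair on a random 2-kb sequence."""
        rng = np.random.default_rng(10)
        bm, am = matrices
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        polya_offset = 1800
        lo, hi = params.branch_spacing
        expected = []
        for start in range(0, len(seq) - am.width + 1):
            junction = start + am.width - 1
            if junction > polya_offset:
                continue
            w = seq[start : start + am.width]
            if not am.matches_required(w):
                continue
            acv = consensus_value(w, am)
            if acv < params.acceptor_cv_threshold:
                continue
            branches = []
            for gap in range(lo, hi + 1):
                b_start = junction - gap - bm.width
                if b_start < 0:
                    continue
                bwin = seq[b_start : b_start + bm.width]
                bcv = consensus_value(bwin, bm)
                if bcv >= params.branch_cv_threshold:
                    branches.append((-bcv, b_start, bwin))
            if branches:
                best = min(branches)
                expected.append((junction, w, best[1], best[2]))
        got = [
            (c.junction_offset, c.acceptor.window, c.branch.start, c.branch.window)
            for c in scan_cryptic_acceptors(seq, polya_offset, params, bm, am)
        ]
        assert got == expected


class TestRanking:
    def test_rank_order_follows_distance_to_polya(self, matrices, params):
        rng = np.random.default_rng(12)
        bm, am = matrices
        iseq = planted_intron(matrices, rng, dists=(30, 120, 260))
        ranked = rank_cryptic_sites(scan_cryptic_acceptors(iseq, 400, params, bm, am))
        assert [(c.rank, c.dist_to_polya) for c in ranked] == [
            (1, 30), (2, 120), (3, 260),
        ]

    def test_masking_rank1_promotes_rank2(self, matrices, params):
        rng = np.random.default_rng(12)
        bm, am = matrices
        iseq = planted_intron(matrices, rng, dists=(30, 120, 260))
        ranked = rank_cryptic_sites(scan_cryptic_acceptors(iseq, 400, params, bm, am))
        masked = list(iseq)
        masked[ranked[0].junction_offset - 1] = "T"  # destroy rank 1's AG
        reranked = rank_cryptic_sites(
            scan_cryptic_acceptors("".join(masked), 400, params, bm, am)
        )
        assert reranked[0].junction_offset == ranked[1].junction_offset
        assert reranked[0].rank == 1

    def test_single_site_gets_rank_one(self, matrices, params):
        rng = np.random.default_rng(13)
        bm, am = matrices
        iseq = planted_intron(matrices, rng, dists=(60,))
        ranked = rank_cryptic_sites(scan_cryptic_acceptors(iseq, 400, params, bm, am))
        assert [c.rank for c in ranked] == [1]

    def test_empty_input(self):
        assert rank_cryptic_sites([]) == []
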