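"""Binomial significance machinery, candidate enumeration and greedy extraction."""

import math

import numpy as np
import pytest

from peakmotifs import (
    BonferroniContext,
    EncodedSequenceSet,
    MarkovBackground,
    MotifDiscovery,
    apply_bonferroni,
    candidate_count_uniform,
    count_abundance,
    enumerate_candidates,
    log10_binomial_tail,
    motif_space_size,
)


class TestBinomialTail:
    # expected values frozen from an exact arbitrary-precision summation
    @pytest.mark.parametrize(
        "n,N,q,expected",
        [
            (3345, 5000, 764 / 5000, -1471.5369811050625),
            (50, 200, 0.1, -9.0373473751931887),
            (3, 10, 0.2, -0.49187382555021024),
            (180, 500, 0.0778, -70.351701293821457),
            (40, 60, 0.35, -6.2279602625132684),
            (120, 200, 1 / 3, -13.952882043520054),
        ],
    )
    def test_matches_high_precision_oracle(self, n, N, q, expected):
        assert log10_binomial_tail(n, N, q) == pytest.approx(expected, rel=1e-6)

    def test_trivial_values(self):
        assert log10_binomial_tail(0, 5000, 0.15) == 0.0
        assert log10_binomial_tail(1, 1, 0.5) == pytest.approx(math.log10(0.5))

    def test_degenerate_q_rejected(self):
        for q in (0.0, 1.0):
            with pytest.raises(ValueError):
                log10_binomial_tail(5, 10, q)

    def test_strictly_decreasing_in_n(self):
        vals = [log10_binomial_tail(n, 300, 0.12) for n in range(0, 301, 10)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_moderate_tail_matches_direct_sum(self):
        from scipy import stats

        direct = math.log10(stats.binom.sf(24, 100, 0.2) + stats.binom.pmf(24, 100, 0.2))
        assert log10_binomial_tail(24, 100, 0.2) == pytest.approx(direct, rel=1e-9)


class TestBonferroni:
    def test_identity_and_cap(self):
        assert apply_bonferroni(-10.0, BonferroniContext(1)) == -10.0
        assert apply_bonferroni(-0.5, BonferroniContext(100)) == 0.0

    def test_worked_example_scale(self):
        lp = log10_binomial_tail(3345, 5000, 764 / 5000)
        assert apply_bonferroni(lp, int(8.6e8)) == pytest.approx(-1462.3, abs=1.0)

    def test_invalid_multiplier(self):
        with pytest.raises(ValueError):
            BonferroniContext(0)


class TestCandidates:
    def test_space_size(self):
        assert motif_space_size(8) == 15**8 == 2_562_890_625

    def test_k2_hand_computed_filter(self):
        # uniform background, L=3, q0=0.3, both strands:
        # AA: p=1/16, Q = 1-(15/16)^4 ~ 0.227 -> kept; AN: p=1/4, Q ~ 0.684 -> excluded
        cand = enumerate_candidates(2, MarkovBackground.uniform(), 3, q0=0.3, strands="both")
        got = {m.letters: q for m, q in cand.motifs()}
        assert "AA" in got and got["AA"] == pytest.approx(1 - (15 / 16) ** 4, rel=1e-12)
        assert "AN" not in got
        assert "NN" not in got  # Q = 1 never passes

    def test_enumeration_matches_closed_form_count(self):
        bg = MarkovBackground.uniform()
        for strands in ("single", "both"):
            cand = enumerate_candidates(3, bg, 20, q0=0.3, strands=strands)
            assert cand.M == candidate_count_uniform(3, 20, 0.3, strands)

    def test_candidate_fraction_monotone_in_q0(self):
        bg = MarkovBackground.uniform()
        counts = [candidate_count_uniform(4, 50, q0, "both") for q0 in (0.05, 0.1, 0.3, 0.6, 0.9)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] <= motif_space_size(4)

    def test_large_k_requires_explicit_opt_in(self):
        with pytest.raises(ValueError, match="allow_large"):
            enumerate_candidates(8, MarkovBackground.uniform(), 201)


class TestCountAbundance:
    def test_all_n_counts_every_sequence(self):
        s = EncodedSequenceSet(["ACGT", "TTTT", "GGGG"], k=2)
        assert count_abundance("NN", s) == 3

    def test_hand_count_with_reverse_strand(self):
        s = EncodedSequenceSet(["AAAA", "TTTT", "GGGG"], k=2)
        assert count_abundance("AA", s, both_strands=True) == 2
        assert count_abundance("AA", s, both_strands=False) == 1

    def test_masking_drives_count_to_zero(self):
        s = EncodedSequenceSet(["AAAA", "TTAA"], k=2)
        s.mask_motif(__import__("peakmotifs").IupacMotif("NN"))
        assert count_abundance("AA", s) == 0


class TestGreedyDiscovery:
    # q_strands="single": the expected-abundance convention of the original
    # GPU tool, which keeps short motifs testable at this tiny scale
    PARAMS = dict(
        k=3, f0=0.05, q0=0.8, p0=1e-3, q_strands="single",
        background="uniform", method="exhaustive",
    )

    def test_deterministic_reruns(self, mini_fixture):
        d1 = MotifDiscovery(**self.PARAMS).fit(mini_fixture.sequences)
        d2 = MotifDiscovery(**self.PARAMS).fit(mini_fixture.sequences)
        assert d1.report_.equals(d2.report_)

    def test_reported_stats_reproducible_from_mask_replay(self, mini_fixture):
        """Replaying the masking sequence reproduces each motif's recorded n."""
        disc = MotifDiscovery(**self.PARAMS, max_iterations=6).fit(mini_fixture.sequences)
        replay = EncodedSequenceSet(mini_fixture.sequences, k=3)
        for stat in disc.motifs_:
            n = count_abundance(stat.motif, replay, both_strands=True)
            assert n == stat.n
            assert stat.F == stat.n / stat.N
            replay.mask_motif(stat.motif, both_strands=True)

    def test_selection_satisfies_criterion_strictly(self, mini_fixture):
        disc = MotifDiscovery(**self.PARAMS).fit(mini_fixture.sequences)
        for stat in disc.motifs_:
            assert stat.F > self.PARAMS["f0"]
            assert stat.Q < self.PARAMS["q0"]
            assert stat.log10_p_bonf < math.log10(self.PARAMS["p0"])

    def test_masking_monotone_abundance(self, mini_fixture):
        disc = MotifDiscovery(**self.PARAMS, max_iterations=8).fit(mini_fixture.sequences)
        fresh = EncodedSequenceSet(mini_fixture.sequences, k=3)
        probe = disc.motifs_[0].motif
        last = count_abundance(probe, fresh)
        for stat in disc.motifs_:
            fresh.mask_motif(stat.motif)
            now = count_abundance(probe, fresh)
            assert now <= last
            last = now

    def test_null_sequences_yield_nothing(self, null_fixture):
        disc = MotifDiscovery(k=4, p0=1e-6, markov_order=1).fit(null_fixture.sequences)
        assert disc.motifs_ == []

    def test_bonferroni_context_frozen_across_iterations(self, mini_fixture):
        disc = MotifDiscovery(**self.PARAMS, max_iterations=5).fit(mini_fixture.sequences)
        M = disc.n_candidates_
        for stat in disc.motifs_:
            assert stat.log10_p_bonf == pytest.approx(
                min(0.0, stat.log10_p + math.log10(M)), abs=1e-12
            )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MotifDiscovery(k=2).fit(["ACGT"])
        with pytest.raises(ValueError):
            MotifDiscovery(k=3, f0=0.0).fit(["ACGT"])


class TestHillClimb:
    def test_recovers_strong_planted_word(self, rng):
        # TGACGTCA-expansion words planted in 60% of 500 uniform sequences
        from peakmotifs import PlantSpec, SyntheticSpec, generate_sequences

        spec = SyntheticSpec(
            n_sequences=500,
            length=101,
            plants=(PlantSpec("TGACGTCA", 0.6),),
            betas=(3.0, 0.5),
            seed=4,
        )
        _, seqs, _, _ = generate_sequences(spec)
        disc = MotifDiscovery(k=8, method="hillclimb", max_iterations=1, random_state=0).fit(seqs)
        assert disc.motifs_
        top = disc.motifs_[0].motif
        planted = "TGACGTCA"
        agree = max(
            sum(a == b for a, b in zip(top.letters, planted)),
            sum(a == b for a, b in zip(top.reverse_complement().letters, planted)),
        )
        assert agree >= 6
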