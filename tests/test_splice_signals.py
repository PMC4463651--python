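"""PWM training, splice-site scores, U1 duplex energy, branch sites,
percentiles and inefficiency flags."""

from __future__ import annotations

import itertools
import re

import numpy as np
import pytest

from microintron import (
    find_branch_sites,
    flag_inefficient,
    percentile_score,
    score_intron,
    ss_score,
    train_pwm,
    u1_duplex_energy,
)
from microintron.splice_signals import U1_TEMPLATE_3TO5, PwmModel

CONSENSUS_DONOR = "CAGGTAAGT"     # perfect complement of the U1 5' end


def _synthetic_donors(n=100, seed=0):
    """Donor sites drawn around the consensus with per-position noise."""
    rng = np.random.default_rng(seed)
    sites = []
    for _ in range(n):
        site = [
            b if rng.random() < 0.7 else "ACGT"[rng.integers(4)]
            for b in CONSENSUS_DONOR
        ]
        sites.append("".join(site))
    return sites


class TestTrainPwm:
    def test_degenerate_collection(self):
        pwm = train_pwm(["GTAAGT"] * 100, "donor", pseudocount=0.5)
        idx = "ACGT".index("G")
        assert pwm.freq[0, idx] > 98
        assert np.allclose(pwm.freq.sum(axis=1), 100)

    def test_uniform_collection(self):
        rng = np.random.default_rng(1)
        sites = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(2000)]
        pwm = train_pwm(sites, "donor")
        assert np.all(np.abs(pwm.freq - 25) < 4)

    def test_minimum_site_count(self):
        with pytest.raises(ValueError, match=">= 20"):
            train_pwm(["GTAAGT"] * 19, "donor")

    def test_ragged_lengths_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            train_pwm(["GTAAGT"] * 20 + ["GTAAG"], "donor")


class TestSsScore:
    def test_consensus_scores_100_anticonsensus_0(self):
        pwm = train_pwm(_synthetic_donors(), "donor")
        consensus = "".join("ACGT"[j] for j in pwm.freq.argmax(axis=1))
        anti = "".join("ACGT"[j] for j in pwm.freq.argmin(axis=1))
        assert ss_score(consensus, pwm) == pytest.approx(100.0)
        assert ss_score(anti, pwm) == pytest.approx(0.0)

    def test_value_matches_hand_summation(self):
        """Score equals the spreadsheet-style column-sum transform."""
        pwm = train_pwm(_synthetic_donors(), "donor")
        site = "CAGGTAAGT"
        t = sum(pwm.freq[i, "ACGT".index(b)] for i, b in enumerate(site))
        t_min = pwm.freq.min(axis=1).sum()
        t_max = pwm.freq.max(axis=1).sum()
        expected = 100 * (t - t_min) / (t_max - t_min)
        assert ss_score(site, pwm) == pytest.approx(expected)

    def test_monotone_in_column_frequency(self):
        """Replacing a base by one with a higher column frequency never
        decreases the score."""
        pwm = train_pwm(_synthetic_donors(), "donor")
        rng = np.random.default_rng(2)
        for _ in range(50):
            site = list("".join(rng.choice(list("ACGT"), 9)))
            pos = rng.integers(9)
            base_scores = pwm.freq[pos]
            better = "ACGT"[int(base_scores.argmax())]
            upgraded = site.copy()
            upgraded[pos] = better
            assert ss_score("".join(upgraded), pwm) >= ss_score("".join(site), pwm)

    def test_n_contributes_column_minimum(self):
        pwm = train_pwm(_synthetic_donors(), "donor")
        with_n = "NAGGTAAGT"
        worst_first = "".join("ACGT"[int(pwm.freq[0].argmin())]) + "AGGTAAGT"
        assert ss_score(with_n, pwm) == pytest.approx(ss_score(worst_first, pwm))


class TestU1DuplexEnergy:
    def test_perfect_complement_is_global_minimum(self):
        """Brute force over all 4^9 donor 9-mers: the perfect complement
        of the U1 template has the (unique) minimum energy."""
        energies = {}
        for mer in itertools.product("ACGT", repeat=9):
            s = "".join(mer)
            energies[s] = u1_duplex_energy(s)
        min_e = min(energies.values())
        argmins = [s for s, e in energies.items() if e == min_e]
        assert argmins == [CONSENSUS_DONOR]

    def test_single_mutants_strictly_weaker(self):
        e0 = u1_duplex_energy(CONSENSUS_DONOR)
        for pos in range(9):
            for b in "ACGT":
                if b == CONSENSUS_DONOR[pos]:
                    continue
                mut = CONSENSUS_DONOR[:pos] + b + CONSENSUS_DONOR[pos + 1:]
                assert u1_duplex_energy(mut) > e0

    def test_no_complementarity_gives_zero(self):
        # donor pairing nowhere with GUCCAUUCA (3'->5')
        assert u1_duplex_energy("ACAAACCAA") == 0.0

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError):
            u1_duplex_energy("NAGGTAAGT")


class TestFindBranchSites:
    def test_pattern_instance(self):
        assert find_branch_sites("gggCTGACggg") == [(3, "CTGAC")]

    def test_no_matches(self):
        assert find_branch_sites("GGGGGGGG") == []

    def test_overlapping_matches(self):
        assert find_branch_sites("TTAATTTAC") == [(0, "TTAAT"), (4, "TTTAC")]

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(4)
        oracle = re.compile(r"(?=([CT]T[ACGT]A[CT]))")
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), 60))
            expected = [(m.start(), m.group(1)) for m in oracle.finditer(seq)]
            assert find_branch_sites(seq) == expected

    def test_window_restriction(self):
        seq = "CTGAC" + "G" * 50 + "TTCAC" + "GGG"
        hits = find_branch_sites(seq, search_window=20, exclude_3p=3)
        assert hits == [(55, "TTCAC")]

    def test_window_longer_than_intron_rejected(self):
        with pytest.raises(ValueError):
            find_branch_sites("ACGT", search_window=10)


class TestPercentileScore:
    def test_extremes_and_midrank(self):
        ref = sorted([1.0, 2.0, 3.0, 4.0, 5.0])
        assert percentile_score(0.5, ref) == 0.0
        assert percentile_score(9.0, ref) == 1.0
        assert percentile_score(3.0, ref) == pytest.approx(0.5)

    def test_recovers_empirical_cdf(self):
        """Percentile of a value against its own collection matches a
        brute-force below+ties count."""
        rng = np.random.default_rng(5)
        vals = list(np.round(rng.normal(size=200), 1))
        ref = sorted(vals)
        for v in vals[:50]:
            brute = (sum(x < v for x in ref) + 0.5 * sum(x == v for x in ref)) \
                / len(ref)
            assert percentile_score(v, ref) == pytest.approx(brute)

    def test_strong_donors_beat_random(self):
        pwm = train_pwm(_synthetic_donors(), "donor")
        rng = np.random.default_rng(6)
        random_sites = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(300)]
        ref = sorted(ss_score(s, pwm) for s in random_sites)
        strong = [s for s in _synthetic_donors(seed=9)
                  if sum(a == b for a, b in zip(s, CONSENSUS_DONOR)) >= 8]
        strong_p = np.mean([percentile_score(ss_score(s, pwm), ref)
                            for s in strong])
        rand_p = np.mean([percentile_score(ss_score(s, pwm), ref)
                          for s in random_sites])
        assert strong_p > 0.9
        assert abs(rand_p - 0.5) < 0.05


class TestFlagInefficient:
    @pytest.mark.parametrize("values,expected", [
        ((0.05, 0.08), True),
        ((0.05, 0.30), False),
        ((None, None), True),
        ((None, 0.09), True),
        ((0.10, 0.01), False),      # 0.1 is not < 0.1
        ((0.5, 0.9), False),
    ])
    def test_truth_table(self, values, expected):
        assert flag_inefficient(values) is expected


class TestScoreIntron:
    def test_integrated_scoring(self):
        donors = _synthetic_donors()
        acceptors = ["TTTTTTTTTTTTCAGGT"[:16] for _ in range(30)]
        donor_pwm = train_pwm(donors, "donor")
        acceptor_pwm = train_pwm(acceptors, "acceptor")
        refs = {
            "donor_ss": sorted(ss_score(s, donor_pwm) for s in donors),
            "donor_dg": sorted(-u1_duplex_energy(s) for s in donors),
            "acceptor_ss": sorted(ss_score(s, acceptor_pwm) for s in acceptors),
            "branch": [0.0, 1.0, 2.0, 3.0, 4.0],
        }
        intron = "GTAAGT" + "G" * 30 + "CTGAC" + "TTTTT" + "CAG"
        scores = score_intron(
            ("tx", 1), CONSENSUS_DONOR, "TTTTTTTTTTTTCAGG"[:16], intron,
            donor_pwm, acceptor_pwm, references=refs)
        assert scores.donor_ss > 90
        assert scores.branch_hits
        assert set(scores.inefficient_flags) == {"donor", "acceptor"}
        assert scores.inefficient_flags["donor"] is False
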