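"""Profile-HMM correctness: exhaustive path enumeration and screening truth.

The oracle walks the full state graph (flanks N/C, uniform local entry,
match/insert/delete, fixed exit probability) recursively in probability
space, independently of the vectorised forward/Viterbi recursions.
"""

import math

import numpy as np
import pytest

from barcodekit.screen import (
    ProfileHMM,
    build_profile_hmm,
    forward_log_odds,
    screen,
    viterbi_log_odds,
)
from barcodekit.simulate import SimConfig, simulate_contaminants, simulate_dataset
from conftest import make_record

NT = "ACGT"


def enumerate_log_odds(hmm, seq):
    """Sum over all state paths by explicit recursion (oracle)."""
    x = [NT.index(c) for c in seq]
    n = len(x)
    K = hmm.n_match_states
    t = hmm.transitions
    tau = hmm.tau

    def successors(state):
        kind, k = state
        if kind == "S":
            return [(("B", None), 0.5), (("N", None), 0.5)]
        if kind == "N":
            return [(("N", None), 0.5), (("B", None), 0.5)]
        if kind == "B":
            return [(("M", k2), 1.0 / K) for k2 in range(K)]
        if kind == "M":
            if k == K - 1:
                return [(("E", None), 1.0)]
            keep = 1.0 - tau
            return [
                (("M", k + 1), keep * t[k, 0, 0]),
                (("I", k), keep * t[k, 0, 1]),
                (("D", k + 1), keep * t[k, 0, 2]),
                (("E", None), tau),
            ]
        if kind == "I":
            return [
                (("M", k + 1), t[k, 1, 0]),
                (("I", k), t[k, 1, 1]),
                (("D", k + 1), t[k, 1, 2]),
            ]
        if kind == "D":
            if k == K - 1:
                return [(("E", None), 1.0)]
            return [
                (("M", k + 1), t[k, 2, 0]),
                (("I", k), t[k, 2, 1]),
                (("D", k + 1), t[k, 2, 2]),
            ]
        if kind == "E":
            return [(("C", None), 0.5), (("T", None), 0.5)]
        if kind == "C":
            return [(("C", None), 0.5), (("T", None), 0.5)]
        raise AssertionError(state)

    def emission(state, sym):
        kind, k = state
        if kind == "M":
            return hmm.match_emissions[k, sym]
        if kind == "I":
            return hmm.insert_emissions[sym]
        if kind in ("N", "C"):
            return hmm.background[sym]
        return None  # silent

    def prob_from(state, pos):
        if state == ("T", None):
            return 1.0 if pos == n else 0.0
        total = 0.0
        for nxt, p in successors(state):
            em = emission(nxt, x[pos]) if pos < n else emission(nxt, 0)
            if em is None:  # silent successor
                total += p * prob_from(nxt, pos)
            elif pos < n:
                total += p * hmm_emit(nxt, pos) * prob_from(nxt, pos + 1)
        return total

    def hmm_emit(state, pos):
        return emission(state, x[pos])

    p = prob_from(("S", None), 0)
    null = float(np.prod([hmm.background[s] for s in x]))
    return math.log2(p / null)


def toy_hmm(K, rng, tau=0.1):
    em = rng.dirichlet(np.ones(4), size=K)
    trans = rng.dirichlet(np.ones(3), size=(max(K - 1, 0), 3))
    return ProfileHMM(
        match_emissions=em,
        insert_emissions=np.full(4, 0.25),
        background=np.full(4, 0.25),
        transitions=trans,
        tau=tau,
    )


class TestBuild:
    def test_identical_gapless_training(self):
        hmm = build_profile_hmm(["ACGT"] * 4)
        assert hmm.n_match_states == 4
        for k, base in enumerate("ACGT"):
            assert np.argmax(hmm.match_emissions[k]) == NT.index(base)

    def test_gap_heavy_column_not_a_match_state(self):
        # column 1 has 60% gaps with threshold 0.5 -> insert column
        seqs = ["A-GT", "A-GT", "A-GT", "ACGT", "ACGT"]
        hmm = build_profile_hmm(seqs)
        assert hmm.n_match_states == 3
        # exactly half gapped is also excluded (strictly-below rule)
        hmm2 = build_profile_hmm(["A-GT", "A-GT", "ACGT", "ACGT"])
        assert hmm2.n_match_states == 3

    def test_distributions_normalized(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT-"), size=20)) for _ in range(6)]
        hmm = build_profile_hmm(seqs)
        assert np.allclose(hmm.match_emissions.sum(axis=1), 1.0)
        assert np.allclose(hmm.transitions.sum(axis=2), 1.0)
        assert hmm.background.sum() == pytest.approx(1.0)

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            build_profile_hmm(["ACGT"])

    def test_all_gap_columns_rejected(self):
        with pytest.raises(ValueError, match="no column"):
            build_profile_hmm(["--", "--", "--"])

    def test_json_round_trip(self):
        hmm = build_profile_hmm(["ACGT", "AC-T", "ACGT"])
        back = ProfileHMM.from_json(hmm.to_json())
        assert np.allclose(back.match_emissions, hmm.match_emissions)
        assert np.allclose(back.transitions, hmm.transitions)


class TestForward:
    @pytest.mark.parametrize("K", [1, 2, 3])
    @pytest.mark.parametrize("L", [1, 2, 3])
    def test_forward_equals_path_enumeration(self, K, L):
        rng = np.random.default_rng(100 * K + L)
        hmm = toy_hmm(K, rng)
        for _ in range(5):
            seq = "".join(rng.choice(list(NT), size=L))
            got = forward_log_odds(hmm, seq)
            expected = enumerate_log_odds(hmm, seq)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_forward_on_trained_profile_matches_enumeration(self):
        hmm = build_profile_hmm(["AC-T", "ACGT", "A-GT"])
        for seq in ("ACG", "AGT", "TTT"):
            assert forward_log_odds(hmm, seq) == pytest.approx(
                enumerate_log_odds(hmm, seq), abs=1e-9
            )

    @pytest.mark.parametrize("K", [1, 2, 3])
    def test_viterbi_never_exceeds_forward(self, K):
        rng = np.random.default_rng(K)
        hmm = toy_hmm(K, rng)
        for L in (1, 2, 3, 5):
            seq = "".join(rng.choice(list(NT), size=L))
            assert viterbi_log_odds(hmm, seq) <= forward_log_odds(hmm, seq) + 1e-9

    def test_training_sequence_outscores_random(self):
        cfg = SimConfig(seed=41, seq_length=150)
        training = simulate_contaminants(1.0, 6, cfg, stream="contaminant-training")
        hmm = build_profile_hmm(training)
        rng = np.random.default_rng(41)
        train_score = forward_log_odds(hmm, training[0].sequence)
        rand_scores = [
            forward_log_odds(hmm, "".join(rng.choice(list(NT), size=150)))
            for _ in range(10)
        ]
        assert all(train_score > s for s in rand_scores)

    def test_invalid_symbol_rejected(self):
        hmm = build_profile_hmm(["ACGT", "ACGT"])
        with pytest.raises(ValueError):
            forward_log_odds(hmm, "AC-T")
        with pytest.raises(ValueError):
            forward_log_odds(hmm, "")


@pytest.fixture(scope="module")
def trained():
    cfg = SimConfig(
        seed=43, seq_length=200, n_genera=13, species_per_genus=2,
        individuals_per_species=1,
    )
    training = simulate_contaminants(1.0, 8, cfg, stream="contaminant-training")
    return cfg, build_profile_hmm(training), training


class TestScreen:
    def test_training_sequence_flagged(self, trained):
        cfg, hmm, training = trained
        result = screen(training[:2], hmm)
        assert len(result.flagged) == 2

    def test_divergent_plant_records_kept(self, trained):
        """Plant- vs contaminant-origin separation with planted labels.

        The two roots are 1.0 substitutions/site apart (so the families
        differ at well over 30% of columns); at the default 0-bit threshold
        no record is misassigned.
        """
        cfg, hmm, _ = trained
        plants, _ = simulate_dataset(cfg)
        contams = simulate_contaminants(1.0, 25, cfg, stream="contaminants")
        assert len(plants) >= 25
        result = screen(list(plants) + contams, hmm)
        flagged = {r.record_id for r in result.flagged}
        plant_errors = sum(1 for r in plants if r.record_id in flagged)
        contam_errors = sum(1 for r in contams if r.record_id not in flagged)
        assert plant_errors == 0 and contam_errors == 0

    def test_empty_input(self, trained):
        _, hmm, _ = trained
        result = screen([], hmm)
        assert result.kept == () and result.flagged == ()

    def test_deterministic(self, trained):
        cfg, hmm, training = trained
        r1 = screen(training, hmm)
        r2 = screen(training, hmm)
        assert r1.scores == r2.scores
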