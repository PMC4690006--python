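import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpkfamily import cpkannot, synthgen
from cpkfamily.cpkannot import (
    annotate,
    call_acylation,
    detect_ef_hands,
    physchem,
)
from cpkfamily.seqio import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def planted_window(overrides=None):
    """A 26-residue frame on neutral background with chosen 1-based residues."""
    w = ["G"] * 26
    defaults = {14: "D", 16: "D", 24: "D", 25: "E", 26: "L"}
    defaults.update(overrides or {})
    for pos, res in defaults.items():
        w[pos - 1] = res
    return "".join(w)


def brute_force_ef_hands(sequence, search_start=1):
    """Independent all-frames enumeration + greedy selection."""
    candidates = []
    for s in range(search_start - 1, len(sequence) - 26 + 1):
        w = sequence[s:s + 26]
        score = sum(
            [w[13] == "D", w[15] == "D", w[23] in "DE" or w[24] in "DE", w[25] == "L"]
        )
        if score >= 3:
            candidates.append((s, score))
    chosen = []
    for s, _score in sorted(candidates, key=lambda c: (-c[1], c[0])):
        if len(chosen) < 4 and all(abs(s - c) >= 26 for c in chosen):
            chosen.append(s)
    return sorted(c + 1 for c in chosen), [s + 1 for s, _ in candidates]


class TestDetectEfHands:
    def test_four_planted_windows_recovered(self):
        spacer = "G" * 4
        seq = spacer.join(planted_window() for _ in range(4))
        hands = detect_ef_hands(seq)
        assert [h.start for h in hands] == [1, 31, 61, 91]
        assert all(h.has_dxd and h.has_del for h in hands)
        assert [h.index for h in hands] == [1, 2, 3, 4]

    def test_disrupted_window_drops_out(self):
        spacer = "G" * 4
        windows = [planted_window() for _ in range(4)]
        windows[1] = planted_window({14: "A", 16: "A"})  # score drops to 2
        seq = spacer.join(windows)
        hands = detect_ef_hands(seq)
        assert [h.start for h in hands] == [1, 61, 91]

    def test_short_sequence_yields_empty(self):
        assert detect_ef_hands("G" * 25) == []
        assert detect_ef_hands("G" * 40, search_start=20) == []

    def test_gapped_sequence_rejected(self):
        with pytest.raises(ValueError, match="ungapped"):
            detect_ef_hands("G-" * 20)

    def test_matches_brute_force_on_random_sequences(self):
        rng = random.Random(99)
        for trial in range(30):
            seq = "".join(rng.choice(AA) for _ in range(rng.randint(30, 400)))
            expected_starts, _ = brute_force_ef_hands(seq)
            assert [h.start for h in detect_ef_hands(seq)] == expected_starts

    def test_candidate_frequency_matches_enumeration_on_long_random(self):
        rng = random.Random(7)
        seq = "".join(rng.choice(AA) for _ in range(10_000))
        _, candidates = brute_force_ef_hands(seq)
        # same rule set, evaluated through the public scorer
        ours = [
            s + 1
            for s in range(len(seq) - 26 + 1)
            if cpkannot.core_score(seq[s:s + 26]) >= 3
        ]
        assert ours == candidates

    def test_matches_brute_force_on_synthetic_cpks(self):
        for seed in range(5):
            for profile in ("higher", "lower"):
                rec, _ = synthgen.generate_cpk(profile, seed=seed, mutation_rate=0.05)
                expected, _ = brute_force_ef_hands(rec.sequence)
                assert [h.start for h in detect_ef_hands(rec.sequence)] == expected


class TestAnnotate:
    def test_clean_higher_profile_is_cpk(self):
        rec, truth = synthgen.generate_cpk("higher", seed=0, mutation_rate=0.0)
        ann = annotate(rec)
        assert ann.is_cpk
        assert ann.lineage_profile == "higher-plant"
        assert tuple(h.start for h in ann.ef_hands) == truth.ef_hand_starts

    def test_clean_lower_profile_classification(self):
        rec, _ = synthgen.generate_cpk("lower", seed=1, mutation_rate=0.0)
        ann = annotate(rec)
        assert ann.is_cpk
        assert ann.lineage_profile == "lower-eukaryote"
        assert sum(h.has_dxd for h in ann.ef_hands) == 2
        assert sum(h.has_dxxe for h in ann.ef_hands) >= 1

    def test_truncated_ef_region_rejected(self):
        rec, truth = synthgen.generate_cpk("higher", seed=2, mutation_rate=0.0)
        cut = truth.ef_hand_starts[3] - 1  # drop the fourth window
        ann = annotate(ProteinRecord(rec.id, rec.sequence[:cut]))
        assert not ann.is_cpk
        assert ann.reject_reason == cpkannot.REJECT_FEW_EFHANDS

    def test_gapped_input_is_error(self):
        with pytest.raises(ValueError, match="ungapped"):
            annotate(ProteinRecord("g", "MG-NC"))

    def test_clade_hint_restricts_catalogs(self):
        rec, _ = synthgen.generate_cpk("lower", seed=3, mutation_rate=0.0)
        assert annotate(rec).clade_used == "lower"
        hinted = annotate(rec, clade_hint="higher")
        assert hinted.clade_used == "higher"


class TestAcylation:
    def test_consensus_prefix_called(self):
        call = call_acylation("MGNCCRAAA")
        assert call.myristoylation
        assert call.palmitoylation_motif == "MGNCCR"  # longest matching prefix
        assert call.palmitoylation

    def test_no_gly2_blocks_palmitoylation(self):
        call = call_acylation("MANCCAAA")
        assert not call.myristoylation
        assert not call.palmitoylation

    def test_gly2_without_cysteines(self):
        call = call_acylation("MG")
        assert call.myristoylation
        assert not call.palmitoylation

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            call_acylation("M")

    @settings(derandomize=True, max_examples=300)
    @given(st.text(alphabet=AA, min_size=2, max_size=12))
    def test_palmitoylation_implies_myristoylation(self, seq):
        call = call_acylation(seq)
        assert call.myristoylation or not call.palmitoylation


class TestPhyschem:
    def test_diglycine_mass(self):
        profile = physchem("GG")
        assert profile.mass_kda * 1000 == pytest.approx(132.12, abs=0.01)

    def test_pi_orders_acidic_below_basic(self):
        assert physchem("D" * 20).pi < 7 < physchem("K" * 20).pi

    def test_composition_fractions(self):
        profile = physchem("LLLK")
        assert profile.composition == {"K": 0.25, "L": 0.75}
        assert sum(profile.composition.values()) == pytest.approx(1.0)

    def test_unknown_residue_leaves_mass_undefined(self):
        profile = physchem("MGXCC")
        assert profile.mass_kda is None and profile.pi is None
        assert "unknown" in profile.note
        assert profile.composition["X"] == pytest.approx(0.2)

    def test_mass_additivity_minus_water(self):
        rng = random.Random(11)
        for _ in range(10):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 30)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 30)))
            total = physchem(a + b).mass_kda * 1000
            parts = physchem(a).mass_kda * 1000 + physchem(b).mass_kda * 1000
            assert total == pytest.approx(parts - 18.0153, abs=0.01)
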