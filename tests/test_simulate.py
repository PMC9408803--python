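"""Synthetic family generator: determinism, closed-form expectations, truth."""

import numpy as np
import pytest

from allerisc.arisc import arisc_matrix
from allerisc.fasta import write_fasta
from allerisc.simulate import (
    FamilySpec,
    expected_pairwise_stats,
    generate_family,
    generate_study,
    hamming_identity,
)


class TestGenerateFamily:
    def test_full_identity_and_no_blocks_gives_clones(self):
        records, _ = generate_family(
            FamilySpec(n_members=5, length=120, target_identity=1.0, seed=4)
        )
        sequences = {r.sequence for r in records}
        assert len(sequences) == 1

    def test_identical_spec_and_seed_is_byte_deterministic(self, tmp_path):
        spec = FamilySpec(
            n_members=6,
            length=150,
            target_identity=0.8,
            planted_motifs=[("WWCHKNGGWW", 0.8)],
            tm_segments=1,
            signal_peptide=True,
            seed=99,
        )
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(generate_family(spec)[0], p1)
        write_fasta(generate_family(spec)[0], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_pairwise_identity_matches_closed_form(self):
        """Mean position-wise identity between members tracks the mutation
        model's expectation (approximately p^2 plus coincidence terms)."""
        spec = FamilySpec(
            n_members=10, length=1000, target_identity=0.7, similar_sub_fraction=0.5, seed=17
        )
        records, truth = generate_family(spec)
        expected = truth.expected["F1"]["identity"]
        observed = np.mean(
            [
                hamming_identity(records[i].sequence, records[j].sequence)
                for i in range(10)
                for j in range(i + 1, 10)
            ]
        )
        assert observed == pytest.approx(expected, abs=3.0)
        # sanity on the closed form itself: dominated by p^2
        assert expected / 100.0 == pytest.approx(0.7**2, abs=0.03)

    def test_truth_table_contains_planted_consensus_exactly(self):
        consensus = "MHYYDDKRCPWM"
        spec = FamilySpec(
            n_members=8,
            length=200,
            target_identity=0.6,
            planted_motifs=[(consensus, 1.0)],
            seed=23,
        )
        records, truth = generate_family(spec)
        by_id = {r.id: r.sequence for r in records}
        for rid, sites in truth.motif_sites.items():
            for cons, start in sites:
                assert by_id[rid][start : start + len(cons)] == cons

    def test_blocks_that_cannot_fit_are_rejected(self):
        spec = FamilySpec(
            n_members=2,
            length=70,
            target_identity=0.9,
            tm_segments=3,
            signal_peptide=True,
            seed=0,
        )
        with pytest.raises(ValueError, match="do not fit"):
            generate_family(spec)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FamilySpec(n_members=1)
        with pytest.raises(ValueError):
            FamilySpec(target_identity=0.0)
        with pytest.raises(ValueError):
            FamilySpec(planted_motifs=[("ABC", 1.0)])  # width < 6


class TestExpectedStats:
    def test_arisc_is_average_of_identity_and_similarity(self):
        for p, q in [(0.9, 0.5), (0.7, 0.0), (0.5, 1.0)]:
            e = expected_pairwise_stats(p, q)
            assert e["arisc"] == pytest.approx((e["identity"] + e["similarity"]) / 2)
            assert e["identity"] <= e["similarity"]

    def test_perfect_conservation_gives_100(self):
        e = expected_pairwise_stats(1.0, 0.5)
        assert e["identity"] == pytest.approx(100.0)
        assert e["arisc"] == pytest.approx(100.0)

    def test_more_similar_substitutions_mostly_raise_similarity(self):
        """Raising q moves substitutions into the positive-scoring partner
        sets: similarity climbs steeply, while identity rises only through
        the small coincidence term (both members hitting the same partner)."""
        low_q = expected_pairwise_stats(0.7, 0.1)
        high_q = expected_pairwise_stats(0.7, 0.9)
        sim_gain = high_q["similarity"] - low_q["similarity"]
        id_gain = high_q["identity"] - low_q["identity"]
        assert sim_gain > 20.0
        assert 0 <= id_gain < 0.2 * sim_gain


class TestGenerateStudy:
    def test_paper_like_preset_shape(self):
        records, truth = generate_study(preset="paper_like", seed=0)
        assert len(records) == 60
        sizes = {
            fam: sum(1 for f in truth.family_of.values() if f == fam)
            for fam in ("I", "II", "III", "IV")
        }
        assert sizes == {"I": 9, "II": 10, "III": 12, "IV": 29}
        assert len({r.id for r in records}) == 60

    def test_between_family_arisc_below_within(self):
        specs = [
            FamilySpec(n_members=3, length=250, target_identity=0.85, label=f"F{i + 1}")
            for i in range(2)
        ]
        records, truth = generate_study(specs=specs, seed=8)
        m = arisc_matrix(records)
        fam = [truth.family_of[i] for i in m.ids]
        n = len(m.ids)
        within = [
            m.values[i, j] for i in range(n) for j in range(i + 1, n) if fam[i] == fam[j]
        ]
        between = [
            m.values[i, j] for i in range(n) for j in range(i + 1, n) if fam[i] != fam[j]
        ]
        assert max(between) < min(within)

    def test_duplicate_family_labels_rejected(self):
        specs = [FamilySpec(label="F1"), FamilySpec(label="F1")]
        with pytest.raises(ValueError, match="collision"):
            generate_study(specs=specs, seed=0)

    def test_indels_produce_length_variation(self):
        spec = FamilySpec(
            n_members=6, length=300, target_identity=0.9, indel_rate=0.01, seed=2
        )
        records, _ = generate_family(spec)
        assert len({len(r.sequence) for r in records}) > 1
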