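"""ZOOPS EM motif discovery: planted recovery, determinism, presence."""

import numpy as np
import pytest

from allerisc.motifs import (
    MotifSearchConfig,
    discover_motifs,
    estimate_background,
    encode,
    motif_presence,
    write_meme_minimal,
)
from allerisc.records import ProteinRecord
from allerisc.simulate import FamilySpec, generate_family
from helpers import random_protein

PLANTED = "WWCHKNGGWW"


def _planted_family(seed=7, consensus=PLANTED, n=12, length=200, prob=1.0):
    spec = FamilySpec(
        n_members=n,
        length=length,
        target_identity=0.05,  # unrelated backbones; only the motif is shared
        planted_motifs=[(consensus, prob)],
        label="F1",
        seed=seed,
    )
    return generate_family(spec)


def _fast_cfg(**kw):
    return MotifSearchConfig(max_motifs=1, width_grid=(8, 10, 15), **kw)


class TestDiscovery:
    def test_recovers_planted_block_in_every_sequence(self):
        records, truth = _planted_family()
        motif = discover_motifs(records, _fast_cfg(seed=1))[0]
        assert motif.consensus == PLANTED
        assert len(motif.occurrences) == len(records)
        starts = {rid: start for rid, start, _ in motif.occurrences}
        for rid, sites in truth.motif_sites.items():
            assert starts[rid] == sites[0][1]

    def test_no_shared_block_scores_far_below_planted(self):
        rng = np.random.default_rng(13)
        noise = [
            ProteinRecord(id=f"n{i}", sequence=random_protein(rng, 200)) for i in range(12)
        ]
        records, _ = _planted_family()
        planted_llr = discover_motifs(records, _fast_cfg(seed=1))[0].log_likelihood_ratio
        found = discover_motifs(noise, _fast_cfg(seed=1))
        noise_llr = found[0].log_likelihood_ratio if found else 0.0
        assert noise_llr < 0.25 * planted_llr

    def test_same_seed_gives_identical_pwms(self):
        records, _ = _planted_family()
        m1 = discover_motifs(records, _fast_cfg(seed=5))[0]
        m2 = discover_motifs(records, _fast_cfg(seed=5))[0]
        assert np.array_equal(m1.pwm, m2.pwm)
        assert m1.occurrences == m2.occurrences

    def test_masking_lets_a_second_motif_surface(self):
        spec = FamilySpec(
            n_members=12,
            length=220,
            target_identity=0.05,
            planted_motifs=[(PLANTED, 1.0), ("MHYYDDKRCPWM", 1.0)],
            label="F1",
            seed=21,
        )
        records, _ = generate_family(spec)
        cfg = MotifSearchConfig(max_motifs=2, width_grid=(10, 12, 15))
        motifs = discover_motifs(records, cfg)
        assert len(motifs) == 2
        assert {m.consensus for m in motifs} == {PLANTED, "MHYYDDKRCPWM"}

    def test_pwm_columns_are_stochastic(self):
        records, _ = _planted_family()
        motif = discover_motifs(records, _fast_cfg(seed=2))[0]
        assert np.allclose(motif.pwm.sum(axis=0), 1.0, atol=1e-9)
        assert (motif.pwm > 0).all()

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError, match="at least 2"):
            discover_motifs([ProteinRecord(id="a", sequence="MKVLATGH")])
        short = [
            ProteinRecord(id="a", sequence="MKV"),
            ProteinRecord(id="b", sequence="MKL"),
        ]
        with pytest.raises(ValueError, match="shorter than the minimum"):
            discover_motifs(short, MotifSearchConfig())


class TestPresence:
    def test_consensus_bearing_record_is_present(self):
        records, _ = _planted_family()
        motifs = discover_motifs(records, _fast_cfg(seed=1))
        extra = ProteinRecord(
            id="extra", sequence="M" * 40 + PLANTED + "K" * 40
        )
        pres = motif_presence(list(records) + [extra], motifs)
        assert pres["motif_1"].all()

    def test_alien_composition_is_absent(self):
        records, _ = _planted_family()  # W-rich planted motif
        motifs = discover_motifs(records, _fast_cfg(seed=1))
        poly_a = ProteinRecord(id="polyA", sequence="A" * 120)
        pres = motif_presence([poly_a], motifs)
        assert not pres.loc["polyA", "motif_1"]

    def test_member_without_site_is_called_absent(self):
        records, _ = _planted_family()
        motifs = discover_motifs(records, _fast_cfg(seed=1))
        rng = np.random.default_rng(0)
        stripped = list(records)[:-1] + [
            ProteinRecord(id="free", sequence=random_protein(rng, 200))
        ]
        pres = motif_presence(stripped, motifs)
        assert not pres.loc["free", "motif_1"]
        assert pres["motif_1"][:-1].all()


class TestOutputs:
    def test_meme_minimal_format_round_readable(self, tmp_path):
        records, _ = _planted_family()
        motifs = discover_motifs(records, _fast_cfg(seed=1))
        path = tmp_path / "motifs.meme"
        write_meme_minimal(motifs, path)
        text = path.read_text()
        assert text.startswith("MEME version 4")
        assert "letter-probability matrix:" in text
        assert f"w= {motifs[0].width}" in text

    def test_background_estimation_ignores_mask(self):
        enc = [encode("AAAAXXXX"), encode("CCCC")]
        bg = estimate_background(enc, pseudocount=0.0)
        assert bg[0] == pytest.approx(0.5)  # A
        assert bg[1] == pytest.approx(0.5)  # C
        assert bg[2:].sum() == 0
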