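"""Hybridization engine: parameter tables, MFE search, and its oracle."""

import dataclasses
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antisdscan.errors import ParameterTableError
from antisdscan.thermo import (
    CANONICAL_TAIL,
    SD_TETRAMERS,
    EnergyModel,
    LoopLimits,
    derive_sd_threshold,
    duplex_mfe,
    duplex_mfe_batch,
    encode,
    enumerate_duplex_structures,
    load_energy_model,
    score_duplex,
)

rna = st.text(alphabet="ACGU", min_size=1)


class TestEnergyModel:
    def test_qualitative_stack_ordering(self, model):
        # GC-on-GC stacking is stronger than AU-on-AU; both stabilize
        gc = model.stack[1, 1]  # 5'GG3'/3'CC5' => stack[GC][GC]
        au = model.stack[4, 5]  # 5'AA3'/3'UU5' => stack[AU][UA]
        assert gc < au < 0

    def test_loop_penalties_nonnegative_nondecreasing(self, model):
        for table, first in ((model.hairpin, 3), (model.bulge, 1),
                             (model.internal, 2)):
            vals = [model.loop_size_penalty(table, s) for s in range(first, 35)]
            assert all(v >= 0 for v in vals)
            assert vals[-1] >= vals[first + 2 - first]

    def test_missing_dangle_block_defaults_to_zero(self, tmp_path, model):
        text = (
            "[pairs]\nCG GC GU UG AU UA\n[stack]\n"
            + "\n".join(" ".join(["-100"] * 6) for _ in range(6))
        )
        p = tmp_path / "mini.txt"
        p.write_text(text)
        m = load_energy_model(p)
        assert np.all(m.dangle5 == 0) and np.all(m.dangle3 == 0)

    def test_malformed_table_raises(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("[stack]\n1 2 three\n")
        with pytest.raises(ParameterTableError, match="stack"):
            load_energy_model(p)

    def test_checksum_stable(self, model):
        assert model.checksum() == load_energy_model().checksum()


class TestCalibration:
    """The engine must reproduce the reference tetramer energies against
    the canonical anti-SD tail, and the perfect-core pairing energy."""

    EXPECTED = {"AAGG": -7.1, "AGGA": -8.0, "GGAG": -9.3, "GAGG": -9.1}

    @pytest.mark.parametrize("tet", SD_TETRAMERS)
    def test_tetramer_energy(self, model, tet):
        match = duplex_mfe(tet, CANONICAL_TAIL, model)
        assert match.dg == pytest.approx(self.EXPECTED[tet], abs=0.05)

    def test_perfect_core_energy(self, model):
        match = duplex_mfe("AAGGAGG", "CCUCCUU", model)
        assert match.dg == pytest.approx(-13.2, abs=0.1)
        assert match.n_pairs == 7  # full helix, tie broken to more pairs

    def test_threshold_derivation(self, model):
        assert derive_sd_threshold(model) == pytest.approx(-8.4)
        # arithmetic is forced: mean of the four reference values
        assert round(sum(self.EXPECTED.values()) / 4, 1) == -8.4

    def test_zeroed_model_threshold(self, model):
        zero = dataclasses.replace(
            model,
            stack=np.zeros_like(model.stack),
            dangle5=np.zeros_like(model.dangle5),
            dangle3=np.zeros_like(model.dangle3),
            hairpin=np.zeros_like(model.hairpin),
            bulge=np.zeros_like(model.bulge),
            internal=np.zeros_like(model.internal),
            helix_end_blunt=0,
        )
        assert derive_sd_threshold(zero) == 0.0


class TestDuplexMFE:
    def test_no_match_is_distinct_sentinel(self, model):
        assert duplex_mfe("CCCC", "CCCC", model) is None
        assert duplex_mfe("AAA", "AAA", model) is None

    def test_single_forced_pair(self, model):
        match = duplex_mfe("A", "U", model)
        oracle = enumerate_duplex_structures("A", "U", model)
        assert match.pairs == ((0, 0),)
        assert match.dg == oracle.dg  # blunt helix ends only

    def test_structure_score_consistency(self, model):
        for q, t in [("AAGG", CANONICAL_TAIL), ("GGAGG", "CCUCCUU"),
                     ("ACGUACGU", "ACGUACGU")]:
            m = duplex_mfe(q, t, model)
            assert score_duplex(q, t, m.pairs, model) == pytest.approx(
                m.dg, abs=1e-9
            )

    def test_orientation_symmetry(self, model):
        rng = random.Random(7)
        for _ in range(25):
            q = "".join(rng.choice("ACGU") for _ in range(rng.randint(2, 8)))
            t = "".join(rng.choice("ACGU") for _ in range(rng.randint(2, 8)))
            a = duplex_mfe(q, t, model)
            b = duplex_mfe(t, q, model)
            assert (a is None) == (b is None)
            if a is not None:
                assert a.dg == pytest.approx(b.dg)

    def test_monotone_loop_relaxation(self, model):
        q, t = "GGAAACGG", "CCGUACC"
        tight = duplex_mfe(q, t, model, LoopLimits(max_bulge=1, max_internal=1))
        loose = duplex_mfe(q, t, model, LoopLimits(max_bulge=15, max_internal=15))
        assert loose.dg <= tight.dg

    def test_n_bases_are_unpairable(self, model):
        assert duplex_mfe("NNNN", "NNNN", model) is None
        with_n = duplex_mfe("AANGG", CANONICAL_TAIL, model)
        assert all(with_n.query[i] != "N" for i, _ in with_n.pairs)

    def test_rendering_mentions_energy_and_pairs(self, model):
        m = duplex_mfe("AAGGAGG", "CCUCCUU", model)
        text = m.render()
        assert "-13.2 kcal/mol" in text
        assert text.count("\n") == 4


def _random_model(rng) -> EnergyModel:
    base = load_energy_model()
    jitter = rng.integers(-80, 80, size=base.stack.shape)
    return dataclasses.replace(
        base,
        stack=(base.stack + jitter).astype(np.int32),
        dangle5=(base.dangle5 + rng.integers(-30, 30, base.dangle5.shape)).astype(np.int32),
        dangle3=(base.dangle3 + rng.integers(-30, 30, base.dangle3.shape)).astype(np.int32),
    )


class TestOracleEquivalence:
    """duplex_mfe must equal brute-force enumeration, for the shipped
    tables and for random parameter perturbations."""

    def test_random_pairs_shipped_tables(self, model):
        rng = random.Random(2024)
        checked = 0
        for _ in range(200):
            q = "".join(rng.choice("ACGU") for _ in range(rng.randint(2, 6)))
            t = "".join(rng.choice("ACGU") for _ in range(rng.randint(2, 8)))
            dp = duplex_mfe(q, t, model)
            br = enumerate_duplex_structures(q, t, model)
            assert (dp is None) == (br is None)
            if dp is not None:
                assert dp.dg == pytest.approx(br.dg, abs=1e-9), (q, t)
                checked += 1
        assert checked > 120

    def test_random_model_perturbations(self):
        nprng = np.random.default_rng(5)
        rng = random.Random(5)
        for _ in range(8):
            m = _random_model(nprng)
            for _ in range(10):
                q = "".join(rng.choice("ACGU") for _ in range(rng.randint(2, 6)))
                t = "".join(rng.choice("ACGU") for _ in range(rng.randint(2, 8)))
                dp = duplex_mfe(q, t, m)
                br = enumerate_duplex_structures(q, t, m)
                if dp is not None:
                    assert dp.dg == pytest.approx(br.dg, abs=1e-9)

    def test_batch_agrees_with_single(self, model):
        rng = random.Random(99)
        target = CANONICAL_TAIL
        windows = [
            "".join(rng.choice("ACGU") for _ in range(10)) for _ in range(60)
        ]
        batch = duplex_mfe_batch(
            np.stack([encode(w) for w in windows]), target, model
        )
        for w, cents in zip(windows, batch):
            single = duplex_mfe(w, target, model)
            assert round(single.dg * 100) == cents


@settings(max_examples=60, deadline=None)
@given(
    q=st.text(alphabet="ACGU", min_size=1, max_size=5),
    t=st.text(alphabet="ACGU", min_size=1, max_size=6),
)
def test_mfe_never_above_any_enumerated_structure(q, t):
    model = load_energy_model()
    dp = duplex_mfe(q, t, model)
    br = enumerate_duplex_structures(q, t, model)
    if br is None:
        assert dp is None
    else:
        assert dp.dg <= br.dg + 1e-9
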