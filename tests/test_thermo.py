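"""Folding backend: oracle equivalence and the four energy features."""

from __future__ import annotations

import math

import numpy as np
import pytest

from mirtarget import thermo
from mirtarget._fold import (
    FoldEngine,
    can_pair,
    encode,
    structure_energy,
)
from mirtarget.core import Utr, reverse_complement
from tests.conftest import random_rna


class TestEnergyModel:
    def test_wc_stacks_are_stabilising(self, energy_model):
        energy_model.validate()
        wc = [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")]
        idx = {"A": 0, "C": 1, "G": 2, "U": 3}
        for a, b in wc:
            for c, d in wc:
                assert energy_model.stack[idx[a], idx[b], idx[c], idx[d]] <= 0

    def test_stack_table_rotational_symmetry(self, energy_model):
        # stack(XY/WZ) == stack(ZW/YX): the same physical motif read
        # from the other strand
        t = energy_model.stack
        for x in range(4):
            for w in range(4):
                for y in range(4):
                    for z in range(4):
                        a, b = t[x, w, y, z], t[z, y, w, x]
                        assert np.isfinite(a) == np.isfinite(b)
                        if np.isfinite(a):
                            assert a == pytest.approx(b, abs=1e-9)

    def test_rt_matches_physiological_temperature(self, energy_model):
        assert energy_model.rt == pytest.approx(0.61633, abs=1e-4)


class TestEnumeration:
    def test_acgu_has_only_empty_structure(self, energy_model):
        structs = thermo.enumerate_structures("ACGU", energy_model)
        assert [pairs for pairs, _ in structs] == [()]

    def test_empty_structure_always_present(self, energy_model):
        structs = thermo.enumerate_structures("GGGAAACCC", energy_model)
        assert () in [pairs for pairs, _ in structs]

    def test_count_matches_independent_recursion(self, energy_model):
        seq = "GGGAAACCC"
        codes = encode(seq)

        def count(i, j):
            """Independent Motzkin-style recursion with min hairpin 3."""
            if i > j:
                return 1
            total = count(i + 1, j)
            for k in range(i + 4, j + 1):
                if can_pair(int(codes[i]), int(codes[k])):
                    total += count(i + 1, k - 1) * count(k + 1, j)
            return total

        structs = thermo.enumerate_structures(seq, energy_model)
        assert len(structs) == count(0, len(seq) - 1)

    def test_length_cap_enforced(self, energy_model):
        with pytest.raises(ValueError):
            thermo.enumerate_structures("A" * 15, energy_model)


class TestDgDuplex:
    def test_complementary_8mer_is_stack_sum_plus_init(self, backend, energy_model):
        a = "AGGAGGAG"
        b = reverse_complement(a)
        ca, cb = encode(a), encode(b[::-1])  # pairing partner of a[i] is b reversed
        expected = energy_model.duplex_init
        for i in range(7):
            expected += energy_model.stack_energy(
                int(ca[i]), int(cb[i]), int(ca[i + 1]), int(cb[i + 1])
            )
        res = thermo.dg_duplex(a, b, backend)
        assert res.free_energy == pytest.approx(expected, abs=1e-9)
        assert len(res.structure) == 8

    def test_no_complementarity_gives_zero_and_empty(self, backend):
        res = thermo.dg_duplex("AAAA", "AAAA", backend)
        assert res.free_energy == 0.0
        assert res.structure == []

    def test_symmetry_under_strand_swap(self, backend, rng):
        for _ in range(10):
            a = random_rna(rng, int(rng.integers(4, 9)))
            b = random_rna(rng, int(rng.integers(4, 9)))
            assert thermo.dg_duplex(a, b, backend).free_energy == pytest.approx(
                thermo.dg_duplex(b, a, backend).free_energy, abs=1e-9
            )

    def test_too_short_sequences_rejected(self, backend):
        with pytest.raises(ValueError):
            thermo.dg_duplex("A", "ACGU", backend)


class TestDgBinding:
    def test_non_interacting_pair_binds_zero(self, backend):
        assert thermo.dg_binding("AAAA", "AAAA", backend) == pytest.approx(0.0, abs=1e-6)
        assert thermo.dg_binding("AAAAA", "CCCCC", backend) == pytest.approx(0.0, abs=1e-6)

    def test_ensemble_below_mfe(self, backend):
        a = "AGGAGGAG"
        b = reverse_complement(a)
        g_ens = backend.duplex_ensemble(a, b).free_energy
        g_mfe = backend.duplex_mfe(a, b).free_energy
        assert g_ens <= g_mfe + 1e-9

    def test_matches_boltzmann_sum_on_toy_pair(self, backend, energy_model):
        a, b = "GGCAG", "CUGCC"
        structs = thermo.enumerate_structures(a, energy_model, second=b)
        rt = energy_model.rt
        z_pair = sum(math.exp(-e / rt) for _, e in structs)
        za = sum(math.exp(-e / rt) for _, e in thermo.enumerate_structures(a, energy_model))
        zb = sum(math.exp(-e / rt) for _, e in thermo.enumerate_structures(b, energy_model))
        expected = -rt * (math.log(z_pair) - math.log(za) - math.log(zb))
        assert thermo.dg_binding(a, b, backend) == pytest.approx(expected, abs=1e-6)


class TestDgOpen:
    def test_unstructured_window_opens_for_free(self, backend):
        utr = Utr("u", "A" * 60)
        assert thermo.dg_open(utr, 25, 32, backend) == pytest.approx(0.0, abs=1e-6)

    def test_always_non_negative(self, backend, rng):
        for _ in range(25):
            seq = random_rna(rng, 50)
            v = thermo.dg_open(Utr("u", seq), 20, 27, backend,
                               constraint_window=14, fold_flank=10)
            assert v >= 0.0

    def test_matches_enumeration_on_toy_window(self, backend, energy_model):
        seq = "GGCGAAAACGCC"  # 12 nt, structured
        rt = energy_model.rt
        mask = np.zeros(len(seq), dtype=bool)
        mask[4:8] = True
        z_free = sum(
            math.exp(-e / rt) for _, e in thermo.enumerate_structures(seq, energy_model)
        )
        z_con = sum(
            math.exp(-e / rt)
            for _, e in thermo.enumerate_structures(seq, energy_model, constraint_mask=mask)
        )
        expected = -rt * (math.log(z_con) - math.log(z_free))
        got = thermo.dg_open(Utr("u", seq), 4, 8, backend,
                             constraint_window=4, fold_flank=10)
        assert got == pytest.approx(expected, abs=1e-6)
        assert expected >= 0

    def test_invariant_to_flank_size_when_flanks_cannot_pair(self, backend):
        # core of C/G only, poly-A flanks: A pairs only U, so the flank
        # can never pair and must not change the opening cost
        core = "GGCCGCGGCC"
        seq = "A" * 50 + core + "A" * 50
        utr = Utr("u", seq)
        vals = [
            thermo.dg_open(utr, 52, 58, backend, constraint_window=6, fold_flank=flank)
            for flank in (5, 20, 45)
        ]
        assert vals[0] == pytest.approx(vals[1], abs=1e-9)
        assert vals[1] == pytest.approx(vals[2], abs=1e-9)

    def test_site_outside_utr_rejected(self, backend):
        with pytest.raises(ValueError):
            thermo.dg_open(Utr("u", "ACGUACGU"), 6, 12, backend)


class TestDgTotal:
    def test_definition(self):
        assert thermo.dg_total(-20.0, 5.0) == -15.0
        assert thermo.dg_total(-7.25, 0.0) == -7.25

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError):
            thermo.dg_total(None, 1.0)

    def test_recomputation_is_bit_exact(self, backend):
        utr = Utr("u", "GCGCGAUAUAACAUUCCGGCCGGAUAU")
        a = "UGGAAUGUAAAGAAGUAUGUAU"
        region = thermo.site_region(utr.seq, _site(11, 18), len(a))
        d1 = thermo.dg_duplex(a, region, backend).free_energy
        o1 = thermo.dg_open(utr, 11, 18, backend, constraint_window=10, fold_flank=10)
        d2 = thermo.dg_duplex(a, region, backend).free_energy
        o2 = thermo.dg_open(utr, 11, 18, backend, constraint_window=10, fold_flank=10)
        assert thermo.dg_total(d1, o1) == thermo.dg_total(d2, o2)


def _site(start, end):
    from mirtarget.core import TargetSite

    return TargetSite("u", "m", start, end)


class TestOracleEquivalence:
    """DP folding equals brute-force enumeration on random instances."""

    def test_mfe_and_partition_match_enumeration(self, energy_model, rng):
        engine = FoldEngine(energy_model)
        rt = energy_model.rt
        for trial in range(40):
            if trial % 2 == 0:
                seq = random_rna(rng, int(rng.integers(4, 13)))
                structs = thermo.enumerate_structures(seq, energy_model)
                e_dp, pairs = engine.mfe(encode(seq))
                z_dp = engine.partition(encode(seq))
                scored = structure_energy(encode(seq), pairs, energy_model)
            else:
                na = int(rng.integers(2, 7))
                nb = int(rng.integers(2, 13 - na))
                a, b = random_rna(rng, na), random_rna(rng, nb)
                structs = thermo.enumerate_structures(a, energy_model, second=b)
                e_dp, pairs, _ = engine.duplex_mfe(encode(a), encode(b))
                z_all = engine.duplex_partition(encode(a), encode(b))
                z_dp = z_all
                codes = np.concatenate([encode(a), encode(b)])
                scored = structure_energy(codes, pairs, energy_model, cut=na)
            e_min = min(e for _, e in structs)
            z_ref = sum(math.exp(-e / rt) for _, e in structs)
            assert e_dp == pytest.approx(e_min, abs=1e-6)
            assert z_dp == pytest.approx(z_ref, rel=1e-6)
            # the traced structure realises the reported energy
            assert scored == pytest.approx(e_dp, abs=1e-6)
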