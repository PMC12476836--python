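"""Scoring metrics vs brute-force oracles and closed-form examples."""

import gemmi
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slimpae import (
    ContactCounts,
    ResidueProfile,
    alphaslim_profile,
    contact_counts,
    mini_pae,
    min_inter_pae_profile,
    model_confidence,
    normalize_direct,
    normalize_inverse,
    score_pair,
)
from slimpae.errors import (
    ChainCountError,
    ChainLookupError,
    DegenerateInputError,
    DimensionMismatchError,
    DomainError,
)
from conftest import make_record, random_record


def brute_force_mini_pae(pae, nb):
    """Independent double loop over all inter-chain cells."""
    L = pae.shape[0]
    best = np.inf
    for i in range(L):
        for j in range(L):
            if (i < nb) != (j < nb):
                best = min(best, pae[i, j])
    return best


def brute_force_profile(pae, nb, L, chain):
    out = []
    own = range(nb, L) if chain == "B" else range(nb)
    other = range(nb) if chain == "B" else range(nb, L)
    for r in own:
        best = np.inf
        for o in other:
            best = min(best, pae[r, o], pae[o, r])
        out.append(best)
    return np.array(out)


class TestModelConfidence:
    @pytest.mark.parametrize(
        "ptm,iptm,expected", [(1.0, 1.0, 1.0), (0.0, 0.0, 0.0), (0.5, 0.75, 0.7)]
    )
    def test_weighted_combination(self, ptm, iptm, expected):
        assert model_confidence(ptm, iptm) == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_on_unit_square(self, ptm, iptm):
        assert 0.0 <= model_confidence(ptm, iptm) <= 1.0

    @pytest.mark.parametrize("ptm,iptm", [(-0.1, 0.5), (0.5, 1.2)])
    def test_domain_error(self, ptm, iptm):
        with pytest.raises(DomainError):
            model_confidence(ptm, iptm)


class TestMiniPAE:
    def test_planted_inter_block_minimum(self):
        pae = np.ones((4, 4))
        pae[0:2, 2:4] = [[12.0, 9.5], [30.0, 28.0]]
        pae[2:4, 0:2] = 20.0
        assert mini_pae(make_record(pae)).value == 9.5

    def test_constant_matrix(self):
        assert mini_pae(make_record(np.full((4, 4), 15.0))).value == 15.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        rec = random_record(rng, 25, 15)
        assert mini_pae(rec).value == pytest.approx(
            brute_force_mini_pae(rec.pae, 25)
        )

    def test_matches_brute_force_at_L200(self, rng):
        rec = random_record(rng, 120, 80)
        assert mini_pae(rec).value == pytest.approx(
            brute_force_mini_pae(rec.pae, 120)
        )

    def test_invariant_under_chain_block_swap(self, rng):
        rec = random_record(rng, 12, 8)
        perm = np.r_[np.arange(12, 20), np.arange(0, 12)]
        swapped = make_record(
            rec.pae[np.ix_(perm, perm)], chain_lengths=(8, 12),
            plddt=rec.plddt[perm],
        )
        assert mini_pae(swapped).value == mini_pae(rec).value

    def test_single_chain_rejected(self):
        rec = make_record(np.full((4, 4), 5.0), chain_lengths=(4,), chain_ids=("A",))
        with pytest.raises(ChainCountError):
            mini_pae(rec)


class TestMinInterPaeProfile:
    def test_planted_stripe(self):
        pae = np.full((30, 30), 25.0)
        nb = 20
        pae[:nb, :nb] = 1.0
        pae[nb:, nb:] = 1.0
        pae[nb + 7 : nb + 12, :nb] = 2.0  # candidate residues 8-12
        prof = min_inter_pae_profile(
            make_record(pae, chain_lengths=(20, 10)), "B"
        )
        expected = np.full(10, 25.0)
        expected[7:12] = 2.0
        np.testing.assert_array_equal(prof.values, expected)

    def test_profile_min_equals_mini_pae(self, rng):
        rec = random_record(rng, 18, 12)
        prof_b = min_inter_pae_profile(rec, "B")
        assert prof_b.values.min() == pytest.approx(mini_pae(rec).value)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("chain", ["A", "B"])
    def test_matches_brute_force(self, seed, chain):
        rng = np.random.default_rng(100 + seed)
        rec = random_record(rng, 20, 10)
        prof = min_inter_pae_profile(rec, chain)
        np.testing.assert_allclose(
            prof.values, brute_force_profile(rec.pae, 20, 30, chain)
        )

    def test_unknown_chain(self, rng):
        rec = random_record(rng, 5, 5)
        with pytest.raises(ChainLookupError):
            min_inter_pae_profile(rec, "Z")


class TestAlphaSLiM:
    @staticmethod
    def _profiles(bound, unbound, counts):
        return (
            ResidueProfile("B", np.asarray(bound, float)),
            ResidueProfile("B", np.asarray(unbound, float)),
            ContactCounts("B", np.asarray(counts, int)),
        )

    def test_formula(self):
        b, u, n = self._profiles([80, 60], [60, 60], [5, 0])
        prof = alphaslim_profile(b, u, n)
        np.testing.assert_array_equal(prof.values, [100.0, 0.0])
        assert prof.kind == "alphaslim"

    def test_zero_contacts_zero_score(self):
        b, u, n = self._profiles([90, 95], [10, 20], [0, 0])
        assert not alphaslim_profile(b, u, n).values.any()

    def test_equal_plddt_zero_score(self):
        b, u, n = self._profiles([70, 70], [70, 70], [3, 7])
        assert not alphaslim_profile(b, u, n).values.any()

    def test_odd_in_plddt_difference(self, rng):
        bound = rng.uniform(0, 100, 12)
        unbound = rng.uniform(0, 100, 12)
        counts = rng.integers(0, 6, 12)
        b, u, n = self._profiles(bound, unbound, counts)
        fwd = alphaslim_profile(b, u, n).values
        rev = alphaslim_profile(u, b, n).values
        np.testing.assert_allclose(fwd, -rev)

    def test_length_mismatch(self):
        b, u, n = self._profiles([80, 60], [60], [5, 0])
        with pytest.raises(DimensionMismatchError):
            alphaslim_profile(b, u, n)


def write_two_chain_pdb(path, bait_xyz, cand_xyz_per_res):
    """Tiny CA-only PDB: bait chain A atom list, candidate chain B with one
    CA per residue."""
    st_ = gemmi.Structure()
    model = gemmi.Model("1")
    chain_a = gemmi.Chain("A")
    for i, pos in enumerate(bait_xyz):
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*pos)
        res.add_atom(atom)
        chain_a.add_residue(res)
    chain_b = gemmi.Chain("B")
    for i, pos in enumerate(cand_xyz_per_res):
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*pos)
        res.add_atom(atom)
        chain_b.add_residue(res)
    model.add_chain(chain_a)
    model.add_chain(chain_b)
    st_.add_model(model)
    st_.setup_entities()
    st_.write_pdb(str(path))
    return path


class TestContactCounts:
    def test_distant_chains_all_zero(self, tmp_path):
        path = write_two_chain_pdb(
            tmp_path / "far.pdb",
            [(0, 0, 0), (4, 0, 0)],
            [(0, 100, 0), (4, 100, 0)],
        )
        assert not contact_counts(path, "B").counts.any()

    def test_single_contact_at_three_angstrom(self, tmp_path):
        path = write_two_chain_pdb(
            tmp_path / "one.pdb",
            [(0, 0, 0)],
            [(0, 3.0, 0), (0, 50, 0)],
        )
        np.testing.assert_array_equal(
            contact_counts(path, "B", cutoff=4.0).counts, [1, 0]
        )

    @pytest.mark.parametrize("k", [1, 3, 6])
    def test_k_bait_atoms_in_range_count_k(self, tmp_path, k):
        bait = [(0.5 * i, 2.0, 0) for i in range(k)] + [(0, 200, 0)]
        path = write_two_chain_pdb(tmp_path / f"k{k}.pdb", bait, [(0, 0, 0)])
        # brute-force expectation: distances 2..sqrt((0.5(k-1))^2+4) all <= 4
        expected = sum(
            1 for x, y, z in bait if (x**2 + y**2 + z**2) ** 0.5 <= 4.0
        )
        assert contact_counts(path, "B", cutoff=4.0).counts[0] == expected == k

    def test_monotone_in_cutoff(self, tmp_path, rng):
        bait = [tuple(p) for p in rng.uniform(-6, 6, (15, 3))]
        cand = [tuple(p) for p in rng.uniform(-6, 6, (8, 3))]
        path = write_two_chain_pdb(tmp_path / "rand.pdb", bait, cand)
        prev = None
        for cutoff in (2.0, 4.0, 8.0, 16.0):
            counts = contact_counts(path, "B", cutoff=cutoff).counts
            if prev is not None:
                assert np.all(counts >= prev)
            prev = counts

    def test_missing_chain(self, tmp_path):
        path = write_two_chain_pdb(tmp_path / "x.pdb", [(0, 0, 0)], [(5, 0, 0)])
        with pytest.raises(ChainLookupError):
            contact_counts(path, "C")


class TestNormalization:
    def test_direct_examples(self):
        np.testing.assert_allclose(
            normalize_direct([2, 4, 8]), [0.25, 0.5, 1.0]
        )
        np.testing.assert_allclose(normalize_direct([5]), [1.0])

    @given(
        st.lists(st.floats(0.01, 1e4), min_size=1, max_size=30),
        st.floats(0.01, 100),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_direct_scale_invariant_and_max_one(self, values, c):
        base = normalize_direct(values)
        assert base.max() == pytest.approx(1.0)
        np.testing.assert_allclose(
            normalize_direct(np.asarray(values) * c), base, rtol=1e-9
        )

    def test_direct_degenerate(self):
        with pytest.raises(DegenerateInputError):
            normalize_direct([0.0, 0.0])
        with pytest.raises(DegenerateInputError):
            normalize_direct([])

    def test_inverse_as_printed(self):
        # inv = [0.5, 0.25]; norm = (inv - 0.25) / 0.5
        np.testing.assert_allclose(normalize_inverse([2, 4]), [0.5, 0.0])

    def test_inverse_worst_maps_to_zero_best_below_one(self):
        out = normalize_inverse([1.0, 3.0, 9.0])
        assert out[np.argmax([1.0, 3.0, 9.0])] == 0.0
        # best score maps to (inv_max - inv_min)/inv_max, not 1
        assert out[0] == pytest.approx((1.0 - 1 / 9) / 1.0)
        assert out[0] < 1.0

    def test_inverse_identical_values_all_zero(self):
        np.testing.assert_array_equal(normalize_inverse([7.0, 7.0, 7.0]), 0.0)

    def test_inverse_domain_error(self):
        with pytest.raises(DomainError):
            normalize_inverse([2.0, 0.0])
        with pytest.raises(DegenerateInputError):
            normalize_inverse([2.0])


class TestScorePair:
    def test_mc_and_minipae_always_computed(self):
        pae = np.full((4, 4), 10.0)
        pae[0, 3] = 3.1
        rec = make_record(pae, ptm=0.8, iptm=0.9)
        pair = score_pair(rec)
        assert pair.value("MC") == pytest.approx(0.88)
        assert pair.value("MiniPAE") == pytest.approx(3.1)

    def test_alphaslim_absent_without_monomer(self):
        pair = score_pair(make_record(np.full((4, 4), 10.0)))
        assert "AlphaSLiM_max" not in pair.metrics

    def test_ingested_metric_echoed_not_derived(self):
        pair = score_pair(
            make_record(np.full((4, 4), 10.0)), ingested={"MinD": 4.2}
        )
        assert pair.metrics["MinD"].value == 4.2
        assert pair.metrics["MinD"].derived is False

    def test_alphaslim_from_monomer_and_contacts(self):
        pae = np.full((4, 4), 10.0)
        rec = make_record(pae, plddt=[80, 80, 75, 40])
        mono = ResidueProfile("B", [50.0, 40.0])
        cc = ContactCounts("B", [2, 1])
        pair = score_pair(rec, monomer_plddt=mono, contacts=cc)
        # residues: bound [75, 40] - unbound [50, 40] times N [2, 1]
        assert pair.value("AlphaSLiM_max") == pytest.approx(50.0)
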