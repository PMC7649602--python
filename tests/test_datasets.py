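"""Interface truth construction: disruption, contacts, filters, grouping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thoipakit import errors
from thoipakit.datasets import (
    ContactMap,
    MutagenesisRecord,
    TMDRecord,
    call_interface_etra,
    call_interface_structure,
    classify_residue_groups,
    contact_symmetry_fraction,
    helix_orientation,
    interchain_contacts,
    position_disruption,
    read_mutagenesis_tsv,
    write_mutagenesis_tsv,
    xray_inclusion_filter,
)
from thoipakit.synthetic_fixtures import synth_helix_dimer


def _rec(pos=1, w=1.0, m=0.5, wt="L"):
    return MutagenesisRecord("X", pos, wt, "A", w, m)


class TestDisruption:
    @pytest.mark.parametrize(
        "w,m,expected",
        [
            (1.0, 0.76, 0.24),
            (1.0, 1.30, -0.30),  # increased dimerisation gives negative disruption
            (2.0, 1.0, 0.5),
        ],
    )
    def test_single_mutation_disruption(self, w, m, expected):
        assert _rec(w=w, m=m).disruption == pytest.approx(expected)

    def test_position_mean_over_mutations(self):
        recs = [_rec(pos=3, m=0.9), _rec(pos=3, m=0.5)]  # d = 0.1 and 0.5
        (pd_,) = position_disruption(recs)
        assert pd_.position == 3
        assert pd_.d_bar == pytest.approx(0.3)
        assert pd_.n == 2

    def test_wildtype_signal_must_be_positive(self):
        with pytest.raises(errors.InvalidSignalError):
            _rec(w=0.0)

    def test_sequence_validation(self):
        with pytest.raises(IndexError):
            position_disruption([_rec(pos=9)], sequence="LLL")
        with pytest.raises(ValueError):
            position_disruption([_rec(pos=1, wt="G")], sequence="LLL")

    def test_empty_records_rejected(self):
        with pytest.raises(errors.EmptyDataError):
            position_disruption([])

    def test_tsv_round_trip(self, tmp_path):
        recs = [_rec(pos=1, m=0.8), _rec(pos=2, m=1.1, wt="I")]
        path = tmp_path / "mut.tsv"
        write_mutagenesis_tsv(recs, path)
        back = read_mutagenesis_tsv(path)
        assert [(r.position, r.w, r.m) for r in back] == [(1, 1.0, 0.8), (2, 1.0, 1.1)]


class TestInterfaceCallEtra:
    def _positions(self, dbars):
        return [
            type("P", (), {"position": i + 1, "d_bar": d})()
            for i, d in enumerate(dbars)
        ]

    def test_all_zero_profile_gives_empty_interface(self):
        mask = call_interface_etra(self._positions([0.0] * 8), 8)
        assert not mask.any()

    def test_cutoff_boundary_is_inclusive(self):
        mask = call_interface_etra(self._positions([0.24]), 5)
        assert mask[0]

    def test_threshold_scan(self):
        # 20-residue profile with exactly 5 positions above the default cutoff
        rng = np.random.default_rng(3)
        dbars = rng.uniform(0, 0.2, 20)
        hot = rng.choice(20, 5, replace=False)
        dbars[hot] = rng.uniform(0.3, 0.8, 5)
        mask = call_interface_etra(self._positions(dbars), 20)
        # oracle: plain comparison scan
        assert mask.sum() == 5
        assert np.array_equal(np.flatnonzero(mask), np.sort(hot))

    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=30), st.floats(0, 0.9))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_monotone_in_cutoff(self, dbars, cutoff):
        lo = call_interface_etra(self._positions(dbars), len(dbars), cutoff)
        hi = call_interface_etra(self._positions(dbars), len(dbars), cutoff + 0.05)
        # raising the cutoff never adds interface residues
        assert not (hi & ~lo).any()

    def test_empty_positions_rejected(self):
        with pytest.raises(errors.EmptyDataError):
            call_interface_etra([], 10)


def _brute_force_contacts(chain_a, chain_b, d_max=3.5):
    """Independent O(N^2) all-atom-pairs oracle."""
    import biotite.structure as struc

    a = chain_a[np.char.upper(chain_a.element.astype("U3")) != "H"]
    b = chain_b[np.char.upper(chain_b.element.astype("U3")) != "H"]

    def ranks(atoms):
        starts = list(struc.get_residue_starts(atoms)) + [atoms.array_length()]
        out = np.empty(atoms.array_length(), int)
        for r, (s, e) in enumerate(zip(starts, starts[1:]), start=1):
            out[s:e] = r
        return out

    ra, rb = ranks(a), ranks(b)
    pairs = set()
    for i in range(a.array_length()):
        for j in range(b.array_length()):
            if np.linalg.norm(a.coord[i] - b.coord[j]) < d_max:
                pairs.add((int(ra[i]), int(rb[j])))
    return pairs


class TestContacts:
    def _two_atom_chains(self, distance):
        import biotite.structure as struc

        atoms = struc.AtomArray(2)
        atoms.chain_id[:] = ["A", "B"]
        atoms.res_id[:] = [1, 1]
        atoms.res_name[:] = "LEU"
        atoms.atom_name[:] = "CA"
        atoms.element[:] = "C"
        atoms.coord[0] = (0, 0, 0)
        atoms.coord[1] = (distance, 0, 0)
        return atoms[atoms.chain_id == "A"], atoms[atoms.chain_id == "B"]

    def test_pair_below_threshold_is_contact(self):
        a, b = self._two_atom_chains(3.4)
        assert interchain_contacts(a, b).pairs == {(1, 1)}

    def test_pair_at_exact_threshold_is_not_contact(self):
        a, b = self._two_atom_chains(3.5)
        assert interchain_contacts(a, b).pairs == set()

    def test_hydrogens_excluded(self):
        a, b = self._two_atom_chains(3.0)
        b.element[:] = "H"
        with pytest.raises(errors.EmptyStructureError):
            interchain_contacts(a, b)

    @pytest.mark.parametrize("separation,phase", [(10.0, 0.0), (9.6, 35.0), (11.0, 180.0)])
    def test_matches_brute_force_oracle(self, separation, phase):
        atoms, _ = synth_helix_dimer(18, separation=separation, phase_deg=phase)
        a = atoms[atoms.chain_id == "A"]
        b = atoms[atoms.chain_id == "B"]
        cmap = interchain_contacts(a, b)
        assert cmap.pairs == _brute_force_contacts(a, b)

    def test_interface_call_from_pairs(self):
        mask = call_interface_structure(ContactMap(pairs={(5, 5), (5, 6)}), 10)
        assert np.flatnonzero(mask).tolist() == [4, 5]

    def test_empty_map_gives_all_false(self):
        assert not call_interface_structure(ContactMap(pairs=set()), 12).any()

    def test_chain_swap_symmetry(self):
        atoms, _ = synth_helix_dimer(20)
        a = atoms[atoms.chain_id == "A"]
        b = atoms[atoms.chain_id == "B"]
        m_ab = call_interface_structure(interchain_contacts(a, b), 20)
        m_ba = call_interface_structure(interchain_contacts(b, a), 20)
        assert np.array_equal(m_ab, m_ba)

    def test_planted_mask_recovered(self):
        atoms, planted = synth_helix_dimer(24)
        a = atoms[atoms.chain_id == "A"]
        b = atoms[atoms.chain_id == "B"]
        called = call_interface_structure(interchain_contacts(a, b), 24)
        assert np.array_equal(called, planted)


class TestXrayFilter:
    @pytest.mark.parametrize(
        "resolution,orientation,n_iface,keep,reason",
        [
            (3.6, "parallel", 6, False, "resolution"),
            (2.0, "parallel", 3, False, "too_few_interface_residues"),
            (2.0, "antiparallel", 6, False, "orientation"),
            (3.5, "parallel", 4, True, "ok"),
        ],
    )
    def test_rules(self, resolution, orientation, n_iface, keep, reason):
        assert xray_inclusion_filter(resolution, orientation, n_iface) == (keep, reason)

    def test_unknown_orientation(self):
        with pytest.raises(errors.OrientationError):
            xray_inclusion_filter(2.0, "sideways", 5)

    def test_orientation_from_axes(self):
        atoms, _ = synth_helix_dimer(20)
        anti, _ = synth_helix_dimer(20, antiparallel=True)
        ca = lambda arr, c: arr[(arr.chain_id == c) & (arr.atom_name == "CA")].coord
        assert helix_orientation(ca(atoms, "A"), ca(atoms, "B")) == "parallel"
        assert helix_orientation(ca(anti, "A"), ca(anti, "B")) == "antiparallel"


class TestResidueGroups:
    def test_partition_and_assignment(self):
        atoms, planted = synth_helix_dimer(20)
        a = atoms[atoms.chain_id == "A"]
        b = atoms[atoms.chain_id == "B"]
        # a third, non-partner chain touching residue 3 of chain A only
        import biotite.structure as struc

        other = struc.AtomArray(1)
        other.chain_id[:] = "C"
        other.res_id[:] = 1
        other.res_name[:] = "GLY"
        other.atom_name[:] = "CA"
        other.element[:] = "C"
        other.coord[0] = a.coord[(a.res_id == 3) & (a.atom_name == "CB")][0] + [0, 0, 1.0]
        groups = classify_residue_groups(a, b, other_chains=[other])
        assert len(groups) == 20
        assert set(groups) <= {"A", "B", "C"}
        # homotypic contacts win over heterotypic; planted mask residues are group A
        assert np.array_equal(groups == "A", planted)
        assert groups[2] == ("A" if planted[2] else "C")

    def test_missing_partner(self):
        atoms, _ = synth_helix_dimer(20)
        with pytest.raises(errors.ConfigurationError):
            classify_residue_groups(atoms[atoms.chain_id == "A"], None)


class TestSymmetry:
    def test_perfectly_symmetric_map(self):
        mask = np.zeros(10, bool)
        mask[[2, 5, 8]] = True
        cmap = ContactMap(pairs={(3, 3), (6, 6), (9, 9)})
        assert contact_symmetry_fraction(cmap, mask) == 1.0

    def test_long_range_only(self):
        mask = np.zeros(10, bool)
        mask[[0, 5]] = True
        cmap = ContactMap(pairs={(1, 6), (6, 1)})
        assert contact_symmetry_fraction(cmap, mask) == 0.0

    def test_hand_enumerated_toy(self):
        mask = np.zeros(8, bool)
        mask[[2, 6]] = True  # residues 3 and 7
        cmap = ContactMap(pairs={(3, 3), (3, 7), (7, 3)})
        assert contact_symmetry_fraction(cmap, mask) == pytest.approx(0.5)

    def test_no_interface_is_undefined(self):
        with pytest.raises(errors.UndefinedMetricError):
            contact_symmetry_fraction(ContactMap(pairs={(1, 2)}), np.zeros(5, bool))


class TestRecordValidation:
    def test_rejects_bad_sequence(self):
        with pytest.raises(ValueError):
            TMDRecord(id="x", subset="ETRA", sequence="LLXZ")

    def test_rejects_mask_length_mismatch(self):
        with pytest.raises(ValueError):
            TMDRecord(id="x", subset="NMR", sequence="LLL", interface_mask=[True])
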