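"""Interface contact map construction and the CMS collective variable."""

import re

import numpy as np
import pytest

from cmsrefine import (
    Ensemble,
    build_cmif,
    cms_value,
    detect_interface_contacts,
    export_plumed,
    make_toy_complex,
    switching_D,
)
from cmsrefine.contacts import InterfaceContactMap, read_contact_map, write_contact_map
from cmsrefine.fixtures import FixtureSpec
from cmsrefine.structure import AtomRecord, ComplexStructure

from conftest import random_rotation


def _two_residue_complex(distance: float) -> ComplexStructure:
    """One receptor and one ligand residue with Cα atoms ``distance`` apart."""
    atoms = [
        AtomRecord("A", 1, "ALA", "CA", "C", np.zeros(3)),
        AtomRecord("B", 1, "ALA", "CA", "C", np.array([distance, 0.0, 0.0])),
    ]
    return ComplexStructure(atoms, {"A"}, {"B"})


class TestDetectInterfaceContacts:
    def test_strictly_below_cutoff(self):
        assert len(detect_interface_contacts(_two_residue_complex(7.9))) == 1
        assert len(detect_interface_contacts(_two_residue_complex(8.0))) == 0  # boundary excluded

    def test_matches_brute_force_double_loop(self, truth):
        found = detect_interface_contacts(truth, cutoff=8.0)
        rkeys, rxyz = truth.ca_table("receptor")
        lkeys, lxyz = truth.ca_table("ligand")
        expected = {}
        for i, rk in enumerate(rkeys):
            for j, lk in enumerate(lkeys):
                d = float(np.linalg.norm(rxyz[i] - lxyz[j]))
                if d < 8.0:
                    expected[(rk, lk)] = d
        assert found.keys() == expected.keys()
        for pair in expected:
            assert found[pair] == pytest.approx(expected[pair], abs=1e-12)
        assert len(found) >= 10


class TestBuildCmif:
    def test_single_member_reproduces_contact_set(self, truth):
        cmap = build_cmif(Ensemble([truth]))
        observed = detect_interface_contacts(truth)
        assert len(cmap) == len(observed)
        for c in cmap.contacts:
            assert c.support == 1
            assert c.r0 == pytest.approx(observed[(c.receptor_residue, c.ligand_residue)])

    def test_support_counts_and_mean_r0(self):
        m1 = _two_residue_complex(6.0)
        m2 = _two_residue_complex(7.0)
        m3 = _two_residue_complex(9.0)  # pair out of range here
        cmap = build_cmif(Ensemble([m1, m2, m3]))
        assert len(cmap) == 1
        c = cmap.contacts[0]
        assert c.support == 2
        assert c.r0 == pytest.approx(6.5)

    def test_min_support_filters(self):
        m1 = _two_residue_complex(6.0)
        m2 = _two_residue_complex(9.0)
        with pytest.raises(ValueError, match="support"):
            build_cmif(Ensemble([m1, m2]), min_support=2)

    def test_no_interface_is_fatal(self):
        with pytest.raises(ValueError, match="no interface"):
            build_cmif(Ensemble([_two_residue_complex(30.0)]))

    def test_five_member_ensemble_matches_brute_force(self, truth):
        rng = np.random.default_rng(7)
        members = [truth]
        for k in range(4):
            shift = np.zeros(3)
            shift[0] = rng.uniform(-1.0, 1.0)
            members.append(truth.transformed(translation=shift, group="ligand"))
        cmap = build_cmif(Ensemble(members))
        per_pair = {}
        for m in members:
            for pair, d in detect_interface_contacts(m).items():
                per_pair.setdefault(pair, []).append(d)
        assert len(cmap) == len(per_pair)
        for c in cmap.contacts:
            dists = per_pair[(c.receptor_residue, c.ligand_residue)]
            assert c.support == len(dists)
            assert c.r0 == pytest.approx(np.mean(dists), abs=1e-12)


class TestSwitchingFunction:
    def test_reference_distance_gives_exactly_point_six(self):
        assert switching_D(8.0, 8.0) == 0.6
        assert switching_D(3.3, 3.3, n=6, m=10) == 0.6

    def test_zero_distance_gives_one(self):
        assert switching_D(0.0, 5.0) == pytest.approx(1.0)

    def test_arbitrary_precision_value_at_x_two(self):
        # (1 - 2^6) / (1 - 2^10) = 63/1023
        assert switching_D(10.0, 5.0) == pytest.approx(63.0 / 1023.0, abs=1e-15)

    def test_continuous_at_removable_singularity(self):
        for eps in (1e-7, -1e-7):
            assert abs(switching_D(1.0 + eps, 1.0) - 0.6) < 1e-5

    def test_strictly_decreasing_on_grid(self):
        r = np.linspace(0.01, 30.0, 4000)
        d = switching_D(r, 8.0)
        assert np.all(np.diff(d) < 0)

    def test_invalid_reference_distance(self):
        with pytest.raises(ValueError, match="r0"):
            switching_D(1.0, 0.0)


class TestCmsValue:
    def test_zero_when_distances_match_reference(self, truth):
        cmap = build_cmif(Ensemble([truth]))
        assert cms_value(truth, cmap) == pytest.approx(0.0, abs=1e-12)

    def test_single_fully_formed_contact(self):
        from cmsrefine.contacts import Contact

        s = _two_residue_complex(1e-12)
        cmap = InterfaceContactMap([Contact(("A", 1, ""), ("B", 1, ""), r0=6.0)])
        # D(0) = 1, reference 0.6 -> (1 - 0.6)^2
        assert cms_value(s, cmap) == pytest.approx(0.16, abs=1e-9)

    def test_rigid_invariance(self, truth):
        cmap = build_cmif(Ensemble([truth]))
        decoy = truth.transformed(translation=np.array([1.0, 0.5, 0.0]), group="ligand")
        base = cms_value(decoy, cmap)
        rng = np.random.default_rng(11)
        for _ in range(20):
            moved = decoy.transformed(rotation=random_rotation(rng),
                                      translation=rng.normal(scale=20.0, size=3))
            assert cms_value(moved, cmap) == pytest.approx(base, abs=1e-9)

    def test_monotone_growth_as_ligand_leaves(self, truth):
        cmap = build_cmif(Ensemble([truth]))
        values = []
        for shift in (0.5, 1.0, 2.0, 4.0, 8.0):
            decoy = truth.transformed(translation=np.array([shift, 0, 0]), group="ligand")
            values.append(cms_value(decoy, cmap))
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_unresolvable_residue_is_fatal(self, truth):
        cmap = build_cmif(Ensemble([truth]))
        trimmed = ComplexStructure(
            [a for a in truth.atoms if not (a.chain_id == "B" and a.residue_index == 12)],
            {"A"}, {"B"})
        with pytest.raises(KeyError, match="unresolvable"):
            cms_value(trimmed, cmap)


class TestPlumedExport:
    def test_single_contact_map_layout(self, truth):
        cmap = build_cmif(Ensemble([truth]))
        one = InterfaceContactMap(cmap.contacts[:1])
        text = export_plumed(one, truth)
        assert text.count("ATOMS1=") == 1
        assert "ATOMS2=" not in text
        assert text.count("METAD") == 1
        assert "CMDIST" in text

    def test_default_parameters_appear_verbatim(self, truth):
        cmap = build_cmif(Ensemble([truth]))
        text = export_plumed(cmap, truth)
        assert "SIGMA=0.5" in text
        assert "HEIGHT=5" in text
        assert "BIASFACTOR=10" in text
        assert "PACE=1000" in text  # 2 ps at a 2 fs timestep

    def test_grammar_of_keyword_value_lines(self, truth):
        cmap = build_cmif(Ensemble([truth]))
        text = export_plumed(cmap, truth)
        token = re.compile(r"^[A-Za-z_][\w.]*(=(\{[^{}]*\}|[^\s{}]+))?$")
        for line in text.splitlines():
            line = line.strip()
            if not line or line == "...":
                continue
            line = re.sub(r"^\w+:\s+", "", line)  # strip "label:" prefixes
            for tok in re.findall(r"[\w.]+=\{[^{}]*\}|\S+", line):
                if tok == "...":  # PLUMED multi-line continuation marker
                    continue
                assert token.match(tok), f"bad PLUMED token {tok!r}"

    def test_serials_reference_calpha_atoms(self, truth):
        cmap = build_cmif(Ensemble([truth]))
        text = export_plumed(cmap, truth)
        for m in re.finditer(r"ATOMS\d+=(\d+),(\d+)", text):
            for serial in map(int, m.groups()):
                assert truth.atoms[serial - 1].atom_name == "CA"


def test_contact_map_tsv_round_trip(truth, tmp_path):
    cmap = build_cmif(Ensemble([truth]))
    path = tmp_path / "cmap.tsv"
    write_contact_map(cmap, path)
    back = read_contact_map(path)
    assert len(back) == len(cmap)
    assert back.cutoff == cmap.cutoff
    assert back.n_exponent == cmap.n_exponent
    for a, b in zip(cmap.contacts, back.contacts):
        assert a.receptor_residue == b.receptor_residue
        assert a.ligand_residue == b.ligand_residue
        assert a.r0 == pytest.approx(b.r0, abs=1e-9)
        assert a.support == b.support
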