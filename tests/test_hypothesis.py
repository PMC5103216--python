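"""Hypothesis representation, the packaged GPR139 model, exclusion volumes
and serialization."""

import json

import numpy as np
import pytest
from rdkit import Chem

from gpr139pharm import (
    build_hypothesis,
    derive_exclusion_volumes,
    load_hypothesis,
    save_hypothesis,
    select_reference_conformer,
)
from gpr139pharm.chem import Molecule, mol_from_smiles
from gpr139pharm.hypothesis import (
    ExclusionSphere,
    FeatureSite,
    Hypothesis,
    _gpr139_mapping,
)


class TestPackagedModel:
    def test_variant_string_is_aaadhrr(self, model):
        assert model.variant == "AAADHRR"

    def test_seven_sites_six_locations(self, model):
        assert len(model.sites) == 7
        locations = model.locations()
        assert len(locations) == 6
        dual = next(loc for loc in locations if loc.weight == 2)
        assert dual.labels == ("A2", "H6")

    def test_every_matcher_symbol_in_exactly_one_site(self, model):
        labels = sorted(s.label for s in model.sites)
        assert labels == ["A2", "A3", "A4", "D5", "H6", "R1", "R2"]

    def test_terminal_ring_span_exceeds_six_angstrom(self, model):
        # extended 6-atom linker geometry
        span = np.linalg.norm(model.site("R1").position - model.site("R2").position)
        assert span > 6.0

    def test_linker_sites_mutually_close(self, model):
        # A3/D5/A4 all sit on the short polar linker; on the pinned MMFF
        # reference conformer the trans-amide carbonyls put A3-A4 at the
        # upper end of the 1,4-dicarbonyl range (< 4.5 A)
        for a, b in (("A3", "D5"), ("D5", "A4"), ("A3", "A4")):
            dist = np.linalg.norm(model.site(a).position - model.site(b).position)
            assert dist < 4.5

    def test_curated_exclusion_groups_present(self, model):
        tags = {s.provenance for s in model.exclusions}
        assert any("R1-2" in t for t in tags)
        assert any("R1-3" in t for t in tags)
        assert any("R1-5" in t for t in tags)
        assert any("linker-3" in t for t in tags)
        assert any(t.startswith("R2-") for t in tags)

    def test_no_exclusion_inside_a_site_tolerance_sphere(self, model):
        for sphere in model.exclusions:
            for site in model.sites:
                assert np.linalg.norm(sphere.position - site.position) > site.tolerance

    def test_exclusions_clear_of_reference_conformer(self, model, ensemble_1a):
        conf = select_reference_conformer(ensemble_1a)
        for sphere in model.exclusions:
            dists = np.linalg.norm(conf.coords - sphere.position, axis=1)
            assert dists.min() > sphere.radius


class TestBuildHypothesis:
    def test_kind_mismatch_at_d5_names_label(self, ensemble_1a):
        conf = select_reference_conformer(ensemble_1a)
        mapping = _gpr139_mapping(ensemble_1a.mol)
        mapping["D5"] = mapping["A3"]  # carbonyl O cannot be a donor
        with pytest.raises(ValueError, match="D5"):
            build_hypothesis(ensemble_1a, conf, mapping)

    def test_missing_label_rejected(self, ensemble_1a):
        conf = select_reference_conformer(ensemble_1a)
        mapping = _gpr139_mapping(ensemble_1a.mol)
        del mapping["R2"]
        with pytest.raises(ValueError, match="R2"):
            build_hypothesis(ensemble_1a, conf, mapping)

    def test_min_match_cannot_exceed_site_count(self, model):
        with pytest.raises(ValueError):
            Hypothesis(sites=list(model.sites), min_match=8)


class TestExclusionDerivation:
    def _aligned(self, mol_id, coords):
        mol = Chem.MolFromSmiles("C" * len(coords))  # alkane graph placeholder
        conf = Chem.Conformer(len(coords))
        for i, xyz in enumerate(coords):
            conf.SetAtomPosition(i, [float(x) for x in xyz])
        m = Chem.RWMol(mol)
        m.AddConformer(conf, assignId=True)
        return Molecule(mol_id, m.GetMol(), [0.0])

    def test_identical_sets_add_no_spheres(self, model):
        coords = np.array([[20.0, 0, 0], [21.5, 0, 0], [23.0, 0, 0]])
        active = self._aligned("a", coords)
        inactive = self._aligned("i", coords)
        out = derive_exclusion_volumes(model, [active], [inactive])
        assert len(out.exclusions) == len(model.exclusions)

    def test_single_distant_extra_atom_gives_one_sphere(self, model):
        base = np.array([[20.0, 0, 0], [21.5, 0, 0], [23.0, 0, 0]])
        extra = np.vstack([base, [[23.0, 3.0, 0.0]]])
        active = self._aligned("a", base)
        inactive = self._aligned("i", extra)
        out = derive_exclusion_volumes(model, [active], [inactive])
        added = out.exclusions[len(model.exclusions):]
        assert len(added) == 1
        assert np.allclose(added[0].position, [23.0, 3.0, 0.0])

    def test_empty_inactive_set_warns_and_returns_unchanged(self, model):
        with pytest.warns(UserWarning):
            out = derive_exclusion_volumes(model, [], [])
        assert out is model

    def test_added_spheres_never_clash_derivation_actives(self, model):
        base = np.array([[20.0, 0, 0], [21.5, 0.5, 0], [23.0, 0, 0.5]])
        extra = np.vstack([base + 0.1, [[25.0, 4.0, 0.0]], [[20.0, -4.0, 0.0]]])
        active = self._aligned("a", base)
        inactive = self._aligned("i", extra)
        out = derive_exclusion_volumes(model, [active], [inactive])
        for sphere in out.exclusions[len(model.exclusions):]:
            dists = np.linalg.norm(base - sphere.position, axis=1)
            assert dists.min() > sphere.radius


class TestSerialization:
    def test_round_trip_field_by_field(self, model, tmp_path):
        path = tmp_path / "model.json"
        save_hypothesis(model, path)
        back = load_hypothesis(path)
        assert back.min_match == model.min_match
        assert back.variant == model.variant
        assert back.provenance == model.provenance
        for s1, s2 in zip(back.sites, model.sites):
            assert s1.label == s2.label
            assert s1.allowed_kinds == s2.allowed_kinds
            assert s1.tolerance == s2.tolerance
            assert np.array_equal(s1.position, s2.position)
        for e1, e2 in zip(back.exclusions, model.exclusions):
            assert e1.radius == e2.radius and e1.provenance == e2.provenance
            assert np.array_equal(e1.position, e2.position)

    def test_missing_min_match_defaults_to_four_with_warning(self, model, tmp_path):
        path = tmp_path / "model.json"
        save_hypothesis(model, path)
        payload = json.loads(path.read_text())
        del payload["min_match"]
        path.write_text(json.dumps(payload))
        with pytest.warns(UserWarning, match="min_match"):
            back = load_hypothesis(path)
        assert back.min_match == 4

    def test_malformed_json_reports_position(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text('{"schema_version": 1,\n "sites": [}')
        with pytest.raises(json.JSONDecodeError) as err:
            load_hypothesis(path)
        assert err.value.lineno >= 1

    def test_schema_version_mismatch_is_explicit(self, model, tmp_path):
        path = tmp_path / "model.json"
        save_hypothesis(model, path)
        payload = json.loads(path.read_text())
        payload["schema_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="schema version"):
            load_hypothesis(path)


class TestInvariantChecks:
    def test_duplicate_labels_rejected(self):
        site = FeatureSite("A3", {"acceptor"}, [0, 0, 0])
        with pytest.raises(ValueError):
            Hypothesis(sites=[site, FeatureSite("A3", {"acceptor"}, [1, 0, 0])], min_match=1)

    def test_nonpositive_geometry_parameters_rejected(self):
        with pytest.raises(ValueError):
            FeatureSite("A3", {"acceptor"}, [0, 0, 0], tolerance=0.0)
        with pytest.raises(ValueError):
            ExclusionSphere([0, 0, 0], radius=-1.0)
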