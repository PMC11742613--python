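import numpy as np
import pytest

from trpcensus.depth import (
    DepthProfile,
    MembraneFrame,
    StructureModel,
    classify_region,
    compare_trp_depths,
    hox_orientation_filter,
    orient_frame,
    parse_structure,
    place_membrane,
    residue_depths,
    write_structure,
)
from trpcensus.simulate import BundleSpec, gen_helical_bundle

PDB_SNIPPET = """\
ATOM      1  N   ALA A   1       0.000   0.000  -1.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       1.000   1.000   0.000  1.00  0.00           C
ATOM      4  CA  TRP A   2       0.000   0.000   3.800  1.00  0.00           C
ATOM      5  CA  LEU A   3       0.000   0.000   7.600  1.00  0.00           C
ATOM      6  CA  UNK A   4       0.000   0.000  11.400  1.00  0.00           C
END
"""


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestParseStructure:
    def test_ca_extraction_ignores_side_chain_and_nonstandard(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(PDB_SNIPPET)
        model = parse_structure(path)
        assert len(model) == 3  # UNK skipped, CB/N ignored
        assert model.residue_types == "AWL"
        assert model.coords[1, 2] == pytest.approx(3.8)

    def test_round_trip_with_writer(self, tmp_path):
        model, _ = gen_helical_bundle(BundleSpec(n_helices=2), seed=4)
        write_structure(model, tmp_path / "b.pdb")
        back = parse_structure(tmp_path / "b.pdb")
        assert back.residue_types == model.residue_types
        assert np.abs(back.coords - model.coords).max() <= 1e-3

    def test_no_ca_raises(self, tmp_path):
        path = tmp_path / "e.pdb"
        path.write_text("END\n")
        with pytest.raises(ValueError):
            parse_structure(path)


class TestPlaceMembrane:
    def test_recovers_planted_frame(self):
        model, truth = gen_helical_bundle(BundleSpec(), seed=1)
        frame = place_membrane(model)
        angle = np.degrees(np.arccos(min(1.0, abs(frame.normal @ truth.frame.normal))))
        assert angle <= 5.0
        centroid = model.coords.mean(axis=0)
        center_err = abs(
            (centroid @ frame.normal - frame.d0)
            - (centroid @ truth.frame.normal - truth.frame.d0)
        )
        assert center_err <= 2.0

    def test_rotation_equivariance(self):
        spec = BundleSpec(rotation_deg=(35.0, 70.0, 10.0))
        model, truth = gen_helical_bundle(spec, seed=2)
        frame = place_membrane(model)
        angle = np.degrees(np.arccos(min(1.0, abs(frame.normal @ truth.frame.normal))))
        assert angle <= 5.0

    def test_translation_invariance_of_normal(self):
        base, _ = gen_helical_bundle(BundleSpec(), seed=3)
        moved = StructureModel(
            base.accession, base.residue_numbers, base.residue_types,
            base.coords + np.array([100.0, 100.0, 100.0]),
        )
        f1 = place_membrane(base)
        f2 = place_membrane(moved)
        assert abs(f1.normal @ f2.normal) == pytest.approx(1.0, abs=1e-6)

    def test_too_few_residues_raises(self):
        model = StructureModel("tiny", tuple(range(1, 11)), "A" * 10,
                               np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError):
            place_membrane(model)

    def test_collinear_model_raises(self):
        coords = np.column_stack([np.zeros(30), np.zeros(30), np.arange(30.0)])
        model = StructureModel("line", tuple(range(1, 31)), "L" * 30, coords)
        with pytest.raises(ValueError, match="collinear"):
            place_membrane(model)


class TestOrientFrame:
    def _model_along_z(self):
        coords = np.column_stack(
            [np.zeros(40), np.zeros(40) + np.linspace(0, 1, 40), np.linspace(-20, 19, 40)]
        )
        return StructureModel("m", tuple(range(1, 41)), "L" * 40, coords)

    def test_flips_when_reference_negative(self):
        model = self._model_along_z()
        frame = MembraneFrame(np.array([0.0, 0.0, 1.0]), 0.0)
        oriented = orient_frame(frame, model, {1, 2, 3})  # residues near z=-20
        z = model.coords[:3] @ oriented.normal - oriented.d0
        assert z.mean() > 0
        assert oriented.oriented

    def test_unchanged_when_reference_positive(self):
        model = self._model_along_z()
        frame = MembraneFrame(np.array([0.0, 0.0, 1.0]), 0.0)
        oriented = orient_frame(frame, model, {39, 40})
        assert oriented.normal @ frame.normal == pytest.approx(1.0)

    def test_empty_reference_raises(self):
        model = self._model_along_z()
        frame = MembraneFrame(np.array([0.0, 0.0, 1.0]), 0.0)
        with pytest.raises(ValueError):
            orient_frame(frame, model, set())

    def test_planted_cytoplasmic_cterm_positive(self):
        for seed in range(5):
            model, truth = gen_helical_bundle(BundleSpec(tilt_deg=10.0), seed=seed)
            frame = place_membrane(model)
            lo, hi = truth.cterm_residue_range
            oriented = orient_frame(frame, model, range(lo, hi + 1))
            mask = [lo <= n <= hi for n in model.residue_numbers]
            z = model.coords[mask] @ oriented.normal - oriented.d0
            assert z.mean() > 0


class TestResidueDepths:
    def test_projection_example(self):
        model = StructureModel("m", (1,) * 0 + (1,), "W", np.array([[3.0, -7.0, 10.0]]))
        frame = MembraneFrame(np.array([0.0, 0.0, 1.0]), 0.0)
        profile = residue_depths(model, frame)
        assert profile.z[0] == pytest.approx(10.0)

    def test_window_masking_and_conservation(self):
        coords = np.column_stack([np.zeros(3), np.zeros(3), [10.0, 45.0, -41.0]])
        model = StructureModel("m", (1, 2, 3), "WWW", coords)
        frame = MembraneFrame(np.array([0.0, 0.0, 1.0]), 0.0)
        profile = residue_depths(model, frame)
        assert list(profile.included) == [True, False, False]
        assert profile.included.sum() + (~profile.included).sum() == len(model)
        assert profile.trp_depths().tolist() == [10.0]

    def test_rigid_motion_invariance(self):
        spec_a = BundleSpec(trp_depths=(-20.0, 5.0))
        spec_b = BundleSpec(trp_depths=(-20.0, 5.0),
                            rotation_deg=(40.0, 15.0, 120.0),
                            translation=(30.0, -60.0, 12.0))
        model_a, truth_a = gen_helical_bundle(spec_a, seed=7)
        model_b, truth_b = gen_helical_bundle(spec_b, seed=7)
        za = residue_depths(model_a, truth_a.frame).z
        zb = residue_depths(model_b, truth_b.frame).z
        assert np.abs(za - zb).max() <= 1e-9

    def test_planted_trp_depths_recovered(self):
        spec = BundleSpec(tilt_deg=15.0, trp_depths=(-20.0, 7.5, 18.0))
        model, truth = gen_helical_bundle(spec, seed=11)
        frame = place_membrane(model)
        lo, hi = truth.cterm_residue_range
        frame = orient_frame(frame, model, range(lo, hi + 1))
        profile = residue_depths(model, frame)
        err = np.abs(profile.z - truth.true_z)
        assert (err <= 2.0).mean() >= 0.95


class TestClassifyRegion:
    @pytest.mark.parametrize("z,region", [
        (20.0, "cytoplasmic_space"),
        (-20.0, "lumenal_space"),
        (0.0, "cytoplasmic_interface_core"),
        (18.0, "cytoplasmic_interface_core"),
        (-18.0, "lumenal_interface_core"),
        (18.01, "cytoplasmic_space"),
        (-0.01, "lumenal_interface_core"),
    ])
    def test_regions(self, z, region):
        assert classify_region(z) == region

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            classify_region(float("nan"))


class TestHoxOrientationFilter:
    def _model(self, hox_z, nterm_z):
        n = 40
        z = np.concatenate([
            np.full(10, nterm_z), np.linspace(-15, 15, 20), np.full(10, hox_z)
        ])
        coords = np.column_stack([np.linspace(0, 5, n), np.zeros(n), z])
        return StructureModel("m", tuple(range(1, n + 1)), "L" * n, coords)

    def test_same_side_rejected(self):
        model = self._model(hox_z=25.0, nterm_z=22.0)
        frame = MembraneFrame(np.array([0.0, 0.0, 1.0]), 0.0, oriented=True)
        assert hox_orientation_filter(model, frame, (31, 40), (1, 10)) == "reject"

    def test_opposite_sides_pass(self):
        model = self._model(hox_z=25.0, nterm_z=-15.0)
        frame = MembraneFrame(np.array([0.0, 0.0, 1.0]), 0.0, oriented=True)
        assert hox_orientation_filter(model, frame, (31, 40), (1, 10)) == "pass"

    def test_absent_range_raises(self):
        model = self._model(25.0, -15.0)
        frame = MembraneFrame(np.array([0.0, 0.0, 1.0]), 0.0, oriented=True)
        with pytest.raises(ValueError):
            hox_orientation_filter(model, frame, (100, 120), (1, 10))

    def test_generator_misoriented_bundle_rejected(self):
        good, truth_g = gen_helical_bundle(BundleSpec(hox_side=+1), seed=5)
        bad, truth_b = gen_helical_bundle(BundleSpec(hox_side=-1), seed=5)
        for model, truth, expected in [(good, truth_g, "pass"), (bad, truth_b, "reject")]:
            verdict = hox_orientation_filter(
                model, truth.frame, truth.hox_residue_range, truth.nterm_residue_range
            )
            assert verdict == expected


class TestCompareTrpDepths:
    def _profile(self, depths, acc="p"):
        n = len(depths)
        return DepthProfile(acc, tuple(range(1, n + 1)), "W" * n,
                            np.asarray(depths, float), np.ones(n, dtype=bool))

    def test_identical_cohorts(self):
        prof = self._profile([1.0, 2.0, 3.0, 4.0])
        res = compare_trp_depths([prof], [prof])
        assert res.statistic == pytest.approx(16 / 2)
        assert res.p_value == pytest.approx(1.0)

    def test_cohort_without_trp_raises(self):
        prof = self._profile([1.0])
        no_trp = DepthProfile("q", (1,), "A", np.array([1.0]), np.array([True]))
        with pytest.raises(ValueError):
            compare_trp_depths([prof], [no_trp])

    def test_reports_medians_and_counts(self):
        a = self._profile([-20.0, -19.0, -21.0])
        b = self._profile([5.0, 6.0, 7.0, 8.0])
        res = compare_trp_depths([a], [b])
        assert res.extra["n_trp_a"] == 3
        assert res.extra["n_trp_b"] == 4
        assert res.extra["median_a"] == pytest.approx(-20.0)
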