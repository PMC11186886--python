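"""Fibril model construction: screw replication, C2 assembly, tail grafting,
periodic sizing, ion bookkeeping and placement."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from crossbeta.builder import (
    IonCounts,
    IonRecipe,
    ScrewParameters,
    StrandTemplate,
    build_fibril,
    c2_assemble,
    extend_n_terminus,
    hairpin_template,
    ion_counts,
    place_ions,
    replicate_strand,
    size_periodic_unit,
)
from crossbeta.geometry import kabsch_rmsd
from crossbeta.sequences import variant_sequence


class TestScrew:
    def test_transforms_compose(self):
        screw = ScrewParameters(rise=4.8, twist=2.2, axis=(0.1, 0.2, 1.0), origin=(3, 2, 1))
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 3)) * 10
        once_then_twice = screw.apply(screw.apply(pts, 1.0), 2.0)
        assert np.allclose(once_then_twice, screw.apply(pts, 3.0), atol=1e-10)

    def test_pure_translation_when_untwisted(self):
        screw = ScrewParameters(rise=4.8, twist=0.0)
        template = hairpin_template("human")
        stack = replicate_strand(template, 2, screw)
        sid = stack.get_annotation("strand_id")
        delta = stack.coord[sid == 1] - stack.coord[sid == 0]
        assert np.allclose(delta, [0.0, 0.0, 4.8], atol=1e-6)

    def test_screw_power_matches_matrix_product(self):
        """Strand 2 at 2.2°/4.8 Å equals the transform composed twice."""
        screw = ScrewParameters(rise=4.8, twist=2.2)
        template = hairpin_template("human")
        stack = replicate_strand(template, 3, screw)
        sid = stack.get_annotation("strand_id")
        composed = screw.apply(screw.apply(template.atoms.coord, 1.0), 1.0)
        assert np.allclose(stack.coord[sid == 2], composed, atol=1e-9)

    def test_axial_extent_of_18_strands(self):
        screw = ScrewParameters(rise=4.8, twist=0.0)
        stack = replicate_strand(hairpin_template("human"), 18, screw)
        sid = stack.get_annotation("strand_id")
        z0 = stack.coord[sid == 0][:, 2].mean()
        z17 = stack.coord[sid == 17][:, 2].mean()
        assert np.isclose(z17 - z0, 17 * 4.8, atol=1e-6)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError):
            ScrewParameters(axis=(0, 0, 0))


class TestC2Assembly:
    def test_exact_c2_image(self):
        screw = ScrewParameters(rise=4.8, twist=1.5)
        layer = replicate_strand(hairpin_template("human"), 3, screw)
        shifted = layer.copy()
        shifted.coord = layer.coord + np.array([0.0, 12.0, 0.0])  # off-axis
        model = c2_assemble(shifted, screw=screw, axial_shift=0.0)
        l1 = model.atoms.coord[np.isin(model.atoms.get_annotation("strand_id"), model.layer_strands(1))]
        l2 = model.atoms.coord[np.isin(model.atoms.get_annotation("strand_id"), model.layer_strands(2))]
        # distances from the axis (z) are preserved under the 180° rotation
        r1 = np.linalg.norm(l1[:, :2], axis=1)
        r2 = np.linalg.norm(l2[:, :2], axis=1)
        assert np.allclose(r1, r2, atol=1e-9)
        assert np.allclose(l2[:, :2], -l1[:, :2], atol=1e-9)

    @pytest.mark.parametrize("n_per_layer, n_chains", [(18, 36), (24, 48)])
    def test_model_sizes(self, n_per_layer, n_chains):
        """18 strands/layer → the 36-mer; 24 → the 48-mers."""
        layer = replicate_strand(
            hairpin_template("human"), n_per_layer, ScrewParameters()
        )
        layer.coord = layer.coord + np.array([0.0, 12.0, 0.0])  # off-axis
        model = c2_assemble(layer)
        assert model.n_strands == n_chains
        assert len(model.topology[model.topology.layer == 1]) == n_per_layer
        assert len(model.topology[model.topology.layer == 2]) == n_per_layer


class TestExtendNTerminus:
    def test_full_length_chain(self):
        template = hairpin_template("human")
        seq = variant_sequence("human")
        full = extend_n_terminus(template.atoms, str(seq)[:16])
        res_ids = np.unique(full.res_id)
        assert res_ids.min() == 1 and res_ids.max() == 42
        # contiguity: every peptide bond C(i)-N(i+1) near 1.33 Å
        for i in range(1, 42):
            c = full.coord[(full.res_id == i) & (full.atom_name == "C")][0]
            n = full.coord[(full.res_id == i + 1) & (full.atom_name == "N")][0]
            assert np.linalg.norm(n - c) < 1.6
        # prefix CA trace is approximately linear (extended conformation)
        ca = np.array([
            full.coord[(full.res_id == r) & (full.atom_name == "CA")][0]
            for r in range(1, 17)
        ])
        centred = ca - ca.mean(axis=0)
        direction = np.linalg.svd(centred)[2][0]
        residual = centred - np.outer(centred @ direction, direction)
        assert np.abs(residual).max() < 2.0

    def test_empty_prefix_is_identity(self):
        template = hairpin_template("human")
        assert extend_n_terminus(template.atoms, "") is template.atoms

    def test_glycine_prefix_has_no_side_chains(self):
        template = hairpin_template("human")
        full = extend_n_terminus(template.atoms, "G" * 4)
        prefix = full[full.res_id <= 16]
        assert not (prefix.atom_name == "CB").any()


class TestPeriodicSizing:
    @pytest.mark.parametrize(
        "twist, expected", [(1.915, 94), (2.0, 90), (2.2, 82), (180.0, 1)]
    )
    def test_strand_counts(self, twist, expected):
        assert size_periodic_unit(twist) == expected

    def test_argmin_property(self):
        for twist in (1.7, 1.9, 2.1, 3.3):
            n = size_periodic_unit(twist)
            errs = {k: abs(k * twist - 180.0) for k in range(1, 400)}
            assert errs[n] == min(errs.values())

    def test_zero_twist_rejected(self):
        with pytest.raises(ValueError):
            size_periodic_unit(0.0)


class TestIonCounts:
    def test_model_I_neutralization(self):
        """36 chains at −3 need 108 Na⁺ and nothing else."""
        counts = ion_counts(-3, 36)
        assert counts == IonCounts(n_na=108, n_cl=0, n_zn=0)

    def test_one_zn_equivalent_for_48_chains(self):
        counts = ion_counts(
            -3, 48, IonRecipe(concentration=0.1, zn_equivalents=1.0), box_volume=3.0e5
        )
        assert counts.n_zn == 48

    def test_trivial_neutral_system(self):
        assert ion_counts(0, 10) == IonCounts(0, 0, 0)

    @pytest.mark.parametrize("charge, chains, conc, zn", [
        (-3, 36, 0.0, 0.0), (-3, 48, 0.1, 0.0), (-3, 48, 0.1, 1.0),
        (-2, 48, 0.1, 1.0), (-3, 188, 0.1, 0.0),
    ])
    def test_neutrality_enforced(self, charge, chains, conc, zn):
        counts = ion_counts(
            charge, chains, IonRecipe(concentration=conc, zn_equivalents=zn),
            box_volume=1.2e6,
        )
        assert counts.total_charge() + charge * chains == 0
        assert min(counts.n_na, counts.n_cl, counts.n_zn) >= 0

    def test_impossible_neutralization_raises(self):
        with pytest.raises(ValueError):
            ion_counts(+5, 10)  # positive protein, no anions available

    def test_salt_concentration_volume_scaling(self):
        c1 = ion_counts(-3, 48, IonRecipe(concentration=0.1), box_volume=1.0e6)
        c2 = ion_counts(-3, 48, IonRecipe(concentration=0.1), box_volume=2.0e6)
        assert abs(c2.n_cl - 2 * c1.n_cl) <= 1


class TestPlaceIons:
    def test_count_clearance_determinism(self, small_model):
        counts = IonCounts(n_na=40, n_cl=0, n_zn=0)
        placed = place_ions(small_model, counts, seed=9)
        ions = placed.ions
        assert ions.array_length() == 40
        coords = ions.coord
        assert cKDTree(coords).query(coords, k=2)[0][:, 1].min() >= 2.5
        assert cKDTree(small_model.protein.coord).query(coords)[0].min() >= 2.5
        again = place_ions(small_model, counts, seed=9)
        assert np.array_equal(placed.ions.coord, again.ions.coord)

    def test_zero_ions_identity(self, small_model):
        assert place_ions(small_model, IonCounts(0, 0, 0), seed=1) is small_model


def test_build_fibril_layers_are_separated(small_model):
    sid = small_model.atoms.get_annotation("strand_id")
    l1 = small_model.atoms.coord[np.isin(sid, small_model.layer_strands(1))]
    l2 = small_model.atoms.coord[np.isin(sid, small_model.layer_strands(2))]
    assert cKDTree(l1).query(l2)[0].min() > 3.0


def test_template_from_pdb_round_trip(tmp_path, small_model):
    from crossbeta.trajectory_io import write_pdb

    strand = small_model.strand(0)
    path = tmp_path / "strand.pdb"
    write_pdb(strand, path)
    template = StrandTemplate.from_pdb(path)
    assert template.atoms.array_length() == strand.array_length()
    assert kabsch_rmsd(template.atoms.coord, strand.coord, superpose_first=False) < 1e-2
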