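"""Ion-contact statistics: engine correctness, ledgers, profiles, kinetics,
density grids."""

import numpy as np
import pandas as pd
import pytest

import biotite.structure as struc

from crossbeta import ions as ionmod
from crossbeta.builder import ScrewParameters, build_fibril
from crossbeta.synthetic import IonBathSpec, make_ion_bath
from crossbeta.trajectory_io import Trajectory


def brute_force_contacts(frame, species, cutoff, box):
    """All-pairs minimum-image oracle for one frame."""
    prot = frame[~frame.hetero]
    ion_mask = frame.hetero & (frame.res_name == {"Na": "NA", "Cl": "CL", "Zn": "ZN"}[species])
    ion_coords = frame.coord[ion_mask]
    sid = prot.get_annotation("strand_id")
    n_strands = sid.max() + 1
    per_res = np.zeros((n_strands, 42), dtype=int)
    per_str = np.zeros(n_strands, dtype=int)
    total = 0
    for ion in ion_coords:
        d = prot.coord - ion
        if box is not None:
            d -= box * np.round(d / box)
        hit = np.linalg.norm(d, axis=1) <= cutoff
        if not hit.any():
            continue
        total += 1
        pairs = {(int(s), int(r)) for s, r in zip(sid[hit], prot.res_id[hit])}
        for s, r in pairs:
            per_res[s, r - 1] += 1
        for s in {p[0] for p in pairs}:
            per_str[s] += 1
    return per_res, per_str, total


@pytest.fixture(scope="module")
def bath(small_model):
    return make_ion_bath(
        small_model,
        IonBathSpec(n_na=50, n_cl=10, n_zn=8, enrichment=4.0),
        seed=13,
        n_frames=10,
    )


class TestContactEngine:
    def test_matches_brute_force_on_bath(self, bath):
        for f in (0, 4, 9):
            frame = bath.frame(f)
            box = bath.frame_box(f)
            for species in ("Na", "Cl", "Zn"):
                sl = ionmod.ions_in_contact(frame, species, box=box)
                per_res, per_str, total = brute_force_contacts(frame, species, 3.5, box)
                assert np.array_equal(sl.per_residue, per_res)
                assert np.array_equal(sl.per_strand, per_str)
                assert sl.total_ions == total

    def test_cutoff_monotonicity(self, bath):
        frame = bath.frame(0)
        box = bath.frame_box(0)
        prev = None
        for cutoff in (2.5, 3.5, 5.0, 8.0):
            sl = ionmod.ions_in_contact(frame, "Na", cutoff=cutoff, box=box)
            if prev is not None:
                assert (sl.per_residue >= prev.per_residue).all()
                assert (sl.per_strand >= prev.per_strand).all()
            prev = sl

    def test_unknown_species_rejected(self, bath):
        with pytest.raises(ValueError):
            ionmod.ions_in_contact(bath.frame(0), "Mg")

    def test_single_planted_ion(self, small_model):
        """An ion 3.0 Å from an Asp1 atom is credited to residue 1 only of
        that strand; at 3.6 Å from everything it is credited nowhere."""
        protein = small_model.protein
        sid = protein.get_annotation("strand_id")
        target = protein.coord[(sid == 0) & (protein.res_id == 1) & (protein.atom_name == "CB")][0]
        # direction pointing away from all other protein atoms
        others = protein.coord[~((sid == 0) & (protein.res_id == 1))]
        away = target - others[np.linalg.norm(others - target, axis=1).argmin()]
        away /= np.linalg.norm(away)

        ion = struc.AtomArray(1)
        ion.coord = (target + 3.0 * away)[None]
        ion.res_name = np.array(["NA"])
        ion.atom_name = np.array(["NA"])
        ion.element = np.array(["NA"])
        ion.chain_id = np.array(["i"])
        ion.res_id = np.array([1])
        ion.hetero = np.ones(1, bool)
        ion.set_annotation("strand_id", np.array([-1]))
        frame = protein + ion
        sl = ionmod.ions_in_contact(frame, "Na")
        assert sl.per_residue[0, 0] >= 1
        assert sl.per_strand.sum() == sl.per_strand[0]

        # far ion: nowhere
        far = ion.copy()
        far.coord = protein.coord.max(axis=0)[None] + 50.0
        sl2 = ionmod.ions_in_contact(protein + far, "Na")
        assert sl2.per_residue.sum() == 0 and sl2.total_ions == 0


class TestLedger:
    def test_identity_on_planted_counts(self):
        """1.20 Na + 2×0.49 Zn − 0.45 Cl = 1.73 — the printed ledger row."""
        row = ionmod.ion_charge_ledger(na=1.20, zn=0.49, cl=0.45)
        assert np.isclose(row["total_ion_charge"], 1.73)
        assert np.isclose(row["cations_per_strand"], 1.69)
        assert np.isclose(row["zn_na_ratio"], 0.49 / 1.20)

    def test_unit_counts(self):
        row = ionmod.ion_charge_ledger(na=1.0, zn=1.0, cl=0.0)
        assert row["cations_per_strand"] == 2.0
        assert row["total_ion_charge"] == 3.0
        assert row["zn_na_ratio"] == 1.0

    def test_zero_guards(self):
        assert ionmod.ion_charge_ledger(0.0, 0.0, 0.0)["zn_na_ratio"] == 0.0
        assert np.isnan(ionmod.ion_charge_ledger(0.0, 0.5, 0.0)["zn_na_ratio"])

    def test_summary_rows_satisfy_identities(self, bath):
        df = ionmod.strand_ion_summary(bath)
        assert np.allclose(df.cations_per_strand, df.na + df.zn)
        assert np.allclose(df.total_ion_charge, df.na + 2 * df.zn - df.cl)
        mean = df.attrs["mean"]
        assert np.isclose(
            mean["total_ion_charge"], mean["na"] + 2 * mean["zn"] - mean["cl"]
        )

    def test_empty_window_rejected(self, bath):
        with pytest.raises(ValueError):
            ionmod.strand_ion_summary(bath, window=slice(5, 5))


class TestTimeSeries:
    def test_static_frames_constant(self, small_model):
        bath = make_ion_bath(
            small_model, IonBathSpec(n_na=30, enrichment=2.0), seed=3, n_frames=1
        )
        frozen = Trajectory(
            coords=np.repeat(bath.coords, 5, axis=0),
            atoms=bath.atoms,
            box=np.repeat(bath.box, 5, axis=0),
            topology=bath.topology,
        )
        ts = ionmod.contact_time_series(frozen, "Na")
        assert ts.total_contacts.nunique() == 1
        assert ts.attrs["saturation_frame"] == 0

    def test_attachment_rate_recovered(self, small_model):
        lam_true = 0.004
        bath = make_ion_bath(
            small_model,
            IonBathSpec(n_na=60, enrichment=8.0, attachment_rate=lam_true),
            seed=21,
            n_frames=40,
            dt=100.0,
        )
        ts = ionmod.contact_time_series(bath, "Na")
        lam, _ = ionmod.fit_attachment_rate(bath.times, ts.total_contacts.values)
        assert abs(lam - lam_true) / lam_true < 0.2

    def test_no_ions_all_zero(self, small_model):
        bath = make_ion_bath(
            small_model, IonBathSpec(n_na=5, n_zn=0), seed=1, n_frames=3
        )
        ts = ionmod.contact_time_series(bath, "Zn")
        assert (ts.total_contacts == 0).all()


class TestResidueProfile:
    def test_planted_positions_flagged_exactly(self, small_model):
        planted = (1, 3, 7, 11, 22, 42)
        hits = 0
        for seed in range(5):
            b = make_ion_bath(
                small_model,
                IonBathSpec(n_na=60, enrichment=6.0, anchor_positions=planted),
                seed=seed,
                n_frames=15,
            )
            prof = ionmod.residue_contact_profile(b, "Na")
            if tuple(prof[prof.enriched].position) == planted:
                hits += 1
        assert hits >= 4  # exact recovery in ≥80% of seeds

    def test_odd_enrichment_summary(self, small_model):
        planted = (1, 3, 7, 11)
        b = make_ion_bath(
            small_model,
            IonBathSpec(n_na=60, enrichment=6.0, anchor_positions=planted),
            seed=2,
            n_frames=15,
        )
        prof = ionmod.residue_contact_profile(b, "Na")
        # shell spill credits even sequence neighbours too, so the parity
        # contrast is a shifted mean, not a clean separation
        assert prof.attrs["odd_mean"] > prof.attrs["even_mean"]
        assert (prof[prof.enriched].position % 2 == 1).all()

    def test_uniform_bath_rarely_flags(self, small_model):
        flags = 0
        for seed in range(12):
            b = make_ion_bath(
                small_model, IonBathSpec(n_na=60, enrichment=0.0), seed=seed, n_frames=10
            )
            prof = ionmod.residue_contact_profile(b, "Na")
            flags += int(prof.enriched.sum())
        assert flags / (12 * 42) < 0.05

    def test_no_contacts_zero_profile(self, small_model):
        b = make_ion_bath(small_model, IonBathSpec(n_na=3), seed=1, n_frames=2)
        prof = ionmod.residue_contact_profile(b, "Zn")
        assert (prof.mean_contacts_per_strand == 0).all()
        assert not prof.enriched.any()


class TestDensityGrid:
    def test_mass_conservation(self, bath):
        grid = ionmod.density_grid(bath, "Na", window=slice(0, bath.n_frames), align=False)
        assert np.isclose(grid.total_mass(), 50.0, rtol=1e-6)

    def test_single_static_ion_occupies_one_voxel(self, small_model):
        bath = make_ion_bath(small_model, IonBathSpec(n_na=1), seed=5, n_frames=1)
        grid = ionmod.density_grid(bath, "Na", window=slice(0, 1), align=False)
        assert (grid.data > 0).sum() == 1
        assert np.isclose(grid.total_mass(), 1.0)

    def test_gaussian_cloud_centroid_recovered(self, small_model):
        rng = np.random.default_rng(17)
        centre = np.asarray(small_model.box) / 2
        n = 1000
        atoms = small_model.protein
        ion = struc.AtomArray(1)
        ion.res_name = np.array(["NA"])
        ion.atom_name = np.array(["NA"])
        ion.element = np.array(["NA"])
        ion.chain_id = np.array(["i"])
        ion.res_id = np.array([1])
        ion.hetero = np.ones(1, bool)
        ion.set_annotation("strand_id", np.array([-1]))
        ion.coord = centre[None]
        combined = atoms + ion
        coords = np.tile(combined.coord, (n, 1, 1))
        coords[:, -1, :] = centre + rng.normal(0, 2.0, (n, 3))
        traj = Trajectory(coords=coords, atoms=combined, topology=small_model.topology)
        grid = ionmod.density_grid(traj, "Na", window=slice(0, n), align=False)
        centres = [
            grid.origin[d] + grid.voxel * (np.arange(grid.data.shape[d]) + 0.5)
            for d in range(3)
        ]
        mesh = np.meshgrid(*centres, indexing="ij")
        weight = grid.data / grid.data.sum()
        centroid = np.array([(m * weight).sum() for m in mesh])
        assert np.linalg.norm(centroid - centre) < 0.2

    def test_zero_voxel_rejected(self, bath):
        with pytest.raises(ValueError):
            ionmod.density_grid(bath, "Na", voxel=0.0)
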