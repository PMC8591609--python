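"""Generator contracts: seed determinism, truth metadata, tunable statistics."""

import numpy as np
import pytest

from dendricomplex import radius_of_gyration, select
from dendricomplex.dendrimer_model import DendrimerSpec, build_topology
from dendricomplex.synthetic_data import (
    BeadDendrimerModel,
    TitrationModel,
    add_point_cloud,
    gen_complex_ensemble,
    gen_dendrimer_ensemble,
    gen_planted_hbond_ensemble,
    gen_reference_solids,
    gen_spectra_series,
    gen_titration,
)


def _model(**kw):
    kw.setdefault("topology", build_topology(DendrimerSpec("PPI", 2)))
    kw.setdefault("n_frames", 10)
    return BeadDendrimerModel(**kw)


class TestTitrationGenerator:
    def test_seeded_series_reproducible(self):
        a = gen_titration(TitrationModel(noise_sd=1.0, seed=42))
        b = gen_titration(TitrationModel(noise_sd=1.0, seed=42))
        assert np.array_equal(a.y, b.y)
        c = gen_titration(TitrationModel(noise_sd=1.0, seed=43))
        assert not np.array_equal(a.y, c.y)

    def test_truth_recorded_in_metadata(self):
        s = gen_titration(TitrationModel(n=33.0, plateau=-30.0, noise_sd=0.5))
        assert s.meta["truth"]["n"] == 33.0
        assert s.meta["truth"]["plateau"] == -30.0

    def test_grid_must_span_truth(self):
        with pytest.raises(ValueError, match="inside the ratio grid"):
            TitrationModel(n=60.0)

    def test_flat_model_flagged_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            s = gen_titration(TitrationModel(initial=-30.0, plateau=-30.0))
        assert s.meta["degenerate"]

    def test_equal_mixture_spectrum_has_unit_ratio(self):
        from dendricomplex.titration_assays import fluorescence_ratio

        s = gen_spectra_series([10.0], n_true=20.0, quench_depth=0.0)[0]
        assert s.meta["truth"]["theta"] == 0.5
        assert fluorescence_ratio(s) == pytest.approx(1.0, abs=1e-12)


class TestBeadEnsembles:
    def test_same_seed_identical_ensembles(self):
        a = gen_dendrimer_ensemble(_model(seed=7))
        b = gen_dendrimer_ensemble(_model(seed=7))
        assert np.array_equal(a.coords, b.coords)

    def test_mean_rog_hits_target(self):
        ens = gen_dendrimer_ensemble(_model(target_rog=1.284, stiffness=50.0,
                                            n_frames=25, seed=1))
        rog = radius_of_gyration(ens, ("core", "dendrimer"))
        assert rog.mean() == pytest.approx(1.284, rel=0.02)

    def test_stiffness_controls_size_fluctuations(self):
        rigid = gen_dendrimer_ensemble(_model(stiffness=100.0, n_frames=25, seed=3))
        floppy = gen_dendrimer_ensemble(_model(stiffness=3.0, n_frames=25, seed=3))
        sd = lambda e: radius_of_gyration(e, ("core", "dendrimer")).std(ddof=1)
        assert sd(rigid) < sd(floppy) / 3

    def test_bead_count_matches_topology(self):
        topo = build_topology(DendrimerSpec("PPI", 3))
        ens = gen_dendrimer_ensemble(_model(topology=topo))
        assert ens.n_atoms == topo.total_amine_count + 1  # + core bead
        assert (ens.labels == "core").sum() == 1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            _model(n_frames=0)
        with pytest.raises(ValueError):
            _model(segment_length=-1.0)


class TestComplexes:
    def test_ligand_count_and_groups(self, internal_complex):
        rb = select(internal_complex, "RB")
        assert rb.size == 10
        assert len(np.unique(internal_complex.resids[rb])) == 10

    def test_internal_vs_surface_placement(self, rigid_ensemble):
        from dendricomplex import internalization_fraction, radial_density

        rog = radius_of_gyration(rigid_ensemble, ("core", "dendrimer")).mean()
        internal = gen_complex_ensemble(rigid_ensemble, depth="internal", seed=5)
        surface = gen_complex_ensemble(rigid_ensemble, depth="surface", seed=5)
        f_in = internalization_fraction(
            radial_density(internal, "RB", "core",
                           bins=np.arange(0.0, 4.0, 0.05)), rog)
        prof_s = radial_density(surface, "RB", "core",
                                bins=np.arange(0.0, 4.0, 0.05))
        f_surf = internalization_fraction(prof_s, rog)
        assert f_in > 0.8
        assert f_surf < 0.2

    def test_numeric_depth_and_bad_args(self, rigid_ensemble):
        ens = gen_complex_ensemble(rigid_ensemble, n_ligands=3, depth=1.0, seed=0)
        assert select(ens, "RB").size == 3
        with pytest.raises(ValueError):
            gen_complex_ensemble(rigid_ensemble, n_ligands=0)
        with pytest.raises(ValueError):
            gen_complex_ensemble(rigid_ensemble, depth="inside-out")

    def test_point_cloud_labels_and_determinism(self, rigid_ensemble):
        a = add_point_cloud(rigid_ensemble, "ion_Cl", 50, 1.0, 2.0, seed=2)
        b = add_point_cloud(rigid_ensemble, "ion_Cl", 50, 1.0, 2.0, seed=2)
        assert np.array_equal(a.coords, b.coords)
        assert select(a, "ion_Cl").size == 50

    def test_planted_hbond_truth_metadata(self):
        ens, D, H, A = gen_planted_hbond_ensemble(n_frames=3, n_planted=4, seed=0)
        assert ens.meta["truth"]["n_planted"] == 4
        assert len(D) == len(H)


class TestReferenceSolids:
    def test_truth_metadata_carries_closed_forms(self):
        shell = gen_reference_solids("hollow_shell", r_in=0.9)
        t = shell.meta["truth"]
        assert t["cavity_volume"] == pytest.approx(4 / 3 * np.pi * 0.9 ** 3)
        assert t["shell_radius"] == pytest.approx(0.9 + 0.15 + 0.3)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            gen_reference_solids("torus")

    def test_seeded_solids_reproducible(self):
        a = gen_reference_solids("solid_ball", n_points=500, seed=3)
        b = gen_reference_solids("solid_ball", n_points=500, seed=3)
        assert np.array_equal(a.coords, b.coords)
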