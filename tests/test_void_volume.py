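"""Grid/flood-fill SASA volumes and the probe-sweep cavity estimator."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dendricomplex.synthetic_data import gen_complex_ensemble, gen_reference_solids
from dendricomplex.void_volume import (
    VoidVolumeError,
    atom_radii,
    probe_sweep,
    sasa_volume,
    void_ratio,
    void_volume_estimate,
)

SPHERE = lambda r: 4 / 3 * np.pi * r ** 3


class TestSasaVolume:
    def test_single_atom_inflated_sphere(self):
        v = sasa_volume(np.zeros((1, 3)), np.array([0.15]), probe=0.3,
                        spacing=0.05)
        assert v == pytest.approx(SPHERE(0.45), rel=0.05)

    def test_two_far_atoms_are_additive(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        v = sasa_volume(coords, np.array([0.15, 0.2]), probe=0.3, spacing=0.05)
        assert v == pytest.approx(SPHERE(0.45) + SPHERE(0.5), rel=0.05)

    def test_sealed_shell_encloses_interior(self):
        """A shell whose gaps are far below the probe swallows its cavity."""
        shell = gen_reference_solids("hollow_shell", r_in=1.0,
                                     aperture_clearance=0.0)
        R = shell.meta["truth"]["shell_radius"]
        v = sasa_volume(shell.coords[0], shell.radii, probe=0.3, spacing=0.05)
        assert v == pytest.approx(SPHERE(R + 0.15 + 0.3), rel=0.05)

    def test_grid_refinement_converges(self):
        vols = [sasa_volume(np.zeros((1, 3)), np.array([0.2]), 0.3, sp)
                for sp in (0.05, 0.025)]
        assert abs(vols[1] - vols[0]) / vols[1] < 0.02

    def test_coarse_grid_warns(self):
        with pytest.warns(UserWarning, match="spacing"):
            sasa_volume(np.zeros((1, 3)), np.array([0.2]), probe=0.3, spacing=0.2)

    def test_empty_frame_rejected(self):
        with pytest.raises(VoidVolumeError):
            sasa_volume(np.zeros((0, 3)), np.zeros(0), 0.3)


class TestProbeSweep:
    def test_volume_monotone_in_probe_radius(self):
        ball = gen_reference_solids("bead_ball", radius=0.8)
        sweep = probe_sweep(ball.coords[0], ball.radii,
                            probes=(0.3, 0.4, 0.6, 0.8, 1.0), spacing=0.05)
        assert np.all(np.diff(sweep.volumes) > 0)

    def test_descending_probes_rejected(self):
        with pytest.raises(VoidVolumeError):
            probe_sweep(np.zeros((1, 3)), np.array([0.2]), probes=(0.5, 0.3))


class TestVoidEstimate:
    def test_solid_ball_has_no_cavities(self):
        ball = gen_reference_solids("bead_ball", radius=1.0)
        sweep = void_volume_estimate(ball.coords[0], ball.radii, spacing=0.05)
        assert sweep.void_volume <= 0.05 * ball.meta["truth"]["total_volume"]

    def test_hollow_shell_recovers_interior_volume(self):
        shell = gen_reference_solids("hollow_shell", r_in=1.0)
        truth = shell.meta["truth"]["cavity_volume"]
        sweep = void_volume_estimate(shell.coords[0], shell.radii, spacing=0.05)
        assert sweep.void_volume == pytest.approx(truth, rel=0.15)

    def test_single_sphere_extrapolation_consistent(self):
        """One sphere has identical structure at every probe: void ~ 0."""
        sweep = void_volume_estimate(np.zeros((1, 3)), np.array([0.3]),
                                     spacing=0.05)
        assert sweep.void_volume < 0.05 * SPHERE(0.6)

    def test_rotation_invariance_within_grid_error(self):
        shell = gen_reference_solids("hollow_shell", r_in=0.8)
        rot = Rotation.random(random_state=7).as_matrix()
        v0 = void_volume_estimate(shell.coords[0], shell.radii, spacing=0.05)
        v1 = void_volume_estimate(shell.coords[0] @ rot.T, shell.radii,
                                  spacing=0.05)
        assert abs(v1.void_volume - v0.void_volume) / v0.void_volume < 0.05

    def test_cuberoot_deviation_mode(self):
        shell = gen_reference_solids("hollow_shell", r_in=1.0)
        sweep = void_volume_estimate(shell.coords[0], shell.radii, spacing=0.1,
                                     deviation_space="cuberoot")
        assert sweep.void_volume >= 0
        assert sweep.meta["deviation_space"] == "cuberoot"

    def test_too_few_fit_points_rejected(self):
        with pytest.raises(VoidVolumeError, match="fit"):
            void_volume_estimate(np.zeros((1, 3)), np.array([0.2]),
                                 probes=(0.3, 0.4), fit_min=0.4)


class TestVoidRatio:
    def test_identical_pipelines_give_unity(self, rigid_ensemble):
        small = rigid_ensemble
        complex_ens = gen_complex_ensemble(small, n_ligands=2, seed=1)
        with pytest.warns(UserWarning, match="no RB"):
            r = void_ratio(small, small, probes=(0.3, 0.4, 0.5, 0.6),
                           spacing=0.1, frames=slice(0, 2))
        assert r == pytest.approx(1.0, abs=1e-12)
        # with RB present the ligand beads are excluded before the sweep,
        # so an uncompacted complex also gives 1 exactly
        r2 = void_ratio(complex_ens, small, probes=(0.3, 0.4, 0.5, 0.6),
                        spacing=0.1, frames=slice(0, 2))
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_compacted_scaffold_loses_cavity_volume(self, rigid_ensemble):
        compacted = gen_complex_ensemble(rigid_ensemble, n_ligands=2,
                                         scaffold_compaction=0.90, seed=1)
        r = void_ratio(compacted, rigid_ensemble,
                       probes=(0.3, 0.4, 0.5, 0.6, 0.7), spacing=0.075,
                       frames=slice(0, 3))
        assert r < 1.0


def test_atom_radii_prefers_explicit_then_table(rigid_ensemble):
    assert np.all(atom_radii(rigid_ensemble) == 0.12)
    from dendricomplex.ensemble_io import ConformationEnsemble

    ens = ConformationEnsemble(
        coords=np.zeros((1, 2, 3)), masses=np.ones(2),
        labels=np.asarray(["dendrimer"] * 2, dtype=object),
        elements=np.asarray(["N", "O"], dtype=object),
    )
    assert np.allclose(atom_radii(ens), [0.155, 0.152])
    ens.elements[1] = "Qq"
    with pytest.raises(VoidVolumeError):
        atom_radii(ens)
    assert np.allclose(atom_radii(ens, default=0.17), [0.155, 0.17])
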