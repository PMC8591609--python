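"""Geometric hydrogen-bond detection against exhaustive and planted oracles."""

import numpy as np
import pytest

from dendricomplex.ensemble_io import ConformationEnsemble
from dendricomplex.hbond_analysis import (
    HBondCriteria,
    HBondInputError,
    find_hbonds,
    hbond_count_summary,
)
from dendricomplex.synthetic_data import gen_planted_hbond_ensemble


def _ens(coords, labels):
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    return ConformationEnsemble(
        coords=coords, masses=np.ones(n),
        labels=np.asarray(labels, dtype=object),
        elements=np.asarray(["X"] * n, dtype=object),
    )


def brute_force_hbonds(ens, donors, hydrogens, acceptors, criteria):
    """Reference triple loop, no spatial indexing."""
    found = set()
    for f in range(ens.n_frames):
        xyz = ens.coords[f]
        for d, h in zip(donors, hydrogens):
            for a in acceptors:
                if a == d:
                    continue
                v_a = xyz[a] - xyz[d]
                dist = np.linalg.norm(v_a)
                if dist > criteria.max_da_distance:
                    continue
                v_h = xyz[h] - xyz[d]
                cos_t = v_h @ v_a / (np.linalg.norm(v_h) * dist)
                ang = np.degrees(np.arccos(np.clip(cos_t, -1, 1)))
                if ang <= criteria.max_angle_deg:
                    found.add((f, d, h, a))
    return found


class TestGeometry:
    def test_collinear_pair_within_cutoffs_found(self):
        ens = _ens([[0, 0, 0], [0.10, 0, 0], [0.29, 0, 0]],
                   ["dendrimer", "dendrimer", "water"])
        recs = find_hbonds(ens, [0], [1], [2])
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(0.29)
        assert recs[0].angle == pytest.approx(0.0, abs=1e-9)
        assert recs[0].hb_class == "with_water"

    def test_bent_geometry_rejected(self):
        ang = np.radians(60.0)
        h = [0.10 * np.cos(ang), 0.10 * np.sin(ang), 0.0]
        ens = _ens([[0, 0, 0], h, [0.29, 0, 0]],
                   ["dendrimer", "dendrimer", "water"])
        assert find_hbonds(ens, [0], [1], [2]) == []

    def test_distance_cutoff_applies_to_donor_acceptor(self):
        ens = _ens([[0, 0, 0], [0.10, 0, 0], [0.36, 0, 0]],
                   ["dendrimer", "dendrimer", "water"])
        assert find_hbonds(ens, [0], [1], [2]) == []
        loose = HBondCriteria(max_da_distance=0.40)
        assert len(find_hbonds(ens, [0], [1], [2], loose)) == 1

    def test_detached_hydrogen_is_a_list_error(self):
        ens = _ens([[0, 0, 0], [0.5, 0, 0], [0.29, 0, 0]],
                   ["dendrimer", "dendrimer", "water"])
        with pytest.raises(HBondInputError, match="covalently"):
            find_hbonds(ens, [0], [1], [2])

    def test_classification_by_group_labels(self):
        base = [[0, 0, 0], [0.10, 0, 0], [0.29, 0, 0]]
        for acc_label, expected in [("dendrimer", "internal"), ("core", "internal"),
                                    ("water", "with_water"), ("RB", "with_RB"),
                                    ("ion_Cl", "other")]:
            ens = _ens(base, ["dendrimer", "dendrimer", acc_label])
            assert find_hbonds(ens, [0], [1], [2])[0].hb_class == expected


class TestOracleEquivalence:
    def test_matches_exhaustive_search_on_random_frames(self, rng):
        """Dense random frames against the brute-force triple loop."""
        n_frames, n_donors, n_acc = 25, 15, 30
        coords = np.empty((n_frames, 2 * n_donors + n_acc, 3))
        donors = np.arange(n_donors) * 2
        hydrogens = donors + 1
        acceptors = 2 * n_donors + np.arange(n_acc)
        for f in range(n_frames):
            d_pos = rng.uniform(0, 1.2, (n_donors, 3))
            h_dir = rng.normal(size=(n_donors, 3))
            h_dir /= np.linalg.norm(h_dir, axis=1, keepdims=True)
            coords[f, donors] = d_pos
            coords[f, hydrogens] = d_pos + 0.10 * h_dir
            coords[f, acceptors] = rng.uniform(0, 1.2, (n_acc, 3))
        labels = ["dendrimer"] * (2 * n_donors) + ["water"] * n_acc
        ens = _ens(coords, labels)
        crit = HBondCriteria()
        recs = find_hbonds(ens, donors, hydrogens, acceptors, crit)
        got = {(r.frame, r.donor, r.hydrogen, r.acceptor) for r in recs}
        expected = brute_force_hbonds(ens, donors, hydrogens, acceptors, crit)
        assert got == expected
        assert len(expected) > 0  # the fixture actually exercises the search

    @pytest.mark.parametrize("loose", [
        HBondCriteria(max_da_distance=0.45),
        HBondCriteria(max_angle_deg=50.0),
        HBondCriteria(max_da_distance=0.45, max_angle_deg=50.0),
    ])
    def test_loosening_cutoffs_never_loses_bonds(self, rng, loose):
        ens, D, H, A = gen_planted_hbond_ensemble(n_frames=4, n_planted=3, seed=8)
        jitter = rng.normal(scale=0.02, size=ens.coords.shape)
        jitter[:, H] = jitter[:, D]   # keep hydrogens bonded
        ens.coords = ens.coords + jitter
        tight = set((r.frame, r.donor, r.acceptor)
                    for r in find_hbonds(ens, D, H, A))
        wide = set((r.frame, r.donor, r.acceptor)
                   for r in find_hbonds(ens, D, H, A, loose))
        assert tight <= wide


class TestSummary:
    def test_planted_contacts_recovered_exactly(self):
        ens, D, H, A = gen_planted_hbond_ensemble(n_frames=10, n_planted=5, seed=2)
        recs = find_hbonds(ens, D, H, A)
        summary = hbond_count_summary(recs, ens.n_frames)
        assert summary["with_water"] == (5.0, 0.0)
        assert summary["internal"] == (0.0, 0.0)

    def test_mean_and_sd_conventions(self):
        ens, D, H, A = gen_planted_hbond_ensemble(n_frames=2, n_planted=5, seed=0)
        recs = [r for r in find_hbonds(ens, D, H, A)]
        # thin frame 1 down to 3 bonds to get per-frame counts [5, 3]
        drop = [r for r in recs if r.frame == 1][:2]
        recs = [r for r in recs if r not in drop]
        s_sample = hbond_count_summary(recs, 2, sd="sample")
        s_pop = hbond_count_summary(recs, 2, sd="population")
        assert s_sample["with_water"] == (4.0, pytest.approx(np.sqrt(2)))
        assert s_pop["with_water"] == (4.0, pytest.approx(1.0))
        assert s_sample.sd_convention == "sample"

    def test_empty_records_give_zero(self):
        s = hbond_count_summary([], 5)
        assert s["with_RB"] == (0.0, 0.0)

    def test_class_counts_sum_to_total(self, rng):
        ens, D, H, A = gen_planted_hbond_ensemble(n_frames=6, n_planted=4, seed=1)
        recs = find_hbonds(ens, D, H, A)
        s = hbond_count_summary(recs, ens.n_frames)
        total_mean = sum(v[0] for v in s.per_class.values())
        assert total_mean * ens.n_frames == pytest.approx(len(recs))

    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            hbond_count_summary([], 0)
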