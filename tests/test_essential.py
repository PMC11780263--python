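"""Superposition and essential-dynamics identities."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from comdyn.essential import (
    FitError,
    fit_ed,
    project,
    project_structure,
    rmsd,
    superpose,
)
from comdyn.order_params import Frameset
from comdyn.synthetic import interpolated_frames


def quaternion_rmsd(mobile, target):
    """Independent superposition oracle (Horn's quaternion method)."""
    x = mobile - mobile.mean(axis=0)
    y = target - target.mean(axis=0)
    sxx = x.T @ y
    sxy = sxx
    k = np.empty((4, 4))
    k[0, 0] = sxy[0, 0] + sxy[1, 1] + sxy[2, 2]
    k[0, 1] = k[1, 0] = sxy[1, 2] - sxy[2, 1]
    k[0, 2] = k[2, 0] = sxy[2, 0] - sxy[0, 2]
    k[0, 3] = k[3, 0] = sxy[0, 1] - sxy[1, 0]
    k[1, 1] = sxy[0, 0] - sxy[1, 1] - sxy[2, 2]
    k[1, 2] = k[2, 1] = sxy[0, 1] + sxy[1, 0]
    k[1, 3] = k[3, 1] = sxy[0, 2] + sxy[2, 0]
    k[2, 2] = -sxy[0, 0] + sxy[1, 1] - sxy[2, 2]
    k[2, 3] = k[3, 2] = sxy[1, 2] + sxy[2, 1]
    k[3, 3] = -sxy[0, 0] - sxy[1, 1] + sxy[2, 2]
    lam = np.linalg.eigvalsh(k)[-1]
    msd = (np.sum(x**2) + np.sum(y**2) - 2 * lam) / len(x)
    return np.sqrt(max(msd, 0.0))


class TestSuperpose:
    def test_recovers_rigid_transform(self):
        rng = np.random.default_rng(0)
        target = rng.normal(size=(25, 3))
        rot = Rotation.from_rotvec([0.3, -0.9, 1.4]).as_matrix()
        mobile = target @ rot.T + np.array([2.0, -1.0, 0.5])
        fitted, r = superpose(mobile, target)
        assert r == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(fitted, target, atol=1e-9)

    def test_mirror_image_keeps_proper_rotation(self):
        rng = np.random.default_rng(1)
        target = rng.normal(size=(20, 3))
        mirror = target * np.array([-1.0, 1.0, 1.0])
        _, r = superpose(mirror, target)
        assert r > 0.1  # an improper rotation would give ~0

    def test_matches_quaternion_oracle_on_fixture(self, bundle):
        r = rmsd(bundle.state_a.coords, bundle.state_b.coords)
        r_q = quaternion_rmsd(bundle.state_a.coords, bundle.state_b.coords)
        assert r == pytest.approx(r_q, abs=1e-9)

    def test_too_few_beads_rejected(self):
        with pytest.raises(FitError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_configuration_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(FitError):
            superpose(line, line)


class TestFitED:
    def test_identical_frames_zero_eigenvalues(self, bundle):
        frames = Frameset(
            structure=bundle.state_a,
            coords=np.repeat(bundle.state_a.coords[None], 5, axis=0),
        )
        model = fit_ed(frames)
        np.testing.assert_allclose(model.eigenvalues, 0.0, atol=1e-12)

    def test_one_dimensional_motion_dominates(self, bundle):
        frames = interpolated_frames(bundle.state_a, bundle.state_b,
                                     n_frames=31, noise_sigma=0.002, seed=3)
        model = fit_ed(frames)
        assert model.eigenvalues[0] > 50 * model.eigenvalues[1]
        # EV1 aligned with the interstate displacement
        fitted_b, _ = superpose(bundle.state_b.coords, model.reference)
        disp = fitted_b.ravel() - superpose(
            bundle.state_a.coords, model.reference
        )[0].ravel()
        cos = abs(model.eigenvectors[0] @ disp) / np.linalg.norm(disp)
        assert cos > 0.99

    def test_eigenvectors_orthonormal_and_trace_identity(self, bundle):
        frames = interpolated_frames(bundle.state_a, bundle.state_b,
                                     n_frames=15, noise_sigma=0.01, seed=4)
        model = fit_ed(frames)
        g = model.eigenvectors @ model.eigenvectors.T
        np.testing.assert_allclose(g, np.eye(len(g)), atol=1e-8)
        # trace(cov) == total variance of fitted coordinates == sum(evals)
        rows = np.vstack([
            superpose(f, model.reference)[0].ravel() for f in frames.coords
        ])
        total_var = rows.var(axis=0, ddof=0).sum()
        assert model.eigenvalues.sum() == pytest.approx(total_var, abs=1e-8)

    def test_selection_restricts_analysis(self, bundle):
        sel = np.arange(60)
        frames = interpolated_frames(bundle.state_a, bundle.state_b, 8)
        model = fit_ed(frames, selection=sel)
        assert model.eigenvectors.shape[1] == 180

    def test_too_few_frames_rejected(self, bundle):
        frames = Frameset(structure=bundle.state_a,
                          coords=bundle.state_a.coords[None])
        with pytest.raises(FitError):
            fit_ed(frames)


class TestProject:
    def test_projection_variance_equals_eigenvalue(self, bundle):
        frames = interpolated_frames(bundle.state_a, bundle.state_b,
                                     n_frames=25, noise_sigma=0.005, seed=5)
        model = fit_ed(frames)
        proj = project(frames, model, n_vec=4)
        for k in range(4):
            assert proj[:, k].var(ddof=0) == pytest.approx(
                model.eigenvalues[k], abs=1e-8
            )

    def test_mean_structure_projects_to_origin(self, bundle):
        frames = interpolated_frames(bundle.state_a, bundle.state_b, 9)
        model = fit_ed(frames)
        mean_coords = frames.coords.mean(axis=0)
        # the ensemble mean fitted to itself projects at the origin
        proj = project_structure(mean_coords, model)
        np.testing.assert_allclose(proj, 0.0, atol=1e-6)

    def test_endpoints_project_on_opposite_signs(self, bundle):
        frames = interpolated_frames(bundle.state_a, bundle.state_b, 21)
        model = fit_ed(frames, orient=bundle.state_b.coords)
        pa = project_structure(bundle.state_a.coords, model)[0]
        pb = project_structure(bundle.state_b.coords, model)[0]
        assert pb < 0 < pa  # orient structure (B) forced negative
        sep = abs(pa - pb)
        fitted_b, _ = superpose(bundle.state_b.coords, model.reference)
        fitted_a, _ = superpose(bundle.state_a.coords, model.reference)
        disp_norm = np.linalg.norm(fitted_b - fitted_a)
        assert sep == pytest.approx(disp_norm, rel=1e-6)

    def test_rigid_transform_of_inputs_leaves_projections_unchanged(self, bundle):
        frames = interpolated_frames(bundle.state_a, bundle.state_b, 11)
        model = fit_ed(frames, orient=bundle.state_b.coords)
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        moved = Frameset(
            structure=bundle.state_a,
            coords=frames.coords @ rot.T + np.array([3.0, 1.0, -2.0]),
        )
        np.testing.assert_allclose(
            project(moved, model, 2), project(frames, model, 2), atol=1e-8
        )
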