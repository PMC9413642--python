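"""Diffusion FEM: mesh sanity, Green's-function oracle, inverse fit."""

import math

import numpy as np
import pytest

from tissueoptics.diffusion_fem import (
    DiffusionProblem,
    build_mesh,
    infinite_medium_kernel,
    invert_from_boundary,
    solve_fluence,
    surface_fluence_map,
)
from tissueoptics.kubelka_munk import penetration_depth


class TestMesh:
    def test_mesh_sanity(self):
        mesh = build_mesh(0.05)
        assert mesh.triangles.shape[0] >= 2000
        x = mesh.nodes[mesh.triangles, 0]
        y = mesh.nodes[mesh.triangles, 1]
        area = 0.5 * (
            (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
            - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0])
        )
        assert np.all(area > 0)

    def test_source_node_near_center(self):
        mesh = build_mesh(0.05)
        node = mesh.nearest_node((1.5, 1.0))
        assert np.linalg.norm(mesh.nodes[node] - [1.5, 1.0]) <= mesh.h

    def test_degenerate_h_rejected(self):
        with pytest.raises(ValueError):
            build_mesh(0.0)
        with pytest.raises(ValueError):
            build_mesh(1.0)


class TestSolve:
    def test_zero_source(self, coarse_mesh):
        prob = DiffusionProblem(mu_a=1.0, mu_s_reduced=10.0, source_strength=0.0)
        fld = solve_fluence(prob, coarse_mesh)
        assert np.allclose(fld.values, 0.0)

    def test_mirror_symmetry(self, coarse_mesh):
        prob = DiffusionProblem(mu_a=1.0, mu_s_reduced=10.0)
        fld = solve_fluence(prob, coarse_mesh)
        nodes = coarse_mesh.nodes
        for dx in (0.25, 0.5, 0.75):
            left = coarse_mesh.nearest_node((1.5 - dx, 1.0))
            right = coarse_mesh.nearest_node((1.5 + dx, 1.0))
            assert fld.values[left] == pytest.approx(fld.values[right], rel=1e-8)

    def test_nonnegative_and_interior_maximum(self, coarse_mesh):
        prob = DiffusionProblem(mu_a=0.8, mu_s_reduced=5.9)
        fld = solve_fluence(prob, coarse_mesh)
        assert np.min(fld.values) > -1e-10
        assert np.argmax(fld.values) == fld.source_node

    def test_matches_infinite_medium_kernel_brain_980(self):
        """FEM vs K0(mu_eff r)/(2 pi D) for the lowest-attenuation preset."""
        mu_a, mu_sp = 0.8, 5.9
        prob = DiffusionProblem(mu_a=mu_a, mu_s_reduced=mu_sp)
        assert prob.D == pytest.approx(0.04975, abs=1e-5)
        assert prob.mu_eff == pytest.approx(4.010, abs=2e-3)
        mesh = build_mesh(0.01)
        fld = solve_fluence(prob, mesh)
        src = mesh.nodes[fld.source_node]
        mid = np.where(np.abs(mesh.nodes[:, 1] - src[1]) < 1e-12)[0]
        r = mesh.nodes[mid, 0] - src[0]
        mfp = 1.0 / (mu_a + mu_sp)
        delta = penetration_depth(mu_a, mu_sp)
        sel = (np.abs(r) > mfp) & (np.abs(r) < 3 * delta)
        want = infinite_medium_kernel(np.abs(r[sel]), mu_a, prob.D)
        rel = np.abs(fld.values[mid][sel] / want - 1.0)
        assert rel.max() < 0.05

    def test_h_convergence(self):
        """L2 difference to a reference solution shrinks by >= 2x per refinement."""
        prob = DiffusionProblem(mu_a=1.0, mu_s_reduced=10.0)
        ref_mesh = build_mesh(0.0125)
        ref = solve_fluence(prob, ref_mesh)
        errs = []
        for h in (0.1, 0.05, 0.025):
            mesh = build_mesh(h)
            fld = solve_fluence(prob, mesh)
            # compare on common coarse probe points away from the source
            pts = [(x, y) for x in np.arange(0.3, 2.8, 0.25)
                   for y in np.arange(0.3, 1.8, 0.25)
                   if abs(x - 1.5) + abs(y - 1.0) > 0.3]
            a = np.array([fld.values[mesh.nearest_node(p)] for p in pts])
            b = np.array([ref.values[ref_mesh.nearest_node(p)] for p in pts])
            errs.append(np.linalg.norm(a - b))
        assert errs[1] < errs[0] / 2.0
        assert errs[2] < errs[1] / 2.0

    def test_decay_rate_matches_penetration_depth(self):
        """ln Phi falls with slope ~ mu_eff = 1/delta along the mid-line."""
        mu_a, mu_sp = 1.2, 10.5
        prob = DiffusionProblem(mu_a=mu_a, mu_s_reduced=mu_sp)
        mesh = build_mesh(0.01)
        fld = solve_fluence(prob, mesh)
        src = mesh.nodes[fld.source_node]
        mid = np.where(np.abs(mesh.nodes[:, 1] - src[1]) < 1e-12)[0]
        r = mesh.nodes[mid, 0] - src[0]
        delta = penetration_depth(mu_a, mu_sp)
        sel = (r > delta) & (r < 3 * delta)
        # remove the K0 prefactor curvature: Phi ~ r^-1/2 exp(-mu_eff r)
        lnphi = np.log(fld.values[mid][sel]) + 0.5 * np.log(r[sel])
        slope = np.polyfit(r[sel], lnphi, 1)[0]
        assert -slope == pytest.approx(1.0 / delta, rel=0.05)


class TestSurfaceMap:
    def test_profile_symmetric_and_peaked_under_source(self, coarse_mesh):
        prob = DiffusionProblem(mu_a=1.0, mu_s_reduced=10.0)
        fld = solve_fluence(prob, coarse_mesh)
        s, phi = surface_fluence_map(fld)
        assert phi.max() <= fld.values.max()
        # peak on the bottom edge sits at the source's orthogonal projection
        bottom = s <= coarse_mesh.width
        xb = coarse_mesh.nodes[coarse_mesh.boundary_nodes[bottom], 0]
        assert xb[np.argmax(phi[bottom])] == pytest.approx(1.5, abs=coarse_mesh.h)
        # mirror symmetry of the bottom profile about x = 1.5
        pb = phi[bottom]
        assert np.allclose(pb, pb[::-1], rtol=1e-8)

    def test_longer_wavelength_retains_more_central_peak(self, coarse_mesh):
        """At 980 nm (low attenuation) the boundary profile retains a much
        larger fraction of the near-source fluence than at 532 nm: the light
        reaches the surface rather than being scattered/absorbed en route."""
        def retained_fraction(mu_a, mu_sp):
            prob = DiffusionProblem(mu_a=mu_a, mu_s_reduced=mu_sp)
            fld = solve_fluence(prob, coarse_mesh)
            _, phi = surface_fluence_map(fld)
            near = fld.values[coarse_mesh.nearest_node((1.6, 1.0))]
            return phi.max() / near

        # brain presets: 980 nm vs 532 nm
        assert retained_fraction(0.8, 5.9) > 10.0 * retained_fraction(4.0, 14.3)


class TestInversion:
    def test_noiseless_recovery_within_one_percent(self, coarse_mesh):
        mu_a, D = 0.8, 1.0 / (3.0 * (0.8 + 5.9))
        prob = DiffusionProblem(mu_a=mu_a, D=D)
        _, phi = surface_fluence_map(solve_fluence(prob, coarse_mesh))
        res = invert_from_boundary(phi, coarse_mesh, initial_guess=(0.3, 0.1))
        assert res.mu_a_hat == pytest.approx(mu_a, rel=0.01)
        assert res.D_hat == pytest.approx(D, rel=0.01)
        assert res.chi2 < 1e-12

    def test_noisy_replicates_recover_median_mu_a(self, coarse_mesh):
        mu_a, D = 1.0, 0.035
        prob = DiffusionProblem(mu_a=mu_a, D=D)
        _, phi = surface_fluence_map(solve_fluence(prob, coarse_mesh))
        rng = np.random.default_rng(99)
        estimates = []
        for _ in range(10):
            noisy = phi * (1.0 + 0.01 * rng.standard_normal(phi.size))
            res = invert_from_boundary(noisy, coarse_mesh,
                                       initial_guess=(0.5, 0.05), max_iter=200)
            estimates.append(res.mu_a_hat)
        assert np.median(estimates) == pytest.approx(mu_a, rel=0.10)

    def test_all_zero_profile_rejected(self, coarse_mesh):
        zeros = np.zeros(coarse_mesh.boundary_nodes.size)
        with pytest.raises(ValueError, match="degenerate"):
            invert_from_boundary(zeros, coarse_mesh, initial_guess=(1.0, 0.05))

    def test_wrong_profile_length_rejected(self, coarse_mesh):
        with pytest.raises(ValueError, match="boundary nodes"):
            invert_from_boundary(np.ones(7), coarse_mesh, initial_guess=(1.0, 0.05))
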