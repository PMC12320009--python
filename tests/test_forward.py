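"""Forward-model and inverse tests.

The spherical-conductor field has two independent checks used here:

* the radial component of the external field equals the radial component of
  the free-space (Biot-Savart) dipole field — volume currents in a sphere
  produce no radial field (exact identity);
* the full field agrees with a Geselowitz surface-integral evaluation: the
  free-space dipole field plus the integral of the surface potential
  (single-sphere Legendre series) against the boundary kernel, computed by
  quadrature — an independent numerical route through the same physics.
"""

import numpy as np
import pytest

import neotag as nt
from neotag.forward import (dipole_field, hemispheric_sources, lateral_rois,
                            make_source_grid, minimum_norm_inverse,
                            sphere_lead_field)

MU04PI = 1e-7
R_HEAD = 0.065


def tangentialise(ori, pos):
    rad = pos / np.linalg.norm(pos)
    ori = np.asarray(ori, float) - (ori @ rad) * rad
    return ori / np.linalg.norm(ori)


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def monopole_potential(r_obs, r0, sigma=0.33, nmax=80, radius=R_HEAD):
    """Boundary potential of a unit current monopole in an insulated sphere
    (Legendre series; recurrence evaluation)."""
    b = np.linalg.norm(r0)
    r = np.linalg.norm(r_obs)
    cosg = (r_obs @ r0) / (r * b) if b > 0 else 1.0
    tot = 0.0
    p_prev, p_cur = 1.0, cosg                      # P0, P1
    for n in range(1, nmax + 1):
        term = (b**n / r**(n + 1)
                + (n + 1) * b**n * r**n / (n * radius**(2 * n + 1))) * p_cur
        tot += term
        p_prev, p_cur = p_cur, ((2 * n + 1) * cosg * p_cur
                                - n * p_prev) / (n + 1)
    return tot / (4 * np.pi * sigma)


def dipole_potential(r_obs, r0, q, sigma=0.33, h=1e-6):
    """Dipole potential as the directional source-derivative of the
    monopole series (central finite differences)."""
    tot = 0.0
    for k in range(3):
        e = np.zeros(3)
        e[k] = h
        tot += q[k] * (monopole_potential(r_obs, r0 + e, sigma)
                       - monopole_potential(r_obs, r0 - e, sigma)) / (2 * h)
    return tot


def fibonacci_sphere(n):
    i = np.arange(n) + 0.5
    z = 1 - 2 * i / n
    phi = np.pi * (1 + 5**0.5) * i
    s = np.sqrt(1 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def geselowitz_field(sens, ori, r0, q, npts=6000, sigma=0.33):
    """Surface-integral evaluation of the external field of a dipole in a
    homogeneous sphere: free-space term minus the surface-potential term."""
    pts = fibonacci_sphere(npts) * R_HEAD
    dS = 4 * np.pi * R_HEAD**2 / npts
    V = np.array([dipole_potential(p, r0, q, sigma) for p in pts])
    normals = pts / R_HEAD
    a = sens - r0
    b_inf = MU04PI * np.cross(q, a) / np.linalg.norm(a) ** 3
    d = sens[None, :] - pts
    dn = np.linalg.norm(d, axis=1)
    surface = (np.cross(normals, d / dn[:, None] ** 3)
               * (V * dS)[:, None]).sum(axis=0)
    return (b_inf - MU04PI * sigma * surface) @ ori


# --------------------------------------------------------------------------

class TestDipoleField:
    def test_radial_dipole_is_silent(self, small_array):
        pos = np.array([c.position for c in small_array])
        ori = np.array([c.orientation for c in small_array])
        src = np.array([0.01, 0.03, 0.02])
        field = dipole_field(pos, ori, src, src / np.linalg.norm(src),
                             np.zeros(3))
        tangential = dipole_field(pos, ori, src,
                                  tangentialise(np.array([1.0, 0, 0]), src),
                                  np.zeros(3))
        assert np.abs(field).max() < 1e-12 * np.abs(tangential).max()

    def test_dipole_at_centre_is_silent(self, small_array):
        pos = np.array([c.position for c in small_array])
        ori = np.array([c.orientation for c in small_array])
        field = dipole_field(pos, ori, np.zeros(3), [1.0, 0, 0], np.zeros(3))
        assert np.abs(field).max() < 1e-25

    def test_linearity_and_superposition(self, small_array):
        pos = np.array([c.position for c in small_array])
        ori = np.array([c.orientation for c in small_array])
        src = np.array([0.0, 0.035, 0.02])
        q1 = tangentialise(np.array([1.0, 0, 0]), src)
        q2 = tangentialise(np.array([0.0, 0.2, 1.0]), src)
        f1 = dipole_field(pos, ori, src, q1, np.zeros(3))
        f2 = dipole_field(pos, ori, src, q2, np.zeros(3))
        f12 = dipole_field(pos, ori, src, 2 * q1 + 3 * q2, np.zeros(3))
        assert np.allclose(f12, 2 * f1 + 3 * f2, rtol=1e-12)

    def test_radial_projection_matches_free_space_dipole(self, small_array):
        """Exact identity: volume currents add no radial field component."""
        src = np.array([0.005, 0.038, 0.018])
        q = tangentialise(np.array([1.0, 0.1, 0.4]), src) * 1e-9
        for c in small_array:
            if c.axis_label != "radial":
                continue
            rad = c.position / np.linalg.norm(c.position)
            got = dipole_field(c.position, rad, src, q, np.zeros(3))[0]
            a = c.position - src
            want = (MU04PI * np.cross(q, a) / np.linalg.norm(a) ** 3) @ rad
            assert abs(got - want) < 1e-9 * max(abs(want), 1e-30)

    def test_agrees_with_geselowitz_surface_integral(self):
        """Independent numerical oracle within 1% on a coarse test."""
        src = np.array([0.0, 0.03, 0.02])
        q = tangentialise(np.array([1.0, 0.0, 0.3]), src) * 1e-9
        sens = np.array([0.02, 0.05, 0.04])
        sens = sens / np.linalg.norm(sens) * (R_HEAD + 0.006)
        for ori in (np.array([0.0, 0, 1.0]), np.array([1.0, 0, 0]),
                    sens / np.linalg.norm(sens)):
            got = dipole_field(sens, ori, src, q, np.zeros(3))[0]
            want = geselowitz_field(sens, ori, src, q)
            assert abs(got - want) <= 0.01 * max(abs(want), 1e-16)


class TestLeadField:
    def test_shape_and_radial_column_silence(self, small_array):
        grid = make_source_grid(R_HEAD, 0.015)
        fm = sphere_lead_field(small_array, grid, np.zeros(3))
        assert fm.lead_field.shape == (len(small_array), len(grid) * 3)
        # for every source, the radially oriented moment is silent
        scale = np.abs(fm.lead_field).max()
        for s, p in enumerate(grid):
            norm = np.linalg.norm(p)
            if norm < 1e-9:
                continue
            rad = p / norm
            col = fm.lead_field[:, 3 * s:3 * s + 3] @ rad
            assert np.abs(col).max() < 1e-10 * scale

    def test_sources_outside_shell_rejected(self, small_array):
        with pytest.raises(ValueError):
            sphere_lead_field(small_array, np.array([[0.0, 0.0, 0.08]]),
                              np.zeros(3))


@pytest.fixture(scope="module")
def setup():
    chans = nt.make_sensor_array(27, R_HEAD, 20, seed=1)
    grid = make_source_grid(R_HEAD, 0.01)
    fm = sphere_lead_field(chans, grid, np.zeros(3))
    pos = np.array([c.position for c in chans])
    ori = np.array([c.orientation for c in chans])
    return chans, grid, fm, pos, ori


class TestMinimumNorm:
    def test_zero_data_zero_activation(self, setup):
        chans, grid, fm, _, _ = setup
        est = minimum_norm_inverse(fm, np.zeros(len(chans)),
                                   np.eye(len(chans)))
        assert np.allclose(est.values, 0.0)

    def test_raw_estimate_scales_linearly_with_data(self, setup):
        chans, grid, fm, pos, ori = setup
        src = np.array([0.0, 0.04, 0.02])
        q = tangentialise(np.array([1.0, 0, 0.3]), src) * 1e-9
        d = dipole_field(pos, ori, src, q, np.zeros(3))
        e1 = minimum_norm_inverse(fm, d, np.eye(len(chans)),
                                  noise_normalize=None)
        e2 = minimum_norm_inverse(fm, 4 * d, np.eye(len(chans)),
                                  noise_normalize=None)
        assert np.allclose(e2.values, 4 * e1.values, rtol=1e-9)

    def test_noiseless_dipole_localised_within_one_grid_spacing(self, setup):
        chans, grid, fm, pos, ori = setup
        for src in ([0.0, 0.04, 0.02], [0.01, 0.03, 0.03],
                    [0.0, 0.04, 0.015]):
            src = np.array(src)
            q = tangentialise(np.array([1.0, 0.2, 0.3]), src) * 1e-9
            d = dipole_field(pos, ori, src, q, np.zeros(3))
            est = minimum_norm_inverse(fm, d, np.eye(len(chans)))
            err = np.linalg.norm(grid[np.argmax(est.values)] - src)
            assert err <= 0.01 + 1e-12

    def test_asymmetric_covariance_rejected(self, setup):
        chans, grid, fm, _, _ = setup
        C = np.eye(len(chans))
        C[0, 1] = 0.5
        with pytest.raises(ValueError):
            minimum_norm_inverse(fm, np.zeros(len(chans)), C)


class TestHemisphericSources:
    def test_single_left_dipole_dominates_left_roi(self, setup):
        chans, grid, fm, pos, ori = setup
        src = np.array([0.0, 0.042, 0.015])          # left (+y)
        q = tangentialise(np.array([1.0, 0, 0.3]), src) * 1e-9
        d = dipole_field(pos, ori, src, q, np.zeros(3))
        est = minimum_norm_inverse(fm, d, np.eye(len(chans)))
        left, right = lateral_rois(grid)
        (li, lv), (ri, rv) = hemispheric_sources(est, left, right)
        assert lv > 3 * rv
        assert np.linalg.norm(grid[li] - src) <= 0.015

    def test_bilateral_recovery_with_noise_across_seeds(self, setup):
        """Both hemispheric maxima within 1.5 grid spacings over 20 runs."""
        chans, grid, fm, pos, ori = setup
        tl = np.array([0.0, 0.042, 0.015])
        tr = tl * np.array([1, -1, 1])
        d0 = np.zeros(len(chans))
        for t in (tl, tr):
            q = tangentialise(np.array([1.0, 0, 0.3]) * np.array(
                [1, np.sign(t[1]), 1]), t) * 1e-9
            d0 += dipole_field(pos, ori, t, q, np.zeros(3))
        left, right = lateral_rois(grid)
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            d = d0 + rng.normal(0, 0.05 * np.abs(d0).max(), len(chans))
            est = minimum_norm_inverse(fm, d, np.eye(len(chans)))
            (li, _), (ri, _) = hemispheric_sources(est, left, right)
            ok += (np.linalg.norm(grid[li] - tl) <= 0.015
                   and np.linalg.norm(grid[ri] - tr) <= 0.015)
        assert ok == 20

    def test_empty_roi_raises(self, setup):
        chans, grid, fm, _, _ = setup
        est = minimum_norm_inverse(fm, np.zeros(len(chans)),
                                   np.eye(len(chans)))
        with pytest.raises(ValueError):
            hemispheric_sources(est, np.zeros(len(grid), bool),
                                np.ones(len(grid), bool))


class TestLocalizeOddball:
    def test_single_participant_equals_individual(self, small_array):
        rng = np.random.default_rng(20)
        grid = make_source_grid(R_HEAD, 0.015)
        fm = sphere_lead_field(small_array, grid, np.zeros(3))
        freqs = np.arange(0, 10.0, 0.05)
        C = (rng.normal(size=(len(small_array), len(freqs)))
             + 1j * rng.normal(size=(len(small_array), len(freqs))))
        cov = np.eye(len(small_array))
        group = nt.localize_oddball([C], freqs, fm, cov)
        est = minimum_norm_inverse(fm, C, cov)
        from neotag.freqtag import spectrum_snr
        snr, _ = spectrum_snr(est.values**2, freqs)
        assert np.allclose(group.values, snr, equal_nan=True)

    def test_injected_3hz_dipole_peaks_at_true_location(self, small_array):
        rng = np.random.default_rng(21)
        grid = make_source_grid(R_HEAD, 0.012)
        fm = sphere_lead_field(small_array, grid, np.zeros(3))
        pos = np.array([c.position for c in small_array])
        ori = np.array([c.orientation for c in small_array])
        src = np.array([0.0, 0.036, 0.024])
        q = tangentialise(np.array([1.0, 0, 0.3]), src) * 1e-9
        topo = dipole_field(pos, ori, src, q, np.zeros(3))
        freqs = np.arange(0, 10.0, 0.05)
        i3 = np.argmin(np.abs(freqs - 3.0))
        scale = 0.02 * np.abs(topo).max()
        specs = []
        for _ in range(3):
            C = scale * (rng.normal(size=(len(small_array), len(freqs)))
                         + 1j * rng.normal(size=(len(small_array),
                                                 len(freqs))))
            C[:, i3] += topo
            specs.append(C)
        cov = np.eye(len(small_array)) * scale**2
        group = nt.localize_oddball(specs, freqs, fm, cov)
        vals = group.values[:, i3]
        assert np.linalg.norm(grid[np.nanargmax(vals)] - src) <= 0.012 + 1e-12
        # and away from the line the source SNR is near 1
        i_off = np.argmin(np.abs(freqs - 5.0))
        assert abs(np.nanmedian(group.values[:, i_off]) - 1.0) < 0.5
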