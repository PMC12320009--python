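"""Spherical-head dipole forward model and noise-normalised minimum-norm inverse.

The forward solution is the analytic external magnetic field of a current
dipole inside a homogeneous spherical conductor (Sarvas' closed form).  Two
properties of that geometry are load-bearing for the whole package:

* a radially oriented dipole produces **no** external field, which is why
  tangential auditory sources dominate MEG and why the generator only uses
  tangential dipoles;
* the field depends on the conductor only through the sphere centre, so no
  conductivity value is needed.

The inverse is a minimum-norm estimate ``W = L^T (L L^T + lam C)^-1`` with an
identity source covariance, followed by dSPM-style noise normalisation
(each source component divided by its projected noise standard deviation),
which removes the depth bias of the raw minimum-norm map.  Free-orientation
sources are reported as the norm over their three components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ForwardModel",
    "SourceEstimate",
    "dipole_field",
    "sphere_lead_field",
    "make_source_grid",
    "minimum_norm_inverse",
    "localize_oddball",
    "hemispheric_sources",
    "lateral_rois",
]

MU0_OVER_4PI = 1e-7  # T·m/A


@dataclass
class ForwardModel:
    """Lead fields of free-orientation dipoles on a source grid.

    ``lead_field`` has shape (n_channels, n_sources * 3): three columns per
    source, the field of a unit dipole (1 A·m) along x, y, z, projected on
    each channel's measurement axis.
    """

    source_grid: np.ndarray          # (n_sources, 3) metres
    lead_field: np.ndarray           # (n_channels, n_sources * 3) T / (A·m)
    sphere_centre: np.ndarray        # (3,) metres
    conductor: str = "homogeneous_sphere"

    @property
    def n_sources(self) -> int:
        return self.source_grid.shape[0]


@dataclass
class SourceEstimate:
    """Noise-normalised source activations (dimensionless) on a grid."""

    grid: np.ndarray                 # (n_sources, 3)
    values: np.ndarray               # (n_sources,) or (n_sources, n_bins)
    orientation: str = "free_norm"   # norm over the 3 free components
    significant: np.ndarray | None = None


def dipole_field(sensor_pos, sensor_ori, dipole_pos, dipole_moment, centre):
    """Field of one current dipole in a homogeneous sphere (Sarvas formula).

    All positions in metres relative to an arbitrary origin; ``centre`` is the
    sphere centre.  Moment in A·m.  Returns the field component (tesla) along
    each sensor orientation; inputs may be (3,) or (n, 3) for the sensors.
    """
    r = np.atleast_2d(np.asarray(sensor_pos, float) - centre)
    ori = np.atleast_2d(np.asarray(sensor_ori, float))
    r0 = np.asarray(dipole_pos, float) - np.asarray(centre, float)
    q = np.asarray(dipole_moment, float)

    a_vec = r - r0                                     # (n, 3)
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(a < 1e-12) or np.any(rn < 1e-12):
        raise ValueError("sensor coincides with source or sphere centre")
    ar = np.einsum("ij,ij->i", a_vec, r)               # a · r
    r0r = r @ r0                                       # r0 · r
    F = a * (rn * a + rn**2 - r0r)
    gF = ((a**2 / rn + ar / a + 2 * a + 2 * rn)[:, None] * r
          - (a + 2 * rn + ar / a)[:, None] * r0)
    qxr0 = np.cross(q, r0)                             # (3,)
    B = (MU0_OVER_4PI / F**2)[:, None] * (
        F[:, None] * qxr0 - (r @ qxr0)[:, None] * gF)
    return np.einsum("ij,ij->i", B, ori)


def sphere_lead_field(channels, source_grid, centre) -> ForwardModel:
    """Assemble the lead-field matrix for a channel list and source grid.

    Sources must lie strictly inside the sensor shell; each gets three
    columns (unit dipoles along x, y, z).
    """
    centre = np.asarray(centre, float)
    grid = np.atleast_2d(np.asarray(source_grid, float))
    pos = np.array([c.position for c in channels])
    ori = np.array([c.orientation for c in channels])
    r_sens = np.linalg.norm(pos - centre, axis=1).min()
    r_src = np.linalg.norm(grid - centre, axis=1)
    if np.any(r_src >= r_sens):
        raise ValueError("source grid extends to or beyond the sensor shell")
    L = np.empty((len(channels), grid.shape[0] * 3))
    eye = np.eye(3)
    for s, src in enumerate(grid):
        for k in range(3):
            L[:, 3 * s + k] = dipole_field(pos, ori, src, eye[k], centre)
    return ForwardModel(source_grid=grid, lead_field=L, sphere_centre=centre)


def make_source_grid(radius: float, spacing: float = 0.0075,
                     fraction: float = 0.85, centre=(0.0, 0.0, 0.0),
                     upper_only: bool = True) -> np.ndarray:
    """Regular cubic grid of candidate sources inside ``fraction * radius``.

    ``upper_only`` drops the lower half (z < 0) where the infant head model
    has no cortex of interest; spacing default 7.5 mm.
    """
    centre = np.asarray(centre, float)
    rmax = fraction * radius
    n = int(np.floor(rmax / spacing))
    ax = np.arange(-n, n + 1) * spacing
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    keep = np.linalg.norm(pts, axis=1) <= rmax
    if upper_only:
        keep &= pts[:, 2] >= -1e-12
    return pts[keep] + centre


def minimum_norm_inverse(forward: ForwardModel, data, noise_cov,
                         lam: float | None = None, snr: float = 3.0,
                         noise_normalize: str | None = "sloreta"
                         ) -> SourceEstimate:
    """Minimum-norm inverse with depth-bias correction by noise normalisation.

    Parameters
    ----------
    data : ndarray, (n_channels,) or (n_channels, n_bins), real or complex
        A field topography at one time point, or Fourier coefficients per
        frequency bin.
    noise_cov : ndarray (n_channels, n_channels)
        Symmetric positive-definite noise covariance (regularise upstream if
        estimated from few samples).
    lam : float, optional
        Regularisation weight on the noise covariance.  Default uses the
        common SNR heuristic ``lam = trace(L L^T) / trace(C) / snr**2``.
    snr : float
        Assumed amplitude SNR for the default ``lam`` (3 is the field's
        conventional choice for evoked data).
    noise_normalize : {"sloreta", "dspm", None}
        Depth-bias correction.  ``"sloreta"`` (default) standardises each
        source's 3-vector estimate by its resolution covariance block
        ``(W L)_jj`` and has zero intrinsic localisation bias for point
        sources; ``"dspm"`` divides each component by its projected noise
        standard deviation ``sqrt(diag(W C W^T))``; ``None`` returns the
        raw (tesla-scaled) minimum-norm amplitudes.

    Returns
    -------
    SourceEstimate
        Per-source norm over the three components; dimensionless when
        normalisation is on.
    """
    L = forward.lead_field
    C = np.asarray(noise_cov, float)
    if C.shape != (L.shape[0], L.shape[0]):
        raise ValueError("noise covariance shape does not match channel count")
    if not np.allclose(C, C.T, atol=1e-10 * max(1e-30, abs(C).max())):
        raise ValueError("noise covariance must be symmetric")
    if noise_normalize not in ("sloreta", "dspm", None):
        raise ValueError("noise_normalize must be 'sloreta', 'dspm' or None")
    if lam is None:
        lam = np.trace(L @ L.T) / np.trace(C) / snr**2
    G = L @ L.T + lam * C
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular inverse system; increase lam (regularisation) or "
            "provide a full-rank noise covariance") from err
    W = L.T @ Ginv                                    # (3S, n_channels)
    d = np.asarray(data)
    vec = d[:, None] if d.ndim == 1 else d
    s = W @ vec                                       # (3S, n_bins)
    n_src = forward.n_sources
    if noise_normalize == "dspm":
        noise_sd = np.sqrt(np.einsum("ij,jk,ik->i", W, C, W))
        noise_sd[noise_sd == 0] = np.inf
        s = s / noise_sd[:, None]
        val = np.sqrt((np.abs(s) ** 2).reshape(n_src, 3, -1).sum(axis=1))
    elif noise_normalize == "sloreta":
        # per-source 3x3 resolution blocks (W L)_jj; pseudo-inverse because
        # the radial direction is silent in a spherical conductor (rank 2)
        val = np.empty((n_src, vec.shape[1]))
        for j in range(n_src):
            blk = slice(3 * j, 3 * j + 3)
            M = W[blk] @ L[:, blk]
            Minv = np.linalg.pinv(M, rcond=1e-10, hermitian=True)
            sj = s[blk]                                # (3, n_bins)
            val[j] = np.sqrt(np.abs(
                np.einsum("ib,ij,jb->b", sj.conj(), Minv, sj)))
    else:
        val = np.sqrt((np.abs(s) ** 2).reshape(n_src, 3, -1).sum(axis=1))
    if d.ndim == 1:
        val = val[:, 0]
    return SourceEstimate(grid=forward.source_grid, values=val)


def localize_oddball(participant_coefficients, freq_grid, forward: ForwardModel,
                     noise_cov, lam: float | None = None,
                     flank_exclude: float = 0.1, flank_extent: float = 0.4):
    """Group source-level SNR spectra for the frequency-tagging paradigm.

    SNR is not linear in the field, so group-averaged sensor SNR cannot be
    source-projected.  Instead, each participant's epoch-averaged Fourier
    coefficients are inverted per frequency bin, source power spectra and
    their flanking-bin SNRs are computed per participant, and the group mean
    of the SNR spectra is returned.

    Parameters
    ----------
    participant_coefficients : list of ndarray (n_channels, n_bins), complex
        Epoch-averaged Fourier coefficients per participant (same grid).
    freq_grid : ndarray (n_bins,)

    Returns
    -------
    SourceEstimate with ``values`` of shape (n_sources, n_bins): the group
    mean of per-participant source-level SNR spectra (NaN at bins lacking
    full flanks).
    """
    from .freqtag import spectrum_snr  # shared flanking-bin definition

    snrs = []
    for coeffs in participant_coefficients:
        est = minimum_norm_inverse(forward, coeffs, noise_cov, lam=lam)
        power = est.values**2                          # (n_sources, n_bins)
        snr, _ = spectrum_snr(power, freq_grid,
                              flank_exclude=flank_exclude,
                              flank_extent=flank_extent)
        snrs.append(snr)
    return SourceEstimate(grid=forward.source_grid,
                          values=np.mean(snrs, axis=0))


def lateral_rois(grid: np.ndarray, centre=(0, 0, 0), min_lateral: float = 0.4):
    """Left/right temporal ROI masks: lateral wedges around the ±y axis.

    A source belongs to a hemisphere ROI when its |y| coordinate (relative to
    the centre) exceeds ``min_lateral`` times its radial distance, i.e. it
    sits in a wedge around the interaural axis where the auditory cortices
    lie.  Returns (left_mask, right_mask); left is y > 0.
    """
    rel = grid - np.asarray(centre, float)
    r = np.linalg.norm(rel, axis=1)
    r[r == 0] = np.inf
    lat = rel[:, 1] / r
    return lat > min_lateral, lat < -min_lateral


def hemispheric_sources(estimate: SourceEstimate, left_mask, right_mask):
    """Maximally activated source within each hemisphere's auditory ROI.

    Returns ((left_index, left_value), (right_index, right_value)) where the
    indices address ``estimate.grid``.  For spectral estimates the maximum is
    taken over the per-source peak value.
    """
    vals = estimate.values
    score = vals if vals.ndim == 1 else np.nanmax(vals, axis=1)
    out = []
    for mask in (left_mask, right_mask):
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError("empty hemisphere ROI")
        idx = np.flatnonzero(mask)
        best = idx[np.nanargmax(score[idx])]
        out.append((int(best), float(score[best])))
    return tuple(out)
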