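"""Template-layout channel matching for group averaging.

Different participants wear different cap sizes, so group averages are formed
after matching each participant's channels to a shared 2D template layout.
Channels are projected from the head sphere to the plane with an azimuthal
equidistant projection (preserves angular distance from the vertex) and
matched to the template bijectively by global optimal assignment on projected
distance — greedy nearest-position matching can deadlock two nearby sensors
on the same template slot, the global assignment cannot.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["project_2d", "match_channels"]


def project_2d(positions: np.ndarray, centre=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Azimuthal equidistant projection of head-surface points to the plane."""
    rel = np.atleast_2d(positions) - np.asarray(centre, float)
    rel = rel / np.linalg.norm(rel, axis=1, keepdims=True)
    theta = np.arccos(np.clip(rel[:, 2], -1.0, 1.0))
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def match_channels(template_channels, channels, centre=(0.0, 0.0, 0.0)):
    """Map each template slot to one participant channel (same axis label).

    Returns an integer array ``idx`` with ``idx[i]`` the participant-channel
    index assigned to template slot ``i``, or -1 when the participant has no
    channel of that axis type left to assign.  Matching is solved per axis
    label as a rectangular linear assignment on 2D projected distance.
    """
    t_ids = [c.channel_id for c in template_channels]
    p_ids = [c.channel_id for c in channels]
    if t_ids == p_ids and all(
            np.allclose(a.position, b.position)
            for a, b in zip(template_channels, channels)):
        return np.arange(len(t_ids))        # identical montage: identity

    idx = np.full(len(template_channels), -1, int)
    t_xy = project_2d(np.array([c.position for c in template_channels]), centre)
    p_xy = project_2d(np.array([c.position for c in channels]), centre)
    for axis in {c.axis_label for c in template_channels}:
        ti = [i for i, c in enumerate(template_channels)
              if c.axis_label == axis]
        pi = [j for j, c in enumerate(channels) if c.axis_label == axis]
        if not ti or not pi:
            continue
        cost = np.linalg.norm(t_xy[ti][:, None, :] - p_xy[pi][None, :, :],
                              axis=2)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            idx[ti[r]] = pi[c]
    return idx
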