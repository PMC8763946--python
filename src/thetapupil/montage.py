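"""Equidistant EEG montage generation on the unit sphere.

The recordings this package analyses come from caps with electrodes arranged
in equidistant positions rather than on the 10-10 system.  For synthetic
cohorts we lay out ``n`` electrodes on a spherical cap with a Fibonacci
lattice, which is deterministic and close to equidistant.  A handful of
midline sensors that the sensor-level theta analysis refers to by name
(Cz, FCz, FC1, Fz, F1, CPz, F2) are assigned to the lattice points nearest
their canonical directions so that electrode-set averages can be requested
by label.
"""

from __future__ import annotations

import numpy as np

#: canonical unit-sphere directions (x right, y anterior, z superior) for the
#: named midline/near-midline sensors used in the sensor-level theta average.
_ANCHORS = {
    "Cz": (0.0, 0.0, 1.0),
    "FCz": (0.0, 0.39, 0.92),
    "Fz": (0.0, 0.72, 0.70),
    "CPz": (0.0, -0.39, 0.92),
    "FC1": (-0.25, 0.37, 0.89),
    "F1": (-0.19, 0.70, 0.69),
    "F2": (0.19, 0.70, 0.69),
}

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def equidistant_montage(
    n_channels: int = 60, z_min: float = -0.25
) -> tuple[list[str], np.ndarray]:
    """Return ``(names, positions)`` for an equidistant cap montage.

    Positions are unit vectors covering the spherical cap ``z >= z_min``
    (scalp coverage down to slightly below the equator).  Channels are named
    ``E01 .. Enn`` except for the lattice points closest to the canonical
    directions of the named midline sensors, which take those labels.
    """
    if n_channels < 8:
        raise ValueError("montage needs at least 8 channels")
    k = np.arange(n_channels)
    z = 1.0 - (k + 0.5) * (1.0 - z_min) / n_channels
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    phi = k * _GOLDEN_ANGLE
    pos = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])

    names = [f"E{i + 1:02d}" for i in range(n_channels)]
    taken: set[int] = set()
    for label, direction in _ANCHORS.items():
        d = np.asarray(direction, float)
        d /= np.linalg.norm(d)
        order = np.argsort(-pos @ d)
        for idx in order:
            if idx not in taken:
                names[int(idx)] = label
                taken.add(int(idx))
                break
    return names, pos


def arc_distances(positions: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (radians) between unit-sphere points."""
    p = np.asarray(positions, float)
    cosd = np.clip(p @ p.T, -1.0, 1.0)
    return np.arccos(cosd)
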