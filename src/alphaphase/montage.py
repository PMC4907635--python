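"""30-channel 10-20 montage: labels, regions, schematic positions, adjacency.

The montage mirrors a standard 30-electrode recording referenced to linked
mastoids, plus VEOG/HEOG oculogram channels.  Positions are schematic 2-D
head coordinates (x: left negative / right positive, y: anterior positive)
used only to derive a neighbour graph for cluster-based permutation tests;
they are not fitted head-model coordinates.
"""

from __future__ import annotations

import numpy as np

#: Frontal region used for the frontal individual-alpha-frequency estimate.
FRONTAL = (
    "FP1", "FP2", "F3", "F4", "F7", "F8", "FC3", "FC4", "FT7", "FT8",
    "C3", "C4", "T7", "T8", "FZ", "FCZ", "CZ",
)

#: Posterior region used for the posterior individual-alpha-frequency estimate.
POSTERIOR = (
    "CP3", "CP4", "TP7", "TP8", "P3", "P4", "P7", "P8",
    "O1", "O2", "PZ", "POZ", "OZ",
)

SCALP = FRONTAL + POSTERIOR
EOG = ("VEOG", "HEOG")
CHANNELS = SCALP + EOG

MIDLINE = ("FZ", "FCZ", "CZ", "PZ", "POZ", "OZ")
LATERAL = tuple(ch for ch in SCALP if ch not in MIDLINE)

#: Left-posterior sites where visuospatial attention suppresses alpha
#: amplitude in the simulated sessions (contralateral cue -> lower alpha).
SUPPRESSION_SITES = ("C3", "CP3", "P3", "P7", "O1")

# Schematic 2-D positions (arbitrary head units).
POSITIONS = {
    "FP1": (-1.0, 4.0), "FP2": (1.0, 4.0),
    "F7": (-2.4, 3.0), "F3": (-1.2, 3.0), "FZ": (0.0, 3.0),
    "F4": (1.2, 3.0), "F8": (2.4, 3.0),
    "FT7": (-2.7, 1.9), "FC3": (-1.35, 1.9), "FCZ": (0.0, 1.9),
    "FC4": (1.35, 1.9), "FT8": (2.7, 1.9),
    "T7": (-3.0, 0.8), "C3": (-1.5, 0.8), "CZ": (0.0, 0.8),
    "C4": (1.5, 0.8), "T8": (3.0, 0.8),
    "TP7": (-2.7, -0.3), "CP3": (-1.35, -0.3), "CP4": (1.35, -0.3),
    "TP8": (2.7, -0.3),
    "P7": (-2.4, -1.4), "P3": (-1.2, -1.4), "PZ": (0.0, -1.4),
    "P4": (1.2, -1.4), "P8": (2.4, -1.4),
    "POZ": (0.0, -2.2),
    "O1": (-1.4, -2.3), "OZ": (0.0, -2.8), "O2": (1.4, -2.3),
}

#: Distance threshold (head units) under which two electrodes are neighbours.
ADJACENCY_THRESHOLD = 1.6


def hemisphere(channel: str) -> str:
    """Return 'left', 'right' or 'midline' for a scalp channel label."""
    if channel in MIDLINE:
        return "midline"
    x = POSITIONS[channel][0]
    return "left" if x < 0 else "right"


def homotopic(channel: str) -> str:
    """Mirror a lateral channel label across the midline (C3 <-> C4)."""
    if channel in MIDLINE:
        return channel
    pairs = {"1": "2", "2": "1", "3": "4", "4": "3", "7": "8", "8": "7"}
    return channel[:-1] + pairs[channel[-1]]


def adjacency(channels=None, threshold: float = ADJACENCY_THRESHOLD):
    """Neighbour sets from the schematic positions.

    Parameters
    ----------
    channels : sequence of str, optional
        Channel subset (default: all 30 scalp channels).  Neighbour sets are
        restricted to this subset.
    threshold : float
        Euclidean distance below which two electrodes count as adjacent.

    Returns
    -------
    dict mapping channel -> frozenset of neighbouring channels (symmetric,
    irreflexive).
    """
    if channels is None:
        channels = SCALP
    channels = list(channels)
    pos = np.array([POSITIONS[ch] for ch in channels])
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    neigh = {}
    for i, ch in enumerate(channels):
        close = (d[i] < threshold) & (d[i] > 0)
        neigh[ch] = frozenset(channels[j] for j in np.flatnonzero(close))
    return neigh
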