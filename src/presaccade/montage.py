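"""High-density electrode montage with virtual 10-20 grouping.

The default layout emulates a 128-channel geodesic sensor net on a spherical
head: channels are placed on the scalp sphere in a fixed, mirror-symmetric
arrangement, and subsets of channels are averaged into twenty "virtual 10-20"
electrodes (FrontalZ, CentralZ, ..., Occipital2).  The group membership table
ships with the package; channels listed in no group are recorded but excluded
from group-level analyses.

Left/right analysis (contralateral vs. ipsilateral recoding) relies on a
mirror pairing: every off-midline channel has a partner at the x-negated
position, and paired lateral groups (e.g. Parietal3/Parietal4) pair up
member-by-member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import FormatError, InvalidMontageError, PairingError

MIDLINE_GROUPS = ("FrontalZ", "CentralZ", "ParietalZ", "OccipitalZ")

#: Lateral groups come in (left, right) pairs whose member lists correspond
#: element-by-element under the mirror map.
GROUP_PAIRS = (
    ("FrontalPole1", "FrontalPole2"),
    ("Frontal3", "Frontal4"),
    ("Frontal7", "Frontal8"),
    ("Central3", "Central4"),
    ("Temporal3", "Temporal4"),
    ("Temporal5", "Temporal6"),
    ("Parietal3", "Parietal4"),
    ("Occipital1", "Occipital2"),
)


def load_virtual_groups() -> dict[str, list[int]]:
    """Load the shipped virtual 10-20 membership table (group -> indices)."""
    text = resources.files("presaccade.data").joinpath("virtual_1020.tsv").read_text()
    groups: dict[str, list[int]] = {}
    for line in text.strip().splitlines():
        name, members = line.split("\t")
        groups[name] = [int(m) for m in members.split(",")]
    return groups


@dataclass
class Montage:
    """Electrode names, positions (mm, head coordinates) and groupings."""

    channels: list[str]
    positions: np.ndarray
    fiducials: dict[str, np.ndarray] = field(default_factory=dict)
    virtual_groups: dict[str, list[str]] = field(default_factory=dict)
    mirror_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.channels) != len(set(self.channels)):
            raise FormatError("duplicate channel names in montage")
        if self.positions.shape != (len(self.channels), 3):
            raise FormatError("positions must be (n_channels, 3)")
        seen: dict[str, str] = {}
        for group, members in self.virtual_groups.items():
            for ch in members:
                if ch in seen:
                    raise InvalidMontageError(
                        f"channel {ch} in both {seen[ch]} and {group}"
                    )
                seen[ch] = group

    def index(self, channel: str) -> int:
        return self.channels.index(channel)

    def group_of(self, channel: str) -> str | None:
        """Virtual group containing ``channel``, or None if ungrouped."""
        for group, members in self.virtual_groups.items():
            if channel in members:
                return group
        return None

    def group_channels(self, group: str) -> list[str]:
        if group not in self.virtual_groups:
            raise KeyError(f"unknown virtual group {group!r}")
        return list(self.virtual_groups[group])

    def mirror_partner(self, channel: str) -> str:
        if channel not in self.mirror_map:
            raise PairingError(f"channel {channel} has no mirror partner")
        return self.mirror_map[channel]

    def copy(self) -> "Montage":
        return Montage(
            channels=list(self.channels),
            positions=self.positions.copy(),
            fiducials={k: np.array(v) for k, v in self.fiducials.items()},
            virtual_groups={k: list(v) for k, v in self.virtual_groups.items()},
            mirror_map=dict(self.mirror_map),
        )


def _unit(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Direction on the sphere: theta = polar angle from vertex, phi = azimuth
    from anterior midline (positive toward the right ear)."""
    t = np.deg2rad(theta_deg)
    p = np.deg2rad(phi_deg)
    return np.array([np.sin(t) * np.sin(p), np.sin(t) * np.cos(p), np.cos(t)])


# Angular slots for the midline groups, in the member order of the shipped
# table.  (theta, phi) with phi = 0 anterior, 180 posterior.
_MIDLINE_SLOTS: dict[str, list[tuple[float, float]]] = {
    "FrontalZ": [(25, 0), (31, 0), (37, 0), (43, 0), (49, 0), (55, 0)],
    "CentralZ": [(16, 0), (8, 0), (0, 0), (8, 180), (16, 180)],
    "ParietalZ": [(30, 180), (38, 180), (46, 180), (54, 180)],
    "OccipitalZ": [(64, 180), (72, 180), (80, 180)],
}

# Cluster centers for the left lateral groups (right = mirrored azimuth).
_LEFT_CENTERS: dict[str, tuple[float, float]] = {
    "FrontalPole1": (72, -18),
    "Frontal3": (54, -30),
    "Frontal7": (72, -55),
    "Central3": (40, -90),
    "Temporal3": (72, -90),
    "Temporal5": (72, -130),
    "Parietal3": (54, -150),
    "Occipital1": (72, -162),
}

# Deterministic within-cluster offsets (d_theta, d_phi) per member index.
_CLUSTER_OFFSETS = [(0, 0), (9, 0), (0, 14), (9, 14), (-9, 7), (0, -12)]


def make_montage(n_channels: int = 128, scalp_radius_mm: float = 92.0) -> Montage:
    """Build the default mirror-symmetric 128-channel montage.

    Channel names are ``E1`` ... ``E{n}``; positions lie on the sphere of
    radius ``scalp_radius_mm``.  Raises :class:`InvalidMontageError` when
    ``n_channels`` cannot host the shipped group table.
    """
    table = load_virtual_groups()
    max_idx = max(max(v) for v in table.values())
    if n_channels < max_idx:
        raise InvalidMontageError(
            f"montage needs at least {max_idx} channels, got {n_channels}"
        )

    angles: dict[int, tuple[float, float]] = {}
    for group in MIDLINE_GROUPS:
        for idx, slot in zip(table[group], _MIDLINE_SLOTS[group]):
            angles[idx] = slot
    for left_group, right_group in GROUP_PAIRS:
        theta_c, phi_c = _LEFT_CENTERS[left_group]
        for k, (li, ri) in enumerate(zip(table[left_group], table[right_group])):
            dt, dp = _CLUSTER_OFFSETS[k]
            angles[li] = (theta_c + dt, phi_c + dp)
            angles[ri] = (theta_c + dt, -(phi_c + dp))

    grouped = set(angles)
    free = sorted(set(range(1, n_channels + 1)) - grouped)
    if len(free) % 2:  # keep the layout mirror-complete
        raise InvalidMontageError("ungrouped channel count must be even")
    n_pairs = len(free) // 2
    # Ungrouped channels fill two inferior rings (cheek/neck positions).
    ring_a = [(95.0, -15.0 - 15.0 * k) for k in range(min(n_pairs, 11))]
    ring_b = [(110.0, -18.0 - 16.0 * k) for k in range(n_pairs - len(ring_a))]
    slots = ring_a + ring_b
    mirror_idx: dict[int, int] = {}
    for k in range(n_pairs):
        li, ri = free[2 * k], free[2 * k + 1]
        theta, phi = slots[k]
        angles[li] = (theta, phi)
        angles[ri] = (theta, -phi)
        mirror_idx[li], mirror_idx[ri] = ri, li
    for left_group, right_group in GROUP_PAIRS:
        for li, ri in zip(table[left_group], table[right_group]):
            mirror_idx[li], mirror_idx[ri] = ri, li
    for group in MIDLINE_GROUPS:
        for idx in table[group]:
            mirror_idx[idx] = idx

    channels = [f"E{i}" for i in range(1, n_channels + 1)]
    positions = np.array(
        [scalp_radius_mm * _unit(*angles[i]) for i in range(1, n_channels + 1)]
    )
    fiducials = {
        "nasion": np.array([0.0, scalp_radius_mm, 0.0]),
        "lpa": np.array([-scalp_radius_mm, 0.0, 0.0]),
        "rpa": np.array([scalp_radius_mm, 0.0, 0.0]),
        "vertex": np.array([0.0, 0.0, scalp_radius_mm]),
    }
    virtual_groups = {g: [f"E{i}" for i in idxs] for g, idxs in table.items()}
    mirror_map = {f"E{i}": f"E{j}" for i, j in mirror_idx.items()}
    return Montage(channels, positions, fiducials, virtual_groups, mirror_map)


def write_montage(montage: Montage, path: str | Path) -> Path:
    """Write whitespace-delimited ``name x y z`` rows; fiducials prefixed."""
    path = Path(path)
    lines = []
    for name, pos in montage.fiducials.items():
        lines.append(f"fid {name} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f}")
    for name, pos in zip(montage.channels, montage.positions):
        lines.append(f"{name} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_montage(path: str | Path, attach_groups: bool = True) -> Montage:
    """Read a montage text file and attach the shipped virtual 10-20 groups.

    Channels named ``E<n>`` pick up their group membership from the shipped
    table; missing fiducials disable registration (with a warning) but do not
    fail the read.
    """
    import warnings

    path = Path(path)
    channels: list[str] = []
    positions: list[list[float]] = []
    fiducials: dict[str, np.ndarray] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        if parts[0] == "fid":
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: bad fiducial row")
            fiducials[parts[1]] = np.array([float(x) for x in parts[2:5]])
            continue
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 'name x y z'")
        if parts[0] in channels:
            raise FormatError(f"{path}:{lineno}: duplicate channel {parts[0]}")
        channels.append(parts[0])
        positions.append([float(x) for x in parts[1:4]])
    if not fiducials:
        warnings.warn(
            f"{path}: no fiducial rows; electrode registration disabled",
            stacklevel=2,
        )
    pos = np.asarray(positions)
    groups: dict[str, list[str]] = {}
    if attach_groups:
        table = load_virtual_groups()
        present = set(channels)
        for g, idxs in table.items():
            members = [f"E{i}" for i in idxs if f"E{i}" in present]
            if members:
                groups[g] = members
    mirror = _mirror_map_from_positions(channels, pos)
    return Montage(channels, pos, fiducials, groups, mirror)


def _mirror_map_from_positions(
    channels: list[str], positions: np.ndarray, tol_mm: float = 1e-3
) -> dict[str, str]:
    """Recover the left/right pairing by matching x-negated positions."""
    mirror: dict[str, str] = {}
    flipped = positions * np.array([-1.0, 1.0, 1.0])
    for i, name in enumerate(channels):
        d = np.linalg.norm(flipped - positions[i], axis=1)
        j = int(np.argmin(d))
        if d[j] <= tol_mm:
            mirror[name] = channels[j]
    return mirror
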