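"""Residue-anchored reference frames and water-internal axis triads.

A hydration site is defined relative to a local coordinate system carried by
an amino-acid side chain.  The z-axis is the mean normal of all planes that
can be formed from triplets of a designated atom subset, sign-fixed so that
its angle alpha with the vector to a neighbouring residue's geometric centre
stays inside (-90 deg, 90 deg); this keeps the xy-plane orientation stable
under internal bond rotations (e.g. flipping of a carboxylate).  The x-axis
connects a two-atom subset, orthogonalised against z; y completes a
right-handed triad.  The frame origin is the geometric centre of the union
of both subsets.

Each water molecule additionally carries an internal triad built from its
O-H bond vectors; the dot-product autocorrelation of these axes measures
rotational relaxation while the water occupies a site.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .trajectory_io import AtomRecord, AtomSelection, Frame, Trajectory

__all__ = [
    "DegenerateGeometryError",
    "ReferenceFrameSpec",
    "LocalFrame",
    "WaterAxes",
    "DEFAULT_SUBSETS",
    "make_frame_spec",
    "mean_plane_normal",
    "build_frame",
    "to_local",
    "from_local",
    "water_axes",
    "water_axis_series",
]

_UNIT_TOL = 1e-9
_PARALLEL_TOL = 1e-6  # rad; raw x vs z degeneracy threshold


class DegenerateGeometryError(ValueError):
    """Raised when a geometric construction is ill-defined (collinear or
    parallel inputs)."""


#: Substitute side-chain subsets for common anchor residues.  These are
#: overridable configuration, not canonical values: any rigid subset with
#: >= 3 atoms for z and exactly 2 for x is valid.
DEFAULT_SUBSETS: Mapping[str, tuple[tuple[str, ...], tuple[str, str]]] = {
    "ASP": (("CB", "CG", "OD1", "OD2"), ("OD1", "OD2")),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"), ("CG", "CZ")),
    "HIS": (("CB", "CG", "ND1", "CD2", "CE1", "NE2"), ("ND1", "NE2")),
}


@dataclass(frozen=True)
class ReferenceFrameSpec:
    """Defines one residue-anchored frame.

    ``neighbor_residue`` fixes the sign of the z-axis: the frame is flipped,
    if needed, so the angle alpha between z and the origin->neighbour-centre
    vector lies in (-90 deg, 90 deg).  It has no default and must be chosen
    per site.
    """

    residue: tuple[str, int]
    z_subset: tuple[str, ...]
    x_subset: tuple[str, str]
    neighbor_residue: tuple[str, int]

    def __post_init__(self) -> None:
        if len(self.z_subset) < 3:
            raise ValueError("z_subset needs at least 3 atom names")
        if len(self.x_subset) != 2:
            raise ValueError("x_subset needs exactly 2 atom names")


def make_frame_spec(
    residue_name: str,
    residue: tuple[str, int],
    neighbor_residue: tuple[str, int],
    subsets: Mapping[str, tuple[tuple[str, ...], tuple[str, str]]] = DEFAULT_SUBSETS,
) -> ReferenceFrameSpec:
    """Build a spec from the per-residue-type subset table."""
    try:
        z_subset, x_subset = subsets[residue_name.upper()]
    except KeyError:
        raise KeyError(
            f"no default atom subsets for residue type {residue_name!r}; "
            "provide z_subset/x_subset explicitly"
        ) from None
    return ReferenceFrameSpec(
        residue=residue,
        z_subset=z_subset,
        x_subset=x_subset,
        neighbor_residue=neighbor_residue,
    )


@dataclass(frozen=True)
class LocalFrame:
    """Orthonormal right-handed triad (ex, ey, ez) at ``origin``.

    ``alpha`` is the angle (degrees) between ez and the origin->neighbour
    vector; the sign convention guarantees -90 < alpha < 90.
    """

    origin: np.ndarray
    ex: np.ndarray
    ey: np.ndarray
    ez: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        for v in (self.ex, self.ey, self.ez):
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise ValueError("frame axes must be unit vectors")
        if not -90.0 < self.alpha < 90.0:
            raise ValueError(f"alpha must lie in (-90, 90) deg, got {self.alpha}")

    def rotation(self) -> np.ndarray:
        """Rows are (ex, ey, ez): local = rotation() @ (r - origin)."""
        return np.stack([self.ex, self.ey, self.ez])


@dataclass(frozen=True)
class WaterAxes:
    """Internal triad of one water in one frame.

    Rx is the O->H1 unit vector, Rz the unit normal of the molecular plane
    (O->H1 x O->H2), and Ry = Rx x Rz.  Ry follows the construction
    literally, which makes the triad left-handed; handedness is irrelevant
    to the dot-product autocorrelations this triad feeds.
    """

    Rx: np.ndarray
    Ry: np.ndarray
    Rz: np.ndarray

    def axis(self, name: str) -> np.ndarray:
        return {"x": self.Rx, "y": self.Ry, "z": self.Rz}[name]


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"{what} has zero length")
    return v / n


def mean_plane_normal(points: np.ndarray) -> np.ndarray:
    """Mean unit normal over all 3-point combinations of ``points``.

    Each triplet's normal is sign-flipped to have a non-negative dot product
    with the first non-degenerate triplet's normal before averaging.  For
    the intended inputs -- rigid, near-planar side-chain subsets, whose
    triplet normals all share a hemisphere -- this makes the result
    independent of the atom order (up to overall sign, which build_frame
    fixes via the neighbour convention).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 3:
        raise ValueError("need at least three 3-vectors")
    scale = max(np.linalg.norm(points - points.mean(axis=0), axis=1).max(), 1e-12)
    reference = None
    normals = []
    for i, j, k in combinations(range(points.shape[0]), 3):
        n = np.cross(points[j] - points[i], points[k] - points[i])
        norm = np.linalg.norm(n)
        if norm < 1e-9 * scale**2:
            continue  # collinear triplet carries no plane
        n = n / norm
        if reference is None:
            reference = n
        elif float(n @ reference) < 0.0:
            n = -n
        normals.append(n)
    if reference is None:
        raise DegenerateGeometryError(
            "all triplets are collinear; no plane normal is defined"
        )
    return _unit(np.mean(normals, axis=0), "mean plane normal")


def _resolve_atom(
    topology: Sequence[AtomRecord], chain: str, resnum: int, name: str
) -> int:
    """Topology index of an atom; for altloc copies, the highest occupancy wins."""
    best = None
    for i, rec in enumerate(topology):
        if rec.chain == chain and rec.residue_number == resnum and rec.name == name:
            if best is None or rec.occupancy > topology[best].occupancy:
                best = i
    if best is None:
        raise KeyError(f"atom {name} of residue {chain}{resnum} not found in topology")
    return best


def _residue_center(
    topology: Sequence[AtomRecord], frame: Frame, chain: str, resnum: int
) -> np.ndarray:
    idx = [
        i
        for i, rec in enumerate(topology)
        if rec.chain == chain and rec.residue_number == resnum
    ]
    if not idx:
        raise KeyError(f"residue {chain}{resnum} not found in topology")
    return frame.coordinates[idx].mean(axis=0)


def build_frame(
    frame: Frame, topology: Sequence[AtomRecord], spec: ReferenceFrameSpec
) -> LocalFrame:
    """Construct the residue-anchored frame for one trajectory frame."""
    chain, resnum = spec.residue
    z_idx = [_resolve_atom(topology, chain, resnum, n) for n in spec.z_subset]
    x_idx = [_resolve_atom(topology, chain, resnum, n) for n in spec.x_subset]

    z_points = frame.coordinates[z_idx]
    ez = mean_plane_normal(z_points)

    union_idx = sorted(set(z_idx) | set(x_idx))
    origin = frame.coordinates[union_idx].mean(axis=0)

    neighbor = _residue_center(topology, frame, *spec.neighbor_residue)
    to_neighbor = _unit(neighbor - origin, "origin->neighbor vector")
    cos_alpha = float(np.clip(ez @ to_neighbor, -1.0, 1.0))
    if cos_alpha < 0.0:
        ez = -ez
        cos_alpha = -cos_alpha
    if cos_alpha <= np.cos(np.deg2rad(90.0) - 1e-9):
        # neighbour centre lies exactly in the xy-plane: sign undecidable
        raise DegenerateGeometryError(
            "neighbor direction perpendicular to z-axis; alpha convention undefined"
        )
    alpha = float(np.rad2deg(np.arccos(cos_alpha)))

    raw_x = frame.coordinates[x_idx[0]] - frame.coordinates[x_idx[1]]
    raw_x = _unit(raw_x, "raw x-axis")
    sin_angle = np.linalg.norm(np.cross(raw_x, ez))
    if sin_angle < _PARALLEL_TOL:
        raise DegenerateGeometryError("x-subset vector is parallel to the z-axis")
    ex = _unit(raw_x - (raw_x @ ez) * ez)
    ey = np.cross(ez, ex)
    return LocalFrame(origin=origin, ex=ex, ey=ey, ez=ez, alpha=alpha)


def to_local(coords: np.ndarray, frame: LocalFrame) -> np.ndarray:
    """Express lab-frame coordinates in the local frame."""
    coords = np.asarray(coords, dtype=float)
    return (coords - frame.origin) @ frame.rotation().T


def from_local(local_coords: np.ndarray, frame: LocalFrame) -> np.ndarray:
    """Inverse of :func:`to_local`."""
    local_coords = np.asarray(local_coords, dtype=float)
    return local_coords @ frame.rotation() + frame.origin


def water_axes(O: np.ndarray, H1: np.ndarray, H2: np.ndarray) -> WaterAxes:
    """Internal axes of one water from its three atom positions.

    H1/H2 ordering matters for Rx (hydrogens are ordered by atom serial
    upstream); Rz and Ry keep consistent handedness either way.
    """
    oh1 = np.asarray(H1, float) - np.asarray(O, float)
    oh2 = np.asarray(H2, float) - np.asarray(O, float)
    rx = _unit(oh1, "O-H1 bond vector")
    normal = np.cross(oh1, oh2)
    if np.linalg.norm(normal) < 1e-9 * np.linalg.norm(oh1) * np.linalg.norm(oh2):
        raise DegenerateGeometryError("O-H bond vectors are parallel")
    rz = _unit(normal)
    ry = np.cross(rx, rz)
    return WaterAxes(Rx=rx, Ry=ry, Rz=rz)


def water_axis_series(
    traj: Trajectory,
    spec: ReferenceFrameSpec,
    water_oxygens: AtomSelection,
) -> np.ndarray:
    """Water internal axes for every water and frame, in the residue frame.

    Returns an array of shape (n_waters, n_frames, 3, 3) whose last two
    axes hold the rows (Rx, Ry, Rz).  For each water oxygen the two
    hydrogens of the same residue are identified by element and ordered by
    atom serial (the H1/H2 tie-break Rx depends on).  Waters without two
    hydrogens get NaN entries, which downstream correlation code rejects
    only where the water is bound.
    """
    o_idx = water_oxygens.as_array()
    n_w = len(o_idx)

    # hydrogen lookup per water residue, serial-ordered
    h_pairs: list[tuple[int, int] | None] = []
    by_res: dict[tuple[str, int], list[int]] = {}
    for i, rec in enumerate(traj.topology):
        if rec.is_hydrogen_like:
            by_res.setdefault((rec.chain, rec.residue_number), []).append(i)
    for i in o_idx:
        rec = traj.topology[i]
        hs = sorted(
            by_res.get((rec.chain, rec.residue_number), []),
            key=lambda k: traj.topology[k].serial,
        )
        h_pairs.append((hs[0], hs[1]) if len(hs) >= 2 else None)

    have_h = np.array([p is not None for p in h_pairs])
    h1_idx = np.array([p[0] if p else 0 for p in h_pairs])
    h2_idx = np.array([p[1] if p else 0 for p in h_pairs])

    axes = np.full((n_w, traj.n_frames, 3, 3), np.nan)
    for k, frame in enumerate(traj.frames):
        local = build_frame(frame, traj.topology, spec)
        R = local.rotation()
        O = frame.coordinates[o_idx]
        oh1 = frame.coordinates[h1_idx] - O
        oh2 = frame.coordinates[h2_idx] - O
        rx = oh1 / np.linalg.norm(oh1, axis=1, keepdims=True)
        cross = np.cross(oh1, oh2)
        norms = np.linalg.norm(cross, axis=1, keepdims=True)
        degenerate = have_h & (norms[:, 0] < 1e-12)
        if degenerate.any():
            j = int(np.flatnonzero(degenerate)[0])
            raise DegenerateGeometryError(
                f"parallel O-H bond vectors for water at topology index "
                f"{o_idx[j]} in frame {k}"
            )
        rz = cross / norms
        ry = np.cross(rx, rz)
        # express in the residue frame: row vectors times R^T
        triad = np.stack([rx, ry, rz], axis=1)  # (n_w, 3, 3)
        axes[have_h, k] = triad[have_h] @ R.T
    return axes
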