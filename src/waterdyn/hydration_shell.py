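"""Hydration-shell definition: radial distribution, cutoff, occupancy.

The "bound" state of a water at a site is purely radial: its oxygen lies
within a cutoff of the residue-anchored frame origin.  The cutoff is the
first minimum of the solvent radial distribution function g(r) computed
around that origin, mirroring how a first hydration layer is conventionally
delimited.  Distances honour the minimum-image convention when an
orthorhombic box is present.

Defaults: bin width 0.05 A, r_max 8 A, smoothing window 5 bins.  The
distance criterion uses the frame origin (one number per residue); a
per-atom-subset minimum-distance variant is available via
``mode="subset-min"`` and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .reference_frames import ReferenceFrameSpec, build_frame, _resolve_atom
from .trajectory_io import AtomRecord, AtomSelection, Trajectory

__all__ = [
    "RDFProfile",
    "OccupancySeries",
    "radial_distribution",
    "first_minimum",
    "occupancy_matrix",
    "write_rdf_tsv",
    "write_occupancy_tsv",
]


@dataclass
class RDFProfile:
    """Solvent radial distribution around a site origin.

    ``g`` is normalised so that an ideal gas gives g ~ 1; ``mean_density``
    (count / A^3) is the normalising solvent density over the r_max sphere.
    ``raw_counts`` keeps the un-normalised per-bin pair counts so that
    conservation (sum of counts == counted pairs) stays checkable.
    """

    bin_centers: np.ndarray
    g: np.ndarray
    bin_width: float
    r_max: float
    n_frames: int
    mean_density: float
    raw_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")
        spacing = np.diff(self.bin_centers)
        if np.any(spacing <= 0) or not np.allclose(spacing, self.bin_width, atol=1e-9):
            raise ValueError("bin centers must increase by bin_width")


@dataclass
class OccupancySeries:
    """Per-water, per-frame shell membership indicators.

    ``B`` has shape (N_W, N_f) with entries in {0, 1}; row order follows
    ``water_ids``.
    """

    water_ids: list[str]
    B: np.ndarray
    timestep: float
    cutoff: float

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B)
        if self.B.ndim != 2 or self.B.shape[0] != len(self.water_ids):
            raise ValueError("B must be (n_waters, n_frames) matching water_ids")
        if self.B.shape[1] < 1:
            raise ValueError("need at least one frame")
        if not np.isin(self.B, (0, 1)).all():
            raise ValueError("B entries must be 0 or 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        self.B = self.B.astype(np.int8)

    @property
    def n_waters(self) -> int:
        return self.B.shape[0]

    @property
    def n_frames(self) -> int:
        return self.B.shape[1]


def _minimum_image(disp: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return disp
    return disp - box * np.round(disp / box)


def _site_distances(
    coords: np.ndarray,
    solvent_idx: np.ndarray,
    origin: np.ndarray,
    subset_coords: np.ndarray | None,
    box: np.ndarray | None,
) -> np.ndarray:
    """Distances from solvent atoms to the site (origin or nearest subset atom)."""
    if subset_coords is None:
        disp = _minimum_image(coords[solvent_idx] - origin, box)
        return np.linalg.norm(disp, axis=1)
    disp = _minimum_image(
        coords[solvent_idx][:, None, :] - subset_coords[None, :, :], box
    )
    return np.linalg.norm(disp, axis=2).min(axis=1)


def _frame_subset_coords(
    frame_coords: np.ndarray,
    topology: Sequence[AtomRecord],
    spec: ReferenceFrameSpec,
) -> np.ndarray:
    chain, resnum = spec.residue
    idx = sorted(
        {_resolve_atom(topology, chain, resnum, n) for n in (*spec.z_subset, *spec.x_subset)}
    )
    return frame_coords[idx]


def radial_distribution(
    traj: Trajectory,
    spec: ReferenceFrameSpec,
    solvent: AtomSelection,
    bin_width: float = 0.05,
    r_max: float = 8.0,
    mode: str = "origin",
) -> RDFProfile:
    """Solvent g(r) around the per-frame local-frame origin.

    Counts in each spherical shell are normalised by the exact shell volume
    and by the mean solvent density within the r_max sphere, so a uniform
    ideal gas yields g ~ 1.  With ``mode="subset-min"`` the distance is the
    minimum over the frame-defining atom subset instead of the origin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if r_max <= bin_width:
        raise ValueError("r_max must exceed bin_width")
    if len(solvent) == 0:
        raise ValueError("empty solvent selection")
    if mode not in ("origin", "subset-min"):
        raise ValueError(f"unknown RDF mode {mode!r}")

    solvent_idx = solvent.as_array()
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins, dtype=np.int64)

    for frame in traj.frames:
        if frame.box is not None and r_max > frame.box.min() / 2:
            raise ValueError(
                f"r_max={r_max} A exceeds half the smallest box edge "
                f"({frame.box.min() / 2:.3f} A)"
            )
        local = build_frame(frame, traj.topology, spec)
        subset = (
            _frame_subset_coords(frame.coordinates, traj.topology, spec)
            if mode == "subset-min"
            else None
        )
        r = _site_distances(
            frame.coordinates, solvent_idx, local.origin, subset, frame.box
        )
        hist, _ = np.histogram(r, bins=edges)
        counts += hist

    n_frames = traj.n_frames
    sphere_volume = 4.0 / 3.0 * np.pi * edges[-1] ** 3
    mean_density = counts.sum() / (n_frames * sphere_volume)
    shell_volumes = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = counts / (n_frames * shell_volumes * mean_density)
    g = np.nan_to_num(g)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return RDFProfile(
        bin_centers=centers,
        g=g,
        bin_width=bin_width,
        r_max=float(edges[-1]),
        n_frames=n_frames,
        mean_density=float(mean_density),
        raw_counts=counts,
    )


def first_minimum(
    profile: RDFProfile, smooth_window: int = 5, min_depth_ratio: float = 0.35
) -> float:
    """Hydration cutoff: first interior local minimum of smoothed g(r)
    after the first local maximum exceeding 1.

    Smoothing is a centred moving average weighted by shell volume, i.e. a
    kernel estimate of g built from aggregated counts; this keeps the
    estimate well-supported at small r, where individual bins hold tiny
    volumes and raw g is dominated by Poisson noise.  To be accepted, a
    candidate minimum must additionally descend to at most
    ``min_depth_ratio`` times the running maximum of g since the peak, so
    noise wiggles on a hydration plateau are skipped (set the ratio to 1 to
    disable).  Exact ties (a flat plateau of minimal values, as arises when
    a region is fully depleted) resolve to the plateau's midpoint bin.
    Boundary bins never qualify.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    if not 0 < min_depth_ratio <= 1:
        raise ValueError("min_depth_ratio must lie in (0, 1]")
    g = np.asarray(profile.g, dtype=float)
    if g.size < max(smooth_window, 3):
        raise ValueError("profile too short for the smoothing window")
    if smooth_window > 1:
        inner = profile.bin_centers - profile.bin_width / 2.0
        outer = profile.bin_centers + profile.bin_width / 2.0
        weight = outer**3 - inner**3  # proportional to shell volume
        kernel = np.ones(smooth_window)
        num = np.convolve(g * weight, kernel, mode="same")
        den = np.convolve(weight, kernel, mode="same")
        smoothed = num / den
    else:
        smoothed = g

    # locate the first local maximum with g > 1
    peak = None
    for i in range(1, g.size - 1):
        if (
            smoothed[i] > 1.0
            and smoothed[i] >= smoothed[i - 1]
            and smoothed[i] >= smoothed[i + 1]
        ):
            peak = i
            break
    if peak is None:
        raise ValueError("no first minimum found: no local maximum with g > 1")

    run_max = smoothed[peak]
    i = peak + 1
    while i < g.size - 1:
        run_max = max(run_max, smoothed[i])
        if smoothed[i] < smoothed[i - 1]:
            if smoothed[i + 1] > smoothed[i]:
                # strict interior minimum
                if smoothed[i] <= min_depth_ratio * run_max:
                    return float(profile.bin_centers[i])
            elif smoothed[i + 1] == smoothed[i]:
                j = i
                while j < g.size - 1 and smoothed[j + 1] == smoothed[j]:
                    j += 1
                if (
                    j < g.size - 1
                    and smoothed[j + 1] > smoothed[j]
                    and smoothed[i] <= min_depth_ratio * run_max
                ):
                    return float(profile.bin_centers[(i + j) // 2])
                i = j
                continue
        i += 1
    raise ValueError("no first minimum found before the profile boundary")


def occupancy_matrix(
    traj: Trajectory,
    spec: ReferenceFrameSpec,
    water_oxygens: AtomSelection,
    cutoff: float,
    mode: str = "origin",
) -> OccupancySeries:
    """Indicator matrix B[j, k] = 1 iff water j's oxygen is within ``cutoff``
    of the frame-k site origin."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    idx = water_oxygens.as_array()
    for i in idx:
        rec = traj.topology[i]
        if rec.element.upper() != "O":
            raise ValueError(
                f"water selection contains non-oxygen atom {rec.name} "
                f"(element {rec.element}) at index {i}"
            )
    B = np.zeros((len(idx), traj.n_frames), dtype=np.int8)
    for k, frame in enumerate(traj.frames):
        local = build_frame(frame, traj.topology, spec)
        subset = (
            _frame_subset_coords(frame.coordinates, traj.topology, spec)
            if mode == "subset-min"
            else None
        )
        r = _site_distances(frame.coordinates, idx, local.origin, subset, frame.box)
        B[:, k] = r <= cutoff
    water_ids = [
        f"{traj.topology[i].chain}:{traj.topology[i].residue_number}:"
        f"{traj.topology[i].residue_name}"
        for i in idx
    ]
    return OccupancySeries(
        water_ids=water_ids, B=B, timestep=traj.timestep, cutoff=cutoff
    )


def write_rdf_tsv(path: str | Path, profile: RDFProfile) -> None:
    with Path(path).open("w") as fh:
        fh.write("bin_center_A\tg\n")
        for r, g in zip(profile.bin_centers, profile.g):
            fh.write(f"{r:.4f}\t{g:.6f}\n")


def write_occupancy_tsv(path: str | Path, series: OccupancySeries) -> None:
    with Path(path).open("w") as fh:
        times = "\t".join(
            f"{k * series.timestep:.3f}" for k in range(series.n_frames)
        )
        fh.write(f"water_id\t{times}\n")
        for wid, row in zip(series.water_ids, series.B):
            fh.write(wid + "\t" + "\t".join(str(int(b)) for b in row) + "\n")
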