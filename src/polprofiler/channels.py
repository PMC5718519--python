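"""Two-probe internal channel-volume computation on a voxel grid.

A large probe (default 7.0 A) rolled over the van der Waals surface defines
the molecular envelope; a small probe (default 2.7 A) defines the solvent-
excluded body.  Channels are the connected components (26-connectivity) of
envelope-minus-body space, reported in cubic Angstrom.

Probe semantics: the large-probe region is computed with solvent
flood-filled from the grid boundary, so internal pockets the probe cannot
reach count as interior.  The subtracted small-probe region is the plain
rolling-probe closure without a reachability constraint, so sealed cavities
survive the subtraction and are reported as components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .chemtables import vdw_radius
from .structure_io import Selection, Structure


class GridError(ValueError):
    pass


@dataclass
class VoxelGrid:
    origin: np.ndarray       # (3,) A
    spacing: float           # A
    dims: tuple[int, int, int]
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def voxel_centers(self, mask: np.ndarray) -> np.ndarray:
        idx = np.argwhere(mask)
        return self.origin + (idx + 0.5) * self.spacing

    @property
    def voxel_volume(self) -> float:
        return self.spacing ** 3


@dataclass
class Channel:
    component_id: int
    voxel_count: int
    volume: float            # A^3
    bounding_box: tuple[np.ndarray, np.ndarray]
    min_dist_dna: float | None = None
    min_dist_dntp: float | None = None
    outer: bool = False


@dataclass
class ChannelSet:
    channels: list[Channel]
    grid: VoxelGrid
    labels: np.ndarray
    r_big: float
    r_small: float
    spacing: float

    def volumes(self) -> list[float]:
        return sorted((c.volume for c in self.channels), reverse=True)

    def total_volume(self) -> float:
        return float(sum(c.volume for c in self.channels))


def _atom_arrays(atoms: Selection | list) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(atoms, Selection):
        coords = atoms.coords()
        radii = np.array([vdw_radius(a.element) for a in atoms.atoms])
    else:
        coords = np.array([a.coords for a in atoms]).reshape(-1, 3)
        radii = np.array([vdw_radius(a.element) for a in atoms])
    if coords.shape[0] == 0:
        raise GridError("no atoms to grid")
    return coords, radii


def make_grid(coords: np.ndarray, radii: np.ndarray, probe: float,
              spacing: float = 0.5, extra_pad: float = 2.0) -> VoxelGrid:
    """Grid covering all atoms plus their radii, the probe and padding."""
    if spacing <= 0:
        raise GridError("spacing must be positive")
    pad = float(radii.max() + probe + extra_pad)
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    dims = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1
                 for i in range(3))
    return VoxelGrid(origin=lo, spacing=spacing, dims=dims)


def _rasterize_spheres(grid: VoxelGrid, coords: np.ndarray,
                       radii: np.ndarray) -> np.ndarray:
    """Boolean mask of voxel centers inside any sphere."""
    mask = np.zeros(grid.dims, dtype=bool)
    sp = grid.spacing
    for center, r in zip(coords, radii):
        rel = (center - grid.origin) / sp - 0.5
        lo = np.maximum(np.floor(rel - r / sp).astype(int), 0)
        hi = np.minimum(np.ceil(rel + r / sp).astype(int) + 1,
                        np.array(grid.dims))
        if np.any(lo >= hi):
            continue
        ii, jj, kk = np.meshgrid(*(np.arange(lo[d], hi[d])
                                   for d in range(3)), indexing="ij")
        d2 = ((ii - rel[0]) ** 2 + (jj - rel[1]) ** 2 +
              (kk - rel[2]) ** 2) * sp * sp
        sub = d2 <= r * r
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= sub
    return mask


_FACE = ndimage.generate_binary_structure(3, 1)      # 6-connectivity
_FULL = np.ones((3, 3, 3), dtype=bool)               # 26-connectivity


def _boundary_connected(mask: np.ndarray) -> np.ndarray:
    """Subset of ``mask`` 6-connected to the grid boundary."""
    labels, n = ndimage.label(mask, structure=_FACE)
    if n == 0:
        return mask.copy()
    edge_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            edge_labels.update(np.unique(face[face > 0]).tolist())
    keep = np.isin(labels, sorted(edge_labels))
    return keep


def excluded_region(atoms: Selection | list, probe: float,
                    grid: VoxelGrid | None = None, spacing: float = 0.5,
                    seal_cavities: bool = True) -> tuple[np.ndarray,
                                                         VoxelGrid]:
    """Probe-excluded (molecular) region for the given probe radius.

    The probe-accessible region is every voxel whose center lies at least
    r_atom + r_probe from every atom center; the excluded region is its
    complement dilated back by the probe radius (two distance transforms:
    the standard rolling-probe closure).  With ``seal_cavities`` the
    accessible region is first restricted to the component connected to the
    grid boundary, so probe-unreachable pockets count as excluded.
    """
    coords, radii = _atom_arrays(atoms)
    if grid is None:
        grid = make_grid(coords, radii, probe, spacing=spacing)
    else:
        pad_needed = coords.min(axis=0) - (radii.max() + probe)
        if np.any(grid.origin > pad_needed + grid.spacing):
            raise GridError("grid too small for atoms plus probe padding")
    occupied_dilated = _rasterize_spheres(grid, coords, radii + probe)
    if probe <= 0:
        return occupied_dilated, grid
    accessible = ~occupied_dilated
    if seal_cavities:
        accessible = _boundary_connected(accessible)
    # distance (A) from every voxel to the nearest accessible voxel
    dist = ndimage.distance_transform_edt(
        ~accessible, sampling=[grid.spacing] * 3)
    excluded = dist > probe
    return excluded, grid


def channel_volumes(atoms: Selection | list, r_big: float = 7.0,
                    r_small: float = 2.7, spacing: float = 0.5,
                    min_volume: float = 100.0) -> ChannelSet:
    """Label channel components between the two probe surfaces.

    channel = excluded(r_big, sealed) AND NOT excluded(r_small, unsealed)
    AND NOT inside any atom; components below ``min_volume`` (default
    100 A^3) are dropped.
    """
    coords, radii = _atom_arrays(atoms)
    grid = make_grid(coords, radii, r_big, spacing=spacing)
    big, _ = excluded_region(atoms, r_big, grid=grid, seal_cavities=True)
    small, _ = excluded_region(atoms, r_small, grid=grid,
                               seal_cavities=False)
    inside = _rasterize_spheres(grid, coords, radii)
    mask = big & ~small & ~inside
    labels, n = ndimage.label(mask, structure=_FULL)
    channels = []
    if n:
        counts = np.bincount(labels.ravel())
        for cid in range(1, n + 1):
            volume = counts[cid] * grid.voxel_volume
            if volume < min_volume:
                labels[labels == cid] = 0
                continue
            idx = np.argwhere(labels == cid)
            lo = grid.origin + idx.min(axis=0) * grid.spacing
            hi = grid.origin + (idx.max(axis=0) + 1) * grid.spacing
            channels.append(Channel(
                component_id=cid, voxel_count=int(counts[cid]),
                volume=float(volume), bounding_box=(lo, hi)))
    channels.sort(key=lambda c: -c.volume)
    grid.masks["channel"] = mask
    return ChannelSet(channels=channels, grid=grid, labels=labels,
                      r_big=r_big, r_small=r_small, spacing=spacing)


def annotate_channels(cs: ChannelSet, s: Structure,
                      outer_threshold: float = 5.0,
                      max_probe_points: int = 4000) -> ChannelSet:
    """Annotate each component with its minimum distance to DNA and dNTP
    atoms; components farther than ``outer_threshold`` from both are
    flagged as outer channels."""
    from scipy.spatial import cKDTree

    dna = np.array([a.coords for r in s.residues_of("dna")
                    for a in r.atoms]).reshape(-1, 3)
    dntp = np.array([a.coords for r in s.residues_of("dntp_ligand")
                     for a in r.atoms]).reshape(-1, 3)
    trees = {
        "dna": cKDTree(dna) if len(dna) else None,
        "dntp": cKDTree(dntp) if len(dntp) else None,
    }
    for channel in cs.channels:
        pts = cs.grid.voxel_centers(cs.labels == channel.component_id)
        if len(pts) > max_probe_points:
            step = len(pts) // max_probe_points + 1
            pts = pts[::step]
        for key, attr in (("dna", "min_dist_dna"),
                          ("dntp", "min_dist_dntp")):
            tree = trees[key]
            if tree is None:
                setattr(channel, attr, None)
                continue
            setattr(channel, attr, float(tree.query(pts)[0].min()))
        dists = [d for d in (channel.min_dist_dna, channel.min_dist_dntp)
                 if d is not None]
        channel.outer = bool(dists) and min(dists) > outer_threshold
    return cs


def write_channel_cloud(cs: ChannelSet, path, stride: int = 1) -> None:
    """Channel voxels as a PDB pseudo-atom cloud for visualisation."""
    lines = []
    serial = 0
    for channel in cs.channels:
        pts = cs.grid.voxel_centers(cs.labels == channel.component_id)
        for p in pts[::stride]:
            serial += 1
            lines.append(
                f"HETATM{serial % 100000:5d}  Q   CHN X{channel.component_id % 10000:4d}"
                f"    {p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00"
                f"           X")
    lines.append("END")
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")
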