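"""Interface geometry and cavity metrics.

Four per-frame observables characterize a dimer interface and its binding
pockets:

* :func:`centroid_distance` — Euclidean distance between the geometric
  centers of two atom selections (the two protomers).
* :func:`sasa` — solvent-accessible surface area by the Shrake–Rupley
  method: quasi-uniform test points on each solvent-expanded sphere
  (van der Waals radius + probe radius, probe 1.4 Å by default), a point
  being exposed iff outside every other expanded sphere.
* :func:`contact_area` — buried surface between two chains,
  (SASA(A) + SASA(B) − SASA(A∪B)) / 2.
* :func:`pocket_volume` — POVME-style grid count: points of a regular grid
  inside an inclusion sphere that fall outside every solvent-expanded
  protein atom, times the grid-cell volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomRecord

__all__ = ["RadiiTable", "PocketSpec", "centroid_distance", "sasa",
           "contact_area", "pocket_volume", "sphere_points"]


@dataclass(frozen=True)
class RadiiTable:
    """Van der Waals radii by element, plus the solvent probe radius (Å)."""

    radii: dict[str, float] = field(default_factory=dict)
    probe: float = 1.4

    def __post_init__(self) -> None:
        if not self.radii:
            object.__setattr__(self, "radii", _load_default_radii())
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("radii must be > 0")
        if self.probe < 0:
            raise ValueError("probe radius must be ≥ 0")

    def radius(self, element: str) -> float:
        el = element.strip()
        for key in (el, el.capitalize(), el.upper()):
            if key in self.radii:
                return self.radii[key]
        raise KeyError(f"no van der Waals radius for element {element!r}")

    def for_topology(self, topology: list[AtomRecord],
                     indices=None) -> np.ndarray:
        idx = range(len(topology)) if indices is None else indices
        return np.array([self.radius(topology[i].element) for i in idx])


def _load_default_radii() -> dict[str, float]:
    text = resources.files("allopath.data").joinpath("vdw_radii.tsv").read_text()
    radii = {}
    for line in text.splitlines()[1:]:
        if line.strip():
            el, r = line.split("\t")
            radii[el] = float(r)
    return radii


@dataclass(frozen=True)
class PocketSpec:
    """Grid-volume parameters for one pocket.

    The inclusion sphere is centered on the pocket-lining residue centroid
    unless an explicit ``center`` is given.
    """

    lining: object = None      # ResidueSelection of the pocket lining
    center: tuple[float, float, float] | None = None
    inclusion_radius: float = 10.0
    grid_spacing: float = 0.5

    def __post_init__(self) -> None:
        if not self.inclusion_radius > self.grid_spacing > 0:
            raise ValueError("need inclusion_radius > grid_spacing > 0")


def centroid_distance(frame: np.ndarray, sel_a: np.ndarray,
                      sel_b: np.ndarray) -> float:
    """Distance between the unweighted geometric centers of two selections."""
    sel_a, sel_b = np.asarray(sel_a, int), np.asarray(sel_b, int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError("selections must be nonempty")
    frame = np.asarray(frame, float)
    return float(np.linalg.norm(frame[sel_a].mean(axis=0)
                                - frame[sel_b].mean(axis=0)))


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit-sphere points (golden-section spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sasa(frame: np.ndarray, radii: np.ndarray | RadiiTable,
         topology: list[AtomRecord] | None = None,
         probe: float = 1.4, n_sphere_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley.

    ``radii`` is either a per-atom radius array (Å, without probe) or a
    :class:`RadiiTable`, in which case ``topology`` supplies the elements
    and the table's own probe radius is used.
    """
    frame = np.asarray(frame, float)
    if isinstance(radii, RadiiTable):
        if topology is None:
            raise ValueError("topology required when passing a RadiiTable")
        r = radii.for_topology(topology)
        probe = radii.probe
    else:
        r = np.asarray(radii, float)
    if len(r) != len(frame):
        raise ValueError("one radius per atom required")
    return _sasa_arrays(frame, r, probe, n_sphere_points)


def sasa_with_table(frame: np.ndarray, topology: list[AtomRecord],
                    table: RadiiTable | None = None,
                    n_sphere_points: int = 960) -> np.ndarray:
    """Convenience wrapper: per-atom SASA using a radii table and topology."""
    table = table or RadiiTable()
    r = table.for_topology(topology)
    return _sasa_arrays(frame, r, table.probe, n_sphere_points)


def _sasa_arrays(frame: np.ndarray, r: np.ndarray, probe: float,
                 n_sphere_points: int) -> np.ndarray:
    frame = np.asarray(frame, float)
    expanded = np.asarray(r, float) + probe
    unit = sphere_points(n_sphere_points)
    tree = cKDTree(frame)
    rmax = expanded.max()
    areas = np.empty(len(frame))
    for i in range(len(frame)):
        pts = frame[i] + expanded[i] * unit
        cand = tree.query_ball_point(frame[i], expanded[i] + rmax)
        neigh = [j for j in cand if j != i
                 and np.linalg.norm(frame[j] - frame[i]) < expanded[i] + expanded[j]]
        if neigh:
            d2 = ((pts[:, None, :] - frame[neigh][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (expanded[np.asarray(neigh)] ** 2)[None, :]).any(axis=1)
            exposed = int((~buried).sum())
        else:
            exposed = n_sphere_points
        areas[i] = exposed / n_sphere_points * 4.0 * np.pi * expanded[i] ** 2
    return areas


def contact_area(frame: np.ndarray, topology: list[AtomRecord],
                 sel_a: np.ndarray, sel_b: np.ndarray,
                 table: RadiiTable | None = None,
                 n_sphere_points: int = 960) -> float:
    """Buried surface area between two disjoint atom selections (Å²).

    ``(SASA(A alone) + SASA(B alone) − SASA(A∪B)) / 2``; negative quadrature
    noise is floored at zero with a warning.
    """
    table = table or RadiiTable()
    sel_a, sel_b = np.asarray(sel_a, int), np.asarray(sel_b, int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError("selections must be nonempty")
    if np.intersect1d(sel_a, sel_b).size:
        raise ValueError("selections must be disjoint")
    frame = np.asarray(frame, float)
    r_a = table.for_topology(topology, sel_a)
    r_b = table.for_topology(topology, sel_b)
    both = np.concatenate([sel_a, sel_b])
    r_ab = np.concatenate([r_a, r_b])
    a_alone = _sasa_arrays(frame[sel_a], r_a, table.probe, n_sphere_points).sum()
    b_alone = _sasa_arrays(frame[sel_b], r_b, table.probe, n_sphere_points).sum()
    combined = _sasa_arrays(frame[both], r_ab, table.probe, n_sphere_points).sum()
    area = 0.5 * (a_alone + b_alone - combined)
    if area < 0:
        if area < -1.0:
            warnings.warn(f"contact area {area:.2f} Å² below zero beyond "
                          "quadrature noise; flooring at 0")
        area = 0.0
    return float(area)


def pocket_volume(frame: np.ndarray, topology: list[AtomRecord],
                  pocket: PocketSpec, table: RadiiTable | None = None,
                  lining_indices: np.ndarray | None = None) -> float:
    """Solvent-accessible pocket volume (Å³) by inclusion-sphere grid count.

    A regular grid of spacing ``pocket.grid_spacing`` covers the inclusion
    sphere; a grid point counts toward the volume iff it lies inside the
    sphere and outside every solvent-expanded protein atom.

    ``lining_indices`` (atom indices of the pocket-lining residues) defines
    the sphere center as their centroid when ``pocket.center`` is not given.
    """
    table = table or RadiiTable()
    frame = np.asarray(frame, float)
    if pocket.center is not None:
        center = np.asarray(pocket.center, float)
    else:
        if lining_indices is None or len(lining_indices) == 0:
            raise ValueError("pocket needs an explicit center or lining atoms")
        center = frame[np.asarray(lining_indices, int)].mean(axis=0)

    h = pocket.grid_spacing
    R = pocket.inclusion_radius
    ax = np.arange(-R, R + h / 2, h)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1) + center
    inside = ((pts - center) ** 2).sum(axis=1) <= R * R
    pts = pts[inside]
    if len(pts) == 0:
        raise ValueError("inclusion sphere contains no grid points; "
                         "increase the radius or refine the grid")

    if len(frame):
        expanded = table.for_topology(topology) + table.probe
        tree = cKDTree(frame)
        rmax = expanded.max()
        neighbors = tree.query_ball_point(pts, rmax)
        free = np.ones(len(pts), dtype=bool)
        for p, neigh in enumerate(neighbors):
            if not neigh:
                continue
            d2 = ((frame[neigh] - pts[p]) ** 2).sum(axis=1)
            if (d2 < expanded[np.asarray(neigh)] ** 2).any():
                free[p] = False
        count = int(free.sum())
    else:
        count = len(pts)
    return float(count) * h ** 3
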