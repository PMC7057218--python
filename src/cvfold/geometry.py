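"""Characteristic vectors (CVs) and the complete CV graph.

A characteristic vector summarises a short peptide window: it points from
the centroid of the window's C-alpha atoms to the centroid of its carbonyl
O atoms.  Over overlapping tripeptides the CV field smooths the backbone
into a descriptor whose modulus and inter-vector angles separate helices
(modulus ~2.2 A, consecutive angles 5-10 deg) from strands (~1.4 A,
50-55 deg).  All pairwise angles and midpoint distances are kept in a
complete graph so that both secondary structure (near-diagonal relations)
and tertiary structure (cross-fragment relations) can be queried.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from .structures import ConnectedStretch

DEGENERATE_MODULUS = 1e-9


class UndefinedAngleError(ValueError):
    """Angle request involving a zero-modulus (degenerate) CV."""


@dataclasses.dataclass
class CharacteristicVector:
    origin: np.ndarray            # centroid of window CA atoms
    tip: np.ndarray               # centroid of window carbonyl O atoms
    window: tuple[int, ...]       # residue indices local to the stretch
    stretch_index: int = 0

    @property
    def vector(self) -> np.ndarray:
        return self.tip - self.origin

    @property
    def modulus(self) -> float:
        return float(np.linalg.norm(self.vector))

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.origin + self.tip)

    @property
    def degenerate(self) -> bool:
        return self.modulus < DEGENERATE_MODULUS


def compute_cvs(stretch: ConnectedStretch, window: int = 3,
                stretch_index: int = 0) -> list[CharacteristicVector]:
    """Sliding-window CVs along one connected stretch, N to C.

    Returns ``len(stretch) - window + 1`` vectors (empty if the stretch is
    shorter than the window); consecutive CVs overlap by ``window - 1``
    residues so each residue joins at most ``window`` vectors.
    """
    if window < 3:
        raise ValueError("CV window must be >= 3 residues")
    n = len(stretch)
    if n < window:
        return []
    ca = stretch.ca_coords()
    ox = np.array([r.coord("O") for r in stretch.residues])
    cvs = []
    for i in range(n - window + 1):
        sel = slice(i, i + window)
        cvs.append(CharacteristicVector(
            origin=ca[sel].mean(axis=0),
            tip=ox[sel].mean(axis=0),
            window=tuple(range(i, i + window)),
            stretch_index=stretch_index,
        ))
    return cvs


def cv_angle(a: CharacteristicVector, b: CharacteristicVector) -> float:
    """Angle between two CVs in degrees, in [0, 180]; direction only."""
    if a.degenerate or b.degenerate:
        raise UndefinedAngleError("angle with a zero-modulus CV is undefined")
    cosv = float(np.dot(a.vector, b.vector) / (a.modulus * b.modulus))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def cv_distance(a: CharacteristicVector, b: CharacteristicVector,
                mode: str = "midpoint") -> float:
    """Euclidean distance between two CVs (between midpoints by default,
    configurable to origin-origin)."""
    if mode == "midpoint":
        return float(np.linalg.norm(a.midpoint - b.midpoint))
    if mode == "origin":
        return float(np.linalg.norm(a.origin - b.origin))
    raise ValueError(f"unknown distance mode {mode!r}")


@dataclasses.dataclass
class CVGraph:
    """Complete undirected CV graph held as dense angle/distance matrices.

    ``angles[i, j]`` is NaN when either CV is degenerate; the diagonal is 0.
    """

    cvs: list[CharacteristicVector]
    angles: np.ndarray
    distances: np.ndarray
    distance_mode: str = "midpoint"

    def __len__(self) -> int:
        return len(self.cvs)

    @property
    def n_edges(self) -> int:
        n = len(self.cvs)
        return n * (n - 1) // 2

    def moduli(self) -> np.ndarray:
        return np.array([cv.modulus for cv in self.cvs])

    def sequence_neighbours(self, i: int) -> list[int]:
        """CVs adjacent in sequence (same stretch, window shifted by one)."""
        cv = self.cvs[i]
        out = []
        for j in (i - 1, i + 1):
            if 0 <= j < len(self.cvs):
                other = self.cvs[j]
                if (other.stretch_index == cv.stretch_index
                        and abs(other.window[0] - cv.window[0]) == 1):
                    out.append(j)
        return out

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        for i, cv in enumerate(self.cvs):
            g.add_node(i, modulus=cv.modulus,
                       stretch=cv.stretch_index,
                       window=",".join(map(str, cv.window)))
        n = len(self.cvs)
        for i in range(n):
            for j in range(i + 1, n):
                ang = self.angles[i, j]
                g.add_edge(i, j,
                           angle=float(ang) if np.isfinite(ang) else -1.0,
                           distance=float(self.distances[i, j]))
        return g

    def write_graphml(self, path: str | Path) -> Path:
        import networkx as nx
        path = Path(path)
        nx.write_graphml(self.to_networkx(), path)
        return path


def build_cv_graph(cvs: Sequence[CharacteristicVector],
                   distance_mode: str = "midpoint") -> CVGraph:
    """Assemble the complete graph over a CV list."""
    cvs = list(cvs)
    if not cvs:
        raise ValueError("cannot build a CV graph without CVs")
    n = len(cvs)
    vec = np.array([cv.vector for cv in cvs])
    mod = np.linalg.norm(vec, axis=1)
    pts = (np.array([cv.midpoint for cv in cvs]) if distance_mode == "midpoint"
           else np.array([cv.origin for cv in cvs]))
    diff = pts[:, None, :] - pts[None, :, :]
    distances = np.linalg.norm(diff, axis=-1)
    ok = mod >= DEGENERATE_MODULUS
    safe_mod = np.where(ok, mod, 1.0)
    unit = vec / safe_mod[:, None]
    cosm = np.clip(unit @ unit.T, -1.0, 1.0)
    angles = np.degrees(np.arccos(cosm))
    bad = ~(ok[:, None] & ok[None, :])
    angles[bad] = np.nan
    np.fill_diagonal(angles, 0.0)
    np.fill_diagonal(distances, 0.0)
    return CVGraph(cvs=cvs, angles=angles, distances=distances,
                   distance_mode=distance_mode)


def structure_cvs(stretches: Sequence[ConnectedStretch], window: int = 3
                  ) -> list[CharacteristicVector]:
    """CVs for every stretch of a structure, concatenated in order."""
    out: list[CharacteristicVector] = []
    for si, stretch in enumerate(stretches):
        out.extend(compute_cvs(stretch, window=window, stretch_index=si))
    return out


def consecutive_cv_angles(graph: CVGraph) -> np.ndarray:
    """Angles between sequence-consecutive CVs, one value per adjacent pair."""
    vals = []
    for i in range(len(graph)):
        for j in graph.sequence_neighbours(i):
            if j == i + 1:
                vals.append(graph.angles[i, j])
    return np.array(vals)
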