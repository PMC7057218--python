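"""Synthetic backbone fixtures with known ground truth.

Chains are grown in internal coordinates (NeRF-style placement from bond
length, bond angle and torsion) so that phi/psi are controlled exactly.
Canonical torsions: alpha-helix phi=-57, psi=-47; beta-strand phi=-139,
psi=+135 with a deterministic alternating +/-20 degree pleat on both phi
and psi.  A uniform (-139, +135) repeat produces a strongly twisted strand
whose consecutive-CV angles (~57 deg) overshoot the 50-55 deg range
observed for real strands; the symmetric two-residue pleat emulates the
flattening that sheet hydrogen bonding imposes and restores the observed
statistics (mean CV modulus ~1.5 A, consecutive angles ~53 deg).  Every
assembled fixture ships the ground-truth annotation it was built from.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .structures import (BackboneAtom, ChainResidue, ConnectedStretch,
                         Provenance, split_into_stretches, write_structure)

# ideal main-chain internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -139.0, 135.0
STRAND_PLEAT_PHI = 20.0     # alternating phi pleat, degrees
STRAND_PLEAT_PSI = 20.0     # alternating psi pleat, degrees
OMEGA = 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given A-B-C with |CD|=bond, angle(BCD)=angle and
    torsion(ABCD)=torsion (degrees)."""
    angle = np.deg2rad(angle)
    torsion = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(torsion),
        np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _torsion_track(kind: str, length: int) -> list[tuple[float, float]]:
    if kind == "ah":
        return [(HELIX_PHI, HELIX_PSI)] * length
    if kind == "bs":
        return [(STRAND_PHI + (STRAND_PLEAT_PHI if i % 2 else -STRAND_PLEAT_PHI),
                 STRAND_PSI + (STRAND_PLEAT_PSI if i % 2 else -STRAND_PLEAT_PSI))
                for i in range(length)]
    if kind == "coil":
        # a fixed, irregular walk through the bridge region between the
        # two ideal basins, where helix and strand penalties stay balanced
        track = []
        for i in range(length):
            phi = -110.0 + 15.0 * np.sin(1.7 * i + 0.5)
            psi = 40.0 + 45.0 * np.sin(0.9 * i)
            track.append((phi, psi))
        return track
    raise ValueError(f"unknown element type {kind!r}")


def build_chain_from_torsions(torsions: Sequence[tuple[float, float]],
                              chain_id: str = "A", start_seq: int = 1,
                              res_name: str = "ALA") -> ConnectedStretch:
    """Grow a poly-residue backbone from a (phi, psi) track.

    phi of the first residue and psi of the last have no flanking atom, but
    psi is still used to orient every carbonyl O (torsion N-CA-C-O =
    psi + 180), so the track length equals the residue count.
    """
    n = len(torsions)
    if n < 1:
        raise ValueError("need at least one residue")
    N = [np.zeros(3)]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = np.deg2rad(ANGLE_N_CA_C)
    C = [CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n):
        psi_prev = torsions[i - 1][1]
        phi = torsions[i][0]
        N.append(place_atom(N[i - 1], CA[i - 1], C[i - 1],
                            BOND_C_N, ANGLE_CA_C_N, psi_prev))
        CA.append(place_atom(CA[i - 1], C[i - 1], N[i],
                             BOND_N_CA, ANGLE_C_N_CA, OMEGA))
        C.append(place_atom(C[i - 1], N[i], CA[i],
                            BOND_CA_C, ANGLE_N_CA_C, phi))
    residues = []
    for i in range(n):
        psi = torsions[i][1]
        O = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        atoms = {
            "N": BackboneAtom("N", N[i]),
            "CA": BackboneAtom("CA", CA[i]),
            "C": BackboneAtom("C", C[i]),
            "O": BackboneAtom("O", O),
        }
        if res_name == "CYS":
            # approximate S-gamma out along the CB direction; fixtures only
            cb_dir = _tetrahedral_direction(N[i], CA[i], C[i])
            atoms["SG"] = BackboneAtom("SG", CA[i] + 2.8 * cb_dir)
        residues.append(ChainResidue(chain_id=chain_id,
                                     seq_id=(start_seq + i, ""),
                                     res_name=res_name, atoms=atoms))
    return ConnectedStretch(residues, Provenance(source="fixture",
                                                 chain_id=chain_id))


def _tetrahedral_direction(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    u = n - ca
    v = c - ca
    bisector = u / np.linalg.norm(u) + v / np.linalg.norm(v)
    normal = np.cross(u, v)
    d = -bisector / np.linalg.norm(bisector) + normal / np.linalg.norm(normal)
    return d / np.linalg.norm(d)


def build_ideal_element(kind: str, length: int, chain_id: str = "A",
                        start_seq: int = 1, res_name: str = "ALA"
                        ) -> ConnectedStretch:
    """Ideal helix ('ah'), strand ('bs') or irregular coil ('coil')."""
    if length < 3:
        raise ValueError("elements need >= 3 residues")
    return build_chain_from_torsions(_torsion_track(kind, length),
                                     chain_id=chain_id, start_seq=start_seq,
                                     res_name=res_name)


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


@dataclasses.dataclass
class ElementSpec:
    kind: str                    # ah | bs | coil
    length: int
    rotation: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))
    res_names: Sequence[str] | None = None


@dataclasses.dataclass
class FixtureSpec:
    elements: list[ElementSpec]
    noise_sigma: float = 0.0
    carbonyl_residues: Sequence[int] = ()
    carbonyl_angle: float = 0.0
    seed: int = 0
    separate_chains: bool = True


@dataclasses.dataclass
class GroundTruth:
    """What the generator actually built, element by element."""
    labels: list[str]                    # per residue, in element order
    fragments: list[tuple[int, int, str]]  # (start, stop, label), residue idx
    element_of_residue: list[int]


def _element_stretch(i: int, el: ElementSpec, chain_id: str,
                     start_seq: int) -> ConnectedStretch:
    if el.res_names is not None:
        if len(el.res_names) != el.length:
            raise ValueError("res_names length mismatch")
        track = _torsion_track(el.kind, el.length)
        residues = []
        # build homogeneous then rename: backbone identical for any residue type
        stretch = build_chain_from_torsions(track, chain_id=chain_id,
                                            start_seq=start_seq)
        for res, name in zip(stretch, el.res_names):
            res.res_name = name
            if name == "CYS" and "SG" not in res.atoms:
                cb = _tetrahedral_direction(res.coord("N"), res.coord("CA"),
                                            res.coord("C"))
                res.atoms["SG"] = BackboneAtom("SG", res.coord("CA") + 2.8 * cb)
            residues.append(res)
        stretch = ConnectedStretch(residues, stretch.provenance)
    else:
        stretch = build_ideal_element(el.kind, el.length, chain_id=chain_id,
                                      start_seq=start_seq)
    from .structures import transform_stretch
    return transform_stretch(stretch, el.rotation, el.translation)


def assemble_fold(spec: FixtureSpec) -> tuple[list[ConnectedStretch], GroundTruth]:
    """Place the elements of a fixture and emit its ground truth.

    Elements are centred before their placement transform is applied, then
    either left as separate chains (default) or concatenated into one chain
    whose breaks fail the bond test, which keeps each element a separate
    connected stretch either way.
    """
    if not spec.elements:
        raise ValueError("fixture needs at least one element")
    chain_ids = [chr(ord("A") + i % 26) for i in range(len(spec.elements))]
    stretches: list[ConnectedStretch] = []
    labels: list[str] = []
    fragments: list[tuple[int, int, str]] = []
    element_of: list[int] = []
    start = 0
    seq = 1
    for i, el in enumerate(spec.elements):
        cid = chain_ids[i] if spec.separate_chains else "A"
        stretch = _element_stretch(i, el, cid, seq)
        # centre the element on its CA centroid before the placement transform
        centre = stretch.ca_coords().mean(axis=0)
        from .structures import transform_stretch
        stretch = transform_stretch(stretch, np.eye(3), -centre)
        stretch = transform_stretch(stretch, el.rotation, el.translation)
        stretches.append(stretch)
        labels.extend([el.kind] * el.length)
        if el.kind != "coil":
            fragments.append((start, start + el.length - 1, el.kind))
        element_of.extend([i] * el.length)
        start += el.length
        seq += el.length + 4
    truth = GroundTruth(labels=labels, fragments=fragments,
                        element_of_residue=element_of)
    if spec.noise_sigma > 0 or spec.carbonyl_residues:
        stretches = perturb(stretches, spec.noise_sigma,
                            spec.carbonyl_residues, spec.carbonyl_angle,
                            spec.seed)
    return stretches, truth


def perturb(stretches: Sequence[ConnectedStretch], noise_sigma: float = 0.0,
            carbonyl_residues: Sequence[int] = (), carbonyl_angle: float = 0.0,
            seed: int = 0) -> list[ConnectedStretch]:
    """Gaussian coordinate noise and/or carbonyl misorientation.

    Noise is sequence-correlated: a per-residue Gaussian displacement field
    (per-coordinate std ``noise_sigma``, correlation length ~4 residues)
    moves all atoms of a residue together, plus a small independent
    per-atom jitter (10% of sigma).  This emulates the low-frequency
    conformational variation that fold libraries sample; fully independent
    per-atom noise of comparable size would break peptide bonds, which no
    real conformer does.

    ``carbonyl_residues`` are flat residue indices over the concatenated
    stretches; their O atom is rotated by ``carbonyl_angle`` degrees about
    the local C-CA axis, emulating carbonyls twisted off the helical axis.
    """
    rng = np.random.default_rng(seed)
    out: list[ConnectedStretch] = []
    flat = 0
    target = set(carbonyl_residues)
    for stretch in stretches:
        disp = np.zeros((len(stretch), 3))
        if noise_sigma > 0:
            corr = 4.0        # residues
            half = int(4 * corr)
            kern = np.exp(-0.5 * (np.arange(-half, half + 1) / corr) ** 2)
            kern /= np.linalg.norm(kern)      # unit L2: variance-preserving
            raw = rng.normal(scale=noise_sigma,
                             size=(len(stretch) + 2 * half, 3))
            disp = np.stack([np.convolve(raw[:, k], kern, mode="valid")
                             for k in range(3)], axis=1)
        residues = []
        for ri, res in enumerate(stretch):
            atoms = {}
            for name, atom in res.atoms.items():
                pos = atom.position.copy()
                if noise_sigma > 0:
                    pos = pos + disp[ri] + rng.normal(scale=0.1 * noise_sigma,
                                                     size=3)
                atoms[name] = dataclasses.replace(atom, position=pos)
            if flat in target and carbonyl_angle != 0.0:
                c = atoms["C"].position
                ca = atoms["CA"].position
                R = rotation_matrix(ca - c, carbonyl_angle)
                o = atoms["O"].position
                atoms["O"] = dataclasses.replace(atoms["O"],
                                                 position=c + R @ (o - c))
            residues.append(dataclasses.replace(res, atoms=atoms))
            flat += 1
        out.append(ConnectedStretch(residues, stretch.provenance))
    return out


def chain_with_break(length: int, break_after: int,
                     kind: str = "ah") -> list[ConnectedStretch]:
    """One chain whose residues beyond ``break_after`` are shifted 5 A away,
    producing a guaranteed bond-test failure at that position."""
    stretch = build_ideal_element(kind, length)
    residues = []
    for i, res in enumerate(stretch):
        if i >= break_after:
            atoms = {n: dataclasses.replace(a, position=a.position + np.array([0, 0, 5.0]))
                     for n, a in res.atoms.items()}
            res = dataclasses.replace(res, atoms=atoms)
        residues.append(res)
    return split_into_stretches(residues, stretch.provenance)


def write_fixture(stretches: Sequence[ConnectedStretch], truth: GroundTruth,
                  pdb_path: str | Path) -> Path:
    """Write fixture coordinates plus a JSON ground-truth sidecar."""
    pdb_path = Path(pdb_path)
    write_structure(stretches, pdb_path)
    sidecar = pdb_path.with_suffix(".truth.json")
    sidecar.write_text(json.dumps({
        "labels": truth.labels,
        "fragments": [list(f) for f in truth.fragments],
        "element_of_residue": truth.element_of_residue,
    }, indent=1))
    return pdb_path
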