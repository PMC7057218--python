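"""Reading, filtering and writing of protein main-chain coordinates.

Structures are reduced to *connected stretches* of complete main-chain
residues.  A residue is kept only if all four backbone atoms (N, CA, C, O)
are present after altloc/occupancy filtering; chain connectivity is decided
by the C(i)-N(i+1) bond distance, never by residue numbering, so renumbered
or insertion-coded chains partition identically.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

MAIN_CHAIN = ("N", "CA", "C", "O")

#: Accepted range for the C(i)-N(i+1) peptide-bond distance, in Angstrom.
#: Wide enough to keep distorted low-resolution peptide bonds connected.
CN_BOND_RANGE = (1.1, 1.8)


class StructureFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when parsing yields zero complete main-chain residues."""


@dataclasses.dataclass
class BackboneAtom:
    name: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 20.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclasses.dataclass
class ChainResidue:
    """One complete main-chain residue (exactly one altloc per atom)."""

    chain_id: str
    seq_id: tuple[int, str]          # (number, insertion code)
    res_name: str
    atoms: dict[str, BackboneAtom]   # keys N/CA/C/O, optionally SG for Cys

    def __post_init__(self) -> None:
        missing = [n for n in MAIN_CHAIN if n not in self.atoms]
        if missing:
            raise ValueError(f"residue {self.label} missing atoms {missing}")

    @property
    def label(self) -> str:
        num, icode = self.seq_id
        return f"{self.chain_id}/{self.res_name}{num}{icode.strip()}"

    def coord(self, name: str) -> np.ndarray:
        return self.atoms[name].position

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"].position


@dataclasses.dataclass
class Provenance:
    source: str = "memory"
    model_index: int = 0
    chain_id: str = "A"


@dataclasses.dataclass
class ConnectedStretch:
    """A maximal run of residues connected by peptide C-N bonds."""

    residues: list[ChainResidue]
    provenance: Provenance = dataclasses.field(default_factory=Provenance)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues])


def is_peptide_bonded(a: ChainResidue, b: ChainResidue,
                      bond_range: tuple[float, float] = CN_BOND_RANGE) -> bool:
    d = float(np.linalg.norm(b.coord("N") - a.coord("C")))
    return bond_range[0] <= d <= bond_range[1]


def _pick_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by lowest altloc letter
    return min(atoms, key=lambda a: (-a.occ, a.altloc or " "))


def _residue_from_gemmi(chain_id: str, res: gemmi.Residue) -> ChainResidue | None:
    atoms: dict[str, BackboneAtom] = {}
    wanted = set(MAIN_CHAIN) | {"SG"}
    for name in wanted:
        cands = [a for a in res if a.name == name]
        if not cands:
            continue
        best = _pick_altloc(cands)
        occ = min(max(float(best.occ), 0.0), 1.0)
        atoms[name] = BackboneAtom(
            name=name,
            position=np.array([best.pos.x, best.pos.y, best.pos.z]),
            occupancy=occ,
            b_factor=float(best.b_iso),
            altloc=best.altloc or "",
        )
    if any(n not in atoms for n in MAIN_CHAIN):
        return None
    icode = res.seqid.icode if res.seqid.icode and res.seqid.icode != " " else ""
    return ChainResidue(chain_id=chain_id, seq_id=(res.seqid.num, icode),
                        res_name=res.name, atoms=atoms)


def split_into_stretches(residues: Sequence[ChainResidue],
                         provenance: Provenance,
                         bond_range: tuple[float, float] = CN_BOND_RANGE,
                         ) -> list[ConnectedStretch]:
    """Partition an ordered residue list at every failed C-N bond test."""
    stretches: list[ConnectedStretch] = []
    current: list[ChainResidue] = []
    for res in residues:
        if current and not is_peptide_bonded(current[-1], res, bond_range):
            stretches.append(ConnectedStretch(current, provenance))
            current = []
        current.append(res)
    if current:
        stretches.append(ConnectedStretch(current, provenance))
    return stretches


_WATER = {"HOH", "WAT", "DOD"}


def parse_structure(path: str | Path, model_index: int = 0,
                    keep_all_chains: bool = True) -> list[ConnectedStretch]:
    """Parse a PDB file into connected main-chain stretches.

    Waters are discarded, one altloc is kept per atom (highest occupancy,
    ties to the lowest altloc letter) and residues missing any of N/CA/C/O
    are dropped.  Stretches split wherever the C-N distance leaves
    ``CN_BOND_RANGE``.  All chains are parsed; selection of a single
    representative monomer is a downstream concern.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no models")
    if model_index >= len(st):
        raise IndexError(f"model {model_index} not in {path} ({len(st)} models)")
    model = st[model_index]

    stretches: list[ConnectedStretch] = []
    for chain in model:
        if not keep_all_chains and stretches:
            break
        residues = []
        for res in chain:
            if res.name in _WATER:
                continue
            cr = _residue_from_gemmi(chain.name, res)
            if cr is not None:
                residues.append(cr)
        prov = Provenance(source=str(path), model_index=model_index,
                          chain_id=chain.name)
        stretches.extend(split_into_stretches(residues, prov))
    if not any(len(s) for s in stretches):
        raise EmptyStructureError(f"{path}: no complete main-chain residues")
    return stretches


def write_structure(stretches: Iterable[ConnectedStretch], path: str | Path,
                    chain_override: Mapping[int, str] | None = None,
                    b_factor_override: float | None = None) -> Path:
    """Write stretches as a standard PDB file.

    ``chain_override`` maps stretch index -> chain identifier (used by the
    decomposition output, one chain per group); ``b_factor_override`` sets a
    common B factor on every atom (used by library generation).
    """
    st = gemmi.Structure()
    st.name = "cvfold"
    model = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    for si, stretch in enumerate(stretches):
        for res in stretch:
            cid = (chain_override or {}).get(si, res.chain_id)
            if cid not in chains:
                chains[cid] = gemmi.Chain(cid)
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_id[0], res.seq_id[1] or " ")
            for name in (*MAIN_CHAIN, "SG"):
                if name not in res.atoms:
                    continue
                atom = res.atoms[name]
                ga = gemmi.Atom()
                ga.name = name
                ga.element = gemmi.Element("S" if name == "SG" else name[0])
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.b_iso = (b_factor_override if b_factor_override is not None
                            else atom.b_factor)
                gres.add_atom(ga)
            chains[cid].add_residue(gres)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path


def transform_stretch(stretch: ConnectedStretch, rotation: np.ndarray,
                      translation: np.ndarray) -> ConnectedStretch:
    """Return a rigidly transformed copy (x -> R x + t) of a stretch."""
    rotation = np.asarray(rotation, float)
    translation = np.asarray(translation, float)
    out = []
    for res in stretch:
        atoms = {
            name: dataclasses.replace(a, position=rotation @ a.position + translation)
            for name, a in res.atoms.items()
        }
        out.append(dataclasses.replace(res, atoms=atoms))
    return ConnectedStretch(out, stretch.provenance)
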