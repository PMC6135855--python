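"""PDB reading/writing and chain segmentation.

Structures are reduced to their main-chain representation (N, CA, C, O per
residue); each chain is split into gap-free segments — consecutive runs of
standard residues with continuous author numbering and C-alpha steps below
the chain-break cutoff — which are the unit indexed by the fragment
database.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

log = logging.getLogger(__name__)

MAINCHAIN_ATOMS = ("N", "CA", "C", "O")

#: chain-continuity cutoff: consecutive residues further apart than this
#: (C-alpha to C-alpha) are treated as a physical chain break even when the
#: author numbering is continuous.
CA_BREAK_CUTOFF = 4.5

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class FormatError(ValueError):
    """Raised when input text cannot be interpreted as a PDB structure."""


@dataclasses.dataclass
class Residue:
    """One residue reduced to its main-chain atoms.

    ``mainchain`` maps atom name (N, CA, C, O) to a 3-vector in angstroms.
    Selenomethionine is mapped to MET and counted as standard; every other
    non-standard residue is retained only so segmentation can split at it.
    """

    name: str
    num: int
    icode: str = ""
    mainchain: dict = dataclasses.field(default_factory=dict)
    standard: bool = False

    @property
    def seq_id(self) -> str:
        return f"{self.num}{self.icode}"

    @property
    def letter(self) -> str:
        return _THREE_TO_ONE.get(self.name, "X")

    @property
    def ca(self) -> np.ndarray | None:
        return self.mainchain.get("CA")

    @property
    def complete(self) -> bool:
        return all(a in self.mainchain for a in MAINCHAIN_ATOMS)

    def mainchain_array(self) -> np.ndarray:
        """(4, 3) array in N, CA, C, O order; raises if incomplete."""
        if not self.complete:
            raise ValueError(f"residue {self.name} {self.seq_id} is missing "
                             "a main-chain atom")
        return np.array([self.mainchain[a] for a in MAINCHAIN_ATOMS])


@dataclasses.dataclass
class Chain:
    id: str
    residues: list = dataclasses.field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.letter for r in self.residues)


@dataclasses.dataclass
class ChainSegment:
    """A gap-free run of standard residues from one chain."""

    source_id: str
    residues: list

    def __post_init__(self) -> None:
        self.sequence = "".join(r.letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues])

    def mainchain_coords(self) -> np.ndarray:
        """(L, 4, 3) array; residues missing atoms get NaN rows."""
        out = np.full((len(self.residues), 4, 3), np.nan)
        for i, r in enumerate(self.residues):
            for j, a in enumerate(MAINCHAIN_ATOMS):
                if a in r.mainchain:
                    out[i, j] = r.mainchain[a]
        return out


def three_to_one(name: str) -> str:
    return _THREE_TO_ONE.get(name, "X")


def one_to_three(letter: str) -> str:
    try:
        return _ONE_TO_THREE[letter.upper()]
    except KeyError:
        raise ValueError(f"unknown amino-acid letter {letter!r}") from None


def _pick_altloc(atoms: Iterable[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved toward altloc 'A' (blank first)
    return max(atoms, key=lambda a: (a.occ, -ord(a.altloc or "A")))


def read_structure(pdb_text: str) -> list[Chain]:
    """Parse PDB text into main-chain residue lists, one per chain.

    Only the first model of multi-model files is used.  Alternate locations
    are resolved to the highest-occupancy conformer (ties favour altloc
    'A').  MSE is renamed to MET and treated as standard; all other HETATM
    residues are kept but flagged non-standard so segmentation splits at
    them.  Chains without a single C-alpha are skipped with a warning.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB text: {exc}") from exc
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise FormatError("no ATOM records found")

    chains: list[Chain] = []
    for gch in st[0]:
        chain = Chain(id=gch.name)
        for gres in gch:
            name = gres.name
            if name == "MSE":
                name = "MET"
            res = Residue(name=name,
                          num=gres.seqid.num,
                          icode=gres.seqid.icode.strip(),
                          standard=name in _THREE_TO_ONE)
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in gres:
                if atom.name in MAINCHAIN_ATOMS:
                    by_name.setdefault(atom.name, []).append(atom)
            for aname, alts in by_name.items():
                pos = _pick_altloc(alts).pos
                res.mainchain[aname] = np.array([pos.x, pos.y, pos.z])
            chain.residues.append(res)
        if not any(r.ca is not None for r in chain.residues):
            log.warning("chain %s has no C-alpha atoms; skipped", gch.name)
            continue
        chains.append(chain)
    return chains


def read_structure_file(path: str | Path) -> list[Chain]:
    return read_structure(Path(path).read_text())


def segment_chain(residues: Sequence[Residue], min_length: int = 5,
                  ca_break: float = CA_BREAK_CUTOFF,
                  source_id: str = "") -> list[ChainSegment]:
    """Split a residue list into gap-free segments.

    Breaks occur at author-numbering discontinuities, at non-standard
    residues (the offending residue is dropped), at residues without a
    C-alpha, and wherever consecutive C-alphas are ``ca_break`` or more
    apart.  Segments shorter than ``min_length`` are discarded.
    """
    segments: list[ChainSegment] = []
    current: list[Residue] = []

    def flush() -> None:
        if len(current) >= min_length:
            segments.append(ChainSegment(source_id=source_id,
                                         residues=list(current)))
        current.clear()

    for res in residues:
        if not res.standard or res.ca is None:
            flush()
            continue
        if current:
            prev = current[-1]
            contiguous = (res.num == prev.num + 1 and not res.icode) or \
                         (res.num == prev.num and res.icode != prev.icode)
            if not contiguous or \
                    float(np.linalg.norm(res.ca - prev.ca)) >= ca_break:
                flush()
        current.append(res)
    flush()
    return segments


def write_model(chains: Sequence[Chain], path: str | Path | None = None) -> str:
    """Serialize chains to PDB text (and optionally a file).

    Every residue must carry the full N, CA, C, O set; the round trip
    through :func:`read_structure` preserves coordinates to the 10^-3
    angstrom precision of the format.
    """
    st = gemmi.Structure()
    model = gemmi.Model("1")
    for chain in chains:
        gch = gemmi.Chain(chain.id)
        for res in chain.residues:
            if not res.complete:
                raise ValueError(
                    f"residue {res.name} {res.seq_id} in chain {chain.id} "
                    "is missing a main-chain atom; refusing to write")
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.num, res.icode or " ")
            for aname in MAINCHAIN_ATOMS:
                atom = gemmi.Atom()
                atom.name = aname
                x, y, z = res.mainchain[aname]
                atom.pos = gemmi.Position(x, y, z)
                atom.element = gemmi.Element(aname[0])
                atom.occ = 1.0
                gres.add_atom(atom)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    text = st.make_pdb_string()
    if path is not None:
        Path(path).write_text(text)
    return text
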