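"""Reading and writing structures, reference alignments, and manifests.

A :class:`Structure` is an ordered chain of Cα coordinates — the universal
input of every aligner here.  Residues are kept in file order and all
alignment indices are 0-based positions into that order, never author
residue numbers: the alignment math downstream is purely positional.
Chains with missing interior residues are used as-is.

PDB parsing and writing go through gemmi; only ATOM records of the requested
chain contribute, only Cα atoms are kept (first-listed alternate location,
preferring altloc 'A'), and residues lacking a Cα are skipped.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .geometry import Transform

__all__ = [
    "Structure",
    "ReferenceAlignment",
    "ChainNotFoundError",
    "NoCACoordinatesError",
    "AlignmentFormatError",
    "read_pdb_ca",
    "write_pdb_ca",
    "read_reference_alignment",
    "write_reference_alignment",
    "read_manifest",
    "file_checksum",
]


class ChainNotFoundError(ValueError):
    """The requested chain identifier does not occur in the file."""


class NoCACoordinatesError(ValueError):
    """The requested chain contains no usable Cα atoms."""


class AlignmentFormatError(ValueError):
    """A reference-alignment file violates the two-column monotone format."""


_AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA_1TO3 = {v: k for k, v in _AA_3TO1.items()}


@dataclass(frozen=True)
class Structure:
    """An ordered Cα chain.

    Fields
    ------
    id:
        label, conventionally PDB id + chain (e.g. ``"1opyA"``).
    chain_id:
        one-character chain identifier used when writing PDB.
    residue_numbers, insertion_codes, amino_acids:
        per-residue metadata in file order; amino acids are 1-letter codes
        (``X`` for nonstandard residues).
    coords:
        (n, 3) float array of Cα positions in Å, all finite.
    """

    id: str
    chain_id: str
    residue_numbers: tuple[int, ...]
    insertion_codes: tuple[str, ...]
    amino_acids: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        n = len(self.residue_numbers)
        if coords.shape != (n, 3):
            raise ValueError("coords must be (n, 3) matching the residue count")
        if n and not np.all(np.isfinite(coords)):
            raise ValueError("all Cα coordinates must be finite")
        if not (len(self.insertion_codes) == n and len(self.amino_acids) == n):
            raise ValueError("per-residue metadata lengths must agree")
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def transformed(self, t: Transform) -> "Structure":
        """The same chain with coordinates mapped x -> R x + t."""
        return Structure(
            self.id,
            self.chain_id,
            self.residue_numbers,
            self.insertion_codes,
            self.amino_acids,
            t.apply(self.coords),
        )

    def with_id(self, new_id: str) -> "Structure":
        return Structure(
            new_id, self.chain_id, self.residue_numbers,
            self.insertion_codes, self.amino_acids, self.coords,
        )


@dataclass(frozen=True)
class ReferenceAlignment:
    """A gold-standard correspondence: strictly increasing (i, j) index pairs."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pairs = tuple((int(i), int(j)) for i, j in self.pairs)
        for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
            if not (i1 > i0 and j1 > j0):
                raise AlignmentFormatError(
                    f"pairs must be strictly increasing in both columns; "
                    f"({i0},{j0}) is followed by ({i1},{j1})"
                )
        if pairs and (pairs[0][0] < 0 or pairs[0][1] < 0):
            raise AlignmentFormatError("alignment indices must be nonnegative")
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def read_pdb_ca(path: str | os.PathLike, chain: str) -> Structure:
    """Extract one chain's Cα trace from a PDB file.

    Keeps one residue per (residue number, insertion code) with its Cα
    coordinate; HETATM and non-Cα atoms are ignored; for alternate locations
    the altloc-'A' record is used if present, otherwise the first listed;
    residues without a Cα are skipped.  Uses the first model only.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such structure file: {path}")
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise NoCACoordinatesError(f"{path}: file contains no models")
    model = st[0]
    gchain = model.find_chain(chain)
    if gchain is None:
        present = ", ".join(ch.name for ch in model) or "(none)"
        raise ChainNotFoundError(
            f"{path}: chain {chain!r} not present (chains: {present})"
        )

    numbers: list[int] = []
    icodes: list[str] = []
    aas: list[str] = []
    xyz: list[tuple[float, float, float]] = []
    for res in gchain:
        if res.het_flag != "A":  # ATOM records only
            continue
        cas = [a for a in res if a.name == "CA"]
        if not cas:
            continue
        atom = next((a for a in cas if a.altloc == "A"), cas[0])
        numbers.append(res.seqid.num)
        icodes.append(res.seqid.icode if res.seqid.icode.strip() else " ")
        aas.append(_AA_3TO1.get(res.name.upper(), "X"))
        xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))

    if not xyz:
        raise NoCACoordinatesError(f"{path}: chain {chain!r} has no Cα atoms")
    return Structure(
        id=f"{st.name.lower() if st.name else os.path.basename(str(path)).split('.')[0]}{chain}",
        chain_id=chain,
        residue_numbers=tuple(numbers),
        insertion_codes=tuple(icodes),
        amino_acids="".join(aas),
        coords=np.array(xyz, dtype=float),
    )


def write_pdb_ca(s: Structure, path: str | os.PathLike) -> None:
    """Write the Cα trace as PDB ATOM records (fixed-point, 3 decimals)."""
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    chain = gemmi.Chain(s.chain_id or "A")
    for k in range(len(s)):
        res = gemmi.Residue()
        res.name = _AA_1TO3.get(s.amino_acids[k], "UNK")
        res.seqid = gemmi.SeqId(s.residue_numbers[k], s.insertion_codes[k])
        res.het_flag = "A"
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        x, y, z = s.coords[k]
        atom.pos = gemmi.Position(x, y, z)
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_reference_alignment(path: str | os.PathLike) -> ReferenceAlignment:
    """Parse the two-column 0-based residue-index pair format.

    Blank lines and ``#`` comments are ignored.  Pairs must be strictly
    increasing in both columns; a violation is reported with its line number.
    """
    pairs: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            fields = text.split()
            if len(fields) != 2:
                raise AlignmentFormatError(
                    f"{path}:{lineno}: expected two whitespace-separated "
                    f"indices, got {line.strip()!r}"
                )
            try:
                i, j = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise AlignmentFormatError(
                    f"{path}:{lineno}: non-integer index in {line.strip()!r}"
                ) from exc
            if pairs and not (i > pairs[-1][0] and j > pairs[-1][1]):
                raise AlignmentFormatError(
                    f"{path}:{lineno}: pair ({i}, {j}) breaks strict "
                    f"monotonicity after {pairs[-1]}"
                )
            pairs.append((i, j))
    return ReferenceAlignment(tuple(pairs))


def write_reference_alignment(
    al: ReferenceAlignment, path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for i, j in al.pairs:
            fh.write(f"{i} {j}\n")


def read_manifest(path: str | os.PathLike) -> list[dict]:
    """Parse a benchmark manifest: one ``pdbA chainA pdbB chainB [refalign]``
    line per structure pair, with optional ``label=`` tags (e.g. family)."""
    rows: list[dict] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            fields = text.split()
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: manifest line needs at least "
                    f"'pdbA chainA pdbB chainB'"
                )
            row = {
                "pdb_a": fields[0],
                "chain_a": fields[1],
                "pdb_b": fields[2],
                "chain_b": fields[3],
                "ref_align": None,
                "label": None,
            }
            for extra in fields[4:]:
                if extra.startswith("label="):
                    row["label"] = extra[len("label="):]
                else:
                    row["ref_align"] = extra
            rows.append(row)
    return rows


def file_checksum(path: str | os.PathLike) -> str:
    """SHA-256 of a file's bytes, for logging input provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()
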