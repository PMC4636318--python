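"""Structure and sequence I/O for the distortion-analysis pipeline.

In-memory containers are light dataclasses; parsing and serialisation of the
standard formats is delegated to established libraries (biotite for PDB,
Biopython for FASTA/Clustal, scikit-bio for Newick).

Conventions
-----------
* Residue indices follow the author numbering of the input PDB (1-based,
  possibly non-contiguous); no renumbering is ever applied.
* A multi-MODEL PDB yields one :class:`Frame` per MODEL.  Frame 1 is labelled
  ``"initial"`` by default; later frames can be labelled/timestamped by the
  caller (e.g. MD snapshot times in ns).
* Insertion codes are rejected with an explicit error: silently shifting the
  numbering of downstream residues would corrupt every positional label.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Residue",
    "Frame",
    "FrameSet",
    "Alignment",
    "StructureError",
    "AlignmentError",
    "read_structure",
    "write_structure",
    "read_alignment",
    "write_alignment",
    "write_newick",
    "write_tsv",
    "write_outputs",
]


class StructureError(ValueError):
    """Raised for malformed or unsupported structural input."""


class AlignmentError(ValueError):
    """Raised for malformed alignment input."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(
                f"atom {self.name!r}: coordinate must be a finite 3-vector"
            )


@dataclass
class Residue:
    index: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise StructureError(
                f"residue {self.name}{self.index}: duplicate atom names"
            )

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.index} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coord(self, name: str) -> np.ndarray:
        return self.atom(name).coord

    @property
    def has_backbone(self) -> bool:
        return all(self.has_atom(n) for n in ("N", "CA", "C", "O"))


@dataclass
class Frame:
    """A single structural state: chains of ordered residues."""

    chains: dict[str, list[Residue]]
    label: str = ""
    time_ns: float | None = None
    #: Optional construction metadata (e.g. hinge axis of a programmed kink);
    #: carried by synthetic builders, ignored by readers/writers.
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chain_id, residues in self.chains.items():
            idx = [r.index for r in residues]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise StructureError(
                    f"chain {chain_id}: residue indices must strictly increase"
                )

    def chain(self, chain_id: str | None = None) -> list[Residue]:
        if chain_id is None:
            chain_id = next(iter(self.chains))
        return self.chains[chain_id]

    def residue(self, index: int, chain_id: str | None = None) -> Residue:
        for r in self.chain(chain_id):
            if r.index == index:
                return r
        raise KeyError(f"no residue with index {index}")

    def residues_in(
        self, start: int, end: int, chain_id: str | None = None
    ) -> list[Residue]:
        """Residues with ``start <= index <= end`` (author numbering)."""
        return [r for r in self.chain(chain_id) if start <= r.index <= end]

    def iter_atoms(self) -> Iterator[tuple[str, Residue, Atom]]:
        for chain_id, residues in self.chains.items():
            for res in residues:
                for atom in res.atoms:
                    yield chain_id, res, atom

    def copy(self) -> "Frame":
        chains = {
            cid: [
                Residue(r.index, r.name, [Atom(a.name, a.element, a.coord.copy()) for a in r.atoms])
                for r in residues
            ]
            for cid, residues in self.chains.items()
        }
        return Frame(chains, label=self.label, time_ns=self.time_ns, meta=dict(self.meta))

    def topology(self) -> tuple:
        return tuple(
            (cid, tuple((r.index, r.name, tuple(a.name for a in r.atoms)) for r in residues))
            for cid, residues in self.chains.items()
        )

    def coords(self) -> np.ndarray:
        return np.array([a.coord for _, _, a in self.iter_atoms()])

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        for (_, _, atom), xyz in zip(self.iter_atoms(), coords, strict=True):
            atom.coord = xyz


@dataclass
class FrameSet:
    """Ordered frames sharing an identical chain/residue/atom topology."""

    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureError("FrameSet requires at least one frame")
        topo = self.frames[0].topology()
        for k, f in enumerate(self.frames[1:], start=2):
            if f.topology() != topo:
                raise StructureError(f"frame {k} topology differs from frame 1")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    def select(self, labels: Iterable[str]) -> "FrameSet":
        wanted = set(labels)
        picked = [f for f in self.frames if f.label in wanted]
        if not picked:
            raise StructureError(f"no frames with labels {sorted(wanted)}")
        return FrameSet(picked)


@dataclass
class Alignment:
    """Gapped sequences with unique ids; all rows equal length."""

    records: list[tuple[str, str]]
    #: Optional map from positional label (e.g. "5.45") to column index,
    #: attached by generators or by numbering helpers.
    column_labels: dict[str, int] | None = None

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.records]
        if len(ids) != len(set(ids)):
            raise AlignmentError("alignment ids must be unique")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            bad = [i for i, s in self.records if len(s) != len(self.records[0][1])]
            raise AlignmentError(f"unequal gapped lengths for ids: {bad}")
        self.records = [(i, s.upper()) for i, s in self.records]

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def sequence(self, seq_id: str) -> str:
        for i, s in self.records:
            if i == seq_id:
                return s
        raise KeyError(f"no sequence {seq_id!r}")

    def column(self, j: int) -> str:
        return "".join(s[j] for _, s in self.records)

    def to_matrix(self) -> np.ndarray:
        """Rows as a (n_sequences, n_columns) array of single characters."""
        return np.array([list(s) for _, s in self.records], dtype="U1")


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

_STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _check_pdb_coordinates(path: Path) -> None:
    """Light pre-scan so malformed coordinates can be reported by line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    txt = line[lo:hi].strip()
                    try:
                        float(txt)
                    except ValueError:
                        raise StructureError(
                            f"{path}: malformed coordinate {txt!r} on line {lineno}"
                        ) from None


def read_structure(
    path: str | Path,
    labels: Sequence[str] | None = None,
    times_ns: Sequence[float | None] | None = None,
) -> FrameSet:
    """Read a (possibly multi-MODEL) PDB file into a :class:`FrameSet`.

    One frame per MODEL record; a single un-modelled structure yields one
    frame.  Alternate locations are resolved to the highest occupancy;
    hydrogens are retained.  Frame 1 is labelled ``"initial"`` unless
    ``labels`` overrides it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_pdb_coordinates(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None, altloc="occupancy")
    if np.any(stack.ins_code != ""):
        bad = sorted(set(stack.res_id[stack.ins_code != ""].tolist()))
        raise StructureError(
            f"{path}: insertion codes are not supported (residues {bad})"
        )

    frames: list[Frame] = []
    n_models = stack.stack_depth()
    for m in range(n_models):
        arr = stack[m]
        chains: dict[str, list[Residue]] = {}
        for cid in np.unique(arr.chain_id):
            sub = arr[arr.chain_id == cid]
            residues = []
            for res_id in np.unique(sub.res_id):
                rsub = sub[sub.res_id == res_id]
                atoms = [
                    Atom(name=an, element=el, coord=xyz)
                    for an, el, xyz in zip(
                        rsub.atom_name, rsub.element, rsub.coord
                    )
                ]
                residues.append(Residue(int(res_id), str(rsub.res_name[0]), atoms))
            chains[str(cid)] = residues
        if labels is not None and m < len(labels):
            label = labels[m]
        else:
            label = "initial" if m == 0 else f"model{m + 1}"
        t = times_ns[m] if times_ns is not None and m < len(times_ns) else None
        frames.append(Frame(chains, label=label, time_ns=t))
    return FrameSet(frames)


def _frame_to_atom_array(frame: Frame) -> bst.AtomArray:
    n = sum(1 for _ in frame.iter_atoms())
    arr = bst.AtomArray(n)
    for i, (cid, res, atom) in enumerate(frame.iter_atoms()):
        arr.chain_id[i] = cid
        arr.res_id[i] = res.index
        arr.res_name[i] = res.name
        arr.atom_name[i] = atom.name
        arr.element[i] = atom.element
        arr.hetero[i] = res.name not in _STANDARD_AA3
        arr.coord[i] = atom.coord
    return arr


def write_structure(obj: Frame | FrameSet, path: str | Path) -> Path:
    """Write a frame or frame set as a (multi-MODEL) PDB file, 3-decimal coords."""
    path = Path(path)
    frames = obj.frames if isinstance(obj, FrameSet) else [obj]
    arrays = [_frame_to_atom_array(f) for f in frames]
    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        pdb.set_structure(bst.stack(arrays))
    pdb.write(str(path))
    return path


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a FASTA or Clustal alignment; gaps preserved, case normalised."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("fasta", "clustal"):
        raise AlignmentError(f"unsupported alignment format {format!r}")
    if format == "fasta":
        # AlignIO rejects ragged FASTA outright; parse records ourselves via
        # SeqIO so the error can list the offending ids.
        from Bio import SeqIO

        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        return Alignment(records)
    msa = AlignIO.read(str(path), format)
    return Alignment([(r.id, str(r.seq)) for r in msa])


def write_alignment(alignment: Alignment, path: str | Path, format: str = "fasta") -> Path:
    path = Path(path)
    if format == "fasta":
        with open(path, "w") as fh:
            for sid, seq in alignment.records:
                fh.write(f">{sid}\n")
                for k in range(0, len(seq), 60):
                    fh.write(seq[k : k + 60] + "\n")
    elif format == "clustal":
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        msa = MultipleSeqAlignment(
            [SeqRecord(Seq(s), id=i, description="") for i, s in alignment.records]
        )
        AlignIO.write(msa, str(path), "clustal")
    else:
        raise AlignmentError(f"unsupported alignment format {format!r}")
    return path


# ---------------------------------------------------------------------------
# Trees and tables
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path, support_as_percent: bool = True) -> Path:
    """Write a scikit-bio ``TreeNode`` as Newick with branch lengths.

    Internal nodes with a ``support`` attribute (fraction in [0, 1]) are
    labelled with integer percent supports.
    """
    tree = tree.copy()
    for node in tree.non_tips():
        sup = getattr(node, "support", None)
        if sup is not None and support_as_percent:
            node.name = str(int(round(100 * float(sup))))
    buf = io.StringIO()
    tree.write(buf, format="newick")
    Path(path).write_text(buf.getvalue())
    return Path(path)


def write_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return Path(path)


def write_outputs(obj, path: str | Path, format: str) -> Path:
    """Dispatch an object to the matching writer; unsupported pairs error."""
    if format == "pdb" and isinstance(obj, (Frame, FrameSet)):
        return write_structure(obj, path)
    if format in ("fasta", "clustal") and isinstance(obj, Alignment):
        return write_alignment(obj, path, format)
    if format == "newick":
        return write_newick(obj, path)
    if format == "tsv":
        if hasattr(obj, "to_frame"):
            obj = obj.to_frame()
        if isinstance(obj, pd.DataFrame):
            return write_tsv(obj, path)
    raise ValueError(f"cannot write {type(obj).__name__} as {format!r}")
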