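"""Backbone hydrogen-bond detection and i→i−4 / i→i−5 register occupancy.

A canonical α-helix is held together by backbone amide(i) → carbonyl(i−4)
hydrogen bonds.  A one-residue bulge locally widens the helix to a π-like
turn: the i→i−4 bonds around the bulge break and i→i−5 bonds appear.  The
per-position occupancy of both bond types across trajectory frames is the
fingerprint used to tell a bulged from a merely kinked helix.

Detection uses HBPLUS-style geometric criteria: donor–acceptor (N···O)
distance, hydrogen–acceptor (H···O) distance and the N–H···O angle.  The
amide hydrogen is built geometrically when the input has no hydrogens;
proline, which has no amide hydrogen, never donates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geom import angle_deg, unit
from .structio import Frame, FrameSet, Residue

__all__ = [
    "HBondCriteria",
    "HBond",
    "RegisterProfile",
    "ContactTrace",
    "amide_hydrogen",
    "detect_backbone_hbonds",
    "register_profile",
    "contact_distance_trace",
]

#: Offsets considered for helical backbone bonds (3-10 through π register).
_OFFSETS = range(2, 7)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond criteria (Å, degrees)."""

    max_DA: float = 3.5
    max_HA: float = 2.5
    min_DHA_angle: float = 120.0

    def __post_init__(self) -> None:
        if not self.max_HA < self.max_DA:
            raise ValueError("max_HA must be smaller than max_DA")
        if not 90.0 < self.min_DHA_angle <= 180.0:
            raise ValueError("min_DHA_angle must lie in (90, 180]")


@dataclass(frozen=True)
class HBond:
    donor_residue: int
    acceptor_residue: int
    offset: int  # donor − acceptor; 4 ⇒ i→i−4
    da_distance: float
    dha_angle: float | None  # None when no hydrogen was available


def amide_hydrogen(res: Residue, prev: Residue | None) -> np.ndarray | None:
    """Return the amide H position, built geometrically if absent.

    The hydrogen is placed 1.01 Å from N along the external bisector of the
    C(i−1)–N–CA angle (in-plane trans amide).  Returns ``None`` for proline,
    chain-initial residues without a preceding carbonyl carbon, or residues
    missing N/CA.
    """
    if res.name == "PRO":
        return None
    if res.has_atom("H"):
        return res.coord("H")
    if prev is None or not prev.has_atom("C") or not (res.has_atom("N") and res.has_atom("CA")):
        return None
    n = res.coord("N")
    u1 = unit(n - prev.coord("C"))
    u2 = unit(n - res.coord("CA"))
    return n + 1.01 * unit(u1 + u2)


def detect_backbone_hbonds(
    frame: Frame,
    criteria: HBondCriteria | None = None,
    chain: str | None = None,
) -> list[HBond]:
    """Detect intra-chain backbone N–H···O=C bonds at offsets 2–6.

    A bond is reported when DA ≤ ``max_DA`` and, whenever a hydrogen is known
    or constructible, additionally HA ≤ ``max_HA`` and the D–H···A angle is
    ≥ ``min_DHA_angle``.  Offsets are author-index differences, so numbering
    gaps between separate segments never produce spurious short-range bonds.
    Residues missing N or O are skipped.
    """
    criteria = criteria or HBondCriteria()
    residues = frame.chain(chain)
    by_index = {r.index: r for r in residues}
    prev_of = {r.index: by_index.get(r.index - 1) for r in residues}

    bonds: list[HBond] = []
    for res in residues:
        if not res.has_atom("N") or res.name == "PRO":
            continue
        h = amide_hydrogen(res, prev_of[res.index])
        n = res.coord("N")
        for offset in _OFFSETS:
            acc = by_index.get(res.index - offset)
            if acc is None or not acc.has_atom("O"):
                continue
            o = acc.coord("O")
            da = float(np.linalg.norm(n - o))
            if da > criteria.max_DA:
                continue
            dha: float | None = None
            if h is not None:
                ha = float(np.linalg.norm(h - o))
                if ha > criteria.max_HA:
                    continue
                dha = angle_deg(n, h, o)
                if dha < criteria.min_DHA_angle:
                    continue
            bonds.append(HBond(res.index, acc.index, offset, da, dha))
    return bonds


@dataclass
class RegisterProfile:
    """Per-position occupancy of i→i−4 and i→i−5 bonds across frames.

    Occupancy is keyed by the *donor* position.  ``positions`` are BW labels
    when a numbering is supplied, else stringified residue indices.
    """

    positions: list[str]
    residue_indices: list[int]
    occupancy_i4: np.ndarray
    occupancy_i5: np.ndarray
    n_frames: int
    phase: str = ""

    def __post_init__(self) -> None:
        for occ in (self.occupancy_i4, self.occupancy_i5):
            if np.any((occ < 0) | (occ > 1)):
                raise ValueError("occupancies must lie in [0, 1]")

    def occupancy(self, position: str, offset: int) -> float:
        j = self.positions.index(position)
        return float((self.occupancy_i4 if offset == 4 else self.occupancy_i5)[j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "residue_index": self.residue_indices,
                "occ_i4": self.occupancy_i4,
                "occ_i5": self.occupancy_i5,
            }
        )


def register_profile(
    frames: FrameSet | Frame,
    helix: tuple[int, int],
    numbering=None,
    criteria: HBondCriteria | None = None,
    frame_labels: list[str] | None = None,
    chain: str | None = None,
    phase: str = "",
) -> RegisterProfile:
    """Occupancy of i→i−4 / i→i−5 bonds for donors in a helix span.

    ``helix`` is an (inclusive) author residue-index range.  ``frame_labels``
    restricts the frames used (e.g. production snapshots only).
    """
    if isinstance(frames, Frame):
        frames = FrameSet([frames])
    selected = frames.select(frame_labels) if frame_labels is not None else frames
    start, end = helix
    donors = [r.index for r in selected[0].residues_in(start, end, chain)]
    if not donors:
        raise ValueError(f"no residues in helix span {helix}")

    count4 = {i: 0 for i in donors}
    count5 = {i: 0 for i in donors}
    for frame in selected:
        for bond in detect_backbone_hbonds(frame, criteria, chain):
            if bond.donor_residue in count4:
                if bond.offset == 4:
                    count4[bond.donor_residue] += 1
                elif bond.offset == 5:
                    count5[bond.donor_residue] += 1

    nf = len(selected)
    if numbering is not None:
        labels = [numbering.label_of(i) for i in donors]
    else:
        labels = [str(i) for i in donors]
    return RegisterProfile(
        positions=labels,
        residue_indices=donors,
        occupancy_i4=np.array([count4[i] / nf for i in donors]),
        occupancy_i5=np.array([count5[i] / nf for i in donors]),
        n_frames=nf,
        phase=phase,
    )


@dataclass
class ContactTrace:
    """Per-frame distance between two named atoms."""

    frame_labels: list[str]
    times_ns: list[float | None]
    distances: np.ndarray
    atom_a: tuple[str, str]
    atom_b: tuple[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame_labels,
                "time_ns": self.times_ns,
                "distance_A": self.distances,
            }
        )


def contact_distance_trace(
    frames: FrameSet,
    atom_a: tuple[str, str],
    atom_b: tuple[str, str],
    numbering=None,
    chain: str | None = None,
) -> ContactTrace:
    """Euclidean distance between two atoms across frames.

    Each atom is addressed as ``(position, atom_name)`` where position is a
    BW label (requires ``numbering``) or an author residue index.
    """

    def resolve(frame: Frame, spec: tuple[str, str]) -> np.ndarray:
        pos, name = spec
        if numbering is not None and isinstance(pos, str):
            index = numbering.index_of(pos)
        else:
            index = int(pos)
        res = frame.residue(index, chain)
        if not res.has_atom(name):
            raise KeyError(f"residue {res.name}{index} has no atom {name!r}")
        return res.coord(name)

    dists = [
        float(np.linalg.norm(resolve(f, atom_a) - resolve(f, atom_b))) for f in frames
    ]
    return ContactTrace(
        frame_labels=[f.label for f in frames],
        times_ns=[f.time_ns for f in frames],
        distances=np.array(dists),
        atom_a=atom_a,
        atom_b=atom_b,
    )
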