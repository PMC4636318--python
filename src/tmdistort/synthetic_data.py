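"""Seeded generators for helices, trajectories and alignments with known truth.

Every analysis stage of the package is exercised against constructions whose
ground truth is programmed in, so correctness never depends on external
downloads:

* ideal α-helices built residue-by-residue from internal coordinates
  (standard bond lengths/angles, default torsions φ=−57°, ψ=−47°, ω=180°);
* kinked helices in which the C-terminal arm is rigidly rotated about an
  axis through the pivot Cα, so the programmed inter-arm angle is exact;
* bulged helices with one extra residue whose π-like turn torsions were
  chosen by a grid search near (φ, ψ) = (−75°, −35°) under the register
  contract: ≥1 i→i−5 bond and ≥2 broken i→i−4 bonds near the bulge,
  canonical register elsewhere (the contract, not the preset, is what the
  builder guarantees — it fails loudly if unmet);
* multi-frame trajectories with per-frame bend targets and i.i.d. Gaussian
  coordinate noise;
* alignments sampled column-by-column from consensus/conservation profiles,
  with group structure and an optional planted one-column deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geom import any_perpendicular, place_atom, rotate_about_axis, unit
from .hbond_register import detect_backbone_hbonds
from .helix_geometry import arm_axis, bend_angle
from .structio import Alignment, Atom, Frame, FrameSet, Residue

__all__ = [
    "HelixSpec",
    "TrajectorySpec",
    "ColumnProfile",
    "MsaSpec",
    "make_ideal_helix",
    "make_kinked_helix",
    "make_bulged_helix",
    "make_trajectory",
    "make_msa",
    "set_bend",
    "strip_hydrogens",
    "AA3",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

# Standard backbone geometry (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.01
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 116.2, 121.7, 120.8


@dataclass
class HelixSpec:
    n_residues: int
    sequence: str | None = None  # 1-letter; default poly-Ala
    phi: float = -57.0
    psi: float = -47.0
    omega: float = 180.0

    def __post_init__(self) -> None:
        if self.n_residues < 8:
            raise ValueError("helix needs at least 8 residues")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")

    def seq(self) -> str:
        return self.sequence or "A" * self.n_residues


@dataclass
class TrajectorySpec:
    n_frames: int
    noise_sigma: float
    bend_schedule: list[float] | None
    seed: int
    labels: list[str] | None = None
    times_ns: list[float | None] | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be ≥ 0")
        if self.bend_schedule is not None and len(self.bend_schedule) != self.n_frames:
            raise ValueError("bend_schedule length must equal n_frames")


# ---------------------------------------------------------------------------
# Backbone construction
# ---------------------------------------------------------------------------

def _build_chain(
    sequence: str,
    torsions: list[tuple[float, float]],
    omega: float = 180.0,
    first_index: int = 1,
) -> list[Residue]:
    """Build an all-backbone peptide (N, CA, C, O, amide H; ring for Pro)
    from per-residue (φ, ψ) torsions via NeRF chain extension."""
    n_res = len(sequence)
    assert len(torsions) == n_res
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    th = np.radians(180.0 - _A_N_CA_C)
    C = CA + _B_CA_C * np.array([np.cos(th), np.sin(th), 0.0])

    backbone: list[dict[str, np.ndarray]] = [{"N": N, "CA": CA, "C": C}]
    for i in range(1, n_res):
        phi_i, _ = torsions[i]
        _, psi_prev = torsions[i - 1]
        prev = backbone[-1]
        n_next = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi_prev)
        ca_next = place_atom(prev["CA"], prev["C"], n_next, _B_N_CA, _A_C_N_CA, omega)
        c_next = place_atom(prev["C"], n_next, ca_next, _B_CA_C, _A_N_CA_C, phi_i)
        backbone.append({"N": n_next, "CA": ca_next, "C": c_next})

    residues: list[Residue] = []
    for i, atoms in enumerate(backbone):
        aa = sequence[i]
        name3 = AA3[aa]
        _, psi_i = torsions[i]
        # carbonyl O: anti to the next amide N (dihedral N-CA-C-O = ψ + 180)
        o = place_atom(atoms["N"], atoms["CA"], atoms["C"], _B_C_O, _A_CA_C_O, psi_i + 180.0)
        alist = [
            Atom("N", "N", atoms["N"]),
            Atom("CA", "C", atoms["CA"]),
            Atom("C", "C", atoms["C"]),
            Atom("O", "O", o),
        ]
        if name3 == "PRO":
            cb = place_atom(atoms["C"], atoms["N"], atoms["CA"], 1.53, 103.0, 115.0)
            cg = place_atom(atoms["N"], atoms["CA"], cb, 1.50, 104.0, 30.0)
            cd = place_atom(atoms["CA"], cb, cg, 1.51, 106.0, -35.0)
            alist += [Atom("CB", "C", cb), Atom("CG", "C", cg), Atom("CD", "C", cd)]
        else:
            if i > 0:
                prev_c = backbone[i - 1]["C"]
                h = atoms["N"] + _B_N_H * unit(
                    unit(atoms["N"] - prev_c) + unit(atoms["N"] - atoms["CA"])
                )
                alist.insert(1, Atom("H", "H", h))
            if name3 != "GLY":
                cb = place_atom(atoms["C"], atoms["N"], atoms["CA"], 1.53, 110.5, 122.5)
                alist.append(Atom("CB", "C", cb))
        residues.append(Residue(first_index + i, name3, alist))
    return residues


def make_ideal_helix(spec: HelixSpec, first_index: int = 1, chain_id: str = "A") -> Frame:
    """Canonical α-helix: straight axis, full i→i−4 backbone register."""
    torsions = [(spec.phi, spec.psi)] * spec.n_residues
    residues = _build_chain(spec.seq(), torsions, spec.omega, first_index)
    return Frame({chain_id: residues}, label="ideal")


def set_bend(
    frame: Frame,
    helix: tuple[int, int],
    pivot: int,
    target_deg: float,
    chain: str | None = None,
) -> Frame:
    """Return a copy re-hinged so the arm-axis bend angle equals ``target_deg``.

    The C-terminal arm (residues pivot+1 … helix end) is rigidly rotated
    about an axis through the pivot Cα perpendicular to the current arm-axis
    plane, which changes the inter-arm angle by exactly the applied delta.
    """
    out = frame.copy()
    cid = chain or next(iter(out.chains))
    start, end = helix
    ca_n = np.array([r.coord("CA") for r in out.residues_in(start, pivot - 1, cid)])
    ca_c = np.array([r.coord("CA") for r in out.residues_in(pivot + 1, end, cid)])
    if len(ca_n) < 6 or len(ca_c) < 6:
        raise ValueError("each arm needs ≥6 residues for re-hinging")
    u = arm_axis(ca_n).direction
    v = arm_axis(ca_c).direction
    cross = np.cross(u, v)
    if np.linalg.norm(cross) < 1e-8:  # arms parallel: pick any perpendicular
        axis = any_perpendicular(u)
    else:
        axis = unit(cross)
    current = np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))
    delta = target_deg - current
    origin = out.residue(pivot, cid).coord("CA")
    for res in out.residues_in(pivot + 1, end, cid):
        for atom in res.atoms:
            atom.coord = rotate_about_axis(atom.coord[None, :], origin, axis, delta)[0]
    hinges = dict(out.meta.get("hinges", {}))
    hinges[(cid, helix)] = {"pivot": pivot, "angle": target_deg}
    out.meta["hinges"] = hinges
    out.meta.setdefault("hinge", {"chain": cid, "helix": helix, "pivot": pivot})
    out.meta["hinge"].update(angle=target_deg)
    return out


def make_kinked_helix(
    spec: HelixSpec, kink_angle: float, pivot: int, first_index: int = 1
) -> Frame:
    """Ideal helix with the C-arm rigidly rotated to a programmed kink angle."""
    n = spec.n_residues
    p = pivot - first_index + 1
    if not (6 <= p <= n - 6):
        raise ValueError("pivot must leave ≥6 residues in each arm")
    frame = make_ideal_helix(spec, first_index)
    helix = (first_index, first_index + n - 1)
    if kink_angle == 0:
        # exactly the ideal helix; just record the hinge for re-hinging
        frame.meta["hinge"] = {"chain": "A", "helix": helix, "pivot": pivot, "angle": 0.0}
    else:
        frame = set_bend(frame, helix, pivot, kink_angle)
    frame.label = "kinked"
    return frame


# π-like turn torsion presets for the bulge builder, in search order.
# Found once by a grid search over (φ, ψ) starting near (−75, −35) for the
# two turn residues preceding the bulge position, accepting presets that
# satisfy the register contract below; the contract is re-verified at build
# time.  The first preset yields the textbook π-bulge signature: four
# consecutive donors lose their i→i−4 bond and two of them gain i→i−5.
_BULGE_PRESETS: list[tuple[float, float]] = [
    (-60.0, -75.0),
    (-100.0, -40.0),
    (-80.0, -50.0),
    (-90.0, -60.0),
    (-105.0, -60.0),
    (-120.0, -50.0),
    (-75.0, -35.0),
]


def _bulge_contract_ok(frame: Frame, bulge_index: int, n_total: int, first_index: int) -> bool:
    """Check: ≥1 i→i−5 and ≥2 missing i→i−4 near the bulge, canonical
    i→i−4 register away from it."""
    bonds = detect_backbone_hbonds(frame)
    i4 = {b.donor_residue for b in bonds if b.offset == 4}
    i5 = {b.donor_residue for b in bonds if b.offset == 5}
    lo, hi = bulge_index - 2, bulge_index + 2
    near_i5 = any(lo <= d <= hi for d in i5)
    near_missing_i4 = sum(
        1 for d in range(lo, hi + 1) if d >= first_index + 4 and d not in i4
    )
    last = first_index + n_total - 1
    far_ok = all(
        d in i4
        for d in range(first_index + 4, last + 1)
        if not (bulge_index - 3 <= d <= bulge_index + 3)
    )
    far_i5 = any(d in i5 for d in range(first_index, last + 1) if not (lo <= d <= hi))
    return near_i5 and near_missing_i4 >= 2 and far_ok and not far_i5


def make_bulged_helix(
    spec: HelixSpec, bulge_position: int, first_index: int = 1
) -> Frame:
    """Helix with one extra residue forming a π-like bulge.

    The returned helix has ``n_residues + 1`` residues; the inserted turn is
    centred on ``bulge_position``.  The register contract (broken i→i−4,
    gained i→i−5 around the bulge, canonical elsewhere) is verified with the
    H-bond detector; if no torsion preset satisfies it the builder raises.
    """
    n = spec.n_residues + 1
    p = bulge_position - first_index + 1
    if not (5 <= p <= n - 5):
        raise ValueError("bulge position must be ≥5 residues from each end")
    seq = spec.seq()
    seq = seq[: p - 1] + seq[p - 1] + seq[p - 1 :]  # duplicate the bulge residue
    for phi_b, psi_b in _BULGE_PRESETS:
        torsions = [(spec.phi, spec.psi)] * n
        # widened turn on the two residues preceding the bulge position:
        # the register shift (lost i→i−4, gained i→i−5) lands on the donors
        # at and just after the bulge position itself
        for j in (p - 3, p - 2):
            torsions[j] = (phi_b, psi_b)
        residues = _build_chain(seq, torsions, spec.omega, first_index)
        frame = Frame({"A": residues}, label="bulged")
        if _bulge_contract_ok(frame, bulge_position, n, first_index):
            frame.meta["bulge"] = {
                "position": bulge_position,
                "torsions": (phi_b, psi_b),
            }
            return frame
    raise RuntimeError(
        "no torsion preset satisfies the bulge register contract; "
        "refusing to return a helix without the programmed i→i−5 register"
    )


def strip_hydrogens(frame: Frame) -> Frame:
    out = frame.copy()
    for residues in out.chains.values():
        for res in residues:
            res.atoms = [a for a in res.atoms if a.element != "H"]
    return out


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def make_trajectory(base: Frame, spec: TrajectorySpec) -> FrameSet:
    """Frames of ``base`` re-hinged per the bend schedule plus Gaussian noise.

    The base must have been built with a pivot (kinked or re-hinged helix)
    for a non-trivial schedule; requesting nonzero bends on a pivot-less
    base is an error.  Deterministic for a fixed seed.
    """
    hinge = base.meta.get("hinge")
    schedule = spec.bend_schedule
    if schedule is not None and hinge is None and any(t != 0 for t in schedule):
        raise ValueError("bend schedule requires a base built with a pivot")
    rng = np.random.default_rng(spec.seed)
    frames = []
    for k in range(spec.n_frames):
        if schedule is not None and hinge is not None:
            f = set_bend(
                base, hinge["helix"], hinge["pivot"], schedule[k], hinge["chain"]
            )
        else:
            f = base.copy()
        if spec.noise_sigma > 0:
            coords = f.coords()
            coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)
            f.set_coords(coords)
        f.label = (
            spec.labels[k] if spec.labels is not None else f"frame{k + 1}"
        )
        f.time_ns = spec.times_ns[k] if spec.times_ns is not None else None
        frames.append(f)
    return FrameSet(frames)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class ColumnProfile:
    """Sampling profile of one alignment column.

    ``consensus`` is a residue, or a per-group mapping for group-informative
    columns.  Each sequence draws the consensus with probability
    ``conservation`` and otherwise a uniform draw from ``background``.
    """

    consensus: str | dict[str, str]
    conservation: float = 0.8
    background: str = "ACDEFGHIKLMNQRSTVWY"  # no proline unless planted

    def __post_init__(self) -> None:
        if not 0.0 < self.conservation <= 1.0:
            raise ValueError("conservation must lie in (0, 1]")

    def consensus_for(self, group: str) -> str:
        if isinstance(self.consensus, dict):
            return self.consensus[group]
        return self.consensus


@dataclass
class MsaSpec:
    n_sequences: int
    column_profiles: list[ColumnProfile]
    group_labels: list[str]
    anchor_columns: dict[str, int] = field(default_factory=dict)
    planted_deletion_column: int | None = None
    deletion_group: str | None = None
    ids: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_labels) != self.n_sequences:
            raise ValueError("one group label per sequence required")
        if self.ids is not None and len(self.ids) != self.n_sequences:
            raise ValueError("one id per sequence required")
        ncol = len(self.column_profiles)
        for lab, col in self.anchor_columns.items():
            if not 0 <= col < ncol:
                raise ValueError(f"anchor column {lab} out of range")
        if self.planted_deletion_column is not None:
            if self.deletion_group is None:
                raise ValueError("planted deletion requires a deletion_group")
            if self.planted_deletion_column in self.anchor_columns.values():
                raise ValueError("cannot plant the deletion on an anchor column")
            if not 0 <= self.planted_deletion_column < ncol:
                raise ValueError("planted deletion column out of range")


def make_msa(spec: MsaSpec) -> Alignment:
    """Sample a gapped alignment from per-column profiles.

    Sequences of the deletion group carry a gap at the planted column (they
    lack that residue), so that with the gap in place all anchor columns
    align across groups.  Group identity is encoded in the sequence ids.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    counters: dict[str, int] = {}
    records: list[tuple[str, str]] = []
    for s in range(spec.n_sequences):
        group = spec.group_labels[s]
        if spec.ids is not None:
            sid = spec.ids[s]
        else:
            counters[group] = counters.get(group, 0) + 1
            sid = f"{group}_{counters[group]:02d}"
        row = []
        for j, prof in enumerate(spec.column_profiles):
            if (
                spec.planted_deletion_column == j
                and group == spec.deletion_group
            ):
                row.append("-")
                continue
            consensus = prof.consensus_for(group)
            if rng.random() < prof.conservation:
                row.append(consensus)
            else:
                pool = prof.background.replace(consensus, "") or prof.background
                row.append(pool[rng.integers(len(pool))])
        records.append((sid, "".join(row)))
    aln = Alignment(records)
    aln.column_labels = dict(spec.anchor_columns) or None
    return aln
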