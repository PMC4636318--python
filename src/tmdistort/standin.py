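"""Synthetic stand-ins for the reference structural and sequence data.

Everything in this module is *synthetic*: a desk-scale seven-helix receptor
trajectory and a 52-sequence LGR-family-like alignment whose ground truth is
programmed in, emulating the study conditions of the analysed system —

* a TSHR-like transmembrane domain (residues 410–694, one chain) whose TM2
  carries a π-bulge register (i→i−4 bonds broken at 2.56–2.59, i→i−5 bonds
  donated by 2.57 and 2.58) and whose TM5 relaxes from an initial 26° kink
  at the 5.46 hinge to a straight ~9° production conformation, while TM2
  relaxes from 33° to ~22°;
* five frames (initial model + 10/20/40/60 ns snapshots) with Gaussian
  coordinate noise and per-helix rigid drift scheduled so the production
  Cα RMSD reaches a first plateau near 2.5 Å and a late plateau near 3 Å;
* an E3.37–N5.47 side-chain contact that tightens in the late frames
  (rotamer reorientation accompanying the second plateau);
* a 52-sequence alignment in three sub-groups (glycoprotein-hormone-
  receptor/LGR4–6-like, RXFP1/2-like, and a *C. intestinalis* expansion)
  with the Y5.38 motif in group 2, Y5.39 in groups 1 and 3, a conserved
  N5.47, and a one-residue deletion planted at position 5.45 in group 1.

The sequences and coordinates are constructions, not database entries; the
residue identities at documented positions (N432, D474, L483, I484, E506,
R519, W546, N590, A593, Y601, D633, P639, N674, P675 …) are the only parts
meant to be faithful.
"""

from __future__ import annotations

import numpy as np

from ._geom import any_perpendicular, rotate_about_axis, unit
from .bw_numbering import (
    BWNumbering,
    TSHR_HELIX_SPANS,
    parse_label,
    tshr_reference_numbering,
)
from .helix_geometry import arm_axis
from .structio import Alignment, Atom, Frame, FrameSet, Residue
from .synthetic_data import ColumnProfile, MsaSpec, _build_chain, make_msa, set_bend

__all__ = [
    "tshr_like_sequence",
    "tshr_like_numbering",
    "make_receptor_standin",
    "make_lgr_like_alignment",
    "LGR_GROUPS",
    "FRAME_LABELS",
    "PRODUCTION_LABELS",
    "TM2_BEND_SCHEDULE",
    "TM5_BEND_SCHEDULE",
    "CONTACT_SCHEDULE",
]

# ---------------------------------------------------------------------------
# Sequence
# ---------------------------------------------------------------------------

#: Residue identities documented for the receptor; everything else is filler.
_KNOWN_RESIDUES = {
    410: "D", 432: "N", 474: "D", 482: "L", 483: "L", 484: "I", 491: "C",
    506: "E", 519: "R", 546: "W", 582: "L", 583: "Y", 588: "L", 590: "N",
    593: "A", 601: "Y", 633: "D", 639: "P", 660: "K", 674: "N", 675: "P",
    694: "S",
}

_FILLER = "LIVAFTLSVM"


def tshr_like_sequence() -> list[tuple[int, str]]:
    """Synthetic TSHR-like sequence covering residues 410–694.

    Anchor and mutant positions carry their documented amino acids; filler
    positions cycle through a hydrophobic-rich pattern.  This is a stand-in
    for the real receptor sequence, sufficient for numbering and for the
    synthetic structures built on top of it.
    """
    return [
        (i, _KNOWN_RESIDUES.get(i, _FILLER[i % len(_FILLER)]))
        for i in range(410, 695)
    ]


def tshr_like_numbering() -> BWNumbering:
    return tshr_reference_numbering(tshr_like_sequence())


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

FRAME_LABELS = ["initial", "10ns", "20ns", "40ns", "60ns"]
PRODUCTION_LABELS = FRAME_LABELS[1:]
FRAME_TIMES_NS = [0.0, 10.0, 20.0, 40.0, 60.0]

#: Per-frame bend targets (degrees): initial kinked model, then the relaxed
#: production conformation (means 22° for TM2, 9° for TM5).
TM2_BEND_SCHEDULE = [33.0, 23.0, 22.0, 21.0, 22.0]
TM5_BEND_SCHEDULE = [26.0, 10.0, 9.0, 9.0, 8.0]

#: Hinge pivots: TM2 at 2.58 (residue 482), TM5 at 5.46 (residue 589),
#: flanking the deleted 5.45.
_TM2_PIVOT, _TM5_PIVOT = 482, 589

#: π-turn torsions of the TM2 bulge: three consecutive residues at
#: 2.55–2.57 (479–481), placing the broken i→i−4 run on donors 2.56–2.59
#: and the i→i−5 bonds on donors 2.57/2.58.  Values from the documented
#: torsion search maximising the geometric margin of that register pattern
#: under the production-phase hinge angle and coordinate noise.
_TM2_TURN = {
    479: (-88.9, -80.5),
    480: (-84.3, -28.0),
    481: (-51.1, -81.8),
}

#: E3.37–N5.47 side-chain contact distance schedule (Cδ···Nδ2, Å): apart in
#: the early production frames, H-bonded after the rotamer flip at ~35 ns.
CONTACT_SCHEDULE = [6.0, 8.0, 7.5, 3.5, 3.4]

#: Per-helix rigid drift amplitude (Å) per frame, scheduled so the domain
#: Cα RMSD vs the initial model plateaus near 2.5 Å (10–20 ns) and 3 Å
#: (40–60 ns).
DRIFT_SCHEDULE = [0.0, 1.81, 1.81, 2.31, 2.31]

_NOISE_SIGMA = 0.15
_RING_RADIUS = 11.0


def _helix_residue_ranges(numbering: BWNumbering) -> dict[int, tuple[int, int]]:
    return {h: numbering.span_indices(h) for h in sorted(TSHR_HELIX_SPANS)}


def _build_helix_segment(start: int, end: int, sequence: dict[int, str]) -> list[Residue]:
    seq = "".join(sequence[i] for i in range(start, end + 1))
    n = len(seq)
    torsions = [(-57.0, -47.0)] * n
    for res_idx, tw in _TM2_TURN.items():
        if start <= res_idx <= end:
            torsions[res_idx - start] = tw
    return _build_chain(seq, torsions, 180.0, first_index=start)


def _place_segment(residues: list[Residue], slot: int, up: bool) -> None:
    """Rigidly move a built helix onto the TM-bundle ring, axis along ±z."""
    ca = np.array([r.coord("CA") for r in residues])
    axis = arm_axis(ca).direction
    target = np.array([0.0, 0.0, 1.0 if up else -1.0])
    v = np.cross(axis, target)
    s, c = np.linalg.norm(v), float(np.dot(axis, target))
    if s > 1e-12:
        rot_axis, ang = unit(v), np.degrees(np.arctan2(s, c))
    else:
        rot_axis, ang = any_perpendicular(axis), (0.0 if c > 0 else 180.0)
    centroid = ca.mean(axis=0)
    theta = 2.0 * np.pi * slot / 7.0
    ring = _RING_RADIUS * np.array([np.cos(theta), np.sin(theta), 0.0])
    for res in residues:
        for atom in res.atoms:
            moved = rotate_about_axis(atom.coord[None, :], centroid, rot_axis, ang)[0]
            atom.coord = moved - centroid + ring


def _base_frame() -> tuple[Frame, dict[int, tuple[int, int]]]:
    numbering = tshr_like_numbering()
    seq = dict(tshr_like_sequence())
    ranges = _helix_residue_ranges(numbering)
    residues: list[Residue] = []
    for h, (start, end) in ranges.items():
        segment = _build_helix_segment(start, end, seq)
        _place_segment(segment, slot=h - 1, up=(h % 2 == 1))
        residues.extend(segment)
    residues.sort(key=lambda r: r.index)
    return Frame({"A": residues}, label="base"), ranges


def _program_contact(frame: Frame, distance: float) -> None:
    """Place the E506 / N590 side-chain atoms so Cδ(506)···Nδ2(590) equals
    the scheduled distance (the rotamer state is encoded in the distance)."""
    ca_e = frame.residue(506).coord("CA")
    ca_n = frame.residue(590).coord("CA")
    u = unit(ca_e - ca_n)
    perp = any_perpendicular(u)
    nd2 = ca_n + 2.4 * u
    cg_n = ca_n + 1.5 * u + 0.3 * perp
    od1 = cg_n + 1.2 * perp
    cd_e = nd2 + distance * unit(ca_e - nd2)
    cg_e = cd_e + 1.5 * unit(ca_e - cd_e)
    oe1 = cd_e + 1.25 * perp
    oe2 = cd_e - 1.25 * perp

    def put(res: Residue, name: str, element: str, coord: np.ndarray) -> None:
        if res.has_atom(name):
            res.atom(name).coord = coord
        else:
            res.atoms.append(Atom(name, element, coord))

    res_e, res_n = frame.residue(506), frame.residue(590)
    put(res_e, "CG", "C", cg_e)
    put(res_e, "CD", "C", cd_e)
    put(res_e, "OE1", "O", oe1)
    put(res_e, "OE2", "O", oe2)
    put(res_n, "CG", "C", cg_n)
    put(res_n, "OD1", "O", od1)
    put(res_n, "ND2", "N", nd2)


def make_receptor_standin(seed: int = 0) -> tuple[FrameSet, BWNumbering]:
    """Synthetic five-frame receptor trajectory with programmed ground truth.

    Frame 1 is the kinked initial model (TM2 33°, TM5 26°); frames 2–5 are
    the 10/20/40/60 ns production snapshots (TM2 ≈ 22°, TM5 ≈ 9°, bulged TM2
    register, tightening E3.37–N5.47 contact, drifting helices + noise).
    """
    numbering = tshr_like_numbering()
    base, ranges = _base_frame()
    span2, span5 = ranges[2], ranges[5]
    rng = np.random.default_rng(seed)

    frames = []
    for k, label in enumerate(FRAME_LABELS):
        f = set_bend(base, span2, _TM2_PIVOT, TM2_BEND_SCHEDULE[k])
        f = set_bend(f, span5, _TM5_PIVOT, TM5_BEND_SCHEDULE[k])
        if DRIFT_SCHEDULE[k] > 0:
            # deterministic "breathing": each helix slides radially outward,
            # which the rigid-body superposition cannot absorb, so the drift
            # amplitude maps directly onto the per-frame RMSD plateau
            for h, (start, end) in ranges.items():
                theta = 2.0 * np.pi * (h - 1) / 7.0
                radial = np.array([np.cos(theta), np.sin(theta), 0.0])
                shift = DRIFT_SCHEDULE[k] * radial
                for res in f.residues_in(start, end):
                    for atom in res.atoms:
                        atom.coord = atom.coord + shift
        if _NOISE_SIGMA > 0:
            coords = f.coords()
            f.set_coords(coords + rng.normal(0.0, _NOISE_SIGMA, coords.shape))
        _program_contact(f, CONTACT_SCHEDULE[k])
        f.label = label
        f.time_ns = FRAME_TIMES_NS[k]
        f.meta = {}
        frames.append(f)
    return FrameSet(frames), numbering


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

#: Sub-groups emulating the three clades of the family: glycoprotein hormone
#: receptors + LGR4–6 (group 1, carries the TM5 deletion), relaxin-receptor
#: like (group 2, Y5.38), and a C. intestinalis-specific expansion (group 3).
#: All 52 entries are synthetic sequences; the ids only mimic the naming
#: style of Uniprot entry names.
LGR_GROUPS: dict[str, list[str]] = {
    "GPHR": [
        "TSHR_HUMAN", "FSHR_HUMAN", "LHCGR_HUMAN", "LGR4_HUMAN", "LGR5_HUMAN",
        "LGR6_HUMAN", "TSHR_DANRE", "FSHR_DANRE", "LHCGR_DANRE", "LGR4_DANRE",
        "LGR5_DANRE", "LGR6_DANRE", "GPHRA_BRAFL", "GPHRB_BRAFL", "GPHR_DROME",
        "GPHR_CAEEL", "GPHRA_NEMVE", "GPHRB_NEMVE", "GPHR_CIOIN", "LGR4_CIOIN",
    ],
    "RXFP": [
        "RXFP1_HUMAN", "RXFP2_HUMAN", "RXFP1_DANRE", "RXFP2_DANRE",
        "RXFPA_BRAFL", "RXFPB_BRAFL", "LGR3_DROME", "LGR4_DROME",
        "RXFPA_CAEEL", "RXFPB_CAEEL", "RXFPA_NEMVE", "RXFPB_NEMVE",
        "RXFP1_CIOIN", "RXFP2_CIOIN", "RXFPC_BRAFL", "RXFPC_NEMVE",
    ],
    "CION": [f"LGRC{i:02d}_CIOIN" for i in range(1, 17)],
}

#: Fully conserved family anchors.
_FULL_COLUMNS = {
    "1.50": "N", "2.50": "D", "3.25": "C", "3.50": "R", "4.50": "W",
    "5.47": "N", "5.58": "Y", "6.50": "P", "7.50": "P",
}

#: The tyrosine motif separating the sub-groups.
_MOTIF_COLUMNS = {
    "5.38": {"GPHR": "L", "RXFP": "Y", "CION": "I"},
    "5.39": {"GPHR": "Y", "RXFP": "L", "CION": "Y"},
}

#: TM5 block between the tyrosine motif and N5.47: hydrophobic pattern with
#: polar interruptions flanking 5.45 so the deletion site is identifiable
#: by hydrophobicity-class scoring.
_TM5_BLOCK = {
    "5.40": "L", "5.41": "F", "5.42": "S", "5.43": "L", "5.44": "T",
    "5.45": "L", "5.46": "S", "5.48": "V", "5.49": "A", "5.50": "A",
    "5.51": "I", "5.52": "L", "5.53": "G", "5.54": "V", "5.55": "F",
    "5.56": "I", "5.57": "V",
}

#: Positions where class A receptors usually carry their TM2/TM5 prolines;
#: this family has none, which is why the helix conformations cannot be
#: predicted from a proline pattern.
_NO_PROLINE_COLUMNS = {"2.58": "L", "2.59": "L", "2.60": "I", "5.50": "A"}

#: Group-diagnostic consensus triples giving the clades a clean signal.
_SIGNATURE_CONSENSUS = [
    {"GPHR": "F", "RXFP": "T", "CION": "K"},
    {"GPHR": "V", "RXFP": "N", "CION": "E"},
    {"GPHR": "M", "RXFP": "S", "CION": "R"},
]


def _all_column_labels() -> list[str]:
    labels = []
    for h, (lo, hi) in sorted(TSHR_HELIX_SPANS.items()):
        (_, plo, _), (_, phi, _) = parse_label(lo), parse_label(hi)
        labels.extend(f"{h}.{p:02d}" for p in range(plo, phi + 1))
    return labels


def make_lgr_like_alignment(
    seed: int = 0,
) -> tuple[Alignment, dict[str, list[str]]]:
    """Synthetic 52-sequence LGR-like alignment over the seven TM spans.

    Three sub-groups with diagnostic columns, the Y5.38/Y5.39 motif split,
    fully conserved anchors, no prolines at 2.58/2.59/2.60/5.50, and a
    one-residue deletion planted at position 5.45 in the group 1 sequences.
    Returns the alignment (column labels attached) and the group → ids map.
    """
    labels = _all_column_labels()
    col_of = {lab: j for j, lab in enumerate(labels)}

    profiles: list[ColumnProfile] = []
    sig_cycle = 0
    for j, lab in enumerate(labels):
        if lab in _FULL_COLUMNS:
            profiles.append(ColumnProfile(_FULL_COLUMNS[lab], 1.0))
        elif lab in _MOTIF_COLUMNS:
            profiles.append(ColumnProfile(_MOTIF_COLUMNS[lab], 1.0))
        elif lab in _TM5_BLOCK:
            profiles.append(ColumnProfile(_TM5_BLOCK[lab], 0.8))
        elif lab in _NO_PROLINE_COLUMNS:
            profiles.append(ColumnProfile(_NO_PROLINE_COLUMNS[lab], 0.8))
        elif j % 6 == 3:  # group-diagnostic columns, spread along the spans
            profiles.append(
                ColumnProfile(_SIGNATURE_CONSENSUS[sig_cycle % 3], 0.9)
            )
            sig_cycle += 1
        elif j % 5 == 0:
            profiles.append(ColumnProfile(_FILLER[j % len(_FILLER)], 0.6))
        else:
            profiles.append(ColumnProfile(_FILLER[(j * 3) % len(_FILLER)], 0.8))

    ids = [sid for grp in LGR_GROUPS.values() for sid in grp]
    group_labels = [grp for grp, members in LGR_GROUPS.items() for _ in members]
    spec = MsaSpec(
        n_sequences=len(ids),
        column_profiles=profiles,
        group_labels=group_labels,
        anchor_columns={lab: col_of[lab] for lab in ("5.38", "5.39", "5.47", "5.58")},
        planted_deletion_column=col_of["5.45"],
        deletion_group="GPHR",
        ids=ids,
        seed=seed,
    )
    alignment = make_msa(spec)
    alignment.column_labels = col_of
    return alignment, {g: list(m) for g, m in LGR_GROUPS.items()}
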