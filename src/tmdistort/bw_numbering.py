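"""Ballesteros–Weinstein (BW) residue numbering with indel support.

BW labels are strings ``"h.pp"`` (helix number, two-digit position) in which
the most conserved residue of each transmembrane helix is ``h.50``.  Labels
are assigned by signed offset from one anchor residue per helix.  Declared
deletions are labels that map to no residue — counting simply skips them —
and insertions get suffixed labels ``"h.pp+k"`` so the ``.50`` frame is never
shifted.

All arithmetic is done on integer (helix, position) pairs parsed from the
label, never on a float representation, to avoid the ``5.5`` vs ``5.50``
ambiguity.

The thyrotropin receptor (TSHR) reference numbering uses the seven anchors
N432 (1.50), D474 (2.50), R519 (3.50), W546 (4.50), Y601 (5.58; TM5 is
anchored on the highly conserved tyrosine because glycoprotein hormone
receptors lack P5.50), P639 (6.50) and P675 (7.50), plus a one-residue
deletion at 5.45 that reflects the loss of the TM5 bulge residue in this
receptor family.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Anchor",
    "Indel",
    "BWNumbering",
    "NumberingError",
    "DELETED",
    "parse_label",
    "format_label",
    "assign_numbering",
    "tshr_reference_numbering",
    "TSHR_ANCHORS",
    "TSHR_HELIX_SPANS",
    "TSHR_INDELS",
]


class NumberingError(ValueError):
    """Raised when anchors, spans or residues are inconsistent."""


class _Deleted:
    """Sentinel returned when a label is a declared deletion."""

    def __repr__(self) -> str:  # pragma: no cover
        return "DELETED"

    def __bool__(self) -> bool:
        return False


DELETED = _Deleted()

_LABEL_RE = re.compile(r"^(\d)\.(\d{2})(?:\+(\d+))?$")


def parse_label(label: str) -> tuple[int, int, int]:
    """Parse ``"h.pp"`` or ``"h.pp+k"`` into (helix, position, insertion)."""
    m = _LABEL_RE.match(label)
    if not m:
        raise NumberingError(f"malformed BW label {label!r}")
    return int(m.group(1)), int(m.group(2)), int(m.group(3) or 0)


def format_label(helix: int, position: int, insertion: int = 0) -> str:
    base = f"{helix}.{position:02d}"
    return f"{base}+{insertion}" if insertion else base


@dataclass(frozen=True)
class Anchor:
    helix: int
    residue_index: int
    bw_label: str

    def __post_init__(self) -> None:
        h, _, ins = parse_label(self.bw_label)
        if h != self.helix:
            raise NumberingError(
                f"anchor label {self.bw_label} does not belong to helix {self.helix}"
            )
        if ins:
            raise NumberingError("anchor labels cannot be insertion labels")


@dataclass(frozen=True)
class Indel:
    bw_position: str
    kind: str  # "deletion" | "insertion"

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion"):
            raise NumberingError(f"unknown indel kind {self.kind!r}")
        parse_label(self.bw_position)


@dataclass
class BWNumbering:
    """Bidirectional residue-index ↔ BW-label map."""

    forward: dict[int, str]
    reverse: dict[str, tuple[int, str]]
    helix_spans: dict[int, tuple[str, str]]
    deleted: set[str] = field(default_factory=set)

    def label_of(self, residue_index: int) -> str:
        try:
            return self.forward[residue_index]
        except KeyError:
            raise KeyError(f"residue {residue_index} carries no BW label") from None

    def residue_of(self, label: str):
        """Return ``(residue_index, amino_acid)``; ``DELETED`` for deleted labels."""
        parse_label(label)
        if label in self.deleted:
            return DELETED
        try:
            return self.reverse[label]
        except KeyError:
            raise KeyError(f"label {label} is outside the numbered spans") from None

    def index_of(self, label: str) -> int:
        res = self.residue_of(label)
        if res is DELETED:
            raise NumberingError(f"label {label} is a declared deletion")
        return res[0]

    def labels_in_span(self, helix: int) -> list[str]:
        """Ordered labels of a helix span, deletions excluded."""
        lo, hi = self.helix_spans[helix]
        (_, plo, _), (_, phi, _) = parse_label(lo), parse_label(hi)
        out = []
        for p in range(plo, phi + 1):
            lab = format_label(helix, p)
            if lab in self.reverse:
                out.append(lab)
            for k in range(1, 10):
                ins = format_label(helix, p, k)
                if ins in self.reverse:
                    out.append(ins)
        return out

    def span_indices(self, helix: int) -> tuple[int, int]:
        """First and last author residue index of a helix span."""
        labs = self.labels_in_span(helix)
        return self.reverse[labs[0]][0], self.reverse[labs[-1]][0]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"residue_index": i, "aa": self.reverse[lab][1], "bw_label": lab}
            for i, lab in sorted(self.forward.items())
        ]
        return pd.DataFrame(rows)


def _span_labels(
    helix: int,
    span: tuple[str, str],
    deletions: set[str],
    insertions: set[str],
) -> list[str]:
    """Ordered labels a helix span assigns to residues (deletions skipped)."""
    (h_lo, p_lo, _), (h_hi, p_hi, _) = parse_label(span[0]), parse_label(span[1])
    if h_lo != helix or h_hi != helix or p_lo > p_hi:
        raise NumberingError(f"invalid span {span} for helix {helix}")
    labels = []
    for p in range(p_lo, p_hi + 1):
        lab = format_label(helix, p)
        if lab not in deletions:
            labels.append(lab)
        k = 1
        while format_label(helix, p, k) in insertions:
            labels.append(format_label(helix, p, k))
            k += 1
    return labels


def assign_numbering(
    residues: list[tuple[int, str]],
    anchors: list[Anchor],
    indels: list[Indel] = (),
    spans: dict[int, tuple[str, str]] | None = None,
) -> BWNumbering:
    """Assign BW labels by signed offset from each helix anchor.

    ``residues`` is the ordered (author index, one-letter amino acid) list of
    the chain.  Within each declared span, consecutive residues map to
    consecutive labels except across declared indels: a deletion at 5.45
    means label 5.45 maps to no residue and counting continues with 5.44/5.46
    adjacent in sequence.
    """
    if spans is None:
        raise NumberingError("helix spans are required")
    seen: set[int] = set()
    for a in anchors:
        if a.helix in seen:
            raise NumberingError(f"two anchors declared for helix {a.helix}")
        seen.add(a.helix)

    deletions = {i.bw_position for i in indels if i.kind == "deletion"}
    insertions = {i.bw_position for i in indels if i.kind == "insertion"}
    order = [idx for idx, _ in residues]
    aa = dict(residues)
    pos_in_chain = {idx: k for k, idx in enumerate(order)}

    forward: dict[int, str] = {}
    reverse: dict[str, tuple[int, str]] = {}
    for anchor in anchors:
        if anchor.helix not in spans:
            continue
        if anchor.residue_index not in pos_in_chain:
            raise NumberingError(
                f"anchor residue {anchor.residue_index} (helix {anchor.helix}) "
                "is absent from the sequence"
            )
        labels = _span_labels(anchor.helix, spans[anchor.helix], deletions, insertions)
        if anchor.bw_label not in labels:
            raise NumberingError(
                f"anchor label {anchor.bw_label} outside span {spans[anchor.helix]}"
            )
        a_slot = labels.index(anchor.bw_label)
        a_chain = pos_in_chain[anchor.residue_index]
        for slot, lab in enumerate(labels):
            chain_pos = a_chain + (slot - a_slot)
            if chain_pos < 0 or chain_pos >= len(order):
                raise NumberingError(
                    f"helix {anchor.helix}: span {spans[anchor.helix]} extends "
                    "past the available residues"
                )
            idx = order[chain_pos]
            forward[idx] = lab
            reverse[lab] = (idx, aa[idx])
    return BWNumbering(forward, reverse, dict(spans), deleted=set(deletions))


# ---------------------------------------------------------------------------
# TSHR reference numbering
# ---------------------------------------------------------------------------

TSHR_ANCHORS: list[Anchor] = [
    Anchor(1, 432, "1.50"),
    Anchor(2, 474, "2.50"),
    Anchor(3, 519, "3.50"),
    Anchor(4, 546, "4.50"),
    Anchor(5, 601, "5.58"),
    Anchor(6, 639, "6.50"),
    Anchor(7, 675, "7.50"),
]

#: Expected amino acid at each anchor, used as a sanity check on input.
_TSHR_ANCHOR_AA = {432: "N", 474: "D", 519: "R", 546: "W", 601: "Y", 639: "P", 675: "P"}

#: Default helix spans.  Chosen to cover every position discussed for this
#: receptor (2.46, 2.57–2.60, 3.22–3.55, 5.38–5.58, 6.44, 7.35, 7.49).
TSHR_HELIX_SPANS: dict[int, tuple[str, str]] = {
    1: ("1.35", "1.60"),
    2: ("2.38", "2.66"),
    3: ("3.22", "3.55"),
    4: ("4.39", "4.63"),
    5: ("5.38", "5.63"),
    6: ("6.30", "6.60"),
    7: ("7.33", "7.56"),
}

TSHR_INDELS: list[Indel] = [Indel("5.45", "deletion")]


def tshr_reference_numbering(
    tshr_sequence: list[tuple[int, str]],
    spans: dict[int, tuple[str, str]] | None = None,
) -> BWNumbering:
    """TSHR numbering with the seven anchors and the TM5 deletion at 5.45.

    ``tshr_sequence`` must cover residues D410–S694 of the transmembrane
    domain.  Anchor residue identities are validated and a mismatch names the
    offending anchor.
    """
    aa = dict(tshr_sequence)
    indices = sorted(aa)
    if not indices or indices[0] > 410 or indices[-1] < 694:
        raise NumberingError("sequence must cover residues 410–694")
    for idx, expect in _TSHR_ANCHOR_AA.items():
        if aa.get(idx) != expect:
            raise NumberingError(
                f"anchor residue {expect}{idx} mismatch: found {aa.get(idx)!r}"
            )
    return assign_numbering(
        sorted(tshr_sequence),
        TSHR_ANCHORS,
        TSHR_INDELS,
        spans or TSHR_HELIX_SPANS,
    )
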