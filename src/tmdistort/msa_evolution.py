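"""Sequence-side evolutionary analysis of the LGR receptor family.

Covers the analyses that localise a one-residue deletion in TM5 of the
glycoprotein hormone receptors: p-distances over the transmembrane columns,
bootstrapped neighbor-joining trees, per-column conservation categories
(full / 80% / 60% type conservation, gaps counting against), the tyrosine
motif at positions 5.38 vs 5.39 that separates the receptor sub-groups, a
proline census at the positions where class A GPCRs usually carry their
TM2/TM5 prolines, and the hydrophobic-pattern scan that scores every
candidate gap placement between the Y5.38/Y5.39 and Y5.58 anchors.

Tree construction itself is the standard Saitou–Nei algorithm (scikit-bio);
everything scored on top of it is implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .bw_numbering import parse_label
from .structio import Alignment

__all__ = [
    "HYDROPHOBIC",
    "DEFAULT_CLASSES",
    "ColumnCategory",
    "GapScanResult",
    "pdistance_matrix",
    "nj_tree",
    "bipartitions",
    "is_monophyletic",
    "conservation_profile",
    "y_motif_classify",
    "scan_gap_positions",
    "proline_census",
]

#: Binary hydrophobicity class used for gap-placement scoring.
HYDROPHOBIC = frozenset("AVLIMFCW")

#: Default residue-class partition for type conservation (covers all 20 aa).
DEFAULT_CLASSES: dict[str, frozenset] = {
    "hydrophobic": frozenset("AVLIMFCW"),
    "polar": frozenset("STNQYGHP"),
    "basic": frozenset("KR"),
    "acidic": frozenset("DE"),
}


# ---------------------------------------------------------------------------
# Distances and trees
# ---------------------------------------------------------------------------

def _region_columns(alignment: Alignment, region) -> list[int]:
    if region is None:
        return list(range(alignment.n_columns))
    if isinstance(region, tuple) and len(region) == 2:
        start, end = region
        return list(range(start, end + 1))
    return list(region)


def pdistance_matrix(alignment: Alignment, region=None) -> DistanceMatrix:
    """p-distances (differing sites / compared sites) over a column region.

    Only columns where neither sequence is gapped are compared; a pair with
    zero comparable sites is an error naming the pair.
    """
    cols = _region_columns(alignment, region)
    if not cols:
        raise ValueError("empty column region")
    mat = alignment.to_matrix()[:, cols]
    ids = alignment.ids
    n = len(ids)
    ok = mat != "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise ValueError(f"no comparable sites for pair ({ids[i]}, {ids[j]})")
            diff = int((mat[i][both] != mat[j][both]).sum())
            d[i, j] = d[j, i] = diff / comparable
    return DistanceMatrix(d, ids=ids)


def _clamp_negative_lengths(tree: TreeNode) -> bool:
    clamped = False
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    return clamped


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Nontrivial bipartitions of an (unrooted) tree, each canonicalised as
    the lexicographically smaller leaf set of the split."""
    tips = frozenset(t.name for t in tree.tips())
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            other = tips - side
            out.add(min(side, other, key=lambda s: tuple(sorted(s))))
    return out


def nj_tree(
    distances: DistanceMatrix,
    alignment: Alignment | None = None,
    region=None,
    bootstrap_reps: int = 0,
    seed: int = 0,
) -> TreeNode:
    """Saitou–Nei neighbor-joining tree with optional bootstrap supports.

    Negative branch lengths are clamped to zero (warned).  When
    ``bootstrap_reps`` > 0 and an alignment is given, columns are resampled
    with replacement per replicate and each internal node of the main tree
    gets a ``support`` attribute equal to its bipartition frequency.
    """
    if distances.shape[0] < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    raw = nj(distances, neg_as_zero=False)
    if _clamp_negative_lengths(raw):
        warnings.warn("negative NJ branch lengths clamped to 0", stacklevel=2)
    tree = raw

    if bootstrap_reps > 0:
        if alignment is None:
            raise ValueError("bootstrap requires the alignment")
        cols = _region_columns(alignment, region)
        rng = np.random.default_rng(seed)
        counts: dict[frozenset, int] = {}
        for _ in range(bootstrap_reps):
            sample = [cols[k] for k in rng.integers(0, len(cols), size=len(cols))]
            dm = pdistance_matrix(alignment, sample)
            rep = nj(dm, neg_as_zero=True)
            for split in bipartitions(rep):
                counts[split] = counts.get(split, 0) + 1
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            tips = frozenset(t.name for t in tree.tips())
            if 1 < len(side) < len(tips) - 1:
                key = min(side, tips - side, key=lambda s: tuple(sorted(s)))
                node.support = counts.get(key, 0) / bootstrap_reps
    return tree


def is_monophyletic(tree: TreeNode, ids) -> bool:
    """True if ``ids`` form one side of a bipartition of the unrooted tree."""
    ids = frozenset(ids)
    tips = frozenset(t.name for t in tree.tips())
    if not ids <= tips:
        raise ValueError("ids not all present in the tree")
    if len(ids) in (1, len(tips) - 1, len(tips)):
        return True
    key = min(ids, tips - ids, key=lambda s: tuple(sorted(s)))
    return key in bipartitions(tree)


# ---------------------------------------------------------------------------
# Conservation and motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnCategory:
    column: int
    category: str  # "full" | "type80" | "type60" | "none"
    best_class: str | None
    fraction: float


def conservation_profile(
    alignment: Alignment, classes: dict[str, frozenset] | None = None
) -> list[ColumnCategory]:
    """Categorise each column by residue/class conservation (≥ thresholds).

    "full" requires a single residue in every sequence (gaps break it);
    otherwise the best residue-class fraction decides type80 (≥0.8) /
    type60 (≥0.6) / none.  Gaps count against conservation.
    """
    classes = classes or DEFAULT_CLASSES
    covered = frozenset().union(*classes.values())
    if covered != frozenset("ACDEFGHIKLMNPQRSTVWY"):
        raise ValueError("classes must partition the 20 amino acids")
    mat = alignment.to_matrix()
    n = len(alignment)
    out = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        residues, counts = np.unique(col[col != "-"], return_counts=True)
        if len(residues) == 1 and counts[0] == n:
            out.append(ColumnCategory(j, "full", str(residues[0]), 1.0))
            continue
        best_name, best_frac = None, 0.0
        for name, members in classes.items():
            frac = float(np.isin(col, list(members)).sum()) / n
            if frac > best_frac:
                best_name, best_frac = name, frac
        if best_frac >= 0.8:
            cat = "type80"
        elif best_frac >= 0.6:
            cat = "type60"
        else:
            cat = "none"
        out.append(ColumnCategory(j, cat, best_name, best_frac))
    return out


def _column_for(alignment: Alignment, label: str, column_labels=None) -> int:
    labels = column_labels or alignment.column_labels
    if not labels or label not in labels:
        raise KeyError(f"no column known for position {label}")
    return labels[label]


def y_motif_classify(
    alignment: Alignment,
    column_labels: dict[str, int] | None = None,
    accept_phe: bool = False,
) -> dict[str, tuple[str, bool]]:
    """Classify each sequence by which column carries the tyrosine motif.

    Returns id → (label, flagged): label is "Y5.38", "Y5.39" or "none";
    sequences with the motif in both or neither column are "none" with the
    flag set.  With ``accept_phe`` the motif accepts Y or F.
    """
    c38 = _column_for(alignment, "5.38", column_labels)
    c39 = _column_for(alignment, "5.39", column_labels)
    motif = {"Y", "F"} if accept_phe else {"Y"}
    out = {}
    for sid, seq in alignment.records:
        at38, at39 = seq[c38] in motif, seq[c39] in motif
        if at38 and not at39:
            out[sid] = ("Y5.38", False)
        elif at39 and not at38:
            out[sid] = ("Y5.39", False)
        else:
            out[sid] = ("none", True)
    return out


def proline_census(
    alignment: Alignment,
    positions: list[str],
    column_labels: dict[str, int] | None = None,
) -> dict[str, tuple[int, list[str]]]:
    """Count sequences carrying proline at each named position."""
    out = {}
    for label in positions:
        col = _column_for(alignment, label, column_labels)
        ids = [sid for sid, seq in alignment.records if seq[col] == "P"]
        out[label] = (len(ids), ids)
    return out


# ---------------------------------------------------------------------------
# Gap-placement scan
# ---------------------------------------------------------------------------

@dataclass
class GapScanResult:
    scores: dict[str, float]
    best: str
    tie: bool
    block: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": list(self.scores), "score": list(self.scores.values())}
        )


def _block_labels(column_labels: dict[str, int], start: str, end: str) -> list[str]:
    (h0, p0, _), (h1, p1, _) = parse_label(start), parse_label(end)
    labs = [
        lab
        for lab in column_labels
        if h0 == parse_label(lab)[0] == h1 and p0 <= parse_label(lab)[1] <= p1
    ]
    return sorted(labs, key=lambda l: column_labels[l])


def scan_gap_positions(
    alignment: Alignment,
    short_group: list[str],
    candidates: list[str],
    column_labels: dict[str, int] | None = None,
    block: tuple[str, str] = ("5.38", "5.58"),
    hydrophobic: frozenset = HYDROPHOBIC,
) -> GapScanResult:
    """Score every candidate gap placement by hydrophobic-pattern agreement.

    The sequences of ``short_group`` are exactly one residue shorter than the
    others over the anchored block.  For each candidate position the short
    sequences are realigned with their gap at that position, and the score is
    the sum over block columns of the fraction of short sequences whose
    residue matches the column's majority hydrophobicity class (majority
    taken over the full-length reference sequences; gaps never match).  Ties
    go to the smallest position and are flagged.
    """
    labels = column_labels or alignment.column_labels
    if not labels:
        raise ValueError("column labels are required for the gap scan")
    block_labs = _block_labels(labels, *block)
    block_cols = [labels[lab] for lab in block_labs]
    if any(c not in labels.values() for c in block_cols):
        raise ValueError("block columns unresolved")
    for cand in candidates:
        if cand not in block_labs:
            raise ValueError(f"candidate {cand} outside the anchored block")

    short = set(short_group)
    ref_rows = [seq for sid, seq in alignment.records if sid not in short]
    short_rows = [(sid, seq) for sid, seq in alignment.records if sid in short]
    if not ref_rows or not short_rows:
        raise ValueError("need both short-group and reference sequences")

    # column majority hydrophobicity over the reference sequences
    majority_hydro: list[bool] = []
    for c in block_cols:
        k = sum(1 for row in ref_rows if row[c] in hydrophobic)
        majority_hydro.append(k > len(ref_rows) / 2)

    # short-group residues across the block, gaps removed
    stripped: list[tuple[str, str]] = []
    for sid, seq in short_rows:
        residues = "".join(seq[c] for c in block_cols).replace("-", "")
        if len(residues) != len(block_cols) - 1:
            raise ValueError(
                f"{sid}: expected exactly one fewer residue than block columns "
                f"({len(residues)} vs {len(block_cols)})"
            )
        stripped.append((sid, residues))

    scores: dict[str, float] = {}
    for cand in candidates:
        g = block_labs.index(cand)
        total = 0.0
        for _, resids in stripped:
            placed = resids[:g] + "-" + resids[g:]
            match = sum(
                1
                for ch, is_h in zip(placed, majority_hydro)
                if ch != "-" and (ch in hydrophobic) == is_h
            )
            total += match / len(block_cols)
        scores[cand] = total / len(stripped)

    best_score = max(scores.values())
    top = [c for c in candidates if scores[c] >= best_score - 1e-9]
    best = min(top, key=lambda l: parse_label(l))
    return GapScanResult(scores=scores, best=best, tie=len(top) > 1, block=block_labs)
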