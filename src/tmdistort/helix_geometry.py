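"""Helix axis fitting, bend angles, and straight/kink/bulge classification.

The bend angle of a helix is defined as the angle between the principal axes
of its N-terminal and C-terminal arms about a pivot residue (the pivot
itself belongs to neither arm).  Arm axes are total-least-squares lines
through the Cα positions — the first principal component of the centred
points, sign-oriented N→C.

Distortions are classified from two independent lines of evidence:

* the *proline proximity* rule — in proline-stabilised distortions the
  proline ring sits against the carbonyls of the preceding turn: close to
  O(i−3)/O(i−4) for a kink, O(i−4)/O(i−5) for a bulge (one extra residue in
  the preceding turn);
* the *register* rule — a bulge breaks consecutive i→i−4 backbone H-bonds
  and introduces i→i−5 bonds, whereas a kink merely bends the axis.

When both are supplied and disagree, the register verdict wins and the
conflict is flagged in the evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hbond_register import RegisterProfile
from .structio import Frame, FrameSet

__all__ = [
    "Axis",
    "BendTrace",
    "PivotResult",
    "DistortionCall",
    "fit_axis",
    "fit_axis_points",
    "arm_axis",
    "bend_angle",
    "detect_pivot",
    "classify_distortion",
]

#: Register-free kink threshold (degrees): separates a straight production
#: helix (~9°) from a genuinely kinked one (≥ ~26°).
KINK_THRESHOLD_DEG = 15.0

#: Minimum residues per arm for an axis fit.
MIN_ARM = 6


@dataclass
class Axis:
    direction: np.ndarray  # unit vector, oriented first→last point
    centroid: np.ndarray
    n_points: int

    def __post_init__(self) -> None:
        assert abs(np.linalg.norm(self.direction) - 1.0) < 1e-9


def fit_axis_points(points: np.ndarray) -> Axis:
    """Total-least-squares line (first principal direction) through ≥2 points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("line fit requires ≥2 ordered 3D points")
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    direction = vt[0]
    if np.dot(direction, pts[-1] - pts[0]) < 0:
        direction = -direction
    return Axis(direction / np.linalg.norm(direction), centroid, len(pts))


def fit_axis(calpha_points: np.ndarray) -> Axis:
    """Total-least-squares line through ordered Cα points (≥6 required)."""
    pts = np.asarray(calpha_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < MIN_ARM:
        raise ValueError(f"axis fit requires ≥{MIN_ARM} ordered 3D points")
    return fit_axis_points(pts)


def _calphas(frame: Frame, start: int, end: int, chain: str | None) -> np.ndarray:
    coords = [
        r.coord("CA") for r in frame.residues_in(start, end, chain) if r.has_atom("CA")
    ]
    return np.array(coords)


#: One-turn smoothing window (α-helix: 3.6 residues/turn).  Averaging Cα
#: positions over one full turn collapses the helical spiral onto the axis,
#: removing the phase-dependent tilt a raw line fit picks up on arms that
#: span a non-integer number of turns.
_TURN_WEIGHTS = np.array([1.0, 1.0, 1.0, 0.6])


def _smooth_one_turn(points: np.ndarray) -> np.ndarray:
    w = _TURN_WEIGHTS / _TURN_WEIGHTS.sum()
    k = len(w)
    if len(points) < k + 2:
        return points
    return np.array(
        [w @ points[i : i + k] for i in range(len(points) - k + 1)]
    )


def arm_axis(calpha_points: np.ndarray) -> Axis:
    """Axis of a helical arm: line fit through one-turn-smoothed Cα points."""
    pts = np.asarray(calpha_points, dtype=float)
    if len(pts) < MIN_ARM:
        raise ValueError(f"arm axis requires ≥{MIN_ARM} Cα positions")
    smoothed = _smooth_one_turn(pts)
    ax = fit_axis_points(smoothed)
    if np.dot(ax.direction, pts[-1] - pts[0]) < 0:  # orient on the raw trace
        ax.direction = -ax.direction
    return ax


def _arm_axes(
    frame: Frame, helix: tuple[int, int], pivot: int, chain: str | None
) -> tuple[Axis, Axis]:
    start, end = helix
    n_pts = _calphas(frame, start, pivot - 1, chain)
    c_pts = _calphas(frame, pivot + 1, end, chain)
    if len(n_pts) < MIN_ARM or len(c_pts) < MIN_ARM:
        raise ValueError(
            f"arms around pivot {pivot} have {len(n_pts)}/{len(c_pts)} Cα; "
            f"each needs ≥{MIN_ARM} — widen the helix span"
        )
    return arm_axis(n_pts), arm_axis(c_pts)


@dataclass
class BendTrace:
    """Per-frame bend angle of one helix."""

    frame_labels: list[str]
    times_ns: list[float | None]
    angles: np.ndarray  # degrees, in [0, 180)
    helix: tuple[int, int]
    pivot: int

    def __post_init__(self) -> None:
        if np.any((self.angles < 0) | (self.angles >= 180)):
            raise ValueError("bend angles must lie in [0, 180)")

    def mean(self, labels: list[str] | None = None) -> float:
        if labels is None:
            return float(self.angles.mean())
        mask = [lab in labels for lab in self.frame_labels]
        if not any(mask):
            raise ValueError(f"no frames with labels {labels}")
        return float(self.angles[np.array(mask)].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame_labels,
                "time_ns": self.times_ns,
                "angle_deg": self.angles,
            }
        )


def bend_angle(
    frame_or_set: Frame | FrameSet,
    helix: tuple[int, int],
    pivot: int | str = "auto",
    chain: str | None = None,
):
    """Angle (degrees) between N- and C-arm axes; a trace for a FrameSet."""
    if isinstance(frame_or_set, FrameSet):
        first = frame_or_set[0]
        p = detect_pivot(first, helix, chain).index if pivot == "auto" else int(pivot)
        angles = [bend_angle(f, helix, p, chain) for f in frame_or_set]
        return BendTrace(
            frame_labels=[f.label for f in frame_or_set],
            times_ns=[f.time_ns for f in frame_or_set],
            angles=np.array(angles),
            helix=helix,
            pivot=p,
        )
    frame = frame_or_set
    p = detect_pivot(frame, helix, chain).index if pivot == "auto" else int(pivot)
    ax_n, ax_c = _arm_axes(frame, helix, p, chain)
    cosang = np.clip(np.dot(ax_n.direction, ax_c.direction), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


@dataclass(frozen=True)
class PivotResult:
    index: int
    angle: float  # max local inter-window angle, degrees


def detect_pivot(
    frame: Frame, helix: tuple[int, int], chain: str | None = None
) -> PivotResult:
    """Residue maximising local bending (two sliding 6-residue arm windows).

    Ties go to the smallest index.  For an essentially straight helix the
    reported max angle is small and the caller should treat the helix as
    straight.
    """
    start, end = helix
    residues = [r.index for r in frame.residues_in(start, end, chain)]
    if len(residues) < 2 * MIN_ARM + 1:
        raise ValueError(f"helix span {helix} too short for pivot detection")
    best: PivotResult | None = None
    for p in residues[MIN_ARM:-MIN_ARM]:
        n_pts = _calphas(frame, p - MIN_ARM, p - 1, chain)
        c_pts = _calphas(frame, p + 1, p + MIN_ARM, chain)
        if len(n_pts) < MIN_ARM or len(c_pts) < MIN_ARM:
            continue
        u = arm_axis(n_pts).direction
        v = arm_axis(c_pts).direction
        ang = float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))
        if best is None or ang > best.angle + 1e-12:
            best = PivotResult(p, ang)
    if best is None:
        raise ValueError(f"no valid pivot windows in span {helix}")
    return best


@dataclass
class DistortionCall:
    verdict: str  # "straight" | "kink" | "bulge"
    evidence: dict = field(default_factory=dict)
    conflict: bool = False


def _register_verdict(register: RegisterProfile, bend: float | None) -> tuple[str, dict]:
    occ4, occ5 = register.occupancy_i4, register.occupancy_i5
    broken = occ4 < 0.5
    # longest run of consecutive broken i→i−4 donors
    run = best_run = 0
    for b in broken:
        run = run + 1 if b else 0
        best_run = max(best_run, run)
    has_i5 = bool(np.any(occ5 >= 0.5))
    ev = {
        "broken_i4_positions": [p for p, b in zip(register.positions, broken) if b],
        "i5_positions": [
            p for p, o in zip(register.positions, occ5) if o >= 0.5
        ],
        "max_broken_run": best_run,
    }
    if has_i5 and best_run >= 2:
        return "bulge", ev
    if bend is not None and bend >= KINK_THRESHOLD_DEG:
        return "kink", ev
    return "straight", ev


def _proline_verdict(
    frame: Frame, proline: int, chain: str | None
) -> tuple[str, dict]:
    res = frame.residue(proline, chain)
    ring = [res.coord(n) for n in ("N", "CB", "CG", "CD") if res.has_atom(n)]
    if not ring:
        raise ValueError(f"residue {proline} has no ring atoms for the proline rule")
    d: dict[int, float] = {}
    for k in (3, 4, 5):
        try:
            o = frame.residue(proline - k, chain).coord("O")
        except KeyError:
            continue
        d[k] = min(float(np.linalg.norm(r - o)) for r in ring)
    if len(d) < 3:
        raise ValueError(f"carbonyl O missing at one of positions −3..−5 of {proline}")
    smallest = sorted(d, key=d.get)[:2]
    ev = {f"d_minus_{k}": round(d[k], 3) for k in (3, 4, 5)}
    if set(smallest) == {4, 5}:
        return "bulge", ev
    if set(smallest) == {3, 4}:
        return "kink", ev
    # degenerate {3, 5} pair: decide by which flanking carbonyl is closer
    return ("bulge" if d[5] < d[3] else "kink"), ev


def classify_distortion(
    frame: Frame,
    helix: tuple[int, int],
    proline: int | None = None,
    register: RegisterProfile | None = None,
    chain: str | None = None,
) -> DistortionCall:
    """Classify a helix as straight, kink or bulge.

    At least one evidence source (a proline position or a register profile)
    must be supplied.  The register rule calls "bulge" when ≥1 position has
    i→i−5 occupancy ≥ 0.5 *and* ≥2 consecutive positions have i→i−4
    occupancy < 0.5; otherwise "kink" iff the bend angle is ≥ 15°, else
    "straight".
    """
    if proline is None and register is None:
        raise ValueError("supply a proline position and/or a register profile")

    bend: float | None = None
    pivot: int | None = None
    try:
        piv = detect_pivot(frame, helix, chain)
        pivot = piv.index
        bend = bend_angle(frame, helix, pivot, chain)
    except ValueError:
        pass

    evidence: dict = {"bend_angle_deg": bend, "pivot": pivot}
    verdicts: dict[str, str] = {}
    if proline is not None:
        v, ev = _proline_verdict(frame, proline, chain)
        verdicts["proline"] = v
        evidence["proline"] = ev
    if register is not None:
        v, ev = _register_verdict(register, bend)
        verdicts["register"] = v
        evidence["register"] = ev

    conflict = len(set(verdicts.values())) > 1
    # register evidence wins on conflict
    verdict = verdicts.get("register", verdicts.get("proline"))
    evidence["rules"] = verdicts
    return DistortionCall(verdict=verdict, evidence=evidence, conflict=conflict)
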