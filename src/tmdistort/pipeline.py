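"""Trajectory-analysis orchestration: superposition, RMSD, bends, register.

``run_report`` binds the whole structural analysis into one deterministic,
configured run: read frames → assign numbering → Cα RMSD trace vs the
initial frame → per-helix bend traces → production-phase H-bond register
profiles → side-chain contact trace → straight/kink/bulge verdicts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bw_numbering import BWNumbering
from .hbond_register import (
    HBondCriteria,
    contact_distance_trace,
    register_profile,
)
from .helix_geometry import BendTrace, bend_angle, classify_distortion
from .structio import Frame, FrameSet, write_tsv

__all__ = [
    "Selection",
    "Superposition",
    "Report",
    "superpose",
    "apply_superposition",
    "rmsd_trace",
    "run_report",
]


@dataclass(frozen=True)
class Selection:
    """Atom selection: chain, residue index set (None = all), atom names."""

    chain: str | None = None
    residues: frozenset | None = None
    atom_names: tuple[str, ...] = ("CA",)

    def resolve(self, frame: Frame) -> tuple[list[tuple[str, int, str]], np.ndarray]:
        keys, coords = [], []
        cid = self.chain or next(iter(frame.chains))
        for res in frame.chain(cid):
            if self.residues is not None and res.index not in self.residues:
                continue
            for name in self.atom_names:
                if res.has_atom(name):
                    keys.append((cid, res.index, name))
                    coords.append(res.coord(name))
        return keys, np.array(coords)


@dataclass
class Superposition:
    rotation: np.ndarray  # 3×3, det = +1
    translation: np.ndarray
    rmsd: float
    selection: Selection

    def __post_init__(self) -> None:
        assert abs(np.linalg.det(self.rotation) - 1.0) < 1e-6
        assert self.rmsd >= 0

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation/translation mapping mobile onto reference."""
    pm, qm = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - pm).T @ (reference - qm)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = qm - rot @ pm
    return rot, trans


def superpose(
    mobile: Frame, reference: Frame, selection: Selection | None = None
) -> Superposition:
    """Optimal rigid (Kabsch) superposition over a selection (≥3 atoms)."""
    selection = selection or Selection()
    keys_m, xyz_m = selection.resolve(mobile)
    keys_r, xyz_r = selection.resolve(reference)
    if keys_m != keys_r:
        missing = sorted(set(keys_r).symmetric_difference(keys_m))
        raise ValueError(f"selection mismatch between frames: {missing[:10]}")
    if len(keys_m) < 3:
        raise ValueError("selection must resolve to at least 3 atoms")
    rot, trans = _kabsch(xyz_m, xyz_r)
    moved = xyz_m @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - xyz_r) ** 2, axis=1))))
    return Superposition(rot, trans, rmsd, selection)


def apply_superposition(frame: Frame, sup: Superposition) -> Frame:
    out = frame.copy()
    out.set_coords(sup.transform(out.coords()))
    return out


@dataclass
class RmsdTrace:
    frame_labels: list[str]
    times_ns: list[float | None]
    rmsd: np.ndarray
    selection_name: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": self.frame_labels, "time_ns": self.times_ns, "rmsd_A": self.rmsd}
        )


def rmsd_trace(
    frames: FrameSet,
    reference: int = 0,
    selection: Selection | None = None,
    name: str = "",
) -> RmsdTrace:
    """Per-frame RMSD after superposition onto the reference frame."""
    ref = frames[reference]
    values = [superpose(f, ref, selection).rmsd for f in frames]
    values[reference] = 0.0  # exact at the reference, not 1e-8
    return RmsdTrace(
        frame_labels=[f.label for f in frames],
        times_ns=[f.time_ns for f in frames],
        rmsd=np.array(values),
        selection_name=name,
    )


# ---------------------------------------------------------------------------
# Configured report
# ---------------------------------------------------------------------------

@dataclass
class Report:
    rmsd: dict[str, RmsdTrace]
    bends: dict[str, BendTrace]
    registers: dict[str, object]
    contact: object
    verdicts: dict[str, object]
    config: dict
    version: str = __version__
    seed: int | None = None

    def summary(self) -> dict:
        """JSON-serialisable summary of every section (deterministic)."""
        out: dict = {"version": self.version, "seed": self.seed, "config": self.config}
        out["rmsd"] = {
            name: {
                "frames": t.frame_labels,
                "rmsd_A": [round(float(v), 4) for v in t.rmsd],
            }
            for name, t in self.rmsd.items()
        }
        out["bends"] = {
            name: {
                "frames": t.frame_labels,
                "pivot": t.pivot,
                "angle_deg": [round(float(v), 3) for v in t.angles],
            }
            for name, t in self.bends.items()
        }
        out["registers"] = {
            name: {
                "positions": rp.positions,
                "occ_i4": [round(float(v), 3) for v in rp.occupancy_i4],
                "occ_i5": [round(float(v), 3) for v in rp.occupancy_i5],
                "n_frames": rp.n_frames,
                "phase": rp.phase,
            }
            for name, rp in self.registers.items()
        }
        if self.contact is not None:
            out["contact"] = {
                "frames": self.contact.frame_labels,
                "distance_A": [round(float(v), 3) for v in self.contact.distances],
            }
        out["verdicts"] = {
            name: {"verdict": c.verdict, "conflict": c.conflict}
            for name, c in self.verdicts.items()
        }
        return out

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(self.summary(), indent=2, sort_keys=True) + "\n"
        )
        for name, trace in {**self.rmsd, **self.bends}.items():
            write_tsv(trace.to_frame(), out_dir / f"{name}.tsv")
        for name, rp in self.registers.items():
            write_tsv(rp.to_frame(), out_dir / f"{name}.tsv")
        if self.contact is not None:
            write_tsv(self.contact.to_frame(), out_dir / "contact.tsv")
        return out_dir / "report.json"


def run_report(
    frames: FrameSet,
    numbering: BWNumbering,
    helices: dict[str, dict],
    contact: tuple[tuple[str, str], tuple[str, str]] | None = None,
    production_labels: list[str] | None = None,
    criteria: HBondCriteria | None = None,
    config_echo: dict | None = None,
    seed: int | None = None,
) -> Report:
    """Run the full structural analysis for a configured set of helices.

    ``helices`` maps a name (e.g. "TM2") to ``{"helix": int, "pivot": "2.58"}``
    where ``helix`` is the BW helix number resolved through ``numbering`` and
    ``pivot`` a BW label.  ``production_labels`` selects the frames used for
    register profiles, production bend means and verdicts.
    """
    criteria = criteria or HBondCriteria()
    production = production_labels or [f.label for f in frames][1:]

    # two RMSD selections: the whole modelled domain and the helices only
    helix_res: set[int] = set()
    for cfg in helices.values():
        lo, hi = numbering.span_indices(cfg["helix"])
        helix_res.update(range(lo, hi + 1))
    rmsd = {
        "rmsd_domain": rmsd_trace(frames, 0, Selection(), name="domain"),
        "rmsd_helices": rmsd_trace(
            frames, 0, Selection(residues=frozenset(helix_res)), name="helices"
        ),
    }

    bends: dict[str, BendTrace] = {}
    registers: dict[str, object] = {}
    verdicts: dict[str, object] = {}
    for name, cfg in helices.items():
        span = numbering.span_indices(cfg["helix"])
        pivot = numbering.index_of(cfg["pivot"])
        bends[f"bend_{name}"] = bend_angle(frames, span, pivot)
        rp = register_profile(
            frames,
            span,
            numbering,
            criteria,
            frame_labels=production,
            phase="production",
        )
        registers[f"register_{name}"] = rp
        verdicts[name] = classify_distortion(
            frames.select(production)[0], span, register=rp
        )

    trace = None
    if contact is not None:
        trace = contact_distance_trace(frames, contact[0], contact[1], numbering)

    return Report(
        rmsd=rmsd,
        bends=bends,
        registers=registers,
        contact=trace,
        verdicts=verdicts,
        config=config_echo or {},
        seed=seed,
    )
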