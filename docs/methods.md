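# Methods

## Problem and model

Transmembrane helices of class A GPCRs are frequently distorted, and the
two recurring distortion types have distinct structural signatures:

* a **kink** bends the helix axis while keeping the canonical α-helical
  i→i−4 backbone hydrogen bonds; when a proline stabilises it, the proline
  ring packs against the carbonyl oxygens at positions −3 and −4;
* a **bulge** carries one extra residue in a turn, breaking a run of
  i→i−4 bonds and introducing i→i−5 bonds; a stabilising proline ring sits
  against the carbonyls at −4 and −5.

The package quantifies both signatures — axis geometry and H-bond register
— and applies them to the thyrotropin receptor (TSHR), whose TM2 and TM5
lack proline, so the distortion type must be inferred rather than read off
the sequence.  The sequence-side analyses ask the same question across the
LGR family: a one-residue deletion in TM5 of the glycoprotein hormone
receptor branch, placed where it best preserves the hydrophobic pattern
between the conserved tyrosine anchors, implies these receptors lost the
TM5 bulge and keep a straight TM5.

## Residue numbering

Ballesteros–Weinstein labels `h.pp` are assigned per helix by signed offset
from one anchor residue, over configurable label spans.  Arithmetic is done
on integer (helix, position) pairs, never on a decimal representation, to
avoid the `5.5` / `5.50` ambiguity.  Declared deletions are labels mapped
to no residue — lookups return an explicit `DELETED` sentinel and offset
counting skips them — and insertions get `h.pp+k` suffix labels so the
`.50` frame never shifts.  The TSHR reference numbering uses anchors
N432 (1.50), D474 (2.50), R519 (3.50), W546 (4.50), Y601 (5.58, because the
family lacks P5.50, the usual TM5 anchor), P639 (6.50), P675 (7.50) and the
TM5 deletion at 5.45.  Default helix spans (TM1 1.35–1.60, TM2 2.38–2.66,
TM3 3.22–3.55, TM4 4.39–4.63, TM5 5.38–5.63, TM6 6.30–6.60, TM7 7.33–7.56)
cover every position the analyses touch; they are configuration, not
biology, and can be overridden.

The real TSHR sequence is not bundled; a synthetic stand-in sequence
(`standin.tshr_like_sequence`) carries the documented residue identities at
all anchor and analysis positions and hydrophobic filler elsewhere.

## Bend angles

The bend angle of a helix about a pivot is the angle between the axes of
its N-terminal and C-terminal arms (the pivot residue belongs to neither).
Arm axes are total-least-squares lines through the arm's Cα positions after
**one-turn smoothing**: a moving average with weights (1, 1, 1, 0.6)/3.6
spanning one α-helical turn.  A raw line fit through the spiralling Cα
trace of a short arm tilts by several degrees depending on where in the
turn the arm starts and ends; averaging over one turn collapses the spiral
onto the axis and removes that phase artifact (ideal-helix bend drops from
≈5° to ≈0.4°).  `fit_axis` itself remains a plain first-principal-direction
fit — it is the generic primitive, validated against a brute-force
direction search — while `arm_axis` adds the smoothing for helical arms.

Pivot auto-detection slides two six-residue arm windows along the helix and
takes the residue maximising the inter-window angle (ties → smallest
index).  Default pivots for TSHR: 2.58 for TM2 (the distorted stretch is
2.56–2.59) and 5.46 for TM5 (flanking the deleted 5.45).

Programmed kinks are exact by construction: the C-arm is rigidly rotated
about an axis through the pivot Cα perpendicular to the plane of the two
arm axes, which changes the inter-arm angle by exactly the applied delta.
Bend recovery on noiseless constructions is exact to numerical precision;
at 0.15 Å coordinate noise the mean error stays well under 1°.

Comparisons of absolute angles between different axis-fitting conventions
can differ by a few degrees, which is why receptor-level angle checks use a
±5° band while construction-level checks use ±2°.

## Hydrogen bonds and register occupancy

Backbone N–H···O=C bonds are detected with HBPLUS-like geometric criteria:
donor–acceptor N···O ≤ 3.5 Å, and — whenever a hydrogen is present or
constructible — H···O ≤ 2.5 Å and ∠N–H···O ≥ 120°.  The amide hydrogen is
placed 1.01 Å from N along the external bisector of the C(i−1)–N–CA angle
when the input has no hydrogens; the synthetic builders use the same
construction, so detection is identical with and without explicit
hydrogens.  Proline never donates.  Offsets are author-index differences
capped at 2–6, so numbering gaps between separate helices cannot produce
spurious short-range bonds.

Register occupancy is the fraction of selected frames in which the donor at
a position forms the i→i−4 (or i→i−5) bond, **keyed by the donor**; the
statement "two i→i−5 bonds involve 2.57 and 2.58" is therefore
donor-positional by definition.  Present/absent statements use a 0.5
occupancy threshold, matching binary language over a small snapshot set.

## Distortion classification

With a register profile: **bulge** iff ≥1 position has i→i−5 occupancy
≥ 0.5 *and* ≥2 consecutive positions have i→i−4 occupancy < 0.5; otherwise
**kink** iff the bend angle ≥ 15°, else **straight**.  The 15° threshold
separates a relaxed, straight helix (≈9°) from a genuinely kinked one
(≥ ≈26°).  With a proline: the two smallest of the ring–carbonyl distances
d(−3), d(−4), d(−5) decide ({−4, −5} → bulge, {−3, −4} → kink; the
degenerate {−3, −5} pair is broken by whichever flanking carbonyl is
closer).  When both evidence sources disagree the register verdict wins and
the conflict is flagged.

## Superposition and RMSD

Rigid superposition is the Kabsch algorithm (SVD of the covariance with a
reflection guard), validated against an independent quaternion-based
solver.  RMSD traces superpose every frame onto frame 1 over a selection;
two selections are emitted — all Cα of the modelled domain, and the helices
only — mirroring the two conventional traces.  The trace is pinned to
exactly 0 at the reference index.

## Sequence analyses

* **p-distance**: differing / comparable sites over columns where neither
  sequence is gapped; exact per-column counting (no correction), pairs with
  zero comparable sites are an error.
* **Neighbor joining**: Saitou–Nei agglomeration (scikit-bio's
  implementation) on the p-distance matrix; negative branch lengths are
  clamped to zero with a warning.  Bootstrap resamples columns with
  replacement (default 500 replicates, seeded); supports are bipartition
  frequencies attached to internal nodes and written as integer percents in
  Newick output.  Sub-group claims are checked as monophyly (the group
  forms one side of a bipartition of the unrooted tree), because
  "sub-group" has no other algorithmic definition.
* **Conservation categories**: "full" needs one residue in every sequence;
  otherwise the best residue-class fraction decides type80 (≥ 0.8) /
  type60 (≥ 0.6) / none, with gaps counting against.  The default class
  partition is hydrophobic {A V L I M F C W}, polar {S T N Q Y G H P},
  basic {K R}, acidic {D E}; it is configurable and must partition the 20
  amino acids.
* **Gap-placement scan**: the short-group sequences (exactly one residue
  shorter over the anchored Y5.38/5.39…Y5.58 block) are realigned with the
  gap at each candidate position; the score is the mean per-sequence
  fraction of block columns whose residue matches the column's majority
  hydrophobicity class, with the majority taken over the full-length
  reference sequences and gaps never matching.  The binary
  hydrophobic/other scale is the weakest sufficient assumption for a
  "hydrophobic pattern" argument and is overridable.  Because the score
  only sees the class, a gap placed anywhere inside a run of same-class
  columns scores identically — candidate sites are only identifiable up to
  such runs, ties go to the smallest position and are flagged.

## Synthetic data

Helices are built residue-by-residue from internal coordinates (N–Cα
1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å, N–H 1.01 Å; standard bond
angles; default torsions φ = −57°, ψ = −47°, ω = 180°), giving a straight
axis and a complete i→i−4 register under the default criteria.  Bulges use
π-like turn torsions on the two residues preceding the bulge position,
chosen once by a grid search starting near (φ, ψ) = (−75°, −35°) with the
register contract as the acceptance test; the contract (≥1 i→i−5 bond and
≥2 broken i→i−4 near the bulge, canonical register elsewhere) is
re-verified at build time and the builder raises rather than return a
helix without the programmed register.  Trajectories re-hinge the base
frame to per-frame bend targets and add i.i.d. isotropic Gaussian noise per
atom, uncorrelated across frames; everything is seeded and bit-reproducible.

Alignments are sampled per column from consensus/conservation profiles
(optionally per-group consensus), with a planted one-column deletion
realised as a gap in the deletion group.  Conservation levels are
continuous in (0, 1]; the canonical settings are 1.0 / 0.8 / 0.6.

### Receptor and family stand-ins

`standin.py` provides the receptor-scale and family-scale study conditions
as synthetic constructions:

* a seven-helix bundle (helices on an 11 Å ring, residues 410–694) whose
  TM2 carries a three-residue π-turn (torsions found by a search maximising
  the geometric margin of the target register under the production hinge
  angle and noise) producing broken i→i−4 bonds at 2.56–2.59 and i→i−5
  donors at 2.57/2.58; five frames with bend schedules TM2 33° → ≈22° and
  TM5 26° → ≈9°, deterministic radial helix drift calibrated so the domain
  Cα RMSD plateaus near 2.5 Å (10–20 ns) and 3 Å (40–60 ns), 0.15 Å
  coordinate noise, and an E3.37–N5.47 side-chain contact that tightens
  from ≈8 Å to ≈3.5 Å in the late frames;
* a 52-sequence alignment in three sub-groups (20 + 16 + 16) with fully
  conserved anchors, group-diagnostic columns, the Y5.38 (group 2) vs
  Y5.39 (groups 1 and 3) motif, no prolines at 2.58/2.59/2.60/5.50, and
  the TM5 deletion planted at 5.45 in group 1 with polar neighbours at
  5.44/5.46 so the class-based scan can localise it exactly.

What these stand-ins do **not** emulate: real side-chain packing, membrane
physics, correlated thermal motion, equilibration-phase dynamics, or real
sequence phylogenies.  Passing receptor-level checks therefore demonstrates
that the *analysis stack* recovers programmed ground truth under noise at
realistic magnitudes — not that any particular biological system behaves
this way.  With only four production snapshots an occupancy is a quarter
count; a marginal bond flickering with the noise draw can occasionally move
a position across the 0.5 threshold (observed in roughly 1 in 20 seeds for
the TM2 register pattern).

## Problem sizes

Tests and the acceptance script use 30-residue helices, five-frame
trajectories, 20-seed robustness loops, all 4- and 5-taxon topologies for
the NJ oracle, and the 52-sequence alignment with 500 bootstrap replicates
— sizes at which every analysis is exact or statistically stable and the
whole suite runs in seconds.

## Known limitations

* Bend angles depend on the axis convention; only construction-programmed
  angles are exact, and cross-method comparisons deserve a ±5° band.
* H-bond criteria are geometric, not energetic; the defaults emulate
  HBPLUS-style practice but are configuration.
* The gap scan's class-based score cannot distinguish positions within a
  same-class run (flagged as ties).
* NJ is distance-based; no likelihood or Bayesian alternatives are
  provided.
* mmCIF, compressed trajectory formats and structure validation beyond
  backbone completeness are out of scope.
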