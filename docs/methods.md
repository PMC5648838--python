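# Methods

## Model

A *dynophore* condenses all protein–ligand interactions detected over an MD
trajectory into a single annotated model. The procedure is:

1. **Alignment.** Every frame is superposed onto frame 0 by a proper-rotation
   Kabsch fit (SVD of the centered covariance, smallest singular vector
   flipped when the determinant would be −1) of a fit selection, by default
   the Cα atoms of standard amino-acid residues. The whole frame, ligand
   included, moves with its fitted transform. Frame 0 is the reference purely
   for determinism; any fixed frame gives the same statistics since they
   depend only on interatomic distances and angles, which are rigid-motion
   invariant.
2. **Perception.** Ligand atoms are typed into feature templates by a rule
   table over elements, bonds and formal charges (below). The environment is
   partitioned per residue into partners of class protein, metal, hydroxide,
   water or other-het, each with its own donor/acceptor atoms, charged
   groups and apolar atoms derived by the same chemistry rules.
3. **Detection.** Per frame, each (template, partner) pair is tested against
   the geometric criteria; at most one event per pair per frame is kept,
   carrying the minimal qualifying distance. Water partners are excluded by
   default (reports concern protein/ion/hydroxide partners); a flag includes
   them.
4. **Aggregation.** Events sharing (interaction type, ligand atom set) form a
   superfeature. A superfeature *occurs* in a frame when it has at least one
   detected environment interaction there — feature existence alone does not
   count, since for a fixed typing the feature always exists; the reported
   quantity is interaction time.

### Frequencies

- superfeature occurrence frequency = 100 · |occurrence frames| / N_frames;
- partner interaction frequency = 100 · |frames where that partner
  interacts| / |superfeature occurrence frames|.

Partners can interact simultaneously, so partner frequencies may sum past
100%. Exports round to one decimal place for display while the JSON keeps
full precision. Statistics are frame-additive: concatenating trajectories
sums occurrence counts, so replicate simulations can be concatenated before
analysis.

## Perception rule table

| Feature | Rule |
| --- | --- |
| HBD | O/N with ≥ 1 explicit bonded H; one template per heavy atom |
| HBA | O with formal charge ≤ 0; N with ≤ 2 bonds (keeps amide/ammonium N out). A tetrahedral borate is one *grouped* acceptor on (B, O, O, O) rather than three separate ones, matching how boronic-acid transition-state analogs are conventionally described; carboxylate oxygens stay individual acceptors, so per-oxygen H-bond frequencies remain reportable alongside the grouped charge. |
| PI | N with formal +1 or four bonds; guanidinium/amidinium carbon with ≥ 2 N neighbors (3 N always counts, 2 N needs a positive charge), grouped with its nitrogens |
| NI | carboxylate (both terminal O, one template), tetrahedral borate (B + oxygens), sulfonate, phosphate, bare hydroxide O |
| H | connected components of carbons bonded only to C/H/S, size ≥ 3 |

A charged group's position is its heavy-atom centroid; a feature's spatial
point is the unweighted centroid of its template heavy atoms.

## Interaction criteria

All thresholds live in one config object, readable from a flat `key = value`
file (`--criteria`, `--show-config` on the CLI):

| parameter | default | meaning |
| --- | --- | --- |
| hbond_dist_min / max | 2.5 / 3.8 Å | donor–acceptor heavy-atom window |
| hbond_angle_min | 130° | D–H⋯A angle; best hydrogen wins, one event |
| ionic_dist_max | 5.5 Å | charged-group centroid distance |
| metal_coord_max | 3.0 Å | NI features vs. metal cations; metal coordination is folded into the ionic event class rather than a separate feature type |
| hydrophobic_dist_max | 4.5 Å | closest apolar heavy-atom pair |

These are standard literature geometric criteria; perception thresholds in
commercial pharmacophore tools are unpublished, so agreement with any
particular tool is not guaranteed and the values are deliberately exposed
for recalibration. A donor without explicit hydrogens is evaluated on
heavy-atom distance alone, with a single warning. Hydrophobic contact uses a
single closest-pair distance, not a buried-fraction criterion.

Detection prescreens partners with a KD-tree around the ligand atoms at
`max(cutoffs) + 3.5 Å`; the margin exceeds twice the largest charged-group
centroid offset (< 1.75 Å per side), so the result is provably identical to
the brute-force all-pairs scan, and a test asserts this equivalence on
randomized frames.

## Trajectory metrics

- **RMSD** per frame over a selection, after an optional Kabsch pre-fit (on
  the same selection by default, g_rms style; a separate fit selection may
  be given).
- **RMSF** per atom about the time-average position on the aligned
  trajectory; per-residue reduction is the mean over each residue's selected
  atoms (for a Cα selection this is the familiar per-residue curve).
- **Pocket volume**: grid points at the requested spacing (default 0.5 Å)
  inside an inclusion sphere (default 10 Å radius, e.g. centered on the
  boron of a bound boronic acid) count toward the volume unless inside any
  occluding atom's van der Waals sphere plus probe radius (default probe 0).
  Protein and ion atoms occlude; ligand and water do not. There is no
  contiguity filtering of grid points — the simplest defensible scheme,
  configurable via an explicit occluder selection. Grid points satisfy
  |r − center| ≤ radius; volume = spacing³ × unoccluded count. The empty
  10 Å sphere evaluates to 4175.1 ų at 0.5 Å spacing, −0.33% from the
  analytic 4188.8 ų, and converges as spacing shrinks.

## I/O conventions

Coordinates are Å, times ps. PDB parsing is delegated to MDAnalysis (DCD and
XTC likewise); residue numbers are taken verbatim from the file, selections
use the file's (1-based) residue numbering while frames are 0-based. Bonds
come from CONECT records when present, otherwise from a distance rule,
`d < 1.6 · (r_cov(a) + r_cov(b))`, with two guards the plain cutoff lacks:
hydrogens never bond to each other and each hydrogen bonds only to its
nearest in-range heavy atom. Formal charges are read from the PDB charge
column (else 0), missing elements derived from atom-name first letters.
Written PDBs carry 3-decimal coordinates, so round-trips are exact only to
5·10⁻⁴ Å — relevant when comparing statistics computed before and after a
file round-trip.

## Synthetic data: what it emulates and what it does not

The toy generator produces a pseudo-receptor of nine sites — backbone
carbonyl, serine-like OH, two carboxylates, a guanidinium, a methyl side
chain, two Mn²⁺ and a hydroxide, echoing an arginase-like active site — on a
25 Å circle, and a probe ligand (an amino-acid-like probe with carboxylate,
protonated amine, hydroxyl and three-carbon tail, or a boronate probe
C–B(OH)₃⁻). Per frame, each ligand group is placed by exact trilateration so
its interaction point sits at the scheduled on/off distance from the
partner's anchor; sites co-scheduled to one group are clustered 5 Å apart so
two simultaneous distance constraints remain satisfiable (three or more
raise a feasibility error naming the frame). Hydrogens are re-aimed along
the donor→acceptor line when their H-bond is active, giving ideal 180°
angles, and parked pointing away otherwise, so no unscheduled H-bond can
pass the 130° gate.

Distance jitter is Gaussian, seeded, truncated at 3σ *and* at 95% of the
schedule's window margin; the second bound is what makes schedule-exactness
unconditional — validation additionally requires σ ≤ half the margin. An
optional rigid tumble (uniform random rotation + translation per frame)
exercises the alignment path; by construction it changes no statistic.

The generator is a measurement standard, not a simulation: ligand groups
move independently (inter-group bonds stretch), internal geometry is
idealized, there is no solvent, thermal motion, or force field. Passing
tests therefore demonstrate that the *analysis* is correct — that detection,
aggregation and reporting reproduce a known interaction script exactly —
not that any particular real system behaves this way. On real trajectories
the geometric criteria themselves (not validated against experiment here)
dominate what is detected.

Volume phantoms follow the same philosophy: a marker atom at the sphere
center plus occluder pseudo-atoms. The half-space slab places its top atom
layer one mean effective sphere height (vdW radius minus the lattice's mean
sagitta, 1.682 Å for carbon at 0.6 Å spacing) below z = 0, so the occlusion
boundary averages to the plane and the measured volume is the analytic
half-sphere to within ~1%.

## Numerical choices and degenerate inputs

- Kabsch requires ≥ 3 points and rejects collinear configurations
  (rank check at 1e-8); reflections are never returned.
- Ties among multiple hydrogens on one donor: the largest D–H⋯A angle wins;
  among multiple qualifying atom pairs of one (template, partner): minimal
  distance wins. Both are deterministic.
- Histogram bins: width 0.1 Å from the minimum observed distance floored to
  one decimal up to the feature type's maximum cutoff, half-open `[lo, hi)`
  with the last bin closed.
- Zero-event cases: a histogram on no events is an error; a dynophore with
  zero superfeatures is valid (warning) and exports an empty report;
  partner frequency at zero occurrences returns NaN with a warning.
- RMSF on a single frame is an error (undefined fluctuation); an empty
  selection is an error for metrics but only a warning for generic
  selection resolution.
- Pseudo-atom PDB serials wrap at 99999 per format convention.

## Limitations

- No aromatic/π-stacking or halogen-bond feature types; the rule table is
  not SMARTS-extensible.
- Hydrophobic perception splits by connected component, not by individual
  ring/chain within a fused apolar region.
- No conformational clustering, SASA, or pocket contiguity analysis.
- Protonation states are taken as given in the input file; perception
  trusts the explicit hydrogens and formal charges present.
- The pipeline holds all frame coordinates in memory; microsecond-scale
  trajectories should be strided or chunked by the caller.
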