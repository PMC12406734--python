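# Methods

## Scope and model

`mdinet` analyses ensembles of protein MD trajectories — one reference
system plus any number of variants, each with replicate runs — and reduces
them to (i) backbone fluctuation descriptors and (ii) a differential
residue-interaction network. It deliberately implements the plain
geometric, threshold-based definitions practitioners use with HBPLUS/VMD
rather than any energetic model: an interaction either satisfies the
geometry in a frame or it does not, and its strength is a frame fraction.

### Hydrogen bonds

A candidate is a (donor heavy atom D, covalent hydrogen H, acceptor A,
acceptor antecedent AA) quadruple enumerated from per-residue chemistry
tables (`src/mdinet/data/residue_chemistry.tsv`), never from geometry.
Same-residue pairs are excluded; adjacent-residue backbone pairs are kept
(no i→i+1 exclusion). A frame contains the bond iff

|D−A| ≤ 3.9 Å, |H−A| ≤ 2.5 Å, and the D-H-A, H-A-AA, D-A-AA angles are all
≥ 90°,

all inclusive. Statistics are keyed at the (donor atom, acceptor atom)
level — "present" means *any* hydrogen of that donor passes against that
acceptor — and a residue-pair roll-up (element-wise max over the pair's
atom keys) is emitted alongside, since network figures are usually labelled
by residues. Explicit donor hydrogens are required; a tagged donor with no
bonded hydrogen is a hard error, never silently protonated.

### Salt bridges

Side chains only: Asp/Glu carboxylate oxygens vs Lys/Arg side-chain
nitrogens. Histidine is excluded by default because its charge is
protonation-state dependent (`ChemistryRoles.default(include_histidine_basic=True)`
opts in); terminal amine/carboxylate groups are likewise excluded, matching
conventional side-chain salt-bridge analysis. Detection is two-stage, as in
the VMD workflow: an *atomic* candidate test (any O within ≤ 3.2 Å of any N
in ≥ 1 retained frame) and a *group center-of-mass* occupancy test
(COM-COM ≤ 3.5 Å per frame). The COM is mass-weighted over the charged-group
atoms; for the all-oxygen and all-nitrogen groups involved this equals the
geometric centroid, so the choice only matters if the tables are edited to
mix elements. The candidate test is applied to retained (post-trim) frames;
applying it before trimming would only ever enlarge the candidate set, and
every candidate's occupancy is computed from retained frames regardless.

### Aggregation, trimming, thresholds

Strength/occupancy is computed per replicate over retained frames and
aggregated across replicates by the **maximum** — the convention that asks
"did any replicate sustain this contact?". `TrimPolicy(discard_fraction=0.1)`
drops the leading 10 % of frames of every replicate from *all* statistics
(RMSD series, RMSF, candidate detection, occupancies), mirroring the usual
practice of analysing only the equilibrated tail (e.g. the last 900 ns of a
1 μs run).

Every geometric comparison is inclusive exactly as printed, with a 1e-9
numerical slack (`GEOM_EPS`) so a geometry constructed exactly at a cutoff
is inside it regardless of floating-point rounding. The two *reporting*
thresholds differ in kind: the salt-bridge occupancy filter is strict
("more than 40 %"), while the H-bond variation filter is inclusive
("≥ 40 points").

### Differential network

`build_networks` evaluates the union of candidate keys across all systems
in every system, so an edge absent somewhere appears there with strength 0
(for salt bridges the occupancy is recomputed wherever the residue pair
exists topologically). "Variation" of an H-bond edge is the absolute
percentage-point spread (max − min) of its aggregated strengths across
systems — an absolute reading, because the strengths are themselves
percentages and a relative reading would explode near zero. A
variant-vs-reference reading (largest |variant − reference| gap) is
available via `hb_variation_mode="vs_reference"`. Classification uses the
same 40 % level for both kinds (no separate classification threshold is
defined anywhere, so the reporting level is reused): lost / gained /
retained / absent by which side of the level the reference and the variant
sit. Variation is invariant to relabelling systems and to the choice of
reference; classification is reference-relative by definition.

### Fluctuation descriptors

Kabsch superposition (closed-form SVD, determinant-corrected so the
rotation is always proper) over the backbone selection {N, CA, C, O}. The
same set is used for RMSF, reading "backbone atoms" consistently with the
RMSD definition. RMSD is against the initial frame. RMSF uses a two-pass
mean structure: superpose retained frames onto frame 1, average,
re-superpose onto the mean, then per-atom root time-averaged squared
displacement, averaged per residue. One re-superposition pass, no iteration
to convergence and no mass weighting: differences beyond one pass are far
below the test tolerances, and uniform weights are the stated convention.
Degenerate selections (< 3 atoms, collinear clouds) are errors.

## Synthetic data: what it emulates, what it does not

The generator exists because the real inputs — multi-microsecond
membrane-embedded ensembles — cannot be regenerated or shipped. It emulates
the *statistical* structure the analysis consumes:

* **Topology**: idealized extended peptides, template-complete (including
  polar hydrogens), built from the same residue tables the analysis uses.
  Side-chain atoms are placed by a deterministic clearance-maximizing walk
  of the template tree; geometry is *not* physically minimized, and the
  analysis must not assume realistic stereochemistry beyond template
  bonding.
* **Fluctuation**: isotropic per-atom Gaussian jitter with known σ, so
  per-residue RMSF has the closed form σ√3.
* **Contacts**: each designed contact follows a two-state Markov chain
  whose stationary occupancy equals its target, with mean bound dwell
  (default 20 frames) giving MD-like autocorrelation. The contact-group
  atoms are pinned (jitter-exempt) and placed at a bound geometry that
  satisfies the criteria by ≥ 0.3 Å margin or an unbound one that violates
  them by the same margin, so the detected state equals the chain state
  exactly and measured occupancy equals the recorded ground truth
  frame-for-frame.
* **Rigid motion**: optional random rotation + translation per frame, to
  exercise superposition.

Sampling error of an occupancy estimate uses the dwell-corrected effective
sample size n_eff = n·(a+b)/(2−a−b) for switch probabilities a, b (the
exact variance inflation of a two-state chain), not the i.i.d. binomial n.

What it does **not** emulate: force-field energetics, solvent/membrane,
anisotropic or correlated motions, realistic side-chain rotamers,
transition-path geometry between bound and unbound. Passing tests therefore
demonstrate that the *measurement* machinery is correct and calibrated, not
that any biological conclusion transfers; on real trajectories the inputs
are simply different numbers through the same code path.

### The reference-vs-variants fixture

`make_reference_variant_fixture` builds a 33-residue host peptide, 4 systems
(reference WT + variants M1–M3), 3 replicates each, 10 ps frame spacing,
with: a strong salt bridge (85 % in WT, 5 % in every variant), a motif
triplet — two salt bridges and one backbone-amide-to-carboxylate H-bond —
at 70–80 % in WT/M1/M2 and 5 % in M3, and a 20 % distractor bridge
everywhere. The default length (2000 frames/replicate) is chosen so the
max-over-3-replicates estimate of the 20 % distractor stays below the 40 %
reporting filter with a ≈ 4σ margin under the dwell-corrected error model;
the replicate count and frame spacing mirror the standard three-replicate
simulation design. Salt-bridged Lys/Asp pairs in the fixture also register
as incidental NZ→O H-bond edges — as they do physically — which the tests
treat as expected extra edges, asserting on the designed keys.

## Numerical and design choices

* Comparisons: inclusive cutoffs with 1e-9 slack; strict reporting filters
  with 1e-12 slack; occupancies are exact frame-count fractions.
* Superposition of whole trajectories is batched (one SVD per frame via
  `numpy.linalg.svd` on stacked 3×3 matrices).
* PDB I/O goes through MDAnalysis (fixed-column multi-model PDB; one MODEL
  per frame, topology from MODEL 1, 3-decimal coordinates); parse failures
  are re-raised naming the offending MODEL or line. Binary trajectory
  formats plug in through `trajectory_from_frames` (any iterator of
  n_atoms × 3 Å arrays).
* Bonds always come from residue templates, never from distance inference —
  deterministic and robust to the generator's distorted geometries.
* Determinism: all randomness flows from NumPy PCG64 generators seeded as
  `[seed, system_index, replicate_index]`; reruns with the same seed and
  config produce byte-identical output bundles, and the run log records
  every effective threshold plus input hashes (and no timestamps).
* Problem sizes in the test suite (up to 50 atoms / 200 frames for
  brute-force cross-checks, 3 × 5000 frames for occupancy recovery, 10 000
  frames for RMSF recovery, 2000-frame fixtures) are the package's chosen
  desk-scale operating points: large enough that the dwell-corrected error
  bounds are tight, small enough to run anywhere.

## Known limitations

* Protein atoms only; no solvent-mediated bridges, no PDBx/mmCIF, no ions.
* H-bond chemistry tables cover the 20 standard residues with polar
  hydrogens only (CHARMM-style names); sulfur acceptors (Met SD) are
  omitted; nonstandard residues degrade to role-free with a warning.
* The 40 % variation filter compares aggregated (max-over-replicate)
  strengths; replicate-level dispersion is reported in the tables but not
  used for significance — the method is intentionally threshold-based, not
  a statistical test.
* RMSF has no printed reference values to validate against on real systems;
  its validation here is the closed-form σ√3 recovery and monotonicity
  properties.
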