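# Methods

This note records the models, parameter choices and numerical decisions
behind `cleavescan`, and what the synthetic test systems do and do not
establish about real proteins.

## Scope of the physical model

The pipeline's contract is *conformational coverage and steric
discrimination*, not thermodynamics.  Three deliberate simplifications
follow from that:

- **Torsion-space Metropolis search instead of stochastic dynamics.**
  The conformational search runs in internal coordinates: backbone
  φ/ψ rotations at ideal bond lengths and angles (a stand-in for
  bond-constrained dynamics), Metropolis-accepted at a high effective
  temperature (600 K by default).  The two scientific levers of the
  original protocol are preserved — the hot search and the
  local-elevation distance bias — because downstream stages consume only
  a diverse conformer set, not kinetics.  An optional equilibration ramp
  (ten stages, 60 K → 600 K, harmonic positional restraints from
  2.5×10⁴ kJ mol⁻¹ nm⁻² weakening tenfold per stage before release)
  precedes production, mirroring the heat-up protocols used for such
  searches; the LE bias activates only in production.
- **A compact united-atom force field.**  Eight nonbonded types cover
  backbone atoms, generic side-chain beads and two probe beads; apolar
  hydrogens are folded into CH1/CH2/CH3 beads and only the amide
  hydrogen is explicit (with zero Lennard-Jones volume).  Conventions:
  E_bond = k(b−b0)², E_angle = k(θ−θ0)², E_torsion = k(1+cos(mφ−δ)),
  untruncated LJ + Coulomb with ε_r = 1 and prefactor
  138.935 kJ mol⁻¹ nm e⁻², geometric combination for cross LJ pairs.
  The table is bundled as documented plain text and fully pluggable; the
  pipeline's logic, not the parameterisation, is the contribution.
- **Vacuum electrostatics, no cutoff.**  The systems are small (a few
  hundred atoms); untruncated sums are affordable and avoid cutoff
  artefacts in the sign-sensitive retention filter.

## Nonbonded exclusions

All nonbonded sums — including the cross-group interaction energies used
by the retention filters — skip atom pairs within three bonds of each
other in the bond graph (1-2, 1-3, 1-4 neighbours).  This matters at the
two covalent junctions the pipeline creates: the stitched N-terminus is
bonded to the body, and the grafted substrate is bonded to the retained
recognition-site peptide.  Counting those bonded pairs as nonbonded
contacts would put a +10³ kJ/mol term in every cross energy and make the
strict `E < 0` retention rule vacuous.  A flag restores the literal
all-pairs sum for free groups.

## Local-elevation bias

The memory potential lives on a uniform distance grid (`NGRID` points,
endpoints inclusive) between the peptide's terminal backbone N and C
atoms.  Each production step deposits one visit at the nearest grid
point (ties to the lower index; out-of-range distances clamp to the end
points).  The bias at distance d is

    B(d) = Σ_g n_g · CLES · [ exp(−x²/2σ²) − exp(−r²/2σ²)·x²/r² ]₊ ,

x = d − c_g, σ = WLES·Δ, r = RLES·Δ, summed over grid points with
|x| < r.  The quadratic tail term brings each local function continuously
to zero at the truncation radius while leaving the value at a visited
centre exactly n_g·CLES — a plain truncated Gaussian cannot satisfy both
properties at once (at r = 2.5Δ, σ = 2Δ the jump would be 0.46·n·CLES).
The bias is clipped at zero, hence everywhere non-negative.

**Deposit increment at fixture scale.**  Published LE protocols pair
increments of order 10⁻⁵ kJ/mol with ~10⁸ production steps; the fixture
systems run ~10³ steps, so their default `CLES = 0.5 kJ/mol` preserves
the cumulative deposited bias per unit of sampling.  The scaling was
fixed from this argument, not tuned to test outcomes.

## Stitching

The ligation fit uses four backbone atoms spanning the junction peptide
bond: C and O of the residue preceding the overlap residue, N and H of
the overlap residue (Cα substitutes when the amide hydrogen is absent).
After Kabsch superposition the output takes the peptide's atoms up to
and including the overlap residue's Cα and the body's atoms after it;
the fit-atom set is configurable because the published descriptions of
the four atoms are themselves ambiguous between the carbonyl/amide set
and a Cα-adjacent set.  A post-fit RMSD above 0.05 nm warns (the
conformer's junction geometry is unusual) but does not abort.  During
clash relaxation only the peptide-contributed atoms before the junction
Cα move; the body is bitwise untouched, which also makes the bulk of
every stitched frame identical — the property that lets the RMSD matrix
use a single common alignment reference.

## Minimizer

Steepest descent with an adaptive step: the step length caps the largest
single-atom displacement (initial 0.005 nm), grows ×1.2 on acceptance,
shrinks ×0.5 on rejection; rejected steps do not count toward the step
cap (configurable).  Termination: an accepted step changing the energy
by less than the tolerance (0.5 kJ/mol by default, interpreted as
|E_i − E_{i−1}| of accepted iterates), the step cap (100), or step-length
underflow.  The energy minimised is the full potential restricted to
terms involving mobile atoms — frozen–frozen terms are constants with
zero gradient, so this is exact and substantially cheaper.

## Clustering

The greedy neighbour-count algorithm: repeatedly take the structure with
the most neighbours within the cutoff as a centre, remove it and its
neighbours, until the pool is empty; ties break to the lowest frame id,
making the partition deterministic.  The cutoff search bisects on a
10⁻⁴ nm grid for a target cluster count, returning the nearest
achievable count with a warning when the target is skipped (counts can
jump).  One caveat is intrinsic to the algorithm, not this
implementation: the cluster count is *not* strictly monotone in the
cutoff — on a few percent of random distance matrices the count rises by
1–2 somewhere along a cutoff ladder, and an exhaustive simulation of the
greedy rule reproduces every such inversion exactly.  The coverage-based
variant returns the smallest grid cutoff whose top-N most-populated
clusters hold the requested fraction of frames, treating coverage as
non-decreasing in the cutoff and guarding the rare non-monotone corner
with a backward scan.

## Grafting

The substrate conformer carries an ACE cap whose carbonyl stands in for
the P1 carbonyl of the upstream (tag) chain.  Grafting superposes the
cap C, O and residue-1 N, H onto the template's P1–P1′ peptide-bond
atoms, deletes the template peptide from those fit atoms through P4′,
and keeps P5…P1 as the bound recognition-site stand-in.  Because the cap
methyl then coincides with the retained P1 Cα (both model the same
atom), the junction consumes it and a P1 Cα–cap C bond restores the
pre-cleavage chain connectivity; this anchors the substrate in the site
during the substrate-only relaxation exactly as the uncleaved chain
would.  Energy groups: `E_interaction` is protease ↔ substrate (the
retained template residues belong to neither group, configurable);
`E_bulk` additionally drops the substrate's N-terminal span, isolating
how the protein body sits against the enzyme.  Retention is strictly
`E_interaction < 0`, identical to the stitch filter.

## Synthetic systems

- **Peptides** are built by natural-extension (NeRF) placement from
  ideal internal coordinates (N–Cα 0.147, Cα–C 0.153, C–N 0.133,
  C=O 0.123, N–H 0.100 nm; standard backbone angles; ω = 180°), extended
  (φ,ψ = −120°,120°) or α-helical (−57°,−47°); non-glycine residues get
  a single Cβ bead.
- **Bodies** are helix–turn–helix stubs with per-seed torsion jitter and
  an extended native N-terminal span; a deterministic retry loop
  enforces the self-clash contract — every nonbonded pair of beads with
  nonzero LJ volume farther apart than 0.25 nm.  The amide hydrogen is
  exempt: it has no steric radius in the united-atom picture, and a real
  α-helix necessarily places it ~0.21 nm from the i−4 carbonyl oxygen.
- **Receptors** are surface grooves: five rails of attractive CH3 beads
  forming the floor and side walls of a half-open channel (width 1.2 nm)
  that encloses the unprimed subsites and ends at the scissile nitrogen,
  leaving the primed side at the surface where a folded substrate body
  must sit.  The blocked variant fills S1′–S4′ with purely repulsive
  beads.  An earlier closed-tube design over all nine subsites was
  rejected during fixture design because it sterically excluded most
  legitimate conformers — a folded body cannot enter a tunnel.

**What the fixtures show, and what they do not.**  Passing tests
demonstrate that the pipeline's machinery is correct (exact geometric
oracles, filter exactness, determinism) and that the score separates a
sterically open from an obstructed active site under realistic
conformational diversity.  They do not validate the absolute energy
scale, real protease chemistry, side-chain packing, or solvent effects;
on real systems the readout remains a relative ranking across substrate
candidates, exactly as the underlying method intends.

## Problem sizes

Study-scale defaults for the synthetic systems: 6-residue sampled
peptide (5 flexible + 1 overlap), 30-residue body, 2 sampling replicates
of 600 production steps, 50 selected frames, 10 target clusters.  These
sizes were chosen so the complete analysis, including the obstructed
receptor whose relaxations always exhaust the 100-step budget, completes
in minutes on one CPU while every stage still operates on genuinely
diverse ensembles.

## Known limitations

- Secondary-structure input is a per-residue H/E/C string; no predictor
  is bundled.
- Side chains are single beads: rotamer-level steric detail is absent.
- The clustered mode inherits the target-count caveat above: sparse
  retained sets can make the exact target unattainable (the nearest
  achievable count is reported, with a warning).
- File-based runs require the active-site template as a PDB with the
  bound peptide on its own chain plus a small YAML map; crystallographic
  subtleties (altlocs, insertion codes, symmetry) are out of scope.
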