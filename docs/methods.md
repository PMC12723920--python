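# Methods

`replisim` simulates the haploid budding-yeast nucleus as a system of
self-avoiding, semi-flexible lattice polymers that replicate themselves
during S-phase, and implements the analyses used to characterize the
resulting spatio-temporal organization: in-silico Hi-C, fork radial
distributions, replication-foci (RFi) clustering, and chromatin-mobility
statistics.

## Lattice and chain model

Chromatin is coarse-grained at 1 kb per monomer with a 20 nm bead diameter
(sigma), the standard 50 bp/nm fiber compaction.  Monomers occupy sites of
an fcc lattice, represented as integer triples of even coordinate sum; one
integer step is sigma/sqrt(2) and the 12 nearest neighbours sit exactly at
sigma.  Bonds are nearest-neighbour vectors.  Chain stiffness enters
through the discrete bending energy

    H_bend = kappa * sum_i (1 - cos theta_i),   kappa = 3.217 kT,

which maps to a 100 nm Kuhn length at this discretization.  Excluded
volume is hard: at most one monomer per site, with a single, explicitly
tracked exception for newborn monomers (below).

Dynamics are kinetic Monte Carlo.  A sweep (1 MCS) performs one trial move
per currently existing monomer: a monomer is picked uniformly, a target
site is proposed uniformly from the geometric candidate set (the sites
adjacent to *all* of its bonded neighbours, excluding its current site),
and the move is accepted with the Metropolis probability min(1, e^-dH) on
the total Hamiltonian.  Because the candidate set is determined by the
neighbours' positions alone, the proposal is symmetric and detailed
balance holds; the test suite verifies the equilibrium distribution of a
three-monomer chain against exhaustive enumeration.

### Equilibration accelerators

With strictly local moves, a tethered chain translates only by kink
diffusion, which makes the initial approach to the Rabl configuration
(below) extremely slow.  Two additional Metropolis moves with symmetric
proposals on the same Hamiltonian are therefore available for
*equilibration only* (they sample the identical Boltzmann ensemble but do
not correspond to physical dynamics): reptation (slithering-snake) trials
and rigid whole-chain translations.  Both require linear, unreplicated
chains; all production dynamics and every measured observable use purely
local moves.

## Nuclear geometry and Rabl organization

The nucleus is a sphere of radius R = 1000 nm carved from a 70-cell box
(one cell = 28.28 nm); sites outside the sphere are permanently blocked.
The spindle pole body (SPB) sits at the +z pole.  Tethers (k = 100 kT per
squared bead diameter — effectively hard constraints):

* **Centromeres** are free in a spherical shell 250–325 nm from the SPB
  and pay +k d^2 outside it (d = distance to the SPB).
* **Telomeres** feel the outward drive k (950^2 - d^2) inside 950 nm of
  the center and nothing beyond — i.e. they diffuse freely within 50 nm of
  the envelope.  (The equivalent form -k d^2 with a branch constant of
  -k 950^2 has the same gradient; writing it with the constant absorbed
  keeps the potential continuous at the shell boundary, which is required
  for the shell to be reachable by Metropolis dynamics at this k.)
* An impermeable **nucleolus wall** truncates the sphere 800 nm from the
  center on the pole opposite the SPB (cap height 200 nm).  Chromosome 12
  is split at 460 kb into two chains; the two rDNA-boundary beads at the
  split pay +k z^2 in the height z above the wall plane and therefore live
  on it, standing in for the rDNA repeats inside the nucleolus.

The genome table (sacCer3 lengths and centromere midpoints at 1 kb) ships
with the package; 16 chromosomes give 17 chains and 12,064 monomers, a G1
volumic fraction of ~1.7% that doubles to ~3.4% when fully replicated.

### Initialization

Two constructions are provided.  `initialize_genome` is the reference
procedure: each chain starts at one of 17 sunflower-packed points of the
equatorial plane, receives a V-shaped backbone of two straight L/8
branches in random non-crossing directions, and grows to full length by
random bond subdivision (a new monomer is inserted at a free site adjacent
to both ends of a randomly chosen bond), chains built in random order.
`initialize_rabl` instead anchors each chain at its centromere on the SPB
shell (chain B of chromosome 12 at its rDNA boundary near the wall) and
grows the two arms around straight descending backbones, filling space
round-robin across all arms.  Because the equilibrium ensemble is fixed by
the Hamiltonian, both constructions relax to the same Rabl state; the
centromere-seeded build merely skips the long transient in which
centromeres would have to be dragged across the nucleus, and is what the
presets and the acceptance script use.  `relax_to_g1` then equilibrates
with a configurable fraction of reptation/translation trials, monitoring
total energy and anchor distances.

## Replication

### 1D kinetics

Initiation is a bimolecular reaction between a limiting pool of N_f = 120
firing factors and a multiset of potential origins (p-oris).  At S-phase
entry each chromosome draws floor(L/5) monomers with replacement,
weighted by the Initiation Probability Landscape Signal (IPLS, 1 kb bins).
Every unreplicated p-ori entry undergoes one firing trial per MCS with
probability

    Prob_firing = (N_f(t) - N_forks(t)/2) * OriginRate,

OriginRate = 1e-9 per MCS, where the pool ramps in as
N_f (1 - 0.13 e^(-t/tau)), tau = 90 s.  Each live fork advances one
monomer with probability v * dt = 2.75e-6 per MCS (v = 2.2 kb/min,
dt = 0.075 ms).  Firing opens a bubble with two diverging forks
(consuming one factor), converging forks merge (releasing one), and a
fork reaching a chain end opens its bubble.  Free factors always equal
N_f(t) - N_forks/2, so factor bookkeeping is implicit in the fork count.

The 1D-only ensemble runner (`run_1d_ensemble`) implements exactly these
rules on genomic bins, using geometric inter-event skipping when the
combined per-MCS event probability is below 1% (event typing by rate
share; the O(q^2) chance of two events in one MCS is neglected in that
regime, a <0.5% rate bias) and plain per-MCS binomial trials otherwise.
Because the model has no 3D feedback onto firing or stepping, the 1D
runner reproduces the coupled engine's replication timing; a test asserts
this equivalence.

Edge rules (the underlying event algebra leaves these open): firing
trials at a chain-end bin, within one bin of a chain end, or adjacent to
an existing junction are skipped without consuming a factor; if an
advance would place a junction on a chain-end bin the bubble opens
immediately.  End bins therefore replicate passively, by forks arriving
from the interior.

### 3D duplication

Origin firing inserts a newborn monomer *at the same lattice site* as its
template, bonded to the two maternal neighbours of the origin; excluded
volume is transiently violated (at most two monomers per site, only via
this path) and re-established by diffusion, since moves into empty sites
are always available to the co-located pair.  The two flanking monomers
acquire triple connectivity and are the replication forks.  Fork advance
inserts the next newborn at the junction's site and moves the triple
connectivity outward; merges and telomere openings replicate the
converging/terminal pair of monomers together.  The maternal monomer of
each locus keeps the Sister Chromatid 1 label and the newborn becomes
SC2, which makes merge concatenation automatic and gives all dynamics
analyses a copy (SC1) that exists at every time.  Newborns inherit their
template's tether role, so both sisters of a centromere remain attached
to the SPB after passage.

Bending angles follow the strands through each junction: the maternal
pair (prev, next) plus the SC2 pair (bubble-side copy, outward maternal
neighbour).

### Sister-fork scenarios

In the *interacting* scenario the two forks born from one origin are
coupled by a flat-bottomed elastic well,

    H = -J_sister                          d <= th
    H =  J_sister (d^2/th^2 - 2)           d >  th,

J_sister = 100 kT, th = 50 nm: a well of depth J_sister saturating below
th with quadratic stiffness J_sister/th^2 outside (zero crossing at
sqrt(2) th).  The pairing dissolves permanently when either partner dies
(merge or chain-end opening); survivors diffuse freely and no new
pairings are ever formed.  In the *non-interacting* scenario forks evolve
independently.  Optional non-specific contact attraction between all
forks, H = -J_f x (fork pairs within 40 nm of each other), is available
behind `j_forks` (default 0; 1.7 kT is the explored value); an
incrementally maintained per-site fork-proximity field (54 offsets up to
40 nm) makes its evaluation O(1) per trial and a test cross-checks the
field against a direct pair count.

## Analyses

**In-silico Hi-C.**  Two monomers are in contact when their Euclidean
distance is strictly below r_c = 80 nm.  Sister copies pool onto genomic
bins (up to four copy-pairs per bin pair per frame).  Maps are balanced by
iterative correction (masking all-zero bins; convergence when the CV of
non-masked marginals drops below 1e-5, max 200 iterations), the expected
P(s) is the genome-average diagonal mean over valid intra-chromosomal
pixels, and observed/expected divides by P(|i-j|) in cis and the mean
trans frequency otherwise.  Pileups aggregate anchor-centered O/E windows
(on-diagonal) or anchor-pair cross-windows normalized by P_intra(10 kb)
(off-diagonal).  Cross-dataset operations: gamma = P_exp/P_sim at 16 kb,
the closed-form MSE-optimal alpha between P(s) curves, convex map mixing
and Pearson similarity over shared unmasked pixels.  Maps export to a
multi-resolution HDF5 container following the cooler schema (1–16 kb
layers) plus dense TSV for small maps.

**Fork radial distribution.**  Distances to the SPB are histogrammed in
5 nm shells and divided by the accessible shell volume.  The default
normalizer is the exact sphere-sphere intersection volume
V(r) = pi r^3 (8R - 3r) / (12R), under which a uniform point cloud is
flat; the cap-of-height-r formula V(r) = (3R - r) r^2 pi / 3 (exact for
axial slabs, an approximation for distance shells) is available as
`volume="cap"`.

**Replication foci.**  RFi are connected components of the fork adjacency
graph at threshold theta (inclusive), computed with networkx and verified
against a brute-force union-find oracle.  Preset thresholds 60/125/160/
200 nm; 125 nm is the 3D-SIM-like default.  The microscopy-style estimate
divides each focus's fork count by the frame total, scales by a reference
total (229), and casts to an even number as 2*round_half_up(x/2) — so a
lone fork maps to one sister pair, mirroring the experimental assumption
of sister-fork colocalization; the rounding rule is configurable.

**Mobility.**  MSD is averaged over start times, monomers and
trajectories on SC1 copies; physical units come from the time mapping.
The mapping itself is calibrated on a single chromosome-4-sized chain
(1531 monomers, ~5% density, periodic box) by matching
MSD = A tau_MCS^1/2 to the experimentally observed 0.01 tau^1/2 um^2 law
(tau in seconds), giving dt = (A/0.01)^2.  The fixed-exponent fit is taken
over the physical window 0.1–1 s where the experimental law applies,
iterated to self-consistency between the window (set in seconds) and dt.
A local-slope criterion was rejected: on this move set the apparent
exponent is ~0.65 through the intermediate regime (semiflexible
crossover) and passes through 0.5 only entering confined saturation, so a
slope-selected window lands on the wrong regime.  The calibration yields
0.077–0.085 ms/MCS across seeds, within ~13% of the reference
0.075 ms/MCS used for all defaults.  The replication-aligned statistic SD(t, tau = 15 s) shifts
every locus's squared-displacement series so its replication instant is
t = 0 and averages in time bins.

## Synthetic IPLS generator

The generator emulates the inferred yeast initiation landscape: a sparse,
peaky, non-negative 1 kb track with 111 early peaks (signal uniform in
6–15, i.e. > 5) and 615 late peaks (uniform in 1.2–4.8), matching the
published landscape's summary statistics (726 origins over ~12 Mb), over
a weak uniform background (< 0.05) whose local maxima enlarge the peak
population without entering either origin class.  Half of the early peaks
are placed within 100 kb of a centromere, reflecting the observed
centromere-proximal enrichment of early origins that drives the early-S
replication wave toward the SPB; peaks keep 5 kb minimum separation and
avoid the outer 3 kb of each chain.  Classification (strict local maxima,
plateaus counted once at their leftmost bin; early = top 15% of peaks by
height intersected with signal > 5; late = remaining peaks above 1)
recovers the planted classes exactly by construction, which the tests
assert.  What the generator does *not* emulate: the empirical height
distribution and spatial autocorrelation of the real landscape,
subtelomeric late-origin clusters, and chromosome-specific efficiency
differences.  Consequently the 1D ensemble on the synthetic landscape
reproduces the reference kinetics' bulk behavior (fork-count peak near
the 2 N_f = 240 cap a few minutes into S-phase; >95% of the genome
replicated by ~30 min) but its *last-locus* S-phase duration (~45 min) is
longer than the ~30 min reported for the real landscape, because randomly
placed origins leave occasional telomere-distal gaps that finish late.

## Scaled-down experiments

Full-scale trajectories (24 M MCS of a 12–24 k monomer system, hundreds
of repeats) are outside a desk-scale budget, so the packaged experiments
(`replisim.experiments`, also used by `scripts/acceptance.py`) rescale
time: OriginRate and fork speed are multiplied, and the factor-ramp tau
divided, by a common factor, which leaves the entire replication program
unchanged on the compressed axis while the polymer relaxes less between
replication events.  Problem sizes used: the fountain contrast runs a
300 kb chromosome with three early origins at rescale 400 and measures
contact enrichment at the current fork-pair coordinates against the raw
contact frequency at matched separation; the mobility-dip ensemble runs a
single-origin 160 kb chromosome at rescale 40, chosen so the measurement
lag stays below the per-monomer fork residence time (the regime in which
the pairing constraint is visible, as it is at full scale where
15 s << 1 kb / v); the genome-wide early-S RFi count runs the full
nucleus at rescale 300 and counts foci in frames whose fork count matches
the microscopy comparison window.  Passing these tests demonstrates the
mechanisms (pairing-driven fountains, focus halving, fork-passage dip,
catenation slowdown) at reduced statistics; quantities tied to the full
ensemble (e.g. the ~11% centromere contact enrichment) carry wider error
bars at this scale.

## Known limitations

No strand crossing exists, so catenations formed at merges persist — this
is a feature of the model (it produces the post-replication mobility
drop) but also means late-S configurations are not topologically
equilibrated.  Nuclear volume is fixed through S-phase.  There is no
cohesin/loop extrusion, no fork stalling or checkpoint signaling, and no
3D feedback onto firing rates.  The published IPLS track itself is an
external input; the built-in generator is a statistical stand-in, not a
reconstruction.
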