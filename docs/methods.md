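# Methods

This note documents the models implemented in `memlipid`, the parameter
conventions, the design choices that were genuinely open, and what the
validation strategy does and does not establish.

## Contact criterion

A residue–lipid contact exists in a frame when the minimum distance between
any protein heavy atom of the residue and any heavy atom of the lipid
headgroup is ≤ `d_cut` (default 4.0 Å). Headgroup membership is a per-species
atom-name set: POPC = {N, C11–C15, P, O11–O14}, POPA = {P, O11–O14}
(CHARMM36 names). The phosphate-plus-choline moiety is the solvent-exposed
part of the lipid a 4 Å criterion can plausibly reach; whether glycerol
carbons count as "headgroup" is genuinely convention-dependent, so the sets
are user-overridable per residue name rather than hard-coded.

Distances are 3D Euclidean with the minimum-image convention applied in
x and y only: the bilayer is periodic in-plane, while z (the membrane
normal) is treated as non-periodic, which also keeps leaflet logic
unambiguous. Contacts are evaluated against both leaflets; at 4 Å only the
proximal leaflet is geometrically reachable, so no leaflet pre-filter is
applied. Correctness is defined by an all-pairs brute-force scan; the
vectorised implementation is required by test to agree with it exactly.

Contact probability is the fraction of frames in contact with ≥ 1 lipid.
When a system contains several copies of an identical peptide, probabilities
are averaged across copies at equivalent *sequence positions* (not residue
numbers), so renumbered copies are tolerated; grouping chains of unequal
length or differing sequence is an error. Stable-residue sets use a strict
`>` comparison at the threshold (0.5 and 0.8 are the conventional cutoffs),
so a residue at exactly 50 % is not "stable at > 50 %". By default
probabilities are computed over all frames; a `start_ps` option drops an
equilibration window when wanted.

## Residence times

A dwell event is a maximal run of consecutive contact frames for one
(residue, lipid) pair. Its residence time is literally first-to-last time,

    t_res = t_f − t_i = (k − 1)·dt        (k-frame run),

so a single-frame contact has t_res = 0. This is deliberately not the
"occupancy time" k·dt, a common alternative that differs by one frame
spacing per event; conservation of contact frames is instead guaranteed via
the run-length sum, which tests check against the raw contact record.
Default gap tolerance is zero frames — any non-contact frame ends the
event; a `gap_frames` option exists for robustness studies but is off by
default. Events truncated by either trajectory end are flagged `censored`;
they count toward aggregate residence time but are excluded from mean-dwell
estimates, which would otherwise be biased low.

Eligibility follows the field convention of computing lipid residence only
around residues already in membrane contact for > 50 % of frames; the
eligible set can be overridden explicitly.

Residence statistics are sensitive to the sampling interval:
`stride_sensitivity` recomputes events on frame-subsampled records with
effective spacing stride·dt, where gaps shorter than the stride become
invisible and events merge. Subsampling and gap tolerance are distinct
mechanisms and both are exposed; neither is asserted to be "the" correction.

## In-plane radial distribution function

g_2D(r) uses xy-projected minimum-image distances from reference atoms to
target-species phosphorus atoms:

    g(r) = ⟨n(r)⟩ / (2π r Δr ρ),

with ρ the *instantaneous* per-frame in-plane density (targets / Lx·Ly),
since NPT boxes fluctuate. Defaults Δr = 0.2 Å and r_max = 12 Å resolve
first/second/third coordination peaks (≈ 4–6 Å spacing) without committing
to figure-read peak positions. Profiles are averaged over reference atoms
(pooling all reference–target pairs) and frames; per-reference profiles can
be had by passing single-atom selections.

Leaflet scope defaults to `auto`: the leaflet whose phosphate plane is
nearest the reference atoms at the first frame. Cross-leaflet pairs are
geometrically impossible below ~12 Å in a real bilayer, so this default is
a bookkeeping convenience, not a physical assumption.

Reference-atom naming: lysine's terminal nitrogen is NZ. For arginine the
guanidinium has NE/NH1/NH2 in standard nomenclature and informal usage
("Nδ") is ambiguous; the default is NE with the others selectable — the
choice is configuration, never silently resolved.

Block convergence reports max over r of |g_block − g_full| per time block.
On a stationary field this metric is bounded by Poisson counting noise;
a drifting field shows block-dependent deviations.

## Enrichment

A lipid is "near" a residue region in a frame when it contacts ≥ 1 region
residue under the contact criterion. The local species fraction is the
ratio of frame-averaged counts ⟨near of species⟩ / ⟨all near⟩; the global
fraction comes from topology composition (366 POPC + 50 POPA → PA fraction
0.120). When no lipid is ever near, the result is flagged undefined rather
than silently zero.

## Geometry episodes

Salt bridges pair basic side-chain nitrogens (Arg, Lys, His — histidine is
counted basic) with lipid phosphate oxygens (O11–O14; for reduced
single-bead lipid models the headgroup bead stands in). The cutoff defaults
to 4.0 Å N···O, matching the only distance criterion the contact analysis
itself uses; it is overridable. No angular criterion is applied — these are
distance episodes, not hydrogen-bond assignments. Multivalent intervals are
computed by interval algebra over per-lipid event sets: maximal runs of
frames with an identical simultaneous partner set of size ≥ 2. Every such
interval is by construction a subset of each contributing event.

Shared-lipid tracking collapses each lipid's per-frame set of contacted
regions into windows of constant region set; windows partition the lipid's
in-contact frames exactly, and episodes are ranked by total multi-region
duration. Region presets for the cRaf kinase domain: NtA = 340–342, basic
cluster = {391, 398, 399, 400, 401}, AS = {462, 463, 494–497}.

Helix orientation fits a line through the helix Cα coordinates per frame
(dominant SVD direction) and reports θ = arccos|axis·ẑ| ∈ [0°, 90°]; the
absolute value folds the axis sign ambiguity, so 90° means lying flat on
the membrane. The default helix span 391–408 covers the αC-helix segment
carrying the polybasic cluster and is configurable, since helical limits
are assignment-dependent. At least 4 Cα atoms are required. Note that a
finite ideal helix's fitted axis deviates from its geometric axis by
O(1/n²) unless the span covers whole turns; the 1° test tolerance reflects
this. θ is reported, not thresholded — "perpendicular" is a description,
not a cutoff.

Spine collinearity takes the unweighted centroid of each spine residue's
side-chain heavy atoms (default spine F408, L397, F487, H466; extended set
adds W342) and reports the RMS point-to-line distance from the best-fit
line. Glycine in a spine set is an error (no side chain).

Inter-chain independence reports per-frame minimum heavy-atom distances
between protein chains and flags frames below the contact cutoff — a check
that peptide copies sample the membrane independently rather than
interacting.

## Motif scanning and composition groups

Motif patterns are fixed-length element lists (fixed residue, alternative
set, wildcard, wildcard repeat) over the 20 standard codes; scanning
reports all, possibly overlapping, matches left to right, with positions in
caller-supplied numbering (offset + 1-based index). Two Raf presets ship:
strict `R x E x{4} [RK] [KR] T R` (default) and relaxed
`[RK] x E x{4} [RK] [KR] [TLQ] R`.

Membrane-interacting residue sets are classified by composition fractions
(basic {R,K,H}, aromatic {F,W,Y}, hydrophobic {A,V,L,I,M,P}): group 1
(largely basic) at basic ≥ 0.6 with aromatic+hydrophobic < 0.25; group 2
(basic plus aromatic/hydrophobic) at basic ≥ 0.25 with
aromatic+hydrophobic ≥ 0.25; group 3 otherwise. The reference grouping is
given by example only, so the 0.6/0.25 thresholds are this package's own
calibration, kept as configurable arguments with the six documented
membrane-binding domains as the regression test.

The interface-code builder renders an ordered residue set as a compact
string. Two separator conventions exist: the default is purely positional
(adjacent → concatenated, gap of one → `.`, larger → `..`); with optional
per-residue structural-element labels the separators instead encode element
provenance (`.` within an element, `..` across elements), which is the
convention used for published membrane-binding-surface codes such as
`YYW..R.RKTR..RN.RW`. The positional default was chosen because it needs no
structural input; the labelled mode exists because the two conventions
genuinely disagree on sparse surfaces.

## Synthetic generator

The generator emulates only the geometry the analyses consume: two leaflets
of single-bead lipids (name P) at ±18 Å, peptide residues as a Cα bead 5 Å
above the leaflet plane plus one side-chain bead in the plane
(nitrogen-named for basic residues), an orthorhombic box, and seeded 2D
Gaussian random walks (default σ = 1 Å/frame, a plausible in-plane lipid
displacement at 10 ps spacing) wrapped periodically. Default composition is
183 POPC + 25 POPA per leaflet in a 120 × 120 Å patch — the reference
bilayer of the motivating study, 12 % PA at ≈ 62 Å²/lipid — and the
generator rejects boxes below 60 Å²/lipid as unphysical.

Binding rules drive dwell schedules. A scripted rule pins its dedicated
lipid inside 0.8× the contact radius of the partner residue for declared
frame intervals (uniform-in-disc jitter keeps RDF peaks finite-width) and
keeps it outside 1.5× the radius otherwise; all other lipids are also
excluded from rule residues' zones, so a rule residue's contacts are
*exactly* its schedule and recovery tests can assert equality, not
approximation. Rules sharing a `lipid_tag` drive one lipid jointly (the
multivalent/shared-lipid construction); the lipid then sits near the
anchors' centroid, which requires those anchors to be mutually close, and
anchors of unrelated rules must be ≥ 2.5× the contact radius apart or the
generator refuses the spec. A stochastic rule runs a two-state chain with
per-frame unbinding probability `p_unbind` and rebinding probability
`p_bind` (default 0.1 — needed so a finite run accumulates the hundreds of
events the statistical recovery tests require), giving geometric dwell
lengths with mean residence time dt·(1−p_unbind)/p_unbind.

All randomness flows from one seed through numpy's PCG64; the fixture
manifest records seed, algorithm and the exact draw order, and a test
replays the free-lipid walk independently from that documentation.

What passing these tests shows: the analysis stack measures back exactly
what was constructed — geometry, schedules, compositions, episode algebra.
What it does not show: anything about force-field realism. The generator
has no energetics, no z-fluctuations, no lipid flip-flop, no conformational
dynamics, and chance contacts at unscripted residues follow hard-disc
geometry, not electrostatics. Quantities from real trajectories
(residence-time magnitudes, RDF peak positions, enrichment levels) depend
on the underlying simulation and are not reproduced by the fixtures.

## Problem sizes and numerical choices

Test fixtures are deliberately small: scripted recovery uses 100-frame,
~80-lipid systems; the stochastic-dwell fixture runs 60 000 frames of a
3-lipid system to accumulate ≥ 500 events; uniform-field calibration uses
200 lipids × 400 independent frames (≥ 10⁴ pair samples per bin region);
the stationarity check uses 9 reference atoms × 400 lipids × 400 frames so
Poisson noise sits well inside the 0.2 agreement band. Leaflet ties (P
exactly at the midplane) go to the upper leaflet. MTRAJ text output prints
6 decimals and round-trips to that precision; DCD round-trips at float32
(1e-4 Å). Hydrogens are identified from the PDB element column, falling
back to a leading-H name heuristic with a logged warning. Degenerate inputs
(zero lipids, empty selections, glycine spines, single chains) raise
errors rather than returning empty statistics silently.

## Known limitations

- DCD support targets the CHARMM/NAMD little-endian dialect via MDAnalysis;
  XTC/TRR/GRO and velocities are out of scope.
- Lipid identity is positional: periodic-image identity swaps of a lipid
  are not corrected in residence bookkeeping.
- No kinetic modelling (survival curves, Markov states) is attempted on
  dwell events; the statistics are descriptive.
- Salt-bridge detection is distance-only; no donor–acceptor geometry.
- The classification thresholds are calibrated to a small set of published
  examples and should be re-examined before use on novel domain families.
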