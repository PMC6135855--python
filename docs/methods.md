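# Methods

## The problem and the approach

`loopforge` models a missing loop in a protein structure by retrieving,
from a database of experimentally observed chain segments, fragments
whose *flank geometry* matches the gap, and grafting the best of them
into the template. The working assumption is empirical rather than
physical: backbone fragments constrained by similar anchor geometry and
similar local-conformation context tend to adopt similar structures,
even across unrelated proteins. The pipeline therefore never folds
anything — every candidate conformation existed in some chain of the
database — and its honesty about failure is structural: when the
database holds no fragment with a low profile divergence, the target is
flagged low-confidence rather than papered over.

## Database construction

Chains from the input PDB files are reduced to main-chain atoms
(N, Cα, C, O) and split into gap-free segments at (i) author-numbering
discontinuities, (ii) non-standard residues (selenomethionine is
renamed to MET and kept; every other modified residue is dropped and
splits the segment), (iii) residues without a Cα, and (iv) consecutive
Cα pairs 4.5 Å or more apart. The distance criterion supplements the
numbering one because deposited files can number right across a
physical chain break. Alternate locations resolve to the
highest-occupancy conformer (ties favour altloc A); only the first
model of multi-model files is used; hydrogens, side chains and ligands
are ignored throughout, since the method uses main-chain geometry only.
Segments shorter than flank + 1 residues (5 by default) can never
contribute a search window and are discarded at build time. Segment
ordering is lexicographic by source id and position, so a database
build is byte-reproducible regardless of filesystem order.

## Search

A query consists of the 4 residues on each side of the gap (flanks must
be complete and contiguous with the gap, otherwise the query is
rejected rather than silently shrunk) plus the loop length and
sequence. Candidate windows have exactly flank + loop + flank residues
— the method models fixed-length gaps, with no indel tolerance, because
the kernel requires equal point counts and model building assumes the
full target sequence.

Three criteria are evaluated per window on Cα coordinates:

* **Binet–Cauchy kernel** on the two concatenated 8-point flank
  matrices, each centered at its own geometric center. Centering is
  joint over both flanks of a side (one matrix per structure, not one
  per flank), so the kernel sees the *relative placement* of the two
  anchors, which is the actual constraint on the loop. The cutoff is
  0.9 for loops of at most 8 residues and 0.8 for longer ones — longer
  loops tolerate more anchor strain. Negative kernel values (mirror
  images) fail the positive cutoffs automatically; no absolute value is
  taken.
* **Rigidity** ≤ 3 Å. The score is implemented as the maximum absolute
  difference between each point's distance to its own set's geometric
  center, combined with the end-to-end (first-to-last Cα) distance
  difference. A naive paired-coordinate-difference reading of the first
  term is also provided (`rigidity_mode="printed"`), but it depends on
  the arbitrary lab frame of each database entry and is not the
  default: a search criterion must be invariant to how a structure was
  deposited.
* **flank RMSD** ≤ 4 Å after optimal (Kabsch) superposition, Cα only —
  consistent with the Cα-based kernel; assessment RMSDs (below) use all
  four main-chain atoms.

Because the end-to-end term is a lower bound on the Rigidity score, an
anchor-distance prefilter prunes windows exactly, without changing
results (verified against the unpruned scan in the tests). Windows with
collinear or coplanar flank sets have a singular Gram matrix; the
kernel is undefined there and the window is skipped. Hits are sorted by
descending kernel score, ties by source id and offset, making the
search independent of input order.

Before searching, chains with global sequence identity to the target
above 70% are removed. Identity is computed by Needleman–Wunsch global
alignment with BLOSUM62, gap open 11 / extend 1, as matches over
alignment length — a standard choice the method itself does not pin
down further.

## Filter cascade

1. **Sequence**: sum of positionwise BLOSUM62 scores between the query
   loop sequence and the candidate loop sequence; strictly negative
   totals are discarded (a total of exactly zero is kept).
2. **Clustering**: complete-linkage hierarchical clustering on pairwise
   loop Cα RMSD, cut at 1 Å. Distances are computed in the common query
   frame without per-pair refitting — the candidates are already
   superposed via their flanks, which is also the frame they will be
   grafted in, and it makes the pairwise matrix a plain Euclidean
   computation. Complete linkage guarantees cluster diameter ≤ cutoff.
   Candidate sets larger than 25,000 are clustered iteratively over
   consecutive chunks of 25,000, carrying one representative per
   cluster forward, until at most 25,000 remain, followed by a final
   full pass; on well-separated clusters this reproduces the
   single-pass result exactly (tested). The representative is the
   member with the highest BLOSUM score, ties broken by higher kernel
   score, then source order.
3. **Profile divergence**: fragments are encoded over a 27-letter
   structural alphabet. Each overlapping 4-residue Cα window is
   described by four rigid-motion-invariant numbers — d(1,3), d(1,4),
   d(2,4) in Å and the signed tetrahedral volume in Å³ (the sign
   carries chirality) — and assigned to the nearest of 27 prototype
   descriptors. Per-residue profiles are pseudocount-smoothed one-hot
   rows (ε = 10⁻⁴ per letter before renormalization, keeping every
   Kullback–Leibler term finite); the window starting at a residue
   defines its letter, and the trailing three residues inherit the last
   window. Profiles are compared by the average positionwise
   Jensen–Shannon divergence with natural logarithms, so values are in
   nats, bounded by ln 2, and the thresholds 0.40 (filter) and 0.20
   (confidence) apply unchanged. Candidates with divergence strictly
   above 0.40 are discarded.

   The package ships a default alphabet
   (`data/default_alphabet_synthetic.txt`), trained once by seeded
   k-means on the windows of a large batch of synthetic helix–loop–
   helix structures and canonically sorted (by d(1,4), then volume) for
   reproducible letter indices. It is a synthetic stand-in: users with
   a published 27-letter alphabet can drop it in via
   `SAAlphabet.load`, and precomputed L×27 query profiles (for example
   from a sequence-based predictor) are accepted as plain-text files.
   When no query profile is supplied, the query-side profile is derived
   from the best-kernel-score candidate's loop grafted between the
   template flanks — a deterministic, structure-only fallback that
   preserves the key identity: if the database contains the native
   fragment and the flanks are exact, its divergence is exactly 0.
   Candidate-side profiles are always encoded over the full
   flank+loop+flank window (junction geometry informs the loop rows)
   and then restricted to the loop positions.
4. **Clash**: after grafting, any loop Cα strictly closer than 3 Å to
   a non-loop Cα disqualifies the model. A separation of exactly 3 Å is
   allowed. Loop-internal contacts are not tested — the candidate comes
   from a real (or synthetic-native) structure.

All boundary conventions follow the strict inequalities of the
filtering rules: BLOSUM 0 kept, JSD = 0.40 kept, 3.0 Å not a clash,
min(JSD) = 0.20 still high-confidence.

## Model building and selection

Grafting is rigid: the superposition that mapped the candidate flanks
onto the query flanks carries the candidate's loop main chain into the
template; loop residues are renamed to the query loop sequence (no side
chains beyond the naming — side-chain construction belongs to an
optional refinement hook, a callable applied to each grafted model) and
renumbered continuously into the gap. Peptide-bond continuity at the
junctions (C–N < 2.5 Å) is reported as a quality flag, not enforced,
since flank noise legitimately strains the junction.

Each surviving model carries two scores. The JSD is reused from the
filtering stage (it is a property of the candidate, not of the graft).
The second score is a statistical potential behind a pluggable callable
interface. The built-in `ContactPotential` is a deliberately simple
main-chain contact statistic — *not* DOPE, whose parameter tables are
not public: pair distances between main-chain atoms of residues at
sequence separation ≥ 2 are histogrammed in 0.5 Å bins up to 10 Å over
the fragment database, and bin energies are
−ln((observed + 1)/(expected + 1)) against a distance-squared
(volume-element) reference scaled to the same total count. Scoring sums
bin energies over loop-vs-environment pairs; clashing placements land
in bins the database never populates and are penalized, native-like
contact distances score negatively. The score is deterministic given
the database.

The final model set is the union of the 5 best candidates by ascending
JSD and the 5 best by ascending potential; a candidate present in both
top sets appears once (`selected_by="both"`, deduplicated by source
fragment), so at most 10 models are returned, fewer when the sets
overlap or fewer candidates survive. Ties are broken by the other
score, then provenance order. The per-target confidence index is
min(JSD) over the post-clash candidate set; ≤ 0.20 marks the target
high-confidence. An empty candidate set is a valid outcome: empty model
list, low confidence, and a stage report showing where the cascade
emptied.

## Quality assessment

Three RMSD variants over main-chain atoms (N, Cα, C, O), differing only
in which atoms define the superposition: **local** (best fit of the
loop itself), **flanked** (fit the flank residues — 4 per side by
default, 2 configurable — then measure the loop without refitting) and
**global** (fit everything except the loop). Local RMSD is never larger
than the RMSD under any fixed superposition, including the flank fit;
no ordering between flanked and global is asserted in general.

## Synthetic fixtures: what they emulate, and what they do not

The generator produces helix–loop–helix targets: two ideal α-helical
Cα segments (2.3 Å radius, 1.5 Å rise, 100°/residue, giving 3.83 Å
steps) joined by a seeded self-avoiding random-walk loop with steps in
[3.7, 3.9] Å and a 3.5 Å closest-approach floor. N, C and O atoms are
placed synthetically along the inter-Cα directions at standard bond
lengths — idealized, not Ramachandran-accurate, but sufficient for
every main-chain computation in the package. A planted database
contains each target's *donor* (same coordinates, every non-loop
residue mutated, keeping chain identity near 50% so homolog exclusion
retains it while the sequence filter still accepts the loop) plus decoy
chains whose Cα traces are planar zig-zags: planar point sets are
rank-deficient, so no decoy window can ever match a three-dimensional
query — decoys exercise window enumeration and the degenerate-input
path without contaminating recovery statistics. Template error is
emulated by deleting the loop and adding isotropic Gaussian noise
(σ = 0.3 Å in the standard conditions, chosen to put flank RMSDs in the
regime reported for homology-model templates, ~0.9–1.0 Å).

Passing these tests therefore shows that the machinery is correct —
exact recovery when the answer is present, graceful degradation under
anchor noise, every threshold applied as specified. It does *not* show
that real loops are predicted accurately: real databases contain
near-misses rather than planted answers, real profiles come from
predictors with their own error, and real templates have correlated,
not isotropic, errors (a rigid-segment noise option exists for the
latter). Accuracy on real targets depends on database coverage and is
outside what synthetic fixtures can certify.

## Problem sizes and numerical choices

The test suite runs at desk scale: 20 planted fixtures covering loop
lengths 5–29, a shared 50-structure database (20 donors + 30 decoys)
for end-to-end recovery, 100–1,000-trial property checks for the kernel
identities and invariances. The full suite completes in well under a
minute. Degenerate kernels raise a dedicated error (Gram determinant
below 10⁻¹² of its trace bound); zero entries are legal in raw
distributions (0·log 0 = 0) but profiles are pseudocount-smoothed;
superposition uses `scipy`'s Kabsch implementation, whose residual on
identical inputs is ~10⁻⁷ Å, the tolerance used for "zero" RMSD
assertions. PDB output rounds coordinates to 10⁻³ Å, so quantities
recomputed from written files are near-exact rather than exact.

## Known limitations

Single-loop, single-chain modeling only; no side-chain packing, energy
minimization or all-atom clash model (Cα-only, as specified); the
built-in potential is a coarse contact statistic and should be replaced
via the scorer interface when a calibrated potential is available; the
shipped structural alphabet is synthetic-trained and should be swapped
for a published alphabet in production use; mmCIF input is not
supported.
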