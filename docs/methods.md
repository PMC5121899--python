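# Methods

## The curation model

A miRNA locus is modelled as a precursor interval on a genome with two
non-overlapping arm intervals (5p and 3p) in transcript orientation;
minus-strand precursors are stored reverse-complemented so every
downstream computation happens in transcript space, with 0-based,
half-open coordinates throughout.  Evidence for a locus comes from two
independent sources that the verdict combines:

* **Biogenesis.** Collapsed small-RNA reads are assigned to an arm when
  their 5′ end falls within a small tolerance (default 2 nt) of the arm's
  annotated 5′ end and the read lies inside the precursor padded by the
  same tolerance.  Counts are normalised to reads per million mapped
  (RPM) per library.  The knockdown contrast is
  `log2((mean depleted RPM + pc) / (mean control RPM + pc))` with
  pseudocount `pc = 0.25` RPM; replicates are averaged on the RPM scale
  before the ratio.  A genuine Dicer substrate must fall below −0.5.
  The baseline for this contrast is a set of negative-control regions:
  maximal genomic runs shorter than 500 nt covered at ≥10× in every
  control library and disjoint from known miRNA/coding loci; their median
  log2FC estimates the pure normalisation drift (it is slightly positive
  whenever miRNA reads, removed by the knockdown, are a non-trivial
  fraction of the library).
* **Structure.** The precursor is folded and must form a single-stem
  hairpin (exactly one terminal loop, loop length within a sanity window,
  default 8–40 nt), with free energy strictly below −22 kcal/mol, more
  than 16 base pairs between mature and star, and a 2-nt 3′ overhang on
  each arm of the duplex — the geometric signature of Drosha/Dicer
  processing.  Overhangs are measured from the arm intervals against the
  realised pairing: the number of an arm's 3′-terminal bases beyond its
  last base paired into the other arm.

Candidates matching a reference mature catalogue (ungapped local
alignment of ≥19 columns with ≤1 mismatch; ungapped because mature miRNAs
are short and an indel would break seed identity anyway) are accepted as
conserved by homology and bypass the novel-miRNA criteria.  Loci whose
precursor *and* ±50 nt of flanking context are perfectly identical to
another locus are assembly artefacts; the lowest-coordinate copy is kept.
Contexts truncated at a contig end are compared over the symmetric
minimum flank, and the truncation is recorded.

## Folding backend

The internal folder computes the maximum-pairing pseudoknot-free
structure by dynamic programming (Watson–Crick plus G:U pairs, minimum
hairpin loop of 3 unpaired bases).  Among structures with the maximal
pair count, ties are broken toward minimum stack energy, scored with an
embedded nearest-neighbour table (Turner-style 37 °C Watson–Crick stack
free energies; any stack containing a G:U pair is approximated by a flat
−1.2 kcal/mol).  The reported free energy is the stack sum of the chosen
structure; the per-enclosed-unpaired-base loop penalty defaults to 0 so
that an isolated closing pair can never raise the energy, keeping the
model monotone under helix extension and giving unstructured sequences an
energy of exactly 0.  This model is intentionally *not* equivalent to a
full thermodynamic folder: it has no dangling ends, loop-size terms or
ensemble view.  The `external` backend delegates to ViennaRNA's `RNAfold`
and parses its dot-bracket and minimum free energy; requesting it when
the executable is absent raises an explicit error rather than silently
falling back.  The energy threshold (−22 kcal/mol) was calibrated on
conserved miRNAs in the original protocol and is exposed in the
configuration, as are all other thresholds.

The pair-count optimality of the internal DP is tested against an
independent brute-force recursion for random sequences up to 30 nt, and
designed hairpins are cross-checked against `RNAfold`.

## Seed families and arms

The seed is the mature hexamer at 1-based positions 2–7 (the published
family-defining seeds are 6-mers; positions 2–8 are available by
configuration).  Families are equivalence classes under exact seed
identity; conserved members keep their reference family name, novel
families are numbered in descending order of their most expressed member.
The mature arm is the higher-count arm over control libraries; when the
max/min ratio (minimum floored at one read) is below 2 both arms are
co-mature.  For co-mature loci the knockdown criterion is evaluated on
the stronger arm.

## Dollo gain/loss

Family presence/absence (with a "present in genome, no expression" state
counting as present) is mapped onto a fixed rooted species tree under
Dollo parsimony: each family arises exactly once — on the edge subtending
the LCA of the species carrying it — and is lost on the minimal set of
edges subtending the maximal all-absent subtrees inside that clade.
Families constrained as ancestral (`root_present`) have their gain placed
before the root ("root or earlier") and contribute losses only.  This
direct construction is provably optimal; the test suite nevertheless
checks it against exhaustive enumeration of all internal-state
assignments for every presence pattern on the 7-leaf tree.  Equal-cost
loss placements do not arise under this construction because the maximal
all-absent subtree decomposition is unique.

## Clusters and regression

Genomic clusters chain precursor loci along a contig by single linkage
with inter-locus gaps ≤ 20 kb, strand-agnostic, requiring ≥2 members.
The 20 kb default keeps known clusters with a single >12 kb internal gap
in one piece while not chaining across typical intergenic distances; it
is configurable because no universal rule exists.  Cluster length vs
genome size is summarised by ordinary least squares with r² the squared
Pearson correlation.

## Target baselines

The internal target predictor is one deliberately simple algorithm: a
site needs perfect Watson–Crick complementarity of the seed to the
transcript, and the ungapped duplex around the seed (G:U allowed outside
it) must reach ≤ −12 kcal/mol under the same stack table as the folder;
one pair is kept per (miRNA, transcript).  Externally computed prediction
sets are ingested as pair lists, filtered at the same threshold, and
combined by strict intersection.  Group comparisons (conserved vs
specific vs mock) use per-miRNA target counts and two-sided Welch tests.
Mock miRNAs are uniform-random sequences excluded from sharing a full
sequence or a seed with any known mature; both the 22-nt and 20-nt
variants are supported (the literature uses both lengths), with 22 nt as
the default.

## The synthetic data generator

The generator is the package's study-condition bed: it plants true
hairpins (stems of 19–23 pairs with GC-biased composition so the stack
energy clears −22 kcal/mol with margin, loops of 8–40 nt built from
A/C-only sequence so loops and overhangs cannot compete with the designed
stem, 2-nt 3′ overhangs) and five decoy classes, each violating exactly
one criterion: missing star reads, a second disjoint stem-loop (two
terminal loops), a 16-pair duplex, blunt ends, or Dicer-independent
expression.  Every design is verified against the folding backend at
construction and redrawn if any non-targeted criterion would fail.
Libraries are simulated with Poisson totals split multinomially over read
variants (85 % of reads at the annotated 5′ end, 15 % at +1; three 3′
lengths), a 0.4 star:mature ratio, knockdown scaling of planted arms in
depleted libraries, fully covered 300-nt background blocks (the
negative-control material) and ~2,000 scattered background read positions
whose mass keeps planted miRNA reads a small fraction of each library.
All randomness flows through seeded `numpy` generators; identical seeds
give identical outputs end to end.

What passing tests on this generator do show: the pipeline's decision
logic discriminates each criterion independently at realistic depths and
effect sizes, and the expression machinery is unbiased on null regions.
What they do not show: robustness to sequencing errors, adapters,
multi-mapping repeats, isomiR complexity beyond ±1 5′ wobble, RNA
editing, or cross-mapping between paralogous loci — real libraries are
messier on all of these axes.

## Problem sizes and numerical choices

Default verification scales were chosen to keep the full suite fast on a
laptop-class single core: 10 true + 10 decoy loci on a 60 kb genome at
depth 200 for recovery runs, 20 seeded replicates for the
negative-control baseline, 200 random sequences (≤30 nt) for the folding
oracle and all 2⁷ presence patterns for the Dollo oracle.  All strict
inequalities in the criteria are implemented as stated (a log2FC exactly
at the threshold, a 16-pair duplex, an 18-column alignment and an arm
ratio of exactly 2 all fail).  Floating-point comparisons inside the
folding traceback use a 10⁻⁶ energy tolerance; boundary tests probe
strictness at exactly representable ratios.

## Known limitations

* The internal energy model is a screening heuristic; borderline
  precursors (|ΔG| near 22 kcal/mol) should be re-evaluated with the
  external backend.
* The 5′-homogeneity threshold (0.66) is a package default — the
  underlying protocol names the criterion but no number — and is
  surfaced in the configuration rather than asserted as canonical.
* Read-to-arm assignment is exact-match based (collapsed, error-free
  reads); aligning noisy reads is upstream scope.
* Reciprocal antisense loci are not automatically collapsed into single
  gene records; they must be merged in the input candidate list.
* Dollo mapping assumes the input tree is correct and complete; absence
  in a species is taken at face value even though it may reflect an
  incomplete genome or shallow sequencing.
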