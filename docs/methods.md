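# Methods

## Signature model

`dbcbin` characterizes a nucleotide sequence by a de Bruijn chain (DBC)
signature. The sequence (and its reverse complement — DNA is double
stranded, so composition must be strand-invariant) is scanned for all
order-`k` and order-`(k+1)` words; words never span a non-ACGT character,
because the sequence is first split into maximal A/C/G/T segments
(`sanitize`). The `(k+1)`-word counts define a walk on the de Bruijn graph
of observed `k`-words: the transition probability from word `u` to word `v`
is the count of the `(k+1)`-word `u·last(v)` divided by the total count of
`(k+1)`-words starting with `u`. Nodes are the `k`-words occurring as a
prefix or suffix of a counted `(k+1)`-word; a node with no counted outgoing
edge gets a uniform row.

Two artifacts of this chain enter the signature:

1. **Stationary distribution π.** The raw chain can be reducible (several
   absorbing components), so it is damped: `P ← (1−λ)P + λU` with `U`
   uniform over the *observed* nodes and `λ = 0.01`. Damping over observed
   nodes only — rather than all `4^k` words — guarantees a unique π without
   flooding the signature with words the sequence never contains. π is
   computed by power iteration from the uniform vector, declared converged
   when successive iterates differ by ≤ `tol = 1e-12` in max norm (this
   difference equals the stationarity residual ‖πP − π‖∞ at exit), with a
   10,000-iteration cap that raises rather than silently truncating. Power
   iteration was chosen over an eigensolver for determinism: no dependence
   on eigenvector sign/phase or LAPACK ordering conventions; the dense
   eigendecomposition is retained as an independent oracle in the tests and
   the acceptance script (agreement is ~1e-12, far inside the 1e-8 check).

2. **Connectivity weights w.** Strongly connected components are computed
   on the undamped counted-edge graph (scipy's `csgraph`); each node's
   weight is its component's share of the total `(k+1)`-word count mass.
   This captures how strongly each part of the graph is tied into the walk:
   repeat-driven or low-complexity subgraphs that trap the damped chain get
   discounted by their actual mass share.

The signature entry for an observed word `u` is `π(u)·w(u)`, embedded at
`u`'s lexicographic index (A<C<G<T) in a `4^k` vector, zeros elsewhere,
renormalized to sum to 1. When the graph is a single component (`w ≡ 1`)
the signature reduces to π itself. The exact historical combination of
these ingredients was never published alongside the method; the `π·w`
product is this package's reconstruction, chosen because it uses exactly
the two named artifacts and degrades gracefully to π. Signatures of a
sequence and its reverse complement agree entrywise to 1e-12 by
construction (identical strand-symmetric count tables).

Sequences with no segment of length ≥ `k+1` have no chain; they raise
`UnsignableSequenceError` and the classifier routes them to an explicit
`unbinned_unsignable` status so input counts are always conserved.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 3 | word length of the signature (2–4 typical; vector length `4^k`). k=3 balances resolution against the `64×64` chain size and trains well from a few kb. |
| `λ` (damping) | 0.01 | uniform mixing over observed nodes; any positive value yields uniqueness, 0.01 perturbs π by ≲1% while keeping power iteration fast. |
| `tol` | 1e-12 | power-iteration convergence in max norm. |
| `metric` | euclidean | distance between signature vectors; cosine available. |
| `min_length` | 1,000 bases | contigs below this are not binned (short contigs carry too little compositional signal). |
| `max_distance` | disabled | nearest-centroid distance cut-off; see calibration below. |
| `report_top_n` | 2 | ranked bins reported per contig, supporting best-two-bins scoring. |
| `min_train_length` | 1,000 bases | training sequences below this are skipped (with a logged count). |

A bin centroid is the **unweighted** mean of its members' signatures. The
plain mean treats each training sequence as one observation of the taxon's
composition; a length-weighted mean (exposed via `length_weighted=True`)
would instead approximate the signature of the pooled sequence and lets one
long replicon dominate.

Ties in centroid distance break lexicographically on bin name, so repeated
runs are byte-identical.

### Distance-cutoff calibration

The distance cut-off that defines negatives is data-dependent and is not
hard-coded. `calibrate_distance_cutoff` takes a freshly trained library and
returns a quantile (default 0.99) of all member-to-own-centroid distances:
queries farther than essentially every training member was from its own
centroid are plausibly from taxa the library does not cover. The
acceptance script uses this calibration for the withheld-taxon specificity
measurement.

## Evaluation conventions

Per contig: **tp** — its true bin is among its best `top_n` ranked bins;
**fn** — a trained bin exists for it but it is unbinned *or* its true bin
is absent from the top `top_n` (a wrong call is a missed positive, matching
the sensitivity denominator "contigs for which bins existed"); **tn** — no
trained bin exists and it was left unbinned; **fp** — no trained bin exists
but it was binned anyway. Sensitivity = tp/(tp+fn), specificity =
tn/(tn+fp); a zero denominator reports `n/a`, never 0 or 1. Rank-level
scoring (genus calls scored at class level, etc.) is done by mapping bin
names through a label table before comparison.

`sweep_cutoffs` evaluates a grid of (min_length, max_distance) pairs,
computing each contig's signature and centroid distances once. Each length
grid point defines the *candidate pool* — the run "bins all contigs longer
than L" and contigs below L are excluded from that grid point's evaluation
rather than counted as false negatives — while the distance cut-off
determines negatives within the pool. This matches how length-restricted
binning runs are reported in practice and makes sensitivity across length
cut-offs measure per-contig signal, not pool composition.

## Synthetic data

The simulator emulates the assumptions the binner relies on: each taxon has
a homogeneous compositional fingerprint, distinct between taxa. A family of
order-`m` Markov models (default `m = 3`, so signature orders 2–4 straddle
the generative order) shares one smooth Dirichlet base table; each model
mixes in its own spiky Dirichlet preference table with weight
`separation ∈ [0,1]`. Separation 0 gives identical models; the
total-variation distance between corresponding rows grows linearly in
separation, so one knob controls difficulty. Contig lengths are drawn
log-uniformly (default 1–20 kb), echoing the length skew of real
assemblies. One seed fans out through `SeedSequence` spawning, so adding a
model or a contig never shifts the others.

What the simulator does **not** emulate: sequencing error, chimeric or
misassembled contigs, strain-level mixtures, horizontal transfer, GC skew
along replicons, repeat structure, or conserved genes shared across taxa.
Passing tests therefore demonstrate that the method recovers compositional
structure when it exists and that the machinery is numerically correct —
not that any particular sensitivity will be achieved on a real metagenome,
where inter-taxon composition overlaps far more than at the separations
used here.

## Problem sizes and numerical choices

The test suite and acceptance script run, per invocation: 100 random
chains for the stationarity oracle (k ∈ {2,3,4}); 50 sequences × 3 orders
for strand invariance; 3 models × 200 fragments (1–20 kb) at separation
0.6 for the conservation property; 5 models × 200 query contigs at
separation 0.8 — trained on 30 held-out fragments per model from the
disjoint half of each 600 kb genome — for end-to-end sensitivity and
withheld-taxon specificity; and a 20,000-contig batch against a 10-bin
library for throughput. These sizes keep a full run in well under a minute
on one core while leaving every measured quantity stable across seeds.

Degenerate inputs are handled explicitly rather than silently: empty FASTA
files, duplicate ids, sequence before a header (all with line numbers),
all-ambiguous sequences, empty count tables, empty libraries, undefined
ratios, and top-n requests exceeding the ranked list all raise.

## Known limitations

* The `π·w` signature formula is a reconstruction (see above); absolute
  distance values are not comparable to other DBC implementations.
* Centroids are per-sequence means; a taxon trained from one short contig
  gets a noisy centroid, and nothing currently down-weights such bins.
* Classification is flat (one library, one rank); hierarchical cascades
  across ranks must be composed manually via taxon-label mapping.
* Loaded libraries store centroids only, so distance-cutoff calibration
  requires a freshly trained library.
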