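# Methods

## The per-site consistency index

Given a rooted phylogeny and a matching nucleotide alignment, every
alignment column is scored independently. Each tip carries a character
set: the IUPAC expansion of its nucleotide (`A`→{A}, `R`→{A,G}, …,
`N`→{A,C,G,T}; `U` is read as `T`). Gaps are treated exactly like `N`
— fully ambiguous — rather than as a fifth state: indels are not
substitutions, and letting a gap join any resolution means missing data
can only lower, never raise, a site's change count (a property the test
suite asserts).

A single post-order pass then computes the site's minimum number of
state changes ℓ (its parsimony tree length). At each internal node the
children's sets are folded left to right in input order: the running
set is replaced by its intersection with the next child's set when that
intersection is non-empty, otherwise by the union, and each union step
increments ℓ. On binary trees this is the classic Fitch count and is
provably minimal; the suite verifies it against an independent
brute-force oracle that enumerates every assignment of one nucleotide
per internal node (feasible to 12 tips; 1000 random instances with
ambiguity codes included).

On a multifurcation the left-to-right fold is *not* the multifurcating
tree's own minimum: it is exactly the Fitch score of the node's
ladderized binary resolution in child order, and since contracting
edges can only raise a parsimony score, the fold can undercount the
multifurcation's true minimum (star tree with tip sets {A},{A},{C},{C}:
fold 1, true minimum 2) but never overcount it. Hartigan's algorithm
would be exact there; the fold was kept because it matches the
two-child description the consistency-index literature uses, input
polytomies are rare in the rooted, resolved trees this tool targets,
and an undercount can only make flagging more conservative. The tests
pin both properties (equality on the ladder resolution, ≤ on the
polytomy).

With *s* the number of distinct unambiguous nucleotides at the site
(ambiguous tips contribute to the downpass sets but not to *s*), the
consistency index is CI = (s − 1)/ℓ for s ≥ 2, and CI = 1 for invariant
or all-ambiguous sites, which are never flagged. s − 1 is the number of
changes a best-case tree would need, so CI ∈ (0, 1], CI = 1 iff the
site is perfectly consistent, and a site is flagged iff CI < 1. The
index is sometimes stated in the inverted orientation ℓ/(s − 1); the
orientation used here is the standard one under which "CI < 1 ⇒
homoplasious" holds.

Outputs are 1-based everywhere users see positions. The annotated tree
marks each internal node at which the fold took a union step for a
flagged site with that site's position(s), as a `[&homoplasy=…]`
comment placed immediately after the node's closing element — the
placement FigTree, icytree and ape re-attach to the correct node.
Because sites are scored independently, removing flagged columns
cannot change the score of the remaining columns, so running the
detector on its own filtered output flags nothing (asserted in the
suite).

### Numerical and degenerate cases

- ℓ = 0 with s ≥ 2 is impossible by construction; the code raises
  rather than returning an undefined CI.
- Unary internal nodes in input Newick are spliced out with branch
  lengths summed; they carry no parsimony information.
- A filtered alignment with zero remaining sites is written (with a
  warning), not refused, so pipelines survive pathological inputs.
- Label matching between tree and alignment is exact string equality
  (after Newick quote handling); any mismatch aborts with the
  symmetric difference of the two label sets.

## The validation simulation

The simulator is a discrete-time stochastic susceptible–infectious
process in a closed population of 200, seeded with one infected
individual. Per time-step, in order: each susceptible is infected with
probability 1 − (1 − β)^I (β = 0.001 per infected–susceptible pair,
I = current infected count), copying the genome of a uniformly chosen
infector; every infected individual (including this step's) gains
Poisson(0.5) mutations; each infected individual is sampled — removed
and its sequence recorded — with probability 0.05. The run stops at 100
samples; an epidemic that dies out first is discarded and restarted
with a fresh seed-derived stream (bounded retries). These parameter
values are the study conditions, not tuning knobs.

Mutation uses an infinite-sites representation: every mutation event
creates a new registry column, ancestral allele drawn uniformly from
{A,C,G,T} and derived allele uniformly from the other three; sampled
genomes are realised against the full registry at the end. Under
infinite sites each derived allele arises exactly once, so every
polymorphic column is perfectly consistent with the true transmission
genealogy — `true_transmission_tree` builds that genealogy from the
recorded who-infected-whom chain, and the suite asserts zero flags on
it. A typical run yields on the order of 1000–3000 polymorphic
columns across the 100 samples.

Trees are rebuilt from alignments by neighbor joining on pairwise
Hamming distances (sites with an ambiguous member skipped pairwise),
with negative branch lengths clamped to zero and midpoint rooting.
NJ was chosen as the built-in rebuilder to keep the harness fast and
self-contained; it is a stand-in for maximum-likelihood reconstruction,
and the experiment runner accepts an external tree file so users can
substitute an ML tree. NJ is exact on additive distance matrices
(asserted in the suite); on simulated data its trees are slightly
noisier than ML ones, which if anything depresses detection rates, so
headline numbers are checked as a band rather than a point.

### Inserting known homoplasies

Per insertion, two internal, non-root clades *i*, *j* with disjoint tip
sets are drawn; a site is selected (without replacement across
insertions) at which *i*'s tips are monomorphic for an allele found
nowhere else; that allele overwrites the site in *j*'s tips. One
tightening beyond plain non-nestedness is applied: the union of the two
clades' tip sets may not be separable by a single edge of the tree
(donor and recipient may not be sibling clades under a binary parent,
nor jointly cover everything outside one clade). Without it the
inserted allele can occupy a *convex* tip set — one change explains it,
the site's CI stays 1, and the insertion is not a homoplasy on the very
tree it was built against. With it, detection against the pre-insertion
tree recovers every inserted site, a guarantee the suite asserts at
100 % over 50 replicates. Recombination donors/recipients keep the
plain non-nested rule, since no such guarantee rides on them.

Recombination is emulated per event by overwriting a random contiguous
100 bp region of a recipient clade with the donor clade's per-site
consensus (majority among A/C/G/T, ties broken in A<C<G<T order;
all-ambiguous columns left untouched).

### The detection experiment

Per replicate: simulate an outbreak; build the NJ tree from the clean
alignment; insert k homoplasies (k drawn uniformly from 0–100 unless
fixed in the configuration); optionally apply recombination events;
rebuild the tree from the modified alignment; run detection; score the
proportion of inserted positions flagged and count flagged-but-not-
inserted positions as false positives. Replicates with k = 0 have no
defined proportion and are excluded from the mean and quantiles but
still contribute false-positive counts. Each replicate draws all its
randomness from a stream derived from (master seed, replicate index),
so runs are reproducible and order-independent.

The headline statistics — reproduced from scratch by
`scripts/acceptance.py` — are computed over 200 replicates, which keeps
the full experiment under a minute on one CPU while leaving the
quantile estimates stable to within a point or two across master seeds.
The unit-test suite additionally runs shrunken configurations (40–60
individuals, 12–20 samples) where a single replicate is milliseconds.

## What the simulation does and does not show

The generator produces clonally evolving, completely sampled-or-not
sequences with no rate heterogeneity, no back mutation, no indels, no
sequencing error, and mutation counts that are honest Poisson draws.
Passing its tests shows the detector recovers homoplasies whose origin
is known with certainty, and that detection degrades exactly as
expected when recombination scrambles the signal (non-increasing in
the number of events; asserted with a one-sided rank test). It does
not show robustness to alignment error, model misspecification in tree
building, or recurrent mutation at genuinely fast sites — on real data
those appear as flagged sites whose interpretation is up to the user.
Detection is also inherently circular: the tree used to find
homoplasies is built from the sequences that contain them, so inserted
homoplasies that end up adjacent on the rebuilt tree are undetectable
in principle, which is why the observed detection rate sits near, but
not at, 100 %.

## Known limitations

- Polytomy scores are ladder-resolution scores (see above), a
  conservative lower bound on the multifurcation's own minimum.
- The consistency index flags recurrent *patterns*; it cannot say
  whether a flagged site is convergence, recombination or error, and
  heavy recombination should be handled before tree building, not by
  this tool.
- Input trees are used exactly as rooted in the file; no re-rooting.
- Nucleotide data only: no protein alphabets, NEXUS/PHYLIP, or
  multi-tree files.
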