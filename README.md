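# homoplasy

Identify homoplasious sites in a nucleotide alignment against a rooted
phylogeny, using the per-site consistency index.

A homoplasy is an identical nucleotide shared by taxa through something
other than descent — convergent evolution, recombination, or sequencing
error. Such sites contradict the tree and, in number, can distort it.
This package takes a rooted Newick tree and a FASTA alignment whose
labels match the tree's tips, scores every alignment column, and
reports the columns that cannot be explained by a single origin on the
tree. It is aimed at people analysing densely sampled pathogen
whole-genome data (transmission studies, outbreak phylogenetics), where
flagged sites usually mean either interesting biology or a filtering
problem, and either way should be looked at before the tree is
interpreted.

## The statistic

For each alignment site, a Fitch-style set downpass computes the
minimum number of state changes the tree needs to explain the tip
nucleotides (the site's parsimony *tree length* ℓ): tips carry the
IUPAC expansion of their character as a subset of {A,C,G,T}, and each
internal node takes the intersection of its children's sets when that
is non-empty, otherwise their union, counting one change per union.
With *s* the number of distinct unambiguous nucleotides observed at the
site, the consistency index is

    CI = (s − 1) / ℓ,

the ratio of the fewest changes any tree could need to the changes this
tree needs. CI = 1 means the site is perfectly consistent; CI < 1 flags
it as homoplasious. Invariant sites (s ≤ 1) are defined as CI = 1.
Ambiguous characters (`N`, IUPAC codes, `-`) join whichever resolution
is cheapest and never create spurious flags.

The package also contains the validation harness used to demonstrate
that this works: a discrete-time outbreak simulator whose sequences
evolve under an infinite-sites model (so the clean data contain no
homoplasies by construction), procedures that insert known homoplasies
and recombination events into the simulated alignments, a
neighbor-joining tree rebuilder, and an experiment runner that scores
how many inserted sites are recovered.

## Worked example

A quartet tree `((A,B),(C,D));` and ten sites, one of which (position
4) has pattern A/T/A/T — the same substitution on two unrelated
branches:

```
$ homoplasy detect --fasta aln.fasta --tree tree.nwk --out-dir results
10 sites scanned, 1 inconsistent
```

`results/consistency_report.csv`:

```
Position,ConsistencyIndex,MinimumNumberChangesOnTree,CountsACGT
4,0.5,2,2:0:0:2
```

Position 4 needs ℓ = 2 changes for s = 2 observed nucleotides
(2 A's and 2 T's, the `CountsACGT` column), so CI = (2−1)/2 = 0.5 < 1
and the site is flagged. `results/annotated_tree.nwk` marks the
internal nodes where the downpass had to place a change, in a comment
dialect FigTree/icytree/ape can display:

```
((A,B)[&homoplasy=4],(C,D)[&homoplasy=4]);
```

and `results/filtered_alignment.fasta` is the input alignment with the
flagged column removed (9 sites). Add `--includeConsistent` to get a
report row for every site. The same pipeline is available as library
calls (`homoplasy.find_homoplasies(tree, alignment)`).

The simulation study runs from the CLI too:

```
$ homoplasy simulate --replicates 200 --seed 1 --out summary.csv
200 replicates: mean detection 98.8% (2.5%: 93.3%, 97.5%: 100.0%), 199 scored
```

Each replicate simulates an outbreak (200 individuals, infectiousness
0.001 per infected–susceptible pair per step, Poisson mutation mean
0.5 per sequence per step, sampling probability 0.05, run until 100
samples), inserts a uniform-random 0–100 known homoplasies, rebuilds
the tree from the modified alignment, and reports the proportion of
inserted sites recovered. The numbers above say the detector recovers
on average 98.8 % of the homoplasies it was asked to find, with 95 % of
replicates between 93.3 % and 100 %.

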