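# Methods

## The problem

Short-read RNA-seq assemblers reconstruct transcript isoforms from spliced
alignments against a reference genome. Every spliced aligner makes
systematic mistakes: some true junctions are never reported (missed
splice sites), some reported junctions are artifacts (mismapping around
repeats, sequencing error near splice sites). An assembler working from a
single aligner's BAM inherits those mistakes. spliceweave instead takes
one coordinate-sorted SAM/BAM *per aligner* for the same sample and
reconciles them: junctions reported concordantly by every aligner are
treated as high-confidence, aligner-specific junctions as low-confidence,
and the path search is steered accordingly.

## Model

### Per-aligner splice graphs

Reads from all inputs are clustered into gene loci: maximal regions in
which the union of read blocks and spanned introns is connected; a single
uncovered, unspanned base ends a locus. Junction strand comes from the
XS tag; a locus takes the majority strand of its junction reads and is
split by strand only when the two strands' junction sets are disjoint.

Each locus is segmented into partial exons by cutting the cross-aligner
union coverage at every aligner's splice sites ({donor+1, acceptor}
positions). Using one shared boundary set for all aligners is what makes
the later merge an exact interval match. Per aligner, a DAG is built on
these segments:

- **node weight** — average per-base coverage from that aligner's reads
  (each mate counted, deletions covered, introns not), with a read
  reported at N sites (`NH:i:N`) contributing 1/N everywhere;
- **junction edges** — weighted by summed 1/N support of spanning mates;
- **adjacency edges** — between genomically contiguous segments, weighted
  by reads whose single block spans the shared boundary. The underlying
  graph model has one edge per splice junction; adjacency edges are our
  addition, without which no path could traverse an internal alternative
  splice site that cuts an exon into two segments. They are weighted,
  filtered, and labeled exactly like junction edges.

Five pruning criteria then run once each, in order: (1) edges with weight
< 1; (2) at nodes with at least two out-edges (resp. in-edges), any such
edge below 10% of the node's total out- (in-) weight; (3) out-edges below
3% of the node's total in-weight, and symmetrically; (4) edges below 2%
of the graph's mean edge weight, the mean taken as the graph stands
entering this criterion; (5) isolated nodes with weight < 10. All
comparisons are strict, so a weight exactly at a threshold survives.
Filtering is applied per aligner, before merging.

### The labeled splice graph

The N filtered graphs of a locus are merged by node/edge union. Each
edge gets a label recording cross-aligner agreement:

- **1** — absent from at least one aligner's graph;
- **2−** — present in all N graphs but with differing supporting-read
  sets (read identity compared by query name + mate flag);
- **2+** — present in all N graphs with identical read sets.

Weights are arithmetic means over the graphs in which the element
appears (not divided by N): dividing by N would silently halve a
filtered-through junction that only one aligner reports, which is
precisely the signal worth keeping at its observed strength. With N = 1
every edge is trivially 2+ and merging is the identity.

### Labeled paired paths

Each mate is projected onto the merged graph: the projection exists iff
the read's junctions are edges of the filtered graph, within-block
segment transitions are adjacency edges, and internal nodes are covered
end-to-end. Mate paths p1 (k nodes) and p2 (q nodes) join through a
shared terminal sub-path of s nodes when that sub-path contains at least
one edge (s ≥ 2) and the union has k + q − s ≥ 3 nodes. Joined paths are
deduplicated per aligner; coverage is the summed 1/N of generating
fragments (1/max(nh1, nh2) when mates differ). The per-aligner sets are
unioned into PP_L and labeled by the same rule as edges, with fragment-id
sets in the role of read sets and coverage averaged over appearing
aligners.

A consequence worth stating: a mate pair with a positive inner gap can
never satisfy the shared-edge requirement, so paired paths only arise
from overlapping mates (fragment length < 2 × read length) whose overlap
spans a junction, or from reads bridging two junctions across a short
exon. The rule is implemented as written; libraries with long inserts
will simply drive the assembler from edge seeds.

### Label-prioritized bottleneck extraction

Transcripts are extracted iteratively:

1. **Seed.** The highest-priority unused seed: paired paths labeled 2+,
   then 2−, then edges 2+, then 2−, then label-1 paths or edges together;
   within a class, largest weight, ties broken toward more nodes, then
   leftmost coordinate.
2. **Subgraph.** The seed plus everything co-reachable to its first node
   and reachable from its last node; synthetic origin/destination nodes
   attach to sources/sinks with ∞-weight, label-1 connectors.
3. **DP.** Edges are numbered by topological order (source index, target
   index). With m, n the seed's first/last edges, Exp_m = Exp_n = cov(S).
   Forward, for i = n+1…N: the predecessor i′ is chosen among the
   in-edges of i's source restricted to {n} ∪ already-assigned edges, by
   label class (2+ > 2− > 1) and then largest Exp; Exp_i =
   min(weight(i), Exp_i′). The backward pass mirrors this with Suc.
   Traceback starts at the destination (origin) connector with the
   largest Exp — ties by label class, then smallest edge id — and follows
   Pre (Suc) to the seed. Restricting predecessors to assigned edges is
   our resolution of an under-specified corner: the nominal ∞
   initialization of unassigned edges would admit tracebacks that never
   reach the seed.
4. **Update.** f_min, the minimum real-edge weight on the extracted path,
   is subtracted from its edges; edges hitting zero are relabeled 1;
   path edges are marked covered, and paired paths contained contiguously
   in the path are marked used.

The loop runs until no unused paired path and no uncovered edge remains
(an uncovered edge is always an available seed, so this implies full
edge coverage). Each iteration consumes at least its own seed, bounding
iterations by |E| + |PP|; a hard cap of |E| + |PP| + |V| turns
non-progress into an error rather than silent truncation. Duplicate node
sequences are emitted once. Isolated nodes that survived criterion 5 are
emitted as single-exon transcripts.

When every edge shares one label, the DP is the classic maximum-
bottleneck path computation on a DAG, exact for paths through the seed;
the test suite checks this against exhaustive path enumeration on
hundreds of random DAGs. With mixed labels the label class overrides the
bottleneck bound, trading expression for cross-aligner reliability.

### Output

Consecutive path nodes joined by adjacency edges merge into exons;
junction edges become introns. Transcripts shorter than
`--min-transcript-length` (default 200 nt of exonic sequence, mirroring
common assembler defaults) are suppressed. GTF output carries
`gene_id locus.K`, `transcript_id locus.K.M`, and `cov` = f_min, ordered
deterministically by (chrom, start, transcript id); repeated runs are
byte-identical.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `--min-junction-weight` | 1.0 | criterion 1: absolute edge support |
| `--branch-ratio` | 0.1 | criterion 2: minor-branch fraction at a node |
| `--cross-ratio` | 0.03 | criterion 3: out-edge vs total in-weight |
| `--mean-ratio` | 0.02 | criterion 4: fraction of mean edge weight |
| `--min-single-exon-cov` | 10.0 | criterion 5: isolated-node coverage |
| `--min-transcript-length` | 200 | exonic nt below which output is suppressed |

The five filter defaults are the method's published operating point; the
pipeline exposes them because depth and library type shift what
"relatively low weight" means.

## The synthetic-data generator

`spliceweave.simulate` emulates the two-aligner study design at desk
scale. `make_truth` builds loci of 5–7 backbone exons (100–250 nt,
introns 250–1100 nt) with one alternative-splicing region per locus
placed at least two exons from either end; the 1–4 isoforms per locus
are drawn from a variant menu (plain, skipped exon or extended 5'
donor, alternative exon, short exon followed by the alternative exon).
Per-locus totals are log-uniform (≈32–80 expected fragments per kb unit
of depth) and isoform shares are drawn in [0.7, 1] before normalisation,
so no isoform falls below ~19% of its locus. These choices are load-
bearing: they guarantee by construction that every true junction clears
the relative-weight filters at the default depth, and that every maximal
path in the true splice graph is a true chain. The event regions sit
deep enough in the transcript that both mates' spanning windows cover
their junctions.

`simulate_fragments` samples fragments per transcript proportional to
expression × length (depth = fragments per kb per expression unit,
default 10), with stratified starts so junction-spanning counts are
stable. The default geometry is a short-insert library: 220 nt fragments
read as 2 × 150 nt, giving an 80 nt mate overlap so that paired paths
actually form (see above). `emulate_aligner` writes a valid
coordinate-sorted SAM per aligner profile: junction dropout removes the
whole mate pair when either mate spans a designated junction (the
missed-junction failure mode of real mappers); read-set jitter renames a
fraction of junction fragments with an aligner-specific suffix, forcing
2− labels on shared junctions; multi-mapping duplicates a fraction of
fragments to a decoy region with NH=2 on all records. Sequence content
is never consulted downstream, so SEQ fields are N-runs of correct
length.

What the generator does **not** model: sequencing errors, base
qualities, indels, coverage biases (GC, 3' end), intron retention,
overlapping genes, or multi-event isoform combinatorics within one
locus. Passing the recovery tests therefore demonstrates correctness of
the graph/label/DP machinery under clean, identifiable conditions — not
performance on real libraries, where mosaic paths across independent
alternative events are a genuine failure mode of any bottleneck-style
extractor.

## Evaluation

`intron_chain_match` scores a predicted GTF against a reference: a
multi-exon prediction is correct iff its ordered intron chain matches a
reference transcript exactly (chromosome and, where both are stranded,
strand); precision = correct/predicted, recall = matched/reference,
F = 2pr/(p+r), all on the multi-exon sets. Single-exon predictions are
scored separately by ≥ 80% reciprocal overlap and excluded from the
headline counts.

## Numerical choices and degenerate inputs

- Weights are floats; an edge is "zero" below 1e-9 and is then clamped
  and relabeled.
- All orderings (node, edge, seed, traceback ties) are resolved by
  genomic coordinate, making the whole pipeline deterministic; the CLI's
  `--seed` is reserved for any future randomized tie-breaking and is
  unused by default.
- Empty inputs: a header-only SAM is an empty stream; a locus with no
  surviving nodes yields no transcripts; an empty transcript list yields
  a header-only GTF.
- Mates of a fragment falling into different loci are treated as two
  single-end reads for weighting and never form paired paths.
- Unknown CIGAR opcodes skip the record with a warning; unsorted input
  and a missing sequence dictionary abort with explicit errors.

## Known limitations

- No annotation-guided mode and no long-read support.
- f_min is a bottleneck residue, not an abundance estimate; transcripts
  extracted late in the loop can report cov near 0.
- Filters are single-pass by design; filtering is not idempotent.
- The locus-strand majority vote can misassign antisense single-exon
  fragments inside a stranded locus.
- Problem sizes in the tests and the acceptance script (loci per truth
  set, depth, DAG sizes for the DP oracle) are chosen so the full
  validation runs in seconds on one core; they are desk-scale stand-ins
  for the multi-million-read experiments the method targets.
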