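# Methods

This note documents the models, rules and numerical choices behind
`mirscout`, what the synthetic data does and does not emulate, and the known
limitations.

## The precursor model

`mirscout` targets *canonical* miRNA precursors: ~60–200 nt RNAs whose MFE
structure is a single stem-loop, with the mature miR excised from one arm
and its partner miR\* from the opposite arm, both clear of the hairpin loop.
Everything the filters test follows from this model; families with atypical
biogenesis (loop-derived matures, branched precursors, repeat-derived
families) are expected to be rejected and must be curated by hand.

## Coordinates

All internal coordinates are 0-based half-open with explicit strand.
Conversion to/from the 1-based inclusive conventions of GFF3 and the engine
reports happens only in `formats_io`; minus-strand engine hits (reported
with from > to) are flipped at parse time. This keeps three engine dialects
from drifting off by one.

## Homology filters

| Filter | Default | Applies to | Boundary |
|---|---|---|---|
| E-value | ≤ 0.01 | all engines | inclusive |
| HSP length | ≥ 20 nt | blast | inclusive |
| Coverage | ≥ 0.70 | blast (query), cm (model) | inclusive |
| Bitscore | > log₂(2N) | cm | strict |
| nBit = bitscore/ge | ≥ 0.32 | cm rescue | inclusive |
| Candidate cap | 100 per family | merged regions | bitscore ties → lower E-value → genomic order |

N is the genome size (total target length unless overridden); ge the
family's curated gathering cutoff. The HMM path relies on the engine's own
inclusion threshold plus the E-value cut; no coverage test is applied
there. Coverage needs the query/model length, which blast's tabular output
does not carry: parsers accept an id → length map and leave coverage
unevaluable (`None`, treated as passing) when the length is unknown.

Regions are formed by transitive closure of ≥ 1 nt overlap (same sequence,
strand and family, half-open semantics, so abutting intervals do not
merge); the result is independent of input order. Opposite-strand
overlapping regions of one family are resolved lexicographically by
(higher bitscore, lower E-value, higher coverage); an exact tie keeps the
plus strand and logs a warning. The loser is reported, not deleted.

## Mature placement

Each family mature is aligned semi-globally (mature end-to-end, free end
gaps on the precursor) with +1/−1/−2 scoring. The score floor of
0.6 × mature length is an implementation choice exposed in config, as is
the scoring triple. The best-scoring mature becomes the anchor; among
equal-scoring placements the 5'-most wins (deterministic tie-break).
A second, non-overlapping mature on the opposite arm becomes the miR\*;
otherwise the miR\* window is predicted as the base-paired partner region
of the miR in the MFE structure (windows that straddle the miR in badly
distorted folds are rejected). Precursors are trimmed to the miR/miR\*
span plus a 10-nt flank (flank size is a config choice; with no miR\* the
span reaches 70 + flank nt toward the predicted opposite arm).

## Arm-consistency rule

The check counts hairpin loops *between the 5'-most and 3'-most mature
boundaries*: exactly one is required (zero means both matures sit on one
arm; two or more means the region branches into a multi-loop). Neither
mature may reach more than 3 nt into that loop — Drosha/Dicer processing
is not nucleotide-exact, so a strict 0 would reject valid annotations
(tolerance configurable). Structure outside the miR/miR\* span is ignored:
trimmed precursors retain ~10 nt genomic flanks, and a spurious 3-bp flank
hairpin must not disqualify a genuine stem-loop. When no miR\* is known the
whole structure must be a single hairpin.

## Folding

MFE folding delegates to a pluggable engine; the default is the ViennaRNA
bindings (37 °C, default parameters, strand-specific), and an adapter for
any RNAfold-compatible command line is provided. Results are cached by
sequence. The MFE filter accepts `mfe ≤ −10.0` kcal/mol — the boundary is
applied inclusively, with a config switch for strict comparison.

## Consensus comparison and tree edit distance

Structures are encoded as ordered trees: each base pair an internal `P`
node containing its enclosed region, each unpaired base a `U` leaf, all
under a virtual root `R`. Full expansion makes the distance sensitive to
bulge and loop size changes, the scale on which the ted ≤ 7 threshold
operates. The distance is the Zhang–Shasha ordered tree edit distance with
unit costs (insert = delete = relabel = 1), implemented with a numba-jitted
dynamic program and cross-checked in the test suite against an independent
memoized brute-force recursion.

The family consensus is computed from the alignment's SS_cons anchor
pairs: duplicate rows are collapsed, and a pair survives iff every
distinct row with non-gap bases at both columns can form a Watson–Crick or
G-U pair (support fraction configurable, default 1.0). Two properties
motivated this rule over a simple ≥ 50% majority: collapsing duplicates
makes re-adding an exact copy of a family member provably a no-op (ted 0),
and the all-rows requirement makes the consensus sensitive to a *single*
disruptive candidate among several family rows — with a 50% majority, one
bad row among five members can never move any pair, and the conformance
test would pass garbage. The candidate row is placed by global alignment
against the column-majority sequence; candidate bases falling into
insertions relative to the column system are dropped, so both consensus
strings share the alignment coordinates (a documented approximation — a
covariance-model alignment adapter can replace it). The augmented
consensus is *valid* if it still contains a hairpin and retains ≥ 50% of
the default consensus pairs.

## Decision cascade

Discard if: placement failed (`no mature anchor`), length > 200 nt,
MFE above threshold, or arm verdict ≠ valid — in that order, so every
discarded candidate carries the first failing filter as its reason.
Otherwise accept with confidence **High** iff the augmented consensus is
valid and ted ≤ 7, else **Medium**. Medium therefore records, by
definition, a consensus-conformance failure; analyses that ask whether a
candidate "passes the full cascade" (e.g. the mutation series) count only
High.

## Synthetic worlds

`make_hairpin` builds stem + loop + reverse-complement(stem) with ~10%
G-U wobbles, ~8% internal mismatches and occasional 1-nt bulges on the 3'
arm, then folds and re-draws (bounded) until the result is a single valid
hairpin with MFE ≤ −10. The perturbations matter: a perfect-complement
stem folds near −0.77 kcal/mol/nt and shrugs off heavy mutation loads,
whereas genuine precursors sit near −0.3 to −0.6 kcal/mol/nt and lose
their structure under 10–20% point mutations — the behaviour the imperfect
stems reproduce. The miR is the 22-nt window 2 nt into the 5' arm; the
miR\* is its base-paired window on the 3' arm.

Families are five siblings of the base hairpin (3 substitutions each),
each validated to be a placeable, foldable precursor — emulating curated
alignments, which contain genuine family members; SS_cons is the
construction structure. Decoys are dinucleotide shuffles (Altschul–Erikson
Eulerian-walk shuffle) of the implanted hairpins: same composition,
structure destroyed. Worlds also emit pre-computed blast-dialect hit
tables covering truth *and* decoy loci — the over-sensitive-homology
scenario in which structural filters, not sequence similarity, must reject
the decoys (a blastn run would never surface a shuffled decoy in the first
place). Background sequence is i.i.d. uniform; decoy hardness comes from
the shuffled hairpins, not from background composition (a documented
limitation — no repeats, no isochores, no Markov structure). All
randomness flows from one numpy PCG64 generator, so a fixed seed
reproduces a world byte for byte.

Passing tests on these worlds show that the cascade recovers planted
canonical precursors and rejects composition-matched non-structures; they
do not show performance on real genomes, where repeat-derived families,
atypical precursors and annotation ambiguity dominate the error budget.

## Problem sizes

The shipped validation runs use a 1 Mb genome with 20 implanted precursors
and 20 decoys for the end-to-end study, 24 independent precursors × 3
mutation loads for the mutation series, and 500–1000 random tree pairs for
the oracle comparison — sizes at which every quantity is stable across
seeds while the whole suite completes in well under a minute.

## Known limitations

- The mature-anchoring stage is a deliberate simplification of full
  family-alignment correction pipelines; its acceptance surface is
  behavioural (correct placements on known truth), not bit-compatibility
  with any external tool.
- The fallback consensus rule evaluates only SS_cons anchor pairs; pairs
  a candidate might *add* are invisible to it (a CM/alignment-folding
  adapter removes this blind spot).
- cmsearch is consumed only through its tabular output; the pipeline does
  not build or calibrate covariance models.
- No pseudoknots, no partition-function folding, no suboptimal structures.
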