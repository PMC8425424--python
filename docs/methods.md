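# Methods

## Model

A chain file describes a pairwise alignment between two genome builds as a
set of scored *chains*; each chain is an ordered run of ungapped aligned
blocks separated by gaps on the source ("target"/`t` in UCSC terms) and/or
destination ("query"/`q`) sequence. All internal coordinates are 0-based
half-open; chain files are already in that convention and are stored
verbatim, including reverse-strand destination coordinates on `-` chains
(the forward-strand position of a point is recovered as
`dest_size − raw − 1` at the lifting layer). VCF positions (1-based) are
converted only at the VCF module boundary.

Within one aligned block the lift is affine with slope +1 (`+` chains) or
−1 (`-` chains). The forward and reverse chain sets therefore induce two
piecewise affine partial maps `f` and `g`; a source position `x` is

- `Reject_1` when `f` is undefined at `x` (outside all chains, inside a
  chain gap, or an unresolved tie — see *Ambiguity* below);
- `CHR_Jump_1` when `f(x)` lies on a different chromosome, where "different"
  means the normalized name differs **or** the destination is not in the
  scanned chromosome set (unlocalized/unplaced/alternate contigs are valid
  destinations but always count as jumps);
- `Reject_2` / `CHR_Jump_2` / `POS_Jump` by the same tests applied to
  `g(f(x))`;
- `Stable` iff `g(f(x)) = x`.

The order of the tests is fixed and the categories are mutually exclusive;
in particular a base whose back-conversion lands on the wrong chromosome at
the wrong offset is counted once, as `CHR_Jump_2` — the wrong chromosome is
the stronger and earlier observation.

### Scan modes

`per_base` applies the classifier to every position; it is the reference
semantics and is used directly on toy genomes and in cross-checks.
`interval` resolves each source chromosome into maximal intervals carrying
a single affine outcome (an elementary-interval sweep over all block
spans, with overlap resolution identical to the per-base policy), projects
each mapped piece into destination space, intersects it with the reverse
pieces, and compares the composed affine map `g∘f` with the identity:
identity holds on a piece iff the product of slopes is +1 and the combined
intercept is 0. Output intervals are exact, not sampled, so the two modes
are extensionally equal — an equality the test suite asserts on every
fixture rather than assumes.

### Ambiguity policy

When aligned blocks of several chains cover a base with conflicting
destinations, the highest-scoring chain wins; an exact score tie between
disagreeing chains is `ambiguous`, which the scanner folds into the Reject
categories — mirroring conversion tools' refusal of multi-mapped features
while keeping the engine deterministic. Chains that agree on the
destination are not ambiguous. The same resolution is implemented twice,
per base and piecewise, and the equivalence tests pin them together.

## VCF conversion

Variant conversion composes the positional lift with a reference-allele
check at each of the two conversions, inserted between the Reject and
CHR_Jump tests (a conversion tool drops a mismatching variant before any
chromosome bookkeeping can see it):

- *drop-on-mismatch* dialect: the variant fails if the target-build base
  differs from the (strand-adjusted) ref;
- *update-ref* dialect: the ref is rewritten to the target base and the
  variant fails only if the alt equals the updated ref;
- a target base that is any IUPAC ambiguity code fails in both dialects.

On `-`-strand chains ref and alt are reverse-complemented before the
comparison; without this every reverse-orientation variant would spuriously
mismatch. Genotypes are carried opaquely and compared, for discordance
metrics, as unphased allele multisets (`0/1 ≡ 1|0`); position discordance
is the fraction of converted variants with no aligned variant at the same
locus, and genotype discordance is computed only over position matches.
Multi-sample files are handled single-sample (first sample column).

1-bp BED records wider than one base are routed to the rejected stream with
reason `invalid_width` rather than raising, so the mapped/rejected
partition always conserves counts; multi-base interval conversion is out of
scope throughout.

## Synthetic build pairs

The generator realizes a declarative rearrangement script into paired
genomes, both chain files and per-base truth labels. Design choices that
matter:

- **Truth by construction.** Operations must be disjoint (validated), so
  each operation determines its interval's category analytically:
  deletions → `Reject_1`; cross-chromosome translocations → `CHR_Jump_1`;
  an *asymmetric back-map* (the reverse chain for a block is dropped,
  redirected to another chromosome, or shifted) → `Reject_2` /
  `CHR_Jump_2` / `POS_Jump`; everything else, including inversions,
  same-chromosome translocations and plain duplications, is `Stable`.
- **Controllable ambiguity.** Chain scores are block-length sums. A
  duplication's copy chain gets half the original's score, so the lift
  deterministically resolves to the original (stable); with
  `score_tie=True` the scores tie exactly and the duplicated interval
  becomes ambiguous, hence `Reject_1`. Duplications of < 2 bp are rejected
  so the halved score is strictly smaller.
- **Homologous jump targets.** The source sequence at an asymmetric
  back-map's target is made identical to the source interval's sequence.
  Real chromosome/position jumps arise in duplicated, highly similar
  sequence, where the reference base at the wrong locus usually *matches*;
  without the copy, nearly every jumped variant would be reported as a
  reference mismatch at the second conversion instead of as a jump, and
  the jump categories would be unreachable in VCF mode. (That mismatch
  pathway is itself real and remains reachable through crafted base
  lookups in the tests.)
- **Sequences** are uniform random A/C/G/T per seed; biological base
  composition is a non-goal. Forward chains merge colinear runs (deletions
  become source gaps, insertions destination gaps); reverse chains are one
  single-block chain per destination segment. Everything is deterministic
  per `(script, seed)` and emitted chain files re-parse and re-validate.

What the generator does **not** emulate: sequence homology driving real
chain construction, repeat structure, N gaps, centromere/telomere biology,
and chain fragmentation of real UCSC files. Passing tests therefore
demonstrate the correctness of the algorithm over arbitrary valid chain
files, not the specific category proportions of any real build pair; real
proportions are whatever the real chain files induce.

### Study conditions and problem sizes

Randomized checks use seeded scripts over 2 chromosomes of ~5–7.5 kb with
4–8 operations of mixed kinds (intervals 20–200 bp, margin 1 bp) — large
enough that every category and chain topology occurs, small enough that
the exhaustive per-base oracle stays trivially cheap. The acceptance
script scans 20 such pairs (~250 kb total), cross-checks modes on a ~50 kb
pair, and stratifies ~40 variants per category for the VCF workflow.
Simulated SNVs have refs matching the source sequence, uniformly drawn
alts and unphased genotypes.

## Annotation overlap

Overlap statistics are exact bp arithmetic on canonical interval sets
(sorted, disjoint, book-ended neighbours merged — the distance-0 merge of
`bedtools merge`, against which the implementation is cross-checked). The
headline statistic is `|A ∩ B| / |A|`; an empty category yields
not-applicable (never 0). The three annotation sets (gap, contig
difference, segmental duplication) are decomposed into exclusive,
*multiple* (strictly more than one set — the stricter of the two plausible
readings, chosen deliberately) and *other* components, which provably
partition the genome. Centromere rows can be removed from a gap table
before comparison (they dominate one build's gap track but not the
other's) and are returned separately for re-attribution. Proportions are
reported raw and rounded to 0.1 %.

## Numerical and degenerate-input choices

- Coordinates never leave 0-based half-open space except at the VCF
  boundary; all interval arithmetic is integer-exact, no tolerances exist
  anywhere.
- Positions at block boundaries belong to the half-open block containing
  them; zero-width intervals are dropped; negative-width intervals raise.
- A chromosome listed for scanning but absent from all chains is wholly
  `Reject_1` (it cannot convert); unknown chromosomes in lookups are
  unmapped, not errors, logged once per name.
- Duplicate chain ids (observed in real files) warn and are keyed by
  ordinal; chromosome names are kept verbatim and normalized (case-fold,
  strip `chr`) only in comparisons.
- Equal-score ties that *agree* on the destination map normally; ordinal
  order breaks ties only for reporting which chain was used, never for the
  destination.

## Limitations

- Parity with the `liftOver` binary's internal chain selection on
  pathological overlapping-chain inputs is not guaranteed; the ambiguity
  policy is deterministic and documented, and on well-formed UCSC file
  pairs (where tools agree) it reproduces chain-determined behaviour.
- Multi-base interval conversion (split/partial mappings) is explicitly
  out of scope.
- The per-base mode is O(genome); use the interval mode beyond toy scales.
- `--threads` is accepted but execution is serial; outputs are
  canonically ordered either way, so the flag is forward-compatible
  plumbing only.
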