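# cupscan

**Conversion-unstable positions (CUPs) between genome builds, identified by
round-trip liftover over chain files.**

Coordinate "liftover" between reference genome builds (e.g. GRCh37 ⇄ GRCh38)
is driven entirely by a pair of chain files — scored, gapped pairwise
alignments between the builds. For most bases the conversion is a clean
one-to-one mapping, but a small fraction of positions misbehave: they fail to
convert, land on a different chromosome, or fail to return to their original
locus when converted back. Variants at such positions silently acquire wrong
coordinates (and wrong annotation) in converted call sets. `cupscan` finds
these positions directly from the chain files, independent of any particular
conversion tool, and provides the pre-exclusion workflow that makes converted
SNV sets stable by construction.

## The algorithm

Every base-pair position `x` of the source build is pushed through the round
trip *source → target → source* and assigned exactly one category, tested in
this order:

| category     | meaning                                                          |
|--------------|------------------------------------------------------------------|
| `Reject_1`   | first conversion fails (no chain, chain gap, or ambiguous tie)   |
| `CHR_Jump_1` | first conversion lands on a different chromosome (incl. unplaced/unlocalized/alternate contigs) |
| `Reject_2`   | back-conversion of the mapped point fails                        |
| `CHR_Jump_2` | back-conversion returns to the wrong chromosome                  |
| `POS_Jump`   | back-conversion returns to the wrong position                    |
| `Stable`     | the round trip is the identity                                   |

Everything except `Stable` is a CUP; the last four categories are the
*novel* CUPs that conversion tools do not themselves report. Writing the
forward lift as a piecewise affine map `f` (slope ±1 per chain block) and the
reverse lift as `g`, a position is stable iff `g(f(x)) = x`; the scanner
evaluates this either exhaustively per base or exactly on intervals by
composing the two piecewise maps — the two modes produce identical output,
and the interval mode makes whole-genome scans cheap.

For VCF SNVs the same round trip runs with a reference-allele check at each
conversion, in both tool dialects (drop-on-mismatch à la Picard LiftoverVcf,
or update-the-ref à la CrossMap, where a variant fails only if the alt equals
the updated ref; IUPAC ambiguity codes always mismatch), adding `Mismatch_1`
and `Mismatch_2` categories. Pre-excluding variants at novel CUPs *before*
conversion yields exactly the same stable variant set as running the full
round-trip classification afterwards — that equivalence is the point of the
workflow, and it is enforced by the test suite.

Because no public fixture can ship two full builds, the package includes a
first-class synthetic-build generator: a declarative rearrangement script
(deletions, insertions, inversions, translocations, duplications, asymmetric
back-mappings) is realized into paired toy genomes, exact chain files for
both directions, and analytically known truth labels for every base.

## Worked example

Simulate a build pair, then scan it:

```bash
cupscan simulate --seed 7 --variants 100 --out demo/sim
cupscan scan --fwd-chain demo/sim/fwd.chain --rev-chain demo/sim/rev.chain \
             --chrom-sizes demo/sim/source.sizes --out demo/scan
```

which prints

```
  category    bp  pct_of_build
    Stable 12793     96.137371
  Reject_1   152      1.142256
CHR_Jump_1   172      1.292553
  Reject_2    66      0.495980
CHR_Jump_2   124      0.931840
  POS_Jump     0      0.000000
```

Of this 13,307 bp toy source build, 96.1 % converts stably; 152 bp fall in
regions deleted from (or ambiguous in) the destination build and fail the
first conversion; 172 bp translocate to another chromosome; 66 bp cannot be
converted back; and 124 bp return to the wrong chromosome (no position jumps
were scripted for this seed). `demo/scan/` contains one sorted, merged BED
per category plus the `summary.tsv` shown above, and the generator's
`truth.*.bed` files in `demo/sim/` match the scan output exactly.

The Python API mirrors the CLI:

```python
import cupscan as cs

real = cs.realize(cs.random_script(seed=7))
scan = cs.scan_genome(real.fwd, real.rev, real.source_sizes, mode="interval")
scan.counts  # {Stable: 12793, Reject_1: 152, ...}
```

Other subcommands: `cupscan lift` (1-bp BED liftover with reject reasons),
`cupscan overlap` (overlap proportions |A∩B|/|A| of CUP categories with
assembly annotation sets — gap, contig-difference and segmental-duplication
tracks, with optional centromere removal from the gap set),
`cupscan vcf-convert`, `cupscan vcf-filter` and `cupscan concordance` for
the SNV workflow. Real UCSC chain files (e.g. `hg38ToHg19.over.chain.gz`)
are parsed by the same `chain_io` module; scanning a full human build uses
the interval mode.

## Layout

- `src/cupscan/chain_io.py` — chain parsing/validation/indexing/serialization
- `src/cupscan/lift_engine.py` — per-base lifts and the piecewise affine map
- `src/cupscan/cup_scan.py` — round-trip classifier and genome scan
- `src/cupscan/region_annotate.py` — annotation overlap statistics
- `src/cupscan/vcf_convert.py` — VCF dialects, pre-exclusion, discordance
- `src/cupscan/synthetic_builds.py` — build-pair generator with truth labels
- `src/cupscan/cli.py` — the `cupscan` command
- `docs/methods.md` — model, assumptions, parameter choices, limitations
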