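# wormko

A toolkit for the computational side of PCR-based gene-knockout screening
in *Caenorhabditis elegans*.

Targeted deletion alleles in the worm are classically obtained by
mutagenizing large populations, arraying them in 96-well libraries, and
hunting for deletion PCR products with nested primer sets: pooled DNA is
screened on gels, positive row/column pools are addressed back to single
wells, and sib selection over a few generations isolates a single animal
carrying the deletion. The allele is then sequenced, validated (by
diagnostic PCR or array-CGH), and — if homozygotes cannot be recovered —
stabilized as a balanced heterozygote. `wormko` implements the pieces of
that pipeline that are algorithmic:

* **`wormko.breakcall`** — deletion-breakpoint calling from a deletion
  product (or a pair of inward Sanger reads) against its wild-type
  amplicon, with canonical normalization of the three break types:
  *clean*, *ambiguous* (microhomology at the break allows several
  equivalent placements; the left breakpoint is reported at the rightmost
  possible position) and *insertion* (minimal insert, maximal matched
  flanks). A deletion with h bp of breakpoint microhomology has ambiguity
  width h + 1.
* **`wormko.seqmodel`** — amplicon / gene-model / allele types, the
  silent-allele rule (a deletion that does not cross an exon boundary is
  not a knockout), and size/band-shift consistency checks.
* **`wormko.screensim`** — a seeded stochastic simulator of the whole
  screen (library, row/column pooling, nested-PCR detection with
  per-template sensitivity `s`, addressing, sib selection with Mendelian
  1:2:1 selfing and lethal-allele handling) plus reaction accounting.
* **`wormko.cghval`** — synthetic aCGH probe tracks, run/threshold
  copy-loss calling (het ≈ −1, hom at the signal floor), target-deletion
  validation with reporting of extra deletions, and diagnostic-PCR logic.
* **`wormko.accounting`** — gene-family knockout coverage (round-half-up
  percent), worm–yeast essentiality set arithmetic, and chromosome-bin
  histograms, with the published consortium count tables built in.
* **`wormko.fixtures` / `wormko.io` / `wormko.cli`** — planted-truth
  fixture generation (every planted case is canonical by construction),
  FASTA/GFF3/BED/TSV/VCF/JSON I/O, and a `wormko` command with one
  subcommand per workflow step.

## Worked example

```python
from wormko import Amplicon, call_breakpoint

amp = Amplicon(id="t", seq="AAAGCTGCTTT",
               ext_left=0, int_left=0, int_right=11, ext_right=11)
rep = call_breakpoint(amp, "AAAGCTTT", min_anchor=0)
a = rep.allele
print(a.break_class, a.left, a.right, a.ambiguity_width,
      rep.flank_left, rep.flank_right)
```

prints

```
ambiguous 6 9 4 AAAGCT TT
```

The product `AAAGCTTT` can be explained by deleting `GCT` at four
equivalent positions (left breakpoint 3, 4, 5 or 6 — the `GCT` repeat is
3 bp of microhomology, so the ambiguity width is 4); the canonical report
places the left breakpoint rightmost, at 6, giving flanks `AAAGCT` / `TT`.

On the simulator side:

```sh
wormko make-fixtures --seed 3 --n-cases 5 --out-dir demo
wormko simulate-screen --scenario demo/scenario.json --replicates 2 --seed 4 --out-dir demo/sim
```

```
5 planted cases -> demo
2 replicates: 2 detected, 0 recovered homozygous -> demo/sim
```

(The demo scenario — ten 96-well plates of 500 genomes at a per-target
deletion rate of 2e-5 — holds a handful of carriers, so pooled screening
detects them, but recovering a homozygote additionally requires surviving
addressing and the sib-selection rounds; per-replicate traces are in
`demo/sim/screens.json`.)

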