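# Methods

This note documents the models implemented in `wormko`, the parameters
that matter, and what the synthetic fixtures do and do not emulate.

## Coordinates and conventions

All positions are 0-based, half-open internally. Report writers emit
1-based inclusive coordinates for display (the genome-browser convention)
and every writer states its convention in a header line. Sequences are
uppercase ACGT; ambiguity codes are rejected at construction.

## Breakpoint calling and normalization

A deletion product is modeled as `amplicon[:L] + insert + amplicon[R:]`
with `L < R`. Valid placements are bounded exactly by the longest common
prefix `P` and suffix `S` of product and amplicon:

* zero-insert placements exist iff `P + S >= |product|`; they form the
  contiguous range `L in [|product| - S, P]`, all with the same deletion
  size. The break is **clean** if the range has one element and
  **ambiguous** otherwise; the range length is the ambiguity width, which
  equals microhomology length + 1 for a pure tandem context.
* otherwise the minimal insert length is `|product| - P - S`, attained
  uniquely at `L = P`, `R = |amplicon| - S`. Minimizing the insert is
  therefore equivalent to maximizing both matched flanks, and the
  flank-maximality conditions (`insert[0] != amplicon[L]`,
  `insert[-1] != amplicon[R-1]`) hold by construction of `P` and `S`.

The canonical report uses the rightmost `L` for ambiguous breaks (the
microhomology bases are pushed onto the left flank) and the unique
minimal-insert placement for insertion breaks. `enumerate_decompositions`
realizes the same choice by exhaustive enumeration and an explicit sort
`(insert length, -matched flank total, -L)`; the test suite checks
agreement between the direct construction and the enumeration over every
plantable `(L, R, insert <= 3 bp)` on short amplicons (~10^5 cases), and
an independent re-implementation of the enumeration lives in the tests.

**Anchors.** A decomposition is only accepted when the product shares at
least `min_anchor` exact bases with each amplicon flank (default 10 bp),
which makes spurious flank matches on random sequence negligible at
amplicon scale; callers working with tiny synthetic examples can lower it.

**Read merging.** `call_from_reads` expects two inward Sanger reads off
the internal primers; the right read's orientation is auto-detected by
which strand anchors on the amplicon suffix. Reads are merged at the
largest overlap whose mismatch fraction is within `max_mismatch_rate`
(default 0: exact). Conflicting overlap positions are resolved in favour
of the base farther from its own read's ends — Sanger quality degrades
toward read ends — and the number of such resolutions is surfaced as
`merge_conflicts` on the report so disagreeing reads are never silently
trusted. Heterozygous templates are assumed to yield only the shorter
deletion product, so no mixed-trace deconvolution is attempted.

## Silent-allele and size rules

A deletion is exonic iff its open interval, lifted to chromosome
coordinates, strictly contains an exon start or end; a deletion abutting
but not crossing a boundary is silent. The predicate uses boundary
positions only and is strand-symmetric. Whether intron-only deletions
that remove a splice branch point should ever count as damaging is an
open biological question; the boundary-crossing rule is applied as
stated. The 3 kb deletion-size cap is a consequence of flanking-primer
placement, not of the algorithm, so `check_size_bound` is a validation
check rather than a hard rejection. Band-shift consistency compares the
predicted product (`internal span - deletion + insert`) with the gel
estimate under a fractional tolerance (gel sizing is coarse; 15% is a
reasonable default, 0 demands exactness).

## Screen simulator

One seeded `numpy` generator drives every draw, so a run is reproducible
bit-for-bit given (scenario, seed), and the per-reaction draw count is
fixed (two draws) so runs at different sensitivities are coupled
draw-for-draw — which is also how the monotonicity-in-`s` law is tested.

* **Library** — each of `genomes_per_well` genomes in each of `n_wells`
  wells carries the target deletion independently with
  `deletion_rate_per_target`. Default plates are 8 x 12; libraries of
  125k–1.4M genomes are flagged as matching the published screening scale.
* **Pooling** — one pool per plate row and per plate column (20 pools per
  96-well plate); a pool's mutant fraction is the mean of its member-well
  fractions. Mutant *content* (fraction x pool size) is conserved between
  the row and column views.
* **Detection** — a reaction on a template with carrier fraction `f`
  samples `m ~ Poisson(f x templates_per_reaction)` templates,
  conditioned on `m >= 1` when the pool truly contains a carrier: the
  protocol sizes its library sampling so that represented genomes are not
  lost at DNA prep, and the truncation is what makes `s = 1` detection
  certain for every carrier pool. The reaction fires with probability
  `1 - (1 - s)^m`; carrier-free templates never fire (nested PCR is
  modeled as fully specific). Duplicate screening ORs two independent
  reactions — the OR rule maximizes sensitivity, matching the protocol's
  intent of not losing hits. `templates_per_reaction` defaults to 10,000.
* **Addressing** — candidate wells are positive-row x positive-column
  intersections per plate, each retested individually. A plate whose
  positives have no intersection (a false-negative row or column), or
  whose candidates all fail the retest, raises a lost-at-addressing flag.
* **Sib selection** — each round picks `sib_plan[r]` single founder
  animals (multivariate hypergeometric over genotype counts) from the
  current population after one selfing expansion (brood factor 100,
  census capped at 10^6 with proportional rescaling; only frequencies
  matter to the draws). Founder sub-populations are PCR-tested — only the
  deletion band is scored, so positivity means the founder carries the
  allele — and the walk recurses into a positive sub-population,
  preferring a homozygous founder, which terminates the screen as
  `homozygous`. Lethal alleles remove homozygous progeny before
  reproduction (surviving adults from a selfed heterozygote are 2:1
  het:WT), so lethal runs end `persistent_heterozygous` (ready for
  balancing) or `lost`, never `homozygous`. Each plan entry is a number
  of single-founder sub-populations; the laboratory practice of seeding
  early rounds with many animals is collapsed into the founder picks, a
  simplification that understates recovery rates for wells with very rare
  carriers (see Limitations).
* **Reactions** — pool screens (x2 under duplicates) + addressing retests
  + sib tests; e.g. ten duplicate-screened 96-well plates cost 400 pool
  reactions against a 960-reaction per-well baseline, and a single-hit
  screen with plan (24, 24, 24) on one plate costs 40 + 1 + 72 = 113.

## CGH validation

Probe log2 ratios are 0 for two copies, −1 for heterozygous loss, and −4
for homozygous loss — a finite proxy for the signal floor; only the
ordering hom ≪ het < 0 matters. The caller takes maximal runs of at
least `min_probes` (default 3) consecutive probes below the het cut
(default −0.5) and classifies a run homozygous when its mean is below the
hom cut (default −2.0). These are standard aCGH heuristics, not
calibrated to any particular array design. A PCR-detected deletion is
confirmed when a call covers at least 50% of its interval; calls not
touching the target are reported as extra deletions. Probe membership in
a deletion is decided by the probe midpoint. With noise SD 0.2 and at
least 5 probes per deletion, planted recovery is complete with zero false
calls over hundreds of seeded tracks; sensitivity degrades monotonically
as noise grows past the het cut.

Diagnostic PCR is modeled logically: the design is valid only if the
internal primer lies wholly inside the deletion and the external primer
wholly outside, in which case a product from the mutant strain implies a
retained intact copy of the target (the rare failure mode that gets a
strain discarded).

## Accounting

Coverage percentages use round-half-up to integer percent (implemented
with decimal arithmetic to avoid binary-float artifacts on exact halves).
This convention reproduces the published family rows used in tests
(kinases 380/416 → 91, cadherins 11/12 → 92, innexins 25/25 → 100,
lethal fraction 1436/6013 → 24); the published transcription-factor row
prints 90% for 866/941, which no standard rounding yields, so the package
reports the computed 92 for that row. Ortholog inference is out of scope:
essentiality sets arrive as id lists (or are synthesized with given
cardinalities), and the overlap partition satisfies the conservation laws
`worm_only + shared` and `yeast_only + shared` by construction.

## Fixture generator

Defaults emulate the published screens: a 2199-bp amplicon with 25-bp
primers (2099-bp wild-type internal product, the band size of the worked
screening example), deletions uniform on 200–2000 bp, insertion breaks
with probability 1097/4101 ≈ 0.27, insert sizes from a geometric body
(mean 3 bp) with an 87/1097 ≈ 8% heavy tail uniform on 100–2000 bp, and
a geometric-ish microhomology distribution on 0–10 bp (P(h) ∝ 2^−h).
Microhomology and insert-end constraints are engineered by local base
edits around the planted break so that the planted truth is canonical by
construction (verified against the brute-force oracle in tests); the
edited amplicon is returned with the case. Read noise is substitution
only; chromatogram artifacts, indel noise, and mixed heterozygous traces
are not emulated, so passing round-trip tests demonstrate correctness of
the calling and normalization logic, not robustness to raw Sanger data.

## Problem sizes used in checks

The exhaustive oracle-equivalence sweep uses amplicons of 25/30/40 bp
with all placements and inserts up to 3 bp (~10^5 cases); planted-truth
recovery uses 1,000 full-scale fixture cases in the tests and 300 in the
acceptance script; Mendelian laws use 10^4 offspring; specificity uses
10^4 seeded screens in the tests and 2 x 10^3 in the acceptance script;
CGH recovery uses 200 seeded tracks. These sizes give comfortable
statistical resolution for the assertions made (e.g. binomial SE ~0.5%
at n = 10^4).

## Known limitations

* Single-founder sib rounds (above) make recovery from wells with carrier
  frequency ≪ 1/plan-size pessimistic compared with density-staged
  laboratory sibbing.
* The PCR sensitivity model is one-parameter per template; it reproduces
  the qualitative law (rarer templates in bigger pools are harder to
  detect) but is not calibrated to any measured nested-PCR titration.
* The CGH model has no dye-swap/replicate structure and no copy-gain
  calling.
* Breakpoint calling is amplicon-scale by design; it does not align
  against whole genomes and does not detect inversions or multi-segment
  events.
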