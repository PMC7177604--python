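# Methods

## The measurement

Circular chromosome conformation capture (4C) fixes chromatin, digests it
with a frequent (4 bp) first cutter, ligates spatially proximal fragments,
circularizes with a second cutter, and inverse-PCR-amplifies everything
ligated to one chosen fragment — the *viewpoint*. Because the polymer
nature of chromatin makes contact frequency fall steeply with linear
genomic distance, the sequenced ligation partners pile up around the
viewpoint's position on the linear chromosome. Two consequences drive this
package:

1. a viewpoint placed *inside an unmapped transgene (T-DNA) insertion*
   produces, when its reads are aligned to the unedited reference genome,
   a contact peak at the insertion site — localization without any prior
   knowledge of where the transgene landed, independent of copy number and
   of whether the transgene borders are intact;
2. an interruption of the linear template (inversion, translocation)
   truncates the contact decay on exactly one side, so the signal falls
   off a cliff at the breakpoint — a *one-sided discontinuity* — and the
   missing signal reappears as a "cis-like" block at the partner locus.

## The statistic

All analysis lives on the grid of first-cutter restriction sites
(Csp6I, `GTAC`; DpnII `GATC` is the circularizing cutter and plays no role
in the statistics). Per site:

* **raw count** — reads whose trimmed sequence starts exactly at either
  boundary of the site (4C reads always begin flush at a restriction-site
  boundary after primer trimming);
* **unique coverage** — the indicator `min(count, 1)`. Collapsing to a
  binary value removes PCR and sequencing amplification bias; every
  downstream quantity depends on the indicator only, so duplicating reads
  changes nothing (a tested invariant);
* **p-score** — with `n` sites inside a 50 kb window centered on the site
  (membership by genomic position, inclusive; truncated, never
  re-centered, at chromosome ends), `k` of them covered, and `p0` the
  covered-site fraction of the *whole chromosome*, the one-tailed upper
  binomial tail `P(X >= k)`, `X ~ Bin(n, p0)`, measures local enrichment;
  the track stores `-log10(p)`, capped at 300 (p floored at 1e-300). The
  tail is computed by `scipy`'s regularized incomplete beta, which is
  accurate far into the tail. The focal site counts in its own window.
  No multiple-testing correction is applied to the track: the p-score is
  a signal; thresholds belong to peak calling.

**Peaks.** Candidate regions are maximal runs of sites with p-score above
`min_score` (default 5, i.e. p < 1e-5 — with ~5e5 sites genome-wide the
expected number of false windows stays well below one); runs closer than
`merge_gap` (default 20 kb, deliberately below the window size so
genuinely separate insertions a window apart never fuse) are merged. The
summit is the top-scoring site (ties: midpoint of the tied run, rounded
down). For a cutoff c ∈ {0.5, 0.8, 0.9}, the *peak base* is the contiguous
run of sites scoring ≥ c × summit around the summit, the *center* is the
base midpoint, and the *DPC* (distance from peak center) to the known or
true viewpoint position is the localization-error metric. The 50% base is
the headline cutoff: asymmetry of the signal is worst near the top of the
peak, so the half-height center sits closest to the viewpoint — the
simulation battery reproduces the ordering median DPC(50%) ≤ DPC(80%) ≤
DPC(90%).

**Discontinuities.** For each side of the 50% base, the covered-site
fraction is measured in a `flank` (50 kb) window starting `skip` bp beyond
the base boundary, and a side is called a drop when (a) its fraction is at
or below the chromosome background `p0`, (b) the opposite fraction exceeds
`p0`, and (c) a two-sided Fisher exact test on the two flanks'
covered/uncovered counts gives p < 0.01. The `skip` (default: half the
scoring window) exists because a windowed score smears a cliff over half a
window: the 50% boundary lands systematically short of the cliff, and a
flank flush against it would mix dense and sparse sites, hiding real
breaks. `skip=0` restores the flush definition.

**Fusions.** A candidate rearrangement is expressed as two chromosome
segment ends (keep-side and orientation each); the hybrid chromosome is
their concatenation with a bijective lift-over map on retained bases.
Coverage tracks lift onto the hybrid (site order reversing under
reverse-orientation segments), and *junction continuity* applies the same
three-condition drop criterion across the junction: a correct fusion shows
no drop (the profile continues across the junction), a fusion placed
hundreds of kb off shows a one-sided drop and is rejected. Independently,
paired-end libraries from the same plant localize transgene borders
directly: pairs with exactly one mate on the plasmid contig are
deduplicated by their coordinate pair (the standard PCR-duplicate proxy),
clustered within 2 kb, and clusters with ≥ 2 nonredundant pairs become
insertion calls; `junction_read_support` counts nonredundant pairs
crossing a postulated fusion point on its reconstructed template.

## The simulator

`simulate` generates i.i.d. random chromosomes at GC 0.36 (the
Arabidopsis genome-wide value), applies structural events (insertion,
inversion, reciprocal translocation) recording every induced junction,
and draws reads from the *edited* genome that are analyzed against the
*unedited* reference — the asymmetry that produces insertion peaks and
discontinuities, exactly as in the real experimental design.

4C reads pick a restriction fragment end: with probability
`trans_fraction` (default 0.05) uniformly genome-wide, otherwise on the
viewpoint chromosome with probability ∝ `max(d, d0)^(-alpha)` (defaults
d0 = 1 kb, alpha = 1). The power law is the canonical 3C-derived contact
decay; colloquial descriptions of the decay as "exponential" refer to its
steepness, and alpha is configurable. Reads carry the 4 nt barcode + ≥15 nt
primer prefix and are truncated to `read_length` (75). No sequencing
errors are introduced by default: the built-in mapper is exact-prefix, and
error modeling is a robustness knob, not a correctness requirement.
Paired-end fragments are sampled uniformly (accessibility-library-like),
mates lifted back to reference/plasmid coordinates through the block
structure the way a soft-clipping aligner would place them (majority
block). Every output is a pure function of (parameters, seed).

What the generator does **not** model: chromatin domain structure (TADs,
compartments — real trans and long-cis backgrounds are not uniform), PCR
duplicates beyond exact duplication, sequencing errors, mappability
variation, or restriction-site density biases beyond base composition.
Passing the battery therefore demonstrates correctness of the *analysis*
under the stated contact model, not performance on real libraries.

## Depth, genome size, and resolution

Unique coverage saturates: with N cis reads and the alpha = 1 kernel, the
per-site coverage rate is roughly `lambda(d) ≈ 2N/(Z d)` (Z ≈ 0.12 for a
few-Mb chromosome), so sites are near-certainly covered out to
`d* ≈ 16 N` bp. The method's behavior splits into two regimes:

* **Sharp-peak regime** (`d*` well below the chromosome length and
  comparable to the window): the chromosome background p0 is a few
  percent, the peak is tall and narrow, half-height boundaries fall on a
  steep coverage gradient, and the DPC reaches the kb scale. Real
  experiments (tens of Mb chromosomes, ~10⁴–10⁵ informative reads) and
  this package's rearrangement scenarios (10–12 Mb genomes, 10,000 reads,
  d* ≈ 170 kb) sit here.
* **Saturated regime** (`d*` a large fraction of the chromosome): most of
  the chromosome is covered (p0 > 0.5), the p-score plateaus and its
  summit is set by local restriction-site density rather than by the
  viewpoint, and half-height boundaries wobble by tens of kb. The
  localization battery's standard conditions (10 Mb genome, 50,000 reads —
  d* ≈ 0.8 Mb on a 3.5 Mb chromosome) are in this regime: the top peak
  still identifies the correct chromosome and insertion region in 20/20
  seeds and the cutoff ordering holds, but the median DPC(50%) is ~17 kb,
  not kb-scale; at 250,000 reads coverage reaches 98% and no peak rises
  above threshold at all. Matching read depth to genome size (roughly
  ≤ 5 × 10³ reads per 10 Mb for alpha = 1) keeps the assay in the
  sharp-peak regime.

## Why an inversion's two drops face the same way

For a viewpoint at sample position near the (sample-)left end of an
inverted segment [s, e), reference coordinates just *right* of s are the
image of sample positions near e — sample-distant, hence sparse — and
reference coordinates just right of e are sample-distant too. Both cliffs
therefore face right (mirror-symmetrically, both face left for a
viewpoint near the other end; a mid-segment viewpoint yields a single
symmetric peak and no cliff). No contact-decay geometry produces two drops
facing each other from one inverted segment; facing drops are instead the
signature of the two *ends of a deleted or translocated* interval. The
inversion test battery asserts the true signature: two peaks whose single
drop calls localize both segment ends.

## Numerical and procedural choices

* Coordinates are 0-based half-open internally and in all BED/bedGraph
  output; the human-readable report is 1-based inclusive (stated in its
  header).
* Demultiplexing is exact: a 4 nt barcode offers no mismatch budget.
  Subsampling is a seeded order-preserving draw without replacement.
* The built-in mapper requires a unique exact match on ≥ `min_prefix`
  (15) bp and consistency over the full overlap; reads matching zero or
  several fragment ends are discarded — no rescue, no random placement.
  Imported alignments snap 5' anchors to the nearest site boundary within
  ±5 bp (strand-aware); farther records are tallied `off_site`.
* Degenerate (IUPAC) recognition sequences and non-palindromic enzymes
  are rejected; `N` never matches. Fragments without an internal
  second-cutter site are retained.
* Summit ties resolve to the midpoint of the tied run; peak ranking is by
  summit score with (chromosome, position) as deterministic tie-breaks.
* The rearrangement scenario analyses call peaks at min_score 25 and
  merge gap 50 kb (one scoring window): their viewpoint chromosomes carry
  a heavy contact-tail background in which score-5 fluctuations occur far
  from any breakpoint, while the true peaks score above 80; and
  supra-threshold spillover from windows straddling a cliff belongs to the
  same blurred feature as the peak itself. Library defaults are unchanged.

## Known limitations

* Breakpoint calls are placed at half-height base boundaries and inherit
  the half-window blur (~10–25 kb here); base-pair-exact junctions are
  out of scope by design (targeted PCR/sequencing territory).
* The junction-support read counter uses exact substring matching on the
  junction template; it is intended for simulated or error-free reads.
* The internal structure of multi-copy transgene concatemers is not
  modeled or resolved (a long-read problem).
* Performance targets desk scale (tens of Mb, 10⁵–10⁶ reads), where every
  battery in the test suite completes in seconds to a couple of minutes.
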