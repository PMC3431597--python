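# Methods

## The measurement being modelled

A single Purkinje cell from an F1 hybrid (B6 × JF1) is lysed and its mRNA
reverse-transcribed with an adaptor-attached oligo-dT primer. Because the
*Pcdh-β* genes are single-exon, transcripts are identified by 3′-RACE rather
than exon PCR, and the cDNA is divided into three equal aliquots *before*
amplification. Nested multiplex PCR then scores each of six assayed β genes
(*β3, β9, β10, β15, β19, β22*) per tube, and direct Sanger sequencing of
each positive tube reads the bases at known B6-vs-JF1 polymorphisms near
the gene's polyadenylation signal, assigning the product to one parental
allele, to both (heterozygous trace), or flagging a conflict.

The split matters because single-cell cDNA is scarce: a gene represented by
one captured molecule can amplify in at most one tube, so requiring
agreement across all three tubes (a 3/3 pattern) excludes single-molecule
sampling artifacts — up to the quantifiable residual risk formalized by the
artifact null below.

## Generative model (`synthetic_data`)

Per cell, for each parental allele independently, each of the cluster's
isoforms is expressed with probability `q` (independent Bernoulli draws).
Expressed (allele, isoform) pairs capture `c ~ ZTPoisson(mu)` cDNA
molecules; each molecule picks a polyA site by the gene's usage weights.
All molecules are assigned to `n_tubes` tubes by a uniform multinomial
(equal aliquots). A tube is positive for a gene iff ≥ 1 template landed in
it *and* a Bernoulli(`amp_prob`) amplification succeeds. Sequencing a
positive tube reports, at every variant site, the majority allele's base,
or the IUPAC two-base code when the minor allele's template fraction in
that tube is ≥ `het_minor_fraction` (direct Sanger sequencing only detects
a minor allele above a trace fraction).

Parameter defaults and their rationale:

| parameter | default | units | why |
|---|---|---|---|
| `n_tubes` | 3 | tubes | the split design (3.3-µl aliquots) |
| `expression_prob` (q) | 0.052 | per isoform per allele | sets E[distinct expressed β genes] = 22·(1−(1−q)²) ≈ 2.23, the repertoire scale estimated for Purkinje cells |
| `copies_mean` (µ) | 3 | molecules | low single-cell capture; produces 2/3 and 1/3 patterns at realistic rates (no published copy numbers exist to calibrate against) |
| `amp_prob` (a) | 0.95 | per tube | nested PCR from ≥1 template rarely fails outright |
| `het_minor_fraction` (h) | 0.20 | fraction | conventional Sanger minor-allele sensitivity bound |
| `control_copies_mean` | 100 | molecules | *Pcp-2*/*β-actin* are abundant; controls should saturate in good cells |
| `negative_control_interval` | 7 | cells | one no-cell control after every 7 cells, mirroring the 1-8/1-16/… layout |

A single seeded `numpy` generator is threaded through every draw; the seed
is echoed in all output headers, and a fixed seed reproduces the output
tables byte-for-byte.

The generator emulates the *statistical* structure the inference assumes —
stochastic promoter choice, low-copy capture, tube splitting, dropout and
trace-limited het calling. It does not emulate PCR chemistry or efficiency
differences between isoforms, chromatogram noise, cross-contamination, or
cell-picking failures; passing recovery tests therefore validates the
inference logic under the stated sampling model, not robustness to those
real-data failure modes.

## Allele calling (`allelic_inference`)

Per tube, the variant-site base calls collapse to `A`, `B`, `het` or a
within-tube conflict; bases matching neither allele are treated as
sequencing-error sites and excluded. Product-level rules:

* any heterozygous tube, **or** two clean tubes reporting opposite pure
  alleles → `biallelic` (both alleles are demonstrably in the cell's pooled
  cDNA — the split design implies the cross-tube rule even though only the
  within-tube heterozygous case is ever printed);
* all readable tubes agreeing on one pure allele → `monoallelic-A/B`;
* conflicting sites within one tube → `inconsistent` (excluded from the
  monoallelic fraction's numerator *and* denominator);
* no readable site → `insufficient`.

Cells enter the statistics only if the Purkinje marker *Pcp-2* and
*β-actin* both amplified and the actin product reads biallelic. "Intense
expression" of the controls is operationalized as ≥ 1 positive tube:
requiring 3/3 for the controls at `amp_prob` = 0.95 would discard ~14% of
genuinely good cells for reasons unrelated to cell quality, whereas a
no-cell control still fails (it has no products at all).

The headline fraction is restricted to 3/3 products (2/3 and 1/3 products
receive calls but are reported separately), and is printed as an integer
percent, matching the conventional precision for such fractions.

## Statistics (`stats`)

**Artifact null.** If each of `k` tubes independently amplifies one
molecule whose parental allele is a fair draw, all `k` agree with
probability `2·(1/2)^k` — 25% for `k` = 3. This single-molecule-per-tube
formalization is the only one reproducing the stated 25%. The Monte-Carlo
generalization replays the full split/amplify/readout engine for arbitrary
copy numbers; the simulator reproduces the analytic value when conditioned
on the one-molecule-per-tube event.

**χ².** Observed (monoallelic, biallelic) counts are tested against
expected `(N·0.25, N·0.75)` with a plain two-category, 1-df goodness-of-fit
χ² and no Yates correction (the expected counts 4.5/13.5 permit it, and the
correction is for 2×2 tables, not binomial goodness of fit). For (17, 1)
the statistic is (17−4.5)²/4.5 + (1−13.5)²/13.5 ≈ 46.3, p ≈ 10⁻¹¹.

**Repertoire.** `genes_per_cell(18, 28)` = 0.64 (2 dp) and
`extrapolate_repertoire(0.64, 6, 22)` = 2.3 (1 dp), assuming no frequency
distortion between isoforms. Two readings of the positive count are
computed and reported side by side: the cell-level count (number of cells
with ≥ 1 3/3 gene — the published 18/28 usage) and the product-level count
(number of distinct 3/3 genes summed over cells). They differ when a cell
expresses several assayed genes: the cell-level rate saturates at 1 per
cell and therefore *underestimates* the per-cell expectation by a factor
≈ (1−(1−p)ⁿ)/(np) (about −22% at the default parameters), while the
product-level count is the unbiased estimator of genes per cell. The
recovery tests consequently score the product-level estimator against the
closed form 22·(1−(1−q)²); the cell-level rate is kept because it
reproduces the printed 0.64 → 2.3 arithmetic.

**Diversity.** One isoform per allele with the two alleles distinct gives
`n(n−1)` ordered pairs per cluster; the α/β/γ product
132 · 462 · 342 = 20,856,528 is computed in exact integer arithmetic.

## Probe and primer design (`probe_design`)

Pairwise similarity is global-alignment percent identity: match +1,
mismatch −1, gap open −2, gap extend −0.5, end gaps free, identity =
matches / alignment columns with terminal gaps excluded (the measure is
recorded in every report; whether the published 84%/65% thresholds refer to
global or best-local identity is not stated, so the definition used here is
made explicit). Probe *window scanning*, by contrast, compares candidate
windows to each comparison sequence **ungapped** — best identity over all
sliding offsets — because a probe hybridizes over its full contiguous
length, and a gapped score would let a short perfect sub-match of a
divergent window masquerade as near-identity, destroying the ≤ 65%
specificity criterion. Under a shared measure the pan (min identity ≥ 84%)
and specific (max identity ≤ 65%) window sets are provably disjoint.

Strain-discriminating variants come from the same global alignment:
substitutions are reported per position (1-based on strain A), contiguous
indels as single events flagged by type; only substitutions populate the
allele-calling variant map. PolyA signals are the canonical hexamers
AATAAA/ATTAAA found 10–40 nt upstream of a cleavage position (no signal
sequence is named in the source; these are the canonical mammalian
hexamers). Observed cleavage positions cluster by single linkage: a gap
greater than the tolerance starts a new 3′-terminus, so tolerance 0
distinguishes same-signal/adjacent-nucleotide heterogeneity that
tolerance 1 merges.

No deposited sequence data ships with the package: probe computations on
the real *Pcdh-β* coding sequences require a user-supplied FASTA (GenBank
NM_053128–NM_053147), and the test suite exercises the same operations and
thresholds on synthetic families with planted conserved/divergent blocks,
labelled as synthetic stand-ins.

## Fixture and its discrepancies (`fixture`)

The 28-cell / 5-control dataset is transcribed from the published per-cell
lists and summary counts. The source text is internally inconsistent in
three places, and the fixture carries the inconsistencies openly rather
than reconciling them: the monoallelic list prints one entry ("*β19* in
Cell #1-5") twice — both occurrences are kept, since the printed totals
(18 products, 17 monoallelic, 94%) count them separately — the per-product
list spans 14 cells while the summary counts 18 3/3-positive cells, and
only 3 of the 5 2/3 cells are named. `build_purkinje_fixture()` recomputes
every derivable count from the rows, compares it with the stored printed
count, and surfaces each mismatch as a warning. Per-product parental-allele
assignments are not printed (only the 7 B6 / 10 JF1 totals), so those
fields are null.

## Test problem sizes and numerical choices

The simulation-backed tests use 500 cells (truth-class recovery,
biallelic-truth false-call rate), 2,000 cells (repertoire-estimator
recovery, ±10%), 10,000 truth-only cells (mean expressed genes, ±0.05) and
10⁵ Monte-Carlo replicates (artifact null, 3 standard errors) — sizes at
which the expected Monte-Carlo error is several times smaller than each
test's tolerance. Recovery tests run at `copies_mean` = 30 and
`amp_prob` = 1: detection of an expressed gene is then essentially certain
(the chance a tube receives none of ≥ 30 molecules is ~10⁻⁵), so the tests
score the inference rules rather than the capture efficiency; at the
default µ = 3 the three-tube coincidence detects only ~23% of expressed
genes, which is a property of the assay being modelled, not of the
inference. All stochastic tests fix their seeds. Ties in the heterozygous
readout cannot occur (a 50% minor fraction always meets `h` ≤ 0.5);
polyA usage weights are renormalized at construction so conservation holds
to the integer; diversity products use Python integers (no overflow).

## Known limitations

* The generative law for promoter choice (independent Bernoulli) is the
  minimal assumption; real promoter choice may be correlated within or
  across alleles, and nothing here can detect that.
* Copy-number and capture-efficiency defaults are calibrated only to
  reproduce qualitative pattern frequencies (3/3 vs 2/3 vs 1/3), since no
  quantitative single-cell capture estimates exist for this assay.
* Sequencing errors are modelled only as unreadable bases at variant
  sites, not as miscalls that mimic the other allele.
* The cell-level repertoire rate is biased low whenever cells express more
  than one assayed gene (see above); both estimators are reported so the
  choice is explicit.
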