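# splitrace

Split single-cell 3′-RACE simulation and monoallelic-expression inference
for clustered protocadherin (*Pcdh*) genes.

## The problem

The clustered protocadherins — the *Pcdh-α* (12 variable isoforms), *Pcdh-β*
(22) and *Pcdh-γ* (19) gene clusters — are a leading candidate for giving
individual vertebrate neurons unique cell-surface identities. Each isoform
has its own promoter, and single neurons stochastically express a small
random subset of isoforms, often from only one of the two parental
chromosomes. The *β* cluster is the hard case: its 22 genes are single-exon,
so an exon-targeted RT-PCR cannot tell transcript from genomic DNA. The
workaround is 3′-RACE (the transcripts are polyadenylated), applied to
single Purkinje cells from an F1 hybrid (B6 × JF1) so that strain
polymorphisms near the polyA signal reveal the allele of origin of every
PCR product.

Because a single cell yields only a handful of cDNA molecules, a transcript
could look "monoallelic" simply because one molecule was sampled. The assay
therefore splits each cell's cDNA into **three PCR tubes** before nested
amplification: a product confirmed in all three tubes (a *3/3 pattern*)
cannot come from one molecule. Under the worst-case null — each tube
amplifies a single molecule whose parental allele is a fair coin —
all three tubes still agree with probability

> P(artifactual monoallelic) = 2 · (1/2)³ = **25%**,

so an observed monoallelic fraction must be tested against 25%, not 0%.

`splitrace` implements this whole analysis as a tested, reusable pipeline:

* **`synthetic_data`** — a generative simulator of diploid single-cell
  isoform expression (independent Bernoulli(*q*) promoter choice per allele,
  zero-truncated Poisson(*μ*) capture, multinomial tube splitting,
  per-tube amplification dropout, Sanger-style heterozygous base calling);
* **`allelic_inference`** — tube-pattern classification (3/3 … 0/3), product
  allele calling from per-tube base calls at strain variant sites, the
  *Pcp-2*/*β-actin* QC gate, monoallelic-fraction aggregation and
  parental-allele balance;
* **`stats`** — the artifact null `2·(1/2)^k`, a Monte-Carlo generalization,
  1-df χ² goodness of fit, the repertoire estimator
  (rate × *n*<sub>total</sub>/*n*<sub>assayed</sub>) and the combinatorial
  diversity counts *n*(*n*−1) per cluster;
* **`probe_design`** — percent-identity computations for pan vs
  isoform-specific probe windows, strain-discriminating variant detection,
  polyA-signal hexamer scanning and 3′-terminus clustering;
* **`io_utils` / `fixture` / `pipeline` / `cli`** — TSV/FASTA formats with
  provenance headers, the transcribed 28-cell Purkinje dataset, and a
  `splitrace` command-line tool.

## Worked example

```python
>>> from splitrace import run_pipeline
>>> report = run_pipeline({"mode": "fixture"})
>>> for key in ("n_monoallelic_3of3", "n_products_3of3", "monoallelic_percent",
...             "artifact_null_percent", "chi_square", "chi_square_p",
...             "genes_per_cell_rate", "repertoire_extrapolated",
...             "total_diversity"):
...     print(key, report[key])
n_monoallelic_3of3 17
n_products_3of3 18
monoallelic_percent 94
artifact_null_percent 25.0
chi_square 46.2962962962963
chi_square_p 1.0165593635824554e-11
genes_per_cell_rate 0.64
repertoire_extrapolated 2.3
total_diversity 20856528
```

Reading the numbers: of the 18 products confirmed in all three tubes, 17
were monoallelic (**94%**), which a χ² test rejects against the 25%
single-molecule artifact null at *p* ≈ 10⁻¹¹ (far below 10⁻⁴) — the
monoallelic expression is real, not a sampling artifact. 18 of 28 cells
were positive for the 6-gene panel (**0.64** genes/cell), extrapolating to
**2.3** expressed β genes per cell over the full 22-gene cluster. One
isoform per allele per cluster gives 12·11 = 132, 22·21 = 462 and
19·18 = 342 ordered pairs, whose product (≈ 2.1 × 10⁷) is enough to give
more than 20 million Purkinje cells distinct identities.

The same machinery runs end-to-end on simulated data with known truth:

```bash
splitrace simulate --cells 200 --seed 7 --out out/
splitrace call --in out/dataset.tsv --variants out/variants.tsv \
               --polya out/polya.tsv --out out/
splitrace stats --calls out/calls.tsv --cells 200
```

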