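"""Generative model of split single-cell 3'-RACE data with known truth.

The model mirrors the measurement process the inference assumes:

1. *Promoter choice.*  For each parental allele independently, each isoform
   of the cluster is expressed with probability ``q`` (independent Bernoulli
   draws; the minimal assumption for stochastic, allele-autonomous promoter
   choice).
2. *Capture.*  Every expressed (allele, isoform) contributes a number of
   captured cDNA molecules drawn from a zero-truncated Poisson with mean
   ``mu``; each molecule picks a polyadenylation site by its usage weight.
3. *Split.*  The cell's cDNA is divided over ``n_tubes`` equal aliquots, so
   molecules fall into tubes uniformly and independently (multinomial).
4. *Amplification and readout.*  A tube is positive for a gene iff at least
   one template landed in it and a Bernoulli(``amp_prob``) amplification
   succeeds.  Direct sequencing of a positive tube reads, at every variant
   site, the majority allele's base -- or the IUPAC heterozygous code when
   the minor allele's template fraction reaches ``het_minor_fraction``
   (Sanger traces only reveal a minor allele above a trace fraction).

Ground truth (per-allele expressed sets, copy numbers, per-molecule polyA
choice) is retained so inference can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .allelic_inference import ProductRecord
from .cluster import (
    ACTIN,
    CONTROL_GENES,
    PCP2,
    ClusterSpec,
    StrainVariantMap,
    synthetic_variant_map,
)
from .errors import ParameterError

SILENT = "silent"
TRUTH_MONO_A = "monoallelic-A"
TRUTH_MONO_B = "monoallelic-B"
TRUTH_BIALLELIC = "biallelic"
NO_CELL_CONTROL = "no-cell-control"


@dataclass(frozen=True)
class SimParams:
    """Tunable parameters of the generative model.

    ``expression_prob`` (q) defaults to 0.052 so that the expected number of
    distinct expressed beta genes per cell, ``22 * (1 - (1-q)^2)``, is ~2.23,
    matching the repertoire scale estimated for Purkinje cells.
    ``copies_mean`` (mu, zero-truncated Poisson) defaults to 3 so that 2/3
    and 1/3 tube patterns arise at realistic rates.  ``amp_prob`` is the
    per-tube nested-PCR success probability given at least one template.
    ``control_copies_mean`` governs the abundant Pcp-2/actin controls.
    """

    n_tubes: int = 3
    expression_prob: float = 0.052
    copies_mean: float = 3.0
    amp_prob: float = 0.95
    het_minor_fraction: float = 0.20
    control_copies_mean: float = 100.0
    negative_control_interval: int = 7
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_tubes < 1:
            raise ParameterError("n_tubes must be >= 1")
        if not 0.0 <= self.expression_prob <= 1.0:
            raise ParameterError("expression_prob must be in [0, 1]")
        if self.copies_mean <= 0:
            raise ParameterError("copies_mean must be > 0")
        if not 0.0 < self.amp_prob <= 1.0:
            raise ParameterError("amp_prob must be in (0, 1]")
        if not 0.0 <= self.het_minor_fraction <= 0.5:
            raise ParameterError("het_minor_fraction must be in [0, 0.5]")
        if self.control_copies_mean <= 0:
            raise ParameterError("control_copies_mean must be > 0")
        if self.negative_control_interval < 1:
            raise ParameterError("negative_control_interval must be >= 1")


@dataclass
class CellTruth:
    """Ground truth for one simulated cell.

    ``copies`` maps ``(allele_name, gene)`` to captured cDNA copies;
    ``polya_counts`` maps the same key to a per-position molecule count
    (conserving ``copies``).
    """

    cell_id: str
    alleles: tuple[str, str]
    copies: dict[tuple[str, str], int] = field(default_factory=dict)
    polya_counts: dict[tuple[str, str], dict[int, int]] = field(default_factory=dict)

    @property
    def genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for (_, gene), n in self.copies.items():
            if n > 0:
                seen.setdefault(gene)
        return tuple(seen)

    def expressed(self, allele: str) -> frozenset:
        return frozenset(
            g for (a, g), n in self.copies.items() if a == allele and n > 0
        )

    def copies_by_allele(self, gene: str) -> tuple[int, int]:
        return tuple(self.copies.get((a, gene), 0) for a in self.alleles)

    def total_copies(self, gene: str) -> int:
        return sum(self.copies_by_allele(gene))

    def truth_class(self, gene: str) -> str:
        on_a, on_b = (n > 0 for n in self.copies_by_allele(gene))
        if on_a and on_b:
            return TRUTH_BIALLELIC
        if on_a:
            return TRUTH_MONO_A
        if on_b:
            return TRUTH_MONO_B
        return SILENT


@dataclass
class MoleculeAssignment:
    """Aggregated molecule-to-tube assignment for one cell.

    ``counts`` maps ``(allele, gene, polya_position)`` to a length-``n_tubes``
    vector of template counts; per-key sums equal the cell's captured copies
    (conservation).
    """

    n_tubes: int
    counts: dict[tuple[str, str, int], np.ndarray]

    def gene_allele_tube_counts(
        self, gene: str, alleles: Sequence[str]
    ) -> dict[str, np.ndarray]:
        out = {a: np.zeros(self.n_tubes, dtype=int) for a in alleles}
        for (allele, g, _), vec in self.counts.items():
            if g == gene:
                out[allele] += vec
        return out

    def total_assigned(self, gene: str) -> int:
        return int(
            sum(vec.sum() for (_, g, _), vec in self.counts.items() if g == gene)
        )


def _zero_truncated_poisson(mu: float, size: int, rng: np.random.Generator) -> np.ndarray:
    draws = rng.poisson(mu, size=size)
    while True:
        zeros = draws == 0
        if not zeros.any():
            return draws
        draws[zeros] = rng.poisson(mu, size=int(zeros.sum()))


def simulate_cell_truth(
    spec: ClusterSpec,
    variants: StrainVariantMap,
    params: SimParams,
    rng: np.random.Generator,
    cell_id: str = "cell",
) -> CellTruth:
    """Draw one cell's per-allele expressed isoforms, copies and polyA choices."""
    truth = CellTruth(cell_id=cell_id, alleles=variants.allele_names)
    q = params.expression_prob
    n = spec.n_isoforms
    for allele in variants.allele_names:
        expressed_mask = rng.random(n) < q
        idx = np.flatnonzero(expressed_mask)
        if idx.size == 0:
            continue
        copies = _zero_truncated_poisson(params.copies_mean, idx.size, rng)
        for i, c in zip(idx, copies):
            gene = spec.isoform_ids[int(i)]
            _add_molecules(truth, allele, gene, int(c), variants, rng)
    return truth


def _add_molecules(
    truth: CellTruth,
    allele: str,
    gene: str,
    n_copies: int,
    variants: StrainVariantMap,
    rng: np.random.Generator,
) -> None:
    """Register ``n_copies`` captured molecules, each drawing a polyA site."""
    if n_copies <= 0:
        return
    truth.copies[(allele, gene)] = truth.copies.get((allele, gene), 0) + n_copies
    pa = variants.polya_for(gene)
    if pa:
        weights = np.array([s.weight for s in pa])
        counts = rng.multinomial(n_copies, weights / weights.sum())
        positions = [s.position for s in pa]
    else:
        counts, positions = [n_copies], [0]
    store = truth.polya_counts.setdefault((allele, gene), {})
    for pos, c in zip(positions, counts):
        if c > 0:
            store[pos] = store.get(pos, 0) + int(c)


def add_control_expression(
    truth: CellTruth,
    variants: StrainVariantMap,
    params: SimParams,
    rng: np.random.Generator,
    genes: Sequence[str] = CONTROL_GENES,
) -> CellTruth:
    """Add abundant biallelic control transcripts (Pcp-2, beta-actin)."""
    for gene in genes:
        for allele in variants.allele_names:
            c = int(
                _zero_truncated_poisson(params.control_copies_mean, 1, rng)[0]
            )
            _add_molecules(truth, allele, gene, c, variants, rng)
    return truth


def split_and_amplify(
    truth: CellTruth,
    variants: StrainVariantMap,
    params: SimParams,
    rng: np.random.Generator,
    *,
    return_assignment: bool = False,
):
    """Split the cell's molecules over tubes and read out each gene.

    Returns the list of :class:`ProductRecord` for genes with at least one
    positive tube (optionally also the :class:`MoleculeAssignment`).  Every
    simulated gene must be present in the variant map.
    """
    k = params.n_tubes
    tube_probs = np.full(k, 1.0 / k)
    counts: dict[tuple[str, str, int], np.ndarray] = {}
    for (allele, gene), per_pos in truth.polya_counts.items():
        variants.sites_for(gene)  # raises ConfigurationError if unknown
        for pos, c in per_pos.items():
            counts[(allele, gene, pos)] = rng.multinomial(c, tube_probs)
    assignment = MoleculeAssignment(n_tubes=k, counts=counts)

    products: list[ProductRecord] = []
    for gene in truth.genes:
        per_allele = assignment.gene_allele_tube_counts(gene, truth.alleles)
        n_a, n_b = per_allele[truth.alleles[0]], per_allele[truth.alleles[1]]
        totals = n_a + n_b
        positives = []
        site_calls = []
        sites = variants.sites_for(gene)
        for t in range(k):
            positive = totals[t] > 0 and rng.random() < params.amp_prob
            positives.append(bool(positive))
            if not positive:
                site_calls.append(())
                continue
            minor = min(n_a[t], n_b[t])
            het = minor > 0 and minor / totals[t] >= params.het_minor_fraction
            calls = []
            for s in sites:
                if het:
                    base = s.het_code
                elif n_a[t] >= n_b[t]:
                    base = s.base_a
                else:
                    base = s.base_b
                calls.append((s.position, base))
            site_calls.append(tuple(calls))
        if any(positives):
            products.append(
                ProductRecord(
                    cell_id=truth.cell_id,
                    gene=gene,
                    tube_positives=tuple(positives),
                    site_calls=tuple(site_calls),
                )
            )
    if return_assignment:
        return products, assignment
    return products


@dataclass
class SimulatedExperiment:
    """A batch of simulated cells plus everything needed to analyse them."""

    dataset: pd.DataFrame
    truth: pd.DataFrame
    variants: StrainVariantMap
    params: SimParams
    spec: ClusterSpec
    seed: int | None
    products: dict[str, list[ProductRecord]]
    control_cells: tuple[str, ...]

    @property
    def cell_ids(self) -> tuple[str, ...]:
        return tuple(self.products)


def _site_calls_string(calls: tuple[tuple[int, str], ...]) -> str:
    if not calls:
        return "."
    return ";".join(f"{pos}:{base}" for pos, base in calls)


def simulate_experiment(
    n_cells: int,
    spec: ClusterSpec | None = None,
    variants: StrainVariantMap | None = None,
    params: SimParams | None = None,
    seed: int | None = None,
    *,
    assayed_genes: Sequence[str] | None = None,
    include_controls: bool = True,
) -> SimulatedExperiment:
    """Simulate a full split 3'-RACE experiment.

    Emits one dataset row per (cell, assayed gene, tube) and one truth row per
    (cell, expressed gene).  No-cell negative controls are interleaved after
    every ``params.negative_control_interval`` real cells and produce no
    products.  Reproducible given ``seed``.
    """
    if n_cells < 0:
        raise ParameterError("n_cells must be >= 0")
    spec = spec or ClusterSpec.beta()
    params = params or SimParams()
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    control_genes = CONTROL_GENES if include_controls else ()
    if variants is None:
        variants = synthetic_variant_map(tuple(spec.isoform_ids) + tuple(control_genes), rng)
    if assayed_genes is None:
        assayed_genes = tuple(spec.isoform_ids) + tuple(control_genes)

    interval = params.negative_control_interval
    dataset_rows: list[dict] = []
    truth_rows: list[dict] = []
    products: dict[str, list[ProductRecord]] = {}
    control_cells: list[str] = []

    n_real = 0
    sample_index = 0
    while n_real < n_cells:
        sample_index += 1
        cell_id = f"1-{sample_index}"
        is_control = include_controls and sample_index % (interval + 1) == 0
        if is_control:
            control_cells.append(cell_id)
            products[cell_id] = []
            truth_rows.append(
                {
                    "cell_id": cell_id,
                    "is_control": 1,
                    "gene": ".",
                    "truth_class": NO_CELL_CONTROL,
                    "copies_a": 0,
                    "copies_b": 0,
                }
            )
            cell_products: list[ProductRecord] = []
        else:
            n_real += 1
            truth = simulate_cell_truth(spec, variants, params, rng, cell_id)
            if include_controls:
                add_control_expression(truth, variants, params, rng, control_genes)
            cell_products = split_and_amplify(truth, variants, params, rng)
            products[cell_id] = cell_products
            for gene in truth.genes:
                ca, cb = truth.copies_by_allele(gene)
                truth_rows.append(
                    {
                        "cell_id": cell_id,
                        "is_control": 0,
                        "gene": gene,
                        "truth_class": truth.truth_class(gene),
                        "copies_a": ca,
                        "copies_b": cb,
                    }
                )
        by_gene = {p.gene: p for p in cell_products}
        for gene in assayed_genes:
            rec = by_gene.get(gene)
            for t in range(params.n_tubes):
                positive = bool(rec and rec.tube_positives[t])
                dataset_rows.append(
                    {
                        "cell_id": cell_id,
                        "gene": gene,
                        "tube_index": t + 1,
                        "positive": int(positive),
                        "site_calls": _site_calls_string(rec.site_calls[t])
                        if rec
                        else ".",
                    }
                )

    dataset_cols = ["cell_id", "gene", "tube_index", "positive", "site_calls"]
    truth_cols = ["cell_id", "is_control", "gene", "truth_class", "copies_a", "copies_b"]
    dataset = pd.DataFrame(dataset_rows, columns=dataset_cols)
    truth_df = pd.DataFrame(truth_rows, columns=truth_cols)
    return SimulatedExperiment(
        dataset=dataset,
        truth=truth_df,
        variants=variants,
        params=params,
        spec=spec,
        seed=seed,
        products=products,
        control_cells=tuple(control_cells),
    )


def dataset_to_products(dataset: pd.DataFrame) -> dict[str, list[ProductRecord]]:
    """Rebuild per-cell ProductRecords from a dataset table.

    Genes with no positive tube yield no record, matching the simulator's
    in-memory output.
    """
    products: dict[str, list[ProductRecord]] = {}
    for cell_id, cell_df in dataset.groupby("cell_id", sort=False):
        recs: list[ProductRecord] = []
        for gene, gene_df in cell_df.groupby("gene", sort=False):
            gene_df = gene_df.sort_values("tube_index")
            positives = tuple(bool(v) for v in gene_df["positive"])
            if not any(positives):
                continue
            site_calls = []
            for s in gene_df["site_calls"]:
                if s == "." or s == "" or pd.isna(s):
                    site_calls.append(())
                else:
                    site_calls.append(
                        tuple(
                            (int(part.split(":")[0]), part.split(":")[1])
                            for part in str(s).split(";")
                        )
                    )
            recs.append(
                ProductRecord(
                    cell_id=str(cell_id),
                    gene=str(gene),
                    tube_positives=positives,
                    site_calls=tuple(site_calls),
                )
            )
        products[str(cell_id)] = recs
    return products
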