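"""Product classification and allele calling for split 3'-RACE tables.

One cell's cDNA is split across ``n`` PCR tubes before nested amplification,
so a transcript present as several molecules should amplify in every tube
(3/3), while a single stray molecule can reach at most one tube.  Direct
sequencing of each tube's product at known strain polymorphisms then reads
out the parental allele(s) present.  This module turns per-tube positivity
and per-tube base calls into one of five product-level classes:

``monoallelic-A`` / ``monoallelic-B``
    every readable tube reports the same pure parental allele;
``biallelic``
    any tube is heterozygous at a variant site, or two clean tubes report
    opposite pure alleles (both alleles demonstrably present in the cell);
``inconsistent``
    variant sites *within* one tube disagree on the allele;
``insufficient``
    no readable variant site in any positive tube.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as _scistats

from .cluster import ACTIN, CONTROL_GENES, PCP2, StrainVariantMap, VariantSite
from .errors import ParameterError

MONOALLELIC_A = "monoallelic-A"
MONOALLELIC_B = "monoallelic-B"
BIALLELIC = "biallelic"
INCONSISTENT = "inconsistent"
INSUFFICIENT = "insufficient"

ALLELE_CALLS = (MONOALLELIC_A, MONOALLELIC_B, BIALLELIC, INCONSISTENT, INSUFFICIENT)

#: Per-tube site calls: one tuple of ``(position, base)`` pairs per tube,
#: empty for negative tubes.  ``base`` is a pure base or an IUPAC het code.
SiteCalls = tuple[tuple[tuple[int, str], ...], ...]


@dataclass
class ProductRecord:
    """One (cell, gene) 3'-RACE outcome across the split tubes."""

    cell_id: str
    gene: str
    tube_positives: tuple[bool, ...]
    site_calls: SiteCalls = ()
    allele_call: str | None = None

    def __post_init__(self) -> None:
        self.tube_positives = tuple(bool(t) for t in self.tube_positives)
        if not self.tube_positives:
            raise ParameterError("tube_positives must not be empty")
        if self.site_calls:
            if len(self.site_calls) != len(self.tube_positives):
                raise ParameterError("site_calls must have one entry per tube")
            self.site_calls = tuple(
                tuple((int(p), str(b)) for p, b in tube) for tube in self.site_calls
            )
        else:
            self.site_calls = tuple(() for _ in self.tube_positives)

    @property
    def pattern(self) -> str:
        return classify_tube_pattern(self.tube_positives)

    @property
    def n_positive(self) -> int:
        return sum(self.tube_positives)


@dataclass(frozen=True)
class CellQC:
    """QC verdict for one cell.

    A cell passes only if the Purkinje marker (Pcp-2) and beta-actin both
    amplified and the actin product reads biallelic, as an abundant
    housekeeping transcript must.
    """

    cell_id: str
    pcp2_positive: bool
    actin_positive: bool
    actin_biallelic: bool
    reason: str = ""

    @property
    def passed(self) -> bool:
        return self.pcp2_positive and self.actin_positive and self.actin_biallelic


def classify_tube_pattern(tube_positives: Sequence[bool]) -> str:
    """Return the ``k/n`` positivity pattern, e.g. ``"3/3"`` or ``"2/3"``."""
    if len(tube_positives) == 0:
        raise ParameterError("tube_positives must not be empty")
    k = sum(bool(t) for t in tube_positives)
    return f"{k}/{len(tube_positives)}"


def _tube_allele(
    calls: Iterable[tuple[int, str]], sites_by_pos: Mapping[int, VariantSite]
) -> str | None:
    """Collapse one tube's site calls to 'A', 'B', 'het', 'inconsistent'.

    Bases matching neither allele nor the het code are sequencing-error sites
    and are excluded; a tube with no readable site returns ``None``.
    """
    seen: set[str] = set()
    for pos, base in calls:
        site = sites_by_pos.get(pos)
        if site is None:
            continue
        if base == site.base_a:
            seen.add("A")
        elif base == site.base_b:
            seen.add("B")
        elif base == site.het_code:
            seen.add("het")
        # else: sequencing-error site, excluded
    if not seen:
        return None
    if "het" in seen:
        return "het"
    if seen == {"A"}:
        return "A"
    if seen == {"B"}:
        return "B"
    return "inconsistent"  # pure A and pure B sites within one tube


def call_product_allele(
    site_calls: SiteCalls, variant_sites: Sequence[VariantSite]
) -> str:
    """Classify a product from its per-tube base calls at the variant sites.

    Parameters
    ----------
    site_calls:
        One tuple of ``(position, base)`` pairs per tube (empty for negative
        tubes).
    variant_sites:
        The gene's known strain polymorphisms.
    """
    sites_by_pos = {s.position: s for s in variant_sites}
    tube_states = [
        _tube_allele(tube, sites_by_pos) for tube in site_calls if len(tube) > 0
    ]
    tube_states = [t for t in tube_states if t is not None]
    if not tube_states:
        return INSUFFICIENT
    if "inconsistent" in tube_states:
        return INCONSISTENT
    observed = set(tube_states)
    if "het" in observed or observed == {"A", "B"}:
        return BIALLELIC
    return MONOALLELIC_A if observed == {"A"} else MONOALLELIC_B


def call_products(
    products: Iterable[ProductRecord], variants: StrainVariantMap
) -> list[ProductRecord]:
    """Fill ``allele_call`` on each record and return the same records."""
    out = []
    for rec in products:
        rec.allele_call = call_product_allele(
            rec.site_calls, variants.sites_for(rec.gene)
        )
        out.append(rec)
    return out


def qc_gate(
    cell_records: Iterable[ProductRecord],
    variants: StrainVariantMap,
    *,
    pcp2_gene: str = PCP2,
    actin_gene: str = ACTIN,
) -> CellQC:
    """QC one cell from its product records (controls included).

    A control is "positive" if it amplified in at least one tube; no-cell
    controls, which yield no products at all, therefore fail.  Missing control
    rows fail the cell with an explanatory reason.
    """
    records = list(cell_records)
    cell_ids = {r.cell_id for r in records}
    if len(cell_ids) > 1:
        raise ParameterError(f"qc_gate expects one cell, got {sorted(cell_ids)}")
    cell_id = records[0].cell_id if records else "?"

    by_gene = {r.gene: r for r in records}
    pcp2 = by_gene.get(pcp2_gene)
    actin = by_gene.get(actin_gene)

    pcp2_positive = pcp2 is not None and pcp2.n_positive >= 1
    actin_positive = actin is not None and actin.n_positive >= 1
    actin_biallelic = False
    reasons = []
    if pcp2 is None:
        reasons.append(f"missing {pcp2_gene} control")
    elif not pcp2_positive:
        reasons.append(f"{pcp2_gene} negative")
    if actin is None:
        reasons.append(f"missing {actin_gene} control")
    elif not actin_positive:
        reasons.append(f"{actin_gene} negative")
    else:
        call = actin.allele_call or call_product_allele(
            actin.site_calls, variants.sites_for(actin_gene)
        )
        actin_biallelic = call == BIALLELIC
        if not actin_biallelic:
            reasons.append(f"{actin_gene} not biallelic ({call})")
    return CellQC(
        cell_id=cell_id,
        pcp2_positive=pcp2_positive,
        actin_positive=actin_positive,
        actin_biallelic=actin_biallelic,
        reason="; ".join(reasons),
    )


@dataclass(frozen=True)
class MonoallelicSummary:
    """Monoallelic vs biallelic tally among products of a given pattern.

    ``fraction`` is ``None`` when no product is eligible; ``percent`` rounds
    to the nearest integer percent, the precision at which such fractions are
    conventionally reported.
    """

    n_monoallelic: int
    n_biallelic: int
    n_inconsistent: int
    n_insufficient: int
    pattern_filter: str

    @property
    def n_eligible(self) -> int:
        return self.n_monoallelic + self.n_biallelic

    @property
    def fraction(self) -> float | None:
        if self.n_eligible == 0:
            return None
        return self.n_monoallelic / self.n_eligible

    @property
    def percent(self) -> int | None:
        f = self.fraction
        return None if f is None else round(100 * f)


def aggregate_monoallelic_fraction(
    calls: pd.DataFrame,
    pattern_filter: str = "3/3",
    *,
    control_genes: Sequence[str] = CONTROL_GENES,
) -> MonoallelicSummary:
    """Tally allele calls among products matching ``pattern_filter``.

    ``calls`` must have columns ``gene``, ``pattern`` and ``allele_call`` and
    should contain only QC-passed cells.  Control genes are dropped.
    Inconsistent/insufficient products are counted separately and never enter
    the fraction's numerator or denominator.
    """
    required = {"gene", "pattern", "allele_call"}
    missing = required - set(calls.columns)
    if missing:
        raise ParameterError(f"calls table lacks columns: {sorted(missing)}")
    sub = calls[
        (calls["pattern"] == pattern_filter) & ~calls["gene"].isin(control_genes)
    ]
    ac = sub["allele_call"].astype(str)
    n_mono = int(ac.str.startswith("monoallelic").sum())
    n_bi = int((ac == BIALLELIC).sum())
    n_inc = int((ac == INCONSISTENT).sum())
    n_ins = int((ac == INSUFFICIENT).sum())
    return MonoallelicSummary(n_mono, n_bi, n_inc, n_ins, pattern_filter)


@dataclass(frozen=True)
class AlleleBalance:
    """Counts of monoallelic products per parental allele, with a two-sided
    exact binomial test against equal usage (p=0.5)."""

    n_allele_a: int
    n_allele_b: int
    allele_names: tuple[str, str]
    p_value: float | None

    @classmethod
    def from_counts(
        cls, n_allele_a: int, n_allele_b: int, allele_names: tuple[str, str] = ("A", "B")
    ) -> "AlleleBalance":
        total = n_allele_a + n_allele_b
        if total == 0:
            return cls(0, 0, allele_names, None)
        p = _scistats.binomtest(n_allele_a, total, 0.5, alternative="two-sided").pvalue
        return cls(n_allele_a, n_allele_b, allele_names, float(p))


def allele_balance(
    calls: pd.DataFrame, allele_names: tuple[str, str] = ("A", "B")
) -> AlleleBalance:
    """Parental-allele balance among monoallelic products in a calls table."""
    ac = calls["allele_call"].astype(str)
    n_a = int((ac == MONOALLELIC_A).sum())
    n_b = int((ac == MONOALLELIC_B).sum())
    return AlleleBalance.from_counts(n_a, n_b, allele_names)


def products_to_calls_table(products: Iterable[ProductRecord]) -> pd.DataFrame:
    """Per-product call table: cell_id, gene, pattern, allele_call."""
    rows = [
        {
            "cell_id": r.cell_id,
            "gene": r.gene,
            "pattern": r.pattern,
            "allele_call": r.allele_call if r.allele_call is not None else ".",
        }
        for r in products
    ]
    return pd.DataFrame(rows, columns=["cell_id", "gene", "pattern", "allele_call"])
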