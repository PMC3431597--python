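"""Domain types shared across the pipeline.

The clustered protocadherins (Pcdh) are three tandem gene clusters on mouse
chromosome 18.  Each variable isoform has its own promoter; the beta cluster
consists of 22 single-exon genes with no constant exons, so its transcripts
are read out directly as 3'-polyadenylated mRNAs.  Allele-of-origin is
resolved in F1 hybrids (B6 x JF1 by default) through strain polymorphisms in
the 3' region of each gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ConfigurationError, ParameterError

#: IUPAC ambiguity code for a heterozygous base call (two-base mixtures only).
IUPAC_HET: dict[frozenset, str] = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

_NUCLEOTIDES = frozenset("ACGT")

#: Default parental strain labels for the F1 hybrid design.
DEFAULT_ALLELES: tuple[str, str] = ("B6", "JF1")

#: Control transcripts used by the QC gate: a Purkinje-cell identity marker
#: and an abundant housekeeping gene expected biallelic.
PCP2 = "Pcp2"
ACTIN = "actin"
CONTROL_GENES: tuple[str, str] = (PCP2, ACTIN)


@dataclass(frozen=True)
class ClusterSpec:
    """Isoform inventory of one Pcdh cluster.

    Parameters
    ----------
    cluster_name:
        One of ``"alpha"``, ``"beta"``, ``"gamma"``.
    n_isoforms:
        Number of variable isoforms (12 alpha, 22 beta, 19 gamma by default).
    isoform_ids:
        Ordered unique labels, e.g. ``("b1", ..., "b22")``.
    """

    cluster_name: str
    n_isoforms: int
    isoform_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_isoforms < 1:
            raise ParameterError("n_isoforms must be >= 1")
        if len(self.isoform_ids) != self.n_isoforms:
            raise ParameterError(
                f"isoform_ids has {len(self.isoform_ids)} labels for "
                f"n_isoforms={self.n_isoforms}"
            )
        if len(set(self.isoform_ids)) != self.n_isoforms:
            raise ParameterError("isoform labels must be unique")

    @staticmethod
    def alpha() -> "ClusterSpec":
        return ClusterSpec("alpha", 12, tuple(f"a{i}" for i in range(1, 13)))

    @staticmethod
    def beta(n_isoforms: int = 22) -> "ClusterSpec":
        return ClusterSpec(
            "beta", n_isoforms, tuple(f"b{i}" for i in range(1, n_isoforms + 1))
        )

    @staticmethod
    def gamma() -> "ClusterSpec":
        return ClusterSpec("gamma", 19, tuple(f"g{i}" for i in range(1, 20)))


@dataclass(frozen=True)
class VariantSite:
    """A biallelic strain polymorphism on a gene's 3' region.

    ``position`` is 1-based on the gene sequence; ``base_a``/``base_b`` are
    the bases carried by the first/second parental allele.
    """

    position: int
    base_a: str
    base_b: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ParameterError("variant position must be 1-based (>= 1)")
        for b in (self.base_a, self.base_b):
            if b not in _NUCLEOTIDES:
                raise ParameterError(f"variant base {b!r} is not one of ACGT")
        if self.base_a == self.base_b:
            raise ParameterError(
                f"variant at {self.position} has identical bases on both alleles"
            )

    @property
    def het_code(self) -> str:
        """IUPAC code reported when both alleles are read in one tube."""
        return IUPAC_HET[frozenset((self.base_a, self.base_b))]


@dataclass(frozen=True)
class PolyASite:
    """A cleavage/poly(A)-addition position with its usage probability."""

    position: int
    weight: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ParameterError("polyA position must be 1-based (>= 1)")
        if not 0.0 < self.weight <= 1.0:
            raise ParameterError("polyA usage weight must be in (0, 1]")


@dataclass
class StrainVariantMap:
    """Per-gene strain polymorphisms and polyadenylation sites.

    A gene without at least one variant site cannot be allele-called and is
    rejected at construction, mirroring the assay-design requirement that
    every target carry a JF1-vs-B6 polymorphism near its polyA signal.
    """

    variant_sites: Mapping[str, tuple[VariantSite, ...]]
    polya_sites: Mapping[str, tuple[PolyASite, ...]]
    allele_names: tuple[str, str] = DEFAULT_ALLELES

    def __post_init__(self) -> None:
        if len(self.allele_names) != 2 or self.allele_names[0] == self.allele_names[1]:
            raise ParameterError("allele_names must be two distinct labels")
        self.variant_sites = {g: tuple(v) for g, v in self.variant_sites.items()}
        self.polya_sites = {g: tuple(v) for g, v in self.polya_sites.items()}
        for gene, sites in self.variant_sites.items():
            if not sites:
                raise ConfigurationError(
                    f"gene {gene!r} has no variant sites; allele calling is "
                    "impossible for it"
                )
        for gene, sites in self.polya_sites.items():
            if sites:
                total = sum(s.weight for s in sites)
                if abs(total - 1.0) > 1e-9:
                    raise ParameterError(
                        f"polyA usage weights for {gene!r} sum to {total}, not 1"
                    )

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.variant_sites)

    def sites_for(self, gene: str) -> tuple[VariantSite, ...]:
        try:
            return self.variant_sites[gene]
        except KeyError:
            raise ConfigurationError(
                f"gene {gene!r} is absent from the variant map"
            ) from None

    def polya_for(self, gene: str) -> tuple[PolyASite, ...]:
        return self.polya_sites.get(gene, ())


def synthetic_variant_map(
    genes: Iterable[str],
    rng: np.random.Generator | None = None,
    *,
    n_variant_sites: int = 2,
    n_polya_range: tuple[int, int] = (1, 3),
    region: tuple[int, int] = (2200, 2600),
    allele_names: tuple[str, str] = DEFAULT_ALLELES,
) -> StrainVariantMap:
    """Generate a random but valid variant/polyA map for simulation.

    Each gene receives ``n_variant_sites`` substitutions at distinct positions
    in ``region`` (1-based), with distinct bases on the two alleles, and a
    uniformly drawn number of polyA sites with Dirichlet-flat usage weights.
    """
    rng = np.random.default_rng(rng)
    bases = sorted(_NUCLEOTIDES)
    lo, hi = region
    variant_sites: dict[str, tuple[VariantSite, ...]] = {}
    polya_sites: dict[str, tuple[PolyASite, ...]] = {}
    for gene in genes:
        positions = rng.choice(np.arange(lo, hi), size=n_variant_sites, replace=False)
        sites = []
        for pos in sorted(int(p) for p in positions):
            a, b = rng.choice(len(bases), size=2, replace=False)
            sites.append(VariantSite(pos, bases[a], bases[b]))
        variant_sites[gene] = tuple(sites)

        n_pa = int(rng.integers(n_polya_range[0], n_polya_range[1] + 1))
        pa_positions = sorted(
            int(p) for p in rng.choice(np.arange(hi, hi + 200), size=n_pa, replace=False)
        )
        weights = rng.dirichlet(np.ones(n_pa))
        # renormalize exactly so the invariant holds despite float rounding
        weights = weights / weights.sum()
        polya_sites[gene] = tuple(
            PolyASite(p, float(w)) for p, w in zip(pa_positions, weights)
        )
    return StrainVariantMap(variant_sites, polya_sites, allele_names)
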