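"""Statistical core: artifact null, chi-square, repertoire, diversity.

The split design exists to rule out a sampling artifact: if each of the k
tubes amplified a single cDNA molecule from a truly biallelic transcript
pool, all k tubes would show the same parental allele with probability
``2 * (1/2)**k`` (25% at k=3), so an observed monoallelic fraction must be
tested against that null rather than against zero.  The repertoire
estimator extrapolates the per-cell expression rate from the assayed subset
of isoforms to the full cluster, and the diversity combinatorics count
ordered pairs of distinct isoforms (one per allele) per cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _scistats

from .allelic_inference import BIALLELIC, call_product_allele
from .cluster import StrainVariantMap, VariantSite
from .errors import ParameterError
from .synthetic_data import CellTruth, SimParams, split_and_amplify

SINGLE_MOLECULE = "single-molecule-per-tube"
GENERAL = "general"


@dataclass(frozen=True)
class ArtifactNullModel:
    """Null model for artifactual all-tubes-same-allele patterns.

    In the ``single-molecule-per-tube`` regime each tube independently
    amplifies one molecule whose parental allele is equiprobable; this is
    the only regime with a closed-form rate.  The ``general`` regime places
    ``molecules_per_allele`` copies of each allele in the pool and runs the
    full split/amplify/readout engine.
    """

    n_tubes: int = 3
    regime: str = SINGLE_MOLECULE
    molecules_per_allele: int = 1
    amp_prob: float = 1.0
    het_minor_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.n_tubes < 1:
            raise ParameterError("n_tubes must be >= 1")
        if self.regime not in (SINGLE_MOLECULE, GENERAL):
            raise ParameterError(f"unknown regime {self.regime!r}")
        if self.molecules_per_allele < 1:
            raise ParameterError("molecules_per_allele must be >= 1")


@dataclass(frozen=True)
class ArtifactRateEstimate:
    rate: float
    standard_error: float
    n_reps: int


def artifact_null_probability(n_tubes: int) -> float:
    """P(all tubes show the same allele) under the single-molecule null.

    Each of ``n_tubes`` tubes amplifies one molecule whose parental allele is
    an independent fair draw, so the probability that all agree is
    ``2 * (1/2)**n_tubes`` -- 0.25 for the three-tube design.
    """
    if n_tubes < 1:
        raise ParameterError("n_tubes must be >= 1")
    return 2.0 * 0.5**n_tubes


def monte_carlo_artifact_rate(
    model: ArtifactNullModel, n_reps: int, seed: int | None = None
) -> ArtifactRateEstimate:
    """Simulated fraction of truly biallelic cells read as 3/3 monoallelic.

    The single-molecule regime is simulated directly (one fair allele draw
    per tube); the general regime pushes a biallelic cell with
    ``molecules_per_allele`` copies per allele through the split/amplify
    engine and counts replicates in which every tube is positive and the
    product call is monoallelic.
    """
    if n_reps < 100:
        raise ParameterError("n_reps must be >= 100")
    rng = np.random.default_rng(seed)
    k = model.n_tubes
    if model.regime == SINGLE_MOLECULE:
        draws = rng.integers(0, 2, size=(n_reps, k))
        same = np.all(draws == draws[:, :1], axis=1)
        rate = float(same.mean())
    else:
        params = SimParams(
            n_tubes=k,
            amp_prob=model.amp_prob,
            het_minor_fraction=model.het_minor_fraction,
        )
        site = VariantSite(position=1, base_a="A", base_b="G")
        variants = StrainVariantMap({"g": (site,)}, {"g": ()}, ("A1", "A2"))
        hits = 0
        for _ in range(n_reps):
            truth = CellTruth(cell_id="rep", alleles=("A1", "A2"))
            truth.copies = {
                ("A1", "g"): model.molecules_per_allele,
                ("A2", "g"): model.molecules_per_allele,
            }
            truth.polya_counts = {
                ("A1", "g"): {0: model.molecules_per_allele},
                ("A2", "g"): {0: model.molecules_per_allele},
            }
            products = split_and_amplify(truth, variants, params, rng)
            if not products:
                continue
            rec = products[0]
            if rec.n_positive != k:
                continue
            call = call_product_allele(rec.site_calls, (site,))
            if call.startswith("monoallelic"):
                hits += 1
        rate = hits / n_reps
    se = math.sqrt(max(rate * (1.0 - rate), 1e-12) / n_reps)
    return ArtifactRateEstimate(rate=rate, standard_error=se, n_reps=n_reps)


def chi_square_monoallelic(
    n_mono: int, n_bi: int, null_rate: float
) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square of (mono, bi) counts vs the null rate.

    Two categories, no continuity correction: the observed counts are tested
    against expected ``(N * null_rate, N * (1 - null_rate))``.
    """
    total = n_mono + n_bi
    if total < 1:
        raise ParameterError("n_mono + n_bi must be >= 1")
    if not 0.0 < null_rate < 1.0:
        raise ParameterError("null_rate must be in (0, 1)")
    expected = [total * null_rate, total * (1.0 - null_rate)]
    statistic, p_value = _scistats.chisquare([n_mono, n_bi], f_exp=expected)
    return float(statistic), float(p_value)


@dataclass(frozen=True)
class RepertoireEstimate:
    """Per-cell expression rate over the assayed genes, extrapolated to the
    whole cluster assuming no frequency distortion between isoforms."""

    n_positive: int
    n_cells: int
    n_assayed: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if not 0 <= self.n_positive:
            raise ParameterError("n_positive must be >= 0")
        if self.n_assayed < 1 or self.n_total < self.n_assayed:
            raise ParameterError("need 1 <= n_assayed <= n_total")

    @property
    def rate(self) -> float:
        return genes_per_cell(self.n_positive, self.n_cells)

    @property
    def genes_per_cell_extrapolated(self) -> float:
        return extrapolate_repertoire(self.rate, self.n_assayed, self.n_total)


def genes_per_cell(n_positive_cells: int, n_cells: int) -> float:
    """Expression rate per assayed gene set, to 2 decimal places (18/28 -> 0.64)."""
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    if not 0 <= n_positive_cells:
        raise ParameterError("n_positive_cells must be >= 0")
    return round(n_positive_cells / n_cells, 2)


def extrapolate_repertoire(rate: float, n_assayed: int, n_total: int) -> float:
    """Scale the assayed-subset rate to the full cluster, to 1 decimal place.

    Assumes no distortion of expression frequencies between isoforms, so the
    per-cell expectation scales by ``n_total / n_assayed`` (0.64 * 22/6 -> 2.3).
    """
    if n_assayed < 1:
        raise ParameterError("n_assayed must be >= 1")
    if n_total < n_assayed:
        raise ParameterError("n_total must be >= n_assayed")
    return round(rate * n_total / n_assayed, 1)


def expected_genes_per_cell(n_isoforms: int, expression_prob: float) -> float:
    """Closed-form E[# distinct expressed genes] = n * (1 - (1-q)^2) for a
    diploid cell with independent per-allele expression probability q."""
    return n_isoforms * (1.0 - (1.0 - expression_prob) ** 2)


def cluster_pair_combinations(n_isoforms: int) -> int:
    """Ordered pairs of distinct isoforms, one per allele: n * (n - 1)."""
    if n_isoforms < 1:
        raise ParameterError("n_isoforms must be >= 1")
    return n_isoforms * (n_isoforms - 1)


def total_diversity(counts: Iterable[int]) -> int:
    """Product of per-cluster pair combinations, in exact integer arithmetic.

    With the (12, 22, 19) isoform counts of the alpha/beta/gamma clusters this
    exceeds 20 million distinct single-cell identities.
    """
    counts = list(counts)
    for c in counts:
        if c < 0:
            raise ParameterError("cluster isoform counts must be >= 0")
    return math.prod(cluster_pair_combinations(c) if c >= 1 else 0 for c in counts)
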