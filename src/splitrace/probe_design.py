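"""Sequence computations behind the assay design.

Three problems are covered:

* probe placement -- a *pan* probe must sit in a window conserved across the
  whole isoform family (high minimum identity), while an *isoform-specific*
  probe needs a window divergent from every paralog (low maximum identity);
* strain-discriminating variants -- substitutions/indels between the two
  parental haplotypes near the functional polyA signal, which power the
  allele calling;
* 3'-terminus structure -- canonical polyadenylation signal hexamers
  upstream of a cleavage site, and single-linkage clustering of observed
  cleavage positions into distinct termini.

Pairwise "similarity" is operationalized as global-alignment percent
identity with terminal gaps excluded (match +1, mismatch -1, gap open -2,
extend -0.5; end gaps free).  Window scanning, however, compares candidate
probe windows to each comparison sequence *ungapped* (best identity over
all sliding offsets): a probe hybridizes over its full contiguous length,
and a gapped score would let a short perfect sub-match masquerade as a
fully identical probe.  Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .cluster import VariantSite
from .errors import ParameterError

#: Canonical polyadenylation signal hexamers.
POLYA_HEXAMERS: tuple[str, ...] = ("AATAAA", "ATTAAA")

#: Alignment scoring, recorded in outputs for reproducibility.
ALIGN_SCORING = {
    "match": 1.0,
    "mismatch": -1.0,
    "open_gap": -2.0,
    "extend_gap": -0.5,
}

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class ProbeWindow:
    """A candidate probe interval on a target sequence (1-based inclusive)."""

    gene: str
    start: int
    end: int
    min_identity_within_family: float | None = None
    max_identity_to_offtargets: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParameterError("window start must be <= end")
        for v in (self.min_identity_within_family, self.max_identity_to_offtargets):
            if v is not None and not 0.0 <= v <= 100.0:
                raise ParameterError("identities must be percentages in [0, 100]")


@dataclass(frozen=True)
class PolyASignalHit:
    """A polyadenylation-signal hexamer upstream of a cleavage position."""

    hexamer: str
    start: int  # 1-based start of the hexamer
    distance: int  # cleavage_position - start


@dataclass(frozen=True)
class CleavageSiteCluster:
    """A group of cleavage positions forming one distinct 3'-terminus."""

    representative: int
    members: tuple[int, ...]
    gene: str | None = None
    signal: str | None = None
    signal_position: int | None = None


@dataclass(frozen=True)
class DiscriminatingVariant:
    """A sequence difference between the two parental strains.

    ``position`` is 1-based on strain A (for deletions, the base preceding
    the missing segment).  ``kind`` is ``substitution``, ``insertion``
    (present in A only) or ``deletion`` (present in B only).
    """

    position: int
    kind: str
    bases_a: str
    bases_b: str


def _check_sequence(seq: str, name: str = "sequence") -> str:
    if not seq:
        raise ParameterError(f"{name} must be non-empty")
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ParameterError(f"{name} contains non-nucleotide characters: {sorted(bad)}")
    return seq


def make_aligner(free_end_gaps: bool = True) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = ALIGN_SCORING["match"]
    aligner.mismatch_score = ALIGN_SCORING["mismatch"]
    aligner.open_gap_score = ALIGN_SCORING["open_gap"]
    aligner.extend_gap_score = ALIGN_SCORING["extend_gap"]
    if free_end_gaps:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # Biopython < 1.86 naming
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def _identity_from_alignment(alignment, seq_a: str, seq_b: str) -> float:
    """Matches / alignment columns between the first and last aligned blocks
    (terminal gaps excluded)."""
    blocks_a, blocks_b = alignment.aligned
    if len(blocks_a) == 0:
        return 0.0
    matches = 0
    columns = 0
    prev_a_end = prev_b_end = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            columns += (a0 - prev_a_end) + (b0 - prev_b_end)  # internal gaps
        for ca, cb in zip(seq_a[a0:a1], seq_b[b0:b1]):
            columns += 1
            if ca == cb:
                matches += 1
        prev_a_end, prev_b_end = a1, b1
    return 100.0 * matches / columns if columns else 0.0


def global_percent_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of the best global alignment of two sequences.

    Symmetric; identical sequences score 100.  Terminal gaps are excluded
    from the column count, so a short probe aligned inside a longer gene is
    scored only over the aligned span.
    """
    seq_a = _check_sequence(seq_a, "seq_a")
    seq_b = _check_sequence(seq_b, "seq_b")
    aligner = make_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    return _identity_from_alignment(alignment, seq_a, seq_b)


def best_ungapped_identity(probe: str, subject: str) -> float:
    """Best percent identity of an ungapped sliding comparison.

    The shorter sequence is slid along the longer one; identity at each
    offset is matches over the shorter length, and the maximum is returned.
    This is the hybridization-relevant measure for contiguous probes.
    """
    probe = _check_sequence(probe, "probe")
    subject = _check_sequence(subject, "subject")
    short, long_ = (probe, subject) if len(probe) <= len(subject) else (subject, probe)
    s = np.frombuffer(short.encode(), dtype=np.uint8)
    l = np.frombuffer(long_.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(l, len(s))
    per_offset = (windows == s).mean(axis=1)
    return 100.0 * float(per_offset.max())


def _as_named(seqs) -> list[tuple[str, str]]:
    if isinstance(seqs, Mapping):
        return [(str(k), _check_sequence(v, k)) for k, v in seqs.items()]
    return [(str(k), _check_sequence(v, k)) for k, v in seqs]


def find_pan_probe_region(
    family,
    window_length: int,
    min_identity: float,
    *,
    reference: str | None = None,
    step: int = 1,
) -> list[ProbeWindow]:
    """Windows on a reference conserved across every family member.

    ``family`` maps names to sequences (>= 2 members).  Each window of the
    reference is compared ungapped (:func:`best_ungapped_identity`) to every
    *other* member; windows whose minimum identity is >= ``min_identity``
    are returned sorted by that minimum, descending.  No qualifying window
    yields an empty list.
    """
    members = _as_named(family)
    if len(members) < 2:
        raise ParameterError("pan-probe search needs >= 2 family members")
    if reference is None:
        ref_name, ref_seq = members[0]
    else:
        match = [m for m in members if m[0] == reference]
        if not match:
            raise ParameterError(f"reference {reference!r} not in family")
        ref_name, ref_seq = match[0]
    others = [(n, s) for n, s in members if n != ref_name]
    if window_length > min(len(s) for _, s in members):
        raise ParameterError("window_length exceeds the shortest family sequence")

    hits = []
    for start0 in range(0, len(ref_seq) - window_length + 1, step):
        window = ref_seq[start0 : start0 + window_length]
        worst = min(best_ungapped_identity(window, s) for _, s in others)
        if worst >= min_identity:
            hits.append(
                ProbeWindow(
                    gene=ref_name,
                    start=start0 + 1,
                    end=start0 + window_length,
                    min_identity_within_family=worst,
                )
            )
    hits.sort(key=lambda w: (-w.min_identity_within_family, w.start))
    return hits


def find_specific_probe_region(
    target: tuple[str, str],
    offtargets,
    window_length: int,
    max_identity: float,
    *,
    step: int = 1,
) -> list[ProbeWindow]:
    """Windows on the target divergent from every off-target paralog.

    Returns windows whose *maximum* identity to any off-target is
    <= ``max_identity``, sorted by that maximum ascending.  An empty
    off-target set is an error (specificity is undefined).
    """
    name, seq = target[0], _check_sequence(target[1], target[0])
    off = _as_named(offtargets)
    if not off:
        raise ParameterError("specific-probe search needs >= 1 off-target")
    if window_length > len(seq):
        raise ParameterError("window_length exceeds the target sequence")

    hits = []
    for start0 in range(0, len(seq) - window_length + 1, step):
        window = seq[start0 : start0 + window_length]
        worst = max(best_ungapped_identity(window, s) for _, s in off)
        if worst <= max_identity:
            hits.append(
                ProbeWindow(
                    gene=name,
                    start=start0 + 1,
                    end=start0 + window_length,
                    max_identity_to_offtargets=worst,
                )
            )
    hits.sort(key=lambda w: (w.max_identity_to_offtargets, w.start))
    return hits


def find_discriminating_variants(
    seq_strain_a: str,
    seq_strain_b: str,
    region: tuple[int, int] | None = None,
) -> list[DiscriminatingVariant]:
    """Aligned differences between two strain haplotypes of one gene region.

    Substitutions are reported per position; a contiguous indel is reported
    as a single event.  Positions are 1-based on strain A (offset by
    ``region`` start when a sub-region of A is analysed).  Identical
    sequences give an empty list -- such a gene cannot be allele-called.
    """
    seq_a = _check_sequence(seq_strain_a, "seq_strain_a")
    seq_b = _check_sequence(seq_strain_b, "seq_strain_b")
    offset = 0
    if region is not None:
        start, end = region
        if not 1 <= start <= end <= len(seq_a):
            raise ParameterError("region out of bounds on strain A")
        offset = start - 1
        seq_a = seq_a[start - 1 : end]

    alignment = make_aligner().align(seq_a, seq_b)[0]
    blocks_a, blocks_b = alignment.aligned
    variants: list[DiscriminatingVariant] = []
    prev_a_end = prev_b_end = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        a0, a1, b0, b1 = int(a0), int(a1), int(b0), int(b1)
        if prev_a_end is not None:
            da, db = a0 - prev_a_end, b0 - prev_b_end
            if da > 0:  # bases in A absent from B
                variants.append(
                    DiscriminatingVariant(
                        position=offset + prev_a_end + 1,
                        kind="insertion",
                        bases_a=seq_a[prev_a_end:a0],
                        bases_b="-",
                    )
                )
            if db > 0:  # bases in B absent from A; anchored to preceding A base
                variants.append(
                    DiscriminatingVariant(
                        position=offset + prev_a_end,
                        kind="deletion",
                        bases_a="-",
                        bases_b=seq_b[prev_b_end:b0],
                    )
                )
        for i, (ca, cb) in enumerate(zip(seq_a[a0:a1], seq_b[b0:b1])):
            if ca != cb:
                variants.append(
                    DiscriminatingVariant(
                        position=offset + a0 + i + 1,
                        kind="substitution",
                        bases_a=ca,
                        bases_b=cb,
                    )
                )
        prev_a_end, prev_b_end = a1, b1
    variants.sort(key=lambda v: v.position)
    return variants


def substitutions_to_variant_sites(
    variants: Iterable[DiscriminatingVariant],
) -> tuple[VariantSite, ...]:
    """Keep substitutions as allele-calling sites (indels are flagged but not
    used for base calling)."""
    return tuple(
        VariantSite(v.position, v.bases_a, v.bases_b)
        for v in variants
        if v.kind == "substitution"
    )


def find_polya_signals(
    sequence: str,
    cleavage_position: int,
    *,
    hexamers: Sequence[str] = POLYA_HEXAMERS,
    min_upstream: int = 10,
    max_upstream: int = 40,
) -> list[PolyASignalHit]:
    """Canonical polyA-signal hexamers 10-40 nt upstream of a cleavage site.

    Distance is measured from the hexamer start to the cleavage position;
    hits are returned nearest-first.  No hit yields an empty list.
    """
    seq = _check_sequence(sequence)
    if not 1 <= cleavage_position <= len(seq):
        raise ParameterError("cleavage position outside the sequence")
    hits = []
    for hexamer in hexamers:
        idx = seq.find(hexamer)
        while idx != -1:
            start = idx + 1  # 1-based
            distance = cleavage_position - start
            if min_upstream <= distance <= max_upstream:
                hits.append(PolyASignalHit(hexamer, start, distance))
            idx = seq.find(hexamer, idx + 1)
    hits.sort(key=lambda h: (h.distance, h.hexamer))
    return hits


def cluster_3prime_termini(
    cleavage_positions: Sequence[int],
    tolerance: int,
    *,
    gene: str | None = None,
    sequence: str | None = None,
) -> list[CleavageSiteCluster]:
    """Single-linkage clustering of observed cleavage positions.

    Sorted positions are chained while consecutive gaps are <= ``tolerance``;
    a larger gap starts a new cluster, so the cluster count is the number of
    distinct 3'-termini.  Tolerance 0 separates adjacent-nucleotide
    heterogeneity (same signal, cleavage one base apart); tolerance 1 merges
    it.  If ``sequence`` is given, each cluster is annotated with the nearest
    upstream polyA-signal hexamer.
    """
    if len(cleavage_positions) == 0:
        raise ParameterError("need >= 1 cleavage position")
    if tolerance < 0:
        raise ParameterError("tolerance must be >= 0")
    ordered = sorted(int(p) for p in cleavage_positions)
    groups: list[list[int]] = [[ordered[0]]]
    for p in ordered[1:]:
        if p - groups[-1][-1] <= tolerance:
            groups[-1].append(p)
        else:
            groups.append([p])

    clusters = []
    for members in groups:
        # modal position, smallest on ties
        counts: dict[int, int] = {}
        for m in members:
            counts[m] = counts.get(m, 0) + 1
        representative = max(sorted(counts), key=lambda m: counts[m])
        signal = signal_position = None
        if sequence is not None:
            hits = find_polya_signals(sequence, representative)
            if hits:
                signal, signal_position = hits[0].hexamer, hits[0].start
        clusters.append(
            CleavageSiteCluster(
                representative=representative,
                members=tuple(members),
                gene=gene,
                signal=signal,
                signal_position=signal_position,
            )
        )
    return clusters
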