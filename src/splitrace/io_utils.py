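"""File formats: FASTA, provenance-stamped TSV tables, key-value config.

All tables are tab-separated UTF-8 with LF line endings and ``"."`` as the
null token.  Every written table carries ``# key=value`` header lines with a
schema version and parameter provenance, and re-reading a written table
yields an equal in-memory value.
"""

from __future__ import annotations

import io
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cluster import PolyASite, StrainVariantMap, VariantSite
from .errors import ConfigurationError, FastaParseError
from .synthetic_data import SimParams

log = logging.getLogger("splitrace")

SCHEMA_VERSION = "1"
NULL_TOKEN = "."

_FASTA_ALLOWED = frozenset("ACGTUNRYSWKMBDHV-*.acgtunryswkmbdhv")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` mapping.

    Sequences are normalized to upper case (logged when normalization fired).
    Malformed input raises :class:`FastaParseError` with the line number; an
    empty file returns an empty mapping with a warning.
    """
    path = Path(path)
    text = path.read_text()
    in_record = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if len(stripped) == 1:
                raise FastaParseError("header line has no identifier", lineno)
            in_record = True
        else:
            if not in_record:
                raise FastaParseError(
                    "sequence data before any '>' header", lineno
                )
            bad = set(stripped) - _FASTA_ALLOWED
            if bad:
                raise FastaParseError(
                    f"invalid sequence characters {sorted(bad)}", lineno
                )
    records: dict[str, str] = {}
    had_lower = False
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            had_lower = True
        records[rec.id] = seq.upper()
    if not records:
        log.warning("FASTA file %s contained no records", path)
    if had_lower:
        log.info("FASTA file %s: mixed-case sequences normalized to upper case", path)
    return records


def write_fasta(records: Mapping[str, str], path, width: int = 60) -> None:
    """Write sequences as wrapped FASTA; round-trips byte-identically with
    :func:`read_fasta` for upper-case, 60-column input."""
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with path.open("w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def write_table(df: pd.DataFrame, path, meta: Mapping[str, object] | None = None) -> None:
    """Write a TSV with ``# key=value`` provenance header lines."""
    path = Path(path)
    header = {"schema_version": SCHEMA_VERSION}
    if meta:
        header.update({str(k): v for k, v in meta.items()})
    with path.open("w", newline="\n") as handle:
        for key, value in header.items():
            handle.write(f"# {key}={value}\n")
        df.to_csv(handle, sep="\t", index=False, lineterminator="\n")


def read_table(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a provenance-stamped TSV back into (DataFrame, metadata)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as handle:
        pos = handle.tell()
        line = handle.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            pos = handle.tell()
            line = handle.readline()
        handle.seek(pos)
        df = pd.read_csv(handle, sep="\t", float_precision="round_trip",
                         dtype={"cell_id": str, "gene": str,
                                "site_calls": str,
                                "allele_call": str,
                                "pattern": str,
                                "truth_class": str})
    return df, meta


def read_config(path) -> dict:
    """Parse a key: value config file (YAML subset)."""
    with Path(path).open() as handle:
        cfg = yaml.safe_load(handle)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ConfigurationError("config must be a mapping of key: value pairs")
    return cfg


_SIM_PARAM_KEYS = {
    "n_tubes",
    "expression_prob",
    "copies_mean",
    "amp_prob",
    "het_minor_fraction",
    "control_copies_mean",
    "negative_control_interval",
    "seed",
}

#: Config keys consumed by the pipeline itself rather than by SimParams.
_PIPELINE_KEYS = {"mode", "n_cells", "assayed_genes", "n_total_isoforms", "n_isoforms"}


def sim_params_from_config(cfg: Mapping[str, object]) -> SimParams:
    """Build :class:`SimParams` from a config mapping; unknown keys error."""
    unknown = set(cfg) - _SIM_PARAM_KEYS - _PIPELINE_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown config key(s): {', '.join(sorted(unknown))}"
        )
    kwargs = {k: cfg[k] for k in _SIM_PARAM_KEYS if k in cfg}
    return SimParams(**kwargs)


def write_variant_map(variants: StrainVariantMap, sites_path, polya_path) -> None:
    """Serialize a variant map to two TSVs (variant sites, polyA sites)."""
    site_rows = [
        {
            "gene": gene,
            "position": s.position,
            "base_a": s.base_a,
            "base_b": s.base_b,
        }
        for gene in variants.genes
        for s in variants.sites_for(gene)
    ]
    pa_rows = [
        {"gene": gene, "position": s.position, "weight": repr(s.weight)}
        for gene in variants.genes
        for s in variants.polya_for(gene)
    ]
    meta = {
        "allele_a": variants.allele_names[0],
        "allele_b": variants.allele_names[1],
    }
    write_table(
        pd.DataFrame(site_rows, columns=["gene", "position", "base_a", "base_b"]),
        sites_path,
        meta,
    )
    write_table(
        pd.DataFrame(pa_rows, columns=["gene", "position", "weight"]),
        polya_path,
        meta,
    )


def read_variant_map(sites_path, polya_path=None) -> StrainVariantMap:
    """Rebuild a :class:`StrainVariantMap` from its TSV serialization."""
    sites_df, meta = read_table(sites_path)
    alleles = (meta.get("allele_a", "B6"), meta.get("allele_b", "JF1"))
    variant_sites: dict[str, list[VariantSite]] = {}
    for row in sites_df.itertuples(index=False):
        variant_sites.setdefault(str(row.gene), []).append(
            VariantSite(int(row.position), str(row.base_a), str(row.base_b))
        )
    polya_sites: dict[str, list[PolyASite]] = {}
    if polya_path is not None and Path(polya_path).exists():
        pa_df, _ = read_table(polya_path)
        for row in pa_df.itertuples(index=False):
            polya_sites.setdefault(str(row.gene), []).append(
                PolyASite(int(row.position), float(row.weight))
            )
    return StrainVariantMap(
        {g: tuple(v) for g, v in variant_sites.items()},
        {g: tuple(v) for g, v in polya_sites.items()},
        alleles,
    )
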