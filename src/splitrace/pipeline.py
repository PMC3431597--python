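"""End-to-end orchestration: simulate -> call -> stats (or fixture -> stats).

Every stage failure is re-raised as :class:`PipelineError` tagged with the
stage name; all intermediates are written when an output directory is given,
and the seed and parameters are logged.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import allelic_inference as inf
from . import io_utils, stats
from .cluster import CONTROL_GENES, ClusterSpec, StrainVariantMap
from .errors import ConfigurationError, PipelineError, SplitRaceError
from .fixture import build_purkinje_fixture
from .synthetic_data import SimulatedExperiment, simulate_experiment

log = logging.getLogger("splitrace")

#: Isoform counts of the three Pcdh clusters, for the diversity arithmetic.
CLUSTER_SIZES = {"alpha": 12, "beta": 22, "gamma": 19}


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def call_experiment(
    experiment: SimulatedExperiment,
    *,
    assayed_genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """QC every cell and allele-call every product of a simulated experiment.

    Returns ``(calls, qc)``: the per-product call table restricted to
    QC-passed cells (controls included as rows, but flagged), and the per-cell
    QC table.
    """
    variants = experiment.variants
    qc_rows = []
    call_records = []
    for cell_id, records in experiment.products.items():
        qc = inf.qc_gate(records, variants) if records else inf.CellQC(
            cell_id, False, False, False, "no products"
        )
        qc_rows.append(
            {
                "cell_id": cell_id,
                "pcp2_positive": int(qc.pcp2_positive),
                "actin_positive": int(qc.actin_positive),
                "actin_biallelic": int(qc.actin_biallelic),
                "passed": int(qc.passed),
                "reason": qc.reason or ".",
            }
        )
        if not qc.passed:
            continue
        for rec in inf.call_products(records, variants):
            if assayed_genes is not None and rec.gene not in (
                tuple(assayed_genes) + CONTROL_GENES
            ):
                continue
            call_records.append(rec)
    calls = inf.products_to_calls_table(call_records)
    qc_df = pd.DataFrame(
        qc_rows,
        columns=[
            "cell_id",
            "pcp2_positive",
            "actin_positive",
            "actin_biallelic",
            "passed",
            "reason",
        ],
    )
    return calls, qc_df


def summarize_calls(
    calls: pd.DataFrame,
    n_cells: int,
    *,
    n_assayed: int,
    n_total: int,
    n_tubes: int = 3,
    allele_names: tuple[str, str] = ("A", "B"),
) -> dict:
    """Compute the full statistics block from a per-product call table."""
    beta_calls = calls[~calls["gene"].isin(CONTROL_GENES)]
    summary = inf.aggregate_monoallelic_fraction(beta_calls, "3/3")
    balance = inf.allele_balance(beta_calls[beta_calls["pattern"] == "3/3"], allele_names)
    null_rate = stats.artifact_null_probability(n_tubes)
    report: dict = {
        "n_cells": n_cells,
        "n_products_3of3": summary.n_eligible,
        "n_monoallelic_3of3": summary.n_monoallelic,
        "n_biallelic_3of3": summary.n_biallelic,
        "n_inconsistent": summary.n_inconsistent,
        "n_insufficient": summary.n_insufficient,
        "monoallelic_percent": summary.percent,
        "artifact_null_percent": 100.0 * null_rate,
        f"n_allele_{allele_names[0]}": balance.n_allele_a,
        f"n_allele_{allele_names[1]}": balance.n_allele_b,
        "allele_balance_p": balance.p_value,
    }
    if summary.n_eligible > 0:
        chi2, p = stats.chi_square_monoallelic(
            summary.n_monoallelic, summary.n_biallelic, null_rate
        )
        report["chi_square"] = chi2
        report["chi_square_p"] = p
    three = beta_calls[beta_calls["pattern"] == "3/3"]
    n_positive_cells = three["cell_id"].nunique()
    n_products = len(three)
    report["n_cells_3of3"] = n_positive_cells
    rate_cells = stats.genes_per_cell(n_positive_cells, n_cells)
    rate_products = stats.genes_per_cell(n_products, n_cells)
    report["genes_per_cell_rate"] = rate_cells
    report["genes_per_cell_product_rate"] = rate_products
    report["repertoire_extrapolated"] = stats.extrapolate_repertoire(
        rate_cells, n_assayed, n_total
    )
    report["repertoire_extrapolated_products"] = stats.extrapolate_repertoire(
        rate_products, n_assayed, n_total
    )
    for name, size in CLUSTER_SIZES.items():
        report[f"pair_combinations_{name}"] = stats.cluster_pair_combinations(size)
    report["total_diversity"] = stats.total_diversity(CLUSTER_SIZES.values())
    return report


def fixture_report() -> dict:
    """Statistics block recomputed from the transcribed in-source dataset."""
    fixture = build_purkinje_fixture()
    summary = inf.aggregate_monoallelic_fraction(fixture.products, "3/3")
    null_rate = stats.artifact_null_probability(3)
    chi2, p = stats.chi_square_monoallelic(
        summary.n_monoallelic, summary.n_biallelic, null_rate
    )
    balance = inf.AlleleBalance.from_counts(
        fixture.allele_totals["B6"], fixture.allele_totals["JF1"], ("B6", "JF1")
    )
    rate = stats.genes_per_cell(
        fixture.summary["n_cells_3of3"], fixture.summary["n_cells"]
    )
    report = {
        "n_cells": fixture.summary["n_cells"],
        "n_products_3of3": summary.n_eligible,
        "n_monoallelic_3of3": summary.n_monoallelic,
        "n_biallelic_3of3": summary.n_biallelic,
        "monoallelic_percent": summary.percent,
        "artifact_null_percent": 100.0 * null_rate,
        "chi_square": chi2,
        "chi_square_p": p,
        "n_allele_B6": balance.n_allele_a,
        "n_allele_JF1": balance.n_allele_b,
        "allele_balance_p": balance.p_value,
        "genes_per_cell_rate": rate,
        "repertoire_extrapolated": stats.extrapolate_repertoire(
            rate,
            fixture.summary["n_assayed_genes"],
            fixture.summary["n_cluster_genes"],
        ),
    }
    for name, size in CLUSTER_SIZES.items():
        report[f"pair_combinations_{name}"] = stats.cluster_pair_combinations(size)
    report["total_diversity"] = stats.total_diversity(CLUSTER_SIZES.values())
    for w in fixture.warnings:
        log.warning("fixture: %s", w)
    return report


def _write_report(report: Mapping, out_dir: Path) -> None:
    rows = [{"quantity": k, "value": v} for k, v in report.items()]
    io_utils.write_table(pd.DataFrame(rows), out_dir / "summary.tsv")


def run_pipeline(
    config: Mapping,
    out_dir=None,
    seed: int | None = None,
) -> dict:
    """Run the configured pipeline and return the statistics report.

    ``config["mode"]`` selects ``"simulate"`` (default; requires
    ``n_cells``) or ``"fixture"``.  With ``out_dir`` set, all intermediates
    (dataset, truth, calls, QC, summary) are written as provenance-stamped
    TSVs.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    mode = config.get("mode", "simulate")

    if mode == "fixture":
        with _stage("fixture"):
            fixture = build_purkinje_fixture()
            report = fixture_report()
            if out is not None:
                io_utils.write_table(fixture.products, out / "fixture_products.tsv")
                io_utils.write_table(fixture.dataset, out / "fixture_dataset.tsv")
                _write_report(report, out)
        return report

    if mode != "simulate":
        raise PipelineError("config", f"unknown mode {mode!r}")

    with _stage("simulate"):
        if "n_cells" not in config:
            raise ConfigurationError("missing config key: n_cells")
        n_cells = int(config["n_cells"])
        params = io_utils.sim_params_from_config(config)
        seed = seed if seed is not None else params.seed
        log.info("simulate: n_cells=%d seed=%s params=%s", n_cells, seed, params)
        experiment = simulate_experiment(n_cells, params=params, seed=seed)
        if out is not None:
            meta = {"seed": seed, "params": params}
            io_utils.write_table(experiment.dataset, out / "dataset.tsv", meta)
            io_utils.write_table(experiment.truth, out / "truth.tsv", meta)
            io_utils.write_variant_map(
                experiment.variants, out / "variants.tsv", out / "polya.tsv"
            )

    with _stage("call"):
        assayed = config.get("assayed_genes")
        calls, qc = call_experiment(experiment, assayed_genes=assayed)
        if out is not None:
            io_utils.write_table(calls, out / "calls.tsv", {"seed": seed})
            io_utils.write_table(qc, out / "qc.tsv", {"seed": seed})

    with _stage("stats"):
        n_assayed = len(assayed) if assayed else experiment.spec.n_isoforms
        n_passed = int(qc["passed"].sum())
        report = summarize_calls(
            calls,
            n_passed,
            n_assayed=n_assayed,
            n_total=experiment.spec.n_isoforms,
            n_tubes=experiment.params.n_tubes,
            allele_names=experiment.variants.allele_names,
        )
        report["seed"] = seed
        if out is not None:
            _write_report(report, out)
    return report
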