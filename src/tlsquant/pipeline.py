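"""End-to-end orchestration: simulate a cohort bundle, run all stages.

The pipeline composes the library stages per patient — TLS detection and
classification, compartmental densities, TLS cluster assignment, panel TMB
— plus cohort-level signature scoring and stratified survival analysis.
Every run writes a manifest with the full configuration and its hash, and
identical config + inputs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as tio
from .quantify import (
    PhenotypeDef,
    assign_patient_cluster,
    compute_compartment_densities,
)
from .signatures import (
    TLS_CHEMOKINE_12,
    filter_genes,
    normalize_cp10k,
    qc_spots,
    score_signature,
)
from .stats import cox_fit, logrank_test, stratify_by_median
from .tls import (
    TlsThresholds,
    classify_aggregate,
    detect_aggregates,
    localize_tls,
    measure_aggregate,
)
from .tmb import TmbConfig, compute_tmb
from .version import __version__

__all__ = ["RunConfig", "run_pipeline", "simulate_bundle", "DEFAULT_PHENOTYPES"]

DEFAULT_PHENOTYPES = [
    PhenotypeDef("CD20_B", ("CD20",)),
    PhenotypeDef("CD4_T", ("CD4",)),
    PhenotypeDef("CD8_T", ("CD8",)),
    PhenotypeDef("FDC", ("CD21", "CD23")),
]


@dataclass
class RunConfig:
    """Everything a run needs: inputs, thresholds and output location."""

    out_dir: str
    patients: list[dict] = field(default_factory=list)  # patient_id, cells, regions, [variants, panel]
    expression: str | None = None  # genes×samples TSV
    survival: str | None = None  # survival CSV
    survival_covariates: list[str] = field(default_factory=list)
    thresholds: TlsThresholds = field(default_factory=TlsThresholds)
    min_component_size: int = 20
    tmb_config: TmbConfig = field(default_factory=TmbConfig)
    phenotypes: list[PhenotypeDef] = field(default_factory=lambda: list(DEFAULT_PHENOTYPES))
    signature_genes: tuple[str, ...] = TLS_CHEMOKINE_12.genes
    qc_max_mito_frac: float = 0.30
    qc_min_genes: int = 300
    qc_gene_min_samples: int = 5
    seed: int = 0

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["signature_genes"] = list(self.signature_genes)
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML (or JSON) file."""
        import yaml

        doc = yaml.safe_load(Path(path).read_text())
        kwargs = dict(doc)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = TlsThresholds(**kwargs["thresholds"])
        if "tmb_config" in kwargs:
            kwargs["tmb_config"] = TmbConfig(**kwargs["tmb_config"])
        if "phenotypes" in kwargs:
            kwargs["phenotypes"] = [
                PhenotypeDef(
                    p["name"],
                    tuple(p.get("positive", ())),
                    tuple(p.get("negative", ())),
                )
                for p in kwargs["phenotypes"]
            ]
        if "signature_genes" in kwargs:
            kwargs["signature_genes"] = tuple(kwargs["signature_genes"])
        return cls(**kwargs)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(cfg: RunConfig) -> pd.DataFrame:
    """Run every configured stage; returns the per-patient summary table.

    Writes, under ``cfg.out_dir``: per-patient TLS calls, rule traces and
    density tables; a cohort ``patients.tsv``; signature scores and Hi/Lo
    labels when expression is configured; survival statistics when a
    survival table is configured; and ``manifest.json``.
    """
    if not cfg.patients:
        raise ValueError("no patients configured")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    from .signatures import GeneSignature

    signature = GeneSignature("signature", tuple(cfg.signature_genes))
    summary_rows = []
    for pat in cfg.patients:
        pid = pat["patient_id"]
        cells = tio.read_cells(pat["cells"])
        regions = tio.read_regions(pat["regions"])
        aggs = detect_aggregates(
            cells, cfg.thresholds.contact_distance_um, cfg.min_component_size
        )
        calls = []
        for a in aggs:
            a = measure_aggregate(a, cells, cfg.phenotypes)
            call = localize_tls(classify_aggregate(a, cfg.thresholds), regions)
            calls.append(call)
        tio.write_tls_calls(
            calls, out / f"{pid}.tls_calls.tsv", out / f"{pid}.tls_trace.json"
        )
        density = compute_compartment_densities(cells, calls, regions, cfg.phenotypes)
        tio.write_density_table(density, out / f"{pid}.densities.tsv", pid)

        n_etls = sum(c.tls_class == "eTLS" for c in calls)
        n_mtls = sum(c.tls_class == "mTLS" for c in calls)
        row = {
            "patient_id": pid,
            "n_aggregates": len(calls),
            "n_eTLS": n_etls,
            "n_mTLS": n_mtls,
            "cluster": assign_patient_cluster(n_etls, n_mtls),
        }
        if pat.get("variants") and pat.get("panel"):
            variants = tio.read_variants_tsv(pat["variants"])
            panel = tio.read_panel(pat["panel"])
            res = compute_tmb(variants, panel, cfg.tmb_config)
            row["tmb"] = res.tmb
            row["eligible_variants"] = res.eligible_count
            row["effective_size_mb"] = res.effective_size_mb
            pd.DataFrame(res.trace).to_csv(
                out / f"{pid}.tmb_trace.tsv", sep="\t", index=False
            )
        summary_rows.append(row)

    summary = pd.DataFrame(summary_rows)

    if cfg.expression:
        matrix = tio.read_matrix_tsv(cfg.expression)
        matrix, qc_report = qc_spots(
            matrix, max_mito_frac=cfg.qc_max_mito_frac, min_genes=cfg.qc_min_genes
        )
        matrix = filter_genes(matrix, cfg.qc_gene_min_samples)
        qc_report.to_csv(out / "qc_removed_spots.tsv", sep="\t", index=False)
        scores = score_signature(normalize_cp10k(matrix), signature)
        labels = stratify_by_median(scores.scores.to_dict())
        pd.DataFrame(
            {
                "sample_id": scores.scores.index,
                "score": scores.scores.to_numpy(),
                "label": [labels[s] for s in scores.scores.index],
            }
        ).to_csv(out / "signature_scores.tsv", sep="\t", index=False)

    if cfg.survival:
        records = tio.read_survival(cfg.survival)
        surv_out: dict = {"n": len(records), "n_events": sum(r.event for r in records)}
        if cfg.survival_covariates:
            cox = cox_fit(records, cfg.survival_covariates)
            surv_out["cox"] = {
                k: {
                    "log_hr": cox.coef[k],
                    "se": cox.se[k],
                    "hr": cox.hr[k],
                    "ci95": [cox.ci_low[k], cox.ci_high[k]],
                    "p": cox.p[k],
                }
                for k in cox.coef
            }
            cov = cfg.survival_covariates[0]
            values = {r.subject_id: dict(r.covariates)[cov] for r in records}
            labels = stratify_by_median(values)
            grp_hi = [r for r in records if labels[r.subject_id] == "Hi"]
            grp_lo = [r for r in records if labels[r.subject_id] == "Lo"]
            if grp_hi and grp_lo:
                chi2, p = logrank_test(grp_hi, grp_lo)
                surv_out["logrank_median_split"] = {
                    "covariate": cov, "chi2": chi2, "p": p,
                    "n_hi": len(grp_hi), "n_lo": len(grp_lo),
                }
        (out / "survival.json").write_text(json.dumps(surv_out, sort_keys=True, indent=1))

    summary.to_csv(out / "patients.tsv", sep="\t", index=False)
    manifest = {
        "config": cfg.to_jsonable(),
        "config_sha256": _config_hash(cfg),
        "tlsquant_version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return summary


def simulate_bundle(
    out_dir,
    seed: int = 0,
    n_patients: int = 3,
) -> dict:
    """Write a small synthetic cohort bundle with its ground-truth sidecar.

    Each patient gets a 3×3 mm tissue with a central core, 0–3 planted
    aggregates spanning all three classes, background cells, a variant
    table with a known filter mix, and the cohort gets an expression matrix
    with planted signature elevation plus proportional-hazards survival.
    Returns the RunConfig-ready dict of paths.
    """
    import numpy as np
    from shapely.geometry import Polygon, box

    from .synthetic import (
        AggregateSpec,
        TissueSimSpec,
        generate_expression,
        generate_panel,
        generate_survival,
        generate_tissue,
        generate_variant_table,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth_doc: dict = {"patients": {}}
    patients = []

    agg_menu = [
        dict(n_cells=400, diameter_um=300.0, frac_cd20=0.7, n_fdc=0),
        dict(n_cells=450, diameter_um=320.0, frac_cd20=0.65, n_fdc=3),
        dict(n_cells=150, diameter_um=180.0, frac_cd20=0.8, n_fdc=0),  # too small
    ]
    centers = [(750.0, 750.0), (2250.0, 750.0), (750.0, 2250.0), (2250.0, 2250.0)]
    for i in range(n_patients):
        pid = f"PT{i:03d}"
        tissue = box(0, 0, 3000, 3000)
        core = Polygon([(1000, 1000), (2000, 1000), (2000, 2000), (1000, 2000)])
        stroma = tissue.difference(core)
        n_aggs = int(rng.integers(0, 4))
        aggs = [
            AggregateSpec(center=centers[j], **agg_menu[int(rng.integers(0, len(agg_menu)))])
            for j in range(n_aggs)
        ]
        spec = TissueSimSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            tissue_polygon=tissue,
            core_polygon=core,
            stroma_polygon=stroma,
            margin_band_um=400.0,
            n_background_cells=800,
            background_phenotype_freqs={"B": 0.1, "CD4_T": 0.2, "CD8_T": 0.2},
            aggregates=aggs,
        )
        cells, regions, truth = generate_tissue(spec)
        tio.write_cells(cells, out / f"{pid}.cells.csv")
        tio.write_regions(regions, out / f"{pid}.regions.geojson")

        panel = generate_panel(int(rng.integers(0, 2**31 - 1)))
        mix = {
            "eligible": int(rng.integers(0, 30)),
            "db": 8,
            "proximity": int(rng.integers(0, 4)),
            "high_af": int(rng.integers(0, 4)),
            "mnv": int(rng.integers(0, 3)),
            "low_vaf": int(rng.integers(0, 3)),
            "cosmic": int(rng.integers(0, 3)),
        }
        variants, vtruth = generate_variant_table(
            int(rng.integers(0, 2**31 - 1)), sum(mix.values()), panel, mix
        )
        tio.write_variants_tsv(variants, out / f"{pid}.variants.tsv")
        tio.write_panel(panel, out / f"{pid}.panel.tsv")

        truth_doc["patients"][pid] = {
            "planted_aggregates": truth.planted_aggregates,
            "expected_eligible": vtruth.expected_eligible,
        }
        patients.append(
            {
                "patient_id": pid,
                "cells": str(out / f"{pid}.cells.csv"),
                "regions": str(out / f"{pid}.regions.geojson"),
                "variants": str(out / f"{pid}.variants.tsv"),
                "panel": str(out / f"{pid}.panel.tsv"),
            }
        )

    matrix, etruth = generate_expression(
        seed=int(rng.integers(0, 2**31 - 1)),
        n_genes=500,
        n_samples=60,
        signature=TLS_CHEMOKINE_12,
        effect=1.0,
        frac_hi=0.5,
    )
    tio.write_matrix_tsv(matrix, out / "expression.tsv")
    truth_doc["signature_truth"] = etruth.signature_truth

    records, struth = generate_survival(
        seed=int(rng.integers(0, 2**31 - 1)), n=200, true_log_hr=0.7, censor_rate=0.2
    )
    tio.write_survival(records, out / "survival.csv")
    truth_doc["survival_truth"] = struth.survival_truth

    (out / "ground_truth.json").write_text(json.dumps(truth_doc, sort_keys=True, indent=1))
    return {
        "patients": patients,
        "expression": str(out / "expression.tsv"),
        "survival": str(out / "survival.csv"),
        "survival_covariates": ["group"],
    }
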