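"""Readers and writers for the pipeline's plain-text formats.

Cell tables travel as CSV (``cell_id,x_um,y_um`` plus one 0/1 column per
marker), regions as GeoJSON FeatureCollections with a ``role`` property
(tissue / core / stroma), variants as a TSV dialect or VCF, panel intervals
as BED-like TSV (0-based half-open), expression as genes×samples TSV or MTX
triplet with id sidecars, and survival as CSV.  Writers and readers
round-trip: reading back a written object reproduces it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .quantify import PhenotypeDef
from .signatures import ExpressionMatrix, GeneSignature
from .stats import SurvivalRecord
from .tls import CellTable, RegionSet, TlsCall
from .tmb import PanelRegions, VariantRecord

__all__ = [
    "read_cells", "write_cells",
    "read_regions", "write_regions",
    "read_variants_tsv", "write_variants_tsv", "read_variants_vcf",
    "read_panel", "write_panel",
    "read_matrix_tsv", "write_matrix_tsv", "read_matrix_mtx", "write_matrix_mtx",
    "read_survival", "write_survival",
    "read_phenotypes", "write_phenotypes",
    "read_signatures", "write_tls_calls", "write_density_table",
]

_FIXED_CELL_COLS = ("cell_id", "x_um", "y_um")


def read_cells(path) -> CellTable:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _FIXED_CELL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    panel = tuple(c for c in df.columns if c not in _FIXED_CELL_COLS)
    for m in panel:
        bad = ~df[m].isin([0, 1])
        if bad.any():
            raise ValueError(
                f"{path}: marker column {m!r} not 0/1 at row {int(bad.idxmax())}"
            )
    df["cell_id"] = df["cell_id"].astype(str)
    return CellTable(panel=panel, df=df)


def write_cells(cells: CellTable, path) -> None:
    cells.df.to_csv(path, index=False)


def write_regions(regions: RegionSet, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"role": role},
            "geometry": mapping(geom),
        }
        for role, geom in (
            ("tissue", regions.tissue),
            ("core", regions.core),
            ("stroma", regions.stroma),
        )
        if geom is not None
    ]
    doc = {
        "type": "FeatureCollection",
        "properties": {"margin_band_um": regions.margin_band_um},
        "features": features,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_regions(path) -> RegionSet:
    doc = json.loads(Path(path).read_text())
    geoms = {}
    for feat in doc.get("features", []):
        role = feat.get("properties", {}).get("role")
        if role not in ("tissue", "core", "stroma"):
            raise ValueError(f"{path}: feature with unknown role {role!r}")
        geoms[role] = shape(feat["geometry"])
    if "tissue" not in geoms:
        raise ValueError(f"{path}: no feature with role 'tissue'")
    return RegionSet(
        tissue=geoms["tissue"],
        core=geoms.get("core"),
        stroma=geoms.get("stroma"),
        margin_band_um=float(doc.get("properties", {}).get("margin_band_um", 500.0)),
    )


_VARIANT_COLS = [
    "chrom", "pos", "ref", "alt", "variant_type", "vaf", "depth",
    "consequence", "in_coding", "gnomad_exome", "gnomad_genome",
    "kg1000", "cosmic_count",
]


def write_variants_tsv(variants: list[VariantRecord], path) -> None:
    df = pd.DataFrame([{c: getattr(v, c) for c in _VARIANT_COLS} for v in variants],
                      columns=_VARIANT_COLS)
    df["in_coding"] = df["in_coding"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _VARIANT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing variant columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                VariantRecord(
                    chrom=str(row["chrom"]), pos=int(row["pos"]),
                    ref=str(row["ref"]), alt=str(row["alt"]),
                    variant_type=str(row["variant_type"]), vaf=float(row["vaf"]),
                    depth=int(row["depth"]), consequence=str(row["consequence"]),
                    in_coding=bool(int(row["in_coding"])),
                    gnomad_exome=int(row["gnomad_exome"]),
                    gnomad_genome=int(row["gnomad_genome"]),
                    kg1000=int(row["kg1000"]),
                    cosmic_count=int(row["cosmic_count"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: malformed variant at row {i}: {exc}") from exc
    return out


#: default VCF INFO keys for the annotation fields the cascade needs
DEFAULT_VCF_INFO_MAP = {
    "vaf": "VAF", "depth": "DP", "variant_type": "VT",
    "consequence": "CSQ", "in_coding": "CODING",
    "gnomad_exome": "GNOMAD_EX", "gnomad_genome": "GNOMAD_GE",
    "kg1000": "KG1000", "cosmic_count": "COSMIC",
}


def read_variants_vcf(path, info_map: dict | None = None) -> list[VariantRecord]:
    """Read annotated variants from VCF with a configurable INFO mapping."""
    from cyvcf2 import VCF  # optional dependency, imported on use

    info_map = {**DEFAULT_VCF_INFO_MAP, **(info_map or {})}
    out = []
    for rec in VCF(str(path)):
        info = {}
        for field, key in info_map.items():
            val = rec.INFO.get(key)
            if val is None:
                raise ValueError(
                    f"{path}: {rec.CHROM}:{rec.POS} missing declared INFO key {key!r}"
                )
            info[field] = val
        out.append(
            VariantRecord(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0],
                variant_type=str(info["variant_type"]), vaf=float(info["vaf"]),
                depth=int(info["depth"]), consequence=str(info["consequence"]),
                in_coding=bool(int(info["in_coding"])),
                gnomad_exome=int(info["gnomad_exome"]),
                gnomad_genome=int(info["gnomad_genome"]),
                kg1000=int(info["kg1000"]),
                cosmic_count=int(info["cosmic_count"]),
            )
        )
    return out


def write_panel(panel: PanelRegions, path) -> None:
    df = pd.DataFrame(
        panel.intervals,
        columns=["chrom", "start", "end", "coverage", "low_confidence"],
    )
    df["low_confidence"] = df["low_confidence"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_panel(path) -> PanelRegions:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    need = ["chrom", "start", "end", "coverage", "low_confidence"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing panel columns {missing}")
    return PanelRegions(
        intervals=[
            (str(r.chrom), int(r.start), int(r.end), float(r.coverage),
             bool(int(r.low_confidence)))
            for r in df.itertuples()
        ]
    )


def write_matrix_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_matrix_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ExpressionMatrix(df)


def write_matrix_mtx(matrix: ExpressionMatrix, prefix) -> None:
    """MTX triplet: <prefix>.mtx plus <prefix>.genes.tsv / .samples.tsv."""
    from scipy import io as spio
    from scipy import sparse

    prefix = Path(prefix)
    spio.mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(matrix.values.to_numpy()))
    pd.Series(matrix.gene_ids).to_csv(str(prefix) + ".genes.tsv", index=False, header=False)
    pd.Series(matrix.sample_ids).to_csv(str(prefix) + ".samples.tsv", index=False, header=False)


def read_matrix_mtx(prefix) -> ExpressionMatrix:
    from scipy import io as spio

    prefix = Path(prefix)
    mat = spio.mmread(str(prefix) + ".mtx").toarray()
    genes = pd.read_csv(str(prefix) + ".genes.tsv", header=None)[0].tolist()
    samples = pd.read_csv(str(prefix) + ".samples.tsv", header=None)[0].tolist()
    return ExpressionMatrix(pd.DataFrame(mat, index=genes, columns=samples))


def write_survival(records: list[SurvivalRecord], path) -> None:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "time_months": r.time, "event": r.event}
        row.update(dict(r.covariates))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_survival(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    need = ["subject_id", "time_months", "event"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing survival columns {missing}")
    covs = [c for c in df.columns if c not in need]
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                SurvivalRecord(
                    subject_id=str(row["subject_id"]),
                    time=float(row["time_months"]),
                    event=int(row["event"]),
                    covariates=tuple((c, row[c]) for c in covs),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: malformed record at row {i}: {exc}") from exc
    return out


def write_phenotypes(defs: list[PhenotypeDef], path) -> None:
    doc = [
        {"name": d.name, "positive": list(d.required_positive),
         "negative": list(d.required_negative)}
        for d in defs
    ]
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def read_phenotypes(path) -> list[PhenotypeDef]:
    doc = json.loads(Path(path).read_text())
    return [
        PhenotypeDef(
            name=d["name"],
            required_positive=tuple(d.get("positive", ())),
            required_negative=tuple(d.get("negative", ())),
        )
        for d in doc
    ]


def read_signatures(path) -> dict[str, GeneSignature]:
    doc = json.loads(Path(path).read_text())
    return {name: GeneSignature(name, tuple(genes)) for name, genes in doc.items()}


def write_tls_calls(calls: list[TlsCall], tsv_path, trace_path=None) -> None:
    rows = []
    for i, c in enumerate(calls):
        row = {
            "aggregate_id": i,
            "tls_class": c.tls_class,
            "localization": c.localization,
            "n_cells": c.aggregate.n_cells,
            "max_feret_um": c.aggregate.max_feret_um,
            "hull_area_mm2": c.aggregate.hull_area_mm2,
        }
        for k, v in sorted(c.aggregate.composition.items()):
            row[f"n_{k}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if trace_path is not None:
        traces = [
            {"aggregate_id": i, "rule_trace": c.rule_trace,
             "member_ids": list(map(str, c.aggregate.member_ids))}
            for i, c in enumerate(calls)
        ]
        Path(trace_path).write_text(json.dumps(traces, indent=1, sort_keys=True))


def write_density_table(density: pd.DataFrame, path, patient_id: str | None = None) -> None:
    df = density.copy()
    if patient_id is not None:
        df.insert(0, "patient", patient_id)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
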