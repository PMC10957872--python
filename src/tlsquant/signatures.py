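"""Expression-matrix QC, gene-signature scoring and over-representation.

Spot-level QC removes samples with a mitochondrial-count fraction above 30%
or fewer than 300 detected genes; gene-level QC drops genes observed in
fewer than 5 samples.  Signature scores aggregate a gene list per sample,
either as the mean of log1p expression (``mean_log``) or the mean of
gene-wise z-scores (``zmean``).  The 12-chemokine TLS signature commonly
used to flag TLS presence in bulk and spatial transcriptomes is built in;
population marker sets for abundance estimation are user-supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "SignatureScores",
    "TLS_CHEMOKINE_12",
    "qc_spots",
    "filter_genes",
    "normalize_cp10k",
    "score_signature",
    "estimate_abundance",
    "overrepresentation_test",
]


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")


#: 12-chemokine TLS signature (CCL and CXCL family members whose joint
#: overexpression marks tertiary lymphoid structure formation).
TLS_CHEMOKINE_12 = GeneSignature(
    "TLS_12_chemokine",
    (
        "CCL2", "CCL3", "CCL4", "CCL5", "CCL8", "CCL18",
        "CCL19", "CCL21", "CXCL9", "CXCL10", "CXCL11", "CXCL13",
    ),
)


@dataclass
class ExpressionMatrix:
    """Non-negative gene × sample matrix with genes as the DataFrame index."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any() or self.values.columns.duplicated().any():
            raise ValueError("gene and sample ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SignatureScores:
    signature: str
    method: str
    scores: pd.Series  # indexed by sample id
    missing_genes: tuple[str, ...] = ()


def qc_spots(
    matrix: ExpressionMatrix,
    mito_genes: list[str] | None = None,
    mito_prefix: str = "MT-",
    max_mito_frac: float = 0.30,
    min_genes: int = 300,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove damaged spots/samples.

    A sample is removed iff its mitochondrial fraction exceeds
    ``max_mito_frac`` (strictly) or it detects fewer than ``min_genes``
    genes (strictly).  Returns the filtered matrix and a report of removed
    sample ids with reasons.
    """
    vals = matrix.values
    if mito_genes is None:
        mito_mask = vals.index.str.startswith(mito_prefix)
    else:
        mito_mask = vals.index.isin(mito_genes)
    totals = vals.sum(axis=0)
    mito_frac = vals.loc[mito_mask].sum(axis=0) / totals.replace(0, np.nan)
    mito_frac = mito_frac.fillna(0.0)
    n_detected = (vals > 0).sum(axis=0)

    fail_mito = mito_frac > max_mito_frac
    fail_genes = n_detected < min_genes
    removed = fail_mito | fail_genes
    report = pd.DataFrame(
        {
            "sample_id": vals.columns[removed],
            "mito_frac": mito_frac[removed].to_numpy(),
            "n_detected": n_detected[removed].to_numpy(),
            "reason": [
                ";".join(
                    r
                    for r, f in (("high_mito", fm), ("few_genes", fg))
                    if f
                )
                for fm, fg in zip(fail_mito[removed], fail_genes[removed])
            ],
        }
    )
    kept = vals.loc[:, ~removed]
    if kept.shape[1] == 0:
        raise ValueError("all samples removed by spot QC")
    return ExpressionMatrix(kept), report


def filter_genes(matrix: ExpressionMatrix, min_samples: int = 5) -> ExpressionMatrix:
    """Drop genes with nonzero counts in fewer than ``min_samples`` samples."""
    nz = (matrix.values > 0).sum(axis=1)
    return ExpressionMatrix(matrix.values.loc[nz >= min_samples])


def normalize_cp10k(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Library-size normalization to counts per 10,000 per sample."""
    totals = matrix.values.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("cannot normalize samples with zero total counts")
    return ExpressionMatrix(matrix.values * (1e4 / totals))


def score_signature(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    method: str = "mean_log",
) -> SignatureScores:
    """Per-sample signature score.

    ``mean_log``: mean of log(1 + value) over the signature genes present.
    ``zmean``: mean of gene-wise z-scores (each gene standardized across
    samples; constant genes contribute 0).  Genes absent from the matrix are
    reported, not fatal, unless none is present.
    """
    present = [g for g in signature.genes if g in matrix.values.index]
    missing = tuple(g for g in signature.genes if g not in matrix.values.index)
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} in matrix")
    sub = matrix.values.loc[present]
    if method == "mean_log":
        scores = np.log1p(sub).mean(axis=0)
    elif method == "zmean":
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        z = sub.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
        scores = z.mean(axis=0)
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    return SignatureScores(signature.name, method, scores, missing)


def estimate_abundance(
    matrix: ExpressionMatrix,
    marker_sets: dict[str, GeneSignature],
    method: str = "mean_log",
) -> dict[str, SignatureScores]:
    """Metagene-style abundance score per population from user marker sets."""
    return {pop: score_signature(matrix, sig, method) for pop, sig in marker_sets.items()}


def overrepresentation_test(selected: set, universe: set, annotation: set) -> float:
    """Hypergeometric upper-tail over-representation p-value.

    Probability of drawing at least the observed overlap between
    ``selected`` and ``annotation`` when sampling ``len(selected)`` genes
    without replacement from ``universe``.
    """
    if not universe:
        raise ValueError("empty universe")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    if not annotation <= universe:
        raise ValueError("annotation genes must be a subset of the universe")
    overlap = len(selected & annotation)
    return float(
        stats.hypergeom.sf(overlap - 1, len(universe), len(annotation), len(selected))
    )
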