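"""Discrete signatures and ranked vectors from differential-expression tables.

The significance rule is the inclusive two-part gate used throughout the
package: a gene is called up if ``fdr <= fdr_max`` and ``log2fc >= lfc_min``,
down if ``fdr <= fdr_max`` and ``log2fc <= -lfc_min`` (defaults 0.1 and 1.0,
both thresholds inclusive).  Multiple-testing adjustment is
Benjamini-Hochberg; tables read without an fdr column must pass through
:func:`add_fdr` before thresholding so that the adjustment step is explicit.

Fold-change rankings and top-k selections break ties by gene identifier
(ascending lexicographic), making every ordering deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .datatypes import DETable, RankedVector, Signature, ValidationError

__all__ = [
    "bh_adjust",
    "add_fdr",
    "extract_signature",
    "combine_signatures",
    "top_k",
    "rank_by_fc",
    "PCAResult",
    "pca_projection",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    Sort ascending, q_(i) = p_(i) * m / i, enforce monotonicity from the
    largest rank down, cap at 1.  Input order is restored on return.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-D array of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def add_fdr(table: DETable) -> DETable:
    """Return a copy of ``table`` with BH-adjusted p-values in the fdr column."""
    data = table.data.copy()
    data["fdr"] = bh_adjust(data["pvalue"].to_numpy())
    return DETable(data, label=table.label, species=table.species)


def extract_signature(
    table: DETable, fdr_max: float = 0.1, lfc_min: float = 1.0
) -> Signature:
    """Up/down gene sets passing the inclusive significance gate.

    Requires fdr on every record (apply :func:`add_fdr` first if the source
    table carried raw p-values only).  Monotone in both thresholds: relaxing
    ``fdr_max`` or ``lfc_min`` never shrinks either set.
    """
    if not table.has_fdr:
        raise ValidationError(
            f"table '{table.label}' has no fdr values; run add_fdr first"
        )
    if lfc_min <= 0:
        raise ValidationError("lfc_min must be positive")
    if not 0 <= fdr_max <= 1:
        raise ValidationError("fdr_max must lie in [0, 1]")
    df = table.data
    sig = df["fdr"] <= fdr_max
    up = frozenset(df.loc[sig & (df["log2fc"] >= lfc_min), "gene"])
    down = frozenset(df.loc[sig & (df["log2fc"] <= -lfc_min), "gene"])
    return Signature(up=up, down=down, fdr_max=fdr_max, lfc_min=lfc_min,
                     source_label=table.label)


def combine_signatures(a: Signature, b: Signature, mode: str = "union") -> Signature:
    """Combine two signatures of the same contrast (e.g. replicate data sets).

    ``union`` pools each direction and drops genes with conflicting calls
    (up in one, down in the other) to preserve disjointness; ``intersect``
    keeps only genes called in the same direction in both.  The combined
    label records the mode so downstream outputs stay self-describing.
    """
    if mode not in ("union", "intersect"):
        raise ValidationError(f"unknown combination mode '{mode}'")
    if (a.fdr_max, a.lfc_min) != (b.fdr_max, b.lfc_min):
        raise ValidationError(
            "signatures extracted at different thresholds cannot be combined"
        )
    if mode == "union":
        up = (a.up | b.up) - (a.down | b.down)
        down = (a.down | b.down) - (a.up | b.up)
    else:
        up = a.up & b.up
        down = a.down & b.down
    return Signature(
        up=up, down=down, fdr_max=a.fdr_max, lfc_min=a.lfc_min,
        source_label=f"{mode}({a.source_label},{b.source_label})",
    )


def top_k(table: DETable, k: int, direction: str = "increased") -> set[str]:
    """The k genes with the largest (``increased``) or smallest (``decreased``)
    log2 fold change; ties broken by gene identifier."""
    if direction not in ("increased", "decreased"):
        raise ValidationError(f"unknown direction '{direction}'")
    if not 1 <= k <= len(table):
        raise ValidationError(
            f"k={k} out of range for table of {len(table)} genes"
        )
    ranking = rank_by_fc(
        table, order="descending" if direction == "increased" else "ascending"
    )
    return set(ranking.genes[:k])


def rank_by_fc(table: DETable, order: str = "descending") -> RankedVector:
    """Full deterministic ordering of the table by log2 fold change."""
    if order not in ("descending", "ascending"):
        raise ValidationError(f"unknown order '{order}'")
    df = table.data
    asc = order == "ascending"
    ordered = df.sort_values(
        ["log2fc", "gene"], ascending=[asc, True], kind="mergesort"
    )
    return RankedVector(
        genes=tuple(ordered["gene"]),
        values=tuple(float(v) for v in ordered["log2fc"]),
        order=order,
    )


@dataclass
class PCAResult:
    """Sample coordinates and per-component variance fractions.

    The sign of each component is fixed by forcing its largest-magnitude gene
    loading positive, so coordinates are reproducible across library versions.
    """

    coordinates: pd.DataFrame  # samples x components, columns PC1..PCk
    variance_fractions: np.ndarray
    components: np.ndarray  # components x genes loadings


def pca_projection(matrix, n_components: int = 2) -> PCAResult:
    """Mean-centered PCA of a samples x genes matrix (DataFrame or ndarray)."""
    if isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
        index = matrix.index
    else:
        values = np.asarray(matrix, dtype=float)
        index = pd.RangeIndex(values.shape[0])
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValidationError("pca_projection needs a 2-D matrix with >= 2 samples")
    max_comp = min(values.shape[0] - 1, values.shape[1])
    if not 1 <= n_components <= max_comp:
        raise ValidationError(
            f"n_components={n_components} exceeds min(samples-1, genes)={max_comp}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(values)
    components = pca.components_.copy()
    for i in range(n_components):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1.0
            scores[:, i] *= -1.0
    coords = pd.DataFrame(
        scores, index=index, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return PCAResult(coords, pca.explained_variance_ratio_.copy(), components)
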