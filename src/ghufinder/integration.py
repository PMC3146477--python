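"""Cross-tabulation of the three clusterings into a lattice of elements.

The TF-binding clustering, the histone-acetylation clustering and the
expression clustering partition the shared gene universe three ways.  Each
gene lands in exactly one lattice cell ("element") named ``T{i}H{j}E{m}``
after its three cluster labels.  Elements whose gene count stands out are
candidates for genetic harmonious units: counts over all lattice cells are
standardized and converted through the Student-t CDF, and elements above a
high t-CDF cut-off (default 0.99) are selected.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ELEMENT_ID_RE = re.compile(r"^T\d+H\d+E\d+$")


def element_id(tf: int, hm: int, expr: int) -> str:
    return f"T{tf}H{hm}E{expr}"


@dataclass
class ElementGrid:
    """Assignment of genes to the k_tf × k_hm × k_expr element lattice."""

    k_tf: int
    k_hm: int
    k_expr: int
    gene_elements: pd.Series  # gene id → element id
    counts: pd.Series         # element id → gene count, over the full lattice

    @property
    def element_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_elements(self) -> int:
        return self.k_tf * self.k_hm * self.k_expr

    def genes_in(self, element: str) -> list[str]:
        mask = self.gene_elements == element
        return list(self.gene_elements.index[mask])

    def gene_lists(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {e: [] for e in self.element_ids}
        for gene, elem in self.gene_elements.items():
            out[elem].append(gene)
        return out


@dataclass
class ElementSelection:
    """Per-element counts, t-CDF values and the selection flag."""

    table: pd.DataFrame  # columns: n_genes, t_cdf, selected
    threshold: float

    @property
    def selected(self) -> list[str]:
        sub = self.table[self.table["selected"]]
        return list(sub.sort_values("t_cdf", ascending=False).index)


def assign_elements(
    tf_labels: pd.Series,
    hm_labels: pd.Series,
    expr_labels: pd.Series,
    k_tf: int | None = None,
    k_hm: int | None = None,
    k_expr: int | None = None,
) -> ElementGrid:
    """Partition the shared genes into lattice elements.

    The three labelings must cover the same gene list (1-based labels).
    Lattice sizes default to the largest label seen on each axis.
    """
    genes = list(tf_labels.index)
    for name, labels in (("histone-acetylation", hm_labels), ("expression", expr_labels)):
        missing = set(genes).symmetric_difference(labels.index)
        if missing:
            raise ValueError(f"gene {sorted(missing)[0]!r} missing from the {name} labeling")

    k_tf = int(k_tf or tf_labels.max())
    k_hm = int(k_hm or hm_labels.max())
    k_expr = int(k_expr or expr_labels.max())
    for axis, labels, size in (
        ("TF", tf_labels, k_tf), ("HM", hm_labels, k_hm), ("EXPR", expr_labels, k_expr)
    ):
        if labels.min() < 1 or labels.max() > size:
            raise ValueError(f"{axis} labels out of range 1..{size}")

    ids = pd.Series(
        [
            element_id(int(tf_labels[g]), int(hm_labels[g]), int(expr_labels[g]))
            for g in genes
        ],
        index=genes,
        name="element",
    )
    lattice = [
        element_id(t, h, e)
        for t, h, e in product(range(1, k_tf + 1), range(1, k_hm + 1), range(1, k_expr + 1))
    ]
    counts = ids.value_counts().reindex(lattice, fill_value=0).astype(int)
    assert counts.sum() == len(genes)
    return ElementGrid(k_tf=k_tf, k_hm=k_hm, k_expr=k_expr, gene_elements=ids, counts=counts)


def counts_to_tcdf(counts: pd.Series) -> pd.Series:
    """Standardize element counts and map through the Student-t CDF.

    The t statistic for element e is ``(N_e − mean(N)) / sd(N)`` with the
    sample standard deviation over *all* lattice elements (empty ones
    included) and ``df = #elements − 1``.  If every count is equal the
    statistic is undefined and all values are reported as 0.5.
    """
    if len(counts) < 2:
        raise ValueError("need at least two elements to standardize counts")
    values = counts.to_numpy(dtype=float)
    sd = values.std(ddof=1)
    if sd == 0:
        logger.warning("counts_to_tcdf: all element counts equal; returning 0.5 everywhere")
        return pd.Series(0.5, index=counts.index, name="t_cdf")
    t = (values - values.mean()) / sd
    cdf = stats.t.cdf(t, df=len(values) - 1)
    return pd.Series(cdf, index=counts.index, name="t_cdf")


def score_elements(grid: ElementGrid, threshold: float = 0.99) -> ElementSelection:
    """Attach t-CDF values and the strict-threshold selection flag."""
    tcdf = counts_to_tcdf(grid.counts)
    table = pd.DataFrame(
        {"n_genes": grid.counts, "t_cdf": tcdf, "selected": tcdf > threshold}
    )
    return ElementSelection(table=table, threshold=threshold)


def select_by_tcdf(selection: ElementSelection, threshold: float | None = None) -> list[str]:
    """Elements with t-CDF strictly above the threshold, best first."""
    thr = selection.threshold if threshold is None else threshold
    table = selection.table
    chosen = table[table["t_cdf"] > thr].sort_values("t_cdf", ascending=False)
    return list(chosen.index)


def write_selection(selection: ElementSelection, path) -> None:
    selection.table.to_csv(path, sep="\t", index_label="element_id")


def write_gene_lists(grid: ElementGrid, path) -> None:
    frame = grid.gene_elements.rename_axis("gene_id").reset_index()
    frame[["element", "gene_id"]].rename(columns={"element": "element_id"}).to_csv(
        path, sep="\t", index=False
    )
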