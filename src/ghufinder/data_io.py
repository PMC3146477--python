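"""Loading and normalization of gene × feature tables.

All datasets (TF-binding t-CDFs, acetylated-histone intensities, histone
occupancy, expression profiles) are tab-delimited tables with a header row
of feature identifiers and a first column of gene identifiers.  Gene
identifiers are matched across datasets by exact string comparison after
whitespace trimming and uppercasing; no alias resolution is attempted.

The acetylation table is put on a per-nucleosome scale by dividing each
intensity by the averaged occupancy of the corresponding histone family
(the occupancy-normalized table is tagged ``AHplus``).  Because the
nucleosome core consists of two H2A-H2B dimers and an H3-H4 tetramer, H4
intensities are normalized by H3 occupancy and H2A intensities by H2B
occupancy.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VALID_TAGS = ("TR", "AH", "HS", "AHplus", "EXPR")

#: Occupancy family measured for each histone.
HISTONE_FAMILY = {"H3": "H3", "H4": "H3", "H2A": "H2B", "H2B": "H2B"}

#: Antibody grouping of the occupancy table: four antibodies against H3 and
#: three against H2B.  Real datasets with different column names supply their
#: own grouping via :func:`load_normalization_config`.
DEFAULT_ANTIBODY_GROUPS: dict[str, list[str]] = {
    "H3": ["H3_ab1", "H3_ab2", "H3_ab3", "H3_ab4"],
    "H2B": ["H2B_ab1", "H2B_ab2", "H2B_ab3"],
}

_RESIDUE_RE = re.compile(r"^(H2A|H2B|H3|H4)K(\d+)$", re.IGNORECASE)


class MatrixFormatError(ValueError):
    """Raised when an input table violates the expected dialect."""


def _clean_gene_id(gene: object) -> str:
    return str(gene).strip().upper()


@dataclass
class GeneMatrix:
    """A labeled genes × features real-valued table.

    Parameters
    ----------
    data:
        DataFrame with unique gene identifiers as index and unique feature
        identifiers as columns; values must be finite floats.
    tag:
        Dataset label, one of ``TR``, ``AH``, ``HS``, ``AHplus``, ``EXPR``.
    """

    data: pd.DataFrame
    tag: str

    def __post_init__(self) -> None:
        if self.tag not in VALID_TAGS:
            raise ValueError(f"unknown dataset tag {self.tag!r}; expected one of {VALID_TAGS}")
        idx = self.data.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise MatrixFormatError(f"duplicate gene id {dup!r} in {self.tag} table")
        cols = self.data.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise MatrixFormatError(f"duplicate feature id {dup!r} in {self.tag} table")
        if self.data.isna().any().any():
            raise MatrixFormatError(f"{self.tag} table contains missing values after loading")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset(self, genes: Sequence[str]) -> "GeneMatrix":
        """Restrict to the given genes, preserving their order."""
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from {self.tag} table: {missing[:5]}")
        return GeneMatrix(self.data.loc[list(genes)].copy(), self.tag)


def load_matrix(path: str | Path, tag: str) -> GeneMatrix:
    """Read a TSV table (header = feature ids, first column = gene ids).

    Rows containing missing values are dropped and the drop count is logged;
    a non-numeric cell raises :class:`MatrixFormatError` naming the offending
    row and column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.columns.size == 0:
        raise MatrixFormatError(f"{path}: no feature columns found (malformed header?)")
    raw.index = [_clean_gene_id(g) for g in raw.index]
    raw.columns = [str(c).strip() for c in raw.columns]

    converted_cols = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            gene = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise MatrixFormatError(
                f"{path}: non-numeric cell at gene {gene!r}, feature {col!r}"
            )
        converted_cols[col] = converted
    numeric = pd.DataFrame(converted_cols, index=raw.index)

    n_before = len(numeric)
    numeric = numeric.dropna(axis=0, how="any")
    dropped = n_before - len(numeric)
    if dropped:
        logger.warning("%s: dropped %d row(s) with missing values", path, dropped)
    if numeric.index.has_duplicates:
        dup = numeric.index[numeric.index.duplicated()][0]
        raise MatrixFormatError(f"{path}: duplicate gene id {dup!r}")
    return GeneMatrix(numeric.astype(float), tag)


def write_matrix(matrix: GeneMatrix, path: str | Path) -> None:
    """Write a table in the same TSV dialect accepted by :func:`load_matrix`."""
    matrix.data.to_csv(Path(path), sep="\t", index_label="gene")


@dataclass
class OccupancyMap:
    """Per-gene averaged histone occupancy for the H3 and H2B families."""

    table: pd.DataFrame  # genes × families

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def families(self) -> list[str]:
        return list(self.table.columns)


def average_occupancy(
    hs: GeneMatrix, antibody_groups: Mapping[str, Sequence[str]] | None = None
) -> OccupancyMap:
    """Average the occupancy table over the antibodies of each histone family.

    Every feature of ``hs`` must belong to exactly one family group.
    """
    groups = dict(antibody_groups) if antibody_groups is not None else DEFAULT_ANTIBODY_GROUPS
    assigned: dict[str, str] = {}
    for family, features in groups.items():
        for feat in features:
            if feat in assigned:
                raise ValueError(f"antibody {feat!r} assigned to both {assigned[feat]!r} and {family!r}")
            if feat not in hs.data.columns:
                raise ValueError(f"antibody {feat!r} (family {family!r}) absent from HS table")
            assigned[feat] = family
    orphans = [c for c in hs.data.columns if c not in assigned]
    if orphans:
        raise ValueError(f"HS feature(s) not in any antibody group: {orphans}")

    table = pd.DataFrame(
        {family: hs.data[list(features)].mean(axis=1) for family, features in groups.items()},
        index=hs.data.index,
    )
    return OccupancyMap(table)


def build_family_map(
    feature_ids: Sequence[str], overrides: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Map each acetyl-lysine feature (e.g. ``H4K16``) to its occupancy family.

    Feature ids are parsed as ``<histone>K<position>`` case-insensitively;
    unparseable ids must be covered by ``overrides``.
    """
    overrides = dict(overrides or {})
    mapping: dict[str, str] = {}
    for feat in feature_ids:
        if feat in overrides:
            family = overrides[feat]
            if family not in ("H3", "H2B"):
                raise ValueError(f"override for {feat!r} maps to unknown family {family!r}")
            mapping[feat] = family
            continue
        m = _RESIDUE_RE.match(feat.strip())
        if m is None:
            raise ValueError(f"cannot parse residue feature id {feat!r} as <histone>K<position>")
        mapping[feat] = HISTONE_FAMILY[m.group(1).upper()]
    return mapping


def normalize_acetylation(
    ah: GeneMatrix,
    occ: OccupancyMap,
    family_map: Mapping[str, str] | None = None,
    eps: float = 1e-12,
) -> GeneMatrix:
    """Build the occupancy-normalized acetylation table (tag ``AHplus``).

    Operates on the gene intersection of the acetylation table and the
    occupancy map; each cell is divided by the averaged occupancy of the
    gene's corresponding histone family.  Genes whose occupancy is not
    strictly positive (≤ ``eps``) are excluded with a warning rather than
    clamped.
    """
    if family_map is None:
        family_map = build_family_map(ah.feature_ids)
    shared = [g for g in ah.gene_ids if g in occ.table.index]
    if not shared:
        raise ValueError("no genes shared between the acetylation and occupancy tables")

    occ_shared = occ.table.loc[shared]
    families = [family_map[f] for f in ah.feature_ids]
    ok = (occ_shared[sorted(set(families))] > eps).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("normalize_acetylation: excluded %d gene(s) with non-positive occupancy", n_dropped)
    kept = [g for g, flag in zip(shared, ok) if flag]

    divisor = occ_shared.loc[kept, families].to_numpy(dtype=float)
    values = ah.data.loc[kept].to_numpy(dtype=float) / divisor
    return GeneMatrix(pd.DataFrame(values, index=kept, columns=ah.feature_ids), "AHplus")


def intersect_genes(tables: Sequence[GeneMatrix | OccupancyMap]) -> list[str]:
    """Ordered intersection of gene universes (order of the first table)."""
    if len(tables) < 2:
        raise ValueError("need at least two tables to intersect")
    first = tables[0].gene_ids
    others = [set(t.gene_ids) for t in tables[1:]]
    shared = [g for g in first if all(g in s for s in others)]
    if not shared:
        raise ValueError("empty gene intersection across tables")
    return shared


def load_normalization_config(path: str | Path) -> dict:
    """Read antibody grouping / residue-family overrides from a YAML file.

    Recognized keys: ``antibody_groups`` (family → list of HS column names)
    and ``family_map`` (AH column name → ``H3`` | ``H2B``).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out = {
        "antibody_groups": cfg.get("antibody_groups", DEFAULT_ANTIBODY_GROUPS),
        "family_map": cfg.get("family_map"),
    }
    return out
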