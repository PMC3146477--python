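"""Functional-category enrichment of element gene lists.

Selected elements are characterized against a gene-set annotation (GMT or
two-column flat file, standing in for a FunCat-style catalogue).  For each
category the one-sided hypergeometric tail probability
``p = P(X ≥ overlap)`` is computed with the run's shared gene universe as
the population.  Elements with at least one category below the cut-off
(default p < 0.01, uncorrected, matching common practice for this style of
screen) are promoted to *pattern-elements*.

When category identifiers look hierarchical (dot-separated numeric codes
such as ``01.03``), only levels 1 and 2 of the hierarchy are tested.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

_FUNCAT_ID_RE = re.compile(r"^\d+(\.\d+)*$")


@dataclass
class AnnotationSet:
    """Category id → gene-id set, with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str]

    def __len__(self) -> int:
        return len(self.sets)

    def category_level(self, category: str) -> int | None:
        """Hierarchy depth for dot-separated numeric ids, else None."""
        if _FUNCAT_ID_RE.match(category):
            return category.count(".") + 1
        return None

    def testable_categories(self, max_level: int = 2) -> list[str]:
        out = []
        for cat in self.sets:
            level = self.category_level(cat)
            if level is None or level <= max_level:
                out.append(cat)
        return out

    def restricted_to(self, background: Iterable[str]) -> "AnnotationSet":
        bg = frozenset(background)
        return AnnotationSet(
            sets={c: s & bg for c, s in self.sets.items()},
            descriptions=dict(self.descriptions),
        )


@dataclass
class EnrichmentResult:
    """Hypergeometric overlap test of one element against one category."""

    element_id: str
    category_id: str
    overlap: int
    element_size: int
    category_size: int  # within the background universe
    background_size: int
    p_value: float


@dataclass
class PatternElementHit:
    """A selected element with its significantly enriched categories."""

    element_id: str
    significant: list[EnrichmentResult]

    @property
    def best_p(self) -> float:
        return min(r.p_value for r in self.significant)


def load_annotation(path: str | Path) -> AnnotationSet:
    """Read a GMT file (``category<TAB>description<TAB>gene...``) or a
    two-column ``category<TAB>gene`` flat file.

    Duplicate genes within a category are de-duplicated; empty categories
    are skipped with a warning.
    """
    path = Path(path)
    gmt_sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    is_flat = lines and all(len(ln.split("\t")) == 2 for ln in lines)
    for ln in lines:
        fields = ln.split("\t")
        if is_flat:
            cat, gene = fields
            gmt_sets.setdefault(cat, set()).add(gene.strip().upper())
            descriptions.setdefault(cat, "")
        else:
            cat, desc, genes = fields[0], fields[1] if len(fields) > 1 else "", fields[2:]
            members = {g.strip().upper() for g in genes if g.strip()}
            if not members:
                logger.warning("load_annotation: skipping empty category %r", cat)
                continue
            gmt_sets.setdefault(cat, set()).update(members)
            descriptions[cat] = desc
    empty = [c for c, s in gmt_sets.items() if not s]
    for cat in empty:
        logger.warning("load_annotation: skipping empty category %r", cat)
        del gmt_sets[cat]
    return AnnotationSet(
        sets={c: frozenset(s) for c, s in gmt_sets.items()}, descriptions=descriptions
    )


def write_annotation(annot: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cat, genes in annot.sets.items():
            desc = annot.descriptions.get(cat, "")
            fh.write("\t".join([cat, desc, *sorted(genes)]) + "\n")


def enrich_element(
    genes: Sequence[str],
    background: Sequence[str],
    annot: AnnotationSet,
    element_id: str = "",
    max_level: int = 2,
) -> list[EnrichmentResult]:
    """Hypergeometric tail p-values of one element against all categories.

    Population = background universe, successes = category ∩ background,
    draws = element size.  Categories with no gene in the background are not
    testable and are omitted.
    """
    bg = set(background)
    element = set(genes)
    if not element <= bg:
        stray = sorted(element - bg)[0]
        raise ValueError(f"element gene {stray!r} not in the background universe")
    M = len(bg)
    N = len(element)
    results = []
    for cat in annot.testable_categories(max_level=max_level):
        members = annot.sets[cat] & bg
        n = len(members)
        if n == 0:
            continue
        overlap = len(element & members)
        p = float(hypergeom.sf(overlap - 1, M, n, N))
        results.append(
            EnrichmentResult(
                element_id=element_id,
                category_id=cat,
                overlap=overlap,
                element_size=N,
                category_size=n,
                background_size=M,
                p_value=min(p, 1.0),
            )
        )
    return results


def select_pattern_elements(
    selected_elements: Sequence[str],
    results: Mapping[str, Sequence[EnrichmentResult]],
    alpha: float = 0.01,
) -> list[PatternElementHit]:
    """Keep elements with at least one category at ``p < alpha`` (strict)."""
    hits = []
    for elem in selected_elements:
        if elem not in results:
            raise ValueError(f"no enrichment results for selected element {elem!r}")
        significant = [r for r in results[elem] if r.p_value < alpha]
        if significant:
            significant.sort(key=lambda r: r.p_value)
            hits.append(PatternElementHit(element_id=elem, significant=significant))
    return hits
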