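"""Synthetic dataset bundles with planted genetic harmonious units.

The generator emulates the statistical shape of the four study tables:

* **TR-like** — per-gene TF-binding scores in [0, 1].  TFs are split into
  blocks; genes of a TF cluster draw their block's scores from a Beta
  distribution concentrated near 0.95 ("bound") and all other scores from
  one centred near 0.3 ("unbound"), so the table stays in the t-CDF range
  by construction.
* **AH-like / HS-like** — positive acetylation intensities with residue
  structure and positive nucleosome occupancy.  Each acetylation cluster
  has a characteristic subset of the 11 lysine residues whose mean is
  shifted by the acetylation effect size (in within-group standard
  deviation units); per-gene occupancy multiplies both tables so the
  occupancy normalization has real work to do.
* **Expression** — per-cluster condition profiles (mutually orthogonal
  cosine shapes) plus Gaussian noise.
* **Annotation** — one functional category per planted GHU covering its
  genes, plus random decoy categories.

Every gene carries a triple of ground-truth cluster labels.  A planted GHU
is an *over-populated* label combination: its member genes all share one
(tf, hm, expr) triple, while the remaining genes are spread round-robin
over the other lattice cells, mimicking a genome in which most regulatory
programs are evenly represented and a few co-regulated modules stand out.
A null bundle (``structured=False``) keeps the same noise models but turns
all signals off: uniform binding, no residue shifts, profile-free
expression, and only decoy categories.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .data_io import GeneMatrix
from .enrichment import AnnotationSet, write_annotation
from .integration import element_id

#: The 11 acetyl-lysine residues measured by the acetylation table.
DEFAULT_RESIDUES = [
    "H4K8", "H4K12", "H4K16",
    "H3K9", "H3K14", "H3K18", "H3K23", "H3K27",
    "H2AK7", "H2BK11", "H2BK16",
]

_HISTONES = ["H3", "H4", "H2A", "H2B"]


@dataclass(frozen=True)
class PlantedGHU:
    """One planted unit: a (tf, hm, expr) cluster triple and its size."""

    tf_cluster: int
    hm_cluster: int
    expr_cluster: int
    n_genes: int = 30

    @property
    def element_id(self) -> str:
        return element_id(self.tf_cluster, self.hm_cluster, self.expr_cluster)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic bundle; defaults give the desk-scale setup."""

    n_genes: int = 1000
    n_tfs: int = 40
    n_residues: int = 11
    n_conditions: int = 4
    k_tf: int = 4
    k_hm: int = 4
    k_expr: int = 3
    ghus: tuple[PlantedGHU, ...] = (
        PlantedGHU(1, 1, 1, 30),
        PlantedGHU(2, 2, 2, 30),
        PlantedGHU(3, 3, 3, 30),
    )
    bound_mean: float = 0.95
    bound_precision: float = 20.0
    unbound_mean: float = 0.30
    unbound_precision: float = 10.0
    acetyl_base: float = 2.0
    acetyl_noise_sd: float = 1.0
    acetyl_effect_size: float = 3.0  # mean shift in within-group sd units
    occupancy_sigma: float = 0.3
    antibody_sigma: float = 0.1
    expr_amplitude: float = 2.0
    expr_noise_sd: float = 1.0
    n_decoy_categories: int = 20
    decoy_category_size: int = 30
    structured: bool = True
    seed: int = 0

    @classmethod
    def null(cls, n_genes: int = 300, n_tfs: int = 20, seed: int = 0, **kwargs) -> "SyntheticSpec":
        """A no-structure bundle: noise-only tables, decoy categories only."""
        return cls(
            n_genes=n_genes,
            n_tfs=n_tfs,
            ghus=(),
            acetyl_effect_size=0.0,
            structured=False,
            seed=seed,
            **kwargs,
        )

    def validate(self) -> None:
        planted = sum(g.n_genes for g in self.ghus)
        if planted > self.n_genes:
            raise ValueError(
                f"planted genes ({planted}) exceed the gene total ({self.n_genes})"
            )
        triples = [(g.tf_cluster, g.hm_cluster, g.expr_cluster) for g in self.ghus]
        if len(set(triples)) != len(triples):
            raise ValueError("planted GHUs must occupy distinct lattice cells")
        for g in self.ghus:
            if not (1 <= g.tf_cluster <= self.k_tf
                    and 1 <= g.hm_cluster <= self.k_hm
                    and 1 <= g.expr_cluster <= self.k_expr):
                raise ValueError(f"planted GHU {g} outside the cluster lattice")
            if g.n_genes <= 0:
                raise ValueError("planted GHU sizes must be positive")
        for name in ("n_genes", "n_tfs", "n_residues", "n_conditions", "k_tf", "k_hm", "k_expr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticBundle:
    """Generated tables plus the ground truth they were built from."""

    tr: GeneMatrix
    ah: GeneMatrix
    hs: GeneMatrix
    expr: GeneMatrix
    annotation: AnnotationSet
    true_labels: pd.DataFrame      # genes × (tf, hm, expr), 1-based
    planted_elements: list[str]
    planted_genes: dict[str, list[str]]
    spec: SyntheticSpec

    @property
    def all_planted_genes(self) -> set[str]:
        return {g for genes in self.planted_genes.values() for g in genes}


def _residue_names(n: int) -> list[str]:
    if n == len(DEFAULT_RESIDUES):
        return list(DEFAULT_RESIDUES)
    return [f"{_HISTONES[i % 4]}K{4 * (i // 4) + 5 + i % 4}" for i in range(n)]


def _round_robin_partition(items: Sequence, n_groups: int) -> list[list]:
    groups: list[list] = [[] for _ in range(n_groups)]
    for i, item in enumerate(items):
        groups[i % n_groups].append(item)
    return groups


def _beta_params(mean: float, precision: float) -> tuple[float, float]:
    return mean * precision, (1.0 - mean) * precision


def generate_bundle(spec: SyntheticSpec) -> SyntheticBundle:
    """Deterministically generate a bundle from the spec's seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(spec.n_genes)]
    residues = _residue_names(spec.n_residues)
    conditions = [f"cond_{c + 1}" for c in range(spec.n_conditions)]
    tf_ids = [f"TF{i + 1:03d}" for i in range(spec.n_tfs)]

    labels = _assign_labels(spec, genes, rng)

    tr = _make_binding(spec, genes, tf_ids, labels["tf"], rng)
    ah, hs = _make_acetylation(spec, genes, residues, labels["hm"], rng)
    expr = _make_expression(spec, genes, conditions, labels["expr"], rng)
    annotation = _make_annotation(spec, genes, labels, rng)

    planted_genes = {}
    for ghu in spec.ghus:
        mask = (
            (labels["tf"] == ghu.tf_cluster)
            & (labels["hm"] == ghu.hm_cluster)
            & (labels["expr"] == ghu.expr_cluster)
            & labels["planted"]
        )
        planted_genes[ghu.element_id] = list(labels.index[mask])

    return SyntheticBundle(
        tr=tr,
        ah=ah,
        hs=hs,
        expr=expr,
        annotation=annotation,
        true_labels=labels[["tf", "hm", "expr"]],
        planted_elements=[g.element_id for g in spec.ghus],
        planted_genes=planted_genes,
        spec=spec,
    )


def _assign_labels(spec: SyntheticSpec, genes: list[str], rng: np.random.Generator) -> pd.DataFrame:
    order = rng.permutation(len(genes))
    labels = pd.DataFrame(
        {"tf": 0, "hm": 0, "expr": 0, "planted": False}, index=genes
    )
    pos = 0
    for ghu in spec.ghus:
        members = [genes[i] for i in order[pos:pos + ghu.n_genes]]
        pos += ghu.n_genes
        labels.loc[members, ["tf", "hm", "expr"]] = (
            ghu.tf_cluster, ghu.hm_cluster, ghu.expr_cluster
        )
        labels.loc[members, "planted"] = True

    lattice = list(product(range(1, spec.k_tf + 1), range(1, spec.k_hm + 1), range(1, spec.k_expr + 1)))
    planted_cells = {(g.tf_cluster, g.hm_cluster, g.expr_cluster) for g in spec.ghus}
    open_cells = [c for c in lattice if c not in planted_cells] or lattice
    background = [genes[i] for i in order[pos:]]
    for i, gene in enumerate(background):
        t, h, e = open_cells[i % len(open_cells)]
        labels.loc[gene, ["tf", "hm", "expr"]] = (t, h, e)
    return labels


def _make_binding(
    spec: SyntheticSpec, genes, tf_ids, tf_labels: pd.Series, rng: np.random.Generator
) -> GeneMatrix:
    a_u, b_u = _beta_params(spec.unbound_mean, spec.unbound_precision)
    values = rng.beta(a_u, b_u, size=(len(genes), len(tf_ids)))
    if spec.structured:
        a_b, b_b = _beta_params(spec.bound_mean, spec.bound_precision)
        tf_blocks = _round_robin_partition(list(range(len(tf_ids))), spec.k_tf)
        for cluster in range(1, spec.k_tf + 1):
            rows = np.flatnonzero((tf_labels == cluster).to_numpy())
            cols = np.asarray(tf_blocks[cluster - 1], dtype=int)
            if rows.size and cols.size:
                values[np.ix_(rows, cols)] = rng.beta(a_b, b_b, size=(rows.size, cols.size))
    return GeneMatrix(pd.DataFrame(values, index=genes, columns=tf_ids), "TR")


def _make_acetylation(
    spec: SyntheticSpec, genes, residues, hm_labels: pd.Series, rng: np.random.Generator
) -> tuple[GeneMatrix, GeneMatrix]:
    n = len(genes)
    acetyl = spec.acetyl_base + rng.normal(0.0, spec.acetyl_noise_sd, size=(n, len(residues)))
    if spec.structured and spec.acetyl_effect_size > 0:
        shift = spec.acetyl_effect_size * spec.acetyl_noise_sd
        residue_sets = _round_robin_partition(list(range(len(residues))), spec.k_hm)
        for cluster in range(1, spec.k_hm + 1):
            rows = np.flatnonzero((hm_labels == cluster).to_numpy())
            cols = np.asarray(residue_sets[cluster - 1], dtype=int)
            if rows.size and cols.size:
                acetyl[np.ix_(rows, cols)] += shift
    acetyl = np.clip(acetyl, 0.05, None)

    occupancy = {
        fam: rng.lognormal(0.0, spec.occupancy_sigma, size=n) for fam in ("H3", "H2B")
    }
    family_of = {r: ("H3" if r.startswith(("H3", "H4")) else "H2B") for r in residues}
    occ_cols = np.column_stack([occupancy[family_of[r]] for r in residues])
    ah_values = acetyl * occ_cols
    ah = GeneMatrix(pd.DataFrame(ah_values, index=genes, columns=residues), "AH")

    hs_cols = {}
    for fam, n_ab in (("H3", 4), ("H2B", 3)):
        for j in range(n_ab):
            noise = rng.lognormal(0.0, spec.antibody_sigma, size=n)
            hs_cols[f"{fam}_ab{j + 1}"] = occupancy[fam] * noise
    hs = GeneMatrix(pd.DataFrame(hs_cols, index=genes), "HS")
    return ah, hs


def _condition_profiles(spec: SyntheticSpec) -> np.ndarray:
    c = np.arange(spec.n_conditions)
    profiles = np.stack(
        [
            spec.expr_amplitude * np.cos(np.pi * e * (c + 0.5) / spec.n_conditions)
            for e in range(spec.k_expr)
        ]
    )
    return profiles


def _make_expression(
    spec: SyntheticSpec, genes, conditions, expr_labels: pd.Series, rng: np.random.Generator
) -> GeneMatrix:
    n = len(genes)
    values = rng.normal(0.0, spec.expr_noise_sd, size=(n, len(conditions)))
    if spec.structured:
        profiles = _condition_profiles(spec)
        values += profiles[expr_labels.to_numpy() - 1]
    return GeneMatrix(pd.DataFrame(values, index=genes, columns=conditions), "EXPR")


def _make_annotation(
    spec: SyntheticSpec, genes, labels: pd.DataFrame, rng: np.random.Generator
) -> AnnotationSet:
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for i, ghu in enumerate(spec.ghus, start=1):
        mask = (
            (labels["tf"] == ghu.tf_cluster)
            & (labels["hm"] == ghu.hm_cluster)
            & (labels["expr"] == ghu.expr_cluster)
            & labels["planted"]
        )
        cat = f"GHU{i}_FUNCTION"
        sets[cat] = frozenset(labels.index[mask])
        descriptions[cat] = f"function of planted unit {ghu.element_id}"
    size = min(spec.decoy_category_size, spec.n_genes)
    for j in range(1, spec.n_decoy_categories + 1):
        cat = f"DECOY{j:02d}"
        sets[cat] = frozenset(rng.choice(genes, size=size, replace=False))
        descriptions[cat] = "random decoy category"
    return AnnotationSet(sets=sets, descriptions=descriptions)


@dataclass
class RecoveryScore:
    """Gene-level recovery of planted GHU membership plus per-axis ARIs."""

    precision: float
    recall: float
    ari: dict[str, float]
    n_pattern_elements: int
    n_reported_genes: int


def score_recovery(result, bundle: SyntheticBundle) -> RecoveryScore:
    """Score a pipeline result against the bundle's ground truth.

    ``result`` is a :class:`~ghufinder.pipeline.PipelineResult`; reported
    genes are those inside its pattern-elements.
    """
    reported: set[str] = set()
    for elem in result.pattern_elements:
        reported.update(result.grid.genes_in(elem))
    planted = bundle.all_planted_genes
    tp = len(reported & planted)
    precision = tp / len(reported) if reported else 0.0
    recall = tp / len(planted) if planted else 0.0

    ari = {}
    for axis in ("tf", "hm", "expr"):
        pred = result.labels[axis]
        truth = bundle.true_labels.loc[pred.index, axis]
        ari[axis] = float(adjusted_rand_score(truth.to_numpy(), pred.to_numpy()))
    return RecoveryScore(
        precision=precision,
        recall=recall,
        ari=ari,
        n_pattern_elements=len(result.pattern_elements),
        n_reported_genes=len(reported),
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write the four TSV tables, a GMT annotation and a ground-truth JSON."""
    from .data_io import write_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(bundle.tr, outdir / "tr.tsv")
    write_matrix(bundle.ah, outdir / "ah.tsv")
    write_matrix(bundle.hs, outdir / "hs.tsv")
    write_matrix(bundle.expr, outdir / "expr.tsv")
    write_annotation(bundle.annotation, outdir / "annotation.gmt")
    truth = {
        "planted_elements": bundle.planted_elements,
        "planted_genes": bundle.planted_genes,
        "true_labels": {
            axis: bundle.true_labels[axis].to_dict() for axis in ("tf", "hm", "expr")
        },
        "seed": bundle.spec.seed,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
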