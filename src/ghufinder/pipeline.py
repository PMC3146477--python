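"""End-to-end GHU detection pipeline.

Order of operations, mirroring the study design:

1. Average the occupancy table per histone family and divide the
   acetylation table by it (``AH`` → ``AH+``).
2. Intersect the gene universes of the TF-binding, normalized-acetylation
   and expression tables.
3. Soft-cluster each table (spectral embedding + vMF mixture EM) and take
   maximum-posterior labels.
4. Cross the three labelings into the element lattice, convert element
   counts to t-CDFs and select elements above the cut-off.
5. Test each selected element for functional-category enrichment against
   the shared-gene background; elements with a category at p < α become
   pattern-elements.
6. Characterize each pattern-element: TF-scores, SDAL residue testing and
   the mean expression profile.

The defaults (k = 10 for the two ChIP-chip tables, k = 5 for expression,
κ = 10, 1000 EM restarts, t-CDF > 0.99, enrichment α = 0.01) are the
full-scale study settings; synthetic desk-scale runs override them.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import pattern_stats
from .data_io import GeneMatrix, average_occupancy, intersect_genes, normalize_acetylation
from .enrichment import AnnotationSet, PatternElementHit, enrich_element, select_pattern_elements
from .integration import ElementGrid, ElementSelection, assign_elements, score_elements
from .pattern_stats import GHUPattern, RandomizationResult, randomization_test
from .spectral_vmf import SoftClusterModel, cluster_genes, hard_assign

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    k_tf: int = 10
    k_hm: int = 10
    k_expr: int = 5
    kappa: float = 10.0
    n_restarts: int = 1000
    tol: float = 1e-8
    max_iter: int = 500
    tcdf_threshold: float = 0.99
    enrich_alpha: float = 0.01
    anova_alpha: float = 0.01
    tukey_alpha: float = 0.05
    tf_score_threshold: float = 0.8
    seed: int | None = None


@dataclass
class PipelineResult:
    genes: list[str]
    labels: dict[str, pd.Series]
    models: dict[str, SoftClusterModel]
    grid: ElementGrid
    selection: ElementSelection
    selected_elements: list[str]
    enrichment: dict[str, list]
    pattern_hits: list[PatternElementHit]
    patterns: list[GHUPattern]
    config: PipelineConfig

    @property
    def pattern_elements(self) -> list[str]:
        return [hit.element_id for hit in self.pattern_hits]

    def enrichment_pvalues(self) -> np.ndarray:
        """Per-selected-element enrichment p-value (best category each).

        Each selected element is summarized by the p-value of its most
        over-represented category; these element-level values feed the
        randomization control.
        """
        pvals = [
            min((r.p_value for r in self.enrichment[elem]), default=1.0)
            for elem in self.selected_elements
        ]
        return np.asarray(pvals, dtype=float)

    def summary(self) -> dict:
        return {
            "n_genes": len(self.genes),
            "n_selected_elements": len(self.selected_elements),
            "n_pattern_elements": len(self.pattern_elements),
            "selected_elements": self.selected_elements,
            "pattern_elements": self.pattern_elements,
            "log_likelihood": {a: m.log_likelihood for a, m in self.models.items()},
        }


def build_ahplus(
    ah: GeneMatrix,
    hs: GeneMatrix,
    antibody_groups: Mapping[str, list[str]] | None = None,
    family_map: Mapping[str, str] | None = None,
) -> GeneMatrix:
    """Occupancy-normalize the acetylation table (steps shared by all runs)."""
    occ = average_occupancy(hs, antibody_groups)
    return normalize_acetylation(ah, occ, family_map)


def run_core(
    tr: GeneMatrix,
    ahplus: GeneMatrix,
    expr: GeneMatrix,
    annotation: AnnotationSet,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Cluster, cross-tabulate, select and characterize on prepared tables."""
    shared = intersect_genes([tr, ahplus, expr])
    tables = {
        "tf": (tr.subset(shared), config.k_tf),
        "hm": (ahplus.subset(shared), config.k_hm),
        "expr": (expr.subset(shared), config.k_expr),
    }

    master = np.random.SeedSequence(config.seed)
    axis_seeds = dict(zip(tables, master.spawn(len(tables))))
    models: dict[str, SoftClusterModel] = {}
    labels: dict[str, pd.Series] = {}
    for axis, (table, k) in tables.items():
        model = cluster_genes(
            table,
            k,
            kappa=config.kappa,
            n_restarts=config.n_restarts,
            seed=axis_seeds[axis],
            tol=config.tol,
            max_iter=config.max_iter,
        )
        models[axis] = model
        labels[axis] = hard_assign(model)

    # genes dropped inside any clustering (zero-information rows) leave the run
    clustered = [g for g in shared if all(g in labels[a].index for a in labels)]
    if len(clustered) < len(shared):
        logger.warning(
            "run_core: %d gene(s) dropped during clustering", len(shared) - len(clustered)
        )
    labels = {a: s.loc[clustered] for a, s in labels.items()}

    grid = assign_elements(
        labels["tf"], labels["hm"], labels["expr"],
        k_tf=config.k_tf, k_hm=config.k_hm, k_expr=config.k_expr,
    )
    selection = score_elements(grid, threshold=config.tcdf_threshold)
    selected = selection.selected

    enrichment: dict[str, list] = {}
    for elem in selected:
        enrichment[elem] = enrich_element(
            grid.genes_in(elem), clustered, annotation, element_id=elem
        )
    hits = select_pattern_elements(selected, enrichment, alpha=config.enrich_alpha)

    tr_shared = tr.subset(clustered)
    ah_shared = ahplus.subset(clustered)
    expr_shared = expr.subset(clustered)
    patterns = []
    for hit in hits:
        genes = grid.genes_in(hit.element_id)
        patterns.append(
            GHUPattern(
                element_id=hit.element_id,
                genes=genes,
                tf_scores=pattern_stats.tf_score(
                    tr_shared, genes, threshold=config.tf_score_threshold,
                    element_id=hit.element_id,
                ),
                sdal=pattern_stats.run_sdal(
                    ah_shared, genes,
                    anova_alpha=config.anova_alpha, tukey_alpha=config.tukey_alpha,
                    element_id=hit.element_id,
                ),
                expression=pattern_stats.expression_profile(
                    expr_shared, genes, element_id=hit.element_id
                ),
            )
        )

    return PipelineResult(
        genes=clustered,
        labels=labels,
        models=models,
        grid=grid,
        selection=selection,
        selected_elements=selected,
        enrichment=enrichment,
        pattern_hits=hits,
        patterns=patterns,
        config=config,
    )


def run_pipeline(
    tr: GeneMatrix,
    ah: GeneMatrix,
    hs: GeneMatrix,
    expr: GeneMatrix,
    annotation: AnnotationSet,
    config: PipelineConfig = PipelineConfig(),
    antibody_groups: Mapping[str, list[str]] | None = None,
    family_map: Mapping[str, str] | None = None,
) -> PipelineResult:
    """Full run from raw tables: normalization then :func:`run_core`."""
    ahplus = build_ahplus(ah, hs, antibody_groups, family_map)
    return run_core(tr, ahplus, expr, annotation, config)


def randomized_control(
    tr: GeneMatrix,
    ahplus: GeneMatrix,
    expr: GeneMatrix,
    annotation: AnnotationSet,
    config: PipelineConfig = PipelineConfig(),
    n_rand: int = 10,
    alpha: float = 0.01,
    seed: int | None = None,
) -> RandomizationResult:
    """Shuffled-table control: rerun selection on randomized tables and
    compare enrichment p-value distributions by Mann-Whitney U."""

    def run_fn(tables: Mapping[str, GeneMatrix]) -> np.ndarray:
        result = run_core(tables["TR"], tables["AHplus"], tables["EXPR"], annotation, config)
        return result.enrichment_pvalues()

    datasets = {"TR": tr, "AHplus": ahplus, "EXPR": expr}
    return randomization_test(run_fn, datasets, n_rand=n_rand, alpha=alpha, seed=seed)


def write_result(result: PipelineResult, outdir: str | Path) -> None:
    """Write the TSV/JSON report bundle for a pipeline run."""
    from .integration import write_gene_lists, write_selection

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_selection(result.selection, outdir / "elements.tsv")
    write_gene_lists(result.grid, outdir / "element_genes.tsv")

    rows = []
    for elem, results in result.enrichment.items():
        for r in results:
            rows.append(
                {
                    "element_id": r.element_id,
                    "category_id": r.category_id,
                    "overlap": r.overlap,
                    "element_size": r.element_size,
                    "category_size": r.category_size,
                    "background_size": r.background_size,
                    "p_value": r.p_value,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "element_id", "category_id", "overlap", "element_size",
            "category_size", "background_size", "p_value",
        ],
    ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    pattern_rows = []
    for pat in result.patterns:
        pattern_rows.append(
            {
                "element_id": pat.element_id,
                "n_genes": len(pat.genes),
                "significant_tfs": ",".join(pat.significant_tfs),
                "anova_f": pat.sdal.f_statistic,
                "anova_p": pat.sdal.anova_p,
                "sdal_passed": pat.sdal.anova_passed,
                "red_residues": ",".join(
                    r for r, c in pat.sdal.residue_classes.items() if c == "red"
                ),
                "blue_residues": ",".join(
                    r for r, c in pat.sdal.residue_classes.items() if c == "blue"
                ),
                "expression_means": ",".join(f"{v:.4f}" for v in pat.expression.means),
            }
        )
    pd.DataFrame(
        pattern_rows,
        columns=[
            "element_id", "n_genes", "significant_tfs", "anova_f", "anova_p",
            "sdal_passed", "red_residues", "blue_residues", "expression_means",
        ],
    ).to_csv(outdir / "patterns.tsv", sep="\t", index=False)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2)
    for axis, model in result.models.items():
        with open(outdir / f"model_{axis}.json", "w") as fh:
            json.dump(model.to_dict(), fh)
        model.posterior_frame().to_csv(outdir / f"posteriors_{axis}.tsv", sep="\t")
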