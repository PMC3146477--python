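"""Characterization of pattern-elements and the randomization control.

Three views describe each pattern-element:

* **TF-score** — for each transcription factor, the mean binding t-CDF over
  the element's genes.  A score above 0.8 (= 0.9 × 0.9, i.e. binding to 90%
  of the genes with probability 90%) flags the TF as characteristic.
* **SDAL** (statistical detection of differentially acetylated lysines) —
  a two-step test over the 11 acetyl-lysine residues of the
  occupancy-normalized acetylation table: one-way ANOVA across residues
  (α = 0.01) followed, for passing elements, by the Tukey-Kramer
  studentized-range comparison of all 55 residue pairs (p < 0.05).
  Residues are then colored: *red* for residues significantly higher than
  at least one other and never significantly lower, *blue* for residues
  significantly below some red residue, *yellow* otherwise.
* **Expression profile** — the per-condition mean over the element's genes,
  with individual traces retained.

The randomization control shuffles rows and columns of each input table,
reruns the full selection, and compares the resulting enrichment p-values
with the observed ones by a two-sided Mann-Whitney U test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GeneMatrix

logger = logging.getLogger(__name__)

TF_SCORE_THRESHOLD = 0.8  # = 0.9 * 0.9


@dataclass
class TFScoreTable:
    element_id: str
    scores: pd.Series  # TF id → mean binding t-CDF over element genes
    threshold: float = TF_SCORE_THRESHOLD

    @property
    def significant(self) -> list[str]:
        """TFs with score strictly above the threshold."""
        return list(self.scores.index[self.scores > self.threshold])


@dataclass
class PairwiseComparison:
    residue_a: str
    residue_b: str
    mean_diff: float  # mean(a) − mean(b)
    p_value: float
    significant: bool


@dataclass
class SDALResult:
    element_id: str
    f_statistic: float
    anova_p: float
    anova_passed: bool
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    residue_classes: dict[str, str] = field(default_factory=dict)


@dataclass
class ExpressionProfile:
    element_id: str
    means: pd.Series        # condition → mean over element genes
    traces: pd.DataFrame    # genes × conditions


@dataclass
class GHUPattern:
    """Full characterization of one pattern-element."""

    element_id: str
    genes: list[str]
    tf_scores: TFScoreTable
    sdal: SDALResult
    expression: ExpressionProfile

    @property
    def significant_tfs(self) -> list[str]:
        return self.tf_scores.significant


@dataclass
class RandomizationResult:
    observed_pvalues: np.ndarray
    randomized_pvalues: list[np.ndarray]
    u_statistic: float
    p_value: float
    alpha: float
    n_rand: int

    @property
    def reject(self) -> bool:
        return self.p_value < self.alpha


def tf_score(
    tr: GeneMatrix, element_genes: Sequence[str], threshold: float = TF_SCORE_THRESHOLD,
    element_id: str = "",
) -> TFScoreTable:
    """Mean binding t-CDF of every TF over the element's genes."""
    if len(element_genes) == 0:
        raise ValueError("cannot score an empty element")
    sub = tr.subset(element_genes)
    scores = sub.data.mean(axis=0)
    scores.name = "tf_score"
    return TFScoreTable(element_id=element_id, scores=scores, threshold=threshold)


def _residue_groups(ahplus: GeneMatrix, element_genes: Sequence[str]) -> list[np.ndarray]:
    sub = ahplus.subset(element_genes)
    return [sub.data[col].to_numpy(dtype=float) for col in sub.feature_ids]


def sdal_anova(
    ahplus: GeneMatrix, element_genes: Sequence[str], alpha: float = 0.01, element_id: str = ""
) -> SDALResult:
    """One-way ANOVA with residues as groups and per-gene values as observations."""
    if len(element_genes) < 2:
        raise ValueError("SDAL requires at least two genes in the element")
    groups = _residue_groups(ahplus, element_genes)
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        logger.warning("sdal_anova: zero variance everywhere; F undefined, reported as non-pass")
        return SDALResult(element_id, float("nan"), float("nan"), False)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat, p = stats.f_oneway(*groups)
    if not np.isfinite(p):
        logger.warning("sdal_anova: degenerate F statistic; reported as non-pass")
        return SDALResult(element_id, float(f_stat), float("nan"), False)
    return SDALResult(element_id, float(f_stat), float(p), bool(p < alpha))


def tukey_kramer(
    ahplus: GeneMatrix, element_genes: Sequence[str], alpha: float = 0.05, element_id: str = ""
) -> list[PairwiseComparison]:
    """Studentized-range comparison of all residue pairs (Tukey-Kramer).

    Uses the pooled within-group variance; with the balanced groups produced
    by a gene × residue table this coincides with Tukey's HSD.
    """
    groups = _residue_groups(ahplus, element_genes)
    residues = ahplus.feature_ids
    if any(len(g) < 2 for g in groups):
        raise ValueError("each residue group needs at least two observations")
    res = stats.tukey_hsd(*groups)
    means = [float(np.mean(g)) for g in groups]
    out = []
    for i, j in combinations(range(len(residues)), 2):
        p = float(res.pvalue[i, j])
        out.append(
            PairwiseComparison(
                residue_a=residues[i],
                residue_b=residues[j],
                mean_diff=means[i] - means[j],
                p_value=p,
                significant=bool(p < alpha),
            )
        )
    return out


def classify_residues(
    pairs: Sequence[PairwiseComparison], residues: Sequence[str]
) -> dict[str, str]:
    """Color residues red / blue / yellow from the significant pair list.

    red: significantly higher than ≥1 residue and never significantly lower;
    blue: not red, never significantly higher, and significantly lower than
    at least one red residue; yellow: everything else (including residues
    that are both above one residue and below another).
    """
    above: dict[str, set[str]] = {r: set() for r in residues}
    below: dict[str, set[str]] = {r: set() for r in residues}
    for pair in pairs:
        if not pair.significant:
            continue
        hi, lo = (
            (pair.residue_a, pair.residue_b)
            if pair.mean_diff > 0
            else (pair.residue_b, pair.residue_a)
        )
        above[hi].add(lo)
        below[lo].add(hi)

    classes = {}
    red = {r for r in residues if above[r] and not below[r]}
    for r in residues:
        if r in red:
            classes[r] = "red"
        elif not above[r] and below[r] & red:
            classes[r] = "blue"
        else:
            classes[r] = "yellow"
    return classes


def run_sdal(
    ahplus: GeneMatrix,
    element_genes: Sequence[str],
    anova_alpha: float = 0.01,
    tukey_alpha: float = 0.05,
    element_id: str = "",
) -> SDALResult:
    """Two-step SDAL: ANOVA gate, then Tukey-Kramer and residue coloring."""
    result = sdal_anova(ahplus, element_genes, alpha=anova_alpha, element_id=element_id)
    if result.anova_passed:
        result.pairwise = tukey_kramer(
            ahplus, element_genes, alpha=tukey_alpha, element_id=element_id
        )
        result.residue_classes = classify_residues(result.pairwise, ahplus.feature_ids)
    return result


def expression_profile(
    expr: GeneMatrix, element_genes: Sequence[str], element_id: str = ""
) -> ExpressionProfile:
    if len(element_genes) == 0:
        raise ValueError("cannot profile an empty element")
    sub = expr.subset(element_genes)
    return ExpressionProfile(
        element_id=element_id, means=sub.data.mean(axis=0), traces=sub.data.copy()
    )


def randomize_dataset(
    x: GeneMatrix, seed: int | np.random.Generator | np.random.SeedSequence | None = None
) -> GeneMatrix:
    """Shuffle both rows and columns of the value table.

    The multiset of values in every original row and column is preserved
    (rows and columns are permuted as wholes), but the linkage between gene
    ids and their values — and hence to the other tables — is broken.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = x.values
    row_perm = rng.permutation(values.shape[0])
    col_perm = rng.permutation(values.shape[1])
    shuffled = values[np.ix_(row_perm, col_perm)]
    return GeneMatrix(
        pd.DataFrame(shuffled, index=x.gene_ids, columns=x.feature_ids), x.tag
    )


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact for small untied samples, otherwise
    the normal approximation with tie correction."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    pooled = np.concatenate([x, y])
    small = len(x) <= 20 and len(y) <= 20
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def randomization_test(
    run_fn: Callable[[Mapping[str, GeneMatrix]], np.ndarray],
    datasets: Mapping[str, GeneMatrix],
    n_rand: int = 10,
    alpha: float = 0.01,
    seed: int | None = None,
) -> RandomizationResult:
    """Compare observed enrichment p-values against shuffled-table reruns.

    ``run_fn`` maps a dataset bundle to the enrichment p-values of its
    selected elements.  Each replicate independently shuffles every table,
    reruns the pipeline and contributes its p-values; replicates selecting
    nothing contribute an empty set (logged).  The pooled randomized
    p-values are compared with the observed ones by a two-sided
    Mann-Whitney U test.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be at least 1")
    observed = np.asarray(run_fn(datasets), dtype=float)
    master = np.random.SeedSequence(seed)
    randomized: list[np.ndarray] = []
    for rep, child in enumerate(master.spawn(n_rand)):
        rng = np.random.default_rng(child)
        shuffled = {name: randomize_dataset(tab, rng) for name, tab in datasets.items()}
        pvals = np.asarray(run_fn(shuffled), dtype=float)
        if pvals.size == 0:
            logger.info("randomization_test: replicate %d selected zero elements", rep)
        randomized.append(pvals)

    pooled = np.concatenate(randomized) if randomized else np.empty(0)
    if observed.size == 0 or pooled.size == 0:
        logger.warning("randomization_test: empty sample(s); test is inconclusive (p = 1)")
        u, p = float("nan"), 1.0
    else:
        u, p = mann_whitney(observed, pooled)
    return RandomizationResult(
        observed_pvalues=observed,
        randomized_pvalues=randomized,
        u_statistic=u,
        p_value=p,
        alpha=alpha,
        n_rand=n_rand,
    )
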