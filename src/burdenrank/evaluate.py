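"""Replicate-level evaluation of the gene-ranking pipeline.

For a simulated scenario with a known spiked disease gene, three
metrics summarize performance across replicates:

1. the **rank** of the disease gene (sensitivity);
2. **power** — the fraction of replicates in which the disease gene's
   p-value passes the genome-wide significance level (GWSL);
3. the number of **significant autosomal candidate genes** at the GWSL
   (specificity: extra significant genes are false leads).

External tools' per-gene p-value tables can be summarized with the same
metrics for side-by-side comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from burdenrank.scoring import AUTOSOMES, GeneScoreMatrix, _norm_chrom
from burdenrank.simulate import (
    FrequencyPanel,
    SimulatedCohort,
    SimulationSpec,
    simulate_one_replicate,
)
from burdenrank.stats import (
    GWSL_DEFAULT,
    GeneTestResult,
    RunConfig,
    rank_genes,
    significant_genes,
    test_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class ReplicateOutcome:
    replicate: int
    target_rank: int
    target_p: float
    target_log_p: float
    n_significant_autosomal: int


@dataclass
class ScenarioSummary:
    """Aggregate of the three metrics over a scenario's replicates."""

    n_replicates: int
    mean_rank: float
    median_rank: float
    power: float
    mean_significant: float
    alpha: float
    spec_fingerprint: str = ""


def evaluate_replicate(
    case_matrix: GeneScoreMatrix,
    control_matrix: GeneScoreMatrix,
    target_gene: str,
    config: Optional[RunConfig] = None,
    replicate: int = 0,
    gene_chrom: Optional[dict[str, str]] = None,
) -> ReplicateOutcome:
    """Run the composite test end-to-end and extract the three metrics.

    ``gene_chrom`` maps gene ids to chromosome labels for the autosomal
    restriction of the significant-gene count; with no map every tested
    gene is counted (correct for autosome-only matrices).  A target gene
    absent from the results (never scored in either cohort) is assigned
    the worst possible rank G+1 so power arithmetic stays defined.
    """
    config = config or RunConfig()
    results = rank_genes(test_matrix(case_matrix, control_matrix, config), config)
    sig = significant_genes(results, config.alpha)
    if gene_chrom is not None:
        sig = [r for r in sig if _norm_chrom(gene_chrom.get(r.gene_id, "")) in AUTOSOMES]
    target = next((r for r in results if r.gene_id == target_gene), None)
    if target is None:
        logger.warning(
            "target gene %s untested in replicate %d; rank set to G+1",
            target_gene,
            replicate,
        )
        return ReplicateOutcome(
            replicate=replicate,
            target_rank=len(results) + 1,
            target_p=1.0,
            target_log_p=0.0,
            n_significant_autosomal=len(sig),
        )
    return ReplicateOutcome(
        replicate=replicate,
        target_rank=target.rank,
        target_p=target.p,
        target_log_p=target.log_p,
        n_significant_autosomal=len(sig),
    )


def evaluate_simulated_replicate(
    cases: SimulatedCohort,
    controls: SimulatedCohort,
    target_gene: str,
    config: Optional[RunConfig] = None,
    replicate: int = 0,
) -> ReplicateOutcome:
    """Evaluate one simulated cohort pair via the vectorized scoring path."""
    config = config or RunConfig()
    model = config.model
    gene_chrom = cases.panel.gene_chrom()
    return evaluate_replicate(
        cases.gene_score_matrix(model),
        controls.gene_score_matrix(model),
        target_gene,
        config,
        replicate=replicate,
        gene_chrom=gene_chrom,
    )


def summarize_scenario(
    outcomes: Sequence[ReplicateOutcome],
    alpha: float = GWSL_DEFAULT,
    spec_fingerprint: str = "",
) -> ScenarioSummary:
    """Aggregate replicate outcomes; power = fraction with target p < alpha."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("summarize_scenario requires at least one outcome")
    ranks = np.array([o.target_rank for o in outcomes], dtype=float)
    log_alpha = np.log(alpha) if alpha > 0 else -np.inf
    passed = np.array([o.target_log_p < log_alpha for o in outcomes])
    n_sig = np.array([o.n_significant_autosomal for o in outcomes], dtype=float)
    return ScenarioSummary(
        n_replicates=len(outcomes),
        mean_rank=float(ranks.mean()),
        median_rank=float(np.median(ranks)),
        power=float(passed.mean()),
        mean_significant=float(n_sig.mean()),
        alpha=alpha,
        spec_fingerprint=spec_fingerprint,
    )


def run_scenario(
    spec: SimulationSpec,
    panel: FrequencyPanel,
    config: Optional[RunConfig] = None,
) -> tuple[list[ReplicateOutcome], ScenarioSummary]:
    """Simulate, score and test every replicate of a scenario."""
    if spec.spike_gene is None:
        raise ValueError("scenario evaluation requires spec.spike_gene")
    config = config or RunConfig(model=spec.model.value)
    outcomes = []
    for k in range(spec.n_replicates):
        cases, controls = simulate_one_replicate(spec, panel, k)
        outcomes.append(
            evaluate_simulated_replicate(
                cases, controls, spec.spike_gene, config, replicate=k
            )
        )
    fingerprint = f"{spec.model.value}:{spec.n_cases}v{spec.n_controls}:seed{spec.seed}"
    return outcomes, summarize_scenario(outcomes, config.alpha, fingerprint)


def summarize_external_pvalues(
    tables: Iterable[pd.DataFrame],
    target_gene: str,
    alpha: float = GWSL_DEFAULT,
    gene_chrom: Optional[dict[str, str]] = None,
) -> ScenarioSummary:
    """Apply the three metrics to third-party per-gene p-value tables.

    Each table needs columns ``gene`` and ``p``; one table per
    replicate.  Ranking is ascending p with ties broken by gene id.
    """
    outcomes = []
    for k, df in enumerate(tables):
        df = df.sort_values(["p", "gene"], kind="stable").reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        hit = df[df["gene"] == target_gene]
        sig = df[df["p"] < alpha]
        if gene_chrom is not None:
            sig = sig[
                sig["gene"].map(lambda g: _norm_chrom(gene_chrom.get(g, "")) in AUTOSOMES)
            ]
        if hit.empty:
            rank, p = len(df) + 1, 1.0
        else:
            rank, p = int(hit["rank"].iloc[0]), float(hit["p"].iloc[0])
        outcomes.append(
            ReplicateOutcome(
                replicate=k,
                target_rank=rank,
                target_p=p,
                target_log_p=float(np.log(max(p, 1e-300))),
                n_significant_autosomal=len(sig),
            )
        )
    return summarize_scenario(outcomes, alpha, "external")
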