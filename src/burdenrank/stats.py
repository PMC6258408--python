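"""Two-part case-control gene test, Fisher combination and genome-wide ranking.

Gene-score distributions from rare-variant cohorts are zero-inflated:
most individuals score 0 and the few positive scores are themselves
skewed.  Each gene is therefore tested with a composite statistic:

* binomial component ``Z1`` — is the *proportion* of non-zero scores
  higher in cases than controls?  With ``N1`` cases, ``N2`` controls,
  ``r = N2 / N1`` and ``n1``/``n2`` non-zero counts, under the null
  ``n1 ~ Binomial(n1 + n2, 1 / (1 + r))`` and

      Z1 = (n1/(n1+n2) - 1/(1+r)) / sqrt( r / ((1+r)^2 (n1+n2)) )

  with a one-tailed p-value ``p1`` from the standard normal upper tail.

* Wilcoxon component ``Z2`` — among the non-zero scores only, are the
  case values higher?  A standardized one-tailed Wilcoxon rank-sum test
  with tied-rank variance adjustment and continuity correction gives
  ``p2``.  Restricting to non-zero scores keeps the two components
  nearly independent: the proportion signal lives entirely in Z1.

* Fisher's method combines them: ``X = -2 (ln p1 + ln p2)`` is referred
  to a chi-square distribution with 4 degrees of freedom; the gene's
  p-value is ``P(chi2_4 > X)``.  All combination math runs in log space
  so extremely significant genes keep a finite ``log_p`` for ranking
  even when ``p`` underflows to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

#: genome-wide significance level: 0.05 Bonferroni-corrected over the
#: ~18,500 autosomal protein-coding genes, rounded to two significant figures
GWSL_DEFAULT = 2.7e-6

#: floor applied to p1/p2 before taking logs
P_FLOOR = 1e-300


@dataclass(frozen=True)
class CohortCounts:
    """Cohort sizes: ``N1`` cases, ``N2`` controls, ``r = N2 / N1``."""

    N1: int
    N2: int

    def __post_init__(self):
        if self.N1 < 1 or self.N2 < 1:
            raise ValueError("both cohorts must contain at least one individual")

    @property
    def r(self) -> float:
        return self.N2 / self.N1


@dataclass
class TwoPartComponents:
    n1: int
    n2: int
    Z1: float
    p1: float
    p2: float
    testable: bool = True


@dataclass
class GeneTestResult:
    gene_id: str
    components: TwoPartComponents
    chi2_stat: float
    p: float
    log_p: float  # natural log, finite even when p underflows
    rank: Optional[int] = None

    @property
    def log10_p(self) -> float:
        return self.log_p / math.log(10.0)


@dataclass
class RunConfig:
    """Test configuration: inheritance model, significance cutoff, flags."""

    model: str = "AR"
    alpha: float = GWSL_DEFAULT
    exact_binomial: bool = False

    def __post_init__(self):
        if not (0.0 <= self.alpha < 1.0) and self.alpha != 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")


def binomial_component(
    n1: int, n2: int, counts: CohortCounts, exact: bool = False
) -> tuple[float, float]:
    """Standardized proportion statistic Z1 and its one-tailed p-value.

    ``exact=True`` replaces the normal upper-tail area with the exact
    binomial tail ``P(X >= n1)``, ``X ~ Binomial(n1+n2, 1/(1+r))`` —
    useful when ``n1 + n2`` is small and the normal approximation is
    coarse.  Z1 itself is always the standardized statistic.
    """
    n = n1 + n2
    if n < 1:
        raise ValueError("binomial component requires n1 + n2 >= 1")
    r = counts.r
    p0 = 1.0 / (1.0 + r)
    z1 = (n1 / n - p0) / math.sqrt(r / ((1.0 + r) * (1.0 + r) * n))
    if exact:
        p1 = float(sps.binom.sf(n1 - 1, n, p0))
    else:
        p1 = float(sps.norm.sf(z1))
    return z1, p1


def wilcoxon_component(
    case_nonzero: Sequence[float], control_nonzero: Sequence[float]
) -> float:
    """One-tailed (cases greater) rank-sum p from the normal approximation.

    Inputs are the strictly positive gene scores of each cohort.  The
    statistic is the case rank sum, standardized with the tied-rank
    variance adjustment and a 0.5 continuity correction.  If either side
    is empty there is nothing to compare and ``p2 = 1``.
    """
    x = np.asarray(case_nonzero, dtype=float)
    y = np.asarray(control_nonzero, dtype=float)
    m, k = len(x), len(y)
    if m == 0 or k == 0:
        return 1.0
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w = ranks[:m].sum()
    n = m + k
    mu = m * (n + 1) / 2.0
    # tied-rank variance adjustment
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = m * k / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return 0.5
    z = (w - mu - 0.5) / math.sqrt(var)
    return float(sps.norm.sf(z))


def fisher_combine(p1: float, p2: float) -> tuple[float, float, float]:
    """Fisher's method over two one-tailed p-values.

    Returns ``(chi2_stat, p, log_p)`` where ``chi2_stat = -2 (ln p1 +
    ln p2)`` and ``p`` is the survival function of the chi-square
    distribution with 4 degrees of freedom at ``chi2_stat`` (closed
    form ``exp(-x/2) * (1 + x/2)``).  ``log_p`` is the natural-log
    survival probability, computed in log space so it stays finite when
    ``p`` underflows.
    """
    if not (0.0 < p1 <= 1.0) or not (0.0 < p2 <= 1.0):
        raise ValueError(f"p-values must lie in (0, 1], got {p1}, {p2}")
    chi2_stat = -2.0 * (math.log(p1) + math.log(p2))
    # chi-square df=4 survival in closed form, exact in log space:
    # S(x) = exp(-x/2) * (1 + x/2)
    log_p = -chi2_stat / 2.0 + math.log1p(chi2_stat / 2.0)
    p = math.exp(log_p) if log_p > -745 else 0.0
    return chi2_stat, p, log_p


def test_gene(
    gene_id: str,
    case_scores: Sequence[float],
    control_scores: Sequence[float],
    counts: Optional[CohortCounts] = None,
    config: Optional[RunConfig] = None,
) -> GeneTestResult:
    """Composite two-part test of one gene's case vs control scores.

    ``case_scores`` / ``control_scores`` are the full per-individual
    gene-score vectors (length N1 and N2, zeros included).  A gene with
    no non-zero score in either cohort is untestable and reported with
    ``p = 1``.
    """
    config = config or RunConfig()
    case = np.asarray(case_scores, dtype=float)
    control = np.asarray(control_scores, dtype=float)
    if np.any(case < 0) or np.any(control < 0):
        raise ValueError("gene scores must be non-negative")
    if counts is None:
        counts = CohortCounts(N1=len(case), N2=len(control))
    if len(case) != counts.N1 or len(control) != counts.N2:
        raise ValueError(
            f"score vector lengths ({len(case)}, {len(control)}) do not match "
            f"cohort sizes ({counts.N1}, {counts.N2})"
        )
    case_nz = case[case > 0]
    control_nz = control[control > 0]
    n1, n2 = len(case_nz), len(control_nz)
    if n1 + n2 == 0:
        comp = TwoPartComponents(n1=0, n2=0, Z1=0.0, p1=1.0, p2=1.0, testable=False)
        return GeneTestResult(gene_id, comp, chi2_stat=0.0, p=1.0, log_p=0.0)
    z1, p1 = binomial_component(n1, n2, counts, exact=config.exact_binomial)
    p2 = wilcoxon_component(case_nz, control_nz)
    p1 = max(p1, P_FLOOR)
    p2 = max(p2, P_FLOOR)
    chi2_stat, p, log_p = fisher_combine(p1, p2)
    comp = TwoPartComponents(n1=n1, n2=n2, Z1=z1, p1=p1, p2=p2)
    return GeneTestResult(gene_id, comp, chi2_stat=chi2_stat, p=p, log_p=log_p)


def test_matrix(case_matrix, control_matrix, config: Optional[RunConfig] = None):
    """Test every gene seen in either cohort's gene-score matrix.

    Accepts two :class:`~burdenrank.scoring.GeneScoreMatrix` objects
    (genes absent from one cohort contribute all-zero score vectors) and
    returns an unranked list of :class:`GeneTestResult`.
    """
    config = config or RunConfig()
    counts = CohortCounts(
        N1=len(case_matrix.individuals), N2=len(control_matrix.individuals)
    )
    genes = sorted(set(case_matrix.genes) | set(control_matrix.genes))
    return [
        test_gene(
            g,
            case_matrix.gene_scores(g),
            control_matrix.gene_scores(g),
            counts,
            config,
        )
        for g in genes
    ]


def rank_genes(
    results: Sequence[GeneTestResult], config: Optional[RunConfig] = None
) -> list[GeneTestResult]:
    """Sort genes by significance and assign ranks 1..G.

    Ordering: ascending ``log_p`` (robust to p-value underflow), ties
    broken by descending chi-square statistic, then descending ``n1``,
    then gene id — fully deterministic regardless of input order.
    """
    ordered = sorted(
        results,
        key=lambda res: (
            res.log_p,
            -res.chi2_stat,
            -res.components.n1,
            res.gene_id,
        ),
    )
    out = []
    for i, res in enumerate(ordered, start=1):
        out.append(
            GeneTestResult(
                gene_id=res.gene_id,
                components=res.components,
                chi2_stat=res.chi2_stat,
                p=res.p,
                log_p=res.log_p,
                rank=i,
            )
        )
    return out


def significant_genes(
    ranked: Sequence[GeneTestResult], alpha: float = GWSL_DEFAULT
) -> list[GeneTestResult]:
    """Genes with ``p < alpha``, preserving rank order.

    The comparison uses ``log_p`` so genes whose p-value underflowed to
    0 are always retained for any positive alpha.
    """
    if alpha <= 0:
        return []
    log_alpha = math.log(alpha)
    return [res for res in ranked if res.log_p < log_alpha]
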