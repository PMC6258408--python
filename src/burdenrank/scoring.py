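"""Per-individual gene scores under Mendelian inheritance models.

For each (gene, individual) pair the observed rare-variant scores are
reduced to a single gene score measuring deleterious mutation load:

* recessive models (AR, XR): the sum of the two highest normalized
  variant scores, or 0 when fewer than two variants remain after cis
  collapsing.  Bounded by [0, 2]; a biallelic hit with two perfect
  variants scores exactly 2.
* dominant models (AD, XD): the single highest normalized score, or 0
  with no variants.  Bounded by [0, 1].

A homozygous variant is represented as two call records with the same
locus and score, so it contributes ``2 s`` under recessive models.
Variants annotated as lying on the same chromosome copy (``phase_group``)
are collapsed to the highest-scoring member first: a cis pair carries
only one functional haplotype and must not satisfy the biallelic
requirement on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOMES = frozenset(str(i) for i in range(1, 23))
X_CHROMS = frozenset({"X"})
_KNOWN_CHROMS = AUTOSOMES | X_CHROMS | {"Y"}


class InheritanceModel(str, Enum):
    """Mendelian inheritance model selecting the gene-scoring rule.

    AR/AD operate on autosomal genes (chr1-22); XR/XD on X-linked genes.
    Y, MT and unplaced contigs are excluded from every model.
    """

    AR = "AR"
    AD = "AD"
    XR = "XR"
    XD = "XD"

    @property
    def recessive(self) -> bool:
        return self in (InheritanceModel.AR, InheritanceModel.XR)

    @property
    def x_linked(self) -> bool:
        return self in (InheritanceModel.XR, InheritanceModel.XD)

    @property
    def chromosomes(self) -> frozenset:
        return X_CHROMS if self.x_linked else AUTOSOMES

    @property
    def max_score(self) -> float:
        return 2.0 if self.recessive else 1.0


def _norm_chrom(chrom: str) -> str:
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class VariantCall:
    """One observed variant in one individual.

    ``s`` is the normalized deleteriousness in [0, 1).  ``alt_coverage``
    and ``ref_coverage`` are optional read counts used by the cis
    preprocessor; ``phase_group`` marks variants asserted to lie on the
    same chromosome copy.
    """

    individual_id: str
    gene_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    s: float
    alt_coverage: Optional[int] = None
    ref_coverage: Optional[int] = None
    phase_group: Optional[str] = None

    def __post_init__(self):
        if not (0.0 <= self.s <= 1.0):
            raise ValueError(f"normalized score must lie in [0, 1], got {self.s}")
        for cov in (self.alt_coverage, self.ref_coverage):
            if cov is not None and (int(cov) != cov or cov < 0):
                raise ValueError(f"coverages must be non-negative integers, got {cov}")

    @property
    def key(self) -> tuple:
        return (_norm_chrom(self.chrom), self.pos, self.ref, self.alt)


def collapse_cis(calls: Sequence[VariantCall]) -> list[VariantCall]:
    """Keep only the highest-scoring call within each phase group.

    Calls sharing a ``phase_group`` label are asserted to lie in cis;
    only the member with the highest score survives (ties broken by the
    smaller (chrom, pos, ref, alt) tuple, deterministically).  Calls
    without a phase group pass through unchanged.  Input order of the
    survivors is preserved.
    """
    best: dict[str, VariantCall] = {}
    for call in calls:
        if call.phase_group is None:
            continue
        cur = best.get(call.phase_group)
        if cur is None or (-call.s, call.key) < (-cur.s, cur.key):
            best[call.phase_group] = call
    out = []
    for call in calls:
        if call.phase_group is None or best[call.phase_group] is call:
            out.append(call)
    return out


def gene_score_recessive(scores: Iterable[float]) -> float:
    """Sum of the two highest scores; 0 when fewer than two variants.

    The biallelic requirement of recessive inheritance: one deleterious
    allele is not sufficient, so singleton (and empty) lists score 0.
    """
    top = sorted(scores, reverse=True)[:2]
    if len(top) < 2:
        return 0.0
    return float(top[0] + top[1])


def gene_score_dominant(scores: Iterable[float]) -> float:
    """Highest score, or 0 for an empty list."""
    scores = list(scores)
    if not scores:
        return 0.0
    return float(max(scores))


@dataclass
class GeneScoreMatrix:
    """Gene x individual matrix of per-individual gene scores.

    Stored dense as a DataFrame (genes as rows, individuals as columns);
    absent (gene, individual) pairs are exactly 0.  ``cohort`` is a free
    label ("case" / "control").
    """

    data: pd.DataFrame
    model: InheritanceModel
    cohort: str = ""

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.data.columns)

    def score(self, gene: str, individual: str) -> float:
        if gene not in self.data.index or individual not in self.data.columns:
            return 0.0
        return float(self.data.at[gene, individual])

    def gene_scores(self, gene: str) -> np.ndarray:
        """All individuals' scores for one gene (zeros if gene unseen)."""
        if gene not in self.data.index:
            return np.zeros(len(self.data.columns))
        return self.data.loc[gene].to_numpy(dtype=float)


def build_gene_score_matrix(
    calls: Iterable[VariantCall],
    model: InheritanceModel,
    individuals: Optional[Sequence[str]] = None,
    cohort: str = "",
    hemizygous_double: bool = False,
) -> GeneScoreMatrix:
    """Reduce a cohort's variant calls to one score per gene per individual.

    For every (gene, individual): collapse phase-grouped cis variants,
    then apply the model's scoring rule.  Genes on chromosomes outside
    the model's scope are excluded (AR/AD keep autosomes 1-22, XR/XD
    keep X); calls on other contigs are skipped with a warning.

    ``individuals`` fixes the column set (individuals with no calls get
    all-zero columns); by default columns are the individuals observed
    in ``calls``.  ``hemizygous_double`` lets a single X variant count
    twice under XR, for hemizygous male exomes whose variant lists carry
    one record per X locus (off by default: two records required).
    """
    model = InheritanceModel(model)
    wanted = model.chromosomes
    grouped: dict[tuple[str, str], list[VariantCall]] = {}
    seen_individuals: list[str] = []
    seen_set = set()
    n_skipped = 0
    for call in calls:
        if call.individual_id not in seen_set:
            seen_set.add(call.individual_id)
            seen_individuals.append(call.individual_id)
        chrom = _norm_chrom(call.chrom)
        if chrom not in wanted:
            if chrom not in _KNOWN_CHROMS:
                n_skipped += 1
            continue
        grouped.setdefault((call.gene_id, call.individual_id), []).append(call)
    if n_skipped:
        logger.warning("skipped %d calls on unrecognized contigs", n_skipped)

    if individuals is None:
        individuals = seen_individuals
    individuals = list(individuals)
    col_index = {ind: j for j, ind in enumerate(individuals)}

    genes = sorted({g for g, _ in grouped})
    row_index = {g: i for i, g in enumerate(genes)}
    mat = np.zeros((len(genes), len(individuals)))
    for (gene, ind), gcalls in grouped.items():
        if ind not in col_index:
            continue
        scores = [c.s for c in collapse_cis(gcalls)]
        if model.recessive:
            if hemizygous_double and len(scores) == 1:
                scores = scores * 2
            value = gene_score_recessive(scores)
        else:
            value = gene_score_dominant(scores)
        mat[row_index[gene], col_index[ind]] = value
    df = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=individuals)
    return GeneScoreMatrix(data=df, model=model, cohort=cohort)


def scores_from_arrays(
    gene_idx: np.ndarray,
    ind_idx: np.ndarray,
    s: np.ndarray,
    n_genes: int,
    n_individuals: int,
    recessive: bool,
) -> np.ndarray:
    """Vectorized gene-score matrix from parallel call arrays.

    Fast path used by the simulator: ``gene_idx``/``ind_idx`` are integer
    codes, ``s`` the normalized scores.  No cis collapsing is applied
    (simulated background variants are unphased, in trans by
    construction).  Returns a dense (n_genes, n_individuals) array.
    """
    mat = np.zeros((n_genes, n_individuals))
    if len(s) == 0:
        return mat
    flat = gene_idx.astype(np.int64) * n_individuals + ind_idx.astype(np.int64)
    order = np.lexsort((-s, flat))
    flat = flat[order]
    s_sorted = s[order]
    # first element of each (gene, individual) run is its maximum score
    starts = np.ones(len(flat), dtype=bool)
    starts[1:] = flat[1:] != flat[:-1]
    top1_pos = np.flatnonzero(starts)
    top1 = s_sorted[top1_pos]
    cells = flat[top1_pos]
    if recessive:
        run_len = np.diff(np.append(top1_pos, len(flat)))
        has_second = run_len >= 2
        value = np.zeros(len(cells))
        value[has_second] = top1[has_second] + s_sorted[top1_pos[has_second] + 1]
    else:
        value = top1
    mat.ravel()[cells] = value
    return mat
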