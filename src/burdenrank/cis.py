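"""Collapse likely-cis variant pairs before gene scoring.

Recessive scoring requires two hits on different chromosome copies, so
unrecognized cis pairs inflate gene scores.  Without phasing, two
signals identify likely cis relationships:

* **read-coverage concordance** — two variants within 100 bp are covered
  by largely the same reads when in cis, so their alt/ref coverage
  ratios agree.  A two-sided Fisher's exact test on the 2x2 coverage
  table calls the pair cis when ``p >= 0.4`` (concordant ratios) and
  trans when ``p < 0.4``; pairs farther than 100 bp apart or lacking
  coverage are left untested.

* **cohort co-occurrence** — two or more identical rare variants seen
  together in two or more unrelated case individuals are almost
  certainly in cis, because independent co-occurrence of variants this
  rare is vanishingly unlikely.  (Diseases genuinely caused by a variant
  combination defeat this heuristic; disable it for allele-complex
  scenarios.)

In both cases only the highest-scoring member of a cis set is kept.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Sequence

from scipy import stats as sps

from burdenrank.scoring import VariantCall

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100
DEFAULT_CIS_P = 0.4


def coverage_cis_test(
    a: VariantCall,
    b: VariantCall,
    window: int = DEFAULT_WINDOW,
    cis_p: float = DEFAULT_CIS_P,
) -> str:
    """Classify a variant pair of one individual as cis / trans / untested.

    Returns ``"untested"`` when the variants are more than ``window`` bp
    apart, on different chromosomes, or lack coverage counts.  Otherwise
    a two-sided Fisher's exact test compares the alt:ref coverage ratios;
    ``p >= cis_p`` means the ratios are concordant (cis).
    """
    if a.individual_id != b.individual_id:
        raise ValueError("coverage test applies to one individual's variant pair")
    covs = (a.alt_coverage, a.ref_coverage, b.alt_coverage, b.ref_coverage)
    if any(c is None for c in covs):
        return "untested"
    if any(c < 0 for c in covs):
        raise ValueError("coverage counts must be non-negative")
    if a.chrom != b.chrom or abs(a.pos - b.pos) > window:
        return "untested"
    table = [[a.alt_coverage, a.ref_coverage], [b.alt_coverage, b.ref_coverage]]
    if (a.alt_coverage + a.ref_coverage) == 0 or (b.alt_coverage + b.ref_coverage) == 0:
        return "untested"
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return "cis" if p >= cis_p else "trans"


def apply_coverage_collapse(
    calls: Sequence[VariantCall],
    window: int = DEFAULT_WINDOW,
    cis_p: float = DEFAULT_CIS_P,
) -> list[VariantCall]:
    """Collapse coverage-concordant nearby pairs to their top-scoring member.

    All pairs within ``window`` bp are tested left-to-right; cis
    relations are merged transitively into groups (union-find) and each
    group keeps only its highest-scoring call (ties: smallest locus
    tuple).  Calls judged trans, untested, or isolated pass through.
    Output order follows the input.
    """
    calls = list(calls)
    parent = list(range(len(calls)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(len(calls)), key=lambda i: (calls[i].chrom, calls[i].pos))
    for ii, jj in itertools.combinations(order, 2):
        a, b = calls[ii], calls[jj]
        if a.chrom != b.chrom or abs(a.pos - b.pos) > window:
            continue
        if coverage_cis_test(a, b, window=window, cis_p=cis_p) == "cis":
            ri, rj = find(ii), find(jj)
            if ri != rj:
                parent[rj] = ri

    best: dict[int, int] = {}
    for i, call in enumerate(calls):
        root = find(i)
        j = best.get(root)
        if j is None or (-call.s, call.key) < (-calls[j].s, calls[j].key):
            best[root] = i
    keep = set(best.values())
    return [c for i, c in enumerate(calls) if i in keep]


def cooccurrence_filter(calls: Iterable[VariantCall]) -> list[VariantCall]:
    """Drop lower-scoring members of variant sets shared by >= 2 individuals.

    For each gene, any set of >= 2 identical variants (same chrom, pos,
    ref, alt) observed concurrently in >= 2 distinct individuals is
    treated as a cis haplotype: in every carrier of the full set, only
    the highest-scoring member variant is kept.  Individuals carrying
    just part of the set are untouched.  Output is independent of input
    order.
    """
    calls = list(calls)
    # gene -> variant key -> set of individuals carrying it
    carriers: dict[str, dict[tuple, set]] = {}
    score_of: dict[tuple, float] = {}
    for c in calls:
        carriers.setdefault(c.gene_id, {}).setdefault(c.key, set()).add(
            c.individual_id
        )
        score_of[(c.gene_id, c.key)] = c.s

    # for each gene, find maximal groups of variants co-occurring in >= 2 people
    drop: set[tuple] = set()  # (gene, individual, variant key)
    for gene, varmap in carriers.items():
        keys = sorted(varmap)
        for ka, kb in itertools.combinations(keys, 2):
            shared = varmap[ka] & varmap[kb]
            if len(shared) < 2:
                continue
            sa = score_of[(gene, ka)]
            sb = score_of[(gene, kb)]
            loser = kb if (-sa, ka) < (-sb, kb) else ka
            for ind in shared:
                drop.add((gene, ind, loser))
    if drop:
        logger.info("co-occurrence filter removed %d gene/individual variants", len(drop))
    return [
        c for c in calls if (c.gene_id, c.individual_id, c.key) not in drop
    ]
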