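"""Whole-exome cohort simulation from an allele-frequency panel.

The simulator emulates rare-variant WES cohorts the way large reference
panels (ExAC-style) describe them: a catalog of sites, each with one or
more alternate alleles, per-population allele frequencies and a
PHRED-scaled deleteriousness score.  For every simulated individual,
each site is an independent multinomial draw over {each alt with its
frequency in the individual's population; reference with the remaining
mass} — e.g. with alt frequencies 0.2% (A>T) and 0.5% (A>G), an
individual carries A>T with probability 0.002, A>G with 0.005, and no
variant with 0.993.  At most one alt is emitted per site per individual,
and frequencies are applied per individual (not per haplotype), so
background homozygotes are not generated.

Case cohorts receive a pathogenic **spike-in**: a chosen fraction of
cases is selected uniformly without replacement and each selected case
receives two draws (with replacement — equal draws model a homozygote)
from a pathogenic-variant list under recessive models, or one draw
under dominant models.  Controls are never spiked.

A synthetic panel generator stands in for the real reference download:
it fabricates a rare-variant site catalog (Poisson variant counts per
gene, Beta-distributed frequencies truncated below a rarity cutoff, a
benign/deleterious score mixture) with deterministic content per seed.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from burdenrank.scores import normalize_score
from burdenrank.scoring import (
    GeneScoreMatrix,
    InheritanceModel,
    VariantCall,
    scores_from_arrays,
)

logger = logging.getLogger(__name__)

#: rarity ceiling for spike-in variants (maximum population frequency)
SPIKE_MAF_LIMIT = 0.005

_PANEL_FIXED_COLS = ("chrom", "pos", "ref", "alt", "gene", "score")


class FrequencyPanel:
    """Site/allele/per-population frequency + score catalog.

    One row per alternate allele with columns ``chrom, pos, ref, alt,
    gene, score`` (PHRED scale) plus one frequency column per population
    label.  Alleles sharing (chrom, pos, ref) form one site; their
    frequencies within any population must sum to at most 1.
    """

    def __init__(self, df: pd.DataFrame, populations: Sequence[str]):
        populations = list(populations)
        missing = [c for c in (*_PANEL_FIXED_COLS, *populations) if c not in df.columns]
        if missing:
            raise ValueError(f"panel is missing columns: {missing}")
        df = df.reset_index(drop=True).copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(int)
        freqs = df[populations].to_numpy(dtype=float)
        if np.any(freqs < 0) or np.any(freqs > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if np.any(df["score"].to_numpy(dtype=float) < 0):
            raise ValueError("panel scores must be >= 0 (PHRED scale)")
        site_keys = pd.MultiIndex.from_frame(df[["chrom", "pos", "ref"]])
        site_codes, _ = pd.factorize(site_keys, sort=True)
        for j, pop in enumerate(populations):
            sums = np.bincount(site_codes, weights=freqs[:, j])
            if np.any(sums > 1.0 + 1e-12):
                raise ValueError(
                    f"alt frequencies at one site exceed 1 in population {pop!r}"
                )
        self.df = df
        self.populations = populations
        self._site_codes = site_codes
        self._n_sites = int(site_codes.max()) + 1 if len(df) else 0
        self._freqs = freqs
        # cumulative interval [lo, hi) of each allele within its site,
        # per population: one uniform per site selects at most one alt
        self._lo = np.empty_like(freqs)
        self._hi = np.empty_like(freqs)
        for j in range(freqs.shape[1]):
            csum = np.zeros(self._n_sites)
            order = np.argsort(site_codes, kind="stable")
            lo = np.empty(len(df))
            for i in order:
                s = site_codes[i]
                lo[i] = csum[s]
                csum[s] += freqs[i, j]
            self._lo[:, j] = lo
            self._hi[:, j] = lo + freqs[:, j]
        genes = df["gene"].astype(str)
        self.gene_ids = sorted(genes.unique())
        self._gene_codes = (
            pd.Categorical(genes, categories=self.gene_ids).codes.astype(np.int64)
        )
        self._scores_s = normalize_score(df["score"].to_numpy(dtype=float))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_sites(self) -> int:
        return self._n_sites

    def max_freq(self) -> np.ndarray:
        """Per-allele maximum frequency across populations."""
        if not len(self.df):
            return np.zeros(0)
        return self._freqs.max(axis=1)

    def population_index(self, label: str) -> int:
        try:
            return self.populations.index(label)
        except ValueError:
            raise KeyError(f"unknown population {label!r}") from None

    def gene_chrom(self) -> dict[str, str]:
        return dict(zip(self.df["gene"].astype(str), self.df["chrom"]))

    def to_tsv(self, path: Union[str, Path]) -> None:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: Union[str, Path], populations: Optional[Sequence[str]] = None
    ) -> "FrequencyPanel":
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
        if populations is None:
            populations = [c for c in df.columns if c not in _PANEL_FIXED_COLS]
        return cls(df, populations)


def filter_panel(panel: FrequencyPanel, maf_cutoff: float) -> FrequencyPanel:
    """Retain alleles whose maximum population frequency is <= cutoff.

    Mirrors rare-disease variant filtering: common alleles are almost
    certainly benign and are removed before both simulation and testing.
    """
    if not (0.0 < maf_cutoff <= 1.0):
        raise ValueError(f"maf_cutoff must lie in (0, 1], got {maf_cutoff}")
    keep = panel.max_freq() <= maf_cutoff
    return FrequencyPanel(panel.df.loc[keep], panel.populations)


@dataclass(frozen=True)
class PathogenicVariant:
    """A spike-in allele: locus, gene, and PHRED-scaled score."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    score: float

    @property
    def s(self) -> float:
        return normalize_score(self.score)


@dataclass
class SimulationSpec:
    """Full description of one simulation scenario.

    Defaults follow rare-Mendelian practice: the panel is pre-filtered
    at maximum population frequency 0.5% for recessive models and 0.01%
    for dominant models, frequencies come from the panel-wide
    ``adjusted`` population, and 30 replicate cohort pairs are drawn.
    """

    n_cases: int
    n_controls: int
    model: Union[str, InheritanceModel] = InheritanceModel.AR
    maf_cutoff: Optional[float] = None  # None -> 0.005 (recessive) / 0.0001 (dominant)
    frequency_field: str = "adjusted"
    case_admixture: Optional[dict[str, float]] = None
    control_admixture: Optional[dict[str, float]] = None
    sex_ratio: float = 0.5  # fraction of males, recorded for X-linked runs
    spike_gene: Optional[str] = None
    spike_proportion: float = 0.0
    pathogenic_variants: Sequence[PathogenicVariant] = ()
    spike_mode: str = "random"  # or "fixed-pair"
    n_replicates: int = 30
    seed: int = 0

    def __post_init__(self):
        self.model = InheritanceModel(self.model)
        if not (0.0 <= self.spike_proportion <= 1.0):
            raise ValueError("spike_proportion must lie in [0, 1]")
        if self.spike_mode not in ("random", "fixed-pair"):
            raise ValueError(f"unknown spike_mode {self.spike_mode!r}")
        if self.maf_cutoff is None:
            self.maf_cutoff = 0.005 if self.model.recessive else 0.0001
        for adm in (self.case_admixture, self.control_admixture):
            if adm is not None and abs(sum(adm.values()) - 1.0) > 1e-9:
                raise ValueError("admixture weights must sum to 1")

    def admixture_for(self, cohort: str) -> dict[str, float]:
        adm = self.case_admixture if cohort == "case" else self.control_admixture
        return adm if adm is not None else {self.frequency_field: 1.0}


@dataclass
class SimulatedCohort:
    """One simulated cohort: background draws plus any spiked calls.

    Background variants are stored as parallel index arrays into the
    panel; spiked calls as explicit records.  ``spiked_individuals`` is
    the subset of individuals that received pathogenic alleles.
    """

    panel: FrequencyPanel
    individual_ids: list[str]
    cohort: str
    ind_idx: np.ndarray  # background call -> individual position
    allele_idx: np.ndarray  # background call -> panel row
    populations_drawn: list[str]
    sexes: list[str]
    spiked_calls: list[tuple[int, PathogenicVariant]] = field(default_factory=list)
    spiked_individuals: list[str] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def n_calls(self) -> int:
        return len(self.allele_idx) + len(self.spiked_calls)

    def to_calls(self) -> list[VariantCall]:
        """Materialize every call as a :class:`VariantCall` record."""
        df = self.panel.df
        chroms = df["chrom"].to_numpy()
        poss = df["pos"].to_numpy()
        refs = df["ref"].to_numpy()
        alts = df["alt"].to_numpy()
        genes = df["gene"].to_numpy()
        out = []
        for i, a in zip(self.ind_idx, self.allele_idx):
            out.append(
                VariantCall(
                    individual_id=self.individual_ids[i],
                    gene_id=str(genes[a]),
                    chrom=str(chroms[a]),
                    pos=int(poss[a]),
                    ref=str(refs[a]),
                    alt=str(alts[a]),
                    s=float(self.panel._scores_s[a]),
                )
            )
        for i, pv in self.spiked_calls:
            out.append(
                VariantCall(
                    individual_id=self.individual_ids[i],
                    gene_id=pv.gene,
                    chrom=pv.chrom,
                    pos=pv.pos,
                    ref=pv.ref,
                    alt=pv.alt,
                    s=pv.s,
                )
            )
        return out

    def gene_score_matrix(self, model: Union[str, InheritanceModel]) -> GeneScoreMatrix:
        """Vectorized per-gene, per-individual scoring of the cohort.

        Simulated background variants occupy distinct sites and carry no
        phase information (all in trans by construction), so no cis
        collapsing applies; spiked homozygotes appear as two copies of
        one variant and score ``2 s`` under recessive models.
        """
        model = InheritanceModel(model)
        gene_ids = list(self.panel.gene_ids)
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        for _, pv in self.spiked_calls:
            if pv.gene not in gene_pos:
                gene_pos[pv.gene] = len(gene_ids)
                gene_ids.append(pv.gene)
        g_idx = [self.panel._gene_codes[self.allele_idx]]
        i_idx = [self.ind_idx]
        s_val = [self.panel._scores_s[self.allele_idx]]
        if self.spiked_calls:
            g_idx.append(
                np.array([gene_pos[pv.gene] for _, pv in self.spiked_calls])
            )
            i_idx.append(np.array([i for i, _ in self.spiked_calls]))
            s_val.append(np.array([pv.s for _, pv in self.spiked_calls]))
        mat = scores_from_arrays(
            np.concatenate(g_idx),
            np.concatenate(i_idx),
            np.concatenate(s_val),
            n_genes=len(gene_ids),
            n_individuals=self.n_individuals,
            recessive=model.recessive,
        )
        # restrict to the model's chromosomes
        gene_chrom = self.panel.gene_chrom()
        for _, pv in self.spiked_calls:
            gene_chrom.setdefault(pv.gene, pv.chrom)
        wanted = model.chromosomes
        keep = np.array([gene_chrom.get(g) in wanted for g in gene_ids])
        df = pd.DataFrame(
            mat[keep],
            index=pd.Index([g for g, k in zip(gene_ids, keep) if k], name="gene"),
            columns=self.individual_ids,
        )
        return GeneScoreMatrix(data=df, model=model, cohort=self.cohort)


def simulate_individual(
    panel: FrequencyPanel,
    population_weights: dict[str, float],
    rng: np.random.Generator,
) -> list[VariantCall]:
    """Draw one individual's variant list (convenience single-sample path).

    The individual's population is drawn from ``population_weights``;
    each site then yields at most one alternate allele via the
    multinomial rule described in the module docstring.
    """
    cohort = simulate_cohort(panel, 1, population_weights, rng, cohort="single")
    return cohort.to_calls()


def simulate_cohort(
    panel: FrequencyPanel,
    n_individuals: int,
    population_weights: dict[str, float],
    rng: np.random.Generator,
    cohort: str = "",
    id_prefix: Optional[str] = None,
    sex_ratio: float = 0.5,
    block_size: int = 256,
) -> SimulatedCohort:
    """Vectorized background simulation of a whole cohort.

    One uniform deviate per (individual, site) is compared against the
    cumulative alt-frequency intervals of the individual's population,
    which realizes the per-site multinomial draw exactly.  Individuals
    are processed population-by-population in blocks to bound memory.
    """
    labels = list(population_weights)
    weights = np.array([population_weights[p] for p in labels], dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("population weights must be non-negative and sum to 1")
    pop_cols = [panel.population_index(p) for p in labels]
    id_prefix = id_prefix or (cohort or "ind")
    ids = [f"{id_prefix}_{i:05d}" for i in range(n_individuals)]
    pop_draw = rng.choice(len(labels), size=n_individuals, p=weights)
    sexes = np.where(rng.random(n_individuals) < sex_ratio, "M", "F").tolist()

    site_of_allele = panel._site_codes
    n_sites = panel.n_sites
    ind_parts, allele_parts = [], []
    for li, col in enumerate(pop_cols):
        members = np.flatnonzero(pop_draw == li)
        lo = panel._lo[:, col]
        hi = panel._hi[:, col]
        for start in range(0, len(members), block_size):
            block = members[start : start + block_size]
            u = rng.random((len(block), n_sites))
            v = u[:, site_of_allele]
            rows, cols = np.nonzero((v >= lo) & (v < hi))
            ind_parts.append(block[rows])
            allele_parts.append(cols)
    ind_idx = (
        np.concatenate(ind_parts) if ind_parts else np.zeros(0, dtype=np.int64)
    )
    allele_idx = (
        np.concatenate(allele_parts) if allele_parts else np.zeros(0, dtype=np.int64)
    )
    return SimulatedCohort(
        panel=panel,
        individual_ids=ids,
        cohort=cohort,
        ind_idx=ind_idx.astype(np.int64),
        allele_idx=allele_idx.astype(np.int64),
        populations_drawn=[labels[i] for i in pop_draw],
        sexes=sexes,
    )


def validate_pathogenic_variants(
    variants: Sequence[PathogenicVariant], panel: FrequencyPanel
) -> None:
    """Reject spike-in alleles that are common in the reference panel.

    Pathogenic Mendelian alleles are rare; a spike-in variant that is
    present in the panel with maximum population frequency above 0.5%
    indicates a mis-specified scenario.
    """
    if not len(panel.df):
        return
    idx = {
        (c, p, r, a): i
        for i, (c, p, r, a) in enumerate(
            zip(panel.df["chrom"], panel.df["pos"], panel.df["ref"], panel.df["alt"])
        )
    }
    mf = panel.max_freq()
    for pv in variants:
        row = idx.get((pv.chrom, pv.pos, pv.ref, pv.alt))
        if row is not None and mf[row] > SPIKE_MAF_LIMIT:
            raise ValueError(
                f"spike-in variant {pv.chrom}:{pv.pos} {pv.ref}>{pv.alt} has "
                f"panel frequency {mf[row]:.4f} > {SPIKE_MAF_LIMIT}"
            )


def spike_pathogenic(
    cohort: SimulatedCohort,
    spec: SimulationSpec,
    rng: np.random.Generator,
) -> SimulatedCohort:
    """Insert pathogenic alleles into a fraction of case individuals.

    ``round(spike_proportion * n_cases)`` individuals are selected
    uniformly without replacement.  Recessive models give each selected
    case two draws with replacement from the pathogenic list (equal
    draws = homozygote, recorded as two copies); dominant models give
    one.  ``fixed-pair`` mode inserts the first two listed variants
    concurrently into every selected case, modelling an allele complex.
    Controls are never passed through this function.
    """
    if spec.spike_proportion == 0:
        return cohort
    if not spec.pathogenic_variants:
        raise ValueError("spike requested but pathogenic_variants is empty")
    validate_pathogenic_variants(spec.pathogenic_variants, cohort.panel)
    n_spike = round(spec.spike_proportion * cohort.n_individuals)
    if n_spike < 1:
        logger.warning(
            "spike_proportion %.4f of %d cases selects no individual",
            spec.spike_proportion,
            cohort.n_individuals,
        )
        return cohort
    chosen = rng.choice(cohort.n_individuals, size=n_spike, replace=False)
    variants = list(spec.pathogenic_variants)
    spiked_calls = list(cohort.spiked_calls)
    for i in chosen:
        i = int(i)
        if spec.spike_mode == "fixed-pair":
            if len(variants) < 2:
                raise ValueError("fixed-pair spike mode needs >= 2 variants")
            picks = variants[:2]
        elif spec.model.recessive:
            picks = [variants[int(j)] for j in rng.integers(len(variants), size=2)]
        else:
            picks = [variants[int(rng.integers(len(variants)))]]
        spiked_calls.extend((i, pv) for pv in picks)
    return replace(
        cohort,
        spiked_calls=spiked_calls,
        spiked_individuals=sorted(
            set(cohort.spiked_individuals)
            | {cohort.individual_ids[int(i)] for i in chosen}
        ),
    )


def _replicate_rng(seed: int, k: int) -> np.random.Generator:
    # stable cross-platform derivation: child sequence keyed by (seed, k)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), k]))


def simulate_replicates(
    spec: SimulationSpec, panel: FrequencyPanel
) -> list[tuple[SimulatedCohort, SimulatedCohort]]:
    """Generate ``n_replicates`` independent (case, control) cohort pairs.

    Replicate ``k`` draws from a generator seeded deterministically by
    ``(spec.seed, k)``: the full list is reproducible and each replicate
    is independently reproducible.
    """
    return [
        simulate_one_replicate(spec, panel, k) for k in range(spec.n_replicates)
    ]


def simulate_one_replicate(
    spec: SimulationSpec, panel: FrequencyPanel, k: int = 0
) -> tuple[SimulatedCohort, SimulatedCohort]:
    """Simulate replicate ``k`` of a scenario: filtered panel, background
    draws for both cohorts, pathogenic spike-in for the cases."""
    rng = _replicate_rng(spec.seed, k)
    filtered = filter_panel(panel, spec.maf_cutoff)
    cases = simulate_cohort(
        filtered,
        spec.n_cases,
        spec.admixture_for("case"),
        rng,
        cohort="case",
        id_prefix=f"case_r{k}",
        sex_ratio=spec.sex_ratio,
    )
    controls = simulate_cohort(
        filtered,
        spec.n_controls,
        spec.admixture_for("control"),
        rng,
        cohort="control",
        id_prefix=f"ctrl_r{k}",
        sex_ratio=spec.sex_ratio,
    )
    cases = spike_pathogenic(cases, spec, rng)
    return cases, controls


# ---------------------------------------------------------------------------
# synthetic panel fixture generator


def _default_variants_per_gene(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.poisson(25.0, size=n)


def _default_freq(rng: np.random.Generator, n: int) -> np.ndarray:
    # rare-variant site frequency spectrum: sharply skewed toward 0,
    # truncated at the 0.5% rarity ceiling
    f = rng.beta(0.5, 500.0, size=n)
    over = f > 0.005
    for _ in range(10):
        if not over.any():
            break
        f[over] = rng.beta(0.5, 500.0, size=int(over.sum()))
        over = f > 0.005
    return np.minimum(f, 0.005)


def _default_scores(rng: np.random.Generator, n: int) -> np.ndarray:
    # mixture: mostly benign low-PHRED mass plus a deleterious tail
    deleterious = rng.random(n) < 0.2
    scores = rng.gamma(2.0, 2.0, size=n)  # benign bulk, mean 4
    scores[deleterious] = rng.uniform(15.0, 40.0, size=int(deleterious.sum()))
    return scores


def make_synthetic_panel(
    n_genes: int = 2000,
    variants_per_gene: Callable[[np.random.Generator, int], np.ndarray] = None,
    freq_distribution: Callable[[np.random.Generator, int], np.ndarray] = None,
    score_distribution: Callable[[np.random.Generator, int], np.ndarray] = None,
    populations: Sequence[str] = ("adjusted",),
    seed: int = 0,
    include_x: bool = False,
    private_allele_fraction: float = 0.0,
    multi_alt_fraction: float = 0.02,
) -> FrequencyPanel:
    """Fabricate a rare-variant frequency panel with deterministic content.

    Genes are laid out round-robin on autosomes 1-22 (plus an optional X
    block), each in its own 1 Mb window.  Per gene the variant count is
    Poisson(25); each variant gets a truncated-Beta frequency (skewed
    rare, <= 0.5%) per population and a PHRED score from a benign bulk /
    deleterious tail mixture.  ``private_allele_fraction`` makes that
    fraction of alleles private to one random population (frequency 0
    elsewhere) for stratification scenarios; ``multi_alt_fraction``
    turns that fraction of sites tri-allelic.  When more than one
    population is requested and none is called ``adjusted``, an
    ``adjusted`` column equal to the across-population mean is added.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (0.0 <= private_allele_fraction <= 1.0):
        raise ValueError("private_allele_fraction must lie in [0, 1]")
    variants_per_gene = variants_per_gene or _default_variants_per_gene
    freq_distribution = freq_distribution or _default_freq
    score_distribution = score_distribution or _default_scores
    populations = list(populations)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 9151]))

    chroms = [str(c) for c in range(1, 23)] + (["X"] if include_x else [])
    counts = np.maximum(variants_per_gene(rng, n_genes), 1)
    rows = []
    bases = np.array(list("ACGT"))
    for g in range(n_genes):
        gene = f"GENE{g:05d}"
        chrom = chroms[g % len(chroms)]
        window_start = 1_000_000 * (g // len(chroms) + 1)
        n_var = int(counts[g])
        pos = np.sort(
            rng.choice(np.arange(window_start, window_start + 100_000), n_var, False)
        )
        ref = bases[rng.integers(4, size=n_var)]
        alt_shift = rng.integers(1, 4, size=n_var)
        alt = bases[(np.searchsorted(bases, ref) + alt_shift) % 4]
        for i in range(n_var):
            rows.append((chrom, int(pos[i]), str(ref[i]), str(alt[i]), gene))
            if rng.random() < multi_alt_fraction:
                alt2 = bases[(np.searchsorted(bases, ref[i]) + ((alt_shift[i] % 3) + 1)) % 4]
                rows.append((chrom, int(pos[i]), str(ref[i]), str(alt2), gene))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene"])
    n_alleles = len(df)
    df["score"] = score_distribution(rng, n_alleles)
    for pop in populations:
        df[pop] = freq_distribution(rng, n_alleles)
    if private_allele_fraction > 0 and len(populations) > 1:
        private = rng.random(n_alleles) < private_allele_fraction
        owner = rng.integers(len(populations), size=n_alleles)
        for j, pop in enumerate(populations):
            col = df[pop].to_numpy()
            col[private & (owner != j)] = 0.0
            df[pop] = col
    if "adjusted" not in populations and len(populations) > 1:
        df["adjusted"] = df[populations].mean(axis=1)
        populations = populations + ["adjusted"]
    return FrequencyPanel(df, populations)


def default_pathogenic_variants(
    panel: FrequencyPanel,
    gene: str,
    n: int = 20,
    min_score: float = 25.0,
    max_score: float = 40.0,
    seed: int = 0,
) -> list[PathogenicVariant]:
    """Fabricate a pathogenic spike-in list for one panel gene.

    Creates ``n`` novel alleles (absent from the panel) inside the
    gene's coordinate range with PHRED scores uniform on
    ``[min_score, max_score]`` — a stand-in for a curated
    disease-mutation catalog.
    """
    sub = panel.df[panel.df["gene"] == gene]
    if sub.empty:
        raise KeyError(f"gene {gene!r} not in panel")
    chrom = str(sub["chrom"].iloc[0])
    lo_pos, hi_pos = int(sub["pos"].min()), int(sub["pos"].max()) + 1000
    existing = set(zip(sub["pos"], sub["ref"], sub["alt"]))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 40427]))
    out: list[PathogenicVariant] = []
    while len(out) < n:
        pos = int(rng.integers(lo_pos, hi_pos))
        ref, alt = "ACGT"[int(rng.integers(4))], "ACGT"[int(rng.integers(4))]
        if ref == alt or (pos, ref, alt) in existing:
            continue
        existing.add((pos, ref, alt))
        out.append(
            PathogenicVariant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=gene,
                score=float(rng.uniform(min_score, max_score)),
            )
        )
    return out
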