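"""File readers/writers, run manifests, and the end-to-end pipeline.

The primary exchange format is a per-individual variant TSV with
columns::

    individual_id  gene_id  chrom  pos  ref  alt  score  alt_cov  ref_cov  phase_group

``score`` is either a normalized [0, 1) value or a PHRED-scale value
(``score_scale="phred"``); the trailing coverage/phase columns may be
empty or absent.  A cohort is a directory of such files (one per
individual) or a single combined TSV.  Multi-sample VCF input is a
convenience layer: genotypes 0/1 map to one call, 1/1 to two copies of
the call, and gene assignment comes from a user-supplied BED of gene
intervals (0-based half-open, converted to 1-based internally).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from burdenrank import __version__
from burdenrank.scores import normalize_score
from burdenrank.scoring import (
    InheritanceModel,
    VariantCall,
    build_gene_score_matrix,
)
from burdenrank.stats import (
    GWSL_DEFAULT,
    GeneTestResult,
    RunConfig,
    rank_genes,
    test_matrix,
)

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "individual_id",
    "gene_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "score",
    "alt_cov",
    "ref_cov",
    "phase_group",
]


@dataclass
class RunManifest:
    """Provenance record emitted once per run."""

    tool_version: str
    command: str
    config: dict
    input_checksums: dict[str, str]
    seed: Optional[int] = None
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def checksum(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _parse_row(fields: list[str], score_scale: str, path, lineno: int) -> VariantCall:
    if len(fields) < 7:
        raise ValueError(f"{path}:{lineno}: expected >= 7 columns, got {len(fields)}")
    ind, gene, chrom, pos, ref, alt, score = fields[:7]
    extra = fields[7:] + [""] * (3 - len(fields[7:]))
    try:
        pos = int(pos)
        score = float(score)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if score_scale == "phred":
        score = normalize_score(score)
    elif not (0.0 <= score <= 1.0):
        raise ValueError(
            f"{path}:{lineno}: normalized score {score} outside [0, 1]"
        )

    def _int_or_none(x):
        return int(x) if x not in ("", ".", "NA") else None

    try:
        return VariantCall(
            individual_id=ind,
            gene_id=gene,
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            s=score,
            alt_coverage=_int_or_none(extra[0]),
            ref_coverage=_int_or_none(extra[1]),
            phase_group=extra[2] if extra[2] not in ("", ".", "NA") else None,
        )
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: {exc}") from exc


def read_cohort_tsv(
    path: Union[str, Path],
    score_scale: str = "normalized",
    skip_bad_lines: bool = False,
) -> list[VariantCall]:
    """Read a cohort from a directory of per-individual TSVs or one TSV.

    Malformed lines abort with file/line context unless
    ``skip_bad_lines`` is set, in which case they are logged and
    dropped.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix in (".tsv", ".txt"))
        if not files:
            raise FileNotFoundError(f"no .tsv files in cohort directory {path}")
    else:
        files = [path]
    calls: list[VariantCall] = []
    for f in files:
        with open(f) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if lineno == 1 and fields[0] == "individual_id":
                    continue
                try:
                    calls.append(_parse_row(fields, score_scale, f, lineno))
                except ValueError as exc:
                    if skip_bad_lines:
                        logger.warning("skipping bad line: %s", exc)
                    else:
                        raise
    return calls


def write_cohort_tsv(
    calls: Iterable[VariantCall], path: Union[str, Path], per_individual: bool = False
) -> None:
    """Write calls as cohort TSV(s); canonical sort for reproducibility."""
    calls = sorted(
        calls, key=lambda c: (c.individual_id, c.gene_id, c.key)
    )
    path = Path(path)

    def _row(c: VariantCall) -> str:
        return "\t".join(
            [
                c.individual_id,
                c.gene_id,
                c.chrom,
                str(c.pos),
                c.ref,
                c.alt,
                f"{c.s:.10g}",
                "" if c.alt_coverage is None else str(c.alt_coverage),
                "" if c.ref_coverage is None else str(c.ref_coverage),
                c.phase_group or "",
            ]
        )

    header = "\t".join(COHORT_COLUMNS)
    if per_individual:
        path.mkdir(parents=True, exist_ok=True)
        by_ind: dict[str, list[VariantCall]] = {}
        for c in calls:
            by_ind.setdefault(c.individual_id, []).append(c)
        for ind, ind_calls in by_ind.items():
            out = path / f"{ind}.tsv"
            out.write_text("\n".join([header] + [_row(c) for c in ind_calls]) + "\n")
    else:
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for c in calls:
                fh.write(_row(c) + "\n")


def read_gene_bed(path: Union[str, Path]) -> pd.DataFrame:
    """Read gene intervals from BED (chrom, start, end, name; 0-based
    half-open) into a 1-based inclusive interval table."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int) + 1  # to 1-based inclusive
    df["end"] = df["end"].astype(int)
    return df


def read_cohort_vcf(
    path: Union[str, Path],
    gene_bed: Union[str, Path],
    score_table=None,
) -> list[VariantCall]:
    """Read a multi-sample VCF into variant calls.

    Genotypes with one alt allele yield one call; homozygous-alt
    genotypes yield two copies of the call (two score copies under
    recessive scoring).  Variants outside every gene interval, or
    unscored under the table's ``drop`` policy, are excluded.  Requires
    :mod:`pysam`.
    """
    import pysam  # optional dependency, imported lazily

    bed = read_gene_bed(gene_bed)
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            chrom = rec.chrom[3:] if rec.chrom.lower().startswith("chr") else rec.chrom
            hits = bed[
                (bed["chrom"] == chrom)
                & (bed["start"] <= rec.pos)
                & (rec.pos <= bed["end"])
            ]
            if hits.empty:
                continue
            for alt in rec.alts or ():
                if score_table is not None:
                    s = score_table.normalized((chrom, rec.pos, rec.ref, alt))
                    if s is None:
                        continue
                else:
                    s = 0.0
                for sample in samples:
                    gt = rec.samples[sample].get("GT") or ()
                    alt_index = (rec.alts or ()).index(alt) + 1
                    n_copies = sum(1 for a in gt if a == alt_index)
                    for gene in hits["gene"]:
                        calls.extend(
                            VariantCall(
                                individual_id=sample,
                                gene_id=str(gene),
                                chrom=chrom,
                                pos=rec.pos,
                                ref=rec.ref,
                                alt=alt,
                                s=float(s),
                            )
                            for _ in range(n_copies)
                        )
    return calls


def results_to_frame(
    ranked: Sequence[GeneTestResult], alpha: float = GWSL_DEFAULT
) -> pd.DataFrame:
    """Ranked gene table: rank, gene, counts, statistics, significance."""
    log_alpha = math.log(alpha) if alpha > 0 else -math.inf
    return pd.DataFrame(
        {
            "rank": [r.rank for r in ranked],
            "gene": [r.gene_id for r in ranked],
            "n_case_nonzero": [r.components.n1 for r in ranked],
            "n_control_nonzero": [r.components.n2 for r in ranked],
            "Z1": [r.components.Z1 for r in ranked],
            "p1": [r.components.p1 for r in ranked],
            "p2": [r.components.p2 for r in ranked],
            "chi2": [r.chi2_stat for r in ranked],
            "p": [r.p for r in ranked],
            "log10_p": [r.log10_p for r in ranked],
            "significant": [r.log_p < log_alpha for r in ranked],
        }
    )


def run_pipeline(
    case_path: Union[str, Path],
    control_path: Union[str, Path],
    model: Union[str, InheritanceModel] = "AR",
    alpha: float = GWSL_DEFAULT,
    score_scale: str = "normalized",
    out_table: Optional[Union[str, Path]] = None,
    out_manifest: Optional[Union[str, Path]] = None,
    command: str = "run_pipeline",
    skip_bad_lines: bool = False,
) -> pd.DataFrame:
    """Read two cohorts, score, test, rank; write the table and manifest.

    Raises ``RuntimeError`` when no gene is testable (e.g. empty
    cohorts after filtering) so callers can exit non-zero.
    """
    model = InheritanceModel(model)
    case_calls = read_cohort_tsv(case_path, score_scale, skip_bad_lines)
    control_calls = read_cohort_tsv(control_path, score_scale, skip_bad_lines)
    case_m = build_gene_score_matrix(case_calls, model, cohort="case")
    control_m = build_gene_score_matrix(control_calls, model, cohort="control")
    if not case_m.individuals or not control_m.individuals:
        raise RuntimeError("empty cohort: no individuals with calls")
    config = RunConfig(model=model.value, alpha=alpha)
    results = rank_genes(test_matrix(case_m, control_m, config), config)
    if not any(r.components.testable for r in results):
        raise RuntimeError("zero testable genes")
    table = results_to_frame(results, alpha)
    if out_table is not None:
        table.to_csv(out_table, sep="\t", index=False)
    if out_manifest is not None:
        checksums = {}
        for p in (Path(case_path), Path(control_path)):
            if p.is_file():
                checksums[str(p)] = checksum(p)
            else:
                for f in sorted(p.iterdir()):
                    if f.is_file():
                        checksums[str(f)] = checksum(f)
        RunManifest(
            tool_version=__version__,
            command=command,
            config={
                "model": model.value,
                "alpha": alpha,
                "score_scale": score_scale,
            },
            input_checksums=checksums,
        ).write(out_manifest)
    return table
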