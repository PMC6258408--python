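"""Variant deleteriousness scores: PHRED-scale normalization and score tables.

Variant effect predictors such as CADD report a PHRED-like scaled score
``C`` (larger = more deleterious, unbounded above).  For gene scoring the
raw score is mapped onto the unit interval by

    s = 1 - 10 ** (-C / 10)

so that ``C = 0 -> s = 0``, ``C = 10 -> s = 0.9``, ``C = 20 -> s = 0.99``
and ``s -> 1`` as ``C -> inf``.  Score systems that are already ranked on
a 0..1 scale (e.g. DANN, REVEL) can be loaded with the ``pre-normalized``
dialect, which bypasses the transform.
"""

from __future__ import annotations

import gzip
import logging
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np

logger = logging.getLogger(__name__)

#: sentinel returned by :meth:`ScoreTable.lookup` for unscored variants
MISSING = None

VariantKey = tuple[str, int, str, str]

_VALID_DIALECTS = ("cadd-tsv", "generic-tsv", "pre-normalized")
_MISSING_POLICIES = ("drop", "zero", "error")


def normalize_score(C):
    """Map a PHRED-like scaled deleteriousness score onto [0, 1).

    Parameters
    ----------
    C : float or array-like
        PHRED-like scaled score(s), must be >= 0.

    Returns
    -------
    float or ndarray
        ``1 - 10**(-C/10)``, strictly increasing in ``C``.

    Raises
    ------
    ValueError
        If any input score is negative or not finite.
    """
    arr = np.asarray(C, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("PHRED-scaled scores must be finite and >= 0")
    s = -np.expm1(arr * (-np.log(10.0) / 10.0))
    if np.isscalar(C) or isinstance(C, numbers.Number):
        return float(s)
    return s


def denormalize_score(s):
    """Invert :func:`normalize_score`: ``C = -10 * log10(1 - s)``."""
    arr = np.asarray(s, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 1):
        raise ValueError("normalized scores must lie in [0, 1)")
    C = -10.0 / np.log(10.0) * np.log1p(-arr)
    if np.isscalar(s) or isinstance(s, numbers.Number):
        return float(C)
    return C


def _validate_key(key) -> VariantKey:
    try:
        chrom, pos, ref, alt = key
    except (TypeError, ValueError) as exc:
        raise ValueError(f"variant key must be (chrom, pos, ref, alt): {key!r}") from exc
    chrom = str(chrom)
    pos = int(pos)
    if pos < 1:
        raise ValueError(f"position must be 1-based positive, got {pos}")
    ref = str(ref).upper()
    alt = str(alt).upper()
    if not ref or not alt:
        raise ValueError(f"empty ref/alt in key {key!r}")
    return (chrom, pos, ref, alt)


@dataclass
class ScoreTable:
    """Exact-match lookup from (chrom, pos, ref, alt) to a raw score.

    Coordinates are 1-based VCF-convention; indels are keyed by their
    left-aligned minimal representation.  ``provenance`` is a free-text
    label ("CADD", "DANN", "synthetic", ...).  ``pre_normalized`` marks
    tables whose stored values are already on the 0..1 scale.
    """

    scores: dict[VariantKey, float] = field(default_factory=dict)
    provenance: str = "unknown"
    pre_normalized: bool = False
    missing_policy: str = "drop"

    def __post_init__(self):
        if self.missing_policy not in _MISSING_POLICIES:
            raise ValueError(
                f"missing_policy must be one of {_MISSING_POLICIES}, "
                f"got {self.missing_policy!r}"
            )

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, key) -> bool:
        return _validate_key(key) in self.scores

    def add(self, key, C: float) -> None:
        key = _validate_key(key)
        C = float(C)
        if key in self.scores:
            if self.scores[key] != C:
                raise ValueError(
                    f"duplicate key {key} with conflicting scores "
                    f"{self.scores[key]} != {C}"
                )
            logger.warning("duplicate key %s with equal score, deduplicated", key)
            return
        self.scores[key] = C

    def lookup(self, key):
        """Return the raw score for ``key`` or the missing-marker ``None``."""
        return self.scores.get(_validate_key(key), MISSING)

    def normalized(self, key):
        """Return the normalized score in [0, 1) for ``key``.

        Missing keys are resolved per ``missing_policy``: ``drop`` returns
        ``None`` (the caller excludes the variant, with a warning),
        ``zero`` returns 0.0 and ``error`` raises ``KeyError``.
        """
        C = self.lookup(key)
        if C is MISSING:
            if self.missing_policy == "error":
                raise KeyError(f"no score for variant {key}")
            if self.missing_policy == "zero":
                return 0.0
            logger.warning("no score for variant %s; dropped", key)
            return None
        if self.pre_normalized:
            return float(C)
        return normalize_score(C)


def load_score_table(
    path: Union[str, Path],
    dialect: str = "cadd-tsv",
    missing_policy: str = "drop",
    provenance: str | None = None,
) -> ScoreTable:
    """Load a tab-separated score table.

    Dialects
    --------
    ``cadd-tsv``
        Columns chrom, pos, ref, alt, raw_score, phred_score; the PHRED
        column (last) is stored.  Header lines starting with ``#`` and a
        literal header row are skipped.
    ``generic-tsv``
        Columns chrom, pos, ref, alt, score (PHRED scale).
    ``pre-normalized``
        Columns chrom, pos, ref, alt, score with score already in [0, 1];
        stored verbatim and never re-normalized.

    Gzip-compressed files (``.gz``) are read transparently.  Rows that do
    not parse raise with their line number; duplicated keys with equal
    scores are deduplicated with a warning, conflicting duplicates raise.
    """
    if dialect not in _VALID_DIALECTS:
        raise ValueError(f"dialect must be one of {_VALID_DIALECTS}, got {dialect!r}")
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    pre_norm = dialect == "pre-normalized"
    table = ScoreTable(
        provenance=provenance or ("CADD" if dialect == "cadd-tsv" else dialect),
        pre_normalized=pre_norm,
        missing_policy=missing_policy,
    )
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and _looks_like_header(fields):
                continue
            try:
                chrom, pos, ref, alt = fields[:4]
                score = float(fields[-1])
                key = _validate_key((chrom, pos, ref, alt))
                if pre_norm and not (0.0 <= score <= 1.0):
                    raise ValueError(
                        f"pre-normalized score {score} outside [0, 1]"
                    )
                if not pre_norm and score < 0:
                    raise ValueError(f"negative PHRED score {score}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: cannot parse row: {exc}") from exc
            table.add(key, score)
    logger.info("loaded %d scores from %s (%s)", len(table), path, dialect)
    return table


def _looks_like_header(fields: Iterable[str]) -> bool:
    fields = list(fields)
    if len(fields) < 5:
        return False
    try:
        int(fields[1])
        return False
    except ValueError:
        return True
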