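"""Reading, validating and filtering GWAS summary-statistic tables.

A :class:`StudySet` holds one trait's per-SNP association records (effect
sizes on the additive scale: log-odds for case-control outcomes, SD units for
normalised metabolite exposures). Tables are delimited text with a header;
heterogeneous source headers are resolved through a ``column_map`` so that six
differently-formatted GWAS exports can feed one pipeline.

Canonical columns: SNP, CHR, POS, EA, OA, EAF, BETA, SE, P. CHR/POS/EAF are
optional; EAF is kept as missing when absent because the palindromic-SNP
policy downstream needs to know it is unavailable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: canonical column names, in output order
CANONICAL_COLUMNS = ("SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P")
_REQUIRED = ("SNP", "EA", "OA", "BETA", "SE", "P")

_VALID_BASES = frozenset("ACGT")


class Role(str, Enum):
    EXPOSURE = "exposure"
    OUTCOME = "outcome"


@dataclass(frozen=True)
class SnpAssociation:
    """One variant's summary statistics in one GWAS.

    ``beta``/``se`` are the per-effect-allele estimate and its standard
    error; ``pvalue`` the association p-value. ``eaf`` is the effect-allele
    frequency, ``None`` when the source does not report frequencies.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValidationError("variant_id must be nonempty")
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())
        if not self.effect_allele or not self.other_allele:
            raise ValidationError(f"{self.variant_id}: empty allele")
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"{self.variant_id}: effect and other allele are identical "
                f"({self.effect_allele})"
            )
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.variant_id}: beta must be finite")
        if not (0 < self.pvalue <= 1):
            raise ValidationError(
                f"{self.variant_id}: pvalue must be in (0, 1], got {self.pvalue}"
            )
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValidationError(
                f"{self.variant_id}: eaf must be in [0, 1], got {self.eaf}"
            )
        if self.pos is not None and self.pos < 1:
            raise ValidationError(f"{self.variant_id}: pos must be >= 1")

    @property
    def is_biallelic_snp(self) -> bool:
        """True for single-base substitutions with A/C/G/T alleles."""
        return (
            len(self.effect_allele) == 1
            and len(self.other_allele) == 1
            and self.effect_allele in _VALID_BASES
            and self.other_allele in _VALID_BASES
        )


@dataclass
class StudySet:
    """Ordered collection of :class:`SnpAssociation` for one trait."""

    trait_name: str
    role: Role
    records: list[SnpAssociation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(
                f"{self.trait_name}: duplicate variant_id(s): {', '.join(dupes)}"
            )
        self._by_id = {r.variant_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._by_id

    def get(self, variant_id: str) -> SnpAssociation | None:
        return self._by_id.get(variant_id)

    def to_frame(self) -> pd.DataFrame:
        """Render as a DataFrame with the canonical columns."""
        rows = [
            {
                "SNP": r.variant_id,
                "CHR": r.chrom,
                "POS": r.pos,
                "EA": r.effect_allele,
                "OA": r.other_allele,
                "EAF": r.eaf,
                "BETA": r.beta,
                "SE": r.se,
                "P": r.pvalue,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _coerce_float(value, what: str, line: int, variant: str) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"line {line} ({variant}): malformed {what} value {value!r}"
        ) from None
    return out


def read_summary_table(
    path: str | Path,
    trait_name: str,
    role: Role | str,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
    strict: bool = True,
) -> StudySet:
    """Read a delimited summary-statistics table into a validated StudySet.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Mapping from canonical names (``SNP``, ``EA``, ``OA``, ``EAF``,
        ``BETA``, ``SE``, ``P``, optionally ``CHR``/``POS``) to the file's
        actual header names. Canonical names present in the file need no entry.
    strict
        If True (default) any invalid row raises :class:`ValidationError`
        naming its line; if False invalid rows are skipped with a logged
        warning.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"summary table not found: {path}")
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    cmap = dict(column_map or {})
    resolved = {c: cmap.get(c, c) for c in CANONICAL_COLUMNS}
    missing = [c for c in _REQUIRED if resolved[c] not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) "
            + ", ".join(f"{c} (looked for {resolved[c]!r})" for c in missing)
        )

    records: list[SnpAssociation] = []
    n_skipped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        raw = dict(zip(df.columns, row))
        variant = str(raw[resolved["SNP"]]).strip()

        def _opt(col: str):
            name = resolved[col]
            if name not in df.columns:
                return None
            v = str(raw[name]).strip()
            return None if v in ("", "NA", "NaN", "nan", ".") else v

        try:
            eaf_raw = _opt("EAF")
            pos_raw = _opt("POS")
            rec = SnpAssociation(
                variant_id=variant,
                effect_allele=str(raw[resolved["EA"]]).strip(),
                other_allele=str(raw[resolved["OA"]]).strip(),
                beta=_coerce_float(raw[resolved["BETA"]], "BETA", line, variant),
                se=_coerce_float(raw[resolved["SE"]], "SE", line, variant),
                pvalue=_coerce_float(raw[resolved["P"]], "P", line, variant),
                eaf=None if eaf_raw is None else _coerce_float(eaf_raw, "EAF", line, variant),
                chrom=_opt("CHR"),
                pos=None if pos_raw is None else int(float(pos_raw)),
            )
        except ValidationError as err:
            if strict:
                raise ValidationError(f"{path} line {line}: {err}") from None
            logger.warning("%s line %d skipped: %s", path, line, err)
            n_skipped += 1
            continue
        records.append(rec)

    if not records:
        logger.warning("%s: table for %s contains no data rows", path, trait_name)
    if n_skipped:
        logger.warning("%s: skipped %d invalid row(s)", path, n_skipped)
    return StudySet(trait_name=trait_name, role=Role(role), records=records)


def write_summary_table(study: StudySet, path: str | Path, delimiter: str = "\t") -> None:
    """Write a StudySet in the canonical column layout.

    Floats are written with the shortest round-trip representation, so a
    read → write → read cycle preserves every field exactly.
    """
    df = study.to_frame()
    df.to_csv(path, sep=delimiter, index=False, na_rep="")


def select_instruments(study: StudySet, p_threshold: float) -> StudySet:
    """Keep records with ``pvalue <= p_threshold``, preserving order.

    The genome-wide threshold 5e-8 selects standard instruments; 5e-6 is the
    suggestive threshold used when no variant reaches genome-wide significance.
    """
    if study.role is not Role.EXPOSURE:
        raise ConfigurationError("instrument selection applies to exposure StudySets")
    if not (p_threshold > 0):
        raise ConfigurationError(f"p_threshold must be positive, got {p_threshold}")
    kept = [r for r in study.records if r.pvalue <= p_threshold]
    if not kept:
        logger.warning(
            "%s: no instruments at p <= %g (of %d candidates)",
            study.trait_name, p_threshold, len(study),
        )
    return StudySet(trait_name=study.trait_name, role=study.role, records=kept)


@dataclass(frozen=True)
class ProxySubstitution:
    missing_id: str
    proxy_id: str
    r2: float


def read_proxy_map(path: str | Path, delimiter: str = "\t") -> list[ProxySubstitution]:
    """Read a proxy table with columns MISSING_SNP, PROXY_SNP, R2."""
    df = pd.read_csv(path, sep=delimiter)
    for col in ("MISSING_SNP", "PROXY_SNP", "R2"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: proxy map missing column {col}")
    return [
        ProxySubstitution(str(r.MISSING_SNP), str(r.PROXY_SNP), float(r.R2))
        for r in df.itertuples(index=False)
    ]


def apply_proxy_map(
    exposure: StudySet,
    outcome: StudySet,
    proxy_map: Iterable[ProxySubstitution] | Sequence[tuple[str, str, float]],
    r2_min: float = 0.8,
) -> StudySet:
    """Substitute LD proxies for instruments absent from the outcome GWAS.

    An exposure instrument missing from ``outcome`` is re-keyed to the first
    proxy in ``proxy_map`` with r² >= ``r2_min`` that is present in the
    outcome; its exposure-side statistics are retained under the proxy's
    identity (the proxy stands in for the same signal). Instruments that stay
    unresolved are dropped; substitutions, alternatives and drops are logged.
    LD computation itself is out of scope — the map is user-supplied.
    """
    subs: list[ProxySubstitution] = []
    for entry in proxy_map:
        if not isinstance(entry, ProxySubstitution):
            entry = ProxySubstitution(str(entry[0]), str(entry[1]), float(entry[2]))
        if not (0 <= entry.r2 <= 1):
            raise ValidationError(f"proxy r2 must be in [0, 1], got {entry.r2}")
        subs.append(entry)

    by_missing: dict[str, list[ProxySubstitution]] = {}
    for s in subs:
        by_missing.setdefault(s.missing_id, []).append(s)

    records: list[SnpAssociation] = []
    n_dropped = 0
    for rec in exposure.records:
        if rec.variant_id in outcome:
            records.append(rec)
            continue
        candidates = by_missing.get(rec.variant_id, [])
        chosen = None
        for cand in candidates:
            if cand.r2 >= r2_min and cand.proxy_id in outcome:
                chosen = cand
                break
        if chosen is None:
            n_dropped += 1
            logger.info(
                "%s: instrument %s absent from %s and unresolvable by proxy; dropped",
                exposure.trait_name, rec.variant_id, outcome.trait_name,
            )
            continue
        alternatives = [c.proxy_id for c in candidates if c is not chosen]
        logger.info(
            "%s: %s -> proxy %s (r2=%.3f)%s",
            exposure.trait_name, rec.variant_id, chosen.proxy_id, chosen.r2,
            f"; alternatives not used: {alternatives}" if alternatives else "",
        )
        records.append(replace(rec, variant_id=chosen.proxy_id))
    if n_dropped:
        logger.warning(
            "%s: dropped %d instrument(s) absent from %s with no usable proxy",
            exposure.trait_name, n_dropped, outcome.trait_name,
        )
    return StudySet(trait_name=exposure.trait_name, role=exposure.role, records=records)
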