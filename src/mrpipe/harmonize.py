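"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs every instrument's outcome effect expressed per copy of
the *exposure's* effect allele. Sources differ in which allele they call the
effect allele and in which DNA strand they report, so three situations must be
resolved for each shared variant:

* swapped alleles — the outcome's effect allele is the exposure's other
  allele: negate the outcome beta and complement its frequency;
* strand flips — the outcome reports the opposite strand: complement its
  alleles first, then apply the swap rule if needed;
* palindromic SNPs (A/T or C/G) — strand cannot be inferred from the alleles;
  allele frequencies arbitrate when both are informative (far from 0.5),
  otherwise the variant is dropped as ambiguous.

Standard errors are never altered: re-coding an allele reverses the sign of an
effect but not its precision.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd

from .exceptions import AnalysisError, ValidationError
from .summary_io import Role, SnpAssociation, StudySet

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default half-width of the allele-frequency ambiguity window around 0.5
DEFAULT_PALINDROMIC_EAF_WINDOW = 0.08


class HarmonizationStatus(str, Enum):
    KEPT = "kept"
    ALLELE_FLIPPED = "allele_flipped"
    STRAND_FLIPPED = "strand_flipped"
    DROPPED_PALINDROMIC = "dropped_palindromic"
    DROPPED_INCOMPATIBLE = "dropped_incompatible"

    @property
    def usable(self) -> bool:
        return self in (
            HarmonizationStatus.KEPT,
            HarmonizationStatus.ALLELE_FLIPPED,
            HarmonizationStatus.STRAND_FLIPPED,
        )


_USABLE = (
    HarmonizationStatus.KEPT,
    HarmonizationStatus.ALLELE_FLIPPED,
    HarmonizationStatus.STRAND_FLIPPED,
)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome effect pair on a common effect allele.

    For dropped statuses the betas are unusable and set to ``nan`` so nothing
    downstream can silently consume them.
    """

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    effect_allele: str
    status: HarmonizationStatus = HarmonizationStatus.KEPT
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None

    def __post_init__(self) -> None:
        if self.status in _USABLE:
            if not (self.se_exposure > 0 and self.se_outcome > 0):
                raise ValidationError(
                    f"{self.variant_id}: standard errors must be > 0 for usable records"
                )


def complement_alleles(allele: str) -> str:
    """Base-wise complement of an A/C/G/T allele string (e.g. ``AG`` -> ``TC``)."""
    try:
        return "".join(_COMPLEMENT[b] for b in allele.upper())
    except KeyError as err:
        raise ValidationError(f"non-ACGT base {err.args[0]!r} in allele {allele!r}") from None


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the biallelic pair is A/T or C/G in either order."""
    ea, oa = effect_allele.upper(), other_allele.upper()
    if len(ea) != 1 or len(oa) != 1 or ea not in _COMPLEMENT or oa not in _COMPLEMENT:
        raise ValidationError(f"palindromy is defined for single-base pairs, got {ea}/{oa}")
    return _COMPLEMENT[ea] == oa


def _dropped(exp: SnpAssociation, out: SnpAssociation, status: HarmonizationStatus) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        variant_id=exp.variant_id,
        beta_exposure=float("nan"),
        se_exposure=exp.se,
        beta_outcome=float("nan"),
        se_outcome=out.se,
        effect_allele=exp.effect_allele,
        status=status,
        eaf_exposure=exp.eaf,
        eaf_outcome=out.eaf,
    )


def harmonize_pair(
    exposure_rec: SnpAssociation,
    outcome_rec: SnpAssociation,
    palindromic_eaf_window: float = DEFAULT_PALINDROMIC_EAF_WINDOW,
) -> HarmonizedInstrument:
    """Express one outcome association on the exposure's effect allele.

    Palindromic pairs are oriented by comparing which side of 0.5 the two
    effect-allele frequencies fall on, but only when both frequencies are
    present and outside 0.5 ± ``palindromic_eaf_window``; otherwise the
    variant is dropped as ambiguous. Indels and records whose alleles cannot
    be reconciled by swapping and/or strand complement are dropped as
    incompatible.
    """
    if exposure_rec.variant_id != outcome_rec.variant_id:
        raise ValueError(
            f"variant_id mismatch: {exposure_rec.variant_id} vs {outcome_rec.variant_id}"
        )
    exp, out = exposure_rec, outcome_rec
    if not exp.is_biallelic_snp or not out.is_biallelic_snp:
        return _dropped(exp, out, HarmonizationStatus.DROPPED_INCOMPATIBLE)

    def _build(beta_out: float, eaf_out: float | None, status: HarmonizationStatus):
        return HarmonizedInstrument(
            variant_id=exp.variant_id,
            beta_exposure=exp.beta,
            se_exposure=exp.se,
            beta_outcome=beta_out,
            se_outcome=out.se,
            effect_allele=exp.effect_allele,
            status=status,
            eaf_exposure=exp.eaf,
            eaf_outcome=eaf_out,
        )

    if is_palindromic(exp.effect_allele, exp.other_allele):
        # alleles cannot distinguish strand; the outcome pair must be the same
        # palindromic pair, possibly written in the other order
        pair = {out.effect_allele, out.other_allele}
        if pair != {exp.effect_allele, exp.other_allele}:
            return _dropped(exp, out, HarmonizationStatus.DROPPED_INCOMPATIBLE)
        beta_out, eaf_out = out.beta, out.eaf
        if out.effect_allele != exp.effect_allele:  # written swapped: re-key first
            beta_out = -beta_out
            eaf_out = None if eaf_out is None else 1.0 - eaf_out
        w = palindromic_eaf_window
        if exp.eaf is None or eaf_out is None:
            return _dropped(exp, out, HarmonizationStatus.DROPPED_PALINDROMIC)
        if abs(exp.eaf - 0.5) <= w or abs(eaf_out - 0.5) <= w:
            return _dropped(exp, out, HarmonizationStatus.DROPPED_PALINDROMIC)
        if (exp.eaf < 0.5) == (eaf_out < 0.5):
            status = (
                HarmonizationStatus.KEPT
                if out.effect_allele == exp.effect_allele
                else HarmonizationStatus.ALLELE_FLIPPED
            )
            return _build(beta_out, eaf_out, status)
        # frequencies disagree: the outcome labels refer to the other strand
        return _build(-beta_out, 1.0 - eaf_out, HarmonizationStatus.STRAND_FLIPPED)

    exp_pair = (exp.effect_allele, exp.other_allele)
    out_pair = (out.effect_allele, out.other_allele)
    comp_pair = (complement_alleles(out.effect_allele), complement_alleles(out.other_allele))
    if out_pair == exp_pair:
        return _build(out.beta, out.eaf, HarmonizationStatus.KEPT)
    if out_pair == exp_pair[::-1]:
        eaf = None if out.eaf is None else 1.0 - out.eaf
        return _build(-out.beta, eaf, HarmonizationStatus.ALLELE_FLIPPED)
    if comp_pair == exp_pair:
        return _build(out.beta, out.eaf, HarmonizationStatus.STRAND_FLIPPED)
    if comp_pair == exp_pair[::-1]:
        eaf = None if out.eaf is None else 1.0 - out.eaf
        return _build(-out.beta, eaf, HarmonizationStatus.STRAND_FLIPPED)
    return _dropped(exp, out, HarmonizationStatus.DROPPED_INCOMPATIBLE)


@dataclass
class HarmonizationResult:
    """Usable instruments plus the per-status audit for one trait pair."""

    exposure_name: str
    outcome_name: str
    instruments: list[HarmonizedInstrument]
    dropped: list[HarmonizedInstrument]
    audit: dict[str, int]
    n_exposure_instruments: int

    def __iter__(self):
        return iter(self.instruments)

    def __len__(self) -> int:
        return len(self.instruments)


def harmonize_sets(
    exposure: StudySet,
    outcome: StudySet,
    palindromic_eaf_window: float = DEFAULT_PALINDROMIC_EAF_WINDOW,
) -> HarmonizationResult:
    """Harmonize every shared variant, in exposure order, with an audit.

    Instruments absent from the outcome are counted in the audit under
    ``absent_from_outcome``; run :func:`~mrpipe.summary_io.apply_proxy_map`
    beforehand if proxies are available. Raises :class:`AnalysisError` when
    the intersection, or the usable subset, is empty.
    """
    if exposure.role is not Role.EXPOSURE or outcome.role is not Role.OUTCOME:
        raise AnalysisError(
            f"expected exposure/outcome roles, got {exposure.role.value}/{outcome.role.value}"
        )
    audit: Counter[str] = Counter()
    usable: list[HarmonizedInstrument] = []
    dropped: list[HarmonizedInstrument] = []
    n_shared = 0
    for rec in exposure.records:
        out_rec = outcome.get(rec.variant_id)
        if out_rec is None:
            audit["absent_from_outcome"] += 1
            continue
        n_shared += 1
        h = harmonize_pair(rec, out_rec, palindromic_eaf_window)
        audit[h.status.value] += 1
        (usable if h.status.usable else dropped).append(h)
    if n_shared == 0:
        raise AnalysisError(
            f"no shared variants between exposure {exposure.trait_name!r} "
            f"and outcome {outcome.trait_name!r}"
        )
    logger.info(
        "harmonized %s -> %s: %d/%d usable (%s)",
        exposure.trait_name, outcome.trait_name, len(usable), len(exposure),
        ", ".join(f"{k}={v}" for k, v in sorted(audit.items())),
    )
    if not usable:
        raise AnalysisError(
            f"no usable instruments for {exposure.trait_name!r} -> "
            f"{outcome.trait_name!r} after harmonization "
            f"({', '.join(f'{k}={v}' for k, v in sorted(audit.items()))})"
        )
    return HarmonizationResult(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        instruments=usable,
        dropped=dropped,
        audit=dict(audit),
        n_exposure_instruments=len(exposure),
    )


_TSV_COLUMNS = ["SNP", "EA", "BETA_EXP", "SE_EXP", "BETA_OUT", "SE_OUT", "STATUS"]


def write_harmonized_tsv(
    instruments: list[HarmonizedInstrument], path: str | Path
) -> None:
    """Write instruments in the harmonized TSV layout used as fixtures."""
    df = pd.DataFrame(
        [
            {
                "SNP": h.variant_id,
                "EA": h.effect_allele,
                "BETA_EXP": h.beta_exposure,
                "SE_EXP": h.se_exposure,
                "BETA_OUT": h.beta_outcome,
                "SE_OUT": h.se_outcome,
                "STATUS": h.status.value,
            }
            for h in instruments
        ],
        columns=_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_harmonized_tsv(path: str | Path) -> list[HarmonizedInstrument]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: harmonized TSV missing columns {missing}")
    return [
        HarmonizedInstrument(
            variant_id=str(r.SNP),
            beta_exposure=float(r.BETA_EXP),
            se_exposure=float(r.SE_EXP),
            beta_outcome=float(r.BETA_OUT),
            se_outcome=float(r.SE_OUT),
            effect_allele=str(r.EA),
            status=HarmonizationStatus(r.STATUS),
        )
        for r in df.itertuples(index=False)
    ]
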