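"""Allele harmonization between exposure and outcome summary statistics.

Both tables must refer their effects to the same allele before any causal
estimate is formed. The rules, applied per variant present in both tables:

* alleles match directly -- keep as is;
* outcome alleles are swapped -- negate the outcome effect and complement its
  effect-allele frequency;
* alleles match only after strand complement (A<->T, C<->G on both outcome
  alleles) -- complement, then apply the direct/swap rule;
* palindromic pairs (A/T or C/G) are strand-ambiguous and excluded outright
  (an opt-in frequency window can rescue clearly non-ambiguous ones);
* anything else is an irreconcilable allele mismatch.

No proxy-variant lookup is attempted: a variant missing from the outcome is
dropped, with its reason logged in the exclusion audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .summary_io import SummaryRecord, SummaryTable

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: fixed enumeration of exclusion reasons used in audit tables
REASON_PALINDROMIC = "palindromic"
REASON_NOT_IN_OUTCOME = "not_in_outcome"
REASON_NOT_IN_EXPOSURE = "not_in_exposure"
REASON_ALLELE_MISMATCH = "allele_mismatch"


def is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects aligned to one shared effect allele."""

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float
    eaf_out: float

    def __post_init__(self):
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValueError("standard errors must be positive")


@dataclass
class HarmonizedSet:
    """Analysis-ready instrument set plus the per-variant exclusion audit."""

    exposure_name: str
    outcome_name: str
    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        ids = [i.variant_id for i in self.instruments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate instruments")
        if set(ids) & {v for v, _ in self.exclusions}:
            raise ValueError("variant both included and excluded")

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def beta_exp(self) -> np.ndarray:
        return np.array([i.beta_exp for i in self.instruments])

    @property
    def se_exp(self) -> np.ndarray:
        return np.array([i.se_exp for i in self.instruments])

    @property
    def beta_out(self) -> np.ndarray:
        return np.array([i.beta_out for i in self.instruments])

    @property
    def se_out(self) -> np.ndarray:
        return np.array([i.se_out for i in self.instruments])

    @property
    def variant_ids(self) -> list[str]:
        return [i.variant_id for i in self.instruments]

    def exclusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exclusions, columns=["variant_id", "reason"])


@dataclass
class MVInstrument:
    """One variant's effect vector across several exposures, plus the outcome."""

    variant_id: str
    beta_exp: np.ndarray  # length n_exposures
    se_exp: np.ndarray
    beta_out: float
    se_out: float


@dataclass
class MVHarmonizedSet:
    """Multi-exposure analogue of :class:`HarmonizedSet`."""

    exposure_names: list[str]
    outcome_name: str
    instruments: list[MVInstrument] = field(default_factory=list)
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def beta_exp(self) -> np.ndarray:
        """(n_snv, n_exposures) matrix of exposure effects."""
        return np.array([i.beta_exp for i in self.instruments])

    @property
    def se_exp(self) -> np.ndarray:
        return np.array([i.se_exp for i in self.instruments])

    @property
    def beta_out(self) -> np.ndarray:
        return np.array([i.beta_out for i in self.instruments])

    @property
    def se_out(self) -> np.ndarray:
        return np.array([i.se_out for i in self.instruments])

    @property
    def variant_ids(self) -> list[str]:
        return [i.variant_id for i in self.instruments]

    def exclusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exclusions, columns=["variant_id", "reason"])


def _align(rec: SummaryRecord, ref_ea: str, ref_oa: str) -> tuple[float, bool] | str:
    """Orient ``rec`` onto the reference allele pair.

    Returns ``(sign, flipped_freq)`` where the record's beta is multiplied by
    ``sign`` and its eaf complemented when ``flipped_freq``; or a failure
    reason string.
    """
    if is_palindromic(ref_ea, ref_oa):
        return REASON_PALINDROMIC
    ea, oa = rec.effect_allele, rec.other_allele
    for _ in range(2):  # as read, then strand-complemented
        if (ea, oa) == (ref_ea, ref_oa):
            return (1.0, False)
        if (ea, oa) == (ref_oa, ref_ea):
            return (-1.0, True)
        ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    return REASON_ALLELE_MISMATCH


def harmonize(exposure: SummaryTable, outcome: SummaryTable,
              palindromic_maf_window: float | None = None,
              eaf_warn_tol: float = 0.2) -> HarmonizedSet:
    """Align each exposure variant with its outcome record on one effect allele.

    The exposure coding is the reference. All failures are per-variant
    exclusions, never errors. By default every palindromic variant is excluded;
    passing ``palindromic_maf_window`` (e.g. 0.42) opts into the common
    frequency rescue: a palindromic variant is kept (possibly frequency
    flipped) when both frequencies are decisively away from 0.5.

    Effect-allele frequency discordance beyond ``eaf_warn_tol`` after alignment
    is logged as a warning, not an exclusion (no frequency filter is applied).
    """
    out_by_id = {r.variant_id: r for r in outcome.records}
    hset = HarmonizedSet(exposure.trait_name, outcome.trait_name)
    for erec in exposure.records:
        orec = out_by_id.get(erec.variant_id)
        if orec is None:
            hset.exclusions.append((erec.variant_id, REASON_NOT_IN_OUTCOME))
            continue
        if is_palindromic(erec.effect_allele, erec.other_allele):
            resolved = None
            if palindromic_maf_window is not None:
                resolved = _resolve_palindrome(erec, orec, palindromic_maf_window)
            if resolved is None:
                hset.exclusions.append((erec.variant_id, REASON_PALINDROMIC))
                continue
            sign, flip = resolved
        else:
            aligned = _align(orec, erec.effect_allele, erec.other_allele)
            if isinstance(aligned, str):
                hset.exclusions.append((erec.variant_id, aligned))
                continue
            sign, flip = aligned
        eaf_out = 1.0 - orec.eaf if flip else orec.eaf
        if abs(erec.eaf - eaf_out) > eaf_warn_tol:
            logger.warning("allele-frequency discordance at %s: exposure %.3f vs outcome %.3f",
                           erec.variant_id, erec.eaf, eaf_out)
        hset.instruments.append(HarmonizedInstrument(
            variant_id=erec.variant_id,
            beta_exp=erec.beta, se_exp=erec.se,
            beta_out=sign * orec.beta, se_out=orec.se,
            eaf_exp=erec.eaf, eaf_out=eaf_out,
        ))
    return hset


def _resolve_palindrome(erec: SummaryRecord, orec: SummaryRecord,
                        window: float) -> tuple[float, bool] | None:
    """Infer a palindromic variant's orientation from allele frequencies.

    Both frequencies must fall outside [window, 1-window]; on the same side
    the tables already agree, on opposite sides the outcome is flipped.
    """
    if window >= 0.5:
        return None
    e_low, o_low = erec.eaf < window, orec.eaf < window
    e_high, o_high = erec.eaf > 1 - window, orec.eaf > 1 - window
    if not ((e_low or e_high) and (o_low or o_high)):
        return None
    if (e_low and o_low) or (e_high and o_high):
        return (1.0, False)
    return (-1.0, True)


def merge_multivariable(exposures: list[SummaryTable], outcome: SummaryTable,
                        p_threshold: float = 5e-8) -> MVHarmonizedSet:
    """Build the joint instrument set for multivariable MR.

    The candidate set is the union of variants reaching ``p_threshold`` in at
    least one exposure (the standard union-of-instruments strategy). Every
    candidate must carry a record in every exposure table and the outcome;
    all records are harmonized to the coding of the first exposure table that
    contains the variant. Palindromes and irreconcilable pairs are excluded.
    """
    if len(exposures) < 2:
        raise ConfigurationError("multivariable MR needs at least 2 exposures")
    candidates: list[str] = []
    seen: set[str] = set()
    for table in exposures:
        for rec in table.records:
            if rec.pval < p_threshold and rec.variant_id not in seen:
                seen.add(rec.variant_id)
                candidates.append(rec.variant_id)

    maps = [{r.variant_id: r for r in t.records} for t in exposures]
    out_map = {r.variant_id: r for r in outcome.records}
    mset = MVHarmonizedSet([t.trait_name for t in exposures], outcome.trait_name)
    for vid in candidates:
        recs = [m.get(vid) for m in maps]
        if any(r is None for r in recs):
            mset.exclusions.append((vid, REASON_NOT_IN_EXPOSURE))
            continue
        orec = out_map.get(vid)
        if orec is None:
            mset.exclusions.append((vid, REASON_NOT_IN_OUTCOME))
            continue
        ref = recs[0]
        if is_palindromic(ref.effect_allele, ref.other_allele):
            mset.exclusions.append((vid, REASON_PALINDROMIC))
            continue
        betas, ses = [ref.beta], [ref.se]
        reason = None
        for rec in recs[1:]:
            aligned = _align(rec, ref.effect_allele, ref.other_allele)
            if isinstance(aligned, str):
                reason = aligned
                break
            betas.append(aligned[0] * rec.beta)
            ses.append(rec.se)
        if reason is None:
            aligned = _align(orec, ref.effect_allele, ref.other_allele)
            if isinstance(aligned, str):
                reason = aligned
        if reason is not None:
            mset.exclusions.append((vid, reason))
            continue
        sign = aligned[0]
        mset.instruments.append(MVInstrument(
            variant_id=vid,
            beta_exp=np.array(betas), se_exp=np.array(ses),
            beta_out=sign * orec.beta, se_out=orec.se,
        ))
    return mset
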