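"""GWAS summary-statistics containers, tab-delimited I/O, and instrument filters.

One :class:`SummaryTable` holds per-variant association statistics for a single
trait. Instrument selection follows the usual two-sample MR recipe: keep
genome-wide significant variants (strict ``p < 5e-8``), then greedily prune for
linkage disequilibrium against a caller-supplied r² matrix, optionally dropping
whole chromosomes (e.g. chromosome 19 to sever the APOE locus).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: canonical column names; a ``column_map`` maps these onto a file's header
COLUMNS = (
    "variant_id",
    "chrom",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)


@dataclass(frozen=True)
class SummaryRecord:
    """One variant's association with one trait.

    ``beta`` is the effect per copy of ``effect_allele`` on the trait scale
    (log odds per allele for binary traits); ``eaf`` is the effect-allele
    frequency in the GWAS sample.
    """

    variant_id: str
    chrom: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self):
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError("non-SNV allele")
        if self.effect_allele == self.other_allele:
            raise ValueError("identical alleles")
        if not self.se > 0:
            raise ValueError("nonpositive SE")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValueError("eaf out of range")
        if not 0.0 < self.pval <= 1.0:
            raise ValueError("pval out of range")
        if self.n <= 0:
            raise ValueError("nonpositive sample size")


@dataclass
class SummaryTable:
    """Ordered collection of :class:`SummaryRecord`, unique by ``variant_id``.

    ``rejections`` records rows that failed validation at parse time as
    ``(row_number, variant_id, reason)``; it is carried as an audit side
    channel and excluded from equality.
    """

    trait_name: str
    trait_type: str  # "continuous" | "binary"
    unit: str
    records: list[SummaryRecord] = field(default_factory=list)
    rejections: list[tuple[int, str, str]] = field(default_factory=list, compare=False, repr=False)

    def __post_init__(self):
        if not self.unit:
            raise ValueError("unit must be non-empty")
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        ids = [r.variant_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({v for v in ids if ids.count(v) > 1})
            raise ValueError(f"duplicate variant_id: {', '.join(dup)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def get(self, variant_id: str) -> SummaryRecord | None:
        for r in self.records:
            if r.variant_id == variant_id:
                return r
        return None

    def with_records(self, records: list[SummaryRecord]) -> "SummaryTable":
        return replace(self, records=list(records), rejections=list(self.rejections))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{c: getattr(r, c) for c in COLUMNS} for r in self.records],
                            columns=list(COLUMNS))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, trait_name: str, trait_type: str = "continuous",
                   unit: str = "SD") -> "SummaryTable":
        table = cls(trait_name, trait_type, unit)
        for i, row in enumerate(df.itertuples(index=False), start=1):
            d = row._asdict()
            try:
                rec = SummaryRecord(
                    variant_id=str(d["variant_id"]),
                    chrom=str(d["chrom"]),
                    effect_allele=str(d["effect_allele"]).upper(),
                    other_allele=str(d["other_allele"]).upper(),
                    eaf=float(d["eaf"]),
                    beta=float(d["beta"]),
                    se=float(d["se"]),
                    pval=float(d["pval"]),
                    n=int(d["n"]),
                )
            except (ValueError, TypeError) as exc:
                reason = str(exc) if str(exc) else "unparseable row"
                table.rejections.append((i, str(d.get("variant_id", "?")), reason))
                continue
            table.records.append(rec)
        # re-validate uniqueness after filling
        table.__post_init__()
        return table


def read_summary(path, column_map: dict | None = None, *, trait_name: str = "trait",
                 trait_type: str = "continuous", unit: str = "SD") -> SummaryTable:
    """Read a tab-delimited summary-statistics file into a :class:`SummaryTable`.

    ``column_map`` maps canonical names (:data:`COLUMNS`) to the file's header
    names, so common GWAS dialects (``effect``/``stderr``/``p`` ...) can be
    ingested. Gzip-compressed input is accepted transparently. Rows violating
    record invariants are rejected with row-numbered reasons collected in
    ``table.rejections``.
    """
    df = pd.read_csv(path, sep="\t", compression="infer", dtype=str)
    cmap = dict(column_map or {})
    rename = {}
    for canon in COLUMNS:
        src = cmap.get(canon, canon)
        if src not in df.columns:
            raise ConfigurationError(f"missing column {src!r} (for {canon!r}) in {path}")
        rename[src] = canon
    df = df.rename(columns=rename)[list(COLUMNS)]
    table = SummaryTable.from_frame(df, trait_name, trait_type, unit)
    if table.rejections:
        for row, vid, reason in table.rejections:
            logger.warning("rejected row %d (%s): %s", row, vid, reason)
    return table


def write_summary(table: SummaryTable, path) -> None:
    """Write the canonical tab-delimited format (lossless round trip)."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def rejection_frame(table: SummaryTable) -> pd.DataFrame:
    """Machine-readable audit of rows rejected at parse time."""
    return pd.DataFrame(table.rejections, columns=["row", "variant_id", "reason"])


@dataclass
class ClumpSpec:
    """Greedy LD-clumping specification.

    ``ld`` is a symmetric variant×variant r² matrix (unit diagonal) indexed by
    variant_id. Real reference panels are out of scope; the synthetic module
    emits matching matrices, which keeps the published per-trait thresholds
    (0.001 / 0.05 / 0.1) exercisable without panel downloads.
    """

    r2_threshold: float
    ld: pd.DataFrame
    p_threshold: float = 5e-8

    def __post_init__(self):
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in (0, 1]")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        m = self.ld.to_numpy(dtype=float)
        if self.ld.shape[0] != self.ld.shape[1] or list(self.ld.index) != list(self.ld.columns):
            raise ValueError("ld matrix must be square with matching index/columns")
        if not np.allclose(m, m.T, atol=1e-8) or not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError("ld matrix must be symmetric with unit diagonal")


def filter_significant(table: SummaryTable, p_threshold: float = 5e-8) -> SummaryTable:
    """Keep records with ``pval < p_threshold`` (strict), order preserved."""
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must be in (0, 1]")
    return table.with_records([r for r in table.records if r.pval < p_threshold])


def clump(table: SummaryTable, spec: ClumpSpec) -> SummaryTable:
    """Greedy LD clumping: repeatedly keep the smallest-p remaining variant and
    drop everything correlated with it above ``spec.r2_threshold``.

    P-value ties break on variant_id lexicographic order for determinism. The
    result is mutually independent at the threshold.
    """
    missing = [v for v in table.variant_ids if v not in spec.ld.index]
    if missing:
        raise ValueError(f"variant(s) absent from LD matrix: {', '.join(missing)}")
    remaining = sorted(table.records, key=lambda r: (r.pval, r.variant_id))
    kept_ids: list[str] = []
    while remaining:
        best = remaining.pop(0)
        kept_ids.append(best.variant_id)
        row = spec.ld.loc[best.variant_id]
        remaining = [r for r in remaining if row[r.variant_id] <= spec.r2_threshold]
    kept_set = set(kept_ids)
    return table.with_records([r for r in table.records if r.variant_id in kept_set])


def exclude_chromosome(table: SummaryTable, chrom: str) -> SummaryTable:
    """Drop all records on ``chrom`` (e.g. "19" for the APOE sensitivity run)."""
    kept = [r for r in table.records if r.chrom != str(chrom)]
    n_removed = len(table.records) - len(kept)
    if n_removed:
        logger.info("excluded %d variant(s) on chromosome %s from %s",
                    n_removed, chrom, table.trait_name)
    return table.with_records(kept)
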