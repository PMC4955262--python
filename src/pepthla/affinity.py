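"""Peptide–HLA binding affinity: table ingestion, binder classification, mock.

Binding prediction itself (a neural-network webserver in production use) is a
pluggable external step: this module consumes its TSV output, classifies
binders by the conventional IC50 cutoffs (< 50 nM strong, < 500 nM weak), and
provides a deterministic hash-based mock predictor for tests and synthetic
runs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

STRONG_CUT_NM = 50.0
WEAK_CUT_NM = 500.0


class AffinityError(ValueError):
    pass


def classify_binder(
    ic50_nM: float, strong_cut: float = STRONG_CUT_NM, weak_cut: float = WEAK_CUT_NM
) -> str:
    """Classify an IC50 (nM) as 'strong', 'weak' or 'non'.

    Both comparisons are strict: strong iff ic50 < strong_cut, weak iff
    strong_cut <= ic50 < weak_cut.  IC50 exactly at a cutoff falls in the
    weaker class.
    """
    if not ic50_nM > 0:
        raise AffinityError(f"IC50 must be positive, got {ic50_nM!r}")
    if ic50_nM < strong_cut:
        return "strong"
    if ic50_nM < weak_cut:
        return "weak"
    return "non"


@dataclass(frozen=True)
class AffinityRecord:
    peptide: str
    allele: str
    ic50_nM: float
    binder_class: str

    @classmethod
    def make(cls, peptide: str, allele: str, ic50_nM: float,
             strong_cut: float = STRONG_CUT_NM, weak_cut: float = WEAK_CUT_NM):
        return cls(peptide, allele, float(ic50_nM),
                   classify_binder(ic50_nM, strong_cut, weak_cut))


@dataclass
class AffinityTable:
    """All affinity records for one allele, keyed by peptide."""

    allele: str
    records: dict[str, AffinityRecord]

    def __len__(self) -> int:
        return len(self.records)

    def ic50(self, peptide: str) -> float | None:
        rec = self.records.get(peptide)
        return None if rec is None else rec.ic50_nM

    def is_binder(self, peptide: str, max_ic50: float = WEAK_CUT_NM) -> bool:
        """Putative-complex criterion: predicted IC50 below *max_ic50*.

        A peptide absent from the table counts as a non-binder.
        """
        ic50 = self.ic50(peptide)
        return ic50 is not None and ic50 < max_ic50


def read_affinity_table(
    tsv_source: str | Path, allele: str | None = None
) -> AffinityTable:
    """Read a predictor-output TSV (columns: peptide, ic50[, allele]).

    Duplicate peptides are resolved by keeping the minimum IC50 (with a
    warning); non-numeric IC50 values are rejected with the offending line
    number.
    """
    df = pd.read_csv(tsv_source, sep="\t", dtype={"peptide": str})
    missing = {"peptide", "ic50"} - set(df.columns)
    if missing:
        raise AffinityError(f"affinity table missing columns: {sorted(missing)}")
    if allele is None:
        if "allele" not in df.columns:
            raise AffinityError("allele neither a column nor supplied")
        alleles = df["allele"].unique()
        if len(alleles) != 1:
            raise AffinityError(f"expected a single allele, found {list(alleles)}")
        allele = str(alleles[0])
    ic50 = pd.to_numeric(df["ic50"], errors="coerce")
    bad = ic50.isna() | (ic50 <= 0)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise AffinityError(
            f"non-numeric or non-positive ic50 {df['ic50'][bad.idxmax()]!r} "
            f"at line {line} of {tsv_source}"
        )
    records: dict[str, AffinityRecord] = {}
    n_dup = 0
    for pep, val in zip(df["peptide"], ic50):
        prev = records.get(pep)
        if prev is not None:
            n_dup += 1
            if val >= prev.ic50_nM:
                continue
        records[pep] = AffinityRecord.make(pep, allele, float(val))
    if n_dup:
        logger.warning("%d duplicate peptides resolved by minimum IC50", n_dup)
    return AffinityTable(allele, records)


def mock_affinity(peptide: str, allele: str, seed: int = 0) -> float:
    """Deterministic stand-in IC50 in (0, 50000] nM.

    Stable across platforms and Python processes (no ``hash()``): derived
    from a blake2b digest of (peptide, allele, seed).
    """
    h = hashlib.blake2b(f"{peptide}|{allele}|{seed}".encode(), digest_size=8)
    frac = int.from_bytes(h.digest(), "big") / 2**64  # [0, 1)
    return (1.0 - frac) * 50000.0  # (0, 50000]


def mock_affinity_table(
    peptides, allele: str, seed: int = 0, overrides: dict[str, float] | None = None
) -> AffinityTable:
    """Build a full mock table, optionally pinning specific peptides' IC50s."""
    overrides = overrides or {}
    records = {}
    for pep in peptides:
        ic50 = overrides.get(pep, mock_affinity(pep, allele, seed))
        records[pep] = AffinityRecord.make(pep, allele, ic50)
    return AffinityTable(allele, records)


def write_affinity_table(table: AffinityTable, path: str | Path) -> None:
    rows = [
        (r.peptide, table.allele, r.ic50_nM, r.binder_class)
        for r in table.records.values()
    ]
    pd.DataFrame(rows, columns=["peptide", "allele", "ic50", "binder_class"]).to_csv(
        path, sep="\t", index=False
    )
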