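"""Group-wise RPKM summaries and the cancer-specificity / off-target rules.

Expression enters the analysis twice.  A candidate target must come from a
gene highly expressed in its tumor type (75th-percentile RPKM > 5.0 across
the type's samples) and essentially silent in every essential normal tissue
(max 75th-percentile RPKM < 0.5).  A similar peptide only counts as an
off-target risk if its source gene is expressed in some essential normal
tissue (95th-percentile RPKM > 0.5).  Reproductive tissues (breast, cervix,
fallopian tube, testis, uterus, vagina) are non-essential — they can be
sacrificed during therapy — and are ignored by both normal-tissue rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR_P75_MIN = 5.0     # RPKM; ~1 transcript copy present in >=25% of samples
NORMAL_P75_MAX = 0.5    # RPKM; ~0 copies in essential normal tissue
OFFTARGET_P95_MIN = 0.5  # RPKM; off-target gene detectable in essential tissue

#: Normal tissues treated as sacrificable (male/female reproductive organs).
NON_ESSENTIAL_TISSUES = frozenset(
    {"breast", "cervix", "fallopian tube", "testis", "uterus", "vagina"}
)


class ExpressionError(ValueError):
    pass


def percentile(values, q: float) -> float:
    """Inclusive linear-interpolation percentile (rank (n-1)*q/100).

    q=0 gives the minimum, q=100 the maximum.  Matches the default of
    mainstream numerics libraries; the choice matters for boundary genes and
    is therefore pinned here.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ExpressionError("percentile of empty value set")
    if not np.all(np.isfinite(arr)):
        raise ExpressionError("non-finite expression values")
    if not 0 <= q <= 100:
        raise ExpressionError(f"q must be in [0, 100], got {q}")
    return float(np.percentile(arr, q, method="linear"))


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    source: str          # TCGA | GTEx | synthetic
    group: str           # cancer-type code or normal-tissue name
    is_cancer: bool
    is_essential: bool = True  # meaningful for normal samples only


@dataclass(frozen=True)
class ExpressionSummary:
    gene: str
    group: str
    is_cancer: bool
    is_essential: bool
    p75: float
    p95: float
    n_samples: int


@dataclass
class SummarySet:
    """All (gene, group) summaries, with fast lookup."""

    summaries: dict[tuple[str, str], ExpressionSummary]
    cancer_groups: set[str] = field(default_factory=set)
    essential_normal_groups: set[str] = field(default_factory=set)

    def get(self, gene: str, group: str) -> ExpressionSummary | None:
        return self.summaries.get((gene, group))

    def genes(self) -> set[str]:
        return {g for g, _ in self.summaries}


def read_expression(
    matrix_path: str | Path, meta_path: str | Path
) -> tuple[pd.DataFrame, list[SampleMeta]]:
    """Read a gene×sample RPKM TSV and its sample-metadata TSV."""
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta_df = pd.read_csv(meta_path, sep="\t", dtype=str)
    required = {"sample_id", "source", "group", "is_cancer"}
    missing = required - set(meta_df.columns)
    if missing:
        raise ExpressionError(f"metadata missing columns: {sorted(missing)}")
    truthy = {"1", "true", "yes", "y"}
    metas = []
    for _, row in meta_df.iterrows():
        is_cancer = str(row["is_cancer"]).strip().lower() in truthy
        ess_raw = str(row.get("is_essential", "")).strip().lower()
        is_essential = (not is_cancer) and (
            ess_raw in truthy
            or (ess_raw in {"", "nan"} and row["group"].lower() not in NON_ESSENTIAL_TISSUES)
        )
        metas.append(SampleMeta(row["sample_id"], row["source"], row["group"],
                                is_cancer, is_essential))
    missing_samples = {m.sample_id for m in metas} - set(mat.columns)
    if missing_samples:
        raise ExpressionError(f"samples absent from matrix: {sorted(missing_samples)[:5]}")
    if (mat.values < 0).any():
        raise ExpressionError("negative RPKM values in matrix")
    return mat, metas


def summarize(matrix: pd.DataFrame, samples: list[SampleMeta]) -> SummarySet:
    """Per-(gene, group) 75th and 95th percentile RPKM summaries.

    Cancer-type groups and normal-tissue groups are summarized identically.
    Duplicate gene rows are aggregated by max beforehand (conservative toward
    off-target detection).
    """
    if matrix.index.duplicated().any():
        logger.warning("duplicate gene rows aggregated by max")
        matrix = matrix.groupby(level=0).max()
    summaries: dict[tuple[str, str], ExpressionSummary] = {}
    cancer_groups: set[str] = set()
    essential_normals: set[str] = set()
    by_group: dict[str, list[SampleMeta]] = {}
    for m in samples:
        by_group.setdefault(m.group, []).append(m)
    for group, members in by_group.items():
        ids = [m.sample_id for m in members if m.sample_id in matrix.columns]
        if not ids:
            logger.warning("group %s has zero samples in matrix; omitted", group)
            continue
        is_cancer = members[0].is_cancer
        is_essential = (not is_cancer) and all(m.is_essential for m in members)
        if is_cancer:
            cancer_groups.add(group)
        elif is_essential:
            essential_normals.add(group)
        sub = matrix[ids].to_numpy(dtype=float)
        p75 = np.percentile(sub, 75, axis=1, method="linear")
        p95 = np.percentile(sub, 95, axis=1, method="linear")
        for gene, a, b in zip(matrix.index, p75, p95):
            summaries[(gene, group)] = ExpressionSummary(
                gene, group, is_cancer, is_essential, float(a), float(b), len(ids)
            )
    return SummarySet(summaries, cancer_groups, essential_normals)


def gene_expression_for_peptide(
    genes: set[str] | list[str], summaries: SummarySet, group: str, stat: str = "p75"
) -> float:
    """Max over the peptide's source genes of the group's summary statistic.

    Peptides occurring in multiple genes take the maximum (errs toward
    caution: a peptide is as expressed as its most-expressed source).
    """
    vals = []
    for gene in genes:
        s = summaries.get(gene, group)
        if s is not None:
            vals.append(getattr(s, stat))
    if not vals:
        raise ExpressionError(f"no expression summary for genes {sorted(genes)} in {group}")
    return max(vals)


def _present_genes(genes, summaries: SummarySet) -> set[str]:
    known = summaries.genes()
    present = {g for g in genes if g in known}
    if not present:
        raise ExpressionError(f"none of genes {sorted(set(genes))} in expression data")
    if len(present) < len(set(genes)):
        logger.warning("genes %s absent from expression data", sorted(set(genes) - present))
    return present


def is_cancer_specific(
    genes: set[str] | list[str],
    cancer_type: str,
    summaries: SummarySet,
    tumor_cut: float = TUMOR_P75_MIN,
    normal_cut: float = NORMAL_P75_MAX,
) -> bool:
    """Tumor p75 > tumor_cut AND max essential-normal p75 < normal_cut.

    Both inequalities are strict; values exactly at a cutoff fail.
    """
    if cancer_type not in summaries.cancer_groups:
        raise ExpressionError(f"unknown cancer type {cancer_type!r}")
    present = _present_genes(genes, summaries)
    tumor_p75 = gene_expression_for_peptide(present, summaries, cancer_type, "p75")
    if not tumor_p75 > tumor_cut:
        return False
    for tissue in summaries.essential_normal_groups:
        if gene_expression_for_peptide(present, summaries, tissue, "p75") >= normal_cut:
            return False
    return True


def offtarget_expressed(
    genes: set[str] | list[str],
    summaries: SummarySet,
    cut: float = OFFTARGET_P95_MIN,
) -> bool:
    """True iff any essential normal tissue has p95 > cut (strict)."""
    present = _present_genes(genes, summaries)
    return any(
        gene_expression_for_peptide(present, summaries, tissue, "p95") > cut
        for tissue in summaries.essential_normal_groups
    )


def expressing_tissues(
    genes: set[str] | list[str],
    summaries: SummarySet,
    cut: float = OFFTARGET_P95_MIN,
) -> list[tuple[str, float]]:
    """Essential normal tissues with p95 > cut, sorted by p95 descending."""
    present = _present_genes(genes, summaries)
    out = []
    for tissue in summaries.essential_normal_groups:
        p95 = gene_expression_for_peptide(present, summaries, tissue, "p95")
        if p95 > cut:
            out.append((tissue, p95))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def write_summaries(summaries: SummarySet, path: str | Path) -> None:
    rows = [
        (s.gene, s.group, int(s.is_cancer), int(s.is_essential), s.p75, s.p95, s.n_samples)
        for s in summaries.summaries.values()
    ]
    df = pd.DataFrame(
        rows, columns=["gene", "group", "is_cancer", "is_essential", "p75", "p95", "n_samples"]
    ).sort_values(["gene", "group"])
    df.to_csv(path, sep="\t", index=False)
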