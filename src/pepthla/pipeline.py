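"""End-to-end target discovery, off-target attachment and prioritization.

The four-stage strategy: (1) enumerate proteome 9-mers, (2) keep peptides
predicted to bind the HLA allele (IC50 < 500 nM), (3) keep peptides whose
source gene is cancer-specific by the RPKM percentile rules, (4) for each
target find all proteome peptides at DoS >= 5, keep those that bind the
allele and are expressed in essential normal tissue — the predicted
off-targets — optionally discarding hits that agree with the target at
fewer than 3 TCR-important positions.  Targets are then ranked: fewest
off-targets at DoS >= 6 first, then fewest at DoS >= 5, then higher tumor
expression, so the safest targets surface at the top.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .affinity import AffinityTable
from .expression import SummarySet, expressing_tissues, is_cancer_specific, offtarget_expressed
from .proteome import ProteomeIndex
from .similarity import NeighborIndex, SimilarityHit, find_similar, important_overlap
from .structure_contacts import ImportanceProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the strategy, with their production defaults."""

    allele: str = "HLA-A*02:01"
    strong_ic50_nM: float = 50.0
    binder_ic50_nM: float = 500.0       # putative-complex gate for targets
    offtarget_ic50_max: float = 500.0   # binder gate for off-target candidates
    tumor_p75_min: float = 5.0
    normal_p75_max: float = 0.5
    offtarget_p95_min: float = 0.5
    min_dos: int = 5
    min_important_overlap: int = 3
    vote_threshold: int = 2


@dataclass
class TargetCandidate:
    peptide: str
    allele: str
    cancer_type: str
    ic50_nM: float
    tumor_p75: float
    source_genes: list[str]


@dataclass
class OffTarget:
    peptide: str
    dos: int
    ic50_nM: float
    source_genes: list[str]
    expressing_tissues: list[tuple[str, float]]
    important_overlap: int | None = None


@dataclass
class PrioritizedTarget:
    target: TargetCandidate
    offtargets: list[OffTarget]
    n_offtargets_dos5: int
    n_offtargets_dos6: int
    rank: int = 0


def discover_targets(
    index: ProteomeIndex,
    affinities: AffinityTable,
    summaries: SummarySet,
    config: PipelineConfig = PipelineConfig(),
) -> list[TargetCandidate]:
    """Peptides that bind the allele and are cancer-specific somewhere.

    One candidate per (peptide, cancer type) pair — a peptide specific to
    two cancer types yields two candidates.  Peptides without an affinity
    record are counted and treated as non-binders.
    """
    targets: list[TargetCandidate] = []
    n_missing = 0
    known_genes = summaries.genes()
    for pep_seq in sorted(index.peptides):
        rec = affinities.records.get(pep_seq)
        if rec is None:
            n_missing += 1
            continue
        if not rec.ic50_nM < config.binder_ic50_nM:
            continue
        genes = index[pep_seq].gene_symbols
        present = genes & known_genes
        if not present:
            continue
        for cancer_type in sorted(summaries.cancer_groups):
            if is_cancer_specific(present, cancer_type, summaries,
                                  config.tumor_p75_min, config.normal_p75_max):
                tumor_p75 = max(
                    summaries.get(g, cancer_type).p75 for g in present
                    if summaries.get(g, cancer_type)
                )
                targets.append(TargetCandidate(
                    pep_seq, affinities.allele, cancer_type,
                    rec.ic50_nM, tumor_p75, sorted(genes),
                ))
    if n_missing:
        logger.warning("%d indexed peptides had no affinity record (non-binders)",
                       n_missing)
    return targets


def attach_offtargets(
    target: TargetCandidate,
    index: ProteomeIndex | NeighborIndex,
    affinities: AffinityTable,
    summaries: SummarySet,
    importance_profile: ImportanceProfile | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> list[OffTarget]:
    """Similar + binding + essential-tissue-expressed peptides for one target.

    With an importance profile, hits sharing fewer than
    ``min_important_overlap`` identical *important* positions are discarded
    (a TCR needs at least that many contact positions to cross-react).
    """
    known_genes = summaries.genes()
    hits = find_similar(target.peptide, index, config.min_dos,
                        query_genes=set(target.source_genes))
    out: list[OffTarget] = []
    for hit in hits:
        rec = affinities.records.get(hit.candidate.sequence)
        if rec is None or not rec.ic50_nM < config.offtarget_ic50_max:
            continue
        genes = hit.candidate.gene_symbols & known_genes
        if not genes or not offtarget_expressed(genes, summaries, config.offtarget_p95_min):
            continue
        overlap = None
        if importance_profile is not None:
            overlap = important_overlap(hit, importance_profile.important_positions)
            if overlap < config.min_important_overlap:
                continue
        out.append(OffTarget(
            hit.candidate.sequence, hit.dos, rec.ic50_nM,
            sorted(hit.candidate.gene_symbols),
            expressing_tissues(genes, summaries, config.offtarget_p95_min),
            overlap,
        ))
    return out


def prioritize(
    targets_with_offtargets: list[tuple[TargetCandidate, list[OffTarget]]],
) -> list[PrioritizedTarget]:
    """Rank targets: fewest DoS>=6 off-targets, then DoS>=5, then tumor p75.

    Remaining ties break lexicographically on the peptide so the ranking is
    a deterministic permutation of the input regardless of its order.
    """
    rows = []
    for target, offs in targets_with_offtargets:
        n5 = sum(1 for o in offs if o.dos >= 5)
        n6 = sum(1 for o in offs if o.dos >= 6)
        rows.append(PrioritizedTarget(target, offs, n5, n6))
    rows.sort(key=lambda r: (r.n_offtargets_dos6, r.n_offtargets_dos5,
                             -r.target.tumor_p75, r.target.peptide,
                             r.target.cancer_type))
    for i, r in enumerate(rows, 1):
        r.rank = i
    return rows


def write_reports(prioritized: list[PrioritizedTarget], out_dir: str | Path) -> None:
    """Deterministic TSV reports: ranked targets + per-target off-target lists."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        (r.rank, r.target.cancer_type, r.target.peptide,
         ";".join(r.target.source_genes), r.target.ic50_nM,
         round(r.target.tumor_p75, 4), r.n_offtargets_dos5, r.n_offtargets_dos6)
        for r in prioritized
    ]
    pd.DataFrame(rows, columns=[
        "rank", "tumor", "peptide", "gene", "IC50", "RPKM.tumor", "Sim.5", "Sim.6",
    ]).to_csv(out / "targets.tsv", sep="\t", index=False)

    off_rows = []
    for r in prioritized:
        for o in r.offtargets:
            tissues = ";".join(f"{t}:{p95:.3g}" for t, p95 in o.expressing_tissues[:4])
            off_rows.append((
                r.rank, r.target.peptide, o.peptide, o.dos, o.ic50_nM,
                ";".join(o.source_genes), tissues,
                "" if o.important_overlap is None else o.important_overlap,
            ))
    pd.DataFrame(off_rows, columns=[
        "target_rank", "target", "off.target", "DoS", "IC50",
        "off.target.gene", "normal.tissue.samples", "important.overlap",
    ]).to_csv(out / "offtargets.tsv", sep="\t", index=False)


def run_pipeline(
    index: ProteomeIndex,
    affinities: AffinityTable,
    summaries: SummarySet,
    importance_profile: ImportanceProfile | None = None,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> tuple[list[PrioritizedTarget], dict]:
    """Run stages 2-4 over a built index; returns ranking and stage counts."""
    targets = discover_targets(index, affinities, summaries, config)
    nbr = NeighborIndex(index) if isinstance(index, ProteomeIndex) else index
    pairs = [
        (t, attach_offtargets(t, nbr, affinities, summaries, importance_profile, config))
        for t in targets
    ]
    ranked = prioritize(pairs)
    summary = {
        "n_peptides": index.n_peptides,
        "n_binders": sum(
            1 for p in index.peptides
            if affinities.is_binder(p, config.binder_ic50_nM)
        ),
        "n_targets": len(targets),
        "n_unique_target_peptides": len({t.peptide for t in targets}),
        "n_offtarget_links": sum(len(offs) for _, offs in pairs),
        "config": {k: (sorted(v) if isinstance(v, (set, frozenset)) else v)
                   for k, v in vars(config).items()},
    }
    logger.info("pipeline: %s", summary)
    if out_dir is not None:
        write_reports(ranked, out_dir)
        with open(Path(out_dir) / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return ranked, summary
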