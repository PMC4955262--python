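"""Canonical proteome ingestion and exhaustive 9-mer enumeration.

HLA class I molecules predominantly present 9-residue peptides, so the unit
of analysis throughout the package is the 9-mer.  This module reads a protein
FASTA (UniProtKB-style), applies the HLA-allele and lincRNA-product filters
that define the representative proteome, and enumerates every overlapping
9-mer window together with its gene provenance.  Identical 9-mers arising
from different proteins are merged into a single peptide whose gene set is
the union of its sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids.  Anything else (B, J, O, U, X, Z, ...) is
#: treated as non-standard and windows containing it are dropped.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

K = 9  # peptide length; the package is 9-mer only


class ProteomeError(ValueError):
    """Malformed or empty proteome input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One canonical protein sequence with its filter flags."""

    accession: str
    gene_symbol: str
    sequence: str
    is_hla_variant: bool = False
    allele_name: str = ""
    is_lincRNA_product: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ProteomeError(f"protein {self.accession}: empty sequence")


@dataclass
class ProteinSet:
    """An ordered collection of proteins with unique accessions."""

    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise ProteomeError(f"duplicate accession {rec.accession}")
            seen.add(rec.accession)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class Peptide9:
    """A distinct 9-mer with every (accession, gene, 1-based start) occurrence."""

    sequence: str
    occurrences: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def gene_symbols(self) -> set[str]:
        return {g for _, g, _ in self.occurrences}


@dataclass
class ProteomeIndex:
    """Deduplicated map from 9-mer sequence to :class:`Peptide9`."""

    peptides: dict[str, Peptide9]
    n_proteins: int

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    def __contains__(self, seq: str) -> bool:
        return seq in self.peptides

    def __getitem__(self, seq: str) -> Peptide9:
        return self.peptides[seq]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the accession→flags side manifest (TSV).

    Columns: accession, gene_symbol, is_hla_variant, allele_name, is_lincRNA.
    Header conventions in FASTA files vary by release, so flags live in an
    explicit manifest rather than being guessed from headers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"accession", "gene_symbol"}
    missing = required - set(df.columns)
    if missing:
        raise ProteomeError(f"manifest missing columns: {sorted(missing)}")
    for col in ("is_hla_variant", "is_lincRNA"):
        if col not in df.columns:
            df[col] = ""
    if "allele_name" not in df.columns:
        df["allele_name"] = ""
    return df.set_index("accession")


def _truthy(s: str) -> bool:
    return str(s).strip().lower() in {"1", "true", "yes", "y"}


def read_proteome(
    fasta_source: str | Path,
    manifest: pd.DataFrame | None = None,
    exclude_lincRNA: bool = True,
) -> ProteinSet:
    """Parse a protein FASTA into a :class:`ProteinSet`.

    The FASTA header's first whitespace-delimited token is the accession
    (``sp|P43356|MAGA2_HUMAN`` style pipes are split and the middle field
    used).  Gene symbols and filter flags come from *manifest* when given;
    otherwise the gene symbol defaults to the accession.  Records flagged as
    lincRNA products are excluded when *exclude_lincRNA* is on, since
    lincRNAs are not known to be translated.
    """
    records: list[ProteinRecord] = []
    n_linc_dropped = 0
    try:
        parsed = list(SeqIO.parse(str(fasta_source), "fasta"))
    except Exception as exc:  # Bio raises assorted ValueErrors
        raise ProteomeError(f"malformed FASTA {fasta_source}: {exc}") from exc
    if not parsed:
        raise ProteomeError(f"empty FASTA input: {fasta_source}")
    for rec in parsed:
        token = rec.id
        if "|" in token:
            parts = token.split("|")
            accession = parts[1] if len(parts) >= 2 and parts[1] else parts[0]
        else:
            accession = token
        seq = str(rec.seq).upper().strip("*")
        if not seq:
            raise ProteomeError(f"malformed FASTA record {accession}: empty sequence")
        gene, hla, allele, linc = accession, False, "", False
        if manifest is not None and accession in manifest.index:
            row = manifest.loc[accession]
            gene = row["gene_symbol"] or accession
            hla = _truthy(row["is_hla_variant"])
            allele = str(row["allele_name"])
            linc = _truthy(row["is_lincRNA"])
        if exclude_lincRNA and linc:
            n_linc_dropped += 1
            continue
        records.append(
            ProteinRecord(accession, gene, seq, is_hla_variant=hla, allele_name=allele,
                          is_lincRNA_product=linc)
        )
    if n_linc_dropped:
        logger.info("excluded %d lincRNA-product records", n_linc_dropped)
    return ProteinSet(records)


#: Allele groups kept as proteome representatives — the highest-frequency
#: alleles of each locus in the studied population.
DEFAULT_KEEP_ALLELES = frozenset({"HLA-A*02", "HLA-B*07", "HLA-C*07", "HLA-DRB1*15"})


def filter_hla_variants(
    proteins: ProteinSet,
    keep_allele_names: Iterable[str] = DEFAULT_KEEP_ALLELES,
) -> ProteinSet:
    """Keep only the HLA allele products named in *keep_allele_names*.

    Non-HLA records pass through untouched.  An allele-group name such as
    ``HLA-A*02`` also matches more specific names (``HLA-A*02:01``).
    A keep-list entry matching nothing in the set triggers a warning only.
    """
    keep = set(keep_allele_names)
    kept: list[ProteinRecord] = []
    matched: set[str] = set()
    for rec in proteins:
        if not rec.is_hla_variant:
            kept.append(rec)
            continue
        hit = next(
            (k for k in keep if rec.allele_name == k or rec.allele_name.startswith(k + ":")),
            None,
        )
        if hit is not None:
            matched.add(hit)
            kept.append(rec)
    for k in keep - matched:
        logger.warning("keep-list allele %s matched no manifest record", k)
    return ProteinSet(kept)


def extract_9mers(protein_set: ProteinSet) -> ProteomeIndex:
    """Enumerate every standard-alphabet 9-mer window across the proteome.

    Windows containing any non-standard character are dropped.  Proteins
    shorter than 9 residues contribute nothing.  Identical 9-mers from
    different proteins merge into one entry with multiple occurrences.
    """
    peptides: dict[str, Peptide9] = {}
    for rec in protein_set:
        seq = rec.sequence
        # positions of non-standard residues, to skip windows overlapping them
        bad = [i for i, c in enumerate(seq) if c not in STANDARD_AA]
        bad_iter = iter(bad + [len(seq) + K])
        next_bad = next(bad_iter)
        for start in range(len(seq) - K + 1):
            while next_bad < start:
                next_bad = next(bad_iter)
            if next_bad < start + K:
                continue
            win = seq[start : start + K]
            pep = peptides.get(win)
            if pep is None:
                pep = peptides[win] = Peptide9(win)
            pep.occurrences.append((rec.accession, rec.gene_symbol, start + 1))
    return ProteomeIndex(peptides, n_proteins=len(protein_set))


def write_index(index: ProteomeIndex, path: str | Path) -> None:
    """Write the peptide index as TSV: peptide, genes (;-joined), occurrences."""
    rows = []
    for seq in sorted(index.peptides):
        pep = index.peptides[seq]
        occ = ",".join(f"{a}:{g}:{s}" for a, g, s in pep.occurrences)
        rows.append((seq, ";".join(sorted(pep.gene_symbols)), occ))
    df = pd.DataFrame(rows, columns=["peptide", "gene_symbols", "occurrences"])
    df.to_csv(path, sep="\t", index=False)


def read_index(path: str | Path, n_proteins: int = 0) -> ProteomeIndex:
    """Inverse of :func:`write_index`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    peptides: dict[str, Peptide9] = {}
    for _, row in df.iterrows():
        occs = []
        for item in str(row["occurrences"]).split(","):
            acc, gene, start = item.rsplit(":", 2)
            occs.append((acc, gene, int(start)))
        peptides[row["peptide"]] = Peptide9(row["peptide"], occs)
    return ProteomeIndex(peptides, n_proteins=n_proteins)
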