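"""Synthetic inputs with planted, verifiable truth for every pipeline stage.

Real inputs to the target-discovery pipeline are a canonical proteome, a
binding-affinity table, tumor/normal RPKM matrices, and peptide–HLA–TCR
crystal structures.  None are redistributable at test scale, so this module
generates small stand-ins in the same file formats with *planted* truth:
target peptides embedded in dedicated genes whose expression satisfies the
cancer-specificity rule, off-target peptides at prescribed DoS from their
targets with essential-tissue expression, and toy 3-chain structures whose
coordinates realize a prescribed 9-position contact pattern exactly.

Every generator verifies its own guarantee after sampling (by running the
corresponding analysis operation) and re-draws on violation, turning
probabilistic construction into a deterministic contract.  All output is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .affinity import AffinityRecord, AffinityTable, mock_affinity
from .expression import (SampleMeta, is_cancer_specific, offtarget_expressed,
                         summarize)
from .proteome import STANDARD_AA, K, ProteinRecord, ProteinSet, extract_9mers
from .similarity import dos

AA = "".join(sorted(STANDARD_AA))


class FixtureError(ValueError):
    pass


@dataclass
class PlantedOffTarget:
    target_peptide: str
    offtarget_peptide: str | None  # None: derive by mutating 9-dos positions
    dos: int
    expressing_tissue: str
    gene: str = ""
    ic50_nM: float = 100.0


@dataclass
class PlantedTarget:
    peptide: str
    cancer_type: str
    gene: str = ""
    ic50_nM: float = 100.0


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_background_proteins: int = 20
    protein_length_range: tuple[int, int] = (40, 80)
    planted_targets: list[PlantedTarget] = field(default_factory=list)
    planted_offtargets: list[PlantedOffTarget] = field(default_factory=list)
    cancer_types: list[str] = field(default_factory=lambda: ["SKCM", "LAML", "DLBC"])
    essential_tissues: list[str] = field(
        default_factory=lambda: ["brain", "liver", "lung", "heart", "kidney", "skin"]
    )
    non_essential_tissues: list[str] = field(default_factory=lambda: ["testis"])
    samples_per_group: int = 8
    allele: str = "HLA-A*02:01"

    def __post_init__(self):
        for t in self.planted_targets:
            if len(t.peptide) != K or any(c not in STANDARD_AA for c in t.peptide):
                raise FixtureError(f"planted target {t.peptide!r} is not a valid 9-mer")
            if t.cancer_type not in self.cancer_types:
                self.cancer_types.append(t.cancer_type)
        for o in self.planted_offtargets:
            if not 0 <= o.dos <= 9:
                raise FixtureError(f"planted DoS {o.dos} not realizable")
            if o.expressing_tissue not in self.essential_tissues:
                raise FixtureError(
                    f"planted off-target tissue {o.expressing_tissue!r} not essential"
                )
        if any(self.samples_per_group < 1 for _ in (0,)) or self.samples_per_group < 1:
            raise FixtureError("samples_per_group must be >= 1")


def _mutate(peptide: str, n_mut: int, rng: np.random.Generator) -> str:
    """Substitute n_mut distinct positions with different residues."""
    positions = rng.choice(K, size=n_mut, replace=False)
    out = list(peptide)
    for p in positions:
        choices = [c for c in AA if c != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def resolve_offtargets(spec: FixtureSpec) -> list[PlantedOffTarget]:
    """Materialize off-target sequences at their prescribed DoS.

    Off-targets given as None are derived by mutating 9−DoS positions of the
    target; explicit sequences are checked.  All planted peptides must be
    mutually distinct and cross-pairs (a target vs a plant belonging to a
    different target) must stay below DoS 5 so the planted structure is the
    only similarity structure present.
    """
    rng = np.random.default_rng(spec.seed + 1)
    targets = {t.peptide for t in spec.planted_targets}
    resolved: list[PlantedOffTarget] = []
    for j, o in enumerate(spec.planted_offtargets):
        if o.target_peptide not in targets:
            raise FixtureError(f"off-target {j} references unplanted target {o.target_peptide}")
        seq = o.offtarget_peptide
        for _ in range(200):
            if seq is None:
                seq = _mutate(o.target_peptide, 9 - o.dos, rng)
            d, _ = dos(o.target_peptide, seq)
            if d != o.dos:
                raise FixtureError(
                    f"off-target {seq} has DoS {d} to {o.target_peptide}, planted {o.dos}"
                )
            clash = seq in targets or any(r.offtarget_peptide == seq for r in resolved)
            cross = any(
                dos(t, seq)[0] >= 5
                for t in targets if t != o.target_peptide
            )
            if not clash and not cross:
                break
            if o.offtarget_peptide is not None:
                raise FixtureError(f"explicit off-target {seq} collides with another plant")
            seq = None
        else:
            raise FixtureError("could not realize planted off-target without collision")
        resolved.append(PlantedOffTarget(o.target_peptide, seq, o.dos,
                                         o.expressing_tissue, o.gene, o.ic50_nM))
    return resolved


def _assign_genes(spec: FixtureSpec, offtargets: list[PlantedOffTarget]) -> None:
    for i, t in enumerate(spec.planted_targets, 1):
        if not t.gene:
            t.gene = f"TGT{i}"
    for j, o in enumerate(offtargets, 1):
        if not o.gene:
            o.gene = f"OFT{j}"


def gen_proteome(spec: FixtureSpec) -> tuple[ProteinSet, list[PlantedOffTarget]]:
    """Random-background proteome with every planted peptide embedded.

    Each planted target and off-target peptide sits verbatim inside its own
    dedicated protein/gene.  Background proteins are re-drawn if any of
    their 9-mers reaches DoS >= 5 with a planted target, so planted
    similarity is the only similarity in the fixture.
    """
    rng = np.random.default_rng(spec.seed)
    offtargets = resolve_offtargets(spec)
    _assign_genes(spec, offtargets)
    records: list[ProteinRecord] = []
    targets = [t.peptide for t in spec.planted_targets]

    def chars(n: int) -> str:
        return "".join(rng.choice(list(AA), size=n)) if n else ""

    def embed(peptide: str, accession: str, gene: str) -> ProteinRecord:
        # redraw flanks until no *accidental* window reaches DoS 5 with a
        # planted target (the embedded peptide's own window is exempt)
        lo, hi = spec.protein_length_range
        for _ in range(100):
            flank = max(0, (int(rng.integers(lo, hi + 1)) - K) // 2)
            seq = chars(flank) + peptide + chars(flank)
            windows = [seq[s: s + K] for s in range(len(seq) - K + 1)]
            if all(w == peptide or all(dos(w, t)[0] < 5 for t in targets)
                   for w in windows):
                return ProteinRecord(accession, gene, seq)
        raise FixtureError(f"could not embed {peptide} clear of accidental similarity")

    for i, t in enumerate(spec.planted_targets, 1):
        records.append(embed(t.peptide, f"SYN_T{i}", t.gene))
    for j, o in enumerate(offtargets, 1):
        records.append(embed(o.offtarget_peptide, f"SYN_O{j}", o.gene))
    for b in range(1, spec.n_background_proteins + 1):
        for _ in range(100):
            lo, hi = spec.protein_length_range
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(list(AA), size=length))
            windows = [seq[s: s + K] for s in range(len(seq) - K + 1)]
            if all(dos(w, t)[0] < 5 for w in windows for t in targets):
                break
        else:
            raise FixtureError("could not draw a background protein clear of the plants")
        records.append(ProteinRecord(f"SYN_B{b}", f"BG{b}", seq))
    return ProteinSet(records), offtargets


def gen_affinity(
    spec: FixtureSpec, protein_set: ProteinSet, offtargets: list[PlantedOffTarget]
) -> AffinityTable:
    """Mock affinity table: planted peptides bind, background does not.

    Planted targets and off-targets receive their prescribed IC50 (< 500 nM);
    every other proteome 9-mer gets a deterministic non-binding value in
    [600, 40600) nM so the binder gate isolates the planted structure.
    """
    index = extract_9mers(protein_set)
    overrides = {t.peptide: t.ic50_nM for t in spec.planted_targets}
    overrides.update({o.offtarget_peptide: o.ic50_nM for o in offtargets})
    records = {
        pep: AffinityRecord.make(
            pep, spec.allele,
            overrides.get(pep, 600.0 + mock_affinity(pep, spec.allele, spec.seed) * 0.8),
        )
        for pep in index.peptides
    }
    return AffinityTable(spec.allele, records)


def gen_expression(
    spec: FixtureSpec, offtargets: list[PlantedOffTarget], n_background_genes: int = 10
) -> tuple[pd.DataFrame, list[SampleMeta]]:
    """RPKM matrix + metadata realizing the planted expression guarantees.

    Target genes: tumor p75 > 5 in their cancer type, all normal p75/p95
    < 0.5.  Off-target genes: p95 > 0.5 in their essential tissue, low
    elsewhere.  Background genes: log-normal noise verified to be neither
    cancer-specific nor accidentally similar to a plant's guarantee profile.
    Guarantees are re-checked by running the actual classification rules and
    violating genes are re-drawn (bounded retries).
    """
    rng = np.random.default_rng(spec.seed + 2)
    _assign_genes(spec, offtargets)
    groups: list[tuple[str, bool, bool]] = []  # (group, is_cancer, is_essential)
    groups += [(c, True, False) for c in spec.cancer_types]
    groups += [(t, False, True) for t in spec.essential_tissues]
    groups += [(t, False, False) for t in spec.non_essential_tissues]
    samples: list[SampleMeta] = []
    for g, is_cancer, is_ess in groups:
        source = "synthetic"
        for k in range(spec.samples_per_group):
            samples.append(SampleMeta(f"{g}_s{k}", source, g, is_cancer, is_ess))
    n = len(samples)
    col_group = [s.group for s in samples]

    def draw_row(kind: str, home: str | None) -> np.ndarray:
        row = np.empty(n)
        for idx, g in enumerate(col_group):
            if kind == "target":
                if g == home:
                    row[idx] = rng.uniform(8.0, 30.0)
                else:
                    row[idx] = rng.uniform(0.0, 0.1)
            elif kind == "offtarget":
                if g == home:
                    row[idx] = rng.uniform(1.0, 10.0)
                else:
                    row[idx] = rng.uniform(0.0, 0.1)
            else:
                row[idx] = rng.lognormal(mean=-1.0, sigma=1.0)
        return row

    gene_rows: dict[str, np.ndarray] = {}
    plan: list[tuple[str, str, str | None]] = []
    for t in spec.planted_targets:
        plan.append((t.gene, "target", t.cancer_type))
    for o in offtargets:
        plan.append((o.gene, "offtarget", o.expressing_tissue))
    for b in range(1, n_background_genes + 1):
        plan.append((f"BG{b}", "background", None))

    sample_ids = [s.sample_id for s in samples]
    for gene, kind, home in plan:
        for _ in range(100):
            row = draw_row(kind, home)
            mat = pd.DataFrame([row], index=[gene], columns=sample_ids)
            summ = summarize(mat, samples)
            if kind == "target":
                ok = is_cancer_specific({gene}, home, summ) and not offtarget_expressed({gene}, summ)
            elif kind == "offtarget":
                ok = offtarget_expressed({gene}, summ) and not any(
                    is_cancer_specific({gene}, c, summ) for c in spec.cancer_types
                )
            else:
                ok = not any(is_cancer_specific({gene}, c, summ) for c in spec.cancer_types)
            if ok:
                gene_rows[gene] = row
                break
        else:
            raise FixtureError(f"could not realize expression guarantee for {gene}")
    matrix = pd.DataFrame(gene_rows, index=sample_ids).T
    matrix.index.name = "gene"
    return matrix, samples


# ---------------------------------------------------------------------------
# toy structures


def build_pdb(atoms: list[tuple[str, int, str, str, str, tuple[float, float, float]]]) -> str:
    """Format (chain, resseq, resname, name, element, xyz) rows as PDB text."""
    lines = []
    for serial, (chain, resseq, resname, name, element, (x, y, z)) in enumerate(atoms, 1):
        aname = name if len(name) >= 4 else f" {name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {aname:<4s}{'':1s}{resname:>3s} {chain:1s}"
            f"{resseq:4d}{'':1s}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


#: Contact distance realizing a 0.2 Å vdW gap between two carbons.
_CONTACT_DIST = 2 * 1.70 + 0.2


def gen_toy_structure(
    pattern, seed: int = 0, structure_id: str = "TOY"
) -> tuple[str, dict]:
    """Minimal 3-chain PDB realizing a prescribed 9-position contact pattern.

    The peptide chain P holds 9 alanine-like residues spaced 10 Å apart with
    a CB pseudo side chain; probe carbons of the partner chain T sit at a
    0.2 Å vdW gap from the CB of exactly the pattern's important positions
    and > 8 Å from everything else; chain H is an inert far-away HLA
    stand-in.  ``contact_pattern`` on the result returns *pattern* exactly.
    Returns (pdb_text, chain_manifest).
    """
    pattern = tuple(bool(v) for v in pattern)
    if len(pattern) != 9:
        raise FixtureError("pattern must have length 9")
    atoms = []
    for i in range(9):
        x = 10.0 * (i + 1)
        atoms += [
            ("P", i + 1, "ALA", "N", "N", (x - 1.2, -1.0, 0.0)),
            ("P", i + 1, "ALA", "CA", "C", (x, 0.0, 0.0)),
            ("P", i + 1, "ALA", "C", "C", (x + 1.2, -1.0, 0.0)),
            ("P", i + 1, "ALA", "O", "O", (x + 1.2, -2.2, 0.0)),
            ("P", i + 1, "ALA", "CB", "C", (x, 1.5, 0.0)),
        ]
    # inert HLA stand-in, far from peptide and probes
    for j, x in enumerate((0.0, 25.0, 50.0, 75.0)):
        atoms.append(("H", j + 1, "GLY", "CA", "C", (x, -25.0, 0.0)))
    # partner probes at the planted gap; plus a distant anchor so the chain
    # exists even for the all-false pattern
    res = 1
    for i, on in enumerate(pattern):
        if on:
            x = 10.0 * (i + 1)
            atoms.append(("T", res, "UNK", "C1", "C", (x, 1.5 + _CONTACT_DIST, 0.0)))
            res += 1
    atoms.append(("T", res, "UNK", "C1", "C", (-20.0, 30.0, 0.0)))
    manifest = {"peptide_chain": "P", "hla_chains": ["H"], "partner_chains": ["T"]}
    _ = seed  # geometry is deterministic; seed kept for interface stability
    return build_pdb(atoms), manifest


# ---------------------------------------------------------------------------
# on-disk fixture sets


def write_fixture_set(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write FASTA, manifest, affinity, expression, metadata and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteins, offtargets = gen_proteome(spec)
    with open(out / "proteome.fasta", "w") as fh:
        for rec in proteins:
            fh.write(f">{rec.accession} {rec.gene_symbol}\n{rec.sequence}\n")
    man = pd.DataFrame(
        [(r.accession, r.gene_symbol, "", "", "") for r in proteins],
        columns=["accession", "gene_symbol", "is_hla_variant", "allele_name", "is_lincRNA"],
    )
    man.to_csv(out / "manifest.tsv", sep="\t", index=False)

    table = gen_affinity(spec, proteins, offtargets)
    from .affinity import write_affinity_table
    write_affinity_table(table, out / "affinity.tsv")

    matrix, samples = gen_expression(spec, offtargets)
    matrix.to_csv(out / "expression.tsv", sep="\t")
    pd.DataFrame(
        [(s.sample_id, s.source, s.group, int(s.is_cancer), int(s.is_essential))
         for s in samples],
        columns=["sample_id", "source", "group", "is_cancer", "is_essential"],
    ).to_csv(out / "meta.tsv", sep="\t", index=False)

    truth = {
        "seed": spec.seed,
        "allele": spec.allele,
        "targets": [
            {"peptide": t.peptide, "cancer_type": t.cancer_type,
             "gene": t.gene, "ic50_nM": t.ic50_nM}
            for t in spec.planted_targets
        ],
        "offtargets": [
            {"target": o.target_peptide, "offtarget": o.offtarget_peptide,
             "dos": o.dos, "tissue": o.expressing_tissue, "gene": o.gene,
             "ic50_nM": o.ic50_nM}
            for o in offtargets
        ],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
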