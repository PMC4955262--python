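"""Contact patterns from peptide–HLA–TCR/antibody structures and their ROC.

Crystal structures of 9-mer/HLA-A*02:01/TCR (or TCR-like antibody) complexes
tell us which of the 9 peptide positions actually touch the therapeutic
molecule.  A position is *important* when it makes a hydrophobic contact
(van der Waals gap between a side-chain atom and any partner atom within
[0.0, 0.4] Å) or a hydrogen bond (donor–acceptor distance < 4 Å; when
explicit hydrogens are present, additionally a near-linear D–H–A geometry)
with the TCR/antibody.  Each structure yields a 9-bit contact pattern;
voting over the unique patterns gives a sequence-agnostic importance
predictor, validated by leave-one-out ROC.

Note on the angle criterion: the conventional "angle less than 30°" for a
hydrogen bond is implemented as deviation from linearity, i.e. the D–H–A
angle must be at least 150° — a literal D–H–A < 30° is geometrically
impossible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)


class StructureError(ValueError):
    pass


#: Comparisons against configured cutoffs snap to this tolerance so that a
#: distance specified exactly at a boundary behaves per the boundary rule
#: regardless of binary representation of the coordinates.
GEOM_EPS = 1e-9


#: Bondi-style van der Waals radii (Å).  Overridable via GeometryConfig.
DEFAULT_VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "ZN": 1.39, "MG": 1.73, "CA": 2.31, "NA": 2.27, "K": 2.75, "FE": 2.00,
}

#: Peptide backbone atom names excluded from hydrophobic-contact detection.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"})


@dataclass(frozen=True)
class GeometryConfig:
    """Geometric cutoffs for contact, hydrogen-bond and clash detection."""

    vdw_gap_min: float = 0.0        # Å, signed gap d - r1 - r2, inclusive
    vdw_gap_max: float = 0.4        # Å, inclusive
    hbond_da_max: float = 4.0       # Å, donor-acceptor distance, strict <
    hbond_angle_dev_max: float = 30.0  # degrees off linear D-H-A, inclusive
    clash_overlap: float = 0.6      # Å, strict > to flag a clash
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))

    def radius(self, element: str) -> float:
        try:
            return self.vdw_radii[element.upper()]
        except KeyError:
            raise StructureError(f"no van der Waals radius for element {element!r}")


@dataclass(frozen=True)
class Atom:
    chain: str
    residue_index: int   # 1..9 within the peptide chain; author seq id otherwise
    residue_name: str
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass
class ComplexStructure:
    structure_id: str
    atoms: list[Atom]
    peptide_chain: str
    hla_chains: set[str]
    partner_chains: set[str]

    @property
    def has_hydrogens(self) -> bool:
        return any(a.element == "H" for a in self.atoms)

    def chain_atoms(self, chains: set[str] | str) -> list[Atom]:
        if isinstance(chains, str):
            chains = {chains}
        return [a for a in self.atoms if a.chain in chains]


def parse_structure(
    file: str | Path,
    chain_manifest: dict[str, object] | None = None,
    structure_id: str | None = None,
) -> ComplexStructure:
    """Load a PDB/mmCIF complex and resolve chain roles.

    *chain_manifest* maps ``peptide_chain`` to a chain id and ``hla_chains``/
    ``partner_chains`` to iterables of chain ids.  Without a manifest the
    unique chain with exactly 9 residues becomes the peptide (ambiguity is an
    error), the longest remaining chain the HLA, and the rest the partner.
    The peptide chain must have exactly 9 residues; peptide residues are
    renumbered 1..9 in chain order.
    """
    st = gemmi.read_structure(str(file))
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"no models in {file}")
    model = st[0]
    sid = structure_id or st.name or Path(str(file)).stem

    chain_residues = {ch.name: len(ch) for ch in model}
    if chain_manifest:
        pep_chain = str(chain_manifest["peptide_chain"])
        hla = {str(c) for c in chain_manifest.get("hla_chains", ())}
        partner = {str(c) for c in chain_manifest.get("partner_chains", ())}
        if not partner:
            partner = set(chain_residues) - {pep_chain} - hla
    else:
        nine = [name for name, n in chain_residues.items() if n == 9]
        if len(nine) != 1:
            raise StructureError(
                f"{sid}: cannot auto-detect peptide chain "
                f"({len(nine)} chains with 9 residues); provide a manifest"
            )
        pep_chain = nine[0]
        others = sorted(
            (n for n in chain_residues if n != pep_chain),
            key=lambda n: -chain_residues[n],
        )
        hla = {others[0]} if others else set()
        partner = set(others[1:])
    if pep_chain not in chain_residues:
        raise StructureError(f"{sid}: peptide chain {pep_chain!r} not in structure")
    if chain_residues[pep_chain] != 9:
        raise StructureError(
            f"{sid}: peptide chain {pep_chain!r} has {chain_residues[pep_chain]} "
            "residues, expected 9"
        )

    atoms: list[Atom] = []
    for ch in model:
        for ridx, res in enumerate(ch, start=1):
            res_index = ridx if ch.name == pep_chain else res.seqid.num
            for at in res:
                elem = at.element.name.upper() if at.element else ""
                if not elem:
                    raise StructureError(f"{sid}: unknown element for atom {at.name} "
                                         f"in {ch.name}/{res.name}{res.seqid.num}")
                pos = at.pos
                atoms.append(Atom(ch.name, res_index, res.name, at.name, elem,
                                  (pos.x, pos.y, pos.z)))
    return ComplexStructure(sid, atoms, pep_chain, hla, partner)


def _dist(a: Atom, b: Atom) -> float:
    return math.dist(a.xyz, b.xyz)


def hydrophobic_contact_positions(
    struct: ComplexStructure, cfg: GeometryConfig = GeometryConfig()
) -> set[int]:
    """Peptide positions whose side chains make a vdW contact with the partner.

    A contact is a signed gap d − r(a) − r(b) within [vdw_gap_min,
    vdw_gap_max] between a peptide side-chain atom and *any* atom of a
    partner (TCR/antibody) chain.  HLA-chain atoms never count as partners;
    peptide backbone atoms are excluded.
    """
    partner = struct.chain_atoms(struct.partner_chains)
    positions: set[int] = set()
    for a in struct.chain_atoms(struct.peptide_chain):
        if a.name in BACKBONE_ATOMS or a.residue_index in positions:
            continue
        ra = cfg.radius(a.element)
        for b in partner:
            gap = _dist(a, b) - ra - cfg.radius(b.element)
            if cfg.vdw_gap_min - GEOM_EPS <= gap <= cfg.vdw_gap_max + GEOM_EPS:
                positions.add(a.residue_index)
                break
    return positions


def _attached_hydrogens(owner: Atom, pool: list[Atom], max_bond: float = 1.3) -> list[Atom]:
    return [h for h in pool
            if h.element == "H" and h.chain == owner.chain
            and h.residue_index == owner.residue_index and _dist(h, owner) < max_bond]


def _angle_deviation(d: Atom, h: Atom, a: Atom) -> float:
    """Deviation of the D-H-A angle from linearity, degrees."""
    v1 = np.subtract(d.xyz, h.xyz)
    v2 = np.subtract(a.xyz, h.xyz)
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    return 180.0 - angle


def hydrogen_bond_positions(
    struct: ComplexStructure, cfg: GeometryConfig = GeometryConfig()
) -> set[int]:
    """Peptide positions hydrogen-bonded to a partner chain.

    Donors and acceptors are N/O atoms.  A pair qualifies when the
    donor–acceptor distance is below ``hbond_da_max`` (strict) and, in
    structures that contain explicit hydrogens, some hydrogen attached to
    either pair atom lies within ``hbond_angle_dev_max`` of D–H–A linearity.
    Crystal structures usually lack hydrogens, in which case the distance
    criterion alone decides — no hydrogen placement is invented.
    """
    pep = [a for a in struct.chain_atoms(struct.peptide_chain) if a.element in ("N", "O")]
    partner = [a for a in struct.chain_atoms(struct.partner_chains)
               if a.element in ("N", "O")]
    use_angle = struct.has_hydrogens
    all_atoms = struct.atoms
    positions: set[int] = set()
    for a in pep:
        if a.residue_index in positions:
            continue
        for b in partner:
            if not _dist(a, b) < cfg.hbond_da_max - GEOM_EPS:
                continue
            if not use_angle:
                positions.add(a.residue_index)
                break
            ok = False
            for donor, acceptor in ((a, b), (b, a)):
                for h in _attached_hydrogens(donor, all_atoms):
                    if _angle_deviation(donor, h, acceptor) <= cfg.hbond_angle_dev_max:
                        ok = True
                        break
                if ok:
                    break
            if ok:
                positions.add(a.residue_index)
                break
    return positions


@dataclass(frozen=True)
class ContactPattern:
    """Per-structure 9-position importance vector."""

    structure_id: str
    important: tuple[bool, ...]

    def __post_init__(self):
        if len(self.important) != 9:
            raise StructureError("contact pattern must have length 9")

    @property
    def important_positions(self) -> frozenset[int]:
        return frozenset(i + 1 for i, v in enumerate(self.important) if v)


def contact_pattern(
    struct: ComplexStructure, cfg: GeometryConfig = GeometryConfig()
) -> ContactPattern:
    """important[i] = hydrophobic contact OR hydrogen bond at position i+1."""
    hydro = hydrophobic_contact_positions(struct, cfg)
    hbond = hydrogen_bond_positions(struct, cfg)
    marked = hydro | hbond
    return ContactPattern(struct.structure_id,
                          tuple((i + 1) in marked for i in range(9)))


def unique_patterns(patterns: list[ContactPattern]) -> dict[tuple[bool, ...], list[str]]:
    """Deduplicate patterns by vector; provenance structure ids retained."""
    if not patterns:
        raise StructureError("no patterns to deduplicate")
    out: dict[tuple[bool, ...], list[str]] = {}
    for p in patterns:
        out.setdefault(p.important, []).append(p.structure_id)
    return out


@dataclass(frozen=True)
class ImportanceProfile:
    peptide: str
    important_positions: frozenset[int]
    method: str
    vote_threshold: int


def vote_importance(
    patterns: list[tuple[bool, ...]] | dict[tuple[bool, ...], list[str]],
    vote_threshold: int = 2,
    peptide: str = "",
    method: str = "simple",
) -> ImportanceProfile:
    """Vote positional importance over unique contact patterns.

    Position i is non-important iff fewer than *vote_threshold* patterns mark
    it important; important otherwise.  The production default threshold of 2
    trades sensitivity for a zero false-positive rate on known complexes.
    """
    if isinstance(patterns, dict):
        patterns = list(patterns)
    if vote_threshold < 0:
        raise StructureError("vote_threshold must be >= 0")
    counts = [sum(p[i] for p in patterns) for i in range(9)]
    important = frozenset(i + 1 for i in range(9) if counts[i] >= vote_threshold)
    return ImportanceProfile(peptide, important, method, vote_threshold)


def detect_clashes(
    struct: ComplexStructure, cfg: GeometryConfig = GeometryConfig()
) -> bool:
    """True iff any inter-chain atom pair overlaps by more than clash_overlap."""
    by_chain: dict[str, list[Atom]] = {}
    for a in struct.atoms:
        by_chain.setdefault(a.chain, []).append(a)
    chains = sorted(by_chain)
    for i, c1 in enumerate(chains):
        for c2 in chains[i + 1:]:
            for a in by_chain[c1]:
                ra = cfg.radius(a.element)
                for b in by_chain[c2]:
                    if _dist(a, b) < ra + cfg.radius(b.element) - cfg.clash_overlap - GEOM_EPS:
                        return True
    return False


@dataclass
class RocResult:
    """Pooled leave-one-out ROC: per-threshold confusion counts and AUC."""

    thresholds: list[int]
    points: list[dict]   # threshold, TP, FP, TN, FN, TPR, FPR
    auc: float
    #: pooled per-position (vote count, truth-is-non-important) pairs
    scores: list[tuple[int, bool]] = field(default_factory=list)


def loo_roc(
    patterns: list[ContactPattern],
    predictor_kind: str = "simple",
    thresholds: list[int] | None = None,
    modeled: dict[str, list[ContactPattern]] | None = None,
) -> RocResult:
    """Leave-one-out ROC of the positional-importance predictor.

    For each held-out complex the remaining complexes' unique patterns (or,
    for the modeling-based predictor, the supplied pre-modeled structures for
    that complex) vote on each of its 9 positions.  The positive class is
    *non-important*: a position is predicted non-important at threshold t
    when fewer than t patterns mark it important.  Confusion counts are
    pooled over all held-out positions; the curve is swept over t and the
    AUC computed by the trapezoidal rule with (0,0) and (1,1) appended.
    """
    if len(patterns) < 2:
        raise StructureError("leave-one-out needs at least 2 complexes")
    if predictor_kind not in ("simple", "modeling"):
        raise StructureError(f"unknown predictor kind {predictor_kind!r}")
    if predictor_kind == "modeling" and modeled is None:
        raise StructureError("modeling predictor requires pre-modeled structures")

    # votes per held-out position, with its truth label (True = non-important)
    pairs: list[tuple[int, bool]] = []
    max_votes = 0
    for held in patterns:
        if predictor_kind == "simple":
            rest = [p for p in patterns if p.structure_id != held.structure_id]
            train = list(unique_patterns(rest))
        else:
            mod = modeled.get(held.structure_id, [])
            train = list(unique_patterns(mod)) if mod else []
        if not train:
            logger.warning("no training patterns for %s; skipped", held.structure_id)
            continue
        counts = [sum(p[i] for p in train) for i in range(9)]
        max_votes = max(max_votes, *counts)
        for i in range(9):
            pairs.append((counts[i], not held.important[i]))

    n_pos = sum(1 for _, truth in pairs if truth)
    n_neg = len(pairs) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise StructureError("AUC undefined: a truth class is absent from the pooled positions")

    if thresholds is None:
        thresholds = list(range(0, max_votes + 2))
    points = []
    for t in thresholds:
        tp = sum(1 for v, truth in pairs if v < t and truth)
        fp = sum(1 for v, truth in pairs if v < t and not truth)
        fn = n_pos - tp
        tn = n_neg - fp
        points.append({
            "threshold": t, "TP": tp, "FP": fp, "TN": tn, "FN": fn,
            "TPR": tp / n_pos, "FPR": fp / n_neg,
        })
    curve = sorted({(p["FPR"], p["TPR"]) for p in points} | {(0.0, 0.0), (1.0, 1.0)})
    auc = float(np.trapezoid([y for _, y in curve], [x for x, _ in curve]))
    return RocResult(list(thresholds), points, auc, pairs)


def transform_structure(struct: ComplexStructure, rotation, translation) -> ComplexStructure:
    """Apply a rigid motion (3x3 rotation + translation) to every atom."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    atoms = [replace(a, xyz=tuple(R @ np.asarray(a.xyz) + t)) for a in struct.atoms]
    return replace(struct, atoms=atoms)
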