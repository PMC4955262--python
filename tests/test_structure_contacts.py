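import math

import numpy as np
import pytest
from scipy.stats import rankdata

from pepthla.structure_contacts import (Atom, ComplexStructure, ContactPattern,
                                        GeometryConfig, StructureError,
                                        contact_pattern, detect_clashes,
                                        hydrogen_bond_positions,
                                        hydrophobic_contact_positions, loo_roc,
                                        parse_structure, transform_structure,
                                        unique_patterns, vote_importance)
from pepthla.synthetic import build_pdb, gen_toy_structure

CC_CONTACT = 2 * 1.70  # two carbon vdW radii


def peptide_backbone(i):
    """ALA-like residue i (1-based) of the toy geometry."""
    x = 10.0 * i
    return [
        Atom("P", i, "ALA", "N", "N", (x - 1.2, -1.0, 0.0)),
        Atom("P", i, "ALA", "CA", "C", (x, 0.0, 0.0)),
        Atom("P", i, "ALA", "C", "C", (x + 1.2, -1.0, 0.0)),
        Atom("P", i, "ALA", "O", "O", (x + 1.2, -2.2, 0.0)),
        Atom("P", i, "ALA", "CB", "C", (x, 1.5, 0.0)),
    ]


def toy_struct(extra_partner_atoms, structure_id="T"):
    atoms = [a for i in range(1, 10) for a in peptide_backbone(i)]
    atoms.append(Atom("H", 1, "GLY", "CA", "C", (0.0, -30.0, 0.0)))
    atoms += extra_partner_atoms
    return ComplexStructure(structure_id, atoms, "P", {"H"}, {"T"})


def probe(i, gap, element="C", name="C1", res=1):
    """Partner atom at the given vdW gap above residue i's CB."""
    r = GeometryConfig().radius(element)
    return Atom("T", res, "UNK", name, element, (10.0 * i, 1.5 + 1.70 + r + gap, 0.0))


class TestHydrophobicContacts:
    def test_gap_inside_window_detected(self):
        s = toy_struct([probe(3, 0.2)])
        assert hydrophobic_contact_positions(s) == {3}

    @pytest.mark.parametrize("gap, expected", [
        (0.0, {4}), (0.4, {4}),     # inclusive bounds
        (0.41, set()), (-0.05, set()), (5.0, set()),
    ])
    def test_gap_boundaries(self, gap, expected):
        s = toy_struct([probe(4, gap)])
        assert hydrophobic_contact_positions(s) == expected

    def test_backbone_contact_does_not_count(self):
        # probe at perfect gap from residue 5's backbone O only
        o = Atom("T", 1, "UNK", "C1", "C",
                 (10.0 * 5 + 1.2, -2.2 - (1.70 + 1.52 + 0.2), 0.0))
        assert hydrophobic_contact_positions(toy_struct([o])) == set()

    def test_hla_chain_atoms_never_count(self):
        s = toy_struct([])
        s.atoms.append(Atom("H", 2, "GLY", "CA", "C", (10.0 * 2, 1.5 + CC_CONTACT + 0.2, 0.0)))
        assert hydrophobic_contact_positions(s) == set()

    def test_missing_radius_is_config_error(self):
        s = toy_struct([probe(3, 0.2)])
        with pytest.raises(StructureError):
            hydrophobic_contact_positions(s, GeometryConfig(vdw_radii={"N": 1.55}))


def hb_probe(i, da_dist, element="N"):
    """Partner donor/acceptor below residue i's backbone O."""
    return Atom("T", 1, "UNK", "N1", element, (10.0 * i + 1.2, -2.2 - da_dist, 0.0))


class TestHydrogenBonds:
    def test_distance_only_without_hydrogens(self):
        assert hydrogen_bond_positions(toy_struct([hb_probe(3, 3.0)])) == {3}
        assert hydrogen_bond_positions(toy_struct([hb_probe(3, 4.5)])) == set()
        # strict cutoff: D-A exactly 4.0 is out
        assert hydrogen_bond_positions(toy_struct([hb_probe(3, 4.0)])) == set()

    def test_carbon_partner_is_not_a_donor_or_acceptor(self):
        assert hydrogen_bond_positions(toy_struct([hb_probe(3, 3.0, element="C")])) == set()

    @pytest.mark.parametrize("theta_deg, included", [(0.0, True), (45.0, False)])
    def test_angle_criterion_with_explicit_hydrogen(self, theta_deg, included):
        # donor N on the partner, H attached at 1.0 A; theta tilts the D-H
        # direction away from the acceptor axis, growing the D-H-A deviation
        donor = hb_probe(3, 3.0)
        dx, dy, dz = donor.xyz
        th = math.radians(theta_deg)
        h = Atom("T", 1, "UNK", "H1", "H",
                 (dx + math.sin(th), dy + math.cos(th), dz))
        s = toy_struct([donor, h])
        assert s.has_hydrogens
        got = hydrogen_bond_positions(s)
        assert got == ({3} if included else set())


class TestClashes:
    def two_atom_struct(self, dist):
        # partner carbon at `dist` from residue 1's CA, approaching along +z
        # so no other peptide atom comes near
        atoms = [a for i in range(1, 10) for a in peptide_backbone(i)]
        atoms.append(Atom("H", 1, "GLY", "CA", "C", (0.0, -30.0, 0.0)))
        atoms.append(Atom("T", 1, "UNK", "C1", "C", (10.0, 0.0, dist)))
        return ComplexStructure("c", atoms, "P", {"H"}, {"T"})

    def test_deep_overlap_is_clash(self):
        assert detect_clashes(self.two_atom_struct(1.0))  # overlap 2.4 > 0.6

    def test_boundary_overlap_is_not_clash(self):
        assert not detect_clashes(self.two_atom_struct(CC_CONTACT - 0.6))
        assert detect_clashes(self.two_atom_struct(CC_CONTACT - 0.61))

    def test_well_separated_toy_is_clash_free(self):
        pdb, man = gen_toy_structure([1] * 9)
        assert not detect_clashes(_parse(pdb, man))


def _parse(pdb_text, manifest, tmp_name="s.pdb", tmp_path=None, sid="S"):
    import tempfile
    from pathlib import Path
    with tempfile.TemporaryDirectory() as d:
        p = Path(d) / tmp_name
        p.write_text(pdb_text)
        return parse_structure(p, manifest, structure_id=sid)


class TestParseStructure:
    def test_roundtrip_with_manifest(self):
        pdb, man = gen_toy_structure([0, 1, 0, 0, 1, 0, 1, 0, 0])
        s = _parse(pdb, man)
        assert s.peptide_chain == "P"
        assert s.partner_chains == {"T"}
        assert contact_pattern(s).important_positions == {2, 5, 7}

    def test_autodetect_unique_9mer_chain(self):
        pdb, _ = gen_toy_structure([1, 0, 0, 0, 0, 0, 0, 0, 0])
        s = _parse(pdb, None)
        assert s.peptide_chain == "P"

    def test_wrong_peptide_length_rejected(self):
        atoms = [(("P", i, "ALA", "CA", "C", (4.0 * i, 0, 0))) for i in range(1, 8)]
        atoms += [("T", 1, "UNK", "C1", "C", (0, 30, 0))]
        with pytest.raises(StructureError, match="9"):
            _parse(build_pdb(atoms), {"peptide_chain": "P", "hla_chains": [],
                                      "partner_chains": ["T"]})

    def test_two_9mer_chains_without_manifest_ambiguous(self):
        atoms = [("A", i, "ALA", "CA", "C", (4.0 * i, 0, 0)) for i in range(1, 10)]
        atoms += [("B", i, "ALA", "CA", "C", (4.0 * i, 20, 0)) for i in range(1, 10)]
        with pytest.raises(StructureError, match="auto-detect"):
            _parse(build_pdb(atoms), None)


class TestPatternsAndVoting:
    def test_pattern_is_union_of_contact_kinds(self):
        s = toy_struct([probe(3, 0.2), hb_probe(5, 3.0)])
        assert contact_pattern(s).important_positions == {3, 5}

    def test_unique_patterns_dedup_with_provenance(self):
        a = ContactPattern("s1", (True,) + (False,) * 8)
        b = ContactPattern("s2", (True,) + (False,) * 8)
        c = ContactPattern("s3", (False,) * 9)
        uniq = unique_patterns([a, b, c])
        assert len(uniq) == 2
        assert uniq[a.important] == ["s1", "s2"]
        with pytest.raises(StructureError):
            unique_patterns([])

    def test_vote_thresholds(self):
        pats = [(True,) + (False,) * 8, (True,) * 9, (False,) * 9]
        assert vote_importance(pats, 0).important_positions == frozenset(range(1, 10))
        assert vote_importance(pats, 4).important_positions == frozenset()
        assert vote_importance(pats, 2).important_positions == {1}

    def test_vote_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        pats = [tuple(rng.random(9) < 0.5) for _ in range(7)]
        prev = vote_importance(pats, 0).important_positions
        for t in range(1, 9):
            cur = vote_importance(pats, t).important_positions
            assert cur <= prev
            prev = cur


class TestRigidMotionInvariance:
    def test_patterns_and_clashes_unchanged(self):
        rng = np.random.default_rng(3)
        pdb, man = gen_toy_structure(tuple(rng.random(9) < 0.5))
        s = _parse(pdb, man)
        # random rotation via QR; proper rotation enforced
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = transform_structure(s, q, [12.0, -7.0, 3.0])
        assert contact_pattern(moved).important == contact_pattern(s).important
        assert detect_clashes(moved) == detect_clashes(s)


def mw_auc(scores, labels):
    """Mann-Whitney AUC with tie correction (rank-statistic oracle)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    ranks = rankdata(scores)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


class TestLooRoc:
    def random_patterns(self, rng, n, p=0.5):
        return [ContactPattern(f"s{i}", tuple(rng.random(9) < p)) for i in range(n)]

    def test_truth_telling_predictor_scores_1(self):
        rng = np.random.default_rng(4)
        pats = self.random_patterns(rng, 12)
        modeled = {p.structure_id: [ContactPattern(p.structure_id + "m", p.important)]
                   for p in pats}
        roc = loo_roc(pats, "modeling", modeled=modeled)
        assert roc.auc == pytest.approx(1.0, abs=1e-12)

    def test_auc_matches_rank_statistic_oracle(self):
        rng = np.random.default_rng(5)
        pats = self.random_patterns(rng, 15)
        roc = loo_roc(pats, "simple")
        votes = np.array([v for v, _ in roc.scores])
        truth = np.array([t for _, t in roc.scores])
        assert roc.auc == pytest.approx(mw_auc(-votes, truth), abs=1e-9)

    def test_degenerate_truth_class_raises(self):
        pats = [ContactPattern(f"s{i}", (True,) * 9) for i in range(3)]
        with pytest.raises(StructureError, match="AUC undefined"):
            loo_roc(pats, "simple")

    def test_uninformed_predictor_is_chance_level(self):
        rng = np.random.default_rng(6)
        pats = self.random_patterns(rng, 40)
        modeled = {p.structure_id: self.random_patterns(rng, 5) for p in pats}
        roc = loo_roc(pats, "modeling", modeled=modeled)
        assert roc.auc == pytest.approx(0.5, abs=0.07)
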