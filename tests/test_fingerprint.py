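"""Geometric contact operators on planted toy complexes."""

import itertools

import numpy as np
import pytest

from compskit import fingerprint as fp
from compskit import synthetic


@pytest.fixture(scope="module")
def toy_complex(tmp_path_factory):
    """Planted complex: 2 H-bonds, 1 hydrophobic contact, 1 bridging water."""
    path = tmp_path_factory.mktemp("toy") / "complex.pdb"
    spec = synthetic.ToyComplexSpec(n_hbonds=2, n_hydrophobic=1, n_bridges=1)
    _, manifest = synthetic.gen_toy_complex(spec, out_path=path)
    return path, manifest


@pytest.fixture(scope="module")
def toy_model(toy_complex):
    path, _ = toy_complex
    return fp.parse_structure(path, "L")[0]


def hbond_key(hb):
    return frozenset(
        [(hb.donor.residue, hb.donor.atom_name), (hb.acceptor.residue, hb.acceptor.atom_name)]
    )


def contact_key(hc):
    return frozenset(
        [(hc.atom_a.residue, hc.atom_a.atom_name), (hc.atom_b.residue, hc.atom_b.atom_name)]
    )


def brute_force_hbonds(s, criteria):
    """Exhaustive all-pairs evaluation, independent of the neighbor-search
    implementation path."""
    donor, acceptor = s.donor_acceptor_masks()
    excluded = s.excluded_pairs()
    coords = s.coord
    res_key = [(str(c), int(r)) for c, r in zip(s.atoms.chain_id, s.atoms.res_id)]
    found = set()
    n = len(s)
    for i in range(n):
        for j in range(i + 1, n):
            if res_key[i] == res_key[j] or frozenset((i, j)) in excluded:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d > criteria.hbond_distance:
                continue
            if (donor[i] and acceptor[j]) or (donor[j] and acceptor[i]):
                found.add(frozenset((i, j)))
    return found


def brute_force_hydrophobic(s, criteria):
    apolar = s.apolar_mask(criteria)
    excluded = s.excluded_pairs()
    coords = s.coord
    res_key = [(str(c), int(r)) for c, r in zip(s.atoms.chain_id, s.atoms.res_id)]
    found = set()
    idx = np.flatnonzero(apolar)
    for i, j in itertools.combinations(idx, 2):
        i, j = int(i), int(j)
        if res_key[i] == res_key[j] or frozenset((i, j)) in excluded:
            continue
        if np.linalg.norm(coords[i] - coords[j]) <= criteria.hydrophobic_distance:
            found.add(frozenset((i, j)))
    return found


class TestParseStructure:
    def test_single_model(self, toy_complex):
        path, manifest = toy_complex
        frames = fp.parse_structure(path, manifest["ligand_chain"])
        assert len(frames) == 1
        assert len(frames[0].ligand_residues()) == 4  # 2 SER + 1 ALA + 1 SER

    def test_multi_model(self, tmp_path):
        spec = synthetic.ToyComplexSpec(n_hbonds=1, n_models=3)
        path = tmp_path / "multi.pdb"
        synthetic.gen_toy_complex(spec, out_path=path)
        frames = fp.parse_structure(path, "L")
        assert len(frames) == 3
        assert [f.model_index for f in frames] == [0, 1, 2]

    def test_missing_ligand_chain_rejected(self, toy_complex):
        path, _ = toy_complex
        with pytest.raises(fp.EmptySelectionError):
            fp.parse_structure(path, "Z")


class TestDetectors:
    def test_planted_hbonds_found(self, toy_model, toy_complex):
        _, manifest = toy_complex
        inter = [h for h in fp.detect_hbonds(toy_model) if h.kind == "inter"]
        planted = [p for p in manifest["plants"] if p["kind"] == "hbond"]
        assert len(inter) == len(planted)
        for hb in inter:
            assert hb.distance == pytest.approx(2.9, abs=0.05)

    def test_hbond_beyond_cutoff_ignored(self, toy_model):
        tight = fp.InteractionCriteria(hbond_distance=2.5)
        assert [h for h in fp.detect_hbonds(toy_model, tight) if h.kind == "inter"] == []

    def test_planted_hydrophobic_found(self, toy_model):
        inter = [c for c in fp.detect_hydrophobic(toy_model) if c.kind == "inter"]
        assert len(inter) == 1
        assert inter[0].distance == pytest.approx(3.8, abs=0.05)

    def test_hydrophobic_beyond_cutoff_ignored(self, toy_model):
        tight = fp.InteractionCriteria(hydrophobic_distance=3.0)
        assert [
            c for c in fp.detect_hydrophobic(toy_model, tight) if c.kind == "inter"
        ] == []

    def test_bridging_water_found(self, toy_model, toy_complex):
        _, manifest = toy_complex
        bridges = fp.bridge_waters(toy_model)
        assert len(bridges) == 1
        bw = bridges[0]
        assert bw.ligand_legs and bw.target_legs

    def test_water_near_single_partner_excluded(self, tmp_path):
        # without the target-side group in reach, the water has one leg only
        spec = synthetic.ToyComplexSpec(
            n_hbonds=1, n_hydrophobic=0, n_bridges=1, n_models=2,
            absent_frames={"bridge_0": (1,)},
        )
        path = tmp_path / "b.pdb"
        synthetic.gen_toy_complex(spec, out_path=path)
        frames = fp.parse_structure(path, "L")
        assert len(fp.bridge_waters(frames[0])) == 1
        assert len(fp.bridge_waters(frames[1])) == 0


class TestOracleAndInvariances:
    def test_brute_force_equivalence(self, toy_model):
        """Neighbor-search detectors equal an exhaustive all-pairs scan."""
        criteria = fp.InteractionCriteria()
        got_hb = {
            frozenset((h.donor.index, h.acceptor.index))
            for h in fp.detect_hbonds(toy_model, criteria)
        }
        assert got_hb == brute_force_hbonds(toy_model, criteria)
        got_hc = {
            frozenset((c.atom_a.index, c.atom_b.index))
            for c in fp.detect_hydrophobic(toy_model, criteria)
        }
        assert got_hc == brute_force_hydrophobic(toy_model, criteria)

    def test_atom_order_permutation_invariance(self, toy_model):
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(toy_model))
        shuffled = fp.StructureModel(toy_model.atoms[perm], ["L"])
        for detect, key in (
            (fp.detect_hbonds, hbond_key),
            (fp.detect_hydrophobic, contact_key),
        ):
            assert {key(x) for x in detect(toy_model)} == {
                key(x) for x in detect(shuffled)
            }

    def test_cutoff_monotonicity(self, toy_model):
        """Enlarging cutoffs never removes a reported contact."""
        small = fp.InteractionCriteria(hbond_distance=3.0, hydrophobic_distance=4.0)
        large = fp.InteractionCriteria(hbond_distance=3.5, hydrophobic_distance=5.0)
        hb_small = {hbond_key(h) for h in fp.detect_hbonds(toy_model, small)}
        hb_large = {hbond_key(h) for h in fp.detect_hbonds(toy_model, large)}
        assert hb_small <= hb_large
        hc_small = {contact_key(c) for c in fp.detect_hydrophobic(toy_model, small)}
        hc_large = {contact_key(c) for c in fp.detect_hydrophobic(toy_model, large)}
        assert hc_small <= hc_large


class TestResidueFingerprints:
    def test_counts_localized_to_planted_residues(self, toy_complex):
        path, manifest = toy_complex
        fps = fp.residue_fingerprints(fp.parse_structure(path, "L"))
        by_id = {f.res_id: f for f in fps}
        for plant in manifest["plants"]:
            f = by_id[plant["ligand_res"]]
            if plant["kind"] == "hbond":
                assert f.inter_hbonds == 1 and f.inter_hydrophobic == 0
            elif plant["kind"] == "hydrophobic":
                assert f.inter_hydrophobic == 1 and f.inter_hbonds == 0
            else:  # bridge: water-mediated only, no direct contact
                assert f.total_inter == 0

    def test_contactless_residues(self, toy_complex):
        path, manifest = toy_complex
        fps = fp.residue_fingerprints(fp.parse_structure(path, "L"))
        bridge_res = [
            p["ligand_res"] for p in manifest["plants"] if p["kind"] == "bridge"
        ]
        assert [rid for rid, _ in fp.contactless_residues(fps)] == bridge_res

    def test_occupancy_is_exact_frame_fraction(self, tmp_path):
        spec = synthetic.ToyComplexSpec(
            n_hbonds=1, n_hydrophobic=1, n_models=4,
            absent_frames={"hbond_0": (1, 3)},
        )
        path = tmp_path / "frames.pdb"
        synthetic.gen_toy_complex(spec, out_path=path)
        fps = fp.residue_fingerprints(fp.parse_structure(path, "L"))
        by_id = {f.res_id: f for f in fps}
        assert by_id[1].occupancy == 0.5       # present in 2 of 4 frames
        assert by_id[1].inter_hbonds == 0.5    # mean count over frames
        assert by_id[2].occupancy == 1.0

    def test_partner_lists(self, toy_complex):
        path, manifest = toy_complex
        fps = fp.residue_fingerprints(fp.parse_structure(path, "L"))
        by_id = {f.res_id: f for f in fps}
        hb0 = manifest["plants"][0]
        partners = by_id[hb0["ligand_res"]].partners
        assert ("A", hb0["target_res"], "ASN") in partners


class TestDifferentialFingerprint:
    def _fingerprints(self, tmp_path, n_hbonds):
        spec = synthetic.ToyComplexSpec(n_hbonds=n_hbonds, n_hydrophobic=0)
        path = tmp_path / f"c{n_hbonds}.pdb"
        synthetic.gen_toy_complex(spec, out_path=path)
        return fp.residue_fingerprints(fp.parse_structure(path, "L"))

    def test_identical_inputs_empty_difference(self, tmp_path):
        a = self._fingerprints(tmp_path, 2)
        diff = fp.differential_fingerprint(a, a)
        assert all(not g and not l for g, l in zip(diff["gained"], diff["lost"]))

    def test_gained_contact_and_antisymmetry(self, tmp_path):
        a = self._fingerprints(tmp_path, 1)
        b = self._fingerprints(tmp_path, 2)
        ab = fp.differential_fingerprint(a, b)
        ba = fp.differential_fingerprint(b, a)
        row_ab = ab[ab.position == 1].iloc[0]
        row_ba = ba[ba.position == 1].iloc[0]
        assert row_ab["gained"] == row_ba["lost"]
        assert row_ab["lost"] == row_ba["gained"]

    def test_unmapped_positions_reported(self, tmp_path):
        a = self._fingerprints(tmp_path, 2)
        b = self._fingerprints(tmp_path, 1)
        diff = fp.differential_fingerprint(a, b)
        assert (diff[diff.position == 2]["status"] == "unmapped").all()


class TestCriteriaValidation:
    def test_bad_distance(self):
        with pytest.raises(ValueError):
            fp.InteractionCriteria(hbond_distance=-1.0)

    def test_bad_angle(self):
        with pytest.raises(ValueError):
            fp.InteractionCriteria(hbond_angle=270.0)
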