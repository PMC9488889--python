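"""Geometric interaction fingerprints of protein-peptide complexes.

Per-residue tallies of hydrogen bonds and hydrophobic contacts, within the
bound peptide (intramolecular) and between peptide and target protein
(intermolecular), plus detection of bridging waters that are simultaneously
hydrogen-bonded to both molecules.  Multi-model coordinate files are treated
as frame series and aggregated into mean counts and occupancies.

Default geometric criteria are community-standard fingerprint values:
hydrogen bond = donor/acceptor heavy atoms within 3.5 A (and D-H...A angle
>= 120 deg when explicit hydrogens are present); hydrophobic contact = two
apolar heavy atoms within 4.5 A, where an apolar atom is a carbon or sulfur
not covalently bonded to nitrogen or oxygen (bonds inferred from covalent
radii).  Donor/acceptor chemistry for hydrogen-free crystal structures comes
from a fixed residue-template table covering the 20 standard amino acids,
water, and the nonstandard residues of the compstatin peptides (D-Tyr,
1-methyl-Trp, sarcosine, N-methyl-Ile).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

import biotite.structure as struc
from biotite.structure.io import pdb as pdb_io
from biotite.structure.io import pdbx as pdbx_io

__all__ = [
    "InteractionCriteria",
    "StructureModel",
    "AtomRef",
    "HBond",
    "HydrophobicContact",
    "BridgingWater",
    "ResidueFingerprint",
    "parse_structure",
    "detect_hbonds",
    "detect_hydrophobic",
    "bridge_waters",
    "residue_fingerprints",
    "contactless_residues",
    "differential_fingerprint",
    "fingerprints_to_frame",
]

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# residues whose backbone amide nitrogen carries no hydrogen
_N_METHYLATED = {"PRO", "SAR", "IML", "MLE", "MVA", "MLZ", "HYP"}

# side-chain donor (D) / acceptor (A) heavy atoms per residue template
_SIDECHAIN_TABLE: dict[str, dict[str, str]] = {
    "SER": {"OG": "DA"},
    "THR": {"OG1": "DA"},
    "TYR": {"OH": "DA"},
    "ASN": {"ND2": "D", "OD1": "A"},
    "GLN": {"NE2": "D", "OE1": "A"},
    "ASP": {"OD1": "A", "OD2": "A"},
    "GLU": {"OE1": "A", "OE2": "A"},
    "LYS": {"NZ": "D"},
    "ARG": {"NE": "D", "NH1": "D", "NH2": "D"},
    "HIS": {"ND1": "DA", "NE2": "DA"},
    "TRP": {"NE1": "D"},
    # compstatin nonstandard residues
    "DTY": {"OH": "DA"},  # D-tyrosine: phenolic OH as in TYR
    "SAR": {},            # sarcosine: no polar side chain
    "IML": {},            # N-methyl isoleucine
    "MTR": {},            # 1-methyl tryptophan: indole NE1 methylated, no donor
    "1MW": {},
    "4IN": {},
    # residues with no polar side-chain heavy atoms
    "GLY": {},
    "ALA": {},
    "VAL": {},
    "LEU": {},
    "ILE": {},
    "PRO": {},
    "PHE": {},
    "MET": {},
    "CYS": {},
}

_COVALENT_RADII = {"C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "H": 0.31, "P": 1.07}
_BOND_TOLERANCE = 0.45


class EmptySelectionError(ValueError):
    """Raised when a chain selection matches no atoms."""


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric cutoffs of the fingerprint operators."""

    hbond_distance: float = 3.5   # donor-acceptor heavy-atom distance, A
    hbond_angle: float = 120.0    # minimum D-H...A angle, degrees
    hydrophobic_distance: float = 4.5  # apolar heavy-atom distance, A
    strict_apolar: bool = True    # exclude C/S bonded to N or O

    def __post_init__(self) -> None:
        if self.hbond_distance <= 0 or self.hydrophobic_distance <= 0:
            raise ValueError("distance cutoffs must be positive")
        if not 0 < self.hbond_angle <= 180:
            raise ValueError("angle cutoff must lie in (0, 180]")


@dataclass(frozen=True)
class AtomRef:
    """Identity of one atom in author numbering."""

    chain: str
    res_name: str
    res_id: int
    atom_name: str
    index: int

    @property
    def residue(self) -> tuple[str, int, str]:
        return (self.chain, self.res_id, self.res_name)


@dataclass(frozen=True)
class HBond:
    donor: AtomRef
    acceptor: AtomRef
    distance: float
    kind: str  # inter | intra_ligand | intra_target | water_leg | other


@dataclass(frozen=True)
class HydrophobicContact:
    atom_a: AtomRef
    atom_b: AtomRef
    distance: float
    kind: str


@dataclass(frozen=True)
class BridgingWater:
    water: AtomRef
    ligand_legs: tuple[HBond, ...]
    target_legs: tuple[HBond, ...]


@dataclass(frozen=True)
class ResidueFingerprint:
    """Aggregated interaction counts of one ligand residue (frame means)."""

    res_id: int
    res_name: str
    inter_hbonds: float
    intra_hbonds: float
    inter_hydrophobic: float
    intra_hydrophobic: float
    partners: frozenset[tuple[str, int, str]]
    occupancy: float
    n_frames: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")

    @property
    def total_inter(self) -> float:
        return self.inter_hbonds + self.inter_hydrophobic


class StructureModel:
    """One coordinate frame with ligand / target / water role labels."""

    def __init__(
        self,
        atoms: struc.AtomArray,
        ligand_chains: Sequence[str],
        target_chains: Sequence[str] | None = None,
        model_index: int = 0,
    ) -> None:
        if not np.all(np.isfinite(atoms.coord)):
            raise ValueError("coordinates must be finite")
        self.atoms = atoms
        self.model_index = model_index
        self.ligand_chains = tuple(ligand_chains)
        chain = atoms.chain_id
        water = np.isin(atoms.res_name, list(WATER_NAMES))
        ligand = np.isin(chain, list(self.ligand_chains)) & ~water
        if target_chains is None:
            target = ~ligand & ~water
        else:
            target = np.isin(chain, list(target_chains)) & ~ligand & ~water
        if not ligand.any():
            raise EmptySelectionError(
                f"no ligand atoms in chains {self.ligand_chains}"
            )
        self.role = np.full(atoms.array_length(), "other", dtype="<U6")
        self.role[target] = "target"
        self.role[ligand] = "ligand"
        self.role[water] = "water"
        self._bond_adjacency: list[set[int]] | None = None

    # -- convenience accessors ------------------------------------------------

    def __len__(self) -> int:
        return self.atoms.array_length()

    @property
    def coord(self) -> np.ndarray:
        return self.atoms.coord

    def ref(self, i: int) -> AtomRef:
        a = self.atoms
        return AtomRef(
            chain=str(a.chain_id[i]),
            res_name=str(a.res_name[i]),
            res_id=int(a.res_id[i]),
            atom_name=str(a.atom_name[i]),
            index=i,
        )

    def ligand_residues(self) -> list[tuple[int, str]]:
        mask = self.role == "ligand"
        out: list[tuple[int, str]] = []
        for rid, rname in zip(self.atoms.res_id[mask], self.atoms.res_name[mask]):
            key = (int(rid), str(rname))
            if key not in out:
                out.append(key)
        return out

    # -- chemistry ------------------------------------------------------------

    def bond_adjacency(self) -> list[set[int]]:
        """Covalent-bond adjacency inferred from covalent radii."""
        if self._bond_adjacency is not None:
            return self._bond_adjacency
        n = len(self)
        adj: list[set[int]] = [set() for _ in range(n)]
        coords = self.coord
        elements = np.asarray(
            [e if e in _COVALENT_RADII else "C" for e in self.atoms.element]
        )
        radii = np.array([_COVALENT_RADII[e] for e in elements])
        max_bond = 2.0 * radii.max() + _BOND_TOLERANCE
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(max_bond):
            limit = radii[i] + radii[j] + _BOND_TOLERANCE
            if np.linalg.norm(coords[i] - coords[j]) <= limit:
                adj[i].add(j)
                adj[j].add(i)
        self._bond_adjacency = adj
        return adj

    def excluded_pairs(self) -> set[frozenset[int]]:
        """Atom pairs separated by <= 2 covalent bonds (1-2 and 1-3)."""
        adj = self.bond_adjacency()
        excluded: set[frozenset[int]] = set()
        for i, neighbors in enumerate(adj):
            for j in neighbors:
                excluded.add(frozenset((i, j)))
                for k in adj[j]:
                    if k != i:
                        excluded.add(frozenset((i, k)))
        return excluded

    def donor_acceptor_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Heavy-atom donor/acceptor flags from the residue template table.

        Residues missing from the table fall back to an element heuristic
        (N and O both treated as donor and acceptor), which is the safe
        assumption for hydrogen-free structures of unknown chemistry.
        """
        a = self.atoms
        n = len(self)
        donor = np.zeros(n, dtype=bool)
        acceptor = np.zeros(n, dtype=bool)
        for i in range(n):
            el = a.element[i]
            if el not in ("N", "O"):
                continue
            res = str(a.res_name[i])
            name = str(a.atom_name[i])
            if res in WATER_NAMES:
                donor[i] = acceptor[i] = True
                continue
            # backbone
            if name == "N":
                donor[i] = res not in _N_METHYLATED
                continue
            if name in ("O", "OXT"):
                acceptor[i] = True
                continue
            table = _SIDECHAIN_TABLE.get(res)
            if table is None:
                donor[i] = acceptor[i] = True  # unknown residue fallback
                continue
            flags = table.get(name, "")
            donor[i] = "D" in flags
            acceptor[i] = "A" in flags
        return donor, acceptor

    def apolar_mask(self, criteria: InteractionCriteria) -> np.ndarray:
        """Apolar heavy atoms: C or S, optionally excluding those covalently
        bonded to N or O."""
        a = self.atoms
        mask = np.isin(a.element, ["C", "S"])
        if criteria.strict_apolar:
            adj = self.bond_adjacency()
            for i in np.flatnonzero(mask):
                if any(a.element[j] in ("N", "O") for j in adj[i]):
                    mask[i] = False
        return mask

    def hydrogens_of(self, i: int) -> list[int]:
        return [j for j in self.bond_adjacency()[i] if self.atoms.element[j] == "H"]

    def has_hydrogens(self) -> bool:
        return bool(np.any(self.atoms.element == "H"))


def parse_structure(
    path: str | Path,
    ligand_chains: str | Sequence[str],
    target_chains: Sequence[str] | None = None,
) -> list[StructureModel]:
    """Read a PDB or mmCIF file into one :class:`StructureModel` per model.

    ``ligand_chains`` selects the peptide; remaining non-water chains are the
    target unless ``target_chains`` narrows them.  Author residue numbering
    is preserved.
    """
    path = Path(path)
    if isinstance(ligand_chains, str):
        ligand_chains = [ligand_chains]
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif", ".pdbx"):
        cif = pdbx_io.CIFFile.read(str(path))
        stack = pdbx_io.get_structure(cif, model=None)
    else:
        pdbf = pdb_io.PDBFile.read(str(path))
        stack = pdbf.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        frames = [stack]
    else:
        frames = [stack[i] for i in range(stack.stack_depth())]
    return [
        StructureModel(frame, ligand_chains, target_chains, model_index=k)
        for k, frame in enumerate(frames)
    ]


# ---------------------------------------------------------------------------
# contact operators


def _pair_kind(role_a: str, role_b: str) -> str:
    roles = {role_a, role_b}
    if roles == {"ligand", "target"}:
        return "inter"
    if roles == {"ligand"}:
        return "intra_ligand"
    if roles == {"target"}:
        return "intra_target"
    if "water" in roles:
        return "water_leg"
    return "other"


def _hbond_angle_ok(
    s: StructureModel, donor: int, acceptor: int, min_angle: float
) -> bool:
    """True when some hydrogen on the donor satisfies the D-H...A angle."""
    hydrogens = s.hydrogens_of(donor)
    if not hydrogens:
        return True  # heavy-atom-only donor: distance criterion governs
    coords = s.coord
    best = 0.0
    for h in hydrogens:
        dh = coords[donor] - coords[h]
        ah = coords[acceptor] - coords[h]
        denom = np.linalg.norm(dh) * np.linalg.norm(ah)
        if denom == 0:
            continue
        cosang = np.clip(np.dot(dh, ah) / denom, -1.0, 1.0)
        best = max(best, float(np.degrees(np.arccos(cosang))))
    return best >= min_angle


def detect_hbonds(
    s: StructureModel,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> list[HBond]:
    """Hydrogen bonds: donor and acceptor heavy atoms within the distance
    cutoff, different residues, not covalently related (bond path > 2); with
    explicit hydrogens the D-H...A angle must exceed the angle cutoff."""
    donor_mask, acceptor_mask = s.donor_acceptor_masks()
    polar = np.flatnonzero(donor_mask | acceptor_mask)
    if polar.size == 0:
        return []
    coords = s.coord
    tree = cKDTree(coords[polar])
    excluded = s.excluded_pairs()
    res_key = [
        (str(c), int(r)) for c, r in zip(s.atoms.chain_id, s.atoms.res_id)
    ]
    check_angles = s.has_hydrogens()
    bonds: list[HBond] = []
    seen: set[tuple[int, int]] = set()
    for a, b in tree.query_pairs(criteria.hbond_distance):
        i, j = int(polar[a]), int(polar[b])
        if res_key[i] == res_key[j]:
            continue
        if frozenset((i, j)) in excluded:
            continue
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        # one bond per atom pair; when both directions are chemically valid
        # (e.g. hydroxyl-hydroxyl) the lower-index donor is reported
        for don, acc in ((i, j), (j, i)):
            if not (donor_mask[don] and acceptor_mask[acc]):
                continue
            if frozenset((don, acc)) in seen:
                break
            if check_angles and not _hbond_angle_ok(
                s, don, acc, criteria.hbond_angle
            ):
                continue
            seen.add(frozenset((don, acc)))
            bonds.append(
                HBond(
                    donor=s.ref(don),
                    acceptor=s.ref(acc),
                    distance=dist,
                    kind=_pair_kind(s.role[don], s.role[acc]),
                )
            )
            break
    bonds.sort(key=lambda h: (h.donor.index, h.acceptor.index))
    return bonds


def detect_hydrophobic(
    s: StructureModel,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> list[HydrophobicContact]:
    """Hydrophobic contacts: pairs of apolar heavy atoms within the cutoff,
    different residues, deduplicated per atom pair."""
    apolar = np.flatnonzero(s.apolar_mask(criteria))
    if apolar.size == 0:
        return []
    coords = s.coord
    tree = cKDTree(coords[apolar])
    excluded = s.excluded_pairs()
    res_key = [
        (str(c), int(r)) for c, r in zip(s.atoms.chain_id, s.atoms.res_id)
    ]
    contacts: list[HydrophobicContact] = []
    for a, b in tree.query_pairs(criteria.hydrophobic_distance):
        i, j = sorted((int(apolar[a]), int(apolar[b])))
        if res_key[i] == res_key[j]:
            continue
        if frozenset((i, j)) in excluded:
            continue
        contacts.append(
            HydrophobicContact(
                atom_a=s.ref(i),
                atom_b=s.ref(j),
                distance=float(np.linalg.norm(coords[i] - coords[j])),
                kind=_pair_kind(s.role[i], s.role[j]),
            )
        )
    contacts.sort(key=lambda c: (c.atom_a.index, c.atom_b.index))
    return contacts


def bridge_waters(
    s: StructureModel,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> list[BridgingWater]:
    """Waters hydrogen-bonded simultaneously to at least one ligand polar
    atom and one target polar atom.  Returns an empty list when the structure
    has no waters."""
    hbonds = detect_hbonds(s, criteria)
    legs: dict[int, dict[str, list[HBond]]] = {}
    for hb in hbonds:
        if hb.kind != "water_leg":
            continue
        for water_side, partner_side in ((hb.donor, hb.acceptor), (hb.acceptor, hb.donor)):
            if s.role[water_side.index] == "water":
                partner_role = s.role[partner_side.index]
                if partner_role in ("ligand", "target"):
                    entry = legs.setdefault(
                        water_side.index, {"ligand": [], "target": []}
                    )
                    entry[partner_role].append(hb)
    out = []
    for widx in sorted(legs):
        entry = legs[widx]
        if entry["ligand"] and entry["target"]:
            out.append(
                BridgingWater(
                    water=s.ref(widx),
                    ligand_legs=tuple(entry["ligand"]),
                    target_legs=tuple(entry["target"]),
                )
            )
    return out


def residue_fingerprints(
    frames: StructureModel | Sequence[StructureModel],
    criteria: InteractionCriteria = InteractionCriteria(),
) -> list[ResidueFingerprint]:
    """Per-ligand-residue interaction profile.

    For a frame series the counts are means over frames and ``occupancy`` is
    the exact fraction of frames in which the residue makes at least one
    intermolecular contact.
    """
    if isinstance(frames, StructureModel):
        frames = [frames]
    if not frames:
        raise ValueError("at least one frame is required")
    residues = frames[0].ligand_residues()
    acc: dict[int, dict[str, float]] = {
        rid: {"ih": 0.0, "ah": 0.0, "ip": 0.0, "ap": 0.0, "frames_with": 0.0}
        for rid, _ in residues
    }
    partners: dict[int, set[tuple[str, int, str]]] = {rid: set() for rid, _ in residues}
    names = {rid: name for rid, name in residues}

    for frame in frames:
        per_res_inter = {rid: 0 for rid, _ in residues}
        for hb in detect_hbonds(frame, criteria):
            for side, other in ((hb.donor, hb.acceptor), (hb.acceptor, hb.donor)):
                if frame.role[side.index] != "ligand":
                    continue
                rid = side.res_id
                if rid not in acc:
                    continue
                if hb.kind == "inter":
                    acc[rid]["ih"] += 1
                    per_res_inter[rid] += 1
                    partners[rid].add(other.residue)
                elif hb.kind == "intra_ligand":
                    acc[rid]["ah"] += 1.0
        for hc in detect_hydrophobic(frame, criteria):
            for side, other in ((hc.atom_a, hc.atom_b), (hc.atom_b, hc.atom_a)):
                if frame.role[side.index] != "ligand":
                    continue
                rid = side.res_id
                if rid not in acc:
                    continue
                if hc.kind == "inter":
                    acc[rid]["ip"] += 1
                    per_res_inter[rid] += 1
                    partners[rid].add(other.residue)
                elif hc.kind == "intra_ligand":
                    acc[rid]["ap"] += 1.0
        for rid, count in per_res_inter.items():
            if count > 0:
                acc[rid]["frames_with"] += 1

    n_frames = len(frames)
    out = []
    for rid, _ in residues:
        rec = acc[rid]
        out.append(
            ResidueFingerprint(
                res_id=rid,
                res_name=names[rid],
                inter_hbonds=rec["ih"] / n_frames,
                intra_hbonds=rec["ah"] / n_frames,
                inter_hydrophobic=rec["ip"] / n_frames,
                intra_hydrophobic=rec["ap"] / n_frames,
                partners=frozenset(partners[rid]),
                occupancy=rec["frames_with"] / n_frames,
                n_frames=n_frames,
            )
        )
    return out


def contactless_residues(fps: Iterable[ResidueFingerprint]) -> list[tuple[int, str]]:
    """Ligand residues with zero intermolecular interactions."""
    return [(fp.res_id, fp.res_name) for fp in fps if fp.total_inter == 0]


def differential_fingerprint(
    a: Sequence[ResidueFingerprint],
    b: Sequence[ResidueFingerprint],
    position_map: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Per-position gained/lost interaction partners between two complexes.

    ``position_map`` maps residue positions of ``a`` onto positions of ``b``
    (identity by default).  Positions that cannot be matched are reported
    with status 'unmapped' rather than dropped.  Swapping the inputs swaps
    the gained and lost sets.
    """
    by_id_a = {fp.res_id: fp for fp in a}
    by_id_b = {fp.res_id: fp for fp in b}
    if position_map is None:
        position_map = {rid: rid for rid in by_id_a}
    rows = []
    for pos_a in sorted(by_id_a):
        pos_b = position_map.get(pos_a)
        fp_a = by_id_a[pos_a]
        if pos_b is None or pos_b not in by_id_b:
            rows.append(
                {
                    "position": pos_a,
                    "gained": frozenset(),
                    "lost": frozenset(),
                    "status": "unmapped",
                }
            )
            continue
        fp_b = by_id_b[pos_b]
        rows.append(
            {
                "position": pos_a,
                "gained": frozenset(fp_b.partners - fp_a.partners),
                "lost": frozenset(fp_a.partners - fp_b.partners),
                "status": "ok",
            }
        )
    return pd.DataFrame(rows, columns=["position", "gained", "lost", "status"])


def fingerprints_to_frame(fps: Sequence[ResidueFingerprint]) -> pd.DataFrame:
    """Tabular form of a fingerprint set, suitable for CSV export."""
    return pd.DataFrame(
        [
            {
                "res_id": fp.res_id,
                "res_name": fp.res_name,
                "inter_hbonds": fp.inter_hbonds,
                "intra_hbonds": fp.intra_hbonds,
                "inter_hydrophobic": fp.inter_hydrophobic,
                "intra_hydrophobic": fp.intra_hydrophobic,
                "occupancy": fp.occupancy,
                "partners": ";".join(
                    f"{c}:{r}{n}" for c, r, n in sorted(fp.partners)
                ),
            }
            for fp in fps
        ]
    )
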