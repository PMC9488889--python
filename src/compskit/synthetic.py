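"""Seeded generators for every input the analysis stages consume.

Each generator emulates the statistical structure its analysis assumes:
single-cycle sensorgrams drawn from the 1:1 model at SAR-table-like rate
constants, mono- and bivalent calorimetric titrations under the standard
protocol (5 uM cell, 50/25 uM syringe, 2 ul injections), small coordinate
files with planted hydrogen bonds / hydrophobic contacts / bridging waters,
and ovalbumin-ELISA-like inhibition plates.  Truth tables are first-class
outputs so tests never re-derive ground truth from generated data; identical
(config, seed) pairs give byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import biotite.structure as struc
from biotite.structure.io import pdb as pdb_io

from . import itc, spr

__all__ = [
    "gen_sensorgram_panel",
    "gen_itc_panel",
    "ToyComplexSpec",
    "InfeasibleGeometryError",
    "gen_toy_complex",
    "gen_elisa_plate",
]


# ---------------------------------------------------------------------------
# SPR sensorgram panel


def gen_sensorgram_panel(
    seed: int,
    compounds: pd.DataFrame | None = None,
    noise_sd: float = 0.5,
    r_max: float = 50.0,
    schedule: spr.InjectionSchedule | None = None,
    outdir: str | Path | None = None,
) -> tuple[dict[str, spr.Sensorgram], pd.DataFrame]:
    """One single-cycle sensorgram per compound plus a truth table.

    ``compounds`` defaults to the replicate-mean SAR reference table; rate
    constants are converted from table units (1e6 M^-1 s^-1 / 1e-3 s^-1).
    """
    if compounds is None:
        compounds = spr.SAR_TABLE[spr.SAR_TABLE["compound"] != "Cp40 (reported)"]
    if schedule is None:
        schedule = spr.InjectionSchedule.single_cycle(dt=5.0)
    rng_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, len(compounds))
    grams: dict[str, spr.Sensorgram] = {}
    truth_rows = []
    for (row, sub_seed) in zip(compounds.itertuples(index=False), rng_seeds):
        k_a = row.ka_1e6 * 1e6
        k_d = row.kdiss_1e3 * 1e-3
        if k_a <= 0 or k_d <= 0:
            raise ValueError(f"compound {row.compound!r} has non-positive rates")
        p = spr.KineticParameters(k_a=k_a, k_d=k_d, r_max=r_max)
        grams[row.compound] = spr.simulate_single_cycle(
            schedule, p, noise_sd=noise_sd, seed=int(sub_seed), compound=row.compound
        )
        truth_rows.append(
            {
                "compound": row.compound,
                "k_a": k_a,
                "k_d": k_d,
                "r_max": r_max,
                "kd_nm": spr.derive_kd(k_a, k_d) * 1e9,
                "noise_sd": noise_sd,
                "seed": int(sub_seed),
            }
        )
    truth = pd.DataFrame(truth_rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, gram in grams.items():
            safe = name.replace(" ", "_").replace("/", "-").replace("(", "").replace(")", "")
            gram.to_csv(outdir / f"sensorgram_{safe}.csv")
        truth.to_csv(outdir / "sensorgram_truth.csv", index=False)
    return grams, truth


# ---------------------------------------------------------------------------
# ITC panel


def gen_itc_panel(
    seed: int,
    kd_m: float = 0.1e-6,
    dh_cal_per_mol: float = -10_000.0,
    noise_sd: float = 0.0,
    outdir: str | Path | None = None,
) -> tuple[dict[str, itc.BindingIsotherm], pd.DataFrame]:
    """Monovalent and bivalent titration scenarios plus a truth table.

    Monovalent: 50 uM titrant, one site per molecule (truth N = 1).
    Bivalent: 25 uM titrant carrying two equivalent entities (so the active-
    entity concentration is the same 50 uM); fitted titrate-normalized
    stoichiometry is 0.5.
    """
    scenarios = {
        "monovalent": dict(syringe=50e-6, sites=1, truth_n=1.0),
        "bivalent": dict(syringe=25e-6, sites=2, truth_n=0.5),
    }
    rng_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, len(scenarios))
    model = itc.ThermoModel(kd_m=kd_m, dh_cal_per_mol=dh_cal_per_mol, n=1.0)
    isos: dict[str, itc.BindingIsotherm] = {}
    truth_rows = []
    for (name, cfg), sub_seed in zip(scenarios.items(), rng_seeds):
        protocol = itc.TitrationProtocol(syringe_conc_m=cfg["syringe"])
        isos[name] = itc.simulate_titration(
            protocol,
            model,
            noise_sd=noise_sd,
            seed=int(sub_seed) if noise_sd > 0 else None,
            sites_per_titrant=cfg["sites"],
        )
        truth_rows.append(
            {
                "scenario": name,
                "n_true": cfg["truth_n"],
                "kd_m": kd_m,
                "dh_cal_per_mol": dh_cal_per_mol,
                "syringe_conc_m": cfg["syringe"],
                "sites_per_titrant": cfg["sites"],
                "noise_sd": noise_sd,
            }
        )
    truth = pd.DataFrame(truth_rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, iso in isos.items():
            iso.to_csv(outdir / f"itc_{name}.csv")
        truth.to_csv(outdir / "itc_truth.csv", index=False)
    return isos, truth


# ---------------------------------------------------------------------------
# toy coordinate files with planted interactions


class InfeasibleGeometryError(ValueError):
    """Raised when a planted-interaction spec cannot satisfy the detection
    criteria plus guard margin."""


@dataclass(frozen=True)
class ToyComplexSpec:
    """Planted-interaction specification for a toy peptide-protein complex.

    Each planted interaction occupies an isolated slot (25 A spacing) so no
    accidental contacts arise; ``absent_frames`` lists, per plant id (e.g.
    'hbond_0'), the model indices in which the interaction is broken by
    displacing the target-side group, enabling occupancy tests.
    """

    n_hbonds: int = 1
    n_hydrophobic: int = 1
    n_bridges: int = 0
    hbond_distance: float = 2.9
    hydrophobic_distance: float = 3.8
    bridge_distance: float = 2.8
    n_models: int = 1
    absent_frames: dict = field(default_factory=dict)
    hbond_cutoff: float = 3.5
    hydrophobic_cutoff: float = 4.5
    guard_margin: float = 0.75


_SLOT_SPACING = 25.0
_MIN_CONTACT = 2.2  # below this the planted pair would be a clash


def _check_feasible(spec: ToyComplexSpec) -> None:
    if not _MIN_CONTACT <= spec.hbond_distance <= spec.hbond_cutoff:
        raise InfeasibleGeometryError(
            f"planted H-bond distance {spec.hbond_distance} outside "
            f"[{_MIN_CONTACT}, {spec.hbond_cutoff}]"
        )
    if not _MIN_CONTACT <= spec.hydrophobic_distance <= spec.hydrophobic_cutoff:
        raise InfeasibleGeometryError(
            f"planted hydrophobic distance {spec.hydrophobic_distance} outside "
            f"[{_MIN_CONTACT}, {spec.hydrophobic_cutoff}]"
        )
    if not _MIN_CONTACT <= spec.bridge_distance <= spec.hbond_cutoff:
        raise InfeasibleGeometryError(
            f"planted bridge distance {spec.bridge_distance} outside "
            f"[{_MIN_CONTACT}, {spec.hbond_cutoff}]"
        )
    # the broken-state displacement (+6 A) must exceed cutoff + guard margin
    if spec.hbond_distance + 6.0 < spec.hbond_cutoff + spec.guard_margin:
        raise InfeasibleGeometryError("guard margin too large for displacement")
    if spec.n_models < 1:
        raise InfeasibleGeometryError("n_models must be >= 1")
    for plant, frames in spec.absent_frames.items():
        if any(f < 0 or f >= spec.n_models for f in frames):
            raise InfeasibleGeometryError(
                f"absent frame index out of range for {plant}"
            )


def _atom(chain, res_id, res_name, name, element, xyz):
    return {
        "chain": chain,
        "res_id": res_id,
        "res_name": res_name,
        "name": name,
        "element": element,
        "xyz": np.asarray(xyz, dtype=float),
    }


def _ser_residue(chain: str, res_id: int, x0: float) -> list[dict]:
    """Serine with the hydroxyl pointing to +y; OG is the planted donor."""
    return [
        _atom(chain, res_id, "SER", "N", "N", (x0, 0.0, 0.0)),
        _atom(chain, res_id, "SER", "CA", "C", (x0 + 1.46, 0.0, 0.0)),
        _atom(chain, res_id, "SER", "CB", "C", (x0 + 1.97, 1.43, 0.0)),
        _atom(chain, res_id, "SER", "OG", "O", (x0 + 1.97, 2.86, 0.0)),
        _atom(chain, res_id, "SER", "C", "C", (x0 + 2.05, -1.25, 0.0)),
        _atom(chain, res_id, "SER", "O", "O", (x0 + 1.55, -2.35, 0.0)),
    ]


def _asn_residue(chain: str, res_id: int, anchor: np.ndarray) -> list[dict]:
    """Asparagine with OD1 placed at ``anchor``, side chain extending +y."""
    ax, ay, az = anchor
    return [
        _atom(chain, res_id, "ASN", "OD1", "O", (ax, ay, az)),
        _atom(chain, res_id, "ASN", "CG", "C", (ax, ay + 1.23, az)),
        _atom(chain, res_id, "ASN", "ND2", "N", (ax + 1.10, ay + 1.95, az)),
        _atom(chain, res_id, "ASN", "CB", "C", (ax - 1.05, ay + 2.15, az)),
        _atom(chain, res_id, "ASN", "CA", "C", (ax - 1.20, ay + 3.62, az)),
        _atom(chain, res_id, "ASN", "N", "N", (ax - 2.52, ay + 4.28, az)),
        _atom(chain, res_id, "ASN", "C", "C", (ax - 0.05, ay + 4.49, az)),
        _atom(chain, res_id, "ASN", "O", "O", (ax - 0.05, ay + 5.72, az)),
    ]


def _ala_residue(chain: str, res_id: int, cb: np.ndarray, flip: bool) -> list[dict]:
    """Alanine with CB placed at ``cb``; the backbone extends away from the
    contact axis (+y when ``flip`` else -y)."""
    s = 1.0 if flip else -1.0
    bx, by, bz = cb
    return [
        _atom(chain, res_id, "ALA", "CB", "C", (bx, by, bz)),
        _atom(chain, res_id, "ALA", "CA", "C", (bx + 0.60, by + s * 1.40, bz)),
        _atom(chain, res_id, "ALA", "N", "N", (bx + 2.02, by + s * 1.85, bz)),
        _atom(chain, res_id, "ALA", "C", "C", (bx - 0.45, by + s * 2.55, bz)),
        _atom(chain, res_id, "ALA", "O", "O", (bx - 0.10, by + s * 3.72, bz)),
    ]


def gen_toy_complex(
    spec: ToyComplexSpec = ToyComplexSpec(),
    out_path: str | Path | None = None,
) -> tuple[str, dict]:
    """Emit a PDB-format toy complex realizing the planted interactions.

    Returns the PDB text and a manifest listing the ground truth (plant ids,
    involved residues, per-frame presence).  Ligand residues are on chain L,
    target residues on chain A, bridging waters on chain W.
    """
    _check_feasible(spec)
    plants: list[dict] = []
    slot = 0

    def frames_present(plant_id: str) -> list[bool]:
        absent = set(spec.absent_frames.get(plant_id, ()))
        return [k not in absent for k in range(spec.n_models)]

    lig_res = 0
    tgt_res = 0
    wat_res = 0
    base_atoms: list[dict] = []   # frame-invariant ligand atoms
    mobile: list[tuple[dict, str]] = []  # (atom, plant_id) target/water atoms

    for i in range(spec.n_hbonds):
        pid = f"hbond_{i}"
        x0 = slot * _SLOT_SPACING
        lig_res += 1
        tgt_res += 1
        ser = _ser_residue("L", lig_res, x0)
        og = ser[3]["xyz"]
        anchor = og + np.array([0.0, spec.hbond_distance, 0.0])
        asn = _asn_residue("A", tgt_res, anchor)
        base_atoms.extend(ser)
        mobile.extend((a, pid) for a in asn)
        plants.append(
            {
                "id": pid,
                "kind": "hbond",
                "ligand_res": lig_res,
                "target_res": tgt_res,
                "distance": spec.hbond_distance,
                "present": frames_present(pid),
            }
        )
        slot += 1

    for i in range(spec.n_hydrophobic):
        pid = f"hydrophobic_{i}"
        x0 = slot * _SLOT_SPACING
        lig_res += 1
        tgt_res += 1
        cb_l = np.array([x0 + 2.0, 1.4, 0.0])
        ala_l = _ala_residue("L", lig_res, cb_l, flip=False)
        cb_t = cb_l + np.array([0.0, spec.hydrophobic_distance, 0.0])
        ala_t = _ala_residue("A", tgt_res, cb_t, flip=True)
        base_atoms.extend(ala_l)
        mobile.extend((a, pid) for a in ala_t)
        plants.append(
            {
                "id": pid,
                "kind": "hydrophobic",
                "ligand_res": lig_res,
                "target_res": tgt_res,
                "distance": spec.hydrophobic_distance,
                "present": frames_present(pid),
            }
        )
        slot += 1

    for i in range(spec.n_bridges):
        pid = f"bridge_{i}"
        x0 = slot * _SLOT_SPACING
        lig_res += 1
        tgt_res += 1
        wat_res += 1
        ser = _ser_residue("L", lig_res, x0)
        og = ser[3]["xyz"]
        gap = spec.hbond_cutoff + 2.0 * spec.guard_margin  # no direct H-bond
        anchor = og + np.array([0.0, gap, 0.0])
        asn = _asn_residue("A", tgt_res, anchor)
        half = gap / 2.0
        h = float(np.sqrt(max(spec.bridge_distance**2 - half**2, 0.04)))
        water = _atom("W", wat_res, "HOH", "O", "O", og + np.array([0.0, half, h]))
        base_atoms.extend(ser)
        mobile.extend((a, pid) for a in asn)
        mobile.append((water, pid))
        plants.append(
            {
                "id": pid,
                "kind": "bridge",
                "ligand_res": lig_res,
                "target_res": tgt_res,
                "water_res": wat_res,
                "distance": spec.bridge_distance,
                "present": frames_present(pid),
            }
        )
        slot += 1

    if not base_atoms:
        raise InfeasibleGeometryError("spec plants no interactions")

    presence = {p["id"]: p["present"] for p in plants}
    frames = []
    for k in range(spec.n_models):
        atoms = struc.AtomArray(len(base_atoms) + len(mobile))
        records = list(base_atoms) + [
            (
                dict(a, xyz=a["xyz"] + np.array([0.0, 6.0, 0.0]))
                if not presence[pid][k]
                else a
            )
            for a, pid in mobile
        ]
        for n, rec in enumerate(records):
            atoms.chain_id[n] = rec["chain"]
            atoms.res_id[n] = rec["res_id"]
            atoms.res_name[n] = rec["res_name"]
            atoms.atom_name[n] = rec["name"]
            atoms.element[n] = rec["element"]
            atoms.coord[n] = rec["xyz"]
            atoms.hetero[n] = rec["res_name"] == "HOH"
        frames.append(atoms)
    stack = struc.stack(frames)

    pdbf = pdb_io.PDBFile()
    pdbf.set_structure(stack if spec.n_models > 1 else frames[0])
    pdb_text = "\n".join(pdbf.lines) + "\n"
    manifest = {
        "n_models": spec.n_models,
        "ligand_chain": "L",
        "target_chain": "A",
        "water_chain": "W",
        "plants": plants,
    }
    if out_path is not None:
        out_path = Path(out_path)
        out_path.write_text(pdb_text)
        out_path.with_suffix(".manifest.json").write_text(
            json.dumps(manifest, indent=1)
        )
    return pdb_text, manifest


# ---------------------------------------------------------------------------
# ELISA plates


def gen_elisa_plate(
    seed: int,
    scenario: str = "responsive",
    concentrations_um: np.ndarray | None = None,
    ic50_um: float = 0.3,
    hill: float = 1.5,
    reference_signal: float = 2.0,
    background: float = 0.2,
    noise_sd: float = 0.02,
    lognormal_noise: bool = False,
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Classical-pathway inhibition plate for one species scenario.

    'responsive' yields a logistic inhibition curve over the 0.04-5 uM
    inhibitor window; 'non-responsive' a flat signal at the no-inhibitor
    reference.  Background and reference wells are included as rows.
    """
    if scenario not in ("responsive", "non-responsive"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if concentrations_um is None:
        concentrations_um = np.round(np.geomspace(0.04, 5.0, 8), 4)
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations_um, dtype=float)
    window = reference_signal - background
    if scenario == "responsive":
        activation = 1.0 / (1.0 + (conc / ic50_um) ** hill)
    else:
        activation = np.ones_like(conc)
    signal = background + window * activation
    if noise_sd > 0:
        if lognormal_noise:
            signal = signal * rng.lognormal(0.0, noise_sd, size=signal.shape)
        else:
            signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    rows = [
        {"well_type": "background", "concentration_um": np.nan, "signal": background},
        {"well_type": "reference", "concentration_um": 0.0, "signal": reference_signal},
    ]
    rows += [
        {"well_type": "sample", "concentration_um": c, "signal": s}
        for c, s in zip(conc, signal)
    ]
    plate = pd.DataFrame(rows, columns=["well_type", "concentration_um", "signal"])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        safe = scenario.replace("-", "_")
        plate.to_csv(outdir / f"elisa_{safe}.csv", index=False)
    return plate
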