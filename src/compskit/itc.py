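"""Isothermal titration calorimetry: single-site isotherms with free
stoichiometry.

The cell holds the titrate (protein, total concentration Mt) and the syringe
the titrant (peptide, A0).  For a single-site model with N equivalent sites
per titrate molecule, dissociation constant K_D and molar binding enthalpy
dH, the heat content of the cell at composition (At, Mt) is

    Q = (N Mt dH V0 / 2) * [x - sqrt(x^2 - 4 At / (N Mt))],
    x = 1 + At/(N Mt) + K_D/(N Mt),

the root of the mass-action quadratic.  Stoichiometry N is parameterized as
sites per titrate molecule so that a bivalent titrant (two active entities
per molecule, e.g. two peptide units bridged by PEG) fits with N = 0.5: an
isotherm generated by two equivalent entities per titrant at molar
concentration A is algebraically identical to a single-site isotherm with
N -> N/2, K_D -> K_D/2 and dH -> 2 dH in molar titrant units, so the
noiseless recovery of N = 0.5 is exact.

Injections follow the perfusion (overfill/displacement) convention: each
injection of volume dV displaces cell content, so after cumulative injected
volume V the titrate is diluted by exp(-V/V0) and the titrant accumulates to
A0 (1 - exp(-V/V0)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "TitrationProtocol",
    "ThermoModel",
    "BindingIsotherm",
    "IsothermFit",
    "InsufficientCurvatureError",
    "cumulative_heat",
    "injection_compositions",
    "predict_heats",
    "simulate_titration",
    "fit_isotherm",
    "wiseman_c",
]


class InsufficientCurvatureError(ValueError):
    """Raised when an isotherm is statistically flat and cannot constrain
    the binding parameters."""


@dataclass(frozen=True)
class TitrationProtocol:
    """Instrument protocol of one titration.

    Defaults follow the standard small-cell protocol used for the compstatin
    analogs: 5 uM protein in the cell, 50 uM peptide in the syringe, 2 ul
    injections; cell volume 200 ul (instrument-typical).
    """

    cell_volume_l: float = 200e-6
    cell_conc_m: float = 5e-6
    syringe_conc_m: float = 50e-6
    injection_volume_l: float = 2e-6
    n_injections: int = 19
    temperature_k: float = 298.15

    def __post_init__(self) -> None:
        for name in (
            "cell_volume_l",
            "cell_conc_m",
            "syringe_conc_m",
            "injection_volume_l",
            "temperature_k",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_injections < 5:
            raise ValueError("at least 5 injections are required")


@dataclass(frozen=True)
class ThermoModel:
    """Single-site thermodynamic model: K_D (M), dH (cal per mol of bound
    titrant) and stoichiometry N (sites per titrate molecule)."""

    kd_m: float
    dh_cal_per_mol: float
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.kd_m <= 0:
            raise ValueError("K_D must be positive")
        if self.n <= 0:
            raise ValueError("stoichiometry N must be positive")
        if self.dh_cal_per_mol == 0:
            raise ValueError("dH must be non-zero to produce heats")


@dataclass
class BindingIsotherm:
    """Per-injection molar ratio At/Mt and normalized heat (cal per mol of
    injectant).  ``raw_heat_cal`` optionally carries the unnormalized
    per-injection heats for bookkeeping checks."""

    molar_ratio: np.ndarray
    heat_cal_per_mol: np.ndarray
    sigma: np.ndarray | None = None
    raw_heat_cal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        self.heat_cal_per_mol = np.asarray(self.heat_cal_per_mol, dtype=float)
        if self.molar_ratio.shape != self.heat_cal_per_mol.shape:
            raise ValueError("molar_ratio and heats must have equal length")
        if not np.all(np.diff(self.molar_ratio) > 0):
            raise ValueError("molar ratio must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "molar_ratio": self.molar_ratio,
                "heat_cal_per_mol": self.heat_cal_per_mol,
            }
        )
        if self.sigma is not None:
            df["sigma"] = self.sigma
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BindingIsotherm":
        df = pd.read_csv(path)
        missing = {"molar_ratio", "heat_cal_per_mol"} - set(df.columns)
        if missing:
            raise ValueError(f"isotherm CSV missing columns: {sorted(missing)}")
        sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
        return cls(
            df["molar_ratio"].to_numpy(),
            df["heat_cal_per_mol"].to_numpy(),
            sigma=sigma,
        )


@dataclass(frozen=True)
class IsothermFit:
    """Fitted single-site model with standard errors and diagnostics."""

    model: ThermoModel
    offset_cal_per_mol: float
    stderr: dict[str, float | None]
    c_value: float
    residual_norm: float
    converged: bool
    ill_conditioned: bool
    message: str = ""


def wiseman_c(n: float, mt: float, kd: float) -> float:
    """Wiseman c-value N Mt / K_D: curvature index of the isotherm."""
    return n * mt / kd


def cumulative_heat(
    at: float | np.ndarray,
    mt: float | np.ndarray,
    m: ThermoModel,
    v_cell: float,
) -> float | np.ndarray:
    """Total heat content (cal) of a cell at total concentrations (At, Mt).

    Closed form of the single-site mass-action quadratic; the discriminant is
    clamped at zero (with a warning) for numerically extreme inputs, which
    corresponds to the stoichiometric-limit heat.
    """
    at = np.asarray(at, dtype=float)
    mt = np.asarray(mt, dtype=float)
    if np.any(at < 0) or np.any(mt < 0):
        raise ValueError("concentrations must be non-negative")
    sites = m.n * mt
    out = np.zeros(np.broadcast(at, mt).shape)
    pos = sites > 0
    x = np.ones_like(out)
    np.divide(at + m.kd_m, sites, out=x, where=pos)
    x += 1.0
    disc = x * x - np.divide(4.0 * at, sites, out=np.zeros_like(out), where=pos)
    if np.any(disc < -1e-12):
        warnings.warn("binding quadratic discriminant clamped at 0", RuntimeWarning)
    disc = np.clip(disc, 0.0, None)
    bound = 0.5 * sites * (x - np.sqrt(disc))  # complex concentration, M
    out = bound * m.dh_cal_per_mol * v_cell
    return float(out) if out.ndim == 0 else out


def injection_compositions(p: TitrationProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Total (At, Mt) in the cell after each injection, perfusion convention."""
    i = np.arange(1, p.n_injections + 1)
    v_cum = i * p.injection_volume_l
    f = np.exp(-v_cum / p.cell_volume_l)
    mt = p.cell_conc_m * f
    at = p.syringe_conc_m * (1.0 - f)
    return at, mt


def predict_heats(
    p: TitrationProtocol,
    m: ThermoModel,
    sites_per_titrant: int = 1,
    offset_cal_per_mol: float = 0.0,
) -> BindingIsotherm:
    """Noise-free isotherm under protocol ``p``.

    ``sites_per_titrant`` > 1 models a multivalent titrant carrying that many
    equivalent binding entities per molecule (dH applies per bound entity);
    heats remain normalized per mol of titrant *molecules* and the molar
    ratio remains molecular At/Mt, which is what makes a bivalent compound
    read out as N = 0.5.

    The observed per-injection heat corrects for the heat content displaced
    from the working volume during each injection:
    dq_i = Q_i - Q_{i-1} + (dV/V0) (Q_i + Q_{i-1}) / 2.
    """
    if sites_per_titrant < 1:
        raise ValueError("sites_per_titrant must be >= 1")
    at, mt = injection_compositions(p)
    at_entities = at * sites_per_titrant
    q = cumulative_heat(at_entities, mt, m, p.cell_volume_l)
    q_prev = np.concatenate([[0.0], q[:-1]])
    dvr = p.injection_volume_l / p.cell_volume_l
    dq = q - q_prev + dvr * (q + q_prev) / 2.0
    mol_injected = p.syringe_conc_m * p.injection_volume_l
    ndh = dq / mol_injected + offset_cal_per_mol
    return BindingIsotherm(
        molar_ratio=at / mt,
        heat_cal_per_mol=ndh,
        raw_heat_cal=dq,
    )


def simulate_titration(
    p: TitrationProtocol,
    m: ThermoModel,
    noise_sd: float = 0.0,
    seed: int | None = None,
    sites_per_titrant: int = 1,
) -> BindingIsotherm:
    """Simulate an integrated-heat isotherm with seeded i.i.d. Gaussian noise
    (``noise_sd`` in cal per mol of injectant)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    iso = predict_heats(p, m, sites_per_titrant=sites_per_titrant)
    heats = iso.heat_cal_per_mol
    sigma = None
    if noise_sd > 0:
        if seed is None:
            raise ValueError("seed is mandatory when noise_sd > 0")
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
        sigma = np.full_like(heats, noise_sd)
    return BindingIsotherm(
        molar_ratio=iso.molar_ratio,
        heat_cal_per_mol=heats,
        sigma=sigma,
        raw_heat_cal=iso.raw_heat_cal,
    )


def fit_isotherm(
    iso: BindingIsotherm,
    p: TitrationProtocol,
    init: ThermoModel | None = None,
    fit_offset: bool = True,
) -> IsothermFit:
    """Least-squares fit of (N, K_D, dH) plus a constant heat-of-dilution
    offset to an integrated isotherm.

    Raises :class:`InsufficientCurvatureError` when the isotherm is
    statistically flat.  Flags the fit ill-conditioned when the Wiseman
    c-value falls outside [1, 1000].
    """
    heats = iso.heat_cal_per_mol
    if heats.size < 5:
        raise ValueError("at least 5 usable injections are required")
    span = float(np.ptp(heats))
    scale = float(np.median(np.abs(heats))) or 1.0
    sigma = float(np.median(iso.sigma)) if iso.sigma is not None else 0.02 * scale
    if span <= 0 or span < 3.0 * sigma:
        raise InsufficientCurvatureError(
            f"isotherm spans {span:.3g} cal/mol, below 3x the heat "
            f"uncertainty ({sigma:.3g} cal/mol)"
        )

    if init is None:
        dh0 = float(heats[0])
        # inflection: molar ratio where cumulative normalized heat crosses half-total
        csum = np.cumsum(heats - heats[-1])
        half = csum[-1] / 2.0
        idx = int(np.searchsorted(csum, half)) if csum[-1] > 0 else int(
            np.searchsorted(-csum, -half)
        )
        n0 = float(iso.molar_ratio[min(max(idx, 0), heats.size - 1)])
        n0 = min(max(n0, 0.05), 10.0)
        init = ThermoModel(kd_m=p.cell_conc_m / 20.0, dh_cal_per_mol=dh0, n=n0)

    params = lmfit.Parameters()
    params.add("n", value=init.n, min=1e-3, max=100.0)
    params.add("log_kd", value=math.log10(init.kd_m), min=-15.0, max=0.0)
    params.add("dh", value=init.dh_cal_per_mol)
    params.add("offset", value=0.0, vary=fit_offset)

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        model = ThermoModel(
            kd_m=10.0 ** pars["log_kd"].value,
            dh_cal_per_mol=pars["dh"].value if pars["dh"].value != 0 else 1e-12,
            n=pars["n"].value,
        )
        pred = predict_heats(p, model, offset_cal_per_mol=pars["offset"].value)
        return pred.heat_cal_per_mol - heats

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = lmfit.minimize(residual, params, method="leastsq")

    kd_fit = 10.0 ** out.params["log_kd"].value
    model = ThermoModel(
        kd_m=kd_fit,
        dh_cal_per_mol=out.params["dh"].value,
        n=out.params["n"].value,
    )
    c = wiseman_c(model.n, p.cell_conc_m, model.kd_m)
    ill = c < 1.0 or c > 1000.0
    if ill:
        warnings.warn(
            f"Wiseman c-value {c:.3g} outside [1, 1000]: fit ill-conditioned",
            UserWarning,
        )
    stderr: dict[str, float | None] = {
        "n": out.params["n"].stderr,
        "dh": out.params["dh"].stderr,
        "offset": out.params["offset"].stderr if fit_offset else None,
    }
    log_err = out.params["log_kd"].stderr
    stderr["kd"] = kd_fit * math.log(10.0) * log_err if log_err is not None else None
    return IsothermFit(
        model=model,
        offset_cal_per_mol=float(out.params["offset"].value),
        stderr=stderr,
        c_value=float(c),
        residual_norm=float(np.linalg.norm(out.residual)),
        converged=bool(out.success),
        ill_conditioned=bool(ill),
        message=str(out.message),
    )
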