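"""Mechanistic ODE model of the surface convertase SPR assay.

Simulates the multi-phase experiment in which factor B (FB) and factor D
(FD) are injected over surface-bound C3b to assemble the C3 convertase
(C3bBb), followed by injection of the C3 substrate.  Reactions (surface
species in RU-equivalents of C3b sites, solution concentrations constant
within a segment):

    C3b + FB  <-> C3bB            (kon_fb, koff_fb)
    C3bB      -> C3bBb            (k_conv, requires FD in solution)
    C3bBb     -> C3b + Bb(lost)   (k_decay, irreversible convertase decay)
    C3 + C3bBb <-> C3:C3bBb       (kon_c3_convertase, koff_c3_convertase)
    C3 + C3b   <-> C3:C3b         (kon_c3_free, koff_c3_free; weak)
    C3:C3bBb  -> C3bBb + C3b_dep  (k_cat, covalent deposition; active FB only)

A compstatin-class inhibitor binds the shared C3/C3b interface site in rapid
pre-equilibrium with occupancy theta = I / (I + K_D); both C3<->C3b(Bb)
association terms are scaled by (1 - theta)^2 because the interface must be
free on the substrate and on the surface side.  Convertase assembly and
decay involve different sites and are untouched by the inhibitor, which is
exactly the experimentally observed behaviour this model encodes.

No rate constants for these steps are published; the defaults are
ILLUSTRATIVE values chosen to reproduce the qualitative assay phenomenology
(convertase half-life of minutes, strong preference of C3 for convertase-
bound over free C3b).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ConvertaseRates",
    "AssayTimeline",
    "SurfaceTrace",
    "simulate_assay",
    "deposition_delta",
    "deposited_delta",
    "substrate_preference_ratio",
]

# approximate molecular masses, kDa, for RU-weighting of bound species
_MASS = {"C3b": 175.0, "FB": 93.0, "Bb": 60.0, "C3": 185.0}

SPECIES = ("c3b_free", "c3bB", "c3bBb", "c3_c3bBb", "c3_c3b", "deposited")

_WEIGHTS = np.array(
    [
        1.0,                                   # c3b_free
        (_MASS["C3b"] + _MASS["FB"]) / _MASS["C3b"],   # c3bB
        (_MASS["C3b"] + _MASS["Bb"]) / _MASS["C3b"],   # c3bBb
        (_MASS["C3b"] + _MASS["Bb"] + _MASS["C3"]) / _MASS["C3b"],  # c3_c3bBb
        (_MASS["C3b"] + _MASS["C3"]) / _MASS["C3b"],   # c3_c3b
        1.0,                                   # deposited (nascent C3b)
    ]
)


@dataclass(frozen=True)
class ConvertaseRates:
    """Rate constants of the convertase assay model (illustrative defaults).

    ``active`` False models the catalytically dead FB mutant: the convertase
    still assembles and binds C3, but the deposition step is switched off.
    """

    kon_fb: float = 1.0e5        # M^-1 s^-1, FB -> surface C3b
    koff_fb: float = 1.0e-2      # s^-1
    k_conv: float = 0.05         # s^-1, FD-dependent C3bB -> C3bBb
    k_decay: float = 0.005       # s^-1, Bb loss (half-life ~2.3 min)
    kon_c3_convertase: float = 2.0e6   # M^-1 s^-1, C3 -> C3bBb
    koff_c3_convertase: float = 0.1    # s^-1 (K_D 50 nM)
    kon_c3_free: float = 2.0e5   # M^-1 s^-1, C3 -> free C3b
    koff_c3_free: float = 1.0    # s^-1 (K_D 5 uM, weak)
    k_cat: float = 0.05          # s^-1, deposition from C3:C3bBb
    inhibitor_kd: float = 0.5e-9  # M, compstatin-class site
    active: bool = True

    def __post_init__(self) -> None:
        for name in (
            "kon_fb",
            "koff_fb",
            "k_conv",
            "k_decay",
            "kon_c3_convertase",
            "koff_c3_convertase",
            "kon_c3_free",
            "koff_c3_free",
            "k_cat",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.inhibitor_kd <= 0:
            raise ValueError("inhibitor_kd must be positive")


@dataclass(frozen=True)
class AssaySegment:
    """One injection phase: solution composition held constant."""

    duration: float
    fb: float = 0.0
    fd: float = 0.0
    c3: float = 0.0
    inhibitor: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        for name in ("fb", "fd", "c3", "inhibitor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} concentration must be non-negative")


@dataclass(frozen=True)
class AssayTimeline:
    """Ordered injection segments of one assay cycle."""

    segments: tuple[AssaySegment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("timeline needs at least one segment")

    @classmethod
    def standard_assay(
        cls,
        convertase: bool = True,
        inhibitor: float = 0.0,
        fb_fd_nm: float = 100.0,
        c3_nm: float = 250.0,
    ) -> "AssayTimeline":
        """FB/FD (or buffer) 180 s + 100 s dissociation, then C3 120 s with
        120 s final dissociation; inhibitor, when present, is kept in the
        running buffer for every phase."""
        fb = fd = fb_fd_nm * 1e-9 if convertase else 0.0
        inh = inhibitor
        return cls(
            (
                AssaySegment(180.0, fb=fb, fd=fd, inhibitor=inh),
                AssaySegment(100.0, inhibitor=inh),
                AssaySegment(120.0, c3=c3_nm * 1e-9, inhibitor=inh),
                AssaySegment(120.0, inhibitor=inh),
            )
        )

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))


@dataclass
class SurfaceTrace:
    """Simulated surface trace: species densities and total response."""

    time: np.ndarray
    species: pd.DataFrame  # one column per entry of SPECIES
    response: np.ndarray
    segment_starts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = self.species.copy()
        df.insert(0, "time_s", self.time)
        df["response_RU"] = self.response
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rhs_factory(seg: AssaySegment, r: ConvertaseRates):
    theta = seg.inhibitor / (seg.inhibitor + r.inhibitor_kd) if seg.inhibitor else 0.0
    block = (1.0 - theta) ** 2
    conv = r.k_conv if seg.fd > 0 else 0.0
    cat = r.k_cat if r.active else 0.0
    kon_cc = r.kon_c3_convertase * seg.c3 * block
    kon_cf = r.kon_c3_free * seg.c3 * block
    kon_fb = r.kon_fb * seg.fb

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        c3b, c3bB, c3bBb, c3conv, c3free, _dep = y
        v_fb_on = kon_fb * c3b
        v_fb_off = r.koff_fb * c3bB
        v_conv = conv * c3bB
        v_decay = r.k_decay * c3bBb
        v_cc_on = kon_cc * c3bBb
        v_cc_off = r.koff_c3_convertase * c3conv
        v_cf_on = kon_cf * c3b
        v_cf_off = r.koff_c3_free * c3free
        v_cat = cat * c3conv
        return np.array(
            [
                -v_fb_on + v_fb_off + v_decay - v_cf_on + v_cf_off,
                v_fb_on - v_fb_off - v_conv,
                v_conv - v_decay - v_cc_on + v_cc_off + v_cat,
                v_cc_on - v_cc_off - v_cat,
                v_cf_on - v_cf_off,
                v_cat,
            ]
        )

    return rhs


def simulate_assay(
    timeline: AssayTimeline,
    rates: ConvertaseRates = ConvertaseRates(),
    initial_c3b_ru: float = 460.0,
    dt: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SurfaceTrace:
    """Integrate the assay ODE system segment by segment.

    Starts from a bare C3b surface of ``initial_c3b_ru`` RU-equivalents.
    The total response is the mass-weighted sum of the species densities.
    """
    if initial_c3b_ru <= 0:
        raise ValueError("initial surface density must be positive")
    y = np.array([initial_c3b_ru, 0.0, 0.0, 0.0, 0.0, 0.0])
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    seg_starts = [0.0]
    t0 = 0.0
    for seg in timeline.segments:
        t_eval = np.arange(0.0, seg.duration + 0.5 * dt, dt)
        sol = solve_ivp(
            _rhs_factory(seg, rates),
            (0.0, seg.duration),
            y,
            t_eval=t_eval,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        if np.any(sol.y < -1e-6):
            raise RuntimeError("negative species density encountered")
        ys = np.clip(sol.y, 0.0, None)
        skip = 1 if times else 0  # drop duplicated segment boundary
        times.append(sol.t[skip:] + t0)
        states.append(ys[:, skip:])
        y = ys[:, -1]
        t0 += seg.duration
        seg_starts.append(t0)
    t = np.concatenate(times)
    ymat = np.concatenate(states, axis=1)
    species = pd.DataFrame(ymat.T, columns=list(SPECIES))
    response = ymat.T @ _WEIGHTS
    return SurfaceTrace(
        time=t,
        species=species,
        response=np.asarray(response),
        segment_starts=np.array(seg_starts[:-1]),
    )


def _c3_segment_start(timeline: AssayTimeline) -> float | None:
    t = 0.0
    for seg in timeline.segments:
        if seg.c3 > 0:
            return t
        t += seg.duration
    return None


def deposition_delta(trace: SurfaceTrace, timeline: AssayTimeline) -> float:
    """Baseline gain over the C3 phase: response after the final dissociation
    minus response immediately before the first C3 injection.  Returns 0 when
    the timeline contains no C3 segment."""
    t_c3 = _c3_segment_start(timeline)
    if t_c3 is None:
        return 0.0
    idx = int(np.searchsorted(trace.time, t_c3)) - 1
    idx = max(idx, 0)
    return float(trace.response[-1] - trace.response[idx])


def deposited_delta(trace: SurfaceTrace, timeline: AssayTimeline) -> float:
    """Change in the covalently deposited pool over the same window as
    :func:`deposition_delta` (model-level ground truth)."""
    t_c3 = _c3_segment_start(timeline)
    if t_c3 is None:
        return 0.0
    dep = trace.species["deposited"].to_numpy()
    idx = max(int(np.searchsorted(trace.time, t_c3)) - 1, 0)
    return float(dep[-1] - dep[idx])


def substrate_preference_ratio(
    rates: ConvertaseRates,
    c3_conc: float,
) -> float:
    """Equilibrium preference of C3 for convertase-bound over free C3b:
    ratio of the bound site fractions at the given C3 concentration.  At
    c3_conc = 0 this is the affinity ratio K_D(free)/K_D(convertase)."""
    if c3_conc < 0:
        raise ValueError("concentration must be non-negative")
    kd_conv = rates.koff_c3_convertase / rates.kon_c3_convertase
    kd_free = rates.koff_c3_free / rates.kon_c3_free
    if c3_conc == 0:
        return kd_free / kd_conv
    f_conv = c3_conc / (c3_conc + kd_conv)
    f_free = c3_conc / (c3_conc + kd_free)
    return f_conv / f_free
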