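"""Cross-species contact conservation and complement-inhibition readouts.

Pairwise global protein alignment (Needleman-Wunsch/Gotoh with affine gaps,
EMBOSS-style penalties), Clustal-style per-column conservation classes,
mapping of inhibitor-contact positions from a reference ortholog onto a
second species, and the percent-inhibition transform used for plate-based
complement activation assays.

The alignment is computed in-package so that the traceback tie-break
(diagonal, then up, then left) is deterministic and documented; the
substitution matrices come from Biopython's collection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentResult",
    "ContactConservationReport",
    "InhibitionCurve",
    "global_align",
    "classify_conservation",
    "map_contact_positions",
    "percent_inhibition",
    "STRONG_GROUPS",
    "WEAK_GROUPS",
]

# Clustal conservation groups (strong: score > 0.5 in PAM250 terms; weak > 0.2)
STRONG_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g)
    for g in ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
)
WEAK_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g)
    for g in (
        "CSA",
        "ATV",
        "SAG",
        "STNK",
        "STPA",
        "SGND",
        "SNDEQK",
        "NDEQHK",
        "NEQHRK",
        "FVLIM",
        "HFY",
    )
)

_GAP = "-"


@dataclass(frozen=True)
class AlignmentResult:
    """Global pairwise alignment with per-column conservation classes."""

    aligned_a: str
    aligned_b: str
    score: float
    classes: tuple[str, ...]
    percent_identity: float
    matrix: str
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences must have equal length")
        if self.percent_identity > 100.0:
            raise ValueError("identity cannot exceed 100%")

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace(_GAP, "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace(_GAP, "")


@dataclass(frozen=True)
class ContactConservationReport:
    """Per-contact-position conservation across the aligned orthologs."""

    rows: pd.DataFrame  # position, ref_residue, ortholog_residue, class, status

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


@dataclass
class InhibitionCurve:
    """Concentration series with percent-inhibition values in [0, 100]."""

    concentrations_m: np.ndarray
    signals: np.ndarray
    background: float
    reference_signal: float
    percent: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration_m": self.concentrations_m,
                "signal": self.signals,
                "percent_inhibition": self.percent,
            }
        )


# ---------------------------------------------------------------------------
# alignment


def _load_matrix(name: str):
    return substitution_matrices.load(name)


def _validate_sequence(seq: str, alphabet: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label} must be non-empty")
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"{label} contains invalid characters: {sorted(bad)}")


def global_align(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal global alignment with affine gap penalties.

    A gap of length L costs ``gap_open + L * gap_extend`` (EMBOSS
    convention), end gaps included.  Ties in the traceback are broken by
    preferring the diagonal, then the gap in ``seq_b`` (up), then the gap in
    ``seq_a`` (left), so the output is reproducible.
    """
    sub = _load_matrix(matrix)
    alphabet = str(sub.alphabet)
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    _validate_sequence(seq_a, alphabet, "seq_a")
    _validate_sequence(seq_b, alphabet, "seq_b")
    if gap_open < 0 or gap_extend < 0:
        raise ValueError("gap penalties must be non-negative")

    n, m = len(seq_a), len(seq_b)
    idx_a = [alphabet.index(c) for c in seq_a]
    idx_b = [alphabet.index(c) for c in seq_b]
    neg = -math.inf
    open_cost = gap_open + gap_extend  # first gap residue pays open + extend

    # Gotoh matrices: M ends in a match, Ix gap in seq_b (up), Iy gap in seq_a
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)
    Iy = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + j * gap_extend)

    for i in range(1, n + 1):
        si = sub[idx_a[i - 1]]
        for j in range(1, m + 1):
            s = si[idx_b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] - open_cost, Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - open_cost, Iy[i, j - 1] - gap_extend)

    # traceback with documented tie-break: diagonal (M) > up (Ix) > left (Iy)
    def _pick(candidates: list[tuple[int, float]], target: float) -> int:
        for state_id, value in candidates:
            if math.isclose(value, target, rel_tol=0.0, abs_tol=1e-9):
                return state_id
        raise AssertionError("traceback lost: no predecessor matches")

    i, j = n, m
    end_scores = (M[i, j], Ix[i, j], Iy[i, j])
    state = int(np.argmax(end_scores))
    score = float(end_scores[state])
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # match/mismatch column
            s = float(sub[idx_a[i - 1], idx_b[j - 1]])
            state = _pick(
                [(0, M[i - 1, j - 1]), (1, Ix[i - 1, j - 1]), (2, Iy[i - 1, j - 1])],
                M[i, j] - s,
            )
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i -= 1
            j -= 1
        elif state == 1:  # gap in seq_b: consume a residue of seq_a
            out_a.append(seq_a[i - 1])
            out_b.append(_GAP)
            state = _pick(
                [(0, M[i - 1, j] - open_cost), (1, Ix[i - 1, j] - gap_extend)],
                Ix[i, j],
            )
            i -= 1
        else:  # gap in seq_a: consume a residue of seq_b
            out_a.append(_GAP)
            out_b.append(seq_b[j - 1])
            state = _pick(
                [(0, M[i, j - 1] - open_cost), (2, Iy[i, j - 1] - gap_extend)],
                Iy[i, j],
            )
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))

    classes = tuple(
        classify_conservation(a, b) for a, b in zip(aligned_a, aligned_b)
    )
    n_ident = sum(1 for c in classes if c == "identical")
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        classes=classes,
        percent_identity=100.0 * n_ident / len(aligned_a),
        matrix=matrix,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def align_score(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Optimal global alignment score only (no traceback)."""
    return global_align(seq_a, seq_b, matrix, gap_open, gap_extend).score


def classify_conservation(a: str, b: str) -> str:
    """Clustal-style column class: identical / strong / weak / dissimilar,
    or 'gap' when either side is a gap."""
    if a == _GAP or b == _GAP:
        return "gap"
    if a == b:
        return "identical"
    pair = {a, b}
    if any(pair <= g for g in STRONG_GROUPS):
        return "strong"
    if any(pair <= g for g in WEAK_GROUPS):
        return "weak"
    return "dissimilar"


def map_contact_positions(
    aln: AlignmentResult,
    positions: Sequence[int],
    numbering_offset: int = 0,
) -> ContactConservationReport:
    """Map reference (seq_a) contact positions through the alignment.

    ``positions`` use the reference author numbering; ``numbering_offset`` is
    subtracted to obtain 1-based indices into seq_a (offset 0 means the
    numbering and the sequence coincide).  Out-of-range positions are
    reported with status 'out_of_range' rather than dropped.
    """
    # alignment column for each seq_a residue index (1-based)
    col_of: dict[int, int] = {}
    ai = 0
    for col, ch in enumerate(aln.aligned_a):
        if ch != _GAP:
            ai += 1
            col_of[ai] = col
    rows = []
    for pos in positions:
        idx = pos - numbering_offset
        if idx < 1 or idx > len(aln.seq_a):
            rows.append(
                {
                    "position": pos,
                    "ref_residue": "",
                    "ortholog_residue": "",
                    "conservation": "",
                    "status": "out_of_range",
                }
            )
            continue
        col = col_of[idx]
        a_res = aln.aligned_a[col]
        b_res = aln.aligned_b[col]
        rows.append(
            {
                "position": pos,
                "ref_residue": a_res,
                "ortholog_residue": b_res,
                "conservation": aln.classes[col],
                "status": "ok",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["position", "ref_residue", "ortholog_residue", "conservation", "status"],
    )
    return ContactConservationReport(rows=df)


# ---------------------------------------------------------------------------
# plate assay readout


def percent_inhibition(
    signal: float | np.ndarray,
    background: float,
    reference_signal: float,
) -> float | np.ndarray:
    """Percent inhibition of complement activation.

    100 * (1 - (signal - background) / (reference - background)), clamped to
    [0, 100]: signals above the no-inhibitor reference are defined as zero
    inhibition, signals below background as complete inhibition.
    """
    if reference_signal <= background:
        raise ValueError("reference signal must exceed background")
    signal = np.asarray(signal, dtype=float)
    pct = 100.0 * (1.0 - (signal - background) / (reference_signal - background))
    pct = np.clip(pct, 0.0, 100.0)
    return float(pct) if pct.ndim == 0 else pct


def inhibition_curve(
    concentrations_m: Sequence[float],
    signals: Sequence[float],
    background: float,
    reference_signal: float,
) -> InhibitionCurve:
    """Bundle a concentration series into an :class:`InhibitionCurve`."""
    conc = np.asarray(concentrations_m, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if conc.shape != sig.shape:
        raise ValueError("concentrations and signals must have equal length")
    pct = percent_inhibition(sig, background, reference_signal)
    return InhibitionCurve(conc, sig, background, reference_signal, np.asarray(pct))
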