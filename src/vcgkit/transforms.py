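"""Linear lead transformations between the 12-lead ECG and Frank VCG.

Every derivation here is a fixed linear map applied samplewise,

    VCG_der = M · E,

where E stacks the eight independent ECG leads (I, II, V1..V6) and M
is a published 3x8 coefficient matrix with rows ordered X, Y, Z.  Four
such matrices are provided:

* ``kors_matrix``  -- Kors regression matrix, fitted by least squares
  on the QRS complex against directly measured Frank leads
  (Kors et al., Eur Heart J 1990).
* ``idt_matrix``   -- inverse Dower transform, the pseudoinverse of
  Dower's ECG-synthesis matrix (Edenbrandt & Pahlm, J Electrocardiol
  1988).
* ``qlsv_matrix`` / ``plsv_matrix`` -- least-squares matrices fitted on
  the QRS complex and the P wave respectively (Guillem et al. 2008).

Also provided: the quasi-orthogonal shortcut (X=V6, Y=II, Z=-0.5*V2),
the Frank resistor-network synthesis from raw electrode potentials,
and a forward VCG->ECG projection used by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .records import (
    INDEPENDENT_LEADS,
    VCG_LEADS,
    LeadError,
    MultichannelRecord,
    derive_limb_leads,
    normalize_lead,
)

__all__ = [
    "TransformMatrix",
    "apply_transform",
    "kors_matrix",
    "idt_matrix",
    "qlsv_matrix",
    "plsv_matrix",
    "quasi_orthogonal_matrix",
    "quasi_orthogonal",
    "frank_synthesis",
    "dower_forward_matrix",
    "get_method",
    "DEFAULT_METHODS",
]


@dataclass(frozen=True)
class TransformMatrix:
    """Named 3xk lead-transformation matrix.

    ``coeffs`` rows are ordered X, Y, Z; column ``j`` multiplies input
    lead ``input_leads[j]``.  Coefficients are dimensionless, so mV in
    gives mV out.
    """

    name: str
    input_leads: tuple[str, ...]
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coeffs, dtype=float)
        leads = tuple(normalize_lead(l) for l in self.input_leads)
        if coeffs.ndim != 2 or coeffs.shape[0] != 3:
            raise ValueError(
                f"transform matrix must have exactly 3 rows (X, Y, Z); "
                f"got shape {coeffs.shape}"
            )
        if coeffs.shape[1] != len(leads):
            raise ValueError(
                f"{coeffs.shape[1]} columns but {len(leads)} input leads"
            )
        if len(set(leads)) != len(leads):
            raise ValueError(f"duplicate input leads: {leads}")
        object.__setattr__(self, "coeffs", coeffs)
        object.__setattr__(self, "input_leads", leads)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coeffs, index=list(VCG_LEADS), columns=list(self.input_leads)
        )

    def to_csv(self, path: str | Path) -> None:
        """Export for audit: rows X, Y, Z; columns labelled by input lead."""
        self.to_frame().to_csv(Path(path), index_label="lead")

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None) -> "TransformMatrix":
        frame = pd.read_csv(Path(path), index_col=0)
        if list(frame.index) != list(VCG_LEADS):
            raise ValueError(f"matrix CSV rows must be X, Y, Z; got {list(frame.index)}")
        return cls(
            name=name or Path(path).stem,
            input_leads=tuple(str(c) for c in frame.columns),
            coeffs=frame.to_numpy(dtype=float),
        )


def apply_transform(matrix: TransformMatrix, ecg: MultichannelRecord) -> MultichannelRecord:
    """Apply a lead transformation samplewise: out[t] = M · E[t].

    Returns a 3-lead X/Y/Z record with the same length and sampling
    rate.  Raises :class:`LeadError` naming the first missing input
    lead; limb leads derivable from I and II are derived on the fly.
    """
    missing = [l for l in matrix.input_leads if not ecg.has_lead(l)]
    if missing and {"III", "aVR", "aVL", "aVF"} & set(missing):
        if ecg.has_lead("I") and ecg.has_lead("II"):
            ecg = derive_limb_leads(ecg)
            missing = [l for l in matrix.input_leads if not ecg.has_lead(l)]
    if missing:
        raise LeadError(
            f"transform {matrix.name!r} needs lead {missing[0]!r}, absent from "
            f"record {ecg.record_id!r}"
        )
    e = ecg.select(matrix.input_leads)          # (n, k)
    xyz = e @ matrix.coeffs.T                   # (n, 3)
    return MultichannelRecord(
        samples=xyz, lead_labels=VCG_LEADS, fs=ecg.fs, record_id=ecg.record_id
    )


# ---------------------------------------------------------------------------
# Published coefficient matrices.
#
# Column order everywhere: I, II, V1, V2, V3, V4, V5, V6.
# Values transcribed from the original publications cited in the module
# docstring; stored verbatim, never re-derived.
# ---------------------------------------------------------------------------

_KORS = np.array([
    [0.38, -0.07, -0.13,  0.05, -0.01,  0.14,  0.06,  0.54],
    [-0.07,  0.93,  0.06, -0.02, -0.05,  0.06, -0.17,  0.13],
    [0.11, -0.23, -0.43, -0.06, -0.14, -0.20, -0.11,  0.31],
])

_IDT = np.array([
    [0.156, -0.010, -0.172, -0.074,  0.122,  0.231,  0.239,  0.194],
    [-0.227,  0.887,  0.057, -0.019, -0.106, -0.022,  0.041,  0.048],
    [0.022,  0.102, -0.229, -0.310, -0.246, -0.063,  0.055,  0.108],
])

_QLSV = np.array([
    [0.199, -0.018, -0.147, -0.058,  0.037,  0.139,  0.232,  0.226],
    [-0.164,  0.503,  0.023, -0.085, -0.003,  0.033,  0.060,  0.104],
    [0.085, -0.130, -0.184, -0.163, -0.193, -0.119, -0.023,  0.043],
])

_PLSV = np.array([
    [0.266, -0.088, -0.319, -0.198,  0.026,  0.191,  0.322,  0.280],
    [-0.088,  0.503,  0.022, -0.112,  0.006,  0.033,  0.037,  0.112],
    [0.080, -0.132, -0.188, -0.173, -0.221, -0.112,  0.002,  0.031],
])


def _matrix(name: str, coeffs: np.ndarray) -> TransformMatrix:
    return TransformMatrix(name=name, input_leads=INDEPENDENT_LEADS, coeffs=coeffs.copy())


def kors_matrix() -> TransformMatrix:
    """Kors regression matrix (3x8, leads I, II, V1..V6)."""
    return _matrix("kors", _KORS)


def idt_matrix() -> TransformMatrix:
    """Inverse Dower transformation matrix (3x8, leads I, II, V1..V6)."""
    return _matrix("idt", _IDT)


def qlsv_matrix() -> TransformMatrix:
    """QLSV least-squares matrix optimised for the QRS complex."""
    return _matrix("qlsv", _QLSV)


def plsv_matrix() -> TransformMatrix:
    """PLSV least-squares matrix optimised for the P wave."""
    return _matrix("plsv", _PLSV)


def quasi_orthogonal_matrix() -> TransformMatrix:
    """Quasi-orthogonal rule as a sparse matrix: X=V6, Y=II, Z=-0.5*V2."""
    coeffs = np.zeros((3, 8))
    leads = INDEPENDENT_LEADS
    coeffs[0, leads.index("V6")] = 1.0
    coeffs[1, leads.index("II")] = 1.0
    coeffs[2, leads.index("V2")] = -0.5
    return TransformMatrix(name="quasi", input_leads=leads, coeffs=coeffs)


def quasi_orthogonal(ecg: MultichannelRecord) -> MultichannelRecord:
    """Quasi-orthogonal lead approximation: X = V6, Y = II, Z = -0.5·V2."""
    for lead in ("V6", "II", "V2"):
        if not ecg.has_lead(lead):
            raise LeadError(
                f"quasi-orthogonal transform needs lead {lead!r}, absent from "
                f"record {ecg.record_id!r}"
            )
    xyz = np.column_stack([
        ecg.lead("V6"),
        ecg.lead("II"),
        -0.5 * ecg.lead("V2"),
    ])
    return MultichannelRecord(
        samples=xyz, lead_labels=VCG_LEADS, fs=ecg.fs, record_id=ecg.record_id
    )


# Frank resistor-network weights: potential at each corrected-lead tap
# as a combination of the seven electrode potentials I, E, C, A, M, F, H.
_FRANK_WEIGHTS = {
    "X": {"A": 0.610, "C": 0.171, "I": -0.781},
    "Y": {"F": 0.655, "M": 0.345, "H": -1.000},
    "Z": {"A": 0.133, "M": 0.736, "I": -0.264, "E": -0.374, "C": -0.231},
}

FRANK_ELECTRODES = ("I", "E", "C", "A", "M", "F", "H")


def frank_synthesis(
    potentials: Mapping[str, np.ndarray | float], fs: float = 1000.0,
    record_id: str = "frank",
) -> MultichannelRecord:
    """Synthesise corrected orthogonal leads from Frank electrode potentials.

    ``potentials`` maps each electrode label in ``FRANK_ELECTRODES``
    (I, E, C, A, M, F, H — electrode clips, not ECG leads) to a channel
    in mV.  Scalars are broadcast to length-1 channels.  Implements the
    resistor-network combination:

        Px = 0.610·A + 0.171·C − 0.781·I
        Py = 0.655·F + 0.345·M − 1.000·H
        Pz = 0.133·A + 0.736·M − 0.264·I − 0.374·E − 0.231·C
    """
    channels: dict[str, np.ndarray] = {}
    for name in FRANK_ELECTRODES:
        if name not in potentials:
            raise LeadError(f"missing Frank electrode potential {name!r}")
        channels[name] = np.atleast_1d(np.asarray(potentials[name], dtype=float))
    lengths = {c.shape[0] for c in channels.values()}
    if len(lengths) != 1:
        raise ValueError(f"electrode channels differ in length: {sorted(lengths)}")
    n = lengths.pop()
    xyz = np.zeros((n, 3))
    for row, lead in enumerate(VCG_LEADS):
        for electrode, weight in _FRANK_WEIGHTS[lead].items():
            xyz[:, row] += weight * channels[electrode]
    return MultichannelRecord(
        samples=xyz, lead_labels=VCG_LEADS, fs=fs, record_id=record_id
    )


def dower_forward_matrix() -> np.ndarray:
    """Forward VCG→ECG projection: the 8x3 pseudoinverse of the IDT matrix.

    Maps (X, Y, Z) to the eight independent leads (I, II, V1..V6) such
    that ``idt_matrix().coeffs @ F`` is the 3x3 identity; used by the
    simulator so the inverse Dower transform recovers the generating
    VCG exactly in the noiseless limit.
    """
    return np.linalg.pinv(_IDT)


def get_method(name: str) -> TransformMatrix:
    """Look up a transformation method by name (kors, idt, qlsv, plsv, quasi)."""
    key = name.strip().lower()
    builders = {
        "kors": kors_matrix,
        "idt": idt_matrix,
        "qlsv": qlsv_matrix,
        "plsv": plsv_matrix,
        "quasi": quasi_orthogonal_matrix,
    }
    if key not in builders:
        raise KeyError(
            f"unknown transformation method {name!r}; expected one of {sorted(builders)}"
        )
    return builders[key]()


DEFAULT_METHODS = ("kors", "idt", "qlsv", "quasi")
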