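"""Core multichannel record type and I/O for ECG/VCG signals.

A record is a uniformly sampled matrix of lead voltages in millivolts.
The lead vocabulary covers the conventional 12-lead ECG (of which
I, II, V1..V6 are the eight linearly independent channels) and the
Frank orthogonal leads X, Y, Z.  CSV is the canonical on-disk format;
WFDB (.hea/.dat, as used by PhysioNet databases such as PTB) is an
optional adapter that requires the ``wfdb`` package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical lead vocabulary (standard 12-lead ECG + Frank XYZ).
STANDARD_LEADS = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
    "X", "Y", "Z",
)

#: Eight independent ECG leads forming the input basis of every
#: published transformation matrix (the limb leads III/aVR/aVL/aVF
#: are linear combinations of I and II).
INDEPENDENT_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

VCG_LEADS = ("X", "Y", "Z")

# Case-insensitive aliases -> canonical label.  Covers PTB channel
# names ("vx", "vy", "vz") and common casing variants.
_ALIASES = {lead.lower(): lead for lead in STANDARD_LEADS}
_ALIASES.update({"vx": "X", "vy": "Y", "vz": "Z"})


class LeadError(ValueError):
    """A required lead is missing, unknown, or duplicated."""


class FormatError(ValueError):
    """A file does not conform to the expected record layout."""


def normalize_lead(label: str) -> str:
    """Map a lead label to its canonical form (case-insensitive).

    Unknown labels are returned stripped but otherwise unchanged, so
    custom channels are permitted.  Idempotent.
    """
    key = label.strip().lower()
    return _ALIASES.get(key, label.strip())


@dataclass(frozen=True)
class MultichannelRecord:
    """Simultaneously sampled multichannel signal in mV.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_leads)
        Lead voltages in millivolts; column ``j`` is lead
        ``lead_labels[j]``.
    lead_labels : sequence of str
        Ordered, unique lead names.
    fs : float
        Sampling rate in Hz (> 0).
    record_id : str
        Opaque identifier, e.g. a file stem.
    """

    samples: np.ndarray
    lead_labels: tuple[str, ...]
    fs: float
    record_id: str = "record"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2:
            raise FormatError(
                f"samples must be 2-D (n_samples, n_leads); got shape {samples.shape}"
            )
        labels = tuple(normalize_lead(l) for l in self.lead_labels)
        if samples.shape[1] != len(labels):
            raise FormatError(
                f"{samples.shape[1]} signal columns but {len(labels)} lead labels"
            )
        if samples.shape[0] < 1:
            raise FormatError("record must contain at least one sample")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise LeadError(f"duplicate lead labels: {dupes}")
        if not self.fs > 0:
            raise FormatError(f"sampling rate must be positive; got {self.fs}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "lead_labels", labels)
        object.__setattr__(self, "fs", float(self.fs))

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_leads(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def has_lead(self, label: str) -> bool:
        return normalize_lead(label) in self.lead_labels

    def lead(self, label: str) -> np.ndarray:
        """Return one lead as a 1-D array (a view where possible)."""
        label = normalize_lead(label)
        try:
            j = self.lead_labels.index(label)
        except ValueError:
            raise LeadError(
                f"record {self.record_id!r} has no lead {label!r}; "
                f"available: {list(self.lead_labels)}"
            ) from None
        return self.samples[:, j]

    def select(self, labels: Sequence[str]) -> np.ndarray:
        """Return samples for ``labels`` in order, shape (n_samples, k)."""
        return np.column_stack([self.lead(l) for l in labels])

    def with_samples(self, samples: np.ndarray) -> "MultichannelRecord":
        return replace(self, samples=samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=list(self.lead_labels))


# -- lead algebra --------------------------------------------------------

def derive_limb_leads(record: MultichannelRecord) -> MultichannelRecord:
    """Augment a record with the derived limb leads III, aVR, aVL, aVF.

    Standard lead identities (Einthoven/Goldberger):
    III = II - I, aVR = -(I + II)/2, aVL = I - II/2, aVF = II - I/2.
    Existing channels are left untouched; derived leads already present
    are not duplicated.
    """
    for required in ("I", "II"):
        if not record.has_lead(required):
            raise LeadError(
                f"cannot derive limb leads: record {record.record_id!r} "
                f"is missing lead {required!r}"
            )
    i, ii = record.lead("I"), record.lead("II")
    derived = {
        "III": ii - i,
        "aVR": -(i + ii) / 2.0,
        "aVL": i - ii / 2.0,
        "aVF": ii - i / 2.0,
    }
    new_labels = list(record.lead_labels)
    new_cols = [record.samples]
    for label, signal in derived.items():
        if label not in record.lead_labels:
            new_labels.append(label)
            new_cols.append(signal[:, None])
    return MultichannelRecord(
        samples=np.hstack(new_cols),
        lead_labels=tuple(new_labels),
        fs=record.fs,
        record_id=record.record_id,
    )


# -- I/O -----------------------------------------------------------------

def read_record(
    path: str | Path,
    format: str = "csv",
    fs: float | None = None,
    record_id: str | None = None,
) -> MultichannelRecord:
    """Read a multichannel record from disk.

    CSV layout: a header row of lead labels, one sample per row, values
    in mV with "." as the decimal point.  An optional leading column
    named ``time_s`` is ignored.  For CSV the sampling rate must be
    supplied via ``fs``; for WFDB it is taken from the header and
    amplitudes are converted to mV using the stored gain.
    """
    path = Path(path)
    if format == "csv":
        if fs is None:
            raise ValueError("fs is required when reading CSV records")
        try:
            frame = pd.read_csv(path)
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        with open(path, "r", encoding="utf-8") as fh:
            raw_labels = [t.strip() for t in fh.readline().rstrip("\n").split(",")]
        norm = [normalize_lead(l) for l in raw_labels]
        if len(set(norm)) != len(norm):
            dupes = sorted({l for l in norm if norm.count(l) > 1})
            raise LeadError(f"duplicate lead columns in {path}: {dupes}")
        if raw_labels and raw_labels[0].strip().lower() == "time_s":
            frame = frame.iloc[:, 1:]
            raw_labels = raw_labels[1:]
        if frame.isna().any().any():
            raise FormatError(f"ragged or non-numeric columns in {path}")
        try:
            samples = frame.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric values in {path}: {exc}") from exc
        return MultichannelRecord(
            samples=samples,
            lead_labels=tuple(raw_labels),
            fs=fs,
            record_id=record_id or path.stem,
        )
    if format == "wfdb":
        try:
            import wfdb  # optional adapter; not needed for CSV workflows
        except ImportError as exc:  # pragma: no cover - depends on extras
            raise ImportError(
                "reading WFDB records requires the optional 'wfdb' package "
                "(pip install wfdb)"
            ) from exc
        rec = wfdb.rdrecord(str(path.with_suffix("")))  # pragma: no cover
        sig = np.asarray(rec.p_signal, dtype=float)  # pragma: no cover
        units = [u.lower() for u in rec.units]  # pragma: no cover
        for j, u in enumerate(units):  # pragma: no cover
            if u in ("uv", "µv"):
                sig[:, j] /= 1000.0
        return MultichannelRecord(  # pragma: no cover
            samples=sig,
            lead_labels=tuple(rec.sig_name),
            fs=float(rec.fs),
            record_id=record_id or path.stem,
        )
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'wfdb'")


def write_record(record: MultichannelRecord, path: str | Path, format: str = "csv") -> None:
    """Write a record to CSV (header row of lead labels, values in mV)."""
    if format != "csv":
        raise ValueError(f"unsupported write format {format!r}")
    record.to_frame().to_csv(Path(path), index=False, float_format="%.10g")
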