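"""Per-lead MSE between derived and directly measured VCG.

The accuracy statistic for a transformation method is the mean squared
error between each derived orthogonal lead and the corresponding
directly measured Frank lead, computed over the full record:

    MSE = (1/n) * sum_i (V_i - oV_i)^2    [mV^2]

where ``V`` is the measured reference lead and ``oV`` the derived one.
``evaluate_cohort`` runs the full per-record pipeline (baseline removal
-> transform -> per-lead MSE) and returns a long-format table, one row
per (record, method, lead); ``flag_outliers`` marks values outside the
Tukey inner fences per (method, lead) group without removing any row,
mirroring how remote observations are screened but retained before the
statistical comparison.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocess import BaselineConfig, remove_baseline
from .records import VCG_LEADS, LeadError, MultichannelRecord
from .transforms import DEFAULT_METHODS, apply_transform, get_method

__all__ = ["mse", "evaluate_cohort", "flag_outliers", "MSE_COLUMNS"]

MSE_COLUMNS = ["record_id", "method", "lead", "mse", "outlier_flag"]


def mse(reference: np.ndarray, derived: np.ndarray) -> float:
    """Mean squared error between two equal-length 1-D signals in mV.

    Returns (1/n) * sum (reference - derived)^2, in mV^2.
    """
    reference = np.asarray(reference, dtype=float).ravel()
    derived = np.asarray(derived, dtype=float).ravel()
    if reference.shape != derived.shape:
        raise ValueError(
            f"signal lengths differ: {reference.shape[0]} vs {derived.shape[0]}"
        )
    if reference.size == 0:
        raise ValueError("cannot compute MSE of empty signals")
    diff = reference - derived
    return float(diff @ diff / diff.size)


def evaluate_cohort(
    pairs: Iterable[tuple[MultichannelRecord, MultichannelRecord]],
    methods: Sequence[str] = DEFAULT_METHODS,
    baseline_cfg: BaselineConfig | None = None,
    correct_reference: bool = True,
) -> pd.DataFrame:
    """Per-lead MSE table for a cohort of paired (ECG, reference VCG) records.

    For every record: the ECG is baseline-corrected, each requested
    method derives X/Y/Z, and the per-lead MSE against the reference
    VCG is recorded.  By default the reference Frank leads pass through
    the same baseline correction, so reference drift is not charged to
    the transforms (``correct_reference=False`` compares against the
    raw reference instead).

    Returns a DataFrame with columns record_id, method, lead, mse,
    outlier_flag (initialised False), sorted by (method, lead,
    record_id).
    """
    rows = []
    for ecg, vcg_ref in pairs:
        try:
            ecg_clean = remove_baseline(ecg, baseline_cfg)
            ref = remove_baseline(vcg_ref, baseline_cfg) if correct_reference else vcg_ref
            for name in methods:
                derived = apply_transform(get_method(name), ecg_clean)
                for lead in VCG_LEADS:
                    rows.append(
                        {
                            "record_id": ecg.record_id,
                            "method": name,
                            "lead": lead,
                            "mse": mse(ref.lead(lead), derived.lead(lead)),
                            "outlier_flag": False,
                        }
                    )
        except LeadError as exc:
            raise LeadError(f"record {ecg.record_id!r}: {exc}") from exc
    table = pd.DataFrame(rows, columns=MSE_COLUMNS)
    return table.sort_values(["method", "lead", "record_id"], ignore_index=True)


def _tukey_fences(values: np.ndarray) -> tuple[float, float]:
    """Inner fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR], quartiles by linear interpolation."""
    q1, q3 = np.quantile(values, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def flag_outliers(table: pd.DataFrame, min_group: int = 4) -> pd.DataFrame:
    """Flag remote observations per (method, lead) group; retain all rows.

    A value is flagged when it falls strictly outside the Tukey inner
    fences of its group.  Groups smaller than ``min_group`` get no
    flags (with a warning) because quartiles are meaningless there.
    Returns a copy with the ``outlier_flag`` column filled in; the row
    count never changes.
    """
    out = table.copy()
    out["outlier_flag"] = False
    for (method, lead), group in out.groupby(["method", "lead"], sort=False):
        values = group["mse"].to_numpy(dtype=float)
        if values.size < min_group:
            warnings.warn(
                f"group ({method}, {lead}) has only {values.size} values; "
                "too small for outlier fencing, no flags set",
                stacklevel=2,
            )
            continue
        lo, hi = _tukey_fences(values)
        out.loc[group.index, "outlier_flag"] = (values < lo) | (values > hi)
    return out
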