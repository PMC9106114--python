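"""Baseline-wander removal by Savitzky-Golay trend estimation.

Baseline wander is the slow (< ~0.5 Hz) drift of the ECG isoelectric
line caused by respiration and electrode motion.  A long Savitzky-Golay
window (default 1.2 s, i.e. 1201 samples at 1 kHz) fitted with a cubic
polynomial tracks this drift while passing almost none of the QRS
energy; subtracting the smoothed trend from each lead yields the
baseline-corrected signal.  Edge samples are handled by fitting the
polynomial on the truncated window, so the output keeps the input
length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.signal import savgol_filter

from .records import MultichannelRecord

__all__ = ["BaselineConfig", "estimate_baseline", "remove_baseline"]


def round_to_odd(x: float) -> int:
    """Nearest odd integer >= 1 (ties round up)."""
    n = int(round(x))
    if n % 2 == 0:
        n += 1
    return max(n, 1)


@dataclass(frozen=True)
class BaselineConfig:
    """Savitzky-Golay trend-estimation parameters.

    window_samples must be odd and larger than polyorder; the default
    1201 corresponds to a 1.2 s window at 1 kHz.
    """

    window_samples: int = 1201
    polyorder: int = 3

    def __post_init__(self) -> None:
        window = int(self.window_samples)
        if window % 2 == 0:
            warnings.warn(
                f"Savitzky-Golay window must be odd; rounding {window} up to {window + 1}",
                stacklevel=3,
            )
            window += 1
        if self.polyorder < 0:
            raise ValueError("polyorder must be non-negative")
        if window <= self.polyorder:
            raise ValueError(
                f"window_samples ({window}) must exceed polyorder ({self.polyorder})"
            )
        object.__setattr__(self, "window_samples", window)

    @classmethod
    def from_seconds(
        cls, fs: float, window_seconds: float = 1.2, polyorder: int = 3
    ) -> "BaselineConfig":
        """Window scaled with the sampling rate: round_to_odd(window_seconds·fs)."""
        return cls(window_samples=round_to_odd(window_seconds * fs), polyorder=polyorder)

    def validate_for(self, n_samples: int) -> None:
        if self.window_samples > n_samples:
            raise ValueError(
                f"Savitzky-Golay window ({self.window_samples} samples) exceeds "
                f"record length ({n_samples} samples)"
            )


def estimate_baseline(
    record: MultichannelRecord, cfg: BaselineConfig | None = None
) -> MultichannelRecord:
    """Per-lead smoothed trend with the configured window and order.

    The trend reproduces any polynomial of degree <= polyorder exactly
    (constants and straight lines in particular) and is linear in the
    input signal.
    """
    if cfg is None:
        cfg = BaselineConfig.from_seconds(record.fs)
    cfg.validate_for(record.n_samples)
    trend = savgol_filter(
        record.samples,
        window_length=cfg.window_samples,
        polyorder=cfg.polyorder,
        axis=0,
        mode="interp",
    )
    return record.with_samples(trend)


def remove_baseline(
    record: MultichannelRecord, cfg: BaselineConfig | None = None
) -> MultichannelRecord:
    """Subtract the estimated baseline from every lead.

    Lead labels, length and sampling rate are preserved.
    """
    baseline = estimate_baseline(record, cfg)
    return record.with_samples(record.samples - baseline.samples)
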