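"""Per-voxel linear detrending with an intensity-adjustment QC summary.

Minimal preprocessing: remove each voxel's least-squares linear trend and
re-add its mean, recording how large the correction was relative to the
voxel mean. No spatial smoothing is applied anywhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synthbold import BoldRun

__all__ = ["QcSummary", "detrend_run", "detrend_matrix"]


@dataclass
class QcSummary:
    """Percent intensity adjustments from detrending, one value per voxel.

    Voxels with (near-)zero mean get NaN and are listed in ``flagged``
    rather than producing a divide-by-zero.
    """

    percent_adjustment: np.ndarray
    flagged: np.ndarray

    @property
    def p95(self) -> float:
        valid = self.percent_adjustment[np.isfinite(self.percent_adjustment)]
        return float(np.percentile(valid, 95)) if valid.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voxel": np.arange(self.percent_adjustment.size),
                "percent_adjustment": self.percent_adjustment,
                "flagged": np.isin(
                    np.arange(self.percent_adjustment.size), self.flagged
                ),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def detrend_matrix(data: np.ndarray) -> tuple[np.ndarray, QcSummary]:
    """Remove each row's least-squares line, preserving the row mean."""
    data = np.asarray(data, dtype=float)
    n_vox, n_vol = data.shape
    if n_vol < 3:
        raise ValueError(f"need >= 3 volumes to detrend, got {n_vol}")
    t = np.arange(n_vol, dtype=float)
    tc = t - t.mean()
    slope = data @ tc / (tc @ tc)
    correction = np.outer(slope, tc)
    detrended = data - correction
    means = data.mean(axis=1)
    max_correction = np.abs(correction).max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(
            np.abs(means) > 1e-12, 100.0 * max_correction / np.abs(means), np.nan
        )
    flagged = np.flatnonzero(~np.isfinite(pct))
    return detrended, QcSummary(percent_adjustment=pct, flagged=flagged)


def detrend_run(run: BoldRun) -> tuple[BoldRun, QcSummary]:
    """Detrended copy of ``run`` plus its QC summary."""
    detrended, qc = detrend_matrix(run.data)
    return replace(run, data=detrended), qc
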