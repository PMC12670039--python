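"""Preparation of epochs for spectral analysis.

Three operations: subtraction of time-locked evoked potentials (per
condition), extraction of the analysis window, and z-scoring of feature
columns. Standardisation deliberately uses the population denominator and is
computed once across all epochs, before any cross-validation split; a
fold-wise mode is available but off by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .epochs import EpochSet


def remove_erp(epochs: EpochSet) -> EpochSet:
    """Subtract the per-condition, per-channel mean time course from each trial.

    Removes time-locked (evoked) activity so that only induced activity
    enters the spectral decomposition. The per-condition trial mean of the
    output is zero to numerical precision; the operation is idempotent.
    """
    data = epochs.data.copy()
    for cond in epochs.condition_ids:
        mask = epochs.labels == cond
        data[mask] -= epochs.data[mask].mean(axis=0, keepdims=True)
    return epochs.copy_with(data=data)


def select_window(epochs: EpochSet, t_start_s: float, t_end_s: float) -> EpochSet:
    """Crop epochs to the half-open interval ``[t_start_s, t_end_s)``.

    Sample indexing is 0-based; the output has
    ``round((t_end_s - t_start_s) * srate)`` samples.
    """
    if t_end_s <= t_start_s:
        raise ValueError("t_end_s must exceed t_start_s")
    i0 = int(round((t_start_s - epochs.time_zero_s) * epochs.srate))
    n_out = int(round((t_end_s - t_start_s) * epochs.srate))
    if i0 < 0 or i0 + n_out > epochs.n_samples:
        raise ValueError(
            f"window [{t_start_s}, {t_end_s}) outside epoch span "
            f"[{epochs.times[0]}, {epochs.time_zero_s + epochs.n_samples / epochs.srate})"
        )
    return epochs.copy_with(
        data=epochs.data[:, :, i0 : i0 + n_out].copy(), time_zero_s=t_start_s
    )


def zscore_features(features):
    """Standardise each column to mean 0, sd 1 across all rows.

    Uses the population standard deviation (denominator ``n``) computed over
    the full set of rows. Accepts a 2-D array or DataFrame and returns the
    same type. A zero-variance column raises an error naming the column.
    """
    is_frame = isinstance(features, pd.DataFrame)
    values = np.asarray(features, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("features must be 2-D (rows x columns)")
    if values.shape[0] < 2:
        raise ValueError("at least 2 rows required")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = (
            [features.columns[i] for i in bad] if is_frame else bad.tolist()
        )
        raise ValueError(f"zero-variance column(s): {names}")
    out = (values - mean) / sd
    if is_frame:
        return pd.DataFrame(out, index=features.index, columns=features.columns)
    return out
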