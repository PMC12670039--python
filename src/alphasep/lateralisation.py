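"""Hemispheric lateralisation metrics and the TMS modulation contrast.

The modulation index (MI) quantifies attend-left vs attend-right
lateralisation of a signal S over posterior electrode groups:

    MI_hemi = (S_hemi^left - S_hemi^right) / (0.5 * (S_hemi^left + S_hemi^right))

computed per hemisphere, with the combined MI = MI_left - MI_right to cancel
hemispheric asymmetries. Positive combined MI means the signal decreases
contralateral to the attended side. S is averaged over trials before
entering the formula (subject-level MI). Slope- and intercept-type signals
may legitimately yield negative MI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import Montage
from .spectral import FeatureTable


@dataclass(frozen=True)
class MIResult:
    """Per-hemisphere and combined modulation index for one signal."""

    signal_name: str
    mi_left: float
    mi_right: float
    mi_combined: float
    subject_id: str


def _group_mean(features: FeatureTable, signal: str, label: int, idx) -> float:
    mask = features.labels == label
    if not mask.any():
        raise ValueError(f"condition {label} has no trials")
    return float(features.signal(signal)[np.ix_(mask, idx)].mean())


def modulation_index(
    features: FeatureTable,
    montage: Montage,
    left_label: int,
    right_label: int,
    signal: str = "osc_alpha",
) -> MIResult:
    """Combined modulation index of one signal for one subject.

    ``left_label`` / ``right_label`` are the attend-left and attend-right
    condition labels; swapping them flips the sign of the combined MI.
    """
    li = montage.indices(montage.left_posterior)
    ri = montage.indices(montage.right_posterior)
    if not li or not ri:
        raise ValueError("posterior electrode groups must be non-empty")
    mis = {}
    for hemi, idx in (("left", li), ("right", ri)):
        s_att_left = _group_mean(features, signal, left_label, idx)
        s_att_right = _group_mean(features, signal, right_label, idx)
        denom = 0.5 * (s_att_left + s_att_right)
        if denom == 0:
            raise ZeroDivisionError(
                f"zero MI denominator for the {hemi} hemisphere"
            )
        mis[hemi] = (s_att_left - s_att_right) / denom
    return MIResult(
        signal_name=signal,
        mi_left=mis["left"],
        mi_right=mis["right"],
        mi_combined=mis["left"] - mis["right"],
        subject_id=features.subject_id,
    )


def topographic_difference(
    cond_a: pd.Series,
    cond_b: pd.Series,
    baseline_a: pd.Series,
    baseline_b: pd.Series,
) -> pd.Series:
    """Baseline-corrected per-channel condition difference.

    Returns ``(A - baseline_A) - (B - baseline_B)`` in linear power units,
    keyed by channel label. All four inputs must cover the same channels.
    """
    series = [pd.Series(s) for s in (cond_a, cond_b, baseline_a, baseline_b)]
    index = series[0].index
    for s in series[1:]:
        if set(s.index) != set(index):
            raise ValueError("channel sets differ between inputs")
    a, b, ba, bb = (s.reindex(index) for s in series)
    return (a - ba) - (b - bb)


def tms_modulation(
    features_rh: FeatureTable,
    features_ar: FeatureTable,
    montage: Montage,
    signal: str = "osc_alpha",
) -> float:
    """Rhythmic-minus-arrhythmic TMS contrast over the stimulation cluster.

    Mean of the signal over trials and the right posterior stimulation
    cluster, rhythmic condition minus arrhythmic condition.
    """
    if not montage.stim_cluster:
        raise ValueError("stimulation cluster is empty")
    for table in (features_rh, features_ar):
        missing = set(montage.stim_cluster) - set(table.channels)
        if missing:
            raise ValueError(f"cluster channels absent from table: {sorted(missing)}")
    def cluster_mean(table: FeatureTable) -> float:
        idx = [table.channels.index(c) for c in montage.stim_cluster]
        return float(table.signal(signal)[:, idx].mean())
    return cluster_mean(features_rh) - cluster_mean(features_ar)


def mi_table(results: list[MIResult]) -> pd.DataFrame:
    """Tidy CSV-ready view of MI results."""
    return pd.DataFrame(
        [
            {
                "subject": r.subject_id,
                "signal": r.signal_name,
                "mi_left": r.mi_left,
                "mi_right": r.mi_right,
                "mi_combined": r.mi_combined,
            }
            for r in results
        ]
    )
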