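"""Composite splicing index (mDSI) from per-event PSI values.

For each splice event *j*, a normalized splicing score anchors the
wild-type median PSI at 0 and a reference disease severity at 1:

    s_ij = (PSI_ij - PSI_wt,j) / (PSI_dm95,j - PSI_wt,j)

where PSI_wt,j is the median PSI across wild-type reference samples and
PSI_dm95,j is the 95th percentile of most-severely-affected PSI across the
disease-model reference cohort.  The severity direction is event-specific
(inclusion may rise or fall in disease), so the 95th percentile is taken
on the signed shift away from the wild-type median in the disease
direction.  The composite index for sample *i* (mDSI) is the arithmetic
mean of s_ij over all test events, excluding the negative control.

Reference anchors are fitted once on a reference cohort and then frozen
(serialized to TSV) so that e.g. treated samples are always scored against
the same anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import SpliceEvent

__all__ = [
    "reference_stats",
    "normalize",
    "mdsi",
    "mdsi_table",
    "events_exceeding_shift",
    "read_reference_stats",
    "write_reference_stats",
    "MdsiResult",
]

#: Default minimum |PSI_dm95 - PSI_wt| for an event to be retained.
DEFAULT_EPSILON = 0.02

#: Minimum reference samples per group.
MIN_REFERENCE_SAMPLES = 3

_REF_COLUMNS = ["event", "psi_wt", "psi_dm95", "direction", "retained", "reason"]


def reference_stats(
    psi: pd.DataFrame,
    wt_ids: Sequence[str],
    disease_ids: Sequence[str],
    epsilon: float = DEFAULT_EPSILON,
    min_samples: int = MIN_REFERENCE_SAMPLES,
) -> pd.DataFrame:
    """Fit per-event normalization anchors from a reference cohort.

    Parameters
    ----------
    psi
        Event x sample PSI matrix on the [0, 1] scale; NaN marks undefined
        (low-coverage) estimates.
    wt_ids, disease_ids
        Disjoint sample-id sets for the wild-type and disease-model
        reference groups.
    epsilon
        Events whose anchor separation |psi_dm95 - psi_wt| falls below
        this floor are dropped (scores would blow up on non-responsive
        events).

    Returns
    -------
    DataFrame indexed by event with columns psi_wt, psi_dm95, direction,
    retained, reason.
    """
    wt_ids = list(wt_ids)
    disease_ids = list(disease_ids)
    if set(wt_ids) & set(disease_ids):
        raise ValueError("wild-type and disease reference sets must be disjoint")
    if len(wt_ids) < min_samples or len(disease_ids) < min_samples:
        raise ValueError(
            f"need at least {min_samples} samples per reference group "
            f"(got {len(wt_ids)} WT, {len(disease_ids)} disease)"
        )
    for sid in [*wt_ids, *disease_ids]:
        if sid not in psi.columns:
            raise KeyError(f"sample {sid!r} missing from PSI matrix")

    rows = []
    for event in psi.index:
        wt = psi.loc[event, wt_ids].astype(float).dropna()
        dis = psi.loc[event, disease_ids].astype(float).dropna()
        if len(wt) < min_samples or len(dis) < min_samples:
            rows.append((event, np.nan, np.nan, 0, False, "insufficient defined PSI"))
            continue
        psi_wt = float(wt.median())
        shift = float(dis.median()) - psi_wt
        if shift == 0:
            rows.append((event, psi_wt, np.nan, 0, False, "no disease shift"))
            continue
        direction = 1 if shift > 0 else -1
        # 95th percentile of the shift in the disease direction
        # (linear interpolation between order statistics)
        q95 = float(np.percentile(direction * (dis.to_numpy() - psi_wt), 95))
        psi_dm95 = psi_wt + direction * q95
        if abs(psi_dm95 - psi_wt) < epsilon:
            rows.append(
                (event, psi_wt, psi_dm95, direction, False, "anchor separation below epsilon")
            )
            continue
        rows.append((event, psi_wt, psi_dm95, direction, True, ""))
    stats = pd.DataFrame(rows, columns=_REF_COLUMNS).set_index("event")
    return stats


def normalize(psi: pd.DataFrame, stats: pd.DataFrame) -> pd.DataFrame:
    """Normalize a PSI matrix to per-event splicing scores.

    Scores are the exact ratio (psi - psi_wt) / (psi_dm95 - psi_wt);
    no clamping, so scores below 0 (better than WT median) or above 1
    (beyond the reference severity) are preserved.  Events dropped during
    anchor fitting are omitted from the output.
    """
    retained = stats.index[stats["retained"].astype(bool)]
    missing = [e for e in retained if e not in psi.index]
    if missing:
        raise KeyError(f"events missing from PSI matrix: {missing}")
    sub = psi.loc[retained].astype(float)
    wt = stats.loc[retained, "psi_wt"].astype(float)
    denom = stats.loc[retained, "psi_dm95"].astype(float) - wt
    return sub.sub(wt, axis=0).div(denom, axis=0)


@dataclass(frozen=True)
class MdsiResult:
    sample_id: str
    mdsi: float
    n_events_used: int
    excluded: tuple[tuple[str, str], ...] = ()  # (event, reason)


def mdsi(
    scores: pd.Series,
    roles: Mapping[str, str],
    sample_id: str = ".",
) -> MdsiResult:
    """Composite index for one sample: mean score over test events.

    ``roles`` maps event id to 'test' or 'negative_control'; the negative
    control and events with undefined scores are excluded (recorded in the
    result).  Raises if no usable test event remains.
    """
    excluded: list[tuple[str, str]] = []
    used: list[float] = []
    for event, value in scores.items():
        role = roles.get(event, "test")
        if role == "negative_control":
            excluded.append((event, "negative control"))
        elif pd.isna(value):
            excluded.append((event, "undefined score"))
        else:
            used.append(float(value))
    if not used:
        raise ValueError(f"sample {sample_id}: no usable test-event scores")
    return MdsiResult(
        sample_id=sample_id,
        mdsi=float(np.mean(used)),
        n_events_used=len(used),
        excluded=tuple(excluded),
    )


def mdsi_table(scores: pd.DataFrame, roles: Mapping[str, str]) -> pd.DataFrame:
    """mDSI for every sample (column) of a score matrix."""
    rows = [
        (sid, r.mdsi, r.n_events_used)
        for sid in scores.columns
        for r in [mdsi(scores[sid], roles, sample_id=sid)]
    ]
    return pd.DataFrame(rows, columns=["sample_id", "mdsi", "n_events_used"]).set_index(
        "sample_id"
    )


def events_exceeding_shift(
    psi: pd.DataFrame,
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Events whose group-mean PSI difference exceeds a threshold.

    Group means are taken over defined PSI values; the comparison is on
    |mean(a) - mean(b)| with a strict ``>`` threshold (default 10
    percentage points on the [0, 1] scale).  Returns a table of all events
    with the shift and an ``exceeds`` flag.
    """
    mean_a = psi.loc[:, list(group_a_ids)].astype(float).mean(axis=1, skipna=True)
    mean_b = psi.loc[:, list(group_b_ids)].astype(float).mean(axis=1, skipna=True)
    delta = mean_a - mean_b
    return pd.DataFrame(
        {"delta_psi": delta, "exceeds": delta.abs() > threshold}
    ).sort_values("delta_psi", key=lambda s: -s.abs())


def write_reference_stats(stats: pd.DataFrame, path: str | Path) -> None:
    stats.reset_index().to_csv(path, sep="\t", index=False)


def read_reference_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["reason"] = df["reason"].fillna("")
    return df.set_index("event")
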