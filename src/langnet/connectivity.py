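"""Resting-state functional connectivity from region-level time series.

Per subject: Pearson correlation between every pair of regional time
courses, Fisher r-to-z transformed.  At the group level two conventions
are supported for handling negative edges, matching the two cohort styles:
average the signed subject matrices and then zero negative group edges
("group_then_zero"), or zero each subject's negative edges before
averaging ("subject_then_zero").
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["fisher_z", "subject_connectivity", "group_connectivity"]

R_CLIP = 1.0 - 1e-7  # keep the transform finite at |r| = 1


def fisher_z(r, clip: float = R_CLIP):
    """Fisher r-to-z: z = arctanh(r), with |r| clipped to ``clip`` first.

    Accepts scalars or arrays; raises on |r| > 1.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0):
        raise ValueError("correlations must satisfy |r| <= 1")
    z = np.arctanh(np.clip(arr, -clip, clip))
    return float(z) if np.isscalar(r) or arr.ndim == 0 else z


def subject_connectivity(series: pd.DataFrame) -> pd.DataFrame:
    """Signed Fisher-z connectivity matrix for one subject.

    ``series`` is regions x timepoints with region ids in the index.
    The diagonal is stored as 0 (self-connectivity is never used).
    """
    x = series.to_numpy(dtype=float)
    if x.shape[1] < 5:
        raise ValueError("need at least 5 timepoints")
    if not np.all(np.isfinite(x)):
        raise ValueError("time series contain non-finite values")
    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [str(series.index[i]) for i in flat]
        raise ValueError(f"region(s) {names} have constant time series")
    r = np.corrcoef(x)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    return pd.DataFrame(z, index=series.index, columns=series.index)


def group_connectivity(
    matrices: Sequence[pd.DataFrame], zero_mode: str = "subject_then_zero"
) -> pd.DataFrame:
    """Average subject matrices into the group connectivity matrix.

    zero_mode "group_then_zero": mean across subjects first, then set
    negative group edges to zero.  "subject_then_zero": zero each
    subject's negative edges, then average.  Both yield a symmetric matrix
    with nonnegative off-diagonals and a zero diagonal.
    """
    mats = list(matrices)
    if not mats:
        raise ValueError("at least one subject matrix is required")
    index = mats[0].index
    for m in mats[1:]:
        if not m.index.equals(index):
            raise ValueError("subject matrices have mismatched region order")
    stack = np.stack([m.to_numpy(dtype=float) for m in mats])
    if zero_mode == "group_then_zero":
        out = stack.mean(axis=0)
        out[out < 0] = 0.0
    elif zero_mode == "subject_then_zero":
        out = np.where(stack < 0, 0.0, stack).mean(axis=0)
    else:
        raise ValueError(f"unknown zero_mode {zero_mode!r}")
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=index, columns=index)
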