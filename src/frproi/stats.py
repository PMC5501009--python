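"""Group-level FRP statistics.

Target and non-target ROI FRPs, paired by participant, are compared with
two-sided paired t-tests at every causal time point of every ROI
(255 x 6 cells on the default grid), and a single Benjamini-Hochberg FDR
correction is applied to the pooled p-value grid.  Late positive (P3)
activity is summarized as the mean amplitude in a 300-700 ms
post-fixation window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel
from statsmodels.stats.multitest import multipletests


@dataclass
class SignificanceMask:
    """Per-(ROI, causal time) p-values and FDR decisions."""

    pvals: np.ndarray            # (n_rois, n_causal_times)
    rejected: np.ndarray         # bool, same shape
    q: float
    times: np.ndarray            # causal times, s
    roi_names: tuple
    degenerate: np.ndarray | None = None   # zero-variance cells

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, roi in enumerate(self.roi_names):
            for j, t in enumerate(self.times):
                rows.append(dict(roi=roi, t_s=float(t),
                                 p=float(self.pvals[i, j]),
                                 rejected=bool(self.rejected[i, j])))
        return pd.DataFrame(rows)


def pointwise_paired_ttest(
    target_frps: np.ndarray,
    nontarget_frps: np.ndarray,
    times: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided paired t-test per (ROI, causal time) cell.

    Parameters
    ----------
    target_frps, nontarget_frps : (n_participants, n_rois, n_times)
        Paired by participant along the first axis.
    times : optional epoch time axis; when given, only causal (t > 0)
        columns are tested.

    Returns
    -------
    pvals, degenerate : arrays (n_rois, n_kept_times); degenerate flags
        cells where the paired differences had zero variance (p set 1).
    """
    a = np.asarray(target_frps, dtype=float)
    b = np.asarray(nontarget_frps, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must share a shape")
    if a.shape[0] < 3:
        raise ValueError("need >= 3 participants")
    if times is not None:
        keep = np.asarray(times) > 0
        a, b = a[..., keep], b[..., keep]
    diff = a - b
    degenerate = diff.std(axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        # zero-variance cells are flagged below; silence scipy's
        # catastrophic-cancellation chatter for them
        warnings.simplefilter("ignore", RuntimeWarning)
        res = ttest_rel(a, b, axis=0)
    p = np.asarray(res.pvalue)
    p[degenerate] = 1.0
    return p, degenerate


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over the *pooled* grid (one correction)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros_like(p, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return rejected.reshape(p.shape)


def significance_mask(target_frps, nontarget_frps, times, roi_names,
                      q: float = 0.05) -> SignificanceMask:
    """Paired tests on the causal grid plus a single pooled FDR pass."""
    p, degenerate = pointwise_paired_ttest(target_frps, nontarget_frps, times)
    return SignificanceMask(pvals=p, rejected=bh_fdr(p, q), q=q,
                            times=np.asarray(times)[np.asarray(times) > 0],
                            roi_names=tuple(roi_names), degenerate=degenerate)


def p3_amplitude(roi_frp: np.ndarray, times: np.ndarray,
                 window: tuple = (0.300, 0.700)) -> float:
    """Mean amplitude over window[0] <= t <= window[1] (endpoints included)."""
    times = np.asarray(times)
    sel = (times >= window[0]) & (times <= window[1])
    if not np.any(sel):
        raise ValueError("window outside the epoch")
    return float(np.mean(np.asarray(roi_frp)[..., sel]))
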