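"""Contrast-to-noise scaling and bolus-bootstrap repeatability.

Averaging n breath-hold boluses should improve CNR like sqrt(n); the
scaling analysis fits mean CNR against the number of boluses averaged
with a radical function ``a*sqrt(b*x) + c``.  Repeatability is probed by
re-estimating gray-matter CBV from every 4-of-8 bolus combination (70
combinations) and summarizing with a one-way random-effects intraclass
correlation across subjects.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocess
from .params import BreathHoldProtocol


@dataclass
class RadicalFit:
    a: float
    b: float
    c: float
    r_squared: float

    def __call__(self, x):
        return self.a * np.sqrt(self.b * np.asarray(x, float)) + self.c


def fit_radical(x, y) -> RadicalFit:
    """Least-squares fit of ``a*sqrt(b*x)+c``.

    Only ``a*sqrt(b)`` is identifiable, so the fit is solved exactly as a
    linear model in ``sqrt(x)`` and reported with ``b = 1``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.unique(x).size < 2:
        raise ValueError("radical fit is underdetermined: need >= 2 distinct x")
    X = np.column_stack([np.sqrt(x), np.ones_like(x)])
    (alpha, c), *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - (alpha * np.sqrt(x) + c)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RadicalFit(a=float(alpha), b=1.0, c=float(c), r_squared=r2)


def cnr_vs_boluses(
    ts: "preprocess.TimeSeries4D",
    protocol: BreathHoldProtocol,
    mask: np.ndarray,
    n_grid=tuple(range(1, 9)),
):
    """Mean in-mask CNR as a function of boluses averaged, with the fit.

    Returns ``(table, fit)``; ``fit`` is None (with a warning) when the
    grid cannot constrain the radical model.
    """
    n_grid = tuple(int(n) for n in n_grid)
    if max(n_grid) > protocol.n_blocks:
        raise ValueError("n_grid exceeds available boluses")
    rows = []
    for n in n_grid:
        bav = preprocess.average_boluses(ts, protocol, n_use=n)
        cnr_map, valid = preprocess.cnr(bav)
        rows.append({"n_boluses": n, "mean_cnr": float(np.nanmean(cnr_map[mask & valid]))})
    table = pd.DataFrame(rows)
    try:
        fit = fit_radical(table["n_boluses"], table["mean_cnr"])
    except ValueError as exc:
        warnings.warn(f"radical fit not performed: {exc}")
        fit = None
    return table, fit


def bolus_combinations(n_boluses: int = 8, k_choose: int = 4):
    """Deterministic enumeration of all k-of-n bolus combinations."""
    return list(itertools.combinations(range(n_boluses), k_choose))


def bolus_bootstrap_icc(
    subject_data: list,
    pipeline,
    n_boluses: int = 8,
    k_choose: int = 4,
    literal_within_total: bool = False,
):
    """Choose-k-of-n bolus bootstrap with a one-way random-effects ICC.

    ``subject_data`` holds one object per subject; ``pipeline(subject,
    combination)`` must return the scalar estimate (e.g. mean GM CBV) for
    that bolus combination.  Returns ``(icc, table)`` where the table has
    one row per subject x combination.

    The default ICC is the standard one-way single-measurement estimator
    ICC(1,1) = (MSB - MSW) / (MSB + (k-1) MSW), i.e. between-subject over
    total variance.  ``literal_within_total=True`` instead returns the
    within-subject share of total variance (1 - ICC-like ratio), for
    comparison with the looser verbal definition sometimes used.
    """
    if len(subject_data) < 2:
        raise ValueError("ICC needs at least two subjects")
    combos = bolus_combinations(n_boluses, k_choose)
    rows = []
    for s, subj in enumerate(subject_data):
        for c, combo in enumerate(combos):
            rows.append({"subject": s, "combination": c,
                         "value": float(pipeline(subj, combo))})
    table = pd.DataFrame(rows)
    wide = table.pivot(index="combination", columns="subject", values="value").to_numpy()
    k, n = wide.shape  # k measurements per subject, n subjects
    grand = wide.mean()
    subj_means = wide.mean(axis=0)
    ss_between = k * ((subj_means - grand) ** 2).sum()
    ss_within = ((wide - subj_means[None, :]) ** 2).sum()
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    icc = (msb - msw) / (msb + (k - 1) * msw)
    if literal_within_total:
        icc = 1.0 - icc
    return float(icc), table
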