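"""Exact Bayesian differential expression for unreplicated count libraries.

With one library per condition there are no replicates; significance is
assessed with the Audic-Claverie test, which scores the observed treatment
count y against its posterior predictive distribution given the control
count x and the two library sizes N1, N2 (r = N2/N1):

    P(Y = y | x) = r^y * (x + y)! / (x! y! (1 + r)^(x + y + 1))

The two-sided p-value doubles the smaller tail, capped at 1.  All mass
sums are computed in log space; the upper tail is summed directly (never as
1 - cdf), so tiny tails keep full relative accuracy.

Expression levels are reported as reads per million (RPM) of the library's
clean reads; a zero count is replaced by 0.01 reads when a fold-change must
be formed (the p-value always uses the true zeros).  Calls use the raw-p
gate p <= 0.01 together with a two-fold change; Benjamini-Hochberg adjusted
p-values are reported alongside but do not gate by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from srnapipe.mirna_known import MirnaCountRow

PSEUDOCOUNT = 0.01


def normalize_tpm(count: float, library_size: float) -> float:
    """Reads-per-million normalization: 1e6 * count / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return 1e6 * count / library_size


def _log_pmf(yv: np.ndarray, x: int, log_r: float, log_1pr: float) -> np.ndarray:
    return (
        yv * log_r
        + gammaln(x + yv + 1)
        - gammaln(x + 1)
        - gammaln(yv + 1)
        - (x + yv + 1) * log_1pr
    )


def ac_pvalue(x: int, y: int, N1: float, N2: float) -> float:
    """Two-sided Audic-Claverie p-value for counts x (control) and y (treatment).

    p = min(1, 2 * min(P(Y <= y | x), P(Y >= y | x))); always in (0, 1].
    """
    for name, v in (("x", x), ("y", y)):
        if not float(v).is_integer() or v < 0:
            raise ValueError(f"count {name} must be a non-negative integer, got {v}")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library sizes must be > 0")
    x, y = int(x), int(y)
    r = N2 / N1
    log_r = math.log(r)
    log_1pr = math.log1p(r)

    lower = logsumexp(_log_pmf(np.arange(0, y + 1), x, log_r, log_1pr))

    # upper tail: direct summation from y until the terms are negligible
    block = 1024
    start = y
    total = -np.inf
    while True:
        yv = np.arange(start, start + block)
        lp = _log_pmf(yv, x, log_r, log_1pr)
        total = np.logaddexp(total, logsumexp(lp))
        start += block
        # past the mode the terms decay geometrically; stop once the last
        # term can no longer move the sum
        if lp[-1] < lp[0] and lp[-1] < total - 40:
            break
    upper = total

    p = 2.0 * math.exp(min(lower, upper))
    return min(1.0, p)


@dataclass
class DifferentialCall:
    mirna_id: str
    x: int
    y: int
    N1: float
    N2: float
    norm_x: float
    norm_y: float
    log2fc: float
    p_value: float
    p_bh: float
    call: str  # up | down | unchanged


def call_differential(
    rows: Sequence[MirnaCountRow] | pd.DataFrame,
    control: str,
    treatment: str,
    library_sizes: Mapping[str, float],
    p_threshold: float = 0.01,
    fc_threshold: float = 2.0,
) -> list[DifferentialCall]:
    """Call per-miRNA differential expression between two libraries.

    ``rows`` is a known/novel count matrix (MirnaCountRow list or a frame
    with mirna_id plus one column per library).  up: log2FC >= log2(fc) and
    p <= threshold; down symmetric; everything else unchanged.
    """
    for lib in (control, treatment):
        if lib not in library_sizes:
            raise ValueError(f"library {lib!r} missing from library_sizes")
    N1, N2 = library_sizes[control], library_sizes[treatment]
    if isinstance(rows, pd.DataFrame):
        for lib in (control, treatment):
            if lib not in rows.columns:
                raise ValueError(f"library {lib!r} missing from count matrix")
        items = [(r.mirna_id, int(r[control]), int(r[treatment])) for r in rows.itertuples()]
    else:
        items = [(r.mirna_id, r.counts.get(control, 0), r.counts.get(treatment, 0)) for r in rows]

    lfc_gate = math.log2(fc_threshold)
    calls: list[DifferentialCall] = []
    for mid, x, y in items:
        nx = normalize_tpm(x if x > 0 else PSEUDOCOUNT, N1)
        ny = normalize_tpm(y if y > 0 else PSEUDOCOUNT, N2)
        lfc = math.log2(ny / nx)
        p = ac_pvalue(x, y, N1, N2)
        calls.append(DifferentialCall(mid, x, y, N1, N2,
                                      normalize_tpm(x, N1), normalize_tpm(y, N2),
                                      lfc, p, math.nan, "unchanged"))
    if calls:
        _, p_bh, _, _ = multipletests([c.p_value for c in calls], method="fdr_bh")
        for c, pb in zip(calls, p_bh):
            c.p_bh = float(pb)
            if c.p_value <= p_threshold and c.log2fc >= lfc_gate:
                c.call = "up"
            elif c.p_value <= p_threshold and c.log2fc <= -lfc_gate:
                c.call = "down"
    return calls


def calls_frame(calls: Sequence[DifferentialCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.mirna_id, c.x, c.y, c.norm_x, c.norm_y, c.log2fc, c.p_value, c.p_bh, c.call)
            for c in calls
        ],
        columns=["mirna_id", "x", "y", "norm_x", "norm_y", "log2fc", "p", "p_bh", "call"],
    )
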