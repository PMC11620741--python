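"""Multisensory and sequence integration indices; inverse effectiveness.

Two normalizations of the multisensory response M against its unisensory
components T (tectal) and A (auditory):

* MSI/Max = M / max(T, A)   — >1 means multisensory enhancement;
* MSI/Sum = M / (T + A)     — >1 supralinear, =1 linear, <1 sublinear.

For paired stimuli 50 ms apart the S1-S2 integration index
Resp(1+2) / (Resp1 + Resp2) plays the same role, with Resp1 the lingering
contribution of the first stimulus measured 50 ms after its onset on
S1-only trials.

Inverse effectiveness is the negative dependence of either index on the
magnitude of the unisensory responses, assessed by an ordinary
least-squares regression with an F test of the slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .errors import UndefinedIndexError, StatError


@dataclass(frozen=True)
class MSIRecord:
    M_mV: float
    T_mV: float
    A_mV: float
    msi_max: float
    msi_sum: float
    condition: str = ""

    @property
    def enhancement(self) -> bool:
        return self.msi_max > 1.0

    @property
    def supralinear(self) -> bool:
        return self.msi_sum > 1.0


@dataclass(frozen=True)
class SeqIntegration:
    resp1_mV: float
    resp2_mV: float
    resp12_mV: float
    s1s2_index: float
    sequence: str


@dataclass(frozen=True)
class InverseEffectivenessFit:
    slope: float
    intercept: float
    F_stat: float
    p_value: float
    n: int
    predictor: str
    response: str


def msi_indices(M_mV: float, T_mV: float, A_mV: float,
                condition: str = "") -> MSIRecord:
    """Both multisensory indices for one cell x condition."""
    if max(T_mV, A_mV) <= 0 or (T_mV + A_mV) <= 0:
        raise UndefinedIndexError(
            f"indices undefined for T={T_mV}, A={A_mV} (non-positive denominator)")
    return MSIRecord(
        M_mV=M_mV, T_mV=T_mV, A_mV=A_mV,
        msi_max=M_mV / max(T_mV, A_mV),
        msi_sum=M_mV / (T_mV + A_mV),
        condition=condition,
    )


def s1s2_index(resp1_mV: float, resp2_mV: float, resp12_mV: float,
               sequence: str) -> SeqIntegration:
    """S1-S2 integration index Resp(1+2)/(Resp1 + Resp2).

    For multisensory sequences (AT, TA) this equals MSI/Sum up to the 50-ms
    offset in how the first component is measured.
    """
    denom = resp1_mV + resp2_mV
    if denom <= 0:
        raise UndefinedIndexError(
            f"S1-S2 index undefined for resp1={resp1_mV}, resp2={resp2_mV}")
    return SeqIntegration(resp1_mV, resp2_mV, resp12_mV,
                          resp12_mV / denom, sequence)


def inverse_effectiveness(
    records: Sequence[MSIRecord],
    response: str = "msi_max",
    predictor: str = "max_unisensory",
) -> InverseEffectivenessFit:
    """OLS fit of an MSI index on unisensory response magnitude.

    ``predictor`` is ``max_unisensory`` (max(T, A)) or ``sum_unisensory``
    (T + A); ``response`` is ``msi_max`` or ``msi_sum``.  Reports the slope
    and the F test of the slope (df 1, n-2).
    """
    recs = list(records)
    n = len(recs)
    if n < 3:
        raise StatError(f"need >= 3 records for a regression, got {n}")
    if predictor == "max_unisensory":
        x = np.array([max(r.T_mV, r.A_mV) for r in recs])
    elif predictor == "sum_unisensory":
        x = np.array([r.T_mV + r.A_mV for r in recs])
    else:
        raise StatError(f"unknown predictor {predictor!r}")
    if response == "msi_max":
        y = np.array([r.msi_max for r in recs])
    elif response == "msi_sum":
        y = np.array([r.msi_sum for r in recs])
    else:
        raise StatError(f"unknown response {response!r}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StatError("non-finite values in regression inputs")
    if np.var(x) == 0:
        raise StatError("degenerate predictor: zero variance")

    slope, intercept, F, p = _ols_f(x, y)
    return InverseEffectivenessFit(slope, intercept, F, p, n,
                                   predictor=predictor, response=response)


def _ols_f(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Closed-form simple OLS with the F test of the slope."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    yhat = intercept + slope * x
    sse = float(np.sum((y - yhat) ** 2))
    ssr = float(np.sum((yhat - ym) ** 2))
    if sse <= 0:
        return float(slope), float(intercept), float("inf"), 0.0
    F = ssr / (sse / (n - 2))
    p = float(sps.f.sf(F, 1, n - 2))
    return float(slope), float(intercept), float(F), p
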