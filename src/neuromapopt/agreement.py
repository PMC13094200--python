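"""Inter-method agreement between the two optimal-MAP estimates.

Sessions repeat within patients, so the correlation between the PRx-derived
and the P2/P1-derived optimal MAP is assessed with the repeated-measures
correlation (rmcorr): the common within-patient correlation from the ANCOVA
decomposition with patient as a factor and a shared slope,

    r_rm = SS_xy / sqrt(SS_xx * SS_yy),   df = N - k - 1,

where the sums of squares/products are taken over within-patient-centred
values (N observations, k patients).  Agreement is summarised with classic
Bland-Altman statistics on the per-session differences, fixed in the
orientation PRx-method minus P2/P1-method, plus the fraction of sessions
whose absolute difference stays within a clinical threshold (default 6 mmHg)
and an ordinary least-squares line of the P2/P1-derived on the PRx-derived
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SessionPair",
    "RmcorrResult",
    "BlandAltmanResult",
    "AgreementReport",
    "repeated_measures_corr",
    "bland_altman",
    "within_threshold_fraction",
    "linear_fit",
    "build_report",
    "pairs_to_dataframe",
]


@dataclass
class SessionPair:
    """One monitoring session's pair of optimal-MAP estimates (mmHg)."""

    patient_id: str
    session_id: str
    mapopt_prx: float | None
    mapopt_p2p1: float | None

    @property
    def both_valid(self) -> bool:
        return self.mapopt_prx is not None and self.mapopt_p2p1 is not None

    @property
    def difference(self) -> float:
        """PRx-method minus P2/P1-method, mmHg."""
        return self.mapopt_prx - self.mapopt_p2p1


@dataclass
class RmcorrResult:
    r: float
    ci95: tuple[float, float]
    p_value: float
    df: int


@dataclass
class BlandAltmanResult:
    bias: float          # mean difference, mmHg
    sd_diff: float       # sample SD (n-1), mmHg
    loa_low: float       # bias - multiplier * sd
    loa_high: float
    loa_multiplier: float
    means: np.ndarray    # per-pair (x+y)/2, for plotting
    diffs: np.ndarray


@dataclass
class AgreementReport:
    rmcorr: RmcorrResult | None
    bland: BlandAltmanResult | None
    fraction_within_threshold: float | None
    threshold: float
    slope: float | None
    intercept: float | None
    n_sessions: int
    n_patients: int


def _valid_arrays(pairs: list[SessionPair]):
    kept = [p for p in pairs if p.both_valid]
    pid = np.asarray([p.patient_id for p in kept])
    x = np.asarray([p.mapopt_prx for p in kept], dtype=float)
    y = np.asarray([p.mapopt_p2p1 for p in kept], dtype=float)
    return pid, x, y


def repeated_measures_corr(pairs: list[SessionPair]) -> RmcorrResult:
    """Common within-patient correlation between the two estimates.

    95% CI via the Fisher z-transform with standard error 1/sqrt(df - 1)
    (the repeated-measures analogue of the 1/sqrt(n-3) Pearson rule on
    df = N - k - 1); p-value from the t distribution on the same df.  With a
    single patient this reduces exactly to that patient's Pearson
    correlation.  Raises on zero within-patient variance.
    """
    pid, x, y = _valid_arrays(pairs)
    n = x.size
    if n < 3:
        raise ValueError("rmcorr needs at least 3 valid session pairs")
    groups = pd.Series(pid)
    xc = x - groups.map(pd.Series(x).groupby(groups).mean()).to_numpy()
    yc = y - groups.map(pd.Series(y).groupby(groups).mean()).to_numpy()
    ss_xx = float(np.sum(xc**2))
    ss_yy = float(np.sum(yc**2))
    ss_xy = float(np.sum(xc * yc))
    if ss_xx <= 0 or ss_yy <= 0:
        raise ValueError("zero within-patient variance; rmcorr undefined")
    r = ss_xy / np.sqrt(ss_xx * ss_yy)
    r = float(np.clip(r, -1.0, 1.0))
    k = len(np.unique(pid))
    df = n - k - 1
    if df < 1:
        raise ValueError("not enough error degrees of freedom for rmcorr")
    if abs(r) < 1.0:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * stats.t.sf(abs(t), df)
    else:
        p = 0.0
    if df > 2 and abs(r) < 1.0:
        z = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(df - 1)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (r, r)
    return RmcorrResult(r=r, ci95=ci, p_value=float(p), df=int(df))


def bland_altman(
    pairs: list[SessionPair], loa_multiplier: float = 1.96
) -> BlandAltmanResult:
    """Bias and 95% limits of agreement of (PRx-method minus P2/P1-method)."""
    _, x, y = _valid_arrays(pairs)
    if x.size < 2:
        raise ValueError("Bland-Altman needs at least 2 valid pairs")
    diffs = x - y
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd,
        loa_multiplier=loa_multiplier,
        means=(x + y) / 2.0,
        diffs=diffs,
    )


def within_threshold_fraction(pairs: list[SessionPair], threshold: float = 6.0) -> float:
    """Fraction of valid pairs with |difference| <= threshold (closed boundary)."""
    _, x, y = _valid_arrays(pairs)
    if x.size == 0:
        raise ValueError("no valid pairs")
    return float(np.mean(np.abs(x - y) <= threshold))


def linear_fit(pairs: list[SessionPair]) -> tuple[float, float]:
    """OLS of the P2/P1-derived on the PRx-derived estimate: returns (slope, intercept)."""
    _, x, y = _valid_arrays(pairs)
    if x.size < 2:
        raise ValueError("linear fit needs at least 2 valid pairs")
    if np.var(x) <= 0:
        raise ValueError("zero variance in PRx-derived estimates; fit undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def build_report(pairs: list[SessionPair], threshold: float = 6.0) -> AgreementReport:
    """Assemble every agreement statistic that the pair count permits."""
    pid, x, y = _valid_arrays(pairs)
    n = x.size
    n_pat = len(np.unique(pid)) if n else 0
    rm = None
    try:
        rm = repeated_measures_corr(pairs)
    except ValueError:
        pass
    ba = None
    try:
        ba = bland_altman(pairs)
    except ValueError:
        pass
    frac = within_threshold_fraction(pairs, threshold) if n >= 1 else None
    slope = intercept = None
    try:
        slope, intercept = linear_fit(pairs)
    except ValueError:
        pass
    return AgreementReport(
        rmcorr=rm,
        bland=ba,
        fraction_within_threshold=frac,
        threshold=threshold,
        slope=slope,
        intercept=intercept,
        n_sessions=n,
        n_patients=n_pat,
    )


def pairs_to_dataframe(pairs: list[SessionPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in pairs],
            "session_id": [p.session_id for p in pairs],
            "mapopt_prx_mmhg": [p.mapopt_prx for p in pairs],
            "mapopt_p2p1_mmhg": [p.mapopt_p2p1 for p in pairs],
        }
    )


def pairs_from_dataframe(df: pd.DataFrame) -> list[SessionPair]:
    pairs = []
    for _, row in df.iterrows():
        x = row["mapopt_prx_mmhg"]
        y = row["mapopt_p2p1_mmhg"]
        pairs.append(
            SessionPair(
                patient_id=str(row["patient_id"]),
                session_id=str(row["session_id"]),
                mapopt_prx=None if pd.isna(x) else float(x),
                mapopt_p2p1=None if pd.isna(y) else float(y),
            )
        )
    return pairs
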