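"""Trial statistics: normality routing, paired comparisons with
Hodges-Lehmann confidence intervals, crossover analysis tables, and
Wilcoxon signed-rank power via the asymptotic-relative-efficiency (ARE)
method.

The power calculation mirrors the G*Power convention: the signed-rank
test's power is evaluated with paired-t machinery on an
efficiency-deflated sample size,

    n_eff = ARE * n,   df = n_eff - 1,   delta = dz * sqrt(n_eff),

with ARE = 3/pi (the normal-parent value) by default, continuous
(non-integer) degrees of freedom, and two-sided power from the
noncentral t distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

NORMAL_PARENT_ARE = 3.0 / math.pi


# ---------------------------------------------------------------------------
# Normality routing
# ---------------------------------------------------------------------------

@dataclass
class NormalityAssessment:
    sw_p: float
    skewness: float
    excess_kurtosis: float
    route: str  # 'parametric' or 'nonparametric'


def assess_normality(values: Sequence[float], sw_alpha: float = 0.05,
                     skew_max: float = 2.0,
                     kurt_max: float = 7.0) -> NormalityAssessment:
    """Shapiro-Wilk combined with skewness/kurtosis screens.

    Routes to 'parametric' only when the Shapiro-Wilk test retains the
    null and both moments are inside their bounds.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(x) == 0:
        raise ValueError("normality undefined for a constant sample")
    sw_p = float(sps.shapiro(x).pvalue)
    skew = float(sps.skew(x))
    kurt = float(sps.kurtosis(x))  # excess (Fisher)
    route = ("parametric"
             if sw_p >= sw_alpha and abs(skew) <= skew_max
             and abs(kurt) <= kurt_max
             else "nonparametric")
    return NormalityAssessment(sw_p, skew, kurt, route)


# ---------------------------------------------------------------------------
# Hodges-Lehmann estimate and CI
# ---------------------------------------------------------------------------

def _signrank_cdf(n: int) -> np.ndarray:
    """Null CDF of the signed-rank statistic W+ for sample size n."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:m + 1 - r]
        counts = counts + shifted
    return np.cumsum(counts) / counts.sum()


def _signrank_quantile(p: float, n: int) -> int:
    """Smallest q with P(W+ <= q) >= p under the null."""
    cdf = _signrank_cdf(n)
    return int(np.searchsorted(cdf, p - 1e-12))


def hodges_lehmann_ci(differences: Sequence[float], conf_level: float = 0.95
                      ) -> tuple[float, float, float]:
    """Hodges-Lehmann estimate with a signed-rank-inverted CI.

    The estimate is the median of the n(n+1)/2 Walsh averages.  CI
    endpoints are Walsh-average order statistics at ranks from the exact
    signed-rank null distribution for n <= 50, and from its normal
    approximation above.
    """
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 differences")
    sums = d[:, None] + d[None, :]
    walsh = np.sort(sums[np.triu_indices(n)] / 2.0)
    estimate = float(np.median(walsh))
    m = n * (n + 1) // 2
    alpha = 1.0 - conf_level
    if n <= 50:
        qu = _signrank_quantile(alpha / 2.0, n)
    else:
        sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        z = sps.norm.ppf(alpha / 2.0)
        qu = int(round(m / 2.0 + z * sigma))
    qu = max(qu, 1)
    ql = m - qu
    ci_low = float(walsh[qu - 1])
    ci_high = float(walsh[min(ql, m - 1)])
    return estimate, ci_low, ci_high


# ---------------------------------------------------------------------------
# Paired comparison
# ---------------------------------------------------------------------------

@dataclass
class PairedSample:
    arm_a: np.ndarray
    arm_b: np.ndarray
    patient_ids: Optional[list] = None
    outcome: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.arm_a = np.asarray(self.arm_a, dtype=float)
        self.arm_b = np.asarray(self.arm_b, dtype=float)
        if len(self.arm_a) != len(self.arm_b):
            raise ValueError("paired arms must have equal length")
        if len(self.arm_a) < 2:
            raise ValueError("need at least 2 pairs")
        if not (np.all(np.isfinite(self.arm_a))
                and np.all(np.isfinite(self.arm_b))):
            raise ValueError("paired values must be finite")


@dataclass
class PairedTestResult:
    method: str  # 'paired_t' or 'wilcoxon_signed_rank'
    statistic: float
    p_two_sided: float
    point_estimate: float
    ci_low: float
    ci_high: float
    conf_level: float
    degenerate: bool = False
    normality: Optional[NormalityAssessment] = None


def _wilcoxon_test(d: np.ndarray) -> tuple[float, float]:
    """Signed-rank test: zeros dropped, exact when n <= 25 with no ties,
    otherwise normal approximation with continuity correction."""
    nz = d[d != 0]
    if len(nz) == 0:
        return 0.0, 1.0
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(nz, zero_method="wilcox", correction=(method == "approx"),
                       method=method, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def paired_compare(sample: PairedSample,
                   conf_level: float = 0.95) -> PairedTestResult:
    """Paired comparison of arm B against arm A (differences d = B - A).

    Normally distributed differences get a paired t-test with a t-based
    CI on the mean difference; otherwise a Wilcoxon signed-rank test with
    the Hodges-Lehmann estimate and CI.
    """
    d = sample.arm_b - sample.arm_a
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(d == 0):
        return PairedTestResult("wilcoxon_signed_rank", 0.0, 1.0, 0.0,
                                0.0, 0.0, conf_level, degenerate=True)
    try:
        normality = assess_normality(d)
        route = normality.route
    except ValueError:
        normality, route = None, "nonparametric"

    if route == "parametric":
        mean = float(np.mean(d))
        sem = float(sps.sem(d))
        tstat = mean / sem
        p = 2.0 * sps.t.sf(abs(tstat), n - 1)
        half = sps.t.ppf(0.5 + conf_level / 2.0, n - 1) * sem
        return PairedTestResult("paired_t", tstat, float(p), mean,
                                mean - half, mean + half, conf_level,
                                normality=normality)
    stat, p = _wilcoxon_test(d)
    est, lo, hi = hodges_lehmann_ci(d, conf_level)
    return PairedTestResult("wilcoxon_signed_rank", stat, p, est, lo, hi,
                            conf_level, normality=normality)


# ---------------------------------------------------------------------------
# Wilcoxon power via ARE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    dz: float
    alpha: float = 0.05
    n_pairs: int = 2
    are: float = NORMAL_PARENT_ARE
    two_tailed: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.are <= 1.5):
            raise ValueError("are must be in (0, 1.5]")
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be at least 2")


@dataclass
class PowerResult:
    effective_n: float
    df: float
    delta: float
    t_crit: float
    power: float


def wilcoxon_power(spec: PowerSpec) -> PowerResult:
    """Two-sided signed-rank power by the ARE method (noncentral t with
    continuous degrees of freedom on the efficiency-deflated n)."""
    eff_n = spec.are * spec.n_pairs
    df = eff_n - 1.0
    if df <= 0:
        raise ValueError("effective degrees of freedom must be positive")
    delta = spec.dz * math.sqrt(eff_n)
    tail = spec.alpha / 2.0 if spec.two_tailed else spec.alpha
    t_crit = float(sps.t.ppf(1.0 - tail, df))
    power = float(sps.nct.sf(t_crit, df, delta))
    if spec.two_tailed:
        power += float(sps.nct.cdf(-t_crit, df, delta))
    return PowerResult(effective_n=eff_n, df=df, delta=delta,
                       t_crit=t_crit, power=power)


def required_pairs(dz: float, alpha: float = 0.05,
                   target_power: float = 0.95,
                   are: float = NORMAL_PARENT_ARE,
                   max_n: int = 10 ** 6) -> int:
    """Smallest n with wilcoxon_power(...).power >= target_power."""
    if dz == 0:
        raise ValueError("dz must be nonzero")
    if not (alpha < target_power < 1):
        raise ValueError("target_power must be in (alpha, 1)")
    n = 2
    while n <= max_n:
        if are * n - 1.0 > 0:
            if wilcoxon_power(PowerSpec(dz=dz, alpha=alpha, n_pairs=n,
                                        are=are)).power >= target_power:
                return n
        n += 1
    raise RuntimeError("no sample size met the target power within bounds")


# ---------------------------------------------------------------------------
# Crossover analysis table
# ---------------------------------------------------------------------------

def _arm_summary(values: np.ndarray, route: str) -> str:
    if route == "parametric":
        return f"{np.mean(values):.1f} ({np.std(values, ddof=1):.1f})"
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f} to {q3:.1f})"


def analyze_crossover(summaries: pd.DataFrame,
                      outcomes: Optional[Sequence[str]] = None,
                      conf_level: float = 0.95,
                      arm_col: str = "arm",
                      patient_col: str = "patient_id",
                      arms: tuple = ("conventional", "closed_loop")
                      ) -> pd.DataFrame:
    """Paired per-outcome analysis of a two-arm crossover table.

    ``summaries`` has one row per (patient, arm); differences are
    closed-loop minus conventional.  Returns one row per outcome with the
    per-arm summaries (median/IQR or mean/SD per the normality routing),
    the point estimate with CI, and the two-sided p-value.
    """
    ref_arm, test_arm = arms
    wide = summaries.pivot(index=patient_col, columns=arm_col)
    if outcomes is None:
        outcomes = [c for c in summaries.columns
                    if c not in (arm_col, patient_col)
                    and pd.api.types.is_numeric_dtype(summaries[c])]
    rows = []
    for outcome in outcomes:
        if outcome not in summaries.columns:
            rows.append({"outcome": outcome, "missing": True})
            continue
        sub = wide[outcome].dropna()
        if len(sub) < 3 or ref_arm not in sub.columns or test_arm not in sub.columns:
            rows.append({"outcome": outcome, "missing": True})
            continue
        a = sub[ref_arm].to_numpy(dtype=float)
        b = sub[test_arm].to_numpy(dtype=float)
        res = paired_compare(PairedSample(a, b, outcome=outcome), conf_level)
        route = (res.normality.route if res.normality is not None
                 else "nonparametric")
        rows.append({
            "outcome": outcome,
            "missing": False,
            f"{test_arm}_summary": _arm_summary(b, route),
            f"{ref_arm}_summary": _arm_summary(a, route),
            "method": res.method,
            "estimate": res.point_estimate,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "p_value": res.p_two_sided,
            "n_pairs": len(sub),
        })
    return pd.DataFrame(rows)
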