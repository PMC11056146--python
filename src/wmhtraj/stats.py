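"""Statistical battery over per-class tissue means.

Cross-sectionally each quantitative parameter is compared across the four
tissue classes with a one-way repeated-measures ANOVA (subjects are the
repeated factor) using the Greenhouse-Geisser sphericity correction, followed
by Tukey honestly-significant-difference pairwise contrasts based on the
pooled within-subject error term. Longitudinally, baseline-vs-1-year paired
t tests are run per class and parameter, with Holm's step-down adjustment
applied over the whole 12-test family (3 parameters x 4 classes).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps


@dataclass
class RmAnovaResult:
    f: float
    df1: float  # GG-corrected
    df2: float
    epsilon: float
    p: float
    df1_uncorrected: float
    df2_uncorrected: float


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    estimate: float
    ci_low: float
    ci_high: float
    p_adj: float


@dataclass
class PairedTestRow:
    label: str
    estimate: float  # mean(fu - bl)
    ci_low: float
    ci_high: float
    p_raw: float
    p_holm: float = np.nan
    n: int = 0


def class_means(
    quant_map: np.ndarray,
    masks: dict[str, np.ndarray],
    converged: np.ndarray | None = None,
) -> dict[str, float]:
    """Within-mask arithmetic means of a quantitative map, per class.

    Non-finite voxels and (optionally) non-converged fits are excluded; an
    empty class after exclusion yields NaN so the subject can be dropped
    listwise downstream.
    """
    vol = np.asarray(quant_map, dtype=float)
    out: dict[str, float] = {}
    for name, mask in masks.items():
        m = np.asarray(mask, dtype=bool) & np.isfinite(vol)
        if converged is not None:
            m &= np.asarray(converged, dtype=bool)
        out[name] = float(vol[m].mean()) if m.any() else float("nan")
    return out


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity estimate for an n x k conditions matrix.

    epsilon-hat = (sum lambda)^2 / ((k-1) sum lambda^2) with lambda the
    eigenvalues of the double-centered sample covariance of the k conditions;
    clipped to [1/(k-1), 1]. Equals 1 under compound symmetry.
    """
    x = np.asarray(data, dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need n >= 2 subjects and k >= 2 conditions")
    s = np.cov(x, rowvar=False)
    c = np.eye(k) - np.ones((k, k)) / k
    sdc = c @ s @ c
    tr = np.trace(sdc)
    tr2 = np.trace(sdc @ sdc)
    if tr2 <= 0:
        import warnings

        warnings.warn("zero within-subject covariance; epsilon set to 1")
        return 1.0
    eps = tr * tr / ((k - 1) * tr2)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_gg(data: np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction."""
    x = np.asarray(data, dtype=float)
    if np.isnan(x).any():
        raise ValueError("complete cases only: remove subjects with missing conditions")
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1 = k - 1.0
    df2 = (k - 1.0) * (n - 1.0)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    f = ms_cond / ms_err if ms_err > 0 else 0.0
    eps = gg_epsilon(x)
    p = float(sps.f.sf(f, eps * df1, eps * df2)) if ms_err > 0 else (1.0 if f == 0 else 0.0)
    return RmAnovaResult(
        f=float(f),
        df1=eps * df1,
        df2=eps * df2,
        epsilon=eps,
        p=p,
        df1_uncorrected=df1,
        df2_uncorrected=df2,
    )


def tukey_pairwise(
    data: np.ndarray,
    labels: list[str] | None = None,
    alpha: float = 0.05,
    per_pair_error: bool = False,
) -> list[PairwiseComparison]:
    """Tukey HSD contrasts between repeated-measures conditions.

    Uses the pooled within-subject mean-square error: SE = sqrt(2 MS_err / n),
    p from the studentized range at q = |diff| sqrt(2) / SE with k groups and
    (k-1)(n-1) error df, and CI half-width q_crit SE / sqrt(2). With
    ``per_pair_error`` the SE of each contrast comes from that pair's paired
    differences instead (sensitivity analysis).
    """
    x = np.asarray(data, dtype=float)
    n, k = x.shape
    if labels is None:
        labels = [f"c{i}" for i in range(k)]
    # per-pair mode uses that pair's paired-difference SE and its n-1 df
    df_err = (n - 1) if per_pair_error else (k - 1) * (n - 1)
    grand = x.mean()
    ss_tot = np.sum((x - grand) ** 2)
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ms_err = (ss_tot - ss_cond - ss_subj) / df_err
    means = x.mean(axis=0)
    out = []
    qcrit = sps.studentized_range.ppf(1 - alpha, k, df_err)
    for i, j in combinations(range(k), 2):
        est = float(means[i] - means[j])
        if per_pair_error:
            d = x[:, i] - x[:, j]
            se_q = float(d.std(ddof=1) / np.sqrt(n))
        else:
            se_q = float(np.sqrt(2.0 * ms_err / n))
        if se_q <= 0:
            p_adj = 0.0 if est != 0 else 1.0
            half = 0.0
        else:
            q = abs(est) * np.sqrt(2.0) / se_q
            p_adj = float(sps.studentized_range.sf(q, k, df_err))
            half = float(qcrit * se_q / np.sqrt(2.0))
        out.append(
            PairwiseComparison(
                pair=(labels[i], labels[j]),
                estimate=est,
                ci_low=est - half,
                ci_high=est + half,
                p_adj=min(max(p_adj, 0.0), 1.0),
            )
        )
    return out


def paired_tests(
    data_bl: np.ndarray,
    data_fu: np.ndarray,
    labels: list[str] | None = None,
    ci_level: float = 0.95,
) -> list[PairedTestRow]:
    """Classical paired t test per condition column (estimate = fu - bl)."""
    bl = np.asarray(data_bl, dtype=float)
    fu = np.asarray(data_fu, dtype=float)
    if bl.shape != fu.shape:
        raise ValueError("baseline and follow-up matrices must be matched")
    n, k = bl.shape
    if labels is None:
        labels = [f"c{i}" for i in range(k)]
    rows = []
    for j in range(k):
        d = fu[:, j] - bl[:, j]
        est = float(d.mean())
        sd = float(d.std(ddof=1))
        if sd == 0.0:
            p = 1.0 if est == 0.0 else 0.0
            half = 0.0
        else:
            t = est / (sd / np.sqrt(n))
            p = float(2.0 * sps.t.sf(abs(t), n - 1))
            half = float(sps.t.ppf(0.5 + ci_level / 2.0, n - 1) * sd / np.sqrt(n))
        rows.append(
            PairedTestRow(
                label=labels[j], estimate=est, ci_low=est - half, ci_high=est + half,
                p_raw=p, n=n,
            )
        )
    return rows


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p values (order preserved).

    adjusted_(i) = max_{j <= i} min(1, (m - j + 1) p_(j)) over the ascending
    ranks, mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D list of p values")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def attach_holm(rows: list[PairedTestRow]) -> list[PairedTestRow]:
    """Fill the Holm-adjusted p values across one family of paired tests."""
    adj = holm_adjust([r.p_raw for r in rows])
    for r, a in zip(rows, adj):
        r.p_holm = float(a)
    return rows


def sign_pattern_summary(
    paired_by_param: dict[str, list[PairedTestRow]],
    expected: dict[tuple[str, str], int],
    alpha: float = 0.05,
) -> dict:
    """Compare observed paired-test directions against an expected pattern.

    ``expected`` maps (parameter, class) to +1/-1 for the programmed change
    direction; pairs absent from the map are unconstrained. A programmed pair
    "matches" when the estimate carries the expected sign and its Holm p is
    below alpha.
    """
    per_pair = {}
    n_match = 0
    for param, rows in paired_by_param.items():
        for r in rows:
            key = (param, r.label)
            want = expected.get(key)
            obs_sign = int(np.sign(r.estimate))
            entry = {
                "estimate": r.estimate,
                "p_holm": r.p_holm,
                "expected_sign": want,
                "observed_sign": obs_sign,
            }
            if want is not None:
                entry["match"] = bool(obs_sign == want and r.p_holm < alpha)
                n_match += entry["match"]
            per_pair[f"{param}:{r.label}"] = entry
    n_prog = sum(1 for v in expected.values() if v is not None)
    return {
        "alpha": alpha,
        "n_programmed": n_prog,
        "n_matching": n_match,
        "all_match": n_match == n_prog,
        "pairs": per_pair,
    }
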