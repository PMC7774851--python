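"""Inference layer: normality gating, paired and group tests, and
step-down Holm-Sidak control across test families.

Two fixed families mirror the analysis plan: a *hypothesis* family of
m = 7 comparisons (initiation, absolute error and its flight-time
modulation for each group, plus one between-group comparison of the wall
effect) and an *exploratory* family of m = 16 (eight follow-up tests per
group).  Within a family the i-th smallest raw p is adjusted as
``1 - (1 - p)**(m - i + 1)`` with running-maximum monotonicity, retaining
a family-wise alpha of 0.05.

Test selection is gated by a Shapiro-Wilk normality test (parametric when
p > 0.05) except for the absolute error, which is forced non-parametric a
priori (a positive-definite quantity with optimal central tendency at
zero).  The signed-rank statistic is reported as ``W = T+ - T-`` (so
wall-detrimental effects can carry a sign); zero differences are dropped.
The Mann-Whitney U follows the first-sample convention of
``scipy.stats.mannwhitneyu``, recorded in the result metadata.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "shapiro_gate",
    "wilcoxon_signed",
    "paired_t",
    "mann_whitney",
    "holm_sidak",
    "hypothesis_family",
    "exploratory_family",
    "run_families",
    "null_family_error_rate",
    "FAMILY_MAP",
]

# Auditable family membership: (test name, measure, kind) per family slot.
FAMILY_MAP = {
    "hypothesis": [
        "initiation wall effect [per group x2]",
        "AE wall effect [per group x2]",
        "AE wall effect: flight-time modulation [per group x2]",
        "AE wall effect: between groups",
    ],
    "exploratory": [
        "AE wall effect at 1.0 s [per group x2]",
        "AE wall effect at 1.2 s [per group x2]",
        "AE wall effect: required movement 1.5 m vs 0 m [per group x2]",
        "AE wall effect: curve vs no curve [per group x2]",
        "X_early (curve-signed) wall effect [per group x2]",
        "X_early wall effect, congruent [per group x2]",
        "X_early wall effect, incongruent [per group x2]",
        "AE wall effect: congruent vs incongruent [per group x2]",
    ],
}


@dataclass
class TestResult:
    family: str
    name: str
    group: str
    method: str           # paired_t | wilcoxon | mann_whitney
    statistic: float
    df: float             # nan where not applicable
    p_raw: float
    effect: float         # mean (parametric) or median (non-parametric)
    n: int
    note: str = ""


def shapiro_gate(samples, force_nonparametric: bool = False) -> str:
    """'parametric' when a Shapiro-Wilk test does not reject normality
    (p > 0.05); forced non-parametric branches skip the test."""
    x = np.asarray(samples, dtype=float)
    x = x[~np.isnan(x)]
    if force_nonparametric:
        return "nonparametric"
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        warnings.warn("constant sample; falling back to non-parametric")
        return "nonparametric"
    _, p = sps.shapiro(x)
    return "parametric" if p > 0.05 else "nonparametric"


def wilcoxon_signed(differences) -> tuple[float, float]:
    """Signed-rank test; returns (W = T+ - T-, two-sided p).

    Zeros are dropped.  The p-value is exact for n <= 25 and a normal
    approximation above.
    """
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; W undefined")
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = sps.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    t_minus = float(ranks[d < 0].sum())
    w = t_plus - t_minus
    method = "exact" if n <= 25 else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=False,
                       alternative="two-sided", method=method)
    return w, float(res.pvalue)


def paired_t(differences) -> tuple[float, int, float]:
    """One-sample t on paired differences; returns (t, df, two-sided p)."""
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    if d.size < 3:
        raise ValueError("need at least 3 differences")
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance differences; t undefined")
    res = sps.ttest_1samp(d, 0.0)
    return float(res.statistic), d.size - 1, float(res.pvalue)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U of the first sample)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def holm_sidak(raw_p, m: int | None = None) -> np.ndarray:
    """Step-down Holm-Sidak adjusted p-values, returned in input order.

    ``m`` may exceed the list length (untested family slots still count).
    """
    p = np.asarray(raw_p, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    if m is None:
        m = k
    if m < k:
        raise ValueError("family size m cannot be smaller than the list")
    out = np.full(k, np.nan)
    order = np.argsort(p[finite], kind="stable")
    idx_finite = np.nonzero(finite)[0][order]
    running = 0.0
    for i, idx in enumerate(idx_finite):
        # max() guards the 1-ulp round trip of 1-(1-p)**1 at exponent one
        adj = max(p[idx], 1.0 - (1.0 - p[idx]) ** (m - i))
        running = max(running, adj)
        out[idx] = min(1.0, running)
    return out


def _run_paired(values, family, name, group, force_nonpar=False) -> TestResult:
    d = np.asarray(values, dtype=float)
    d = d[~np.isnan(d)]
    effect = float(np.median(d)) if d.size else math.nan
    try:
        branch = shapiro_gate(d, force_nonparametric=force_nonpar)
        if branch == "parametric":
            t, df, p = paired_t(d)
            return TestResult(family, name, group, "paired_t", t, df, p,
                              float(np.mean(d)), d.size)
        w, p = wilcoxon_signed(d)
        return TestResult(family, name, group, "wilcoxon", w, math.nan, p,
                          effect, d.size)
    except ValueError as exc:
        # Too few (or degenerate) observations: keep the family slot but
        # flag the untestable comparison instead of aborting the family.
        return TestResult(family, name, group, "untestable", math.nan,
                          math.nan, math.nan, effect, d.size, note=str(exc))


def hypothesis_family(groups: dict[str, dict[str, pd.DataFrame]]) -> list[TestResult]:
    """The m = 7 confirmatory comparisons over per-group summaries.

    ``groups`` maps a group name to the dict produced by
    :func:`freekick.metrics.aggregate`.
    """
    results: list[TestResult] = []
    for gname, summ in groups.items():
        results.append(
            _run_paired(summ["initiation"]["effect"], "hypothesis",
                        "initiation wall effect", gname)
        )
        results.append(
            _run_paired(summ["ae"]["effect"], "hypothesis",
                        "AE wall effect", gname, force_nonpar=True)
        )
        results.append(
            _run_paired(summ["ae_flight_diff"]["diff"], "hypothesis",
                        "AE wall effect: flight-time modulation", gname,
                        force_nonpar=True)
        )
    names = list(groups)
    if len(names) == 2:
        a = groups[names[0]]["ae"]["effect"].dropna()
        b = groups[names[1]]["ae"]["effect"].dropna()
        u, p = mann_whitney(a, b)
        results.append(
            TestResult("hypothesis", "AE wall effect: between groups",
                       f"{names[0]} vs {names[1]}", "mann_whitney", u,
                       math.nan, p, float(np.median(a) - np.median(b)),
                       len(a) + len(b), note="U of first group")
        )
    return results


def exploratory_family(groups: dict[str, dict[str, pd.DataFrame]]) -> list[TestResult]:
    """The m = 16 exploratory comparisons (eight per group)."""
    results: list[TestResult] = []
    for gname, summ in groups.items():
        results.extend(
            [
                _run_paired(summ["ae_ft1.0"]["effect"], "exploratory",
                            "AE wall effect at 1.0 s", gname, force_nonpar=True),
                _run_paired(summ["ae_ft1.2"]["effect"], "exploratory",
                            "AE wall effect at 1.2 s", gname, force_nonpar=True),
                _run_paired(summ["ae_required"]["diff"], "exploratory",
                            "AE wall effect: required movement", gname,
                            force_nonpar=True),
                _run_paired(summ["ae_curve"]["diff"], "exploratory",
                            "AE wall effect: curve vs no curve", gname,
                            force_nonpar=True),
                _run_paired(summ["x_early_curve"]["effect"], "exploratory",
                            "X_early (curve) wall effect", gname),
                _run_paired(summ["x_early_congruent"]["effect"], "exploratory",
                            "X_early wall effect, congruent", gname),
                _run_paired(summ["x_early_incongruent"]["effect"],
                            "exploratory",
                            "X_early wall effect, incongruent", gname),
                _run_paired(summ["ae_congruence"]["diff"], "exploratory",
                            "AE wall effect: congruence", gname,
                            force_nonpar=True),
            ]
        )
    return results


def run_families(groups: dict[str, dict[str, pd.DataFrame]]) -> pd.DataFrame:
    """Run both families and adjust within each; returns a tidy table."""
    rows: list[TestResult] = []
    fam_sizes = {}
    hyp = hypothesis_family(groups)
    fam_sizes["hypothesis"] = 7
    exp = exploratory_family(groups)
    fam_sizes["exploratory"] = 16
    frames = []
    for family, results in (("hypothesis", hyp), ("exploratory", exp)):
        table = pd.DataFrame([r.__dict__ for r in results])
        table["p_adj"] = holm_sidak(table["p_raw"].to_numpy(),
                                    m=fam_sizes[family])
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def null_family_error_rate(
    n_reps: int = 1000,
    seed: int = 0,
    n_naive: int = 15,
    n_skilled: int = 10,
    alpha: float = 0.05,
) -> float:
    """Family-wise type-I error of the 7-test family under the null.

    Condition summaries are simulated with identical generative parameters
    for the wall and no-wall conditions (paired per-participant values with
    shared participant effects), the full gate + test + adjustment chain is
    run, and the fraction of repetitions with any adjusted p <= alpha is
    returned.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        groups = {}
        for gname, n in (("naive", n_naive), ("skilled", n_skilled)):
            base_ae = np.abs(rng.normal(0.12, 0.04, n))

            def paired(scale, loc=0.0):
                return loc + rng.normal(0.0, scale, n)

            idx = pd.Index([f"{gname}_{i}" for i in range(n)],
                           name="participant")

            def effectframe(values):
                return pd.DataFrame({"effect": values}, index=idx)

            ae_w = base_ae + rng.normal(0, 0.02, n)
            ae_nw = base_ae + rng.normal(0, 0.02, n)
            eff_short = paired(0.02)
            eff_long = paired(0.02)
            groups[gname] = {
                "initiation": effectframe(paired(0.01)),
                "ae": pd.DataFrame(
                    {"wall": ae_w, "nowall": ae_nw, "effect": ae_w - ae_nw},
                    index=idx,
                ),
                "ae_flight_diff": pd.DataFrame(
                    {"diff": eff_short - eff_long}, index=idx
                ),
            }
        results = hypothesis_family(groups)
        p_adj = holm_sidak(np.array([r.p_raw for r in results]), m=7)
        if np.any(p_adj <= alpha):
            hits += 1
    return hits / n_reps
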