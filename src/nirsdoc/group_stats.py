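"""Nonparametric group statistics for the extracted hemodynamic features.

The feature distributions fail a Kolmogorov-Smirnov normality screen, so all
group contrasts are rank-based: the Mann-Whitney U test (two groups, reported
through its tie-corrected normal approximation Z without continuity
correction) and the Kruskal-Wallis H test (three groups, χ² reference with
k − 1 degrees of freedom).  Descriptives are reported as mean ± SEM.

The module also carries the patient table of the clinical cohort the
paradigm was designed for (diagnosis, sex, age, disease duration, etiology,
CRS-R score) and recomputes its demographic summary.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from nirsdoc.io_formats import TestResult, ValidationError

logger = logging.getLogger(__name__)

#: Clinical features of the 18 patients (14 VS, 4 MCS) of the reference
#: cohort; ages in years, disease duration in months.
PATIENT_TABLE = pd.DataFrame(
    [
        (1, "VS", "M", 57, 2.8, "Stroke", 6),
        (2, "VS", "M", 55, 3.4, "TBI", 6),
        (3, "VS", "M", 60, 2.3, "Anoxic", 6),
        (4, "VS", "M", 64, 2.2, "Stroke", 5),
        (5, "VS", "M", 47, 2.8, "Stroke", 4),
        (6, "VS", "M", 41, 19.9, "Stroke", 5),
        (7, "VS", "M", 60, 2.8, "Anoxic", 5),
        (8, "VS", "M", 31, 25.2, "Anoxic", 7),
        (9, "VS", "F", 45, 15.5, "Anoxic", 7),
        (10, "MCS", "M", 65, 4.0, "TBI", 16),
        (11, "MCS", "M", 48, 1.7, "Stroke", 14),
        (12, "VS", "F", 23, 7.6, "TBI", 7),
        (13, "MCS", "F", 45, 6.4, "TBI", 14),
        (14, "VS", "M", 44, 3.1, "TBI", 6),
        (15, "VS", "M", 59, 8.2, "Stroke", 7),
        (16, "VS", "F", 50, 2.3, "Stroke", 7),
        (17, "VS", "M", 46, 4.1, "TBI", 5),
        (18, "MCS", "M", 21, 14.2, "Anoxic", 11),
    ],
    columns=["patient", "diagnosis", "sex", "age_years", "duration_months",
             "etiology", "crs_r"],
)


# ---------------------------------------------------------------------------
# single tests
# ---------------------------------------------------------------------------


def ks_normality(sample: Sequence[float]) -> TestResult:
    """One-sample Kolmogorov-Smirnov test against N(mean, sd) of the sample.

    Two-sided; the p-value comes from the asymptotic KS distribution.  Note
    that estimating the reference parameters from the sample makes the
    screen conservative, which only errs toward keeping the rank tests.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValidationError("KS normality screen needs n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("KS normality screen undefined for constant sample")
    res = stats.kstest(x, "norm", args=(x.mean(), sd), mode="asymp")
    return TestResult(
        test="KS", groups={"sample": int(x.size)},
        statistic=float(res.statistic), p_value=float(res.pvalue),
    )


def _tie_term(pooled: np.ndarray) -> float:
    """Σ (t³ − t) over tie groups of the pooled data."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _exact_u_counts(n_x: int, n_y: int) -> np.ndarray:
    """Number of rank assignments yielding each U value, via the classical
    recurrence f(m, n, u) = f(m−1, n, u−n) + f(m, n−1, u)."""
    table: dict[tuple[int, int], np.ndarray] = {}

    def f(m: int, n: int) -> np.ndarray:
        if (m, n) in table:
            return table[(m, n)]
        if m == 0 or n == 0:
            arr = np.zeros(m * n + 1)
            arr[0] = 1.0
            table[(m, n)] = arr
            return arr
        arr = np.zeros(m * n + 1)
        a = f(m - 1, n)
        arr[n:n + a.size] += a
        b = f(m, n - 1)
        arr[:b.size] += b
        table[(m, n)] = arr
        return arr

    return f(n_x, n_y)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "asymptotic",
) -> TestResult:
    """Mann-Whitney U with tie-corrected Z (no continuity correction).

    U counts, over all pairs, how often an x observation beats a y
    observation (ties count one half).  Z = (U − n_x n_y / 2) / σ_U with the
    tie-corrected σ_U; Z is negative when x tends to rank lower than y.  The
    two-sided p comes from the normal approximation, or — for
    ``method="exact"`` with no ties and small samples — from full
    enumeration of the U distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = x.size, y.size
    if n_x < 1 or n_y < 1:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    r_x = ranks[:n_x].sum()
    u = r_x - n_x * (n_x + 1) / 2.0
    mu = n_x * n_y / 2.0
    n = n_x + n_y
    tie = _tie_term(pooled)
    tie_corrected = tie > 0
    var = n_x * n_y / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        z, p = 0.0, 1.0
    elif method == "asymptotic":
        z = (u - mu) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    elif method == "exact":
        if tie_corrected:
            raise ValidationError("exact Mann-Whitney p requires tie-free data")
        z = (u - mu) / np.sqrt(var)
        dist = _exact_u_counts(n_x, n_y)
        total = dist.sum()
        u_lo = min(u, n_x * n_y - u)
        p = min(1.0, 2.0 * dist[: int(round(u_lo)) + 1].sum() / total)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(
        test="MWU", groups={"x": n_x, "y": n_y},
        statistic=float(u), z_value=float(z), p_value=float(min(p, 1.0)),
        tie_corrected=tie_corrected,
        context={"method": method},
    )


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H over k ≥ 2 groups, tie-corrected, χ²_{k−1} p-value.

    When every pooled value is identical the tie correction degenerates;
    by convention H = 0 and p = 1 (no evidence of any group difference).
    """
    groups = [np.asarray(s, dtype=float) for s in samples]
    if len(groups) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    sizes = [g.size for g in groups]
    if any(s < 1 for s in sizes):
        raise ValidationError("every group must be non-empty")
    n = int(np.sum(sizes))
    if n < 3:
        raise ValidationError("Kruskal-Wallis needs total n >= 3")
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    h = 0.0
    offset = 0
    for g, s in zip(groups, sizes):
        r_mean = ranks[offset:offset + s].mean()
        h += s * (r_mean - (n + 1) / 2.0) ** 2
        offset += s
    h *= 12.0 / (n * (n + 1))
    tie = _tie_term(pooled)
    correction = 1.0 - tie / (n ** 3 - n)
    if correction <= 0:  # all pooled values identical
        h, p = 0.0, 1.0
    else:
        h /= correction
        p = float(stats.chi2.sf(h, len(groups) - 1))
    return TestResult(
        test="KW",
        groups={f"g{i + 1}": int(s) for i, s in enumerate(sizes)},
        statistic=float(h), p_value=p, tie_corrected=tie > 0,
    )


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------


def summarize(
    features: pd.DataFrame,
    keys: Sequence[str] = ("group", "condition", "chromophore"),
    value_cols: Sequence[str] = ("mean_conc", "slope"),
) -> pd.DataFrame:
    """Mean ± SEM (sd/√n, n−1 denominator) per group cell per feature.

    Missing feature values are excluded from n; single-observation cells get
    an undefined (NaN) SEM and are flagged.
    """
    rows = []
    for cell, sub in features.groupby(list(keys), sort=True):
        cell = cell if isinstance(cell, tuple) else (cell,)
        for col in value_cols:
            vals = sub[col].dropna().values
            n = vals.size
            rows.append({
                **dict(zip(keys, cell)),
                "feature": col,
                "n": n,
                "n_missing": int(sub[col].isna().sum()),
                "mean": float(vals.mean()) if n else float("nan"),
                "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
                "sem_defined": n > 1,
            })
    return pd.DataFrame(rows)


def demographic_summary(subject_table: pd.DataFrame | None = None) -> dict:
    """Recompute the cohort demographics from the patient table.

    Returns the mean and n−1 standard deviation of age (rounded to two
    decimals for reporting), diagnosis counts and the disease-duration range.
    """
    table = PATIENT_TABLE if subject_table is None else subject_table
    if len(table) == 0:
        raise ValidationError("empty subject table")
    ages = table["age_years"].astype(float)
    return {
        "n": int(len(table)),
        "mean_age": round(float(ages.mean()), 2),
        "sd_age": round(float(ages.std(ddof=1)), 2),
        "diagnosis_counts": table["diagnosis"].value_counts().to_dict(),
        "duration_min_months": float(table["duration_months"].min()),
        "duration_max_months": float(table["duration_months"].max()),
    }


# ---------------------------------------------------------------------------
# the comparison grid
# ---------------------------------------------------------------------------


def _values(
    features: pd.DataFrame,
    feature: str,
    chromophore: str,
    condition: str | None = None,
    groups: Iterable[str] | None = None,
) -> np.ndarray:
    sub = features[features["chromophore"] == chromophore]
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    if groups is not None:
        sub = sub[sub["group"].isin(list(groups))]
    return sub[feature].dropna().values


def run_comparisons(
    features: pd.DataFrame,
    feature_cols: Sequence[str] = ("mean_conc", "slope"),
    mode: str = "per-epoch",
) -> list[TestResult]:
    """Execute the full comparison grid on a tidy feature table.

    Per chromophore × feature: within-group SON-vs-MI contrasts for healthy
    controls and for the pooled patient group (Mann-Whitney U), the
    HC-vs-patients contrast per condition (Mann-Whitney U), and the
    HC / MCS / VS three-group contrast per condition (Kruskal-Wallis).
    Retained observations are pooled at the granularity of the feature table
    (epochs × channels in per-epoch mode); every result carries that mode.
    Empty cells skip their contrast with a warning.
    """
    pdoc = ("MCS", "VS")
    results: list[TestResult] = []
    for feature in feature_cols:
        for chrom in ("HbO", "HbR"):
            # within-group condition contrasts
            for name, members in (("HC", ("HC",)), ("pDoC", pdoc)):
                a = _values(features, feature, chrom, "SON", members)
                b = _values(features, feature, chrom, "MI", members)
                if a.size and b.size:
                    res = mann_whitney_u(a, b)
                    res.context.update(contrast=f"{name}: SON vs MI",
                                       feature=feature, chromophore=chrom, mode=mode)
                    results.append(res)
                else:
                    logger.warning("skipping %s SON-vs-MI (%s, %s): empty cell",
                                   name, feature, chrom)
            # two-group and three-group contrasts per condition
            for condition in ("SON", "MI"):
                hc = _values(features, feature, chrom, condition, ("HC",))
                pat = _values(features, feature, chrom, condition, pdoc)
                if hc.size and pat.size:
                    res = mann_whitney_u(hc, pat)
                    res.context.update(contrast=f"HC vs pDoC ({condition})",
                                       feature=feature, chromophore=chrom, mode=mode)
                    results.append(res)
                else:
                    logger.warning("skipping HC-vs-pDoC %s (%s, %s): empty cell",
                                   condition, feature, chrom)
                three = [
                    _values(features, feature, chrom, condition, (g,))
                    for g in ("HC", "MCS", "VS")
                ]
                if all(s.size for s in three):
                    res = kruskal_wallis(three)
                    res.groups = {g: int(s.size)
                                  for g, s in zip(("HC", "MCS", "VS"), three)}
                    res.context.update(contrast=f"HC vs MCS vs VS ({condition})",
                                       feature=feature, chromophore=chrom, mode=mode)
                    results.append(res)
                else:
                    logger.warning("skipping three-group %s (%s, %s): empty cell",
                                   condition, feature, chrom)
    return results


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Optional BH step-up adjusted p-values (not applied by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank in ascending order
        running = min(running, p[idx] * m / i)
        adj[idx] = running
    return adj
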