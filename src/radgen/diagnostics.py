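"""Batch-effect diagnostics and cohort-comparison statistics.

Principal-coordinate embedding (classical metric scaling on Euclidean
distances of standardized features — identical to PCA scores in that
metric) visualizes clustering of radiomic features by acquisition
parameters; the silhouette coefficient quantifies it.  Cohort baseline
tables are compared with chi-square / Fisher's exact tests for
categorical variables (Yates continuity correction for 2×2 tables, none
for r×c) and t / Mann-Whitney tests for continuous ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score

log = logging.getLogger(__name__)


# ------------------------------------------------------------- embedding


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # samples x n_components
    explained_variance: np.ndarray  # fractions, nonincreasing
    groups: dict[str, np.ndarray] = field(default_factory=dict)


def pcoa_embed(X: np.ndarray, n_components: int = 2,
               groups: dict[str, np.ndarray] | None = None) -> EmbeddingResult:
    """Classical scaling of standardized features onto principal coordinates.

    Component sign is fixed by making the largest-magnitude loading of
    each component positive, so the embedding is fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >= 3 samples and >= 2 features")
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("zero-variance matrix")
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    # fix signs: largest-|loading| entry of each right singular vector > 0
    for k in range(len(s)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    coords = U[:, :n_components] * s[:n_components]
    lam = s**2
    frac = lam / lam.sum() if lam.sum() > 0 else lam
    return EmbeddingResult(
        coordinates=coords,
        explained_variance=frac[:n_components],
        groups=dict(groups or {}),
    )


# ------------------------------------------------------------ silhouette


def batch_silhouette(X: np.ndarray, grouping: np.ndarray) -> float:
    """Mean silhouette of ``grouping`` on standardized Euclidean features.

    Groups of size 1 are excluded with a warning.
    """
    X = np.asarray(X, dtype=float)
    grouping = np.asarray(grouping)
    vals, counts = np.unique(grouping, return_counts=True)
    keep_groups = vals[counts >= 2]
    if len(keep_groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    if len(keep_groups) < len(vals):
        log.warning(
            "excluding %d singleton group(s)", len(vals) - len(keep_groups)
        )
    keep = np.isin(grouping, keep_groups)
    Xk, gk = X[keep], grouping[keep]
    sd = Xk.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Xk - Xk.mean(axis=0)) / sd
    return float(silhouette_score(Z, gk, metric="euclidean"))


def batch_report(
    fm, grouping_columns: list[str] | None = None
) -> dict[str, float]:
    """Silhouette per grouping variable on a FeatureMatrix."""
    cols = grouping_columns or [
        "site_id",
        "manufacturer",
        "kernel",
        "slice_thickness",
    ]
    X = fm.values(fm.feature_columns)
    out = {}
    for c in cols:
        if c not in fm.data.columns:
            continue
        try:
            out[c] = batch_silhouette(X, fm.data[c].to_numpy())
        except ValueError:
            out[c] = float("nan")
    return out


# -------------------------------------------------------- cohort compare

#: printed baseline counts of the emulated 642-patient cohort
#: (discovery n=512 vs validation n=130); order matters for r x c tests
TABLE1_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "sex": {"M": (258, 69), "F": (254, 61)},
    "smoking_ever": {"current_or_former": (466, 125), "never": (46, 5)},
    "ecog": {"0": (137, 37), "1": (292, 77), ">=2": (68, 16)},
    "stage": {"III": (52, 11), "IV": (460, 119)},
    "histology": {"adeno": (404, 89), "squamous": (29, 13), "other": (79, 28)},
    "pdl1": {"<1%": (97, 36), "1-49%": (117, 34), ">=50%": (223, 54)},
    "first_line": {"first": (197, 94), "later": (315, 36)},
    "treatment": {"ICI alone": (469, 76), "chemo-ICI": (43, 54)},
    "pfs6": {">=6": (260, 60), "<6": (252, 70)},
}


@dataclass
class TestResult:
    variable: str
    test: str
    statistic: float
    p_value: float
    n_missing: int = 0
    flag: str = ""


def categorical_test(table: np.ndarray, variable: str = "") -> TestResult:
    """Chi-square conventions: Yates for 2x2, none for r x c; Fisher's
    exact (with a flag) when a 2x2 expected cell drops below 5."""
    table = np.asarray(table, dtype=float)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table needs >= 2 rows and columns")
    expected = stats.contingency.expected_freq(table)
    if table.shape == (2, 2) and (expected < 5).any():
        odds, p = stats.fisher_exact(table)
        return TestResult(variable, "fisher_exact", float(odds), float(p),
                          flag="expected<5")
    correction = table.shape == (2, 2)
    res = stats.chi2_contingency(table, correction=correction)
    name = "chi2_yates" if correction else "chi2"
    return TestResult(variable, name, float(res.statistic), float(res.pvalue))


def continuous_test(a: np.ndarray, b: np.ndarray, variable: str = "",
                    normality_alpha: float = 0.05) -> TestResult:
    """t-test when both samples pass a Shapiro normality screen, else
    Mann-Whitney U."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_missing = int(np.isnan(a).sum() + np.isnan(b).sum())
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    normal = (
        stats.shapiro(a).pvalue > normality_alpha
        and stats.shapiro(b).pvalue > normality_alpha
    )
    if normal:
        res = stats.ttest_ind(a, b)
        return TestResult(variable, "t_test", float(res.statistic),
                          float(res.pvalue), n_missing)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(variable, "mann_whitney", float(res.statistic),
                      float(res.pvalue), n_missing)


def cohort_compare(
    table: pd.DataFrame,
    grouping: str = "cohort",
    categorical: list[str] | None = None,
    continuous: list[str] | None = None,
) -> dict[str, TestResult]:
    """Per-variable two-cohort comparison on a tidy clinical table."""
    groups = table[grouping].dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"grouping must have exactly 2 levels, got {len(groups)}")
    g0 = table[table[grouping] == groups[0]]
    g1 = table[table[grouping] == groups[1]]
    out: dict[str, TestResult] = {}
    for var in categorical or []:
        c0 = g0[var].value_counts()
        c1 = g1[var].value_counts()
        levels = [l for l in sorted(set(c0.index) | set(c1.index))
                  if c0.get(l, 0) + c1.get(l, 0) > 0]
        if len(levels) < 2:
            log.warning("variable %s has < 2 nonempty levels; skipped", var)
            continue
        tab = np.array(
            [[c0.get(l, 0) for l in levels], [c1.get(l, 0) for l in levels]]
        ).T  # levels x cohorts
        res = categorical_test(tab, var)
        res.n_missing = int(g0[var].isna().sum() + g1[var].isna().sum())
        out[var] = res
    for var in continuous or []:
        out[var] = continuous_test(
            g0[var].to_numpy(float), g1[var].to_numpy(float), var
        )
    return out


def table1_tests() -> dict[str, TestResult]:
    """Run the categorical comparisons on the printed baseline counts."""
    out = {}
    for var, levels in TABLE1_COUNTS.items():
        tab = np.array([[d, v] for d, v in levels.values()])
        out[var] = categorical_test(tab, var)
    return out
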