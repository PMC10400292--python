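"""Global hyperparameter search optimized for cross-center generalizability.

A scrambled Sobol sequence covers the joint feature-selection / model /
hyperparameter space; every trial is scored by leave-one-center-out
cross-validation on the discovery cohort.  The final model is not the one
with the best average AUC but the most *stable* member of the set of
trials statistically tied with the best and in agreement on calibration
(Nagelkerke R²) and goodness of fit (Brier) — agreement of these metrics
across folds serving as a proxy for generalizability.  Success on the
validation center is judged by whether its AUC falls inside the bootstrap
95% CI of the discovery (out-of-fold) AUC.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy.stats import qmc

from .matrix import FIXED_CLINICAL, FeatureMatrix
from .models import FittedModel, MetricSet, ModelSpec, auc_score, compute_metrics, fit_model
from .selection import (
    f_test_scores,
    mrmr_select,
    spearman_matrix,
    spearman_prune,
    _relief_family_scores,
)

log = logging.getLogger(__name__)


# ----------------------------------------------------------- search space


@dataclass(frozen=True)
class SearchAxis:
    name: str
    kind: str  # continuous | log-continuous | integer | categorical
    domain: tuple

    def realize(self, u: float):
        if self.kind == "continuous":
            lo, hi = self.domain
            return lo + u * (hi - lo)
        if self.kind == "log-continuous":
            lo, hi = self.domain
            return float(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))
        if self.kind == "integer":
            lo, hi = self.domain
            return int(min(hi, lo + int(u * (hi - lo + 1))))
        if self.kind == "categorical":
            vals = list(self.domain)
            return vals[min(len(vals) - 1, int(u * len(vals)))]
        raise ValueError(f"unknown axis kind {self.kind!r}")


@dataclass
class SearchSpace:
    axes: list[SearchAxis]
    n_trials: int = 32
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for ax in self.axes:
            if len(ax.domain) == 0:
                raise ValueError(f"empty domain for axis {ax.name}")


def default_search_space(n_trials: int = 32, seed: int = 0) -> SearchSpace:
    return SearchSpace(
        axes=[
            SearchAxis("spearman_threshold", "continuous", (0.8, 1.0)),
            SearchAxis(
                "method",
                "categorical",
                ("f_test", "relief", "surf", "multisurf", "mrmr"),
            ),
            SearchAxis("k_features", "integer", (5, 20)),
            SearchAxis(
                "family",
                "categorical",
                ("logistic_regression", "gradient_boosted_trees"),
            ),
            SearchAxis("lr_C", "log-continuous", (1e-3, 1e2)),
            SearchAxis("gbt_n_estimators", "integer", (25, 150)),
            SearchAxis("gbt_max_depth", "integer", (1, 4)),
            SearchAxis("gbt_learning_rate", "log-continuous", (0.01, 0.3)),
            SearchAxis("gbt_subsample", "continuous", (0.5, 1.0)),
        ],
        n_trials=n_trials,
        seed=seed,
    )


@dataclass(frozen=True)
class SelectorSpec:
    spearman_threshold: float = 0.9
    method: str = "f_test"
    k_features: int = 10
    fixed_features: tuple[str, ...] = tuple(FIXED_CLINICAL)

    def __post_init__(self) -> None:
        if not (0.8 <= self.spearman_threshold <= 1.0):
            raise ValueError("spearman_threshold must be in [0.8, 1]")
        if self.k_features < len(self.fixed_features):
            raise ValueError("k_features below the number of fixed features")


def sobol_points(space: SearchSpace) -> list[tuple[SelectorSpec, ModelSpec]]:
    """Realize n_trials configurations from a scrambled Sobol sequence."""
    space.validate()
    d = len(space.axes)
    if d > 21201:
        raise ValueError("dimension exceeds the Sobol generator maximum")
    eng = qmc.Sobol(d=d, scramble=True, seed=space.seed)
    U = eng.random(space.n_trials)
    out = []
    for t in range(space.n_trials):
        vals = {ax.name: ax.realize(U[t, j]) for j, ax in enumerate(space.axes)}
        sel = SelectorSpec(
            spearman_threshold=vals.get("spearman_threshold", 0.9),
            method=vals.get("method", "f_test"),
            k_features=vals.get("k_features", 10),
        )
        mdl = ModelSpec(
            family=vals.get("family", "logistic_regression"),
            C=vals.get("lr_C", 1.0),
            n_estimators=vals.get("gbt_n_estimators", 100),
            max_depth=vals.get("gbt_max_depth", 2),
            learning_rate=vals.get("gbt_learning_rate", 0.1),
            subsample=vals.get("gbt_subsample", 1.0),
            seed=space.seed,
        )
        out.append((sel, mdl))
    return out


# ----------------------------------------------------------------- folds


def make_folds(
    fm: FeatureMatrix, discovery_sites: list[str] | tuple[str, ...]
) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """Leave-one-center-out folds: one fold per site, test on that site."""
    sites = list(discovery_sites)
    if len(sites) < 2:
        raise ValueError(
            "cross-center CV needs >= 2 discovery sites "
            "(use repeated stratified CV explicitly for a single site)"
        )
    labels = fm.sites
    folds = []
    for s in sites:
        test = np.nonzero(labels == s)[0]
        train = np.nonzero(np.isin(labels, [t for t in sites if t != s]))[0]
        if len(test) < 10:
            log.warning("site %s has only %d samples", s, len(test))
        if len(test) == 0:
            raise ValueError(f"site {s} has no samples")
        folds.append((train, test, s))
    return folds


# ------------------------------------------------------ per-fold caching


class _FoldCache:
    """Selection statistics reusable across trials for one training fold.

    Spearman/Pearson correlations, F statistics and relief-family weights
    depend only on the fold's training data, not on the trial's
    hyperparameters, so they are computed once per fold.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, names: list[str]):
        self.X = X
        self.y = y
        self.names = names
        self._rho = None
        self._corr = None
        self._f = None
        self._relief: dict[str, np.ndarray] = {}

    @property
    def rho(self) -> np.ndarray:
        if self._rho is None:
            self._rho = spearman_matrix(self.X)
        return self._rho

    @property
    def corr(self) -> np.ndarray:
        if self._corr is None:
            sd = self.X.std(axis=0)
            safe = self.X + (sd == 0) * 1e-9
            c = np.corrcoef(safe, rowvar=False)
            self._corr = np.nan_to_num(np.abs(np.atleast_2d(c)), nan=0.0)
        return self._corr

    @property
    def f_scores(self) -> np.ndarray:
        if self._f is None:
            self._f = f_test_scores(self.X, self.y)
        return self._f

    def relief(self, variant: str) -> np.ndarray:
        if variant not in self._relief:
            self._relief[variant] = _relief_family_scores(self.X, self.y, variant)
        return self._relief[variant]


def _select_features(cache: _FoldCache, sel: SelectorSpec) -> list[str]:
    """Prune then rank/select the free features; fixed features always in."""
    names = cache.names
    survivors = spearman_prune(
        cache.X, names, sel.spearman_threshold, fixed=[], rho=cache.rho
    )
    surv_idx = [names.index(n) for n in survivors]
    n_free = sel.k_features - len(sel.fixed_features)
    if n_free <= 0:
        return list(sel.fixed_features)
    if sel.method == "f_test":
        scores = cache.f_scores[surv_idx]
        order = sorted(range(len(surv_idx)), key=lambda a: (-scores[a], a))
        picked = [survivors[a] for a in order[:n_free]]
    elif sel.method in ("relief", "surf", "multisurf"):
        scores = cache.relief(sel.method)[surv_idx]
        order = sorted(range(len(surv_idx)), key=lambda a: (-scores[a], a))
        picked = [survivors[a] for a in order[:n_free]]
    elif sel.method == "mrmr":
        k = min(n_free, len(survivors))
        picked = mrmr_select(
            cache.X[:, surv_idx],
            cache.y,
            survivors,
            k,
            relevance=cache.f_scores[surv_idx],
            corr=cache.corr[np.ix_(surv_idx, surv_idx)],
        )
    else:
        raise ValueError(f"unknown method {sel.method!r}")
    return picked + list(sel.fixed_features)


# ---------------------------------------------------------------- trials


@dataclass
class TrialResult:
    trial_id: int
    selector: SelectorSpec
    model: ModelSpec
    fold_metrics: list[MetricSet]
    fold_sites: list[str]
    selected_per_fold: list[list[str]]
    oof_pred: np.ndarray  # aligned with the discovery matrix rows
    mean_auc: float = 0.0
    sd_auc: float = 0.0
    mean_brier: float = 1.0
    mean_r2: float = 0.0
    failed_folds: int = 0
    valid: bool = True

    def finalize(self) -> "TrialResult":
        aucs = [m.auc for m in self.fold_metrics]
        if aucs:
            self.mean_auc = float(np.mean(aucs))
            self.sd_auc = float(np.std(aucs))
            self.mean_brier = float(np.mean([m.brier for m in self.fold_metrics]))
            self.mean_r2 = float(
                np.mean([m.nagelkerke_r2 for m in self.fold_metrics])
            )
        else:
            self.valid = False
        return self

    def to_json(self) -> str:
        d = {
            "trial_id": self.trial_id,
            "selector": asdict(self.selector),
            "model": asdict(self.model),
            "fold_sites": self.fold_sites,
            "fold_metrics": [asdict(m) for m in self.fold_metrics],
            "selected_per_fold": self.selected_per_fold,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "mean_brier": self.mean_brier,
            "mean_r2": self.mean_r2,
            "failed_folds": self.failed_folds,
            "valid": self.valid,
        }
        return json.dumps(d)


def run_search(
    fm: FeatureMatrix,
    space: SearchSpace,
    discovery_sites: list[str] | tuple[str, ...] | None = None,
) -> list[TrialResult]:
    """Evaluate every Sobol configuration with leave-one-center-out CV.

    Selection and standardization are computed on training folds only;
    metrics come from the held-out center.  Failed folds are flagged and
    the trial kept; a trial with no successful fold is marked invalid.
    """
    if discovery_sites is None:
        discovery_sites = sorted(set(fm.sites))
    folds = make_folds(fm, discovery_sites)
    free = fm.feature_columns
    Xall = fm.values(free)
    Xfixed = fm.values(list(FIXED_CLINICAL))
    y = fm.labels
    caches = {
        site: _FoldCache(Xall[train], y[train], list(free))
        for train, _, site in folds
    }
    all_cols = {n: j for j, n in enumerate(fm.selectable_columns)}
    Xsel_all = fm.values()

    results = []
    for t, (sel, mdl) in enumerate(sobol_points(space)):
        fold_metrics, fold_sites, selected_pf = [], [], []
        oof = np.full(fm.n_samples, np.nan)
        failed = 0
        for train, test, site in folds:
            try:
                feats = _select_features(caches[site], sel)
                cols = [all_cols[f] for f in feats]
                model = fit_model(
                    Xsel_all[np.ix_(train, cols)], y[train],
                    replace(mdl, seed=space.seed), feats,
                )
                p = model.predict_proba(Xsel_all[np.ix_(test, cols)])
                oof[test] = p
                fold_metrics.append(compute_metrics(p, y[test]))
                fold_sites.append(site)
                selected_pf.append(feats)
            except ValueError as exc:
                log.warning("trial %d fold %s failed: %s", t, site, exc)
                failed += 1
        results.append(
            TrialResult(
                trial_id=t,
                selector=sel,
                model=mdl,
                fold_metrics=fold_metrics,
                fold_sites=fold_sites,
                selected_per_fold=selected_pf,
                oof_pred=oof,
                failed_folds=failed,
            ).finalize()
        )
    return results


# ------------------------------------------------------- final selection


@dataclass
class FinalModel:
    selector: SelectorSpec
    model_spec: ModelSpec
    features: list[str]
    fitted: FittedModel
    oof_pred: np.ndarray
    trial_id: int
    audit: list[tuple[str, float]] = field(default_factory=list)

    def freeze(self) -> None:
        self.audit.append(("final_model_frozen", time.time()))

    @property
    def frozen(self) -> bool:
        return any(e[0] == "final_model_frozen" for e in self.audit)


def select_final_model(
    trials: list[TrialResult],
    fm: FeatureMatrix,
    discovery_sites: list[str] | tuple[str, ...] | None = None,
    brier_tolerance: float = 0.02,
    r2_tolerance: float = 0.05,
) -> FinalModel:
    """One-SE / metric-agreement / minimum-variability rule, then refit.

    Candidates are the trials whose mean AUC is within one fold standard
    error of the best and whose Brier and Nagelkerke R² agree (within
    tolerance) with the best observed values; among them the trial with
    the smallest across-fold AUC spread wins (ties: fewer features, then
    trial id).  The winner is refit on the full discovery cohort.
    """
    valid = [t for t in trials if t.valid]
    if not valid:
        raise ValueError("no valid trial")
    best = max(valid, key=lambda t: t.mean_auc)
    n_folds = max(1, len(best.fold_metrics))
    se = best.sd_auc / np.sqrt(n_folds)
    best_brier = min(t.mean_brier for t in valid)
    best_r2 = max(t.mean_r2 for t in valid)
    candidates = [
        t
        for t in valid
        if t.mean_auc >= best.mean_auc - se
        and t.mean_brier <= best_brier + brier_tolerance
        and t.mean_r2 >= best_r2 - r2_tolerance
    ]
    if candidates:
        winner = min(
            candidates,
            key=lambda t: (t.sd_auc, t.selector.k_features, t.trial_id),
        )
    else:
        log.warning("empty candidate set; falling back to (mean, -sd) rule")
        winner = min(valid, key=lambda t: (-t.mean_auc, t.sd_auc, t.trial_id))

    if discovery_sites is None:
        discovery_sites = sorted(set(fm.sites))
    disc = fm.subset_sites(list(discovery_sites))
    # final feature set: majority vote over the fold-level selections, so
    # the refit model stays representative of the models the CI measured;
    # padded (stable order) from full-discovery re-selection if short
    votes: dict[str, int] = {}
    for sel_set in winner.selected_per_fold:
        for f in sel_set:
            votes[f] = votes.get(f, 0) + 1
    need = max(1, (len(winner.selected_per_fold) + 1) // 2)
    feats = [f for f, c in votes.items() if c >= need]
    if len(feats) < winner.selector.k_features:
        free = disc.feature_columns
        cache = _FoldCache(disc.values(free), disc.labels, list(free))
        for f in _select_features(cache, winner.selector):
            if f not in feats:
                feats.append(f)
            if len(feats) >= winner.selector.k_features:
                break
    else:
        feats = sorted(
            feats, key=lambda f: (-votes[f], f not in winner.selector.fixed_features)
        )[: winner.selector.k_features]
        for f in winner.selector.fixed_features:
            if f not in feats:
                feats.append(f)
    fitted = fit_model(disc.values(feats), disc.labels, winner.model, feats)
    final = FinalModel(
        selector=winner.selector,
        model_spec=winner.model,
        features=feats,
        fitted=fitted,
        oof_pred=winner.oof_pred,
        trial_id=winner.trial_id,
    )
    final.audit.append(("refit_on_discovery", time.time()))
    return final


# -------------------------------------------------------------- verdicts


@dataclass
class GeneralizabilityVerdict:
    discovery_auc: float
    ci_low: float
    ci_high: float
    validation_auc: float | None
    passed: bool | None
    n_bootstrap: int
    seed: int
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.discovery_auc <= self.ci_high):
            raise ValueError("point AUC outside its own CI")


def bootstrap_auc_ci(
    final: FinalModel,
    fm_discovery: FeatureMatrix,
    n_boot: int = 2000,
    seed: int = 0,
) -> GeneralizabilityVerdict:
    """Percentile bootstrap CI of the discovery out-of-fold AUC.

    Patients are resampled with replacement stratified by outcome; each
    replicate's AUC is computed from the final configuration's
    cross-center out-of-fold predictions.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    rng = np.random.default_rng(seed)
    y = fm_discovery.labels
    p = final.oof_pred
    ok = ~np.isnan(p)
    y, p = y[ok], p[ok]
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    point = auc_score(y, p)
    aucs = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        while True:
            i = np.concatenate(
                [rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
            )
            if len(np.unique(y[i])) == 2:
                break
            redrawn += 1
        aucs[b] = auc_score(y[i], p[i])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    lo, hi = min(lo, point), max(hi, point)
    return GeneralizabilityVerdict(
        discovery_auc=point,
        ci_low=float(lo),
        ci_high=float(hi),
        validation_auc=None,
        passed=None,
        n_bootstrap=n_boot,
        seed=seed,
        n_redrawn=redrawn,
    )


def generalizability_test(
    final: FinalModel,
    verdict: GeneralizabilityVerdict,
    fm_validation: FeatureMatrix,
) -> GeneralizabilityVerdict:
    """Pass iff the validation AUC falls inside the discovery CI (closed).

    The final model must have been frozen before validation data is
    touched; this is enforced through the audit trail.
    """
    if not final.frozen:
        raise RuntimeError(
            "final model not frozen before validation access (audit violation)"
        )
    final.audit.append(("validation_touched", time.time()))
    y = fm_validation.labels
    if len(np.unique(y)) < 2:
        raise ValueError("validation set has a single class")
    p = final.fitted.predict_proba(fm_validation.values(final.features))
    val_auc = auc_score(y, p)
    passed = bool(verdict.ci_low <= val_auc <= verdict.ci_high)
    return replace(verdict, validation_auc=float(val_auc), passed=passed)


# ------------------------------------------------- permutation inference


def noninferiority_permutation_test(
    pred_a: np.ndarray,
    pred_b: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Paired permutation test on the AUC difference of two models.

    The null swaps the two models' predictions per patient with
    probability 1/2.  Returns ``(observed_delta, mean_null_delta,
    p_two_sided)`` with ``p = (1 + #{|d*| >= |d|}) / (n_perm + 1)``.
    """
    pa = np.asarray(pred_a, dtype=float)
    pb = np.asarray(pred_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if pa.shape != pb.shape or pa.shape != y.shape:
        raise ValueError("predictions and labels must be paired (same length)")
    rng = np.random.default_rng(seed)
    obs = auc_score(y, pa) - auc_score(y, pb)
    null = np.empty(n_perm)
    for i in range(n_perm):
        swap = rng.random(len(y)) < 0.5
        a = np.where(swap, pb, pa)
        b = np.where(swap, pa, pb)
        null[i] = auc_score(y, a) - auc_score(y, b)
    p = (1 + np.sum(np.abs(null) >= abs(obs) - 1e-15)) / (n_perm + 1)
    return float(obs), float(null.mean()), float(p)
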