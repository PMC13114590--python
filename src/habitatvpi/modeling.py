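"""Feature selection and logistic signature construction.

The selection chain applied to every feature table is:

1. Spearman pruning — of any pair with |rho| > 0.9, keep the member with the
   smaller Mann-Whitney p against the outcome;
2. Mann-Whitney screen — keep features with two-sided p < 0.05;
3. mRMR — greedy mutual-information selection (MID difference scheme,
   equal-frequency 4-bin discretization) down to the top 10;
4. LASSO — L1-penalized logistic path, lambda by stratified 10-fold
   cross-validated log-loss; nonzero-coefficient features survive.

A final backward-eliminated multivariable logistic fit (drop the largest
Wald p until all p < 0.05) yields a signature: intercept, coefficients,
odds ratios with 95% CI, and a Youden-maximizing probability cutoff.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold


@dataclass
class SelectionTrace:
    """Surviving feature names after each selection step."""

    steps: list[tuple[str, list[str]]] = field(default_factory=list)

    def record(self, name: str, survivors: list[str]) -> None:
        if self.steps and not set(survivors) <= set(self.steps[-1][1]):
            raise ValueError("selection steps must be nested")
        self.steps.append((name, list(survivors)))

    @property
    def final(self) -> list[str]:
        return self.steps[-1][1] if self.steps else []

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"steps": [[n, s] for n, s in self.steps]}, fh, indent=1)


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    g0, g1 = x[y == 0], x[y == 1]
    if np.all(g0 == g0[0]) and np.all(g1 == g1[0]) and g0[0] == g1[0]:
        return 1.0
    method = "exact" if (len(g0) < 8 and len(g1) < 8
                         and len(np.unique(np.concatenate([g0, g1])))
                         == len(g0) + len(g1)) else "asymptotic"
    return float(stats.mannwhitneyu(g0, g1, alternative="two-sided",
                                    method=method).pvalue)


def spearman_prune(
    table: pd.DataFrame,
    labels: np.ndarray,
    threshold: float = 0.9,
) -> list[str]:
    """Greedy removal within highly correlated pairs (|Spearman rho| > threshold).

    Features are ranked by univariate Mann-Whitney p (smaller = stronger);
    walking down that ranking, a feature is dropped if it correlates above
    the threshold with an already-kept feature.  Ties in p break on column
    order.
    """
    y = np.asarray(labels)
    cols = list(table.columns)
    if len(cols) < 2:
        return cols
    pvals = {c: _mannwhitney_p(table[c].to_numpy(float), y) for c in cols}
    order = sorted(cols, key=lambda c: (pvals[c], cols.index(c)))
    rho = table[cols].corr(method="spearman").to_numpy()
    idx = {c: i for i, c in enumerate(cols)}
    kept: list[str] = []
    for c in order:
        if all(abs(rho[idx[c], idx[k]]) <= threshold for k in kept):
            kept.append(c)
    return [c for c in cols if c in kept]


def mannwhitney_screen(
    table: pd.DataFrame, labels: np.ndarray, alpha: float = 0.05
) -> list[str]:
    """Keep features whose two-sided Mann-Whitney p against the label < alpha."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    return [
        c for c in table.columns
        if _mannwhitney_p(table[c].to_numpy(float), y) < alpha
    ]


def _discretize_ef(x: np.ndarray, bins: int = 4) -> np.ndarray:
    """Equal-frequency discretization for mutual-information estimation."""
    ranks = stats.rankdata(x, method="average")
    return np.minimum((ranks - 1) * bins // len(x), bins - 1).astype(int)


def _mi_discrete(a: np.ndarray, b: np.ndarray) -> float:
    joint = pd.crosstab(a, b).to_numpy(float)
    p = joint / joint.sum()
    px = p.sum(1, keepdims=True)
    py = p.sum(0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def mrmr_objective(
    selected: list[str], relevance: dict[str, float], redundancy: pd.DataFrame
) -> float:
    """The summed MID objective of a feature subset: sum(relevance) - mean pairwise redundancy."""
    rel = sum(relevance[c] for c in selected)
    if len(selected) < 2:
        return rel
    red = np.mean([
        redundancy.loc[a, b]
        for i, a in enumerate(selected)
        for b in selected[i + 1:]
    ])
    return rel - red


def mrmr_select(
    table: pd.DataFrame, labels: np.ndarray, k: int = 10, bins: int = 4
) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance selection (MID scheme).

    At each step adds the feature maximizing MI(feature; label) minus the
    mean MI(feature; already-selected), with mutual information estimated on
    equal-frequency discretized features.
    """
    cols = list(table.columns)
    if k >= len(cols):
        if k > len(cols):
            warnings.warn(f"requested {k} features but only {len(cols)} available",
                          stacklevel=2)
        return cols
    y = np.asarray(labels)
    disc = {c: _discretize_ef(table[c].to_numpy(float), bins) for c in cols}
    relevance = {c: _mi_discrete(disc[c], y) for c in cols}
    selected = [max(cols, key=lambda c: (relevance[c], -cols.index(c)))]
    remaining = [c for c in cols if c not in selected]
    mi_cache: dict[tuple[str, str], float] = {}

    def _red(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in mi_cache:
            mi_cache[key] = _mi_discrete(disc[a], disc[b])
        return mi_cache[key]

    while len(selected) < k:
        best, best_score = None, -np.inf
        for c in remaining:
            score = relevance[c] - np.mean([_red(c, s) for s in selected])
            if score > best_score:
                best, best_score = c, score
        selected.append(best)
        remaining.remove(best)
    return [c for c in cols if c in selected]


def lasso_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    n_folds: int = 10,
    Cs: int = 25,
) -> tuple[list[str], dict[str, float]]:
    """L1-penalized logistic selection; lambda by stratified CV log-loss.

    Returns (surviving feature names, nonzero coefficients at the chosen
    lambda).  Features are expected already standardized.
    """
    y = np.asarray(labels)
    X = table.to_numpy(dtype=float)
    n_folds = min(n_folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=Cs, cv=cv, penalty="l1", solver="liblinear",
        scoring="neg_log_loss", max_iter=2000, random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    coefs = model.coef_.ravel()
    survivors = [c for c, b in zip(table.columns, coefs) if abs(b) > 1e-8]
    return survivors, {c: float(b) for c, b in zip(table.columns, coefs)
                       if abs(b) > 1e-8}


@dataclass
class SignatureModel:
    """A logistic signature: ln[p/(1-p)] = intercept + sum(coef * feature).

    ``cutoff`` is the probability above which (strictly) a case is classified
    positive.  ``feature_stats`` maps feature name -> (original mean, sd) for
    signatures fitted on z-scored features.
    """

    name: str
    intercept: float
    coefficients: dict[str, float]
    cutoff: float
    feature_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    summary: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must lie in (0, 1)")
        if not all(np.isfinite(list(self.coefficients.values()) + [self.intercept])):
            raise ValueError("non-finite signature parameters")

    def odds_ratios(self) -> dict[str, float]:
        return {c: float(np.exp(b)) for c, b in self.coefficients.items()}

    def to_json(self, path) -> None:
        payload = {
            "format": "habitatvpi.signature.v1",
            "name": self.name,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "cutoff": self.cutoff,
            "feature_stats": {k: list(v) for k, v in self.feature_stats.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "habitatvpi.signature.v1":
            raise ValueError(f"unrecognized signature file: {path}")
        return cls(
            name=payload["name"],
            intercept=payload["intercept"],
            coefficients=payload["coefficients"],
            cutoff=payload["cutoff"],
            feature_stats={k: tuple(v) for k, v in payload["feature_stats"].items()},
        )


def backward_logistic(
    table: pd.DataFrame,
    labels: np.ndarray,
    alpha_stay: float = 0.05,
    name: str = "signature",
    cutoff: float | None = None,
    min_features: int = 0,
) -> SignatureModel:
    """Backward-eliminated multivariable logistic fit.

    Iteratively drops the coefficient with the largest Wald p until all
    remaining p < ``alpha_stay``; the reported summary carries odds ratios
    with Wald 95% CIs.  If ``cutoff`` is None the training-set Youden point
    is used.  Perfect separation raises, naming the offending feature.
    ``min_features`` > 0 stops elimination at that many survivors even if
    some p remain above the threshold (useful on small samples where a
    signature must exist).
    """
    y = np.asarray(labels, dtype=float)
    cols = list(table.columns)
    if not cols:
        raise ValueError("no features provided to backward elimination")
    while True:
        X = sm.add_constant(table[cols].to_numpy(float), has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (Exception,) as exc:
            if min_features > 0 and len(cols) > max(1, min_features):
                cols = cols[:-1]  # degrade: drop a feature and retry
                continue
            raise ValueError(
                f"logistic fit failed (possible separation) with features {cols}: {exc}"
            ) from exc
        if not np.all(np.isfinite(fit.bse)):
            bad = cols[int(np.argmax(~np.isfinite(fit.bse[1:])))]
            raise ValueError(f"perfect separation suspected for feature '{bad}'")
        pvals = fit.pvalues[1:]
        if pvals.max() < alpha_stay or len(cols) <= min_features:
            break
        drop = cols[int(np.argmax(pvals))]
        cols = [c for c in cols if c != drop]
        if not cols:
            raise ValueError("backward elimination removed every feature")
    coef = dict(zip(cols, fit.params[1:]))
    ci = fit.conf_int()
    summary = pd.DataFrame({
        "coef": fit.params[1:],
        "se": fit.bse[1:],
        "odds_ratio": np.exp(fit.params[1:]),
        "or_ci_low": np.exp(ci[1:, 0]),
        "or_ci_high": np.exp(ci[1:, 1]),
        "p": fit.pvalues[1:],
    }, index=cols)
    probs = fit.predict(sm.add_constant(table[cols].to_numpy(float), has_constant="add"))
    cut = youden_cutoff(probs, y.astype(int)) if cutoff is None else cutoff
    return SignatureModel(
        name=name,
        intercept=float(fit.params[0]),
        coefficients={c: float(v) for c, v in coef.items()},
        cutoff=float(cut),
        summary=summary,
    )


def predict_signature(model: SignatureModel, features: pd.DataFrame):
    """Signature probability and class for each case.

    Features are z-scored with the model's stored original-scale statistics
    when available.  Classification is strict: positive iff p > cutoff.
    """
    missing = [c for c in model.coefficients if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature(s): {', '.join(missing)}")
    lin = np.full(len(features), model.intercept, dtype=float)
    for c, b in model.coefficients.items():
        x = features[c].to_numpy(dtype=float)
        if c in model.feature_stats:
            mu, sd = model.feature_stats[c]
            x = (x - mu) / sd
        lin += b * x
    p = 1.0 / (1.0 + np.exp(-lin))
    return p, (p > model.cutoff).astype(int)


def youden_cutoff(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Probability cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Scans the observed probabilities; ties resolve to the lowest cutoff.
    Perfectly separated inputs return the midpoint of the gap.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to derive a cutoff")
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    if p[y == 1].min() > p[y == 0].max():  # perfect separation: midpoint of gap
        return float((p[y == 1].min() + p[y == 0].max()) / 2)
    best_j, best_c = -np.inf, None
    for c in np.unique(p):
        pred = p > c
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return float(best_c)


def vif(table: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_i = 1 / (1 - R²) of feature i on the rest."""
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 features")
    X = table.to_numpy(dtype=float)
    if len(X) <= len(cols):
        raise ValueError("VIF needs more cases than features")
    out = {}
    for i, c in enumerate(cols):
        others = np.delete(X, i, axis=1)
        A = np.hstack([np.ones((len(X), 1)), others])
        coef, *_ = np.linalg.lstsq(A, X[:, i], rcond=None)
        resid = X[:, i] - A @ coef
        ss_tot = ((X[:, i] - X[:, i].mean()) ** 2).sum()
        r2 = 1 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
        if r2 >= 1 - 1e-12:
            warnings.warn(f"exact collinearity involving '{c}'", stacklevel=2)
            out[c] = np.inf
        else:
            out[c] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def select_features(
    table: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    rho_threshold: float = 0.9,
    alpha: float = 0.05,
    mrmr_k: int = 10,
) -> SelectionTrace:
    """Run the full four-step selection chain, recording survivors per step."""
    trace = SelectionTrace()
    trace.record("all", list(table.columns))
    s1 = spearman_prune(table, labels, rho_threshold)
    trace.record("spearman_prune", s1)
    s2 = mannwhitney_screen(table[s1], labels, alpha)
    trace.record("mannwhitney", s2)
    s3 = mrmr_select(table[s2], labels, mrmr_k) if s2 else []
    trace.record("mrmr", s3)
    if s3:
        s4, _ = lasso_select(table[s3], labels, seed=seed)
    else:
        s4 = []
    trace.record("lasso", s4)
    return trace
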