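"""Fertility grouping, group statistics and the discriminant classifier.

Rams are split into adequate- (AF) and low-fertility (LF) groups at one
population SD below the mean conception rate.  Per-ram shape/morphometric
features then feed a two-group linear discriminant with stepwise
Wilks-lambda variable selection (forward entry with backward elimination,
partial-F tests at SAS-style default levels of 0.15), and the fitted model
is evaluated by leave-one-out cross-validation reported as sensitivity
(AF correctly identified), specificity (LF correctly identified) and the
overall error rate (FP + FN over the cohort size).

The estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) and compose with
sklearn model selection; the module-level functions are thin wrappers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "threshold_groups",
    "group_ttest",
    "stepwise_select",
    "fit_lda",
    "loo_crossvalidate",
    "CrossValidationReport",
    "LinearDiscriminant",
    "StepwiseLDA",
    "build_report",
]

DEFAULT_ENTRY_P = 0.15
DEFAULT_STAY_P = 0.15
DEFAULT_MAX_ROUNDS = 20


# ---------------------------------------------------------------------------
# fertility phenotype

def threshold_groups(records) -> tuple[list, float]:
    """Label rams AF/LF at one population SD below the mean conception rate.

    ``records`` is a list of objects with ``conception_rate`` and ``group``
    attributes (e.g. :class:`spermshape.synth.FertilityRecord`) or a
    DataFrame with a ``conception_rate`` column.  Rams strictly below
    ``mean - SD`` (population SD) are labeled LF; rams at or above the
    cutoff are AF.  Returns (labeled records, cutoff).
    """
    if isinstance(records, pd.DataFrame):
        rates = records["conception_rate"].to_numpy(float)
    else:
        rates = np.array([r.conception_rate for r in records], dtype=float)
    if len(rates) < 3:
        raise ValueError("need at least 3 fertility records")
    sd = float(np.std(rates, ddof=0))
    if sd == 0:
        raise ValueError("zero variance in conception rates; cannot threshold")
    cutoff = float(np.mean(rates) - sd)
    if isinstance(records, pd.DataFrame):
        out = records.copy()
        out["group"] = np.where(rates < cutoff, "LF", "AF")
        return out, cutoff
    for r, rate in zip(records, rates):
        r.group = "LF" if rate < cutoff else "AF"
    return records, cutoff


def group_ttest(
    values_by_group: dict[str, np.ndarray], equal_var: bool = True
) -> dict[str, float]:
    """Two-sided independent-samples t-test between two groups.

    Pooled-variance Student's t by default; set ``equal_var=False`` for the
    Welch variant.  Returns t, df, p and per-group mean ± SEM.
    """
    if len(values_by_group) != 2:
        raise ValueError("exactly two groups required")
    (ga, xa), (gb, xb) = values_by_group.items()
    xa, xb = np.asarray(xa, float), np.asarray(xb, float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need at least 2 observations per group")
    t, p = scipy.stats.ttest_ind(xa, xb, equal_var=equal_var)
    if equal_var:
        df = len(xa) + len(xb) - 2
    else:
        va, vb = xa.var(ddof=1) / len(xa), xb.var(ddof=1) / len(xb)
        df = (va + vb) ** 2 / (va**2 / (len(xa) - 1) + vb**2 / (len(xb) - 1))
    return {
        "t": float(t),
        "df": float(df),
        "p": float(p),
        f"mean_{ga}": float(xa.mean()),
        f"sem_{ga}": float(xa.std(ddof=1) / np.sqrt(len(xa))),
        f"mean_{gb}": float(xb.mean()),
        f"sem_{gb}": float(xb.std(ddof=1) / np.sqrt(len(xb))),
    }


# ---------------------------------------------------------------------------
# Wilks-lambda machinery (two groups)

def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _wilks_lambda(X: np.ndarray, y01: np.ndarray) -> float:
    """Wilks' lambda |W|/|T| for a two-group one-way layout."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for g in (0, 1):
        Z = X[y01 == g]
        Zc = Z - Z.mean(axis=0)
        W += Zc.T @ Zc
    sign_t, logdet_t = np.linalg.slogdet(T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_t <= 0 or sign_w <= 0:
        raise np.linalg.LinAlgError("singular scatter matrix")
    return float(np.exp(logdet_w - logdet_t))


def _partial_f(lam_small: float, lam_big: float, n: int, p_in: int) -> tuple[float, float]:
    """Partial F for adding one variable to ``p_in`` already in the model.

    Two groups: F = (n - 2 - p_in) (Λ_small/Λ_big - 1), df (1, n - 2 - p_in).
    """
    df2 = n - 2 - p_in
    if df2 <= 0:
        return np.nan, 1.0
    F = df2 * (lam_small / lam_big - 1.0)
    return float(F), float(scipy.stats.f.sf(F, 1, df2))


@dataclass
class _StepRecord:
    round: int
    action: str       # "enter" | "remove" | "stop"
    feature: str
    partial_F: float
    p_value: float
    wilks_lambda: float


def stepwise_select(
    X,
    labels,
    entry_p: float = DEFAULT_ENTRY_P,
    stay_p: float = DEFAULT_STAY_P,
    max_rounds: int = DEFAULT_MAX_ROUNDS,
    collinearity_r2: float = 0.999,
) -> tuple[list[str], list[_StepRecord]]:
    """Stepwise discriminant variable selection by partial Wilks-lambda F-tests.

    Forward entry of the variable with the smallest partial p-value (if
    below ``entry_p``) followed by backward elimination of any entered
    variable whose p-to-stay exceeds ``stay_p``.  Features are standardized
    internally; candidates nearly collinear with the current set
    (R² above ``collinearity_r2``) are skipped.  Returns the selected
    feature names and a per-round trace.  An empty selection is a valid
    outcome, not an error.
    """
    if not (0 < entry_p < 1 and 0 < stay_p < 1):
        raise ValueError("entry_p and stay_p must be in (0, 1)")
    df = _as_frame(X)
    y01 = _encode_labels(labels, df.index if isinstance(labels, pd.Series) else None)
    n = len(df)
    Z = (df - df.mean()) / df.std(ddof=1).replace(0.0, 1.0)
    Z = Z.to_numpy(float)
    names = list(df.columns)

    selected: list[int] = []
    trace: list[_StepRecord] = []
    lam_cur = 1.0
    for rnd in range(1, max_rounds + 1):
        # --- forward step
        best = None
        for j in range(len(names)):
            if j in selected:
                continue
            cols = Z[:, selected + [j]]
            if selected and _max_r2(Z[:, selected], Z[:, j]) > collinearity_r2:
                continue
            try:
                lam_new = _wilks_lambda(cols, y01)
            except np.linalg.LinAlgError:
                continue
            F, p = _partial_f(lam_cur, lam_new, n, len(selected))
            if np.isfinite(F) and (best is None or p < best[1]):
                best = (j, p, F, lam_new)
        entered = False
        if best is not None and best[1] < entry_p:
            j, p, F, lam_new = best
            selected.append(j)
            lam_cur = lam_new
            trace.append(_StepRecord(rnd, "enter", names[j], F, p, lam_cur))
            entered = True
        # --- backward step(s)
        removed = True
        while removed and len(selected) > 1:
            removed = False
            worst = None
            for j in selected:
                rest = [k for k in selected if k != j]
                lam_rest = _wilks_lambda(Z[:, rest], y01) if rest else 1.0
                F, p = _partial_f(lam_rest, lam_cur, n, len(rest))
                if worst is None or p > worst[1]:
                    worst = (j, p, F, lam_rest)
            if worst is not None and worst[1] > stay_p:
                j, p, F, lam_rest = worst
                selected.remove(j)
                lam_cur = lam_rest
                trace.append(_StepRecord(rnd, "remove", names[j], F, p, lam_cur))
                removed = True
        if not entered:
            trace.append(_StepRecord(rnd, "stop", "", np.nan, np.nan, lam_cur))
            break
    return [names[j] for j in selected], trace


def _max_r2(Zsel: np.ndarray, z: np.ndarray) -> float:
    """R² of candidate column against the span of the selected columns."""
    coef, *_ = np.linalg.lstsq(Zsel, z, rcond=None)
    resid = z - Zsel @ coef
    denom = float(z @ z)
    if denom == 0:
        return 1.0
    return 1.0 - float(resid @ resid) / denom


def _encode_labels(labels, index=None) -> np.ndarray:
    y = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError(f"expected exactly two groups, got {classes}")
    return (y.to_numpy() == classes[1]).astype(int)


# ---------------------------------------------------------------------------
# estimators

class LinearDiscriminant(BaseEstimator, ClassifierMixin):
    """Two-group linear discriminant with pooled within-group covariance.

    Implements the classical linear discriminant functions

        d_g(x) = μ_g' Σ⁻¹ x − ½ μ_g' Σ⁻¹ μ_g + ln π_g,

    with Σ the pooled covariance and π_g the priors (equal by default,
    proportional to group sizes with ``priors="proportional"``).  Fitted
    attributes include the canonical correlation (the correlation between
    the discriminant score and group membership; its square is the
    between-group variance explained) and the Wilks-lambda F-test p-value
    of the model.  Posterior ties go to the majority class (AF when group
    labels are AF/LF).
    """

    def __init__(self, priors: str = "equal", tie_policy: str = "majority"):
        self.priors = priors
        self.tie_policy = tie_policy

    def fit(self, X, y):
        df = _as_frame(X)
        y = pd.Series(y).reset_index(drop=True)
        self.feature_names_in_ = np.array(df.columns, dtype=object)
        self.classes_ = np.array(sorted(y.unique()))
        if len(self.classes_) != 2:
            raise ValueError("two-group discriminant requires exactly two classes")
        Xv = df.to_numpy(float)
        n, p = Xv.shape
        y01 = (y.to_numpy() == self.classes_[1]).astype(int)
        counts = np.array([(y01 == 0).sum(), (y01 == 1).sum()])
        if counts.min() < 2:
            raise ValueError("need at least 2 observations per group")
        self.means_ = np.stack([Xv[y01 == g].mean(axis=0) for g in (0, 1)])
        W = np.zeros((p, p))
        for g in (0, 1):
            Z = Xv[y01 == g] - self.means_[g]
            W += Z.T @ Z
        self.pooled_cov_ = W / (n - 2)
        try:
            cov_inv = np.linalg.inv(self.pooled_cov_)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "singular pooled covariance; reduce or reselect features"
            ) from e
        if self.priors == "equal":
            self.priors_ = np.array([0.5, 0.5])
        elif self.priors == "proportional":
            self.priors_ = counts / n
        else:
            self.priors_ = np.asarray(self.priors, dtype=float)
        # per-group linear discriminant functions
        self.coef_ = self.means_ @ cov_inv                       # (2, p)
        self.intercept_ = (
            -0.5 * np.einsum("gp,gp->g", self.coef_, self.means_) + np.log(self.priors_)
        )
        lam = _wilks_lambda(Xv, y01)
        self.wilks_lambda_ = float(lam)
        self.canonical_correlation_ = float(np.sqrt(max(0.0, 1.0 - lam)))
        df2 = n - p - 1
        if df2 > 0 and lam > 0:
            F = (1.0 - lam) / lam * df2 / p
            self.f_statistic_ = float(F)
            self.p_value_ = float(scipy.stats.f.sf(F, p, df2))
        else:
            self.f_statistic_ = np.nan
            self.p_value_ = np.nan
        self.n_features_in_ = p
        return self

    def _scores(self, X) -> np.ndarray:
        df = _as_frame(X)
        if list(df.columns) != list(self.feature_names_in_) and df.shape[1] == len(
            self.feature_names_in_
        ):
            df.columns = self.feature_names_in_
        Xv = df[list(self.feature_names_in_)].to_numpy(float)
        return Xv @ self.coef_.T + self.intercept_

    def decision_function(self, X) -> np.ndarray:
        s = self._scores(X)
        return s[:, 1] - s[:, 0]

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        majority = self._majority_index()
        pick = np.where(d > 0, 1, 0)
        pick = np.where(d == 0, majority, pick)
        return self.classes_[pick]

    def predict_proba(self, X) -> np.ndarray:
        s = self._scores(X)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)

    def _majority_index(self) -> int:
        if self.tie_policy == "majority" and "AF" in self.classes_:
            return int(np.where(self.classes_ == "AF")[0][0])
        return 0


class StepwiseLDA(BaseEstimator, ClassifierMixin):
    """Stepwise Wilks-lambda feature selection followed by a linear discriminant.

    ``feature_list`` bypasses selection with an explicit model
    specification (the route used when a hand-chosen variable set is to be
    evaluated).  Exposes the union of the selection trace and the
    discriminant's fitted attributes.
    """

    def __init__(
        self,
        entry_p: float = DEFAULT_ENTRY_P,
        stay_p: float = DEFAULT_STAY_P,
        max_rounds: int = DEFAULT_MAX_ROUNDS,
        priors: str = "equal",
        tie_policy: str = "majority",
        feature_list: list[str] | None = None,
    ):
        self.entry_p = entry_p
        self.stay_p = stay_p
        self.max_rounds = max_rounds
        self.priors = priors
        self.tie_policy = tie_policy
        self.feature_list = feature_list

    def fit(self, X, y):
        df = _as_frame(X)
        if self.feature_list is not None:
            selected, trace = list(self.feature_list), []
        else:
            selected, trace = stepwise_select(
                df, y, self.entry_p, self.stay_p, self.max_rounds
            )
        self.selected_features_ = selected
        self.selection_trace_ = trace
        self.classes_ = np.array(sorted(pd.Series(y).unique()))
        if selected:
            self.lda_ = LinearDiscriminant(self.priors, self.tie_policy).fit(
                df[selected], y
            )
            self.canonical_correlation_ = self.lda_.canonical_correlation_
            self.wilks_lambda_ = self.lda_.wilks_lambda_
            self.p_value_ = self.lda_.p_value_
        else:
            self.lda_ = None
            self.canonical_correlation_ = 0.0
            self.wilks_lambda_ = 1.0
            self.p_value_ = 1.0
        self.n_features_in_ = df.shape[1]
        self.feature_names_in_ = np.array(df.columns, dtype=object)
        return self

    def _majority_class(self):
        if "AF" in self.classes_:
            return "AF"
        return self.classes_[0]

    def predict(self, X):
        if self.lda_ is None:  # null model: majority class
            return np.full(len(_as_frame(X)), self._majority_class(), dtype=object)
        return self.lda_.predict(_as_frame(X)[self.selected_features_])

    def decision_function(self, X):
        if self.lda_ is None:
            return np.zeros(len(_as_frame(X)))
        return self.lda_.decision_function(_as_frame(X)[self.selected_features_])


def fit_lda(X, labels, priors: str = "equal") -> LinearDiscriminant:
    """Fit the two-group linear discriminant on an explicit feature set."""
    return LinearDiscriminant(priors=priors).fit(X, labels)


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CrossValidationReport:
    """Leave-one-out confusion counts and the derived prediction rates.

    Sensitivity is the percentage of AF rams identified as AF, specificity
    the percentage of LF rams identified as LF, and the overall error rate
    is (false positives + false negatives) / cohort size.  (In the source
    study's table naming, AF-correct is printed as "true negative" and
    LF-correct as "true positive"; the quantities here are the same
    fractions under the conventional names.)
    """

    af_correct: int
    af_total: int
    lf_correct: int
    lf_total: int
    failed_folds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.af_correct > self.af_total or self.lf_correct > self.lf_total:
            raise ValueError("confusion counts exceed group totals")

    @property
    def n(self) -> int:
        return self.af_total + self.lf_total

    @property
    def sensitivity_pct(self) -> float:
        return round(100.0 * self.af_correct / self.af_total, 1)

    @property
    def specificity_pct(self) -> float:
        return round(100.0 * self.lf_correct / self.lf_total, 1)

    @property
    def overall_error(self) -> float:
        return ((self.af_total - self.af_correct) + (self.lf_total - self.lf_correct)) / self.n

    @property
    def overall_error_pct(self) -> float:
        return round(100.0 * self.overall_error, 1)

    @property
    def overall_error_pct_rounded(self) -> int:
        return int(round(100.0 * self.overall_error))

    def to_dict(self) -> dict:
        return {
            "af_correct": self.af_correct,
            "af_total": self.af_total,
            "lf_correct": self.lf_correct,
            "lf_total": self.lf_total,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "overall_error_pct": self.overall_error_pct,
            "overall_error_pct_rounded": self.overall_error_pct_rounded,
            "failed_folds": list(self.failed_folds),
        }


def loo_crossvalidate(
    X,
    labels,
    priors: str = "equal",
    tie_policy: str = "majority",
    features: list[str] | None = None,
) -> CrossValidationReport:
    """Leave-one-out cross-validation of the linear discriminant.

    Each ram is classified by a discriminant fitted on the remaining n−1
    (feature set held fixed).  Folds whose pooled covariance is singular
    are flagged and counted as errors.  Results do not depend on row order.
    """
    df = _as_frame(X)
    if features is not None:
        df = df[list(features)]
    y = pd.Series(labels).reset_index(drop=True)
    n = len(df)
    af_total = int((y == "AF").sum())
    lf_total = n - af_total
    af_correct = lf_correct = 0
    failed = []
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        try:
            model = LinearDiscriminant(priors, tie_policy).fit(df.iloc[keep], y.iloc[keep])
            pred = model.predict(df.iloc[[i]])[0]
        except (np.linalg.LinAlgError, ValueError):
            # singular pooled covariance or a group emptied by the fold
            failed.append(i)
            continue
        if pred == y.iloc[i]:
            if y.iloc[i] == "AF":
                af_correct += 1
            else:
                lf_correct += 1
    return CrossValidationReport(
        af_correct=af_correct,
        af_total=af_total,
        lf_correct=lf_correct,
        lf_total=lf_total,
        failed_folds=failed,
    )


# ---------------------------------------------------------------------------
# reporting

def build_report(
    model: StepwiseLDA | LinearDiscriminant | None,
    cv: CrossValidationReport,
    summaries: pd.DataFrame | None = None,
    cutoff: float | None = None,
) -> dict:
    """Machine-readable results bundle (JSON-serializable dict)."""
    out: dict = {"cross_validation": cv.to_dict()}
    out["cross_validation"]["error_check"] = (
        (cv.af_total - cv.af_correct) + (cv.lf_total - cv.lf_correct)
    ) / cv.n
    if cutoff is not None:
        out["fertility_cutoff"] = float(cutoff)
    if model is None or (isinstance(model, StepwiseLDA) and not model.selected_features_):
        out["model"] = {
            "null_model": True,
            "note": "no variable met the entry criterion; majority-class baseline",
        }
    else:
        lda = model.lda_ if isinstance(model, StepwiseLDA) else model
        out["model"] = {
            "null_model": False,
            "variables": list(getattr(model, "selected_features_", lda.feature_names_in_)),
            "canonical_correlation": lda.canonical_correlation_,
            "canonical_correlation_squared": lda.canonical_correlation_**2,
            "wilks_lambda": lda.wilks_lambda_,
            "p_value": lda.p_value_,
            "coefficients": {
                str(c): list(map(float, row))
                for c, row in zip(lda.classes_, lda.coef_)
            },
            "intercepts": list(map(float, lda.intercept_)),
            "priors": list(map(float, lda.priors_)),
        }
    if summaries is not None:
        out["group_means"] = {
            g: summaries.loc[summaries["group"] == g]
            .drop(columns=["group"])
            .mean()
            .to_dict()
            for g in sorted(summaries["group"].unique())
        }
    return out


def report_markdown(report: dict) -> str:
    """Human-readable Markdown rendering of :func:`build_report` output."""
    cv = report["cross_validation"]
    lines = ["# Fertility discriminant report", ""]
    if "fertility_cutoff" in report:
        lines += [f"Fertility cutoff (mean − 1 SD): **{report['fertility_cutoff']:.1f}%**", ""]
    m = report["model"]
    if m.get("null_model"):
        lines += ["## Model", "", "No variable met the entry criterion (null model; "
                  "cross-validation uses the majority-class baseline).", ""]
    else:
        lines += [
            "## Model",
            "",
            f"Variables: {', '.join(m['variables'])}",
            f"Canonical correlation: {m['canonical_correlation']:.3f} "
            f"(squared {m['canonical_correlation_squared']:.3f})",
            f"Wilks' lambda: {m['wilks_lambda']:.4f}, p = {m['p_value']:.4g}",
            "",
        ]
    lines += [
        "## Leave-one-out cross-validation",
        "",
        "| Group | Correct | Incorrect |",
        "|---|---|---|",
        f"| AF | {cv['sensitivity_pct']}% ({cv['af_correct']}/{cv['af_total']}) "
        f"| {round(100 - cv['sensitivity_pct'], 1)}% "
        f"({cv['af_total'] - cv['af_correct']}/{cv['af_total']}) |",
        f"| LF | {cv['specificity_pct']}% ({cv['lf_correct']}/{cv['lf_total']}) "
        f"| {round(100 - cv['specificity_pct'], 1)}% "
        f"({cv['lf_total'] - cv['lf_correct']}/{cv['lf_total']}) |",
        "",
        f"Overall error rate: {cv['overall_error_pct']}% "
        f"(prints as {cv['overall_error_pct_rounded']}%)",
        "",
    ]
    return "\n".join(lines)
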