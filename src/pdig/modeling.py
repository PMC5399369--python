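"""Multi-source linear models of the MDS-UPDRS clinical score.

Three models are compared: imaging-only (node degree centralities),
genetics-only (additive SNP codes), and combined, each with clinical
covariates (family history, MoCA, GDS, sex, age, site) and two-way
interactions among candidate predictors.  Model search is backward
stepwise elimination under the overall-model-p criterion: a term is
removed when its removal strictly lowers the p-value of the model's
overall F test, repeated to a fixed point.

Explained variance is decomposed by sequential (Type-I) sums of squares in
term order, so per-term percentages sum exactly to 100*R^2.  Predictive
performance is assessed by leave-one-out cross-validation (term set fixed,
coefficients refit per fold) via RMSE and the Pearson correlation between
predicted and actual scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Term",
    "main_effects",
    "interactions_among",
    "build_design",
    "fit_ols",
    "sequential_anova",
    "backward_stepwise",
    "build_three_models",
    "loocv_predict",
    "RegressionModel",
    "CvResult",
]

DEFAULT_CATEGORICAL = frozenset({"site"})


@dataclass(frozen=True, order=True)
class Term:
    """A model term: one source column (main effect) or two (interaction).

    Interaction columns are elementwise products of the uncentered operand
    columns; operands need not themselves be in the model.
    """

    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.columns) not in (1, 2):
            raise ValueError("terms are main effects or two-way interactions")

    @property
    def name(self) -> str:
        return " x ".join(self.columns)

    @property
    def is_interaction(self) -> bool:
        return len(self.columns) == 2


def main_effects(columns) -> list[Term]:
    return [Term((c,)) for c in columns]


def interactions_among(columns) -> list[Term]:
    cols = list(columns)
    return [Term((cols[i], cols[j])) for i in range(len(cols)) for j in range(i + 1, len(cols))]


def build_design(
    data: pd.DataFrame,
    terms: list[Term],
    categorical: frozenset[str] = DEFAULT_CATEGORICAL,
) -> tuple[pd.DataFrame, dict[Term, list[str]]]:
    """Design matrix with intercept, plus term -> design-column mapping.

    Categorical main effects (by default ``site``) expand into
    reference-coded indicator columns that travel as one term; categorical
    operands are not allowed inside interactions.
    """
    if len(set(terms)) != len(terms):
        raise ValueError("duplicate terms in term set")
    pieces: dict[str, np.ndarray] = {"intercept": np.ones(len(data))}
    mapping: dict[Term, list[str]] = {}
    for term in terms:
        for col in term.columns:
            if col not in data.columns:
                raise ValueError(f"term {term.name!r} needs missing column {col!r}")
            if data[col].isna().any():
                raise ValueError(f"column {col!r} has missing values")
        if term.is_interaction:
            a, b = term.columns
            if a in categorical or b in categorical:
                raise ValueError(f"categorical column in interaction {term.name!r}")
            name = term.name
            pieces[name] = data[a].to_numpy(float) * data[b].to_numpy(float)
            mapping[term] = [name]
        else:
            (col,) = term.columns
            if col in categorical:
                dummies = pd.get_dummies(data[col].astype("category"),
                                         prefix=col, drop_first=True, dtype=float)
                for dcol in dummies.columns:
                    pieces[dcol] = dummies[dcol].to_numpy()
                mapping[term] = list(dummies.columns)
            else:
                pieces[col] = data[col].to_numpy(float)
                mapping[term] = [col]
    X = pd.DataFrame(pieces, index=data.index)
    return X, mapping


@dataclass
class RegressionModel:
    """A fitted linear model with its variance decomposition inputs."""

    terms: list[Term]
    coefficients: pd.Series
    coef_se: pd.Series
    n: int
    n_slopes: int
    r2: float
    adj_r2: float
    f_stat: float
    f_pvalue: float
    residuals: np.ndarray
    y: np.ndarray
    X: pd.DataFrame
    term_columns: dict[Term, list[str]]
    anova: pd.DataFrame | None = None
    stepwise_trace: list[dict] = field(default_factory=list)

    def predict(self, Xnew: pd.DataFrame) -> np.ndarray:
        return Xnew[self.coefficients.index].to_numpy(float) @ self.coefficients.to_numpy()


def _rank_check(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the offending columns by greedy rank growth
        keep: list[int] = []
        for j in range(arr.shape[1]):
            cand = arr[:, keep + [j]]
            if np.linalg.matrix_rank(cand) == len(keep) + 1:
                keep.append(j)
        bad = [X.columns[j] for j in range(arr.shape[1]) if j not in keep]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; dependent columns: {bad}"
        )


def fit_ols(
    y,
    X: pd.DataFrame,
    term_columns: dict[Term, list[str]] | None = None,
    terms: list[Term] | None = None,
) -> RegressionModel:
    """Ordinary least squares with overall F test and fit indices.

    ``X`` must contain an ``intercept`` column.  Rank-deficient designs are
    refused with the offending columns named.
    """
    yv = np.asarray(y, dtype=float)
    n, k = X.shape
    n_slopes = k - 1
    if n <= k:
        raise ValueError(f"need n > p + 1 (n={n}, columns={k})")
    _rank_check(X)
    arr = X.to_numpy(float)
    beta, _, _, _ = np.linalg.lstsq(arr, yv, rcond=None)
    fitted = arr @ beta
    resid = yv - fitted
    ss_total = float(np.sum((yv - yv.mean()) ** 2))
    ss_resid = float(resid @ resid)
    ss_model = ss_total - ss_resid
    r2 = ss_model / ss_total if ss_total > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - n_slopes - 1)
    if n_slopes > 0 and ss_resid > 0:
        f_stat = (ss_model / n_slopes) / (ss_resid / (n - n_slopes - 1))
        f_p = float(stats.f.sf(f_stat, n_slopes, n - n_slopes - 1))
    elif n_slopes > 0:
        f_stat, f_p = np.inf, 0.0
    else:
        f_stat, f_p = np.nan, 1.0
    if terms is None:
        terms = [Term((c,)) for c in X.columns if c != "intercept"]
        term_columns = {t: [t.columns[0]] for t in terms}
    dof = n - k
    sigma2 = ss_resid / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(arr.T @ arr)
    model = RegressionModel(
        terms=list(terms),
        coefficients=pd.Series(beta, index=X.columns),
        coef_se=pd.Series(np.sqrt(np.diag(cov)), index=X.columns),
        n=n,
        n_slopes=n_slopes,
        r2=r2,
        adj_r2=adj_r2,
        f_stat=float(f_stat),
        f_pvalue=f_p,
        residuals=resid,
        y=yv,
        X=X,
        term_columns=dict(term_columns or {}),
    )
    model.anova = sequential_anova(model)
    return model


def sequential_anova(model: RegressionModel) -> pd.DataFrame:
    """Type-I (sequential) ANOVA in term order.

    Each term's sum of squares is the increment in model SS when its
    design columns enter after all earlier terms; F is taken against the
    final model's residual mean square.  Percent explained is
    100 * SS_term / SS_total(y), so the column sums to 100 * R^2.
    """
    X = model.X.to_numpy(float)
    y = model.y
    Q, _ = np.linalg.qr(X)
    proj = Q.T @ y  # projections onto successive orthonormal directions
    ss_total = float(np.sum((y - y.mean()) ** 2))
    dof_resid = model.n - model.n_slopes - 1
    ms_resid = float(model.residuals @ model.residuals) / dof_resid if dof_resid > 0 else np.nan

    col_index = {c: i for i, c in enumerate(model.X.columns)}
    rows = []
    for term in model.terms:
        cols = model.term_columns.get(term, [term.name])
        idx = [col_index[c] for c in cols]
        ss = float(np.sum(proj[idx] ** 2))
        df = len(idx)
        if ms_resid and ms_resid > 0:
            f = (ss / df) / ms_resid
            p = float(stats.f.sf(f, df, dof_resid))
        else:
            f, p = np.inf, 0.0
        rows.append(
            {
                "term": term.name,
                "df": df,
                "sum_sq": ss,
                "F": f,
                "p": p,
                "pct_explained": 100.0 * ss / ss_total if ss_total > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def _prune_to_full_rank(
    data: pd.DataFrame, terms: list[Term], categorical: frozenset[str]
) -> list[Term]:
    """Drop later terms whose columns are linearly dependent on earlier ones."""
    kept: list[Term] = []
    for term in terms:
        X, _ = build_design(data, kept + [term], categorical)
        if np.linalg.matrix_rank(X.to_numpy(float)) == X.shape[1]:
            kept.append(term)
        else:
            warnings.warn(f"dropping collinear term {term.name!r} before stepwise")
    return kept


def backward_stepwise(
    y,
    data: pd.DataFrame,
    full_terms: list[Term],
    categorical: frozenset[str] = DEFAULT_CATEGORICAL,
) -> RegressionModel:
    """Backward elimination under the overall-model-p criterion.

    At each step every current term's removal is evaluated; the removal
    yielding the lowest overall F-test p-value is committed if strictly
    lower than the current model's, with ties broken by earliest position
    in the term list.  Stops when no removal improves, or when one term
    remains.  The elimination trace is stored on the returned model.
    """
    yv = np.asarray(y, dtype=float)
    terms = _prune_to_full_rank(data, list(full_terms), categorical)
    if not terms:
        raise ValueError("no fittable terms")

    # candidate removals are scored on column subsets of one prebuilt design;
    # only committed models get the full fit
    X_full, mapping = build_design(data, terms, categorical)
    arr = X_full.to_numpy(float)
    col_idx = {c: j for j, c in enumerate(X_full.columns)}
    ss_total = float(np.sum((yv - yv.mean()) ** 2))

    def overall_p(term_list: list[Term]) -> float:
        cols = [0] + [col_idx[c] for t in term_list for c in mapping[t]]
        Xs = arr[:, cols]
        n, k = Xs.shape
        beta, _, _, _ = np.linalg.lstsq(Xs, yv, rcond=None)
        resid = yv - Xs @ beta
        ss_resid = float(resid @ resid)
        n_slopes = k - 1
        if n_slopes == 0 or ss_resid <= 0:
            return 0.0 if ss_resid <= 0 else 1.0
        f = ((ss_total - ss_resid) / n_slopes) / (ss_resid / (n - k))
        return float(stats.f.sf(f, n_slopes, n - k))

    current_p = overall_p(terms)
    trace: list[dict] = []
    step = 0
    while len(terms) > 1:
        best_p, best_idx = current_p, None
        for i in range(len(terms)):
            p = overall_p(terms[:i] + terms[i + 1 :])
            if p < best_p:
                best_p, best_idx = p, i
        if best_idx is None:
            break
        step += 1
        trace.append(
            {
                "step": step,
                "removed": terms[best_idx].name,
                "p_before": current_p,
                "p_after": best_p,
                "n_terms_after": len(terms) - 1,
            }
        )
        terms = terms[:best_idx] + terms[best_idx + 1 :]
        current_p = best_p

    X, final_mapping = build_design(data, terms, categorical)
    current = fit_ols(yv, X, final_mapping, terms)
    current.stepwise_trace = trace
    return current


def _capped_interactions(
    feature_groups: list[list[str]],
    covariate_cols: list[str],
    cap: int,
) -> list[Term]:
    """Two-way interactions in priority order, truncated at ``cap``.

    Feature-feature pairs (within and across feature groups) come first,
    then feature-covariate, then covariate-covariate.
    """
    features = [c for grp in feature_groups for c in grp]
    tiers = [
        interactions_among(features),
        [Term((f, c)) for f in features for c in covariate_cols],
        interactions_among(covariate_cols),
    ]
    out: list[Term] = []
    for tier in tiers:
        for t in tier:
            if len(out) >= cap:
                return out
            out.append(t)
    return out


def build_three_models(
    y,
    data: pd.DataFrame,
    imaging_features: list[str],
    snp_features: list[str],
    covariates: list[str],
    categorical: frozenset[str] = DEFAULT_CATEGORICAL,
    interaction_cap: int = 30,
) -> dict[str, RegressionModel]:
    """Fit the imaging-only (A), genetics-only (B) and combined (C) models.

    Each starts from its main effects plus covariates plus capped two-way
    interactions (categorical covariates excluded from interactions) and
    is reduced by :func:`backward_stepwise`.  The cap, together with an
    n > p + 2 guard, keeps an 80-subject design fittable.
    """
    if not imaging_features or not snp_features:
        raise ValueError("imaging and SNP feature sets must be non-empty")
    numeric_cov = [c for c in covariates if c not in categorical]
    n = len(data)

    def initial_terms(groups: list[list[str]]) -> list[Term]:
        mains = main_effects([c for g in groups for c in g] + covariates)
        n_main_cols = sum(
            data[c].nunique() - 1 if c in categorical else 1
            for g in groups for c in g
        ) + sum(
            data[c].nunique() - 1 if c in categorical else 1 for c in covariates
        )
        room = n - n_main_cols - 3  # keep n > p + 2 after interactions
        cap = max(0, min(interaction_cap, room))
        if cap < interaction_cap:
            warnings.warn(f"interaction cap lowered to {cap} to keep the model fittable")
        return mains + _capped_interactions(groups, numeric_cov, cap)

    models = {
        "A": backward_stepwise(y, data, initial_terms([imaging_features]), categorical),
        "B": backward_stepwise(y, data, initial_terms([snp_features]), categorical),
        "C": backward_stepwise(
            y, data, initial_terms([imaging_features, snp_features]), categorical
        ),
    }
    return models


def model_comparison(models: dict[str, RegressionModel]) -> pd.DataFrame:
    rows = []
    for label, m in models.items():
        rows.append(
            {
                "model": label,
                "n_terms": len(m.terms),
                "r2": m.r2,
                "adj_r2": m.adj_r2,
                "f_pvalue": m.f_pvalue,
                "pct_explained_total": float(m.anova["pct_explained"].sum()),
            }
        )
    return pd.DataFrame(rows).set_index("model")


@dataclass
class CvResult:
    """Leave-one-out cross-validation summary."""

    predictions: pd.Series
    rmse: float
    pearson_r: float
    pearson_p: float
    n_folds: int
    skipped_folds: list = field(default_factory=list)


def loocv_predict(
    y,
    data: pd.DataFrame,
    terms: list[Term],
    categorical: frozenset[str] = DEFAULT_CATEGORICAL,
) -> CvResult:
    """Leave-one-out cross-validation with the term set held fixed.

    Each subject is predicted from coefficients refit on the other n-1;
    RMSE and the Pearson correlation between predicted and actual scores
    summarize out-of-sample performance.  Folds whose training design is
    rank deficient are skipped and reported.
    """
    yv = np.asarray(y, dtype=float)
    X, _ = build_design(data, terms, categorical)
    arr = X.to_numpy(float)
    n, k = arr.shape
    if n < k + 3:
        raise ValueError(f"need n >= p + 3 for LOOCV (n={n}, p+1={k})")
    preds = np.full(n, np.nan)
    skipped = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr = arr[mask]
        if np.linalg.matrix_rank(Xtr) < k:
            skipped.append(data.index[i])
            continue
        beta, _, _, _ = np.linalg.lstsq(Xtr, yv[mask], rcond=None)
        preds[i] = arr[i] @ beta
    ok = ~np.isnan(preds)
    rmse = float(np.sqrt(np.mean((preds[ok] - yv[ok]) ** 2)))
    r, rp = stats.pearsonr(yv[ok], preds[ok])
    return CvResult(
        predictions=pd.Series(preds, index=data.index, name="predicted"),
        rmse=rmse,
        pearson_r=float(r),
        pearson_p=float(rp),
        n_folds=int(ok.sum()),
        skipped_folds=skipped,
    )
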