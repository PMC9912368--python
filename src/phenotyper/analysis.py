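"""Multiple imputation, pooled stepwise Cox selection, and risk prediction.

Imputation is chained equations with per-variable method choice: predictive
mean matching (PMM) for categorical, integer-valued or skewed variables,
stochastic model prediction otherwise. Pooling follows Rubin's rules with
Barnard–Rubin degrees of freedom. Stepwise selection is forward with a
backward pass, every add/drop decision using the Wald p-value pooled across
the m imputed fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Imputation

def choose_imputation_method(values: pd.Series, skew_threshold: float = 1.0) -> str:
    """PMM for categorical, integer-valued or skewed variables; else model prediction."""
    observed = values.dropna()
    if observed.empty:
        raise ValueError(f"variable {values.name!r} has no observed values")
    if not pd.api.types.is_numeric_dtype(observed):
        return "PMM"
    arr = observed.to_numpy(dtype=float)
    if np.allclose(arr, np.round(arr)):
        return "PMM"
    if abs(stats.skew(arr)) > skew_threshold:
        return "PMM"
    return "MODEL_PREDICTION"


@dataclass
class ImputationResult:
    m: int
    panels: list[pd.DataFrame]
    method_per_variable: dict[str, str]
    seed: int


def impute(
    panel: pd.DataFrame,
    m: int = 5,
    seed: int = 0,
    variables: list[str] | None = None,
    n_iter: int = 10,
    k_pmm: int = 5,
    skew_threshold: float = 1.0,
    max_missing_frac: float = 0.5,
) -> ImputationResult:
    """Chained-equations multiple imputation.

    ``variables`` are the columns participating as both targets and
    predictors (default: all numeric/categorical columns with the id column
    excluded); include the outcome time and status so the imputation model
    is outcome-aware. Deterministic given ``seed``; observed cells are
    identical across the m panels.
    """
    if variables is None:
        variables = [c for c in panel.columns
                     if c != "participant_id" and panel[c].dtype.kind in "ifbO"]
    work = panel[variables].copy()

    # encode categoricals to integer codes, remembered for decoding
    decoders: dict[str, pd.Index] = {}
    for col in variables:
        if not pd.api.types.is_numeric_dtype(work[col]):
            cat = work[col].astype("category")
            decoders[col] = cat.cat.categories
            codes = cat.cat.codes.astype(float)
            work[col] = codes.where(codes >= 0, np.nan)

    methods: dict[str, str] = {}
    for col in variables:
        src = panel[col] if col not in decoders else work[col]
        if work[col].isna().any():
            methods[col] = "PMM" if col in decoders else choose_imputation_method(
                src, skew_threshold=skew_threshold)
            frac = work[col].isna().mean()
            if frac > max_missing_frac:
                logger.warning("variable %r is %.0f%% missing", col, 100 * frac)

    matrix = work.to_numpy(dtype=float)
    miss_mask = np.isnan(matrix)
    target_cols = [variables.index(c) for c in methods]

    rng = np.random.default_rng(seed)
    panels = []
    for _ in range(m):
        filled = matrix.copy()
        for j in target_cols:  # initialize from observed marginals
            obs = matrix[~miss_mask[:, j], j]
            filled[miss_mask[:, j], j] = rng.choice(obs, size=miss_mask[:, j].sum())
        if target_cols:
            for _ in range(n_iter):
                for j in target_cols:
                    _impute_one(filled, matrix, miss_mask, j,
                                methods[variables[j]], k_pmm, rng)
        completed = panel.copy()
        for idx, col in enumerate(variables):
            values = filled[:, idx]
            if col in decoders:
                codes = np.clip(np.round(values).astype(int), 0, len(decoders[col]) - 1)
                completed[col] = decoders[col][codes]
            else:
                completed[col] = values
        panels.append(completed)
    return ImputationResult(m=m, panels=panels, method_per_variable=methods, seed=seed)


def _impute_one(filled, original, miss_mask, j, method, k_pmm, rng):
    """One chained-equations update of column j in place."""
    n, p = filled.shape
    obs = ~miss_mask[:, j]
    mis = miss_mask[:, j]
    others = [c for c in range(p) if c != j]
    X = np.column_stack([np.ones(n), filled[:, others]])
    y = original[:, j]

    Xo, yo = X[obs], y[obs]
    # ridge-stabilized least squares so constant/collinear predictors don't blow up
    XtX = Xo.T @ Xo + 1e-8 * np.eye(X.shape[1])
    beta = np.linalg.solve(XtX, Xo.T @ yo)
    resid = yo - Xo @ beta
    dof = max(len(yo) - X.shape[1], 1)
    sigma = float(np.sqrt(resid @ resid / dof))

    pred_mis = X[mis] @ beta
    if method == "MODEL_PREDICTION":
        filled[mis, j] = pred_mis + rng.normal(0.0, sigma, size=mis.sum())
    else:  # PMM: draw an observed donor among the k nearest predicted means
        pred_obs = Xo @ beta
        for row, target in zip(np.flatnonzero(mis), pred_mis):
            dist = np.abs(pred_obs - target)
            k = min(k_pmm, len(dist))
            donors = np.argpartition(dist, k - 1)[:k]
            filled[row, j] = yo[rng.choice(donors)]


# ---------------------------------------------------------------------------
# Cox fitting and Rubin pooling

class CoxFitError(RuntimeError):
    pass


def fit_cox(
    panel: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time_years",
    status_col: str = "status",
) -> tuple[pd.Series, pd.DataFrame]:
    """Cox partial-likelihood fit (Efron ties) returning (coefs, covariance)."""
    data = panel[[time_col, status_col] + list(covariates)]
    if data[status_col].sum() < 1:
        raise CoxFitError("no events in the data")
    X = data[covariates].to_numpy(dtype=float)
    with_nan = [c for c, bad in zip(covariates, np.isnan(X).any(axis=0)) if bad]
    if with_nan:
        raise CoxFitError(f"covariate(s) contain missing values: {with_nan}")
    constant = [c for c, sd in zip(covariates, X.std(axis=0)) if sd == 0]
    if constant:
        raise CoxFitError(f"constant covariate(s): {constant}")
    if len(covariates) > 1:
        centered = X - X.mean(axis=0)
        if np.linalg.matrix_rank(centered) < len(covariates):
            corr = np.corrcoef(X, rowvar=False)
            off = np.abs(corr - np.eye(len(covariates)))
            i, j = divmod(int(np.argmax(off)), len(covariates))
            raise CoxFitError(
                f"collinear covariates: {covariates[i]!r} and {covariates[j]!r}")
    fitter = CoxPHFitter()
    try:
        fitter.fit(data, duration_col=time_col, event_col=status_col)
    except Exception as exc:  # lifelines raises several convergence types
        raise CoxFitError(f"Cox fit failed for covariates {covariates}: {exc}") from exc
    return fitter.params_.copy(), fitter.variance_matrix_.copy()


def standardize(panels: list[pd.DataFrame], columns: list[str],
                reference: pd.DataFrame | None = None) -> list[pd.DataFrame]:
    """Z-score ``columns`` using moments from ``reference`` (default: first panel)."""
    ref = reference if reference is not None else panels[0]
    out = []
    for panel in panels:
        scaled = panel.copy()
        for col in columns:
            mu, sd = float(ref[col].mean()), float(ref[col].std(ddof=1))
            scaled[col] = (panel[col] - mu) / (sd if sd > 0 else 1.0)
        out.append(scaled)
    return out


def rubin_pool(
    estimates: list[pd.Series],
    variances: list[pd.Series | pd.DataFrame],
    dfcom: float = np.inf,
) -> pd.DataFrame:
    """Rubin's rules over m fits: pooled coef, SE, and Wald p.

    Total variance T = W̄ + (1 + 1/m)·B with W̄ the mean within-imputation
    variance and B the between-imputation variance. The Wald test uses a
    t reference with Barnard–Rubin degrees of freedom (reducing to the
    classic df when ``dfcom`` is infinite).
    """
    m = len(estimates)
    if m < 2:
        raise ValueError("rubin_pool requires m >= 2 fits")
    index = estimates[0].index
    for est in estimates[1:]:
        if not est.index.equals(index):
            raise ValueError("mismatched coefficient sets across fits")
    coefs = np.vstack([est.to_numpy(dtype=float) for est in estimates])
    within = np.vstack([
        np.diag(v.to_numpy()) if isinstance(v, pd.DataFrame) else v.to_numpy(dtype=float)
        for v in variances
    ])
    qbar = coefs.mean(axis=0)
    wbar = within.mean(axis=0)
    b = coefs.var(axis=0, ddof=1)
    total = wbar + (1 + 1 / m) * b

    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1 + 1 / m) * b / wbar
        df_old = np.where(b > 0, (m - 1) * (1 + 1 / np.where(r > 0, r, np.inf)) ** 2, np.inf)
        if np.isfinite(dfcom):
            lam = (1 + 1 / m) * b / total
            df_obs = (dfcom + 1) / (dfcom + 3) * dfcom * (1 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
    se = np.sqrt(total)
    tstat = np.where(se > 0, qbar / se, np.inf * np.sign(qbar))
    pvals = np.where(np.isfinite(df),
                     2 * stats.t.sf(np.abs(tstat), np.maximum(df, 1e-8)),
                     2 * stats.norm.sf(np.abs(tstat)))
    return pd.DataFrame({
        "coef": qbar, "se": se, "within": wbar, "between": b,
        "total_var": total, "df": df, "p": pvals,
    }, index=index)


@dataclass
class PooledCoxResult:
    forced_vars: list[str]
    selected_vars: list[str]
    summary: pd.DataFrame  # coef, se, HR, ci_low, ci_high, p per variable
    selection_trace: list[tuple[int, str, str, float]] = field(default_factory=list)


def _pooled_fit(panels, covariates, time_col, status_col, dfcom=np.inf):
    fits = [fit_cox(p, covariates, time_col, status_col) for p in panels]
    return rubin_pool([f[0] for f in fits], [f[1] for f in fits], dfcom=dfcom)


def pooled_stepwise_select(
    panels: list[pd.DataFrame] | ImputationResult,
    candidates: list[str],
    forced: list[str] = ("age_at_index", "sex"),
    time_col: str = "time_years",
    status_col: str = "status",
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.05,
) -> PooledCoxResult:
    """Forward-with-backward stepwise Cox selection on pooled Wald p-values.

    Forced variables are always in the model and never tested for removal.
    Ties break on smallest p then alphabetical variable name; revisiting a
    model stops the search with the trace reported so far.
    """
    if isinstance(panels, ImputationResult):
        panels = panels.panels
    forced = list(forced)
    candidates = sorted(set(candidates) - set(forced))
    model: list[str] = []
    trace: list[tuple[int, str, str, float]] = []
    visited = {frozenset()}
    step = 0
    cache: dict[tuple, pd.DataFrame] = {}

    def pooled_fit(covars: list[str]) -> pd.DataFrame:
        key = tuple(sorted(covars))
        if key not in cache:
            cache[key] = _pooled_fit(panels, covars, time_col, status_col)
        return cache[key]

    while True:
        changed = False
        # forward
        best_var, best_p = None, None
        for var in sorted(set(candidates) - set(model)):
            try:
                pooled = pooled_fit(forced + model + [var])
            except CoxFitError as exc:
                logger.warning("skipping candidate %r: %s", var, exc)
                continue
            p = float(pooled.loc[var, "p"])
            if p < alpha_enter and (best_p is None or p < best_p
                                    or (p == best_p and var < best_var)):
                best_var, best_p = var, p
        if best_var is not None:
            model.append(best_var)
            step += 1
            trace.append((step, "add", best_var, best_p))
            changed = True
        # backward
        while model:
            pooled = pooled_fit(forced + model)
            removable = pooled.loc[model, "p"]
            worst = removable.sort_index().idxmax()
            worst_p = float(removable[worst])
            if worst_p <= alpha_remove:
                break
            model.remove(worst)
            step += 1
            trace.append((step, "drop", worst, worst_p))
            changed = True
        key = frozenset(model)
        if key in visited and changed:
            logger.warning("stepwise selection cycled; stopping with model %s", model)
            break
        visited.add(key)
        if not changed:
            break

    final_vars = forced + model
    pooled = pooled_fit(final_vars)
    summary = pooled[["coef", "se", "p"]].copy()
    summary["hr"] = np.exp(summary["coef"])
    summary["ci_low"] = np.exp(summary["coef"] - 1.96 * summary["se"])
    summary["ci_high"] = np.exp(summary["coef"] + 1.96 * summary["se"])
    return PooledCoxResult(forced_vars=forced, selected_vars=model,
                           summary=summary, selection_trace=trace)


# ---------------------------------------------------------------------------
# Risk prediction

def train_validate_split(ids, ratio: tuple[int, int] = (2, 1), seed: int = 0):
    """Random 2:1 partition; |train| = round(2n/3). Deterministic given seed."""
    ids = np.asarray(list(ids))
    if len(ids) < 3:
        raise ValueError("need at least 3 ids to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(ratio[0] * len(ids) / sum(ratio)))
    return ids[perm[:n_train]], ids[perm[n_train:]]


def compute_risk_scores(
    fits: list[tuple[pd.Series, pd.Series]],
    validation_panels: list[pd.DataFrame],
) -> pd.Series:
    """Mean linear predictor over the m (coef, training-mean) fits.

    Each fit pairs a coefficient vector with the training-set covariate
    means used for centering; panel i is scored with fit i and the per-
    participant scores are averaged.
    """
    if len(fits) != len(validation_panels):
        raise ValueError("need one validation panel per fit")
    scores = None
    for (beta, center), panel in zip(fits, validation_panels):
        missing = [c for c in beta.index if c not in panel.columns]
        if missing:
            raise ValueError(f"covariate(s) missing from validation panel: {missing}")
        X = panel[beta.index].to_numpy(dtype=float) - center[beta.index].to_numpy(dtype=float)
        lp = pd.Series(X @ beta.to_numpy(dtype=float), index=panel["participant_id"].to_numpy())
        scores = lp if scores is None else scores + lp
    return scores / len(fits)


def evaluate_auc(scores, event_status, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Mann–Whitney AUC of scores against binary status, DeLong 95% CI."""
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(event_status, dtype=int)
    cases = scores[status == 1]
    controls = scores[status == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present to compute AUC")
    # DeLong via midranks
    def midrank(x):
        order = np.argsort(x, kind="mergesort")
        ranks = stats.rankdata(x)  # average ranks handle ties
        del order
        return ranks
    m, n = len(cases), len(controls)
    combined = np.concatenate([cases, controls])
    tz = midrank(combined)
    tx = midrank(cases)
    ty = midrank(controls)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    var_auc = s01 / m + s10 / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var_auc)
    return float(auc), (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def km_by_median(
    scores: pd.Series,
    tte_records: pd.DataFrame,
    time_col: str = "time_years",
    status_col: str = "status",
) -> dict:
    """Kaplan–Meier curves for score-above-median vs rest, with log-rank p."""
    records = tte_records.set_index("participant_id") if "participant_id" in tte_records else tte_records
    aligned = records.loc[scores.index]
    median = float(np.median(scores.to_numpy()))
    high = scores.to_numpy() > median
    if high.all() or (~high).all():
        raise ValueError("median split produced an empty risk group")
    curves = {}
    for label, mask in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter(label=label)
        km.fit(aligned.loc[mask, time_col], aligned.loc[mask, status_col])
        curves[label] = km
    lr = logrank_test(
        aligned.loc[high, time_col], aligned.loc[~high, time_col],
        aligned.loc[high, status_col], aligned.loc[~high, status_col],
    )
    return {"median": median, "curves": curves, "logrank_p": float(lr.p_value)}
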