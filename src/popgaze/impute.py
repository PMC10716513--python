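"""Multiple imputation of trial-level data and Rubin-rule pooling.

Missing cells are filled by chained equations with a regression-tree
learner: each incomplete column is modelled on all other analysis columns,
and an imputed value is drawn from the observed *donors* that fall in the
same terminal leaf as the missing row (so imputations stay within the
observed support, as in tree-based predictive mean matching).  Classic
predictive-mean matching with a linear learner is available as an
alternative.  Running the chain ``m`` times with independent seeds yields
``m`` completed tables;
model fits across them are pooled with the between/within-imputation
variance decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .models import ModelFit

__all__ = ["ImputationSet", "impute", "pool", "PooledResult"]


@dataclass
class ImputationSet:
    tables: list[pd.DataFrame]
    method: str
    seed: int
    imputed_columns: tuple[str, ...]

    @property
    def m(self) -> int:
        return len(self.tables)


def _is_binary(s: pd.Series) -> bool:
    vals = s.dropna().unique()
    return len(vals) <= 2


def _encode_predictors(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Numeric design for the tree learners (categoricals one-hot coded)."""
    out = {}
    for c in cols:
        s = df[c]
        if pd.api.types.is_numeric_dtype(s):
            out[c] = s.astype(float)
        else:
            for lev in sorted(s.dropna().unique()):
                out[f"{c}={lev}"] = (s == lev).astype(float)
    return pd.DataFrame(out, index=df.index)


def _draw_tree_donors(X_obs, X_mis, y_obs, rng, min_samples_leaf=5):
    """CART step: a donor is drawn among observed rows sharing the missing
    row's terminal leaf."""
    binary = len(np.unique(y_obs)) <= 2
    tree_cls = DecisionTreeClassifier if binary else DecisionTreeRegressor
    tree = tree_cls(min_samples_leaf=min_samples_leaf,
                    random_state=int(rng.integers(2 ** 31)))
    tree.fit(X_obs, y_obs.astype(float))
    leaves_obs = tree.apply(X_obs)
    leaves_mis = tree.apply(X_mis)
    donors = {leaf: y_obs[leaves_obs == leaf]
              for leaf in np.unique(leaves_obs)}
    return np.array([rng.choice(donors[leaf]) for leaf in leaves_mis])


def _draw_pmm_donors(X_obs, X_mis, y_obs, rng, k: int = 5):
    """Predictive-mean matching: a donor is drawn among the k observed rows
    whose linear predictions are closest to the missing row's prediction."""
    from sklearn.linear_model import LinearRegression
    reg = LinearRegression().fit(X_obs, y_obs)
    pred_obs = reg.predict(X_obs)
    pred_mis = reg.predict(X_mis)
    order = np.argsort(pred_obs)
    sorted_pred = pred_obs[order]
    out = np.empty(len(pred_mis))
    for i, pm in enumerate(pred_mis):
        pos = np.searchsorted(sorted_pred, pm)
        lo = max(0, pos - k)
        hi = min(len(sorted_pred), pos + k)
        cand = order[lo:hi]
        cand = cand[np.argsort(np.abs(pred_obs[cand] - pm))[:k]]
        out[i] = y_obs[rng.choice(cand)]
    return out


def _impute_once(table: pd.DataFrame, targets: list[str],
                 predictors: list[str], rng: np.random.Generator,
                 method: str = "regression-tree",
                 n_iter: int = 5) -> pd.DataFrame:
    df = table.copy()
    miss = {c: df[c].isna() for c in targets}
    # Initial fill: random draws from the observed values of each column.
    for c in targets:
        obs = df.loc[~miss[c], c].to_numpy()
        df.loc[miss[c], c] = rng.choice(obs, size=int(miss[c].sum()),
                                        replace=True)
    draw = (_draw_tree_donors if method == "regression-tree"
            else _draw_pmm_donors)
    order = sorted(targets, key=lambda c: miss[c].sum())
    for _ in range(n_iter):
        for c in order:
            m_mask = miss[c]
            if not m_mask.any():
                continue
            others = [p for p in predictors if p != c]
            X = _encode_predictors(df, others)
            y_obs = df.loc[~m_mask, c].to_numpy()
            df.loc[m_mask, c] = draw(X[~m_mask].to_numpy(),
                                     X[m_mask].to_numpy(), y_obs, rng)
    return df


def impute(table: pd.DataFrame, m: int = 100, method: str = "regression-tree",
           seed: int = 0, columns: list[str] | None = None,
           id_columns: tuple[str, ...] = ("infant_id", "trial_index"),
           n_iter: int = 5) -> ImputationSet:
    """Multiple non-parametric imputation of an analysis table.

    ``columns`` limits which columns are imputed (default: every numeric or
    binary column with missing cells).  Identifier columns are never imputed
    nor used as predictors.  Raises if a target column is entirely missing.
    """
    if method not in ("regression-tree", "predictive-mean-matching"):
        raise ValueError(f"unknown imputation method {method!r}")
    candidates = [c for c in table.columns if c not in id_columns]
    if columns is None:
        targets = [c for c in candidates
                   if table[c].isna().any()
                   and (pd.api.types.is_numeric_dtype(table[c])
                        or _is_binary(table[c]))]
    else:
        targets = [c for c in columns if table[c].isna().any()]
    for c in targets:
        if table[c].isna().all():
            raise ValueError(f"column {c!r} is entirely missing")
    predictors = [c for c in candidates
                  if pd.api.types.is_numeric_dtype(table[c])
                  or table[c].nunique() <= 10]
    predictors = [c for c in predictors
                  if c in targets or not table[c].isna().any()]

    ss = np.random.SeedSequence(seed)
    tables = []
    for child in ss.spawn(m):
        rng = np.random.default_rng(child)
        if targets:
            tables.append(_impute_once(table, targets, predictors, rng,
                                       method=method, n_iter=n_iter))
        else:
            tables.append(table.copy())
    return ImputationSet(tables=tables, method=method, seed=seed,
                         imputed_columns=tuple(targets))


@dataclass
class PooledResult:
    params: pd.Series          # pooled point estimates
    se: pd.Series              # total-variance standard errors
    within: pd.Series          # mean within-imputation variance
    between: pd.Series         # between-imputation variance
    df: pd.Series              # large-m reference df per coefficient
    m: int

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        tq = self.df.apply(lambda d: scipy.stats.t.ppf(1 - alpha / 2, d)
                           if np.isfinite(d) else scipy.stats.norm.ppf(1 - alpha / 2))
        return pd.DataFrame({"lower": self.params - tq * self.se,
                             "upper": self.params + tq * self.se})


def pool(fits: list[ModelFit]) -> PooledResult:
    """Combine repeated-imputation fits by the between/within variance
    decomposition: pooled estimate = mean of estimates, total variance
    T = W + (1 + 1/m) B."""
    if not fits:
        raise ValueError("no fits to pool")
    names = list(fits[0].params.index)
    for f in fits[1:]:
        if list(f.params.index) != names:
            raise ValueError("fits have mismatched coefficient sets")
    m = len(fits)
    est = np.vstack([f.params.to_numpy() for f in fits])
    var = np.vstack([f.bse.to_numpy() ** 2 for f in fits])
    qbar = est.mean(axis=0)
    w = var.mean(axis=0)
    b = est.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    t_var = w + (1.0 + 1.0 / m) * b
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1.0 + 1.0 / m) * b / w
        df = np.where(b > 0, (m - 1) * (1.0 + 1.0 / r) ** 2, np.inf)
    idx = pd.Index(names)
    return PooledResult(
        params=pd.Series(qbar, index=idx),
        se=pd.Series(np.sqrt(t_var), index=idx),
        within=pd.Series(w, index=idx),
        between=pd.Series(b, index=idx),
        df=pd.Series(df, index=idx),
        m=m,
    )
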