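"""Island-size statistics: metrics-table assembly, log-area regressions,
pairwise correlations, and LASSO variable selection.

Island area is the ecological proxy for long-term population size, and enters
every model as log10(area).  Because the genomic metrics are highly collinear
(they all track Ne), an L1-penalised regression with island size as the
response picks out which metrics are its most direct correlates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold, LeaveOneOut

METRIC_COLUMNS = [
    "log10_area",
    "genome_het",
    "het_sd",
    "recent_ne",
    "harmonic_ne",
    "roh_n",
    "roh_total_bp",
    "erv_hom_nonref",
]


@dataclass(frozen=True)
class IslandRecord:
    sample: str
    island: str
    area_km2: float
    group: str = ""

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise ValueError(f"island {self.island!r}: area must be positive")


@dataclass
class RegressionFit:
    response: str
    predictor: str
    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    n: int
    excluded_points: Tuple[str, ...] = ()

    def as_dict(self) -> Dict:
        d = dict(self.__dict__)
        d["excluded_points"] = list(self.excluded_points)
        return d


@dataclass
class LassoFit:
    response: str
    coefficients: Dict[str, float]  # standardized scale; zero = excluded
    lambda_selected: float
    cv_scheme: str
    selected: List[str] = field(default_factory=list)

    def as_dict(self) -> Dict:
        return {
            "response": self.response,
            "coefficients": self.coefficients,
            "lambda_selected": self.lambda_selected,
            "cv_scheme": self.cv_scheme,
            "selected": self.selected,
        }


def assemble_table(
    islands: Sequence[IslandRecord],
    het_summaries: Optional[Dict[str, object]] = None,
    roh_summaries: Optional[Dict[str, object]] = None,
    erv_summaries: Optional[Dict[str, object]] = None,
    ne_summaries: Optional[Dict[str, object]] = None,
) -> pd.DataFrame:
    """Join per-sample summaries into one island x metrics DataFrame
    (index: island name).  Missing inputs leave NaN cells; duplicate sample
    ids raise."""
    ids = [rec.sample for rec in islands]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in island records")
    rows = []
    for rec in islands:
        row: Dict[str, object] = {
            "sample": rec.sample,
            "island": rec.island,
            "group": rec.group,
            "area_km2": rec.area_km2,
            "log10_area": np.log10(rec.area_km2),
        }
        h = (het_summaries or {}).get(rec.sample)
        if h is not None:
            row["genome_het"] = h.genome_het
            row["het_sd"] = h.het_sd
        r = (roh_summaries or {}).get(rec.sample)
        if r is not None:
            row["roh_n"] = r.n_segments
            row["roh_windows_n"] = r.n_qualifying_windows
            row["roh_total_bp"] = r.total_length
        e = (erv_summaries or {}).get(rec.sample)
        if e is not None:
            row["erv_hom_nonref"] = e.n_hom_nonref
        n = (ne_summaries or {}).get(rec.sample)
        if n is not None:
            row["recent_ne"] = n.recent_ne
            row["harmonic_ne"] = n.harmonic_mean_ne
        rows.append(row)
    df = pd.DataFrame(rows).set_index("island")
    if df.index.duplicated().any():
        raise ValueError("duplicate island names")
    return df


def simple_regression(
    table: pd.DataFrame,
    response: str,
    predictor: str = "log10_area",
    exclude: Sequence[str] = (),
) -> Tuple[RegressionFit, Optional[RegressionFit]]:
    """OLS of ``response`` on ``predictor`` over complete cases, with Pearson
    r and a two-sided p-value.  When ``exclude`` names islands, a second fit
    without them is returned alongside the full fit."""

    def fit(df: pd.DataFrame, excluded: Tuple[str, ...]) -> RegressionFit:
        sub = df[[predictor, response]].dropna()
        if len(sub) < 3:
            raise ValueError(
                f"need >= 3 complete cases for {response} ~ {predictor}, have {len(sub)}"
            )
        res = sps.linregress(sub[predictor].to_numpy(float), sub[response].to_numpy(float))
        return RegressionFit(
            response=response,
            predictor=predictor,
            slope=float(res.slope),
            intercept=float(res.intercept),
            r=float(res.rvalue),
            r_squared=float(res.rvalue) ** 2,
            p_value=float(res.pvalue),
            n=len(sub),
            excluded_points=excluded,
        )

    full = fit(table, ())
    if not exclude:
        return full, None
    missing = [e for e in exclude if e not in table.index]
    if missing:
        raise KeyError(f"islands to exclude not in table: {missing}")
    reduced = fit(table.drop(index=list(exclude)), tuple(exclude))
    return full, reduced


def holm_adjust(p_values: Sequence[float]) -> List[float]:
    """Holm step-down adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def correlation_matrix(
    table: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, List[Tuple[str, str]]]:
    """Pairwise Pearson correlations over complete cases per pair (pairwise
    deletion, as a correlogram does).  Returns (matrix, undefined_pairs);
    entries involving a constant column or < 3 complete cases are NaN and
    listed explicitly rather than silently propagated."""
    cols = list(columns) if columns is not None else [c for c in METRIC_COLUMNS if c in table.columns]
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    undefined: List[Tuple[str, str]] = []
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            sub = table[[a, b]].dropna()
            x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
            if len(sub) < 3 or np.std(x) == 0 or np.std(y) == 0:
                mat.loc[a, b] = mat.loc[b, a] = np.nan
                undefined.append((a, b))
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat, undefined


def lasso_select(
    table: pd.DataFrame,
    response: str = "log10_area",
    predictors: Optional[Sequence[str]] = None,
    cv: str = "loo",
    n_folds: int = 5,
    seed: int = 0,
    lambda_override: Optional[float] = None,
) -> LassoFit:
    """L1-penalised regression (LASSO, alpha = 1 in elastic-net terms) with
    the penalty weight chosen by cross-validation.

    Predictors are standardized internally (zero mean, unit SD over complete
    cases) and the response is centred, so coefficients are on the
    standardized-predictor scale.  Leave-one-out CV is the default — the
    study designs here have on the order of 8-16 islands, too few for
    meaningful 10-fold splits.  The penalty follows scikit-learn's
    parameterisation: (1/2n)||y - Xb||^2 + lambda * ||b||_1.
    """
    if predictors is None:
        predictors = [c for c in METRIC_COLUMNS if c in table.columns and c != response]
    sub = table[[response, *predictors]].dropna()
    n = len(sub)
    if n < 5:
        raise ValueError(f"need >= 5 complete cases for LASSO, have {n}")
    X = sub[list(predictors)].to_numpy(float)
    y = sub[response].to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [p for p, s in zip(predictors, sd) if s == 0]
        raise ValueError(f"constant predictor column(s): {bad}")
    Xs = (X - X.mean(axis=0)) / sd
    yc = y - y.mean()
    if cv == "loo":
        splitter = LeaveOneOut()
        scheme = f"leave-one-out (n={n})"
    elif cv == "kfold":
        if n < n_folds:
            raise ValueError(
                f"{n} cases is fewer than {n_folds} folds; use cv='loo'"
            )
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        scheme = f"{n_folds}-fold (seed={seed})"
    else:
        raise ValueError(f"unknown cv scheme {cv!r}")
    if lambda_override is not None:
        lam = float(lambda_override)
        scheme = "fixed lambda"
    else:
        cv_model = LassoCV(cv=splitter, alphas=200, max_iter=200_000, tol=1e-8)
        cv_model.fit(Xs, yc)
        lam = float(cv_model.alpha_)
    model = Lasso(alpha=lam, max_iter=500_000, tol=1e-12)
    model.fit(Xs, yc)
    coefs = {p: float(c) for p, c in zip(predictors, model.coef_)}
    return LassoFit(
        response=response,
        coefficients=coefs,
        lambda_selected=lam,
        cv_scheme=scheme,
        selected=[p for p, c in coefs.items() if c != 0.0],
    )


def write_results_json(
    path: str,
    fits: Sequence[RegressionFit],
    corr: Optional[pd.DataFrame] = None,
    lasso: Optional[LassoFit] = None,
) -> None:
    p_values = [f.p_value for f in fits]
    holm = holm_adjust(p_values) if fits else []
    bundle = {
        "regressions": [
            {**f.as_dict(), "p_holm": h} for f, h in zip(fits, holm)
        ],
        "correlations": None if corr is None else json.loads(corr.to_json()),
        "lasso": None if lasso is None else lasso.as_dict(),
    }
    with open(path, "w") as fh:
        json.dump(bundle, fh, indent=2)
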