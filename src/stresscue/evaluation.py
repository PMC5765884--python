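"""Comparing model stress predictions with (simulated) reader responses.

The central object is a 2×2 contingency table crossing the modal human
stress for each item (rows) with the stress a model predicts (columns).
From it we compute:

* row-wise agreement percentages and their unweighted mean;
* signal-detection sensitivity d′ and response bias c.  First-syllable
  stress is treated as the signal class, so with
  H = P(model says 1 | human modal 1) and F = P(model says 1 | human modal 2),

      d′ = z(H) − z(F)         c = −(z(H) + z(F)) / 2,

  where z is the standard-normal quantile.  Under this convention a
  negative c denotes a bias toward first-syllable stress.  Rates of exactly
  0 or 1 are corrected to 1/(2N) and 1 − 1/(2N) before the z-transform.

Item-level analyses — per-cell proportions of second-syllable stress,
fixed-effects logistic regressions on cue indicators (with explicit
complete-separation detection), and split-cohort item reliability — mirror
the treatment of model simulation data, where the model is a single
"subject" and items are the units of analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationError


@dataclass(frozen=True)
class ContingencyTable:
    """Counts with rows = human modal stress, columns = model prediction."""

    n_first_first: int
    n_first_second: int
    n_second_first: int
    n_second_second: int

    def __post_init__(self) -> None:
        for v in self.as_tuple():
            if v < 0:
                raise EvaluationError("negative count")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_first_first, self.n_first_second,
                self.n_second_first, self.n_second_second)

    @property
    def n_human_first(self) -> int:
        return self.n_first_first + self.n_first_second

    @property
    def n_human_second(self) -> int:
        return self.n_second_first + self.n_second_second

    @property
    def total(self) -> int:
        return self.n_human_first + self.n_human_second

    def swapped_rows(self) -> "ContingencyTable":
        return ContingencyTable(self.n_second_first, self.n_second_second,
                                self.n_first_first, self.n_first_second)


@dataclass(frozen=True)
class SDTResult:
    d_prime: float
    criterion: float
    hit_rate: float
    fa_rate: float
    note: str = "signal = first-syllable stress; c < 0 => bias toward first"


@dataclass(frozen=True)
class RegressionResult:
    table: pd.DataFrame  # index = predictor; columns coef, se, p
    separation: dict[str, bool]
    converged: bool
    nobs: int

    @property
    def any_separation(self) -> bool:
        return any(self.separation.values())


def modal_stress(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-item modal stress over valid responses.

    ``responses`` needs columns ``item`` and ``stressed`` (1/2, NaN for
    discarded trials) and optionally a boolean ``discarded`` column.  Returns
    a frame indexed by item with columns ``modal`` and ``tie``; exact ties go
    to first-syllable stress with the tie flag set.  An item with no valid
    response raises :class:`EvaluationError`.
    """
    df = responses.copy()
    if "discarded" in df.columns:
        df = df[~df["discarded"].astype(bool)]
    df = df[df["stressed"].notna()]
    if df.empty:
        raise EvaluationError("no valid responses")
    missing = set(responses["item"]) - set(df["item"])
    if missing:
        raise EvaluationError(f"items without valid responses: {sorted(missing)[:5]}")
    out = {}
    for item, grp in df.groupby("item", sort=True):
        n2 = int((grp["stressed"] == 2).sum())
        n1 = int((grp["stressed"] == 1).sum())
        out[item] = {"modal": 2 if n2 > n1 else 1, "tie": n1 == n2}
    return pd.DataFrame.from_dict(out, orient="index")


def contingency(
    model_preds: Mapping[str, int] | pd.Series,
    human_modal: Mapping[str, int] | pd.Series,
) -> ContingencyTable:
    """Cross-tabulate model predictions against human modal stress."""
    preds = dict(model_preds)
    human = dict(human_modal)
    if set(preds) != set(human):
        raise EvaluationError("model and human item sets differ")
    counts = {(h, m): 0 for h in (1, 2) for m in (1, 2)}
    for item, h in human.items():
        counts[(h, preds[item])] += 1
    return ContingencyTable(counts[(1, 1)], counts[(1, 2)],
                            counts[(2, 1)], counts[(2, 2)])


def _corrected_rate(k: int, n: int) -> float:
    rate = k / n
    if rate == 0.0:
        return 1.0 / (2 * n)
    if rate == 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


def dprime_criterion(t: ContingencyTable) -> SDTResult:
    """Sensitivity d′ and bias c, first-syllable stress as the signal class."""
    if t.n_human_first == 0 or t.n_human_second == 0:
        raise EvaluationError("empty human-stress row")
    hit = _corrected_rate(t.n_first_first, t.n_human_first)
    fa = _corrected_rate(t.n_second_first, t.n_human_second)
    zh, zf = stats.norm.ppf(hit), stats.norm.ppf(fa)
    return SDTResult(
        d_prime=zh - zf,
        criterion=-(zh + zf) / 2.0,
        hit_rate=hit,
        fa_rate=fa,
    )


def agreement_rates(t: ContingencyTable) -> tuple[float, float, float]:
    """Row-wise match percentages (human-first row, human-second row) and
    their unweighted mean."""
    if t.n_human_first == 0 or t.n_human_second == 0:
        raise EvaluationError("empty human-stress row")
    pct1 = 100.0 * t.n_first_first / t.n_human_first
    pct2 = 100.0 * t.n_second_second / t.n_human_second
    return pct1, pct2, (pct1 + pct2) / 2.0


def condition_proportions(
    records: pd.DataFrame,
    by: Sequence[str] | str,
    stressed_col: str = "stressed",
    expected_cells: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Per-cell proportion of second-syllable stress over valid records.

    ``records`` may be trial-level responses or item-level predictions; rows
    with a true ``discarded`` flag or missing stress are excluded.  A cell
    listed in ``expected_cells`` but absent from the data gets a NaN
    proportion and a raised ``empty`` flag rather than an error.
    """
    by = [by] if isinstance(by, str) else list(by)
    df = records.copy()
    if "discarded" in df.columns:
        df = df[~df["discarded"].astype(bool)]
    df = df[df[stressed_col].notna()]
    grouped = df.groupby(by, sort=True)[stressed_col]
    out = grouped.agg(
        p_second=lambda s: (s == 2).mean(), n="size"
    ).reset_index()
    out["empty"] = False
    if expected_cells is not None:
        have = {tuple(row) for row in out[by].itertuples(index=False)}
        rows = []
        for cell in expected_cells:
            cell = (cell,) if not isinstance(cell, tuple) else cell
            if cell not in have:
                rows.append(dict(zip(by, cell), p_second=np.nan, n=0, empty=True))
        if rows:
            out = pd.concat([out, pd.DataFrame(rows)], ignore_index=True)
            out = out.sort_values(by).reset_index(drop=True)
    return out


_SEPARATION_COEF = 12.0  # |log-odds| beyond which a binary effect is unbounded


def _ridge_logit(
    y: np.ndarray, X: np.ndarray, lam: float = 1e-2, n_iter: int = 50
) -> np.ndarray:
    """Weakly ridge-penalised logistic fit by Newton iterations; used only
    as a fallback when the MLE diverges under separation."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1.0 - p), 1e-10)
        H = X.T @ (X * w[:, None]) + lam * np.eye(X.shape[1])
        g = X.T @ (y - p) - lam * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def _binary_separation(y: np.ndarray, x: np.ndarray) -> bool:
    """Complete or quasi-complete separation of a binary outcome by a binary
    predictor: at least one predictor level has a pure outcome, and the level
    means are ordered so the MLE diverges."""
    levels = np.unique(x)
    if len(levels) != 2:
        return False
    m = [y[x == lv].mean() for lv in levels]
    pure = [mi in (0.0, 1.0) for mi in m]
    return (any(pure)) and m[0] != m[1]


def cue_logistic(
    outcomes: Sequence[int] | pd.Series,
    predictors: pd.DataFrame,
    maxiter: int = 200,
    groups: Optional[np.ndarray] = None,
) -> RegressionResult:
    """Maximum-likelihood logistic regression of second-syllable stress on
    cue indicators and covariates.

    ``outcomes`` are stress codes in {1, 2} (or already-binary 0/1).  When
    ``groups`` is given (e.g. item identifiers for trial-level data),
    cluster-robust standard errors are used, which stands in for the
    item-level random intercept of a mixed model.  Separation is detected
    per binary predictor and on coefficient divergence; affected
    coefficients are reported as flagged, never as silently converged
    numbers.  A rank-deficient design raises an error naming the collinear
    columns; a constant outcome raises an error.
    """
    import statsmodels.api as sm

    y = np.asarray(outcomes, dtype=float)
    if set(np.unique(y)) <= {1.0, 2.0}:
        y = y - 1.0
    if len(np.unique(y)) < 2:
        raise EvaluationError("outcome is constant; nothing to model")
    X = predictors.astype(float)
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        collinear = [
            col for col in X.columns
            if np.linalg.matrix_rank(design.drop(columns=[col]).to_numpy()) == rank
        ]
        raise EvaluationError(f"rank-deficient design; collinear columns: {collinear}")

    separation = {}
    for col in X.columns:
        separation[col] = _binary_separation(y, X[col].to_numpy())

    fit_kwargs: dict = {"disp": 0, "maxiter": maxiter}
    if groups is not None:
        codes = pd.factorize(np.asarray(groups))[0]
        fit_kwargs |= {"cov_type": "cluster", "cov_kwds": {"groups": codes}}
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(**fit_kwargs)
            converged = bool(fit.mle_retvals.get("converged", True))
            table = pd.DataFrame(
                {"coef": fit.params, "se": fit.bse, "p": fit.pvalues}
            )
        except Exception:
            # singular Hessian under (quasi-)complete separation: fall back
            # to a weak ridge so a flagged table can still be reported
            coef = _ridge_logit(y, design.to_numpy())
            converged = False
            table = pd.DataFrame(
                {"coef": coef, "se": np.nan, "p": np.nan}, index=design.columns
            )
    table = table.drop(index="const", errors="ignore")
    for col in table.index:
        if abs(table.loc[col, "coef"]) > _SEPARATION_COEF:
            separation[col] = True
    if not converged:
        for col in table.index:
            separation.setdefault(col, False)
    return RegressionResult(
        table=table,
        separation=separation,
        converged=converged and not any(separation.values()),
        nobs=int(len(y)),
    )


def item_reliability(
    props_a: pd.Series, props_b: pd.Series
) -> tuple[float, float]:
    """Pearson correlation of per-item second-syllable-stress proportions
    across two response sets sharing item identifiers."""
    shared = props_a.index.intersection(props_b.index)
    if len(shared) < 3:
        raise EvaluationError(f"only {len(shared)} shared items (< 3)")
    r, p = stats.pearsonr(props_a.loc[shared], props_b.loc[shared])
    return float(r), float(p)
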