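"""Multilevel random-effects meta-regression with t-method inference.

The model is the three-level meta-analytic model

    g_ij = x_ij' beta + u_i + w_ij + e_ij

where i indexes articles, j effects within an article, u_i ~ N(0,
sigma2_article) is the article-level deviation, w_ij ~ N(0, sigma2_study)
the study-within-article deviation and e_ij ~ N(0, v_ij) the sampling error
with known variance v_ij. Effects from the same article are therefore
correlated through u_i, which is the reason the clustering level exists:
multiple tests reported in one article cannot be treated as independent.

Variance components are estimated by restricted maximum likelihood (REML),
profiling out beta by generalized least squares. The marginal covariance is
block diagonal over articles, so all linear algebra is done per article
block (batched over blocks of equal size), with the analytic REML gradient.

Inference uses the t-method: every coefficient's test statistic is referred
to a t distribution with k - p degrees of freedom (k effects, p
coefficients), and omnibus moderator tests divide the joint Wald statistic
by the number of tested coefficients m and refer it to F(m, k - p). This
is the Knapp-Hartung-style adjustment that replaces normal reference
distributions with t/F ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "MetaDataset",
    "ModelSpec",
    "FitResult",
    "OmnibusResult",
    "QResult",
    "reml_fit",
    "coefficient_tests",
    "omnibus_moderator_test",
    "subgroup_effects",
    "cochran_q",
    "filter_subset",
    "MODERATOR_COLUMNS",
]

_LOG_2PI = math.log(2.0 * math.pi)

#: Moderators of the standard coding sheet, in presentation order.
MODERATOR_COLUMNS = [
    "animal_species",
    "animal_class",
    "human_vs_nonhuman",
    "stimulus_modality",
    "test_response",
    "test_type",
    "log_training_length",
    "categories_in_language",
    "vocabulary_size",
    "repetition_of_items",
    "adjacent_dependencies",
    "nonadjacent_dependencies",
]


class ModelError(ValueError):
    """Invalid model specification or degenerate data."""


class DegenerateModeratorError(ModelError):
    """Moderator has a single observed level and cannot be tested."""


# ---------------------------------------------------------------------------
# dataset container


@dataclass
class MetaDataset:
    """A coded table of harmonized effects nested within articles.

    ``data`` has one row per effect with required columns ``article_id``,
    ``study_id``, ``g``, ``v_g``, ``n``; every other column is a moderator.
    ``moderator_schema`` maps moderator name -> "categorical" or
    "continuous" (inferred from dtype when not declared).
    """

    data: pd.DataFrame
    moderator_schema: dict = field(default_factory=dict)
    constant_moderators: frozenset = frozenset()

    REQUIRED = ("article_id", "study_id", "g", "v_g", "n")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ModelError(f"dataset missing required columns: {missing}")
        if len(self.data) == 0:
            raise ModelError("dataset is empty")
        bad = self.data["v_g"] <= 0
        if bad.any():
            raise ModelError(
                f"{int(bad.sum())} effects have non-positive sampling "
                "variance v_g"
            )
        for name in self.moderator_names:
            if name not in self.moderator_schema:
                kind = (
                    "continuous"
                    if pd.api.types.is_numeric_dtype(self.data[name])
                    else "categorical"
                )
                self.moderator_schema[name] = kind

    @property
    def k(self) -> int:
        return len(self.data)

    @property
    def moderator_names(self) -> list:
        return [c for c in self.data.columns if c not in self.REQUIRED]

    def moderator_kind(self, name: str) -> str:
        if name not in self.moderator_schema:
            raise ModelError(f"unknown moderator: {name!r}")
        return self.moderator_schema[name]


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of a fit.

    ``moderators`` lists terms in order; categorical terms expand by
    treatment coding (first level alphabetically is the reference) when
    ``intercept`` is True, and by cell-means coding (one indicator per
    level, no reference) when False. The variance structure is always the
    two-component article/study nesting.
    """

    moderators: tuple = ()
    intercept: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "moderators", tuple(self.moderators))


@dataclass
class QResult:
    Q: float
    df: int
    p: float


@dataclass
class OmnibusResult:
    moderator: str
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class FitResult:
    """A fitted multilevel meta-regression."""

    terms: list
    beta: np.ndarray
    se: np.ndarray
    t_stats: np.ndarray
    df: int
    p_values: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    sigma2_article: float
    sigma2_study: float
    k: int
    p: int
    reml_loglik: float
    vcov: np.ndarray
    Q: QResult
    spec: ModelSpec
    n_starts_agreeing: int = 0

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.beta,
                "se": self.se,
                "t": self.t_stats,
                "df": self.df,
                "p": self.p_values,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


# ---------------------------------------------------------------------------
# design matrix


def build_design(
    dataset: MetaDataset, spec: ModelSpec
) -> tuple[np.ndarray, list]:
    """Expand a ModelSpec into a design matrix and column names.

    Rows with missing values in any used moderator are NOT dropped here;
    callers drop them first (see :func:`_complete_rows`). Raises on rank
    deficiency, naming the offending columns.
    """
    df = dataset.data
    cols: list[np.ndarray] = []
    names: list[str] = []
    if spec.intercept:
        cols.append(np.ones(len(df)))
        names.append("intercept")
    for term in spec.moderators:
        if term not in df.columns:
            raise ModelError(f"unknown moderator: {term!r}")
        kind = dataset.moderator_kind(term)
        if kind == "continuous":
            cols.append(df[term].to_numpy(dtype=float))
            names.append(term)
        else:
            levels = sorted(df[term].dropna().astype(str).unique())
            if len(levels) < 2 and spec.intercept:
                raise DegenerateModeratorError(
                    f"moderator {term!r} has a single observed level"
                )
            use = levels[1:] if spec.intercept else levels
            values = df[term].astype(str)
            for lev in use:
                cols.append((values == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
    if not cols:
        raise ModelError("empty model: no intercept and no moderators")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ModelError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear terms among: {names}"
        )
    return X, names


def _complete_rows(dataset: MetaDataset, moderators: Sequence[str]) -> MetaDataset:
    """Drop rows with missing values in the used moderators, logging counts."""
    df = dataset.data
    used = [m for m in moderators if m in df.columns]
    if not used:
        return dataset
    mask = df[used].notna().all(axis=1)
    n_drop = int((~mask).sum())
    if n_drop:
        logger.info(
            "excluding %d effects with missing values in %s", n_drop, used
        )
        return MetaDataset(
            df[mask].reset_index(drop=True),
            dict(dataset.moderator_schema),
            dataset.constant_moderators,
        )
    return dataset


# ---------------------------------------------------------------------------
# REML machinery


class _BlockStructure:
    """Article blocks of the marginal covariance, grouped by block size."""

    def __init__(self, article_ids: np.ndarray):
        codes, _ = pd.factorize(article_ids)
        order = np.argsort(codes, kind="stable")
        sorted_codes = codes[order]
        boundaries = np.flatnonzero(np.diff(sorted_codes)) + 1
        blocks = np.split(order, boundaries)
        by_size: dict[int, list] = {}
        for b in blocks:
            by_size.setdefault(len(b), []).append(b)
        # groups: list of index arrays with shape (B, m)
        self.groups = [np.array(v) for v in by_size.values()]
        self.n_articles = len(blocks)


def _reml_nll_grad(
    theta: np.ndarray,
    groups: Sequence[np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
    v: np.ndarray,
    const: float,
) -> tuple[float, np.ndarray]:
    """Negative restricted log-likelihood and its gradient in (s2a, s2s)."""
    s2a, s2s = max(theta[0], 0.0), max(theta[1], 0.0)
    k, p = X.shape
    A = np.zeros((p, p))
    b = np.zeros(p)
    c = 0.0
    logdet = 0.0
    cache = []
    for idx in groups:
        B, m = idx.shape
        Vi = np.broadcast_to(np.eye(m) * s2s, (B, m, m)).copy()
        Vi += s2a
        Vi[:, np.arange(m), np.arange(m)] += v[idx]
        Vinv = np.linalg.inv(Vi)
        sign, ld = np.linalg.slogdet(Vi)
        logdet += float(ld.sum())
        Xb = X[idx]  # (B, m, p)
        yb = y[idx]  # (B, m)
        VinvX = Vinv @ Xb  # (B, m, p)
        Vinvy = np.einsum("bmn,bn->bm", Vinv, yb)
        A += np.einsum("bmp,bmq->pq", Xb, VinvX)
        b += np.einsum("bmp,bm->p", Xb, Vinvy)
        c += float(np.einsum("bm,bm->", yb, Vinvy))
        cache.append((idx, Vinv, VinvX, Vinvy))
    Achol = np.linalg.cholesky(A)
    beta = np.linalg.solve(A, b)
    quad = c - float(b @ beta)
    logdetA = 2.0 * float(np.log(np.diag(Achol)).sum())
    ll = -0.5 * ((k - p) * _LOG_2PI + logdet + logdetA + quad) + const

    Ainv = np.linalg.inv(A)
    grad = np.zeros(2)
    for idx, Vinv, VinvX, Vinvy in cache:
        Vinvr = Vinvy - np.einsum("bmp,p->bm", VinvX, beta)
        # d(theta) = sigma2_article: dV is the all-ones block
        rowsum = Vinv.sum(axis=2)  # (B, m): V^-1 1
        t_vec = np.einsum("bmp,bm->bp", VinvX, np.ones_like(rowsum))  # X'V^-1 1
        tr_VinvJ = float(rowsum.sum())
        tr_proj_J = float(np.einsum("bp,pq,bq->", t_vec, Ainv, t_vec))
        r_term_J = float((Vinvr.sum(axis=1) ** 2).sum())
        grad[0] += -0.5 * (tr_VinvJ - tr_proj_J - r_term_J)
        # d(theta) = sigma2_study: dV is the identity block
        tr_Vinv = float(np.trace(Vinv, axis1=1, axis2=2).sum())
        tr_proj_I = float(np.einsum("bmp,pq,bmq->", VinvX, Ainv, VinvX))
        r_term_I = float((Vinvr**2).sum())
        grad[1] += -0.5 * (tr_Vinv - tr_proj_I - r_term_I)
    return -ll, -grad


_MULTISTART = ((0.0, 0.0), (0.1, 0.1), (1.0, 1.0))


def _reml_optimize(
    groups, X, y, v, fix_sigma2: Optional[tuple] = None
) -> tuple[float, float, float, int]:
    """Maximize the restricted likelihood over the variance components.

    Bounded quasi-Newton (L-BFGS-B) with the analytic gradient from three
    fixed starts; returns (s2a, s2s, loglik, n_starts_agreeing). Components
    are truncated at zero by the bounds.
    """
    k, p = X.shape
    sign, logdetXtX = np.linalg.slogdet(X.T @ X)
    const = 0.5 * float(logdetXtX)  # constant in theta; metafor's convention
    if fix_sigma2 is not None and all(s is not None for s in fix_sigma2):
        nll, _ = _reml_nll_grad(np.asarray(fix_sigma2, float), groups, X, y, v, const)
        return fix_sigma2[0], fix_sigma2[1], -nll, 1

    best = None
    solutions = []
    for start in _MULTISTART:
        res = optimize.minimize(
            _reml_nll_grad,
            np.asarray(start, float),
            args=(groups, X, y, v, const),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None), (0.0, None)],
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        solutions.append(res)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ModelError("REML optimization failed to produce a finite optimum")
    agree = sum(1 for r in solutions if abs(r.fun - best.fun) < 1e-6 * (1 + abs(best.fun)))
    s2a, s2s = (float(max(x, 0.0)) for x in best.x)
    return s2a, s2s, -float(best.fun), agree


def _gls_at(groups, X, y, v, s2a, s2s):
    """GLS coefficients and covariance at fixed variance components."""
    p = X.shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    for idx in groups:
        B, m = idx.shape
        Vi = np.broadcast_to(np.eye(m) * s2s, (B, m, m)).copy()
        Vi += s2a
        Vi[:, np.arange(m), np.arange(m)] += v[idx]
        Vinv = np.linalg.inv(Vi)
        Xb = X[idx]
        VinvX = Vinv @ Xb
        A += np.einsum("bmp,bmq->pq", Xb, VinvX)
        b += np.einsum("bmp,bmn,bn->p", Xb, Vinv, y[idx])
    vcov = np.linalg.inv(A)
    beta = vcov @ b
    return beta, vcov


def reml_fit(
    dataset: MetaDataset,
    spec: ModelSpec = ModelSpec(),
    fix_sigma2: Optional[tuple] = None,
) -> FitResult:
    """Fit the multilevel random-effects meta-regression by REML.

    Parameters
    ----------
    dataset
        Harmonized effects nested within articles.
    spec
        Fixed-effect structure (moderators, intercept).
    fix_sigma2
        Optional ``(sigma2_article, sigma2_study)`` pair to hold the
        variance components fixed (e.g. ``(0.0, 0.0)`` reduces the model to
        the fixed-effect weighted regression). ``None`` estimates both.

    Returns
    -------
    FitResult with t-method coefficient inference (df = k - p) and
    Cochran's Q from the weighted fixed-effect fit of the same design.
    """
    dataset = _complete_rows(dataset, spec.moderators)
    X, names = build_design(dataset, spec)
    y = dataset.data["g"].to_numpy(dtype=float)
    v = dataset.data["v_g"].to_numpy(dtype=float)
    k, p = X.shape
    if k <= p:
        raise ModelError(f"need more effects than coefficients (k={k}, p={p})")
    structure = _BlockStructure(dataset.data["article_id"].to_numpy())
    s2a, s2s, loglik, agree = _reml_optimize(
        structure.groups, X, y, v, fix_sigma2
    )
    beta, vcov = _gls_at(structure.groups, X, y, v, s2a, s2s)
    se = np.sqrt(np.diag(vcov))
    df = k - p
    t_stats = beta / se
    p_values = 2.0 * stats.t.sf(np.abs(t_stats), df)
    tcrit = stats.t.ppf(0.975, df)
    q = cochran_q(dataset, spec)
    return FitResult(
        terms=names,
        beta=beta,
        se=se,
        t_stats=t_stats,
        df=df,
        p_values=p_values,
        ci_lower=beta - tcrit * se,
        ci_upper=beta + tcrit * se,
        sigma2_article=s2a,
        sigma2_study=s2s,
        k=k,
        p=p,
        reml_loglik=loglik,
        vcov=vcov,
        Q=q,
        spec=spec,
        n_starts_agreeing=agree,
    )


def restricted_loglik(
    dataset: MetaDataset,
    spec: ModelSpec,
    sigma2_article: float,
    sigma2_study: float,
) -> float:
    """Restricted log-likelihood at given variance components (for oracles)."""
    dataset = _complete_rows(dataset, spec.moderators)
    X, _ = build_design(dataset, spec)
    y = dataset.data["g"].to_numpy(dtype=float)
    v = dataset.data["v_g"].to_numpy(dtype=float)
    structure = _BlockStructure(dataset.data["article_id"].to_numpy())
    _, logdetXtX = np.linalg.slogdet(X.T @ X)
    nll, _ = _reml_nll_grad(
        np.array([sigma2_article, sigma2_study]),
        structure.groups,
        X,
        y,
        v,
        0.5 * float(logdetXtX),
    )
    return -nll


# ---------------------------------------------------------------------------
# inference helpers


def coefficient_tests(fit: FitResult) -> pd.DataFrame:
    """Per-coefficient t statistics, p values and CIs (t-method, df = k - p)."""
    return fit.summary_frame()


def omnibus_moderator_test(
    dataset: MetaDataset, moderator: str, spec: Optional[ModelSpec] = None
) -> OmnibusResult:
    """Joint F test that a moderator explains heterogeneity.

    Fits intercept + moderator, then tests the moderator's m coefficients
    jointly: F = (Wald chi-square)/m on F(m, k - p).
    """
    if spec is None:
        spec = ModelSpec(moderators=(moderator,), intercept=True)
    kind = dataset.moderator_kind(moderator)
    if kind == "categorical":
        observed = dataset.data[moderator].dropna().astype(str).nunique()
        if observed < 2:
            raise DegenerateModeratorError(
                f"moderator {moderator!r} is constant; omnibus test undefined"
            )
    else:
        values = dataset.data[moderator].dropna().to_numpy(dtype=float)
        if np.allclose(values, values[0]):
            raise DegenerateModeratorError(
                f"moderator {moderator!r} is constant; omnibus test undefined"
            )
    fit = reml_fit(dataset, spec)
    sel = [
        i
        for i, t in enumerate(fit.terms)
        if t == moderator or t.startswith(f"{moderator}[")
    ]
    m = len(sel)
    bsel = fit.beta[sel]
    vsel = fit.vcov[np.ix_(sel, sel)]
    wald = float(bsel @ np.linalg.solve(vsel, bsel))
    F = wald / m
    df2 = fit.df
    p = float(stats.f.sf(F, m, df2))
    return OmnibusResult(moderator=moderator, F=F, df1=m, df2=df2, p=p)


def subgroup_effects(dataset: MetaDataset, factor: str) -> pd.DataFrame:
    """Per-level weighted mean effects via a cell-means (no intercept) fit.

    Each coefficient is that level's model-based mean effect with t-method
    SE/CI; the variance components are shared across levels. Levels with no
    effects are simply absent (they have no indicator column).
    """
    if dataset.moderator_kind(factor) != "categorical":
        raise ModelError(f"subgroup factor {factor!r} must be categorical")
    spec = ModelSpec(moderators=(factor,), intercept=False)
    fit = reml_fit(dataset, spec)
    frame = fit.summary_frame()
    frame["level"] = [t[len(factor) + 1 : -1] for t in frame["term"]]
    return frame[
        ["level", "estimate", "se", "t", "df", "p", "ci_lower", "ci_upper"]
    ]


def cochran_q(dataset: MetaDataset, spec: Optional[ModelSpec] = None) -> QResult:
    """Cochran's Q heterogeneity statistic from the fixed-effect fit.

    Q = sum w_i (g_i - x_i' beta_FE)^2 with w_i = 1/v_i and beta_FE the
    inverse-variance weighted least-squares fit of the same design;
    df = k - p (k - 1 for the intercept-only model). Referred to
    chi-square(df).
    """
    if spec is None:
        spec = ModelSpec()
    dataset = _complete_rows(dataset, spec.moderators)
    X, _ = build_design(dataset, spec)
    y = dataset.data["g"].to_numpy(dtype=float)
    w = 1.0 / dataset.data["v_g"].to_numpy(dtype=float)
    k, p = X.shape
    if k < 2:
        raise ModelError("Cochran's Q requires at least 2 effects")
    Xw = X * w[:, None]
    beta = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    resid = y - X @ beta
    Q = float(w @ resid**2)
    df = k - p
    return QResult(Q=Q, df=df, p=float(stats.chi2.sf(Q, df)))


def filter_subset(
    dataset: MetaDataset,
    predicate: Callable[[pd.Series], bool] | Mapping[str, object],
) -> MetaDataset:
    """Subset by a row predicate (or {column: value} map), flagging constants.

    Moderators that are constant within the subset are recorded in
    ``constant_moderators`` so downstream moderator analyses skip them —
    e.g. a subgroup tested only in the auditory modality cannot support a
    modality moderator.
    """
    df = dataset.data
    if isinstance(predicate, Mapping):
        mask = pd.Series(True, index=df.index)
        for col, val in predicate.items():
            mask &= df[col] == val
    else:
        mask = df.apply(predicate, axis=1)
    sub = df[mask].reset_index(drop=True)
    if len(sub) == 0:
        raise ModelError("predicate matched no effects")
    constants = set()
    for name in dataset.moderator_names:
        non_null = sub[name].dropna()
        if non_null.nunique() <= 1:
            constants.add(name)
    if constants:
        logger.info("constant moderators in subset (skipped): %s", sorted(constants))
    return MetaDataset(sub, dict(dataset.moderator_schema), frozenset(constants))
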