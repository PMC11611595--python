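"""First-principles statistical procedures for the exudate analysis.

Implements the study's statistical layer directly on numpy: bootstrapped
two-sample Welch t-tests with Benjamini-Hochberg adjustment, two-sample
Kolmogorov-Smirnov tests (asymptotic and small-sample exact), Bray-Curtis
dissimilarity on binary data, multi-factor PERMANOVA with sequential sums
of squares on a Gower-centered distance matrix, and PCA with per-variable
squared cosines including supplementary categorical variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb, exp

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class StatResult:
    statistic: float
    p_value: float
    method: str
    df: float | None = None
    n_resamples: int | None = None
    p_adjusted: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------- bootstrap t

def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    denom = np.sqrt(vx / nx + vy / ny)
    if denom == 0:
        return 0.0
    return float((x.mean() - y.mean()) / denom)


def bootstrap_t_test(x, y, n_boot: int = 10000, seed: int = 0) -> StatResult:
    """Bootstrap two-sample test of equal means via the Welch t statistic.

    The null reference distribution recenters each group to the pooled mean
    and resamples within groups with replacement; the two-sided p-value is
    (1 + #{|t*| >= |t_obs|}) / (n_boot + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    t_obs = _welch_t(x, y)
    pooled = np.concatenate([x, y]).mean()
    x0 = x - x.mean() + pooled
    y0 = y - y.mean() + pooled
    xs = rng.choice(x0, size=(n_boot, len(x)), replace=True)
    ys = rng.choice(y0, size=(n_boot, len(y)), replace=True)

    def _t_rows(a, b):
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        denom = np.sqrt(va / a.shape[1] + vb / b.shape[1])
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (a.mean(axis=1) - b.mean(axis=1)) / denom
        return np.where(denom == 0, 0.0, t)

    t_null = _t_rows(xs, ys)
    p = (1 + int(np.sum(np.abs(t_null) >= abs(t_obs)))) / (n_boot + 1)
    return StatResult(t_obs, p, "bootstrap_welch_t", n_resamples=n_boot, seed=seed)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ------------------------------------------------------------------------ KS

def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    data = np.concatenate([x, y])
    cdf_x = np.searchsorted(np.sort(x), data, side="right") / len(x)
    cdf_y = np.searchsorted(np.sort(y), data, side="right") / len(y)
    return float(np.max(np.abs(cdf_x - cdf_y)))


def _kolmogorov_sf(t: float, terms: int = 101) -> float:
    """Asymptotic Kolmogorov survival function Q(t) = 2 sum (-1)^{k-1} e^{-2k^2 t^2}."""
    if t <= 0:
        return 1.0
    s = 0.0
    for k in range(1, terms):
        s += (-1) ** (k - 1) * exp(-2.0 * k * k * t * t)
    return float(min(max(2.0 * s, 0.0), 1.0))


def _ks_exact_p(n: int, m: int, d: float) -> float:
    """Exact two-sample KS p-value by lattice-path counting (no ties assumed).

    Counts the orderings of the pooled sample whose ECDF difference stays
    strictly below d at every step; p = 1 - paths / C(n+m, n).
    """
    # dynamic program over the (i, j) grid; admissible when |i/n - j/m| < d
    eps = 1e-12
    prev = np.zeros(m + 1, dtype=float)
    prev[0] = 1.0
    for j in range(1, m + 1):
        prev[j] = prev[j - 1] if abs(j / m) < d - eps or j / m < d - eps else 0.0
    # row i = 0 handled above; iterate i = 1..n
    for i in range(1, n + 1):
        cur = np.zeros(m + 1, dtype=float)
        cur[0] = prev[0] if abs(i / n) < d - eps else 0.0
        for j in range(1, m + 1):
            if abs(i / n - j / m) < d - eps:
                cur[j] = cur[j - 1] + prev[j]
        prev = cur
    return float(1.0 - prev[m] / comb(n + m, n))


def ks_two_sample(x, y, mode: str = "auto") -> StatResult:
    """Two-sample KS test: D = sup |ECDF_x - ECDF_y|.

    ``mode``: "exact" (lattice-path enumeration, suited to small samples),
    "asymptotic" (Kolmogorov distribution), or "auto" (exact when
    min(n, m) <= 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    d = _ks_statistic(x, y)
    n, m = len(x), len(y)
    if mode == "auto":
        mode = "exact" if min(n, m) <= 10 else "asymptotic"
    if mode == "exact":
        p = _ks_exact_p(n, m, d)
    elif mode == "asymptotic":
        en = np.sqrt(n * m / (n + m))
        p = _kolmogorov_sf((en + 0.12 + 0.11 / en) * d)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return StatResult(d, p, f"ks_two_sample_{mode}")


# ---------------------------------------------------------------- Bray-Curtis

def bray_curtis_binary(presence: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples of a binary matrix.

    ``presence`` is molecules x samples in {0,1}; for samples with presence
    counts A and B sharing J molecules, d = (A + B - 2J) / (A + B).  Two
    all-empty samples get d = 0 with a warning.
    """
    X = presence.to_numpy(dtype=float).T  # samples x molecules
    if not np.isin(X, (0, 1)).all():
        raise ValueError("matrix must be binary")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    counts = X.sum(axis=1)
    shared = X @ X.T
    denom = counts[:, None] + counts[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (denom - 2 * shared) / denom
    if np.any(denom == 0):
        logger.warning("Bray-Curtis: empty sample pair(s); distance set to 0")
        d = np.where(denom == 0, 0.0, d)
    np.fill_diagonal(d, 0.0)
    ids = list(presence.columns)
    return pd.DataFrame(d, index=ids, columns=ids)


# ------------------------------------------------------------------ PERMANOVA

def _dummy(series: pd.Series) -> np.ndarray:
    levels = sorted(pd.unique(series))
    return np.column_stack([(series == lv).to_numpy(float) for lv in levels[1:]])


def _term_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    if ":" in term:
        a, b = term.split(":")
        da, db = _dummy(design[a]), _dummy(design[b])
        cols = [da[:, i] * db[:, j] for i in range(da.shape[1]) for j in range(db.shape[1])]
        return np.column_stack(cols) if cols else np.empty((len(design), 0))
    return _dummy(design[term])


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def permanova(
    dist: pd.DataFrame,
    design: pd.DataFrame,
    terms: tuple = ("treatment", "day", "treatment:day"),
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Multi-factor PERMANOVA with sequential (Type I) sums of squares.

    The squared distance matrix is Gower-centered to G; for the cumulative
    hat matrices H_k of the growing design (intercept, then each term in
    order), SS_term = tr((H_k - H_{k-1}) G), SS_res = tr((I - H_full) G),
    and pseudo-F_term = (SS_term/df_term) / (SS_res/df_res).  p-values come
    from free permutation of sample rows with add-one smoothing.  Returns a
    table with term, df, SS, R2, F, p ordered as given, plus residual and
    total rows.
    """
    D = dist.to_numpy(dtype=float)
    n = D.shape[0]
    ids = list(dist.index)
    meta = design.set_index("sample_id").loc[ids] if "sample_id" in design.columns \
        else design.loc[ids]
    terms = [t for t in terms]
    usable = []
    for t in terms:
        factors = t.split(":")
        if any(meta[f].nunique() < 2 for f in factors):
            raise ValueError(f"term {t!r}: factor with a single level")
        usable.append(t)

    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    ss_total = float(np.trace(G))
    if ss_total <= 1e-12:
        raise ValueError("degenerate distance matrix: zero total sum of squares")

    # cumulative designs and per-term projector increments
    X = np.ones((n, 1))
    H_prev = _hat(X)
    increments, dfs = [], []
    for t in usable:
        cols = _term_columns(meta, t)
        X = np.column_stack([X, cols])
        H = _hat(X)
        df_t = int(round(np.trace(H - H_prev)))
        if df_t == 0:
            raise ValueError(f"term {t!r} is aliased with earlier terms")
        increments.append(H - H_prev)
        dfs.append(df_t)
        H_prev = H
    H_full = H_prev
    R = np.eye(n) - H_full
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def _stats(Gm: np.ndarray):
        ss_terms = np.array([float(np.sum(inc * Gm)) for inc in increments])
        ss_res = float(np.sum(R * Gm))
        with np.errstate(invalid="ignore", divide="ignore"):
            F = (ss_terms / np.array(dfs)) / (ss_res / df_res)
        return ss_terms, ss_res, F

    ss_terms, ss_res, F_obs = _stats(G)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(usable))
    for _ in range(n_perm):
        idx = rng.permutation(n)
        _, _, F_perm = _stats(G[np.ix_(idx, idx)])
        exceed += F_perm >= F_obs
    p = (1 + exceed) / (n_perm + 1)

    rows = []
    for t, df_t, ss, f, pv in zip(usable, dfs, ss_terms, F_obs, p):
        rows.append({"term": t, "df": df_t, "SS": ss, "R2": ss / ss_total,
                     "F": f, "p_value": pv})
    rows.append({"term": "Residual", "df": df_res, "SS": ss_res,
                 "R2": ss_res / ss_total, "F": np.nan, "p_value": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total, "R2": 1.0,
                 "F": np.nan, "p_value": np.nan})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------------ PCA

@dataclass
class PcaResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # variables x components
    explained_variance: np.ndarray
    squared_cosines: pd.DataFrame  # main + supplementary variables x components
    dropped: list = field(default_factory=list)


def pca_squared_cosines(
    table: pd.DataFrame,
    supplementary: pd.DataFrame | None = None,
) -> PcaResult:
    """PCA on standardized variables with squared cosines.

    Components come from the SVD of the standardized main-variable table;
    supplementary categorical metadata are one-hot coded and projected via
    correlations without influencing the decomposition.  The squared cosine
    of a variable on a component is its squared correlation with the
    component scores, normalized per variable so the cosines of every
    variable (main or supplementary) sum to 1 across all components.
    """
    if len(table) < 3:
        raise ValueError("PCA needs at least 3 samples")
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0)
    dropped = [c for c, s in zip(table.columns, sd) if s == 0]
    if dropped:
        logger.warning("PCA: dropping zero-variance variables %s", dropped)
        table = table.drop(columns=dropped)
        X = table.to_numpy(dtype=float)
        sd = X.std(axis=0)
    if table.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables with nonzero variance")
    Z = (X - X.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    keep = S > S[0] * 1e-12
    U, S, Vt = U[:, keep], S[keep], Vt[keep]
    scores = U * S
    ev = S ** 2 / np.sum(S ** 2)
    comp_names = [f"PC{i+1}" for i in range(len(S))]

    def _sq_cos(frame: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col in frame.columns:
            v = frame[col].to_numpy(dtype=float)
            if v.std() == 0:
                out[col] = np.full(len(S), np.nan)
                continue
            r2 = np.array([np.corrcoef(v, scores[:, k])[0, 1] ** 2
                           for k in range(len(S))])
            out[col] = r2 / r2.sum()
        return pd.DataFrame(out, index=comp_names).T

    cos = _sq_cos(table)
    if supplementary is not None:
        onehot = pd.get_dummies(supplementary.astype(str), prefix_sep="=").astype(float)
        cos = pd.concat([cos, _sq_cos(onehot)])

    return PcaResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=table.columns, columns=comp_names),
        explained_variance=ev,
        squared_cosines=cos,
        dropped=dropped,
    )
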