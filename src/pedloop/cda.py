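"""Canonical discriminant analysis of ancestor birth origins.

The pipeline mirrors the classical multi-step CDA protocol used for
origin classification in livestock genetics: feature assembly from the
pedigree decomposition, a variance-inflation-factor (VIF) collinearity
screen, forward stepwise variable selection, the eigen-solution of
within-scatter-inverse times between-scatter, multivariate significance
tests (Wilks' Lambda with Rao's F approximation, Bartlett's residual
chi-square per function, Pillai's trace), leave-one-out cross-validated
classification with Press's Q, and Mahalanobis distances between group
centroids feeding a UPGMA dendrogram.

Eigenvalue identities used throughout::

    Wilks Lambda      = prod_i 1 / (1 + lambda_i)
    Pillai trace V    = sum_i lambda_i / (1 + lambda_i)
    canonical corr_i  = sqrt(lambda_i / (1 + lambda_i))
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as _sch
import scipy.linalg as sla
from scipy import stats
from scipy.spatial.distance import squareform

FEATURE_COLUMNS = [
    "loop_contribution",
    "founder_to_meanF",
    "founder_to_meanC",
    "coancestry_C",
    "alpha",
]


class CDAError(ValueError):
    """Raised when the discriminant analysis inputs are unusable."""


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------


def alpha_from_coancestry(c: float | np.ndarray) -> float | np.ndarray:
    """Per-record non-random mating coefficient implied by a coancestry.

    Applies ``alpha = 1 - 1/(1 - C)``, the mating-structure identity
    ``(1 - F) = (1 - f)(1 - alpha)`` with the record's own inbreeding term
    set to zero, so a positive coancestry maps to a negative alpha
    (avoidance of the corresponding related mating).
    """
    return 1.0 - 1.0 / (1.0 - np.asarray(c, dtype=float))


def assemble_ancestor_features(
    pedigree,
    loop_contributions,
    founder_to_mean_f,
    founder_to_mean_c,
) -> pd.DataFrame:
    """One row per contributing ancestor with the five analysis variables.

    Parameters
    ----------
    pedigree
        Source of birth municipality/province labels.
    loop_contributions
        :class:`~pedloop.decompose.NCAContribution` of the group mean
        coancestry on the coancestry scale; supplies both the
        ``coancestry_C`` column and (times two, the relationship scale)
        the ``loop_contribution`` column.
    founder_to_mean_f, founder_to_mean_c
        :class:`~pedloop.decompose.FounderContribution` for the group
        mean inbreeding and mean coancestry targets.

    Rows that are zero in every variable are dropped; ancestors without an
    origin label are excluded with a warning.
    """
    c = loop_contributions.on_scale("coancestry").weights
    table = pd.DataFrame(
        {
            "loop_contribution": 2.0 * c,
            "founder_to_meanF": founder_to_mean_f.v,
            "founder_to_meanC": founder_to_mean_c.v,
            "coancestry_C": c,
        }
    ).fillna(0.0)
    table = table.loc[(table != 0.0).any(axis=1)]
    table["alpha"] = alpha_from_coancestry(table["coancestry_C"].to_numpy())
    munis, provs, keep = [], [], []
    for aid in table.index:
        rec = pedigree[aid]
        if rec.municipality is None and rec.province is None:
            warnings.warn(
                f"ancestor {aid!r} has no birth origin label; excluded from CDA",
                stacklevel=2,
            )
            continue
        keep.append(aid)
        munis.append(rec.municipality)
        provs.append(rec.province)
    table = table.loc[keep]
    table["municipality"] = munis
    table["province"] = provs
    table.index.name = "ancestor"
    return table


# ---------------------------------------------------------------------------
# collinearity screen
# ---------------------------------------------------------------------------


def variance_inflation_factors(features: pd.DataFrame) -> pd.Series:
    """VIF of each numeric column regressed (with intercept) on the others.

    Exact linear dependence is reported as ``inf``.
    """
    cols = list(features.columns)
    if len(cols) < 2:
        raise CDAError("need at least two numeric columns for a VIF screen")
    X = features.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(cols):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        design = np.column_stack([np.ones(len(yj)), others])
        coef, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ coef
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst == 0.0:
            out[name] = np.inf
            continue
        r2 = 1.0 - float(resid @ resid) / sst
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def collinearity_screen(
    features: pd.DataFrame, threshold: float = 5.0
) -> tuple[pd.DataFrame, list[dict]]:
    """Iteratively drop the worst-VIF column while any VIF exceeds ``threshold``.

    Never reduces below two columns.  Returns the reduced table and a
    step-by-step report (column, VIF, tolerance = 1/VIF, action).
    """
    numeric = features.select_dtypes(include=[np.number])
    if numeric.shape[1] < 2:
        raise CDAError("need at least two numeric columns for a VIF screen")
    kept = list(numeric.columns)
    report: list[dict] = []
    while len(kept) > 2:
        vifs = variance_inflation_factors(numeric[kept])
        # ties (e.g. exactly dependent pairs) drop the later column, so the
        # leading variable of a duplicated pair survives
        worst = vifs[vifs == vifs.max()].index[-1]
        if not (vifs[worst] > threshold):
            break
        report.append(
            {
                "column": worst,
                "vif": float(vifs[worst]),
                "tolerance": 0.0 if np.isinf(vifs[worst]) else 1.0 / float(vifs[worst]),
                "action": "removed",
            }
        )
        kept.remove(worst)
    final = variance_inflation_factors(numeric[kept])
    for name, v in final.items():
        report.append(
            {
                "column": name,
                "vif": float(v),
                "tolerance": 0.0 if np.isinf(v) else 1.0 / float(v),
                "action": "kept",
            }
        )
    out = features[kept + [c for c in features.columns if c not in numeric.columns]]
    return out, report


# ---------------------------------------------------------------------------
# stepwise variable selection
# ---------------------------------------------------------------------------


def stepwise_variable_selection(
    features: pd.DataFrame,
    group: pd.Series | np.ndarray,
    ridge: float = 0.01,
    max_variables: int | None = None,
) -> tuple[list[str], list[dict]]:
    """Forward stepwise selection by ridge-penalized multinomial likelihood.

    Columns are z-scored and entered one at a time into a multinomial
    logistic regression (L2 penalty strength ``ridge`` on the
    coefficients); a column is retained while it improves the BIC.  Group
    priors are implicit in the likelihood (groups weighted by size).
    Returns the selected column names (original order) and a trace of the
    BIC path; an empty selection with a warning if nothing improves on the
    intercept-only model.
    """
    from sklearn.linear_model import LogisticRegression

    numeric = features.select_dtypes(include=[np.number])
    y = np.asarray(group)
    n = len(y)
    labels, counts = np.unique(y, return_counts=True)
    g = len(labels)
    if g < 2:
        raise CDAError("stepwise selection needs at least two groups")
    base_ll = float(np.sum(counts * np.log(counts / n)))

    def bic(cols: list[str]) -> float:
        if not cols:
            return -2.0 * base_ll + (g - 1) * np.log(n)
        X = numeric[cols].to_numpy(dtype=float)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0.0] = 1.0
        Xz = (X - mu) / sd
        model = LogisticRegression(C=1.0 / ridge, max_iter=2000, tol=1e-8)
        model.fit(Xz, y)
        proba = model.predict_proba(Xz)
        idx = {lab: k for k, lab in enumerate(model.classes_)}
        ll = float(np.sum(np.log(np.maximum(proba[np.arange(n), [idx[v] for v in y]], 1e-300))))
        k = (len(cols) + 1) * (g - 1)
        return -2.0 * ll + k * np.log(n)

    selected: list[str] = []
    remaining = list(numeric.columns)
    current = bic(selected)
    trace = [{"step": 0, "added": None, "bic": current}]
    cap = max_variables or len(remaining)
    step = 0
    while remaining and len(selected) < cap:
        scores = [(bic(selected + [c]), c) for c in remaining]
        best_bic, best_col = min(scores, key=lambda t: (t[0], t[1]))
        if best_bic >= current - 1e-9:
            break
        step += 1
        selected.append(best_col)
        remaining.remove(best_col)
        current = best_bic
        trace.append({"step": step, "added": best_col, "bic": current})
    if not selected:
        warnings.warn("no variable improves the selection criterion", stacklevel=2)
    ordered = [c for c in numeric.columns if c in selected]
    return ordered, trace


# ---------------------------------------------------------------------------
# canonical discriminant model
# ---------------------------------------------------------------------------


@dataclass
class CDAModel:
    """Fitted canonical discriminant solution."""

    variables: list[str]
    groups: list
    group_sizes: pd.Series
    eigenvalues: np.ndarray
    percent_discrimination: np.ndarray
    canonical_correlations: np.ndarray
    raw_coefficients: pd.DataFrame  # variables x functions
    standardized_coefficients: pd.DataFrame
    loadings: pd.DataFrame
    centroids: pd.DataFrame  # groups x functions
    pooled_within_cov: pd.DataFrame
    grand_mean: pd.Series
    n: int
    notices: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def g(self) -> int:
        return len(self.groups)

    def transform(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Canonical scores (centered at the grand mean)."""
        if isinstance(X, pd.DataFrame):
            X = X[self.variables].to_numpy(dtype=float)
        return (X - self.grand_mean.to_numpy()) @ self.raw_coefficients.to_numpy()


def _scatter_matrices(X: np.ndarray, y: np.ndarray):
    labels = sorted(pd.unique(y).tolist())
    grand = X.mean(axis=0)
    p = X.shape[1]
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    sizes = {}
    means = {}
    for lab in labels:
        Xg = X[y == lab]
        sizes[lab] = len(Xg)
        mu = Xg.mean(axis=0)
        means[lab] = mu
        dev = Xg - mu
        W += dev.T @ dev
        dm = (mu - grand).reshape(-1, 1)
        B += len(Xg) * (dm @ dm.T)
    return labels, sizes, means, grand, W, B


def fit_canonical_discriminant(
    features: pd.DataFrame,
    group: pd.Series | np.ndarray | str,
    min_ratio: float = 4.0,
) -> CDAModel:
    """Eigen-solution of within-scatter-inverse times between-scatter.

    Produces ``min(p, g-1)`` canonical functions scaled to unit pooled
    within-group variance of the scores, with standardized coefficients,
    structure loadings (pooled within-group correlations between variables
    and scores) and group centroids.  A warning is issued when the
    observation-to-variable ratio falls below ``min_ratio``; an exactly
    singular within-group scatter is handled by dropping dependent columns
    and, if needed, a small ridge inflation.
    """
    if isinstance(group, str):
        y = features[group].to_numpy()
        numeric = features.drop(columns=[group]).select_dtypes(include=[np.number])
    else:
        y = np.asarray(group)
        numeric = features.select_dtypes(include=[np.number])
    variables = list(numeric.columns)
    X = numeric.to_numpy(dtype=float)
    n, p = X.shape
    if p < 1:
        raise CDAError("no numeric variables to analyze")
    labels, sizes = np.unique(y, return_counts=True)
    if len(labels) < 2:
        raise CDAError("need at least two groups")
    if sizes.min() < 2:
        small = labels[sizes < 2].tolist()
        raise CDAError(f"every group needs at least two rows; too small: {small}")
    notices: list[str] = []
    if n / p < min_ratio:
        msg = (
            f"observation-to-variable ratio {n / p:.2f} is below {min_ratio}:1; "
            "canonical estimates may be unstable"
        )
        warnings.warn(msg, stacklevel=2)
        notices.append(msg)

    # drop exactly dependent columns before inverting the within scatter
    labels_list, size_map, means, grand, W, B = _scatter_matrices(X, y)
    while len(variables) > 1 and np.linalg.matrix_rank(W, tol=1e-10 * max(np.trace(W), 1.0)) < len(variables):
        # pivoted QR on W identifies the most redundant column
        _, _, piv = sla.qr(W, pivoting=True)
        drop = variables[piv[-1]]
        notices.append(f"dropped exactly dependent column {drop!r}")
        warnings.warn(notices[-1], stacklevel=2)
        variables = [v for v in variables if v != drop]
        X = numeric[variables].to_numpy(dtype=float)
        labels_list, size_map, means, grand, W, B = _scatter_matrices(X, y)
    p = len(variables)
    g = len(labels_list)
    try:
        sla.cholesky(W)
    except sla.LinAlgError:
        eps = 1e-8 * np.trace(W) / p
        W = W + eps * np.eye(p)
        notices.append(f"within-group scatter singular; ridge {eps:.3e} added")
        warnings.warn(notices[-1], stacklevel=2)

    evals, evecs = sla.eigh(B, W)  # ascending, vectors with v' W v = 1
    q = min(p, g - 1)
    order = np.argsort(evals)[::-1][:q]
    lam = np.clip(evals[order], 0.0, None)
    V = evecs[:, order] * np.sqrt(n - g)  # unit pooled within-group score variance
    # deterministic sign: largest-|coefficient| entry positive
    for k in range(q):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]

    S_w = W / (n - g)
    func_names = [f"F{k + 1}" for k in range(q)]
    raw = pd.DataFrame(V, index=variables, columns=func_names)
    sd_within = np.sqrt(np.diag(S_w))
    standardized = raw.mul(sd_within, axis=0)
    loadings = pd.DataFrame(
        (S_w @ V) / sd_within[:, None], index=variables, columns=func_names
    )
    centroids = pd.DataFrame(
        [(means[lab] - grand) @ V for lab in labels_list],
        index=labels_list,
        columns=func_names,
    )
    total = lam.sum()
    percent = 100.0 * lam / total if total > 0 else np.zeros_like(lam)
    return CDAModel(
        variables=variables,
        groups=labels_list,
        group_sizes=pd.Series(size_map),
        eigenvalues=lam,
        percent_discrimination=percent,
        canonical_correlations=np.sqrt(lam / (1.0 + lam)),
        raw_coefficients=raw,
        standardized_coefficients=standardized,
        loadings=loadings,
        centroids=centroids,
        pooled_within_cov=pd.DataFrame(S_w, index=variables, columns=variables),
        grand_mean=pd.Series(grand, index=variables),
        n=n,
        notices=notices,
    )


# ---------------------------------------------------------------------------
# statistics on the eigen-solution
# ---------------------------------------------------------------------------


def wilks_lambda(eigenvalues) -> float:
    """``prod 1/(1 + lambda_i)`` over the canonical eigenvalues."""
    lam = np.asarray(eigenvalues, dtype=float)
    return float(np.prod(1.0 / (1.0 + lam)))


def pillai_trace(eigenvalues) -> float:
    """``sum lambda_i/(1 + lambda_i)`` over the canonical eigenvalues."""
    lam = np.asarray(eigenvalues, dtype=float)
    return float(np.sum(lam / (1.0 + lam)))


def canonical_correlations(eigenvalues) -> np.ndarray:
    lam = np.asarray(eigenvalues, dtype=float)
    return np.sqrt(lam / (1.0 + lam))


def eigenvalues_from_shares(first_eigenvalue: float, percents) -> np.ndarray:
    """Full eigenvalue set from the first eigenvalue and discrimination shares.

    Percent of discrimination is proportional to the eigenvalue, so
    ``lambda_i = lambda_1 * pct_i / pct_1``.
    """
    pct = np.asarray(percents, dtype=float)
    return first_eigenvalue * pct / pct[0]


def discriminant_significance_tests(
    eigenvalues, n: int, p: int, g: int
) -> dict:
    """Wilks (Rao's F), Bartlett residual chi-squares, and Pillai's trace.

    ``n`` observations, ``p`` variables, ``g`` groups.  Raises when the
    residual degrees of freedom are non-positive (``n <= g + p``).
    """
    if n <= g + p:
        raise CDAError(f"insufficient residual df: n={n} <= g+p={g + p}")
    lam = np.asarray(eigenvalues, dtype=float)
    q = g - 1
    L = wilks_lambda(lam)

    # Rao's F approximation for Wilks' Lambda
    pq = p * q
    denom = p * p + q * q - 5
    s = np.sqrt((p * p * q * q - 4.0) / denom) if denom > 0 else 1.0
    m_prime = n - 1 - (p + q + 1) / 2.0
    df1 = pq
    df2 = m_prime * s - pq / 2.0 + 1.0
    Ls = L ** (1.0 / s)
    F_wilks = ((1.0 - Ls) / Ls) * (df2 / df1) if L > 0 else np.inf
    p_wilks = float(stats.f.sf(F_wilks, df1, df2)) if np.isfinite(F_wilks) else 0.0

    # Bartlett's residual chi-square for functions k+1..q
    bartlett = []
    factor = n - 1 - (p + g) / 2.0
    nfunc = len(lam)
    for k in range(nfunc):
        L_resid = float(np.prod(1.0 / (1.0 + lam[k:])))
        chi2 = -factor * np.log(L_resid) if L_resid > 0 else np.inf
        df = (p - k) * (g - 1 - k)
        pval = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
        bartlett.append(
            {"function": k + 1, "chi2": float(chi2), "df": int(df), "p_value": pval}
        )

    # Pillai's trace with its F approximation
    Vp = pillai_trace(lam)
    s_p = min(p, q)
    m_p = (abs(p - q) - 1) / 2.0
    n_p = (n - g - p - 1) / 2.0
    df1_p = s_p * (2 * m_p + s_p + 1)
    df2_p = s_p * (2 * n_p + s_p + 1)
    F_pillai = ((2 * n_p + s_p + 1) / (2 * m_p + s_p + 1)) * (Vp / (s_p - Vp))
    p_pillai = float(stats.f.sf(F_pillai, df1_p, df2_p))

    return {
        "wilks": {
            "lambda": L,
            "F": float(F_wilks),
            "df1": float(df1),
            "df2": float(df2),
            "p_value": p_wilks,
        },
        "bartlett": bartlett,
        "pillai": {
            "V": Vp,
            "F": float(F_pillai),
            "df1": float(df1_p),
            "df2": float(df2_p),
            "p_value": p_pillai,
        },
    }


def univariate_equality_tests(
    features: pd.DataFrame, group: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Per-variable one-way Wilks' Lambda (SSW/SST) and F test of mean equality."""
    y = np.asarray(group)
    numeric = features.select_dtypes(include=[np.number])
    n = len(y)
    labels = pd.unique(y)
    g = len(labels)
    rows = []
    for col in numeric.columns:
        x = numeric[col].to_numpy(dtype=float)
        grand = x.mean()
        ssw = 0.0
        ssb = 0.0
        for lab in labels:
            xg = x[y == lab]
            ssw += float(np.sum((xg - xg.mean()) ** 2))
            ssb += len(xg) * (xg.mean() - grand) ** 2
        sst = ssw + ssb
        lam = ssw / sst if sst > 0 else 1.0
        F = (ssb / (g - 1)) / (ssw / (n - g)) if ssw > 0 else np.inf
        pval = float(stats.f.sf(F, g - 1, n - g)) if np.isfinite(F) else 0.0
        rows.append({"variable": col, "wilks_lambda": lam, "F": F, "p_value": pval})
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass
class ClassificationReport:
    """LOOCV confusion matrix and chance-corrected accuracy statistics."""

    confusion: pd.DataFrame  # prior group rows x posterior group columns
    per_group_hit: pd.Series
    overall_hit: float
    press_q: float
    press_q_critical: float
    proportional_chance: float
    max_chance: float
    beats_chance_125: bool
    notices: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.press_q > self.press_q_critical


def _classify(
    x: np.ndarray,
    means: dict,
    cov_inv: np.ndarray,
    priors: dict,
) -> object:
    best, best_score = None, np.inf
    for lab in sorted(means, key=str):
        dev = x - means[lab]
        score = float(dev @ cov_inv @ dev) - 2.0 * np.log(priors[lab])
        if score < best_score:
            best, best_score = lab, score
    return best


def loocv_classification(
    features: pd.DataFrame,
    group: pd.Series | np.ndarray,
    priors: str = "proportional",
    ridge: float = 0.0,
) -> ClassificationReport:
    """Leave-one-out classification by Mahalanobis distance to centroids.

    For every held-out row, group means and the pooled within-group
    covariance are refit on the remaining rows (true cross-validation) and
    the row is assigned to the group minimizing the squared Mahalanobis
    distance penalized by ``-2 ln(prior)``.  Priors are group-size
    proportional by default, or uniform.  Press's Q
    ``(N - n K)^2 / (N (K - 1))`` is compared with the 1%
    chi-square critical value 6.63, and the hit ratio with 1.25 times the
    proportional and maximum chance criteria.
    """
    if priors not in {"proportional", "uniform"}:
        raise CDAError(f"unknown priors {priors!r}")
    y = np.asarray(group)
    numeric = features.select_dtypes(include=[np.number])
    X = numeric.to_numpy(dtype=float)
    n, p = X.shape
    labels = sorted(pd.unique(y).tolist(), key=str)
    K = len(labels)
    notices: list[str] = []
    counts = pd.Series(y).value_counts()
    for lab in labels:
        if counts[lab] == 1:
            notices.append(
                f"group {lab!r} has a single row; it can never be correctly "
                "assigned under leave-one-out"
            )
            warnings.warn(notices[-1], stacklevel=2)
    predicted = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xt, yt = X[mask], y[mask]
        means = {}
        W = np.zeros((p, p))
        sizes = {}
        for lab in np.unique(yt):
            Xg = Xt[yt == lab]
            means[lab] = Xg.mean(axis=0)
            sizes[lab] = len(Xg)
            dev = Xg - means[lab]
            W += dev.T @ dev
        S = W / max(len(Xt) - len(means), 1)
        if ridge > 0.0 or np.linalg.matrix_rank(S) < p:
            S = S + max(ridge, 1e-8 * np.trace(S) / p) * np.eye(p)
        S_inv = np.linalg.inv(S)
        if priors == "proportional":
            pri = {lab: sizes[lab] / len(Xt) for lab in means}
        else:
            pri = {lab: 1.0 / len(means) for lab in means}
        predicted.append(_classify(X[i], means, S_inv, pri))
    predicted = np.asarray(predicted, dtype=object)
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for true, pred in zip(y, predicted):
        confusion.loc[true, pred] += 1
    correct = int(np.sum(predicted == y))
    overall = correct / n
    per_group = pd.Series(
        {lab: confusion.loc[lab, lab] / max(int(counts[lab]), 1) for lab in labels}
    )
    press_q = (n - correct * K) ** 2 / (n * (K - 1))
    shares = np.array([counts[lab] / n for lab in labels])
    prop_chance = float(np.sum(shares**2))
    max_chance = float(shares.max())
    return ClassificationReport(
        confusion=confusion,
        per_group_hit=per_group,
        overall_hit=overall,
        press_q=float(press_q),
        press_q_critical=6.63,
        proportional_chance=prop_chance,
        max_chance=max_chance,
        beats_chance_125=overall >= 1.25 * max(prop_chance, max_chance),
        notices=notices,
    )


def resubstitution_hit_ratio(
    features: pd.DataFrame, group: pd.Series | np.ndarray, priors: str = "proportional"
) -> float:
    """Hit ratio when classifying with the full-sample centroids (no holdout)."""
    y = np.asarray(group)
    numeric = features.select_dtypes(include=[np.number])
    X = numeric.to_numpy(dtype=float)
    n, p = X.shape
    means = {}
    sizes = {}
    W = np.zeros((p, p))
    for lab in np.unique(y):
        Xg = X[y == lab]
        means[lab] = Xg.mean(axis=0)
        sizes[lab] = len(Xg)
        dev = Xg - means[lab]
        W += dev.T @ dev
    S = W / max(n - len(means), 1)
    if np.linalg.matrix_rank(S) < p:
        S = S + 1e-8 * np.trace(S) / p * np.eye(p)
    S_inv = np.linalg.inv(S)
    if priors == "proportional":
        pri = {lab: sizes[lab] / n for lab in means}
    else:
        pri = {lab: 1.0 / len(means) for lab in means}
    correct = sum(_classify(x, means, S_inv, pri) == t for x, t in zip(X, y))
    return correct / n


# ---------------------------------------------------------------------------
# Mahalanobis distances and dendrogram
# ---------------------------------------------------------------------------


def mahalanobis_centroid_distances(
    features: pd.DataFrame, group: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Pairwise Mahalanobis distances between group centroids.

    Uses the pooled within-group covariance as metric; the diagonal is
    exactly zero and the matrix symmetric.
    """
    y = np.asarray(group)
    numeric = features.select_dtypes(include=[np.number])
    X = numeric.to_numpy(dtype=float)
    n, p = X.shape
    labels = sorted(pd.unique(y).tolist(), key=str)
    means = {}
    W = np.zeros((p, p))
    for lab in labels:
        Xg = X[y == lab]
        means[lab] = Xg.mean(axis=0)
        dev = Xg - means[lab]
        W += dev.T @ dev
    S = W / max(n - len(labels), 1)
    if np.linalg.matrix_rank(S) < p:
        S = S + 1e-8 * np.trace(S) / p * np.eye(p)
    S_inv = np.linalg.inv(S)
    D = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if j <= i:
                continue
            dev = means[a] - means[b]
            D[i, j] = D[j, i] = np.sqrt(max(float(dev @ S_inv @ dev), 0.0))
    return pd.DataFrame(D, index=labels, columns=labels)


_LINKAGE_METHODS = {"upgma": "average", "average": "average", "single": "single", "complete": "complete"}


def distance_dendrogram(
    distances: pd.DataFrame, linkage: str = "upgma"
) -> tuple[np.ndarray, str]:
    """Hierarchical agglomeration of a centroid distance matrix.

    Returns the scipy linkage matrix and a Newick string with branch
    lengths (ultrametric heights: each node sits at half its merge
    distance).  UPGMA (= average linkage) is the default.
    """
    if linkage not in _LINKAGE_METHODS:
        raise CDAError(f"unknown linkage {linkage!r}")
    labels = list(distances.index)
    if len(labels) < 2:
        raise CDAError("need at least two groups for a dendrogram")
    condensed = squareform(distances.to_numpy(dtype=float), checks=False)
    Z = _sch.linkage(condensed, method=_LINKAGE_METHODS[linkage])
    tree = _sch.to_tree(Z)

    def newick(node, parent_height: float) -> str:
        height = node.dist / 2.0
        branch = max(parent_height - height, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{branch:.6g}"
        left = newick(node.left, height)
        right = newick(node.right, height)
        return f"({left},{right}):{branch:.6g}"

    return Z, newick(tree, tree.dist / 2.0) + ";"
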