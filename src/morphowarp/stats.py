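"""Geometric-morphometric statistics.

Generalized Procrustes analysis (translation, unit-centroid-size scaling,
SVD rotation with reflections disallowed), shape PCA with broken-stick
retention, Goodall-style Procrustes ANOVA for measurement error, Procrustes
distance permutation tests, multivariate regression of shape on centroid
size (allometry), canonical variate analysis, and Wilks' lambda MANOVA.

Shapes live in the 3D similarity shape space of k landmarks, of dimension
3k - 7 (3 translations, 3 rotations and 1 scale removed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

from .errors import DegenerateConfigurationError, DimensionalityError

_RANK_TOL = 1e-9


# ---------------------------------------------------------------------- #
# Size and superimposition
# ---------------------------------------------------------------------- #

def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid (mm)."""
    config = np.asarray(config, dtype=np.float64).reshape(-1, 3)
    if len(config) < 2:
        raise ValueError("need at least 2 landmarks")
    c = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(c * c)))


def _optimal_rotation(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimizing ||X R - Y||_F."""
    U, _, Vt = np.linalg.svd(X.T @ Y)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


@dataclass
class GPAResult:
    """Aligned configurations (unit centroid size, centred, rotated to the
    consensus), the consensus shape, original centroid sizes, iterations."""

    aligned: np.ndarray  # (n, k, 3)
    consensus: np.ndarray  # (k, 3)
    centroid_sizes: np.ndarray  # (n,) mm
    n_iterations: int

    @property
    def flat(self) -> np.ndarray:
        """(n, 3k) vectorized aligned shapes."""
        n = len(self.aligned)
        return self.aligned.reshape(n, -1)


def gpa_align(configs: np.ndarray, tol: float = 1e-10, max_iter: int = 100) -> GPAResult:
    """Iterative generalized Procrustes analysis.

    Each configuration is centred, scaled to unit centroid size, and rotated
    (proper rotations only — faces have handedness) to the running consensus
    until the consensus stabilizes.
    """
    configs = np.asarray(configs, dtype=np.float64)
    if configs.ndim != 3 or configs.shape[2] != 3:
        raise ValueError("configs must be (n, k, 3)")
    n = len(configs)
    sizes = np.empty(n)
    X = configs.copy()
    for i in range(n):
        X[i] -= X[i].mean(axis=0)
        s = np.sqrt(np.sum(X[i] ** 2))
        if s < 1e-12:
            raise DegenerateConfigurationError(
                f"configuration {i} is degenerate (all landmarks coincident)"
            )
        sizes[i] = s
        X[i] /= s
    consensus = X[0].copy()
    it = 0
    if n > 1:
        for it in range(1, max_iter + 1):
            for i in range(n):
                X[i] = X[i] @ _optimal_rotation(X[i], consensus)
            new = X.mean(axis=0)
            new -= new.mean(axis=0)
            new /= np.sqrt(np.sum(new**2))
            if np.linalg.norm(new - consensus) < tol:
                consensus = new
                break
            consensus = new
        for i in range(n):  # final pass against the converged consensus
            X[i] = X[i] @ _optimal_rotation(X[i], consensus)
    return GPAResult(X, X.mean(axis=0), sizes, it)


def procrustes_distance(meanA: np.ndarray, meanB: np.ndarray) -> float:
    """Full Procrustes distance: align B to A over translation, scale and
    rotation, then take the root summed squared coordinate difference."""
    A = np.asarray(meanA, dtype=np.float64).reshape(-1, 3)
    B = np.asarray(meanB, dtype=np.float64).reshape(-1, 3)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    A = A / np.sqrt(np.sum(A**2))
    B = B / np.sqrt(np.sum(B**2))
    B = B @ _optimal_rotation(B, A)
    # optimal full-Procrustes scale of B onto A
    beta = np.sum(A * B)
    return float(np.sqrt(max(np.sum((A - beta * B) ** 2), 0.0)))


# ---------------------------------------------------------------------- #
# PCA and broken stick
# ---------------------------------------------------------------------- #

@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending, non-negative
    components: np.ndarray  # (p, 3k) loadings in shape space
    scores: np.ndarray  # (n, p)
    pct_variance: np.ndarray
    n_retained_broken_stick: int


def shape_pca(gpa: GPAResult) -> PCAResult:
    """Eigendecomposition of the sample covariance of the vectorized aligned
    shapes about the consensus (divisor n - 1)."""
    Y = gpa.flat - gpa.consensus.reshape(1, -1)
    n = len(Y)
    if n < 2:
        raise ValueError("need at least 2 specimens")
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    eig = s**2 / (n - 1)
    nonzero = eig > _RANK_TOL * max(eig[0], 1e-300) if eig.size else eig > 0
    eig = np.where(nonzero, eig, 0.0)
    total = eig.sum()
    pct = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    scores = U * s
    retained = broken_stick_retain(eig[eig > 0])
    return PCAResult(eig, Vt, scores, pct, retained)


def broken_stick_retain(eigenvalues: np.ndarray) -> int:
    """Broken-stick component retention.

    Over the p non-zero components the expected proportion for component i is
    b_i = (1/p) * sum_{j=i..p} 1/j; components are retained while their
    observed variance proportion strictly exceeds b_i, stopping at the first
    failure.
    """
    eig = np.asarray(eigenvalues, dtype=np.float64)
    eig = eig[eig > 0]
    p = len(eig)
    if p == 0:
        return 0
    prop = eig / eig.sum()
    inv = 1.0 / np.arange(1, p + 1)
    bstick = np.cumsum(inv[::-1])[::-1] / p
    retained = 0
    for i in range(p):
        if prop[i] > bstick[i]:
            retained += 1
        else:
            break
    return retained


def broken_stick_thresholds(p: int) -> np.ndarray:
    """The broken-stick expected proportions b_1..b_p."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


# ---------------------------------------------------------------------- #
# Procrustes ANOVA (Goodall-style, nested design)
# ---------------------------------------------------------------------- #

def procrustes_anova(
    gpa: GPAResult,
    population: Sequence,
    individual: Sequence,
    replicate: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Goodall-style Procrustes ANOVA for the nested design
    replicate < individual < population.

    Sums of squares are squared deviations of the aligned coordinates,
    summed across all 3k coordinates: population means about the grand mean,
    individual means about their population mean, and replicates about their
    individual mean.  Degrees of freedom multiply the design df at each
    stratum by the shape dimension 3k - 7; each stratum's F is tested against
    the next-lower stratum's mean square.  Returns an effects table with
    columns effect, pct_var, SS, MS, DF, F, P.
    """
    Y = gpa.flat
    n, p3k = Y.shape
    shape_dim = p3k - 7
    pop = np.asarray(population)
    ind = np.asarray(individual)
    if replicate is None:
        rep = np.zeros(n, dtype=int)
    else:
        rep = np.asarray(replicate)
    grand = Y.mean(axis=0)

    # per-observation stratum means
    ind_key = np.array([f"{p}\x00{i}" for p, i in zip(pop, ind)])
    pop_means = {g: Y[pop == g].mean(axis=0) for g in np.unique(pop)}
    ind_means = {g: Y[ind_key == g].mean(axis=0) for g in np.unique(ind_key)}
    pm = np.stack([pop_means[g] for g in pop])
    im = np.stack([ind_means[g] for g in ind_key])

    ss_pop = float(np.sum((pm - grand) ** 2))
    ss_ind = float(np.sum((im - pm) ** 2))
    ss_err = float(np.sum((Y - im) ** 2))
    ss_tot = float(np.sum((Y - grand) ** 2))

    n_pop = len(np.unique(pop))
    n_ind_total = len(np.unique(ind_key))
    df_pop = (n_pop - 1) * shape_dim
    df_ind = (n_ind_total - n_pop) * shape_dim
    df_err = (n - n_ind_total) * shape_dim

    has_error = df_err > 0
    if replicate is not None and not has_error:
        raise ValueError("error line requested but no replication in the design")

    rows = []

    def add_row(name, ss, df, ms_below, df_below):
        ms = ss / df if df > 0 else np.nan
        if ms_below is not None and ms_below > 0 and df > 0:
            F = ms / ms_below
            P = float(sps.f.sf(F, df, df_below))
        else:
            F, P = np.nan, np.nan
        rows.append(
            {
                "effect": name,
                "pct_var": 100.0 * ss / ss_tot if ss_tot > 0 else 0.0,
                "SS": ss,
                "MS": ms,
                "DF": df,
                "F": F,
                "P": P,
            }
        )
        return ms

    ms_err = ss_err / df_err if has_error else None
    ms_ind = ss_ind / df_ind if df_ind > 0 else None
    add_row("Population", ss_pop, df_pop, ms_ind, df_ind)
    add_row("Individuals", ss_ind, df_ind, ms_err, df_err if has_error else 0)
    if has_error:
        add_row("Error", ss_err, df_err, None, 0)
    rows.append(
        {
            "effect": "Total",
            "pct_var": 100.0 if ss_tot > 0 else 0.0,
            "SS": ss_tot,
            "MS": np.nan,
            "DF": df_pop + df_ind + (df_err if has_error else 0),
            "F": np.nan,
            "P": np.nan,
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# Permutation tests on Procrustes distances
# ---------------------------------------------------------------------- #

def permutation_test(
    gpa: GPAResult,
    groups: Sequence,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise Procrustes distances between group mean shapes with
    permutation p-values (random relabelling within each pair; add-one rule
    p = (1 + #{perm >= obs}) / (1 + n_perm))."""
    groups = np.asarray(groups)
    uniq = list(pd.unique(groups))
    if any((groups == g).sum() < 2 for g in uniq):
        raise ValueError("every group needs at least 2 members")
    rng = np.random.default_rng(seed)
    rows = []
    for a_i in range(len(uniq)):
        for b_i in range(a_i + 1, len(uniq)):
            ga, gb = uniq[a_i], uniq[b_i]
            A = gpa.aligned[groups == ga]
            Bb = gpa.aligned[groups == gb]
            obs = procrustes_distance(A.mean(axis=0), Bb.mean(axis=0))
            pool = np.concatenate([A, Bb])
            na = len(A)
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(len(pool))
                da = procrustes_distance(
                    pool[perm[:na]].mean(axis=0), pool[perm[na:]].mean(axis=0)
                )
                if da >= obs:
                    count += 1
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "distance": obs,
                    "p": (1 + count) / (1 + n_perm),
                    "n_perm": n_perm,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# Allometry
# ---------------------------------------------------------------------- #

@dataclass
class AllometryResult:
    pct_predicted: float
    p_value: float
    regression_scores: np.ndarray  # (n,)
    coefficients: np.ndarray  # (3k,) shape change per unit size


def allometric_regression(
    gpa: GPAResult,
    size: Optional[np.ndarray] = None,
    groups: Optional[Sequence] = None,
    n_perm: int = 10000,
    seed: int = 0,
    log_size: bool = False,
) -> AllometryResult:
    """Multivariate regression of shape coordinates on centroid size.

    ``groups`` switches to pooled-within regression (group means removed from
    both shape and size).  Size is not log-transformed by default.  The
    permutation p shuffles size against shape; the regression score projects
    each shape onto the normalized regression vector.
    """
    size = gpa.centroid_sizes if size is None else np.asarray(size, dtype=np.float64)
    if log_size:
        size = np.log(size)
    Y = gpa.flat - gpa.flat.mean(axis=0)
    x = size - size.mean()
    if groups is not None:
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            m = groups == g
            Y[m] -= Y[m].mean(axis=0)
            x[m] -= x[m].mean()
    sxx = float(x @ x)
    if sxx < 1e-24:
        raise ValueError("size has zero variance")
    ss_tot = float(np.sum(Y * Y))

    def pct_pred(xv):
        b = (xv @ Y) / (xv @ xv)
        return 100.0 * float((xv @ xv) * (b @ b)) / ss_tot, b

    obs, beta = pct_pred(x)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        stat, _ = pct_pred(rng.permutation(x))
        if stat >= obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    unit = beta / np.linalg.norm(beta) if np.linalg.norm(beta) > 0 else beta
    scores = Y @ unit
    return AllometryResult(obs, p, scores, beta)


# ---------------------------------------------------------------------- #
# CVA
# ---------------------------------------------------------------------- #

@dataclass
class CVAResult:
    eigenvalues: np.ndarray
    variates: np.ndarray  # (p_input, n_cv) canonical vectors in input space
    scores: np.ndarray  # (n, n_cv), pooled within-group variance 1
    mahalanobis: pd.DataFrame  # pairwise distances between group means


def cva(data: np.ndarray, groups: Sequence, n_components: Optional[int] = None) -> CVAResult:
    """Canonical variate analysis: eigenvectors of W^-1 B.

    ``data`` may be (n, p) scores or (n, k, 3) aligned shapes (flattened and
    reduced to a full-rank subspace of dimension <= n - g by PCA first).
    Canonical scores are scaled to unit pooled within-group variance.
    """
    X = np.asarray(data, dtype=np.float64)
    if X.ndim == 3:
        X = X.reshape(len(X), -1)
    groups = np.asarray(groups)
    uniq = list(pd.unique(groups))
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 groups")
    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    # reduce to a full-rank subspace
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > _RANK_TOL * s[0])) if s.size else 0
    rank = min(rank, n - g)
    if n_components is not None:
        rank = min(rank, n_components)
    if rank < 1:
        raise DimensionalityError(
            "no usable dimensions after projection; reduce the data (e.g. PCA "
            "scores) or add specimens"
        )
    basis = Vt[:rank]
    Z = Xc @ basis.T
    W = np.zeros((rank, rank))
    means = {}
    for gr in uniq:
        m = groups == gr
        mu = Z[m].mean(axis=0)
        means[gr] = mu
        D = Z[m] - mu
        W += D.T @ D
    W /= n - g
    Bmat = np.zeros((rank, rank))
    for gr in uniq:
        m = groups == gr
        d = (means[gr] - Z.mean(axis=0))[:, None]
        Bmat += (m.sum()) * (d @ d.T)
    Bmat /= g - 1
    try:
        evals, evecs = linalg.eigh(Bmat, W)
    except linalg.LinAlgError as exc:
        raise DimensionalityError(
            f"singular within-group covariance ({exc}); project to fewer "
            "dimensions first"
        ) from None
    order = np.argsort(evals)[::-1]
    n_cv = min(g - 1, rank)
    evals = np.clip(evals[order][:n_cv], 0.0, None)
    A = evecs[:, order][:, :n_cv]  # a^T W a = 1 -> unit pooled within variance
    scores = Z @ A
    variates = basis.T @ A
    # pairwise Mahalanobis distances between group means
    Winv = np.linalg.inv(W)
    rows = []
    for i in range(g):
        for j in range(i + 1, g):
            d = means[uniq[i]] - means[uniq[j]]
            rows.append(
                {
                    "group_a": uniq[i],
                    "group_b": uniq[j],
                    "mahalanobis": float(np.sqrt(d @ Winv @ d)),
                }
            )
    return CVAResult(evals, variates, scores, pd.DataFrame(rows))


# ---------------------------------------------------------------------- #
# Wilks' MANOVA
# ---------------------------------------------------------------------- #

def manova_wilks(
    responses: np.ndarray,
    group: Sequence,
    covariate: Optional[np.ndarray] = None,
    with_interaction: bool = True,
) -> pd.DataFrame:
    """Wilks' lambda MANOVA of multivariate responses on a group factor and
    an optional continuous covariate (with or without their interaction).

    Returns an effects table (effect, wilks_lambda, df1, df2, F, P) using
    Rao's F approximation.  Responses must span a subspace on which the
    residual covariance is invertible (reduce by PCA first if needed).
    """
    from statsmodels.multivariate.manova import MANOVA

    Y = np.asarray(responses, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, q = Y.shape
    data = pd.DataFrame(Y, columns=[f"y{i}" for i in range(q)])
    data["grp"] = np.asarray(group)
    terms = ["C(grp)"]
    if covariate is not None:
        data["cs"] = np.asarray(covariate, dtype=np.float64)
        terms.append("cs")
        if with_interaction:
            terms.append("C(grp):cs")
    label_map_uni = {
        "C(grp)": "Population",
        "cs": "CS",
        "C(grp):cs": "Population x CS",
    }
    if q == 1:
        # univariate: Wilks' lambda = SSE/(SSE + SSH); Rao's F reduces to the
        # classical partial F of the term
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        fit = smf.ols(f"y0 ~ {' + '.join(terms)}", data=data).fit()
        tbl = sm.stats.anova_lm(fit, typ=3)
        sse = float(tbl.loc["Residual", "sum_sq"])
        df_resid = float(tbl.loc["Residual", "df"])
        rows = []
        for term in terms:
            ssh = float(tbl.loc[term, "sum_sq"])
            df1 = float(tbl.loc[term, "df"])
            lam = sse / (sse + ssh)
            F = (1.0 - lam) / lam * df_resid / df1
            rows.append(
                {
                    "effect": label_map_uni[term],
                    "wilks_lambda": lam,
                    "df1": df1,
                    "df2": df_resid,
                    "F": F,
                    "P": float(sps.f.sf(F, df1, df_resid)),
                }
            )
        return pd.DataFrame(rows)
    lhs = " + ".join(data.columns[:q])
    formula = f"{lhs} ~ {' + '.join(terms)}"
    try:
        mv = MANOVA.from_formula(formula, data=data)
        res = mv.mv_test()
    except Exception as exc:
        raise DimensionalityError(
            f"MANOVA failed ({exc}); reduce responses to a full-rank subspace "
            "(e.g. PCA scores) first"
        ) from None
    label_map = {
        "C(grp)": "Population",
        "cs": "CS",
        "C(grp):cs": "Population x CS",
    }
    rows = []
    for term in terms:
        tbl = res[term]["stat"]
        w = tbl.loc["Wilks' lambda"]
        rows.append(
            {
                "effect": label_map[term],
                "wilks_lambda": float(w["Value"]),
                "df1": float(w["Num DF"]),
                "df2": float(w["Den DF"]),
                "F": float(w["F Value"]),
                "P": float(w["Pr > F"]),
            }
        )
    return pd.DataFrame(rows)
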