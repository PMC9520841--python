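"""Multivariate statistics on Procrustes tangent coordinates.

Implements the discrimination workflow for a two-species x two-sex landmark
dataset: Goodall-style Procrustes ANOVA (isotropic model, sequential sums
of squares), canonical variate analysis with Mahalanobis and shape-distance
permutation tests, two-group discriminant function analysis and
leave-one-out cross-validation, plus the bookkeeping that compares
classifier error with an observer's confusion table.

Tangent coordinate matrices are rank deficient (rank <= 2p - 4 for p 2-D
landmarks), so every covariance-based computation is preceded by projection
onto the principal subspace of the pooled within-group covariance,
retaining eigenvalues above 1e-9 of the largest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FactorialDesign",
    "CVAResult",
    "DFAResult",
    "RankError",
    "procrustes_anova",
    "cva",
    "permutation_test_group_distances",
    "dfa_two_group",
    "loo_cross_validate",
    "classification_improvement",
]

_EIG_REL_TOL = 1e-9


class RankError(ValueError):
    """Raised when a covariance matrix is singular after subspace reduction."""


@dataclass
class FactorialDesign:
    """2 x 2 specimen design: sex (F/M) crossed with species (canis/orientis)."""

    sex: np.ndarray
    species: np.ndarray

    def __post_init__(self) -> None:
        self.sex = np.asarray(self.sex, dtype=object)
        self.species = np.asarray(self.species, dtype=object)
        if len(self.sex) != len(self.species):
            raise ValueError("sex and species must have equal length")

    @classmethod
    def from_labels(cls, labels: pd.DataFrame) -> "FactorialDesign":
        return cls(sex=labels["sex"].to_numpy(), species=labels["species"].to_numpy())

    @property
    def n(self) -> int:
        return len(self.sex)

    def cells(self) -> np.ndarray:
        """Group label per specimen, 'species:sex'."""
        return np.array([f"{sp}:{sx}" for sp, sx in zip(self.species, self.sex)])


@dataclass
class CVAResult:
    axes: np.ndarray  # (2p, k) canonical vectors in tangent space
    eigenvalues: np.ndarray  # (k,)
    percent_variance: np.ndarray  # (k,) summing to 100
    scores: np.ndarray  # (n, k)
    group_names: list[str]
    group_means: np.ndarray  # (g, k) in canonical space
    mahalanobis: pd.DataFrame  # (g, g) distances between group means
    procrustes: pd.DataFrame  # (g, g) tangent-space distances between mean shapes
    p_mahalanobis: pd.DataFrame | None = None
    p_procrustes: pd.DataFrame | None = None
    n_permutations: int = 0
    seed: int | None = None


@dataclass
class DFAResult:
    axis: np.ndarray  # (2p,) discriminant direction in tangent space
    scores: np.ndarray  # (n,)
    cutoff: float
    group_names: list[str]
    resubstitution: pd.DataFrame
    loo: pd.DataFrame
    loo_misclassification: pd.Series  # per-group rate in [0, 1]
    mahalanobis_distance: float
    p_permutation: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    n_unclassifiable: int = 0


# ---------------------------------------------------------------------------
# Procrustes ANOVA


def _rss(Y: np.ndarray, X: np.ndarray) -> float:
    """Residual sum of squares of the least-squares fit Y ~ X, summed over columns."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return float(np.sum(resid**2))


def procrustes_anova(tangent: np.ndarray, design: FactorialDesign) -> pd.DataFrame:
    """Goodall-style Procrustes ANOVA for the sex x species factorial design.

    Sums of squares are sequential (order: sex, species, sex x species),
    computed coordinate-wise from nested least-squares fits and summed over
    all 2p tangent coordinates (isotropic model).  Degrees of freedom are
    the univariate effect df multiplied by the shape-space dimension
    2p - 4; the residual df is (n - cells) * (2p - 4).  Returns a table
    with columns effect, SS, MS, df, F, p.
    """
    Y = np.asarray(tangent, dtype=float)
    n, twop = Y.shape
    if design.n != n:
        raise ValueError("design length must match tangent rows")
    shape_dim = twop - 4
    cells = design.cells()
    cell_names, cell_idx = np.unique(cells, return_inverse=True)
    counts = np.bincount(cell_idx)
    if len(cell_names) != 4 or counts.min() < 1:
        raise ValueError("Procrustes ANOVA requires 4 non-empty sex x species cells")
    if n <= len(cell_names):
        raise ValueError("need more specimens than design cells")

    sex_d = (design.sex == np.unique(design.sex)[0]).astype(float)
    sp_d = (design.species == np.unique(design.species)[0]).astype(float)
    ones = np.ones(n)
    X0 = ones[:, None]
    X1 = np.column_stack([ones, sex_d])
    X2 = np.column_stack([ones, sex_d, sp_d])
    X3 = np.column_stack([ones, sex_d, sp_d, sex_d * sp_d])
    if np.linalg.matrix_rank(X3) < 4:
        raise ValueError("rank-deficient factorial design")

    rss = [_rss(Y, X) for X in (X0, X1, X2, X3)]
    ss = {
        "sex": rss[0] - rss[1],
        "species": rss[1] - rss[2],
        "sex:species": rss[2] - rss[3],
        "residual": rss[3],
    }
    df = {
        "sex": shape_dim,
        "species": shape_dim,
        "sex:species": shape_dim,
        "residual": (n - 4) * shape_dim,
    }
    ms = {k: ss[k] / df[k] for k in ss}
    rows = []
    for effect in ("sex", "species", "sex:species", "residual"):
        if effect == "residual":
            F = p = math.nan
        elif ms["residual"] == 0.0:
            F = p = math.nan  # zero residual variance: F undefined
        else:
            F = ms[effect] / ms["residual"]
            p = float(stats.f.sf(F, df[effect], df["residual"]))
        rows.append(
            {"effect": effect, "SS": ss[effect], "MS": ms[effect], "df": df[effect], "F": F, "p": p}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subspace reduction helpers


def _pooled_within_cov(X: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Pooled within-group covariance with divisor n - g."""
    names, idx = np.unique(groups, return_inverse=True)
    n, d = X.shape
    S = np.zeros((d, d))
    for g in range(len(names)):
        sub = X[idx == g]
        if len(sub) < 2:
            raise ValueError(f"group {names[g]!r} has fewer than 2 specimens")
        dev = sub - sub.mean(axis=0)
        S += dev.T @ dev
    return S / (n - len(names))


def _reduce_basis(S: np.ndarray) -> np.ndarray:
    """Eigenvectors of S with eigenvalue > max eigenvalue * 1e-9, as columns."""
    evals, evecs = np.linalg.eigh(S)
    if evals[-1] <= 0:
        raise RankError("zero within-group variance")
    keep = evals > evals[-1] * _EIG_REL_TOL
    return evecs[:, keep]


# ---------------------------------------------------------------------------
# CVA


def cva(
    tangent: np.ndarray,
    groups: np.ndarray,
    *,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> CVAResult:
    """Canonical variate analysis with permutation tests on group distances.

    Data are pre-projected onto the principal subspace of the pooled
    within-group covariance; the canonical axes solve the between/within
    generalized eigenproblem there (axes scaled so within-group variance
    along each axis is 1).  Mahalanobis distances between group means use
    the pooled within-group covariance (divisor n - g).  With ``n_perm``
    > 0, pairwise permutation p-values are attached for both Mahalanobis
    and mean-shape (Procrustes tangent) distances.
    """
    X = np.asarray(tangent, dtype=float)
    groups = np.asarray(groups)
    names, idx = np.unique(groups, return_inverse=True)
    g = len(names)
    if g < 2:
        raise ValueError("CVA needs at least 2 groups")
    counts = np.bincount(idx)
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 specimens")

    W = _pooled_within_cov(X, groups)
    V = _reduce_basis(W)
    Y = X @ V
    Wr = V.T @ W @ V
    grand = Y.mean(axis=0)
    means = np.stack([Y[idx == k].mean(axis=0) for k in range(g)])
    dev = means - grand
    B = (dev.T * counts) @ dev / (g - 1)

    evals, evecs = _sym_geig(B, Wr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = min(g - 1, Y.shape[1])
    evals = np.clip(evals[:k], 0.0, None)
    A = evecs[:, :k]  # a' Wr a = 1 scaling from the generalized eigensolver
    percent = 100.0 * evals / evals.sum() if evals.sum() > 0 else np.zeros(k)

    scores = (Y - grand) @ A
    gmeans_canon = (means - grand) @ A

    maha = np.zeros((g, g))
    proc = np.zeros((g, g))
    Wr_inv = np.linalg.inv(Wr)
    for a in range(g):
        for b in range(a + 1, g):
            d = means[a] - means[b]
            maha[a, b] = maha[b, a] = float(np.sqrt(d @ Wr_inv @ d))
            proc[a, b] = proc[b, a] = float(np.linalg.norm(d))
    gl = list(names)
    result = CVAResult(
        axes=V @ A,
        eigenvalues=evals,
        percent_variance=percent,
        scores=scores,
        group_names=gl,
        group_means=gmeans_canon,
        mahalanobis=pd.DataFrame(maha, index=gl, columns=gl),
        procrustes=pd.DataFrame(proc, index=gl, columns=gl),
        n_permutations=n_perm,
        seed=seed,
    )
    if n_perm > 0:
        result.p_mahalanobis = permutation_test_group_distances(
            X, groups, statistic="mahalanobis", n_perm=n_perm, seed=seed
        )
        result.p_procrustes = permutation_test_group_distances(
            X, groups, statistic="procrustes", n_perm=n_perm, seed=seed
        )
    return result


def _sym_geig(B: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Generalized symmetric eigenproblem B a = lambda W a with a' W a = 1."""
    from scipy.linalg import eigh

    evals, evecs = eigh(B, W)
    return evals, evecs


def _maha_stat(sub: np.ndarray, mask: np.ndarray) -> float:
    """Mahalanobis distance between the two groups marked by ``mask``.

    The pooled within-group covariance (divisor n - 2) is re-estimated and
    re-reduced to its principal subspace for the given labelling, so the
    statistic is well defined for every permutation of small subsets.
    """
    m1 = sub[mask].mean(axis=0)
    m2 = sub[~mask].mean(axis=0)
    dev1 = sub[mask] - m1
    dev2 = sub[~mask] - m2
    W = (dev1.T @ dev1 + dev2.T @ dev2) / (len(sub) - 2)
    V = _reduce_basis(W)
    d = (m1 - m2) @ V
    Wr = V.T @ W @ V
    return float(np.sqrt(max(0.0, d @ np.linalg.solve(Wr, d))))


def _meandiff_stat(sub: np.ndarray, mask: np.ndarray) -> float:
    """Euclidean distance between group mean tangent vectors (mean-shape distance)."""
    return float(np.linalg.norm(sub[mask].mean(axis=0) - sub[~mask].mean(axis=0)))


def permutation_test_group_distances(
    tangent: np.ndarray,
    groups: np.ndarray,
    *,
    statistic: str = "mahalanobis",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise permutation p-values for between-group distances.

    For every group pair the specimens of the two groups are pooled and
    their labels randomly reassigned ``n_perm`` times; the p-value is
    ``(count of permuted distance >= observed + 1) / (n_perm + 1)``, so
    ties count as extreme and the minimum attainable p is 1/(n_perm + 1).
    Deterministic given ``seed``.
    """
    if statistic not in ("mahalanobis", "procrustes"):
        raise ValueError(f"unknown statistic {statistic!r}")
    X = np.asarray(tangent, dtype=float)
    groups = np.asarray(groups)
    names, idx = np.unique(groups, return_inverse=True)
    g = len(names)
    rng = np.random.default_rng(seed)
    stat_fn = _maha_stat if statistic == "mahalanobis" else _meandiff_stat
    P = np.full((g, g), np.nan)
    np.fill_diagonal(P, 1.0)
    for a in range(g):
        for b in range(a + 1, g):
            pair_rows = (idx == a) | (idx == b)
            sub = X[pair_rows]
            mask = idx[pair_rows] == a
            n1 = int(mask.sum())
            observed = stat_fn(sub, mask)
            count = 0
            perm_mask = np.zeros(len(sub), dtype=bool)
            for _ in range(n_perm):
                sel = rng.permutation(len(sub))[:n1]
                perm_mask[:] = False
                perm_mask[sel] = True
                if stat_fn(sub, perm_mask) >= observed:
                    count += 1
            P[a, b] = P[b, a] = (count + 1) / (n_perm + 1)
    return pd.DataFrame(P, index=list(names), columns=list(names))


# ---------------------------------------------------------------------------
# DFA and leave-one-out


def _fit_discriminant(
    X: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, float, float, float]:
    """Fit the two-group discriminant W^-1 (mu1 - mu2) on rows of X.

    Returns (axis in input space, cutoff, sign of group-1 side, Mahalanobis
    distance between the means).  ``mask`` marks group-1 rows.
    """
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise RankError("both groups need >= 2 specimens to fit a discriminant")
    g1, g2 = X[mask], X[~mask]
    labels = np.where(mask, "a", "b")
    W = _pooled_within_cov(X, labels)
    V = _reduce_basis(W)
    Y1, Y2 = g1 @ V, g2 @ V
    m1, m2 = Y1.mean(axis=0), Y2.mean(axis=0)
    Wr = V.T @ W @ V
    a_red = np.linalg.solve(Wr, m1 - m2)
    axis = V @ a_red
    s1 = float(m1 @ a_red)
    s2 = float(m2 @ a_red)
    cutoff = 0.5 * (s1 + s2)
    sign = 1.0 if s1 >= cutoff else -1.0
    maha = float(np.sqrt(max(0.0, (m1 - m2) @ a_red)))
    return axis, cutoff, sign, maha


def dfa_two_group(
    tangent: np.ndarray,
    labels: np.ndarray,
    *,
    n_perm: int = 10_000,
    seed: int | None = None,
    run_loo: bool = True,
) -> DFAResult:
    """Two-group discriminant function analysis on tangent coordinates.

    The discriminant axis is the pooled within-covariance inverse applied
    to the mean difference, computed in the reduced subspace; specimens are
    classified by their score against the midpoint of the two group mean
    scores.  The permutation p-value tests the Mahalanobis distance between
    group means; leave-one-out cross-validation refits the whole pipeline
    per held-out specimen.
    """
    X = np.asarray(tangent, dtype=float)
    labels = np.asarray(labels)
    names = list(pd.unique(labels))
    if len(names) != 2:
        raise ValueError(f"DFA needs exactly 2 groups, got {names}")
    mask = labels == names[0]
    axis, cutoff, sign, maha = _fit_discriminant(X, mask)
    scores = X @ axis
    assigned = np.where(sign * (scores - cutoff) >= 0, names[0], names[1])
    resub = pd.crosstab(
        pd.Series(labels, name="true"), pd.Series(assigned, name="assigned")
    ).reindex(index=names, columns=names, fill_value=0)

    p_val = None
    if n_perm > 0:
        pmat = permutation_test_group_distances(
            X, labels, statistic="mahalanobis", n_perm=n_perm, seed=seed
        )
        p_val = float(pmat.loc[names[0], names[1]])

    if run_loo:
        loo, rates, n_bad = loo_cross_validate(X, labels)
    else:
        loo = resub * 0
        rates = pd.Series(np.nan, index=names)
        n_bad = 0
    return DFAResult(
        axis=axis,
        scores=scores,
        cutoff=cutoff,
        group_names=names,
        resubstitution=resub,
        loo=loo,
        loo_misclassification=rates,
        mahalanobis_distance=maha,
        p_permutation=p_val,
        n_permutations=n_perm,
        seed=seed,
        n_unclassifiable=n_bad,
    )


def loo_cross_validate(
    tangent: np.ndarray, labels: np.ndarray, seed: int | None = None
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Leave-one-out cross-validation of the two-group discriminant pipeline.

    For each specimen the subspace reduction, discriminant axis and cutoff
    are refit on the remaining n - 1 specimens and the held-out specimen is
    classified.  Returns (contingency table rows=true/cols=assigned,
    per-group misclassification rates, number of unclassifiable specimens
    from rank failures).
    """
    X = np.asarray(tangent, dtype=float)
    labels = np.asarray(labels)
    names = list(pd.unique(labels))
    if len(names) != 2:
        raise ValueError("leave-one-out needs exactly 2 groups")
    counts = pd.Series(labels).value_counts()
    if counts.min() < 3:
        raise ValueError("both groups need >= 3 specimens for leave-one-out")
    n = len(X)
    table = pd.DataFrame(0, index=names, columns=names)
    n_bad = 0
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        try:
            axis, cutoff, sign, _ = _fit_discriminant(X[keep], labels[keep] == names[0])
            score = float(X[i] @ axis)
            pred = names[0] if sign * (score - cutoff) >= 0 else names[1]
            table.loc[labels[i], pred] += 1
        except RankError:
            n_bad += 1
        finally:
            keep[i] = True
    totals = table.sum(axis=1)
    wrong = totals - pd.Series(np.diag(table.values), index=names)
    rates = (wrong / totals.replace(0, np.nan)).fillna(0.0)
    return table, rates, n_bad


# ---------------------------------------------------------------------------
# observer comparison


def _per_class_misclassification(table: pd.DataFrame, exclude: str = "indeterminate") -> pd.Series:
    """Percent misclassified per true class, whole-percent rounding.

    Columns named ``exclude`` (specimens the assigner declined to call) are
    left out of the denominator.
    """
    cols = [c for c in table.columns if c != exclude]
    out = {}
    for cls in table.index:
        if cls == exclude:
            continue
        row = table.loc[cls, cols]
        total = int(row.sum())
        right = int(table.loc[cls, cls]) if cls in cols else 0
        if total == 0:
            out[cls] = math.nan
        else:
            out[cls] = _round_half_away(100.0 * (total - right) / total)
    return pd.Series(out)


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def classification_improvement(
    observer_table: pd.DataFrame, loo_table: pd.DataFrame
) -> pd.DataFrame:
    """Compare per-class misclassification before (observer) and after (LOO).

    Rates are whole percentages; the fold improvement is the ratio of the
    rounded rates, reported to one decimal.  A zero post-rate is flagged
    infinite.
    """
    before = _per_class_misclassification(observer_table)
    after = _per_class_misclassification(loo_table)
    classes = [c for c in before.index if c in after.index]
    rows = []
    for cls in classes:
        b, a = before[cls], after[cls]
        if a == 0:
            fold, inf_flag = math.inf, True
        else:
            fold, inf_flag = round(b / a, 1), False
        rows.append(
            {
                "class": cls,
                "misclassification_before_pct": b,
                "misclassification_after_pct": a,
                "fold_improvement": fold,
                "infinite": inf_flag,
            }
        )
    return pd.DataFrame(rows).set_index("class")
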