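"""Island-biogeography models: log-linear regressions, Mantel tests,
principal coordinates analysis and observed-variable path analysis.

Strategy indices and diversity are regressed on log10 island area (or
isolation) with the conventional significance bands — solid P < 0.05,
marginal 0.05 <= P < 0.10. Community-environment association uses the
Mantel permutation test between distance matrices. The mediation model
(area -> soil properties -> strategy index, plus a direct path) is a
recursive system of per-equation OLS fits on z-standardized observed
variables; with no latent variables this gives the same standardized
path estimates as a structural equation model.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from skbio import DistanceMatrix
from sklearn.base import BaseEstimator

__all__ = [
    "LogLinearRegression",
    "fit_loglinear",
    "MantelResult",
    "mantel",
    "PCoA",
    "pcoa",
    "PathAnalysis",
    "fit_path_model",
    "parse_path_spec",
]


def significance_class(p: float) -> str:
    """Band a p-value: significant (<0.05), marginal (<0.10), ns."""
    if p < 0.05:
        return "significant"
    if p < 0.10:
        return "marginal"
    return "ns"


class LogLinearRegression(BaseEstimator):
    """OLS of y on log10(x), with the significance-band convention.

    Parameters
    ----------
    log_x : bool, default True
        Regress on log10(x) (x must then be strictly positive); set
        False for a plain linear fit.

    Attributes (after fit)
    ----------------------
    slope_, intercept_, r_squared_, p_value_ : float
        p is the two-sided t-test on the slope (exact t distribution).
    significance_ : str
        "significant" (p < 0.05), "marginal" (0.05 <= p < 0.10) or "ns".
    stderr_ : float
        Standard error of the slope.
    n_ : int
    """

    def __init__(self, log_x: bool = True):
        self.log_x = log_x

    def _transform_x(self, x):
        x = np.asarray(x, dtype=float)
        if self.log_x:
            if (x <= 0).any():
                raise ValueError("x must be strictly positive for a log fit")
            return np.log10(x)
        return x

    def fit(self, X, y):
        x = self._transform_x(np.asarray(X, dtype=float).reshape(-1))
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("x and y lengths differ")
        if len(x) < 3:
            raise ValueError("need n >= 3 points")
        if np.ptp(x) == 0:
            raise ValueError("zero variance in x")
        if np.ptp(y) == 0:
            # scipy returns nan correlation here; a flat response is a
            # well-defined degenerate fit
            self.slope_, self.intercept_ = 0.0, float(y[0])
            self.r_squared_, self.p_value_, self.stderr_ = 0.0, 1.0, 0.0
        else:
            res = stats.linregress(x, y)
            self.slope_ = float(res.slope)
            self.intercept_ = float(res.intercept)
            self.r_squared_ = float(res.rvalue**2)
            self.p_value_ = float(res.pvalue)
            self.stderr_ = float(res.stderr)
        self.n_ = len(x)
        self.significance_ = significance_class(self.p_value_)
        return self

    def predict(self, X):
        return self.intercept_ + self.slope_ * self._transform_x(np.asarray(X, dtype=float).reshape(-1))

    def slope_confint(self, level: float = 0.95) -> tuple[float, float]:
        """Exact-t confidence interval for the slope."""
        half = stats.t.ppf(0.5 + level / 2, self.n_ - 2) * self.stderr_
        return self.slope_ - half, self.slope_ + half


def fit_loglinear(x, y, log_x: bool = True) -> LogLinearRegression:
    """Fit y ~ log10(x) (species/strategy-area form); returns the fitted model."""
    return LogLinearRegression(log_x=log_x).fit(x, y)


@dataclass
class MantelResult:
    """Mantel correlation with its permutation p-value."""

    r: float
    p: float
    n_permutations: int
    seed: int
    method: str
    n: int


def _as_dm(d) -> DistanceMatrix:
    if isinstance(d, DistanceMatrix):
        return d
    return DistanceMatrix(np.asarray(d, dtype=float))


def mantel(
    d1,
    d2,
    n_permutations: int = 999,
    seed: int = 0,
    method: str = "pearson",
) -> MantelResult:
    """Two-sided Mantel permutation test between two distance matrices.

    The statistic is the correlation of the vectorized upper triangles;
    the null distribution jointly permutes the rows and columns of d2.
    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_permutations), the
    inclusive estimator. The seed is mandatory for reproducibility.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method: {method!r}")
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    d1, d2 = _as_dm(d1), _as_dm(d2)
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices have different sample labels")
    d2 = d2.filter(d1.ids)  # align order
    n = d1.shape[0]
    m1, m2 = d1.data.copy(), d2.data.copy()
    if method == "spearman":
        # ranks of the off-diagonal values, embedded back symmetrically so
        # permutation and rank transforms commute
        iu = np.triu_indices(n, k=1)
        for m in (m1, m2):
            ranks = stats.rankdata(m[iu])
            full = np.zeros_like(m)
            full[iu] = ranks
            m[:] = full + full.T
    iu = np.triu_indices(n, k=1)
    v1 = m1[iu]
    if np.ptp(v1) == 0 or np.ptp(m2[iu]) == 0:
        raise ValueError("zero variance in distances; Mantel r undefined")
    v1c = v1 - v1.mean()
    v1n = np.sqrt((v1c**2).sum())

    def _corr(mat):
        v = mat[iu]
        vc = v - v.mean()
        return float((v1c @ vc) / (v1n * np.sqrt((vc**2).sum())))

    r_obs = _corr(m2)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if abs(_corr(m2[np.ix_(perm, perm)])) >= abs(r_obs):
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return MantelResult(r_obs, p, n_permutations, seed, method, n)


class PCoA(BaseEstimator):
    """Principal coordinates analysis (classical metric MDS).

    Gower double-centers -d^2/2, eigendecomposes, and scales each axis
    by the square root of its (positive) eigenvalue. Negative eigenvalues
    from non-Euclidean dissimilarities are reported, not corrected;
    proportion explained is taken over the positive eigenvalues only.

    Attributes
    ----------
    coordinates_ : pd.DataFrame
        Samples x axes (PC1, PC2, ...), one axis per positive eigenvalue.
    eigenvalues_ : np.ndarray
        All eigenvalues, sorted descending (negatives included).
    proportion_explained_ : np.ndarray
        Per positive axis, eigenvalue / sum of positive eigenvalues.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, D, y=None):
        dm = _as_dm(D)
        if dm.shape[0] < 3:
            raise ValueError("need at least 3 samples")
        d2 = dm.data.astype(float) ** 2
        n = d2.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ d2 @ J
        eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        tol = max(abs(eigvals[0]), 1.0) * 1e-12
        positive = eigvals > tol
        coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
        k = coords.shape[1]
        if self.n_components is not None:
            k = min(k, self.n_components)
            coords = coords[:, :k]
        self.eigenvalues_ = eigvals
        self.proportion_explained_ = eigvals[positive] / eigvals[positive].sum()
        self.coordinates_ = pd.DataFrame(
            coords, index=list(dm.ids), columns=[f"PC{i + 1}" for i in range(k)]
        )
        return self

    def fit_transform(self, D, y=None) -> pd.DataFrame:
        return self.fit(D).coordinates_


def pcoa(D, n_components: int | None = None) -> PCoA:
    """Fit a :class:`PCoA` on a distance matrix and return the fitted object."""
    return PCoA(n_components=n_components).fit(D)


def parse_path_spec(spec: str) -> list[tuple[str, str]]:
    """Parse "a -> b -> c; a -> c" arrow chains into a directed edge list."""
    edges = []
    for chain in spec.replace("\n", ";").split(";"):
        names = [part.strip() for part in chain.split("->")]
        names = [n for n in names if n]
        for parent, child in zip(names, names[1:]):
            if (parent, child) not in edges:
                edges.append((parent, child))
    if not edges:
        raise ValueError(f"no edges in path spec: {spec!r}")
    return edges


class PathAnalysis(BaseEstimator):
    """Recursive path analysis over observed variables.

    Every endogenous variable is regressed (OLS) on its parents after
    z-standardization, giving standardized path coefficients with
    per-edge p-values and an R^2 per endogenous variable. The indirect
    effect along a directed path is the product of its edge
    coefficients; the total effect of one variable on another is the
    direct edge (0 when absent) plus the sum over all indirect paths.

    Parameters
    ----------
    edges : list of (parent, child) or an arrow-spec string
        e.g. ``"area -> TP -> cwm; area -> cwm"``.
    """

    _COND_LIMIT = 1e8

    def __init__(self, edges):
        self.edges = edges

    def fit(self, data: pd.DataFrame, y=None):
        edges = parse_path_spec(self.edges) if isinstance(self.edges, str) else list(self.edges)
        dag = nx.DiGraph(edges)
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("path specification contains a cycle")
        variables = list(dag.nodes)
        missing = [v for v in variables if v not in data.columns]
        if missing:
            raise ValueError(f"variables absent from data: {missing}")
        frame = data[variables].dropna()
        max_parents = max(dag.in_degree(v) for v in variables)
        if len(frame) < max_parents + 2:
            raise ValueError(
                f"need complete-case n >= {max_parents + 2}, got {len(frame)}"
            )
        z = (frame - frame.mean()) / frame.std(ddof=1)
        coefs: dict[tuple[str, str], float] = {}
        pvals: dict[tuple[str, str], float] = {}
        r2: dict[str, float] = {}
        for child in nx.topological_sort(dag):
            parents = sorted(dag.predecessors(child))
            if not parents:
                continue
            X = z[parents].to_numpy()
            if len(parents) > 1 and np.linalg.cond(X) > self._COND_LIMIT:
                raise ValueError(f"collinear parents for {child!r}: {parents}")
            model = sm.OLS(z[child].to_numpy(), sm.add_constant(X)).fit()
            for j, parent in enumerate(parents):
                coefs[(parent, child)] = float(model.params[j + 1])
                pvals[(parent, child)] = float(model.pvalues[j + 1])
            r2[child] = float(model.rsquared)
        self.dag_ = dag
        self.coefficients_ = coefs
        self.p_values_ = pvals
        self.r_squared_ = r2
        self.n_ = len(frame)
        return self

    def effects(self, source: str, target: str) -> dict:
        """Direct, per-path indirect and total standardized effects."""
        direct = self.coefficients_.get((source, target), 0.0)
        indirect = {}
        for path in nx.all_simple_paths(self.dag_, source, target):
            if len(path) > 2:
                effect = 1.0
                for edge in zip(path, path[1:]):
                    effect *= self.coefficients_[edge]
                indirect[tuple(path)] = effect
        return {
            "direct": direct,
            "indirect": indirect,
            "total": direct + sum(indirect.values()),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parent": a,
                "child": b,
                "coefficient": c,
                "p_value": self.p_values_[(a, b)],
                "significance": significance_class(self.p_values_[(a, b)]),
            }
            for (a, b), c in self.coefficients_.items()
        ]
        return pd.DataFrame(rows)


def fit_path_model(data: pd.DataFrame, spec) -> PathAnalysis:
    """Fit :class:`PathAnalysis` with ``spec`` edges on a per-island table."""
    return PathAnalysis(spec).fit(data)
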