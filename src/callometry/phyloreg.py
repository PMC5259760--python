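"""Comparative regression: OLS, phylogenetic GLS, AICc, bisector lines.

Species are not independent samples: trait residuals covary with shared
ancestry.  GLS handles this by giving the residuals a covariance matrix
derived from the phylogeny.  Five correlation structures are supported:

* NP        — identity (no phylogenetic signal);
* BM        — Brownian motion: cov(i, j) = shared root-to-MRCA path length;
* BM+lambda — Pagel's lambda: BM off-diagonals multiplied by lambda in
              [0, 1]; lambda = 1 recovers BM, lambda = 0 recovers NP;
* BM+rho    — Grafen's rho: node heights h raised to (h/H)^rho x H before
              computing shared paths, bending covariance accumulation;
* OU        — Ornstein-Uhlenbeck: corr(i, j) = exp(-alpha d_ij) with d the
              patristic distance, modelling pull toward an optimum.

Structure parameters are estimated by maximising the (RE)ML likelihood;
candidate structures are ranked by small-sample-corrected AIC.  Because
both body length and call frequency are measured with error, the summary
line is the bisector of the Y-on-X and X-on-Y regressions, whose slope is

    b3 = (b1 b2 - 1 + sqrt((1 + b1^2)(1 + b2^2))) / (b1 + b2),

equivalently the tangent of the mean of the two lines' arctangents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from callometry.errors import (
    DegenerateInputError,
    InsufficientDataError,
    NumericalError,
    ParameterError,
    TreeError,
)

__all__ = [
    "Phylogeny",
    "TraitTable",
    "CorrelationModel",
    "RegressionFit",
    "BisectorLine",
    "ModelComparison",
    "normalize_name",
    "phylo_covariance",
    "gls_fit",
    "ols_fit",
    "aicc",
    "fit_candidates",
    "select_model",
    "bisector",
    "ancova_slopes",
    "shapiro_wilk",
]

ModelKind = Literal["NP", "BM", "BM_lambda", "BM_rho", "OU"]
CANDIDATE_KINDS: tuple[ModelKind, ...] = (
    "NP", "BM", "BM_lambda", "BM_rho", "OU",
)


def normalize_name(name: str) -> str:
    """Case-fold and use underscores so tree tips match table rows."""
    return name.strip().casefold().replace(" ", "_")


@dataclass
class Phylogeny:
    """Rooted tree held as tip names plus precomputed path matrices.

    ``mrca_depth[i, j]`` is the root-to-MRCA path length for tips i and j
    (the BM covariance); its diagonal holds root-to-tip depths.
    ``node_depth_pairs`` retains, for every tip pair, the tree topology
    needed for the Grafen height transform.
    """

    tip_names: list[str]
    mrca_depth: np.ndarray          # n x n shared path lengths
    tip_depths: np.ndarray          # root-to-tip path lengths

    @property
    def n(self) -> int:
        return len(self.tip_names)

    @property
    def height(self) -> float:
        return float(self.tip_depths.max())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        h = self.height
        return bool(np.all(np.abs(self.tip_depths - h) <= rtol * max(h, 1e-300)))

    @classmethod
    def from_dendropy(cls, tree) -> "Phylogeny":
        """Build path matrices from a dendropy Tree (one post-order pass)."""
        tips: list = []
        for leaf in tree.leaf_node_iter():
            tips.append(leaf)
        names = [normalize_name(leaf.taxon.label) for leaf in tips]
        if len(set(names)) != len(names):
            raise TreeError("duplicate tip names after normalization")
        index = {id(leaf): i for i, leaf in enumerate(tips)}
        n = len(tips)
        depth: dict[int, float] = {}
        for node in tree.preorder_node_iter():
            el = node.edge.length
            if el is None:
                el = 0.0
            if el < 0:
                raise TreeError(f"negative branch length {el}")
            parent = node.parent_node
            depth[id(node)] = (depth[id(parent)] if parent else 0.0) + el
        mrca = np.zeros((n, n))
        below: dict[int, list[int]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                below[id(node)] = [index[id(node)]]
                continue
            children = [below.pop(id(c)) for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            mrca[i, j] = mrca[j, i] = d
            merged = [i for ch in children for i in ch]
            below[id(node)] = merged
        tip_depths = np.array([depth[id(leaf)] for leaf in tips])
        np.fill_diagonal(mrca, tip_depths)
        return cls(names, mrca, tip_depths)

    @classmethod
    def from_newick(cls, source: str, from_path: bool = False) -> "Phylogeny":
        import dendropy

        try:
            if from_path:
                tree = dendropy.Tree.get(path=source, schema="newick")
            else:
                tree = dendropy.Tree.get(data=source, schema="newick")
        except OSError:
            raise
        except Exception as exc:  # parser errors vary by dendropy version
            raise TreeError(f"could not parse newick tree: {exc}") from exc
        return cls.from_dendropy(tree)

    def subset(self, names: Sequence[str]) -> "Phylogeny":
        """Restrict to (and order by) the given normalized tip names."""
        wanted = [normalize_name(s) for s in names]
        missing = [s for s in wanted if s not in self.tip_names]
        if missing:
            raise TreeError(f"species missing from tree: {missing}")
        idx = [self.tip_names.index(s) for s in wanted]
        return Phylogeny(
            [self.tip_names[i] for i in idx],
            self.mrca_depth[np.ix_(idx, idx)],
            self.tip_depths[idx],
        )


@dataclass
class TraitTable:
    """Aligned per-species trait vectors on log10 scales."""

    species: list[str]
    x: np.ndarray  # log10 body length (mm)
    y: np.ndarray  # log10 frequency mean (Hz)
    group: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.species) == len(self.x) == len(self.y)):
            raise DegenerateInputError("trait table columns must align")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise DegenerateInputError("trait table contains missing values")

    @property
    def n(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class CorrelationModel:
    """A residual correlation structure and its parameter, if any."""

    kind: ModelKind
    theta: Optional[float] = None
    estimated: bool = False

    @property
    def n_theta(self) -> int:
        return 1 if self.kind in ("BM_lambda", "BM_rho", "OU") else 0

    def label(self) -> str:
        names = {"NP": "NP", "BM": "BM", "BM_lambda": "BM+lambda",
                 "BM_rho": "BM+rho", "OU": "OU"}
        base = names[self.kind]
        if self.theta is not None and self.n_theta:
            return f"{base}({self.theta:.3g})"
        return base


@dataclass
class RegressionFit:
    """A fitted line with its uncertainty, likelihood, and provenance."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    t: float
    df: int
    p: float
    loglik: float
    k: int
    model: CorrelationModel
    direction: Literal["y_on_x", "x_on_y_expressed"] = "y_on_x"
    r2: Optional[float] = None
    centroid: tuple[float, float] = (math.nan, math.nan)
    criterion: Literal["ML", "REML"] = "REML"


@dataclass(frozen=True)
class BisectorLine:
    slope: float
    intercept: float


@dataclass
class ModelComparison:
    """AICc per candidate structure and the selected minimum."""

    fits: dict[str, RegressionFit]
    aicc: dict[str, float]
    best_kind: str

    @property
    def best(self) -> RegressionFit:
        return self.fits[self.best_kind]


def phylo_covariance(tree: Phylogeny, model: CorrelationModel) -> np.ndarray:
    """Residual covariance (relative scale) implied by a structure."""
    n = tree.n
    kind = model.kind
    if kind == "NP":
        return np.eye(n)
    if kind == "BM":
        return tree.mrca_depth.copy()
    if kind == "BM_lambda":
        lam = model.theta
        if lam is None or not 0.0 <= lam <= 1.0:
            raise ParameterError(f"lambda must lie in [0, 1], got {lam}")
        V = tree.mrca_depth * lam
        np.fill_diagonal(V, tree.tip_depths)
        return V
    if kind == "BM_rho":
        rho = model.theta
        if rho is None or rho <= 0:
            raise ParameterError(f"rho must be positive, got {rho}")
        H = tree.height
        if H <= 0:
            raise TreeError("tree height must be positive")
        V = (tree.mrca_depth / H) ** rho * H
        return V
    if kind == "OU":
        alpha = model.theta
        if alpha is None or alpha < 0:
            raise ParameterError(f"alpha must be >= 0, got {alpha}")
        d = (tree.tip_depths[:, None] + tree.tip_depths[None, :]
             - 2.0 * tree.mrca_depth)
        return np.exp(-alpha * d)
    raise ParameterError(f"unknown correlation structure {kind!r}")


def _gls_core(
    X: np.ndarray, y: np.ndarray, V: np.ndarray, criterion: str
) -> tuple[np.ndarray, np.ndarray, float, float, tuple[float, float]]:
    """Generalized least squares with profiled variance.

    Returns (beta, SEs, loglik, sigma2_hat, V-inverse-weighted centroid of
    (x, y)); raises NumericalError on a non-positive-definite V.
    """
    from scipy.linalg import solve_triangular

    n, p = X.shape
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("correlation matrix not positive definite") from exc
    # whiten: solve L z = v, so z' z = v' V^-1 v
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    G = Xw.T @ Xw  # X' V^-1 X
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    if criterion == "REML":
        sigma2_ml = rss / (n - p)
        sign, logdetG = np.linalg.slogdet(G)
        ll = -0.5 * (
            (n - p) * (math.log(2 * math.pi * sigma2_ml) + 1)
            + logdetV + logdetG
        )
    else:
        sigma2_ml = rss / n
        ll = -0.5 * (n * (math.log(2 * math.pi * sigma2_ml) + 1) + logdetV)
    sigma2_unbiased = rss / (n - p)
    cov_beta = sigma2_unbiased * np.linalg.inv(G)
    ses = np.sqrt(np.diag(cov_beta))
    # V^-1-weighted means of the predictor and response columns
    onesw = solve_triangular(L, np.ones(n), lower=True)
    denom = float(onesw @ onesw)
    xbar = float(onesw @ Xw[:, 1]) / denom
    ybar = float(onesw @ yw) / denom
    return beta, ses, ll, sigma2_unbiased, (xbar, ybar)


def _loglik_for_theta(
    theta: float, kind: ModelKind, X, y, tree, criterion
) -> float:
    V = phylo_covariance(tree, CorrelationModel(kind, theta))
    try:
        _, _, ll, _, _ = _gls_core(X, y, V, criterion)
    except NumericalError:
        return -1e12  # finite sentinel keeps the bounded optimizer stable
    return ll


def _estimate_theta(
    kind: ModelKind, X, y, tree: Phylogeny, criterion: str
) -> float:
    """Maximise the profile likelihood of the structure parameter.

    lambda is searched on [0, 1]; rho and alpha on log-scaled ranges with a
    three-point multistart to dodge local optima.
    """
    if kind == "BM_lambda":
        lo, hi, log_scale = 0.0, 1.0, False
    elif kind == "BM_rho":
        lo, hi, log_scale = 1e-3, 10.0, True
    elif kind == "OU":
        h = max(tree.height, 1e-12)
        lo, hi, log_scale = 1e-6, 50.0 / h, True
    else:
        raise ParameterError(f"{kind} has no free structure parameter")

    def neg_ll(u: float) -> float:
        theta = math.exp(u) if log_scale else u
        return -_loglik_for_theta(theta, kind, X, y, tree, criterion)

    a = math.log(lo) if log_scale else lo
    b = math.log(hi) if log_scale else hi
    best_u, best_val = None, np.inf
    thirds = [a + (b - a) * f for f in (0.0, 0.5, 1.0)]
    for start in thirds:
        span = (b - a) / 2
        lo_i, hi_i = max(a, start - span), min(b, start + span)
        res = optimize.minimize_scalar(
            neg_ll, bounds=(lo_i, hi_i), method="bounded",
            options={"xatol": 1e-8},
        )
        if res.fun < best_val:
            best_val, best_u = float(res.fun), float(res.x)
    # compare against the interval endpoints (lambda often sits on one)
    for u in (a, b):
        v = neg_ll(u)
        if v < best_val:
            best_val, best_u = v, u
    return math.exp(best_u) if log_scale else float(best_u)


def gls_fit(
    table: TraitTable,
    tree: Optional[Phylogeny],
    model: CorrelationModel,
    direction: Literal["y_on_x", "x_on_y_expressed"] = "y_on_x",
    criterion: Literal["ML", "REML"] = "REML",
) -> RegressionFit:
    """Fit a line by GLS under a phylogenetic correlation structure.

    For the expressed X-on-Y direction the regression of x on y is fitted
    with the same structure and re-expressed in y-vs-x space: slope 1/b,
    intercept -a/b, with delta-method standard errors.
    """
    if table.n < 4:
        raise InsufficientDataError("GLS needs at least 4 species")
    if model.kind != "NP":
        if tree is None:
            raise TreeError(f"{model.kind} requires a phylogeny")
        tree = tree.subset(table.species)
    else:
        tree = tree.subset(table.species) if tree is not None else Phylogeny(
            [normalize_name(s) for s in table.species],
            np.eye(table.n), np.ones(table.n),
        )

    resp, pred = (table.y, table.x) if direction == "y_on_x" else (
        table.x, table.y)
    X = np.column_stack([np.ones(table.n), pred])

    theta = model.theta
    estimated = model.estimated
    if model.n_theta and theta is None:
        theta = _estimate_theta(model.kind, X, resp, tree, criterion)
        estimated = True
    fitted_model = CorrelationModel(model.kind, theta, estimated)
    V = phylo_covariance(tree, fitted_model)
    beta, ses, ll, _, (pbar, rbar) = _gls_core(X, resp, V, criterion)
    a, b = float(beta[0]), float(beta[1])
    se_a, se_b = float(ses[0]), float(ses[1])
    n = table.n
    dfree = n - 2
    t = b / se_b if se_b > 0 else math.inf
    p = 2.0 * stats.t.sf(abs(t), dfree)
    k = 2 + 1 + (1 if estimated else 0)
    if direction == "y_on_x":
        return RegressionFit(b, se_b, a, se_a, t, dfree, p, ll, k,
                             fitted_model, "y_on_x", None, (pbar, rbar),
                             criterion)
    # raw fit was x = a + b y; express as y = -a/b + x/b
    if b == 0:
        raise NumericalError("X-on-Y slope is zero; cannot re-express")
    slope = 1.0 / b
    intercept = -a / b
    slope_se = se_b / b**2
    intercept_se = math.sqrt(
        (se_a / b) ** 2 + (a * se_b / b**2) ** 2)
    # centroid back in (x, y) space: raw fit had predictor y, response x
    return RegressionFit(slope, slope_se, intercept, intercept_se, t, dfree,
                         p, ll, k, fitted_model, "x_on_y_expressed", None,
                         (rbar, pbar), criterion)


def ols_fit(
    table: TraitTable,
    direction: Literal["y_on_x", "x_on_y_expressed"] = "y_on_x",
) -> RegressionFit:
    """Ordinary least squares line with R^2 and the slope t-test."""
    if table.n < 3:
        raise InsufficientDataError("OLS needs at least 3 points")
    pred = table.x if direction == "y_on_x" else table.y
    if np.var(pred) == 0:
        raise DegenerateInputError("predictor has zero variance")
    fit = gls_fit(table, None, CorrelationModel("NP"), direction, "ML")
    # R^2 of the raw regression (same either direction: squared correlation)
    r = np.corrcoef(table.x, table.y)[0, 1]
    fit.r2 = float(r**2)
    fit.k = 3
    return fit


def aicc(fit: RegressionFit, n: int) -> float:
    """Small-sample Akaike criterion: AIC + 2k(k+1)/(n-k-1)."""
    k = fit.k
    if n <= k + 1:
        raise InsufficientDataError(
            f"AICc undefined for n={n} with k={k} parameters")
    return -2.0 * fit.loglik + 2 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_candidates(
    table: TraitTable,
    tree: Optional[Phylogeny],
    kinds: Sequence[ModelKind] = CANDIDATE_KINDS,
    direction: Literal["y_on_x", "x_on_y_expressed"] = "y_on_x",
    criterion: Literal["ML", "REML"] = "REML",
) -> dict[str, RegressionFit]:
    """Fit every candidate correlation structure on the same data."""
    fits: dict[str, RegressionFit] = {}
    for kind in kinds:
        if kind != "NP" and tree is None:
            continue
        fits[kind] = gls_fit(table, tree, CorrelationModel(kind),
                             direction, criterion)
    return fits


def select_model(fits: dict[str, RegressionFit], n: int) -> ModelComparison:
    """Rank candidate structures by AICc; ties go to fewer parameters."""
    if not fits:
        raise InsufficientDataError("no candidate fits supplied")
    table = {kind: aicc(fit, n) for kind, fit in fits.items()}
    best = min(table, key=lambda kind: (table[kind], fits[kind].k))
    return ModelComparison(fits, table, best)


def bisector_slope(b1: float, b2: float) -> float:
    """Slope of the line bisecting two lines of common slope sign."""
    if b1 + b2 == 0 or b1 * b2 < 0:
        raise NumericalError(
            f"bisector undefined for slopes {b1} and {b2}")
    return (b1 * b2 - 1.0 + math.sqrt((1 + b1**2) * (1 + b2**2))) / (b1 + b2)


def bisector(
    fit_yx: RegressionFit,
    fit_xy_expressed: RegressionFit,
    centroid: Optional[tuple[float, float]] = None,
) -> BisectorLine:
    """Errors-in-both-variables summary line through the common centroid.

    Both component regressions pass through the V-inverse-weighted centroid
    of the data, so the bisector is anchored there; its slope is the
    tangent of the mean of the two slopes' arctangents.
    """
    b3 = bisector_slope(fit_yx.slope, fit_xy_expressed.slope)
    if centroid is None:
        centroid = fit_yx.centroid
    xbar, ybar = centroid
    return BisectorLine(b3, ybar - b3 * xbar)


def ancova_slopes(table: TraitTable) -> tuple[float, tuple[int, int], float]:
    """Test slope heterogeneity between two groups (interaction F-test).

    Compares the full model y ~ x + group + x:group against the reduced
    y ~ x + group; F = ((RSS_red - RSS_full)/1) / (RSS_full/(n-4)).
    """
    if table.group is None:
        raise DegenerateInputError("trait table has no group labels")
    labels = sorted(set(table.group))
    if len(labels) != 2:
        raise DegenerateInputError(f"ANCOVA needs exactly 2 groups, got {labels}")
    g = np.array([1.0 if gi == labels[1] else 0.0 for gi in table.group])
    for lab in labels:
        if sum(1 for gi in table.group if gi == lab) < 3:
            raise InsufficientDataError(f"group {lab!r} has < 3 points")
    n = table.n
    X_full = np.column_stack([np.ones(n), table.x, g, table.x * g])
    X_red = X_full[:, :3]

    def rss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, table.y, rcond=None)
        r = table.y - X @ beta
        return float(r @ r)

    rss_full, rss_red = rss(X_full), rss(X_red)
    df2 = n - 4
    F = (rss_red - rss_full) / (rss_full / df2)
    p = float(stats.f.sf(F, 1, df2))
    return float(F), (1, df2), p


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (gatekeeper for log transforms)."""
    arr = np.asarray(values, dtype=float)
    if not 3 <= arr.size <= 5000:
        raise DegenerateInputError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(arr) == 0:
        raise DegenerateInputError("constant sample")
    res = stats.shapiro(arr)
    return float(res.statistic), float(res.pvalue)
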