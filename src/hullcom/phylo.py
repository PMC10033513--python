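"""Phylogenetic comparative statistics under Brownian motion.

Implements the comparative toolkit used downstream of the volumetric
reconstructions: maximum-likelihood ancestral states with confidence
intervals, phylogenetic generalised least squares (pGLS) with AICc and
isometry classification, permutation-based phylogenetic ANOVA/ANCOVA in
the residual-randomisation (RRPP) style, phylogenetic PCA on the
evolutionary covariance matrix, phylomorphospace coordinates, and Spearman
rank correlations.

Under Brownian motion (BM) a trait accumulates variance linearly with
time, so the expected covariance between two taxa is sigma^2 times the
depth of their most recent common ancestor.  That covariance matrix C
drives every procedure here: GLS estimation weights by C^-1, the RRPP
tests permute residuals in C^(-1/2)-transformed space, and the
evolutionary covariance for PCA is the GLS cross-product weighted by C^-1.
Pagel's lambda (off-diagonal rescaling of C) is available as an
alternative correlation structure, with lambda estimated by maximum
likelihood.

Newick reading/writing is delegated to dendropy; all numerics are done on
arrays extracted from the parsed tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Tree container
# ---------------------------------------------------------------------------


class Phylogeny:
    """A rooted, branch-length-bearing tree with array views for BM
    covariance computations.

    Node ids: tips keep their taxon labels; internal nodes keep their
    Newick label when present, otherwise they are assigned ``nd<k>`` in
    preorder (``nd0`` is the root).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._index()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise PhyloError(f"Newick parse error: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- indexing -----------------------------------------------------------

    def _index(self) -> None:
        nodes = list(self._tree.preorder_node_iter())
        self._nodes = nodes
        self._node_index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=int)
        self.edge_length = np.zeros(n)
        self.depth = np.zeros(n)
        self.is_tip = np.zeros(n, dtype=bool)
        self.node_ids = []
        k_internal = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = self._node_index[id(nd.parent_node)]
                self.parent[i] = p
                bl = nd.edge.length
                if bl is None:
                    raise PhyloError("tree has edges without branch lengths")
                if bl <= 0:
                    raise PhyloError(f"non-positive branch length {bl}")
                self.edge_length[i] = bl
                self.depth[i] = self.depth[p] + bl
            if nd.is_leaf():
                self.is_tip[i] = True
                self.node_ids.append(nd.taxon.label)
            else:
                label = nd.label if nd.label else f"nd{k_internal}"
                self.node_ids.append(label)
                k_internal += 1
        self.tip_indices = np.flatnonzero(self.is_tip)
        self.internal_indices = np.flatnonzero(~self.is_tip)
        self.tip_labels = [self.node_ids[i] for i in self.tip_indices]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise PhyloError("duplicate tip labels")
        # ancestor paths (node -> root) for MRCA lookups
        self._anc = []
        for i in range(n):
            path = []
            j = i
            while j != -1:
                path.append(j)
                j = self.parent[j]
            self._anc.append(path)

    # -- basic properties ---------------------------------------------------

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def n_internal(self) -> int:
        return len(self.internal_indices)

    @property
    def internal_ids(self) -> list:
        return [self.node_ids[i] for i in self.internal_indices]

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.depth[self.tip_indices]
        return bool(np.ptp(d) <= rtol * max(d.max(), 1e-300))

    def _mrca(self, i: int, j: int) -> int:
        ai = set(self._anc[i])
        for k in self._anc[j]:
            if k in ai:
                return k
        raise AssertionError("disconnected tree")

    # -- covariance matrices ------------------------------------------------

    def vcv(self, labels=None) -> pd.DataFrame:
        """BM covariance among tips (unit rate): C[i, j] = depth of the
        MRCA of tips i and j."""
        if labels is None:
            labels = self.tip_labels
        idx = [self.tip_indices[self.tip_labels.index(l)] for l in labels]
        n = len(idx)
        C = np.zeros((n, n))
        for a in range(n):
            C[a, a] = self.depth[idx[a]]
            for b in range(a + 1, n):
                C[a, b] = C[b, a] = self.depth[self._mrca(idx[a], idx[b])]
        return pd.DataFrame(C, index=labels, columns=labels)

    def node_tip_cov(self, tip_labels=None) -> pd.DataFrame:
        """Covariance of every node (tips and internal) with each tip:
        rows all node ids, columns tip labels."""
        if tip_labels is None:
            tip_labels = self.tip_labels
        tips = [self.tip_indices[self.tip_labels.index(l)] for l in tip_labels]
        rows = list(range(len(self._nodes)))
        M = np.zeros((len(rows), len(tips)))
        for r, i in enumerate(rows):
            for c, j in enumerate(tips):
                M[r, c] = self.depth[self._mrca(i, j)]
        return pd.DataFrame(M, index=self.node_ids, columns=tip_labels)

    def node_depths(self) -> pd.Series:
        return pd.Series(self.depth, index=self.node_ids)

    def edges(self) -> list:
        """(parent_id, child_id) for every edge."""
        out = []
        for i in range(1, len(self._nodes)):
            if self.parent[i] != -1:
                out.append((self.node_ids[self.parent[i]], self.node_ids[i]))
        return out

    def prune_to(self, labels) -> "Phylogeny":
        keep = [l for l in self.tip_labels if l in set(labels)]
        missing = set(labels) - set(self.tip_labels)
        if missing:
            logger.warning("prune_to: labels absent from tree: %s", sorted(missing))
        clone = self._tree.extract_tree_with_taxa_labels(keep)
        return Phylogeny(
            dendropy.Tree.get(
                data=clone.as_string(schema="newick"),
                schema="newick",
                preserve_underscores=True,
            )
        )


def read_newick(text: str) -> Phylogeny:
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


# ---------------------------------------------------------------------------
# Alignment helpers
# ---------------------------------------------------------------------------


def _align(tree: Phylogeny, *series_or_frames):
    """Intersect taxa between the tree tips and every table; mismatches are
    logged and dropped."""
    common = set(tree.tip_labels)
    for obj in series_or_frames:
        common &= set(obj.index)
    dropped = set(tree.tip_labels) - common
    if dropped:
        logger.info("dropping taxa absent from data: %s", sorted(dropped))
    labels = [l for l in tree.tip_labels if l in common]
    if not labels:
        raise PhyloError("no taxa shared between tree and data")
    aligned = [obj.loc[labels] for obj in series_or_frames]
    return labels, aligned


def _phylo_mean_and_icov(C: np.ndarray, x: np.ndarray):
    cf = cho_factor(C, lower=True)
    ones = np.ones(len(C))
    iC1 = cho_solve(cf, ones)
    iCx = cho_solve(cf, x)
    denom = ones @ iC1
    mu = float(ones @ iCx / denom)
    return mu, cf, iC1, denom


# ---------------------------------------------------------------------------
# Ancestral states
# ---------------------------------------------------------------------------


def ancestral_states_bm(tree: Phylogeny, values) -> pd.DataFrame:
    """ML ancestral states for a continuous trait under Brownian motion.

    Point estimates are the joint GLS solution (the mode of the Gaussian
    likelihood over all internal-node states); variances are the kriging
    variances including the uncertainty of the estimated root mean, with
    the BM rate fixed at its ML value.  Returns a DataFrame indexed by
    internal-node id with columns estimate, variance, ci_low, ci_high.
    """
    values = pd.Series(values).astype(float)
    if values.isna().any():
        missing = list(values.index[values.isna()])
        raise PhyloError(f"missing trait values for: {missing}")
    labels, (x,) = _align(tree, values)
    x = x.to_numpy()
    n = len(labels)
    C = tree.vcv(labels).to_numpy()
    mu, cf, iC1, denom = _phylo_mean_and_icov(C, x)
    resid = x - mu
    iCr = cho_solve(cf, resid)
    sigma2 = float(resid @ iCr / n)  # ML rate

    M = tree.node_tip_cov(labels)
    rows = []
    for node_id in tree.internal_ids:
        c = M.loc[node_id].to_numpy()
        node_idx = tree.node_ids.index(node_id)
        c_self = tree.depth[node_idx]
        iCc = cho_solve(cf, c)
        est = mu + c @ iCr
        var = sigma2 * (c_self - c @ iCc + (1.0 - np.ones(n) @ iCc) ** 2 / denom)
        var = max(var, 0.0)
        rows.append((node_id, est, var))
    df = pd.DataFrame(rows, columns=["node", "estimate", "variance"]).set_index("node")
    half = 1.96 * np.sqrt(df["variance"])
    df["ci_low"] = df["estimate"] - half
    df["ci_high"] = df["estimate"] + half
    return df


def ancestral_states_table(tree: Phylogeny, traits: pd.DataFrame) -> pd.DataFrame:
    """Ancestral states for several traits: tidy frame indexed by node with
    <trait>, <trait>_var, <trait>_ci_low/_ci_high columns."""
    pieces = {}
    for col in traits.columns:
        a = ancestral_states_bm(tree, traits[col])
        pieces[col] = a["estimate"]
        pieces[f"{col}_var"] = a["variance"]
        pieces[f"{col}_ci_low"] = a["ci_low"]
        pieces[f"{col}_ci_high"] = a["ci_high"]
    return pd.DataFrame(pieces)


# ---------------------------------------------------------------------------
# pGLS
# ---------------------------------------------------------------------------


@dataclass
class PGLSFit:
    coef: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    sigma2: float
    loglik: float
    aicc: float
    n: int
    k: int
    correlation: str
    lam: float | None = None
    df_resid: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _gls_loglik(C: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Profile ML log-likelihood pieces for fixed correlation matrix C."""
    L = cholesky(C, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    n = len(y)
    sigma2_ml = rss / n
    logdetC = 2.0 * float(np.log(np.diag(L)).sum())
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdetC + n)
    return beta, rss, sigma2_ml, loglik, Xw, yw, rank


def pgls(
    y,
    X,
    tree: Phylogeny,
    correlation: str = "BM",
    add_intercept: bool = True,
) -> PGLSFit:
    """Phylogenetic GLS regression with BM (or Pagel's lambda) covariance.

    ``y`` is a Series indexed by taxon, ``X`` a DataFrame (or Series) of
    predictors; an intercept column is prepended unless disabled.  The fit
    is by maximum likelihood; AICc counts the regression coefficients plus
    the BM rate (and lambda when estimated).  Coefficient SEs use the
    unbiased residual variance so a star tree reproduces OLS exactly.
    """
    y = pd.Series(y).astype(float)
    if isinstance(X, pd.Series):
        X = X.to_frame()
    X = pd.DataFrame(X).astype(float)
    labels, (y_al, X_al) = _align(tree, y, X)
    n = len(labels)
    names = list(X_al.columns)
    mat = X_al.to_numpy()
    if add_intercept:
        mat = np.column_stack([np.ones(n), mat])
        names = ["intercept"] + names
    p = mat.shape[1]
    if np.linalg.matrix_rank(mat) < p:
        raise PhyloError(f"rank-deficient design; columns: {names}")
    C = tree.vcv(labels).to_numpy()
    yv = y_al.to_numpy()

    lam = None
    if correlation == "BM":
        Cc = C
        tag = "BM"
        extra = 0
    elif correlation == "lambda":
        diag = np.diag(np.diag(C))

        def neg_ll(l):
            Cl = l * C + (1 - l) * diag
            return -_gls_loglik(Cl, mat, yv)[3]

        grid = np.linspace(0.0, 1.0, 21)
        vals = [neg_ll(l) for l in grid]
        i = int(np.argmin(vals))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
        if hi > lo:
            res = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded")
            lam = float(res.x)
        else:
            lam = float(grid[i])
        Cc = lam * C + (1 - lam) * diag
        tag = f"lambda({lam:.4f})"
        extra = 1
    else:
        raise ValueError(f"unknown correlation {correlation!r}")

    beta, rss, sigma2_ml, loglik, Xw, yw, rank = _gls_loglik(Cc, mat, yv)
    df_resid = n - p
    if df_resid <= 0:
        raise PhyloError("no residual degrees of freedom")
    s2_unbiased = rss / df_resid
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(XtX_inv) * s2_unbiased)
    tcrit = stats.t.ppf(0.975, df_resid)
    k = p + 1 + extra
    if n - k - 1 > 0:
        aicc = -2 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    else:
        logger.warning("AICc undefined for n=%d, k=%d; reporting inf", n, k)
        aicc = np.inf
    return PGLSFit(
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        ci_low=pd.Series(beta - tcrit * se, index=names),
        ci_high=pd.Series(beta + tcrit * se, index=names),
        sigma2=sigma2_ml,
        loglik=loglik,
        aicc=aicc,
        n=n,
        k=k,
        correlation=tag,
        lam=lam,
        df_resid=df_resid,
    )


def allometry_classify(fit: PGLSFit, isometric_slope: float, term: str | None = None):
    """Classify a scaling relationship against an isometric expectation by
    whether the slope's 95% CI lies below, spans, or lies above it."""
    if term is None:
        candidates = [nm for nm in fit.coef.index if nm != "intercept"]
        if not candidates:
            raise ValueError("fit has no slope term")
        term = candidates[0]
    lo, hi = float(fit.ci_low[term]), float(fit.ci_high[term])
    if hi < isometric_slope:
        verdict = "negative"
    elif lo > isometric_slope:
        verdict = "positive"
    else:
        verdict = "isometric"
    return {"term": term, "ci_low": lo, "ci_high": hi,
            "isometric_slope": isometric_slope, "classification": verdict}


# ---------------------------------------------------------------------------
# Permutation ANOVA / ANCOVA (RRPP)
# ---------------------------------------------------------------------------


@dataclass
class PermTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    term: str
    df1: int
    df2: int


def _rss_matrix(Q: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sums of squares of columns of Y against span(Q),
    Q orthonormal."""
    total = np.einsum("ij,ij->j", Y, Y)
    proj = Q.T @ Y
    return total - np.einsum("ij,ij->j", proj, proj)


def phylo_anova(
    trait,
    groups,
    tree: Phylogeny,
    n_perm: int = 999,
    seed: int = 0,
    covariate=None,
    test: str = "group",
) -> PermTestResult:
    """Phylogenetic ANOVA (or ANCOVA slopes test) by residual permutation.

    The response and design are premultiplied by C^(-1/2) (Cholesky of the
    BM covariance), an OLS F statistic is computed for the term of
    interest, and significance comes from randomising the reduced-model
    residuals (RRPP): p = (1 + #{F* >= F}) / (1 + n_perm).

    ``test='group'`` contrasts means (reduced model: intercept, plus the
    covariate when given); ``test='slopes'`` contrasts group-specific
    slopes of the covariate (reduced model: covariate + group, full model
    adds the interaction).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    trait = pd.Series(trait).astype(float)
    groups = pd.Series(groups)
    objs = [trait, groups]
    if covariate is not None:
        covariate = pd.Series(covariate).astype(float)
        objs.append(covariate)
    labels, aligned = _align(tree, *objs)
    y = aligned[0].to_numpy()
    g = aligned[1]
    cov = aligned[2].to_numpy() if covariate is not None else None

    levels = sorted(g.unique())
    if len(levels) < 2:
        raise PhyloError("need >= 2 groups present in tree-matched data")
    counts = g.value_counts()
    small = [lv for lv in levels if counts[lv] < 2]
    if small:
        raise PhyloError(f"groups with < 2 taxa: {small}")
    n = len(labels)
    dummies = np.column_stack(
        [(g == lv).to_numpy(dtype=float) for lv in levels[1:]]
    )

    C = tree.vcv(labels).to_numpy()
    L = cholesky(C, lower=True)

    def w(M):
        return solve_triangular(L, M, lower=True)

    ones = np.ones((n, 1))
    if test == "group":
        if cov is None:
            X_red = ones
            X_full = np.column_stack([ones, dummies])
        else:
            X_red = np.column_stack([ones, cov])
            X_full = np.column_stack([ones, cov, dummies])
        term = "group"
    elif test == "slopes":
        if cov is None:
            raise ValueError("slopes test requires a covariate")
        inter = dummies * cov[:, None]
        X_red = np.column_stack([ones, cov, dummies])
        X_full = np.column_stack([ones, cov, dummies, inter])
        term = "group:covariate"
    else:
        raise ValueError(f"unknown test {test!r}")

    Xr, Xf, yw = w(X_red), w(X_full), w(y)
    Qr, _ = np.linalg.qr(Xr)
    Qf, _ = np.linalg.qr(Xf)
    df1 = X_full.shape[1] - X_red.shape[1]
    df2 = n - X_full.shape[1]
    if df2 <= 0:
        raise PhyloError("no residual degrees of freedom for the full model")

    def f_stat(Y):
        rss_r = _rss_matrix(Qr, Y)
        rss_f = _rss_matrix(Qf, Y)
        num = (rss_r - rss_f) / df1
        den = rss_f / df2
        scale = np.maximum(rss_r, 1e-300)
        F = np.where(num <= 1e-12 * scale, 0.0,
                     np.where(den <= 1e-300, np.inf, num / np.maximum(den, 1e-300)))
        return F

    Y = yw[:, None]
    F_obs = float(f_stat(Y)[0])

    rng = np.random.default_rng(seed)
    fitted_r = Qr @ (Qr.T @ yw)
    resid_r = yw - fitted_r
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    Ystar = fitted_r[:, None] + resid_r[perms].T  # (n, n_perm)
    F_perm = f_stat(Ystar)
    n_ge = int(np.sum(F_perm >= F_obs - 1e-12 * max(abs(F_obs), 1.0)))
    p = (1 + n_ge) / (1 + n_perm)
    return PermTestResult(
        statistic=F_obs, p_value=float(p), n_permutations=n_perm,
        seed=seed, term=term, df1=df1, df2=df2,
    )


# ---------------------------------------------------------------------------
# Phylogenetic PCA
# ---------------------------------------------------------------------------


@dataclass
class PPCAResult:
    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    percent_variance: np.ndarray
    node_scores: pd.DataFrame | None = None
    phylo_mean: pd.Series | None = None


def phylo_pca(
    traits: pd.DataFrame, tree: Phylogeny, project_nodes: bool = False
) -> PPCAResult:
    """PCA of the evolutionary (BM-rate) covariance matrix.

    The trait matrix is centred on the phylogenetic (GLS) mean and the
    covariance is the C^-1-weighted cross-product; tip scores are the
    centred raw data projected on the eigenvectors, and node scores (when
    requested) are projected ancestral-state estimates.
    """
    traits = pd.DataFrame(traits).astype(float)
    if traits.shape[1] < 1:
        raise PhyloError("need at least one trait")
    labels, (X_al,) = _align(tree, traits)
    X = X_al.to_numpy()
    n, p = X.shape
    if n <= p:
        logger.warning(
            "fewer taxa (%d) than traits+1 (%d): covariance is rank-deficient", n, p
        )
    C = tree.vcv(labels).to_numpy()
    cf = cho_factor(C, lower=True)
    ones = np.ones(n)
    iC1 = cho_solve(cf, ones)
    abar = (iC1 @ X) / (ones @ iC1)
    Xc = X - abar
    R = Xc.T @ cho_solve(cf, Xc) / (n - 1)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    pcs = [f"PC{i+1}" for i in range(p)]
    scores = pd.DataFrame(Xc @ evecs, index=labels, columns=pcs)
    loadings = pd.DataFrame(evecs, index=traits.columns, columns=pcs)
    pct = 100.0 * evals / evals.sum()

    node_scores = None
    if project_nodes:
        anc = pd.DataFrame(
            {c: ancestral_states_bm(tree, X_al[c])["estimate"] for c in X_al.columns}
        )
        node_scores = pd.DataFrame(
            (anc.to_numpy() - abar) @ evecs, index=anc.index, columns=pcs
        )
    return PPCAResult(
        eigenvalues=evals,
        loadings=loadings,
        scores=scores,
        percent_variance=pct,
        node_scores=node_scores,
        phylo_mean=pd.Series(abar, index=traits.columns),
    )


# ---------------------------------------------------------------------------
# Phylomorphospace
# ---------------------------------------------------------------------------


def phylomorphospace(tree: Phylogeny, traits: pd.DataFrame, trait_x: str, trait_y: str):
    """Coordinates for a bivariate phylomorphospace: tip points from the
    trait table, internal-node points (with per-trait 95% CIs) from BM
    ancestral states, and the parent->child edge list."""
    labels, (T,) = _align(tree, traits[[trait_x, trait_y]])
    ax = ancestral_states_bm(tree, T[trait_x])
    ay = ancestral_states_bm(tree, T[trait_y])
    tips = pd.DataFrame(
        {"x": T[trait_x], "y": T[trait_y]}, index=labels
    )
    nodes = pd.DataFrame(
        {
            "x": ax["estimate"],
            "x_ci_low": ax["ci_low"],
            "x_ci_high": ax["ci_high"],
            "y": ay["estimate"],
            "y_ci_low": ay["ci_low"],
            "y_ci_high": ay["ci_high"],
        }
    )
    coords = pd.concat(
        [tips[["x", "y"]], nodes[["x", "y"]]], axis=0
    )
    rows = []
    for parent, child in tree.edges():
        if parent in coords.index and child in coords.index:
            rows.append(
                (
                    parent, child,
                    coords.loc[parent, "x"], coords.loc[parent, "y"],
                    coords.loc[child, "x"], coords.loc[child, "y"],
                )
            )
    edges = pd.DataFrame(rows, columns=["parent", "child", "x0", "y0", "x1", "y1"])
    return {"tips": tips, "nodes": nodes, "edges": edges}


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def spearman(x, y, method: str = "t"):
    """Spearman rank correlation with average ranks for ties.

    ``method='t'`` (default) uses the t approximation for the p-value;
    ``method='exact'`` enumerates all permutations (n <= 8 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero rank variance: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if method == "exact":
        if n > 8:
            raise ValueError("exact permutation p only for n <= 8")
        from itertools import permutations

        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, float(p)


def spearman_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rho over the columns of ``df`` (t-approx p-values
    are not included; use :func:`spearman` for a single pair)."""
    cols = list(df.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            rho, _ = spearman(df[a].to_numpy(), df[b].to_numpy())
            out.loc[a, b] = out.loc[b, a] = rho
    return out


# ---------------------------------------------------------------------------
# Across-tree summaries
# ---------------------------------------------------------------------------


def across_trees(fn, trees, *args, **kwargs) -> dict:
    """Apply a scalar-valued analysis to each tree in a distribution of
    topologies; report per-tree values plus the median and 2.5/97.5
    percentiles."""
    vals = [float(fn(tree, *args, **kwargs)) for tree in trees]
    arr = np.asarray(vals)
    return {
        "per_tree": vals,
        "median": float(np.median(arr)),
        "q2.5": float(np.percentile(arr, 2.5)),
        "q97.5": float(np.percentile(arr, 97.5)),
    }
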