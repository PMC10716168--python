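"""PLS association between a developmental slope map and gene expression.

With a univariate response, PLS correlation and PLS regression coincide at
the first component up to scaling; the implementation extracts components
from the SVD of the cross-covariance X'y with deflation (classic PLS1).
Component signs are flipped so each score correlates positively with the
response.  Inference is permutation-based against spatially autocorrelated
surrogate maps of the response; gene-level inference uses bootstrap z-scores
of the component-1 weights with a Bonferroni cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import RegionTable
from .surrogates import SurrogateEnsemble, VariogramSurrogates, sac_pvalue
from .trajectories import SlopeMap


@dataclass
class ExpressionMatrix:
    """Region x gene normalized expression for the cortical subset."""

    values: np.ndarray
    gene_ids: list
    region_ids: np.ndarray  # original region ids (cortical subset)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.region_ids = np.asarray(self.region_ids)
        if self.values.shape != (len(self.region_ids), len(self.gene_ids)):
            raise ValueError("expression shape does not match region/gene ids")


def read_expression(path) -> ExpressionMatrix:
    """TSV with first column region_id, remaining columns gene ids."""
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    return ExpressionMatrix(
        values=df.drop(columns=first).to_numpy(float),
        gene_ids=[str(c) for c in df.columns[1:]],
        region_ids=df[first].to_numpy(),
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, columns=expr.gene_ids)
    df.insert(0, "region_id", expr.region_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def align(slope_map, expression: ExpressionMatrix, regions: RegionTable):
    """Restrict to cortical regions shared by map and expression; z-score.

    Returns (y, X, kept_gene_ids, region_index) where region_index are the
    internal 0-based indices of the rows, y is the z-scored slope vector and
    X the column-z-scored expression.  Constant genes are dropped with a
    warning.
    """
    beta = slope_map.beta_age if isinstance(slope_map, SlopeMap) else np.asarray(slope_map, float)
    cortical_idx = np.flatnonzero(regions.cortical)
    id_to_idx = {rid: i for i, rid in enumerate(regions.ids)}
    expr_rows = []
    map_idx = []
    for row, rid in enumerate(expression.region_ids):
        i = id_to_idx.get(rid)
        if i is not None and regions.cortical[i]:
            expr_rows.append(row)
            map_idx.append(i)
    if len(map_idx) < 10:
        raise ValueError(
            f"only {len(map_idx)} cortical regions shared between slope map "
            "and expression (need >= 10)"
        )
    map_idx = np.asarray(map_idx)
    X = expression.values[np.asarray(expr_rows)]
    y = beta[map_idx]
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant gene column(s)", stacklevel=2
        )
    X = X[:, keep]
    genes = [g for g, k in zip(expression.gene_ids, keep) if k]
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    ysd = y.std(ddof=0)
    if ysd == 0:
        raise ValueError("slope map constant over shared regions")
    y = (y - y.mean()) / ysd
    return y, X, genes, map_idx


@dataclass
class PLSResult:
    weights: np.ndarray     # G x K gene weights
    scores: np.ndarray      # R_c x K region scores
    explained: np.ndarray   # fraction of var(y) per component
    r: np.ndarray           # corr(score_k, y), >= 0 after sign convention
    r1: float
    p_sac: float | None = None

    def to_dict(self) -> dict:
        return {
            "explained": self.explained.tolist(),
            "r": self.r.tolist(),
            "r1": self.r1,
            "p_sac": self.p_sac,
            "n_components": self.weights.shape[1],
        }


def _pls1_weights(X, y, n_components):
    """PLS1: weights/scores by cross-covariance SVD with deflation.

    For a univariate response the dominant singular vector of X'y is
    X'y/||X'y|| itself; deflation removes each score direction from X and y.
    """
    Xd = X.copy()
    yd = y.astype(float).copy()
    W, T = [], []
    for _ in range(n_components):
        c = Xd.T @ yd
        nc = np.linalg.norm(c)
        if nc == 0:
            break
        w = c / nc
        t = Xd @ w
        tt = t @ t
        if tt == 0:
            break
        W.append(w)
        T.append(t)
        Xd -= np.outer(t, (t @ Xd) / tt)
        yd = yd - t * ((t @ yd) / tt)
    return np.column_stack(W), np.column_stack(T)


class PLSCorrelation(BaseEstimator):
    """Univariate-response PLS of gene expression against a brain map.

    Attributes (after ``fit``)
    --------------------------
    x_weights_ : (G, K) gene weight vectors, sign-flipped so that each
        component score correlates positively with y.
    x_scores_ : (R, K) region scores.
    explained_variance_ratio_ : fraction of var(y) captured per component.
    r_ : per-component Pearson correlation of score with y (>= 0).
    """

    def __init__(self, n_components: int = 15):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        R, G = X.shape
        if self.n_components > min(R - 1, G):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(R-1, G)="
                f"{min(R - 1, G)}"
            )
        W, T = _pls1_weights(X, y, self.n_components)
        yc = y - y.mean()
        ss_y = yc @ yc
        k = W.shape[1]
        expl = np.zeros(k)
        rs = np.zeros(k)
        for j in range(k):
            t = T[:, j]
            tc = t - t.mean()
            denom = (tc @ tc) * ss_y
            rs[j] = (tc @ yc) / np.sqrt(denom) if denom > 0 else 0.0
            # scores are mutually orthogonal, so per-component shares add up
            expl[j] = (t @ yc) ** 2 / (t @ t) / ss_y if (t @ t) > 0 else 0.0
            if rs[j] < 0:
                W[:, j] = -W[:, j]
                T[:, j] = -T[:, j]
                rs[j] = -rs[j]
        self.x_weights_ = W
        self.x_scores_ = T
        self.explained_variance_ratio_ = expl
        self.r_ = rs
        return self

    def transform(self, X) -> np.ndarray:
        return np.asarray(X, float) @ self.x_weights_


def pls_fit(X, y, n_components: int = 15) -> PLSResult:
    est = PLSCorrelation(n_components=n_components).fit(X, y)
    return PLSResult(
        weights=est.x_weights_,
        scores=est.x_scores_,
        explained=est.explained_variance_ratio_,
        r=est.r_,
        r1=float(est.r_[0]),
    )


def component1_weights(X, y) -> np.ndarray:
    """Fast path: first-component weight vector only (no deflation needed)."""
    c = np.asarray(X, float).T @ np.asarray(y, float)
    n = np.linalg.norm(c)
    return c / n if n > 0 else c


def surrogate_r1(X, ensemble: SurrogateEnsemble) -> np.ndarray:
    """Component-1 score-map correlations for every surrogate response."""
    X = np.asarray(X, float)
    out = np.empty(ensemble.n)
    for i, ys in enumerate(ensemble.maps):
        ysd = ys.std(ddof=0)
        if ysd == 0:
            out[i] = 0.0
            continue
        yz = (ys - ys.mean()) / ysd
        t = X @ component1_weights(X, yz)
        tc = t - t.mean()
        denom = np.sqrt((tc @ tc) * (yz @ yz))
        out[i] = (tc @ yz) / denom if denom > 0 else 0.0
    return out


def pls_with_sac(X, y, distance_matrix, n_components: int = 15,
                 n_surr: int = 10000, seed: int | None = None,
                 generator: VariogramSurrogates | None = None) -> PLSResult:
    """PLS fit plus SAC-corrected permutation p for the component-1 correlation."""
    result = pls_fit(X, y, n_components=n_components)
    if generator is None:
        generator = VariogramSurrogates().fit(distance_matrix)
    ens = generator.sample(np.asarray(y, float), n_surr, random_state=seed)
    null_r = surrogate_r1(X, ens)
    result.p_sac = sac_pvalue(result.r1, null_r)
    return result


@dataclass
class GeneWeightTable:
    gene_ids: list
    weight: np.ndarray
    sd_boot: np.ndarray
    z: np.ndarray
    p: np.ndarray
    selected: np.ndarray  # 'positive' / 'negative' / 'none'

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "weight": self.weight,
                "sd_boot": self.sd_boot,
                "z": self.z,
                "p": self.p,
                "selected": self.selected,
            }
        )


def bootstrap_gene_weights(X, y, gene_ids=None, n_boot: int = 1000,
                           seed: int | None = None,
                           alpha: float = 0.01) -> GeneWeightTable:
    """Bootstrap z-scores for component-1 gene weights.

    Regions (the observation unit of the spatial regression) are resampled
    with replacement; each bootstrap component is sign-aligned to the
    full-data component before accumulating, preventing z-score deflation
    from reflection ambiguity.  Two-sided normal p-values; selection by
    Bonferroni across genes at ``alpha``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    R, G = X.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(G)]
    w_full = component1_weights(X, y)
    if y.std(ddof=0) == 0:
        raise ValueError("response has zero variance")
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, G))
    kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, R, R)
        yb = y[idx]
        if yb.std(ddof=0) == 0:
            continue
        wb = component1_weights(X[idx], yb)
        if wb @ w_full < 0:
            wb = -wb
        boots[kept] = wb
        kept += 1
    if kept == 0:
        raise ValueError("all bootstrap samples degenerate")
    sd = boots[:kept].std(axis=0, ddof=1)
    with np.errstate(divide="ignore"):
        z = np.where(sd > 0, w_full / np.where(sd > 0, sd, 1.0), np.inf * np.sign(w_full))
    p = 2 * stats.norm.sf(np.abs(z))
    table = GeneWeightTable(
        gene_ids=list(gene_ids), weight=w_full, sd_boot=sd, z=z, p=p,
        selected=np.full(G, "none", dtype=object),
    )
    pos, neg = select_genes(table, alpha=alpha)
    return table


def select_genes(table: GeneWeightTable, alpha: float = 0.01):
    """Bonferroni selection: gene kept iff p * G < alpha (strict).

    Updates ``table.selected`` in place and returns (positive, negative)
    gene-id lists ordered by |z| descending.
    """
    G = len(table.gene_ids)
    sel = (table.p * G < alpha)
    table.selected = np.where(
        sel, np.where(table.weight > 0, "positive", "negative"), "none"
    ).astype(object)
    order = np.argsort(-np.abs(table.z))
    pos = [table.gene_ids[i] for i in order if sel[i] and table.weight[i] > 0]
    neg = [table.gene_ids[i] for i in order if sel[i] and table.weight[i] < 0]
    return pos, neg
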