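"""Synthetic longitudinal cohort, expression and cortical-map generator.

Every input the pipeline consumes can be generated here with known ground
truth: a longitudinal cohort whose edge weights follow the linear
mixed-model structure the trajectory analysis assumes (per-region age
slopes from a smooth spatial field, subject random intercepts and slopes,
scan-level noise), a spatially autocorrelated region x gene expression
matrix containing one planted latent component coupled to the slope field,
disjoint cell-class annotations with one enriched class, and cortical maps
with planted correlations to the slope field.

Default sizes are a desk-scale stand-in for the study's 246-region
parcellation and ~10k-gene expression matrix: 90 regions, 200 subjects with
up to three annual scans, 500 genes.  All randomness flows from one master
seed via numpy SeedSequence spawning, so generated bundles are bit
reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .io import Cohort, Connectome, RegionTable, ScanRecord
from .cortical import CorticalMap
from .transcriptomics import ExpressionMatrix

logger = logging.getLogger(__name__)

MODULE_NAMES = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
)
SUBCORTICAL = "subcortical"


@dataclass
class CohortParams:
    """Generator settings for the longitudinal cohort.

    Units: distances mm, ages years, weights unitless (FA x FN scale is
    arbitrary; the baseline kept-edge weight is O(0.5)).
    """

    n_subjects: int = 200
    max_waves: int = 3
    density: float = 0.15          # kept fraction of region pairs
    lambda_d: float = 60.0         # mm, exponential distance decay of weight
    weight_scale: float = 1.0
    slope_mean: float = 0.02       # per-year mean increase of edge weight
    slope_sd: float = 0.015        # sd of the nodal slope field
    sa_scale: float = 20.0         # mm, length-scale of the slope field
    sigma_u: float = 0.08          # subject random intercept sd (per edge)
    sigma_b: float = 0.01          # subject random age-slope sd
    sigma_eps: float = 0.04        # scan x edge noise sd
    dropout: float = 0.3           # per-wave dropout probability after wave 1
    age_min: float = 6.0
    age_max_baseline: float = 11.0  # wave-1 age; +1 year per later wave
    age_center: float = 9.5        # age at which baseline weights are defined
    tbv_mean: float = 1.25e6       # mm^3
    tbv_sd: float = 7e4
    tbv_growth: float = 8e3        # mm^3 per year
    centres: tuple = ("A", "B")
    quadratic_coef: float = 0.0    # optional curvature of the age effect


@dataclass
class GroundTruth:
    nodal_slope_field: np.ndarray | None = None
    edge_slopes: np.ndarray | None = None
    subject_intercepts: dict | None = None
    subject_slopes: dict | None = None
    truncation_rate: float | None = None
    true_gene_weights: np.ndarray | None = None
    latent: np.ndarray | None = None
    coupling_r: float | None = None
    enriched_class: str | None = None
    true_support_genes: list | None = None
    planted_map_correlations: dict | None = None

    def to_json(self, path) -> None:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            return v

        with open(path, "w") as fh:
            json.dump({k: conv(v) for k, v in asdict(self).items()}, fh, indent=1)


def _spawn(seed, n):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def make_regions(R: int = 90, seed: int | None = None,
                 subcortical_frac: float = 0.1) -> RegionTable:
    """Mirrored two-hemisphere parcellation with 8 functional modules.

    Centroids are sampled in one hemisphere of a 140 x 170 x 120 mm box and
    mirrored across x = 0.  The regions closest to the midline origin are
    flagged subcortical; the cortical remainder is split into 7 modules by
    spatial k-means (per-hemisphere mirrored labels).
    """
    if R % 2:
        raise ValueError("R must be even (hemisphere mirroring)")
    rng = np.random.default_rng(seed)
    half = R // 2
    pts = np.column_stack(
        [
            rng.uniform(6, 70, half),
            rng.uniform(-85, 85, half),
            rng.uniform(-60, 60, half),
        ]
    )
    centroids = np.vstack([pts, pts * np.array([-1.0, 1.0, 1.0])])
    hemi = np.array(["R"] * half + ["L"] * half)
    depth = np.linalg.norm(pts, axis=1)
    n_sub_half = int(round(subcortical_frac * half))
    sub_half = np.argsort(depth)[:n_sub_half]
    subcortical = np.zeros(R, dtype=bool)
    subcortical[sub_half] = True
    subcortical[sub_half + half] = True
    n_modules = min(len(MODULE_NAMES), max(1, (half - n_sub_half) // 2))
    if n_modules < len(MODULE_NAMES):
        warnings.warn(
            f"only {n_modules} cortical modules for R={R} (parcellation too "
            "small for 7)",
            stacklevel=2,
        )
    cort_half = np.flatnonzero(~subcortical[:half])
    km = KMeans(n_clusters=n_modules, n_init=4,
                random_state=int(rng.integers(2**31 - 1)))
    labels_half = km.fit_predict(pts[cort_half])
    module = np.empty(R, dtype=object)
    module[subcortical] = SUBCORTICAL
    for i, lab in zip(cort_half, labels_half):
        module[i] = MODULE_NAMES[lab]
        module[i + half] = MODULE_NAMES[lab]
    return RegionTable(
        ids=np.arange(1, R + 1),
        names=[f"region_{i:03d}" for i in range(1, R + 1)],
        hemisphere=hemi,
        centroids=centroids,
        module=module.astype(str),
        cortical=~subcortical,
    )


def _gp_field(D: np.ndarray, length_scale: float, rng) -> np.ndarray:
    """Zero-mean unit-variance Gaussian-process sample over the centroids."""
    K = np.exp(-(D**2) / (2 * length_scale**2)) + 1e-8 * np.eye(D.shape[0])
    L = np.linalg.cholesky(K)
    f = L @ rng.standard_normal(D.shape[0])
    return (f - f.mean()) / f.std(ddof=0)


def simulate_cohort(regions: RegionTable, seed: int | None = None,
                    params: CohortParams | None = None) -> tuple:
    """Longitudinal cohort with planted per-region developmental slopes.

    Baseline edge weights decay exponentially with centroid distance and
    are thresholded to the target density; each edge's age slope is the
    mean of its endpoints' values in a smooth nodal slope field; subjects
    carry random intercepts and age slopes shared across edges; weights are
    truncated at zero (rate logged, < 1% at defaults).
    """
    p = params or CohortParams()
    rng_field, rng_subj, rng_noise, rng_len = _spawn(seed, 4)
    R = regions.n_regions
    D = regions.distance_matrix()
    mu_full = p.weight_scale * np.exp(-D / p.lambda_d)
    iu, ju = np.triu_indices(R, 1)
    n_keep = int(round(p.density * len(iu)))
    order = np.argsort(-mu_full[iu, ju])
    keep = order[:n_keep]
    ki, kj = iu[keep], ju[keep]
    mu_e = mu_full[ki, kj]

    f = p.slope_mean + p.slope_sd * _gp_field(D, p.sa_scale, rng_field)
    s_e = 0.5 * (f[ki] + f[kj])

    scans = []
    intercepts, slopes = {}, {}
    n_trunc = 0
    n_vals = 0
    for i in range(p.n_subjects):
        sid = f"S{i:04d}"
        u = rng_subj.normal(0, p.sigma_u)
        b = rng_subj.normal(0, p.sigma_b)
        intercepts[sid], slopes[sid] = u, b
        sex = "M" if rng_subj.random() < 0.5 else "F"
        centre = p.centres[int(rng_subj.integers(len(p.centres)))]
        age0 = rng_subj.uniform(p.age_min, p.age_max_baseline)
        tbv0 = rng_subj.normal(p.tbv_mean, p.tbv_sd)
        present = [True]
        for _ in range(1, p.max_waves):
            present.append(present[-1] and rng_subj.random() > p.dropout)
        for wave in range(1, p.max_waves + 1):
            if not present[wave - 1]:
                continue
            age = age0 + (wave - 1)
            da = age - p.age_center
            w_e = (
                mu_e
                + s_e * da
                + p.quadratic_coef * da**2
                + u
                + b * da
                + rng_noise.normal(0, p.sigma_eps, n_keep)
            )
            n_trunc += int(np.sum(w_e < 0))
            n_vals += n_keep
            w_e = np.maximum(w_e, 0.0)
            W = np.zeros((R, R))
            W[ki, kj] = w_e
            W[kj, ki] = w_e
            lengths = np.zeros((R, R))
            lvals = D[ki, kj] + rng_len.normal(0, 2.0, n_keep)
            lvals = np.maximum(lvals, 1.0)
            lengths[ki, kj] = lvals
            lengths[kj, ki] = lvals
            lengths[W == 0] = 0.0
            tbv = tbv0 + p.tbv_growth * (age - p.age_center) + rng_noise.normal(0, 1e4)
            scans.append(
                ScanRecord(
                    subject_id=sid, wave=wave, age=age, sex=sex, tbv=tbv,
                    centre=centre, connectome=Connectome(W, lengths),
                )
            )
    trunc_rate = n_trunc / max(n_vals, 1)
    if trunc_rate > 0.01:
        logger.warning("weight truncation rate %.2e above 1%%", trunc_rate)
    else:
        logger.info("weight truncation rate %.2e", trunc_rate)
    edge_slopes = np.zeros((R, R))
    edge_slopes[ki, kj] = s_e
    edge_slopes[kj, ki] = s_e
    gt = GroundTruth(
        nodal_slope_field=f,
        edge_slopes=edge_slopes,
        subject_intercepts=intercepts,
        subject_slopes=slopes,
        truncation_rate=trunc_rate,
    )
    return Cohort(scans=scans, regions=regions), gt


def simulate_lmm_response(n_subjects: int = 200, seed: int | None = None,
                          beta_age: float = 0.35, beta_age2: float = 0.0,
                          intercept: float = 2.0, sigma_subject: float = 0.5,
                          sigma_slope: float = 0.05, sigma_eps: float = 0.3,
                          beta_sex: float = 0.1, beta_tbv: float = 0.0,
                          max_waves: int = 3, dropout: float = 0.3):
    """Covariate frame + response drawn directly from the trajectory model.

    A lightweight path for Monte-Carlo studies of the mixed model itself
    (no connectomes).  Returns (DataFrame, y).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows, ys = [], []
    for i in range(n_subjects):
        u = rng.normal(0, sigma_subject)
        b = rng.normal(0, sigma_slope)
        sex = "M" if rng.random() < 0.5 else "F"
        centre = "A" if rng.random() < 0.5 else "B"
        age0 = rng.uniform(6, 11)
        tbv0 = rng.normal(1.25e6, 7e4)
        present = True
        for wave in range(1, max_waves + 1):
            if wave > 1:
                present = present and rng.random() > dropout
            if not present:
                continue
            age = age0 + wave - 1
            tbv = tbv0 + 8e3 * (age - 9.5)
            y = (
                intercept
                + u
                + (beta_age + b) * age
                + beta_age2 * age**2
                + beta_sex * (sex == "M")
                + beta_tbv * tbv
                + rng.normal(0, sigma_eps)
            )
            rows.append(
                {"subject": f"S{i:04d}", "wave": wave, "age": age, "sex": sex,
                 "tbv": tbv, "centre": centre}
            )
            ys.append(y)
    return pd.DataFrame(rows), np.asarray(ys)


def simulate_expression(regions: RegionTable, slope_field: np.ndarray,
                        G: int = 500, n_true: int = 50,
                        coupling_r: float = 0.5, sa_scale: float = 20.0,
                        noise_sd: float = 0.35, n_factors: int = 3,
                        white_sd: float = 0.25, seed: int | None = None) -> tuple:
    """Expression matrix with one planted component coupled to the slope map.

    The latent component equals the standardized cortical slope field mixed
    with an orthogonalized independent SA field so that corr(latent, slope)
    is ``coupling_r`` exactly.  Each gene is latent times its true weight
    (+-1 on the support, half positive half negative) plus spatially
    autocorrelated noise.  The SA noise is low-rank — ``n_factors`` shared
    SA fields with per-gene Gaussian loadings, plus white measurement noise
    — mirroring the strong co-expression structure of real regional
    transcriptomes (genes share a few dominant spatial patterns; they are
    not independent spatial fields).
    """
    if n_true > G:
        raise ValueError("n_true cannot exceed the number of genes")
    rng_lat, rng_noise, rng_sup = _spawn(seed, 3)
    cort = np.flatnonzero(regions.cortical)
    Dc = regions.distance_matrix()[np.ix_(cort, cort)]
    a = np.asarray(slope_field, float)[cort]
    a = (a - a.mean()) / a.std(ddof=0)
    e = _gp_field(Dc, sa_scale, rng_lat)
    # orthogonalize so the planted coupling is exact
    e_perp = e - (e @ a) / (a @ a) * a
    e_perp = (e_perp - e_perp.mean()) / e_perp.std(ddof=0)
    latent = coupling_r * a + np.sqrt(1 - coupling_r**2) * e_perp
    support = rng_sup.choice(G, size=n_true, replace=False)
    w_true = np.zeros(G)
    half = n_true // 2
    w_true[support[:half]] = 1.0
    w_true[support[half:]] = -1.0
    factors = np.column_stack(
        [_gp_field(Dc, sa_scale, rng_noise) for _ in range(n_factors)]
    )
    loadings = rng_noise.standard_normal((n_factors, G)) / np.sqrt(n_factors)
    X = (
        np.outer(latent, w_true)
        + noise_sd * factors @ loadings
        + white_sd * rng_noise.standard_normal((len(cort), G))
    )
    expr = ExpressionMatrix(
        values=X,
        gene_ids=[f"gene{g:04d}" for g in range(G)],
        region_ids=regions.ids[cort],
    )
    gt = GroundTruth(
        true_gene_weights=w_true,
        latent=latent,
        coupling_r=coupling_r,
        true_support_genes=[expr.gene_ids[i] for i in np.sort(support)],
    )
    return expr, gt


def simulate_annotations(gene_ids, ground_truth: GroundTruth,
                         seed: int | None = None,
                         enriched_class: str = "excitatory",
                         concentration: float = 0.8,
                         n_decoy_categories: int = 9,
                         decoy_size: int = 50) -> tuple:
    """Disjoint 7-class cell annotations plus GMT-style categories.

    Positive true-support genes are concentrated (80% by default) in one
    designated class; everything else is uniform.  Categories contain the
    positive and negative halves of the true support (sign-homogeneous, as
    a signed mean-score statistic cancels over a balanced set) plus random
    decoys.
    """
    from .enrichment import CELL_CLASSES

    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    w = ground_truth.true_gene_weights
    pos = {g for g, wt in zip(gene_ids, w) if wt > 0}
    neg = {g for g, wt in zip(gene_ids, w) if wt < 0}
    annotation = {}
    others = [c for c in CELL_CLASSES if c != enriched_class]
    for g in gene_ids:
        if g in pos and rng.random() < concentration:
            annotation[g] = enriched_class
        else:
            annotation[g] = str(rng.choice(list(CELL_CLASSES) if g not in pos else others))
    categories = {
        "support_pos": sorted(pos),
        "support_neg": sorted(neg),
    }
    for d in range(n_decoy_categories):
        categories[f"decoy_{d:02d}"] = [
            str(g) for g in rng.choice(gene_ids, size=decoy_size, replace=False)
        ]
    gt = GroundTruth(enriched_class=enriched_class,
                     true_support_genes=list(ground_truth.true_support_genes))
    return annotation, categories, gt


def simulate_cortical_maps(regions: RegionTable, slope_field: np.ndarray,
                           target_rhos: dict | None = None,
                           sa_scale: float = 20.0,
                           seed: int | None = None,
                           laminar_target: str = "L5",
                           laminar_rho: float = 0.6) -> tuple:
    """Cortical maps with planted correlations to the slope field.

    Each named map is rho * standardized slope + sqrt(1-rho^2) * an
    orthogonalized independent SA field.  Six laminar maps are generated
    with exactly one (``laminar_target``) conditionally dependent on the
    slope field; the other five are independent SA fields, so the partial
    correlation analysis should isolate the target.
    """
    if target_rhos is None:
        target_rhos = {"myelin": 0.5, "thickness": -0.4}
    rng = np.random.default_rng(seed)
    cort = np.flatnonzero(regions.cortical)
    Dc = regions.distance_matrix()[np.ix_(cort, cort)]
    a = np.asarray(slope_field, float)[cort]
    a = (a - a.mean()) / a.std(ddof=0)

    def mixed(rho):
        e = _gp_field(Dc, sa_scale, rng)
        e_perp = e - (e @ a) / (a @ a) * a
        e_perp = (e_perp - e_perp.mean()) / e_perp.std(ddof=0)
        return rho * a + np.sqrt(1 - rho**2) * e_perp

    maps = {name: CorticalMap(name, mixed(rho)) for name, rho in target_rhos.items()}
    planted = dict(target_rhos)
    for lam in ("L1", "L2", "L3", "L4", "L5", "L6"):
        if lam == laminar_target:
            maps[lam] = CorticalMap(lam, mixed(laminar_rho))
            planted[lam] = laminar_rho
        else:
            maps[lam] = CorticalMap(lam, _gp_field(Dc, sa_scale, rng))
            planted[lam] = 0.0
    gt = GroundTruth(planted_map_correlations=planted)
    return maps, gt
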