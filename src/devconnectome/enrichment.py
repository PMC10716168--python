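"""Cell-class and gene-category enrichment of PLS-selected genes.

Two nulls are used.  Cell-class overlap is tested against size-matched
random gene draws from the PLS universe (one-sided: enrichment).  Category
mean gene scores are tested against PLS weights refitted to spatially
autocorrelated surrogates of the brain map (two-sided, since weights are
signed), with Benjamini-Hochberg FDR across categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .surrogates import VariogramSurrogates
from .transcriptomics import component1_weights

CELL_CLASSES = (
    "astrocytes",
    "endothelial",
    "excitatory",
    "inhibitory",
    "microglia",
    "oligodendrocytes",
    "OPC",
)


@dataclass
class EnrichmentResult:
    name: str
    observed: float
    null_mean: float
    null_sd: float
    p: float
    q: float | None = None
    n_genes: int = 0


def results_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [r.name for r in results],
            "observed": [r.observed for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "n_genes": [r.n_genes for r in results],
        }
    )


def read_annotations(path) -> dict:
    """TSV gene -> cell class."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_annotations(annotation: dict, path) -> None:
    pd.DataFrame(
        {"gene": list(annotation), "cell_class": list(annotation.values())}
    ).to_csv(path, sep="\t", index=False)


def read_categories(path) -> dict:
    """GMT-style text: category <tab> description <tab> gene1 <tab> gene2 ..."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = parts[2:]
    return out


def write_categories(categories: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in categories.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def cell_type_test(selected_genes, annotation: dict, universe,
                   n_perm: int = 10000, seed: int | None = None,
                   classes=CELL_CLASSES) -> list:
    """Overlap enrichment of the selected genes in each cell class.

    Null: overlap counts of random gene sets of the same size drawn
    uniformly (without replacement) from the universe.  One-sided add-one
    p = (1 + #{null >= observed}) / (n_perm + 1).  Empty selections or
    empty classes yield NaN p.
    """
    universe = list(universe)
    selected = set(selected_genes)
    if not selected <= set(universe):
        raise ValueError("selected genes must be a subset of the universe")
    m = len(selected)
    U = len(universe)
    class_of = np.array([annotation.get(g, "") for g in universe])
    sel_mask = np.array([g in selected for g in universe])
    rng = np.random.default_rng(seed)
    # permutation draws as the first m entries of shuffled index arrays
    draws = np.argsort(rng.random((n_perm, U)), axis=1)[:, :m] if m > 0 else None
    results = []
    for cls in classes:
        cls_mask = class_of == cls
        n_cls = int(cls_mask.sum())
        obs = int(np.sum(sel_mask & cls_mask))
        if m == 0 or n_cls == 0:
            results.append(
                EnrichmentResult(cls, float(obs), np.nan, np.nan, np.nan, None, n_cls)
            )
            continue
        null = cls_mask[draws].sum(axis=1)
        p = float((1 + np.sum(null >= obs)) / (n_perm + 1))
        results.append(
            EnrichmentResult(
                cls, float(obs), float(null.mean()), float(null.std(ddof=1)),
                p, None, n_cls,
            )
        )
    ps = [r.p for r in results if np.isfinite(r.p)]
    if ps:
        qs = iter(multipletests(ps, method="fdr_bh")[1])
        for r in results:
            if np.isfinite(r.p):
                r.q = float(next(qs))
    return results


def category_enrichment_sa(gene_scores, gene_ids, categories: dict,
                           y, X, distance_matrix,
                           n_surr: int = 10000, seed: int | None = None,
                           generator: VariogramSurrogates | None = None) -> list:
    """Category enrichment with a spatial-autocorrelation-aware null.

    Observed statistic per category: mean gene score (component-1 PLS
    weight) over its genes.  Null: the same category means recomputed from
    PLS weights refitted against each SA surrogate of the brain map, with
    each null weight vector sign-aligned to the observed one.  Two-sided
    add-one p, BH-FDR across categories.  Categories with no genes in the
    universe get NaN.
    """
    gene_scores = np.asarray(gene_scores, float)
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    if generator is None:
        generator = VariogramSurrogates().fit(distance_matrix)
    ens = generator.sample(y, n_surr, random_state=seed)
    null_w = np.empty((ens.n, X.shape[1]))
    for i, ys in enumerate(ens.maps):
        sd = ys.std(ddof=0)
        yz = (ys - ys.mean()) / sd if sd > 0 else ys - ys.mean()
        # component-1 weights already carry the score-correlates-positively
        # sign convention, matching the observed weights
        null_w[i] = component1_weights(X, yz)
    results = []
    for name, genes in categories.items():
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        if not idx:
            results.append(EnrichmentResult(name, np.nan, np.nan, np.nan, np.nan, None, 0))
            continue
        obs = float(gene_scores[idx].mean())
        null = null_w[:, idx].mean(axis=1)
        # two-sided around the null center (weights are signed)
        mu = null.mean()
        p = float((1 + np.sum(np.abs(null - mu) >= abs(obs - mu))) / (ens.n + 1))
        results.append(
            EnrichmentResult(
                name, obs, float(null.mean()), float(null.std(ddof=1)), p,
                None, len(idx),
            )
        )
    ps = [r.p for r in results if np.isfinite(r.p)]
    if ps:
        qs = iter(multipletests(ps, method="fdr_bh")[1])
        for r in results:
            if np.isfinite(r.p):
                r.q = float(next(qs))
    return results
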