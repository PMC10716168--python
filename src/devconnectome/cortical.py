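"""Cytoarchitecture correlations: myelin, laminar thicknesses, thickness.

Map-map association uses Spearman rank correlation with permutation
p-values from spatially autocorrelated surrogates of the first map (the
slope map).  Laminar specificity uses partial Spearman correlation: all
maps are rank-transformed, the slope and the target lamina are residualized
on the remaining laminas by least squares, and the residuals are Pearson
correlated; surrogates of the slope map are pushed through the identical
residualization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .surrogates import VariogramSurrogates, sac_pvalue

#: condition-number guard for the laminar control design
_COND_MAX = 1e8


@dataclass
class CorticalMap:
    name: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"cortical map '{self.name}' has non-finite values")


def read_cortical_map(path, name: str | None = None) -> CorticalMap:
    df = pd.read_csv(path, sep="\t")
    return CorticalMap(
        name=name or str(df.columns[1]), values=df.iloc[:, 1].to_numpy(float)
    )


def write_cortical_map(cmap: CorticalMap, region_ids, path) -> None:
    pd.DataFrame({"region_id": region_ids, cmap.name: cmap.values}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, CorticalMap) else np.asarray(m, float)


def spearman_sac(map_a, map_b, distance_matrix, n_surr: int = 10000,
                 seed: int | None = None,
                 generator: VariogramSurrogates | None = None) -> tuple:
    """Spearman rho with SAC permutation p (surrogates of the first map)."""
    a = _values(map_a)
    b = _values(map_b)
    rho = float(stats.spearmanr(a, b).statistic)
    if generator is None:
        generator = VariogramSurrogates().fit(distance_matrix)
    ens = generator.sample(a, n_surr, random_state=seed)
    rb = stats.rankdata(b)
    null = np.empty(ens.n)
    for i, s in enumerate(ens.maps):
        null[i] = np.corrcoef(stats.rankdata(s), rb)[0, 1]
    return rho, sac_pvalue(rho, null)


def _residualize(v: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residual of v after least-squares projection on [1, C]."""
    Z = np.column_stack([np.ones(len(v)), C])
    coef, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ coef


def partial_spearman(a, b, controls) -> float:
    """Partial Spearman: Pearson on rank-transformed residuals.

    With an empty control set this reduces exactly to the simple Spearman
    rho.
    """
    ra = stats.rankdata(_values(a))
    rb = stats.rankdata(_values(b))
    if controls is None or len(controls) == 0:
        return float(np.corrcoef(ra, rb)[0, 1])
    C = np.column_stack([stats.rankdata(_values(c)) for c in controls])
    if np.linalg.cond(np.column_stack([np.ones(len(ra)), C])) > _COND_MAX:
        raise ValueError("collinear control maps (condition number guard)")
    return float(np.corrcoef(_residualize(ra, C), _residualize(rb, C))[0, 1])


def partial_laminar(slope_map, laminas, target: str, distance_matrix,
                    n_surr: int = 10000, seed: int | None = None,
                    generator: VariogramSurrogates | None = None) -> tuple:
    """Partial Spearman of the slope map with one lamina, controlling the rest.

    ``laminas`` maps lamina id -> CorticalMap (or vector); surrogates of the
    slope map are pushed through the identical rank + residualization path.
    Returns (partial rho, p).
    """
    if target not in laminas:
        raise ValueError(f"unknown target lamina '{target}'")
    slope = _values(slope_map)
    tgt = _values(laminas[target])
    controls = [_values(v) for k, v in laminas.items() if k != target]
    C = np.column_stack([stats.rankdata(c) for c in controls])
    if np.linalg.cond(np.column_stack([np.ones(len(slope)), C])) > _COND_MAX:
        raise ValueError("collinear control maps (condition number guard)")
    rt_resid = _residualize(stats.rankdata(tgt), C)
    obs = float(np.corrcoef(_residualize(stats.rankdata(slope), C), rt_resid)[0, 1])
    if generator is None:
        generator = VariogramSurrogates().fit(distance_matrix)
    ens = generator.sample(slope, n_surr, random_state=seed)
    null = np.empty(ens.n)
    for i, s in enumerate(ens.maps):
        rs = _residualize(stats.rankdata(s), C)
        denom = np.linalg.norm(rs - rs.mean()) * np.linalg.norm(rt_resid - rt_resid.mean())
        null[i] = (
            np.corrcoef(rs, rt_resid)[0, 1] if denom > 0 else 0.0
        )
    return obs, sac_pvalue(obs, null)


def cytoarchitecture_table(slope_map, maps: dict, distance_matrix,
                           n_surr: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Spearman + SAC p for every cortical map against the slope map."""
    gen = VariogramSurrogates().fit(distance_matrix)
    rows = []
    rng = np.random.default_rng(seed)
    for name, m in maps.items():
        sub = int(rng.integers(2**31 - 1))
        rho, p = spearman_sac(slope_map, m, distance_matrix, n_surr=n_surr,
                              seed=sub, generator=gen)
        rows.append({"map": name, "rho": rho, "p_sac": p})
    return pd.DataFrame(rows)
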