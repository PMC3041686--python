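"""Two-level analysis of molecular variance with permutation significance.

Partitions squared inter-haplotype distances into among-population and
within-population components in the standard Excoffier decomposition:

    SSD_total  = (1/(2N)) * sum_ij delta2_ij
    SSD_within = sum_pops (1/(2 n_p)) * sum_{ij in pop} delta2_ij
    SSD_among  = SSD_total - SSD_within

with mean squares MS = SSD/df (df_among = P-1, df_within = N-P), variance
components sigma2_within = MS_within and sigma2_among =
(MS_among - MS_within)/n0 where n0 = (N - sum n_p^2 / N)/(P-1), and
Phi_ST = sigma2_among / (sigma2_among + sigma2_within).  Significance is
assessed by permuting individuals across populations (sizes preserved).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

AmovaMetric = Literal["pairwise_differences", "squared_input"]


class NoVarianceError(ValueError):
    """All pairwise distances are zero: no molecular variance to partition."""


@dataclass
class AmovaResult:
    ssd_among: float
    ssd_within: float
    ssd_total: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    clamped: bool
    metric: str
    p_value: float | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def to_table(self) -> pd.DataFrame:
        """Conventional AMOVA table layout (source / df / SSD / variance / %)."""
        return pd.DataFrame(
            [
                {"source": "Among populations", "df": self.df_among,
                 "SSD": self.ssd_among, "variance": self.sigma2_among,
                 "pct": self.pct_among},
                {"source": "Within populations", "df": self.df_within,
                 "SSD": self.ssd_within, "variance": self.sigma2_within,
                 "pct": self.pct_within},
                {"source": "Total", "df": self.df_among + self.df_within,
                 "SSD": self.ssd_total,
                 "variance": self.sigma2_among + self.sigma2_within,
                 "pct": 100.0},
            ]
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _delta2(dm: DistanceMatrix, metric: AmovaMetric) -> np.ndarray:
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix contains missing (saturated) entries")
    if metric == "pairwise_differences":
        return dm.values.copy()
    if metric == "squared_input":
        return dm.values**2
    raise ValueError(f"unknown metric: {metric!r}")


def _components(
    d2: np.ndarray, pop_indices: list[np.ndarray], n: int
) -> tuple[float, float, float, float, float]:
    """(ssd_total, ssd_within, sigma2_among, sigma2_within, phi) for one labelling."""
    p = len(pop_indices)
    ssd_total = d2.sum() / (2.0 * n)
    ssd_within = sum(
        d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx)) for idx in pop_indices
    )
    ssd_among = ssd_total - ssd_within
    df_among, df_within = p - 1, n - p
    ms_among = ssd_among / df_among
    ms_within = ssd_within / df_within if df_within > 0 else 0.0
    sizes = np.array([len(idx) for idx in pop_indices], dtype=float)
    n0 = (n - (sizes**2).sum() / n) / df_among
    sigma2_within = ms_within
    sigma2_among = (ms_among - ms_within) / n0
    total = sigma2_among + sigma2_within
    phi = sigma2_among / total if total > 0 else 0.0
    return ssd_total, ssd_within, sigma2_among, sigma2_within, phi


def amova_components(
    dm: DistanceMatrix,
    pops: dict[str, str],
    metric: AmovaMetric = "pairwise_differences",
) -> AmovaResult:
    """Variance decomposition for one observed labelling (no permutation p)."""
    missing = [i for i in dm.ids if i not in pops]
    if missing:
        raise ValueError(f"ids without population label: {missing}")
    labels = [pops[i] for i in dm.ids]
    pop_names = sorted(set(labels))
    n, p = len(dm.ids), len(pop_names)
    if p < 2:
        raise ValueError("need at least 2 populations")
    if n < 3:
        raise ValueError("need at least 3 individuals")
    d2 = _delta2(dm, metric)
    if not np.any(d2 > 0):
        raise NoVarianceError("no molecular variance: all distances are zero")
    pop_indices = [
        np.flatnonzero(np.array(labels) == name) for name in pop_names
    ]
    ssd_total, ssd_within, s2_among, s2_within, _ = _components(d2, pop_indices, n)

    clamped = False
    if s2_among < 0:
        s2_among, clamped = 0.0, True
    if s2_within < 0:
        s2_within, clamped = 0.0, True
    total = s2_among + s2_within
    pct_among = 100.0 * s2_among / total if total > 0 else 0.0
    phi = s2_among / total if total > 0 else 0.0
    return AmovaResult(
        ssd_among=ssd_total - ssd_within,
        ssd_within=ssd_within,
        ssd_total=ssd_total,
        df_among=p - 1,
        df_within=n - p,
        sigma2_among=s2_among,
        sigma2_within=s2_within,
        pct_among=pct_among,
        pct_within=100.0 - pct_among,
        phi_st=phi,
        clamped=clamped,
        metric=metric,
    )


def amova_permutation_test(
    dm: DistanceMatrix,
    pops: dict[str, str],
    n_permutations: int = 1023,
    seed: int = 0,
    metric: AmovaMetric = "pairwise_differences",
) -> AmovaResult:
    """AMOVA with permutation p-value for Phi_ST.

    Individuals' population labels are permuted uniformly at random with
    population sizes preserved; p = (1 + #{Phi* >= Phi_obs}) /
    (1 + n_permutations), so p is never zero.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    result = amova_components(dm, pops, metric=metric)
    labels = np.array([pops[i] for i in dm.ids])
    pop_names = sorted(set(labels))
    sizes = [int((labels == name).sum()) for name in pop_names]
    n = len(dm.ids)
    d2 = _delta2(dm, metric)
    # unclamped observed Phi, so permuted and observed statistics are comparable
    obs_indices = [np.flatnonzero(labels == name) for name in pop_names]
    phi_obs = _components(d2, obs_indices, n)[4]

    rng = np.random.default_rng(seed)
    boundaries = np.cumsum(sizes)[:-1]
    n_extreme = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        idx = np.split(perm, boundaries)
        phi_star = _components(d2, idx, n)[4]
        if phi_star >= phi_obs - 1e-12:
            n_extreme += 1
    result.p_value = (1 + n_extreme) / (1 + n_permutations)
    result.n_permutations = n_permutations
    result.seed = seed
    return result
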