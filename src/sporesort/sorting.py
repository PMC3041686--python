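"""Kin-discrimination statistics for fluorescent-label mixing experiments.

A mix of two clones (one labelled) is starved, allowed to aggregate and
fruit, and individual fruiting bodies are scored for labelled vs.
unlabelled spores under four treatments: two controls (labelled and
unlabelled cells of the same clone) and two experimental reciprocal mixes
(labelled cells of one clone with unlabelled cells of the other).

For each fruiting body with labelled fraction p and unlabelled fraction
q = 1 - p, the within-body relatedness is r = p^2 + q^2: the probability
that two random spores are clonemates, ranging from 0.5 (complete mixing)
to 1 (complete sorting).  Sorting is detected by the variance ratio
F = mean variance of the two experimental treatments over mean variance
of the two controls, with significance from resampling the pooled
per-fruiting-body proportions without replacement across the four
treatments (treatment sizes preserved).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TREATMENTS = ("ctrl_1", "ctrl_2", "exp_1", "exp_2")
CONTROL_TREATMENTS = ("ctrl_1", "ctrl_2")
EXPERIMENTAL_TREATMENTS = ("exp_1", "exp_2")


class DegenerateControlError(ValueError):
    """Mean control variance is zero: the variance ratio is undefined."""


@dataclass(frozen=True)
class FruitingBodyRecord:
    """Spore counts for one fruiting body under one treatment."""

    fb_id: str
    treatment: str
    n_labeled: int
    n_unlabeled: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment: {self.treatment!r}")
        if self.n_labeled < 0 or self.n_unlabeled < 0:
            raise ValueError("spore counts must be non-negative")
        if self.n_labeled + self.n_unlabeled == 0:
            raise ValueError(f"fruiting body {self.fb_id!r} has no spores")

    @property
    def proportion_labeled(self) -> float:
        return self.n_labeled / (self.n_labeled + self.n_unlabeled)

    @property
    def relatedness(self) -> float:
        return relatedness(self.proportion_labeled)


@dataclass
class SortingExperiment:
    """One reciprocal pairwise mix: fruiting-body counts across 4 treatments."""

    mix_id: str
    clone_a: str
    clone_b: str
    records: list[FruitingBodyRecord]

    def __post_init__(self) -> None:
        for t in TREATMENTS:
            if len(self.by_treatment(t)) < 2:
                raise ValueError(
                    f"treatment {t!r} has fewer than 2 fruiting bodies; "
                    "variance is not estimable"
                )

    def by_treatment(self, treatment: str) -> list[FruitingBodyRecord]:
        return [r for r in self.records if r.treatment == treatment]

    def proportions(self, treatment: str) -> np.ndarray:
        return np.array(
            [r.proportion_labeled for r in self.by_treatment(treatment)]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(r) for r in self.records])
        df.insert(0, "mix_id", self.mix_id)
        df["p_labeled"] = df["n_labeled"] / (df["n_labeled"] + df["n_unlabeled"])
        df["relatedness"] = df["p_labeled"] ** 2 + (1 - df["p_labeled"]) ** 2
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, mix_id: str | None = None,
                   clone_a: str = "?", clone_b: str = "?") -> "SortingExperiment":
        """Build from a table with columns fb_id, treatment, n_labeled, n_unlabeled."""
        if mix_id is not None and "mix_id" in df.columns:
            df = df[df["mix_id"] == mix_id]
        records = [
            FruitingBodyRecord(
                fb_id=str(row.fb_id), treatment=str(row.treatment),
                n_labeled=int(row.n_labeled), n_unlabeled=int(row.n_unlabeled),
            )
            for row in df.itertuples()
        ]
        return cls(mix_id=mix_id or "mix", clone_a=clone_a, clone_b=clone_b,
                   records=records)

    @classmethod
    def from_tsv(cls, path: str | Path, mix_id: str | None = None) -> "SortingExperiment":
        return cls.from_frame(pd.read_csv(path, sep="\t"), mix_id=mix_id)


@dataclass
class RelatednessSummary:
    mean_r: float
    se_r: float | None  # None when only one fruiting body (SE undefined)
    n: int


@dataclass
class SortingResult:
    mix_id: str
    per_record: pd.DataFrame
    mean_r_experimental: float
    se_r_experimental: float | None
    mean_r_control: float
    se_r_control: float | None
    f_ratio: float
    p_value: float
    n_resamples: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mix_id": self.mix_id,
            "mean_r_experimental": self.mean_r_experimental,
            "se_r_experimental": self.se_r_experimental,
            "mean_r_control": self.mean_r_control,
            "se_r_control": self.se_r_control,
            "F": self.f_ratio,
            "p_value": self.p_value,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def relatedness(p: float) -> float:
    """Within-fruiting-body relatedness r = p^2 + (1-p)^2 for labelled fraction p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion {p} outside [0, 1]")
    return p * p + (1.0 - p) * (1.0 - p)


def summarize_relatedness(
    records: Iterable[FruitingBodyRecord],
) -> RelatednessSummary:
    """Mean relatedness over fruiting bodies with its standard error.

    Each fruiting body counts once regardless of spore number; SE is the
    sample standard deviation (n-1 denominator) over sqrt(n), undefined
    (None) for a single body.
    """
    r = np.array([rec.relatedness for rec in records])
    if len(r) == 0:
        raise ValueError("no fruiting bodies to summarize")
    se = float(r.std(ddof=1) / math.sqrt(len(r))) if len(r) > 1 else None
    return RelatednessSummary(mean_r=float(r.mean()), se_r=se, n=len(r))


def variance_ratio(
    exp_1: Sequence[float], exp_2: Sequence[float],
    ctrl_1: Sequence[float], ctrl_2: Sequence[float],
) -> float:
    """F = mean(var(exp_1), var(exp_2)) / mean(var(ctrl_1), var(ctrl_2)).

    Sample variances use the n-1 denominator; a zero mean control variance
    raises DegenerateControlError.
    """
    for name, vals in (("exp_1", exp_1), ("exp_2", exp_2),
                       ("ctrl_1", ctrl_1), ("ctrl_2", ctrl_2)):
        if len(vals) < 2:
            raise ValueError(f"treatment {name} needs >= 2 values")
    v_exp = (np.var(exp_1, ddof=1) + np.var(exp_2, ddof=1)) / 2.0
    v_ctrl = (np.var(ctrl_1, ddof=1) + np.var(ctrl_2, ddof=1)) / 2.0
    if v_ctrl == 0.0:
        raise DegenerateControlError("control proportions are constant")
    return float(v_exp / v_ctrl)


def _resampled_f(pool: np.ndarray, sizes: Sequence[int], n_resamples: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Vectorised variance ratios for resampled treatment assignments.

    Resamples where the shuffled control variance is zero come back as +inf
    (maximally extreme).
    """
    perm = rng.permuted(
        np.broadcast_to(pool, (n_resamples, pool.size)).copy(), axis=1
    )
    b = np.cumsum(sizes)
    c1 = perm[:, : b[0]].var(axis=1, ddof=1)
    c2 = perm[:, b[0]: b[1]].var(axis=1, ddof=1)
    e1 = perm[:, b[1]: b[2]].var(axis=1, ddof=1)
    e2 = perm[:, b[2]:].var(axis=1, ddof=1)
    v_ctrl = (c1 + c2) / 2.0
    v_exp = (e1 + e2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(v_ctrl > 0, v_exp / v_ctrl, np.inf)
    return f


def sorting_permutation_test(
    experiment: SortingExperiment,
    n_resamples: int = 5000,
    seed: int = 0,
) -> SortingResult:
    """One-tailed permutation test for sorting via the variance ratio.

    The per-fruiting-body labelled proportions of all four treatments are
    pooled and resampled without replacement into the four treatments
    (observed sizes preserved) ``n_resamples`` times; the upper-tail
    p-value is (1 + #{F* >= F_obs}) / (1 + n_resamples).
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    props = {t: experiment.proportions(t) for t in TREATMENTS}
    f_obs = variance_ratio(
        props["exp_1"], props["exp_2"], props["ctrl_1"], props["ctrl_2"]
    )
    pool = np.concatenate([props[t] for t in TREATMENTS])
    sizes = [len(props[t]) for t in TREATMENTS]

    rng = np.random.default_rng(seed)
    f_star = _resampled_f(pool, sizes, n_resamples, rng)
    n_extreme = int(np.sum(f_star >= f_obs - 1e-12))
    p_value = (1 + n_extreme) / (1 + n_resamples)

    ctrl = [r for t in CONTROL_TREATMENTS for r in experiment.by_treatment(t)]
    exp = [r for t in EXPERIMENTAL_TREATMENTS for r in experiment.by_treatment(t)]
    s_ctrl = summarize_relatedness(ctrl)
    s_exp = summarize_relatedness(exp)
    return SortingResult(
        mix_id=experiment.mix_id,
        per_record=experiment.to_frame(),
        mean_r_experimental=s_exp.mean_r,
        se_r_experimental=s_exp.se_r,
        mean_r_control=s_ctrl.mean_r,
        se_r_control=s_ctrl.se_r,
        f_ratio=f_obs,
        p_value=p_value,
        n_resamples=n_resamples,
        seed=seed,
    )
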