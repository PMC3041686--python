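"""Pairwise evolutionary distances and group-level distance summaries.

Distances are substitutions per site under the usual closed-form
estimators: p-distance, Jukes-Cantor (JC69) and Tamura-Nei (TN93).  A
composite-likelihood variant of TN93 (``mcl_distances``) shares the two
transition-rate ratios and the base frequencies across all pairs —
estimated once from site-pattern counts pooled over every pair — and then
fits each pair's distance by one-dimensional maximum likelihood under
those shared parameters.  On a two-sequence set the pooled counts are the
pair's own counts and the estimate coincides with the TN93 closed form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .seq import VALID_BASES, AlignedSequenceSet

DeletionPolicy = Literal["pairwise", "complete"]
DistanceModel = Literal["p", "jc69", "tn93"]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Distance estimator's log argument is non-positive: divergence saturated."""


class NoUsableSitesError(ValueError):
    """No alignment column is unambiguous in both sequences."""


@dataclass(frozen=True)
class SitePatternCounts:
    """Site-pattern counts for one sequence pair over its usable columns."""

    usable: int
    identical: int
    transitions_ag: int  # A<->G (purine transitions)
    transitions_ct: int  # C<->T (pyrimidine transitions)
    transversions: int
    base_counts: dict[str, int]  # pooled over both sequences' usable columns

    @property
    def mismatches(self) -> int:
        return self.transitions_ag + self.transitions_ct + self.transversions

    @property
    def p_distance(self) -> float:
        return self.mismatches / self.usable

    def frequencies(self) -> dict[str, float]:
        total = sum(self.base_counts.values())
        return {b: self.base_counts[b] / total for b in "ACGT"}


def complete_deletion_mask(seqs: AlignedSequenceSet) -> np.ndarray:
    """Boolean mask of columns that are unambiguous in every record."""
    arr = np.array([list(s) for s in seqs.sequences])
    return np.isin(arr, list(VALID_BASES)).all(axis=0)


def site_pattern_counts(
    a: str, b: str, mask: np.ndarray | None = None
) -> SitePatternCounts:
    """Count identical sites, the two transition classes, transversions and
    base composition over usable columns of a sequence pair.

    With ``mask=None`` usable columns are those where both records carry an
    unambiguous base (pairwise deletion); a precomputed mask restricts to
    columns valid in a whole set (complete deletion).
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    identical = ts_ag = ts_ct = tv = 0
    counts = {base: 0 for base in "ACGT"}
    for k, (ca, cb) in enumerate(zip(a, b)):
        if mask is not None and not mask[k]:
            continue
        if ca not in VALID_BASES or cb not in VALID_BASES:
            continue
        counts[ca] += 1
        counts[cb] += 1
        if ca == cb:
            identical += 1
        elif {ca, cb} <= PURINES:
            ts_ag += 1
        elif {ca, cb} <= PYRIMIDINES:
            ts_ct += 1
        else:
            tv += 1
    usable = identical + ts_ag + ts_ct + tv
    if usable == 0:
        raise NoUsableSitesError("no usable (jointly unambiguous) sites in pair")
    return SitePatternCounts(
        usable=usable,
        identical=identical,
        transitions_ag=ts_ag,
        transitions_ct=ts_ct,
        transversions=tv,
        base_counts=counts,
    )


def _jc69(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        raise SaturationError(f"JC69 saturated at p-distance {p:.4f}")
    return -0.75 * math.log(arg)


def _tn93_from_counts(
    counts: SitePatternCounts, freqs: dict[str, float] | None = None
) -> float:
    """TN93 closed form from observed pattern proportions and base frequencies."""
    if freqs is None:
        freqs = counts.frequencies()
    pi_a, pi_c, pi_g, pi_t = (freqs[b] for b in "ACGT")
    g_r, g_y = pi_a + pi_g, pi_c + pi_t
    kap_r, kap_y = pi_a * pi_g, pi_c * pi_t
    p1 = counts.transitions_ag / counts.usable
    p2 = counts.transitions_ct / counts.usable
    q = counts.transversions / counts.usable
    if (kap_r == 0 and p1 > 0) or (kap_y == 0 and p2 > 0):
        raise SaturationError("degenerate base composition for observed transitions")
    terms = 0.0
    if kap_r > 0:
        w1 = 1.0 - g_r * p1 / (2.0 * kap_r) - q / (2.0 * g_r)
        if w1 <= 0:
            raise SaturationError("TN93 purine-transition term saturated")
        terms -= (2.0 * kap_r / g_r) * math.log(w1)
    if kap_y > 0:
        w2 = 1.0 - g_y * p2 / (2.0 * kap_y) - q / (2.0 * g_y)
        if w2 <= 0:
            raise SaturationError("TN93 pyrimidine-transition term saturated")
        terms -= (2.0 * kap_y / g_y) * math.log(w2)
    w3 = 1.0 - q / (2.0 * g_r * g_y)
    if w3 <= 0:
        raise SaturationError("TN93 transversion term saturated")
    coef3 = 2.0 * (g_r * g_y - (kap_r * g_y / g_r if g_r > 0 else 0.0)
                   - (kap_y * g_r / g_y if g_y > 0 else 0.0))
    terms -= coef3 * math.log(w3)
    return terms


def distance(a: str, b: str, model: DistanceModel = "jc69",
             mask: np.ndarray | None = None) -> float:
    """Pairwise distance between two aligned sequences under a named model."""
    counts = site_pattern_counts(a, b, mask=mask)
    if model == "p":
        return counts.p_distance
    if model == "jc69":
        return _jc69(counts.p_distance)
    if model == "tn93":
        return _tn93_from_counts(counts)
    raise ValueError(f"unknown model: {model!r}")


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances keyed by sequence id.

    Saturated pairs are stored as NaN with the corresponding entry of
    ``saturated`` set, never as infinities.
    """

    ids: list[str]
    values: np.ndarray
    saturated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if self.saturated is None:
            self.saturated = np.isnan(self.values)
        finite = self.values[~np.isnan(self.values)]
        if np.any(finite < -1e-12):
            raise ValueError("negative distance")
        if not np.allclose(np.nan_to_num(self.values),
                           np.nan_to_num(self.values.T)):
            raise ValueError("distance matrix is not symmetric")

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.6f")

    def to_phylip(self, path: str | Path) -> None:
        """Lower-triangle PHYLIP-style text (distances to 6 d.p.)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{self.values[i, j]:.6f}" for j in range(i))
                fh.write(f"{name:<12s} {row}".rstrip() + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(dtype=float))


def pairwise_distance_matrix(
    seqs: AlignedSequenceSet,
    model: DistanceModel = "jc69",
    deletion: DeletionPolicy = "pairwise",
) -> DistanceMatrix:
    """All-pairs distance matrix under a closed-form model."""
    mask = complete_deletion_mask(seqs) if deletion == "complete" else None
    n = len(seqs)
    values = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = distance(seqs.sequences[i], seqs.sequences[j], model, mask=mask)
            except SaturationError:
                d = np.nan
                saturated[i, j] = saturated[j, i] = True
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=list(seqs.ids), values=values, saturated=saturated)


def pairwise_difference_matrix(
    seqs: AlignedSequenceSet, deletion: DeletionPolicy = "pairwise"
) -> DistanceMatrix:
    """Matrix of raw nucleotide difference counts (AMOVA's haplotypic metric)."""
    mask = complete_deletion_mask(seqs) if deletion == "complete" else None
    n = len(seqs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = site_pattern_counts(seqs.sequences[i], seqs.sequences[j], mask=mask)
            values[i, j] = values[j, i] = c.mismatches
    return DistanceMatrix(ids=list(seqs.ids), values=values)


# --- composite-likelihood (pooled-parameter TN93) distances -----------------


def _pooled_parameters(counts_list: list[SitePatternCounts]):
    """Shared TN93 parameters (frequencies + the two transition/transversion
    rate ratios) from pattern counts pooled over all pairs."""
    base = {b: sum(c.base_counts[b] for c in counts_list) for b in "ACGT"}
    total = sum(base.values())
    freqs = {b: base[b] / total for b in "ACGT"}
    usable = sum(c.usable for c in counts_list)
    p1 = sum(c.transitions_ag for c in counts_list) / usable
    p2 = sum(c.transitions_ct for c in counts_list) / usable
    q = sum(c.transversions for c in counts_list) / usable

    pi_a, pi_c, pi_g, pi_t = (freqs[b] for b in "ACGT")
    g_r, g_y = pi_a + pi_g, pi_c + pi_t
    kap_r, kap_y = pi_a * pi_g, pi_c * pi_t
    # invert the TN93 expectation at the pooled counts: u = beta*t for the
    # pooled pseudo-pair, then kappa_i = alpha_i/beta from the transition terms
    w3 = 1.0 - q / (2.0 * g_r * g_y)
    if w3 <= 0:
        raise SaturationError("pooled transversion fraction saturated")
    u = -math.log(w3)
    if u == 0.0:
        # no transversions pooled; fall back to equal-rate ratios scaled by
        # transition load (degenerate but well-defined)
        return freqs, 1.0, 1.0
    k1 = k2 = 1.0
    if kap_r > 0:
        w1 = 1.0 - g_r * p1 / (2.0 * kap_r) - q / (2.0 * g_r)
        if w1 <= 0:
            raise SaturationError("pooled purine-transition fraction saturated")
        k1 = max((-math.log(w1) / u - g_y) / g_r, 1e-6)
    if kap_y > 0:
        w2 = 1.0 - g_y * p2 / (2.0 * kap_y) - q / (2.0 * g_y)
        if w2 <= 0:
            raise SaturationError("pooled pyrimidine-transition fraction saturated")
        k2 = max((-math.log(w2) / u - g_r) / g_y, 1e-6)
    return freqs, k1, k2


def _tn93_expected_pattern(u: float, freqs: dict[str, float], k1: float, k2: float):
    """Expected (P1, P2, Q) pattern proportions at scaled time u = beta*t."""
    pi_a, pi_c, pi_g, pi_t = (freqs[b] for b in "ACGT")
    g_r, g_y = pi_a + pi_g, pi_c + pi_t
    e_u = math.exp(-u)
    q = 2.0 * g_r * g_y * (1.0 - e_u)
    p1 = p2 = 0.0
    if pi_a * pi_g > 0:
        p1 = (2.0 * pi_a * pi_g / g_r) * (
            g_r + g_y * e_u - math.exp(-(g_r * k1 + g_y) * u)
        )
    if pi_c * pi_t > 0:
        p2 = (2.0 * pi_c * pi_t / g_y) * (
            g_y + g_r * e_u - math.exp(-(g_y * k2 + g_r) * u)
        )
    return p1, p2, q


def _fit_pair_distance(
    counts: SitePatternCounts, freqs: dict[str, float], k1: float, k2: float
) -> float:
    """ML branch length for one pair with rate ratios and frequencies fixed."""
    if counts.mismatches == 0:
        return 0.0
    n1, n2, nq = counts.transitions_ag, counts.transitions_ct, counts.transversions
    n_same = counts.identical

    def neg_loglik(u: float) -> float:
        p1, p2, q = _tn93_expected_pattern(u, freqs, k1, k2)
        same = 1.0 - p1 - p2 - q
        ll = 0.0
        for n_obs, prob in ((n1, p1), (n2, p2), (nq, q), (n_same, same)):
            if n_obs:
                if prob <= 0:
                    return 1e12
                ll += n_obs * math.log(prob)
        return -ll

    res = minimize_scalar(
        neg_loglik, bounds=(1e-10, 20.0), method="bounded",
        options={"xatol": 1e-12},
    )
    u = float(res.x)
    if neg_loglik(u) >= 1e11:
        raise SaturationError("composite-likelihood fit saturated")
    pi_a, pi_c, pi_g, pi_t = (freqs[b] for b in "ACGT")
    g_r, g_y = pi_a + pi_g, pi_c + pi_t
    return 2.0 * u * (pi_a * pi_g * k1 + pi_c * pi_t * k2 + g_r * g_y)


def mcl_distances(
    seqs: AlignedSequenceSet, deletion: DeletionPolicy = "pairwise"
) -> DistanceMatrix:
    """Composite-likelihood TN93 distances with parameters pooled over all pairs.

    Substitution-rate ratios (purine and pyrimidine transitions vs.
    transversions) and base frequencies are estimated once from the pooled
    site-pattern counts; each pair's distance then comes from its own counts
    under those shared parameters.  With two sequences this reproduces the
    plain TN93 estimate.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    mask = complete_deletion_mask(seqs) if deletion == "complete" else None
    n = len(seqs)
    pair_counts: dict[tuple[int, int], SitePatternCounts] = {}
    for i in range(n):
        for j in range(i + 1, n):
            pair_counts[(i, j)] = site_pattern_counts(
                seqs.sequences[i], seqs.sequences[j], mask=mask
            )
    if all(c.mismatches == 0 for c in pair_counts.values()):
        warnings.warn("no variation among sequences; distance matrix is all zero")
        return DistanceMatrix(ids=list(seqs.ids), values=np.zeros((n, n)))
    freqs, k1, k2 = _pooled_parameters(list(pair_counts.values()))
    values = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    for (i, j), c in pair_counts.items():
        try:
            d = _fit_pair_distance(c, freqs, k1, k2)
        except SaturationError:
            d = np.nan
            saturated[i, j] = saturated[j, i] = True
        values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=list(seqs.ids), values=values, saturated=saturated)


# --- group summaries --------------------------------------------------------


@dataclass
class GroupDistanceSummary:
    """Min/mean/max of pairwise distances per unordered group pair.

    ``table`` has one row per unordered group pair (including the diagonal),
    with columns group_a, group_b, n_pairs, min, mean, max; within-group
    rows for singleton groups have n_pairs = 0 and NaN summaries (flagged
    empty).  ``within_max`` maps each group to its maximum within-group
    distance (NaN for singletons).
    """

    table: pd.DataFrame
    within_max: dict[str, float]


def group_summary(dm: DistanceMatrix, groups: dict[str, str]) -> GroupDistanceSummary:
    """Summarise a distance matrix over unordered pairs by group labels."""
    missing = [i for i in dm.ids if i not in groups]
    if missing:
        raise ValueError(f"unlabeled ids: {missing}")
    labels = sorted(set(groups[i] for i in dm.ids))
    cells: dict[tuple[str, str], list[float]] = {}
    for i in range(len(dm.ids)):
        for j in range(i + 1, len(dm.ids)):
            ga, gb = sorted((groups[dm.ids[i]], groups[dm.ids[j]]))
            cells.setdefault((ga, gb), []).append(dm.values[i, j])
    rows = []
    for a_idx, ga in enumerate(labels):
        for gb in labels[a_idx:]:
            vals = np.array(cells.get((ga, gb), []), dtype=float)
            vals = vals[~np.isnan(vals)]
            if len(vals):
                rows.append(
                    dict(group_a=ga, group_b=gb, n_pairs=len(vals),
                         min=vals.min(), mean=vals.mean(), max=vals.max())
                )
            else:
                rows.append(
                    dict(group_a=ga, group_b=gb, n_pairs=0,
                         min=np.nan, mean=np.nan, max=np.nan)
                )
    table = pd.DataFrame(rows)
    within_max = {
        g: float(
            table.query("group_a == @g and group_b == @g")["max"].iloc[0]
        )
        for g in labels
    }
    return GroupDistanceSummary(table=table, within_max=within_max)
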