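"""Seeded generators with known ground truth for every analysis stage.

Three generators emulate the three kinds of experimental data the
analyses consume:

* ``gen_spore_counts`` — per-fruiting-body labelled/unlabelled spore
  counts for a reciprocal mix.  Control bodies draw labelled spores
  Binomial(n, 0.5); experimental bodies first draw a latent labelled
  fraction q ~ Beta(a, a) and then Binomial(n, q).  The Beta(a, a)
  mixture spans complete mixing (a -> inf) to complete sorting (a -> 0)
  and has a closed-form expected relatedness,
  E[r_hat] = 1 - (1 - 1/n) * a / (2a + 1),
  which parameter-recovery tests check.

* ``gen_structured_sequences`` — a star phylogeny: a random ancestral
  sequence, population ancestors mutated per site with probability
  p_between, individuals mutated from their population ancestor with
  probability p_within.  p_between = 0 gives zero expected
  among-population variance.

* ``gen_mating_roster`` — k latent mating types; every unordered pair
  (including selfs) is tested n_replicates times, the true outcome is
  positive iff types differ, and replicate-level false positives and
  negatives are injected at configured rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mating import MatingObservation
from .seq import AlignedSequenceSet, CloneMetadata
from .sorting import FruitingBodyRecord, SortingExperiment, TREATMENTS

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SporeGenConfig:
    """Spore-count generator settings.

    ``sorting_strength`` is the Beta shape a: small a concentrates the
    latent clone fraction near 0/1 (strong sorting); ``math.inf`` is the
    pure-mixing mode (latent fraction pinned at 0.5) and 0.0 the
    hard-sorting mode (latent fraction 0 or 1 with equal probability).
    """

    n_fb_per_treatment: int = 30
    spores_per_fb: int = 100
    sorting_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fb_per_treatment < 2:
            raise ValueError("need >= 2 fruiting bodies per treatment")
        if self.spores_per_fb < 1:
            raise ValueError("spores_per_fb must be >= 1")
        if not (self.sorting_strength >= 0):
            raise ValueError("sorting_strength must be >= 0 (inf allowed)")

    @property
    def expected_relatedness(self) -> float:
        """Closed-form E[r_hat] for experimental fruiting bodies."""
        n, a = self.spores_per_fb, self.sorting_strength
        if math.isinf(a):
            return 1.0 - (1.0 - 1.0 / n) * 0.5
        if a == 0.0:
            return 1.0
        return 1.0 - (1.0 - 1.0 / n) * a / (2.0 * a + 1.0)


def gen_spore_counts(cfg: SporeGenConfig) -> SortingExperiment:
    """Simulate one reciprocal pairwise mix (4 treatments)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.spores_per_fb
    records: list[FruitingBodyRecord] = []
    for treatment in TREATMENTS:
        control = treatment.startswith("ctrl")
        for k in range(cfg.n_fb_per_treatment):
            if control or math.isinf(cfg.sorting_strength):
                q = 0.5
            elif cfg.sorting_strength == 0.0:
                q = float(rng.integers(0, 2))
            else:
                q = float(rng.beta(cfg.sorting_strength, cfg.sorting_strength))
            labeled = int(rng.binomial(n, q))
            records.append(
                FruitingBodyRecord(
                    fb_id=f"{treatment}_fb{k + 1}",
                    treatment=treatment,
                    n_labeled=labeled,
                    n_unlabeled=n - labeled,
                )
            )
    return SortingExperiment(
        mix_id=f"synthetic_a{cfg.sorting_strength}_seed{cfg.seed}",
        clone_a="cloneA", clone_b="cloneB", records=records,
    )


@dataclass(frozen=True)
class SeqGenConfig:
    """Structured-sequence generator settings (star phylogeny)."""

    n_pops: int = 2
    n_per_pop: int = 5
    n_sites: int = 500
    p_between: float = 0.02
    p_within: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.n_per_pop < 1 or self.n_sites < 1:
            raise ValueError("counts must be positive")
        for p in (self.p_between, self.p_within):
            if not 0.0 <= p < 1.0:
                raise ValueError("substitution probabilities must be in [0, 1)")


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < p)
    for k in hits:
        choices = [b for b in "ACGT" if b != out[k]]
        out[k] = choices[rng.integers(0, 3)]
    return out


def gen_structured_sequences(cfg: SeqGenConfig) -> AlignedSequenceSet:
    """Simulate aligned sequences for n_pops populations with known structure."""
    rng = np.random.default_rng(cfg.seed)
    ancestor = _BASES[rng.integers(0, 4, size=cfg.n_sites)]
    ids: list[str] = []
    seqs: list[str] = []
    metadata: dict[str, CloneMetadata] = {}
    for p in range(cfg.n_pops):
        pop_name = f"pop{p + 1}"
        pop_ancestor = _mutate(ancestor, cfg.p_between, rng)
        for k in range(cfg.n_per_pop):
            name = f"{pop_name}_ind{k + 1}"
            ids.append(name)
            seqs.append("".join(_mutate(pop_ancestor, cfg.p_within, rng)))
            metadata[name] = CloneMetadata(
                clone_id=name, population=pop_name, group=None
            )
    return AlignedSequenceSet(ids=ids, sequences=seqs, metadata=metadata)


@dataclass(frozen=True)
class MatingGenConfig:
    """Mating-roster generator settings (k latent mating types)."""

    k_types: int = 2
    clones_per_type: tuple[int, ...] = (2, 23)
    false_negative_rate: float = 0.0
    false_positive_rate: float = 0.0
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_types < 1:
            raise ValueError("k_types must be >= 1")
        if len(self.clones_per_type) != self.k_types:
            raise ValueError("clones_per_type must list one size per type")
        for rate in (self.false_negative_rate, self.false_positive_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("noise rates must be in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def gen_mating_roster(
    cfg: MatingGenConfig,
) -> tuple[list[MatingObservation], dict[str, int]]:
    """Simulate a full pairwise mating roster; returns (observations, true types).

    Every unordered pair, self-pairings included, is tested n_replicates
    times; the true outcome is macrocyst-positive iff mating types differ,
    then per-replicate flips are applied at the configured noise rates.
    """
    rng = np.random.default_rng(cfg.seed)
    clones: list[str] = []
    true_type: dict[str, int] = {}
    for t, size in enumerate(cfg.clones_per_type):
        for k in range(size):
            name = f"t{t + 1}c{k + 1}"
            clones.append(name)
            true_type[name] = t
    observations: list[MatingObservation] = []
    for i, a in enumerate(clones):
        for b in clones[i:]:
            truly_positive = true_type[a] != true_type[b]
            for rep in range(1, cfg.n_replicates + 1):
                positive = truly_positive
                if truly_positive and rng.random() < cfg.false_negative_rate:
                    positive = False
                elif not truly_positive and rng.random() < cfg.false_positive_rate:
                    positive = True
                observations.append(
                    MatingObservation(
                        clone_a=a, clone_b=b, replicate=rep,
                        outcome="macrocysts" if positive else "none",
                    )
                )
    return observations, true_type
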