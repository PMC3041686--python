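# sporesort

Statistics for kin discrimination and cryptic population structure in
social amoebae (Dictyostelia). When starving amoebae aggregate, cells
that join a chimeric fruiting body risk dying as sterile stalk for
non-relatives; clones can instead *sort* into near-clonal fruiting
bodies. `sporesort` implements the analyses needed to quantify that
behaviour and relate it to genetic structure:

* **Sorting / kin discrimination** — per-fruiting-body relatedness
  `r = p² + q²` (p = labelled spore fraction, q = 1 − p; 0.5 = complete
  mixing, 1 = complete sorting), treatment means ± SE, and a one-tailed
  permutation test on the variance ratio
  `F = var(experimental) / var(control)` with proportions resampled
  without replacement across treatments (5000 resamples by default).
* **Haplotypes** — collapse an aligned rDNA multi-FASTA into unique
  haplotypes, strictly or ignoring gap/N columns.
* **Distances** — p, JC69 and TN93 pairwise distances (substitutions per
  site), a composite-likelihood TN93 variant with rate parameters and
  base frequencies pooled across all pairs, and within/between-group
  distance summaries.
* **AMOVA** — two-level analysis of molecular variance
  (among/within populations), Φ_ST, and a label-permutation significance
  test (1023 permutations by default).
* **Mating types** — majority-rule aggregation of replicated macrocyst
  assays, group×group compatibility tables, and mating-type inference by
  2-colouring the compatibility graph (odd cycles such as mutually
  compatible triads indicate more than two types).
* **Synthetic data** — seeded generators with known ground truth for all
  of the above, so every stage is testable end to end.

See `docs/methods.md` for the models, assumptions and design choices.

## Worked example

Simulate one mixing experiment with strong sorting (Beta shape a = 0.2)
and test it:

```python
from sporesort import gen_spore_counts, sorting_permutation_test
from sporesort.synthetic import SporeGenConfig

cfg = SporeGenConfig(n_fb_per_treatment=30, spores_per_fb=100,
                     sorting_strength=0.2, seed=1)
exp = gen_spore_counts(cfg)
res = sorting_permutation_test(exp, n_resamples=5000, seed=2)
print(f"mean r (experimental) = {res.mean_r_experimental:.3f} "
      f"± {res.se_r_experimental:.3f}")
print(f"mean r (control)      = {res.mean_r_control:.3f}")
print(f"F = {res.f_ratio:.1f}, p = {res.p_value:.4g}")
```

prints

```
mean r (experimental) = 0.839 ± 0.024
mean r (control)      = 0.504
F = 80.2, p = 0.0002
```

Experimental fruiting bodies are far more clonal than the 50:50 controls
(mean r 0.84 vs 0.51 — the generator's closed form predicts
E[r̂] = 1 − 0.99·(0.2/1.4) ≈ 0.86 at this sorting strength), the
experimental variance is ~80× the control variance, and no resampled
dataset reached the observed ratio (p = 1/5001 ≈ 2·10⁻⁴): strong
sorting.

The same analyses are available from the shell:

```sh
sporesort simulate --kind sequences --seed 5 --out sim/
sporesort amova --input sim/sequences.fasta --metadata sim/metadata.tsv \
    --n-perm 1023 --seed 2 --out amova_out/
sporesort haplotypes --input sim/sequences.fasta --out haps/
sporesort distances --input sim/sequences.fasta --model mcl --out dist/
```

Every subcommand writes TSV/JSON artifacts plus a `run_log.json` with the
package version, parameters and seed; identical configuration reproduces
identical output.

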