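# avmnet

Lesion-aware connectome analysis of cognitive impairment in unruptured brain
arteriovenous malformations (bAVM).

Cognitive deficits in unruptured bAVM correlate poorly with how much tissue
the lesion destroys. The alternative hypothesis is a *disconnection
syndrome*: the lesion interrupts long-range white-matter pathways, and
cognition tracks the integrity of the remaining structural network rather
than lesion volume. `avmnet` implements the full analysis needed to test
that hypothesis on parcel-level connectomes, for neuroimaging researchers
working with structural (tractography-derived) and functional (BOLD
correlation) connectivity matrices:

- **Network construction** — Pearson FC from time series; SC from
  SIFT2-weighted streamline counts with inverse-node-volume normalization
  `SC[i,j] = counts[i,j] / (vol_i + vol_j)`; exclusion of parcels with
  ≥ 50% lesion overlap; proportional thresholding with deterministic
  tie-breaking.
- **Graph topology** — weighted global efficiency
  `E = mean_{i≠j} 1/d_ij` with `d` from Dijkstra over lengths `1/w`
  (disconnected pairs contribute 0), Onnela weighted clustering,
  strength/degree ranks, and virtual-lesion resilience against a
  random-node-removal null.
- **Structure–function coupling** — per-node Spearman ρ between the SC and
  FC connectivity profiles (self-connections excluded), summarized by
  canonical network.
- **Network Diffusion Model (NDM)** — pathology spread
  `x(t) = e^{−βLt} x₀` on the symmetric normalized Laplacian
  `L = I − D^{−1/2} A D^{−1/2}`; every parcel is swept as seed and the
  *epicenter* is the seed whose diffusion pattern best correlates with the
  empirical morphometry t-map.
- **Inference** — Welch t, Yates-corrected χ², Mann–Whitney U,
  Shapiro–Wilk, OLS and Huber-robust regression (IRLS, c = 1.345),
  Benjamini–Hochberg FDR, edgewise Fisher-z FC comparison, per-parcel
  morphometry t-maps, and a sparsity/lesion-cutoff sensitivity sweep.
- **Synthetic cohort generator** — since patient MRI of this kind is not
  publicly deposited, a seeded generator produces datasets with the
  statistical structure the analysis assumes (hub-bearing distance-decay SC,
  FC coupled to SC with tunable strength γ, contiguous lesions on a toy
  voxel atlas, forward-diffused atrophy, and cognition driven by white-matter
  integrity rather than lesion volume), so the whole pipeline is testable
  end-to-end offline.

## Worked example

```python
import numpy as np
import avmnet as av

cfg = av.SynthConfig(n_nodes=90, n_patients=20, n_controls=20, rng_seed=7)
cohort = av.gen_cohort(cfg)
sc = cohort.truth["template"]

# forward-simulate a deformation map from parcel 30, then recover it
atrophy = av.gen_atrophy_from_seed(sc, seed_parcel=30, t_star=2.5, noise_sd=0.1,
                                   rng=np.random.default_rng(0))
result = av.epicenter_sweep(sc, atrophy)
print(f"epicenter parcel: {result.epicenter}")
print(f"peak correlation: {result.r_max:.3f} at t = {result.t_opt:g}")

vl = av.virtual_lesion(sc, result.epicenter, n_null=1000,
                       rng=np.random.default_rng(1))
print(f"virtual lesion: dE = {vl.delta_pct:.2f}% (p = {vl.p_value:.3f})")
ranks, _ = av.node_strength_rank(sc)
print(f"epicenter strength rank: {ranks[result.epicenter - 1]}/90")
```

Output:

```
epicenter parcel: 30
peak correlation: 0.995 at t = 2.55
virtual lesion: dE = 0.34% (p = 0.308)
epicenter strength rank: 27/90
```

The sweep recovers the true seed (parcel 30) at essentially the planted
diffusion time despite 10% observation noise; removing that epicenter
barely dents global efficiency and is indistinguishable from removing a
random node (p ≈ 0.3) — the epicenter drives pathological spread without
being a topological hub, the signature dissociation this analysis is built
to detect.

The full pipeline (synthesis → network construction → topology → coupling →
NDM → statistics) runs from one config:

```bash
avmnet run --out results/ --seed 7          # or: avmnet run --config cfg.yaml
avmnet synth --seed 1 --out-dir data/       # just the synthetic dataset
```

`results/report.json` is bit-reproducible under a fixed seed.

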