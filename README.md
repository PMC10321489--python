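# paramotif

Paralog-aware network-motif analysis for gene regulatory networks (GRNs)
and protein–protein interaction (PPI) networks, with the supporting
statistics for studying how duplicated genes diverge after whole-genome
duplication (WGD) and small-scale duplication (SSD).

After a genome duplicates, the retained duplicate pairs sit inside
regulatory and physical-interaction networks, and their fate — redundancy,
sub-/neofunctionalization, loss — leaves a measurable footprint in small
recurring subgraphs. `paramotif` detects the five motif types licensed by a
paralogous gene pair:

| motif  | topology |
|--------|----------|
| V      | paralogous regulators T1, T2 share a target g |
| PPI V  | paralogous proteins p1, p2 share an interaction partner x |
| lambda | paralogous targets g1, g2 share a regulator T |
| delta  | a V whose regulators T1, T2 additionally interact physically |
| bifan  | paralogous regulators T1, T2 regulate the same (paralogous) target pair g1, g2 |

and provides the surrounding analysis chain:

- **Significance**: degree-preserving null networks by node-label
  permutation (1000 by default); per-stratum Z = (N_obs − μ_null)/σ_null,
  with Z ≥ 2 called significant.
- **Age groups**: Gaussian-mixture fitting of the Ks (synonymous
  substitutions per site) distribution with a user-fixed number of peaks;
  each peak's age group is the interval mean ± 2σ, and WGD-vs-SSD contrasts
  are made within age groups.
- **Divergence**: saturating Michaelis–Menten fits
  Ka = Vmax·Ks/(Km + Ks) of nonsynonymous vs synonymous divergence.
- **Interaction similarity**: Sørensen–Dice index
  S(A, B) = 2|A∩B| / (|A| + |B|) over the partner sets of a pair.
- **Topology**: scale-free-topology fit (R² of the log–log degree
  regression), quantile-threshold GRN filtering (20 nested subnetworks,
  keep the largest with R² > 0.75), Mann–Whitney U degree comparisons with
  rank-biserial effect sizes.
- **Enrichment**: Fisher's exact tests with Benjamini–Hochberg correction.
- **Synthetic data**: generators for all of the above with exported ground
  truth, including node-disjoint motif planting with exact expected counts.

It is aimed at comparative/evolutionary genomicists who already have a GRN
edge list (e.g. from GENIE3-style inference), a PPI export (STRING-style),
and a classified duplicate-pair table (gene1, gene2, WGD/SSD, Ks, Ka);
producing those inputs is out of scope.

## Worked example

Generate a synthetic study, assign age groups from Ks peaks, and score
V-motif frequencies against 1000 permutation nulls:

```python
from paramotif import (
    simulate_full_study, fit_ks_peaks, split_pairs_by_peak,
    generate_nulls, calculate_z, fit_mm_divergence, sd_similarity,
)
from paramotif.motifs import find_v, count_motifs

study = simulate_full_study(seed=1)
grn, ppi, pairs = study["grn"], study["ppi"], study["pairs"]

peaks = fit_ks_peaks(pairs, n_peaks=2, seed=1)
aged = split_pairs_by_peak(pairs, peaks)

obs = count_motifs(find_v(grn, aged), aged)
nulls = generate_nulls(grn, ppi, aged, n_permutations=1000, seed=2,
                       motif_types=("V",))
print(calculate_z(obs, nulls))
```

The fitted peaks land on the two duplication waves built into the
simulation (`peak 1: mean=0.148 sd=0.048`, `peak 2: mean=1.099 sd=0.192`),
so age group 1 collects recent duplicates (Ks ≈ 0.05–0.25) and group 2
ancient ones (Ks ≈ 0.7–1.5). The Z table for WGD pairs then reads:

```
motif_type mode  age_group  observed  null_mean  null_sd     z  significant
         V  WGD          1        50       1.68     1.56 30.95         True
         V  WGD          2        14       0.58     0.95 14.20         True
```

Both strata hold far more V motifs than degree-matched chance (Z ≥ 2), and
the recent group scores higher than the ancient one — motifs decay with
age. The divergence and similarity contrasts recover the other planted
effects:

```python
fit_mm_divergence(aged, "WGD").vmax   # 0.307
fit_mm_divergence(aged, "SSD").vmax   # 0.510
sd_similarity(ppi, aged).groupby("mode")["similarity"].median()
# SSD 0.133 / WGD 0.533
```

i.e. WGD pairs diverge toward a lower Ka asymptote and keep a much larger
fraction of shared interaction partners than SSD pairs.

The same chain is available as a CLI (`paramotif --help`): `simulate`,
`filter-grn`, `find-motifs`, `motif-zscores`, `ks-peaks`, `mm-fit`,
`similarity`, `degree-compare`, `enrich`.

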