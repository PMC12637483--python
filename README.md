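# loopquant

Quantification of induced chromatin looping from single-allele FISH imaging,
for labs using optogenetic locus-tethering tools (e.g. dCas9 fused to a
blue-light oligomerizer) together with high-throughput DNA/RNA-FISH.

The package takes the tabular output of an imaging segmentation pipeline —
one row per nucleus (area, solidity, nuclear intensities) and one row per
FISH spot (channel, centroid in μm, intensity) — and turns it into
single-allele locus distances, DNA-contact calls, per-cell transcription
metrics, and population statistics. It also covers the upstream imaging
metrics (protein-clustering CV and its kinetics, phase-correlation
registration of sequential imaging rounds) and ships a synthetic-data
generator with known ground truth so the whole chain is testable end to end.

## What it computes

**Clustering metrics.** Protein clustering in a nucleus is summarized by the
coefficient of variation CV = σ/μ of masked nuclear pixel intensities
(population σ). Around a light pulse at t = 0, the CV(t) series yields the
half-maximal clustering time t_c (linear interpolation to halfway between
CV(0) and max CV) and the declustering time t_d (time to fall back to that
level, measured from the maximum). Concentration dependence is summarized by
a 3-parameter logistic fit CV(I) = CV_max / (1 + e^(−k(log I − log I₀))).

**Registration.** Sequential RNA-FISH / DNA-FISH rounds are aligned per
field by an integer-pixel translation from Fourier phase correlation of the
nuclear-stain images; the shift is propagated to spot coordinates.

**Single-allele quantification.** Nuclei pass QC (area ≥ 90 μm² for
U2OS-like cells, 50 for HeLa-like; solidity ≥ 0.9) and a ploidy filter
(exactly n spots per DNA channel). Cross-channel spots are matched
one-to-one greedily in ascending distance; matched pairs under 2 μm are the
single-allele distances, and pairs under 0.27 μm are DNA contacts. Per-cell
summaries carry the fraction of close alleles, nascent-RNA transcription
site counts/intensities, and nuclear GFP intensity, with equal-count
binning by contact fraction (cells with zero contacts form their own bin
"0") or by expression.

**Allele-independence statistics.** Per condition, the observed distribution
of cells with c = 0..n close alleles is compared with the binomial null
f(c) = C(n,c)·p_c^c·(1−p_c)^(n−c) at the pooled close-allele frequency p_c,
via a Pearson chi-square test; pairwise condition contrasts of contact
fractions use the Marascuilo multiple-proportion procedure.

## Worked example

```python
import loopquant as lq
from loopquant import quant

sim = lq.SimulationConfig(n_cells=2000, ploidy=2, p_loop=0.25,
                          rna_p_on=0.4, repression_effect=0.6, seed=1)
nuclei, spots, truth = lq.generate_fish_dataset(sim, condition="light")

cfg = lq.AnalysisConfig(ploidy=2)
kept, _ = quant.qc_filter_nuclei(nuclei, cfg)
kept, _ = quant.ploidy_filter(kept, spots, cfg)
pairs = quant.attach_condition(quant.match_all_nuclei(kept, spots, cfg), kept)
print(lq.condition_contact_fraction(pairs))

cells = quant.summarize_cells(kept, pairs, spots[spots.channel == "rna"])
dist = lq.observed_distribution(cells[cells.n_pairs == 2], 2)
res = lq.independence_test(dist, fitted_params=1)
print(f"p_c={dist.pooled_p_c:.4f} counts={dist.counts.tolist()} "
      f"chi2={res.statistic:.2f} p={res.pvalue:.3g}")
```

prints

```
  condition  fraction  n_contacts  n_alleles
0     light  0.316613        1174       3708
p_c=0.3161 counts=[861, 799, 183] chi2=0.01 p=0.905
```

The contact fraction (~0.32) matches the configured mixture: 25% of alleles
are looped (half-normal separation, nearly always < 0.27 μm) and ~9.6% of
the free Rayleigh-distributed pairs also fall under the threshold. With
independent alleles (no coupling configured), the observed 0/1/2-close-allele
counts are binomial and the chi-square test is, correctly, not significant.

The same flow is available from the shell:

```bash
loopquant simulate --seed 1 --out-dir sim/
loopquant run --config run.yaml --out-dir results/
```

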