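# nucleoflex

Sequence-dependent physical properties of naked DNA — stiffness and the
harmonic cost of wrapping it around a histone core — shape where
nucleosomes sit, and micrococcal nuclease (MNase) digestion reads those
properties out experimentally. `nucleoflex` is a toolkit for the joint
analysis of the two views in yeast-scale genomes:

* **physics** — per-step elastic model of DNA. Each base-pair step is
  described by six helical parameters *(shift, slide, rise, tilt, roll,
  twist)* with a sequence-dependent equilibrium μ and a 6×6 stiffness
  matrix Θ = kT·C⁻¹ obtained by inverting the helical-parameter
  covariance C of a conformational ensemble. From these the package
  computes k_total profiles (the product of the six pure stiffness
  constants, a scalar flexibility summary) and the nucleosome
  deformation energy of every 147 bp window,
  E = Σₛ ½ (xₛ−μₛ)ᵀ Θₛ (xₛ−μₛ), where xₛ is the target wrapped
  conformation at step s. High-energy runs are predicted
  nucleosome-depleted regions, low-energy runs nucleosome-enriched.
* **mnase** — mapped-read handling: r.p.m. coverage, PCR-duplicate
  capping, cut-site tetramer extraction (the 4-mer spanning each
  fragment 5′ end, collapsed with its reverse complement into 136
  canonical pairs) and binomial enrichment statistics over the genomic
  4-mer background.
* **regions** — low-coverage regions (LRs), common low regions (CLRs),
  naked-DNA bias correction of nucleosomal coverage, FFT low-pass
  smoothing, nucleosome calling (peaks ± 73/74 bp) and
  well-positioned/fuzzy classification.
* **aggregate** — strand-aware metagene profiles around TSS/TTS anchors
  or region midpoints, with 0–1 scaling.
* **synth** — a fully deterministic generator of synthetic genomes
  (genes, poly(dA:dT) NDR cassettes, phased and delocalized nucleosome
  arrays) and a sequence-biased digestion simulator that emits
  BED-formatted 54 bp single-end reads for naked and chromatin samples
  together with complete ground truth — every analysis above is tested
  against it.

Coordinates are 0-based half-open everywhere inside the package; BED and
bedGraph are native, GFF3 is converted at the boundary.

## Worked example

Simulate a chromatin MNase experiment at the default study conditions,
call nucleosomes, and predict depleted regions from deformation energy
alone:

```python
import numpy as np
from nucleoflex import (SimConfig, NucleosomeShape, load_dinucleotide_table,
                        energy_profile, predict_regions)
from nucleoflex import mnase, regions, synth

cfg = SimConfig(seed=1, n_fragments=200_000)
genome, truth = synth.generate_genome(cfg)
truth = synth.place_nucleosomes(genome, truth, cfg)
lengths = {c: len(s) for c, s in genome.items()}
reads, _ = synth.simulate_digestion(genome, cfg, truth.dyads, stage=3)

cov = mnase.rpm_normalize(mnase.build_coverage(
    mnase.extend_reads(reads, 147, lengths), lengths))
smoothed = regions.fft_smooth(cov.data)
calls = regions.classify_calls(regions.call_nucleosomes(smoothed),
                               smoothed=smoothed)
print(f"{len(calls)} nucleosome calls "
      f"({sum(c.cls == 'well-positioned' for c in calls)} well-positioned, "
      f"{sum(c.cls == 'fuzzy' for c in calls)} fuzzy)")

table = load_dinucleotide_table()
energy = energy_profile(genome, table, NucleosomeShape.ideal())
depleted, enriched = predict_regions(energy, depleted_quantile=0.8,
                                     enriched_quantile=0.1, min_len=50)
hits = sum(any(d.start < r.end and d.end > r.start for d in depleted)
           for r in truth.ndrs)
print(f"{len(depleted)} predicted depleted regions; "
      f"{hits}/{len(truth.ndrs)} planted NDRs recovered")
E = energy[cfg.chrom_name]
print(f"mean wrapping energy {np.nanmean(E):.1f} kcal/mol; "
      f"NDR windows {np.nanmean([np.nanmean(E[r.start:r.end]) for r in truth.ndrs]):.1f}")
```

prints

```
255 nucleosome calls (179 well-positioned, 76 fuzzy)
60 predicted depleted regions; 60/60 planted NDRs recovered
mean wrapping energy 130.2 kcal/mol; NDR windows 145.9
```

The 255 calls split into sharply phased genic nucleosomes (recovered as
well-positioned) and delocalized intergenic ones (fuzzy); every planted
poly(dA:dT) NDR tract overlaps a predicted high-energy depleted region —
the stiff A-tracts cost ~16 kcal/mol more to wrap than average sequence
under the packaged synthetic stiffness table, and that contrast alone
locates the nucleosome-free promoters.

The same pipeline is available from the shell:

```
nucleoflex simulate --seed 1 --outdir run/
nucleoflex enrich --reads run/reads_naked.bed --genome run/genome.fa --out enrich.tsv
nucleoflex nuccall --track run/coverage_nucleosomal.bedgraph --out calls.bed
nucleoflex run --config pipeline.yaml --outdir run/   # whole pipeline + manifest
```

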