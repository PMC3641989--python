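# dartmap

Linkage and consensus map construction for dominant presence/absence
markers (DArT-style) scored in doubled-haploid (DH) populations, with
sequence-redundancy classification and genetic-to-physical anchoring.
The package targets workflows like consensus mapping in amphidiploid
*Brassica napus* (genomes AACC, chromosomes A1–A10 and C1–C9), where
several biparental DH panels genotyped on a common clone array are
merged into one coordinate system.

## What it computes

**Component maps.** In a DH line a dominant marker segregates 1:1 and
the recombination fraction between two loci is estimated directly as
the discordant fraction of pairwise-complete lines, with the arbitrary
presence/absence phase resolved by `r = min(raw, 1 − raw)`. Mapping is
a three-step process:

1. *Grouping* — a complete graph over markers weighted by `r`; edges
   with `r` above a threshold (default 0.2) are removed and the
   connected components become linkage groups.
2. *Ordering* — the minimum-weight Hamiltonian path (travelling-
   salesman path) through each group under the Σ-adjacent-`r`
   objective: exact Held–Karp dynamic programming up to 12 markers,
   nearest-neighbour + 2-opt beyond (small instances are provably
   optimal against brute force in the test suite).
3. *Distances* — adjacent fractions converted to additive cM by the
   Kosambi function `d = 25·ln((1+2r)/(1−2r))` and accumulated from 0.

**Consensus map.** Starting from a seed (reference) map, each
remaining group on a chromosome is scored by its commonality with the
current consensus, `|corr| × ln(n_shared)` over shared-marker
positions (requiring ≥ 3 shared markers); the best group with
`|corr| > 0.5` is merged by piecewise-linear interpolation through the
shared markers, and the process repeats until no group qualifies.

**Everything around it**: quality filtering (Q > 77, call rate > 97,
reproducibility 100), χ² segregation tests against 1:1 with a 3:1/1:3
two-locus rescue at P < 0.01, co-segregating marker binning, map
summary statistics (lengths, densities, >10 cM gaps, redundancy,
clusters, duplicated loci, cross-map correlations), pairwise global
alignment identity with an 80% redundancy threshold, and physical
placement from 12-column tabular alignment hits with an E ≤ 1e−5
all-hits policy, colinearity (Spearman) and flanking-marker trait
intervals. A seeded simulator generates DH populations, clone
sequences and hit tables with the statistical structure the pipeline
assumes, so every stage is testable without external data.

## Worked example

```bash
dartmap simulate --seed 11 --n-chromosomes 3 --markers-per-chr 15 \
    --chr-length 50 --n-lines 150 --out-dir demo
dartmap qc --genotypes demo/genotypes.tsv --quality demo/quality.tsv --out-dir demo
dartmap map --genotypes demo/genotypes.qc.tsv --quality demo/quality.qc.tsv \
    --anchors demo/truth.tsv --population-id P1 --out demo/map.tsv
dartmap stats --map demo/map.tsv --out demo/stats.tsv
```

This prints, stage by stage:

```
wrote 45 markers x 150 lines
45 -> 38 markers after QC
4 groups, 38 markers -> demo/map.tsv
38 markers, 159.6 cM, mean interval 4.20 cM, 3 gaps
```

QC removes markers whose realised call rate falls below 97% and bins
co-segregating duplicates; the three simulated chromosomes come back
as four linkage groups because one chromosome splits at a weakly
linked gap (adjacent `r` above the 0.2 grouping threshold). The final
line gives the summed group spans, the mean inter-marker interval
(length/markers) and the number of adjacent gaps wider than 10 cM.

The same operations are available as a library:

```python
import dartmap as dm

truth = dm.simulate_truth_map(n_chromosomes=3, markers_per_chr=15, chr_length=50, seed=11)
mat = dm.simulate_dh_population(truth, dm.SimulationConfig(n_lines=150, seed=11))
cmap = dm.build_component_map(mat, "P1")
cmap = dm.assign_chromosomes(cmap, truth.to_frame())
```

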