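# Methods

## Genetic model

The pipeline assumes doubled-haploid (DH) lines from a biparental
cross: every line is fully homozygous, every informative marker is
biallelic, and a dominant presence/absence assay reports one bit per
line. Under Mendelian segregation a locus is present in half the
lines; the recombination fraction `r` between two loci is the
probability that a line is discordant at them, estimated as

    raw = (# pairwise-complete discordant lines) / n_informative
    r   = min(raw, 1 − raw)

The complement handles the arbitrary phase of presence/absence coding
(the assay does not know which parent carries the fragment); whether
complementing occurred is recorded as a `flipped` flag. An estimate is
treated as undefined for graph construction when fewer than
`min_informative = 20` lines are scored at both loci — the smallest
realistic panel (~71 lines) still clears this comfortably at moderate
missingness, while pairs scored on fewer lines carry too little
information to justify an edge.

## Component map construction

1. **Grouping.** Complete graph over markers, edge weight `r`; edges
   with `r > r_threshold` (default 0.2) or undefined estimates are
   dropped; connected components become linkage groups. Singleton
   components are held out rather than forced onto the map.
2. **Ordering.** Minimum-weight Hamiltonian path through each group
   under the Σ-adjacent-`r` objective. `r` is the native edge weight
   of the grouping graph, so the path objective stays in `r`-space;
   Kosambi conversion happens afterwards. Groups of ≤ 12 markers are
   solved exactly by Held–Karp dynamic programming; larger groups use
   nearest-neighbour construction from every start plus 2-opt
   refinement to a local optimum (implemented on a cycle with a
   zero-cost virtual depot so end-segment reversals are ordinary
   moves). Missing pairwise estimates inside a group are imputed at
   `r = 0.5`. Orders are canonicalised to the lexicographically
   smaller of the path and its reversal, making results deterministic.
3. **Distances.** Adjacent-pair fractions are converted by the Kosambi
   mapping function `d = 25·ln((1+2r)/(1−2r))` cM and accumulated from
   0. Adjacent fractions are capped at `r_cap = 0.4999` (a fraction at
   or above 0.5 has no finite map distance). Distances come from the
   direct pairwise estimates, not a multipoint likelihood — multipoint
   re-estimation is deliberately out of scope.

Chromosome labels come from anchor markers with known locations:
majority vote per group (ties stay unassigned), with the group
reversed when its positions correlate negatively with the anchor
positions.

## Consensus integration

The consensus starts as the seed (reference) map, one group per
chromosome. Per chromosome, every remaining candidate group is scored
by commonality = `|corr| × ln(n_common)` where `corr` is the Pearson
correlation between shared-marker positions on the group and on the
current consensus, defined only for `n_common ≥ 3` and non-degenerate
positions. The top-scoring group with `|corr| > 0.5` is merged: shared
markers define a piecewise-linear component→consensus transform
(coincident component anchors are averaged; beyond the terminal
anchors the nearest segment's slope extrapolates; a single surviving
anchor degenerates to a unit-slope translation), all non-shared
markers are mapped through it, and existing consensus positions never
move. Repeat until no group qualifies, then translate each chromosome
so its minimum position is 0.

Decisions taken where the procedure is conventionally underspecified:

- **log base**: natural. Any base rescales all scores by the same
  factor, so the selection order is unchanged; `ln` is recorded in
  output metadata rather than left silent.
- **Correlation**: Pearson on positions (values, not ranks), since the
  gate concerns positional proportionality, not just order.
- **Gate on |corr|** with reversal of negatively oriented groups:
  component map orientation is arbitrary, so a strong negative
  correlation is a strong match in the reversed orientation.
- **Extrapolation**: nearest-segment slope; transiently negative
  coordinates are legal and removed by the final translation.
- **Tie-breaking**: higher score, then larger `n_common`, then
  component input order — fully deterministic.

## Quality control

- Assay filter: `q_value > 77`, `call_rate > 97` (both strict) and
  `reproducibility ≥ 100`, mirroring the selection rules used for
  array-quality clone filtering.
- Segregation: χ² with 1 df on non-missing counts against 1:1, without
  continuity correction; markers failing 1:1 at `alpha = 0.01` are
  rescued if consistent with a two-locus 3:1 or 1:3 ratio; only
  markers failing all three are discarded. Markers with zero scored
  lines are flagged rather than tested.
- Binning: two markers are compatible when they agree on every
  co-scored line and share at least `min_overlap = 20` informative
  lines; bins are connected components of the compatibility graph
  (which makes binning idempotent), represented by the highest-Q
  member with lexicographic tie-break. Missing cells count as
  compatible — two markers never co-observed disagreeing are treated
  as the same assay — and the overlap guard exists because agreement
  on a handful of lines is vacuous evidence. Transitive merging can in
  principle chain A~B~C with A,C unobserved together; with realistic
  call rates this is negligible, and the partition property holds
  regardless.

## Sequence redundancy

Co-positioned markers are checked at the sequence level: global
(Needleman–Wunsch) alignment with match +1, mismatch −1, linear gap
−2, identity = matches / aligned columns × 100, threshold 80%. The
scoring scheme is a package convention (none is conventionally fixed
for this decision rule); what matters is the threshold semantics, and
identity is insensitive to moderate scheme changes at the divergences
being separated (~2% vs ~35%). Among co-optimal alignments the one
maximising matches, then diagonal steps, defines identity — a
deterministic convention implemented as a lexicographic DP whose
optimal score is cross-checked against an independent aligner in the
tests. Both strands are compared (forward and reverse complement) and
the larger identity kept. A bin is a redundancy candidate only if
every pair clears the threshold.

## Physical anchoring

Hits arrive in the standard 12-column tabular alignment layout,
1-based inclusive, minus-strand encoded by `sstart > send`. The filter
keeps **all** hits with `E ≤ 1e−5` — no best-hit collapsing — so
multi-locus homology stays visible. Placement midpoint is the centre
of the subject interval. Colinearity per chromosome is the Spearman
correlation between genetic position and physical midpoint over
markers with a unique best-bit-score placement (ties are excluded and
reported as duplication candidates); the longest strictly decreasing
run of physical ranks is reported as the primary inversion candidate.
Trait intervals are closed intervals between two flanking markers on
one consensus chromosome.

## Synthetic data: what it does and does not emulate

The generator draws marker positions uniformly per chromosome,
converts adjacent gaps to interval fractions by the inverse Kosambi
function, and simulates each DH line as a first-order Markov chain
along the chromosome: first allele Bernoulli(0.5), each subsequent
allele switching with the interval fraction. Genotyping error flips
calls, missingness masks them, and per-marker quality metadata is
emitted with the call rate computed from realised missingness.
Segregation distortion is modelled by re-anchoring named loci to a
shifted allele frequency, which then propagates downstream through
the same chain. Marker sharing between populations is Bernoulli per
marker (`shared_fraction`), emulating crosses in which a clone is
monomorphic. Default noise levels (2% missing, 1% error) and panel
sizes (71–172 lines, study panels named in
`synthetic_data.POPULATION_SIZES`) reflect the DH array-genotyping
regime the pipeline targets.

Not modelled: crossover interference (the chain is Markov, so the
Kosambi distances are a definition, not a consequence of
interference), homoeologous recombination between A and C genomes
(e.g. the A7/C6 interaction seen in real amphidiploids), sequence-
level meiosis, and hybridisation-intensity artefacts. Passing recovery
tests therefore demonstrate correctness of the estimators and
algorithms under the stated model, not robustness to these biological
complications.

## Numerical choices and problem sizes

- Kosambi round-trip is exact to < 1e−12 over `r ∈ [0, 0.4999]`.
- Exact ordering is verified against exhaustive enumeration on
  8-marker instances (100 seeds); heuristic ordering is verified to
  recover linear geometries and the true order in ≥ 95/100 seeded
  200-line replicates of 20 markers spaced 5 cM.
- Component-position recovery is compared after removing the mean
  offset (the 0-anchor end of a map is an arbitrary convention);
  consensus recovery is compared after a per-chromosome affine fit,
  since a consensus coordinate system is only defined up to such a
  transform.
- Segregation-test calibration uses 2,000 markers spaced 200 cM
  (inter-marker correlation ~1e−3) × 100 lines, so the type-I rate has
  approximately binomial sampling error.
- Reported cM values are written at 2 decimals; percentages at 1
  decimal.
- The simulation sizes above (≤ 2,000 markers, ≤ 10,000 lines for
  calibration checks, 5 chromosomes × 30 markers for consensus
  recovery) were chosen as the smallest sizes at which the binomial
  error bands in the tests are meaningful.

## Known limitations

- No multipoint order/distance refinement; positions inherit the
  sampling error of adjacent pairwise estimates, which accumulates as
  a random walk along a group.
- "Attached" placement of low-quality markers onto a framework map is
  not implemented (no well-defined placement rule exists for it).
- The greedy consensus is order-dependent by design (deterministic tie
  rules), and interpolation can place a non-shared marker
  non-monotonically if the component and consensus disagree locally;
  such disagreements surface as order differences, not errors.
- The cluster detector reports maximal co-located runs; overlapping
  cluster windows are merged into the earliest maximal run.
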