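# mrtad

Multi-resolution identification of topologically associating domains
(TADs) from intra-chromosomal Hi-C contact maps.

TADs are contiguous genomic segments whose loci contact each other more
often than they contact the outside; they appear as blocks along the
diagonal of a binned contact map `W`. `mrtad` finds them by maximizing a
resolution-parameterized modularity

```
Q = (1 / 2N) Σ_ij (W_ij − γ E_ij) δ(σ_i, σ_j)
```

where `N` is the total read-pair count, `σ_i` the domain label of bin
`i`, and `γ > 0` a resolution parameter: larger `γ` accepts only stronger
enrichment over background and yields more, smaller domains. The
background `E` is a factorized null model

```
E_ij = κ*_i κ*_j f(|i − j|)
```

that preserves both the empirical distance decay `f(d)` of contacts and
every observed bin coverage `c_i` (`Σ_j E_ij = c_i`); the effective
coverages `κ*_i` are solved by damped fixed-point iteration, a
generalization of matrix balancing. Optimization uses a
contiguity-constrained Louvain heuristic (only segment-endpoint bins may
change label; locked segments merge at the super-bin level, followed by an
exact regrouping of the locked segments); boundaries called in at least 9
of 10 stochastic trials (score ≥ 0.9) become consensus TAD boundaries. An
exact `O(n³)` dynamic program — same shape as the Nussinov recursion —
provides the globally optimal contiguous partition for maps small enough
to afford it, and serves as the oracle the heuristic is measured against.

The package is aimed at chromatin-organization analyses: calling domains
at several scales from one map, comparing domain sets between conditions
(normalized mutual information), and profiling chromatin-peak enrichment
around boundaries. A synthetic Hi-C generator with planted (optionally
nested) domains, power-law distance decay, heterogeneous bin visibility
and Poisson counts makes every stage testable without external data.

## Worked example

Simulate a 200-bin chromosome with 8 planted domains (2× within-domain
enrichment, 2 M read pairs, 40-kb bins), call TADs, and compare against
the planted truth:

```
$ mrtad simulate --spec spec.json --out-map map.coo --out-truth truth.bed
wrote 200-bin map with 8 planted domains

$ mrtad call --map map.coo --format coo --chrom chrS --binsize 40000 \
      --n-bins 200 --gamma 1.0 --trials 10 --cutoff 0.9 --seed 1 \
      --out-tads tads.bed --out-scores scores.bedgraph
8 TADs on chrS at gamma=1 (median size 1e+06 bp, best trial Q 0.049129)

$ head -4 tads.bed
chrS    0       1000000 TAD_1
chrS    1000000 2000000 TAD_2
chrS    2000000 3000000 TAD_3
chrS    3000000 4000000 TAD_4

$ mrtad compare --a tads.bed --b truth.bed --chrom chrS --binsize 40000 --n-bins 200
1.000000
```

The call recovers all 8 planted 1-Mb domains exactly (NMI = 1 against the
truth); `Q ≈ 0.049` is the achieved modularity (0 would mean no
enrichment beyond the coverage- and distance-matched background). A
resolution sweep shows the scale behavior — fewer, larger domains at low
`γ`, progressively finer segmentation as `γ` grows:

```
$ mrtad sweep --map map.coo --format coo --chrom chrS --binsize 40000 \
      --n-bins 200 --gammas 0.75,1.0,1.5,2.25 --seed 1 --out-summary sweep.tsv
 gamma  n_tads  median_size_bp
  0.75       1       8000000.0
  1.00       8       1000000.0
  1.50     200         40000.0
  2.25     200         40000.0
```

`mrtad exact` computes the provably optimal partition (impractical beyond
a few hundred bins), and `mrtad enrich` profiles peak density around
boundaries against a uniform-placement null. The same functionality is
available as a library (`import mrtad`); see `docs/methods.md` for the
model, parameters, and numerical choices.

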