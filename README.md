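# metasig

Alignment-free comparison of metagenomic and metatranscriptomic NGS samples
via *k*-tuple sequence signatures.

## The problem

Comparing microbial community samples (beta diversity) from shotgun
sequencing is hard when assembly and alignment are impractical: communities
mix hundreds of genomes with no references, coverage per genome is low, and
for metatranscriptomes the expressed fraction differs from the underlying
DNA. Alignment-free methods sidestep this by representing each sample as its
*k*-tuple sequence signature — the vector of occurrence counts
`X = (X_w)` of all `4^k` nucleotide words `w` of length `k` over the
sample's reads, counted on both strands because shotgun reads carry no
strand information.

`metasig` implements the complete comparison pipeline for such signatures:

* **Counting** — `count_ktuples` builds the strand-symmetric count vector of
  a FASTA/FASTQ read set (windows containing N are skipped).
* **Background models** — per-sample Markov chains of order `r ∈ {0..3}`
  give each word its expected probability
  `p_w = p(w_1..w_r) · Π p(w_{i+r} | w_i..w_{i+r-1})` and expected count
  `n·p_w`, used to center the observed counts: `X̃_w = X_w − n·p_w`.
* **Eight dissimilarity measures** between samples X and Y at one `(k, r)`:
  * `d2` = `(1 − cos(X, Y))/2` on raw counts;
  * `d2s` = `(1 − D/√(AB))/2` with
    `D = Σ X̃_wỸ_w/√(X̃_w²+Ỹ_w²)`, `A = Σ X̃_w²/√(X̃_w²+Ỹ_w²)`,
    `B = Σ Ỹ_w²/√(X̃_w²+Ỹ_w²)` (range [0, 1]);
  * `d2star` = `(1 − D*/√(A*B*))/2` with
    `D* = Σ X̃_wỸ_w/√(E_X E_Y)`, `A* = Σ X̃_w²/E_X`, `B* = Σ Ỹ_w²/E_Y`,
    `E = n·p_w` (range [0, 1]);
  * `hao` — the CVTree measure: `(1 − cos(a_X, a_Y))/2` on composition
    vectors `a_w = (f(w) − f₀(w))/f₀(w)`, with `f₀` the word's expected
    frequency under the `(k−2)`-order chain;
  * `s2` — relative entropy
    `Σ F_X ln(F_X/P) + Σ F_Y ln(F_Y/Q)` mixing observed frequencies with
    Markov word probabilities;
  * `ma`, `eu`, `ch` — Manhattan/Euclidean/Chebyshev distances on relative
    frequency vectors.
* **Evaluation** — UPGMA clustering into an ultrametric tree, symmetric
  difference between trees (clusters present in exactly one tree; branch
  lengths ignored), classical PCoA with first-axis goodness of fit, and
  Spearman correlation of the first principal coordinate with an external
  gradient covariate.
* **Synthetic communities** — generators for read sets with planted group
  structure, expression-weighted transcript pools, mixture gradients and
  homogeneous indel/substitution sequencing errors, plus subsampling, so the
  whole pipeline is testable with no external data.

Measures requiring an order-`r` centering are undefined for `k < r+1`, and
`hao` for `k < 3`; those combinations are reported as explicit NA matrices.

## Worked example

Simulate a panel of 8 samples from 4 divergent source pools (2 replicates
each, 1000 reads × 150 bp), compare them with `d2s` at `k = 6` under an
order-0 background, cluster, and score against the planted grouping:

```python
import metasig as m

samples, planted = m.make_group_panel(G=4, samples_per_group=2,
                                      n_reads=1000, len_mean=150, seed=7)
dm = m.pairwise_matrix(samples, "d2s", k=6, order=0)
tree = m.upgma(dm)
print(m.symmetric_difference(planted, tree))
```

The matrix shows within-group `d2s` around 0.007–0.014 against
between-group values of 0.18–0.28, so every replicate pair merges first and
all four planted groups appear in the tree. The printed symmetric difference
is `2`: the planted reference is a star of 4 groups (4 nontrivial clusters)
while the binary UPGMA tree on 8 leaves carries 6, so 2 is exactly the floor
a perfect recovery leaves — the two extra clusters are the arbitrary binary
resolution above the groups.

A planted mixture gradient (2 replicates × 4 levels, emulating e.g. an
ocean-depth series) is recovered the same way:

```python
pools = m.make_source_pools(2, seed=11)
grads, cov = m.make_gradient_panel(pools[0], pools[1],
                                   [0, 1/3, 2/3, 1.0], reps=2,
                                   n_reads=2000, seed=5)
rep = m.gradient_report(m.pairwise_matrix(grads, "d2s", 6, 0), cov)
print(f"GOF={rep.gof:.4f} |SRCC|={rep.srcc_abs:.4f}")
# GOF=0.9963 |SRCC|=0.9759
```

0.9759 is the largest Spearman correlation attainable for 8 samples with
tied covariate levels, i.e. the first principal coordinate orders the
samples perfectly by mixing level.

The same workflow is available from the shell:

```bash
metasig simulate group --seed 7 -o panel/
metasig dist --measure d2s -k 6 --order 0 panel/*.fasta -o panel.tsv
metasig cluster panel.tsv -o tree.nwk
metasig treedist panel/planted.nwk tree.nwk
metasig ordinate panel.tsv --covariate depths.tsv
```

`metasig run --config pipeline.yaml` orchestrates the full
count → prob → dist → cluster/ordinate workflow with on-disk reuse of
signature and probability files, and `metasig sample` implements the
repeated-subsampling depth-robustness protocol.

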