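# rewireprio

Guilt-by-rewiring gene prioritization from two-condition expression data.

`rewireprio` ranks genes by their posterior probability of association
with a phenotype (e.g. drought stress) using nothing but a bulk
genes × samples expression matrix with treatment/control labels.  It is
aimed at time-course designs with *small per-stage sample sizes*, where
correlation-based co-expression networks are unreliable and asymptotic
test statistics are not trusted.  The pipeline has three statistical
stages:

1. **Mean-variance (MV) screening.**  For gene *i* with expression
   $X_i = (x_{1i},\dots,x_{ni})$ and binary response $Y$, the MV index

   $$T_n(i) = \sum_{\theta=1}^{C}\sum_{j=1}^{n} \hat p_\theta\,
     \{\hat F_\theta(x_{ji}) - \hat F(x_{ji})\}^2$$

   compares conditional and marginal empirical CDFs; it is model-free and
   rank-based.  Significance comes from K = 5000 label permutations;
   genes with $P_{MV} \le 0.01$ become candidates.

2. **Weighted gene differential co-expression network (WGDCN).**
   Pairwise similarity uses the gray correlation coefficient (GCC),

   $$r_{pq} = \frac{1}{n}\sum_{k=1}^{n}
     \frac{\Delta_{\min} + \rho\,\Delta_{\max}}
          {|x_{kp}-x_{kq}| + \rho\,\Delta_{\max}},$$

   with global extremes over the candidate set, resolution ratio
   ρ = 0.5, symmetrized as $(r_{pq}+r_{qp})/2$ and computed separately
   for treatment and control.  Genes whose GCC crosses the hard
   threshold $r_0 = 0.9$ in opposite directions between conditions are
   joined by an edge weighted by the rewiring strength
   $\mathrm{rewire}_{pq} = |r^{treat}_{pq} - r^{control}_{pq}|$.

3. **Hidden Markov random field (HMRF) prioritization.**  Hidden labels
   $\omega_p \in \{-1,+1\}$ follow an Ising prior on the WGDCN with
   coupling τ₁ (associated pairs), τ₂ (null pairs on edges with weight
   > δ = 0.95) and external field *h* (the 0.90 quantile of the initial
   association potentials).  Evidence scores
   $\xi_p = \Phi^{-1}(1-P_{MV}(p))$ are N(0, 1) under the null and a
   Student-t prior-predictive under association.  Iterated conditional
   modes (ICM) maximizes each gene's conditional until no label flips;
   the converged conditional probabilities are the reported posteriors,
   and the top-20 genes per developmental stage are called crucial.

Stage-wise top lists are stacked into a multilayer network (interlayer
edges join the same gene across stages) summarized by per-layer density,
average degree, average path length, average clustering, and the Jaccard
overlap $\mathrm{Overlap}(i,j) = |A_i \cap A_j| / |A_i \cup A_j|$.

A synthetic-data generator with planted ground truth (null genes,
mean-shifted genes, and a module whose co-expression rewires between
conditions) makes the whole pipeline testable without any downloads.

## Worked example

```python
from rewireprio import (HMRFConfig, build_wgdcn, discrimination_ability,
                        filter_candidates, gcc_by_condition, icm_fit,
                        mv_screen_matrix, rank_genes)
from rewireprio.io import binary_response
from rewireprio.simulate import SyntheticDesign, generate

expr, meta, truth = generate(SyntheticDesign(seed=42))   # 85 genes, 24 samples
y = binary_response(meta, expr.sample_ids)

res = mv_screen_matrix(expr.values, y, expr.gene_ids, k_perms=2000, seed=42)
cand = filter_candidates(res)                             # 26 of 85 genes
sub = expr.subset_genes(cand)
gcc_t, gcc_c = gcc_by_condition(sub, y)
net = build_wgdcn(gcc_t, gcc_c, cand)                     # 153 rewiring edges

p = res.set_index("gene_id").loc[cand, "p_mv"].to_numpy()
state = icm_fit(net, p, HMRFConfig(), gene_ids=cand, k_perms=2000)
print(rank_genes(state, top_k=5)[["gene_id", "posterior", "rank"]])
```

which prints

```
 gene_id  posterior  rank
 de_0004   0.991379     1
 de_0003   0.991373     2
mod_0001   0.991367     3
 de_0002   0.991365     4
mod_0000   0.991363     5
```

All five top-ranked genes are planted signal genes (`de_*` carry a
conditional mean shift, `mod_*` belong to the rewired module); their
posteriors are the converged conditional probabilities of association.
The ranking resolution illustrates why the HMRF step matters: here
`discrimination_ability(p) = 0.192` for the lattice-valued permutation
p-values versus `1.000` for the continuous posteriors — the HMRF
separates genes that the screening p-values cannot tell apart.

The same pipeline is available from the shell:

```bash
rewireprio simulate --out-prefix sim --n-stages 5 --seed 1
rewireprio run-all --expr sim_expression.tsv --meta sim_metadata.tsv \
    --outdir out --seed 1
```

writing per-stage MV tables, edge lists (TSV + GEXF), rankings, DEG
volcano tables, layer statistics, the Jaccard overlap matrix and a run
manifest.  `mv-screen`, `build-network`, `prioritize` and `multilayer`
run the stages individually on plain TSV artifacts.

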