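# rcfgl — rapid condition-adaptive fused graphical lasso

Joint estimation of gene co-expression networks across multiple biological
conditions (tissues, brain regions, treatment groups).  Each condition's
network is the conditional-independence graph of a Gaussian graphical
model: gene pairs with a nonzero entry in the precision matrix
Θ(k) = Σk⁻¹ are connected.  Estimating the K networks jointly borrows
strength across conditions; doing it *adaptively* avoids blurring away the
condition-specific edges that are usually the biological point.

## Model

Given expression matrices Y(1), …, Y(K) (nₖ samples × p genes) with sample
covariances S(k), the estimator minimizes over positive-definite
Θ(1), …, Θ(K)

    − Σₖ nₖ [ log det Θ(k) − tr(S(k) Θ(k)) ]
    + λ₁ Σ_{i≠j} Σₖ |Θij(k)|
    + λ₂ Σ_{i≠j} Σ_{k=1}^{K−1} wij(k,k+1) |Θij(k) − Θij(k+1)|.

The lasso term controls sparsity; the *sequential* fused term couples only
consecutive conditions, and the binary weights wij(k,k+1) switch the
coupling off wherever a differential test (or an oracle, or the user) says
the entry differs between the two conditions.  The sequential form is what
makes the method fast: the ADMM Z-step separates into independent
K-chains, each solved exactly in O(K) by weighted 1-D total-variation
denoising (a taut-string construction) followed by soft-thresholding.
With all-ones weights the method reduces to the non-adaptive sequential
fused graphical lasso (provided as `mode="rfgl"`).

Also included: a sufficient block-diagonal screening rule on the sample
covariances (|nₖ Sij(k)| < λ₁ for all k splits the problem into
independent sub-problems), AIC-based (λ₁, λ₂) selection, a
covariance-distance + hierarchical-clustering heuristic for choosing the
condition order, a scale-free (Barabási–Albert) multi-condition simulator
with exact ground truth, and the usual recovery metrics
(precision/recall at a detection tolerance, SSE, Jaccard overlap of top
edges, edge categories, hub genes).

λ₁ and λ₂ are given on the per-sample scale (they are multiplied by the
mean sample size internally), so useful values live in the familiar
0.01–0.5 range regardless of n.

## Worked example

```python
from rcfgl import (scenario, simulate_scenario, compute_covariance,
                   rcfgl_fit, precision_recall, sse_metric, aic_score)

# three conditions, 100 genes in five 20-gene modules; conditions 1 and 2
# share all modules, condition 3 is fully independent
truth, panel = simulate_scenario(scenario("S2", n=100, block_size=20, seed=1))
cov = compute_covariance(panel)

adaptive = rcfgl_fit(cov, weights=truth.weights, lambda1=0.2, lambda2=0.1)
plain = rcfgl_fit(cov, lambda1=0.2, lambda2=0.1, mode="rfgl")

for name, est in (("RCFGL", adaptive), ("RFGL", plain)):
    rep = precision_recall(est, truth)
    print(f"{name}: converged={est.converged} iterations={est.n_iter} "
          f"precision={rep.precision:.3f} recall={rep.recall:.3f} "
          f"SSE={sse_metric(est, truth):.1f} "
          f"AIC={aic_score(est, cov).aic:.1f}")
```

prints

```
RCFGL: converged=True iterations=115 precision=0.421 recall=0.979 SSE=1205.7 AIC=18665.2
RFGL: converged=True iterations=109 precision=0.325 recall=0.961 SSE=1635.3 AIC=19946.1
```

Both fits recover nearly all true edges (recall ≈ 0.96–0.98), but the
condition-adaptive fit is markedly more precise and has ~26% lower error
on the edge weights: the oracle weights stop it from fusing condition 3's
distinct network into the shared one, while the non-adaptive penalty
blurs the three networks together.

The same workflow is available from the shell:

```sh
rcfgl --seed 1 simulate --scenario S2 --n 100 --outdir study
rcfgl fit study/expression/*.tsv --lambda1 0.2 --lambda2 0.1 \
      --weights oracle:study/truth --outdir study/fit
rcfgl evaluate --fit-dir study/fit --truth-dir study/truth --out study/eval.json
```

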