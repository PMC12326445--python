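# rsvnet

Relative strength variability measures for weighted networks, built for
brain structural connectomes.

## The problem

Weighted structural connectomes — region-by-region matrices whose entries
quantify white-matter connectivity (streamline count, FA, MD, NODDI
parameters) — are usually summarised with a handful of global graph
measures that turn out to be highly mutually correlated. This package
implements a complementary family of measures based on **relative node
strength**: how strong each region is compared with the regions it
connects to.

With node strength `s_i = Σ_j W_ij`, the relative strength of node *i* is
its strength over the mean strength of its neighbours,

    r_i = s_i / ( (1/|N(i)|) Σ_{j∈N(i)} s_j ),

or, in the edge-corrected form used by default, the reciprocal of the mean
of the edge-corrected neighbour/self ratios,

    r_i = [ (1/|N(i)|) Σ_{j∈N(i)} (s_j − W_ij)/(s_i − W_ij) ]⁻¹,

which removes each connecting edge's own contribution to both strengths
(disable the correction and the plain ratio is recovered exactly).

* **RSV** is the sample standard deviation of the `r_i` over all nodes.
  It is high when strong and weak nodes interconnect (core–periphery
  mixing) and zero for any uniform-weight regular graph.
* **hRSV** sorts nodes by strength, slides a window of `w` consecutive
  ranks across the hierarchy (`n − w + 1` windows), and averages the
  within-window standard deviations of `r`. With a small window it is a
  weighted *statistical complexity* measure — low for regular **and**
  random networks, high for structurally diverse ones. Defaults are
  `w = 4` and `w = 21`.

Around the core measures, the package ships everything needed to run and
validate a cohort analysis: cohort prevalence thresholding (keep edges
present in ≥ 50% of subjects), the five standard comparison measures
(strength variance, strength assortativity, density-normalised Onnela
clustering, routing efficiency with inverse-weight lengths, and diffusion
efficiency from closed-form mean first-passage times), synthetic network
archetypes, g-factor extraction from incomplete cognitive batteries
(low-rank completion + first unrotated principal component), and
Gram–Schmidt incremental-R² regression for asking whether a measure
explains outcome variance beyond conventional predictors.

## Worked example

```python
import numpy as np
from rsvnet import WeightedNetwork, relative_strengths, rsv

W = np.zeros((6, 6))
W[0, 1:] = W[1:, 0] = 1.0          # unit-weight star: hub + 5 leaves
star = WeightedNetwork.from_matrix(W)
print(relative_strengths(star, corrected=False).r)
print(rsv(star, corrected=False).value)
```

prints

```
[5.  0.2 0.2 0.2 0.2 0.2]
1.9596
```

The hub is five times stronger than its context (`r = 5`), each leaf five
times weaker (`r = 0.2`); RSV is the spread of those ratios. A ring
lattice at the same density prints `0.0` for both RSV and hRSV — every
node sits in an identical local context. The scripts in `examples/`
walk through each capability (archetype families, the cohort pipeline,
g extraction, incremental prediction) and print what the numbers mean;
`examples/05_incremental_prediction.py`, for instance, plants a −0.08
standardised RSV effect in a synthetic cohort's g and recovers

```
predictor     beta   incr R2      p_fdr
age        0.2987   0.08924   3.14e-42
meanw     -0.0256   0.00065      0.306
erout     -0.0069   0.00005      0.744
RSV       -0.0910   0.00828   3.93e-05
```

A thin CLI wraps the same functions: `rsvnet simulate`, `rsvnet compute`,
`rsvnet gfactor`, `rsvnet incremental`, and `rsvnet replicate`.

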