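# pcgmm — robust multivariable cis-Mendelian randomization

`pcgmm` estimates the causal effects of several correlated risk factors on a
disease outcome using the genetic variants of a **single gene region** as
instruments, from GWAS summary statistics alone. It is aimed at drug-target
epidemiology: given a gene encoding a drug target, which pathway (say,
body-mass index versus type-2-diabetes liability, or expression in one
tissue versus another) carries the effect of perturbing that target on
disease risk?

Variants in one region are too correlated to use directly, so the package
instruments with principal components of a weighted genetic correlation
matrix and fits the multivariable model by a continuously-updating GMM
(CUE) criterion on the component scale. Writing β̃_Y and β̃_X for the
PC-scale outcome and risk-factor coefficients, the estimator solves

    θ̂ = argmin  g(θ)' Ω(θ, κ²)⁻¹ g(θ),      g(θ) = β̃_Y − β̃_X θ,

where Ω combines the sampling covariances of both sides with an
**overdispersion** term (κ²/n_Y)·S⁻¹Λ'ρ²ΛS⁻¹ capturing direct variant
effects on the outcome that bypass the risk factors. κ² is estimated by
matching the minimized objective to its χ²_{p−K} null expectation, which
widens confidence intervals exactly when such pleiotropic noise is present
("robust PC-GMM"); with κ² fixed at 0 the minimized objective doubles as an
overidentification/heterogeneity test. Identification is diagnosed by
**conditional F-statistics** that test, per risk factor, whether its
PC-scale associations are a linear combination of the others' (no
phenotypic heterogeneity = rank reduction = weak instruments).

Also included, because they belong to the same workflow:

- **Colocalization** (Wakefield ABFs, H0–H4 enumeration, p12 sensitivity)
  to ask whether two traits share a causal variant in the region;
- **Bayesian model averaging** over risk-factor subsets with marginal
  inclusion probabilities, for many-candidate settings such as
  tissue-specific expression;
- A **simulator** of the full two-sample design (200 correlated
  instruments, 15 causal, 3 risk factors with effects (−1/3, 0, 1/3),
  phenotypic-heterogeneity parameter ξ and overdispersion parameter κ²)
  used to validate size, power, and calibration of everything above.

## Worked example

Simulate one regional dataset under the built-in design (full phenotypic
heterogeneity ξ = 1, overdispersion κ² = 1, two samples of 20,000), write
it to disk, and analyse it from the command line:

```python
import numpy as np
from pcgmm import SimulationSpec, synthetic_ld, generate_two_sample
from pcgmm.io import write_summary_stats, write_ld_matrix

ld = synthetic_ld()                      # 200-variant regional LD stand-in
sim = generate_two_sample(SimulationSpec(xi=1.0, kappa2=1.0), ld,
                          rng=np.random.default_rng(7))
write_summary_stats(sim.data, "summary.tsv")
write_ld_matrix(ld, "ld.tsv")
np.savetxt("trait_cor.tsv", sim.trait_cor.matrix, delimiter="\t")
```

```bash
pcgmm fit --summary summary.tsv --ld ld.tsv --trait-cor trait_cor.tsv \
          --threshold 0.9999 --robust
```

```text
risk_factor	estimate	ci_lower	ci_upper	p_value	n_pcs	n_variants	kappa2
X1	-0.346836	-0.449906	-0.243765	4.24253e-11	30	200	1.18204
X2	-0.0124335	-0.121485	0.0966184	0.823174	30	200	1.18204
X3	0.43432	0.342617	0.526023	1.65301e-20	30	200	1.18204
```

The true effects are (−1/3, 0, 1/3): the fit recovers both non-null
effects, covers the null for the second risk factor, and estimates the
overdispersion parameter near its generating value κ² = 1 (the `kappa2`
column; the 30 retained components explained 99.99% of weighted variance
among the 200 variants). The same fit without the correction
(`--no-robust`) gives similar point estimates with intervals about three
times narrower — anti-conservative here, as the heterogeneity test makes
plain:

```text
heterogeneity test: Q = 115.6, df = 27, p = 6.21e-13
```

Instrument strength for the same data:

```bash
pcgmm condf --summary summary.tsv --ld ld.tsv --trait-cor trait_cor.tsv --threshold 0.9999
```

```text
risk_factor	conditional_F	df	p_value	strength
X1	186.208	28	0	ok
X2	181.239	28	0	ok
X3	165.616	28	0	ok
```

With ξ = 1 every risk factor has its own causal instruments, so all three
conditional F-statistics are large and the rank-reduction null is firmly
rejected. Re-simulating with `xi=0` collapses F for risk factors 2 and 3
to ≈ 1 (their instruments coincide) while F for risk factor 1 stays high —
the signature of lost phenotypic heterogeneity.

Other entry points: `pcgmm coloc` (posterior probabilities H0–H4 and the
p12 sensitivity grid), `pcgmm bma` (ranked risk-factor subsets and
inclusion probabilities), `pcgmm simulate` / `pcgmm grid` (simulation
cells and sweeps), and `pcgmm pipeline --config run.yaml` for the
end-to-end read → harmonize → filter → prune → transform → fit workflow
with a JSON run manifest. Everything is equally usable as a library
(`pcgmm.pc_reduce`, `pcgmm.fit_robust`, `pcgmm.all_conditional_f`, ...).

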