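# altiscan

Population-genomic inference for two-population highland-colonization
studies: coalescent simulation of isolation-with-migration demographies,
demographic model choice from the folded joint site-frequency spectrum
(SFS), a simulation-calibrated FST / diversity-ratio divergence scan, an
adaptive-allele dosage statistic, and a phenotype-PC x expression
correlation stage.  Everything runs on synthetic data generated by the
package itself, so the full chain is testable without any sequencing data.

The intended user analyzes resequencing panels from a pair of recently
diverged populations (here: highland vs lowland birds, ~11 + 12 diploids,
genome-wide mean FST of a few percent) and wants to (i) infer when the
highland population was founded, (ii) nominate genomic regions under
divergent selection against a properly simulated neutral null rather than
an arbitrary empirical quantile, and (iii) relate candidate loci and
expression to phenotypes.

## The models in brief

**Demography.**  Genealogies follow the continuous-time structured
coalescent: coalescence at rate 1/(2N) per pair within a deme, migration of
single lineages (parameterized as Nm, expected migrant lineages per
generation), merger into an ancestral deme at the split time T.  Eight
nested hypotheses (M1-M8) range from a constant panmictic population to a
split with bidirectional gene flow and founder-size changes.  Fitting
maximizes the multinomial composite likelihood of the folded joint SFS,
`sum_cells n_cell * log p_cell(theta)`, with `p_cell` from branch-weighted
Monte-Carlo under common random numbers, via expectation-conditional-
maximization (20-80 cycles); models are ranked by `AIC = 2k - 2 logL`.

**Scan.**  Per-site Weir-Cockerham FST is compared against the upper 1%
quantile of FST simulated under the fitted demography ("HD-SNPs"); 50-kb
windows are ranked by HD-SNP count (>= 13, at most 1000 windows) and must
also show a lowland/highland diversity ratio above the simulated 95%
quantile.  Passing windows merge into candidate regions, are annotated
against gene models, and a 2x2 chi-square tests over-representation of a
gene category.

**Dosage.**  At each HD-SNP the highland major allele (AF > 0.5) is the
putative high-elevation adaptive allele; per-individual dosages are
compared between groups with a Welch t-test.

See `docs/methods.md` for assumptions, numerical choices, and known
identifiability limits.

## Worked example

```python
from altiscan import (DemographySpec, SampleConfig, simulate_dataset,
                      fold_joint_sfs, global_fst, SFSDemographyModel)

# the default spec is the fitted colonization scenario: highland size
# 85 058, split 2 598 generations ago, 0.08 migrants/generation into the
# highland deme, mu = 3.3e-9, one-year generations
truth = DemographySpec()
vt = simulate_dataset(truth, SampleConfig(n_high=11, n_low=12,
                                          n_sites=20_000, seed=1))
print(f"weighted FST = {global_fst(vt):.4f}")

sfs = fold_joint_sfs(vt)
model = SFSDemographyModel(sfs, model="M3", n_draws=10_000,
                           fixed={"N_low": 350_000.0, "N_anc": 350_000.0,
                                  "M_lh": 0.08})
res = model.fit(seed=1, n_restarts=1)
print(res.summary())
```

Output:

```
weighted FST = 0.0093
SFS demographic fit — model M3
  segregating sites: 20000
  composite logL: -83801.80   AIC: 167607.60   k: 2
  ECM cycles: 20   converged: True
  parameters:
    N_low                350000
    N_anc                350000
    M_lh                   0.08
    T_split             3471.24
    N_high               108041
    (T_split = 3471 years at 1 yr/generation)
```

The simulated panel sits in the weak-differentiation regime (weighted
Weir-Cockerham FST about 0.01 under the point-estimate demography), and
refitting the colonization model to its own simulated output recovers a
split time of the right order — a single 20 000-SNP replicate carries
sampling error of some tens of percent, which shrinks with more SNPs and
with averaging over seeds (the acceptance script below uses 100 000 SNPs
and three seeds).  The fixed nuisance parameters pin the likelihood's
overall scale (see the identifiability discussion in the methods note).

A full synthetic pipeline — simulate, scan, dosage, phenotype/expression —
runs from one config:

```bash
altiscan run --config examples/config.yaml --seed 7 --out results/
```

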