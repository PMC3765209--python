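# kdpselect

Simultaneous selection among *nested* dynamic-model structures and
estimation of their parameters, posed as one mixed-integer nonlinear
program (MINLP) and solved by a mixed-integer scatter-search metaheuristic.

Systems biologists routinely face a family of model candidates that are all
special cases of one superstructure — a base model plus hypothesised
feedback loops that can be switched on or off and shaped by small integer
(Hill) exponents.  Fitting every candidate separately and comparing
afterwards is intractable when the family is large.  `kdpselect` instead
searches the joint space of continuous rate constants **p** and
integer/binary structure switches **q**, minimising the Akaike information
criterion

    AIC(p, q) = −2·Jml(p, q) + 2·Np(q)

where `Jml` is the Gaussian log-likelihood of the time-course data
(measurement standard deviations known, heteroscedastic) and `Np` counts
the decision variables active in the candidate structure.  The smallest AIC
wins: goodness of fit and structural complexity are traded off in a single
number, with no pairwise model comparisons.

The bundled, fully testable case study is a differential-algebraic
superstructure of the KdpD/KdpE two-component system that regulates
potassium homeostasis in *Escherichia coli* (5 ODE states, 2 algebraic
promoter-binding constraints, three optional feedback mechanisms,
1700 nested structures, 25 decision variables).  Because no public dataset
exists, the package generates the in-silico study data itself: two strains
(wild type and a K⁺-uptake-defective mutant) × five extracellular K⁺ levels,
measuring only mRNA and the KdpFABC transporter with 5% multiplicative
noise.  See `docs/methods.md` for the model, the search algorithm, the
identifiability analysis and all numerical choices.

## Worked example

```python
from kdpselect import GenerationProtocol, generate, nominal_parameters
from kdpselect.objective import objective_evaluate
from kdpselect.study import run_recovery_study

# 1. generate the in-silico dataset (2 strains x 5 K+ levels, 5% noise)
s_true, p_true = nominal_parameters()
dataset = generate(GenerationProtocol(seed=2013))
print("AIC at generating truth:", round(objective_evaluate(s_true, p_true, dataset).aic, 1))

# 2. solve the selection/estimation MINLP (one scatter-search run + polish)
study = run_recovery_study(dataset, seed=2013, n_runs=1)
s = study.structure
print("best AIC :", round(study.best_value, 1))
print("structure:", (s.bin1, s.bin2, s.bin3), (s.n1, s.n2, s.n3, s.n4, s.n5))
print("mean residual: %.2f%%" % study.mean_residual_percent)
```

prints (seeds as above):

```
AIC at generating truth: -1679.0
best AIC : -1671.1
structure: (1, 1, 0) (3, 2, 1, 0, 0)
mean residual: 4.19%
```

The single run identifies the generating regulation mechanisms — both the
translation loop (bin1 = 1, with its exact Hill order n1 = 3) and the
proteolysis loop (bin2 = 1), under the linear stimulus-counteraction form
(bin3 = 0) — within 8 AIC units of the generating point, and the mean
relative residual sits at the level of the injected 5% noise (the analytic
expectation for truth-level residuals is 5%·√(2/π) ≈ 3.99%).  Recovered
*structures* are the robust output here; individual exponents such as
n2/n3 are nearly degenerate, and recovered *parameter values* wander along
nearly flat correlated directions of the likelihood — see
`docs/methods.md` for what the in-silico data can and cannot identify.

The same pipeline is available from the shell:

```sh
kdpselect generate --seed 2013 --out out/
kdpselect fit      --dataset out/dataset.csv --seed 3013 --budget 1400 --out out/
kdpselect analyze  --dataset out/dataset.csv --fit-result out/run_result.json --seed 1 --out out/
kdpselect enumerate --exponent-max 3        # -> 1700 nested structures
```

`fit` writes `run_result.json`, a best-so-far trace CSV and a plain-text
report comparing every fitted constant against its nominal value;
`analyze` writes the FIM-based correlation matrix and the msqr sensitivity
ranking.

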