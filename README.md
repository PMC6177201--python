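# nestedmvpa

Subclass-aware chance levels and permutation tests for cross-validated
classification (MVPA).

## The problem

In multivariate pattern analysis a classifier is trained to separate two
conditions and the cross-validated correct classification rate (CCR) is
tested against chance (50% for two balanced classes). In practice the trials
within each class are rarely homogeneous: they come from repeated stimuli,
multiple subjects, sessions or recording blocks. When each of these
*subclasses* belongs entirely to one class (a nested design), a linear
classifier can exploit subclass structure that has nothing to do with the
class difference, and the expected CCR rises above 50% even when the null
hypothesis is true. Trial-wise permutation tests, which shuffle labels over
individual trials, destroy the subclass structure along with the class
structure — their null stays at 50% and they reject far too often.

This package provides, for two-class problems with K subclasses per class:

- a **multilevel Gaussian simulator** for y<sub>ijk</sub> = C<sub>i</sub> +
  S<sub>ij</sub> + ε<sub>ijk</sub> with isotropic components
  σ<sub>C</sub>, σ<sub>S</sub>, σ<sub>W</sub>, including collapse of multiple
  nesting levels and moment-based estimation of the intraclass correlation
  ICC = σ<sub>S</sub>²/(σ<sub>S</sub>²+σ<sub>W</sub>²);
- **linear classifiers with cross-validation**: the mean-difference/midpoint
  classifier ("paper_lda"), a linear SVM, stratified trial-wise k-fold CV and
  leave-one-subclass-out CV;
- **permutation tests**: trial-wise nulls, and balanced *subclass-wise
  (block) permutation* nulls that reassign whole subclasses, K/2 from each
  original class per new class — there are C(K, K/2)²/2 distinct such
  assignments (18 for K=4, 31 752 for K=10) — plus a group-level null over
  subjects;
- the **analytic expected CCR** of the mean-difference classifier: at zero
  class effect the chance level is

  CCR = 1 − (1/π)·arctan√(2(K/ICC − 1)) = 1/2 + (1/π)·arctan λ,
  λ² = (ICC/2K)/(1 − ICC/K),

  which is 50% only at ICC = 0, increases with ICC and decreases with K; a
  one-dimensional integral extends it to a nonzero class-mean separation δ;
- **experiment drivers** for CCR surfaces over (σ<sub>C</sub>, σ<sub>S</sub>)
  grids, theory-vs-simulation validation, and significance-bias maps
  SB = P<sub>σS≠0</sub> − P<sub>σS=0</sub>.

## Worked example

Simulate a dataset with **no class effect** but strong subclass structure
(d=100, K=10 subclasses per class, 12 trials each, σ<sub>C</sub>=0,
σ<sub>S</sub>=0.4, σ<sub>W</sub>=1, so ICC ≈ 0.138), then classify and test:

```sh
$ nestedmvpa simulate --d 100 --k 10 --n 12 --sigma-c 0 --sigma-s 0.4 \
    --sigma-w 1 --seed 42 --out demo.csv
$ nestedmvpa classify --input demo.csv --classifier lda --cv 2fold --seed 1
{"ccr": 0.6666666666666666, "per_fold_ccr": [0.65, 0.6833333333333333],
 "n_test_trials": 240, ...}
```

A 66.7% CCR on null data — the subclass bias at work. The two permutation
tests disagree sharply:

```sh
$ nestedmvpa permtest --input demo.csv --scheme trial --n-perm 199 --seed 2 --out null_trial.csv
{"observed_ccr": 0.6916666666666667, "p_value": 0.005, "scheme": "trial_wise", ...}
$ nestedmvpa permtest --input demo.csv --scheme block --n-perm 199 --seed 2 --out null_block.csv
{"observed_ccr": 0.6916666666666667, "p_value": 0.595, "scheme": "subclass_wise_balanced", ...}
```

Trial-wise permutation calls this highly significant (p = 0.005, a false
positive); the balanced subclass-wise null — which preserves the subclass
structure while removing class information — correctly finds nothing
(p = 0.595). The closed form predicts the inflated chance level for the
projected-coordinate model (`{"ccr_closed_form": 0.5266, ...}` at K=10,
ICC=0.138; the bias grows further with dimensionality), and leave-one-
subclass-out CV removes the bias entirely (`"ccr": 0.425` on the same data).

The same machinery is available from Python:

```python
from nestedmvpa import (SimParams, generate_dataset, cross_validate, CVScheme,
                        block_permutation_null, p_value, corollary_ccr)

data = generate_dataset(SimParams(d=100, K=10, N=12, sigma_C=0,
                                  sigma_S=0.4, sigma_W=1, seed=42))
obs = cross_validate(data, "paper_lda", CVScheme(seed=1)).ccr
null = block_permutation_null(data, "paper_lda", CVScheme(seed=1),
                              n_perm=199, seed=2)
print(obs, p_value(obs, null), corollary_ccr(K=10, icc=0.138))
```

Larger studies (CCR surfaces, significance-bias maps) run via
`nestedmvpa sweep surface|theory|sb --config cfg.yaml --out dir/`; see
`docs/methods.md` for the models and default scales.

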