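# odeident

Structural and practical identifiability analysis — and D-optimal
experiment design — for nonlinear ODE models, aimed at modelers in animal
science and microbial fermentation who need to know *before* collecting
data whether their parameters can be estimated at all, and under which
experimental conditions they can be estimated accurately.

## The problem

A dynamic model

```
dx/dt = f(x, u, p),    y = g(x, u, p),    x(0) = x0
```

is *structurally identifiable* when noise-free input–output data determine
the parameter vector `p` uniquely: `y(t, p̂) = y(t, p*) ⇒ p̂ = p*`.  This
is a property of the model structure and the measurement choice alone.
When it fails, no amount of data or optimizer sophistication can recover
the true parameters — the fit can be perfect while every biologically
meaningful parameter value is wrong.

`odeident` tests the *local* version of this property with the
observability rank condition: stack the Lie derivatives of the measured
outputs,

```
L⁰h = h,    Lʲ⁺¹h = (∂Lʲh/∂x)·f + Σᵢ (∂Lʲh/∂u⁽ⁱ⁾)·u⁽ⁱ⁺¹⁾,
```

and check the generic rank of their Jacobian with respect to the unknown
quantities (unknown parameters, then unknown initial conditions).  Full
column rank ⇔ every quantity is locally identifiable; a rank deficiency
yields null-space directions that show which parameter combinations
compensate each other.  Rank evaluation uses exact rational arithmetic at
random integer points — there is no floating-point rank tolerance.  For
small models an exact symbolic solve of the Taylor-coefficient matching
equations additionally *counts* the indistinguishable parameter sets
(distinguishing e.g. "locally identifiable with 2 solutions" from
"globally unique").

Practical identifiability is quantified through the Fisher information
matrix of a concrete noisy design,

```
FIM = Σₖ S_y(tₖ)ᵀ W S_y(tₖ),    W = diag(1/σ²),
```

with output sensitivities `S_y` from the forward sensitivity equations;
`sqrt(diag(FIM⁻¹))` are Cramér–Rao standard deviations.  Multistart
weighted least squares and profile likelihood complete the toolbox, and
the `oed` module maximizes `log det(FIM)` over constant or
piecewise-linear input signals (D-optimal design).

Six executable example models ship in the zoo: a two-compartment passage
model (`twocomp`), β-casein hydrolysis with competitive product inhibition
and its identifiable reparameterization (`betacasein`,
`betacasein_reduced`), rumen methanogenesis with and without
stoichiometric yield closure (`methanogenesis`, `methanogenesis_reduced`),
and a substrate-inhibited chemostat (`monod_haldane`).

## Worked example

Is the β-casein hydrolysis model identifiable when only the substrate
concentration is measured?

```
$ ident structural betacasein
{
  "generic_rank": 2,
  "n_unknowns": 3,
  "nullspace": [["91260", "71928", "115759"]],
  "verdicts": {
    "Km": "non_identifiable",
    "k": "non_identifiable",
    "kI": "non_identifiable"
  },
  ...
}
```

The Jacobian has generic rank 2 for 3 unknowns: all of `k`, `Km`, `kI` are
non-identifiable, with one compensating direction (the null vector, in
`(k, Km, kI)` coordinates at the evaluation point).  Only two parameter
*combinations* are determined by the data — and indeed the reparameterized
model with `b1 = k·kI/(Km−kI)`, `b2 = Km·(kI+x0)/(Km−kI)` is fully
identifiable:

```
$ ident structural betacasein_reduced --count-solutions
  ...
  "verdicts": {"b1": "locally_identifiable", "b2": "locally_identifiable"},
  "solution_count": {"count": 1, ...}
```

The same library calls are available in Python:

```python
import numpy as np
import odeident as oi

model = oi.get_model("twocomp")
result = oi.test_local_identifiability(model)
print(result.per_quantity_verdict)
# {'p1': 'locally_identifiable', 'p2': 'locally_identifiable',
#  'x1(0)': 'locally_identifiable'}

print(oi.count_output_equivalent_params(model).count)   # 2
```

Measuring only `x2` with `x1(0)` unknown leaves the passage-rate model
*locally* identifiable with exactly **two** output-equivalent solutions —
the fast and slow rate constants swap.  A perfect fit can therefore sit at
entirely wrong parameter values; knowing `x1(0)` (count 1) removes the
ambiguity.

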