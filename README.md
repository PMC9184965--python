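# waddyn

Tools for modelling cell-fate decisions as dynamics on parametrized potential
landscapes.

A differentiating cell population is modelled as noisy overdamped motion on a
potential surface `F(x, θ)` whose shape is steered by signals through the
parameters `θ`. Attractors of the flow are cell fates, index-1 saddles are
decision points, and fate changes happen through two — and only two — kinds of
codimension-one events as `θ` varies:

* **rest-point collisions** (folds): an attractor and a saddle merge and
  annihilate, destroying a fate;
* **connection changes** (flips): the unstable manifold of a saddle switches
  the attractor it feeds, rewiring which decisions are reachable without any
  rest point appearing or disappearing.

The flow is a *Riemannian gradient flow* `ẋ = −G(x)⁻¹ ∇F(x, θ)`: the positive
definite metric `G` never moves rest points or their Morse indices (so the
potential is always a Lyapunov function), but it can redirect saddle
connections — two systems with identical landscapes can make different
decisions. The package provides:

* a catalogue of polynomial landscape families (`waddyn.families`) with exact
  gradients and Hessians, including the compactified elliptic umbilic (the
  canonical binary-flip landscape), standard and dual cusps;
* deterministic and stochastic integration of the metric gradient flow
  (`waddyn.flow`);
* rest-point finding, Morse classification, saddle-manifold tracking and
  decision graphs (`waddyn.geometry`);
* fold-curve tracing, cusp detection/classification, flip location and a full
  bifurcation atlas over a parameter box (`waddyn.bifurcation`);
* an exact census of non-isomorphic fate topologies (`waddyn.census`);
* population simulation with time-dependent signals and fate-proportion
  tables (`waddyn.cellpop`, `waddyn.scenarios`);
* likelihood-free (ABC-SMC) fitting of signal parameters to observed fate
  proportions (`waddyn.abc`);
* expression-correlation signatures of transitions (`waddyn.signatures`);
* a `waddyn` command-line interface driven by YAML/JSON configs
  (`waddyn.config`, `waddyn.cli`).

## Worked example

Rest points and the decision graph of the binary-flip landscape at a point
with three fates (one progenitor, two committed):

```python
import numpy as np
from waddyn import LandscapeModel, make_family, find_rest_points, decision_graph

model = LandscapeModel(make_family("elliptic_umbilic"), theta=[-1.0, 0.1])
for rp in find_rest_points(model):
    print(rp.id, rp.kind, np.round(rp.position, 3), "V=%.3f" % rp.potential)
print("decision graph edges:", decision_graph(model).edges)
```

```
r0 attractor [ 1.908 -2.769] V=-7.943
r1 attractor [-3.153 -0.008] V=-7.461
r2 attractor [1.897 2.748] V=-7.392
r3 saddle1 [0.646 0.039] V=-0.498
r4 saddle1 [-0.493 -0.051] V=0.288
decision graph edges: [('r0', 'r2'), ('r0', 'r1')]
```

The progenitor (`r1`) feeds the lower committed fate (`r0`), which in turn is
connected to the upper fate (`r2`) across the central saddle: a hierarchy of
two binary decisions.

Driving a population through the progenitor-destroying fold forces each cell
to commit. With no signal offset the split is symmetric; a small offset tilts
it strongly:

```python
from waddyn.scenarios import commitment_ramp_table, committed_split

table = commitment_ramp_table([0.0, 0.2], n_cells=400, sigma=0.2, seed=1)
print(committed_split(table))
```

```
  condition  upper_fraction  n_committed
0       b=0          0.4475          400
1     b=0.2          0.0250          400
```

The same computations are available from the command line, driven by a config
file (see `examples/model.yaml` and `examples/fit.yaml`):

```sh
waddyn rest-points --config examples/model.yaml --out rest_points.csv
waddyn simulate --config examples/model.yaml --out fates.csv --n-cells 400 --seed 1
waddyn enumerate-topologies --n 4 --out census.json
waddyn fit --config examples/fit.yaml --observed fates.csv --out posterior.csv
```

Every artifact is written with a `.meta.json` sidecar recording the seed and
package version.

## Reproduction

All results are deterministic given a seed. To run the test suite
(unit tests plus end-to-end property tests; about six minutes on one CPU):

```sh
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

To recompute the headline summary statistics (census size, atlas mechanism
count, fold-discriminant residuals, Lyapunov checks, fate splits, fit
recovery error, pulse persistence):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This runs in about six minutes and writes a JSON object mapping each
statistic to its value and the size of the underlying sample. See `docs/methods.md` for model definitions, numerical
choices and limitations.
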