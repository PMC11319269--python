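# signalfate

Forward and inverse simulation of signal-driven stem-cell fate patterning.

Two stem-cell populations (SC1, SC2) share a plane and never touch each
other; everything they know about the world arrives through two diffusible
chemical signals. Each cell carries a tri-stable genetic switch — two
mutually repressing, self-activating determinants x and y —

    dx/dt = a_x x^n/(b^n + x^n) + k1 b^n/(b^n + y^n) - g1 x
    dy/dt = a_y y^n/(b^n + y^n) + k2 b^n/(b^n + x^n) - g2 y

whose self-activation rates a_x, a_y are biased by the local signal pair
(s1, s2) through saturating transfer functions. High-x resolves to
offspring A (lineage 1) or C (lineage 2), high-y to B or D, the diagonal
state to self-renewal. The signals themselves are stationary patterns of a
confined activator–inhibitor (Turing) system,

    ds_u/dt =   lap(s_u) + gamma (A s_u - s_v + C)
    ds_v/dt = d lap(s_v) + gamma (B s_u - s_v - 1),   0 <= s_u <= su_max,

whose steady states fall into three classes — spots, reverse spots,
stripes — selected by the activator cap su_max. A stochastic population
algorithm (Gillespie/tau-leap switch kinetics, 6×6 look-up tables over
binned signal values, convergence of emergence probabilities) maps any
pair of signal patterns to a six-phenotype cellular pattern; an inverse
map reconstructs binary signal planes from a pattern and recognizes their
class. The package is for computational/systems biologists studying how
positional chemical information is converted into tissue organization.

## Worked example

```python
import numpy as np
from signalfate import (RunConfig, SignalField, run_algorithm1,
                        reconstruct_signals)

cfg = RunConfig(sz=24, max_cycles=2000)
v1 = np.full((24, 24), 5.0); v2 = np.full((24, 24), 5.0)
v1[2:8, 2:8] = 0.0          # signal-1 hole            -> local (s1, s2) = (0, 5)
v2[14:20, 14:20] = 0.0      # signal-2 hole            -> (5, 0)
v1[14:20, 2:8] = 0.0        # overlapping holes        -> (0, 0)
v2[14:20, 2:8] = 0.0
res = run_algorithm1(cfg, seed=7, signals=(SignalField(v1), SignalField(v2)))

codes, counts = np.unique(res.grid.codes, return_counts=True)
print(dict(zip(codes.tolist(), counts.tolist())))
print("cycles to convergence:", res.n_cycles)

planes = reconstruct_signals(res.grid)
diff = np.isin(res.grid.codes, (2, 3, 5, 6))
ok = (planes.s1_plane[diff] == v1[diff] / 5).mean()
print(f"signal-1 recovered on {ok:.0%} of differentiated pixels")
```

prints

```
{1: 34, 2: 230, 3: 20, 4: 254, 5: 16, 6: 22}
cycles to convergence: 20
signal-1 recovered on 100% of differentiated pixels
```

Reading: on the high/high plateau, lineage-1 sites differentiate into A
(code 2, blue) while lineage-2 sites are left neutral and self-renew as SC2
(code 4, green); the signal-1 hole drives lineage-2 sites to C (code 5)
while lineage-1 sites there stay stem (code 1), the signal-2 hole drives
lineage-2 to D (code 6), and the doubly-cold corner yields B (code 3). The
inverse pixel map then recovers the binarized signal planes exactly on
every differentiated pixel.

The same machinery runs from the shell:

```bash
signalfate signals --preset reverse_spot --sz 100 --seed 1 --out out/
signalfate population --config run.yaml --seed 1 --out out/
signalfate invert --pattern out/pattern.csv --out out/
signalfate score --config run.yaml --n 5 --seed 1 --out out/
```

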