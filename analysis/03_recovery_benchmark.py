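#!/usr/bin/env python
"""Monte-Carlo benchmark: is tau_L measurable at the instrument accuracy?

Simulates 20 noisy replicates (3% multiplicative noise) of the glycine
solution and of the same solution in a collagen matrix, refits each, and
compares the recovered L-process relaxation times. Two findings are
checked: the median recovered tau_L stays within 10% of the generating
72 ps, and the glycine and collagen+glycine distributions are
indistinguishable - the synthetic re-enactment of the observation that the
solute rotation (hence the local viscosity) is unaffected by the collagen
network. Writes results/recovery_benchmark.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

import dielax as dx

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

TRUE_TAU_PS = 72.0
rows = []
for system, seed_base in (("glycine_solution", 0), ("collagen_glycine_solution", 1000)):
    model = dx.fixture(system)
    for k in range(20):
        spec = dx.simulate_spectrum(
            model, dx.TDR_BAND, dx.NoiseSpec(0.03, seed=seed_base + k)
        )
        fit = dx.fit_relaxation(spec, dx.FitConfig(seed=k))
        rows.append(
            dict(system=system, replicate=k, tau_L_ps=fit.model.process("L").tau * 1e12)
        )

df = pd.DataFrame(rows)
df.to_csv(OUT / "recovery_benchmark.csv", index=False)

medians = df.groupby("system")["tau_L_ps"].median()
for system, med in medians.items():
    err = abs(med - TRUE_TAU_PS) / TRUE_TAU_PS
    print(f"{system:<28} median tau_L = {med:6.1f} ps  ({err:.1%} from {TRUE_TAU_PS} ps)")

g = df[df.system == "glycine_solution"].tau_L_ps
c = df[df.system == "collagen_glycine_solution"].tau_L_ps
_, p = stats.mannwhitneyu(g, c)
print(f"rank test glycine vs collagen+glycine: p = {p:.2f} "
      f"({'indistinguishable' if p > 0.05 else 'DIFFERENT'})")
print(f"table written to {OUT / 'recovery_benchmark.csv'}")
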