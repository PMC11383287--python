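"""A single demo cell: quiescent when starved, a ~48 h oscillator in media.

Simulates the average serum-starved cell with and without growth factors and
detects division events from the CycB-CDK1 trough marker.
"""

import numpy as np

from lineagesim import (Stimuli, build_demo_model, detect_division,
                        growth_media, simulate_cell, starved_average_state)

model = build_demo_model()
base = starved_average_state(model)

starved = simulate_cell(base.copy(), Stimuli(), 96.0, model=model,
                        stochastic_death=False)
print("starved 96 h: division events =", detect_division(starved),
      " (no mitogens -> the cell sits at a fixed point)")

stimulated = simulate_cell(base.copy(), growth_media(), 200.0, model=model,
                           stochastic_death=False)
divisions = detect_division(stimulated)
periods = np.diff(divisions)
print(f"EGF 3.3 nM + insulin 1721 nM, 200 h: divisions at "
      f"{np.round(divisions, 1)} h")
print(f"inter-division period {periods.mean():.1f} h "
      "(the deterministic cell-cycle length under full growth media)")
print(f"peak ERK activity {stimulated.channel('erk_activity').max():.0f} nM, "
      f"peak CycB-CDK1 {stimulated.channel('cyclinB_cdk1').max():.1f} nM")
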