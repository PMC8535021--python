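"""Simulate one manikin resuscitation scenario and measure it breath by breath.

Generates the easiest training scenario (S1: apnoea, normal compliance,
30 s of optimal PPV to baby-cry) and runs the respiratory-function-monitor
style analysis: per-inflation PIP, PEEP, expired tidal volume and mask leak.
"""

import numpy as np

from venticomp import analyze_episode, simulate_scenario

episode = simulate_scenario("S1", seed=1)
print(f"scenario S1: success (baby-cry) after {episode.success_time:.0f} s "
      f"of effective PPV, {episode.n_breaths} inflations delivered")

seq = analyze_episode(episode)
df = seq.to_frame()
print(f"extracted {seq.n_breaths} inflations, "
      f"total PPV time {seq.total_ppv_time:.1f} s")
print(f"median PIP  {df.pip_mbar.median():5.1f} mbar   (set: 30)")
print(f"median PEEP {df.peep_mbar.median():5.1f} mbar   (set: 5)")
print(f"median eV_T {df.evt_ml_kg.median():5.2f} mL/kg  (per 3.14 kg)")
print(f"median leak {df.leak_pct.median():5.1f} %")
print("PIP/PEEP show the pressures the provider actually delivered; eV_T is")
print("the expired volume per kg (the tidal-volume estimate); leak is the")
print("fraction of inspired volume lost at the face-mask seal.")
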