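"""Inspect the packaged species table and its spawning calendars.

Shows the 11 life histories, then expands one lunar spawner's calendar:
limpets release on new-moon days inside their two seasonal windows.
"""

from datetime import datetime

import numpy as np

from larvanet.biology import (
    assign_pld,
    get_species,
    lunar_phase,
    spawning_events,
    species_params,
)

for sp in species_params():
    windows = ",".join(f"{a}-{b}" for a, b in sp.spawn_days)
    moon = sp.moon_phase or "-"
    print(f"{sp.name:26s} PLD {sp.pld_min:5.0f}-{sp.pld_max:3.0f} d  {sp.pld_class:6s} "
          f"days {windows:15s} moon {moon:4s} habitat {'/'.join(sorted(sp.habitat_set))}")

limpet = get_species("Cellana spp.", n_larvae=6000)
events = spawning_events(limpet, ["site-a", "site-b"], datetime(2011, 1, 1), datetime(2011, 7, 1), seed=0)
days = sorted({e.datetime.date() for e in events})
print(f"\nlimpet spawning: {len(events)} events on {len(days)} new-moon days: {days}")
print("lunar phase on those days:", [round(lunar_phase(datetime(d.year, d.month, d.day, 12)), 3) for d in days])
print("total larvae released:", sum(e.n_released for e in events), "(matches the budget exactly)")

rng = np.random.default_rng(0)
plds = assign_pld(limpet, rng, size=5)
print("five PLD draws (uniform 3-18 d):", np.round(plds, 1))
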