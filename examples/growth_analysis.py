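"""Analyze an expansion time-lapse at normalized covered areas.

Generates a growth sequence (the covered area climbs past four times
the starting area), then samples the network indexes at normalized
areas 1.0 .. 4.0 in steps of 0.5 using linear interpolation of the
time-area series.
"""

import warnings

import veinnet as vn
from veinnet.pipeline import RunConfig, run_prefusion

warnings.filterwarnings("ignore")

scenes = vn.generate_growth_sequence(seed=3, n_frames=10, frame_interval_min=60.0)
config = RunConfig(frame_interval_min=60.0, reps=30, seed=0)
table = run_prefusion(config, frames=[s.frame for s in scenes])

cols = ["normalized_area", "time_min", "CA_mm2", "n_nodes", "n_edges",
        "mean_degree", "nnl", "le", "tortuosity", "ft_norm_50"]
print(table[cols].round(3).to_string(index=False))
# Each row is the network at the moment the cell first covered that
# multiple of its initial area; times between frames come from linear
# interpolation of the (running-max) covered-area series.
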