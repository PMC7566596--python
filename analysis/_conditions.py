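"""Shared study conditions for the analysis drivers.

Three time points mimic the stress time course: the interchromosomal
fraction of RNA-DNA pairs rises from the baseline 0.34 to 0.63, and the set
of designated hub SEs grows monotonically while earlier hubs persist.
"""

from carnet.simulate import SimConfig

SEED = 2020

TIME_POINTS = ("day0", "day3", "day7")
P_INTER = {"day0": 0.34, "day3": 0.50, "day7": 0.63}
# the day-0 hub is a constitutively strong one; hubs recruited later
# strengthen over the time course, mirroring the growth of hub connection
# counts as dysfunction progresses
HUB_SPEC = {
    "day0": {"SE001": 45.0},
    "day3": {"SE001": 45.0, "SE010": 25.0, "SE020": 22.0},
    "day7": {"SE001": 45.0, "SE010": 30.0, "SE020": 27.0, "SE030": 22.0,
             "SE040": 22.0},
}
N_PAIRS = 1_000_000


def base_config() -> SimConfig:
    return SimConfig(seed=SEED)
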