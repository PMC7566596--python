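#!/usr/bin/env python
"""Simulate the three-time-point RNA-DNA interaction study.

Generates the shared annotation set (genome, genes, SEs) and one BEDPE
sample per time point with rising interchromosomal fraction and a growing
hub roster.  Large intermediates go to scratch/sim/; the per-sample summary
table goes to results/.

Finding: the realized interchromosomal fractions track the generating
values (0.34 / 0.50 / 0.63) to within sampling error.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _conditions import HUB_SPEC, N_PAIRS, P_INTER, SEED, TIME_POINTS, base_config

from carnet.pairs import compute_stats, interchromosomal_fraction, write_bedpe
from carnet.simulate import make_annotations, simulate_read_pairs, write_annotations

ROOT = Path(__file__).resolve().parents[1]
SIM_DIR = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = base_config()
    ann = make_annotations(cfg)
    paths = write_annotations(ann, SIM_DIR)
    print(f"annotations: {len(ann.genes)} genes, {len(ann.ses)} SEs -> {SIM_DIR}")

    rows = []
    for i, tp in enumerate(TIME_POINTS):
        pairs = simulate_read_pairs(
            cfg, ann, n_pairs=N_PAIRS, p_inter=P_INTER[tp],
            hub_spec=HUB_SPEC[tp], seed=SEED + 10 + i,
        )
        write_bedpe(pairs, SIM_DIR / f"{tp}.bedpe")
        stats = compute_stats(pairs, sample_id=tp)
        rows.append(
            {
                "sample": tp,
                "total_pairs": stats.total_pairs,
                "inter_pairs": stats.inter_pairs,
                "intra_pairs": stats.intra_pairs,
                "inter_fraction": round(interchromosomal_fraction(stats), 4),
                "generating_p_inter": P_INTER[tp],
                "n_designated_hubs": len(HUB_SPEC[tp]),
            }
        )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "01_sample_stats.tsv", sep="\t", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
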