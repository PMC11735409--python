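#!/usr/bin/env python
"""Trinarize marker levels, gate cells and summarize colony composition.

Reads the disc-colony cell table from results/02/, classifies SOX2 and TBXT
into absent/low/high, gates cells into co-expression classes and writes the
gated table plus composition summary under results/03/.
"""

from axialquant.io import read_table, write_table
from axialquant.markers import composition_summary, default_gates, gate_cells, trinarize

from _common import RESULTS, SEED

OUT = RESULTS / "03"


def main() -> None:
    records, _ = read_table(RESULTS / "02" / "disc" / "cells.csv")
    thresholds = {}
    for marker in ("SOX2", "TBXT"):
        res = trinarize(records[f"mean_{marker}"].to_numpy(), method="gmm")
        records[f"level_{marker}"] = res.levels
        thresholds[marker] = tuple(round(t, 2) for t in res.thresholds)
    records, counts = gate_cells(records, default_gates())
    records["colony_id"] = 1
    per_colony, summary = composition_summary(records)
    OUT.mkdir(parents=True, exist_ok=True)
    write_table(OUT / "cells_gated.csv", records,
                {"stage": "quantify", "seed": SEED, "thresholds": thresholds})
    write_table(OUT / "composition_summary.csv", summary.reset_index(), {"stage": "quantify"})
    print(f"thresholds: {thresholds}")
    print("class proportions:", (counts / counts.sum()).round(3).to_dict())


if __name__ == "__main__":
    main()
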