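#!/usr/bin/env python
"""Tabulate the hot-spot residue (second GXGXG position of the sensor-kinase
G2 box) across a synthetic protein set and annotate with Kyte-Doolittle
hydropathy.

Writes results/hotspot_tally.csv.
"""

from pathlib import Path

import pandas as pd

from tcstune import motif_scan as ms
from tcstune import synthetic_data as sd

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    dist = {"L": 0.35, "I": 0.15, "A": 0.15, "V": 0.10, "F": 0.05,
            "M": 0.05, "T": 0.05, "S": 0.05, "C": 0.03, "W": 0.02}
    recs, _ = sd.gen_protein_set(5000, motif_fraction=0.8,
                                 hotspot_distribution=dist,
                                 config=sd.SyntheticConfig(seed=11))
    tally = ms.tabulate_hotspots(recs)
    df = pd.DataFrame(
        [{"residue": aa, "count": c, "frequency": tally.frequencies[aa],
          "hydropathy": ms.hydropathy_score(aa)}
         for aa, c in sorted(tally.counts.items(), key=lambda kv: -kv[1])])
    df.to_csv(OUT / "hotspot_tally.csv", index=False)

    print(f"{tally.n_sequences_with_motif}/{tally.n_sequences_total} sequences "
          f"carry a G2-box GXGXG motif "
          f"({100 * tally.n_sequences_with_motif / tally.n_sequences_total:.1f}%).")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    hydro = (df.frequency * df.hydropathy).sum()
    print(f"-> frequency-weighted mean hydropathy {hydro:+.2f}: the hot spot "
          f"is dominated by hydrophobic residues, consistent with the site "
          f"tolerating (and being tunable by) hydrophobic substitutions.")


if __name__ == "__main__":
    main()
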