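#!/usr/bin/env python
"""Human microarray arm: quantile normalization, moderated t-test, calls.

Melanoma (19 samples) against nevus (18 samples); a gene is differentially
regulated at linear fold change > 2 and p < 0.05.
"""

import argparse
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from xconcord import tables_io
from xconcord.microarray_de import call_array_de, moderated_t, quantile_normalize


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    data = args.outdir / "data"
    if not (data / "intensities.tsv").exists():
        sys.exit("run analysis/01_simulate.py first")

    intens = tables_io.read_intensity_table(data / "intensities.tsv",
                                            data / "intensity_groups.tsv")
    norm = quantile_normalize(intens)
    res = call_array_de(moderated_t(norm, "nevus", "melanoma"),
                        fold=2.0, p=0.05)
    calls = res.df["call"].value_counts()
    print(f"moderated t (d0 = {res.d0:.3g}, s0^2 = {res.s0_sq:.3g}): "
          f"{calls.get('up', 0)} up, {calls.get('down', 0)} down "
          f"of {len(res.df)} symbols")
    tables_io.write_table(res.df, args.outdir / "de_human.tsv",
                          index_label="symbol")


if __name__ == "__main__":
    main()
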