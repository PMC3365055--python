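#!/usr/bin/env python
"""Cross-species concordance: join fish and human calls on gene symbols,
extract the conserved up/down signature, count motif-style overlaps, and run
hypergeometric over-representation of the conserved set against synthetic
pathway gene sets built from the planted truth.
"""

import argparse
from pathlib import Path
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from xconcord import tables_io
from xconcord.cross_species import (conserved_signature, join_on_symbols,
                                    motif_overlap, over_representation)
from xconcord.diffexpr_nb import call_de, fit_variance
from xconcord.microarray_de import call_array_de, moderated_t, quantile_normalize
from xconcord.rnaseq_quant import collapse_to_genes, size_factors
from xconcord.synthetic_data import SimTruth, score_recovery
from xconcord.tables_io import SignatureSet


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=20120531,
                    help="seed for the synthetic pathway draw")
    args = ap.parse_args()
    data = args.outdir / "data"
    if not (data / "counts.tsv").exists():
        sys.exit("run analysis/01_simulate.py first")

    counts, annotation = tables_io.read_count_table(
        data / "counts.tsv", data / "annotation.tsv", data / "groups.tsv")
    orthologs = tables_io.read_ortholog_table(data / "orthologs.tsv")
    truth = SimTruth(pd.read_csv(data / "truth.tsv", sep="\t",
                                 index_col="gene_id"))

    gene_counts, symbols = collapse_to_genes(counts, annotation)
    combined = gene_counts.relabel_groups({t: "TUM" for t in ("XE", "MM", "UM")})
    sf = size_factors(combined)
    fish_de = call_de(combined, sf, fit_variance(combined, sf), "HP", "TUM",
                      mode="fc_and_p", symbols=symbols)

    factors = size_factors(gene_counts)
    model = fit_variance(gene_counts, factors)
    tumor_contrasts = [call_de(gene_counts, factors, model, "HP", t,
                               mode="fc_only", symbols=symbols)
                       for t in ("XE", "MM", "UM")]

    intens = tables_io.read_intensity_table(data / "intensities.tsv",
                                            data / "intensity_groups.tsv")
    human_de = call_array_de(moderated_t(quantile_normalize(intens),
                                         "nevus", "melanoma"))

    table = join_on_symbols(fish_de, human_de, orthologs,
                            paralog_policy="any_call")
    print(f"symbol join: {len(table.df)} common symbols")
    print(table.status_counts().to_string())
    tables_io.write_table(table.df, args.outdir / "concordance.tsv",
                          index_label="symbol")

    up, down = conserved_signature(table)
    print(f"conserved signature: {len(up)} commonly up, {len(down)} commonly down")
    scores = score_recovery(truth, conserved=(up, down))
    print(scores.round(3).to_string())

    # motif-style overlap: planted up-set as a synthetic proliferative motif
    planted_up = truth.conserved_symbols("up")
    motif = SignatureSet("synthetic_motif_up", frozenset(planted_up), "up")
    rep = motif_overlap(tumor_contrasts, motif, fold=2.0, quantifier="all")
    print(f"motif overlap ({rep.name}): {rep.n_signature} in signature, "
          f"{rep.n_shared} shared with the fish dataset, "
          f"{rep.n_meeting} >{rep.fold:g}-fold up in all tumors")
    tables_io.write_table(rep.df, args.outdir / "overlap_report.tsv")

    # over-representation of the conserved set in synthetic pathways
    universe = set(table.df.index)
    rng = np.random.default_rng(args.seed)
    uni_list = sorted(universe)
    pathways = {
        "planted_conserved_mix": (set(rng.choice(sorted(planted_up & universe),
                                                 size=min(20, len(planted_up)),
                                                 replace=False))
                                  | set(rng.choice(uni_list, 30, replace=False))),
        "random_background": set(rng.choice(uni_list, 50, replace=False)),
    }
    enr = over_representation(up | down, pathways, universe)
    print(enr.round(4).to_string())
    tables_io.write_table(enr, args.outdir / "enrichment.tsv",
                          index_label="pathway")


if __name__ == "__main__":
    main()
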