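#!/usr/bin/env python
"""Cross-species conservation of DMVs, imprinted DMR genes and XCI escapees.

Aggregates the per-species runs through the ortholog map: pairwise DMV-gene
conservation (100*n/min(x, y)), genes with predicted allelic DMRs in >= 2
species ranked by species count, and genes escaping XCI in >= 3 species.
Writes results/cross_species/.
"""

from methcompare.pipeline import cross_species_run

from _common import SPECIES, results_dir, run_species


def main():
    out = results_dir("cross_species")
    results = {
        sp: run_species(sp, ["landscape", "segment", "allelic", "xci", "enrich"])
        for sp in SPECIES
    }
    agg = cross_species_run(results, outdir=out)
    print("DMV-gene conservation (100*n/min(x,y)):")
    print(agg["dmv_conservation"].round(1).to_string())
    print("\nOrthologs with allelic DMRs in >= 2 species:")
    print(agg["dmr_genes"].to_string(index=False))
    print("\nOrthologs escaping XCI in >= 3 species:")
    print(agg["escapees"].to_string(index=False))


if __name__ == "__main__":
    main()
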