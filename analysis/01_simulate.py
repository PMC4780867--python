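"""Generate the six-stage synthetic time course and summarize its truth.

Writes the full fixture directory (genome FASTA, GTF, replicate peak BEDs,
binned count tracks, expression table, motif library, truth manifest) under
scratch/ and the planted bookkeeping tables under results/.
"""

from common import RESULTS, SCRATCH, ensure_dirs, get_fixture

from hemodyn.simulate import manifest_census


def main() -> None:
    ensure_dirs()
    fx = get_fixture()
    outdir = fx.write(SCRATCH / "fixture")
    census = manifest_census(fx.manifest)
    census["dhs_patterns"].to_csv(RESULTS / "fixture_dhs_patterns.tsv",
                                  sep="\t", index=False)
    census["expression_clusters"].to_csv(
        RESULTS / "fixture_expression_clusters.tsv", sep="\t", index=False)
    census["promoter_timelines"].to_csv(
        RESULTS / "fixture_promoter_timelines.tsv", sep="\t", index=False)
    print(f"fixture written to {outdir}")
    print(f"{len(fx.genes)} genes, {len(fx.dhs_truth)} DHS "
          f"({(fx.dhs_truth['kind'] == 'distal').sum()} distal), "
          f"{sum(len(v) for v in fx.tf_peaks.values())} TF peaks, "
          f"{len(fx.config.grn_truth)} planted network edges")
    print("planted DHS pattern populations:")
    print(census["dhs_patterns"].to_string(index=False))


if __name__ == "__main__":
    main()
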