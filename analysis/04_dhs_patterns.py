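"""Six-digit binary DHS dynamics across the stage series.

Reduces replicate DHS peak files to reproducible regions, builds the
cross-stage union, encodes each union DHS as a six-digit presence code in
stage order (e.g. 000110 = open in HE and HP only), classifies rows as
promoter-proximal or distal, and censuses pattern populations with the
>100 eligibility filter used for overlap testing.
"""

from common import RESULTS, SCRATCH, ensure_dirs, get_fixture, pattern_table

from hemodyn import dhs as D


def main() -> None:
    ensure_dirs()
    fx = get_fixture()
    table = pattern_table(fx)
    D.write_pattern_table(table, SCRATCH / "dhs_pattern_table.tsv")
    census = D.pattern_census(table)
    census.to_csv(RESULTS / "dhs_pattern_census.tsv", sep="\t", index=False)
    print(f"{len(table)} union DHS "
          f"({(table['klass'] == 'distal').sum()} distal)")
    print(census.to_string(index=False))
    for a, b in (("HB", "ESC"), ("MAC", "HP")):
        uniq = D.unique_stage_dhs(table, a, b)
        print(f"distal DHS unique to {a} vs {b}: {len(uniq)}")


if __name__ == "__main__":
    main()
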