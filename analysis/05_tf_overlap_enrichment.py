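"""TF binding vs chromatin dynamics and gene expression.

Two integrations: (1) significance of overlap between every TF ChIP peak
set and every eligible DHS pattern (uniform-over-rows null on the union
DHS universe); (2) the expression-cluster x TF matrix combining the
length-weighted gene-set overlap test with H3K27ac bootstrap Z-scores at
the TF sites, flagged at p < 1e-4.
"""

import pandas as pd
from common import RESULTS, ensure_dirs, get_fixture, pattern_table

from hemodyn import dhs as D
from hemodyn import enrichment as E
from hemodyn.intervals import STAGES


def main() -> None:
    ensure_dirs()
    fx = get_fixture()
    table = pattern_table(fx, classify=False)

    rows = []
    for (tf, stage), peaks in sorted(fx.tf_peaks.items()):
        reproducible = D.filter_reproducible(fx.tf_replicates(tf, stage))
        res = E.dhs_pattern_tf_overlap(table, reproducible,
                                       n_resamples=100_000, seed=3)
        for code, r in sorted(res.items()):
            rows.append({"tf": tf, "stage": stage, "code": code,
                         "observed": r.observed, "null_mean": round(r.null_mean, 2),
                         "p": r.p})
    patt = pd.DataFrame(rows)
    patt.to_csv(RESULTS / "dhs_pattern_tf_overlap.tsv", sep="\t", index=False)
    sig = patt[patt["p"] < 1e-4]
    print(f"{len(sig)} significant (pattern, TF@stage) overlaps of {len(patt)}:")
    print(sig.to_string(index=False))

    clusters = {}
    for gid, cl in fx.gene_cluster.items():
        if cl and cl != "FLAT":
            clusters.setdefault(cl, set()).add(gid)
    ac_tracks = {s: fx.tracks[("H3K27ac", s)] for s in STAGES}
    mat = E.integration_matrix(
        clusters, fx.enrichment_peaks, fx.domains, ac_tracks,
        fx.config.bin_size, n_resamples=100_000, seed=5)
    mat.to_csv(RESULTS / "cluster_tf_integration.tsv", sep="\t", index=False)
    print("\ncluster x TF integration (p and H3K27ac Z):")
    print(mat.to_string(index=False))


if __name__ == "__main__":
    main()
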