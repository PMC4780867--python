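"""Synthetic six-stage multi-omics fixture with a machine-readable truth
manifest.

The generator emulates the data shape of a hematopoietic differentiation
time course across the ordered stages ESC, MES, HB, HE, HP and MAC: a small
random genome; gene models with planted expression clusters and four-state
promoter-chromatin timelines; DHS with planted six-digit stage codes and
replicate peak files; TF ChIP peaks nested in DHS with embedded motif
instances; binned count tracks for DHS and four histone marks consistent
with the promoter plan; a planted TF->TF binding graph; and gene-set-
targeted ChIP peaks for enrichment testing.  Everything planted is recorded
in the manifest so downstream recovery can be scored by counting.

Randomness: a single global seed; every component draws from a named
substream (seed + CRC32 of the component name) so adding one component
never perturbs the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chromstate import ACTIVE, POISED, REPRESSED, UNMARKED, MARKS
from .enrichment import RegulatoryDomain, build_regulatory_domains
from .intervals import STAGES, GeneModel, GenomicInterval, write_bed, write_gtf
from .motifs import PWM, pwm_from_consensus, write_meme

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}

#: Planted motif consensus sequences (12-mers) for the fixture library.
MOTIF_CONSENSUS: dict[str, str] = {
    "EBOX": "ATAACAGCTGGT",
    "GATA": "TTCAGATAAGAT",
    "ETS": "CCACAGGAAGTG",
    "TEAD": "TTACATTCCACG",
    "RUNX": "CTTCTGTGGTTT",
    "CEBP": "GATTGCGCAATC",
}

#: Letter code per coarse promoter state used in planted timelines.
STATE_LETTERS = {"A": ACTIVE, "R": REPRESSED, "P": POISED, "U": UNMARKED}
#: Marks deposited at a promoter for each planted coarse state.
MARKS_BY_STATE: dict[str, tuple[str, ...]] = {
    "A": ("DHS", "H3K4me3", "H3K9ac", "H3K27ac"),
    "P": ("DHS", "H3K4me3", "H3K27me3"),
    "R": ("H3K27me3",),
    "U": (),
}

DEFAULT_PATTERN_COUNTS: dict[str, int] = {
    "111111": 400,
    "100000": 300,
    "000001": 300,
    "000110": 200,
    "001000": 200,
    "010000": 150,
    "000100": 150,
    "011111": 100,
    "000011": 100,
    "110000": 100,
}

#: Per-cluster mean log10(FPKM) across the six stages.
DEFAULT_CLUSTER_MEANS: dict[str, tuple[float, ...]] = {
    "C1": (2.0, 1.5, 0.5, 0.2, 0.2, 0.2),     # pluripotency-like, silenced
    "C2": (0.2, 0.5, 1.0, 2.0, 0.8, 0.3),     # HE peak (vasculogenic-like)
    "C3": (-1.0, -1.0, -0.3, 0.5, 1.8, 0.8),  # HP-peaked hematopoietic regulators
    "C4": (-1.0, -1.0, -1.0, -1.0, 0.7, 2.2), # macrophage-only
}
DEFAULT_PROMOTER_PLAN: dict[str, str] = {
    "C1": "AARRRR",
    "C2": "UUPAAR",
    "C3": "UUUPAA",
    "C4": "RRRRPA",
    "FLAT": "AAAAAA",
}

DEFAULT_TF_EXPRESSION: dict[str, tuple[float, ...]] = {
    "Tal1": (0.1, 0.3, 12.0, 25.0, 30.0, 0.5),
    "Lmo2": (0.1, 0.4, 10.0, 22.0, 28.0, 6.0),
    "Gata2": (0.05, 0.2, 8.0, 15.0, 3.0, 0.1),
    "Fli1": (0.1, 0.2, 0.3, 9.0, 20.0, 25.0),
    "Cebpb": (0.1, 0.1, 0.2, 0.3, 5.0, 40.0),
}
DEFAULT_TF_PROMOTER_PLAN: dict[str, str] = {
    "Tal1": "PPAAAR",
    "Lmo2": "PPAAAA",
    "Gata2": "PPAARR",
    "Fli1": "UUPAAA",
    "Cebpb": "UUUPAA",
}
DEFAULT_TF_MOTIF: dict[str, str] = {
    "Tal1": "EBOX", "Lmo2": "EBOX", "Gata2": "GATA", "Fli1": "ETS",
    "Cebpb": "CEBP",
}
DEFAULT_CHIP_AVAILABILITY: dict[str, tuple[str, ...]] = {
    "Tal1": ("HB", "HE", "HP"),
    "Lmo2": ("HB", "HE", "HP"),
    "Gata2": ("HB", "HE"),
    "Fli1": ("HE", "HP", "MAC"),
    "Cebpb": ("HP", "MAC"),
}
#: Fraction of DHS rows of a given code bound by each TF at each stage
#: ("*" = background over all other planted rows).  Binding to rows whose
#: code is still closed at the stage models enhancer priming.
DEFAULT_TF_DHS_BINDING: dict[tuple[str, str], dict[str, float]] = {
    ("Tal1", "HB"): {"001000": 0.6, "000110": 0.5, "*": 0.05},
    ("Tal1", "HE"): {"000110": 0.6, "011111": 0.3, "*": 0.05},
    ("Tal1", "HP"): {"000110": 0.4, "*": 0.05},
    ("Lmo2", "HB"): {"001000": 0.5, "000110": 0.5, "*": 0.05},
    ("Lmo2", "HE"): {"000110": 0.5, "*": 0.05},
    ("Lmo2", "HP"): {"000011": 0.2, "*": 0.05},
    ("Gata2", "HB"): {"001000": 0.4, "*": 0.05},
    ("Gata2", "HE"): {"000110": 0.3, "*": 0.05},
    ("Fli1", "HE"): {"000110": 0.5, "011111": 0.3, "*": 0.05},
    ("Fli1", "HP"): {"000011": 0.4, "*": 0.05},
    ("Fli1", "MAC"): {"000001": 0.3, "*": 0.05},
    ("Cebpb", "HP"): {"000011": 0.4, "*": 0.05},
    ("Cebpb", "MAC"): {"000001": 0.5, "111111": 0.3, "*": 0.05},
}
DEFAULT_GRN_TRUTH: tuple[tuple[str, str, str], ...] = (
    ("Tal1", "Tal1", "HB"), ("Tal1", "Lmo2", "HB"), ("Tal1", "Fli1", "HB"),
    ("Lmo2", "Tal1", "HB"), ("Lmo2", "Lmo2", "HB"), ("Lmo2", "Fli1", "HB"),
    ("Gata2", "Tal1", "HB"), ("Gata2", "Gata2", "HB"),
    ("Tal1", "Tal1", "HE"), ("Tal1", "Lmo2", "HE"), ("Tal1", "Fli1", "HE"),
    ("Tal1", "Gata2", "HE"),
    ("Lmo2", "Tal1", "HE"), ("Lmo2", "Lmo2", "HE"), ("Lmo2", "Fli1", "HE"),
    ("Fli1", "Fli1", "HE"), ("Fli1", "Tal1", "HE"), ("Fli1", "Lmo2", "HE"),
    ("Gata2", "Fli1", "HE"),
    ("Tal1", "Gata2", "HP"), ("Tal1", "Cebpb", "HP"), ("Lmo2", "Gata2", "HP"),
    ("Fli1", "Tal1", "HP"), ("Cebpb", "Cebpb", "HP"), ("Cebpb", "Tal1", "HP"),
    ("Fli1", "Fli1", "MAC"), ("Fli1", "Tal1", "MAC"),
    ("Cebpb", "Cebpb", "MAC"), ("Cebpb", "Fli1", "MAC"),
    ("Cebpb", "Tal1", "MAC"), ("Cebpb", "Lmo2", "MAC"),
    ("Cebpb", "Gata2", "MAC"),
)
#: TF -> list of (stage, number of blood-regulator loci bound there).
DEFAULT_REPROGRAMMING_PLAN: dict[str, tuple[tuple[str, int], ...]] = {
    "Tal1": (("HB", 13),),
    "Lmo2": (("HB", 13),),
    "Gata2": (("HB", 4),),
    "Fli1": (("HE", 5),),
}
#: Gene-set ChIP assay: (tf, stage) -> planted cluster + fractions.
DEFAULT_ENRICHMENT_PLAN: dict[tuple[str, str], dict[str, float]] = {
    ("Gata2", "HB"): {"C2": 0.9, "*": 0.05},
    ("Tal1", "HB"): {"*": 0.05},
    ("Fli1", "HE"): {"*": 0.05},
}
#: Motif -> fraction of DHS rows per code (and "*" background) carrying an
#: embedded instance independent of TF peaks.
DEFAULT_MOTIF_DHS_PLAN: dict[str, dict[str, float]] = {
    "TEAD": {"001000": 0.5, "*": 0.05},
}
#: Extra motif embedding inside TF ChIP peaks (co-localization analysis).
DEFAULT_MOTIF_PEAK_PLAN: dict[tuple[str, str], dict[str, float]] = {
    ("Tal1", "HB"): {"TEAD": 0.4},
    ("Lmo2", "HB"): {"TEAD": 0.4},
}


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic time course."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    bin_size: int = 200
    n_genes: int = 200
    n_flat_genes: int = 39
    gene_span: int = 4_000
    min_gene_gap: int = 5_000
    dhs_width: int = 400
    dhs_min_tss_distance: int = 1_500
    tf_peak_width: int = 200
    n_replicates: int = 2
    replicate_dropout: float = 0.0
    jitter: int = 0
    track_background_mean: float = 1.0
    track_enriched_mean: float = 12.0
    deterministic_tracks: bool = False
    expression_log_sd: float = 0.10
    expression_floor: float = 1.0
    motif_match_prob: float = 0.7
    motif_mutation_rate: float = 0.05
    dhs_pattern_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_COUNTS))
    cluster_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_MEANS))
    promoter_plan_by_cluster: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PROMOTER_PLAN))
    tf_expression: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TF_EXPRESSION))
    tf_promoter_plan: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TF_PROMOTER_PLAN))
    tf_motif: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TF_MOTIF))
    chip_availability: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CHIP_AVAILABILITY))
    tf_dhs_binding: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_TF_DHS_BINDING))
    grn_truth: tuple[tuple[str, str, str], ...] = DEFAULT_GRN_TRUTH
    reprogramming_plan: dict[str, tuple[tuple[str, int], ...]] = field(
        default_factory=lambda: dict(DEFAULT_REPROGRAMMING_PLAN))
    enrichment_plan: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_ENRICHMENT_PLAN))
    motif_dhs_plan: dict[str, dict[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_DHS_PLAN))
    motif_peak_plan: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_PEAK_PLAN))
    n_blood_targets: int = 15

    @property
    def tf_panel(self) -> list[str]:
        return sorted(self.tf_expression)

    def validate(self) -> None:
        for code, n in self.dhs_pattern_counts.items():
            if len(code) != len(STAGES) or set(code) - {"0", "1"}:
                raise ValueError(f"bad pattern code {code!r}")
            if n < 0:
                raise ValueError("pattern counts must be >= 0")
        for prob in (self.replicate_dropout, self.motif_mutation_rate):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for (tf, stage), plan in self.tf_dhs_binding.items():
            if tf not in self.tf_expression:
                raise ValueError(f"binding plan references unknown TF {tf!r}")
            for code in plan:
                if code != "*" and code not in self.dhs_pattern_counts:
                    raise ValueError(
                        f"TF {tf} bound to nonexistent DHS pattern {code!r}")
            if stage not in self.chip_availability.get(tf, ()):
                raise ValueError(f"{tf} has no ChIP availability at {stage}")
        for s, t, stage in self.grn_truth:
            if stage not in self.chip_availability.get(s, ()):
                raise ValueError(f"edge {s}->{t}@{stage}: source lacks ChIP there")
        n_clustered = self.n_genes - len(self.tf_expression) - self.n_flat_genes
        if n_clustered < len(self.cluster_means):
            raise ValueError("not enough genes for the cluster plan")


def _rng(seed: int, *names: str) -> np.random.Generator:
    """Named substream: stable under addition of other components."""
    return np.random.default_rng(
        [int(seed)] + [zlib.crc32(n.encode()) for n in names])


def _min_gap_positions(rng: np.random.Generator, n: int, lo: int, hi: int,
                       min_gap: int) -> np.ndarray:
    """n sorted positions in [lo, hi) with pairwise gaps >= min_gap."""
    slack = (hi - lo) - n * min_gap
    if slack <= 0:
        raise ValueError("interval too small for requested spacing")
    u = np.sort(rng.uniform(0, slack, size=n))
    return (lo + u + min_gap * np.arange(n)).astype(np.int64)


def _revcomp_codes(codes: list[int]) -> list[int]:
    return [3 - c for c in reversed(codes)]


@dataclass
class Fixture:
    """In-memory synthetic time course plus its truth manifest."""

    config: FixtureConfig
    chrom_sizes: dict[str, int]
    genome_codes: dict[str, np.ndarray]
    genes: list[GeneModel]
    gene_cluster: dict[str, str | None]
    promoter_plan: dict[str, str]
    expression: pd.DataFrame
    dhs_truth: pd.DataFrame          # chrom,start,end,code,kind,gene
    domains: list[RegulatoryDomain]
    tf_peaks: dict[tuple[str, str], list[GenomicInterval]]
    enrichment_peaks: dict[tuple[str, str], list[GenomicInterval]]
    replicate_peaks: dict[tuple[str, str, int], list[GenomicInterval]]
    tracks: dict[tuple[str, str], dict[str, np.ndarray]]
    pwms: list[PWM]
    blood_targets: list[str]
    manifest: dict

    _genome_str: dict[str, str] | None = None

    @property
    def genome(self) -> dict[str, str]:
        if self._genome_str is None:
            lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
            self._genome_str = {
                c: lut[codes].tobytes().decode() for c, codes in self.genome_codes.items()
            }
        return self._genome_str

    @property
    def gene_models(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def dhs_replicates(self, stage: str) -> list[list[GenomicInterval]]:
        return [self.replicate_peaks[("DHS", stage, r)]
                for r in range(self.config.n_replicates)]

    def tf_replicates(self, tf: str, stage: str) -> list[list[GenomicInterval]]:
        return [self.replicate_peaks[(f"TF:{tf}", stage, r)]
                for r in range(self.config.n_replicates)]

    def write(self, outdir: str | Path) -> Path:
        """Write the complete fixture directory (text formats only)."""
        import yaml
        from pyfaidx import Faidx

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fasta = out / "genome.fa"
        with open(fasta, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        Faidx(str(fasta)).close()
        write_gtf(self.genes, out / "genes.gtf")
        (out / "peaks").mkdir(exist_ok=True)
        for (assay, stage, rep), ivs in sorted(self.replicate_peaks.items()):
            safe = assay.replace(":", "_")
            write_bed(ivs, out / "peaks" / f"{safe}_{stage}_rep{rep + 1}.bed")
        (out / "tracks").mkdir(exist_ok=True)
        for (mark, stage), per_chrom in sorted(self.tracks.items()):
            rows = []
            for chrom in sorted(per_chrom):
                counts = per_chrom[chrom]
                starts = np.arange(len(counts)) * self.config.bin_size
                rows.append(pd.DataFrame(
                    {"chrom": chrom, "bin_start": starts, "count": counts}))
            pd.concat(rows).to_csv(out / "tracks" / f"{mark}_{stage}.tsv",
                                   sep="\t", index=False)
        self.expression.to_csv(out / "expression.tsv", sep="\t",
                               index_label="gene_id")
        write_meme(self.pwms, out / "motifs.meme")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True))
        cfg = asdict(self.config)
        for key in ("tf_dhs_binding", "enrichment_plan", "motif_peak_plan"):
            cfg[key] = {"|".join(k): v for k, v in cfg[key].items()}
        cfg["grn_truth"] = [list(e) for e in cfg["grn_truth"]]
        (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
        return out


def _plant_genes(config: FixtureConfig) -> tuple[list[GeneModel], dict[str, str | None], dict[str, str], list[str]]:
    rng = _rng(config.seed, "genes")
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    tss_by_chrom = {
        chrom: _min_gap_positions(
            rng, int(n), 30_000, config.chrom_length - 30_000, config.min_gene_gap)
        for chrom, n in zip(chroms, per_chrom)
    }
    tf_panel = sorted(config.tf_expression)
    n_tf = len(tf_panel)
    tf_slots = {(i + 1) * config.n_genes // (n_tf + 1): tf
                for i, tf in enumerate(tf_panel)}
    genes: list[GeneModel] = []
    idx = 0
    for chrom in chroms:
        for tss in tss_by_chrom[chrom]:
            gid = tf_slots.get(idx, f"G{idx:03d}")
            strand = "+" if idx % 2 == 0 else "-"
            tss = int(tss)
            if strand == "+":
                span = GenomicInterval(chrom, tss, tss + config.gene_span)
            else:
                span = GenomicInterval(chrom, tss + 1 - config.gene_span, tss + 1)
            genes.append(GeneModel(gid, chrom, strand, tss, span))
            idx += 1
    cluster_ids = sorted(config.cluster_means)
    non_tf = [g.gene_id for g in genes if g.gene_id not in tf_panel]
    n_clustered = len(non_tf) - config.n_flat_genes
    gene_cluster: dict[str, str | None] = {tf: None for tf in tf_panel}
    for j, gid in enumerate(non_tf):
        if j < n_clustered:
            gene_cluster[gid] = cluster_ids[j % len(cluster_ids)]
        else:
            gene_cluster[gid] = "FLAT"
    promoter_plan = {}
    for g in genes:
        if g.gene_id in tf_panel:
            promoter_plan[g.gene_id] = config.tf_promoter_plan[g.gene_id]
        else:
            promoter_plan[g.gene_id] = config.promoter_plan_by_cluster[
                gene_cluster[g.gene_id]]
    blood = [gid for gid in non_tf if gene_cluster[gid] == "C3"][: config.n_blood_targets]
    return genes, gene_cluster, promoter_plan, blood


def generate_fixture(config: FixtureConfig | None = None) -> Fixture:
    """Generate the full in-memory fixture for a configuration."""
    config = config or FixtureConfig()
    config.validate()
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_sizes = {c: config.chrom_length for c in chroms}
    genes, gene_cluster, promoter_plan, blood = _plant_genes(config)
    gene_by_id = {g.gene_id: g for g in genes}
    domains = build_regulatory_domains(genes, chrom_sizes)
    dom_by_gene = {d.gene_id: d for d in domains}
    tf_panel = sorted(config.tf_expression)
    tf_domains = [dom_by_gene[tf] for tf in tf_panel]

    # ---- genome --------------------------------------------------------
    rng_genome = _rng(config.seed, "genome")
    genome_codes = {
        c: rng_genome.integers(0, 4, size=config.chrom_length).astype(np.uint8)
        for c in chroms
    }

    # ---- planted distal DHS -------------------------------------------
    rng_dhs = _rng(config.seed, "dhs")
    n_dhs = sum(config.dhs_pattern_counts.values())
    tss_by_chrom = {
        c: np.array(sorted(g.tss for g in genes if g.chrom == c)) for c in chroms
    }
    candidates: list[tuple[str, int]] = []
    per_chrom_target = -(-n_dhs // len(chroms))
    for chrom in chroms:
        mids = _min_gap_positions(
            rng_dhs, int(per_chrom_target * 1.6), 5_000,
            config.chrom_length - 5_000, 1_200)
        tss = tss_by_chrom[chrom]
        near = np.searchsorted(tss, mids)
        dist_r = np.where(near < len(tss), np.abs(tss[np.minimum(near, len(tss) - 1)] - mids), np.inf)
        dist_l = np.where(near > 0, np.abs(mids - tss[np.maximum(near - 1, 0)]), np.inf)
        ok = np.minimum(dist_l, dist_r) >= config.dhs_min_tss_distance
        for mid in mids[ok]:
            mid = int(mid)
            in_tf_dom = any(d.chrom == chrom and d.start <= mid < d.end
                            for d in tf_domains)
            if not in_tf_dom:
                candidates.append((chrom, mid))
    if len(candidates) < n_dhs:
        raise ValueError("could not place the requested number of DHS")
    candidates.sort()
    chosen = [candidates[i] for i in
              sorted(rng_dhs.choice(len(candidates), size=n_dhs, replace=False))]
    codes = [c for code, n in sorted(config.dhs_pattern_counts.items())
             for c in [code] * n]
    codes = [codes[i] for i in rng_dhs.permutation(n_dhs)]
    half = config.dhs_width // 2
    dhs_rows = [
        {"chrom": chrom, "start": mid - half, "end": mid + half,
         "code": code, "kind": "distal", "gene": None}
        for (chrom, mid), code in zip(chosen, codes)
    ]
    # promoter DHS follow each gene's planted chromatin timeline
    for g in genes:
        letters = promoter_plan[g.gene_id]
        code = "".join("1" if MARKS_BY_STATE[l] and "DHS" in MARKS_BY_STATE[l] else "0"
                       for l in letters)
        if "1" in code:
            dhs_rows.append({
                "chrom": g.chrom, "start": g.tss - 200, "end": g.tss + 200,
                "code": code, "kind": "promoter", "gene": g.gene_id,
            })
    dhs_truth = pd.DataFrame(dhs_rows).sort_values(
        ["chrom", "start"]).reset_index(drop=True)

    # ---- motif library -------------------------------------------------
    pwms = [pwm_from_consensus(mid, cons, config.motif_match_prob)
            for mid, cons in sorted(MOTIF_CONSENSUS.items())]

    embedded: list[dict] = []
    used_ranges: dict[int, list[tuple[int, int]]] = {}

    def embed(row_idx: int, lo: int, hi: int, motif_id: str,
              rng: np.random.Generator) -> None:
        """Embed one (possibly mutated) motif instance inside [lo, hi)."""
        cons = MOTIF_CONSENSUS[motif_id]
        L = len(cons)
        if hi - lo < L:
            return
        taken = used_ranges.setdefault(row_idx, [])
        for _ in range(20):
            off = int(rng.integers(lo, hi - L + 1))
            if all(off + L <= s or off >= e for s, e in taken):
                break
        else:
            return
        taken.append((off, off + L))
        codes_m = [_BASE_CODE[b] for b in cons]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            codes_m = _revcomp_codes(codes_m)
        codes_m = [
            int(rng.choice([b for b in range(4) if b != c]))
            if rng.random() < config.motif_mutation_rate else c
            for c in codes_m
        ]
        chrom = dhs_truth.at[row_idx, "chrom"]
        genome_codes[chrom][off:off + L] = codes_m
        embedded.append({"dhs_row": int(row_idx), "motif": motif_id,
                         "offset": off, "strand": strand})

    # ---- TF ChIP peaks nested in DHS ----------------------------------
    rng_tf = _rng(config.seed, "tf_peaks")
    distal_idx = dhs_truth.index[dhs_truth["kind"] == "distal"]
    by_code: dict[str, list[int]] = {}
    for i in distal_idx:
        by_code.setdefault(dhs_truth.at[i, "code"], []).append(int(i))
    tf_peaks: dict[tuple[str, str], list[GenomicInterval]] = {}
    peak_meta: dict[tuple[str, str], list[dict]] = {}
    pw = config.tf_peak_width
    for (tf, stage) in sorted(config.tf_dhs_binding):
        plan = config.tf_dhs_binding[(tf, stage)]
        rows: list[int] = []
        star = plan.get("*", 0.0)
        for code, idxs in sorted(by_code.items()):
            frac = plan.get(code, star)
            if frac <= 0:
                continue
            k = int(round(frac * len(idxs)))
            pick = rng_tf.choice(len(idxs), size=min(k, len(idxs)), replace=False)
            rows.extend(idxs[j] for j in sorted(pick))
        peaks, meta = [], []
        for ri in sorted(rows):
            chrom = dhs_truth.at[ri, "chrom"]
            mid = (int(dhs_truth.at[ri, "start"]) + int(dhs_truth.at[ri, "end"])) // 2
            iv = GenomicInterval(chrom, mid - pw // 2, mid + pw // 2)
            peaks.append(iv)
            meta.append({"kind": "dhs", "dhs_row": int(ri),
                         "chrom": chrom, "start": iv.start, "end": iv.end})
            embed(ri, iv.start, iv.end, config.tf_motif[tf], rng_tf)
            extra = config.motif_peak_plan.get((tf, stage), {})
            for motif_id, frac in sorted(extra.items()):
                if rng_tf.random() < frac:
                    embed(ri, iv.start, iv.end, motif_id, rng_tf)
        tf_peaks[(tf, stage)] = peaks
        peak_meta[(tf, stage)] = meta

    # ---- planted network edges ----------------------------------------
    for k, (source, target, stage) in enumerate(sorted(config.grn_truth)):
        g = gene_by_id[target]
        offset = 1_200 + 260 * tf_panel.index(source)
        start = g.tss + offset
        iv = GenomicInterval(g.chrom, start, start + pw)
        tf_peaks.setdefault((source, stage), []).append(iv)
        peak_meta.setdefault((source, stage), []).append(
            {"kind": "edge", "target": target, "chrom": g.chrom,
             "start": iv.start, "end": iv.end})

    # ---- reprogramming-target binding ---------------------------------
    for tf, stage_plans in sorted(config.reprogramming_plan.items()):
        for stage, n_bound in stage_plans:
            if stage not in config.chip_availability.get(tf, ()):
                raise ValueError(f"{tf} reprogramming peaks at {stage} without ChIP")
            for gid in blood[:n_bound]:
                g = gene_by_id[gid]
                start = g.tss + 1_500 + 300 * tf_panel.index(tf)
                iv = GenomicInterval(g.chrom, start, start + pw)
                tf_peaks.setdefault((tf, stage), []).append(iv)
                peak_meta.setdefault((tf, stage), []).append(
                    {"kind": "blood_target", "target": gid, "chrom": g.chrom,
                     "start": iv.start, "end": iv.end})
    for key in tf_peaks:
        pairs = sorted(zip(tf_peaks[key], peak_meta[key]),
                       key=lambda p: p[0].sort_key())
        tf_peaks[key] = [p[0] for p in pairs]
        peak_meta[key] = [p[1] for p in pairs]

    # ---- extra DHS-level motif instances ------------------------------
    rng_motif = _rng(config.seed, "motif_dhs")
    motif_dhs: dict[str, list[int]] = {}
    for motif_id, plan in sorted(config.motif_dhs_plan.items()):
        star = plan.get("*", 0.0)
        rows = []
        for code, idxs in sorted(by_code.items()):
            frac = plan.get(code, star)
            if frac <= 0:
                continue
            k = int(round(frac * len(idxs)))
            pick = rng_motif.choice(len(idxs), size=min(k, len(idxs)), replace=False)
            rows.extend(idxs[j] for j in sorted(pick))
        for ri in sorted(rows):
            embed(ri, int(dhs_truth.at[ri, "start"]),
                  int(dhs_truth.at[ri, "end"]), motif_id, rng_motif)
        motif_dhs[motif_id] = sorted(rows)

    # ---- gene-set ChIP assay (expression-cluster enrichment) ----------
    rng_enr = _rng(config.seed, "enrichment")
    enrichment_peaks: dict[tuple[str, str], list[GenomicInterval]] = {}
    enrichment_targets: dict[str, list[str]] = {}
    cluster_members: dict[str, list[str]] = {}
    for gid, cl in gene_cluster.items():
        if cl is not None:
            cluster_members.setdefault(cl, []).append(gid)
    for cl in cluster_members:
        cluster_members[cl].sort()
    for (tf, stage), plan in sorted(config.enrichment_plan.items()):
        star = plan.get("*", 0.0)
        chosen_genes: list[str] = []
        for cl, members in sorted(cluster_members.items()):
            frac = plan.get(cl, star)
            k = int(round(frac * len(members)))
            pick = rng_enr.choice(len(members), size=min(k, len(members)),
                                  replace=False)
            chosen_genes.extend(members[j] for j in sorted(pick))
        peaks = []
        for gid in sorted(chosen_genes):
            g = gene_by_id[gid]
            start = g.tss + 800
            peaks.append(GenomicInterval(g.chrom, start, start + pw))
        enrichment_peaks[(tf, stage)] = peaks
        enrichment_targets[f"{tf}|{stage}"] = sorted(chosen_genes)

    # ---- expression ----------------------------------------------------
    rng_expr = _rng(config.seed, "expression")
    expr_rows = {}
    for g in genes:
        gid = g.gene_id
        if gid in config.tf_expression:
            expr_rows[gid] = np.array(config.tf_expression[gid], dtype=float)
        elif gene_cluster[gid] == "FLAT":
            noise = rng_expr.normal(0, config.expression_log_sd, size=len(STAGES))
            expr_rows[gid] = 10.0 ** (1.0 + noise)
        else:
            means = np.array(config.cluster_means[gene_cluster[gid]])
            noise = rng_expr.normal(0, config.expression_log_sd, size=len(STAGES))
            expr_rows[gid] = 10.0 ** (means + noise)
    expression = pd.DataFrame.from_dict(expr_rows, orient="index",
                                        columns=list(STAGES))
    expression = expression.loc[[g.gene_id for g in genes]]

    # ---- binned count tracks ------------------------------------------
    rng_tracks = _rng(config.seed, "tracks")
    bs = config.bin_size
    n_bins = {c: chrom_sizes[c] // bs for c in chroms}
    tracks: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for si, stage in enumerate(STAGES):
        lam = {m: {c: np.full(n_bins[c], config.track_background_mean)
                   for c in chroms} for m in MARKS}
        for g in genes:
            letter = promoter_plan[g.gene_id][si]
            lo = max(0, (g.tss - 1000) // bs)
            hi = min(n_bins[g.chrom], -(-(g.tss + 1000) // bs))
            for mark in MARKS_BY_STATE[letter]:
                lam[mark][g.chrom][lo:hi] = config.track_enriched_mean
        open_rows = dhs_truth[(dhs_truth["code"].str[si] == "1")
                              & (dhs_truth["kind"] == "distal")]
        for chrom, start, end in zip(open_rows["chrom"], open_rows["start"],
                                     open_rows["end"]):
            lo = max(0, int(start) // bs)
            hi = min(n_bins[chrom], -(-int(end) // bs))
            lam["DHS"][chrom][lo:hi] = config.track_enriched_mean
        for mark in MARKS:
            if config.deterministic_tracks:
                tracks[(mark, stage)] = {
                    c: np.round(lam[mark][c]).astype(np.int64) for c in chroms}
            else:
                tracks[(mark, stage)] = {
                    c: rng_tracks.poisson(lam[mark][c]).astype(np.int64)
                    for c in chroms}

    # ---- replicate peak files -----------------------------------------
    rng_reps = _rng(config.seed, "replicates")

    def replicate(ivs: list[GenomicInterval]) -> list[GenomicInterval]:
        out = []
        for iv in ivs:
            if config.replicate_dropout and rng_reps.random() < config.replicate_dropout:
                continue
            shift = int(rng_reps.integers(-config.jitter, config.jitter + 1)) \
                if config.jitter else 0
            out.append(GenomicInterval(iv.chrom, max(0, iv.start + shift),
                                       iv.end + shift))
        return sorted(out, key=GenomicInterval.sort_key)

    replicate_peaks: dict[tuple[str, str, int], list[GenomicInterval]] = {}
    for si, stage in enumerate(STAGES):
        open_rows = dhs_truth[dhs_truth["code"].str[si] == "1"]
        stage_dhs = [GenomicInterval(c, int(s), int(e)) for c, s, e in
                     zip(open_rows["chrom"], open_rows["start"], open_rows["end"])]
        for r in range(config.n_replicates):
            replicate_peaks[("DHS", stage, r)] = replicate(stage_dhs)
        for mark in MARKS[1:]:
            regions = []
            for g in genes:
                letter = promoter_plan[g.gene_id][si]
                if mark in MARKS_BY_STATE[letter]:
                    regions.append(GenomicInterval(
                        g.chrom, max(0, g.tss - 1000), g.tss + 1000))
            regions.sort(key=GenomicInterval.sort_key)
            for r in range(config.n_replicates):
                replicate_peaks[(mark, stage, r)] = replicate(regions)
    for (tf, stage), peaks in sorted(tf_peaks.items()):
        for r in range(config.n_replicates):
            replicate_peaks[(f"TF:{tf}", stage, r)] = replicate(peaks)

    # ---- manifest ------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "stages": list(STAGES),
        "chrom_sizes": chrom_sizes,
        "genes": {
            g.gene_id: {
                "chrom": g.chrom, "strand": g.strand, "tss": g.tss,
                "span": [g.span.start, g.span.end],
                "cluster": gene_cluster[g.gene_id],
                "promoter_states": promoter_plan[g.gene_id],
                "expression": [float(v) for v in expression.loc[g.gene_id]],
            } for g in genes
        },
        "dhs": [
            {"chrom": row["chrom"], "start": int(row["start"]),
             "end": int(row["end"]), "code": row["code"], "kind": row["kind"],
             "gene": row["gene"]}
            for row in dhs_truth.to_dict("records")
        ],
        "motif_instances": embedded,
        "motif_dhs_rows": motif_dhs,
        "tf_peaks": {
            f"{tf}|{stage}": meta for (tf, stage), meta in sorted(peak_meta.items())
        },
        "edges": [list(e) for e in sorted(config.grn_truth)],
        "chip_availability": {tf: list(v) for tf, v in
                              sorted(config.chip_availability.items())},
        "blood_targets": blood,
        "reprogramming_plan": {tf: [list(p) for p in plans] for tf, plans in
                               sorted(config.reprogramming_plan.items())},
        "enrichment_targets": enrichment_targets,
        "enrichment_plan": {f"{tf}|{stage}": plan for (tf, stage), plan in
                            sorted(config.enrichment_plan.items())},
    }

    return Fixture(
        config=config, chrom_sizes=chrom_sizes, genome_codes=genome_codes,
        genes=genes, gene_cluster=gene_cluster, promoter_plan=promoter_plan,
        expression=expression, dhs_truth=dhs_truth, domains=domains,
        tf_peaks=tf_peaks, enrichment_peaks=enrichment_peaks,
        replicate_peaks=replicate_peaks, tracks=tracks, pwms=pwms,
        blood_targets=blood, manifest=manifest,
    )


def manifest_census(manifest: Mapping) -> dict[str, pd.DataFrame]:
    """Oracle summary tables recomputed from the manifest by counting."""
    dhs = pd.DataFrame(manifest.get("dhs", []))
    if len(dhs):
        pattern_counts = dhs["code"].value_counts().sort_index()
        patterns = pd.DataFrame({"code": pattern_counts.index,
                                 "count": pattern_counts.values})
    else:
        patterns = pd.DataFrame(columns=["code", "count"])
    genes = manifest.get("genes", {})
    clusters = pd.Series([v["cluster"] for v in genes.values() if v["cluster"]],
                         dtype=object).value_counts().sort_index()
    clusters = pd.DataFrame({"cluster": clusters.index, "count": clusters.values})
    timelines = pd.Series([v["promoter_states"] for v in genes.values()],
                          dtype=object).value_counts().sort_index()
    timelines = pd.DataFrame({"timeline": timelines.index,
                              "count": timelines.values})
    edges = pd.DataFrame(manifest.get("edges", []),
                         columns=["source", "target", "stage"])
    return {"dhs_patterns": patterns, "expression_clusters": clusters,
            "promoter_timelines": timelines, "edges": edges}


# ---------------------------------------------------------------------------
# Planted HMM sequences (chromatin-state recovery fixtures)
# ---------------------------------------------------------------------------

#: Emission profiles of the four canonical promoter states over the five
#: marks (DHS, H3K4me3, H3K9ac, H3K27ac, H3K27me3).
FOUR_STATE_EMISSION = np.array([
    [0.9, 0.9, 0.9, 0.9, 0.1],   # ACTIVE
    [0.9, 0.9, 0.1, 0.1, 0.9],   # POISED
    [0.1, 0.1, 0.1, 0.1, 0.9],   # REPRESSED
    [0.1, 0.1, 0.1, 0.1, 0.1],   # UNMARKED
])


def generate_hmm_fixture(
    n_bins: int = 10_000,
    seed: int = 0,
    emission: np.ndarray | None = None,
    self_transition: float = 0.94,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sample (observations, states, emission, transition) from a planted HMM."""
    emission = FOUR_STATE_EMISSION.copy() if emission is None else np.asarray(emission)
    K, M = emission.shape
    transition = np.full((K, K), (1 - self_transition) / (K - 1))
    np.fill_diagonal(transition, self_transition)
    rng = _rng(seed, "hmm")
    states = np.empty(n_bins, dtype=np.int64)
    states[0] = rng.integers(K)
    for t in range(1, n_bins):
        states[t] = rng.choice(K, p=transition[states[t - 1]])
    X = (rng.random((n_bins, M)) < emission[states]).astype(np.uint8)
    return X, states, emission, transition
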