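"""Synthetic multifocal-tumor data with known ground truth.

Emulates a patient carrying a germline truncal variant who develops several
clonally independent tumors in the same organ: each tumor has a private set
of somatic mutations organised in a small clone tree (linear or branched),
a tumor-specific loss-of-heterozygosity breakpoint on the short arm of
chromosome 3, its own average ploidy (optionally genome-doubled), and
regions sampled at different tumor purities.

The simulator works on a miniature three-chromosome genome (10 Mb each,
100-kb bins) so that every downstream stage — variant validation, clone
trees, joint segmentation, purity/ploidy inference and mirrored-BAF
testing — can be exercised end to end in seconds.

Read-level observations invert the standard purity/ploidy mixture model:

    E[VAF]  = rho * m * ccf / (2(1-rho) + rho*q)
    E[BAF]  = ((1-rho) + rho*b) / (2(1-rho) + rho*q)
    E[logR] = log2((2(1-rho) + rho*q) / D),   D = 2(1-rho) + rho*tau

with alt counts drawn binomially at Poisson-distributed depth and per-bin
Gaussian logR noise plus a linear GC bias term.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimConfigError",
    "CloneTruth",
    "TumorTruth",
    "SyntheticTruth",
    "simulate_patient",
    "simulate_region_reads",
    "simulate_normal_reads",
    "write_fixtures",
    "chr3_annotation",
    "GENOME",
    "BIN_SIZE",
]

# Miniature genome: three 10-Mb chromosomes, fixed 100-kb bins.
GENOME: dict[str, int] = {"1": 10_000_000, "2": 10_000_000, "3": 10_000_000}
BIN_SIZE: int = 100_000

# Chromosome-3 short-arm annotation (1-based inclusive): three genes and the
# centromere, used to label LOH breakpoints.
CHR3_FEATURES: list[tuple[str, int, int]] = [
    ("CLRN1", 1_150_001, 1_250_000),
    ("ALCAM", 2_350_001, 2_450_000),
    ("BFSP2", 4_150_001, 4_250_000),
    ("centromere", 4_900_001, 5_500_000),
]

GERMLINE_VARIANT_ID = "germline_VHL_R120X"
GERMLINE_POS = ("3", 500_001)


class SimConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Study design of one simulated multifocal patient.

    Defaults describe a patient with four clonally independent tumors,
    ~13 truncal mutations each, purities spanning 0.3-0.9, one
    genome-doubled tumor (target ploidy 3.64, i.e. DNA index 1.82) and
    distinct chromosome-3p breakpoints per tumor.
    """

    n_tumors: int = 4
    regions_per_tumor: int | Sequence[int] = 4
    topologies: Sequence[str] = ("linear", "linear", "linear", "branched")
    truncal_mutations: int = 13
    branch_mutations: int = 2
    n_subclones: int = 1
    purity_range: tuple[float, float] = (0.3, 0.9)
    ploidy_per_tumor: Sequence[float] = (2.0, 2.0, 2.0, 3.64)
    depth_mean: float = 100.0
    logr_sd: float = 0.1
    gc_bias_coeff: float = 0.5
    breakpoint_3p: Sequence[int] = (1_200_001, 2_400_001, 5_100_001, 4_200_001)
    error_rate: float = 0.0
    snps_per_bin: int = 2
    het_fraction: float = 0.67
    subclone_ccf: float = 1.0
    seed: int = 0

    def regions_of(self, t: int) -> int:
        if isinstance(self.regions_per_tumor, int):
            return self.regions_per_tumor
        return int(self.regions_per_tumor[t])

    def validate(self) -> None:
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise SimConfigError(f"purity_range must lie in (0,1]: {self.purity_range}")
        if self.n_tumors < 1:
            raise SimConfigError("n_tumors must be >= 1")
        for t in range(self.n_tumors):
            if self.regions_of(t) < 2:
                raise SimConfigError("regions_per_tumor must be >= 2")
        if len(self.breakpoint_3p) < self.n_tumors:
            raise SimConfigError("need one 3p breakpoint per tumor")
        bps = list(self.breakpoint_3p[: self.n_tumors])
        if len(set(bps)) != len(bps):
            raise SimConfigError("3p breakpoints must be distinct across tumors")
        for bp in bps:
            if not (1 < bp <= GENOME["3"]):
                raise SimConfigError(f"breakpoint {bp} outside chromosome 3")
        if len(self.ploidy_per_tumor) < self.n_tumors:
            raise SimConfigError("need one ploidy per tumor")
        for tau in self.ploidy_per_tumor[: self.n_tumors]:
            if tau <= 0:
                raise SimConfigError("ploidy must be > 0")
        for topo in self.topologies[: self.n_tumors]:
            if topo not in ("linear", "branched"):
                raise SimConfigError(f"unknown topology {topo!r}")
        if self.truncal_mutations < 1:
            raise SimConfigError("truncal_mutations must be >= 1")


@dataclass
class CloneTruth:
    """One clone: its new mutations and the regions where it is present."""

    clone_id: str
    parent: str | None
    mutations: list[str]
    regions: list[str]


@dataclass
class TumorTruth:
    tumor_id: str
    regions: list[str]
    topology: str
    clones: list[CloneTruth]
    ploidy: float
    breakpoint_3p: int
    # segments: (chrom, start, end, total copy q, minor copy nB), 1-based inclusive
    segments: list[tuple[str, int, int, int, int]]

    @property
    def dna_index(self) -> float:
        return self.ploidy / 2.0

    def mutation_regions(self) -> dict[str, list[str]]:
        """Region presence of every mutation (clone plus all descendants)."""
        out: dict[str, list[str]] = {}
        for clone in self.clones:
            for mut in clone.mutations:
                out[mut] = list(clone.regions)
        return out

    def state_at(self, chrom: str, pos: int) -> tuple[int, int]:
        """(q, nB) of the truth segment containing a position."""
        for c, s, e, q, nb in self.segments:
            if c == chrom and s <= pos <= e:
                return q, nb
        raise KeyError(f"position {chrom}:{pos} not covered by truth segments")


@dataclass
class SyntheticTruth:
    """Full ground truth for one simulated patient."""

    config: SimConfig
    tumors: list[TumorTruth]
    purity: dict[str, float]                      # region -> rho
    mutations: pd.DataFrame                       # per-mutation metadata
    snps: pd.DataFrame                            # genome-wide SNP panel
    gc: pd.DataFrame                              # per-bin GC fractions

    @property
    def region_ids(self) -> list[str]:
        return [r for t in self.tumors for r in t.regions]

    def tumor_of_region(self, region: str) -> TumorTruth:
        for t in self.tumors:
            if region in t.regions:
                return t
        raise KeyError(f"unknown region {region!r}")

    def presence_matrix(self) -> pd.DataFrame:
        """True binary somatic mutation x region presence matrix."""
        regions = self.region_ids
        rows = {}
        for t in self.tumors:
            for mut, regs in t.mutation_regions().items():
                rows[mut] = [1 if r in regs else 0 for r in regions]
        return pd.DataFrame.from_dict(rows, orient="index", columns=regions).astype(int)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "tumors": [dataclasses.asdict(t) for t in self.tumors],
            "purity": self.purity,
            "mutations": self.mutations.to_dict(orient="list"),
            "snps": self.snps.to_dict(orient="list"),
            "gc": self.gc.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        for key in ("regions_per_tumor",):
            if isinstance(cfg[key], list):
                cfg[key] = tuple(cfg[key])
        for key in ("topologies", "ploidy_per_tumor", "breakpoint_3p", "purity_range"):
            cfg[key] = tuple(cfg[key])
        config = SimConfig(**cfg)
        tumors = []
        for t in payload["tumors"]:
            clones = [CloneTruth(**c) for c in t.pop("clones")]
            t["segments"] = [tuple(s) for s in t["segments"]]
            tumors.append(TumorTruth(clones=clones, **t))
        return cls(
            config=config,
            tumors=tumors,
            purity=payload["purity"],
            mutations=pd.DataFrame(payload["mutations"]),
            snps=pd.DataFrame(payload["snps"]),
            gc=pd.DataFrame(payload["gc"]),
        )


def _genome_bins() -> pd.DataFrame:
    rows = []
    for chrom, length in GENOME.items():
        for start in range(1, length + 1, BIN_SIZE):
            rows.append((chrom, start, min(start + BIN_SIZE - 1, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _copy_segments(tau_target: float, breakpoint: int, tumor_index: int) -> tuple[list, float]:
    """Build truth copy-number segments whose length-weighted mean copy
    number matches the target ploidy as closely as 100-kb bins allow.

    Baseline is diploid (or tetraploid for targets > 3, modelling a genome
    doubling after 3p loss); the 3p LOH region keeps only one haplotype.
    A tumor-specific gain/loss block on chromosome 2 absorbs the remainder.
    """
    bins = _genome_bins()
    n_total = len(bins)
    doubled = tau_target > 3.0
    q_base = 4 if doubled else 2
    nb_base = q_base // 2
    q_loh, nb_loh = (2, 0) if doubled else (1, 0)

    loh_end = breakpoint - 1  # LOH spans chr3:[1, breakpoint-1]
    n_loh = sum((bins.chrom == "3") & (bins.end <= loh_end))

    target_total = int(round(tau_target * n_total))
    base_total = q_base * (n_total - n_loh) + q_loh * n_loh
    delta = target_total - base_total
    if delta > 0:
        q_adj, nb_adj = q_base + 1, nb_base
    else:
        q_adj, nb_adj = q_base - 1, max(nb_base - 1, 0)
    n_adj = abs(delta)
    chr2_bins = GENOME["2"] // BIN_SIZE
    offset = (tumor_index * 25) % max(chr2_bins - n_adj, 1)
    if n_adj > chr2_bins:
        raise SimConfigError(
            f"target ploidy {tau_target} not representable on the miniature genome"
        )

    segments: list[tuple[str, int, int, int, int]] = []
    # chromosome 1: baseline
    segments.append(("1", 1, GENOME["1"], q_base, nb_base))
    # chromosome 2: baseline with one adjustment block
    adj_start = offset * BIN_SIZE + 1
    adj_end = (offset + n_adj) * BIN_SIZE
    if n_adj == 0:
        segments.append(("2", 1, GENOME["2"], q_base, nb_base))
    else:
        if adj_start > 1:
            segments.append(("2", 1, adj_start - 1, q_base, nb_base))
        segments.append(("2", adj_start, adj_end, q_adj, nb_adj))
        if adj_end < GENOME["2"]:
            segments.append(("2", adj_end + 1, GENOME["2"], q_base, nb_base))
    # chromosome 3: LOH then baseline
    loh_bin_end = n_loh * BIN_SIZE
    if n_loh > 0:
        segments.append(("3", 1, loh_bin_end, q_loh, nb_loh))
    if loh_bin_end < GENOME["3"]:
        segments.append(("3", loh_bin_end + 1, GENOME["3"], q_base, nb_base))

    total = sum(((e - s + 1) // BIN_SIZE) * q for _, s, e, q, _ in segments)
    tau_real = total / n_total
    return segments, tau_real


def _clone_tree(
    tumor_id: str,
    regions: list[str],
    topology: str,
    truncal: int,
    branch: int,
    n_subclones: int,
    mut_counter: list[int],
) -> list[CloneTruth]:
    def new_muts(n: int) -> list[str]:
        out = [f"{tumor_id}_M{mut_counter[0] + i:03d}" for i in range(n)]
        mut_counter[0] += n
        return out

    clones = [CloneTruth(f"{tumor_id}_C0", None, new_muts(truncal), list(regions))]
    if branch <= 0:
        return clones
    if topology == "linear":
        parent_regions = list(regions)
        parent_id = clones[0].clone_id
        for k in range(min(n_subclones, len(regions) - 1)):
            child_regions = parent_regions[:-1]  # drop one region per step
            cid = f"{tumor_id}_C{k + 1}"
            clones.append(CloneTruth(cid, parent_id, new_muts(branch), child_regions))
            parent_id, parent_regions = cid, child_regions
    else:  # branched: two sibling subclones in disjoint region subsets
        half = max(1, len(regions) // 2)
        left, right = regions[:half], regions[half:]
        clones.append(CloneTruth(f"{tumor_id}_C1", clones[0].clone_id, new_muts(branch), list(left)))
        clones.append(CloneTruth(f"{tumor_id}_C2", clones[0].clone_id, new_muts(branch), list(right)))
    return clones


def simulate_patient(config: SimConfig) -> SyntheticTruth:
    """Generate the ground truth of one multifocal patient.

    Deterministic given ``config`` (including its seed). Somatic mutation
    sets of distinct tumors are disjoint by construction; one germline
    variant is shared by every sample including the matched normal.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    tumors: list[TumorTruth] = []
    purity: dict[str, float] = {}
    mut_rows = []
    mut_counter = [0]
    next_pos = [100_001]   # somatic mutation positions marched along chr1
    next_pos3 = [160_001]  # second-hit positions marched along the 3p LOH region

    for t in range(config.n_tumors):
        tumor_id = f"T{t + 1}"
        regions = [f"{tumor_id}R{r + 1}" for r in range(config.regions_of(t))]
        topo = config.topologies[t] if t < len(config.topologies) else "linear"
        segments, tau = _copy_segments(
            float(config.ploidy_per_tumor[t]), int(config.breakpoint_3p[t]), t
        )
        clones = _clone_tree(
            tumor_id, regions, topo,
            config.truncal_mutations, config.branch_mutations, config.n_subclones,
            mut_counter,
        )
        tumor = TumorTruth(tumor_id, regions, topo, clones, tau,
                           int(config.breakpoint_3p[t]), segments)
        tumors.append(tumor)
        lo, hi = config.purity_range
        for r in regions:
            purity[r] = float(np.round(rng.uniform(lo, hi), 3))

        doubled = tau > 3.0
        for clone in clones:
            is_trunk = clone.parent is None
            for i, mut in enumerate(clone.mutations):
                if is_trunk and i < 5:
                    # second hits on the retained 3p allele (biallelic
                    # inactivation): land inside every tumor's LOH region,
                    # where VAF = rho*m/(2(1-rho)+rho*q) pins the purity
                    # (logR alone cannot separate rho from rho/2)
                    chrom, pos = "3", next_pos3[0]
                    next_pos3[0] += 50_000
                else:
                    chrom, pos = "1", next_pos[0]
                    next_pos[0] += 50_000
                kind = "indel" if (i % 10) == 9 else "snv"
                ref, alt = ("AC", "A") if kind == "indel" else ("A", "T")
                q, _ = tumor.state_at(chrom, pos)
                m = 2 if (doubled and is_trunk) else 1
                m = min(m, q) if q >= 1 else 1
                ccf = 1.0 if is_trunk else float(config.subclone_ccf)
                mut_rows.append(
                    dict(variant_id=mut, tumor=tumor_id, clone=clone.clone_id,
                         chrom=chrom, pos=pos, ref=ref, alt=alt, kind=kind,
                         multiplicity=m, ccf=ccf)
                )

    mutations = pd.DataFrame(mut_rows)

    # SNP panel, zygosity and B-allele orientation fixed at the patient level
    bins = _genome_bins()
    snp_rows = []
    for _, b in bins.iterrows():
        step = BIN_SIZE // (config.snps_per_bin + 1)
        for k in range(config.snps_per_bin):
            snp_rows.append((b.chrom, b.start + (k + 1) * step))
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos"])
    snps["is_het"] = rng.random(len(snps)) < config.het_fraction
    snps["b_is_minor"] = rng.random(len(snps)) < 0.5
    snps["hom_alt"] = rng.random(len(snps)) < 0.5

    gc = bins.copy()
    gc["gc"] = np.round(rng.uniform(0.35, 0.65, len(bins)), 4)

    return SyntheticTruth(config=config, tumors=tumors, purity=purity,
                          mutations=mutations, snps=snps, gc=gc)


def _expected_vaf(rho: float, m: float, q: float, ccf: float = 1.0) -> float:
    return rho * m * ccf / (2.0 * (1.0 - rho) + rho * q)


def simulate_region_reads(
    truth: SyntheticTruth, region: str, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate sequencing observations for one tumor region.

    Returns ``(variants, snp_counts, logr_track)``:

    * variants — depth/alt-count for every candidate somatic mutation of
      the patient plus the germline variant (alt ~ Binomial(depth, E[VAF]));
    * snp_counts — normal and tumor allele counts at the SNP panel;
    * logr_track — per-bin logR with GC bias and Gaussian noise.
    """
    if region not in truth.purity:
        raise KeyError(f"unknown region {region!r}")
    cfg = truth.config
    if seed is None:
        seed = cfg.seed + 1 + truth.region_ids.index(region)
    rng = np.random.default_rng(seed)

    tumor = truth.tumor_of_region(region)
    rho = truth.purity[region]
    tau = tumor.ploidy
    D = 2.0 * (1.0 - rho) + rho * tau
    present = tumor.mutation_regions()

    # --- candidate variant read counts ----------------------------------
    rows = []
    for _, mut in truth.mutations.iterrows():
        depth = max(int(rng.poisson(cfg.depth_mean)), 1)
        if mut.tumor == tumor.tumor_id and region in present.get(mut.variant_id, ()):
            q, _ = tumor.state_at(mut.chrom, mut.pos)
            p = _expected_vaf(rho, mut.multiplicity, q, mut.ccf)
        else:
            p = cfg.error_rate
        alt = int(rng.binomial(depth, min(max(p, 0.0), 1.0)))
        rows.append(dict(variant_id=mut.variant_id, chrom=mut.chrom, pos=mut.pos,
                         ref=mut.ref, alt_allele=mut.alt, kind=mut.kind,
                         region=region, depth=depth, alt_count=alt,
                         vaf=alt / depth))
    # germline variant: heterozygous in the normal, on the retained 3p allele
    g_chrom, g_pos = GERMLINE_POS
    depth = max(int(rng.poisson(cfg.depth_mean)), 1)
    q_g, nb_g = tumor.state_at(g_chrom, g_pos)
    m_g = q_g - nb_g  # mutant allele retained through LOH
    p_g = ((1.0 - rho) + rho * m_g) / (2.0 * (1.0 - rho) + rho * q_g)
    alt = int(rng.binomial(depth, min(p_g, 1.0)))
    rows.append(dict(variant_id=GERMLINE_VARIANT_ID, chrom=g_chrom, pos=g_pos,
                     ref="C", alt_allele="T", kind="snv", region=region,
                     depth=depth, alt_count=alt, vaf=alt / depth))
    variants = pd.DataFrame(rows)

    # --- SNP allele counts ----------------------------------------------
    snp = truth.snps.copy()
    states = np.array([tumor.state_at(c, p) for c, p in zip(snp.chrom, snp.pos)])
    q_arr, nb_arr = states[:, 0].astype(float), states[:, 1].astype(float)
    b_copies = np.where(snp.b_is_minor, nb_arr, q_arr - nb_arr)
    p_t = ((1.0 - rho) + rho * b_copies) / (2.0 * (1.0 - rho) + rho * q_arr)
    p_n = np.where(snp.is_het, 0.5, np.where(snp.hom_alt, 0.999, 0.001))
    p_t = np.where(snp.is_het, p_t, p_n)  # homozygous SNPs stay homozygous
    n_depth = np.maximum(rng.poisson(cfg.depth_mean, len(snp)), 1)
    t_depth = np.maximum(rng.poisson(cfg.depth_mean, len(snp)), 1)
    n_alt = rng.binomial(n_depth, p_n)
    t_alt = rng.binomial(t_depth, np.clip(p_t, 0.0, 1.0))
    snp_counts = pd.DataFrame({
        "chrom": snp.chrom, "pos": snp.pos, "region": region,
        "normal_ref": n_depth - n_alt, "normal_alt": n_alt,
        "tumor_ref": t_depth - t_alt, "tumor_alt": t_alt,
    })

    # --- logR track ------------------------------------------------------
    track = truth.gc.copy()
    mid = (track.start + track.end) // 2
    states = np.array([tumor.state_at(c, p) for c, p in zip(track.chrom, mid)])
    q_bin = states[:, 0].astype(float)
    expected = np.log2((2.0 * (1.0 - rho) + rho * q_bin) / D)
    noise = rng.normal(0.0, cfg.logr_sd, len(track))
    track["logr"] = expected + cfg.gc_bias_coeff * (track.gc - 0.5) + noise
    track["region"] = region
    logr_track = track[["chrom", "start", "end", "gc", "logr", "region"]]

    return variants, snp_counts, logr_track


def simulate_normal_reads(truth: SyntheticTruth, seed: int | None = None) -> pd.DataFrame:
    """Matched-normal read counts for every candidate variant.

    The germline variant is heterozygous (expected VAF 0.5); somatic
    candidates show only the configured sequencing-error rate.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    for _, mut in truth.mutations.iterrows():
        depth = max(int(rng.poisson(cfg.depth_mean)), 1)
        alt = int(rng.binomial(depth, cfg.error_rate))
        rows.append(dict(variant_id=mut.variant_id, region="normal",
                         depth=depth, alt_count=alt))
    depth = max(int(rng.poisson(cfg.depth_mean)), 1)
    alt = int(rng.binomial(depth, 0.5))
    rows.append(dict(variant_id=GERMLINE_VARIANT_ID, region="normal",
                     depth=depth, alt_count=alt))
    return pd.DataFrame(rows)


def chr3_annotation() -> pd.DataFrame:
    """Gene/centromere annotation of the miniature chromosome 3 (1-based)."""
    return pd.DataFrame(CHR3_FEATURES, columns=["name", "start", "end"]).assign(chrom="3")[
        ["chrom", "start", "end", "name"]
    ]


def write_fixtures(
    truth: SyntheticTruth,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict[str, Path]:
    """Simulate reads for every region and write the full fixture set.

    Emits one VCF per region, a combined variant read-count TSV, a logR
    track TSV plus BED bin definitions, an SNP allele-count TSV, the chr3
    annotation BED, and the ground truth as JSON. All files round-trip
    through :mod:`tumorevo.io`.
    """
    from . import io as tio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_variants, all_snps, all_logr = [], [], []
    paths: dict[str, Path] = {}
    for i, region in enumerate(truth.region_ids):
        rseed = None if seed is None else seed + 1 + i
        variants, snps, logr = simulate_region_reads(truth, region, seed=rseed)
        all_variants.append(variants)
        all_snps.append(snps)
        all_logr.append(logr)
        vcf_path = out / f"{region}.vcf"
        tio.write_region_vcf(variants, vcf_path, region=region)
        paths[f"vcf:{region}"] = vcf_path

    variants = pd.concat(all_variants, ignore_index=True)
    snps = pd.concat(all_snps, ignore_index=True)
    logr = pd.concat(all_logr, ignore_index=True)

    paths["variant_counts"] = out / "variant_counts.tsv"
    variants.to_csv(paths["variant_counts"], sep="\t", index=False)
    paths["normal_counts"] = out / "normal_counts.tsv"
    simulate_normal_reads(truth, seed=truth.config.seed if seed is None else seed) \
        .to_csv(paths["normal_counts"], sep="\t", index=False)
    paths["snp_counts"] = out / "snp_counts.tsv"
    snps.to_csv(paths["snp_counts"], sep="\t", index=False)
    paths["logr"] = out / "logr.tsv"
    logr.to_csv(paths["logr"], sep="\t", index=False, float_format="%.6f")
    paths["bins_bed"] = out / "bins.bed"
    tio.write_bed(truth.gc[["chrom", "start", "end"]], paths["bins_bed"])
    paths["annotation_bed"] = out / "chr3_annotation.bed"
    tio.write_bed(chr3_annotation(), paths["annotation_bed"], name_col="name")
    paths["truth"] = out / "truth.json"
    truth.to_json(paths["truth"])
    return paths
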