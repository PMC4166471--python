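"""End-to-end orchestration: simulate/load -> variants -> clonality ->
segmentation -> purity/ploidy -> allelic imbalance -> report.

Every stage is wrapped so that a failure aborts with the stage name and
cause; all randomness flows from one seed; thresholds actually applied
are logged for the audit trail. The report serialises losslessly to JSON
and byte-identically for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .baf import adjust_mbaf, select_het_snps, test_allelic_imbalance
from .phylogeny import build_clone_tree, delineate_tumors, itb_index
from .purity import (FacsPrior, fit_purity_ploidy, joint_model_selection,
                     ploidy_prior_from_dna_index)
from .segmentation import (SegmentationConfig, joint_segment, map_breakpoint,
                           merge_segments, preprocess_logr)
from .simulate import SimConfig, SyntheticTruth, chr3_annotation, simulate_patient, write_fixtures
from .variants import MutationMatrix, ValidationStatus, build_mutation_matrix, \
    mutational_load, validate_variant, validation_rate

log = logging.getLogger("tumorevo")

__all__ = ["PipelineConfig", "PatientReport", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed driving one pipeline run."""

    out_dir: Path = Path("results")
    seed: int = 0
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # paths when simulate=False
    min_vaf: float = 0.01
    min_depth: int = 50
    gamma: float = 2.0
    winsor_k: float = 2.5
    tau_step: float = 0.05
    lam: float = 1.0
    alpha: float = 0.05
    snp_min_coverage: int = 40
    dna_index: dict = field(default_factory=dict)  # region -> DNA index
    breakpoint_tol: float = 1_000_000.0
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        data["out_dir"] = Path(data.get("out_dir", "results"))
        return cls(**data)


@dataclass
class PatientReport:
    """Full machine-readable result of one patient analysis."""

    data: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(_round_floats(self.data), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PatientReport":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(json.loads(text))

    def __getitem__(self, key: str):
        return self.data[key]


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    return obj


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

@_stage("simulate")
def _stage_simulate(config: PipelineConfig):
    sim_cfg = SimConfig(seed=config.seed, **config.sim_overrides)
    truth = simulate_patient(sim_cfg)
    paths = write_fixtures(truth, Path(config.out_dir) / "inputs")
    return truth, paths


@_stage("load_inputs")
def _stage_load(config: PipelineConfig):
    inp = config.inputs
    # a missing input aborts with the name of the stage that consumes it
    needed_by = {"variant_counts": "variant_processing", "logr": "segmentation",
                 "snp_counts": "allelic_imbalance"}
    for key, stage in needed_by.items():
        if key not in inp or not Path(inp[key]).exists():
            raise PipelineError(stage, FileNotFoundError(
                f"missing required input {key!r}"))
    calls = pd.read_csv(inp["variant_counts"], sep="\t", dtype={"chrom": str})
    normal = (pd.read_csv(inp["normal_counts"], sep="\t")
              if "normal_counts" in inp and Path(inp["normal_counts"]).exists() else None)
    snps = pd.read_csv(inp["snp_counts"], sep="\t", dtype={"chrom": str})
    logr = pd.read_csv(inp["logr"], sep="\t", dtype={"chrom": str})
    annotation = (tio.read_bed(inp["annotation_bed"])
                  if "annotation_bed" in inp and Path(inp["annotation_bed"]).exists()
                  else chr3_annotation())
    return calls, normal, snps, logr, annotation


@_stage("variants")
def _stage_variants(config: PipelineConfig, calls, normal_calls, regions):
    somatic_calls = calls[~calls.get("germline", False).astype(bool)] \
        if "germline" in calls.columns else calls
    matrix = build_mutation_matrix(
        somatic_calls, normal_calls, regions=regions,
        min_vaf=config.min_vaf, min_depth=config.min_depth,
    )
    log.info("variant thresholds: min_vaf=%s min_depth=%s", config.min_vaf, config.min_depth)

    # validation summary over candidate somatic variants
    somatic_ids = [v for v in pd.unique(somatic_calls["variant_id"])
                   if v not in set(matrix.meta.index[matrix.meta.event_class == "germline"])]
    n_attempted = len(somatic_ids)
    validated_ids = set(matrix.somatic.index)
    n_inconclusive = 0
    n_failed = 0
    for vid in somatic_ids:
        if vid in validated_ids:
            continue
        sub = somatic_calls[somatic_calls.variant_id == vid]
        statuses = [validate_variant(depth=int(r.depth), alt_count=int(r.alt_count),
                                     min_vaf=config.min_vaf, min_depth=config.min_depth).status
                    for r in sub.itertuples()]
        if all(s is ValidationStatus.INCONCLUSIVE for s in statuses):
            n_inconclusive += 1
        else:
            n_failed += 1
    stats = {
        "n_attempted": n_attempted,
        "n_failed": n_failed,
        "n_inconclusive": n_inconclusive,
        "validation_rate": validation_rate(n_attempted, n_failed) if n_attempted else None,
    }
    return matrix, stats


@_stage("clonality")
def _stage_clonality(config: PipelineConfig, matrix: MutationMatrix):
    partition = delineate_tumors(matrix, min_shared=1)
    per_tumor = {}
    for tid, regs in partition.blocks.items():
        block = matrix.restrict(regs)
        tree = build_clone_tree(block)
        entry = {
            "regions": regs,
            "topology": tree.topology,
            "newick": tree.to_newick(),
            "tree_json": tree.to_json(),
        }
        try:
            itb = itb_index(block)
            entry["itb"] = itb.value
            entry["n_ubiquitous"] = itb.n_ubiquitous
        except ValueError:
            entry["itb"] = None
        load, med, rng_ = mutational_load(block)
        entry["mutational_load"] = load.to_dict()
        entry["load_median"], entry["load_range"] = med, list(rng_)
        per_tumor[tid] = entry
    return partition, per_tumor


@_stage("segmentation")
def _stage_segmentation(config: PipelineConfig, logr: pd.DataFrame):
    tracks = {r: g.drop(columns="region").reset_index(drop=True)
              for r, g in logr.groupby("region", sort=False)}
    norm = preprocess_logr(tracks, winsor_k=config.winsor_k)
    log.info("segmentation: gamma=%s winsor_k=%s", config.gamma, config.winsor_k)
    segments = joint_segment(norm, SegmentationConfig(gamma=config.gamma,
                                                      winsor_k=config.winsor_k))
    # Re-measure the per-sample segment means on tracks that are
    # GC-corrected and Winsorized but NOT quantile-normalized: the
    # cross-sample quantile mapping equalizes distributions for shared
    # breakpoint detection, but it mixes amplitudes between samples whose
    # aberrant genome fractions differ, which would bias the purity fit.
    meas = preprocess_logr(tracks, winsor_k=config.winsor_k,
                           quantile_normalize=False)
    resid = []
    for seg in segments:
        for s, t in meas.items():
            mask = (t.chrom == seg.chrom) & (t.start >= seg.start) & (t.end <= seg.end)
            vals = t.loc[mask, "logr"].to_numpy(float)
            seg.mean_logr[s] = float(vals.mean())
            resid.append(vals - seg.mean_logr[s])
    resid = np.concatenate(resid)
    logr_sd = float(1.4826 * np.median(np.abs(resid - np.median(resid))))
    return meas, segments, max(logr_sd, 1e-3)


@_stage("purity_ploidy")
def _stage_purity(config: PipelineConfig, segments, matrix, calls, logr_sd,
                  dna_index: Mapping[str, float]):
    seg_frame = pd.DataFrame([
        dict(segment=i, chrom=s.chrom, start=s.start, end=s.end, n_bins=s.n_bins)
        for i, s in enumerate(segments)
    ])

    def seg_of(chrom, pos) -> int | None:
        hit = seg_frame[(seg_frame.chrom == str(chrom)) &
                        (seg_frame.start <= pos) & (seg_frame.end >= pos)]
        return int(hit.segment.iloc[0]) if len(hit) else None

    candidates = {}
    validated = set(matrix.somatic.index)
    for region in matrix.regions:
        seg_df = seg_frame.copy()
        seg_df["mean_logr"] = [segments[i].mean_logr[region] for i in seg_df.segment]
        snvs = calls[(calls.region == region) & (calls.variant_id.isin(validated))].copy()
        snvs["vaf"] = snvs.alt_count / snvs.depth
        snvs["segment"] = [seg_of(c, p) for c, p in zip(snvs.chrom, snvs.pos)]
        snvs = snvs.dropna(subset=["segment"]).astype({"segment": int})
        snvs = snvs.set_index("variant_id")
        prior = ploidy_prior_from_dna_index(dna_index.get(region, 1.0))
        candidates[region] = fit_purity_ploidy(
            seg_df, snvs, prior, tau_step=config.tau_step,
            logr_sd=logr_sd, sample=region,
        )
    log.info("purity/ploidy grid: tau_step=%s lambda=%s", config.tau_step, config.lam)
    selected = joint_model_selection(candidates, lam=config.lam, seed=config.seed)
    return selected, seg_frame


@_stage("allelic_imbalance")
def _stage_baf(config: PipelineConfig, snps, segments, seg_frame, selected, matrix):
    calls_out = []
    segment_tables = {}
    breakpoints = {}
    for region in matrix.regions:
        model = selected[region]
        rho = model.purity
        snp_r = snps[snps.region == region]
        het = select_het_snps(snp_r, min_coverage=config.snp_min_coverage,
                              random_state=config.seed)
        # map het SNPs to segments
        seg_ids = []
        for c, p in zip(het.chrom, het.pos):
            hit = seg_frame[(seg_frame.chrom == str(c)) &
                            (seg_frame.start <= p) & (seg_frame.end >= p)]
            seg_ids.append(int(hit.segment.iloc[0]) if len(hit) else -1)
        het = het.assign(segment=seg_ids)
        rows = []
        n_segments = len(seg_frame)
        for i, seg in seg_frame.iterrows():
            q = int(model.expected_modal_cn[seg.segment])
            sub = het[het.segment == seg.segment]
            call = test_allelic_imbalance(
                sub.mbaf_normal.to_numpy(), sub.mbaf_tumor.to_numpy(),
                n_segments=n_segments, alpha=config.alpha,
                segment_id=f"{region}:{seg.chrom}:{seg.start}-{seg.end}",
            )
            if len(sub) and q >= 1:
                med_mbaf = float(np.median(sub.mbaf_tumor))
                adj = float(np.median(adjust_mbaf(sub.mbaf_tumor.to_numpy(), rho, q)))
                denom = 2 * (1 - rho) + rho * q
                nb = (1.0 - med_mbaf) * denom - (1.0 - rho)
                nb = int(np.clip(round(nb / rho), 0, q))
            else:
                adj, nb = None, max(q // 2, 0)
            rows.append(dict(
                segment=int(seg.segment), chrom=str(seg.chrom),
                start=int(seg.start), end=int(seg.end),
                n_bins=int(seg.n_bins),
                mean_logr=float(segments[seg.segment].mean_logr[region]),
                q=q, nB=nb, clonal=True,
                n_snps=call.n_snps, median_adjusted_mbaf=adj,
                p=call.p_value, p_bonferroni=call.p_bonferroni,
                significant=call.significant,
            ))
            calls_out.append(dict(region=region, **rows[-1]))
        table = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
        breakpoints[region] = _chr3_breakpoint(table)
        segment_tables[region] = merge_segments(table)
    log.info("mBAF thresholds: coverage>%s alpha=%s", config.snp_min_coverage, config.alpha)
    return pd.DataFrame(calls_out), segment_tables, breakpoints


def _chr3_breakpoint(segment_table: pd.DataFrame) -> int | None:
    """End of the LOH run starting at the chromosome-3 terminus: reported
    as the first base of the right-hand (heterozygous) segment.

    Uses the allelic-imbalance significance prefix, which is model-free
    (the Wilcoxon test compares matched normal and tumor mBAF directly),
    rather than the purity-dependent nB estimate.
    """
    chr3 = segment_table[segment_table.chrom == "3"].sort_values("start")
    if chr3.empty or not bool(chr3.iloc[0].significant):
        return None
    for _, seg in chr3.iterrows():
        if not bool(seg.significant):
            return int(seg.start)
    return None


def _tumor_chr3_breakpoint(
    imbalance: pd.DataFrame, regions: Sequence[str], alpha: float
) -> int | None:
    """Consensus 3p breakpoint of one tumor: pool every region's per-segment
    Wilcoxon p-value (Fisher's method), Bonferroni-correct over the
    chromosome-3 segments, and report the start of the first segment after
    the significant LOH prefix."""
    from scipy.stats import combine_pvalues

    chr3 = imbalance[(imbalance["chrom"] == "3") & imbalance["region"].isin(regions)]
    if chr3.empty:
        return None
    pooled = []
    for (start, _end), grp in sorted(chr3.groupby(["start", "end"]).groups.items()):
        ps = chr3.loc[grp, "p"].dropna().to_numpy(float)
        if len(ps) == 0:
            pooled.append((int(start), 1.0))
            continue
        ps = np.clip(ps, 1e-300, 1.0)
        pooled.append((int(start), float(combine_pvalues(ps, method="fisher")[1])))
    thresh = alpha / max(len(pooled), 1)
    if not pooled or pooled[0][1] >= thresh:
        return None
    for start, p in pooled:
        if p >= thresh:
            return start
    return None


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> PatientReport:
    """Execute the full analysis and write the patient report.

    Deterministic for a fixed config (including seed); returns the report
    and writes JSON, TSV tables and plots under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.simulate:
        truth, paths = _stage_simulate(config)
        config = dataclasses.replace(config, inputs={
            k: str(v) for k, v in paths.items()
            if k in ("variant_counts", "normal_counts", "snp_counts", "logr",
                     "annotation_bed")
        })
    calls, normal_calls, snps, logr, annotation = _stage_load(config)

    regions = list(pd.unique(calls["region"]))
    matrix, vstats = _stage_variants(config, calls, normal_calls, regions)
    partition, per_tumor = _stage_clonality(config, matrix)
    tracks, segments, logr_sd = _stage_segmentation(config, logr)

    dna_index = dict(config.dna_index)
    if truth is not None and not dna_index:
        dna_index = {r: truth.tumor_of_region(r).dna_index for r in truth.region_ids}
    selected, seg_frame = _stage_purity(config, segments, matrix, calls, logr_sd, dna_index)
    imbalance, segment_tables, region_breakpoints = _stage_baf(
        config, snps, segments, seg_frame, selected, matrix)

    # per-tumor consensus 3p breakpoints and annotation labels (pooled
    # across the tumor's regions, so one low-purity biopsy cannot truncate
    # the call)
    for tid, entry in per_tumor.items():
        bp = _tumor_chr3_breakpoint(imbalance, entry["regions"], config.alpha)
        if bp is not None:
            name, dist = map_breakpoint(bp, annotation)
            entry["breakpoint_3p"] = bp
            entry["breakpoint_label"] = name
            entry["breakpoint_distance"] = dist
        else:
            entry["breakpoint_3p"] = None
            entry["breakpoint_label"] = None
    # breakpoint-concordance check within blocks: a region whose imbalance
    # extends well beyond the tumor consensus cannot be explained by low
    # power and is flagged (shorter per-region calls can)
    conflicts = [tid for tid, e in per_tumor.items()
                 if e["breakpoint_3p"] is not None and any(
                     region_breakpoints.get(r) is not None
                     and region_breakpoints[r] - e["breakpoint_3p"] > config.breakpoint_tol
                     for r in e["regions"])]

    report = PatientReport({
        "seed": config.seed,
        "regions": matrix.regions,
        "partition": {tid: regs for tid, regs in partition.blocks.items()},
        "partition_conflicts": conflicts,
        "validation": vstats,
        "tumors": per_tumor,
        "models": {
            r: {"purity": m.purity, "ploidy": m.tumor_ploidy,
                "dna_index_prior": dna_index.get(r),
                "dna_index_consistent": (
                    abs(m.tumor_ploidy - 2.0 * dna_index[r]) <= 0.5
                    if r in dna_index else None),
                "log_likelihood": m.log_likelihood, "rank": m.rank}
            for r, m in selected.items()
        },
        "region_breakpoints": region_breakpoints,
        "segments": {r: t.to_dict(orient="records") for r, t in segment_tables.items()},
        "imbalance_significant": int(imbalance.significant.sum()),
    })

    # artifacts
    try:
        matrix.to_tsv(out / "mutation_matrix.tsv")
        partition.to_frame().to_csv(out / "partition.tsv", sep="\t", index=False)
        imbalance.to_csv(out / "imbalance_calls.tsv", sep="\t", index=False,
                         float_format="%.6g")
        for r, t in segment_tables.items():
            tio.write_segments_tsv(t, out / f"segments_{r}.tsv")
        report.to_json(out / "report.json")
        if config.make_plots:
            from . import plots
            plots.plot_presence_heatmap(matrix.somatic, out / "presence.png")
            seg_long = pd.concat([
                t.assign(sample=r) for r, t in segment_tables.items()
            ], ignore_index=True)
            plots.plot_logr_tracks(tracks, seg_long, out / "logr.png")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("report", exc) from exc
    return report
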