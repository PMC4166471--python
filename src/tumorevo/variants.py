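"""Somatic variant validation, mutation matrices and per-region statistics.

Candidate calls from deep amplicon resequencing are verified with the
two-rule scheme used throughout the package: a variant is *validated* in a
region when at least 1% of reads carry the alternate allele, *failed* when
coverage is adequate but the allele fraction falls below that mark, and
*inconclusive* when coverage is below 50x (such cells can neither confirm
nor refute the call and are excluded from matrices, while still counting
as attempted in the validation rate denominator).

Variants found in the matched normal are germline and are excluded from
the somatic rows of the mutation matrix. Copy-number events may be
appended as extra rows so that ubiquitous/shared/private classification
covers both mutation classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationStatus",
    "ValidationResult",
    "VariantObservation",
    "MutationMatrix",
    "validate_variant",
    "validation_rate",
    "build_mutation_matrix",
    "classify_events",
    "mutational_load",
    "assign_driver_category",
    "StepwiseArtifactModel",
    "classify_artifact",
]


class ValidationStatus(str, Enum):
    VALIDATED = "validated"
    FAILED = "failed"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class ValidationResult:
    status: ValidationStatus
    reason: str = ""


@dataclass(frozen=True)
class VariantObservation:
    chrom: str
    pos: int
    ref: str
    alt: str
    region_id: str
    depth: int
    alt_count: int

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


def validate_variant(
    obs: VariantObservation | Mapping | None = None,
    min_vaf: float = 0.01,
    min_depth: int = 50,
    *,
    depth: int | None = None,
    alt_count: int | None = None,
) -> ValidationResult:
    """Apply the coverage and allele-fraction validation rules to one cell.

    The VAF threshold is boundary-inclusive (exactly 1% validates); the
    depth threshold is strict (depth < 50 is inconclusive, exactly 50 is
    evaluable).
    """
    if obs is not None:
        if isinstance(obs, Mapping):
            depth, alt_count = int(obs["depth"]), int(obs["alt_count"])
        else:
            depth, alt_count = obs.depth, obs.alt_count
    if depth is None or alt_count is None:
        raise ValueError("provide an observation or depth/alt_count")
    if depth < 0 or alt_count < 0 or alt_count > depth:
        raise ValueError(f"malformed read counts: depth={depth}, alt={alt_count}")
    if depth < min_depth:
        return ValidationResult(ValidationStatus.INCONCLUSIVE,
                                f"insufficient read coverage (<{min_depth}x)")
    vaf = alt_count / depth if depth else 0.0
    if vaf >= min_vaf:
        return ValidationResult(ValidationStatus.VALIDATED)
    return ValidationResult(ValidationStatus.FAILED,
                            f"variant allele below {min_vaf:.0%} of reads")


def _round_half_up(x: float, dp: int) -> float:
    factor = 10 ** dp
    return math.floor(x * factor + 0.5) / factor


def validation_rate(n_attempted: int, n_failed: int) -> float:
    """Percentage of attempted validations that did not fail, 1 decimal.

    Inconclusive variants stay in the denominator (attempted) but are not
    failures.
    """
    if n_attempted <= 0:
        raise ValueError("n_attempted must be positive")
    if not (0 <= n_failed <= n_attempted):
        raise ValueError("n_failed must lie in [0, n_attempted]")
    return _round_half_up(100.0 * (n_attempted - n_failed) / n_attempted, 1)


@dataclass
class MutationMatrix:
    """Binary event x region presence with per-cell VAF and event metadata.

    ``meta`` has one row per event with columns ``kind`` (snv/indel/cna)
    and ``event_class`` (somatic/germline).
    """

    presence: pd.DataFrame
    vaf: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.presence.index) != list(self.meta.index):
            raise ValueError("presence and meta must share the event index")
        if self.presence.columns.duplicated().any():
            raise ValueError("region identifiers must be unique")

    @property
    def regions(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def somatic(self) -> pd.DataFrame:
        """Presence restricted to somatic rows."""
        keep = self.meta["event_class"] == "somatic"
        return self.presence.loc[keep]

    def somatic_mutations(self) -> pd.DataFrame:
        """Somatic SNV/indel rows only (copy-number rows excluded)."""
        keep = (self.meta["event_class"] == "somatic") & (self.meta["kind"] != "cna")
        return self.presence.loc[keep]

    def restrict(self, regions: Sequence[str]) -> "MutationMatrix":
        """Matrix restricted to a region subset, dropping all-zero somatic rows."""
        presence = self.presence[list(regions)]
        keep = (presence.sum(axis=1) > 0) | (self.meta["event_class"] == "germline")
        return MutationMatrix(presence.loc[keep], self.vaf.loc[keep, list(regions)],
                              self.meta.loc[keep])

    def to_tsv(self, path) -> None:
        from . import io as tio
        tio.write_matrix_tsv(self.presence, self.meta, path)

    @classmethod
    def from_tsv(cls, path) -> "MutationMatrix":
        from . import io as tio
        presence, meta = tio.read_matrix_tsv(path)
        vaf = presence.astype(float) * np.nan
        return cls(presence, vaf, meta)


def build_mutation_matrix(
    calls: pd.DataFrame,
    normal_calls: pd.DataFrame | None = None,
    copy_events: pd.DataFrame | None = None,
    regions: Sequence[str] | None = None,
    min_vaf: float = 0.01,
    min_depth: int = 50,
) -> MutationMatrix:
    """Build the validated mutation x region matrix from read-count tables.

    Parameters
    ----------
    calls:
        Long table with columns variant_id, region, depth, alt_count and
        optionally kind (snv/indel).
    normal_calls:
        Same layout for the matched normal; variants validated there are
        labelled germline and excluded from somatic rows.
    copy_events:
        Optional long table (event_id, region, present) of copy-number
        events, appended as ``cna`` rows.
    """
    if regions is None:
        regions = list(pd.unique(calls["region"]))
    regions = list(regions)
    missing = set(calls["region"]) - set(regions)
    if missing:
        raise ValueError(f"calls reference undeclared regions: {sorted(missing)}")

    germline_ids: set[str] = set()
    if normal_calls is not None:
        for _, row in normal_calls.iterrows():
            res = validate_variant(depth=int(row.depth), alt_count=int(row.alt_count),
                                   min_vaf=min_vaf, min_depth=min_depth)
            if res.status is ValidationStatus.VALIDATED:
                germline_ids.add(row.variant_id)

    kinds = {}
    if "kind" in calls.columns:
        kinds = calls.drop_duplicates("variant_id").set_index("variant_id")["kind"].to_dict()

    variant_ids = list(pd.unique(calls["variant_id"]))
    presence = pd.DataFrame(0, index=variant_ids, columns=regions, dtype=int)
    vaf = pd.DataFrame(np.nan, index=variant_ids, columns=regions, dtype=float)
    inconclusive = pd.DataFrame(False, index=variant_ids, columns=regions)
    for _, row in calls.iterrows():
        res = validate_variant(depth=int(row.depth), alt_count=int(row.alt_count),
                               min_vaf=min_vaf, min_depth=min_depth)
        if res.status is ValidationStatus.VALIDATED:
            presence.loc[row.variant_id, row.region] = 1
            vaf.loc[row.variant_id, row.region] = row.alt_count / row.depth
        elif res.status is ValidationStatus.INCONCLUSIVE:
            inconclusive.loc[row.variant_id, row.region] = True

    meta = pd.DataFrame(index=presence.index)
    meta["kind"] = [kinds.get(v, "snv") for v in presence.index]
    meta["event_class"] = ["germline" if v in germline_ids else "somatic"
                          for v in presence.index]

    # somatic rows validated nowhere are dropped (failed or inconclusive)
    keep = (presence.sum(axis=1) > 0) | (meta["event_class"] == "germline")
    presence, vaf, meta = presence.loc[keep], vaf.loc[keep], meta.loc[keep]

    if copy_events is not None and len(copy_events):
        cn_ids = list(pd.unique(copy_events["event_id"]))
        cn_presence = pd.DataFrame(0, index=cn_ids, columns=regions, dtype=int)
        for _, row in copy_events.iterrows():
            cn_presence.loc[row.event_id, row.region] = int(bool(row.present))
        cn_vaf = pd.DataFrame(np.nan, index=cn_ids, columns=regions)
        cn_meta = pd.DataFrame({"kind": "cna", "event_class": "somatic"}, index=cn_ids)
        presence = pd.concat([presence, cn_presence])
        vaf = pd.concat([vaf, cn_vaf])
        meta = pd.concat([meta, cn_meta])

    return MutationMatrix(presence, vaf, meta)


def classify_events(
    matrix: MutationMatrix, tumor_regions: Sequence[str]
) -> tuple[pd.Series, int]:
    """Classify somatic events as ubiquitous/shared/private within a tumor.

    Returns (per-event class, percentage of ubiquitous events rounded to
    the nearest integer).
    """
    tumor_regions = list(tumor_regions)
    if not tumor_regions or not set(tumor_regions) <= set(matrix.regions):
        raise ValueError("tumor_regions must be a nonempty subset of matrix regions")
    sub = matrix.somatic[tumor_regions]
    sub = sub.loc[sub.sum(axis=1) > 0]
    if sub.empty:
        raise ValueError("no somatic events in the given regions")
    counts = sub.sum(axis=1)
    n = len(tumor_regions)
    classes = pd.Series(
        np.where(counts == n, "ubiquitous", np.where(counts >= 2, "shared", "private")),
        index=sub.index,
    )
    fraction = int(_round_half_up(100.0 * (classes == "ubiquitous").sum() / len(classes), 0))
    return classes, fraction


def mutational_load(matrix: MutationMatrix) -> tuple[pd.Series, float, tuple[int, int]]:
    """Non-synonymous somatic mutation count per region (CNA rows excluded),
    with the median and (min, max) across regions."""
    if not matrix.regions:
        raise ValueError("matrix has no regions")
    counts = matrix.somatic_mutations().sum(axis=0)
    return counts, float(counts.median()), (int(counts.min()), int(counts.max()))


def assign_driver_category(gene: str, driver_table: pd.DataFrame | Mapping[str, int]) -> int | None:
    """Exact-symbol lookup in a user-supplied driver gene table.

    Returns the category (1 = high-confidence driver, 2 = probable driver,
    3 = unknown significance) or None when the gene is absent.
    """
    if isinstance(driver_table, pd.DataFrame):
        table = dict(zip(driver_table["gene"], driver_table["category"]))
    else:
        table = dict(driver_table)
    cat = table.get(gene)
    return int(cat) if cat is not None else None


# ---------------------------------------------------------------------------
# Sequencing-artifact classifier (stepwise logistic regression)
# ---------------------------------------------------------------------------

class StepwiseArtifactModel:
    """Forward-stepwise logistic model of sequencing artifacts.

    Candidate features (strand bias, mapping quality, base quality,
    position-in-read) enter one at a time when a likelihood-ratio test
    against the current model achieves p < ``entry_p``; no interaction
    terms. Calls are kept when the fitted artifact probability is < 0.5.
    """

    def __init__(self, entry_p: float = 0.05, label_col: str = "artifact"):
        self.entry_p = entry_p
        self.label_col = label_col
        self.selected_: list[str] = []
        self.result_ = None
        self.prevalence_: float = float("nan")

    @staticmethod
    def _fit_logit(y: np.ndarray, X: pd.DataFrame):
        import statsmodels.api as sm
        Xc = sm.add_constant(X, has_constant="add")
        model = sm.Logit(y, Xc)
        return model.fit(disp=0, method="lbfgs", maxiter=500)

    def fit(self, training: pd.DataFrame) -> "StepwiseArtifactModel":
        from scipy import stats

        y = training[self.label_col].to_numpy(dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both labels")
        self.prevalence_ = float(y.mean())
        features = [c for c in training.columns if c != self.label_col]
        features = [c for c in features if training[c].nunique() > 1]

        selected: list[str] = []
        current = self._fit_logit(y, training[[]])
        while True:
            best = None
            for feat in features:
                if feat in selected:
                    continue
                trial = self._fit_logit(y, training[selected + [feat]])
                lr = 2.0 * (trial.llf - current.llf)
                p = stats.chi2.sf(max(lr, 0.0), df=1)
                if best is None or p < best[1]:
                    best = (feat, p, trial)
            if best is None or best[1] >= self.entry_p:
                break
            selected.append(best[0])
            current = best[2]
        self.selected_ = selected
        self.result_ = current
        return self

    def predict_proba(self, features: Mapping[str, float] | pd.DataFrame) -> np.ndarray:
        import statsmodels.api as sm

        if self.result_ is None:
            raise RuntimeError("model is not fitted")
        if isinstance(features, Mapping):
            features = pd.DataFrame([features])
        if not self.selected_:
            return np.full(len(features), self.prevalence_)
        X = sm.add_constant(features[self.selected_], has_constant="add")
        return np.asarray(self.result_.predict(X))


def classify_artifact(
    features: Mapping[str, float], training: pd.DataFrame, entry_p: float = 0.05
) -> tuple[float, bool]:
    """Fit the stepwise artifact model and score one call.

    Returns (artifact probability, keep flag); the call is kept when the
    probability is below 0.5.
    """
    model = StepwiseArtifactModel(entry_p=entry_p).fit(training)
    prob = float(model.predict_proba(features)[0])
    return prob, prob < 0.5
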