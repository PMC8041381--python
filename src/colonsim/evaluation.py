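"""Fold-error prediction-performance statistics and grouped summaries.

Accuracy is measured on the log scale: the absolute average fold error

    AAFE = 10^( (1/n) Σ |log10(pred/obs)| )

quantifies overall accuracy (over- and underpredictions cannot cancel), and
the average fold error

    AFE = 10^( (1/n) Σ log10(pred/obs) )

quantifies directional bias (<1 underprediction, >1 overprediction).  A cell
with AAFE ≤ 2 is flagged accurate.  A prediction is "within 2-fold" iff
pred/obs ∈ (1/2, 2] — lower-exclusive, upper-inclusive; this is the interval
convention under which recomputation from 2-decimal-rounded published inputs
reproduces the published boundary counts.  Zero predictions have no defined
log fold error: they are excluded from AAFE/AFE (with a warning) but still
count as not-within-2-fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .records import Dataset

log = logging.getLogger(__name__)

METRICS = ("auc_0t", "frel_colon")
ACCURACY_THRESHOLD = 2.0


@dataclass(frozen=True)
class PredictionPair:
    drug_name: str
    metric: str
    software: str
    formulation: str
    observed: float
    predicted: float
    covariates: dict[str, float] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.observed <= 0:
            raise ValueError("observed must be > 0")
        if self.predicted < 0:
            raise ValueError("predicted must be >= 0")


@dataclass(frozen=True)
class GroupSummary:
    metric: str
    software: str
    formulation: str
    n: int
    n_excluded_zero: int
    aafe: float
    afe: float
    n_within_2fold: int
    pct_within_2fold: int
    accurate: bool


def _positive(pairs: list[PredictionPair]) -> list[PredictionPair]:
    zeros = [p for p in pairs if p.predicted == 0]
    if zeros:
        log.warning(
            "excluding %d zero-prediction pair(s) from AAFE/AFE: %s",
            len(zeros), ", ".join(p.drug_name for p in zeros),
        )
    return [p for p in pairs if p.predicted > 0]


def aafe(pairs: list[PredictionPair]) -> float:
    """Absolute average fold error over the pair set."""
    kept = _positive(list(pairs))
    if not kept:
        raise ValueError("no usable pairs for AAFE")
    mean_abs = sum(abs(math.log10(p.predicted / p.observed)) for p in kept) / len(kept)
    return 10.0 ** mean_abs


def afe(pairs: list[PredictionPair]) -> float:
    """Average (signed) fold error over the pair set."""
    kept = _positive(list(pairs))
    if not kept:
        raise ValueError("no usable pairs for AFE")
    mean = sum(math.log10(p.predicted / p.observed) for p in kept) / len(kept)
    return 10.0 ** mean


def within_fold_count(pairs: list[PredictionPair], fold: float = 2.0) -> tuple[int, int]:
    """Count and integer percentage of predictions within ``fold`` of observed.

    The within interval is (1/fold, fold] and zero predictions count as
    not-within; the percentage is rounded half-up.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    pairs = list(pairs)
    n_within = sum(
        1 for p in pairs
        if p.predicted > 0 and 1.0 / fold < p.predicted / p.observed <= fold
    )
    pct = int(math.floor(100.0 * n_within / len(pairs) + 0.5)) if pairs else 0
    return n_within, pct


def summarize_groups(
    pairs: list[PredictionPair], accuracy_threshold: float = ACCURACY_THRESHOLD
) -> list[GroupSummary]:
    """One summary per (metric, formulation, software) cell, in that order."""
    cells: dict[tuple[str, str, str], list[PredictionPair]] = {}
    for p in pairs:
        cells.setdefault((p.metric, p.formulation, p.software), []).append(p)
    out = []
    for key in sorted(cells):
        metric, formulation, software = key
        group = cells[key]
        n_within, pct = within_fold_count(group)
        group_aafe = aafe(group)
        out.append(
            GroupSummary(
                metric=metric, software=software, formulation=formulation,
                n=len(group),
                n_excluded_zero=sum(1 for p in group if p.predicted == 0),
                aafe=group_aafe, afe=afe(group),
                n_within_2fold=n_within, pct_within_2fold=pct,
                accurate=group_aafe <= accuracy_threshold,
            )
        )
    return out


def summary_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def pairs_from_dataset(dataset: Dataset, software_labels=None) -> list[PredictionPair]:
    """Build enriched prediction pairs from the colon arms of a dataset.

    Each colon arm contributes one AUC pair and one F_rel pair per software
    with both observed and predicted values present.  Trend covariates
    (predicted colonic f_abs, dog Peff, dose/FaSSIF-solubility ratio) are
    attached where resolvable.
    """
    pairs: list[PredictionPair] = []
    for arm in dataset.arms:
        if arm.route != "colon":
            continue
        drug = dataset.drug(arm.drug_name)
        sol_ref = drug.solubility_fassif if drug.solubility_fassif is not None else drug.solubility_buffer
        base_cov = {
            "peff_dog": drug.peff_dog,
            "dose_solubility_ratio": arm.dose / sol_ref,
        }
        softwares = software_labels or sorted(
            set(arm.predicted_auc_0t_by_software) | set(arm.predicted_frel_by_software)
        )
        for software in softwares:
            cov = dict(base_cov)
            if software in arm.predicted_fabs_colon_by_software:
                cov["predicted_fabs_colon"] = arm.predicted_fabs_colon_by_software[software]
            for metric, obs, pred_map in (
                ("auc_0t", arm.observed_auc_0t, arm.predicted_auc_0t_by_software),
                ("frel_colon", arm.observed_frel_colon, arm.predicted_frel_by_software),
            ):
                if obs is None or software not in pred_map:
                    continue
                pairs.append(
                    PredictionPair(
                        drug_name=arm.drug_name, metric=metric, software=software,
                        formulation=arm.formulation, observed=obs,
                        predicted=pred_map[software],
                        covariates={k: v for k, v in cov.items() if v is not None},
                    )
                )
    return pairs


def per_arm_frame(pairs: list[PredictionPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        ratio = p.predicted / p.observed if p.predicted > 0 else float("nan")
        rows.append(
            {
                "drug": p.drug_name, "metric": p.metric, "software": p.software,
                "formulation": p.formulation, "observed": p.observed,
                "predicted": p.predicted, "fold_error": ratio,
                **{f"cov_{k}": v for k, v in sorted(p.covariates.items())},
            }
        )
    return pd.DataFrame(rows)


def trend_table(pairs: list[PredictionPair], covariate: str) -> pd.DataFrame:
    """Long-format table of fold error against one covariate, for plotting.

    ``covariate`` ∈ {predicted_fabs_colon, peff_dog, dose_solubility_ratio};
    pairs without the covariate are dropped with a warning.  The fold error
    column is pred/obs; no statistics beyond that are computed.
    """
    valid = ("predicted_fabs_colon", "peff_dog", "dose_solubility_ratio")
    if covariate not in valid:
        raise ValueError(f"covariate must be one of {valid}")
    rows = []
    dropped = 0
    for p in pairs:
        if covariate not in p.covariates:
            dropped += 1
            continue
        rows.append(
            {
                "drug": p.drug_name, "metric": p.metric, "software": p.software,
                "formulation": p.formulation,
                "covariate": covariate,
                "covariate_value": p.covariates[covariate],
                "fold_error": p.predicted / p.observed if p.predicted > 0 else float("nan"),
            }
        )
    if dropped:
        log.warning("trend_table: dropped %d pair(s) without %s", dropped, covariate)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["covariate_value", "drug", "metric", "software"]).reset_index(drop=True)
    return df
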