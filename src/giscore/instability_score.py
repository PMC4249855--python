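"""The genomic instability score.

For each tumor the score combines two forms of genomic instability that
accumulate when double-strand-break repair by homologous recombination is
lost:

* ``n_cnc`` (n1) — the number of long copy-number-change segments, i.e.
  segments strictly longer than 3 Mb whose log2 tumor/normal ratio is
  strictly above 0.05 or strictly below −0.05 (short or near-neutral
  segments are treated as noise);
* ``n_mut`` (n2) — the number of validated somatic mutations, counting all
  variant types together (silent variants included by default; a
  non-synonymous-only restriction is available as a sensitivity option).

The score is ``K * n_cnc + n_mut`` with K = 0.5 by default; ``select_k``
re-derives K from a grid as the weight whose whole-cohort median split most
significantly discriminates overall survival (smallest two-sided log-rank
p, ties broken toward the smallest K).

Median splits assign ties to the high group, so a cohort whose median score
is 60 is divided into low (< 60) and high (>= 60).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import outcome_stats
from .io_cohort import NONSYNONYMOUS_CLASSES

logger = logging.getLogger("giscore")

MUTATION_SETS = frozenset(
    {"validated_all", "validated_inframe", "validated_frameshift",
     "unvalidated_all", "none"}
)


@dataclass(frozen=True)
class ScoreParams:
    """Parameters of the instability score.

    ``mutation_set`` selects which mutation records contribute to n_mut:
    ``validated_all`` (default), ``validated_inframe`` (validated records
    that are not frame shifts), ``validated_frameshift``,
    ``unvalidated_all`` (every record regardless of validation, for
    level-2-style call sets), or ``none`` (copy-number-only predictor).
    ``include_silent=False`` restricts counting to non-synonymous records.
    """

    k: float = 0.5
    min_segment_length_bp: int = 3_000_000
    gain_threshold: float = 0.05
    loss_threshold: float = -0.05
    mutation_set: str = "validated_all"
    include_silent: bool = True

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("K must be non-negative")
        if self.min_segment_length_bp <= 0:
            raise ValueError("min_segment_length_bp must be positive")
        if not (self.gain_threshold > 0 > self.loss_threshold):
            raise ValueError("need gain_threshold > 0 > loss_threshold")
        if self.mutation_set not in MUTATION_SETS:
            raise ValueError(f"unknown mutation_set {self.mutation_set!r}")


def segment_lengths(segments: pd.DataFrame) -> pd.Series:
    """Segment lengths in bp (1-based inclusive coordinates)."""
    return segments["end_bp"] - segments["start_bp"] + 1


def filter_cnc_segments(segments: pd.DataFrame,
                        params: ScoreParams = ScoreParams()) -> pd.DataFrame:
    """Keep segments that qualify as long copy-number changes.

    All three thresholds are strict: length > ``min_segment_length_bp`` and
    log2 ratio > ``gain_threshold`` or < ``loss_threshold``.
    """
    if segments.empty:
        return segments.copy()
    length_ok = segment_lengths(segments) > params.min_segment_length_bp
    ratio_ok = (segments["log2_ratio"] > params.gain_threshold) | (
        segments["log2_ratio"] < params.loss_threshold
    )
    return segments.loc[length_ok & ratio_ok].reset_index(drop=True)


def _mutation_mask(mutations: pd.DataFrame, params: ScoreParams) -> pd.Series:
    ms = params.mutation_set
    if ms == "none":
        return pd.Series(False, index=mutations.index)
    if ms == "unvalidated_all":
        mask = pd.Series(True, index=mutations.index)
    else:
        mask = mutations["validation_status"] == "validated"
        if ms == "validated_inframe":
            mask &= mutations["variant_class"] != "frame_shift"
        elif ms == "validated_frameshift":
            mask &= mutations["variant_class"] == "frame_shift"
    if not params.include_silent:
        mask &= mutations["variant_class"].isin(NONSYNONYMOUS_CLASSES)
    return mask


def count_mutations(mutations: pd.DataFrame, sample_id,
                    params: ScoreParams = ScoreParams()) -> int:
    """Number of mutation records counted toward n_mut for one sample."""
    if sample_id not in set(mutations["sample_id"]):
        logger.warning("count_mutations: sample %r absent from mutation table", sample_id)
        return 0
    sub = mutations.loc[mutations["sample_id"] == sample_id]
    return int(_mutation_mask(sub, params).sum())


def compute_score(n_cnc: int, n_mut: int, k: float = 0.5) -> float:
    """Score = K * n_cnc + n_mut."""
    if n_cnc < 0 or n_mut < 0:
        raise ValueError("counts must be non-negative")
    return k * n_cnc + n_mut


def score_cohort(segments: pd.DataFrame, mutations: pd.DataFrame,
                 params: ScoreParams = ScoreParams(),
                 samples: Iterable | None = None) -> pd.DataFrame:
    """Per-sample instability scores.

    The sample universe is the union of ids seen in either table plus any
    ids passed in ``samples`` (e.g. the clinical roster); a sample absent
    from one table contributes 0 for that component.

    Returns a DataFrame ``sample_id, n_cnc, n_mut, score`` sorted by id.
    """
    universe = set(segments["sample_id"]) | set(mutations["sample_id"])
    if samples is not None:
        universe |= set(samples)
    idx = pd.Index(sorted(universe), name="sample_id")

    qualifying = filter_cnc_segments(segments, params)
    n_cnc = qualifying.groupby("sample_id").size().reindex(idx, fill_value=0)
    counted = mutations.loc[_mutation_mask(mutations, params)]
    n_mut = counted.groupby("sample_id").size().reindex(idx, fill_value=0)

    out = pd.DataFrame({
        "sample_id": idx,
        "n_cnc": n_cnc.to_numpy(),
        "n_mut": n_mut.to_numpy(),
    })
    out["score"] = params.k * out["n_cnc"] + out["n_mut"]
    return out


def median_split(scores: pd.DataFrame, reference: str = "self",
                 reference_values: Sequence[float] | None = None) -> pd.Series:
    """Label each sample 'high' or 'low' relative to a reference median.

    ``reference='self'`` uses the median of the scores being split;
    ``reference='external'`` uses ``reference_values`` (e.g. wild-type
    patients' scores when classifying BRCA carriers).  Ties go to the high
    group: low iff score < median, high iff score >= median.
    """
    if reference == "self":
        ref = scores["score"].to_numpy()
    elif reference == "external":
        if reference_values is None:
            raise ValueError("reference_values required when reference='external'")
        ref = np.asarray(list(reference_values), dtype=float)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    if len(ref) == 0:
        raise ValueError("empty reference set")
    med = float(np.median(ref))
    labels = np.where(scores["score"].to_numpy() >= med, "high", "low")
    return pd.Series(labels, index=scores.index, name="group")


def select_k(segments: pd.DataFrame, mutations: pd.DataFrame,
             clinical: pd.DataFrame,
             k_grid: Sequence[float] = tuple(np.round(np.arange(0.1, 2.01, 0.1), 2)),
             params: ScoreParams = ScoreParams()) -> tuple[float, pd.DataFrame]:
    """Pick the CNC weight K by overall-survival discrimination.

    For each K in the grid the cohort is scored, split at its median score
    (ties high) and the two groups compared by a two-sided log-rank test on
    overall survival.  Returns the K with the smallest p (ties -> smallest
    K) plus the full per-K table.  A K for which the split is degenerate
    (all samples in one group) is assigned p = 1.
    """
    if len(k_grid) == 0:
        raise ValueError("k_grid must be non-empty")
    clin = clinical.dropna(subset=["os_days"])
    if len(clin) < 2:
        raise ValueError("need at least two samples with overall-survival data")

    rows = []
    for k in k_grid:
        p = _median_split_logrank_p(segments, mutations, clin,
                                    ScoreParams(k=float(k),
                                                min_segment_length_bp=params.min_segment_length_bp,
                                                gain_threshold=params.gain_threshold,
                                                loss_threshold=params.loss_threshold,
                                                mutation_set=params.mutation_set,
                                                include_silent=params.include_silent))
        rows.append({"k": float(k), "logrank_p": p})
    table = pd.DataFrame(rows)
    best = table.sort_values(["logrank_p", "k"], kind="mergesort").iloc[0]
    return float(best["k"]), table


def _median_split_logrank_p(segments, mutations, clinical, params) -> float:
    scores = score_cohort(segments, mutations, params,
                          samples=clinical["sample_id"])
    scores = scores.merge(clinical[["sample_id", "os_days", "os_event"]],
                          on="sample_id")
    group = median_split(scores)
    if group.nunique() < 2:
        return 1.0
    res = outcome_stats.logrank_test([
        (scores.loc[group == g, "os_days"].to_numpy(),
         scores.loc[group == g, "os_event"].to_numpy())
        for g in ("low", "high")
    ])
    return res.p
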