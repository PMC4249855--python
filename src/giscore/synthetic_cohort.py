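"""Synthetic multi-omic ovarian-cancer cohorts.

The generator emits the five input tables the pipeline consumes (segments,
mutations, clinical, gene-level thresholded copy-number calls,
methylation/expression) together with a ground-truth table, reproducing
the statistical structure the analysis assumes:

* a latent HR-deficiency class per sample, with class fractions matching
  a 325-patient serous ovarian carcinoma cohort;
* negative-binomial counts of qualifying long copy-number changes and
  validated somatic mutations, multiplicatively elevated in HR-deficient
  classes (negative binomial rather than Poisson to mimic the
  overdispersion of tumor mutation burden);
* qualifying segments realised concretely (length > 3 Mb, |log2 ratio| >
  0.05) plus decoy segments that each violate exactly one filter, so the
  score filters are exercised on every boundary and scoring the generated
  tables reproduces the ground-truth counts exactly;
* BRCA1/2 mutation records and HR-gene alterations injected to match the
  latent class; bimodal methylation/expression for silenced samples;
* exponential survival with log-hazard linear in the standardized score
  (or in the high/low median-split group), exponential censoring tuned to
  the target censoring fraction, progression-free times bounded by the
  overall-survival times;
* complete response drawn from a logistic model in the standardized
  score, with platinum status derived from a CR-correlated latent.

Everything is driven by one :class:`numpy.random.Generator`, so a fixed
seed reproduces the bundle byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_cohort
from .hr_classification import HRGeneSets

logger = logging.getLogger("giscore")

DEFAULT_CLASS_FRACTIONS = {
    "BRCA1_MUT": 0.13,
    "BRCA2_MUT": 0.10,
    "BRCA1_SILENCED": 0.10,
    "OTHER_HR_DEFICIENT": 0.21,
    # HR_WILDTYPE takes the remainder
}

_VARIANT_MIX = (
    ("missense", 0.55), ("silent", 0.15), ("frame_shift", 0.10),
    ("nonsense", 0.08), ("in_frame_indel", 0.05), ("splice", 0.05),
    ("other", 0.02),
)
_BRCA_NULL_MIX = (("frame_shift", 0.60), ("nonsense", 0.30), ("missense", 0.10))


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


@dataclass(frozen=True)
class CohortSimParams:
    """Study conditions for one simulated cohort.

    Count means are chosen so the wild-type score centres near 60 (the
    whole-cohort median split point) and deficient classes near 90,
    matching the reported wild-type/HR-deficient score separation in
    direction and rough magnitude.  ``hazard_model`` selects whether the
    log hazard is linear in the standardized score (``continuous``) or a
    step between the median-split groups (``median_group``); the default
    ``score_loghr`` makes higher scores protective.
    """

    n_samples: int = 325
    class_fractions: tuple = tuple(DEFAULT_CLASS_FRACTIONS.items())
    # qualifying-CNC counts (negative binomial): mean, dispersion (shape), fold
    cnc_mean_wild: float = 40.0
    cnc_dispersion: float = 8.0
    cnc_effect: float = 1.5
    # validated-mutation counts
    mut_mean_wild: float = 40.0
    mut_dispersion: float = 8.0
    mut_effect: float = 1.5
    #: fraction of emitted segment/mutation rows that must fail the score filters
    decoy_fraction: float = 0.3
    #: silenced-centroid shift, in within-cluster SDs, on both channels
    meth_sep_sd: float = 4.0
    # survival: exponential, per-day baseline hazard (median OS near 3.7 y)
    baseline_hazard: float = 5.2e-4
    score_loghr: float = -0.35
    hazard_model: str = "continuous"
    pfs_hazard_multiplier: float = 1.6
    censor_rate: float = 0.45
    # logistic complete-response model in the standardized score
    response_intercept: float = _logit(0.594)
    response_slope: float = 0.6
    # platinum-sensitivity latent: intercept + slope*z + cr_coef*CR
    platinum_intercept: float = 0.26
    platinum_slope: float = 0.3
    platinum_cr_coef: float = 0.75
    platinum_missing_rate: float = 0.40
    seed: int = 0

    def __post_init__(self):
        fr = dict(self.class_fractions)
        if any(v < 0 for v in fr.values()) or sum(fr.values()) > 1.0 + 1e-9:
            raise ValueError("class fractions must be non-negative and sum to <= 1")
        if self.cnc_dispersion <= 0 or self.mut_dispersion <= 0:
            raise ValueError("dispersions must be positive")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        if not (0 <= self.decoy_fraction < 1):
            raise ValueError("decoy_fraction must be in [0, 1)")
        if self.hazard_model not in {"continuous", "median_group"}:
            raise ValueError(f"unknown hazard_model {self.hazard_model!r}")


@dataclass
class CohortBundle:
    """All generated input tables plus the latent ground truth."""

    segments: pd.DataFrame
    mutations: pd.DataFrame
    clinical: pd.DataFrame
    cn_calls: pd.DataFrame
    two_channel: pd.DataFrame
    truth: pd.DataFrame
    params: CohortSimParams

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io_cohort.write_segments(self.segments, outdir / "segments.seg")
        io_cohort.write_mutations(self.mutations, outdir / "mutations.tsv")
        io_cohort.write_clinical(self.clinical, outdir / "clinical.tsv")
        io_cohort.write_cn_calls(self.cn_calls, outdir / "cn_calls.tsv")
        io_cohort.write_two_channel(self.two_channel, outdir / "brca1_two_channel.tsv")
        truth = self.truth.copy()
        truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)


def _negbin(rng, mean, dispersion):
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def _draw_classes(rng, n, fractions) -> np.ndarray:
    counts = {lab: int(round(f * n)) for lab, f in fractions.items()}
    if sum(counts.values()) > n:
        raise ValueError("infeasible class fractions for this cohort size")
    labels = []
    for lab, c in counts.items():
        labels += [lab] * c
    labels += ["HR_WILDTYPE"] * (n - len(labels))
    return rng.permutation(np.array(labels))


def _categorical(rng, n, spec):
    cats, probs = zip(*spec)
    return rng.choice(cats, size=n, p=np.asarray(probs) / sum(probs))


def simulate_cohort(params: CohortSimParams = CohortSimParams()) -> CohortBundle:
    """Generate one complete cohort bundle (deterministic per seed)."""
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    ids = np.array([f"SIM-{i:04d}" for i in range(n)])
    labels = _draw_classes(rng, n, dict(params.class_fractions))
    deficient = labels != "HR_WILDTYPE"

    # --- latent counts -----------------------------------------------------
    cnc_mean = params.cnc_mean_wild * np.where(deficient, params.cnc_effect, 1.0)
    mut_mean = params.mut_mean_wild * np.where(deficient, params.mut_effect, 1.0)
    n1 = _negbin(rng, cnc_mean, params.cnc_dispersion)
    n2 = _negbin(rng, mut_mean, params.mut_dispersion)
    # carriers / mutation-evidence samples need at least one record to carry
    # the injected HR-gene mutation
    needs_record = np.isin(labels, ["BRCA1_MUT", "BRCA2_MUT"])
    other_kind = np.where(
        labels == "OTHER_HR_DEFICIENT",
        _categorical(rng, n, (("amplification", 0.3),
                              ("homozygous_deletion", 0.4),
                              ("mutation", 0.3))),
        "",
    )
    needs_record |= other_kind == "mutation"
    n2 = np.where(needs_record & (n2 == 0), 1, n2)

    # --- segments (qualifying + decoys) ------------------------------------
    f = params.decoy_fraction
    n_decoy_seg = np.round(n1 * f / (1 - f)).astype(int)
    segments = _make_segments(rng, ids, n1, n_decoy_seg)

    # --- mutations ----------------------------------------------------------
    n_decoy_mut = np.round(n2 * f / (1 - f)).astype(int)
    mutations = _make_mutations(rng, ids, labels, other_kind, n2, n_decoy_mut)

    # --- gene-level CN calls -------------------------------------------------
    cn_calls = _make_cn_calls(rng, ids, other_kind)

    # --- methylation / expression -------------------------------------------
    silenced = labels == "BRCA1_SILENCED"
    meth = rng.normal(0.15 + 0.05 * params.meth_sep_sd * silenced, 0.05)
    meth = np.clip(meth, 0.0, 1.0)
    expr = rng.normal(0.0 - 1.0 * params.meth_sep_sd * silenced, 1.0)
    two_channel = pd.DataFrame({
        "sample_id": ids,
        "methylation_beta": np.round(meth, 6),
        "expression_value": np.round(expr, 6),
    })

    # --- outcomes -------------------------------------------------------------
    score = 0.5 * n1 + n2
    sd = score.std()
    z = (score - score.mean()) / (sd if sd > 0 else 1.0)
    if params.hazard_model == "continuous":
        log_rel = params.score_loghr * z
        is_high = score >= np.median(score)
    else:
        is_high = score >= np.median(score)  # ties to the high group
        log_rel = params.score_loghr * is_high.astype(float)
    hazard = params.baseline_hazard * np.exp(log_rel)
    t_death = rng.exponential(1.0 / hazard)
    if params.censor_rate > 0:
        c_rate = hazard.mean() * params.censor_rate / (1 - params.censor_rate)
        t_censor = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_censor = np.full(n, np.inf)
    os_days = np.minimum(t_death, t_censor)
    os_event = t_death <= t_censor
    t_prog = rng.exponential(1.0 / (hazard * params.pfs_hazard_multiplier))
    t_pfs = np.minimum(t_prog, t_death)
    pfs_days = np.minimum(t_pfs, t_censor)
    pfs_event = t_pfs <= t_censor

    p_cr = 1.0 / (1.0 + np.exp(-(params.response_intercept
                                 + params.response_slope * z)))
    cr = rng.random(n) < p_cr
    p_sens = 1.0 / (1.0 + np.exp(-(params.platinum_intercept
                                   + params.platinum_slope * z
                                   + params.platinum_cr_coef * cr)))
    sens = rng.random(n) < p_sens
    plat = np.where(sens, "sensitive", "resistant")
    plat_missing = rng.random(n) < params.platinum_missing_rate
    plat = np.where(plat_missing, "missing", plat)

    age = np.clip(np.round(rng.normal(59, 10, size=n)), 34, 87)
    clinical = pd.DataFrame({
        "sample_id": ids,
        "age_years": age.astype(int),
        "stage": _categorical(rng, n, (("II", 0.046), ("III", 0.782),
                                       ("IV", 0.169), ("missing", 0.003))),
        "grade": _categorical(rng, n, (("G2", 0.077), ("G3_G4", 0.898),
                                       ("missing", 0.025))),
        "residual_cm": _categorical(rng, n, (("0", 0.185), ("lt1", 0.486),
                                             ("1to2", 0.046), ("gt2", 0.175),
                                             ("missing", 0.108))),
        "response": np.where(cr, "CR", "nonCR"),
        "platinum": plat,
        "os_days": np.round(os_days).astype(int) + 1,
        "os_event": os_event,
        "pfs_days": np.round(pfs_days).astype(int) + 1,
        "pfs_event": pfs_event,
    })
    clinical["pfs_days"] = np.minimum(clinical["pfs_days"], clinical["os_days"])

    truth = pd.DataFrame({
        "sample_id": ids,
        "label": labels,
        "n_cnc_true": n1,
        "n_mut_true": n2,
        "score_true": score,
        "score_z": z,
        "hazard": hazard,
        "is_high": is_high,
        "silenced": silenced,
        "p_cr": p_cr,
    })
    return CohortBundle(segments, mutations, clinical, cn_calls, two_channel,
                        truth, params)


def _make_segments(rng, ids, n_true, n_decoy) -> pd.DataFrame:
    """Qualifying segments plus decoys that each violate exactly one filter."""
    rows_id, starts, ends, ratios = [], [], [], []

    def emit(sample_ids, lengths, ratio):
        rows_id.append(sample_ids)
        s = rng.integers(1, 100_000_000, size=lengths.size)
        starts.append(s)
        ends.append(s + lengths - 1)
        ratios.append(ratio)

    total_true = int(n_true.sum())
    emit(np.repeat(ids, n_true),
         rng.integers(3_000_001, 20_000_000, size=total_true),
         np.round(rng.choice([-1, 1], size=total_true)
                  * rng.uniform(0.10, 1.00, size=total_true), 4))

    total_decoy = int(n_decoy.sum())
    decoy_ids = np.repeat(ids, n_decoy)
    short = rng.random(total_decoy) < 0.5  # violate length, else violate ratio
    # short decoys: length <= 3 Mb (boundary value included), passing ratio
    short_len = rng.integers(50_000, 3_000_001, size=total_decoy)
    short_len[rng.random(total_decoy) < 0.1] = 3_000_000
    # ratio decoys: long, |log2 ratio| <= 0.05 (boundary included)
    flat_ratio = np.round(rng.uniform(-0.049, 0.049, size=total_decoy), 4)
    boundary = rng.random(total_decoy) < 0.1
    flat_ratio[boundary] = rng.choice([-0.05, 0.05], size=int(boundary.sum()))
    lengths = np.where(short, short_len,
                       rng.integers(3_000_001, 20_000_000, size=total_decoy))
    pass_ratio = np.round(rng.choice([-1, 1], size=total_decoy)
                          * rng.uniform(0.10, 1.00, size=total_decoy), 4)
    emit(decoy_ids, lengths, np.where(short, pass_ratio, flat_ratio))

    df = pd.DataFrame({
        "sample_id": np.concatenate(rows_id),
        "chrom": rng.integers(1, 23, size=total_true + total_decoy).astype(str),
        "start_bp": np.concatenate(starts),
        "end_bp": np.concatenate(ends),
        "log2_ratio": np.concatenate(ratios),
    })
    return df.sort_values(["sample_id", "chrom", "start_bp"],
                          kind="mergesort").reset_index(drop=True)


def _make_mutations(rng, ids, labels, other_kind, n_true, n_decoy) -> pd.DataFrame:
    gene_sets = HRGeneSets()
    reserved = {"BRCA1", "BRCA2"} | set(gene_sets.emsy_genes) \
        | set(gene_sets.deficiency_genes)
    pool = np.array([f"GENE{i:04d}" for i in range(2000)])
    assert not (set(pool) & reserved)

    classes, probs = zip(*_VARIANT_MIX)
    total_true = int(n_true.sum())
    df_true = pd.DataFrame({
        "sample_id": np.repeat(ids, n_true),
        "gene": rng.choice(pool, size=total_true),
        "variant_class": rng.choice(classes, size=total_true,
                                    p=np.asarray(probs) / sum(probs)),
        "validation_status": "validated",
    })
    # inject the HR-relevant record as the sample's first validated record so
    # the per-sample count stays exactly n_true
    first_idx = df_true.groupby("sample_id", sort=False).head(1).index
    first_of = dict(zip(df_true.loc[first_idx, "sample_id"], first_idx))
    null_classes, null_p = zip(*_BRCA_NULL_MIX)
    for i, s in enumerate(ids):
        gene = None
        if labels[i] == "BRCA1_MUT":
            gene = "BRCA1"
        elif labels[i] == "BRCA2_MUT":
            gene = "BRCA2"
        elif other_kind[i] == "mutation":
            gene = rng.choice(sorted(gene_sets.deficiency_genes))
        if gene is not None:
            j = first_of[s]
            df_true.loc[j, "gene"] = gene
            df_true.loc[j, "variant_class"] = rng.choice(
                null_classes, p=np.asarray(null_p) / sum(null_p))

    total_decoy = int(n_decoy.sum())
    df_decoy = pd.DataFrame({
        "sample_id": np.repeat(ids, n_decoy),
        "gene": rng.choice(pool, size=total_decoy),
        "variant_class": rng.choice(classes, size=total_decoy,
                                    p=np.asarray(probs) / sum(probs)),
        "validation_status": "unvalidated",
    })
    df = pd.concat([df_true, df_decoy], ignore_index=True)
    return df.sort_values(["sample_id", "gene"],
                          kind="mergesort").reset_index(drop=True)


def _make_cn_calls(rng, ids, other_kind) -> pd.DataFrame:
    gene_sets = HRGeneSets()
    panel = ["EMSY"] + sorted(gene_sets.deficiency_genes) \
        + [f"GENE{i:04d}" for i in range(5)]
    n, g = len(ids), len(panel)
    # background calls never reach the +-2 evidence thresholds
    calls = rng.choice([-1, 0, 1], size=(n, g), p=[0.15, 0.70, 0.15])
    deficiency_cols = [panel.index(x) for x in sorted(gene_sets.deficiency_genes)]
    for i in range(n):
        if other_kind[i] == "amplification":
            calls[i, 0] = 2
        elif other_kind[i] == "homozygous_deletion":
            calls[i, rng.choice(deficiency_cols)] = -2
    df = pd.DataFrame({
        "sample_id": np.repeat(ids, g),
        "gene": np.tile(panel, n),
        "call": calls.ravel(),
    })
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# truth-vs-estimate comparison
# ---------------------------------------------------------------------------

def recovery_report(bundle: CohortBundle, scores: pd.DataFrame,
                    labels: pd.DataFrame | None = None,
                    silenced_set: set | None = None,
                    cox_low_vs_high=None) -> pd.DataFrame:
    """Compare pipeline estimates against the generator's ground truth.

    Rows cover: exact recovery of the latent (n1, n2) counts, the mean
    score gap between HR-deficient and wild-type samples, silenced-set
    recovery accuracy (if a silenced set is given), and the low-vs-high
    Cox log hazard ratio with its CI coverage flag (if a fitted result for
    the ``low`` indicator is given).
    """
    truth = bundle.truth
    if set(scores["sample_id"]) != set(truth["sample_id"]):
        raise ValueError("sample universes of truth and scores differ")
    merged = truth.merge(scores, on="sample_id")

    rows = []
    rows.append({
        "quantity": "count_recovery_exact",
        "truth": 1.0,
        "estimate": float(((merged["n_cnc_true"] == merged["n_cnc"])
                           & (merged["n_mut_true"] == merged["n_mut"])).mean()),
    })
    true_def = merged["label"] != "HR_WILDTYPE"
    rows.append({
        "quantity": "score_gap_deficient_vs_wildtype",
        "truth": float(merged.loc[true_def, "score_true"].mean()
                       - merged.loc[~true_def, "score_true"].mean()),
        "estimate": float(merged.loc[true_def, "score"].mean()
                          - merged.loc[~true_def, "score"].mean()),
    })
    if silenced_set is not None:
        est = merged["sample_id"].isin(silenced_set)
        rows.append({
            "quantity": "silenced_recovery_accuracy",
            "truth": 1.0,
            "estimate": float((est == merged["silenced"]).mean()),
        })
    if cox_low_vs_high is not None:
        s = cox_low_vs_high.summary.iloc[0]
        true_loghr = -bundle.params.score_loghr  # low vs high
        rows.append({
            "quantity": "cox_loghr_low_vs_high",
            "truth": true_loghr,
            "estimate": float(s["coef"]),
            "ci95_low": float(np.log(s["ci95_low"])),
            "ci95_high": float(np.log(s["ci95_high"])),
            "covered": bool(np.log(s["ci95_low"]) <= true_loghr
                            <= np.log(s["ci95_high"])),
        })
    return pd.DataFrame(rows)
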