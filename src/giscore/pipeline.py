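"""End-to-end cohort analysis.

Orchestrates the full study flow on any conforming input bundle:

1. score every sample (``instability_score``),
2. label HR deficiency (``hr_classification``),
3. cohort-characteristics table with per-characteristic tests,
4. BRCA-carrier outcome analysis — carriers split at the wild-type median
   of each channel (mutation count, CNC count, score), compared with
   wild-type patients by log-rank and by multivariate Cox models,
5. whole-cohort median-split survival (OS and PFS), univariate and
   adjusted Cox, equal-interval complete-response and platinum-sensitivity
   trends, and the high/low-score platinum contingency test.

Cox covariate coding: grade G2 is the reference against G3/G4; residual
tumor ("debulking") 0–10 mm (categories 0 and <1 cm) against >10 mm
(1–2 cm and >2 cm); stage II against III/IV; age continuous.  Rows with a
missing covariate are dropped from the model (complete-case).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import io_cohort, outcome_stats
from .hr_classification import (ConsensusConfig, HRGeneSets, assign_hr_labels,
                                classify_brca_mutation, detect_brca1_silencing,
                                flag_hr_gene_alterations)
from .instability_score import ScoreParams, median_split, score_cohort
from .outcome_stats import (FIVE_YEARS_DAYS, bin_response_trend, cox_fit,
                            fisher_exact_2x2, km_fit, logrank_test,
                            wilcoxon_rank_sum)

logger = logging.getLogger("giscore")

#: Table-1 style grouping: wild-type pools truly unaltered samples with
#: non-BRCA HR alterations; silenced samples are excluded from wild-type.
WILDTYPE_LABELS = ("HR_WILDTYPE", "OTHER_HR_DEFICIENT")
CARRIER_LABELS = ("BRCA1_MUT", "BRCA2_MUT")


@dataclass
class AnalysisConfig:
    """Paths, parameters and toggles for a full pipeline run."""

    segments: str = "segments.seg"
    mutations: str = "mutations.tsv"
    clinical: str = "clinical.tsv"
    cn_calls: str = "cn_calls.tsv"
    brca1_meth: str = "brca1_two_channel.tsv"
    outdir: str = "gi_score_out"
    score_params: ScoreParams = field(default_factory=ScoreParams)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    gene_sets: HRGeneSets = field(default_factory=HRGeneSets)
    mutation_dialect: str = "simple_tsv"
    ties: str = "efron"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, val in raw.items():
            if key == "score_params":
                kwargs[key] = ScoreParams(**val)
            elif key == "consensus":
                kwargs[key] = ConsensusConfig(**val)
            elif key == "gene_sets":
                kwargs[key] = HRGeneSets(
                    emsy_genes=frozenset(val.get("emsy_genes", HRGeneSets().emsy_genes)),
                    deficiency_genes=frozenset(
                        val.get("deficiency_genes", HRGeneSets().deficiency_genes)),
                )
            else:
                kwargs[key] = val
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Table 1: cohort characteristics by BRCA status
# ---------------------------------------------------------------------------

@dataclass
class Table1Result:
    table: pd.DataFrame      # characteristic, category, counts per group
    pvalues: dict            # characteristic -> p (None when skipped)
    summary: dict            # group sizes, prevalences (%), CR rate (%)


_T1_CHARACTERISTICS = {
    "stage": ["II", "III", "IV"],
    "grade": ["G2", "G3_G4"],
    "residual_cm": ["0", "lt1", "1to2", "gt2"],
    "response": ["CR", "nonCR"],
    "platinum": ["sensitive", "resistant"],
}


def run_table1(clinical: pd.DataFrame, labels: pd.DataFrame) -> Table1Result:
    """Cohort-characteristics table with per-characteristic tests.

    Categorical characteristics are tested across the four status groups
    (Fisher exact for 2x2 contingencies, chi-square otherwise); age uses
    the Wilcoxon rank-sum test of wild-type against pooled non-wild-type.
    Missing values are excluded from all tests.
    """
    df = clinical.merge(labels[["sample_id", "label"]], on="sample_id",
                        validate="one_to_one")
    group = np.where(df["label"].isin(WILDTYPE_LABELS), "wild_type", df["label"])
    df = df.assign(group=group)
    group_order = ["wild_type", "BRCA1_MUT", "BRCA2_MUT", "BRCA1_SILENCED"]
    present = [g for g in group_order if (df["group"] == g).any()]

    rows, pvalues = [], {}
    n_all = len(df)

    # age: wild-type vs pooled non-wild-type
    wt_age = df.loc[df["group"] == "wild_type", "age_years"].dropna()
    other_age = df.loc[df["group"] != "wild_type", "age_years"].dropna()
    if len(wt_age) and len(other_age):
        pvalues["age_years"] = wilcoxon_rank_sum(wt_age, other_age)
    else:
        logger.warning("table1: empty group for age comparison; test skipped")
        pvalues["age_years"] = None

    for char, cats in _T1_CHARACTERISTICS.items():
        counts = {}
        for cat in cats + ["missing"]:
            row = {"characteristic": char, "category": cat,
                   "all": int((df[char] == cat).sum())}
            for g in group_order:
                row[g] = int(((df[char] == cat) & (df["group"] == g)).sum())
            rows.append(row)
            counts[cat] = row
        table = np.array([
            [counts[cat][g] for g in present] for cat in cats
        ])
        table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0] \
            if table.size else table
        if table.size == 0 or min(table.shape) < 2:
            logger.warning("table1: %s has a single observed category; test skipped",
                           char)
            pvalues[char] = None
        elif table.shape == (2, 2):
            pvalues[char] = fisher_exact_2x2(table).p
        else:
            pvalues[char] = float(sps.chi2_contingency(table).pvalue)

    g_sizes = {g: int((df["group"] == g).sum()) for g in group_order}
    known_resp = df["response"] != "missing"
    summary = {
        "n_cases": n_all,
        **{f"n_{g}": c for g, c in g_sizes.items()},
        "brca1_prevalence_pct": 100.0 * g_sizes["BRCA1_MUT"] / n_all,
        "brca2_prevalence_pct": 100.0 * g_sizes["BRCA2_MUT"] / n_all,
        "silenced_prevalence_pct": 100.0 * g_sizes["BRCA1_SILENCED"] / n_all,
        "cr_rate_pct": (100.0 * (df.loc[known_resp, "response"] == "CR").mean()
                        if known_resp.any() else float("nan")),
    }
    return Table1Result(pd.DataFrame(rows), pvalues, summary)


# ---------------------------------------------------------------------------
# Cox covariate coding
# ---------------------------------------------------------------------------

def cox_covariates(clinical: pd.DataFrame) -> pd.DataFrame:
    """Table-2 covariate coding; rows with missing values get NaN."""
    out = pd.DataFrame(index=clinical.index)
    out["grade_high"] = clinical["grade"].map({"G2": 0.0, "G3_G4": 1.0})
    out["debulk_gt10mm"] = clinical["residual_cm"].map(
        {"0": 0.0, "lt1": 0.0, "1to2": 1.0, "gt2": 1.0})
    out["stage_3_4"] = clinical["stage"].map({"II": 0.0, "III": 1.0, "IV": 1.0})
    out["age_years"] = clinical["age_years"]
    return out


# ---------------------------------------------------------------------------
# BRCA-carrier outcome analysis
# ---------------------------------------------------------------------------

CHANNELS = {"mutation": "n_mut", "cnc": "n_cnc", "score": "score"}


def run_brca_outcome(scores: pd.DataFrame, labels: pd.DataFrame,
                     clinical: pd.DataFrame, ties: str = "efron") -> dict:
    """Split BRCA carriers at the wild-type median of each channel.

    For each channel (mutation count, CNC count, score) the carriers
    (BRCA1 and BRCA2 pooled) are split at the median of the wild-type
    patients' values; each subgroup is compared with wild-type by log-rank
    on OS, and one multivariate Cox model per channel adjusts the High/Low
    indicators for grade, debulking, stage and age.  Returns per-channel
    dicts with log-rank p's, the fitted Cox model and a tidy table.
    """
    df = scores.merge(labels[["sample_id", "label"]], on="sample_id") \
               .merge(clinical, on="sample_id")
    wt = df["label"].isin(WILDTYPE_LABELS)
    carrier = df["label"].isin(CARRIER_LABELS)
    results = {}
    for channel, col in CHANNELS.items():
        ref_values = df.loc[wt, col]
        split = median_split(df.loc[carrier, [col]].rename(columns={col: "score"}),
                             reference="external", reference_values=ref_values)
        sub = df.loc[carrier].assign(subgroup=split.to_numpy())
        out = {"n_wildtype": int(wt.sum())}
        km_wt = km_fit(df.loc[wt, "os_days"], df.loc[wt, "os_event"])
        out["km"] = {"wild_type": km_wt}
        for level in ("high", "low"):
            grp = sub.loc[sub["subgroup"] == level]
            out[f"n_{level}"] = len(grp)
            if grp.empty or not grp["os_event"].any():
                logger.warning("brca outcome: %s-%s subgroup empty or without "
                               "events; log-rank skipped", channel, level)
                out[f"logrank_{level}_p"] = float("nan")
                continue
            res = logrank_test([
                (grp["os_days"].to_numpy(), grp["os_event"].to_numpy()),
                (df.loc[wt, "os_days"].to_numpy(), df.loc[wt, "os_event"].to_numpy()),
            ])
            out[f"logrank_{level}_p"] = res.p
            out["km"][level] = km_fit(grp["os_days"], grp["os_event"])

        model_df = df.loc[wt | carrier].copy()
        model_df["high_brca"] = 0.0
        model_df["low_brca"] = 0.0
        cidx = model_df["label"].isin(CARRIER_LABELS)
        model_df.loc[cidx, "high_brca"] = (split.to_numpy() == "high").astype(float)
        model_df.loc[cidx, "low_brca"] = (split.to_numpy() == "low").astype(float)
        design = pd.concat([model_df[["high_brca", "low_brca"]],
                            cox_covariates(model_df)], axis=1)
        keep = design.notna().all(axis=1)
        design = design.loc[keep, [c for c in design.columns
                                   if design.loc[keep, c].nunique() > 1]]
        out["cox"] = cox_fit(design, model_df.loc[keep, "os_days"],
                             model_df.loc[keep, "os_event"], ties=ties)
        results[channel] = out
    return results


def brca_outcome_table(results: dict) -> pd.DataFrame:
    """Flatten run_brca_outcome output into a tidy Table-2-shaped frame."""
    rows = []
    for channel, out in results.items():
        cox = out["cox"].summary
        for cls, cov in (("High BRCA", "high_brca"), ("Low BRCA", "low_brca")):
            level = "high" if cov == "high_brca" else "low"
            km = out["km"].get(level)
            rate = km.five_year_rate() if km is not None else (np.nan,) * 3
            row = {"channel": channel, "variable": "genomic_instability",
                   "class": cls, "n": out.get(f"n_{level}"),
                   "five_year_rate": rate[0], "rate_ci_low": rate[1],
                   "rate_ci_high": rate[2],
                   "logrank_p": out.get(f"logrank_{level}_p")}
            if cov in cox.index:
                row.update(hr=cox.loc[cov, "hr"], ci_low=cox.loc[cov, "ci95_low"],
                           ci_high=cox.loc[cov, "ci95_high"], cox_p=cox.loc[cov, "p"])
            rows.append(row)
        for cov in ("grade_high", "debulk_gt10mm", "stage_3_4", "age_years"):
            if cov in cox.index:
                rows.append({"channel": channel, "variable": cov, "class": "",
                             "hr": cox.loc[cov, "hr"],
                             "ci_low": cox.loc[cov, "ci95_low"],
                             "ci_high": cox.loc[cov, "ci95_high"],
                             "cox_p": cox.loc[cov, "p"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-cohort analysis
# ---------------------------------------------------------------------------

@dataclass
class WholeCohortResult:
    group: pd.Series                  # 'high'/'low' per sample (cohort order)
    median_score: float
    os_logrank_p: float
    pfs_logrank_p: float
    km: dict                          # (endpoint, group) -> KMEstimate
    cox_os_univariate: object
    cox_os_adjusted: object
    cox_pfs_univariate: object
    cox_pfs_adjusted: object
    cr_trend: object
    platinum_trend: object | None
    platinum_table: np.ndarray | None
    platinum_fisher: object | None
    disease_free_5y: dict

    def metrics(self) -> dict:
        """Scalar metrics as a JSON-serializable dict."""
        m = {
            "median_score": self.median_score,
            "n_high": int((self.group == "high").sum()),
            "n_low": int((self.group == "low").sum()),
            "os_logrank_p": self.os_logrank_p,
            "pfs_logrank_p": self.pfs_logrank_p,
            "os_hr_low_vs_high": self.cox_os_univariate.hazard_ratio("low"),
            "os_hr_low_vs_high_adjusted": self.cox_os_adjusted.hazard_ratio("low"),
            "pfs_hr_low_vs_high": self.cox_pfs_univariate.hazard_ratio("low"),
            "pfs_hr_low_vs_high_adjusted": self.cox_pfs_adjusted.hazard_ratio("low"),
            "cr_trend_slope": self.cr_trend.slope,
            "disease_free_5y": self.disease_free_5y,
        }
        for (endpoint, grp), km in self.km.items():
            m[f"{endpoint}_5y_rate_{grp}"] = km.five_year_rate()[0]
            m[f"{endpoint}_median_years"] = m.get(f"{endpoint}_median_years", {})
            m[f"{endpoint}_median_years"][grp] = km.median_days / io_cohort.DAYS_PER_YEAR
        if self.platinum_fisher is not None:
            m["platinum_fisher_p"] = self.platinum_fisher.p
            m["platinum_trend_slope"] = self.platinum_trend.slope
        return m


def run_whole_cohort(scores: pd.DataFrame, clinical: pd.DataFrame,
                     ties: str = "efron", n_bins: int = 12) -> WholeCohortResult:
    """Median-split survival plus response/platinum trend analyses.

    The whole cohort is split at its median score (ties to the high
    group).  OS and PFS are compared by Kaplan-Meier/log-rank and by Cox
    models with the low group against the high (reference) group, both
    univariate and adjusted.  The CR trend bins all patients with a known
    response into ``n_bins`` equal score intervals; the platinum analyses
    use only patients with a known platinum status and split them at the
    median score *of that subset*.
    """
    df = scores.merge(clinical, on="sample_id", validate="one_to_one")
    group = median_split(df)
    med = float(np.median(df["score"]))

    km, logrank_p, cox_uni, cox_adj = {}, {}, {}, {}
    for endpoint, tcol, ecol in (("os", "os_days", "os_event"),
                                 ("pfs", "pfs_days", "pfs_event")):
        groups = []
        for g in ("low", "high"):
            sel = df.loc[group == g]
            km[(endpoint, g)] = km_fit(sel[tcol], sel[ecol])
            groups.append((sel[tcol].to_numpy(), sel[ecol].to_numpy()))
        logrank_p[endpoint] = logrank_test(groups).p

        low = pd.DataFrame({"low": (group == "low").astype(float)})
        cox_uni[endpoint] = cox_fit(low, df[tcol], df[ecol], ties=ties)
        design = pd.concat([low, cox_covariates(df)], axis=1)
        keep = design.notna().all(axis=1)
        design = design.loc[keep, [c for c in design.columns
                                   if design.loc[keep, c].nunique() > 1]]
        cox_adj[endpoint] = cox_fit(design, df.loc[keep, tcol],
                                    df.loc[keep, ecol], ties=ties)

    known_resp = df["response"] != "missing"
    cr_trend = bin_response_trend(df.loc[known_resp, "score"],
                                  df.loc[known_resp, "response"] == "CR",
                                  n_bins=n_bins)

    platinum_trend = platinum_fisher = platinum_table = None
    known_plat = df["platinum"] != "missing"
    if known_plat.sum() >= n_bins:
        plat = df.loc[known_plat]
        platinum_trend = bin_response_trend(plat["score"],
                                            plat["platinum"] == "sensitive",
                                            n_bins=n_bins)
        med_known = np.median(plat["score"])
        high = plat["score"] >= med_known
        platinum_table = np.array([
            [int((high & (plat["platinum"] == "resistant")).sum()),
             int((high & (plat["platinum"] == "sensitive")).sum())],
            [int((~high & (plat["platinum"] == "resistant")).sum()),
             int((~high & (plat["platinum"] == "sensitive")).sum())],
        ])
        platinum_fisher = fisher_exact_2x2(platinum_table)

    # disease-free at 5 years: event-free fraction among patients with an
    # event before 5 years or follow-up reaching 5 years
    df5 = {}
    counts = {}
    for g in ("high", "low"):
        sel = df.loc[group == g]
        evaluable = sel["pfs_event"] | (sel["pfs_days"] >= FIVE_YEARS_DAYS)
        free = evaluable & ~(sel["pfs_event"] & (sel["pfs_days"] < FIVE_YEARS_DAYS))
        n_eval = int(evaluable.sum())
        df5[g] = 100.0 * int(free.sum()) / n_eval if n_eval else float("nan")
        counts[g] = (int(free.sum()), n_eval - int(free.sum()))
    df5["fisher_p"] = fisher_exact_2x2([counts["high"], counts["low"]]).p \
        if all(sum(c) for c in counts.values()) else float("nan")

    return WholeCohortResult(
        group=group, median_score=med,
        os_logrank_p=logrank_p["os"], pfs_logrank_p=logrank_p["pfs"],
        km=km,
        cox_os_univariate=cox_uni["os"], cox_os_adjusted=cox_adj["os"],
        cox_pfs_univariate=cox_uni["pfs"], cox_pfs_adjusted=cox_adj["pfs"],
        cr_trend=cr_trend, platinum_trend=platinum_trend,
        platinum_table=platinum_table, platinum_fisher=platinum_fisher,
        disease_free_5y=df5,
    )


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_report(config: AnalysisConfig,
               tables: dict | None = None) -> dict:
    """Run the full pipeline and write TSV + JSON outputs.

    ``tables`` may carry pre-loaded DataFrames (keys ``segments``,
    ``mutations``, ``clinical``, ``cn_calls``, ``two_channel``); otherwise
    the paths in the config are read.  Returns the machine-readable
    metrics dict that is also written to ``report.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if tables is None:
        tables = {
            "segments": io_cohort.read_segments(config.segments),
            "mutations": io_cohort.read_mutations(config.mutations,
                                                  dialect=config.mutation_dialect),
            "clinical": io_cohort.read_clinical(config.clinical),
            "cn_calls": io_cohort.read_cn_calls(config.cn_calls),
            "two_channel": io_cohort.read_two_channel(config.brca1_meth),
        }
    clinical = tables["clinical"]

    scores = score_cohort(tables["segments"], tables["mutations"],
                          config.score_params, samples=clinical["sample_id"])
    scores = scores[scores["sample_id"].isin(clinical["sample_id"])].reset_index(drop=True)

    brca_flags = classify_brca_mutation(tables["mutations"])
    silenced, _ = detect_brca1_silencing(
        tables["two_channel"],
        dataclasses.replace(config.consensus, seed=config.seed))
    evidence = flag_hr_gene_alterations(tables["mutations"], tables["cn_calls"],
                                        config.gene_sets)
    labels = assign_hr_labels(brca_flags, silenced, evidence,
                              clinical["sample_id"])

    t1 = run_table1(clinical, labels)
    brca = run_brca_outcome(scores, labels, clinical, ties=config.ties)
    whole = run_whole_cohort(scores, clinical, ties=config.ties)

    sample_out = scores.merge(labels, on="sample_id")
    sample_out["group"] = whole.group.to_numpy()
    sample_out["evidence"] = sample_out["evidence"].map(
        lambda ev: ";".join(f"{g}:{k}" for g, k in ev))
    sample_out.to_csv(outdir / "sample_scores.tsv", sep="\t", index=False)
    t1.table.to_csv(outdir / "table1_counts.tsv", sep="\t", index=False)
    brca_outcome_table(brca).to_csv(outdir / "brca_outcome.tsv", sep="\t",
                                    index=False)
    trend_rows = [{"bin": i, "n": int(n), "cr_rate": r}
                  for i, (n, r) in enumerate(zip(whole.cr_trend.n,
                                                 whole.cr_trend.rate))]
    pd.DataFrame(trend_rows).to_csv(outdir / "cr_trend.tsv", sep="\t", index=False)

    metrics = {
        "config": {"seed": config.seed, "k": config.score_params.k,
                   "mutation_set": config.score_params.mutation_set,
                   "ties": config.ties},
        "table1_summary": t1.summary,
        "table1_pvalues": t1.pvalues,
        "brca_outcome": {
            ch: {k: v for k, v in out.items()
                 if isinstance(v, (int, float)) or k.startswith("logrank")}
            for ch, out in brca.items()
        },
        "whole_cohort": whole.metrics(),
    }
    (outdir / "report.json").write_text(
        json.dumps(metrics, indent=2, default=_json_default, sort_keys=True))
    return metrics


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
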