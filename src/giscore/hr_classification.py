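"""Homologous-recombination deficiency labelling.

Each sample receives exactly one label:

* ``BRCA1_MUT`` / ``BRCA2_MUT`` — at least one non-synonymous BRCA1/2
  mutation record (germline and somatic are not distinguished; silent
  variants do not count);
* ``BRCA1_SILENCED`` — BRCA1 epigenetic silencing, detected by k-means
  consensus clustering on the two-dimensional promoter-methylation /
  expression data; the silenced cluster must show BOTH higher methylation
  and lower expression;
* ``OTHER_HR_DEFICIENT`` — EMSY high-level amplification, or homozygous
  deletion / non-synonymous validated mutation of another HR-pathway gene
  (PTEN, Fanconi-anemia genes, RAD genes, ATM, ATR, CHEK1/2);
* ``HR_WILDTYPE`` — none of the above.

Overlaps resolve by the precedence BRCA1_MUT > BRCA2_MUT > BRCA1_SILENCED
> OTHER_HR_DEFICIENT > HR_WILDTYPE, so the labels partition the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .io_cohort import NONSYNONYMOUS_CLASSES

logger = logging.getLogger("giscore")

HR_LABELS = ("BRCA1_MUT", "BRCA2_MUT", "BRCA1_SILENCED",
             "OTHER_HR_DEFICIENT", "HR_WILDTYPE")

#: core Fanconi-anemia complementation groups
FANCONI_GENES = ("FANCA", "FANCB", "FANCC", "FANCD2", "FANCE", "FANCF",
                 "FANCG", "FANCI", "FANCL", "FANCM")
#: RAD-family recombination genes
RAD_GENES = ("RAD50", "RAD51", "RAD51B", "RAD51C", "RAD51D", "RAD52", "RAD54L")
#: checkpoint / signalling genes of the HR pathway
CHECKPOINT_GENES = ("ATM", "ATR", "CHEK1", "CHEK2")


@dataclass(frozen=True)
class HRGeneSets:
    """Gene rosters screened for non-BRCA HR-pathway alterations.

    The default rosters are editable; EMSY is also known by its locus
    symbol C11orf30.
    """

    emsy_genes: frozenset = frozenset({"EMSY", "C11orf30"})
    deficiency_genes: frozenset = frozenset(
        {"PTEN"} | set(FANCONI_GENES) | set(RAD_GENES) | set(CHECKPOINT_GENES)
    )

    def __post_init__(self):
        if not self.emsy_genes or not self.deficiency_genes:
            raise ValueError("gene sets must be non-empty")


@dataclass(frozen=True)
class ConsensusConfig:
    """Consensus k-means settings for silencing detection."""

    k: int = 2
    n_resamples: int = 100
    subsample_fraction: float = 0.8
    consensus_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be positive")


# ---------------------------------------------------------------------------
# BRCA1/2 mutation flags
# ---------------------------------------------------------------------------

def classify_brca_mutation(mutations: pd.DataFrame) -> dict:
    """Flag samples with >= 1 non-synonymous BRCA1/2 record.

    Returns ``{sample_id: 'BRCA1_MUT' | 'BRCA2_MUT'}``; a sample mutated in
    both genes is flagged BRCA1_MUT (BRCA1 takes precedence).
    """
    nonsyn = mutations.loc[
        mutations["variant_class"].isin(NONSYNONYMOUS_CLASSES)
        & mutations["gene"].isin(["BRCA1", "BRCA2"])
    ]
    flags: dict = {}
    for gene, label in (("BRCA2", "BRCA2_MUT"), ("BRCA1", "BRCA1_MUT")):
        for s in nonsyn.loc[nonsyn["gene"] == gene, "sample_id"].unique():
            flags[s] = label  # BRCA1 pass runs last and overwrites
    return flags


# ---------------------------------------------------------------------------
# BRCA1 epigenetic silencing
# ---------------------------------------------------------------------------

def detect_brca1_silencing(two_channel: pd.DataFrame,
                           cfg: ConsensusConfig = ConsensusConfig()
                           ) -> tuple[set, pd.DataFrame]:
    """Separate epigenetically silenced from non-silenced samples.

    Both channels are z-scored, k-means (k clusters) is run on
    ``n_resamples`` random subsamples, and a pairwise consensus matrix
    (fraction of co-clusterings among co-sampled pairs) is accumulated.
    The final two-way partition cuts an average-linkage tree on
    1 − consensus.  The cluster whose centroid has higher methylation AND
    lower expression is the silenced one; if the centroid ordering is
    discordant between channels no sample is called silenced.

    Returns the silenced sample-id set and the consensus matrix
    (samples x samples DataFrame).
    """
    ids = two_channel["sample_id"].to_numpy()
    X = two_channel[["methylation_beta", "expression_value"]].to_numpy(dtype=float)
    n = len(ids)
    if n < 2 * cfg.k:
        raise ValueError(f"need at least {2 * cfg.k} samples")

    sd = X.std(axis=0)
    empty = set()
    consensus_df = pd.DataFrame(np.eye(n), index=ids, columns=ids)
    if np.all(sd == 0):
        logger.warning("degenerate two-channel data (all points identical); "
                       "no silenced samples called")
        return empty, consensus_df
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    rng = np.random.default_rng(cfg.seed)
    m = max(cfg.k, int(round(cfg.subsample_fraction * n)))
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(cfg.n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        km = KMeans(n_clusters=cfg.k, n_init=2, max_iter=100,
                    random_state=int(rng.integers(0, 2**31 - 1)))
        lab = km.fit_predict(Z[idx])
        same = lab[:, None] == lab[None, :]
        sampled[np.ix_(idx, idx)] += 1
        together[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore"):
        consensus = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus_df = pd.DataFrame(consensus, index=ids, columns=ids)

    dist = 1.0 - (consensus + consensus.T) / 2
    np.fill_diagonal(dist, 0.0)
    tree = linkage(squareform(dist, checks=False), method="average")
    part = fcluster(tree, t=2, criterion="maxclust")
    if len(np.unique(part)) < 2:
        logger.warning("consensus partition degenerate; no silenced samples called")
        return empty, consensus_df

    cents = {c: Z[part == c].mean(axis=0) for c in np.unique(part)}
    # silenced cluster: strictly higher methylation AND strictly lower expression
    by_meth = max(cents, key=lambda c: cents[c][0])
    by_expr = min(cents, key=lambda c: cents[c][1])
    if by_meth != by_expr:
        logger.warning("methylation/expression centroid ordering discordant; "
                       "no silenced samples called")
        return empty, consensus_df
    return set(ids[part == by_meth]), consensus_df


# ---------------------------------------------------------------------------
# other HR-gene alterations
# ---------------------------------------------------------------------------

def flag_hr_gene_alterations(mutations: pd.DataFrame, cn_calls: pd.DataFrame,
                             gene_sets: HRGeneSets = HRGeneSets()) -> dict:
    """Per-sample evidence of non-BRCA HR-pathway alteration.

    Evidence entries are ``(gene, kind)`` with kind in
    {'amplification', 'homozygous_deletion', 'mutation'}: EMSY call +2,
    deficiency-gene call −2, or a validated non-synonymous mutation of a
    deficiency gene.  Single-copy gains/losses are not evidence.
    """
    evidence: dict = {}

    amp = cn_calls.loc[(cn_calls["call"] == 2)
                       & cn_calls["gene"].isin(gene_sets.emsy_genes)]
    for s, g in zip(amp["sample_id"], amp["gene"]):
        evidence.setdefault(s, []).append((g, "amplification"))

    homdel = cn_calls.loc[(cn_calls["call"] == -2)
                          & cn_calls["gene"].isin(gene_sets.deficiency_genes)]
    for s, g in zip(homdel["sample_id"], homdel["gene"]):
        evidence.setdefault(s, []).append((g, "homozygous_deletion"))

    mut = mutations.loc[
        mutations["gene"].isin(gene_sets.deficiency_genes)
        & mutations["variant_class"].isin(NONSYNONYMOUS_CLASSES)
        & (mutations["validation_status"] == "validated")
    ]
    for s, g in mut.drop_duplicates(["sample_id", "gene"])[
            ["sample_id", "gene"]].itertuples(index=False):
        evidence.setdefault(s, []).append((g, "mutation"))
    return evidence


# ---------------------------------------------------------------------------
# label assignment
# ---------------------------------------------------------------------------

def assign_hr_labels(brca_flags: dict, silenced_set: set, other_evidence: dict,
                     samples) -> pd.DataFrame:
    """Combine the three evidence channels into one label per sample.

    Precedence: BRCA1_MUT > BRCA2_MUT > BRCA1_SILENCED > OTHER_HR_DEFICIENT
    > HR_WILDTYPE.  Returns a DataFrame ``sample_id, label, evidence`` over
    the full sample universe.
    """
    rows = []
    for s in sorted(set(samples)):
        if s in brca_flags:
            label = brca_flags[s]
            ev = [("BRCA1" if label == "BRCA1_MUT" else "BRCA2", "mutation")]
        elif s in silenced_set:
            label, ev = "BRCA1_SILENCED", [("BRCA1", "epigenetic_silencing")]
        elif s in other_evidence:
            label, ev = "OTHER_HR_DEFICIENT", list(other_evidence[s])
        else:
            label, ev = "HR_WILDTYPE", []
        rows.append({"sample_id": s, "label": label, "evidence": ev})
    return pd.DataFrame(rows, columns=["sample_id", "label", "evidence"])
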