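import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import giscore as g

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    """A mid-sized default-condition synthetic cohort shared across tests."""
    return g.simulate_cohort(g.CohortSimParams(n_samples=120, seed=11))


@pytest.fixture(scope="session")
def scores(bundle):
    return g.score_cohort(bundle.segments, bundle.mutations,
                          samples=bundle.clinical["sample_id"])


@pytest.fixture(scope="session")
def labels(bundle):
    flags = g.classify_brca_mutation(bundle.mutations)
    silenced, _ = g.detect_brca1_silencing(bundle.two_channel,
                                           g.ConsensusConfig(seed=1))
    evidence = g.flag_hr_gene_alterations(bundle.mutations, bundle.cn_calls)
    return g.assign_hr_labels(flags, silenced, evidence,
                              bundle.clinical["sample_id"])


def printed_table1_cohort():
    """Clinical table + labels encoding the published 325-patient cohort
    characteristics (counts per BRCA-status column), for arithmetic checks
    of the cohort-characteristics report."""
    groups = {
        # label -> (n, stage II/III/IV/missing, grade G2/G3_G4/missing,
        #           residual 0/lt1/1to2/gt2/missing, response CR/nonCR,
        #           platinum sens/res/missing)
        "HR_WILDTYPE": (216, (10, 166, 40, 0), (17, 193, 6),
                        (34, 102, 12, 43, 25), (118, 98), (79, 45, 92)),
        "BRCA1_MUT": (42, (2, 32, 8, 0), (4, 37, 1),
                      (10, 21, 2, 5, 4), (28, 14), (18, 7, 17)),
        "BRCA2_MUT": (33, (1, 29, 2, 1), (2, 30, 1),
                      (8, 17, 1, 4, 3), (25, 8), (19, 3, 11)),
        "BRCA1_SILENCED": (34, (2, 27, 5, 0), (2, 32, 0),
                           (8, 18, 0, 5, 3), (22, 12), (16, 8, 10)),
    }
    rows, label_rows = [], []
    i = 0
    for label, (n, stage, grade, residual, response, plat) in groups.items():
        cats = {
            "stage": np.repeat(["II", "III", "IV", "missing"], stage),
            "grade": np.repeat(["G2", "G3_G4", "missing"], grade),
            "residual_cm": np.repeat(["0", "lt1", "1to2", "gt2", "missing"],
                                     residual),
            "response": np.repeat(["CR", "nonCR"], response),
            "platinum": np.repeat(["sensitive", "resistant", "missing"], plat),
        }
        for k, v in cats.items():
            assert len(v) == n, (label, k)
        for j in range(n):
            sid = f"P{i:04d}"
            rows.append({
                "sample_id": sid, "age_years": 59.0,
                **{k: v[j] for k, v in cats.items()},
                "os_days": 1000.0 + j, "os_event": bool(j % 2),
                "pfs_days": 500.0 + j, "pfs_event": bool(j % 2),
            })
            label_rows.append({"sample_id": sid, "label": label,
                               "evidence": []})
            i += 1
    return pd.DataFrame(rows), pd.DataFrame(label_rows)


def make_segments(rows):
    """rows: (sample_id, chrom, start, end, ratio) tuples."""
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start_bp",
                                       "end_bp", "log2_ratio"])


def make_mutations(rows):
    """rows: (sample_id, gene, variant_class, validation_status) tuples."""
    return pd.DataFrame(rows, columns=["sample_id", "gene", "variant_class",
                                       "validation_status"])
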