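"""Packaged site/cohort count tables for the public multi-site releases.

These are the published per-site subject counts of the four datasets the
framework targets: ABIDE I (15 sites, 18 cohorts since some sites
contributed more than one cohort; 988 subjects total — the release
announcement also mentions 998, but the per-cohort table sums to 988 and
that is what is packaged here), ABIDE II (11 sites, 623 subjects), HBN
(3 sites, 1,385 subjects) and AOMIC (2 resting-state cohorts, 442
subjects).  They serve as realistic site-composition fixtures for the
synthetic generator and for cohort arithmetic checks; no imaging data is
involved.
"""

from __future__ import annotations

from .datasets import CohortManifest, SubjectRecord

__all__ = [
    "ABIDE1_COHORTS",
    "ABIDE2_COHORTS",
    "HBN_COHORTS",
    "AOMIC_COHORTS",
    "cohort_fixture_manifest",
]

# (cohort id, subject count)
ABIDE1_COHORTS = (
    ("CALTECH", 32), ("CMU", 27), ("KKI", 55), ("LEUVEN_1", 29),
    ("LEUVEN_2", 35), ("MAX", 57), ("NYU", 179), ("OLIN", 36),
    ("PITT", 57), ("SBL", 24), ("SDSU", 32), ("TRINITY", 42),
    ("UCLA_1", 73), ("UCLA_2", 26), ("UM_1", 107), ("UM_2", 35),
    ("USM", 100), ("YALE", 42),
)

ABIDE2_COHORTS = (
    ("GU", 104), ("KKI", 197), ("NYU", 27), ("OHSU", 91), ("ONRC", 43),
    ("SDSU", 23), ("TCD", 19), ("UCD", 32), ("UCLA", 32), ("USM", 32),
    ("UMIA", 23),
)

HBN_COHORTS = (("CBIC", 287), ("SI", 345), ("RU", 753))

AOMIC_COHORTS = (("PIOP1", 216), ("PIOP2", 226))

_TABLES = {
    "abide1": (ABIDE1_COHORTS, "source"),
    "abide2": (ABIDE2_COHORTS, "target"),
    "hbn": (HBN_COHORTS, "aux_hbn"),
    "aomic": (AOMIC_COHORTS, "aux_aomic"),
}


def cohort_fixture_manifest(database: str) -> CohortManifest:
    """Expand a packaged cohort-count table to a subject-level manifest.

    One record per subject with the cohort's site id; diagnoses are
    "unknown" (the tables record counts, not labels) except for the
    control-only auxiliary databases (hbn, aomic) where they are
    "control".
    """
    key = database.lower()
    if key not in _TABLES:
        raise ValueError(f"unknown database {database!r}; choose from {sorted(_TABLES)}")
    table, domain = _TABLES[key]
    diagnosis = "control" if key in ("hbn", "aomic") else "unknown"
    records = [
        SubjectRecord(
            subject_id=f"{key}_{site}_{i:04d}",
            site=site,
            domain=domain,
            diagnosis=diagnosis,
        )
        for site, n in table
        for i in range(n)
    ]
    return CohortManifest(records, provenance=f"packaged {key} cohort counts")
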