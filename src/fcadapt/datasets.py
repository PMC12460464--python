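"""Cohort manifests, site summaries, and leakage-free splits.

A cohort manifest lists one subject per row with the metadata the rest
of the pipeline needs: acquisition site, domain membership (the nuisance
variable a domain-adaptation model tries to ignore — e.g. "source",
"target", "aux1"), diagnostic label, and optional age/sex.  The on-disk
dialect is tab-separated UTF-8 with header
``subject_id  site  domain  diagnosis  age  sex`` and empty fields for
missing age/sex, matching phenotype-file conventions of public
neuroimaging releases.

Diagnosis tokens are ``control``, ``autism``, ``asperger`` and
``unknown`` (unlabeled, for semi-supervised training); they are
case-insensitive on read and canonical lower-case on write.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DIAGNOSES",
    "SubjectRecord",
    "CohortManifest",
    "SplitSpec",
    "read_manifest",
    "write_manifest",
    "summarize_by_site",
    "split_cohort",
]

DIAGNOSES = ("control", "autism", "asperger", "unknown")
_COLUMNS = ["subject_id", "site", "domain", "diagnosis", "age", "sex"]


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's manifest row."""

    subject_id: str
    site: str
    domain: str
    diagnosis: str
    age: float | None = None
    sex: str | None = None

    def __post_init__(self):
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(
                f"subject {self.subject_id!r}: unknown diagnosis token "
                f"{self.diagnosis!r} (expected one of {DIAGNOSES})"
            )


@dataclass
class CohortManifest:
    """An ordered collection of subject records with unique ids."""

    records: list[SubjectRecord]
    provenance: str = ""

    def __post_init__(self):
        # empty manifests arise only as degenerate split outputs
        seen: set[str] = set()
        for rec in self.records:
            if rec.subject_id in seen:
                raise ValueError(f"duplicate subject_id {rec.subject_id!r}")
            seen.add(rec.subject_id)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.subject_id, r.site, r.domain, r.diagnosis, r.age, r.sex)
                for r in self.records
            ],
            columns=_COLUMNS,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "CohortManifest":
        records = []
        for _, row in df.iterrows():
            age = row.get("age")
            age = None if age is None or (isinstance(age, float) and np.isnan(age)) else float(age)
            sex = row.get("sex")
            if sex is not None and (sex != sex or str(sex) == ""):  # NaN / empty
                sex = None
            records.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    site=str(row["site"]),
                    domain=str(row["domain"]),
                    diagnosis=str(row["diagnosis"]).strip().lower(),
                    age=age,
                    sex=None if sex is None else str(sex),
                )
            )
        return cls(records, provenance=provenance)

    def subset(self, ids: list[str], provenance: str = "") -> "CohortManifest":
        wanted = set(ids)
        return CohortManifest(
            [r for r in self.records if r.subject_id in wanted], provenance
        )


def read_manifest(path) -> CohortManifest:
    """Read a manifest TSV, validating columns, ids and diagnosis tokens."""
    df = pd.read_csv(
        path, sep="\t", dtype={"subject_id": str, "sex": str},
        float_precision="round_trip",
    )
    required = {"subject_id", "site", "domain", "diagnosis"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path}: missing required column(s) {sorted(missing)}")
    if df.empty:
        raise ValueError(f"manifest {path}: no data rows")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(
            f"manifest {path}: duplicate subject_id {dup.iloc[0]!r} "
            f"(row {dup.index[0] + 2})"
        )
    tokens = df["diagnosis"].astype(str).str.strip().str.lower()
    bad = ~tokens.isin(DIAGNOSES)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"manifest {path}: unknown diagnosis token {df['diagnosis'].iloc[i]!r} "
            f"at row {i + 2} (subject {df['subject_id'].iloc[i]!r})"
        )
    df = df.assign(diagnosis=tokens)
    return CohortManifest.from_frame(df, provenance=str(path))


def write_manifest(manifest: CohortManifest, path) -> None:
    df = manifest.to_frame()
    df["sex"] = df["sex"].fillna("")
    df.to_csv(path, sep="\t", index=False, na_rep="")


def summarize_by_site(manifest: CohortManifest) -> pd.DataFrame:
    """Per-site subject counts with per-diagnosis breakdown and a TOTAL row.

    Rows are ordered lexicographically by site; the final row has
    site="TOTAL" and column sums.
    """
    df = manifest.to_frame()
    counts = (
        df.groupby("site")["diagnosis"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(DIAGNOSES), fill_value=0)
    )
    counts.insert(0, "n", counts.sum(axis=1))
    counts = counts.sort_index()
    total = counts.sum(axis=0).to_frame().T
    total.index = ["TOTAL"]
    out = pd.concat([counts, total])
    out.index.name = "site"
    return out.reset_index()


@dataclass
class SplitSpec:
    """Three-way split specification.

    mode="counts": values are exact subject counts for train/val/test.
    mode="fractions": values are fractions summing to 1.
    stratify_by: subset of {"diagnosis", "site"}; allocation preserves
    stratum proportions within +/- 1 subject via largest-remainder
    rounding on shuffled order.
    """

    mode: str
    values: tuple[float, float, float]
    stratify_by: tuple[str, ...] = ("diagnosis",)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("counts", "fractions"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if len(self.values) != 3 or any(v < 0 for v in self.values):
            raise ValueError("values must be three non-negative numbers")
        if self.mode == "fractions" and abs(sum(self.values) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        bad = set(self.stratify_by) - {"diagnosis", "site"}
        if bad:
            raise ValueError(f"cannot stratify by {sorted(bad)}")


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    base = np.floor(quotas).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:rem]] += 1
    return base


def split_cohort(
    manifest: CohortManifest, spec: SplitSpec
) -> tuple[CohortManifest, CohortManifest, CohortManifest]:
    """Partition a manifest into disjoint train/validation/test manifests.

    The partition is exhaustive, disjoint, deterministic given
    ``spec.seed``, and — in counts mode — hits the requested sizes
    exactly while keeping every stratum's allocation within one subject
    of its proportional quota.
    """
    n = len(manifest)
    if spec.mode == "counts":
        counts = np.array([int(v) for v in spec.values])
        if counts.sum() != n:
            raise ValueError(f"counts sum to {counts.sum()} but manifest has {n} subjects")
    else:
        counts = _largest_remainder(np.array(spec.values, dtype=float) * n, n)

    df = manifest.to_frame()
    if spec.stratify_by:
        keys = df.groupby(list(spec.stratify_by), sort=True).groups
        strata = [list(df.loc[idx, "subject_id"]) for idx in keys.values()]
    else:
        strata = [list(df["subject_id"])]

    frac = counts / n if n else counts
    # per-stratum proportional quotas, rounded within each stratum
    quotas = [np.array([len(s) * f for f in frac]) for s in strata]
    alloc = [_largest_remainder(q, len(s)) for q, s in zip(quotas, strata)]
    alloc = np.array(alloc)

    # repair global totals while keeping each stratum within +/-1 of quota
    quotas = np.array(quotas)
    for _ in range(10 * n + 10):
        diff = alloc.sum(axis=0) - counts
        if not diff.any():
            break
        over = int(np.argmax(diff))
        under = int(np.argmin(diff))
        slack = (alloc[:, over] - quotas[:, over]) - (alloc[:, under] - quotas[:, under])
        cand = np.flatnonzero(alloc[:, over] > 0)
        if cand.size == 0:
            raise ValueError("infeasible split: stratum smaller than requested allocation")
        s = cand[np.argmax(slack[cand])]
        alloc[s, over] -= 1
        alloc[s, under] += 1
    else:  # pragma: no cover - safeguarded above
        raise RuntimeError("split repair did not converge")

    rng = np.random.default_rng(spec.seed)
    parts: list[list[str]] = [[], [], []]
    for ids, a in zip(strata, alloc):
        ids = list(ids)
        rng.shuffle(ids)
        start = 0
        for k in range(3):
            parts[k].extend(ids[start : start + a[k]])
            start += a[k]

    names = ("train", "validation", "test")
    out = tuple(
        manifest.subset(parts[k], provenance=f"{manifest.provenance}:{name}")
        for k, name in enumerate(names)
    )
    return out


def write_split(
    manifests: tuple[CohortManifest, CohortManifest, CohortManifest],
    spec: SplitSpec,
    outdir,
) -> None:
    """Write the three split manifests plus a JSON split report."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = ("train", "validation", "test")
    for name, m in zip(names, manifests):
        write_manifest(m, outdir / f"{name}.tsv")
    report = {
        "sizes": {name: len(m) for name, m in zip(names, manifests)},
        "seed": spec.seed,
        "mode": spec.mode,
        "values": list(spec.values),
        "stratify_by": list(spec.stratify_by),
    }
    (outdir / "split_report.json").write_text(json.dumps(report, indent=2))
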