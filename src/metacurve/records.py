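"""Data model for coded correlation effect sizes.

A record is one coded Pearson correlation between whole-brain volume and an
IQ score in one sample, together with the moderator fields used throughout
the analyses (sample type, reporting status, IQ domain, test description,
g-ness rating, and so on).  Raw IQ-domain labels (``FSIQ``, ``verbal``,
``performance``, ``fluid``, ``spatial``) are mapped onto three canonical
analysis domains, and multiple coded effects from the same independent
sample are reduced to one per domain by configurable preference rules.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, field_validator, model_validator

RawDomain = Literal["FSIQ", "verbal", "performance", "fluid", "spatial"]
Domain = Literal["full_scale", "verbal", "performance"]
SampleType = Literal["healthy", "patient"]
Reporting = Literal["reported", "grey", "personal_communication"]
Gness = Literal["fair", "good", "excellent"]

#: Default raw-label -> canonical-domain mapping.  Fluid-reasoning tests are
#: treated as full-scale measures and spatial tests as performance measures;
#: this reconciles the raw Table-1 labels with the three analysis domains and
#: is exposed as configuration so sensitivity analyses are one argument away.
DEFAULT_DOMAIN_MAP: dict[str, Domain] = {
    "FSIQ": "full_scale",
    "fluid": "full_scale",
    "verbal": "verbal",
    "performance": "performance",
    "spatial": "performance",
}

#: Ordered preference patterns per canonical domain, matched against the raw
#: domain label and the free-text test description.  A lower pattern index is
#: preferred ("conceptually closer" to the domain); ties fall back to larger
#: n and then to file order.  Verbal comprehension / vocabulary is preferred
#: over working-memory subtests, full performance scales over speed subtests.
DEFAULT_PREFERENCE_RULES: dict[str, list[str]] = {
    "full_scale": [],
    "verbal": [
        r"(?i)verbal(?!\s+fluency)",
        r"(?i)\bvoc\b|vocabulary|comprehension|\bcom\b|\bsim\b|NART|VCI",
    ],
    "performance": [
        r"(?i)performance|\bPOI\b|\bPRI\b",
        r"(?i)\bbd\b|block design|\bmr\b|matrix",
    ],
}


class EffectRecord(BaseModel):
    """One coded correlation with its moderator fields."""

    study_label: str
    year: int
    sample_type: SampleType
    mean_age: Optional[float] = None
    male_ratio: Optional[float] = None
    reporting: Reporting
    domain_raw: RawDomain
    test_description: str = ""
    gness: Optional[Gness] = None
    volume_type: Optional[Literal["TBV", "ICV"]] = None
    n: int
    r: float
    zero_imputed: bool = False
    n_covariates: Optional[int] = None
    study_goal_primary: Optional[bool] = None
    sample_id: Optional[str] = None

    @field_validator("n")
    @classmethod
    def _n_at_least_four(cls, v: int) -> int:
        # the Fisher-z sampling variance 1/(n-3) must be finite and positive
        if v < 4:
            raise ValueError(f"n must be >= 4, got {v}")
        return v

    @field_validator("r")
    @classmethod
    def _r_open_interval(cls, v: float) -> float:
        if not -1.0 < v < 1.0:
            raise ValueError(f"r must lie in (-1, 1), got {v}")
        return v

    @field_validator("male_ratio")
    @classmethod
    def _male_ratio_percent(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not 0.0 <= v <= 100.0:
            raise ValueError(f"male_ratio must lie in [0, 100], got {v}")
        return v

    @model_validator(mode="after")
    def _zero_imputed_consistent(self) -> "EffectRecord":
        if self.zero_imputed and self.r != 0.0:
            raise ValueError("zero_imputed records must have r == 0")
        return self

    def sample_key(self) -> tuple:
        """Identity of the independent sample this effect was coded from.

        An explicit ``sample_id`` overrides the default key; otherwise two
        rows are assumed to come from the same sample when they agree on
        study label, mean age, male ratio and sample type (the only fields
        the in-paper study table distinguishes within-study samples by).
        """
        if self.sample_id:
            return (self.sample_id,)
        return (self.study_label, self.mean_age, self.male_ratio, self.sample_type)


@dataclass
class EffectSet:
    """An ordered collection of effects for one analysis domain."""

    records: list[EffectRecord]
    domain: Domain
    independence: Literal["one_per_sample", "all_effects"] = "all_effects"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("EffectSet must be non-empty")
        if self.independence == "one_per_sample":
            keys = [r.sample_key() for r in self.records]
            if len(set(keys)) != len(keys):
                raise ValueError("one_per_sample set contains duplicate samples")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.model_dump() for r in self.records])


def map_domain(domain_raw: str, mapping: Optional[dict[str, Domain]] = None) -> Domain:
    """Map a raw IQ-domain label onto one of the three canonical domains."""
    mapping = DEFAULT_DOMAIN_MAP if mapping is None else mapping
    try:
        return mapping[domain_raw]
    except KeyError:
        raise ValueError(f"unknown IQ domain label: {domain_raw!r}") from None


_COLUMNS = [
    "study_label", "year", "sample_type", "mean_age", "male_ratio", "reporting",
    "iq_domain", "test", "gness", "volume_type", "n", "r", "zero_imputed",
    "n_covariates", "study_goal_primary", "sample_id",
]


def load_dataset(path: str | Path) -> list[EffectRecord]:
    """Load a coded effect-size table from a codebook-format CSV file.

    The header must carry the codebook column names; missing cells are empty,
    booleans are coded 0/1.  Malformed or out-of-range rows raise a
    ``ValueError`` naming the offending row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns and c != "sample_id"]
    if missing:
        raise ValueError(f"dataset header is missing columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        d = dict(zip(df.columns, row))
        try:
            records.append(
                EffectRecord(
                    study_label=d["study_label"],
                    year=int(d["year"]),
                    sample_type=d["sample_type"],
                    mean_age=float(d["mean_age"]) if d["mean_age"] != "" else None,
                    male_ratio=float(d["male_ratio"]) if d["male_ratio"] != "" else None,
                    reporting=d["reporting"],
                    domain_raw=d["iq_domain"],
                    test_description=d["test"],
                    gness=d["gness"] or None,
                    volume_type=d["volume_type"] or None,
                    n=int(d["n"]),
                    r=float(d["r"]),
                    zero_imputed=d["zero_imputed"] in ("1", "True", "true"),
                    n_covariates=int(d["n_covariates"]) if d["n_covariates"] != "" else None,
                    study_goal_primary=(d["study_goal_primary"] in ("1", "True", "true"))
                    if d["study_goal_primary"] != ""
                    else None,
                    sample_id=d.get("sample_id") or None,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"row {i} of {path}: {exc}") from exc
    return records


def load_table1() -> list[EffectRecord]:
    """Load the packaged 454-row in-paper study table."""
    with resources.as_file(
        resources.files("metacurve.data").joinpath("table1_effects.csv")
    ) as p:
        return load_dataset(p)


def resolve_independent(
    records: Iterable[EffectRecord],
    domain: Domain,
    preference_rules: Optional[dict[str, list[str]]] = None,
    domain_map: Optional[dict[str, Domain]] = None,
    log_path: Optional[str | Path] = None,
) -> EffectSet:
    """Reduce the coded effects of one domain to one effect per sample.

    Selection order within a sample: (1) lowest-index preference-rule match
    against the raw domain label / test description, (2) larger n,
    (3) original file order.  The resolution is idempotent and invariant to
    input row order, and every decision can be written to a JSON log.
    """
    rules = (preference_rules or DEFAULT_PREFERENCE_RULES).get(domain, [])
    compiled = [re.compile(p) for p in rules]

    def rank(rec: EffectRecord) -> tuple[int, int]:
        # effects coded under the domain's own raw label are conceptually
        # closest (FSIQ before fluid, performance before spatial), then the
        # test-description preference patterns break ties
        domain_rank = 0 if rec.domain_raw in ("FSIQ", "verbal", "performance") else 1
        for i, pat in enumerate(compiled):
            if pat.search(rec.test_description):
                return (domain_rank, i)
        return (domain_rank, len(compiled))

    in_domain = [
        (pos, r)
        for pos, r in enumerate(records)
        if map_domain(r.domain_raw, domain_map) == domain
    ]
    groups: dict[tuple, list[tuple[int, EffectRecord]]] = {}
    for pos, r in in_domain:
        groups.setdefault(r.sample_key(), []).append((pos, r))

    chosen: list[tuple[int, EffectRecord]] = []
    log = []
    for key, members in groups.items():
        ordered = sorted(members, key=lambda pr: (rank(pr[1]), -pr[1].n, pr[0]))
        pick_pos, pick = ordered[0]
        chosen.append((pick_pos, pick))
        log.append(
            {
                "sample_key": [str(k) for k in key],
                "n_candidates": len(members),
                "chosen_test": pick.test_description,
                "chosen_n": pick.n,
                "chosen_r": pick.r,
                "rule_rank": list(rank(pick)),
            }
        )
    chosen.sort(key=lambda pr: pr[0])
    if log_path is not None:
        Path(log_path).write_text(json.dumps(log, indent=1))
    return EffectSet([r for _, r in chosen], domain=domain, independence="one_per_sample")


def filter_subset(
    effect_set: EffectSet,
    criteria: dict[str, object | Callable[[object], bool]],
) -> EffectSet:
    """Keep records satisfying all field predicates, order preserved.

    Values may be literals (equality) or callables (predicates).  Unknown
    field names raise ``ValueError``.  Filtering by conjunction commutes and
    composes: ``filter(A and B) == filter(filter(., A), B)``.
    """
    fields = EffectRecord.model_fields
    for name in criteria:
        if name not in fields:
            raise ValueError(f"unknown field in filter criteria: {name!r}")

    def keep(rec: EffectRecord) -> bool:
        for name, want in criteria.items():
            have = getattr(rec, name)
            ok = want(have) if callable(want) else have == want
            if not ok:
                return False
        return True

    kept = [r for r in effect_set.records if keep(r)]
    if not kept:
        raise ValueError("filter produced an empty effect set")
    return EffectSet(kept, domain=effect_set.domain, independence=effect_set.independence)
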