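"""Relational study database for the training-strategy review pipeline.

The database is a set of six normalised CSV tables (``studies``, ``arms``,
``components``, ``attributes``, ``outcomes``, ``costs``) describing controlled
trials and interrupted time series of healthcare-provider (HCP) improvement
strategies in low/middle-income countries.  Times are fractional months
relative to the start of the improvement strategy (start = 0; negative times
are the baseline period).  Missing values are empty cells and are mapped to
explicit missing states, never silently to "no".

Strategy components are coded per study arm.  Fine-grained component codes
are collapsed at load time to a closed 16-category vocabulary (five mutually
exclusive training categories plus eleven other strategy categories) via a
packaged mapping file; a ``placebo`` pseudo-component marks placebo arms,
which are analysed together with no-intervention controls.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("hcpmeta")

# --------------------------------------------------------------------------
# Closed vocabularies
# --------------------------------------------------------------------------

#: Mutually exclusive HCP training strategy categories, in canonical order.
TRAINING_CATEGORIES: tuple[str, ...] = (
    "group_inservice",
    "group_preservice",
    "self_study",
    "eov",
    "peer_to_peer",
)

#: Other (non-training) strategy component categories.
OTHER_CATEGORIES: tuple[str, ...] = (
    "community_support",
    "patient_support",
    "infrastructure",
    "hcp_financial_incentives",
    "financing_other_incentives",
    "regulation_governance",
    "group_problem_solving",
    "supervision",
    "other_management",
    "printed_materials_standalone",
    "ict",
)

#: Placebo components are analysed together with control groups.
PLACEBO = "placebo"

COMPONENT_VOCAB: frozenset[str] = frozenset(
    TRAINING_CATEGORIES + OTHER_CATEGORIES + (PLACEBO,)
)

DESIGNS = ("randomised", "non_randomised", "its", "its_controlled")
ITS_DESIGNS = ("its", "its_controlled")
CADRES = ("professional", "lay")
COUNTRY_INCOMES = ("low", "middle", "unknown")
ROB_STATUSES = ("done", "not_done", "unclear", "not_applicable")
SCALES = ("percentage", "continuous")
DIRECTIONS = ("increase_improves", "decrease_improves")
TRISTATE = ("yes", "no")  # empty cell = missing
ONSITE_LEVELS = ("some_or_all_onsite", "all_offsite")  # empty cell = missing
COMPLEXITY_LEVELS = ("single", "multiple")  # empty cell = missing

TRAINING_METHODS = (
    "lecture",
    "interactive_discussion",
    "clinical_practice",
    "role_play",
    "other_method",
)

#: Table name -> ordered column list.  This is the on-disk schema.
SCHEMA: dict[str, list[str]] = {
    "studies": [
        "study_id",
        "design",
        "cadre",
        "country_income",
        "strategy_start_month",
        "publication_year",
        "is_equivalency",
        "rob_domains",
    ],
    "arms": ["arm_id", "study_id", "is_control", "is_gold_standard"],
    "components": ["arm_id", "component_code"],
    "attributes": [
        "arm_id",
        "duration_days",
        *TRAINING_METHODS,
        "printed_materials",
        "computers",
        "group_size",
        "topic_complexity",
        "professional_trainers",
        "content_expert_trainers",
        "onsite",
        "multiple_sessions",
    ],
    "outcomes": [
        "outcome_id",
        "study_id",
        "scale",
        "direction",
        "arm_id",
        "time_month",
        "value",
        "n",
    ],
    "costs": ["arm_id", "total_cost_usd", "n_hcps_trained", "duration_days"],
}

_SORT_KEYS: dict[str, list[str]] = {
    "studies": ["study_id"],
    "arms": ["arm_id"],
    "components": ["arm_id", "component_code"],
    "attributes": ["arm_id"],
    "outcomes": ["outcome_id", "arm_id", "time_month"],
    "costs": ["arm_id"],
}


class SchemaError(ValueError):
    """A table or column required by the schema is missing or malformed."""


class DatabaseValidationError(ValueError):
    """One or more rows violate a database invariant.

    The message lists every violation as ``table[row]: rule``.
    """

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "database validation failed with %d problem(s):\n  %s"
            % (len(problems), "\n  ".join(problems))
        )


def load_component_map(path: Optional[Path] = None) -> dict[str, str]:
    """Return the fine-code -> category mapping used to collapse components.

    By default the packaged mapping ships identity entries for the canonical
    category codes plus common fine-grained codes; pass ``path`` to adapt the
    loader to a differently-coded export without touching core logic.
    """
    if path is None:
        with resources.files("hcpmeta").joinpath("data/component_map.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    mapping = dict(zip(df["fine_code"], df["category"]))
    bad = sorted(set(mapping.values()) - COMPONENT_VOCAB)
    if bad:
        raise SchemaError(f"component map targets unknown categories: {bad}")
    return mapping


# --------------------------------------------------------------------------
# Typed records
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RobDomainStatus:
    """Judgment for one risk-of-bias domain (free-text name)."""

    domain_name: str
    status: str  # done | not_done | unclear | not_applicable

    def __post_init__(self):
        if self.status not in ROB_STATUSES:
            raise ValueError(f"invalid risk-of-bias status {self.status!r}")


def encode_rob_domains(domains: Iterable[RobDomainStatus]) -> str:
    return "|".join(f"{d.domain_name}={d.status}" for d in domains)


def decode_rob_domains(cell) -> list[RobDomainStatus]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    out = []
    for part in str(cell).split("|"):
        name, _, status = part.partition("=")
        out.append(RobDomainStatus(name, status))
    return out


@dataclass
class TrainingAttributes:
    """Implementation attributes of a training component in one arm.

    Tri-state fields are ``"yes"``/``"no"``/``None`` (missing); ``onsite`` is
    ``"some_or_all_onsite"``/``"all_offsite"``/``None``; ``topic_complexity``
    is ``"single"``/``"multiple"``/``None``.
    """

    duration_days: Optional[float] = None
    methods: frozenset[str] = frozenset()
    methods_observed: bool = True
    printed_materials: Optional[str] = None
    computers: Optional[str] = None
    group_size: Optional[float] = None
    topic_complexity: Optional[str] = None
    professional_trainers: Optional[str] = None
    content_expert_trainers: Optional[str] = None
    onsite: Optional[str] = None
    multiple_sessions: Optional[str] = None

    @property
    def n_methods(self) -> Optional[int]:
        return len(self.methods) if self.methods_observed else None


@dataclass
class StudyArm:
    arm_id: str
    study_id: str
    components: frozenset[str]
    is_control: bool
    is_gold_standard: bool = False
    training_attributes: Optional[TrainingAttributes] = None


@dataclass
class Study:
    study_id: str
    design: str
    cadre: str
    country_income: str
    strategy_start_month: float
    rob_domains: list[RobDomainStatus] = field(default_factory=list)
    publication_year: Optional[int] = None
    is_equivalency: bool = False


@dataclass
class OutcomeSeries:
    """One outcome's repeated measurements across arms.

    ``measurements`` is a long table with columns ``arm_id``, ``time_month``,
    ``value`` and optional ``n``; scale and improvement direction are
    constant within the series.
    """

    outcome_id: str
    study_id: str
    scale: str
    direction: str
    measurements: pd.DataFrame


@dataclass
class CostRecord:
    arm_id: str
    total_cost_usd: float
    n_hcps_trained: int
    duration_days: float

    @property
    def cost_per_hcp_per_day(self) -> float:
        return self.total_cost_usd / (self.n_hcps_trained * self.duration_days)


# --------------------------------------------------------------------------
# The database container
# --------------------------------------------------------------------------


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or x == ""


@dataclass
class StudyDatabase:
    """In-memory review database: six pandas tables plus typed accessors."""

    studies: pd.DataFrame
    arms: pd.DataFrame
    components: pd.DataFrame
    attributes: pd.DataFrame
    outcomes: pd.DataFrame
    costs: pd.DataFrame

    # -- construction -------------------------------------------------------

    @classmethod
    def empty(cls) -> "StudyDatabase":
        return cls(**{t: pd.DataFrame(columns=cols) for t, cols in SCHEMA.items()})

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    # -- typed accessors ----------------------------------------------------

    def study(self, study_id: str) -> Study:
        rows = self.studies[self.studies["study_id"] == study_id]
        if rows.empty:
            raise KeyError(study_id)
        r = rows.iloc[0]
        return Study(
            study_id=str(r["study_id"]),
            design=r["design"],
            cadre=r["cadre"],
            country_income=r["country_income"],
            strategy_start_month=float(r["strategy_start_month"]),
            rob_domains=decode_rob_domains(r["rob_domains"]),
            publication_year=None
            if _is_missing(r["publication_year"])
            else int(r["publication_year"]),
            is_equivalency=bool(int(r["is_equivalency"])),
        )

    def iter_studies(self) -> Iterable[Study]:
        for sid in self.studies["study_id"]:
            yield self.study(str(sid))

    def _attributes_for(self, arm_id: str) -> Optional[TrainingAttributes]:
        rows = self.attributes[self.attributes["arm_id"] == arm_id]
        if rows.empty:
            return None
        r = rows.iloc[0]
        methods = frozenset(m for m in TRAINING_METHODS if r[m] == "yes")
        methods_observed = not all(_is_missing(r[m]) for m in TRAINING_METHODS)
        return TrainingAttributes(
            duration_days=None if _is_missing(r["duration_days"]) else float(r["duration_days"]),
            methods=methods,
            methods_observed=methods_observed,
            printed_materials=None if _is_missing(r["printed_materials"]) else r["printed_materials"],
            computers=None if _is_missing(r["computers"]) else r["computers"],
            group_size=None if _is_missing(r["group_size"]) else float(r["group_size"]),
            topic_complexity=None if _is_missing(r["topic_complexity"]) else r["topic_complexity"],
            professional_trainers=None
            if _is_missing(r["professional_trainers"])
            else r["professional_trainers"],
            content_expert_trainers=None
            if _is_missing(r["content_expert_trainers"])
            else r["content_expert_trainers"],
            onsite=None if _is_missing(r["onsite"]) else r["onsite"],
            multiple_sessions=None
            if _is_missing(r["multiple_sessions"])
            else r["multiple_sessions"],
        )

    def arms_of(self, study_id: str) -> list[StudyArm]:
        rows = self.arms[self.arms["study_id"] == study_id]
        out = []
        for _, r in rows.iterrows():
            aid = str(r["arm_id"])
            comps = frozenset(
                self.components.loc[self.components["arm_id"] == aid, "component_code"]
            )
            out.append(
                StudyArm(
                    arm_id=aid,
                    study_id=study_id,
                    components=comps,
                    is_control=bool(int(r["is_control"])),
                    is_gold_standard=bool(int(r["is_gold_standard"])),
                    training_attributes=self._attributes_for(aid),
                )
            )
        return out

    def outcome_ids_of(self, study_id: str) -> list[str]:
        mask = self.outcomes["study_id"] == study_id
        return list(dict.fromkeys(str(x) for x in self.outcomes.loc[mask, "outcome_id"]))

    def outcome_series(self, outcome_id: str) -> OutcomeSeries:
        rows = self.outcomes[self.outcomes["outcome_id"] == outcome_id]
        if rows.empty:
            raise KeyError(outcome_id)
        first = rows.iloc[0]
        return OutcomeSeries(
            outcome_id=str(outcome_id),
            study_id=str(first["study_id"]),
            scale=first["scale"],
            direction=first["direction"],
            measurements=rows[["arm_id", "time_month", "value", "n"]].reset_index(drop=True),
        )

    def measurements(self, outcome_id: str, arm_id: Optional[str] = None) -> pd.DataFrame:
        mask = self.outcomes["outcome_id"] == outcome_id
        if arm_id is not None:
            mask &= self.outcomes["arm_id"] == arm_id
        return self.outcomes[mask]

    def cost_records(self) -> list[CostRecord]:
        return [
            CostRecord(
                arm_id=str(r["arm_id"]),
                total_cost_usd=float(r["total_cost_usd"]),
                n_hcps_trained=int(r["n_hcps_trained"]),
                duration_days=float(r["duration_days"]),
            )
            for _, r in self.costs.iterrows()
        ]

    # -- validation ---------------------------------------------------------

    def validate(self) -> "StudyDatabase":
        """Check referential integrity and all schema invariants.

        Raises :class:`DatabaseValidationError` listing the offending table,
        row identifier and rule for every violation found.
        """
        problems: list[str] = []

        def check_enum(table: str, col: str, allowed, id_col: str, allow_missing=False):
            df = self.table(table)
            if df.empty:
                return
            missing = df[col].isna() | (df[col] == "")
            if not allow_missing and missing.any():
                problems.extend(
                    f"{table}[{i}]: {col} is missing" for i in df.loc[missing, id_col]
                )
            bad = ~missing & ~df[col].isin(allowed)
            for i, v in zip(df.loc[bad, id_col], df.loc[bad, col]):
                problems.append(f"{table}[{i}]: {col}={v!r} not in {sorted(allowed)}")

        for name, cols in SCHEMA.items():
            df = self.table(name)
            if list(df.columns) != cols:
                raise SchemaError(f"table {name!r}: columns {list(df.columns)} != schema {cols}")

        check_enum("studies", "design", DESIGNS, "study_id")
        check_enum("studies", "cadre", CADRES, "study_id")
        check_enum("studies", "country_income", COUNTRY_INCOMES, "study_id")
        for _, r in self.studies.iterrows():
            if _is_missing(r["strategy_start_month"]) or not np.isfinite(
                float(r["strategy_start_month"])
            ):
                problems.append(f"studies[{r['study_id']}]: strategy_start_month not finite")
            try:
                decode_rob_domains(r["rob_domains"])
            except ValueError as exc:
                problems.append(f"studies[{r['study_id']}]: {exc}")
        if self.studies["study_id"].duplicated().any():
            dup = self.studies.loc[self.studies["study_id"].duplicated(), "study_id"]
            problems.extend(f"studies[{d}]: duplicate study_id" for d in dup)

        study_ids = set(str(x) for x in self.studies["study_id"])
        arm_ids = set(str(x) for x in self.arms["arm_id"])
        if self.arms["arm_id"].duplicated().any():
            dup = self.arms.loc[self.arms["arm_id"].duplicated(), "arm_id"]
            problems.extend(f"arms[{d}]: duplicate arm_id" for d in dup)
        for _, r in self.arms.iterrows():
            if str(r["study_id"]) not in study_ids:
                problems.append(f"arms[{r['arm_id']}]: dangling study_id {r['study_id']!r}")

        for tbl, col in (("components", "arm_id"), ("attributes", "arm_id"), ("costs", "arm_id")):
            for _, r in self.table(tbl).iterrows():
                if str(r[col]) not in arm_ids:
                    problems.append(f"{tbl}[{r[col]}]: dangling arm_id")

        check_enum("components", "component_code", COMPONENT_VOCAB, "arm_id")

        # Control arms have no components beyond placebo; training attributes
        # exist exactly for arms with a training component.
        comp_by_arm: dict[str, set[str]] = {}
        for _, r in self.components.iterrows():
            comp_by_arm.setdefault(str(r["arm_id"]), set()).add(r["component_code"])
        attr_arms = set(str(x) for x in self.attributes["arm_id"])
        for _, r in self.arms.iterrows():
            aid = str(r["arm_id"])
            comps = comp_by_arm.get(aid, set())
            is_control = bool(int(r["is_control"]))
            has_training = bool(comps & set(TRAINING_CATEGORIES))
            if is_control and comps - {PLACEBO}:
                problems.append(
                    f"arms[{aid}]: control arm carries non-placebo components {sorted(comps - {PLACEBO})}"
                )
            if not is_control and not comps:
                problems.append(f"arms[{aid}]: non-control arm has no components")
            if has_training and aid not in attr_arms:
                problems.append(f"arms[{aid}]: training arm lacks an attributes row")
            if not has_training and aid in attr_arms:
                problems.append(f"attributes[{aid}]: attributes given for arm without training")
            if len(comps & set(TRAINING_CATEGORIES)) > 1:
                problems.append(
                    f"arms[{aid}]: multiple training categories {sorted(comps & set(TRAINING_CATEGORIES))}"
                )

        for _, r in self.attributes.iterrows():
            aid = str(r["arm_id"])
            if not _is_missing(r["duration_days"]) and float(r["duration_days"]) <= 0:
                problems.append(f"attributes[{aid}]: duration_days must be > 0")
            for col in (*TRAINING_METHODS, "printed_materials", "computers",
                        "professional_trainers", "content_expert_trainers", "multiple_sessions"):
                if not _is_missing(r[col]) and r[col] not in TRISTATE:
                    problems.append(f"attributes[{aid}]: {col}={r[col]!r} not yes/no/missing")
            if not _is_missing(r["onsite"]) and r["onsite"] not in ONSITE_LEVELS:
                problems.append(f"attributes[{aid}]: onsite={r['onsite']!r} invalid")
            if not _is_missing(r["topic_complexity"]) and r["topic_complexity"] not in COMPLEXITY_LEVELS:
                problems.append(f"attributes[{aid}]: topic_complexity={r['topic_complexity']!r} invalid")

        check_enum("outcomes", "scale", SCALES, "outcome_id")
        check_enum("outcomes", "direction", DIRECTIONS, "outcome_id")
        if not self.outcomes.empty:
            oc = self.outcomes
            bad_study = ~oc["study_id"].astype(str).isin(study_ids)
            problems.extend(
                f"outcomes[{o}]: dangling study_id {s!r}"
                for o, s in zip(oc.loc[bad_study, "outcome_id"], oc.loc[bad_study, "study_id"])
            )
            bad_arm = ~oc["arm_id"].astype(str).isin(arm_ids)
            problems.extend(
                f"outcomes[{o}]: dangling arm_id {a!r}"
                for o, a in zip(oc.loc[bad_arm, "outcome_id"], oc.loc[bad_arm, "arm_id"])
            )
            vals = pd.to_numeric(oc["value"], errors="coerce")
            out_of_range = (oc["scale"] == "percentage") & vals.notna() & (
                (vals < 0.0) | (vals > 100.0)
            )
            problems.extend(
                f"outcomes[{o}]: percentage value {v} outside [0, 100]"
                for o, v in zip(oc.loc[out_of_range, "outcome_id"], vals[out_of_range])
            )
            # outcome series metadata must be constant within an outcome_id
            nun = oc.groupby("outcome_id")[["scale", "direction"]].nunique()
            for oid in nun.index[(nun > 1).any(axis=1)]:
                problems.append(f"outcomes[{oid}]: inconsistent scale/direction within series")

        for _, r in self.costs.iterrows():
            aid = str(r["arm_id"])
            if _is_missing(r["total_cost_usd"]) or float(r["total_cost_usd"]) < 0:
                problems.append(f"costs[{aid}]: total_cost_usd must be >= 0")
            if _is_missing(r["n_hcps_trained"]) or int(r["n_hcps_trained"]) <= 0:
                problems.append(f"costs[{aid}]: n_hcps_trained must be > 0")
            if _is_missing(r["duration_days"]) or float(r["duration_days"]) <= 0:
                problems.append(f"costs[{aid}]: duration_days must be > 0")

        if problems:
            raise DatabaseValidationError(problems)
        return self


# --------------------------------------------------------------------------
# CSV round-trip
# --------------------------------------------------------------------------

_STRING_COLS = {
    ("studies", "study_id"),
    ("arms", "arm_id"),
    ("arms", "study_id"),
    ("components", "arm_id"),
    ("attributes", "arm_id"),
    ("outcomes", "outcome_id"),
    ("outcomes", "study_id"),
    ("outcomes", "arm_id"),
    ("costs", "arm_id"),
}


def _normalise(name: str, df: pd.DataFrame) -> pd.DataFrame:
    df = df.reindex(columns=SCHEMA[name]).copy()
    for col in SCHEMA[name]:
        if (name, col) in _STRING_COLS:
            df[col] = df[col].astype(str)
    df = df.sort_values(_SORT_KEYS[name], kind="mergesort").reset_index(drop=True)
    return df


def save_database(db: StudyDatabase, path: str | Path) -> None:
    """Write the six schema tables as CSV with deterministic order.

    Column order follows the schema; rows are sorted on stable keys so that
    two saves of the same database are byte-identical.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name in SCHEMA:
        df = _normalise(name, db.table(name))
        buf = io.StringIO()
        df.to_csv(buf, index=False, lineterminator="\n")
        (path / f"{name}.csv").write_text(buf.getvalue(), encoding="utf-8")


def load_database(
    path: str | Path,
    component_map: Optional[dict[str, str]] = None,
    validate: bool = True,
) -> StudyDatabase:
    """Read a database directory, collapse component codes, and validate.

    Parameters
    ----------
    path
        Directory containing the six schema CSV tables.
    component_map
        Fine-code to category mapping; defaults to the packaged mapping.
        Unknown codes are rejected.
    validate
        Run full invariant validation after loading (on by default).
    """
    path = Path(path)
    tables = {}
    for name, cols in SCHEMA.items():
        f = path / f"{name}.csv"
        if not f.exists():
            raise SchemaError(f"missing table {name!r}: {f}")
        df = pd.read_csv(f, dtype={c: str for (t, c) in _STRING_COLS if t == name},
                         float_precision="round_trip")
        if list(df.columns) != cols:
            raise SchemaError(f"table {name!r}: header {list(df.columns)} != schema {cols}")
        tables[name] = df
        logger.info("loaded %s: %d rows", name, len(df))

    mapping = component_map if component_map is not None else load_component_map()
    comp = tables["components"]
    unknown = sorted(set(comp["component_code"]) - set(mapping))
    if unknown:
        raise DatabaseValidationError(
            [f"components[*]: unknown component code {c!r}" for c in unknown]
        )
    comp = comp.assign(component_code=comp["component_code"].map(mapping))
    tables["components"] = comp.drop_duplicates().reset_index(drop=True)

    db = StudyDatabase(**tables)
    if validate:
        db.validate()
    return db
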