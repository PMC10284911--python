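"""Domain types and curation filters for mechanism-of-action modeling.

This module turns raw characterization tables (drug targets, pathophysiological
motives and their molecular effectors), patient-level adverse-event counts and
pharmacovigilance report counts into the labeled *truth table* of drug–condition
restrictions that constrains network-model training.

Proteins are identified by UniProtKB-style accessions throughout.  Two curation
filters are applied upstream of the truth table:

* the CIOMS "very common" rule — an adverse drug reaction is retained for
  training when its per-trial frequency is at least 10% in at least one trial;
* a minimum-evidence rule for pharmacovigilance report tables — a drug (and its
  targets) is retained when it carries at least five reports for the adverse
  outcome of interest.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

logger = logging.getLogger("moanet")

CIOMS_VERY_COMMON_THRESHOLD = 0.10
DEFAULT_MIN_REPORTS = 5

Sign = Literal[1, -1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class ProteinRef:
    """A protein identified by a UniProtKB-style accession.

    Identity (equality, hashing, ordering) is by accession only; the optional
    human-readable short name is carried along for reporting.
    """

    accession: str
    short_name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("protein accession must be non-empty")


@dataclass(frozen=True, order=True)
class Effector:
    """A protein whose activity change participates in a condition.

    ``direction`` is the pathological activity change: +1 if the protein is
    activated in the pathological state, -1 if inhibited.
    """

    protein: ProteinRef
    direction: int

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError(f"effector direction must be +1 or -1, got {self.direction}")


@dataclass(frozen=True, order=True)
class DrugTarget:
    """A direct drug target with its action sign (+1 activation, -1 inhibition)."""

    protein: ProteinRef
    action: int

    def __post_init__(self) -> None:
        if self.action not in (1, -1):
            raise ValueError(f"target action must be +1 or -1, got {self.action}")


@dataclass(frozen=True)
class MotiveCharacterization:
    """A named pathophysiological process characterized by signed effectors.

    A protein may appear in more than one motive; within a motive each protein
    appears once.
    """

    name: str
    effectors: frozenset[Effector]

    def __post_init__(self) -> None:
        if not self.effectors:
            raise ValueError(f"motive {self.name!r} has no effectors")

    @property
    def proteins(self) -> frozenset[ProteinRef]:
        return frozenset(e.protein for e in self.effectors)


@dataclass(frozen=True)
class DrugCharacterization:
    """A drug characterized by its direct protein targets and action signs."""

    name: str
    targets: frozenset[DrugTarget]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"drug {self.name!r} has no targets")

    @property
    def proteins(self) -> frozenset[ProteinRef]:
        return frozenset(t.protein for t in self.targets)

    def stimulus(self) -> dict[str, int]:
        """Clamp map accession -> action sign used as a model stimulus."""
        return {t.protein.accession: t.action for t in sorted(self.targets)}


def combine_drugs(name: str, *drugs: DrugCharacterization) -> DrugCharacterization:
    """Union of several drugs' target sets, as used for combination therapy.

    Raises ``ValueError`` if two drugs act on a shared target with opposite
    signs (no such conflict exists among the coagulation agents modeled here,
    whose actions are all activating).
    """
    actions: dict[ProteinRef, int] = {}
    for drug in drugs:
        for t in drug.targets:
            if actions.get(t.protein, t.action) != t.action:
                raise ValueError(
                    f"conflicting action signs for {t.protein.accession} in combination {name!r}"
                )
            actions[t.protein] = t.action
    return DrugCharacterization(
        name=name, targets=frozenset(DrugTarget(p, a) for p, a in actions.items())
    )


@dataclass(frozen=True)
class AEProfile:
    """Adverse-event occurrence counts for one clinical trial."""

    trial_id: str
    n_participants: int
    events: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name, count in self.events:
            if count < 0:
                raise ValueError(f"negative occurrence count for {name!r}")


@dataclass(frozen=True)
class ReportRow:
    drug: str
    targets: tuple[str, ...]
    n_reports: int

    def __post_init__(self) -> None:
        if self.n_reports < 0 or int(self.n_reports) != self.n_reports:
            raise ValueError("report count must be a non-negative integer")


@dataclass(frozen=True)
class ReportTable:
    """Pharmacovigilance extract: per-drug report counts with associated targets."""

    rows: tuple[ReportRow, ...]


Relation = Literal["induces", "treats"]


@dataclass(frozen=True)
class Restriction:
    """One labeled drug–condition relationship used as a training constraint.

    ``relation`` is "induces" when the drug is expected to drive the condition's
    effectors toward their pathological direction, "treats" when it is expected
    to drive them the opposite way.  ``label`` is False for an explicit
    non-association.
    """

    stimulus: DrugCharacterization
    condition: str
    response: frozenset[Effector]
    relation: Relation
    label: bool

    def __post_init__(self) -> None:
        if self.relation not in ("induces", "treats"):
            raise ValueError(f"unknown relation {self.relation!r}")
        if not self.response:
            raise ValueError("restriction has an empty response set")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.stimulus.name, self.condition, self.relation)

    def expected_direction(self, effector: Effector) -> int:
        """Activity sign this restriction expects for one response effector."""
        return effector.direction if self.relation == "induces" else -effector.direction


@dataclass(frozen=True)
class TruthTable:
    """The set of labeled restrictions a trained model must satisfy."""

    restrictions: tuple[Restriction, ...]

    def __post_init__(self) -> None:
        labels = {r.label for r in self.restrictions}
        if labels != {True, False}:
            raise ValueError(
                "truth table needs at least one positive and one negative restriction"
            )

    def __len__(self) -> int:
        return len(self.restrictions)

    @property
    def positives(self) -> tuple[Restriction, ...]:
        return tuple(r for r in self.restrictions if r.label)

    @property
    def negatives(self) -> tuple[Restriction, ...]:
        return tuple(r for r in self.restrictions if not r.label)


# ---------------------------------------------------------------------------
# Curation operations
# ---------------------------------------------------------------------------

def normalize_event_name(name: str) -> str:
    """Case-insensitive comparison form with collapsed internal whitespace."""
    return re.sub(r"\s+", " ", name.strip()).casefold()


def classify_ae_frequency(
    count: int, n_participants: int, threshold: float = CIOMS_VERY_COMMON_THRESHOLD
) -> tuple[float, str]:
    """CIOMS frequency class of one adverse event in one trial.

    Returns ``(frequency, class)`` where class is ``"very_common"`` when
    frequency >= 10% (boundary inclusive) and ``"other"`` otherwise.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if count < 0:
        raise ValueError("count must be >= 0")
    freq = count / n_participants
    return freq, ("very_common" if freq >= threshold else "other")


def select_training_adrs(
    profiles: Sequence[AEProfile], forced: Iterable[str] = ()
) -> set[str]:
    """Adverse events retained as model restrictions.

    An event qualifies when it is CIOMS very-common in at least one trial.
    ``forced`` events (e.g. the rare adverse outcome the study is about) are
    always included.  Names are returned in normalized form.
    """
    selected = {normalize_event_name(f) for f in forced}
    for profile in profiles:
        for name, count in profile.events:
            _, cls = classify_ae_frequency(count, profile.n_participants)
            if cls == "very_common":
                selected.add(normalize_event_name(name))
    return selected


def filter_reports(
    table: ReportTable, min_reports: int = DEFAULT_MIN_REPORTS
) -> tuple[set[str], set[str]]:
    """Drugs and targets with consistent report-level evidence.

    Retains rows with ``n_reports >= min_reports`` (boundary inclusive) and
    returns the distinct retained drugs and the union of their targets.
    """
    if min_reports < 1:
        raise ValueError("min_reports must be >= 1")
    drugs: set[str] = set()
    targets: set[str] = set()
    for row in table.rows:
        if row.n_reports >= min_reports:
            drugs.add(row.drug)
            targets.update(row.targets)
    return drugs, targets


def assemble_truth_table(
    indications: Sequence[tuple[DrugCharacterization, MotiveCharacterization]],
    adrs: Sequence[tuple[DrugCharacterization, MotiveCharacterization]],
    ditma_drugs: Sequence[DrugCharacterization],
    negatives: Sequence[tuple[DrugCharacterization, MotiveCharacterization, Relation]],
    outcome: MotiveCharacterization | None = None,
) -> TruthTable:
    """Assemble the training truth table from curated relationship lists.

    * ``indications`` — (drug, condition) pairs the drug treats (label True).
    * ``adrs`` — (drug, condition) pairs the drug induces (label True).
    * ``ditma_drugs`` — drugs known to induce the adverse ``outcome``
      characterization (label True); requires ``outcome``.
    * ``negatives`` — explicit non-associations (label False).  How
      non-associations are chosen is an upstream curation decision; they are
      taken as input rather than sampled here.

    Exact duplicates of the same (drug, condition, relation, label) are
    deduplicated with a logged warning; conflicting labels for the same
    (drug, condition, relation) raise ``ValueError``.
    """
    entries: list[Restriction] = []
    for drug, cond in indications:
        entries.append(Restriction(drug, cond.name, cond.effectors, "treats", True))
    for drug, cond in adrs:
        entries.append(Restriction(drug, cond.name, cond.effectors, "induces", True))
    if ditma_drugs:
        if outcome is None:
            raise ValueError("ditma_drugs given but no outcome characterization")
        for drug in ditma_drugs:
            entries.append(
                Restriction(drug, outcome.name, outcome.effectors, "induces", True)
            )
    for drug, cond, relation in negatives:
        entries.append(Restriction(drug, cond.name, cond.effectors, relation, False))

    if not entries:
        raise ValueError("no restrictions assembled from empty inputs")

    by_key: dict[tuple[str, str, str], Restriction] = {}
    for r in entries:
        prev = by_key.get(r.key)
        if prev is None:
            by_key[r.key] = r
        elif prev.label != r.label:
            raise ValueError(f"conflicting labels for restriction {r.key}")
        else:
            logger.warning("duplicate restriction %s dropped", r.key)
    return TruthTable(tuple(by_key.values()))


# ---------------------------------------------------------------------------
# Tab-separated external interfaces
# ---------------------------------------------------------------------------

def read_drug_characterizations(path: str | Path) -> list[DrugCharacterization]:
    """Read a drug|protein_accession|short_name|action TSV (one row per target)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["drug", "protein_accession", "short_name", "action"], path)
    drugs = []
    for name, grp in df.groupby("drug", sort=True):
        targets = frozenset(
            DrugTarget(ProteinRef(row.protein_accession, row.short_name), int(row.action))
            for row in grp.itertuples()
        )
        drugs.append(DrugCharacterization(str(name), targets))
    return drugs


def read_motive_characterizations(path: str | Path) -> list[MotiveCharacterization]:
    """Read a motive|protein_accession|direction TSV (one row per effector)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["motive", "protein_accession", "direction"], path)
    motives = []
    for name, grp in df.groupby("motive", sort=True):
        effectors = frozenset(
            Effector(ProteinRef(row.protein_accession), int(row.direction))
            for row in grp.itertuples()
        )
        motives.append(MotiveCharacterization(str(name), effectors))
    return motives


def read_ae_profiles(path: str | Path) -> list[AEProfile]:
    """Read a trial_id|n_participants|event|count TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"trial_id": str, "event": str})
    _require_columns(df, ["trial_id", "n_participants", "event", "count"], path)
    profiles = []
    for trial, grp in df.groupby("trial_id", sort=True):
        n = int(grp["n_participants"].iloc[0])
        events = tuple((row.event, int(row.count)) for row in grp.itertuples())
        profiles.append(AEProfile(str(trial), n, events))
    return profiles


def read_report_table(path: str | Path) -> ReportTable:
    """Read a drug|targets|n_reports TSV with semicolon-joined targets."""
    df = pd.read_csv(path, sep="\t", dtype={"drug": str, "targets": str})
    _require_columns(df, ["drug", "targets", "n_reports"], path)
    rows = tuple(
        ReportRow(
            row.drug,
            tuple(t for t in str(row.targets).split(";") if t and t != "nan"),
            int(row.n_reports),
        )
        for row in df.itertuples()
    )
    return ReportTable(rows)


def write_drug_characterizations(drugs: Sequence[DrugCharacterization], path: str | Path) -> None:
    records = [
        {
            "drug": d.name,
            "protein_accession": t.protein.accession,
            "short_name": t.protein.short_name or "",
            "action": t.action,
        }
        for d in drugs
        for t in sorted(d.targets)
    ]
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)


def write_motive_characterizations(
    motives: Sequence[MotiveCharacterization], path: str | Path
) -> None:
    records = [
        {"motive": m.name, "protein_accession": e.protein.accession, "direction": e.direction}
        for m in motives
        for e in sorted(m.effectors)
    ]
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)


def read_truth_table(
    path: str | Path,
    drugs: Sequence[DrugCharacterization],
    motives: Sequence[MotiveCharacterization],
) -> TruthTable:
    """Read a drug|condition|relation|label TSV against known characterizations."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["drug", "condition", "relation", "label"], path)
    drug_by_name = {d.name: d for d in drugs}
    motive_by_name = {m.name: m for m in motives}
    restrictions = []
    for row in df.itertuples():
        if row.drug not in drug_by_name:
            raise ValueError(f"{path}: unknown drug {row.drug!r}")
        if row.condition not in motive_by_name:
            raise ValueError(f"{path}: unknown condition {row.condition!r}")
        motive = motive_by_name[row.condition]
        restrictions.append(
            Restriction(
                stimulus=drug_by_name[row.drug],
                condition=motive.name,
                response=motive.effectors,
                relation=row.relation,
                label=str(row.label).strip().lower() in ("true", "1"),
            )
        )
    return TruthTable(tuple(restrictions))


def write_truth_table(table: TruthTable, path: str | Path) -> None:
    records = [
        {
            "drug": r.stimulus.name,
            "condition": r.condition,
            "relation": r.relation,
            "label": r.label,
        }
        for r in table.restrictions
    ]
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
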