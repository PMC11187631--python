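"""Chemical and biological curation of hERG bioactivity records.

The workflow follows the standard QSAR curation protocol: structures are
standardized (salts stripped, charges neutralized, common chemotypes
normalized, stereo descriptors removed), IC50 values are converted to the
pIC50 scale, censored measurements (">"/"<" qualifiers) are filtered by
task-specific rules, compounds are labeled, and duplicate measurements of
the same standardized structure are resolved.

Three datasets are produced from one raw table, one per learning task:

* ``binary``      — blocker (IC50 < 10 uM) vs nonblocker (IC50 >= 10 uM)
* ``multiclass``  — strong (pIC50 >= 6), moderate/weak (5 <= pIC50 < 6),
                    nonblocker (pIC50 < 5)
* ``regression``  — continuous pIC50, exact ("=") measurements only

Every removal is counted by rule in a :class:`CurationReport`; counts
always balance exactly against the input record count.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from statistics import mean, stdev

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .records_io import ActivityRecord, DatasetTable

RDLogger.DisableLog("rdApp.*")

_NORMALIZER = rdMolStandardize.Normalizer()
_UNCHARGER = rdMolStandardize.Uncharger()

TASKS = ("binary", "multiclass", "regression")

BINARY_LABELS = ("blocker", "nonblocker")
MULTICLASS_LABELS = ("strong", "moderate_weak", "nonblocker")


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds controlling labeling and duplicate resolution.

    binary_inactive_ic50_molar
        IC50 at and above which a compound is a nonblocker (default 10 uM).
    multiclass_strong_pic50 / multiclass_moderate_pic50
        pIC50 class boundaries (defaults 6 and 5).
    regression_dup_sd_max
        maximum sample SD of pIC50 within a duplicate group before the
        whole group is discarded (default 0.2 log units).
    """

    task: str = "binary"
    binary_inactive_ic50_molar: float = 1e-5
    multiclass_strong_pic50: float = 6.0
    multiclass_moderate_pic50: float = 5.0
    regression_dup_sd_max: float = 0.2

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if not self.multiclass_strong_pic50 > self.multiclass_moderate_pic50:
            raise ValueError("strong threshold must exceed moderate threshold")
        if not self.regression_dup_sd_max > 0:
            raise ValueError("regression_dup_sd_max must be positive")


REMOVAL_RULES = (
    "unparseable", "inorganic", "mixture",
    "qualifier_excluded", "duplicate_conflict", "duplicate_high_sd",
    "duplicate_merged",
)


@dataclass
class CurationReport:
    """Per-rule record counts for one curation run.

    ``duplicate_merged`` counts records absorbed into a kept compound when a
    duplicate group is resolved (they are not removals in the chemical
    sense, but counting them keeps exact conservation:
    kept + sum(all other counts) == input records).
    """

    counts: Counter = field(default_factory=Counter)
    kept: int = 0
    input_records: int = 0
    experimental_mae: float | None = None

    def add(self, rule: str, n: int = 1) -> None:
        if rule not in REMOVAL_RULES:
            raise ValueError(f"unknown removal rule {rule!r}")
        self.counts[rule] += n

    def balanced(self) -> bool:
        return self.kept + sum(self.counts.values()) == self.input_records

    def as_dict(self) -> dict:
        out = {rule: self.counts.get(rule, 0) for rule in REMOVAL_RULES}
        out["kept"] = self.kept
        out["input_records"] = self.input_records
        if self.experimental_mae is not None:
            out["experimental_mae"] = self.experimental_mae
        return out


@dataclass(frozen=True)
class CuratedCompound:
    smiles: str                    # canonical, standardized
    pic50: float | None
    label: str | float | None     # class label or regression target


@dataclass
class CuratedDataset:
    compounds: list[CuratedCompound]
    task: str
    report: CurationReport
    config: CurationConfig

    def __len__(self) -> int:
        return len(self.compounds)

    @property
    def smiles(self) -> list[str]:
        return [c.smiles for c in self.compounds]

    @property
    def labels(self) -> list:
        return [c.label for c in self.compounds]

    def to_table(self) -> DatasetTable:
        """Re-express the curated compounds as exact IC50 records.

        Useful for idempotence checks: curating the result removes nothing.
        """
        records = []
        for i, c in enumerate(self.compounds):
            pic50 = c.pic50
            if pic50 is None:  # classification kept without a usable value
                pic50 = 5.0
            molar = 10.0 ** (-pic50)
            records.append(
                ActivityRecord(
                    compound_id=f"C{i}", smiles=c.smiles, assay_type="other",
                    relation="eq", value=molar, units="M",
                )
            )
        return DatasetTable(records=records, provenance=f"curated:{self.task}")


# ---------------------------------------------------------------------------
# structure standardization


def normalize_structure(smiles: str) -> tuple[str | None, str | None]:
    """Standardize one SMILES.

    Returns ``(canonical_smiles, None)`` on success or ``(None, reason)``
    with reason in {"unparseable", "inorganic", "mixture"}.

    Standardization: keep the largest organic fragment (salt/counter-ion
    stripping), normalize common chemotypes (nitro, N-oxide, azide mesomers
    via the RDKit transform set), neutralize charges, strip stereochemistry.
    A structure with no carbon-bearing fragment is inorganic; two or more
    distinct organic fragments constitute a mixture.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None, "unparseable"
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = []
    seen = set()
    for frag in frags:
        if not any(a.GetAtomicNum() == 6 for a in frag.GetAtoms()):
            continue
        can = Chem.MolToSmiles(frag)
        if can not in seen:
            seen.add(can)
            organic.append(frag)
    if not organic:
        return None, "inorganic"
    if len(organic) > 1:
        return None, "mixture"
    mol = organic[0]
    try:
        mol = _NORMALIZER.normalize(mol)
        mol = _UNCHARGER.uncharge(mol)
        Chem.RemoveStereochemistry(mol)
        Chem.SanitizeMol(mol)
    except Exception:
        return None, "unparseable"
    return Chem.MolToSmiles(mol), None


def ic50_to_pic50(ic50_molar: float) -> float:
    """pIC50 = -log10(IC50 in molar)."""
    if not ic50_molar > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_molar!r}")
    return -math.log10(ic50_molar)


# ---------------------------------------------------------------------------
# qualifier and labeling rules

KEEP_AS_IS = "keep_as_is"
KEEP_AS_ACTIVE = "keep_as_active"
KEEP_AS_INACTIVE = "keep_as_inactive"
EXCLUDE = "exclude"


def apply_qualifier_filter(record: ActivityRecord, task: str,
                           config: CurationConfig | None = None) -> str:
    """Decide how a censored (qualifier) measurement is used.

    Classification tasks: a ">" record below 10 uM is uninformative and is
    excluded; at or above 10 uM it is a definite inactive.  A "<" record at
    or below 10 uM is a definite active; above 10 uM it is excluded.
    Regression: every non-"=" record is excluded (the exact value is
    unknowable).  "<="/">=" are treated like "<"/">".
    """
    cfg = config or CurationConfig(task=task)
    cut = cfg.binary_inactive_ic50_molar
    molar = record.value_molar
    rel = {"le": "lt", "ge": "gt"}.get(record.relation, record.relation)
    if task == "regression":
        return KEEP_AS_IS if rel == "eq" else EXCLUDE
    if rel == "eq":
        return KEEP_AS_IS
    # unit conversion leaves values an ulp off the 10 uM boundary; compare
    # with a relative slack far below any reported assay precision
    if rel == "gt":
        return KEEP_AS_INACTIVE if molar >= cut * (1 - 1e-12) else EXCLUDE
    if rel == "lt":
        return KEEP_AS_ACTIVE if molar <= cut * (1 + 1e-12) else EXCLUDE
    raise ValueError(f"unknown relation {record.relation!r}")


#: slack for class boundaries on the pIC50 scale, well below assay precision
_PIC50_EPS = 1e-12


def label_binary(pic50: float, config: CurationConfig | None = None) -> str:
    """Nonblocker iff IC50 >= 10 uM, i.e. pIC50 <= 5; blocker otherwise."""
    cfg = config or CurationConfig()
    boundary = ic50_to_pic50(cfg.binary_inactive_ic50_molar)
    return "nonblocker" if pic50 <= boundary + _PIC50_EPS else "blocker"


def label_multiclass(pic50: float, config: CurationConfig | None = None) -> str:
    """strong iff pIC50 >= 6; moderate_weak iff 5 <= pIC50 < 6; else nonblocker."""
    cfg = config or CurationConfig()
    if pic50 >= cfg.multiclass_strong_pic50 - _PIC50_EPS:
        return "strong"
    if pic50 >= cfg.multiclass_moderate_pic50 - _PIC50_EPS:
        return "moderate_weak"
    return "nonblocker"


# ---------------------------------------------------------------------------
# duplicate resolution


def deduplicate_classification(groups: dict) -> tuple[list, Counter]:
    """Resolve duplicate groups of labeled records.

    ``groups`` maps canonical SMILES to a list of ``(label, pic50)`` tuples
    (pic50 may be None for qualifier-derived labels).  Per group: if all
    labels agree keep one; if a strict-majority label exists keep one record
    with that label; otherwise (tie) remove the whole group.

    Returns (kept list of CuratedCompound, Counter of removal counts in
    records).
    """
    kept: list[CuratedCompound] = []
    removals: Counter = Counter()
    for smi, members in groups.items():
        labels = [label for label, _ in members]
        tally = Counter(labels)
        top_label, top_n = tally.most_common(1)[0]
        runners = [n for lbl, n in tally.items() if lbl != top_label]
        if runners and max(runners) >= top_n:  # tie: conflicting outcomes
            removals["duplicate_conflict"] += len(members)
            continue
        values = [p for label, p in members if label == top_label and p is not None]
        pic50 = mean(values) if values else None
        kept.append(CuratedCompound(smiles=smi, pic50=pic50, label=top_label))
        removals["duplicate_merged"] += len(members) - 1
    return kept, removals


def deduplicate_regression(groups: dict, sd_max: float = 0.2
                           ) -> tuple[list, Counter, list]:
    """Resolve duplicate groups of exact pIC50 measurements.

    ``groups`` maps canonical SMILES to a list of pIC50 values.  A group
    whose sample standard deviation exceeds ``sd_max`` is removed entirely;
    otherwise one compound is kept with the arithmetic-mean pIC50.

    Returns (kept compounds, removal counts, duplicate groups of size >= 2
    before filtering — used to estimate the experimental error).
    """
    kept: list[CuratedCompound] = []
    removals: Counter = Counter()
    duplicate_groups: list[list[float]] = []
    for smi, values in groups.items():
        if len(values) >= 2:
            duplicate_groups.append(list(values))
            sd = stdev(values)
            if sd > sd_max:
                removals["duplicate_high_sd"] += len(values)
                continue
        pic50 = mean(values)
        kept.append(CuratedCompound(smiles=smi, pic50=pic50, label=pic50))
        removals["duplicate_merged"] += len(values) - 1
    return kept, removals, duplicate_groups


def experimental_mae(duplicate_groups: list[list[float]]) -> float:
    """Record-weighted mean absolute deviation from each group's mean.

    Estimates the experimental measurement error from repeated measurements
    of the same compound, before duplicates are removed.
    """
    groups = [g for g in duplicate_groups if len(g) >= 2]
    if not groups:
        raise ValueError("no duplicate group of size >= 2")
    deviations = []
    for g in groups:
        mu = mean(g)
        deviations.extend(abs(v - mu) for v in g)
    return float(mean(deviations))


# ---------------------------------------------------------------------------
# full pipeline


def curate_dataset(table: DatasetTable, config: CurationConfig) -> CuratedDataset:
    """Run the full curation pipeline for one task.

    Order: structure standardization -> unit conversion and pIC50 ->
    qualifier filter -> labeling (classification) -> duplicate resolution.
    The report's counts balance exactly against the input record count.
    """
    if len(table.records) == 0:
        raise ValueError("cannot curate an empty table")
    task = config.task
    report = CurationReport(input_records=len(table.records))

    # stage 1-3: standardize, convert, filter qualifiers; bucket by structure
    groups: dict[str, list] = defaultdict(list)
    for rec in table.records:
        can, reason = normalize_structure(rec.smiles)
        if can is None:
            report.add(reason)
            continue
        pic50 = ic50_to_pic50(rec.value_molar)
        decision = apply_qualifier_filter(rec, task, config)
        if decision == EXCLUDE:
            report.add("qualifier_excluded")
            continue
        if task == "regression":
            groups[can].append(pic50)
        elif task == "binary":
            if decision == KEEP_AS_ACTIVE:
                label, val = "blocker", None
            elif decision == KEEP_AS_INACTIVE:
                label, val = "nonblocker", None
            else:
                label, val = label_binary(pic50, config), pic50
            groups[can].append((label, val))
        else:  # multiclass
            if decision == KEEP_AS_INACTIVE:
                label, val = "nonblocker", None
            elif decision == KEEP_AS_ACTIVE:
                # censored "<v": true pIC50 >= computed bound; tier from the
                # bound is a conservative (weakest-consistent) assignment
                label, val = label_multiclass(pic50, config), None
            else:
                label, val = label_multiclass(pic50, config), pic50
            groups[can].append((label, val))

    # stage 4: duplicates
    if task == "regression":
        kept, removals, dup_groups = deduplicate_regression(
            groups, config.regression_dup_sd_max)
        if any(len(g) >= 2 for g in dup_groups):
            report.experimental_mae = experimental_mae(dup_groups)
    else:
        kept, removals = deduplicate_classification(groups)
    for rule, n in removals.items():
        report.add(rule, n)
    report.kept = len(kept)

    assert report.balanced(), "curation bookkeeping out of balance"
    return CuratedDataset(compounds=kept, task=task, report=report, config=config)
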