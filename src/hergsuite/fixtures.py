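"""Synthetic bioactivity tables with known ground truth.

Real hERG bioactivity exports mix exact and censored measurements,
duplicate measurements with experimental scatter, conflicting duplicate
outcomes, salt forms and the occasional inorganic — and the relationship
between structure and potency lives in substructure (fingerprint bit)
space.  The generator emulates exactly that statistical shape:

* a combinatorial library of valid drug-like molecules (scaffold x
  substituent enumeration, no generative model needed);
* a latent potency model  pIC50 = 4.5 + effect_per_bit * (number of
  planted signal bits set in the compound's fingerprint) + N(0, noise_sd),
  so nonsignal compounds sit below every class boundary and expected label
  counts are closed-form;
* injected anomalies in disjoint, bookkept index ranges: exact duplicates,
  conflicting-label duplicates, censored (">") records and salt forms.

Every injection is logged in a truth dict so curation outcomes are
checkable record-by-record.  ``worked_examples`` packages four published
activity-cliff IC50 values for conversion and labeling tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from rdkit import Chem

from .featurize import FingerprintSpec, fingerprint
from .records_io import ActivityRecord, DatasetTable

_SCAFFOLDS = (
    "c1ccc({A})cc1CCN({B})C",
    "O=C(N{B})c1ccc({A})cc1",
    "c1ccc2c(c1)nc({A})n2{B}",
    "O=C(O)C({A})c1ccccc1{B}",
    "c1cnc({A})cc1OC{B}",
    "C1CN({B})CCC1{A}",
)

_SUBSTITUENTS = (
    "C", "N", "O", "F", "Cl", "Br", "CC", "CCC", "C(C)C", "CO", "CN",
    "CCO", "CCN", "COC", "C(F)(F)F", "CC=O",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Stated world of one synthetic dataset.

    Defaults: 400 compounds; effect_per_bit 1.0 pIC50 units (one signal bit
    lifts a compound from the 4.5 intercept across the binary boundary at
    pIC50 5); noise_sd 0.3 log units, comparable to the experimental error
    estimated from assay duplicates; 10% exact duplicates, 5% conflicting
    duplicates, 5% censored records, 10% salt forms.
    """

    n_compounds: int = 400
    signal_bits: tuple[int, ...] | None = None   # None = auto-pick 3 common bits
    effect_per_bit: float = 1.0
    noise_sd: float = 0.3
    duplicate_fraction: float = 0.10
    conflict_fraction: float = 0.05
    qualifier_fraction: float = 0.05
    salt_fraction: float = 0.10
    fingerprint: FingerprintSpec = field(default_factory=FingerprintSpec)
    seed: int = 0

    def __post_init__(self):
        for name in ("duplicate_fraction", "conflict_fraction",
                     "qualifier_fraction", "salt_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def make_library(n: int, seed: int = 0) -> list[str]:
    """n distinct, valid, drug-like canonical SMILES (deterministic per seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    combos = list(product(range(len(_SCAFFOLDS)), range(len(_SUBSTITUENTS)),
                          range(len(_SUBSTITUENTS))))
    rng = np.random.RandomState(seed)
    rng.shuffle(combos)
    library: list[str] = []
    seen: set[str] = set()
    for si, ai, bi in combos:
        smi = _SCAFFOLDS[si].format(A=_SUBSTITUENTS[ai], B=_SUBSTITUENTS[bi])
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        library.append(can)
        if len(library) == n:
            return library
    raise ValueError(f"requested {n} compounds but only {len(library)} enumerable")


def _auto_signal_bits(fps: np.ndarray, n_bits: int = 3,
                      target_freq: float = 0.4) -> tuple[int, ...]:
    """Pick bits whose library frequency is closest to target_freq."""
    freq = fps.mean(axis=0)
    order = np.argsort(np.abs(freq - target_freq), kind="stable")
    return tuple(int(b) for b in order[:n_bits])


def pic50_to_um(pic50: float) -> float:
    """Concentration in uM corresponding to a pIC50."""
    return 10.0 ** (6.0 - pic50)


def plant_activity(library: list[str], spec: FixtureSpec
                   ) -> tuple[DatasetTable, dict]:
    """Emit activity records with a planted fingerprint-bit signal.

    Returns ``(table, truth)``.  ``truth`` records the signal bits, each
    compound's latent pIC50 and binary label, the index ranges of every
    injected anomaly, and the expected curation report counts per task.
    """
    n = len(library)
    rng = np.random.RandomState(spec.seed)
    fps = np.array([fingerprint(s, spec.fingerprint) for s in library])
    signal_bits = (spec.signal_bits if spec.signal_bits is not None
                   else _auto_signal_bits(fps))
    hits = fps[:, list(signal_bits)].sum(axis=1)
    pic50 = 4.5 + spec.effect_per_bit * hits + rng.normal(0, spec.noise_sd, n)

    n_dup = int(round(spec.duplicate_fraction * n))
    n_conf = int(round(spec.conflict_fraction * n))
    n_qual = int(round(spec.qualifier_fraction * n))
    n_salt = int(round(spec.salt_fraction * n))
    if n_dup + n_conf + n_qual + n_salt > n:
        raise ValueError("anomaly fractions exceed the library size")
    dup_range = range(0, n_dup)
    conf_range = range(n_dup, n_dup + n_conf)
    qual_range = range(n_dup + n_conf, n_dup + n_conf + n_qual)
    salt_range = range(n_dup + n_conf + n_qual, n_dup + n_conf + n_qual + n_salt)

    assays = ("SP", "HEK", "CHO")
    records: list[ActivityRecord] = []

    def rec(i, smiles, value_um, relation="eq"):
        records.append(ActivityRecord(
            compound_id=f"CPD{i:05d}", smiles=smiles,
            assay_type=assays[rng.randint(3)], relation=relation,
            value=value_um, units="uM",
        ))

    for i, smi in enumerate(library):
        if i in qual_range:
            # censored ">" below 10 uM: excluded by every task's rules
            rec(i, smi, 5.0, relation="gt")
            continue
        smiles = smi + ".Cl" if i in salt_range else smi
        rec(i, smiles, pic50_to_um(pic50[i]))
        if i in dup_range:   # exact duplicate: merged, zero SD
            rec(i, smiles, pic50_to_um(pic50[i]))
        if i in conf_range:  # conflicting duplicate: other side of 10 uM,
            flipped = 3.5 if pic50[i] > 5.0 else 6.5  # and SD far above 0.2
            rec(i, smiles, pic50_to_um(flipped))

    labels = np.where(pic50 > 5.0, "blocker", "nonblocker")
    expected = {
        "binary": {
            "qualifier_excluded": n_qual,
            "duplicate_conflict": 2 * n_conf,
            "duplicate_merged": n_dup,
            "kept": n - n_conf - n_qual,
        },
        "regression": {
            "qualifier_excluded": n_qual,
            "duplicate_high_sd": 2 * n_conf,
            "duplicate_merged": n_dup,
            "kept": n - n_conf - n_qual,
        },
    }
    truth = {
        "signal_bits": tuple(signal_bits),
        "pic50": pic50,
        "binary_label": labels,
        "duplicate_ids": list(dup_range),
        "conflict_ids": list(conf_range),
        "qualifier_ids": list(qual_range),
        "salt_ids": list(salt_range),
        "expected_report": expected,
        "n_records": len(records),
    }
    return DatasetTable(records=records, provenance=f"fixture seed={spec.seed}"), truth


def worked_examples() -> DatasetTable:
    """Four published activity-cliff IC50 values as records.

    The potency values (75,000 / 579 / 23.5 / 0.00285 uM) and accession ids
    are published data; the structures are synthetic stand-ins (the source
    figure prints depictions, not SMILES), so these records exercise unit
    conversion and labeling, not structure-specific behavior.
    """
    rows = [
        ("CHEMBL300927", "OC(=O)Cc1ccc(F)cc1", 75000.0),
        ("CHEMBL55835", "OC(=O)C(C)c1ccc(F)cc1", 579.0),
        ("CHEMBL556312", "CN1CCC(CC1)Oc1ccc(Cl)cc1", 23.5),
        ("CHEMBL12713", "CN1CCC(CC1)Oc1ccccc1", 0.00285),
    ]
    records = [
        ActivityRecord(compound_id=cid, smiles=smi, assay_type="SP",
                       relation="eq", value=v, units="uM")
        for cid, smi, v in rows
    ]
    return DatasetTable(records=records, provenance="published worked examples (synthetic stand-in structures)")
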