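"""End-to-end orchestration: curate -> featurize -> train -> predict ->
consensus, with config serialization next to every output for provenance.

``run_pipeline`` is the single entry point.  It curates the three task
datasets from one raw table, trains one model per task, fits an
applicability-domain cutoff per model, predicts every query compound, and
appends the weighted consensus call.  Re-running from the config written
beside the outputs reproduces them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .applicability import fit_ad, in_domain_many
from .consensus import ConsensusConfig, consensus_score, regression_to_label
from .curation import CurationConfig, curate_dataset, normalize_structure
from .featurize import FingerprintSpec, featurize_dataset
from .modeling import ModelSpec, TrainedModelBundle, stratified_split, train_model
from .records_io import DatasetTable, read_activity_table


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    input_path: str = ""
    dialect: str = "simple_csv"
    output_dir: str = "run_output"
    fingerprint: FingerprintSpec = field(default_factory=FingerprintSpec)
    algorithms: dict = field(default_factory=lambda: {
        "binary": "gbt_light", "multiclass": "random_forest", "regression": "svm",
    })
    hyperparameters: dict = field(default_factory=dict)   # per task
    curation: dict = field(default_factory=dict)           # CurationConfig kwargs
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    test_fraction: float = 0.2
    split_seed: int = 42
    model_seed: int = 42
    ad_k: int = 1
    ad_z: float = 0.5

    def as_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "dialect": self.dialect,
            "output_dir": self.output_dir,
            "fingerprint": self.fingerprint.as_dict(),
            "algorithms": dict(self.algorithms),
            "hyperparameters": dict(self.hyperparameters),
            "curation": dict(self.curation),
            "consensus": {
                "w_binary": self.consensus.w_binary,
                "w_agree": self.consensus.w_agree,
                "w_disagree": self.consensus.w_disagree,
                "threshold": self.consensus.threshold,
            },
            "test_fraction": self.test_fraction,
            "split_seed": self.split_seed,
            "model_seed": self.model_seed,
            "ad_k": self.ad_k,
            "ad_z": self.ad_z,
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["fingerprint"] = FingerprintSpec(**d.get("fingerprint", {}))
        d["consensus"] = ConsensusConfig(**d.get("consensus", {}))
        return cls(**d)


def _predict_task(bundle: TrainedModelBundle, ad_model, X) -> dict:
    labels = bundle.predict(X)
    flags, dists = in_domain_many(ad_model, X)
    return {"labels": labels, "in_domain": flags, "distance": dists}


def run_pipeline(config: RunConfig, table: DatasetTable | None = None
                 ) -> pd.DataFrame:
    """Run the whole pipeline; returns the per-compound prediction report.

    ``table`` may be passed directly (e.g. a synthetic fixture); otherwise
    ``config.input_path`` is read.  Outputs written to ``config.output_dir``:
    the report CSV, per-task curation reports (JSON), trained model bundles,
    and the exact RunConfig used (YAML).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: input
    if table is None:
        if not config.input_path or not Path(config.input_path).exists():
            raise StageError("input", f"input path {config.input_path!r} not found")
        table = read_activity_table(config.input_path, dialect=config.dialect)
    if len(table.records) == 0:
        raise StageError("input", "no records to process")

    # --- stage: curation (three task datasets from one table)
    datasets, bundles, ads, tests = {}, {}, {}, {}
    for task in ("binary", "multiclass", "regression"):
        try:
            cfg = CurationConfig(task=task, **config.curation)
            datasets[task] = curate_dataset(table, cfg)
        except ValueError as exc:
            raise StageError("curation", f"task {task}: {exc}") from exc
        with open(out / f"curation_report_{task}.json", "w") as fh:
            json.dump(datasets[task].report.as_dict(), fh, indent=2)

    # --- stage: featurize + split + train per task
    for task, dataset in datasets.items():
        try:
            fps = featurize_dataset(dataset, config.fingerprint)
            y = np.array(dataset.labels)
            train_idx, test_idx = stratified_split(
                y, test_fraction=config.test_fraction,
                seed=config.split_seed, task=task,
            )
            spec = ModelSpec(
                task=task, algorithm=config.algorithms[task],
                fingerprint=config.fingerprint,
                hyperparameters=config.hyperparameters.get(task, {}),
                seed=config.model_seed,
            )
            bundle = train_model(spec, fps.bits[train_idx], y[train_idx],
                                 ids=[fps.ids[i] for i in train_idx])
            ad = fit_ad(fps.bits[train_idx], k=config.ad_k, z=config.ad_z)
            bundle.ad_model = ad
            bundle.save(out / f"model_{task}")
            bundles[task], ads[task] = bundle, ad
            tests[task] = (fps, test_idx, y)
        except (ValueError, KeyError) as exc:
            raise StageError("train", f"task {task}: {exc}") from exc

    # --- stage: predict every curated binary-task compound (the query set)
    query = datasets["binary"]
    fps = featurize_dataset(query, config.fingerprint)
    try:
        per_task = {
            task: _predict_task(bundles[task], ads[task], fps.bits)
            for task in bundles
        }
    except ValueError as exc:
        raise StageError("predict", str(exc)) from exc

    # --- stage: consensus
    rows = []
    for i, compound in enumerate(query.compounds):
        b = str(per_task["binary"]["labels"][i])
        m = str(per_task["multiclass"]["labels"][i])
        pic50_hat = float(per_task["regression"]["labels"][i])
        r = regression_to_label(pic50_hat)
        res = consensus_score(b, m, r, config.consensus)
        rows.append({
            "smiles": compound.smiles,
            "binary_label": b,
            "multiclass_label": m,
            "predicted_pic50": pic50_hat,
            "regression_label": r,
            "consensus_score": res.score,
            "consensus_call": res.call,
            "multiclass_agrees": res.multiclass_agrees,
            "regression_agrees": res.regression_agrees,
            "in_domain_binary": bool(per_task["binary"]["in_domain"][i]),
            "in_domain_multiclass": bool(per_task["multiclass"]["in_domain"][i]),
            "in_domain_regression": bool(per_task["regression"]["in_domain"][i]),
            "ad_distance_binary": float(per_task["binary"]["distance"][i]),
        })
    report = pd.DataFrame(rows)
    report.to_csv(out / "prediction_report.csv", index=False)
    config.to_yaml(out / "run_config.yaml")
    return report


def predict_compounds(smiles_list: list[str], model_dir: str | Path,
                      consensus_config: ConsensusConfig | None = None
                      ) -> pd.DataFrame:
    """Predict new compounds from saved per-task model bundles.

    ``model_dir`` must contain ``model_binary``, ``model_multiclass`` and
    ``model_regression`` directories written by :func:`run_pipeline`.
    """
    model_dir = Path(model_dir)
    bundles = {}
    for task in ("binary", "multiclass", "regression"):
        path = model_dir / f"model_{task}"
        if not path.exists():
            raise StageError("load", f"missing model directory {path}")
        bundles[task] = TrainedModelBundle.load(path)
    cfg = consensus_config or ConsensusConfig()
    fp_spec = bundles["binary"].spec.fingerprint

    standardized = []
    for smi in smiles_list:
        can, reason = normalize_structure(smi)
        standardized.append((smi, can, reason))
    usable = [(smi, can) for smi, can, r in standardized if can is not None]
    if not usable:
        raise StageError("predict", "no standardizable query structures")
    fps = featurize_dataset([can for _, can in usable], fp_spec)

    rows = []
    for (smi, can), fp in zip(usable, fps.bits):
        b = str(bundles["binary"].predict(fp.reshape(1, -1))[0])
        m = str(bundles["multiclass"].predict(fp.reshape(1, -1))[0])
        pic50_hat = float(bundles["regression"].predict(fp.reshape(1, -1))[0])
        res = consensus_score(b, m, regression_to_label(pic50_hat), cfg)
        row = {"smiles": smi, "standardized": can, "binary_label": b,
               "multiclass_label": m, "predicted_pic50": pic50_hat,
               "consensus_score": res.score, "consensus_call": res.call}
        for task in bundles:
            if bundles[task].ad_model is not None:
                flag, dist = in_domain_many(bundles[task].ad_model,
                                            fp.reshape(1, -1))
                row[f"in_domain_{task}"] = bool(flag[0])
        rows.append(row)
    return pd.DataFrame(rows)
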