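"""Chemical-space diagnostics: assay correlation, cross-set similarity,
activity cliffs, SAR continuity/discontinuity and 2D embedding.

An activity cliff is a pair of highly similar molecules (Tanimoto above a
cutoff, 0.8 by default) with strongly divergent activity — opposing
blocker/nonblocker labels or a large pIC50 gap.  Cliffs make the
structure-activity landscape discontinuous and are the hardest cases for
fingerprint QSAR models.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.manifold import TSNE

from .curation import CuratedDataset, label_binary
from .featurize import FingerprintMatrix, FingerprintSpec, featurize_dataset


@dataclass(frozen=True)
class CliffPair:
    smiles_a: str
    smiles_b: str
    similarity: float
    pic50_a: float | None
    pic50_b: float | None
    label_a: str | float | None
    label_b: str | float | None

    @property
    def potency_gap(self) -> float:
        if self.pic50_a is None or self.pic50_b is None:
            return float("nan")
        return abs(self.pic50_a - self.pic50_b)


def assay_correlation(records) -> dict[tuple[str, str], tuple[float, float, int]]:
    """Pearson correlation of per-assay potencies between assay pairs.

    ``records`` is an iterable with ``smiles``, ``assay_type`` and a molar
    value (ActivityRecord works).  Compounds measured in both assays of a
    pair are matched by SMILES (per-assay mean pIC50); each pair needs at
    least 3 shared compounds.  Returns {(assay1, assay2): (r, p, n)} with a
    two-sided p-value from the t-distribution with n-2 df.
    """
    per_assay: dict[str, dict[str, list[float]]] = defaultdict(lambda: defaultdict(list))
    for rec in records:
        pic50 = rec.pic50 if rec.pic50 is not None else -math.log10(rec.value_molar)
        per_assay[rec.assay_type][rec.smiles].append(pic50)
    means = {
        assay: {smi: float(np.mean(v)) for smi, v in by_smiles.items()}
        for assay, by_smiles in per_assay.items()
    }
    out = {}
    for a, b in combinations(sorted(means), 2):
        shared = sorted(set(means[a]) & set(means[b]))
        if len(shared) < 3:
            continue
        x = [means[a][s] for s in shared]
        y = [means[b][s] for s in shared]
        r, p = stats.pearsonr(x, y)
        out[(a, b)] = (float(r), float(p), len(shared))
    if not out:
        raise ValueError("no assay pair shares >= 3 compounds")
    return out


def _tanimoto_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    inter = A @ B.T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return sim


def cross_set_tanimoto(set_a, set_b, same_set: bool | None = None) -> float:
    """Mean Tanimoto similarity over all pairs between two fingerprint sets.

    When the two sets are the same object (or ``same_set=True``), self-pairs
    are excluded from the mean.
    """
    A = set_a.bits if isinstance(set_a, FingerprintMatrix) else np.asarray(set_a)
    B = set_b.bits if isinstance(set_b, FingerprintMatrix) else np.asarray(set_b)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("empty fingerprint set")
    if same_set is None:
        same_set = set_a is set_b
    sim = _tanimoto_matrix(A, B)
    if same_set:
        if A.shape[0] < 2:
            raise ValueError("same-set mean needs >= 2 compounds")
        mask = ~np.eye(A.shape[0], dtype=bool)
        return float(sim[mask].mean())
    return float(sim.mean())


def find_cliffs(dataset: CuratedDataset,
                spec: FingerprintSpec = FingerprintSpec(family="maccs"),
                similarity_cutoff: float = 0.8,
                potency_gap_min: float = 1.0) -> list[CliffPair]:
    """All unordered compound pairs that qualify as activity cliffs.

    A pair qualifies when its Tanimoto similarity is at least the cutoff
    and either the binary labels oppose each other or |delta pIC50| is at
    least ``potency_gap_min`` log units.
    """
    fps = featurize_dataset(dataset, spec)
    sim = _tanimoto_matrix(fps.bits, fps.bits)
    compounds = dataset.compounds
    cliffs = []
    for i, j in combinations(range(len(compounds)), 2):
        if sim[i, j] < similarity_cutoff:
            continue
        ci, cj = compounds[i], compounds[j]
        opposing = False
        if ci.pic50 is not None and cj.pic50 is not None:
            opposing = (label_binary(ci.pic50, dataset.config)
                        != label_binary(cj.pic50, dataset.config))
            gap_hit = abs(ci.pic50 - cj.pic50) >= potency_gap_min
        else:
            gap_hit = False
        if isinstance(ci.label, str) and isinstance(cj.label, str):
            opposing = opposing or (
                (ci.label == "nonblocker") != (cj.label == "nonblocker"))
        if opposing or gap_hit:
            cliffs.append(CliffPair(
                smiles_a=ci.smiles, smiles_b=cj.smiles,
                similarity=float(sim[i, j]),
                pic50_a=ci.pic50, pic50_b=cj.pic50,
                label_a=ci.label, label_b=cj.label,
            ))
    return cliffs


def continuity_discontinuity(dataset: CuratedDataset,
                             spec: FingerprintSpec = FingerprintSpec(family="maccs"),
                             cutoff: float = 0.8
                             ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Raw per-compound SAR continuity and discontinuity scores.

    Continuity for compound i is the potency-weighted mean of reciprocal
    similarities over its pairs (weights = potency products; zero-similarity
    pairs are excluded); high continuity marks smooth SAR regions.
    Discontinuity is the mean of |delta pIC50| * similarity over pairs with
    similarity at or above the cutoff; it measures the local presence of
    activity cliffs.  Returns (cont_i, disc_i, global_cont, global_disc);
    compounds with no qualifying pair get NaN discontinuity and the global
    scores are means over defined compounds.
    """
    compounds = [c for c in dataset.compounds if c.pic50 is not None]
    if len(compounds) < 2:
        raise ValueError("need at least 2 compounds with pIC50")
    fps = featurize_dataset([c.smiles for c in compounds], spec)
    sim = _tanimoto_matrix(fps.bits, fps.bits)
    pot = np.array([c.pic50 for c in compounds], dtype=float)
    n = len(compounds)
    cont = np.full(n, np.nan)
    disc = np.full(n, np.nan)
    for i in range(n):
        others = np.arange(n) != i
        s = sim[i, others]
        p = pot[others]
        w = pot[i] * p
        pos = s > 0
        if pos.any() and w[pos].sum() > 0:
            cont[i] = float(np.sum(w[pos] / s[pos]) / w[pos].sum())
        near = s >= cutoff
        if near.any():
            disc[i] = float(np.mean(np.abs(pot[i] - p[near]) * s[near]))
    if np.all(np.isnan(disc)):
        raise ValueError("no pair above the similarity cutoff: discontinuity undefined")
    global_cont = float(np.nanmean(cont))
    global_disc = float(np.nanmean(disc))
    return cont, disc, global_cont, global_disc


def embed_2d(fps, seed: int = 42, perplexity: float | None = None) -> np.ndarray:
    """t-SNE embedding of a fingerprint matrix into 2D (deterministic per seed)."""
    X = fps.bits if isinstance(fps, FingerprintMatrix) else np.asarray(fps)
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 compounds to embed")
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    if perplexity >= n:
        raise ValueError("perplexity must be below the number of points")
    coords = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca",
    ).fit_transform(X)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return coords
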