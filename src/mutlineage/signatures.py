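"""Penalized attribution of 96-channel catalogues to reference signatures.

Per-sample activities are obtained by a sparse forward-backward selection:
starting from the single best-matching signature, candidates are admitted
only when they raise the reconstruction cosine by more than
``add_penalty`` and retained only while dropping them would cost more than
``remove_penalty``; within the selected support, activities solve the
non-negative least-squares problem.  The lowered penalty pair
(0.005/0.001) is the default for per-sample calls; the conservative pair
(0.05/0.01) is available as ``DEFAULT_PENALTIES``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "ReferenceSignatureSet",
    "SignatureActivity",
    "cosine_similarity",
    "nnls_refit",
    "decompose_signature",
    "activities_to_tsv",
    "LOWERED_PENALTIES",
    "DEFAULT_PENALTIES",
]

LOWERED_PENALTIES = (0.005, 0.001)
DEFAULT_PENALTIES = (0.05, 0.01)


@dataclass
class ReferenceSignatureSet:
    """Named 96-channel signature probability columns."""

    names: list[str]
    matrix: np.ndarray  # (96, k), columns sum to 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix must be channels x signatures matching names")
        if (self.matrix < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("every signature column must sum to 1")

    @property
    def k(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    @classmethod
    def from_tsv(cls, path: str | Path, channels: Sequence[str] | None = None) -> "ReferenceSignatureSet":
        """Read a COSMIC-format TSV: channel-label column + one column per signature."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if channels is not None:
            df = df.reindex(list(channels))
            if df.isna().any().any():
                raise ValueError(f"signature TSV {path} missing required channels")
        return cls(names=list(df.columns), matrix=df.to_numpy())

    def to_tsv(self, path: str | Path, channels: Sequence[str]) -> None:
        df = pd.DataFrame(self.matrix, index=list(channels), columns=self.names)
        df.index.name = "Type"
        df.to_csv(path, sep="\t")


@dataclass
class SignatureActivity:
    sample_id: str
    names: list[str]
    activities: np.ndarray  # (k,) non-negative mutation counts
    reconstruction: np.ndarray  # (96,)
    residual_cosine: float
    penalty_mode: str  # lowered | default | custom

    def nonzero(self) -> dict[str, float]:
        return {n: float(a) for n, a in zip(self.names, self.activities) if a > 0}


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


def _fit_support(catalog: np.ndarray, refs: ReferenceSignatureSet, support: list[int]) -> tuple[np.ndarray, float]:
    sub = refs.matrix[:, support]
    coef, _ = nnls(sub, catalog)
    recon = sub @ coef
    cos = cosine_similarity(catalog, recon) if recon.any() else 0.0
    return coef, cos


def _penalty_mode(add_penalty: float, remove_penalty: float) -> str:
    if (add_penalty, remove_penalty) == LOWERED_PENALTIES:
        return "lowered"
    if (add_penalty, remove_penalty) == DEFAULT_PENALTIES:
        return "default"
    return "custom"


def nnls_refit(
    catalog_vector: Sequence[float],
    refs: ReferenceSignatureSet,
    add_penalty: float = LOWERED_PENALTIES[0],
    remove_penalty: float = LOWERED_PENALTIES[1],
    sample_id: str = "",
) -> SignatureActivity:
    """Sparse penalized NNLS refit of one 96-channel catalogue."""
    if refs.k == 0:
        raise ValueError("reference signature set is empty")
    catalog = np.asarray(catalog_vector, dtype=float)
    if catalog.shape != (refs.matrix.shape[0],):
        raise ValueError(f"catalogue must have {refs.matrix.shape[0]} channels")
    if (catalog < 0).any():
        raise ValueError("catalogue counts must be non-negative")
    mode = _penalty_mode(add_penalty, remove_penalty)
    total = catalog.sum()
    if total == 0:
        k = refs.k
        return SignatureActivity(sample_id, list(refs.names), np.zeros(k), np.zeros_like(catalog), 1.0, mode)

    # forward seed: single best-cosine signature
    seed = int(np.argmax([cosine_similarity(catalog, refs.matrix[:, j]) for j in range(refs.k)]))
    support = [seed]
    _, cos = _fit_support(catalog, refs, support)

    improved = True
    while improved and len(support) < refs.k:
        improved = False
        best_gain, best_j, best_cos = 0.0, None, cos
        for j in range(refs.k):
            if j in support:
                continue
            _, trial_cos = _fit_support(catalog, refs, support + [j])
            if trial_cos - cos > best_gain:
                best_gain, best_j, best_cos = trial_cos - cos, j, trial_cos
        if best_j is not None and best_gain > add_penalty:
            support.append(best_j)
            cos = best_cos
            improved = True
            # backward pass: drop members whose removal barely hurts
            pruning = True
            while pruning and len(support) > 1:
                pruning = False
                for j in list(support):
                    reduced = [s for s in support if s != j]
                    _, red_cos = _fit_support(catalog, refs, reduced)
                    if cos - red_cos < remove_penalty:
                        support = reduced
                        cos = red_cos
                        pruning = True
                        break

    coef, cos = _fit_support(catalog, refs, support)
    activities = np.zeros(refs.k)
    activities[support] = coef
    if activities.sum() > total * (1 + 1e-6):
        activities *= total / activities.sum()
    recon = refs.matrix @ activities
    cos = cosine_similarity(catalog, recon) if recon.any() else 0.0
    return SignatureActivity(sample_id, list(refs.names), activities, recon, cos, mode)


def decompose_signature(
    denovo_vector: Sequence[float],
    refs: ReferenceSignatureSet,
) -> dict:
    """Decompose a de novo 96-channel signature into reference mixtures.

    Full-support NNLS of the probability vector over the reference set;
    the status reflects the reconstruction cosine: "decomposed" above 0.97,
    "novel" below 0.95, "ambiguous" in between.
    """
    if refs.k == 0:
        raise ValueError("reference signature set is empty")
    v = np.asarray(denovo_vector, dtype=float)
    if not np.isclose(v.sum(), 1.0, atol=1e-6):
        raise ValueError("de novo signature vector must sum to 1")
    coef, _ = nnls(refs.matrix, v)
    recon = refs.matrix @ coef
    cos = cosine_similarity(v, recon) if recon.any() else 0.0
    weights = coef / coef.sum() if coef.sum() > 0 else coef
    if cos > 0.97:
        status = "decomposed"
    elif cos < 0.95:
        status = "novel"
    else:
        status = "ambiguous"
    return {
        "weights": {n: float(w) for n, w in zip(refs.names, weights)},
        "cosine": cos,
        "status": status,
    }


def activities_to_tsv(activities: Sequence[SignatureActivity], path: str | Path) -> None:
    """Sample x signature activity table (mutation counts)."""
    if not activities:
        pd.DataFrame().to_csv(path, sep="\t")
        return
    names = activities[0].names
    df = pd.DataFrame(
        [act.activities for act in activities],
        index=[act.sample_id for act in activities],
        columns=names,
    )
    df.index.name = "sample"
    df.to_csv(path, sep="\t")
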