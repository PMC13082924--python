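"""Embedding-space lexicalization analysis: the Δ statistic.

A code is *lexicalized* when its embedding is semantically aligned with
its term's embedding (TP53 with "tumor protein p53"), and arbitrary when
it is not (HP:0001337 with "Tremor"). For pair i within one terminology
and mapping kind,

    Δ_i = cos(term_i, code_i) - mean_{j != i} cos(term_i, code_j)

so Δ ≈ 0 means the matching code is no closer to its term than any other
code, and Δ > 0 indicates alignment. Δ is invariant to uniform scaling of
the embeddings (cosines are scale-free).

Group differences between Δ distributions are tested with a one-way
ANOVA plus Tukey HSD all-pairs post hoc; embeddings can additionally be
projected to two principal components for cluster inspection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DegenerateInputError, ValidationError
from .io import TermCodePair


class EmbeddingProvider(Protocol):
    """Contract: deterministic map string -> fixed-dimension vector."""

    dim: int
    provenance: str

    def embed(self, text: str) -> np.ndarray: ...


@dataclass(frozen=True)
class DeltaScore:
    pair_id: str
    mapping_kind: str  # "term_id" | "term_symbol" | "symbol_id"
    delta: float


def _as_matrix(vectors: Sequence[np.ndarray], names: Sequence[str]) -> np.ndarray:
    mat = np.asarray(vectors, dtype=float)
    if mat.ndim != 2:
        raise ValidationError("vectors must share a single fixed dimension")
    norms = np.linalg.norm(mat, axis=1)
    bad = np.where(norms == 0)[0]
    if bad.size:
        raise DegenerateInputError(f"zero-norm embedding for {names[bad[0]]!r}")
    return mat


def cosine_matrix(
    left: Sequence[np.ndarray],
    right: Sequence[np.ndarray],
    left_names: Sequence[str] | None = None,
    right_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Pairwise cosine similarities; entry (i, j) = cos(left_i, right_j)."""
    left_names = left_names or [f"left[{i}]" for i in range(len(left))]
    right_names = right_names or [f"right[{j}]" for j in range(len(right))]
    L = _as_matrix(left, left_names)
    R = _as_matrix(right, right_names)
    if L.shape[1] != R.shape[1]:
        raise ValidationError(
            f"dimension mismatch: {L.shape[1]} vs {R.shape[1]}"
        )
    Ln = L / np.linalg.norm(L, axis=1, keepdims=True)
    Rn = R / np.linalg.norm(R, axis=1, keepdims=True)
    return np.clip(Ln @ Rn.T, -1.0, 1.0)


def delta_scores(
    pairs: Sequence[TermCodePair],
    provider: EmbeddingProvider,
    mapping_kind: str = "term_id",
) -> list[DeltaScore]:
    """Per-pair Δ within one terminology's term/code lists.

    The non-match pool for pair i is every other code of the same set
    (n - 1 codes), so at least two pairs are required.
    """
    if len(pairs) < 2:
        raise ValidationError("delta requires at least 2 pairs (a non-match pool)")
    terms = [p.term for p in pairs]
    codes = [p.code for p in pairs]
    C = cosine_matrix(
        [provider.embed(t) for t in terms],
        [provider.embed(c) for c in codes],
        left_names=terms,
        right_names=codes,
    )
    n = len(pairs)
    match = np.diag(C)
    nonmatch_mean = (C.sum(axis=1) - match) / (n - 1)
    return [
        DeltaScore(pair_id=p.pair_id, mapping_kind=mapping_kind, delta=float(d))
        for p, d in zip(pairs, match - nonmatch_mean)
    ]


@dataclass
class DeltaComparison:
    """One-way ANOVA over Δ groups plus Tukey HSD all-pairs table."""

    F: float
    p: float
    group_means: dict[str, float]
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, reject
    alpha: float

    def significant_pairs(self) -> list[tuple[str, str]]:
        hits = self.tukey[self.tukey["reject"]]
        return [tuple(sorted((a, b))) for a, b in zip(hits["group1"], hits["group2"])]


def compare_delta_distributions(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> DeltaComparison:
    """Test whether Δ distributions differ across mapping groups."""
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups to compare")
    arrays = {}
    for label, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise ValidationError(f"group {label!r} has fewer than 2 values")
        arrays[label] = arr
    if all(np.var(a) == 0 for a in arrays.values()):
        raise DegenerateInputError(
            "all groups have zero within-group variance; ANOVA is undefined"
        )
    F, p = stats.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[label] * len(a) for label, a in arrays.items()])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey_df = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    ).rename(columns={"p-adj": "p_adj"})
    tukey_df["reject"] = tukey_df["reject"].astype(bool)
    return DeltaComparison(
        F=float(F),
        p=float(p),
        group_means={label: float(a.mean()) for label, a in arrays.items()},
        tukey=tukey_df,
        alpha=alpha,
    )


def project_2d(
    vectors: Sequence[np.ndarray], labels: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Two leading principal components of the (centered) embeddings.

    Returns (coords, explained_variance_ratio). Deterministic: the sign
    of each component is fixed so its largest-magnitude loading is
    positive. Points that coincide in the input coincide in the output.
    """
    mat = np.asarray(vectors, dtype=float)
    if mat.shape[0] < 3:
        raise ValidationError("PCA projection requires at least 3 vectors")
    if np.allclose(mat, mat[0]):
        raise DegenerateInputError("rank-0 data: all vectors identical")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(mat)
    for k in range(2):
        loading = pca.components_[k]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, k] *= -1.0
    return coords, pca.explained_variance_ratio_


def write_embedding_cache(
    strings: Sequence[str], provider: EmbeddingProvider, path: str | Path
) -> None:
    """Portable JSONL embedding cache: one {string, vector} row per string."""
    with Path(path).open("w", encoding="utf-8") as handle:
        for s in strings:
            vec = provider.embed(s)
            handle.write(
                json.dumps({"string": s, "vector": [float(x) for x in vec]}) + "\n"
            )


class CachedEmbeddingProvider:
    """Provider backed by a JSONL cache written by write_embedding_cache."""

    def __init__(self, path: str | Path, provenance: str = "cache"):
        self._vectors: dict[str, np.ndarray] = {}
        with Path(path).open("r", encoding="utf-8") as handle:
            for line in handle:
                if line.strip():
                    row = json.loads(line)
                    self._vectors[row["string"]] = np.asarray(row["vector"], dtype=float)
        dims = {v.shape[0] for v in self._vectors.values()}
        if len(dims) > 1:
            raise ValidationError(f"cache mixes embedding dimensions {sorted(dims)}")
        self.dim = dims.pop() if dims else 0
        self.provenance = provenance

    def embed(self, text: str) -> np.ndarray:
        try:
            return self._vectors[text]
        except KeyError as exc:
            raise ValidationError(f"string not in embedding cache: {text!r}") from exc


__all__ = [
    "EmbeddingProvider",
    "DeltaScore",
    "DeltaComparison",
    "cosine_matrix",
    "delta_scores",
    "compare_delta_distributions",
    "project_2d",
    "write_embedding_cache",
    "CachedEmbeddingProvider",
]
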