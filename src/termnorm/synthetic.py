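"""Synthetic terminologies, responders, and embeddings with planted structure.

Real experiments need a terminology table (HPO/GO/HGNC with literature
counts), two model conditions (baseline and fine-tuned), and an embedding
extractor — none of which are downloadable in a test environment. This
module generates stand-ins whose governing parameters are planted and
therefore recoverable:

* **Terminology**: Zipf-distributed code counts (rank-frequency slope
  ``-zipf_exponent``), a configurable fraction of codes with zero corpus
  evidence (mirroring the 40–50% of ontology identifiers that never
  appear in the literature), arbitrary zero-padded identifiers or
  mnemonic initials-based symbols, and term/annotation counts coupled to
  the code count on the log scale.

* **Responder**: baseline correctness B_i ~ Bernoulli(p_i) with a
  logistic popularity link p_i = sigmoid(a + b*log10(count_i + 1)).
  After "fine-tuning", previously correct items stay correct with
  probability 1 - d; previously incorrect items become correct with
  probability m_i (seen) or g (unseen). The memorization probability
  carries its own logistic popularity link (slope ``mem_link_b``), so
  that more popular facts are easier to consolidate — the planted
  counterpart of the observed gainer-vs-continuing-incorrect popularity
  gap. Wrong answers are other codes/terms from the same table, so
  strict and lenient scoring are exercised realistically.

* **Embeddings**: unit term vectors t_i drawn isotropically; code vector
  c_i = normalize(lambda * t_i + sqrt(1 - lambda^2) * eps_i). lambda = 0
  plants no alignment (mean Δ ≈ 0); lambda = 1 plants perfect alignment.
  Arbitrary-identifier codes additionally share a cluster offset so they
  separate from terms in a 2-D projection, as opaque identifier strings
  do in real embedding spaces.

Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .io import CodeType, TermCodePair, TerminologyTable
from .prompting import EvaluationInstance
from .sampling import SampledSplit

_ADJECTIVES = (
    "distal", "proximal", "chronic", "acute", "focal", "diffuse", "nodular",
    "cystic", "fibrous", "atrophic", "hyperplastic", "dysplastic", "ectopic",
    "congenital", "progressive", "recurrent", "bilateral", "unilateral",
    "segmental", "generalized",
)
_SITES = (
    "cortical", "renal", "hepatic", "cardiac", "femoral", "tibial", "retinal",
    "corneal", "dermal", "neural", "vascular", "bronchial", "gastric",
    "splenic", "thymic",
)
_NOUNS = (
    "atrophy", "hypoplasia", "stenosis", "dysplasia", "fibrosis", "sclerosis",
    "edema", "necrosis", "hypertrophy", "degeneration", "malformation",
    "duplication", "fusion", "agenesis", "cyst", "lesion", "deformity",
    "overgrowth", "thinning", "calcification",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Planted parameters of the synthetic world.

    Defaults state the standard experimental conditions: 5,000-pair
    terminology (enough for a 20x30 two-split design), unit Zipf
    exponent, 40% zero-evidence codes, baseline logistic link
    (a, b) = (-1.5, 0.8) on log10 popularity, planted memorization /
    generalization / degradation rates (0.4, 0.1, 0.05), and a
    memorization popularity link with the same slope as the baseline
    link (one popularity mechanism governs both).
    """

    n_pairs: int = 5000
    zipf_exponent: float = 1.0
    code_scheme: CodeType = CodeType.ARBITRARY_ID
    id_prefix: str = "SYN"
    terminology: str = "SYN"
    namespace: Optional[str] = None
    head_count: int = 100_000
    zero_count_fraction: float = 0.4
    count_coupling: float = 0.7
    baseline_link: tuple[float, float] = (-1.5, 0.8)
    m: float = 0.4
    g: float = 0.1
    d: float = 0.05
    mem_link_b: float = 0.8
    reverse_p_base_factor: float = 1.0
    lambda_align: float = 0.0
    id_cluster_offset: bool = True
    dim: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 40:
            raise ValidationError("n_pairs must be >= 40 (supports >= 20 bins x 2)")
        if self.zipf_exponent <= 0:
            raise ValidationError("zipf_exponent must be > 0")
        for name in ("m", "g", "d", "zero_count_fraction", "lambda_align"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if self.dim < 3:
            raise ValidationError("embedding dim must be >= 3")
        object.__setattr__(self, "code_scheme", CodeType(self.code_scheme))


def _child_rng(seed: int, tag: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


def _symbol_for(term: str, taken: set[str]) -> str:
    base = "".join(word[0] for word in term.split()).upper()
    symbol = base
    k = 2
    while symbol in taken:
        symbol = f"{base}{k}"
        k += 1
    return symbol


def generate_terminology(config: SyntheticConfig) -> TerminologyTable:
    """Generate a long-tailed synthetic terminology table."""
    rng = _child_rng(config.seed, "terminology")
    n = config.n_pairs

    combos = list(itertools.product(_ADJECTIVES, _SITES, _NOUNS))
    order = rng.permutation(len(combos))
    terms = []
    for idx in order[: min(n, len(combos))]:
        adj, site, noun = combos[idx]
        terms.append(f"{adj} {site} {noun}")
    serial = 2
    while len(terms) < n:  # beyond the combinatorial space: numbered variants
        adj, site, noun = combos[order[(len(terms)) % len(combos)]]
        terms.append(f"{adj} {site} {noun} type {serial}")
        serial += 1

    ranks = np.arange(1, n + 1, dtype=float)
    counts = np.rint(config.head_count * ranks ** (-config.zipf_exponent)).astype(int)
    counts = np.maximum(counts, 1)
    n_zero = int(round(config.zero_count_fraction * n))
    if n_zero:
        counts[n - n_zero :] = 0  # the deepest tail carries no corpus evidence

    z = np.log10(counts + 1.0)
    noise_t = rng.normal(0.0, 0.5, size=n)
    noise_a = rng.normal(0.0, 0.5, size=n)
    term_counts = np.rint(10 ** (0.8 + config.count_coupling * z + noise_t) - 1.0)
    annot_counts = np.rint(10 ** (config.count_coupling * z + noise_a) - 1.0)
    term_counts = np.clip(term_counts, 0, None).astype(int)
    annot_counts = np.clip(annot_counts, 0, None).astype(int)

    rows = []
    taken_symbols: set[str] = set()
    for i in range(n):
        if config.code_scheme is CodeType.ARBITRARY_ID:
            code = f"{config.id_prefix}:{i + 1:07d}"
        else:
            code = _symbol_for(terms[i], taken_symbols)
            taken_symbols.add(code)
        rows.append(
            TermCodePair(
                term=terms[i],
                code=code,
                code_type=config.code_scheme,
                terminology=config.terminology,
                namespace=config.namespace,
                code_count=int(counts[i]),
                term_count=int(term_counts[i]),
                annotation_count=int(annot_counts[i]),
            )
        )
    return TerminologyTable(rows=rows, source_label=f"synthetic(seed={config.seed})")


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    return float(np.log(p / (1.0 - p)))


@dataclass
class SyntheticResponder:
    """Planted-rate responder for baseline and fine-tuned conditions.

    Correctness bits are drawn once per (pair, direction) and shared
    across templates and conditions, so repeated queries are consistent
    the way greedy decoding is.
    """

    config: SyntheticConfig
    table: TerminologyTable
    split: SampledSplit
    _B: dict[tuple[str, str], int] = field(default_factory=dict, repr=False)
    _F: dict[tuple[str, str], int] = field(default_factory=dict, repr=False)
    _p_base: dict[str, float] = field(default_factory=dict, repr=False)
    _m_prob: dict[str, float] = field(default_factory=dict, repr=False)
    _wrong_index: dict[tuple[str, str], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        cfg = self.config
        rng = _child_rng(cfg.seed, "responder")
        rows = self.table.rows
        z = np.log10(np.array([r.code_count for r in rows], dtype=float) + 1.0)
        a, b = cfg.baseline_link
        p_fwd = _sigmoid(a + b * z)
        p_rev = np.clip(p_fwd * cfg.reverse_p_base_factor, 0.0, 1.0)
        # memorization probability with its own popularity link, centered
        # on the table's mean log-popularity so m is the typical rate
        m_logit = _logit(cfg.m) + cfg.mem_link_b * (z - z.mean())
        m_prob = np.asarray(_sigmoid(m_logit)) if cfg.mem_link_b != 0 else np.full_like(z, cfg.m)
        seen = set(self.split.train)
        for i, row in enumerate(rows):
            self._p_base[row.pair_id] = float(p_fwd[i])
            self._m_prob[row.pair_id] = float(m_prob[i])
            is_seen = row.pair_id in seen
            for direction, p in (("forward", p_fwd[i]), ("reverse", p_rev[i])):
                B = int(rng.random() < p)
                if B:
                    F = int(rng.random() >= cfg.d)
                else:
                    rate = m_prob[i] if is_seen else cfg.g
                    F = int(rng.random() < rate)
                self._B[(row.pair_id, direction)] = B
                self._F[(row.pair_id, direction)] = F
                # distractor: a different pair's code/term, fixed per key
                j = int(rng.integers(0, len(rows) - 1))
                self._wrong_index[(row.pair_id, direction)] = j if j < i else j + 1

    def _answer(self, instance: EvaluationInstance, bit: int) -> str:
        if instance.pair_id not in self.table:
            raise ValidationError(f"unknown pair {instance.pair_id!r}")
        if bit:
            return instance.gold_answer
        wrong = self.table.rows[self._wrong_index[(instance.pair_id, instance.direction)]]
        return wrong.code if instance.direction == "forward" else wrong.term

    def baseline(self, instance: EvaluationInstance) -> str:
        return self._answer(instance, self._B[(instance.pair_id, instance.direction)])

    def finetuned(self, instance: EvaluationInstance) -> str:
        return self._answer(instance, self._F[(instance.pair_id, instance.direction)])

    def expected_metrics(self, direction: str = "forward") -> dict[str, float]:
        """Analytic expectations of the derived metrics, in percent.

        Computed from the planted per-pair probabilities (not the realized
        bits): memorization = mean over seen of (1-p_i) m_i, generalization
        = mean over unseen of (1-p_i) g, degradation = mean over unseen of
        p_i d.
        """
        factor = 1.0 if direction == "forward" else self.config.reverse_p_base_factor
        p_seen = np.array([min(self._p_base[pid] * factor, 1.0) for pid in self.split.train])
        p_unseen = np.array(
            [min(self._p_base[pid] * factor, 1.0) for pid in self.split.withheld]
        )
        m_seen = np.array([self._m_prob[pid] for pid in self.split.train])
        return {
            "memorization_pct": 100.0 * float(((1.0 - p_seen) * m_seen).mean()),
            "generalization_pct": 100.0 * float(((1.0 - p_unseen) * self.config.g).mean()),
            "degraded_pct": 100.0 * float((p_unseen * self.config.d).mean()),
            "seen_loser_pct": 100.0 * float((p_seen * self.config.d).mean()),
        }


def make_responder(
    config: SyntheticConfig, table: TerminologyTable, split: SampledSplit
) -> SyntheticResponder:
    unknown = [pid for pid in (*split.train, *split.withheld) if pid not in table]
    if unknown:
        raise ValidationError(f"split references pairs absent from the table: {unknown[:5]}")
    return SyntheticResponder(config=config, table=table, split=split)


class SyntheticEmbeddingProvider:
    """Deterministic embeddings with planted term–code alignment lambda."""

    def __init__(self, config: SyntheticConfig, table: TerminologyTable):
        self.dim = config.dim
        self.provenance = f"synthetic(lambda={config.lambda_align}, seed={config.seed})"
        self._seed = config.seed
        rng = _child_rng(config.seed, "embeddings")
        lam = config.lambda_align
        offset = rng.normal(size=config.dim)
        offset /= np.linalg.norm(offset)
        self._vectors: dict[str, np.ndarray] = {}
        for row in table.rows:
            t = rng.normal(size=config.dim)
            t /= np.linalg.norm(t)
            eps = rng.normal(size=config.dim)
            eps /= np.linalg.norm(eps)
            c = lam * t + np.sqrt(max(0.0, 1.0 - lam**2)) * eps
            c /= np.linalg.norm(c)
            if config.id_cluster_offset and row.code_type is CodeType.ARBITRARY_ID:
                c = c + 1.5 * offset
                c /= np.linalg.norm(c)
            self._vectors.setdefault(row.term, t)
            self._vectors.setdefault(row.code, c)

    def embed(self, text: str) -> np.ndarray:
        vec = self._vectors.get(text)
        if vec is not None:
            return vec
        # unknown strings get a stable hash-seeded direction
        rng = _child_rng(self._seed, f"string:{text}")
        v = rng.normal(size=self.dim)
        return v / np.linalg.norm(v)


def make_embedding_provider(
    config: SyntheticConfig, table: TerminologyTable
) -> SyntheticEmbeddingProvider:
    return SyntheticEmbeddingProvider(config, table)


__all__ = [
    "SyntheticConfig",
    "SyntheticResponder",
    "SyntheticEmbeddingProvider",
    "generate_terminology",
    "make_responder",
    "make_embedding_provider",
]
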