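"""16S amplicon pipeline: merge, filter, naive-Bayes classification with
bootstrap confidence, rank escalation, abundance tables and PCA.

The classifier follows the word-based naive Bayes design standard for 16S
reads: 8-mer conditional probabilities per genus with a frequency-based
pseudocount, bootstrap resampling of one eighth of the query's distinct
words, and per-rank confidence obtained by summing genus confidences over
the taxonomy.  A read is accepted at the most specific rank whose
confidence reaches the 0.5 threshold; reads escalated above genus are
displayed as "FamilyName_genus-like" so both the accepted rank and the
best genus candidate stay visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqs import revcomp
from .taxonomy import RANKS, TaxonomyTree


class AmpliconError(ValueError):
    pass


@dataclass
class AmpliconRead:
    id: str
    bases: str
    quals: np.ndarray

    def __post_init__(self):
        self.quals = np.asarray(self.quals, dtype=int)
        if len(self.bases) != self.quals.size:
            raise AmpliconError(f"read {self.id}: quality/base length mismatch")
        if self.quals.size and (self.quals.min() < 0 or self.quals.max() > 60):
            raise AmpliconError(f"read {self.id}: Phred out of [0, 60]")

    def expected_error(self) -> float:
        return float(np.sum(10.0 ** (-self.quals / 10.0)))


# ---------------------------------------------------------------------------
# merging and filtering

def merge_pairs(fwd: AmpliconRead, rev: AmpliconRead, min_overlap: int = 50,
                min_overlap_identity: float = 0.75) -> AmpliconRead | None:
    """Merge a pair by the best ungapped overlap; ``None`` on rejection.

    The reverse read is reverse-complemented, the overlap maximizing
    (matches - mismatches) over all lengths >= ``min_overlap`` is taken,
    and disagreeing bases are resolved to the higher-quality call.
    Merged quality is the pairwise maximum at agreeing positions.
    """
    if not fwd.bases or not rev.bases:
        raise AmpliconError("empty read")
    a = np.frombuffer(fwd.bases.encode(), dtype="S1")
    b = np.frombuffer(revcomp(rev.bases).encode(), dtype="S1")
    bq = rev.quals[::-1]
    best = None
    for L in range(min(a.size, b.size), min_overlap - 1, -1):
        eq = a[-L:] == b[:L]
        score = int(2 * eq.sum() - L)
        if best is None or score > best[0]:
            best = (score, L, eq)
    if best is None:
        return None
    score, L, eq = best
    if eq.mean() < min_overlap_identity:
        return None

    ov_a, ov_b = a[-L:].copy(), b[:L]
    qa, qb = fwd.quals[-L:].copy(), bq[:L]
    take_b = (~eq) & (qb > qa)
    ov = np.where(take_b, ov_b, ov_a)
    ovq = np.where(eq, np.maximum(qa, qb), np.where(take_b, qb, qa))
    bases = a[:-L].tobytes().decode() + ov.tobytes().decode() + b[L:].tobytes().decode()
    quals = np.concatenate([fwd.quals[:-L], ovq, bq[L:]])
    return AmpliconRead(fwd.id.removesuffix("/1"), bases, quals)


def filter_sequences(seqs: list[AmpliconRead], min_length: int = 300,
                     max_expected_error: float = 0.5, min_q: float = 30.0):
    """Keep reads with length >= 300, expected error <= 0.5 and mean Q > 30.

    Returns (retained, rejection log); the log lists every rule that
    fired for each rejected read.
    """
    kept: list[AmpliconRead] = []
    log: list[tuple[str, str]] = []
    for r in seqs:
        if r.quals.size == 0:
            raise AmpliconError(f"read {r.id}: missing qualities")
        reasons = []
        if len(r.bases) < min_length:
            reasons.append("length")
        if r.expected_error() > max_expected_error:
            reasons.append("expected_error")
        if r.quals.mean() <= min_q:
            reasons.append("mean_quality")
        if reasons:
            log.append((r.id, "+".join(reasons)))
        else:
            kept.append(r)
    return kept, log


# ---------------------------------------------------------------------------
# naive-Bayes word model

def _distinct_words(seq: str, k: int) -> list[str]:
    return sorted({seq[i : i + k] for i in range(len(seq) - k + 1)
                   if "N" not in seq[i : i + k]})


@dataclass
class WordModel:
    word_size: int
    genera: list[str]
    genus_sizes: np.ndarray           # M per genus
    word_counts: dict[str, np.ndarray]  # word -> per-genus sequence counts
    n_total: int
    tree: TaxonomyTree

    def log_probs(self, words: list[str]) -> np.ndarray:
        """(W, G) matrix of log P(word | genus)."""
        G = len(self.genera)
        out = np.empty((len(words), G))
        M = self.genus_sizes
        for wi, w in enumerate(words):
            m = self.word_counts.get(w)
            n_w = float(m.sum()) if m is not None else 0.0
            prior = (n_w + 0.5) / (self.n_total + 1.0)
            counts = m if m is not None else 0.0
            out[wi] = np.log((counts + prior) / (M + 1.0))
        return out


def train_word_model(reference: list[tuple[str, str]], tree: TaxonomyTree,
                     word_size: int = 8) -> WordModel:
    """Train the per-genus word model from labeled reference sequences.

    ``reference`` is a list of (genus, sequence).  P(word|genus) =
    (m + prior) / (M + 1) where m counts reference sequences of the genus
    containing the word, M is the genus size, and the prior is the
    pseudocounted overall frequency of the word.
    """
    known = set(tree.genera())
    genera = sorted({g for g, _ in reference})
    for g in genera:
        if g not in known:
            raise AmpliconError(f"reference genus {g!r} absent from taxonomy")
    gi = {g: i for i, g in enumerate(genera)}
    sizes = np.zeros(len(genera))
    word_counts: dict[str, np.ndarray] = {}
    for genus, seq in reference:
        sizes[gi[genus]] += 1
        for w in _distinct_words(seq, word_size):
            if w not in word_counts:
                word_counts[w] = np.zeros(len(genera))
            word_counts[w][gi[genus]] += 1
    return WordModel(word_size, genera, sizes, word_counts, len(reference), tree)


def classify_with_bootstrap(model: WordModel, seq: str, n_bootstrap: int = 100,
                            seed: int = 0) -> dict[str, dict[str, float]]:
    """Bootstrap genus confidences aggregated to every rank.

    Each replicate draws floor(W/8) of the W distinct words with
    replacement and votes for the maximum-likelihood genus (ties broken
    lexicographically).  Rank-r confidence of a taxon is the summed
    confidence of its member genera, so ancestor confidence is always >=
    any descendant's.
    """
    words = _distinct_words(seq, model.word_size)
    if not words:
        raise AmpliconError("sequence shorter than the word size")
    L = model.log_probs(words)  # (W, G)
    rng = np.random.default_rng(seed)
    n_draw = max(1, len(words) // 8)
    idx = rng.integers(0, len(words), size=(n_bootstrap, n_draw))
    scores = L[idx].sum(axis=1)          # (n_bootstrap, G)
    votes = np.argmax(scores, axis=1)    # first max = lexicographic tie-break
    conf = np.bincount(votes, minlength=len(model.genera)) / n_bootstrap

    out: dict[str, dict[str, float]] = {"genus": {}}
    for g, c in zip(model.genera, conf):
        if c > 0:
            out["genus"][g] = float(c)
    for rank in RANKS[1:-1]:  # phylum .. family
        agg: dict[str, float] = {}
        for g, c in out["genus"].items():
            name = model.tree.ancestor_at(g, rank)
            agg[name] = agg.get(name, 0.0) + c
        out[rank] = agg
    return out


@dataclass
class TaxonAssignment:
    id: str
    per_rank: dict[str, tuple[str, float]]  # rank -> (best name, confidence)
    accepted_rank: str | None
    display_name: str


def escalate_assignment(confidences: dict[str, dict[str, float]],
                        threshold: float = 0.5,
                        read_id: str = "") -> TaxonAssignment:
    """Accept the most specific rank whose confidence reaches ``threshold``.

    Escalated reads are displayed as "<AcceptedName>_<genus>-like" so the
    best genus candidate stays recorded; total failures are
    "unclassified".
    """
    per_rank: dict[str, tuple[str, float]] = {}
    for rank in reversed(RANKS[1:]):  # genus .. phylum order for display
        d = confidences.get(rank, {})
        if d:
            name = max(sorted(d), key=lambda n: d[n])
            per_rank[rank] = (name, d[name])
    top_genus = per_rank.get("genus", ("unknown", 0.0))[0]
    for rank in reversed(RANKS[1:]):  # most specific first
        name, conf = per_rank.get(rank, ("", 0.0))
        if conf >= threshold:
            if rank == "genus":
                return TaxonAssignment(read_id, per_rank, "genus", name)
            return TaxonAssignment(
                read_id, per_rank, rank, f"{name}_{top_genus.lower()}-like"
            )
    return TaxonAssignment(read_id, per_rank, None, "unclassified")


# ---------------------------------------------------------------------------
# abundance tables and ordination

def build_abundance_table(assignments: dict[str, list[TaxonAssignment]]):
    """Per-sample relative abundances of display taxa.

    Taxa are the display names (escalated reads form their own taxa).
    Returns (raw, filtered) DataFrames, samples x taxa; the filtered
    table drops taxa nonzero in exactly one sample *after* computing
    relative abundance and does not rescale the remaining columns.
    """
    if len(assignments) < 2:
        raise AmpliconError("abundance tables need at least two samples")
    counts = {
        sample: pd.Series([a.display_name for a in asgns]).value_counts()
        for sample, asgns in assignments.items()
    }
    raw = pd.DataFrame(counts).T.fillna(0.0).sort_index(axis=1)
    raw = raw.div(raw.sum(axis=1), axis=0)
    present_in = (raw > 0).sum(axis=0)
    filtered = raw.loc[:, present_in >= 2]
    return raw, filtered


def total_abundance(table: pd.DataFrame, taxa: list[str]) -> pd.Series:
    """Summed relative abundance of the selected taxa, per sample."""
    missing = [t for t in taxa if t not in table.columns]
    if missing:
        raise AmpliconError(f"taxa absent from table: {missing}")
    return table[list(taxa)].sum(axis=1)


def pca(table: pd.DataFrame, n_components: int = 2):
    """Covariance PCA of a samples x taxa relative-abundance table.

    Returns (coordinates DataFrame, explained-variance fractions).  Sign
    convention: the largest-magnitude loading of each component is
    positive.  A constant table yields all-zero coordinates with a
    warning.
    """
    from sklearn.decomposition import PCA

    if table.shape[0] < 2 or table.shape[1] < 2:
        raise AmpliconError("PCA needs at least 2 samples and 2 taxa")
    X = table.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    k = min(n_components, X.shape[0], X.shape[1])
    if not np.any(np.abs(Xc) > 1e-12):
        warnings.warn("constant abundance table: zero variance")
        coords = pd.DataFrame(np.zeros((X.shape[0], k)), index=table.index,
                              columns=[f"PC{i+1}" for i in range(k)])
        return coords, np.zeros(k)
    model = PCA(n_components=k)
    Y = model.fit_transform(X)
    comps = model.components_
    for i in range(k):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1
            Y[:, i] *= -1
    coords = pd.DataFrame(Y, index=table.index,
                          columns=[f"PC{i+1}" for i in range(k)])
    return coords, model.explained_variance_ratio_
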