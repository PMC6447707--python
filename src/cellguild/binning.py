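"""Composition-signature binning of contigs with marker/function overlay.

Contigs >= 1000 bp are represented by canonical (strand-pooled) 5-mer
frequency vectors, reduced to 50 linear dimensions and embedded in 2D
with Barnes-Hut t-SNE (perplexity 30, theta 0.5, fixed seed), then
grouped by density clustering.  Single-copy marker genes vote a genus
onto each bin and cellulolytic function genes flag candidate helpers
(endoglucanase plus downstream enzymes) and beneficiaries (downstream
enzymes only).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .references import DOWNSTREAM_FEATURES, EC_TO_FEATURE
from .seqs import DNA


class BinningError(ValueError):
    pass


# ---------------------------------------------------------------------------
# canonical k-mer signatures

def _canonical_index(k: int) -> tuple[np.ndarray, int]:
    """Map each of the 4^k k-mer codes to a canonical vector index."""
    comp = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT encoding
    codes = np.arange(4 ** k)
    digits = np.stack([(codes // 4 ** i) % 4 for i in range(k - 1, -1, -1)], axis=1)
    rc_digits = comp[digits][:, ::-1]
    rc_codes = (rc_digits * (4 ** np.arange(k - 1, -1, -1))).sum(axis=1)
    canon = np.minimum(codes, rc_codes)
    uniq = np.unique(canon)
    remap = np.zeros(4 ** k, dtype=np.int64)
    remap[uniq] = np.arange(uniq.size)
    return remap[canon], uniq.size


_CANON_CACHE: dict[int, tuple[np.ndarray, int]] = {}


def n_canonical(k: int = 5) -> int:
    if k not in _CANON_CACHE:
        _CANON_CACHE[k] = _canonical_index(k)
    return _CANON_CACHE[k][1]


def kmer_signature(sequence: str, k: int = 5, min_length: int = 1000) -> np.ndarray:
    """Canonical k-mer frequency vector (sums to 1) of one contig."""
    if len(sequence) < min_length:
        raise BinningError(f"contig shorter than {min_length} bp")
    if k not in _CANON_CACHE:
        _CANON_CACHE[k] = _canonical_index(k)
    canon, dim = _CANON_CACHE[k]
    base = np.full(len(sequence), -1, dtype=np.int64)
    for i, b in enumerate(DNA):
        base[np.frombuffer(sequence.encode(), dtype="S1") == b.encode()] = i
    win = np.lib.stride_tricks.sliding_window_view(base, k)
    valid = (win >= 0).all(axis=1)
    codes = (win * (4 ** np.arange(k - 1, -1, -1))).sum(axis=1)[valid]
    counts = np.bincount(canon[codes], minlength=dim).astype(float)
    total = counts.sum()
    if total == 0:
        raise BinningError("no valid k-mer windows")
    return counts / total


def signatures_for(contigs: list, k: int = 5, min_length: int = 1000) -> pd.DataFrame:
    """Signatures of all contigs >= ``min_length``; shorter ones are skipped."""
    rows, index, skipped = [], [], 0
    for c in contigs:
        if len(c.sequence) < min_length:
            skipped += 1
            continue
        rows.append(kmer_signature(c.sequence, k, min_length))
        index.append(c.id)
    if skipped:
        warnings.warn(f"skipped {skipped} contigs shorter than {min_length} bp")
    return pd.DataFrame(rows, index=index)


# ---------------------------------------------------------------------------
# embedding and clustering

def embed(signatures: pd.DataFrame, intermediate_dims: int = 50,
          perplexity: float = 30.0, theta: float = 0.5,
          seed: int = 0) -> pd.DataFrame:
    """2D neighbor-preserving embedding of signature vectors.

    Linear reduction to ``intermediate_dims`` followed by Barnes-Hut
    t-SNE (``theta`` is the accuracy/speed angle).  Rows are processed in
    sorted-contig-id order, so the embedding is invariant to input order
    at a fixed seed.  Perplexity is auto-reduced with a warning when
    fewer than 3x perplexity points are given.
    """
    from sklearn.decomposition import PCA
    from sklearn.manifold import TSNE

    n = signatures.shape[0]
    if n < 5:
        raise BinningError("embedding needs at least 5 contigs")
    sig = signatures.sort_index()
    if n < 3 * perplexity:
        perplexity = max(2.0, (n - 1) / 3.0)
        warnings.warn(f"perplexity reduced to {perplexity:.1f} for {n} points")
    k = int(min(intermediate_dims, n - 1, sig.shape[1]))
    X = PCA(n_components=k, random_state=seed).fit_transform(sig.to_numpy())
    ts = TSNE(n_components=2, perplexity=perplexity, angle=theta,
              method="barnes_hut", init="pca", random_state=seed)
    Y = ts.fit_transform(X)
    return pd.DataFrame(Y, index=sig.index, columns=["x", "y"])


@dataclass
class Bin:
    id: str
    members: list[str]
    genus_votes: Counter = field(default_factory=Counter)
    function_flags: set[str] = field(default_factory=set)
    candidate: str | None = None  # helper-candidate | beneficiary-candidate


def knn_eps(coords: pd.DataFrame, n_neighbors: int = 5,
            quantile: float = 0.95) -> float:
    """Density radius from the 95th percentile of 5-nearest-neighbor distances.

    Appropriate when points are spread evenly; with sheared-contig input
    many fragments are near-duplicates, the embedding collapses them
    into clumps, and this scale reflects duplicate spacing rather than
    cluster separation (see :func:`default_eps`).
    """
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(coords.to_numpy())
    d, _ = nn.kneighbors(coords.to_numpy())
    return float(np.quantile(d[:, -1], quantile))


def default_eps(coords: pd.DataFrame, diagonal_fraction: float = 0.05) -> float:
    """Density radius: 5% of the embedding bounding-box diagonal.

    Scale-aware in the embedded coordinates, so it bridges the gaps
    between clumps of near-duplicate fragments within one genome region
    while staying far below typical between-genome separations.
    """
    X = coords.to_numpy()
    return float(diagonal_fraction * np.linalg.norm(X.max(axis=0) - X.min(axis=0)))


def cluster_embedding(coords: pd.DataFrame, eps: float | None = None,
                      min_samples: int = 10) -> tuple[list[Bin], list[str]]:
    """Density-based bins plus a noise set."""
    from sklearn.cluster import DBSCAN

    if coords.shape[0] == 0:
        raise BinningError("empty embedding")
    if coords.shape[0] < min_samples:
        return [], list(coords.index)
    X = coords.to_numpy()
    if eps is None:
        rng_span = X.max(axis=0) - X.min(axis=0)
        if np.allclose(rng_span, 0):
            warnings.warn("degenerate all-coincident embedding: single bin")
            return [Bin("bin000", list(coords.index))], []
        eps = default_eps(coords)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(X)
    bins = []
    for lab in sorted(set(labels) - {-1}):
        members = list(coords.index[labels == lab])
        bins.append(Bin(f"bin{lab:03d}", members))
    noise = list(coords.index[labels == -1])
    return bins, noise


# ---------------------------------------------------------------------------
# overlay and quality

def overlay_annotations(bins: list[Bin], annotations: pd.DataFrame,
                        known_contigs: set[str] | None = None) -> list[Bin]:
    """Attach marker-gene genus votes and function flags to bins.

    ``annotations`` is the per-gene table from the annotation stage.
    Bins carrying both endoglucanase and downstream-enzyme contigs are
    marked helper-candidate; downstream-only bins beneficiary-candidate.
    """
    if known_contigs is None:
        known_contigs = {c for b in bins for c in b.members}
    marker_votes: dict[str, Counter] = {}
    func: dict[str, set[str]] = {}
    for _, row in annotations.iterrows():
        contig = row["contig"]
        if contig not in known_contigs:
            warnings.warn(f"annotation on unknown contig {contig}: skipped")
            continue
        if row.get("marker_gene") and row["genus"] != "unassigned":
            marker_votes.setdefault(contig, Counter())[row["genus"]] += 1
        for ec in str(row.get("ec_labels") or "").split(","):
            feat = EC_TO_FEATURE.get(ec)
            if feat:
                func.setdefault(contig, set()).add(feat)
    for b in bins:
        b.genus_votes = Counter()
        b.function_flags = set()
        for c in b.members:
            b.genus_votes.update(marker_votes.get(c, {}))
            b.function_flags |= func.get(c, set())
        down = b.function_flags & set(DOWNSTREAM_FEATURES)
        if "endoglucanase" in b.function_flags and down:
            b.candidate = "helper-candidate"
        elif down:
            b.candidate = "beneficiary-candidate"
        else:
            b.candidate = None
    return bins


def bin_quality(bins: list[Bin], truth: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin purity and per-genome completeness against simulator truth.

    Purity is the largest within-bin genus fraction; completeness is the
    fraction of a genome's (embedded) contigs captured by its best bin.
    """
    genus_of = dict(zip(truth["contig"], truth["genus"]))
    rows = []
    capture: dict[str, Counter] = {}
    for b in bins:
        genera = Counter(genus_of[c] for c in b.members if c in genus_of)
        if not genera:
            continue
        top_genus, top_n = genera.most_common(1)[0]
        rows.append({"bin": b.id, "n": len(b.members),
                     "purity": top_n / sum(genera.values()),
                     "top_genus": top_genus})
        for genus, cnt in genera.items():
            capture.setdefault(genus, Counter())[b.id] += cnt
    purity = pd.DataFrame(rows, columns=["bin", "n", "purity", "top_genus"])
    totals = Counter(truth["genus"])
    comp_rows = []
    for genus, total in sorted(totals.items()):
        best = capture.get(genus, Counter()).most_common(1)
        comp_rows.append({
            "genus": genus,
            "n_contigs": total,
            "completeness": (best[0][1] / total) if best else 0.0,
            "best_bin": best[0][0] if best else "",
        })
    completeness = pd.DataFrame(comp_rows)
    return purity, completeness
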