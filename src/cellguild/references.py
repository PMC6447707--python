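"""Packaged toy reference sets shared by the simulator and the annotator.

Real pipelines for this problem lean on large external databases (CAZy
domain HMMs, transporter classification, bacterial protein references).
This package ships a self-contained miniature counterpart instead: for
each glycoside-hydrolase (GH) / carbohydrate-binding-module (CBM) family
and each functional marker (the cellulolytic enzymes and the two
characterized cellodextrin transporter systems) it carries a curated toy
base protein, per-genus reference variants, and a position-specific
scoring profile with a shuffle-null calibrated score threshold.  All
sequences are built deterministically from a fixed internal seed, so the
simulator that plants mutated copies of them into synthetic genomes and
the annotator that searches for them always agree on the reference set.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .seqs import AA20, mutate_dna, mutate_protein, random_dna, random_protein, revcomp

# ---------------------------------------------------------------------------
# label vocabularies

#: Gene-content features used for helper/beneficiary classification.
ROLE_FEATURES = (
    "endoglucanase",
    "beta_glucosidase",
    "six_phospho_beta_glucosidase",
    "cellobiose_phosphorylase",
    "pts_cel",
    "abc_ceb",
)

#: The "downstream" (intracellular assimilation) enzyme features.
DOWNSTREAM_FEATURES = (
    "beta_glucosidase",
    "six_phospho_beta_glucosidase",
    "cellobiose_phosphorylase",
)

ENZYME_MARKERS = (
    "endoglucanase",
    "beta_glucosidase",
    "six_phospho_beta_glucosidase",
    "cellobiose_phosphorylase",
)
TRANSPORTER_MARKERS = (
    "PTS_CelA",
    "PTS_CelB",
    "PTS_CelC",
    "ABC_CebE",
    "ABC_CebF",
    "ABC_CebG",
    "ABC_MsiK",
)
MARKER_LABELS = ENZYME_MARKERS + TRANSPORTER_MARKERS

#: Universal single-copy marker genes used to vote taxonomy onto bins.
SCM_LABELS = tuple(f"SCM{i:02d}" for i in range(1, 11))

#: RoleFeature -> marker genes planted in a genome carrying that feature.
FEATURE_TO_MARKERS = {
    "endoglucanase": ("endoglucanase",),
    "beta_glucosidase": ("beta_glucosidase",),
    "six_phospho_beta_glucosidase": ("six_phospho_beta_glucosidase",),
    "cellobiose_phosphorylase": ("cellobiose_phosphorylase",),
    "pts_cel": ("PTS_CelA", "PTS_CelB"),
    "abc_ceb": ("ABC_CebE", "ABC_MsiK"),
}

MARKER_TO_FEATURE = {
    **{m: m for m in ENZYME_MARKERS},
    **{m: "pts_cel" for m in TRANSPORTER_MARKERS if m.startswith("PTS_")},
    **{m: "abc_ceb" for m in TRANSPORTER_MARKERS if m.startswith("ABC_")},
}

EC_LABELS = {
    "endoglucanase": "EC:3.2.1.4",
    "beta_glucosidase": "EC:3.2.1.21",
    "six_phospho_beta_glucosidase": "EC:3.2.1.86",
    # no EC number asserted for cellobiose phosphorylase; kept as its own label
    "cellobiose_phosphorylase": "cellobiose_phosphorylase",
}
EC_TO_FEATURE = {v: k for k, v in EC_LABELS.items()}

#: The 13 GH families that contain cellulases.
CELLULASE_FAMILIES = frozenset(
    {"GH5", "GH6", "GH7", "GH8", "GH9", "GH12", "GH44", "GH45",
     "GH48", "GH51", "GH61", "GH74", "GH124"}
)

#: Domain families with packaged profiles: the 13 cellulase GH families,
#: the glucosidase/phosphorylase families, and the CBM types seen linked
#: to cellulases.
GH_PROFILE_FAMILIES = tuple(sorted(CELLULASE_FAMILIES, key=lambda s: int(s[2:]))) + (
    "GH1", "GH3", "GH94",
)
CBM_PROFILE_FAMILIES = ("CBM6", "CBM_X2", "CBM36", "CBM11", "CBM17_18", "CBM30")
DOMAIN_FAMILIES = GH_PROFILE_FAMILIES + CBM_PROFILE_FAMILIES

# v3-v4 amplification primers (degenerate; include the sequencing pads).
PRIMER_F = "TATGGTAATTGTGTGCCAGCMGCCGCGGTAA"
PRIMER_R = "AGTCAGTCAGCCGGACTACHVGGGTWTCTAAT"
# one concrete realization of each degenerate site, planted in the templates
_PRIMER_F_SITE = PRIMER_F.replace("M", "C")
_PRIMER_R_SITE = PRIMER_R.replace("H", "A").replace("V", "C").replace("W", "T")

_SEED_BASE = 777_001  # fixed: the packaged reference set is a constant


def _rng(*tokens) -> np.random.Generator:
    h = _SEED_BASE
    for t in tokens:
        h = zlib.crc32(str(t).encode(), h)
    return np.random.default_rng(h % 2**31)


# ---------------------------------------------------------------------------
# position-specific scoring profiles

_AA_INDEX = {a: i for i, a in enumerate(AA20)}


def encode_aa(protein: str) -> np.ndarray:
    """Residues -> 0..19 indices; unknown residues (X etc.) -> -1."""
    return np.array([_AA_INDEX.get(a, -1) for a in protein], dtype=np.int64)


@dataclass
class Pssm:
    """Log-odds profile over 20 residues with a calibrated hit threshold."""

    label: str
    matrix: np.ndarray  # (L, 20) log-odds
    threshold: float

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def window_scores(self, protein: str) -> np.ndarray:
        """Score of the profile at every window start (empty if too short)."""
        idx = encode_aa(protein)
        L = self.length
        if idx.size < L:
            return np.empty(0)
        safe = np.clip(idx, 0, 19)
        M = np.ascontiguousarray(self.matrix[:, safe])  # (L, N): matrix[i, idx[j]]
        if (idx < 0).any():
            # unknown residues score as the column mean
            M[:, idx < 0] = self.matrix.mean(axis=1)[:, None]
        n_win = idx.size - L + 1
        windows = np.lib.stride_tricks.as_strided(
            M,
            shape=(n_win, L),
            strides=(M.strides[1], M.strides[0] + M.strides[1]),
        )
        return windows.sum(axis=1)

    def best_hits(self, protein: str) -> list[tuple[int, int, float]]:
        """Non-overlapping windows above threshold as (start, end, score)."""
        scores = self.window_scores(protein)
        hits: list[tuple[int, int, float]] = []
        if scores.size == 0:
            return hits
        scores = scores.copy()
        L = self.length
        while True:
            w = int(np.argmax(scores))
            s = float(scores[w])
            if s < self.threshold:
                break
            hits.append((w, w + L, s))
            lo, hi = max(0, w - L + 1), min(scores.size, w + L)
            scores[lo:hi] = -np.inf
        hits.sort()
        return hits

    def best_score(self, protein: str) -> float:
        scores = self.window_scores(protein)
        return float(scores.max()) if scores.size else -np.inf


def build_pssm(label: str, seeds: list[str], n_null: int = 50,
               null_sd_mult: float = 5.0) -> Pssm:
    """Log-odds profile from equal-length ungapped seed sequences.

    The hit threshold is calibrated against a composition-preserving
    shuffle null: the best window score over shuffles of the first seed,
    summarized as mean + ``null_sd_mult`` SD.
    """
    L = len(seeds[0])
    counts = np.full((L, 20), 0.5)
    for s in seeds:
        idx = encode_aa(s)
        counts[np.arange(L), idx] += 1.0
    probs = counts / counts.sum(axis=1, keepdims=True)
    matrix = np.log(probs / 0.05)
    pssm = Pssm(label, matrix, threshold=np.inf)
    rng = _rng("null", label)
    base = np.array(list(seeds[0]))
    null = []
    for _ in range(n_null):
        shuf = "".join(rng.permutation(base))
        null.append(pssm.best_score(shuf))
    null = np.asarray(null)
    pssm.threshold = float(null.mean() + null_sd_mult * null.std())
    return pssm


# ---------------------------------------------------------------------------
# the reference set

@dataclass
class ReferenceSet:
    genera: tuple[str, ...]
    domain_bases: dict[str, str]
    marker_bases: dict[str, str]          # marker label -> base protein
    genus_proteins: dict[tuple[str, str], str]  # (genus, label) -> variant
    family_profiles: dict[str, Pssm]
    marker_profiles: dict[str, Pssm]
    scm_profiles: dict[str, Pssm]
    sixteen_s: dict[str, str]             # genus -> full-length template
    backbone_16s: str
    assign_norm_threshold: float = 0.0
    protein_db: dict[str, tuple[str, str]] = field(default_factory=dict)

    def reference_proteins(self) -> dict[str, tuple[str, str]]:
        """Best-hit database: reference id -> (genus, protein)."""
        return self.protein_db


_GH_LEN = 200
_CBM_LEN = 60
_GENUS_DIVERGENCE = 0.20  # per-genus variants share ~80% identity with the base


def _marker_base(label: str, domain_bases: dict[str, str]) -> str:
    rng = _rng("marker", label)
    if label == "endoglucanase":
        # catalytic GH9 module followed by a CBM30 cellulose-binding module
        return (
            random_protein(8, rng)
            + domain_bases["GH9"]
            + random_protein(18, rng)
            + domain_bases["CBM30"]
            + random_protein(6, rng)
        )
    if label == "beta_glucosidase":
        return random_protein(12, rng) + domain_bases["GH3"] + random_protein(90, rng)
    if label == "six_phospho_beta_glucosidase":
        return random_protein(10, rng) + domain_bases["GH1"] + random_protein(60, rng)
    if label == "cellobiose_phosphorylase":
        return random_protein(15, rng) + domain_bases["GH94"] + random_protein(110, rng)
    lengths = {
        "PTS_CelA": 116, "PTS_CelB": 106, "PTS_CelC": 380,
        "ABC_CebE": 290, "ABC_CebF": 270, "ABC_CebG": 255, "ABC_MsiK": 275,
    }
    return random_protein(lengths[label], rng)


def _build_16s(genera: tuple[str, ...]) -> tuple[str, dict[str, str]]:
    rng = _rng("16s-backbone")
    pre = random_dna(80, rng, gc=0.52)
    insert = random_dna(360, rng, gc=0.52)
    post = random_dna(660, rng, gc=0.52)
    backbone = pre + _PRIMER_F_SITE + insert + revcomp(_PRIMER_R_SITE) + post
    templates = {}
    for genus in genera:
        grng = _rng("16s", genus)
        templates[genus] = (
            mutate_dna(pre, 0.10, grng)
            + _PRIMER_F_SITE
            + mutate_dna(insert, 0.10, grng)
            + revcomp(_PRIMER_R_SITE)
            + mutate_dna(post, 0.10, grng)
        )
    return backbone, templates


def _calibrate_assign_threshold(db: dict[str, tuple[str, str]]) -> float:
    """Shuffle-null ceiling for the normalized best-hit score.

    Scores of shuffled queries against the packaged database, normalized
    by query length; threshold = null mean + 10 SD.
    """
    from .annotate import align_proteins  # local import to avoid a cycle

    rng = _rng("assign-null")
    refs = [p for _, p in list(db.values())[:10]]
    null = []
    for q in refs[:5]:
        arr = np.array(list(q))
        for _ in range(4):
            shuf = "".join(rng.permutation(arr))
            for subj in refs[:5]:
                score, _ident = align_proteins(shuf, subj)
                null.append(score / len(shuf))
    null = np.asarray(null)
    return float(null.mean() + 10.0 * null.std())


@lru_cache(maxsize=4)
def get_references(genera: tuple[str, ...] | None = None) -> ReferenceSet:
    """Build (or fetch the cached) packaged reference set for ``genera``."""
    if genera is None:
        from .taxonomy import default_taxonomy

        genera = tuple(default_taxonomy().genera())
    genera = tuple(genera)

    domain_bases = {}
    for fam in DOMAIN_FAMILIES:
        length = _GH_LEN if fam.startswith("GH") else _CBM_LEN
        domain_bases[fam] = random_protein(length, _rng("domain", fam))

    marker_bases = {m: _marker_base(m, domain_bases) for m in MARKER_LABELS}
    scm_bases = {m: random_protein(220, _rng("scm", m)) for m in SCM_LABELS}

    genus_proteins: dict[tuple[str, str], str] = {}
    for genus in genera:
        for label, base in {**marker_bases, **scm_bases}.items():
            genus_proteins[(genus, label)] = mutate_protein(
                base, 1.0 - _GENUS_DIVERGENCE, _rng("variant", genus, label)
            )

    def profile_for(label: str, base: str) -> Pssm:
        rng = _rng("seeds", label)
        seeds = [mutate_protein(base, 0.85, rng) for _ in range(10)]
        return build_pssm(label, seeds)

    family_profiles = {f: profile_for(f, domain_bases[f]) for f in DOMAIN_FAMILIES}
    marker_profiles = {m: profile_for(m, marker_bases[m]) for m in MARKER_LABELS}
    scm_profiles = {m: profile_for(m, scm_bases[m]) for m in SCM_LABELS}

    backbone, templates = _build_16s(genera)

    db: dict[str, tuple[str, str]] = {}
    for (genus, label), prot in sorted(genus_proteins.items()):
        db[f"{genus}|{label}"] = (genus, prot)

    refs = ReferenceSet(
        genera=genera,
        domain_bases=domain_bases,
        marker_bases=marker_bases,
        genus_proteins=genus_proteins,
        family_profiles=family_profiles,
        marker_profiles=marker_profiles,
        scm_profiles=scm_profiles,
        sixteen_s=templates,
        backbone_16s=backbone,
        protein_db=db,
    )
    refs.assign_norm_threshold = _calibrate_assign_threshold(db)
    return refs
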