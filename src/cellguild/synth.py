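"""Synthetic cellulolytic communities with full truth labels.

Emulates the structure of a two-sample, six-genus community from a
cellulose-rich alkaline niche: order-1 Markov genome backgrounds on a GC
ladder, one 16S locus per genome, role-defining gene cassettes (the
cellulolytic enzymes and cellodextrin transporter systems) plus ten
universal single-copy marker genes, log-normal sample abundances,
sheared contigs straddling the 300/1000 bp thresholds, and v3-v4 paired
amplicon reads bracketed by the degenerate F515/R803 primers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import references as refs
from .seqs import DNA, encode_protein, find_primer, mutate_dna, mutate_protein, revcomp
from .taxonomy import default_taxonomy


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types

@dataclass
class GenomeSpec:
    genus: str
    length: int = 30_000
    gc: float = 0.5
    transition: np.ndarray | None = None  # 4x4 row-stochastic over ACGT
    role: str = "non_participant"         # helper | beneficiary | non_participant
    cassette: tuple[str, ...] = ()
    sixteen_s_id: str | None = None       # defaults to the genus template
    cassette_identity: float = 0.80       # identity of planted genes to refs

    def __post_init__(self):
        if self.transition is None:
            self.transition = gc_transition(self.gc)
        t = np.asarray(self.transition, float)
        if t.shape != (4, 4) or not np.allclose(t.sum(axis=1), 1.0):
            raise SimulationError("transition matrix must be 4x4 row-stochastic")
        if self.role == "beneficiary" and "endoglucanase" in self.cassette:
            raise SimulationError("beneficiary cassettes must exclude endoglucanase")
        if self.role == "helper" and "endoglucanase" not in self.cassette:
            raise SimulationError("helper cassettes must include endoglucanase")
        if self.sixteen_s_id is None:
            self.sixteen_s_id = self.genus


@dataclass
class Feature:
    label: str
    start: int  # 0-based half-open bp, forward coordinates
    end: int
    strand: str  # '+' or '-'


@dataclass
class SyntheticGenome:
    id: str
    sequence: str
    features: list[Feature]
    genus: str
    role: str

    def feature_seq(self, feat: Feature) -> str:
        s = self.sequence[feat.start : feat.end]
        return s if feat.strand == "+" else revcomp(s)

    def sixteen_s(self) -> str:
        for f in self.features:
            if f.label == "16S":
                return self.feature_seq(f)
        raise SimulationError(f"genome {self.id} lacks a 16S locus")


@dataclass
class CommunityProfile:
    sample: str
    abundances: dict[str, float]  # genome id -> relative abundance


@dataclass
class Contig:
    id: str
    sequence: str
    source_genome: str
    source_start: int
    source_end: int
    strand: str = "+"


@dataclass
class ContigSet:
    contigs: list[Contig] = field(default_factory=list)

    def truth(self, genomes: dict[str, SyntheticGenome]) -> pd.DataFrame:
        rows = [
            {
                "contig": c.id,
                "genus": genomes[c.source_genome].genus,
                "role": genomes[c.source_genome].role,
            }
            for c in self.contigs
        ]
        return pd.DataFrame(rows, columns=["contig", "genus", "role"])


# ---------------------------------------------------------------------------
# genome simulation

def gc_transition(gc: float, jitter: float = 0.0,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Row-stochastic order-1 transition matrix with stationary GC ~ ``gc``.

    Optional multiplicative log-normal jitter gives each genome a
    distinguishable k-mer signature beyond its GC content.
    """
    if not 0 < gc < 1:
        raise SimulationError("GC fraction must be in (0, 1)")
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    t = np.tile(base, (4, 1))
    if jitter > 0:
        if rng is None:
            raise SimulationError("jittered transition needs an rng")
        t = t * np.exp(rng.normal(0.0, jitter, size=(4, 4)))
    return t / t.sum(axis=1, keepdims=True)


def markov_background(length: int, transition: np.ndarray, seed: int) -> str:
    """Order-1 Markov background sequence (no planted features)."""
    return _markov_dna(length, np.asarray(transition, float),
                       np.random.default_rng(seed))


def _markov_dna(length: int, transition: np.ndarray,
                rng: np.random.Generator) -> str:
    if length <= 0:
        return ""
    cum = np.cumsum(transition, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    state = int(rng.integers(4))
    for i in range(length):
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        state = min(state, 3)
        out[i] = state
    return "".join(DNA[i] for i in out)


_SIXTEEN_S_SUBSTITUTION = 0.01  # per-base divergence of a genome's 16S copy


def simulate_genome(spec: GenomeSpec, seed: int,
                    reference: refs.ReferenceSet | None = None) -> SyntheticGenome:
    """Draw one truth-labeled genome for ``spec``; deterministic per (spec, seed)."""
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = refs.get_references()

    blocks: list[tuple[str, str]] = []
    template = reference.sixteen_s[spec.sixteen_s_id]
    blocks.append(("16S", _mutate_16s(template, rng)))
    labels = []
    for feature in spec.cassette:
        labels.extend(refs.FEATURE_TO_MARKERS[feature])
    labels.extend(refs.SCM_LABELS)
    for label in labels:
        prot = reference.genus_proteins[(spec.genus, label)]
        prot = mutate_protein(prot, spec.cassette_identity, rng)
        blocks.append((label, encode_protein(prot, rng, gc=spec.gc)))

    feat_bp = sum(len(b) for _, b in blocks)
    min_gap = 50
    bg_total = spec.length - feat_bp
    if bg_total < min_gap * (len(blocks) + 1):
        raise SimulationError(
            f"genome length {spec.length} too short for {feat_bp} bp of features"
        )
    order = rng.permutation(len(blocks))
    gaps = rng.multinomial(bg_total - min_gap * (len(blocks) + 1),
                           np.full(len(blocks) + 1, 1 / (len(blocks) + 1)))
    gaps = gaps + min_gap

    parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    for gi, bi in enumerate(order):
        bg = _markov_dna(int(gaps[gi]), spec.transition, rng)
        parts.append(bg)
        pos += len(bg)
        label, dna = blocks[bi]
        strand = "+" if (label == "16S" or rng.random() < 0.5) else "-"
        parts.append(dna if strand == "+" else revcomp(dna))
        features.append(Feature(label, pos, pos + len(dna), strand))
        pos += len(dna)
    parts.append(_markov_dna(int(gaps[-1]), spec.transition, rng))
    seq = "".join(parts)
    assert len(seq) == spec.length
    features.sort(key=lambda f: f.start)
    return SyntheticGenome(spec.genus, seq, features, spec.genus, spec.role)


def _mutate_16s(template: str, rng: np.random.Generator) -> str:
    """Substitute outside the primer sites so amplification stays possible."""
    f = find_primer(refs.PRIMER_F, template)
    r_site = revcomp(refs._PRIMER_R_SITE)
    r = template.find(r_site)
    fe, re_ = f + len(refs.PRIMER_F), r + len(r_site)
    return (
        mutate_dna(template[:f], _SIXTEEN_S_SUBSTITUTION, rng)
        + template[f:fe]
        + mutate_dna(template[fe:r], _SIXTEEN_S_SUBSTITUTION, rng)
        + template[r:re_]
        + mutate_dna(template[re_:], _SIXTEEN_S_SUBSTITUTION, rng)
    )


# ---------------------------------------------------------------------------
# community structure

def simulate_community(genomes: list[SyntheticGenome], sigma: float = 1.0,
                       n_samples: int = 2, seed: int = 0) -> list[CommunityProfile]:
    """Per-sample log-normal abundances, normalized to sum to one."""
    if not genomes:
        raise SimulationError("need at least one genome")
    if n_samples < 1:
        raise SimulationError("n_samples must be >= 1")
    if sigma <= 0:
        raise SimulationError("log-normal sigma must be positive")
    rng = np.random.default_rng(seed)
    profiles = []
    for s in range(n_samples):
        x = rng.lognormal(mean=0.0, sigma=sigma, size=len(genomes))
        x = x / x.sum()
        profiles.append(
            CommunityProfile(f"sample{s + 1}", {g.id: float(a) for g, a in zip(genomes, x)})
        )
    return profiles


def lognormal_lengths(mean_bp: float = 1400.0, sigma: float = 0.35,
                      lo: int = 400, hi: int = 3000):
    """Contig length sampler straddling the 300/1000 bp analysis thresholds."""
    mu = np.log(mean_bp) - sigma**2 / 2

    def draw(rng: np.random.Generator, size: int) -> np.ndarray:
        return np.clip(rng.lognormal(mu, sigma, size=size), lo, hi).astype(int)

    return draw


def shear_contigs(genomes: list[SyntheticGenome], profile: CommunityProfile,
                  n_contigs: int, length_distribution=None, seed: int = 0,
                  prefix: str = "contig") -> ContigSet:
    """Sample contigs from genomes proportional to sample abundance."""
    if length_distribution is None:
        length_distribution = lognormal_lengths()
    rng = np.random.default_rng(seed)
    gmap = {g.id: g for g in genomes}
    ids = sorted(profile.abundances)
    p = np.array([profile.abundances[i] for i in ids])
    p = p / p.sum()
    out = ContigSet()
    if n_contigs == 0:
        return out
    choices = rng.choice(len(ids), size=n_contigs, p=p)
    lengths = np.atleast_1d(length_distribution(rng, n_contigs))
    for i, (gi, L) in enumerate(zip(choices, lengths)):
        out.contigs.append(_cut(gmap[ids[gi]], int(L), rng, f"{prefix}{i:05d}"))
    return out


def shear_contigs_per_genome(genomes: list[SyntheticGenome], n_per_genome: int,
                             length_distribution=None, seed: int = 0,
                             prefix: str = "contig") -> ContigSet:
    """Fixed number of contigs per genome (even-coverage benchmark layout)."""
    if length_distribution is None:
        length_distribution = lognormal_lengths()
    rng = np.random.default_rng(seed)
    out = ContigSet()
    i = 0
    for g in genomes:
        lengths = np.atleast_1d(length_distribution(rng, n_per_genome))
        for L in lengths:
            out.contigs.append(_cut(g, int(L), rng, f"{prefix}{i:05d}"))
            i += 1
    return out


def _cut(g: SyntheticGenome, length: int, rng: np.random.Generator,
         cid: str) -> Contig:
    if length > len(g.sequence):
        raise SimulationError(
            f"requested contig length {length} exceeds genome {g.id}"
        )
    start = int(rng.integers(0, len(g.sequence) - length + 1))
    seq = g.sequence[start : start + length]
    strand = "+" if rng.random() < 0.5 else "-"
    return Contig(cid, seq if strand == "+" else revcomp(seq),
                  g.id, start, start + length, strand)


# ---------------------------------------------------------------------------
# amplicon simulation

def default_quality(read_length: int, rng: np.random.Generator) -> np.ndarray:
    """Phred profile: high early-cycle quality with a mild 3' decay."""
    base = np.linspace(38.0, 33.0, read_length)
    q = base + rng.normal(0.0, 1.5, size=read_length)
    return np.clip(np.rint(q), 2, 41).astype(int)


def simulate_amplicons(genomes, profile: CommunityProfile,
                       fwd_primer: str = refs.PRIMER_F,
                       rev_primer: str = refs.PRIMER_R,
                       read_length: int = 250, error_rate: float = 0.005,
                       n_pairs: int = 200, seed: int = 0,
                       quality_profile=default_quality):
    """Paired primer-trimmed v3-v4 reads plus a per-read truth table.

    Both primers are matched under IUPAC degeneracy against each
    genome's 16S locus (the reverse primer against the reverse
    complement of the template); reads cover the inter-primer insert
    from both ends so merged pairs reconstruct it.
    """
    from .amplicon import AmpliconRead

    rng = np.random.default_rng(seed)
    gmap = {g.id: g for g in genomes}
    inserts: dict[str, str] = {}
    for gid, g in gmap.items():
        t = g.sixteen_s()
        f = find_primer(fwd_primer, t)
        rc = revcomp(t)
        r = find_primer(rev_primer, rc)
        if f < 0 or r < 0:
            continue
        r_start = len(t) - r - len(rev_primer)  # fwd-coordinate start of rev site
        inserts[gid] = t[f + len(fwd_primer) : r_start]
    if not inserts:
        raise SimulationError("primers match no genome 16S template")

    ids = sorted(i for i in profile.abundances if i in inserts)
    p = np.array([profile.abundances[i] for i in ids])
    p = p / p.sum()
    pairs = []
    truth_rows = []
    for i in range(n_pairs):
        gid = ids[int(rng.choice(len(ids), p=p))]
        insert = inserts[gid]
        fwd_b = insert[:read_length]
        rev_b = revcomp(insert)[:read_length]
        fq = quality_profile(len(fwd_b), rng)
        rq = quality_profile(len(rev_b), rng)
        rid = f"{profile.sample}_read{i:05d}"
        pairs.append(
            (
                AmpliconRead(f"{rid}/1", _seq_errors(fwd_b, error_rate, rng), fq),
                AmpliconRead(f"{rid}/2", _seq_errors(rev_b, error_rate, rng), rq),
            )
        )
        truth_rows.append({"read": rid, "genus": gmap[gid].genus,
                           "genome": gid, "sample": profile.sample})
    truth = pd.DataFrame(truth_rows, columns=["read", "genus", "genome", "sample"])
    return pairs, truth


def _seq_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    return mutate_dna(seq, rate, rng) if rate > 0 else seq


# ---------------------------------------------------------------------------
# the default study community

#: GC ladder with 0.06 pairwise gaps: composition-signature binning needs
#: distinguishable genome backgrounds.
DEFAULT_GC = {
    "Cloacibacterium": 0.33,
    "Paludibacter": 0.39,
    "Exiguobacterium": 0.45,
    "Clostridium": 0.51,
    "Acetivibrio": 0.57,
    "Tolumonas": 0.63,
}

#: Gene cassettes mirroring the helper/beneficiary gene content of the six
#: dominant genera (helpers carry endoglucanase; beneficiaries do not).
DEFAULT_CASSETTES = {
    "Clostridium": ("helper", ("endoglucanase", "beta_glucosidase",
                               "six_phospho_beta_glucosidase", "pts_cel")),
    "Paludibacter": ("helper", ("endoglucanase", "beta_glucosidase",
                                "cellobiose_phosphorylase")),
    "Cloacibacterium": ("beneficiary", ("beta_glucosidase",
                                        "six_phospho_beta_glucosidase")),
    "Exiguobacterium": ("beneficiary", ("beta_glucosidase",
                                        "six_phospho_beta_glucosidase", "pts_cel")),
    "Acetivibrio": ("beneficiary", ("beta_glucosidase",
                                    "six_phospho_beta_glucosidase", "pts_cel")),
    "Tolumonas": ("beneficiary", ("beta_glucosidase",
                                  "six_phospho_beta_glucosidase", "pts_cel")),
}


def default_community_specs(length: int = 30_000,
                            cassette_identity: float = 0.80) -> list[GenomeSpec]:
    """GenomeSpecs for the six-genus study community."""
    specs = []
    for genus in default_taxonomy().genera():
        role, cassette = DEFAULT_CASSETTES[genus]
        gc = DEFAULT_GC[genus]
        rng = np.random.default_rng(zlib.crc32(genus.encode()) % 2**31)
        specs.append(
            GenomeSpec(
                genus=genus, length=length, gc=gc,
                transition=gc_transition(gc, jitter=0.15, rng=rng),
                role=role, cassette=cassette,
                cassette_identity=cassette_identity,
            )
        )
    return specs


def simulate_default_community(seed: int = 0, n_samples: int = 2,
                               sigma: float = 1.0, length: int = 30_000):
    """Genomes + abundance profiles for the default six-genus community."""
    reference = refs.get_references()
    specs = default_community_specs(length=length)
    rng = np.random.default_rng(seed)
    genomes = [
        simulate_genome(s, seed=int(rng.integers(2**31)), reference=reference)
        for s in specs
    ]
    profiles = simulate_community(genomes, sigma=sigma, n_samples=n_samples,
                                  seed=int(rng.integers(2**31)))
    return genomes, profiles


def make_16s_reference(genera: tuple[str, ...] | None = None,
                       n_per_genus: int = 5, divergence: float = 0.01,
                       seed: int = 0) -> list[tuple[str, str]]:
    """Labeled 16S training set: per-genus template copies at ~99% identity."""
    reference = refs.get_references(tuple(genera) if genera else None)
    rng = np.random.default_rng(seed)
    out = []
    for genus in reference.genera:
        t = reference.sixteen_s[genus]
        for _ in range(n_per_genus):
            out.append((genus, mutate_dna(t, divergence, rng)))
    return out
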