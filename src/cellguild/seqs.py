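"""Low-level sequence helpers: IUPAC matching, mutation, codon encoding."""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq
from Bio.Data.CodonTable import unambiguous_dna_by_id

DNA = "ACGT"
AA20 = "ACDEFGHIKLMNPQRSTVWY"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_TABLE = unambiguous_dna_by_id[11]
#: sense codons per amino acid (bacterial/archaeal table)
CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in _TABLE.forward_table.items():
    CODONS_BY_AA.setdefault(aa, []).append(codon)
for codons in CODONS_BY_AA.values():
    codons.sort()
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    return str(Seq(seq).translate(table=11))


def iupac_match(primer: str, template: str) -> bool:
    """True if ``primer`` matches ``template`` position-wise under IUPAC codes."""
    if len(primer) != len(template):
        return False
    return all(t in IUPAC[p] for p, t in zip(primer, template))


def find_primer(primer: str, template: str) -> int:
    """Leftmost 0-based start of an IUPAC match of primer in template, or -1."""
    k = len(primer)
    for i in range(len(template) - k + 1):
        if iupac_match(primer, template[i : i + k]):
            return i
    return -1


def mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-base substitution at ``rate``; substitutions never re-draw the same base."""
    bases = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(bases)) < rate)
    for i in hits:
        alt = [b for b in DNA if b != bases[i].decode()]
        bases[i] = rng.choice(alt).encode()
    return bases.tobytes().decode()


def mutate_protein(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute residues so the expected identity to ``seq`` is ``identity``."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(out)) < (1.0 - identity))
    for i in hits:
        alt = [a for a in AA20 if a != out[i]]
        out[i] = alt[int(rng.integers(len(alt)))]
    return "".join(out)


def random_dna(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(DNA[i] for i in idx)


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AA20[int(i)] for i in rng.integers(0, 20, size=length))


def encode_protein(protein: str, rng: np.random.Generator, gc: float = 0.5) -> str:
    """Reverse-translate with synonymous codons weighted toward the host GC.

    Codon choice is the only degree of freedom the host composition can act
    on without changing the protein, so coding regions inherit a muted
    version of the genome-wide GC signature.
    """
    parts = ["ATG"]
    for aa in protein:
        codons = CODONS_BY_AA[aa]
        gcfrac = np.array([(c.count("G") + c.count("C")) / 3 for c in codons])
        w = gc * gcfrac + (1 - gc) * (1 - gcfrac) + 1e-3
        parts.append(codons[int(rng.choice(len(codons), p=w / w.sum()))])
    # TAA vs TGA weighted the same way
    parts.append("TAA" if rng.random() > gc else "TGA")
    return "".join(parts)
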