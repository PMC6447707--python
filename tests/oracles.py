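"""Independent brute-force oracles used by the equivalence tests.

Deliberately naive implementations (enumeration, direct counting, grid
search) that share no code with the package paths they check.
"""

from itertools import product

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sw_local_score_bruteforce(a: str, b: str, gap_open: float = -11.0,
                              gap_extend: float = -1.0) -> float:
    """Best local alignment score by exhaustive enumeration (tiny inputs).

    Enumerates every substring pair and every gapped alignment between
    them with affine gap costs (first gap residue ``gap_open``, each
    further residue ``gap_extend``).
    """

    def global_best(x: str, y: str) -> float:
        best = [float("-inf")]

        def rec(i, j, score, last):
            if i == len(x) and j == len(y):
                best[0] = max(best[0], score)
                return
            if i < len(x) and j < len(y):
                rec(i + 1, j + 1, score + _B62[x[i], y[j]], "M")
            if i < len(x):
                cost = gap_extend if last == "D" else gap_open
                rec(i + 1, j, score + cost, "D")
            if j < len(y):
                cost = gap_extend if last == "I" else gap_open
                rec(i, j + 1, score + cost, "I")

        rec(0, 0, 0.0, "M")
        return best[0]

    best = 0.0
    for i1, j1 in product(range(len(a) + 1), repeat=2):
        if j1 <= i1:
            continue
        for i2, j2 in product(range(len(b) + 1), repeat=2):
            if j2 <= i2:
                continue
            best = max(best, global_best(a[i1:j1], b[i2:j2]))
    return best


def kmer_counts_direct(seq: str, k: int = 5) -> dict[str, int]:
    """Canonical k-mer counts by a plain dictionary tally."""
    comp = str.maketrans("ACGT", "TGCA")
    out: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if set(w) - set("ACGT"):
            continue
        rc = w.translate(comp)[::-1]
        canon = min(w, rc)
        out[canon] = out.get(canon, 0) + 1
    return out


def pI_grid(protein: str, charge_fn, step: float = 1e-3) -> float:
    """Grid-search pI: the pH with the smallest absolute net charge."""
    best_ph, best_c = 0.0, float("inf")
    ph = step
    while ph < 14.0:
        c = abs(charge_fn(protein, ph))
        if c < best_c:
            best_ph, best_c = ph, c
        ph += step
    return best_ph


def venn_enumeration(a: set, b: set, c: set) -> dict[str, int]:
    """Region counts by per-element membership enumeration."""
    out = {k: 0 for k in ("A", "B", "C", "AB", "AC", "BC", "ABC")}
    for x in a | b | c:
        key = "".join(n for n, s in (("A", a), ("B", b), ("C", c)) if x in s)
        out[key] += 1
    return out
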