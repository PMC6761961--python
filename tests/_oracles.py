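"""Independent brute-force oracles used to cross-check the implementations.

The NG86 oracle recomputes synonymous sites and pathway-averaged synonymous
differences directly from Biopython's translation table, without touching the
package's precomputed lookup tables.
"""

from itertools import permutations

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_syn_sites(seq: str) -> float:
    total = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        aa = _aa(codon)
        syn = 0
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                mut = codon[:pos] + base + codon[pos + 1 :]
                if mut in STOPS:
                    continue  # a change to a stop counts as nonsynonymous
                if _aa(mut) == aa:
                    syn += 1
        total += syn / 3.0
    return total


def oracle_syn_differences(a: str, b: str) -> float:
    """Pathway-averaged synonymous differences; paths through stops excluded,
    falling back to all paths when every ordering is blocked."""
    total = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        diff = [p for p in range(3) if ca[p] != cb[p]]
        if not diff:
            continue

        def walk(order, allow_stops):
            cur, syn = ca, 0.0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if nxt in STOPS and not allow_stops:
                    return None
                if _aa(nxt) == _aa(cur):
                    syn += 1.0
                cur = nxt
            return syn

        paths = [walk(o, False) for o in permutations(diff)]
        valid = [p for p in paths if p is not None]
        if not valid:
            valid = [walk(o, True) for o in permutations(diff)]
        total += sum(valid) / len(valid)
    return total


def oracle_counts(a: str, b: str) -> tuple[float, float]:
    """(mean synonymous sites, synonymous differences) for an aligned pair."""
    s = (oracle_syn_sites(a) + oracle_syn_sites(b)) / 2.0
    return s, oracle_syn_differences(a, b)
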