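"""Codon-level machinery shared by the sequence simulator and the dS estimator.

The genetic code comes from Biopython's standard table.  Everything else is
precomputed at import time into small numpy lookup tables indexed by codon
number (``16*a + 4*b + c`` with A,C,G,T -> 0..3):

* per-codon synonymous/nonsynonymous site counts (NG86 fractional sites;
  changes that create a stop codon count as nonsynonymous),
* per-codon lists of synonymous and nonsynonymous *sense* neighbours (used by
  the simulator, which never introduces internal stops),
* 64x64 tables of pathway-averaged synonymous and total differences between
  codon pairs (mutation paths passing through stop codons are excluded; if
  every ordering is blocked, all orderings are used).
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_table = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_table.stop_codons)
AMINO_ACID = {c: (_table.forward_table[c] if c not in STOP_CODONS else "*") for c in CODONS}
IS_STOP = np.array([c in STOP_CODONS for c in CODONS], dtype=bool)
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]


def _neighbours(codon: str):
    for pos in range(3):
        for b in BASES:
            if b != codon[pos]:
                yield codon[:pos] + b + codon[pos + 1 :]


# NG86 site counts: each of the 3 positions contributes (synonymous changes)/3.
SYN_SITES = np.zeros(64)
NONSYN_SITES = np.zeros(64)
SYN_NEIGHBOURS: list[list[int]] = [[] for _ in range(64)]
NONSYN_SENSE_NEIGHBOURS: list[list[int]] = [[] for _ in range(64)]

for _c in CODONS:
    _i = CODON_INDEX[_c]
    if _c in STOP_CODONS:
        continue
    syn = 0.0
    for _n in _neighbours(_c):
        if _n in STOP_CODONS:
            # counted as nonsynonymous sites; not a legal simulator move
            continue
        if AMINO_ACID[_n] == AMINO_ACID[_c]:
            syn += 1.0
            SYN_NEIGHBOURS[_i].append(CODON_INDEX[_n])
        else:
            NONSYN_SENSE_NEIGHBOURS[_i].append(CODON_INDEX[_n])
    SYN_SITES[_i] = syn / 3.0
    NONSYN_SITES[_i] = 3.0 - syn / 3.0


def _pathway_counts(ci: int, cj: int) -> tuple[float, float]:
    """Pathway-averaged (synonymous, total) differences between two codons."""
    a, b = CODONS[ci], CODONS[cj]
    diff = [p for p in range(3) if a[p] != b[p]]
    if not diff:
        return 0.0, 0.0
    nd = float(len(diff))

    def walk(order, allow_stops):
        cur = a
        syn = 0.0
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if AMINO_ACID[nxt] == AMINO_ACID[cur]:
                syn += 1.0
            cur = nxt
        return syn

    paths = [walk(order, False) for order in permutations(diff)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [walk(order, True) for order in permutations(diff)]
    return float(np.mean(valid)), nd


SD_TABLE = np.zeros((64, 64))
ND_TOTAL_TABLE = np.zeros((64, 64))
for _ci in range(64):
    for _cj in range(64):
        if IS_STOP[_ci] or IS_STOP[_cj]:
            continue
        _sd, _ndt = _pathway_counts(_ci, _cj)
        SD_TABLE[_ci, _cj] = _sd
        ND_TOTAL_TABLE[_ci, _cj] = _ndt


def encode_codons(seq: str) -> np.ndarray:
    """Codon indices for an in-frame DNA string; -1 marks codons with non-ACGT bases."""
    if len(seq) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for i in range(0, len(seq), 3):
        out[i // 3] = CODON_INDEX.get(seq[i : i + 3].upper(), -1)
    return out


def decode_codons(idx: np.ndarray) -> str:
    return "".join(CODONS[i] for i in idx)


def random_sense_codons(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random sense codons (no stops)."""
    sense_idx = np.array([CODON_INDEX[c] for c in SENSE_CODONS])
    return rng.choice(sense_idx, size=n)


def evolve_codons(
    idx: np.ndarray,
    t: float,
    syn_rate: float,
    nonsyn_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve a codon-index array for ``t`` Myr under a Gillespie process.

    Synonymous changes fire at ``syn_rate * S(codon)`` per codon (S = NG86
    synonymous sites of the current codon) and pick a uniform synonymous
    neighbour; nonsynonymous changes fire at ``nonsyn_rate * N(codon)`` and
    pick a uniform nonsynonymous *sense* neighbour, so internal stops are never
    created.  The expected synonymous divergence per synonymous site over a
    branch is ``syn_rate * t``.
    """
    out = idx.copy()
    if t <= 0 or (syn_rate <= 0 and nonsyn_rate <= 0):
        return out
    for k in range(out.size):
        c = int(out[k])
        elapsed = 0.0
        while True:
            rs = syn_rate * SYN_SITES[c]
            rn = nonsyn_rate * NONSYN_SITES[c] if NONSYN_SENSE_NEIGHBOURS[c] else 0.0
            total = rs + rn
            if total <= 0:
                break
            elapsed += rng.exponential(1.0 / total)
            if elapsed >= t:
                break
            if rng.random() < rs / total:
                c = int(SYN_NEIGHBOURS[c][rng.integers(len(SYN_NEIGHBOURS[c]))])
            else:
                c = int(
                    NONSYN_SENSE_NEIGHBOURS[c][rng.integers(len(NONSYN_SENSE_NEIGHBOURS[c]))]
                )
        out[k] = c
    return out
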