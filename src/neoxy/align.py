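"""Alignment contract and desk-scale aligners.

The analysis stages never call an external aligner directly; they accept any
object satisfying a small contract:

* :class:`ExactReadMapper` — exact full-length placement of short reads on a
  reference (the simulator emits error-free reads, so exact matching is the
  appropriate mapper for synthetic data and for the read filters, which the
  source protocols run with strict settings anyway).
* :class:`ExactSeedAligner` — best local hit for a query against a reference:
  exact k-mer seeding plus ungapped extension, reporting identity and the
  aligned fraction of the query.  Production data can instead supply
  precomputed hits through :func:`read_hit_table`.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Hit:
    """Best local alignment of a query against a reference sequence set."""

    chrom: str
    ref_start: int
    strand: str  # '+' or '-'
    matches: int
    aligned_length: int
    query_length: int

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_length if self.aligned_length else 0.0

    @property
    def aligned_fraction(self) -> float:
        return self.aligned_length / self.query_length if self.query_length else 0.0


def _index_kmers(sequences: dict[str, str], k: int) -> dict[str, object]:
    """k-mer -> (chrom, pos) or list of such; skips k-mers containing N."""
    index: dict[str, object] = {}
    for chrom, seq in sequences.items():
        up = seq.upper()
        for pos in range(len(up) - k + 1):
            kmer = up[pos : pos + k]
            if "N" in kmer:
                continue
            cur = index.get(kmer)
            if cur is None:
                index[kmer] = (chrom, pos)
            elif isinstance(cur, list):
                cur.append((chrom, pos))
            else:
                index[kmer] = [cur, (chrom, pos)]
    return index


def _candidates(entry) -> list[tuple[str, int]]:
    return entry if isinstance(entry, list) else [entry]


class ExactReadMapper:
    """Place reads that match a reference exactly (either strand).

    Used for depth tracks and for the "reads not mapping to the female
    genome" filter, where the protocol allows no mismatches on synthetic,
    error-free reads.
    """

    def __init__(self, sequences: dict[str, str], seed_k: int = 31):
        if not sequences:
            raise ValueError("empty reference")
        self.sequences = {c: s.upper() for c, s in sequences.items()}
        self.seed_k = seed_k
        self._index = _index_kmers(self.sequences, seed_k)

    def _locate(self, seq: str) -> tuple[str, int] | None:
        if len(seq) < self.seed_k:
            return None
        entry = self._index.get(seq[: self.seed_k])
        if entry is None:
            return None
        for chrom, pos in _candidates(entry):
            ref = self.sequences[chrom]
            if ref[pos : pos + len(seq)] == seq:
                return chrom, pos
        return None

    def map_read(self, seq: str) -> tuple[str, int, str] | None:
        """Return (chrom, start, strand) of an exact full-length match, else None."""
        up = seq.upper()
        if "N" in up:
            return None
        hit = self._locate(up)
        if hit is not None:
            return hit[0], hit[1], "+"
        hit = self._locate(revcomp(up))
        if hit is not None:
            return hit[0], hit[1], "-"
        return None


class ExactSeedAligner:
    """Best ungapped local hit via exact k-mer seeding and extension.

    The default seed of 31 nt suits near-identical scaffold placement; the
    male/female validation step uses a shorter seed (15 nt) so that hits to
    homologues diverged by ~10-25% are still found and their identity can be
    measured against the significance thresholds.
    """

    def __init__(self, sequences: dict[str, str], seed_k: int = 31):
        if not sequences:
            raise ValueError("empty reference")
        self.sequences = {c: s.upper() for c, s in sequences.items()}
        self.seed_k = seed_k
        self._index = _index_kmers(self.sequences, seed_k)

    def _score(self, query: str, chrom: str, offset: int) -> tuple[int, int, int] | None:
        """Best local ungapped segment of the query placed at ``offset``.

        Scores +1 per match / -1 per mismatch along the diagonal and keeps the
        maximal-sum segment, so unalignable query tails reduce the aligned
        fraction instead of diluting identity.
        """
        ref = self.sequences[chrom]
        q_lo = max(0, -offset)
        q_hi = min(len(query), len(ref) - offset)
        if q_hi <= q_lo:
            return None
        seg = query[q_lo:q_hi]
        ref_seg = ref[offset + q_lo : offset + q_hi]
        best = running = 0
        best_bounds = (0, 0)
        run_start = 0
        matches_prefix = [0]
        for i, (a, b) in enumerate(zip(seg, ref_seg)):
            is_match = a == b
            matches_prefix.append(matches_prefix[-1] + is_match)
            running += 1 if is_match else -1
            if running <= 0:
                running = 0
                run_start = i + 1
            elif running > best:
                best = running
                best_bounds = (run_start, i + 1)
        lo, hi = best_bounds
        if hi <= lo:
            return None
        matches = matches_prefix[hi] - matches_prefix[lo]
        return matches, hi - lo, offset + q_lo + lo

    def _best_for_strand(self, query: str, strand: str) -> Hit | None:
        k = self.seed_k
        best: Hit | None = None
        seen: set[tuple[str, int]] = set()
        for qpos in range(0, len(query) - k + 1):
            entry = self._index.get(query[qpos : qpos + k])
            if entry is None:
                continue
            for chrom, pos in _candidates(entry):
                offset = pos - qpos
                if (chrom, offset) in seen:
                    continue
                seen.add((chrom, offset))
                scored = self._score(query, chrom, offset)
                if scored is None:
                    continue
                matches, alen, start = scored
                if best is None or matches > best.matches:
                    best = Hit(chrom, start, strand, matches, alen, len(query))
        return best

    def best_hit(self, query: str) -> Hit | None:
        up = query.upper()
        fwd = self._best_for_strand(up, "+")
        rev = self._best_for_strand(revcomp(up), "-")
        if fwd is None:
            return rev
        if rev is None or fwd.matches >= rev.matches:
            return fwd
        return rev


def read_hit_table(path) -> dict[str, Hit]:
    """Load precomputed best hits from a TSV (query, chrom, ref_start, strand,
    matches, aligned_length, query_length) — the plug-in point for external
    aligners."""
    df = pd.read_csv(path, sep="\t")
    required = {"query", "chrom", "ref_start", "strand", "matches", "aligned_length", "query_length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return {
        row["query"]: Hit(
            row["chrom"],
            int(row["ref_start"]),
            row["strand"],
            int(row["matches"]),
            int(row["aligned_length"]),
            int(row["query_length"]),
        )
        for _, row in df.iterrows()
    }


class TableAligner:
    """Aligner-contract adapter over a precomputed hit table (keyed by query id)."""

    def __init__(self, hits: dict[str, Hit]):
        self.hits = hits

    def best_hit_by_id(self, query_id: str) -> Hit | None:
        return self.hits.get(query_id)


def depth_tracks(
    reads, mapper: ExactReadMapper, read_length: int | None = None
) -> tuple[dict[str, np.ndarray], int]:
    """Per-base depth arrays from exact read placement.

    ``reads`` is an iterable of sequences or objects with a ``.seq`` attribute.
    Returns (chrom -> float array, number of unmapped reads).
    """
    diffs = {c: np.zeros(len(s) + 1, dtype=np.int64) for c, s in mapper.sequences.items()}
    unmapped = 0
    for r in reads:
        seq = getattr(r, "seq", r)
        placed = mapper.map_read(seq)
        if placed is None:
            unmapped += 1
            continue
        chrom, start, _ = placed
        diffs[chrom][start] += 1
        diffs[chrom][min(start + len(seq), len(mapper.sequences[chrom]))] -= 1
    tracks = {c: np.cumsum(d[:-1]).astype(np.float64) for c, d in diffs.items()}
    return tracks, unmapped
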