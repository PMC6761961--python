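"""Male-specific transcript discovery by read subtraction.

The chain mirrors the source protocol: drop reads with ambiguous bases, drop
male RNA reads that align to the female genome, screen the remainder against
an index of abundant female-read 35-mers (exact matches only, both
orientations), assemble the survivors with a greedy longest-overlap
assembler, then validate each contig — accepted iff it matches the male
genome at 100% identity over >= 90% of its length with no significant female
hit (identity >= 0.8 over >= 0.5 of the contig, configurable).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .align import ExactReadMapper, ExactSeedAligner, Hit, revcomp
from .errors import ConfigurationError

ACCEPTED = "ACCEPTED"
REJECTED_FEMALE_PRESENT = "REJECTED_FEMALE_PRESENT"
REJECTED_LOW_MALE_IDENTITY = "REJECTED_LOW_MALE_IDENTITY"


@dataclass
class KmerIndex:
    """Multiset of fixed-length k-mers above a minimum frequency."""

    k: int = 35
    min_count: int = 10
    counts: dict[str, int] = field(default_factory=dict)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.counts

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class CandidateTranscript:
    id: str
    sequence: str
    supporting_read_count: int
    male_hit: Hit | None
    female_hit: Hit | None
    status: str


def drop_ambiguous(reads) -> list:
    """Remove reads containing any non-ACGT base (run before every stage)."""
    return [r for r in reads if set(_seq(r).upper()) <= set("ACGT")]


def _seq(read) -> str:
    return getattr(read, "seq", read)


def filter_genome_mapped(reads, female_genome: dict[str, str] | None,
                         mapper: ExactReadMapper | None = None) -> list:
    """Keep exactly the reads with no qualifying alignment to the female genome."""
    if mapper is None:
        mapper = ExactReadMapper(female_genome)
    return [r for r in reads if mapper.map_read(_seq(r)) is None]


def build_kmer_index(reads, k: int = 35, min_count: int = 10) -> KmerIndex:
    """Count k-mers over the reads as given (orientations are not merged) and
    drop those below ``min_count`` — rare k-mers are not part of the overall
    signature of the female transcriptome."""
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    counts: Counter[str] = Counter()
    usable = 0
    for r in reads:
        seq = _seq(r).upper()
        if len(seq) < k:
            continue
        usable += 1
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                counts[kmer] += 1
    if reads and not usable:
        raise ConfigurationError(f"k={k} exceeds every read length")
    return KmerIndex(k=k, min_count=min_count,
                     counts={km: c for km, c in counts.items() if c >= min_count})


def subtract_by_kmers(reads, index: KmerIndex) -> tuple[list, dict]:
    """Keep reads none of whose k-length windows (either orientation) matches
    an indexed k-mer exactly; no mismatches, no indels.

    Returns (surviving reads, stats); reads shorter than k cannot be screened
    and are dropped with a counted warning.
    """
    k = index.k
    survivors = []
    stats = {"too_short": 0, "removed": 0, "kept": 0}
    for r in reads:
        seq = _seq(r).upper()
        if len(seq) < k:
            stats["too_short"] += 1
            continue
        rc = revcomp(seq)
        hit = any(seq[i : i + k] in index for i in range(len(seq) - k + 1)) or any(
            rc[i : i + k] in index for i in range(len(rc) - k + 1)
        )
        if hit:
            stats["removed"] += 1
        else:
            stats["kept"] += 1
            survivors.append(r)
    return survivors, stats


def assemble_contigs(reads, min_overlap: int = 30) -> list[tuple[str, int]]:
    """Greedy overlap-layout assembly of error-free reads.

    Identical reads collapse first; then the pair with the longest exact
    suffix-prefix overlap >= ``min_overlap`` is merged repeatedly (ties broken
    lexicographically), working downward through overlap lengths.  Contigs
    that end up as substrings of another contig are dropped.  Returns
    (contig sequence, supporting read count) pairs, deterministically ordered.
    """
    seqs = [(_seq(r)).upper() for r in reads]
    if not seqs:
        return []
    if min_overlap >= max(len(s) for s in seqs):
        raise ConfigurationError("min_overlap must be shorter than the reads")
    support = Counter(seqs)
    # stable ids: lexicographic order of the collapsed input reads
    seq_by_id = {f"r{i:06d}": seq for i, seq in enumerate(sorted(support))}
    count_by_id = {cid: support[seq] for cid, seq in seq_by_id.items()}

    # Merge pairs with the longest exact suffix-prefix overlap first, working
    # downward through overlap lengths; ties broken lexicographically by
    # contig id.  A merged contig keeps the left partner's id (its o-prefix is
    # unchanged), so the per-level prefix index stays valid across merges.
    o = max(len(s) for s in seq_by_id.values()) - 1
    while o >= min_overlap:
        changed = True
        while changed:
            changed = False
            by_prefix: dict[str, list[str]] = {}
            for cid, seq in seq_by_id.items():
                if len(seq) >= o:
                    by_prefix.setdefault(seq[:o], []).append(cid)
            for bucket in by_prefix.values():
                bucket.sort()
            for cid in sorted(seq_by_id):
                seq = seq_by_id.get(cid)
                if seq is None or len(seq) < o:
                    continue
                partner = next(
                    (c for c in by_prefix.get(seq[-o:], ())
                     if c != cid and c in seq_by_id),
                    None,
                )
                if partner is None:
                    continue
                seq_by_id[cid] = seq + seq_by_id.pop(partner)[o:]
                count_by_id[cid] += count_by_id.pop(partner)
                changed = True
        o -= 1

    final = sorted((seq, count_by_id[cid]) for cid, seq in seq_by_id.items())
    kept = []
    for seq, count in final:
        if any(seq != other and seq in other for other, _ in final):
            continue
        kept.append((seq, count))
    return kept


def validate_male_specific(
    contigs,
    male_genome: dict[str, str],
    female_genome: dict[str, str],
    male_min_identity: float = 1.0,
    male_min_len_frac: float = 0.9,
    female_sig_identity: float = 0.8,
    female_sig_len_frac: float = 0.5,
    seed_k: int = 15,
    male_aligner: ExactSeedAligner | None = None,
    female_aligner: ExactSeedAligner | None = None,
) -> list[CandidateTranscript]:
    """Assign ACCEPTED / REJECTED_* status to each assembled contig.

    ``contigs`` is a list of sequences or (sequence, support) pairs.  A short
    alignment seed (default 15 nt) keeps moderately diverged female
    homologues findable so their identity can be tested against the
    significance thresholds.
    """
    if not male_genome or not female_genome:
        raise ConfigurationError("male and female genomes must be non-empty")
    if male_aligner is None:
        male_aligner = ExactSeedAligner(male_genome, seed_k=seed_k)
    if female_aligner is None:
        female_aligner = ExactSeedAligner(female_genome, seed_k=seed_k)
    out = []
    for i, item in enumerate(contigs):
        seq, count = item if isinstance(item, tuple) else (item, 1)
        male_hit = male_aligner.best_hit(seq)
        female_hit = female_aligner.best_hit(seq)
        male_ok = (
            male_hit is not None
            and male_hit.identity >= male_min_identity
            and male_hit.aligned_fraction >= male_min_len_frac
        )
        female_present = (
            female_hit is not None
            and female_hit.identity >= female_sig_identity
            and female_hit.aligned_fraction >= female_sig_len_frac
        )
        if not male_ok:
            status = REJECTED_LOW_MALE_IDENTITY
        elif female_present:
            status = REJECTED_FEMALE_PRESENT
        else:
            status = ACCEPTED
        out.append(CandidateTranscript(f"contig_{i:04d}", seq, count, male_hit,
                                       female_hit, status))
    return out


def run_subtraction(
    candidate_reads,
    other_sex_reads,
    candidate_genome: dict[str, str],
    other_genome: dict[str, str],
    k: int = 35,
    min_count: int = 10,
    min_overlap: int = 30,
) -> tuple[list[CandidateTranscript], dict]:
    """The full subtraction chain for one direction (male-candidate by default;
    swap the arguments for the ZW mirror control)."""
    cand = drop_ambiguous(candidate_reads)
    other = drop_ambiguous(other_sex_reads)
    unmapped = filter_genome_mapped(cand, other_genome)
    index = build_kmer_index(other, k=k, min_count=min_count)
    survivors, kstats = subtract_by_kmers(unmapped, index)
    contigs = assemble_contigs(survivors, min_overlap=min_overlap)
    candidates = validate_male_specific(contigs, candidate_genome, other_genome)
    stats = {
        "input_reads": len(cand),
        "after_genome_filter": len(unmapped),
        "after_kmer_filter": len(survivors),
        "kmer_stats": kstats,
        "n_contigs": len(contigs),
        "n_accepted": sum(c.status == ACCEPTED for c in candidates),
    }
    return candidates, stats


def candidates_table(candidates: list[CandidateTranscript]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(dict(
            id=c.id, length=len(c.sequence), support=c.supporting_read_count,
            status=c.status,
            male_identity=c.male_hit.identity if c.male_hit else float("nan"),
            male_len_frac=c.male_hit.aligned_fraction if c.male_hit else float("nan"),
            female_identity=c.female_hit.identity if c.female_hit else float("nan"),
            female_len_frac=c.female_hit.aligned_fraction if c.female_hit else float("nan"),
        ))
    return pd.DataFrame(rows)
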