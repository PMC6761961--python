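"""Synthetic data with known ground truth for the turnover-detection pipeline.

The generator emulates the study design the downstream stages assume:

* a diploid genome whose X carries recombining pseudoautosomal segments (PAR)
  and one or more non-recombining strata with distinct recombination-arrest
  ages; the Y equals the X inside the PAR and is an independently mutated,
  gene-depleted copy elsewhere,
* uniform-coverage error-free short reads from a male and a female individual,
* codon alignments of XY gametologues evolving on a fixed, time-calibrated
  species tree (X and Y identical until the stratum's arrest age),
* TPM expression matrices under full / absent / partial dosage compensation
  with log-normal noise.

All randomness flows from explicit integer seeds; calls are pure functions of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from . import _codon
from .errors import ConfigurationError
from .io import Read

AUTOSOMAL = "AUTOSOMAL"
PAR = "PAR"
X_HEMI = "X_HEMI"

_BASE2INT = {b: i for i, b in enumerate("ACGT")}
_INT2BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

# X/Y transcript identity below which a Y copy counts as male-specific at the
# sequence level (mirrors the "no significant female alignment" threshold).
Y_SPECIFIC_MAX_IDENTITY = 0.8


@dataclass(frozen=True)
class Stratum:
    """A non-recombining block of the X with its recombination-arrest age (Ma)."""

    interval: tuple[int, int]
    arrest_ma: float


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    autosome_lengths: tuple[int, ...] = (500_000, 500_000)
    x_length: int = 500_000
    par_segments: tuple[tuple[int, int], ...] = ((0, 50_000), (450_000, 500_000))
    strata: tuple[Stratum, ...] = (
        Stratum((50_000, 300_000), 62.0),
        Stratum((300_000, 450_000), 20.0),
    )
    y_gene_retention: float | tuple[float, ...] = (0.25, 0.25)
    n_genes: int = 40
    read_length: int = 100
    depth_female: float = 6.0
    depth_male: float = 6.0
    syn_rate: float = 0.003
    nonsyn_rate: float = 0.003
    n_codons_per_gene: int = 300
    dosage_model: str | dict = "partial:1.5"
    tissues: tuple[str, ...] = ("blood", "brain", "heart", "liver", "kidney", "gonad")
    tpm_dispersion: float = 0.5
    rna_depth: float = 30.0
    y_expression_factor: float = 1.0
    error_rate: float = 0.0

    def retention(self, stratum_index: int) -> float:
        r = self.y_gene_retention
        if isinstance(r, (int, float)):
            return float(r)
        return float(r[stratum_index])

    def validate(self) -> "SimConfig":
        for i, length in enumerate(self.autosome_lengths):
            if length <= 0:
                raise ConfigurationError(f"autosome_lengths[{i}] must be > 0")
        if self.x_length <= 0:
            raise ConfigurationError("x_length must be > 0")
        intervals = [(s, e, f"par_segments[{i}]") for i, (s, e) in enumerate(self.par_segments)]
        intervals += [
            (st.interval[0], st.interval[1], f"strata[{i}]") for i, st in enumerate(self.strata)
        ]
        for s, e, name in intervals:
            if not (0 <= s < e <= self.x_length):
                raise ConfigurationError(f"{name} interval ({s}, {e}) outside [0, x_length)")
        ordered = sorted(intervals)
        for (s1, e1, n1), (s2, e2, n2) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise ConfigurationError(f"{n1} and {n2} overlap")
        for i, st in enumerate(self.strata):
            if st.arrest_ma < 0:
                raise ConfigurationError(f"strata[{i}].arrest_ma must be >= 0")
        for i in range(len(self.strata)):
            r = self.retention(i)
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"y_gene_retention[{i}] must be in [0, 1]")
        if self.syn_rate < 0 or self.nonsyn_rate < 0:
            raise ConfigurationError("syn_rate and nonsyn_rate must be >= 0")
        if self.read_length <= 0:
            raise ConfigurationError("read_length must be > 0")
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        for tissue in self.tissues:
            dosage_factor(self.dosage_model, tissue)  # raises on unknown model
        return self


def dosage_factor(model: str | dict, tissue: str) -> float:
    """Per-allele male X upregulation factor: full -> 2, none -> 1, partial(c) -> c."""
    spec = model.get(tissue, model.get("default")) if isinstance(model, dict) else model
    if spec is None:
        raise ConfigurationError(f"dosage_model has no entry for tissue {tissue!r}")
    name, _, arg = str(spec).partition(":")
    name = name.strip().lower()
    if name == "full":
        return 2.0
    if name == "none":
        return 1.0
    if name == "partial":
        try:
            c = float(arg)
        except ValueError:
            raise ConfigurationError(f"dosage_model partial factor {arg!r} is not a number")
        if not 1.0 <= c <= 2.0:
            raise ConfigurationError("dosage_model partial factor must be in [1, 2]")
        return c
    raise ConfigurationError(f"unknown dosage_model {spec!r}")


@dataclass
class Genome:
    """An individual's genome: the haploid assembly plus per-chromosome copy number."""

    name: str
    sequences: dict[str, str]
    ploidy: dict[str, int]

    def haplotypes(self) -> list[tuple[str, str]]:
        return [
            (f"{chrom}.{i}", self.sequences[chrom])
            for chrom in self.sequences
            for i in range(self.ploidy.get(chrom, 0))
        ]


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, used to score every stage."""

    regions: dict[str, list[tuple[int, int, str]]]
    genes: pd.DataFrame
    x_chrom: str = "X"
    y_chrom: str = "Y"
    expected_tpm: dict = field(default_factory=dict)

    @property
    def y_transcript_ids(self) -> set[str]:
        retained = self.genes[(self.genes["y_copy"] == "retained") & self.genes["y_specific"]]
        return {f"{g}_Y" for g in retained["gene_id"]}

    @property
    def gene_strata(self) -> dict[str, tuple[int, float]]:
        out = {}
        for _, row in self.genes.iterrows():
            if row["stratum"]:
                out[row["gene_id"]] = (int(row["stratum"]), float(row["arrest_ma"]))
        return out

    def label_window(self, chrom: str, start: int, end: int) -> str:
        """Majority ground-truth label of a window (ties go to the first region)."""
        best_label, best_overlap = AUTOSOMAL, 0
        for s, e, label in self.regions.get(chrom, []):
            overlap = min(e, end) - max(s, start)
            if overlap > best_overlap:
                best_label, best_overlap = label, overlap
        return best_label

    def to_dict(self) -> dict:
        return {
            "regions": {c: [[s, e, l] for s, e, l in regs] for c, regs in self.regions.items()},
            "genes": self.genes.replace({np.nan: None}).to_dict(orient="records"),
            "x_chrom": self.x_chrom,
            "y_chrom": self.y_chrom,
            "expected_tpm": {"|".join(k): v for k, v in self.expected_tpm.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            regions={c: [tuple(r) for r in regs] for c, regs in d["regions"].items()},
            genes=pd.DataFrame(d["genes"]),
            x_chrom=d["x_chrom"],
            y_chrom=d["y_chrom"],
            expected_tpm={tuple(k.split("|")): v for k, v in d.get("expected_tpm", {}).items()},
        )


def _random_background(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _to_str(arr: np.ndarray) -> str:
    return _INT2BASE[arr].tobytes().decode()


def _from_str(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    out = np.zeros(arr.size, dtype=np.uint8)
    for base, val in _BASE2INT.items():
        out[arr == ord(base)] = val
    return out


def _mutate_sites(arr: np.ndarray, p_sub: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability p_sub (uniform other base)."""
    out = arr.copy()
    mask = rng.random(arr.size) < p_sub
    if mask.any():
        out[mask] = (out[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    return out


def jc_observed_p(d: float) -> float:
    """Expected observed per-site difference after d substitutions/site (JC69)."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def _x_region_table(cfg: SimConfig) -> list[tuple[int, int, str, int, float]]:
    """Tile [0, x_length) with (start, end, label, stratum_index_1based, arrest)."""
    feats = [(s, e, PAR, 0, 0.0) for s, e in cfg.par_segments]
    for i, st in enumerate(cfg.strata):
        feats.append((st.interval[0], st.interval[1], X_HEMI, i + 1, st.arrest_ma))
    feats.sort()
    if cfg.strata:
        oldest = int(np.argmax([st.arrest_ma for st in cfg.strata]))
        gap_label = (X_HEMI, oldest + 1, cfg.strata[oldest].arrest_ma)
    else:
        gap_label = (PAR, 0, 0.0)
    out, cursor = [], 0
    for s, e, label, idx, arrest in feats:
        if s > cursor:
            out.append((cursor, s, *gap_label))
        out.append((s, e, label, idx, arrest))
        cursor = e
    if cursor < cfg.x_length:
        out.append((cursor, cfg.x_length, *gap_label))
    return out


def _place_genes(regions, n_genes, gene_len, rng) -> list[tuple[int, int]]:
    """Place n_genes non-overlapping gene intervals across regions, allocated
    proportionally to region length (largest-remainder rounding)."""
    lengths = np.array([e - s for s, e, *_ in regions], dtype=float)
    if lengths.sum() == 0 or n_genes == 0:
        return [[] for _ in regions]
    quota = n_genes * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[: n_genes - counts.sum()]:
        counts[i] += 1
    placements = []
    for (s, e, *_), count in zip(regions, counts):
        count = min(count, (e - s) // gene_len)
        slack = (e - s) - count * gene_len
        offsets = np.sort(rng.integers(0, slack + 1, size=count))
        placements.append([(s + off + i * gene_len, s + off + (i + 1) * gene_len)
                           for i, off in enumerate(offsets)])
    return placements


def simulate_genome_pair(cfg: SimConfig) -> tuple[Genome, Genome, SimTruth]:
    """Build the male and female genomes and the ground truth that labels them.

    The female is autosomes + two identical X haplotypes; the male is
    autosomes + X + Y.  The Y equals the X inside the PAR; elsewhere it is a
    mutated copy (total divergence ``2 * syn_rate * arrest``, i.e. both
    post-arrest branches collapsed onto the Y haplotype) with each stratum's
    non-retained genes deleted outright.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gene_len = 3 * cfg.n_codons_per_gene
    sequences: dict[str, str] = {}
    gene_rows = []
    regions: dict[str, list[tuple[int, int, str]]] = {}

    # --- autosomes ---
    for a, length in enumerate(cfg.autosome_lengths):
        chrom = f"A{a + 1}"
        if gene_len > length:
            raise ConfigurationError("n_codons_per_gene: gene longer than autosome")
        arr = _random_background(length, rng)
        placements = _place_genes([(0, length, AUTOSOMAL, 0, 0.0)], cfg.n_genes, gene_len, rng)
        for g, (s, e) in enumerate(placements[0]):
            codons = _codon.random_sense_codons(cfg.n_codons_per_gene, rng)
            arr[s:e] = _from_str(_codon.decode_codons(codons))
            gene_rows.append(
                dict(gene_id=f"{chrom}_g{g:03d}", chrom=chrom, start=s, end=e,
                     label=AUTOSOMAL, stratum=0, arrest_ma=np.nan, y_copy=None,
                     y_start=np.nan, y_end=np.nan, y_identity=np.nan, y_specific=False)
            )
        sequences[chrom] = _to_str(arr)
        regions[chrom] = [(0, length, AUTOSOMAL)]

    # --- X ---
    x_regions = _x_region_table(cfg)
    x_arr = _random_background(cfg.x_length, rng)
    placements = _place_genes(x_regions, cfg.n_genes, gene_len, rng)
    x_genes: list[dict] = []
    for region, placed in zip(x_regions, placements):
        _, _, label, stratum_idx, arrest = region
        for s, e in placed:
            codons = _codon.random_sense_codons(cfg.n_codons_per_gene, rng)
            x_arr[s:e] = _from_str(_codon.decode_codons(codons))
            x_genes.append(
                dict(gene_id=f"X_g{len(x_genes):03d}", chrom="X", start=s, end=e,
                     label=label, stratum=stratum_idx,
                     arrest_ma=arrest if stratum_idx else np.nan,
                     y_copy=None, y_start=np.nan, y_end=np.nan,
                     y_identity=np.nan, y_specific=False)
            )
    x_genes.sort(key=lambda g: g["start"])
    sequences["X"] = _to_str(x_arr)
    regions["X"] = [(s, e, label) for s, e, label, *_ in x_regions]

    # --- retention draw per stratum (deterministic rounded counts) ---
    for i in range(len(cfg.strata)):
        members = [g for g in x_genes if g["stratum"] == i + 1]
        n_keep = int(round(cfg.retention(i) * len(members)))
        keep = set(rng.choice(len(members), size=n_keep, replace=False)) if n_keep else set()
        for j, g in enumerate(members):
            g["y_copy"] = "retained" if j in keep else "deleted"
    for g in x_genes:
        if g["label"] == PAR:
            g["y_copy"] = "par"

    # --- Y: walk the X, copying/mutating/deleting ---
    y_parts: list[np.ndarray] = []
    y_cursor = 0
    boundaries = sorted(
        [(g["start"], g["end"], g) for g in x_genes], key=lambda t: t[0]
    )

    def region_at(pos: int):
        for s, e, label, idx, arrest in x_regions:
            if s <= pos < e:
                return label, arrest
        return PAR, 0.0

    def emit_background(lo: int, hi: int):
        nonlocal y_cursor
        pos = lo
        for s, e, label, idx, arrest in x_regions:
            a, b = max(pos, s), min(hi, e)
            if a >= b:
                continue
            seg = x_arr[a:b]
            if label == X_HEMI:
                seg = _mutate_sites(seg, jc_observed_p(2.0 * cfg.syn_rate * arrest), rng)
            y_parts.append(seg)
            y_cursor += b - a

    cursor = 0
    for s, e, g in boundaries:
        emit_background(cursor, s)
        if g["y_copy"] == "par":
            g["y_start"], g["y_end"] = y_cursor, y_cursor + (e - s)
            g["y_identity"] = 1.0
            y_parts.append(x_arr[s:e])
            y_cursor += e - s
        elif g["y_copy"] == "retained":
            codons = _codon.encode_codons(_to_str(x_arr[s:e]))
            evolved = _codon.evolve_codons(
                codons, 2.0 * g["arrest_ma"], cfg.syn_rate, cfg.nonsyn_rate, rng
            )
            y_seq = _from_str(_codon.decode_codons(evolved))
            g["y_start"], g["y_end"] = y_cursor, y_cursor + (e - s)
            g["y_identity"] = float(np.mean(y_seq == x_arr[s:e]))
            g["y_specific"] = g["y_identity"] < Y_SPECIFIC_MAX_IDENTITY
            y_parts.append(y_seq)
            y_cursor += e - s
        # deleted genes contribute nothing to the Y
        cursor = e
    emit_background(cursor, cfg.x_length)
    sequences["Y"] = _to_str(np.concatenate(y_parts)) if y_parts else ""

    gene_rows.extend(x_genes)
    genes = pd.DataFrame(gene_rows)
    truth = SimTruth(regions=regions, genes=genes)

    autosome_names = [f"A{a + 1}" for a in range(len(cfg.autosome_lengths))]
    female = Genome(
        "female",
        {c: sequences[c] for c in autosome_names + ["X"]},
        {**{c: 2 for c in autosome_names}, "X": 2},
    )
    male = Genome(
        "male",
        {c: sequences[c] for c in autosome_names + ["X", "Y"]},
        {**{c: 2 for c in autosome_names}, "X": 1, "Y": 1},
    )
    return male, female, truth


def simulate_reads(
    genome: Genome,
    depth: float,
    read_length: int,
    seed: int,
    error_rate: float = 0.0,
    strand_specific: bool = False,
) -> list[Read]:
    """Uniform reads at ``depth`` fold-coverage per *haplotype copy*.

    Read count per haplotype is ``round(depth * L / read_length)``; qualities
    are a constant placeholder.  A 6x sample of a diploid individual is
    therefore requested as depth 3 per haplotype (see
    :func:`simulate_sample_reads`).
    """
    from .align import revcomp

    haplotypes = genome.haplotypes()
    if not haplotypes:
        raise ConfigurationError("genome is empty")
    if depth <= 0:
        raise ConfigurationError("depth must be > 0")
    shortest = min(len(seq) for _, seq in haplotypes)
    if read_length > shortest:
        raise ConfigurationError(
            f"read_length {read_length} exceeds shortest sequence length {shortest}"
        )
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    qual = "I" * read_length
    for hap_name, seq in haplotypes:
        n = int(round(depth * len(seq) / read_length))
        starts = rng.integers(0, len(seq) - read_length + 1, size=n)
        strands = np.zeros(n, dtype=bool) if strand_specific else rng.random(n) < 0.5
        for i, (start, minus) in enumerate(zip(starts, strands)):
            frag = seq[start : start + read_length]
            if error_rate > 0:
                arr = _mutate_sites(_from_str(frag), error_rate, rng)
                frag = _to_str(arr)
            if minus:
                frag = revcomp(frag)
            reads.append(Read(f"{hap_name}:{start}:{'-' if minus else '+'}:{i}", frag, qual))
    return reads


def simulate_sample_reads(genome: Genome, cfg: SimConfig, sex: str, seed: int) -> list[Read]:
    """DNA-seq sample at the configured individual-level (diploid) coverage."""
    depth = cfg.depth_male if sex == "male" else cfg.depth_female
    return simulate_reads(genome, depth / 2.0, cfg.read_length, seed,
                          error_rate=cfg.error_rate)


def transcriptome(truth: SimTruth, genome: Genome, sex: str) -> Genome:
    """The individual's transcript set (one transcript per gene; Y copies only
    in the male).  Transcripts equal their genomic gene sequence."""
    seqs: dict[str, str] = {}
    for _, g in truth.genes.iterrows():
        chrom = g["chrom"]
        if chrom in genome.sequences:
            seqs[g["gene_id"]] = genome.sequences[chrom][int(g["start"]) : int(g["end"])]
        if sex == "male" and g["y_copy"] in ("retained",):
            seqs[f"{g['gene_id']}_Y"] = genome.sequences[truth.y_chrom][
                int(g["y_start"]) : int(g["y_end"])
            ]
    return Genome(f"{sex}_transcriptome", seqs, {name: 1 for name in seqs})


def simulate_rna_reads(truth: SimTruth, genome: Genome, cfg: SimConfig, sex: str,
                       seed: int) -> list[Read]:
    """Strand-specific RNA-seq reads at uniform per-transcript depth."""
    return simulate_reads(transcriptome(truth, genome, sex), cfg.rna_depth,
                          cfg.read_length, seed, error_rate=cfg.error_rate,
                          strand_specific=True)


# ---------------------------------------------------------------------------
# Gametologue codon alignments on a species tree
# ---------------------------------------------------------------------------

DEFAULT_FOCAL = "Basiliscus_vittatus"
DEFAULT_SPECIES_TREE = "(Basiliscus_vittatus:85.7,Anolis_carolinensis:85.7);"


@dataclass
class GametologueAlignment:
    gene_id: str
    stratum: int
    arrest_ma: float
    sequences: dict[str, str]


def _node_ages(tree: dendropy.Tree) -> dict:
    ages = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            ages[node] = max(
                ages[ch] + (ch.edge.length or 0.0) for ch in node.child_nodes()
            )
    return ages


def simulate_gametologues(
    cfg: SimConfig,
    species_tree: str = DEFAULT_SPECIES_TREE,
    seed: int = 0,
    focal: str = DEFAULT_FOCAL,
    n_per_stratum: tuple[int, ...] | None = None,
) -> list[GametologueAlignment]:
    """Codon alignments of X/Y gametologues plus outgroup orthologues.

    The focal tip is replaced by an (X, Y) cherry whose node sits at the
    stratum's arrest age; all branches evolve under the codon model at the
    configured synonymous/nonsynonymous rates.  No internal stop codons are
    ever introduced.
    """
    cfg.validate()
    tree = dendropy.Tree.get(data=species_tree, schema="newick")
    ages = _node_ages(tree)
    focal_leaf = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label.replace(" ", "_") == focal:
            focal_leaf = leaf
    if focal_leaf is None:
        raise ConfigurationError(f"focal taxon {focal!r} not found in species tree")
    attach_age = ages[focal_leaf.parent_node] if focal_leaf.parent_node else 0.0

    if n_per_stratum is None:
        n_per_stratum = tuple(
            max(1, int(round(cfg.retention(i) * cfg.n_genes))) for i in range(len(cfg.strata))
        )
    rng = np.random.default_rng(seed)
    out: list[GametologueAlignment] = []
    for si, stratum in enumerate(cfg.strata):
        if stratum.arrest_ma > attach_age + 1e-9:
            raise ConfigurationError(
                f"strata[{si}].arrest_ma {stratum.arrest_ma} exceeds the age "
                f"({attach_age}) of the node where {focal} attaches"
            )
        for g in range(n_per_stratum[si]):
            root_seq = _codon.random_sense_codons(cfg.n_codons_per_gene, rng)
            seqs: dict[str, str] = {}

            def descend(node, seq):
                for child in node.child_nodes():
                    branch = child.edge.length or 0.0
                    if child is focal_leaf:
                        at_arrest = _codon.evolve_codons(
                            seq, branch - stratum.arrest_ma, cfg.syn_rate,
                            cfg.nonsyn_rate, rng)
                        for tip in ("X", "Y"):
                            seqs[tip] = _codon.decode_codons(
                                _codon.evolve_codons(at_arrest, stratum.arrest_ma,
                                                     cfg.syn_rate, cfg.nonsyn_rate, rng))
                    else:
                        evolved = _codon.evolve_codons(seq, branch, cfg.syn_rate,
                                                       cfg.nonsyn_rate, rng)
                        if child.is_leaf():
                            seqs[child.taxon.label.replace(" ", "_")] = \
                                _codon.decode_codons(evolved)
                        else:
                            descend(child, evolved)

            descend(tree.seed_node, root_seq)
            out.append(GametologueAlignment(
                gene_id=f"s{si + 1}_g{g:03d}", stratum=si + 1,
                arrest_ma=stratum.arrest_ma, sequences=seqs))
    return out


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def make_expression_truth(n_x: int, n_autosome: int = 0, n_y: int = 0,
                          arrest_ma: float = 62.0, seed: int = 0) -> SimTruth:
    """A minimal truth table for expression-only simulations (no genomes)."""
    rows = []
    for i in range(n_x):
        has_y = i < n_y
        rows.append(dict(gene_id=f"X_g{i:03d}", chrom="X", start=i, end=i + 1,
                         label=X_HEMI, stratum=1 if has_y else 0,
                         arrest_ma=arrest_ma if has_y else np.nan,
                         y_copy="retained" if has_y else "deleted",
                         y_start=np.nan, y_end=np.nan,
                         y_identity=0.7 if has_y else np.nan, y_specific=has_y))
    for i in range(n_autosome):
        rows.append(dict(gene_id=f"A1_g{i:03d}", chrom="A1", start=i, end=i + 1,
                         label=AUTOSOMAL, stratum=0, arrest_ma=np.nan, y_copy=None,
                         y_start=np.nan, y_end=np.nan, y_identity=np.nan,
                         y_specific=False))
    return SimTruth(regions={"X": [(0, max(n_x, 1), X_HEMI)],
                             "A1": [(0, max(n_autosome, 1), AUTOSOMAL)]},
                    genes=pd.DataFrame(rows))


def simulate_expression(truth: SimTruth, cfg: SimConfig, seed: int):
    """TPM matrix with log-normal noise around construction-time means.

    Per tissue, a hemizygous X gene's male mean is its single allele scaled by
    the dosage factor (full -> 2, none -> 1, partial(c) -> c); the female keeps
    both alleles.  Retained Y gametologues appear as extra male-only rows at
    ``y_expression_factor`` times one allele.  Returns an
    :class:`~neoxy.dosage.ExpressionMatrix` and records the noise-free means
    in ``truth.expected_tpm``.
    """
    from .dosage import ExpressionMatrix

    cfg.validate()
    if not cfg.tissues:
        raise ConfigurationError("tissues must be non-empty")
    rng = np.random.default_rng(seed)
    sigma = cfg.tpm_dispersion
    samples = [(sex, tissue) for sex in ("female", "male") for tissue in cfg.tissues]
    sample_ids = [f"{sex}_{tissue}" for sex, tissue in samples]

    gene_ids, classes, means = [], [], {}
    for _, g in truth.genes.iterrows():
        gid, label = g["gene_id"], g["label"]
        base = {t: float(rng.lognormal(np.log(20.0), 1.0)) for t in cfg.tissues}
        gene_ids.append(gid)
        classes.append("X" if label == X_HEMI else ("PAR" if label == PAR else "AUTOSOME"))
        for tissue in cfg.tissues:
            mu = base[tissue]
            if label == X_HEMI:
                factor = dosage_factor(cfg.dosage_model, tissue)
                means[(gid, "female", tissue)] = mu
                means[(gid, "male", tissue)] = mu / 2.0 * factor
            else:
                means[(gid, "female", tissue)] = mu
                means[(gid, "male", tissue)] = mu
        if g["y_copy"] == "retained":
            ygid = f"{gid}_Y"
            gene_ids.append(ygid)
            classes.append("Y")
            for tissue in cfg.tissues:
                means[(ygid, "female", tissue)] = 0.0
                means[(ygid, "male", tissue)] = base[tissue] / 2.0 * cfg.y_expression_factor

    values = np.zeros((len(gene_ids), len(samples)))
    for j, (sex, tissue) in enumerate(samples):
        noise = rng.lognormal(0.0, sigma, size=len(gene_ids))
        values[:, j] = [means[(gid, sex, tissue)] for gid in gene_ids] * noise
    truth.expected_tpm = {
        (gid, sex, tissue): means[(gid, sex, tissue)]
        for gid in gene_ids for sex, tissue in samples
    }
    matrix = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    sample_meta = pd.DataFrame(
        {"sex": [s for s, _ in samples], "tissue": [t for _, t in samples],
         "species": DEFAULT_FOCAL}, index=sample_ids)
    gene_meta = pd.DataFrame(
        {"chrom_class": classes,
         "orthogroup": [g[:-2] if g.endswith("_Y") else g for g in gene_ids]},
        index=gene_ids)
    return ExpressionMatrix(matrix, sample_meta, gene_meta)
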