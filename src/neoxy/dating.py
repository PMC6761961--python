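"""Gametologue divergence, strata, and the age of the XY system.

Pairwise synonymous divergence (dS) is estimated by Nei–Gojobori (1986)
counting with a Jukes–Cantor multiple-hit correction.  Strata are assigned
from outgroup Y-presence evidence when available (presence in the second
corytophanid species implies arrest before that split, i.e. stratum 1), with
the dS > 0.2 rule as the provisional call otherwise.  Dating follows the
concatenate / codon-bootstrap / fixed-topology branch-length / ultrametric
calibration recipe: branch lengths by non-negative least squares against the
pairwise dS matrix, a strict-clock ultrametricization, and a 95% CI from the
bootstrap replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import nnls

from ._codon import IS_STOP, SD_TABLE, SYN_SITES, encode_codons
from .errors import (
    ConfigurationError,
    InternalStopError,
    LengthMismatchError,
    SaturationError,
)

STRATUM_DS_THRESHOLD = 0.2


@dataclass
class GametologueRecord:
    """One XY pair: coding alignment, dS, outgroup-presence evidence, stratum."""

    gene_id: str
    x_seq: str | None = None
    y_seq: str | None = None
    ds: float | None = None
    outgroup_presence: bool | None = None
    stratum: int | str = "unassigned"


@dataclass
class DatedTree:
    """Calibrated strict-clock tree with the XY-origin estimate."""

    tree: dendropy.Tree
    node_ages_ma: dict[str, float]
    calibration_node: tuple[str, str]
    calibration_age_ma: float
    xy_age_ma: float
    ci95_ma: tuple[float, float] | None = None
    bootstrap_ages_ma: list[float] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = [
            ("xy_age_ma", self.xy_age_ma),
            ("ci95_low_ma", self.ci95_ma[0] if self.ci95_ma else float("nan")),
            ("ci95_high_ma", self.ci95_ma[1] if self.ci95_ma else float("nan")),
            ("calibration_age_ma", self.calibration_age_ma),
            ("n_bootstrap", len(self.bootstrap_ages_ma)),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])

    def to_dict(self) -> dict:
        return {
            "xy_age_ma": self.xy_age_ma,
            "ci95_ma": list(self.ci95_ma) if self.ci95_ma else None,
            "calibration": {
                "node": list(self.calibration_node),
                "age_ma": self.calibration_age_ma,
            },
            "node_ages_ma": self.node_ages_ma,
        }


def _validate_pair(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    if len(a) != len(b) or len(a) % 3:
        raise LengthMismatchError(
            f"aligned CDS lengths {len(a)} and {len(b)} must be equal multiples of 3"
        )
    ca, cb = encode_codons(a), encode_codons(b)
    for name, codons in (("first", ca), ("second", cb)):
        coding = codons[codons >= 0]
        if coding.size and IS_STOP[coding].any():
            raise InternalStopError(f"{name} sequence contains an internal stop codon")
    return ca, cb


def ng86_counts(a: str, b: str) -> tuple[float, float]:
    """(mean synonymous sites S, synonymous differences Sd) for an aligned CDS
    pair.  Ambiguous or gapped codons are excluded pairwise."""
    ca, cb = _validate_pair(a, b)
    ok = (ca >= 0) & (cb >= 0)
    ca, cb = ca[ok], cb[ok]
    if ca.size == 0:
        raise LengthMismatchError("no comparable codons in the alignment")
    s_sites = float((SYN_SITES[ca].sum() + SYN_SITES[cb].sum()) / 2.0)
    sd = float(SD_TABLE[ca, cb].sum())
    return s_sites, sd


def pairwise_ds(cds_a: str, cds_b: str) -> float:
    """NG86 synonymous divergence with Jukes-Cantor correction.

    dS = -(3/4) ln(1 - 4 pS / 3) with pS = Sd / S; raises
    :class:`SaturationError` when pS >= 3/4.
    """
    s_sites, sd = ng86_counts(cds_a, cds_b)
    if s_sites <= 0:
        raise LengthMismatchError("alignment has no synonymous sites")
    p_s = sd / s_sites
    if p_s >= 0.75:
        raise SaturationError(f"pS = {p_s:.3f} >= 0.75: synonymous sites saturated")
    return float(-0.75 * np.log1p(-4.0 * p_s / 3.0))


def classify_stratum(
    record: GametologueRecord, ds_threshold: float = STRATUM_DS_THRESHOLD
) -> GametologueRecord:
    """Assign a stratum: outgroup Y-presence evidence is authoritative
    (present -> stratum 1, absent -> stratum 2); the dS threshold is the
    provisional call when presence is unknown."""
    if record.outgroup_presence is not None:
        record.stratum = 1 if record.outgroup_presence else 2
    elif record.ds is not None:
        record.stratum = 1 if record.ds > ds_threshold else 2
    else:
        record.stratum = "unassigned"
    return record


def concatenate(alignments: list[dict[str, str]]) -> dict[str, str]:
    """Concatenate per-gene alignments sharing a taxon set."""
    if not alignments:
        raise ConfigurationError("no alignments to concatenate")
    taxa = set(alignments[0])
    for aln in alignments[1:]:
        if set(aln) != taxa:
            raise ConfigurationError("alignments do not share a taxon set")
    return {t: "".join(aln[t] for aln in alignments) for t in sorted(taxa)}


def bootstrap_concatenation(
    alignments: list[dict[str, str]], n_rounds: int = 100, seed: int = 0
) -> list[dict[str, str]]:
    """Codon-column bootstrap replicates of the concatenated alignment, each
    with the original length (codon-wise resampling preserves reading frame)."""
    concat = concatenate(alignments)
    n_codons = len(next(iter(concat.values()))) // 3
    if n_codons == 0:
        raise ConfigurationError("empty concatenation")
    rng = np.random.default_rng(seed)
    taxa = sorted(concat)
    codons = {t: [concat[t][3 * i : 3 * i + 3] for i in range(n_codons)] for t in taxa}
    replicates = []
    for _ in range(n_rounds):
        cols = rng.integers(0, n_codons, size=n_codons)
        replicates.append({t: "".join(codons[t][c] for c in cols) for t in taxa})
    return replicates


def ds_matrix(alignment: dict[str, str]) -> pd.DataFrame:
    """Pairwise dS matrix over all taxa of one alignment."""
    taxa = sorted(alignment)
    mat = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            try:
                d = pairwise_ds(alignment[a], alignment[b])
            except SaturationError as exc:
                raise SaturationError(f"pair ({a}, {b}): {exc}") from exc
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat


def gametologue_topology(species_tree: str, focal: str = "Basiliscus_vittatus",
                         xy_tips: tuple[str, str] = ("X", "Y")) -> str:
    """Replace the focal species' tip in a Newick species tree with an
    (X, Y) cherry — the fixed topology on which gametologue branch lengths
    are fitted."""
    tree = dendropy.Tree.get(data=species_tree, schema="newick")
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label.replace(" ", "_") == focal:
            taxa = tree.taxon_namespace
            leaf.taxon = None
            for tip in xy_tips:
                child = leaf.new_child(edge_length=None)
                child.taxon = taxa.new_taxon(tip)
            return tree.as_string(schema="newick", suppress_rooting=True).strip()
    raise ConfigurationError(f"focal taxon {focal!r} not found in species tree")


def _tree_from_newick(topology) -> dendropy.Tree:
    if isinstance(topology, dendropy.Tree):
        tree = topology.clone(depth=1)
    else:
        tree = dendropy.Tree.get(data=topology, schema="newick")
    tree.is_rooted = True
    return tree


def fit_branch_lengths(topology, distances: pd.DataFrame) -> dendropy.Tree:
    """Least-squares branch lengths on a fixed topology.

    Minimizes sum((d_ij - path_ij)^2) subject to non-negative branch lengths
    (solved directly by NNLS, which is the clamp-to-zero refit).
    """
    tree = _tree_from_newick(topology)
    taxa = {leaf.taxon.label.replace(" ", "_"): leaf for leaf in tree.leaf_node_iter()}
    names = sorted(distances.index)
    missing = set(names) - set(taxa)
    if missing:
        raise ConfigurationError(f"topology lacks taxa {sorted(missing)}")
    edges = [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
    edge_idx = {id(e): i for i, e in enumerate(edges)}

    def path_edges(leaf_a, leaf_b):
        anc_a = []
        node = leaf_a
        while node is not None:
            anc_a.append(node)
            node = node.parent_node
        anc_set = {id(n): i for i, n in enumerate(anc_a)}
        node, path_b = leaf_b, []
        while id(node) not in anc_set:
            path_b.append(node.edge)
            node = node.parent_node
        path_a = [n.edge for n in anc_a[: anc_set[id(node)]]]
        return path_a + path_b

    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    design = np.zeros((len(pairs), len(edges)))
    target = np.zeros(len(pairs))
    for r, (a, b) in enumerate(pairs):
        for e in path_edges(taxa[a], taxa[b]):
            design[r, edge_idx[id(e)]] = 1.0
        target[r] = distances.loc[a, b]
    lengths, _ = nnls(design, target)
    for e, val in zip(edges, lengths):
        e.length = float(val)
    return tree


def _tip_path_lengths(tree: dendropy.Tree) -> pd.DataFrame:
    pdm = tree.phylogenetic_distance_matrix()
    names = sorted(t.label.replace(" ", "_") for t in tree.taxon_namespace)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for t1 in tree.taxon_namespace:
        for t2 in tree.taxon_namespace:
            if t1 is not t2:
                mat.loc[
                    t1.label.replace(" ", "_"), t2.label.replace(" ", "_")
                ] = pdm.patristic_distance(t1, t2)
    return mat


def _clock_heights(tree: dendropy.Tree, distances: pd.DataFrame) -> dict:
    """Strict-clock node heights: half the mean tip-tip distance across each
    internal node's child subtrees (WPGMA on the fixed topology).  Children
    deeper than their parent are clamped."""
    heights: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            heights[id(node)] = 0.0
            continue
        subtrees = [
            [l.taxon.label.replace(" ", "_") for l in ch.leaf_iter()]
            for ch in node.child_nodes()
        ]
        cross = [
            distances.loc[a, b]
            for i, g1 in enumerate(subtrees)
            for g2 in subtrees[i + 1 :]
            for a in g1
            for b in g2
        ]
        h = float(np.mean(cross)) / 2.0
        h = max(h, max(heights[id(ch)] for ch in node.child_nodes()))
        heights[id(node)] = h
    return heights


def _find_mrca(tree: dendropy.Tree, labels: tuple[str, str]):
    wanted = {l.replace(" ", "_") for l in labels}
    start = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label.replace(" ", "_") in wanted:
            start = leaf
            break
    if start is None:
        raise ConfigurationError(f"calibration taxa {labels} not found in topology")
    node = start
    while node is not None:
        below = {
            l.taxon.label.replace(" ", "_") for l in node.leaf_iter() if l.taxon is not None
        }
        if wanted <= below:
            return node
        node = node.parent_node
    raise ConfigurationError(f"calibration taxa {labels} not found in topology")


def calibrate_and_date(
    ds_tree: dendropy.Tree,
    calibration_node: tuple[str, str],
    calibration_age_ma: float,
    xy_tips: tuple[str, str] = ("X", "Y"),
    bootstrap_trees: list[dendropy.Tree] | None = None,
) -> DatedTree:
    """Ultrametricize by a strict clock, pin the calibration node to its age,
    and read off the X/Y split age; the 95% CI comes from the bootstrap
    replicates' ages."""

    def xy_age_of(tree: dendropy.Tree) -> tuple[float, dict[str, float]]:
        dist = _tip_path_lengths(tree)
        heights = _clock_heights(tree, dist)
        calib = _find_mrca(tree, calibration_node)
        h_calib = heights[id(calib)]
        if h_calib <= 0:
            raise ConfigurationError("calibration node has zero clock height")
        scale = calibration_age_ma / h_calib
        xy_node = _find_mrca(tree, xy_tips)
        ages = {}
        for node in tree.postorder_internal_node_iter():
            label = ",".join(
                sorted(l.taxon.label.replace(" ", "_") for l in node.leaf_iter())
            )
            ages[label] = heights[id(node)] * scale
        xy_age = heights[id(xy_node)] * scale
        if xy_age > heights[id(calib)] * scale + 1e-9 and not _is_ancestor(calib, xy_node):
            raise ConfigurationError(
                "X/Y split older than the calibration node: tree logic violated"
            )
        return xy_age, ages

    xy_age, ages = xy_age_of(ds_tree)
    boot_ages = []
    if bootstrap_trees:
        for bt in bootstrap_trees:
            boot_ages.append(xy_age_of(bt)[0])
    ci = (
        (float(np.percentile(boot_ages, 2.5)), float(np.percentile(boot_ages, 97.5)))
        if boot_ages
        else None
    )
    return DatedTree(
        tree=ds_tree,
        node_ages_ma=ages,
        calibration_node=calibration_node,
        calibration_age_ma=calibration_age_ma,
        xy_age_ma=xy_age,
        ci95_ma=ci,
        bootstrap_ages_ma=boot_ages,
    )


def _is_ancestor(node, other) -> bool:
    cur = other
    while cur is not None:
        if cur is node:
            return True
        cur = cur.parent_node
    return False


def rescale_age(age_ma: float, old_calibration_ma: float, new_calibration_ma: float) -> float:
    """Node ages scale linearly with the calibration age under a strict clock."""
    if old_calibration_ma <= 0:
        raise ConfigurationError("old_calibration_ma must be > 0")
    return age_ma * new_calibration_ma / old_calibration_ma


def date_xy_system(
    alignments: list[dict[str, str]],
    topology: str,
    calibration_node: tuple[str, str],
    calibration_age_ma: float,
    n_bootstrap: int = 100,
    seed: int = 0,
    xy_tips: tuple[str, str] = ("X", "Y"),
) -> DatedTree:
    """Concatenate stratum-1 gametologue alignments, bootstrap codon columns,
    fit dS branch lengths per replicate, average them, calibrate, and return
    the XY-origin age with its bootstrap 95% CI."""
    replicates = bootstrap_concatenation(alignments, n_rounds=n_bootstrap, seed=seed)
    boot_trees = [fit_branch_lengths(topology, ds_matrix(rep)) for rep in replicates]
    # average branch lengths over replicates on the shared topology
    mean_tree = _tree_from_newick(topology)
    edge_sums = None
    for bt in boot_trees:
        lengths = np.array([
            e.length or 0.0
            for e in bt.preorder_edge_iter()
            if e.head_node is not bt.seed_node
        ])
        edge_sums = lengths if edge_sums is None else edge_sums + lengths
    mean_lengths = edge_sums / len(boot_trees)
    for e, val in zip(
        (e for e in mean_tree.preorder_edge_iter() if e.head_node is not mean_tree.seed_node),
        mean_lengths,
    ):
        e.length = float(val)
    return calibrate_and_date(
        mean_tree, calibration_node, calibration_age_ma,
        xy_tips=xy_tips, bootstrap_trees=boot_trees,
    )
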