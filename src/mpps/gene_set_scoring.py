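"""Gene-set catalogs and single-sample GSEA (ssGSEA) pathway scoring.

A pathway catalog (e.g. the KEGG metabolic pathways) is read from a GMT
file, and each pathway is scored in each sample by a rank-weighted running
sum over that sample's expression ranking. Scores are the *sum* of the
running difference between the weighted in-set ECDF and the uniform
out-of-set ECDF (the single-sample variant), not the maximum deviation.

Scoring depends on each sample's gene ranking only, so any strictly
increasing per-sample transform of expression (a platform effect) leaves
the scores unchanged — the property the downstream pair features rely on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mpps")

__all__ = ["GeneSetCollection", "PathwayScores", "read_gmt", "ssgsea_scores"]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional free-text descriptions.

    `sets` maps set name -> ordered list of unique gene IDs; insertion
    order is the catalog order used downstream for canonical pair
    orientation.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                self.sets[name] = list(dict.fromkeys(genes))

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class PathwayScores:
    """Pathways x samples ssGSEA score matrix.

    `set_sizes` records, per pathway, how many catalog genes were present in
    the expression matrix the scores were computed from.
    """

    scores: pd.DataFrame
    normalized: bool
    set_sizes: pd.Series

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated name, description, genes.

    Duplicate genes within a set are dropped keeping the first occurrence;
    duplicate set names or gene-less lines are errors.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "expected name, description and at least one gene"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise ValueError(f"{path}: line {lineno} ({name!r}) lists no genes")
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name {name!r}")
            sets[name] = list(dict.fromkeys(genes))
            descriptions[name] = desc
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def _validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in expression matrix: {dups[:5]}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in expression matrix: {dups[:5]}")
    values = expr.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-finite values")
    return expr


def ssgsea_scores(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    min_size: int = 5,
    normalize: bool = True,
) -> PathwayScores:
    """Score every gene set in every sample by the ssGSEA running sum.

    Per sample, genes are ranked by expression (largest value = largest
    rank; ties broken by gene ID, lexicographically smaller IDs ranking
    higher). Walking genes in descending rank order, the score of set S is

        sum_k [ P_in(k) - P_out(k) ]

    where P_in is the rank^alpha-weighted cumulative fraction of in-set
    genes seen so far and P_out the uniform cumulative fraction of
    out-of-set genes. Sets with fewer than `min_size` genes present in
    `expr` are dropped with a warning; a set covering the whole gene
    universe is degenerate and an error.

    With `normalize=True` the full score matrix is affinely rescaled so its
    global minimum maps to 0 and maximum to 1; this preserves within-sample
    score ordering, so downstream pair features are unaffected.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {alpha}")
    if min_size < 1:
        raise ValueError("min_size must be a positive integer")
    expr = _validate_expression(expr)

    universe = pd.Index(expr.index)
    n_genes = len(universe)

    kept: dict[str, np.ndarray] = {}
    sizes: dict[str, int] = {}
    for name, genes in sets.sets.items():
        member = universe.isin(genes)
        size = int(member.sum())
        if size >= n_genes:
            raise ValueError(f"gene set {name!r} covers the entire gene universe")
        if size < min_size:
            logger.warning(
                "dropping pathway %r: only %d of %d genes present (min_size=%d)",
                name, size, len(genes), min_size,
            )
            continue
        kept[name] = member
        sizes[name] = size
    if not kept:
        raise ValueError("no gene set meets min_size after intersection with the expression matrix")

    # Deterministic ranking: sort rows lexicographically by gene ID first,
    # then a stable descending argsort per sample breaks expression ties in
    # favour of the lexicographically smaller ID (it gets the higher rank).
    gene_order = np.argsort(universe.to_numpy().astype(str), kind="stable")
    values = expr.to_numpy(dtype=float)[gene_order]
    member_rows = {name: m[gene_order] for name, m in kept.items()}

    # Column s of `desc` lists gene row-positions in descending expression order.
    desc = np.argsort(-values, axis=0, kind="stable")
    # rank at walk position k (0-based) is n_genes - k, identical for all samples
    rank_w = (np.arange(n_genes, 0, -1, dtype=float)) ** alpha

    n_samples = values.shape[1]
    out = np.empty((len(kept), n_samples))
    for row, (name, member) in enumerate(member_rows.items()):
        inset = member[desc]  # (genes, samples) walk-order membership
        w = np.where(inset, rank_w[:, None], 0.0)
        p_in = np.cumsum(w, axis=0) / w.sum(axis=0)
        p_out = np.cumsum(~inset, axis=0) / float(n_genes - sizes[name])
        out[row] = (p_in - p_out).sum(axis=0)

    scores = pd.DataFrame(out, index=list(kept), columns=expr.columns)
    if normalize:
        lo = out.min()
        hi = out.max()
        if hi > lo:
            scores = (scores - lo) / (hi - lo)
        else:
            logger.warning("score matrix is constant; normalization maps everything to 0")
            scores = scores - lo
    return PathwayScores(scores=scores, normalized=normalize, set_sizes=pd.Series(sizes))
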