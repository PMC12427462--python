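"""Compositional preprocessing: relative abundance, rare-taxon filtering,
rarefaction and rank aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import AbundanceTable, ValidationError

__all__ = [
    "relative_abundance",
    "filter_rare_taxa",
    "rarefy",
    "aggregate_taxa",
]


def relative_abundance(table: AbundanceTable) -> pd.DataFrame:
    """Row-normalized proportions (samples x taxa); each row sums to 1."""
    totals = table.totals()
    if (totals == 0).any():
        raise ValidationError("zero-total sample")  # unreachable for a valid table
    return table.counts.div(totals, axis=0)


def filter_rare_taxa(table: AbundanceTable, threshold: float = 1e-5,
                     basis: str = "mean") -> AbundanceTable:
    """Drop taxa below a relative-abundance threshold; samples unchanged.

    The default basis is the mean relative abundance across all samples:
    a taxon is retained iff mean(relabund) >= ``threshold``. Alternative
    bases: ``max`` (retained iff its maximum across samples reaches the
    threshold — the laxest convention) and ``per-sample`` (retained iff it
    reaches the threshold in every sample in which it occurs at all — the
    strictest).
    """
    if not (0 < threshold < 1):
        raise ValidationError(f"threshold must be in (0,1), got {threshold}")
    rel = relative_abundance(table)
    if basis == "mean":
        keep = rel.mean(axis=0) >= threshold
    elif basis == "max":
        keep = rel.max(axis=0) >= threshold
    elif basis == "per-sample":
        masked = rel.where(rel > 0)
        keep = masked.min(axis=0) >= threshold
    else:
        raise ValidationError(f"unknown filter basis {basis!r}")
    if not keep.any():
        raise ValidationError("filter removed every taxon")
    return AbundanceTable(table.counts.loc[:, keep], rank=table.rank)


def rarefy(table: AbundanceTable, depth: int | None = None, seed: int = 0) -> AbundanceTable:
    """Subsample every sample without replacement to a common depth.

    ``depth`` defaults to the minimum per-sample total. Sampling is
    hypergeometric (reads drawn without replacement from the observed pool),
    deterministic for a given seed.
    """
    totals = table.totals()
    if depth is None:
        depth = int(totals.min())
    depth = int(depth)
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    too_shallow = totals[totals < depth]
    if len(too_shallow):
        raise ValidationError(
            f"depth {depth} exceeds totals of samples: {list(too_shallow.index)}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for i, row in enumerate(table.counts.to_numpy()):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    df = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return AbundanceTable(df, rank=table.rank)


def aggregate_taxa(table: AbundanceTable, mapping: dict[str, str],
                   rank: str) -> AbundanceTable:
    """Sum counts of taxa sharing a parent (e.g. species -> genus).

    ``mapping`` sends every taxon id in the table to its parent id at the
    target ``rank``; unmapped taxa are an error.
    """
    missing = [t for t in table.taxon_ids if t not in mapping]
    if missing:
        raise ValidationError(f"taxa without a parent mapping: {missing[:5]}")
    grouped = table.counts.T.groupby(
        table.counts.columns.map(mapping)).sum().T
    return AbundanceTable(grouped, rank=rank)
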