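"""Abundance-weighted functional potential of a community.

Each species contributes its relative abundance to every functional
feature (KEGG KO, KEGG pathway, CAZy family) carried by any of its
genomes, provided the species exceeds a per-sample inclusion threshold
(default 1e-4). The result is an accumulated-potential table per sample:
with binary feature presence and relative-abundance weights every value
lies in [0, 1]. Weights are NOT re-closed after the threshold cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AbundanceTable, GenomeAnnotation, ValidationError
from .profile import relative_abundance

__all__ = ["species_feature_union", "compile_potential", "FunctionalPotentialTable"]

_TYPE_ATTR = {
    "KO": "kegg_kos",
    "PATHWAY": "kegg_pathways",
    "CAZY": "cazy_families",
}


@dataclass
class FunctionalPotentialTable:
    """Samples x features table of accumulated weighted potential.

    ``values`` has a (feature_type, feature_id) column MultiIndex.
    """

    values: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack([0, 1], future_stack=True).reset_index()
        long.columns = ["sample_id", "feature_type", "feature_id", "value"]
        return long.sort_values(["sample_id", "feature_type", "feature_id"]).reset_index(drop=True)

    def subset(self, feature_type: str, feature_ids=None) -> pd.DataFrame:
        """Plain samples x feature_id frame for one feature type."""
        block = self.values[feature_type]
        if feature_ids is not None:
            feature_ids = [f for f in feature_ids if f in block.columns]
            block = block.loc[:, feature_ids]
        return block


def species_feature_union(annotations: list[GenomeAnnotation]) -> dict[str, dict[str, frozenset[str]]]:
    """Per species, the union of its genomes' feature sets by feature type."""
    out: dict[str, dict[str, set]] = {}
    for ann in annotations:
        entry = out.setdefault(ann.species_id, {t: set() for t in _TYPE_ATTR})
        for ftype, attr in _TYPE_ATTR.items():
            entry[ftype] |= getattr(ann, attr)
    return {s: {t: frozenset(v) for t, v in d.items()} for s, d in out.items()}


def compile_potential(table: AbundanceTable,
                      features: dict[str, dict[str, frozenset[str]]],
                      inclusion_threshold: float = 1e-4) -> FunctionalPotentialTable:
    """Accumulate per-sample weighted functional potential.

    A species contributes in a sample iff its relative abundance in THAT
    sample exceeds ``inclusion_threshold``; it then adds its relative
    abundance to each feature it carries. Species without annotations
    contribute nothing.
    """
    if not (0 <= inclusion_threshold < 1):
        raise ValidationError(
            f"inclusion threshold must be in [0,1), got {inclusion_threshold}")
    rel = relative_abundance(table)
    weights = rel.where(rel > inclusion_threshold, 0.0).to_numpy()

    # feature universe, ordered (type, id)
    columns: list[tuple[str, str]] = []
    for ftype in sorted(_TYPE_ATTR):
        ids = set()
        for d in features.values():
            ids |= d.get(ftype, frozenset())
        columns.extend((ftype, f) for f in sorted(ids))
    if not columns:
        raise ValidationError("no functional features found in the annotations")
    col_index = {c: j for j, c in enumerate(columns)}

    # species x feature indicator, aligned to the table's taxa
    indicator = np.zeros((len(table.taxon_ids), len(columns)))
    for i, sp in enumerate(table.taxon_ids):
        d = features.get(sp)
        if not d:
            continue
        for ftype, feats in d.items():
            for f in feats:
                indicator[i, col_index[(ftype, f)]] = 1.0

    values = weights @ indicator
    df = pd.DataFrame(values, index=rel.index,
                      columns=pd.MultiIndex.from_tuples(columns,
                                                        names=["feature_type", "feature_id"]))
    return FunctionalPotentialTable(values=df)
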