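"""Readers, writers and validated domain types for trial tables.

All tabular interchange is plain TSV (tab-separated, UTF-8, header row).
Internal ordering of sample and taxon identifiers is lexicographic so that
every parse of the same data — wide, long or Bracken dialect, in any row
order — yields byte-identical downstream output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "AbundanceTable",
    "GenomeAnnotation",
    "TrialDesign",
    "PalatabilityRecord",
    "DigestibilityRecord",
    "read_abundance_table",
    "read_genome_annotations",
    "write_genome_annotations",
    "write_abundance_table",
    "write_result_table",
]

RANKS = ("species", "genus", "family", "phylum")
FEATURE_TYPES = ("EC", "KO", "PATHWAY", "CAZY")


class ValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


class AbundanceTable:
    """Samples x taxa table of non-negative integer read counts.

    Parameters
    ----------
    counts : DataFrame
        Rows indexed by sample id, columns by taxon id. Reordered
        lexicographically on construction.
    rank : str
        Taxonomic rank of the columns; one of ``species``, ``genus``,
        ``family``, ``phylum``.
    """

    def __init__(self, counts: pd.DataFrame, rank: str = "species"):
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dup}")
        values = counts.to_numpy()
        if values.size == 0:
            raise ValidationError("empty abundance table")
        if np.isnan(values.astype(float)).any():
            raise ValidationError("missing values are not permitted in count tables")
        if (values < 0).any():
            rows = counts.index[(values < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative counts in samples: {rows}")
        frac = np.mod(values.astype(float), 1)
        if (frac != 0).any():
            raise ValidationError("counts must be integers")
        totals = values.sum(axis=1)
        if (totals == 0).any():
            empty = counts.index[totals == 0].tolist()
            raise ValidationError(f"samples with zero total counts: {empty}")
        ordered = counts.astype(np.int64)
        ordered = ordered.sort_index(axis=0).sort_index(axis=1)
        ordered.index.name = "sample_id"
        ordered.columns.name = "taxon_id"
        self.counts = ordered
        self.rank = rank

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    def totals(self) -> pd.Series:
        """Per-sample read totals."""
        return self.counts.sum(axis=1)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return self.rank == other.rank and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        n, m = self.counts.shape
        return f"AbundanceTable(rank={self.rank!r}, samples={n}, taxa={m})"


@dataclass(frozen=True)
class GenomeAnnotation:
    """Feature annotation of a single genome assigned to a parent species."""

    genome_id: str
    species_id: str
    ec_numbers: frozenset[str] = frozenset()
    kegg_kos: frozenset[str] = frozenset()
    kegg_pathways: frozenset[str] = frozenset()
    cazy_families: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.species_id:
            raise ValidationError(f"genome {self.genome_id!r} has empty species_id")
        for name in ("ec_numbers", "kegg_kos", "kegg_pathways", "cazy_families"):
            object.__setattr__(self, name, frozenset(getattr(self, name)))


class TrialDesign:
    """Longitudinal trial metadata: one row per (cat, timepoint) sample.

    Invariants: (cat_id, timepoint_day) unique, diet constant within cat,
    sample_id maps to at most one row, body weight positive.
    """

    COLUMNS = ("cat_id", "sex", "diet", "dose_mg_per_kg",
               "timepoint_day", "body_weight_kg", "sample_id")
    DIETS = ("CD", "T150", "T300")
    DOSES = {"CD": 0, "T150": 150, "T300": 300}

    def __init__(self, rows: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in rows.columns]
        if missing:
            raise ValidationError(f"design missing columns: {missing}")
        df = rows.loc[:, list(self.COLUMNS)].copy()
        if df.duplicated(subset=["cat_id", "timepoint_day"]).any():
            raise ValidationError("duplicate (cat_id, timepoint_day) rows")
        if df["sample_id"].duplicated().any():
            raise ValidationError("a sample_id maps to more than one design row")
        bad_sex = set(df["sex"]) - {"F", "M"}
        if bad_sex:
            raise ValidationError(f"unknown sex codes: {sorted(bad_sex)}")
        bad_diet = set(df["diet"]) - set(self.DIETS)
        if bad_diet:
            raise ValidationError(f"unknown diets: {sorted(bad_diet)}")
        if (df["body_weight_kg"] <= 0).any():
            raise ValidationError("body weight must be positive")
        per_cat = df.groupby("cat_id")["diet"].nunique()
        if (per_cat > 1).any():
            cats = per_cat[per_cat > 1].index.tolist()
            raise ValidationError(f"diet varies within cat: {cats}")
        mismatch = df["dose_mg_per_kg"] != df["diet"].map(self.DOSES)
        if mismatch.any():
            raise ValidationError("dose does not match diet coding")
        self.rows = df.sort_values(["cat_id", "timepoint_day"]).reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        """Metadata indexed by sample_id."""
        return self.rows.set_index("sample_id")

    @property
    def cats(self) -> list[str]:
        return sorted(self.rows["cat_id"].unique())

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class PalatabilityRecord:
    """One cat-day of a two-bowl test: grams eaten per bowl and first choice."""

    cat_id: str
    day: int
    diet_a: str
    diet_b: str
    grams_a: float
    grams_b: float
    first_choice: str  # diet_a, diet_b or "none" (abstention)
    offered_g: float = 100.0

    def __post_init__(self):
        if self.day not in (1, 2):
            raise ValidationError(f"day must be 1 or 2, got {self.day}")
        if self.grams_a < 0 or self.grams_b < 0:
            raise ValidationError("consumption cannot be negative")
        if self.grams_a > self.offered_g or self.grams_b > self.offered_g:
            raise ValidationError("consumption exceeds the offered amount")
        if self.first_choice not in (self.diet_a, self.diet_b, "none"):
            raise ValidationError(
                f"first_choice {self.first_choice!r} is not one of the offered diets")


@dataclass(frozen=True)
class DigestibilityRecord:
    """Daily nutrient intake and fecal output for one cat during collection."""

    cat_id: str
    nutrient: str
    intake_g_per_day: float
    fecal_output_g_per_day: float

    def __post_init__(self):
        if self.intake_g_per_day <= 0:
            raise ValidationError("intake must be strictly positive")
        if self.fecal_output_g_per_day < 0:
            raise ValidationError("fecal output cannot be negative")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_BRACKEN_LVL = {"S": "species", "G": "genus", "F": "family", "P": "phylum"}


def read_abundance_table(path, dialect: str = "wide", rank: str = "species") -> AbundanceTable:
    """Read a count table in ``wide``, ``long`` or ``bracken`` dialect.

    wide
        First column ``sample_id``; remaining columns are taxa.
    long
        Columns ``sample_id``, ``taxon_id``, ``count``; duplicate
        (sample, taxon) pairs are an error.
    bracken
        Bracken report columns ``name``, ``taxonomy_id``, ``taxonomy_lvl``,
        ``new_est_reads``, ``fraction_total_reads``; either one file per
        sample (sample id taken from the file stem) or merged with an extra
        ``sample`` column. ``new_est_reads`` is the count; fractions are
        ignored and recomputed downstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "wide":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index(df.columns[0])
        return AbundanceTable(df, rank=rank)
    if dialect == "long":
        df = pd.read_csv(path, sep="\t")
        need = {"sample_id", "taxon_id", "count"}
        if not need <= set(df.columns):
            raise ValidationError(f"long dialect needs columns {sorted(need)}")
        if df.duplicated(subset=["sample_id", "taxon_id"]).any():
            dup = df[df.duplicated(subset=["sample_id", "taxon_id"], keep=False)]
            raise ValidationError(
                "duplicate (sample, taxon) rows: "
                + ", ".join(f"({r.sample_id},{r.taxon_id})" for r in dup.itertuples()))
        wide = df.pivot(index="sample_id", columns="taxon_id", values="count")
        wide = wide.fillna(0)
        return AbundanceTable(wide, rank=rank)
    if dialect == "bracken":
        df = pd.read_csv(path, sep="\t")
        need = {"name", "taxonomy_id", "taxonomy_lvl", "new_est_reads", "fraction_total_reads"}
        if not need <= set(df.columns):
            raise ValidationError(f"bracken dialect needs columns {sorted(need)}")
        lvls = set(df["taxonomy_lvl"])
        if len(lvls) != 1:
            raise ValidationError(f"mixed taxonomy levels in one report: {sorted(lvls)}")
        lvl = lvls.pop()
        file_rank = _BRACKEN_LVL.get(lvl)
        if file_rank is None:
            raise ValidationError(f"unsupported taxonomy_lvl {lvl!r}")
        if "sample" not in df.columns:
            df = df.assign(sample=path.stem)
        long = df.rename(columns={"sample": "sample_id", "name": "taxon_id",
                                  "new_est_reads": "count"})
        if long.duplicated(subset=["sample_id", "taxon_id"]).any():
            raise ValidationError("duplicate (sample, taxon) rows in Bracken report")
        wide = long.pivot(index="sample_id", columns="taxon_id", values="count").fillna(0)
        return AbundanceTable(wide, rank=file_rank)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_genome_annotations(path) -> list[GenomeAnnotation]:
    """Read a long annotation TSV into one :class:`GenomeAnnotation` per genome.

    Expected columns: ``genome_id``, ``species_id``,
    ``feature_type`` in {EC, KO, PATHWAY, CAZY}, ``feature_id``.
    Duplicate feature rows collapse under set semantics.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"genome_id", "species_id", "feature_type", "feature_id"}
    if not need <= set(df.columns):
        raise ValidationError(f"annotation table needs columns {sorted(need)}")
    unknown = set(df["feature_type"]) - set(FEATURE_TYPES)
    if unknown:
        raise ValidationError(f"unknown feature_type values: {sorted(unknown)}")
    return _annotations_from_frame(df)


def _annotations_from_frame(df: pd.DataFrame) -> list[GenomeAnnotation]:
    out = []
    for genome_id, grp in df.groupby("genome_id", sort=True):
        species = grp["species_id"].unique()
        if len(species) > 1:
            raise ValidationError(
                f"genome {genome_id!r} assigned to multiple species: {sorted(species)}")
        by_type = {t: frozenset(grp.loc[grp["feature_type"] == t, "feature_id"])
                   for t in FEATURE_TYPES}
        out.append(GenomeAnnotation(
            genome_id=str(genome_id), species_id=str(species[0]),
            ec_numbers=by_type["EC"], kegg_kos=by_type["KO"],
            kegg_pathways=by_type["PATHWAY"], cazy_families=by_type["CAZY"]))
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_result_table(table: pd.DataFrame, path) -> None:
    """Write any result table as deterministic TSV (stable column order)."""
    if table is None or len(table) == 0:
        raise ValidationError("refusing to write an empty result table")
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_abundance_table(table: AbundanceTable, path) -> None:
    df = table.counts.reset_index()
    write_result_table(df, path)


def write_genome_annotations(annotations: Iterable[GenomeAnnotation], path) -> None:
    rows = []
    for ann in annotations:
        for ftype, feats in (("EC", ann.ec_numbers), ("KO", ann.kegg_kos),
                             ("PATHWAY", ann.kegg_pathways), ("CAZY", ann.cazy_families)):
            for f in sorted(feats):
                rows.append((ann.genome_id, ann.species_id, ftype, f))
    df = pd.DataFrame(rows, columns=["genome_id", "species_id", "feature_type", "feature_id"])
    df = df.sort_values(["genome_id", "feature_type", "feature_id"]).reset_index(drop=True)
    write_result_table(df, path)
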