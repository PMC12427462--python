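"""Alpha diversity, compositional (CLR/Aitchison) beta diversity and PERMANOVA.

Shannon diversity is computed on rarefied counts in natural-log units.
Beta diversity follows the compositional route: counts are centered
log-ratio (CLR) transformed with a pseudocount, pairwise Euclidean
distance between CLR rows is the Aitchison distance, and ordination is
plain centered PCA of the CLR matrix (whose full-dimensional coordinate
distances equal the Aitchison distances). PERMANOVA partitions the
Gower-centered distance matrix by sequential (Type I) sums of squares and
assesses each term by free permutation of sample labels, mirroring
adonis2 defaults; optional strata restrict permutations within blocks
(e.g. within cat for repeated measures).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AbundanceTable, ValidationError

__all__ = [
    "shannon",
    "shannon_table",
    "clr_transform",
    "aitchison_distance",
    "pca_ordination",
    "OrdinationResult",
    "permanova",
    "PermanovaResult",
]


def shannon(counts) -> float:
    """Shannon index H = -sum p_i ln p_i of one sample; zeros ignored."""
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValidationError("shannon expects a single sample's counts")
    if (c < 0).any():
        raise ValidationError("negative counts")
    total = c.sum()
    if total == 0:
        raise ValidationError("all-zero count vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_table(table: AbundanceTable, subset_label: str = "all") -> pd.DataFrame:
    """Per-sample Shannon H as a tidy result table."""
    rows = [{"sample_id": s, "metric": "shannon",
             "value": shannon(table.counts.loc[s].to_numpy()),
             "rank": table.rank, "subset": subset_label}
            for s in table.sample_ids]
    return pd.DataFrame(rows)


def clr_transform(table: AbundanceTable, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform: log(count + pc) minus the row mean log."""
    if pseudocount <= 0:
        if (table.counts.to_numpy() == 0).any():
            raise ValidationError("pseudocount must be positive when zeros are present")
        pseudocount = 0.0
    logs = np.log(table.counts.to_numpy(dtype=float) + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.counts.index, columns=table.counts.columns)


def aitchison_distance(clr: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between CLR rows; symmetric with zero diagonal."""
    x = clr.to_numpy(dtype=float)
    sq = (x ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * x @ x.T
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(np.maximum(d2, 0.0))
    return pd.DataFrame(d, index=clr.index, columns=clr.index)


@dataclass
class OrdinationResult:
    """Principal-component ordination of a CLR matrix."""

    coordinates: pd.DataFrame          # samples x PCs
    proportion_explained: np.ndarray   # per PC, non-increasing
    clr: pd.DataFrame                  # the matrix ordinated


def pca_ordination(clr: pd.DataFrame) -> OrdinationResult:
    """Centered PCA via SVD; full-rank coordinates preserve Aitchison distances."""
    if len(clr) < 2:
        raise ValidationError("ordination needs at least two samples")
    x = clr.to_numpy(dtype=float)
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, _vt = np.linalg.svd(centered, full_matrices=False)
    coords = u * s
    var = s ** 2
    total = var.sum()
    prop = var / total if total > 0 else np.zeros_like(var)
    names = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=clr.index, columns=names),
        proportion_explained=prop,
        clr=clr,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Sequential-SS PERMANOVA table and permutation settings."""

    table: pd.DataFrame   # rows: terms + Residual + Total; cols df, ss, f, r2, p
    n_permutations: int
    seed: int

    def __repr__(self) -> str:
        return f"PermanovaResult(n_perm={self.n_permutations})\n{self.table}"


def _term_matrix(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Dummy columns for a term; 'a:b' is the elementwise dummy product."""
    parts = term.split(":")
    blocks = []
    for p in parts:
        if p not in meta.columns:
            raise ValidationError(f"design has no column {p!r}")
        col = meta[p]
        if col.dtype.kind in "if" and col.nunique() > 8:
            blocks.append(col.to_numpy(dtype=float)[:, None])
        else:
            blocks.append(pd.get_dummies(col.astype("category")).to_numpy(dtype=float))
    x = blocks[0]
    for b in blocks[1:]:
        x = np.einsum("ij,ik->ijk", x, b).reshape(len(meta), -1)
    return x


def permanova(dist: pd.DataFrame, design, terms: list[str],
              n_perm: int = 999, seed: int = 0,
              strata: str | None = None) -> PermanovaResult:
    """Permutational multivariate ANOVA of a distance matrix.

    Parameters
    ----------
    dist : DataFrame
        Square symmetric distances, indexed by sample id.
    design : TrialDesign or DataFrame
        Sample metadata; a DataFrame must be indexed by sample id.
    terms : list of str
        Model terms in sequential order, e.g. ``["diet", "timepoint_day",
        "diet:timepoint_day"]``.
    strata : str, optional
        Metadata column within whose levels permutations are confined.
    """
    meta = design.to_frame() if hasattr(design, "to_frame") and not isinstance(design, pd.DataFrame) else design
    samples = list(dist.index)
    if list(dist.columns) != samples:
        raise ValidationError("distance matrix rows and columns disagree")
    missing = [s for s in samples if s not in meta.index]
    if missing:
        raise ValidationError(f"design does not cover samples: {missing[:5]}")
    meta = meta.loc[samples]
    n = len(samples)

    d = dist.to_numpy(dtype=float)
    # Gower-centered inner-product matrix of the squared distances
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    ss_total = np.trace(g)

    # cumulative hat matrices for sequential SS
    hats = []
    x = np.ones((n, 1))
    ranks = [1]
    for term in terms:
        x = np.hstack([x, _term_matrix(meta, term)])
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        basis = u[:, s > 1e-10 * s.max()]  # orthonormal basis of the column space
        rank = basis.shape[1]
        if rank == ranks[-1]:
            raise ValidationError(f"term {term!r} adds no degrees of freedom (singular design)")
        ranks.append(rank)
        hats.append(basis @ basis.T)
    df_terms = np.diff(ranks)
    df_resid = n - ranks[-1]
    if df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")

    h0 = np.ones((n, n)) / n
    stack = [h0] + hats

    def all_f(gmat: np.ndarray):
        tr = np.array([np.sum(h * gmat) for h in stack])
        ss_terms = np.diff(tr)
        ss_res = np.trace(gmat) - tr[-1]
        f = (ss_terms / df_terms) / (ss_res / df_resid)
        return ss_terms, ss_res, f

    ss_terms, ss_resid, f_obs = all_f(g)

    rng = np.random.default_rng(seed)
    if strata is not None:
        groups = meta[strata].to_numpy()
        idx_by_group = {v: np.flatnonzero(groups == v) for v in np.unique(groups)}

    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        if strata is None:
            perm = rng.permutation(n)
        else:
            perm = np.arange(n)
            for idx in idx_by_group.values():
                perm[idx] = idx[rng.permutation(len(idx))]
        gp = g[np.ix_(perm, perm)]
        _, _, f_perm = all_f(gp)
        exceed += f_perm >= f_obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, term in enumerate(terms):
        rows.append({"term": term, "df": int(df_terms[i]), "ss": ss_terms[i],
                     "pseudo_f": f_obs[i], "r2": ss_terms[i] / ss_total,
                     "p": pvals[i]})
    rows.append({"term": "Residual", "df": int(df_resid), "ss": ss_resid,
                 "pseudo_f": np.nan, "r2": ss_resid / ss_total, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "ss": ss_total,
                 "pseudo_f": np.nan, "r2": 1.0, "p": np.nan})
    return PermanovaResult(table=pd.DataFrame(rows), n_permutations=n_perm, seed=seed)
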