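"""Shape-diversity and genetic-signal statistics.

PCA on standardized descriptor matrices, per-group convex-hull spread in
PC space, per-group coefficients of variation, Tukey-fence outlier
flagging, and randomized-complete-block (RCBD) ANOVA with broad-sense
heritability on an entry-mean basis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "PCAResult",
    "AnovaResult",
    "build_coefficient_matrix",
    "pca_on_efd",
    "convex_hull_spread",
    "group_cv",
    "flag_outliers",
    "rcbd_anova",
    "broad_sense_heritability",
    "heritability_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PCAResult:
    loadings: np.ndarray                  # (k, p) rows are components
    scores: np.ndarray                    # (n, k)
    explained_variance_ratio: np.ndarray  # (k,)
    mean: np.ndarray                      # (p,) column means removed before SVD

    @property
    def cumulative_variance_ratio(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)


@dataclass(frozen=True)
class AnovaResult:
    """Balanced two-way (genotype + block) ANOVA summary."""

    ms_genotype: float
    ms_block: float
    ms_error: float
    f_genotype: float
    p_genotype: float
    sigma2_g: float
    sigma2_e: float
    n_genotypes: int
    n_blocks: int
    df_genotype: int
    df_error: int

    @property
    def significance(self) -> str:
        """Stars at the 0.05 / 0.001 levels."""
        if self.p_genotype < 0.001:
            return "***"
        if self.p_genotype < 0.05:
            return "*"
        return ""


def build_coefficient_matrix(standardized) -> np.ndarray:
    """Stack standardized records into a (canopies x coefficients) matrix.

    The three constant coefficients (a_1*, b_1*, c_1*) are dropped, since
    they carry no variance by construction.
    """
    mats = [np.asarray(s.coeffs, dtype=float).ravel() for s in standardized]
    lengths = {m.size for m in mats}
    if len(lengths) != 1:
        raise ValueError("standardized records have differing harmonic counts")
    matrix = np.vstack(mats)
    return np.delete(matrix, [0, 1, 2], axis=1)  # a1*, b1*, c1*


def pca_on_efd(matrix: np.ndarray) -> PCAResult:
    """Mean-centered PCA (no variance scaling) via SVD."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.isfinite(x).all():
        raise ValueError("non-finite entries in descriptor matrix")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = (s**2).sum()
    ratio = s**2 / total if total > 0 else np.zeros_like(s)
    return PCAResult(loadings=vt, scores=u * s, explained_variance_ratio=ratio, mean=mean)


def convex_hull_spread(scores: np.ndarray, labels) -> pd.DataFrame:
    """Planar convex-hull area of each group's points in PC1/PC2 space.

    Groups with fewer than 3 points, or with collinear points, get area 0
    and ``degenerate=True``.
    """
    pts = np.asarray(scores, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 2 or pts.shape[0] == 0:
        raise ValueError("scores must be a non-empty (n, >=2) array")
    pts = pts[:, :2]
    labels = np.asarray(labels)
    if len(labels) != len(pts):
        raise ValueError("labels not aligned with scores")
    rows = []
    for group in pd.unique(labels):
        sub = pts[labels == group]
        area, degenerate = 0.0, True
        if len(sub) >= 3:
            try:
                area, degenerate = float(ConvexHull(sub).volume), False
            except QhullError:
                pass  # collinear group
        rows.append({"group": group, "n": len(sub), "hull_area": area, "degenerate": degenerate})
    return pd.DataFrame(rows)


def group_cv(traits: pd.DataFrame, labels, trait_cols=None) -> pd.DataFrame:
    """Coefficient of variation (sample sd / mean) per group and trait.

    Groups of size 1 and zero-mean cells are flagged undefined rather than
    raising.
    """
    labels = np.asarray(labels)
    if len(labels) != len(traits):
        raise ValueError("labels not aligned with trait table")
    if trait_cols is None:
        trait_cols = [c for c in traits.columns if traits[c].dtype.kind in "fi"]
    rows = []
    for group in pd.unique(labels):
        sub = traits.loc[labels == group, trait_cols]
        for trait in trait_cols:
            vals = sub[trait].to_numpy(dtype=float)
            undefined = len(vals) < 2
            cv = np.nan
            if not undefined:
                mean = vals.mean()
                if mean == 0:
                    undefined = True
                else:
                    cv = float(vals.std(ddof=1) / mean)
            rows.append({
                "group": group, "trait": trait, "n": len(vals),
                "cv": cv, "undefined": undefined,
            })
    return pd.DataFrame(rows)


def flag_outliers(
    traits: pd.DataFrame,
    group_col: str,
    trait_cols=None,
    genotype_col: str | None = None,
    id_col: str = "id",
) -> pd.DataFrame:
    """Tukey 1.5*IQR outlier flags per group and trait.

    A value is flagged when it falls outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]
    of its group.  Groups with fewer than 4 members yield no flags (fences
    are not meaningful; logged).  When ``genotype_col`` is given, a
    ``consistency`` column counts, per genotype and trait, in how many
    replicates that genotype was flagged.
    """
    if trait_cols is None:
        trait_cols = [c for c in traits.columns
                      if c not in {group_col, genotype_col, id_col} and traits[c].dtype.kind in "fi"]
    rows = []
    for group, sub in traits.groupby(group_col, sort=False):
        if len(sub) < 4:
            logger.info("group %r has n=%d < 4; no outlier fences computed", group, len(sub))
            continue
        for trait in trait_cols:
            vals = sub[trait].to_numpy(dtype=float)
            q1, q3 = np.percentile(vals, [25, 75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            flagged = (vals < lo) | (vals > hi)
            for i, (idx, row) in enumerate(sub.iterrows()):
                rows.append({
                    "id": row[id_col] if id_col in sub.columns else idx,
                    "trait": trait,
                    "group": group,
                    "value": vals[i],
                    "flagged": bool(flagged[i]),
                    **({"genotype": row[genotype_col]} if genotype_col else {}),
                })
    flags = pd.DataFrame(rows)
    if genotype_col and not flags.empty:
        counts = (flags.groupby(["genotype", "trait"])["flagged"].sum()
                  .rename("consistency").astype(int))
        flags = flags.join(counts, on=["genotype", "trait"])
    return flags


def _balance_records(
    records: pd.DataFrame,
    value_col: str,
    genotype_col: str,
    block_col: str,
) -> pd.DataFrame:
    """Restrict to genotypes sharing the modal block set (balanced core).

    Mirrors the convention of estimating components only on entries with
    the modal replication count; dropped genotypes are logged.
    """
    block_sets = records.groupby(genotype_col)[block_col].apply(frozenset)
    modal = block_sets.value_counts().idxmax()
    keep = block_sets[block_sets == modal].index
    dropped = len(block_sets) - len(keep)
    if dropped:
        logger.info("dropping %d genotypes without the modal block set (k=%d)", dropped, len(modal))
    return records[records[genotype_col].isin(keep)]


def rcbd_anova(
    records: pd.DataFrame,
    value_col: str = "value",
    genotype_col: str = "genotype",
    block_col: str = "block",
) -> AnovaResult:
    """Two-way random-effects ANOVA of a balanced RCBD trait table.

    Sums of squares are the textbook balanced decomposition; variance
    components come from the expected mean squares with truncation at
    zero: sigma2_e = MSE, sigma2_g = max(0, (MSG - MSE) / k).
    """
    records = _balance_records(records, value_col, genotype_col, block_col)
    table = records.pivot_table(index=genotype_col, columns=block_col,
                                values=value_col, aggfunc="first")
    if table.isna().any().any():
        raise ValueError("RCBD table is not balanced after restriction")
    y = table.to_numpy(dtype=float)
    g, k = y.shape
    if g < 2 or k < 2:
        raise ValueError("need at least 2 genotypes and 2 blocks")
    grand = y.mean()
    ss_g = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_b = g * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_e = ss_tot - ss_g - ss_b
    df_g, df_b, df_e = g - 1, k - 1, (g - 1) * (k - 1)
    msg, msb, mse = ss_g / df_g, ss_b / df_b, ss_e / df_e
    f_g = msg / mse if mse > 0 else np.inf
    p_g = float(stats.f.sf(f_g, df_g, df_e)) if np.isfinite(f_g) else 0.0
    sigma2_e = mse
    sigma2_g = max(0.0, (msg - mse) / k)
    return AnovaResult(
        ms_genotype=float(msg), ms_block=float(msb), ms_error=float(mse),
        f_genotype=float(f_g), p_genotype=p_g,
        sigma2_g=float(sigma2_g), sigma2_e=float(sigma2_e),
        n_genotypes=g, n_blocks=k, df_genotype=df_g, df_error=df_e,
    )


def broad_sense_heritability(anova: AnovaResult) -> float:
    """Entry-mean broad-sense heritability H2 = s2g / (s2g + s2e / k).

    Returns NaN (undefined) when both variance components are zero.
    """
    denom = anova.sigma2_g + anova.sigma2_e / anova.n_blocks
    if denom == 0:
        return float("nan")
    return anova.sigma2_g / denom


def heritability_report(
    records: pd.DataFrame,
    value_col: str = "value",
    genotype_col: str = "genotype",
    block_col: str = "block",
    trait_col: str = "trait",
) -> pd.DataFrame:
    """Per-trait ANOVA + heritability table (F, stars, components, k, H2)."""
    rows = []
    for trait, sub in records.groupby(trait_col, sort=False):
        a = rcbd_anova(sub, value_col, genotype_col, block_col)
        rows.append({
            "trait": trait,
            "F_G": a.f_genotype,
            "significance": a.significance,
            "sigma2_g": a.sigma2_g,
            "sigma2_e": a.sigma2_e,
            "k": a.n_blocks,
            "H2": broad_sense_heritability(a),
        })
    return pd.DataFrame(rows)
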