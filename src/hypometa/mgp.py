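"""Marker-gene-profile (MGP) estimation of relative cell-type proportions.

The relative abundance of a cell type across samples is summarized by the
first principal component of the expression of its marker genes: markers
are z-scored across the in-scope samples, the leading component of the
samples x markers matrix is taken as the per-sample score, and the sign is
oriented so the score correlates positively with the mean marker z-score.
Scores are unitless, standardized (mean 0, sd 1) per cell type and scope.

Estimation runs separately per donor; pooled scores feed an ordinary
least-squares interaction model asking whether the inside-mask shift of a
cell type's proportion differs in one donor of interest:

    score ~ inside + donor_flag + inside : donor_flag
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .datatypes import AnnotatedExpression
from .enrichment import GeneRanking, _set_auc

logger = logging.getLogger("hypometa")

__all__ = ["validate_markers", "estimate_mgp", "marker_auc_check", "interaction_test"]


def validate_markers(markers: Mapping[str, Sequence[str]]) -> dict[str, list[str]]:
    """Normalize a cell_type -> marker list map; overlapping markers are
    logged and dropped from every type they appear in."""
    dedup = {t: list(dict.fromkeys(g)) for t, g in markers.items()}
    counts: dict[str, int] = {}
    for genes in dedup.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    shared = {g for g, c in counts.items() if c > 1}
    if shared:
        logger.warning(
            "validate_markers: %d marker(s) shared across types dropped: %s",
            len(shared), sorted(shared)[:10],
        )
    return {t: [g for g in genes if g not in shared] for t, genes in dedup.items()}


def _mgp_one(values: np.ndarray) -> tuple[np.ndarray, float]:
    """First-PC score of a samples x markers z-scored matrix, oriented to
    correlate positively with the mean marker z-score; returns the
    standardized score and the variance fraction captured."""
    pca = PCA(n_components=1, svd_solver="full")
    score = pca.fit_transform(values)[:, 0]
    mean_z = values.mean(axis=1)
    orient = np.corrcoef(score, mean_z)[0, 1]
    if orient < 0:
        score = -score
    score = (score - score.mean()) / score.std(ddof=0)
    return score, float(pca.explained_variance_ratio_[0])


def estimate_mgp(
    expr: AnnotatedExpression,
    markers: Mapping[str, Sequence[str]],
    scope: str = "per-donor",
) -> dict[str, pd.DataFrame]:
    """Estimate relative cell-type proportions from marker expression.

    For each donor (``scope="per-donor"``, the default) or across all
    samples at once (``scope="pooled"``), and for each cell type: markers
    present in the data are z-scored across the in-scope samples (constant
    markers dropped with a warning), and the oriented first principal
    component is the per-sample proportion score.  Requires >= 3 usable
    markers per type and more samples than markers in scope.

    Returns ``{"scores": ..., "summary": ...}`` — per-sample scores in long
    form (sample_id, donor, cell_type, score) and a per-scope/type summary
    with the marker count used and the variance fraction captured.
    """
    markers = validate_markers(markers)
    if scope not in ("per-donor", "pooled"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "per-donor":
        groups = [
            (donor, list(expr.samples.index[expr.samples["donor_id"] == donor]))
            for donor in dict.fromkeys(expr.samples["donor_id"])
        ]
    else:
        groups = [("pooled", list(expr.samples.index))]

    score_rows = []
    summary_rows = []
    gene_index = set(expr.genes)
    for donor, sample_ids in groups:
        sub = expr.expression[sample_ids]
        for cell_type, genes in markers.items():
            present = [g for g in genes if g in gene_index]
            if len(present) < 3:
                raise ValueError(
                    f"cell type {cell_type!r}: fewer than 3 markers with data"
                )
            if len(sample_ids) < len(present) + 1:
                raise ValueError(
                    f"scope {donor!r}: need more samples ({len(sample_ids)}) than "
                    f"markers ({len(present)}) for cell type {cell_type!r}"
                )
            mat = sub.loc[present].to_numpy(dtype=float).T  # samples x markers
            sd = mat.std(axis=0, ddof=0)
            usable = sd > 0
            if not usable.any() or usable.sum() < 3:
                raise ValueError(
                    f"cell type {cell_type!r} in scope {donor!r}: "
                    "fewer than 3 non-constant markers"
                )
            if not usable.all():
                logger.warning(
                    "estimate_mgp: %d constant marker(s) of %s dropped in scope %s",
                    int((~usable).sum()), cell_type, donor,
                )
            z = (mat[:, usable] - mat[:, usable].mean(axis=0)) / sd[usable]
            score, var_frac = _mgp_one(z)
            for sid, s in zip(sample_ids, score):
                score_rows.append(
                    {"sample_id": sid, "donor": donor, "cell_type": cell_type, "score": s}
                )
            summary_rows.append(
                {
                    "scope": donor,
                    "cell_type": cell_type,
                    "n_markers_used": int(usable.sum()),
                    "variance_fraction": var_frac,
                }
            )
    return {
        "scores": pd.DataFrame(score_rows),
        "summary": pd.DataFrame(summary_rows),
    }


def marker_auc_check(
    de_ranking: GeneRanking, markers: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-cell-type AUC of marker genes on a differential-expression ranking.

    The set-size filter of the GO analysis is waived for marker sets;
    types with fewer than 3 markers in the ranking universe are skipped.
    """
    markers = validate_markers(markers)
    pos = de_ranking.positions()
    rows = []
    for cell_type, genes in markers.items():
        present = [g for g in genes if g in pos]
        if len(present) < 3:
            logger.info("marker_auc_check: %s skipped (<3 markers in universe)", cell_type)
            continue
        res = _set_auc(de_ranking, present)
        if res is None:
            logger.info("marker_auc_check: %s skipped (degenerate universe)", cell_type)
            continue
        n_in, auc, p = res
        rows.append(
            {
                "cell_type": cell_type,
                "n_genes": n_in,
                "AUC": auc,
                "p": p,
                "direction": "up" if auc > 0.5 else ("down" if auc < 0.5 else "none"),
            }
        )
    return pd.DataFrame(rows, columns=["cell_type", "n_genes", "AUC", "p", "direction"])


def interaction_test(
    scores: pd.Series | np.ndarray,
    inside_flag: np.ndarray,
    donor_of_interest_flag: np.ndarray,
    one_sided: bool = False,
) -> dict[str, float]:
    """OLS test for an inside-mask x donor-of-interest interaction.

    Fits ``score ~ inside + donor + inside:donor`` and reports the
    interaction coefficient, its t statistic and two-sided p (halved,
    direction-aware, when ``one_sided``).  Requires both flags to vary and
    at least 8 samples; a collinear design (e.g. the interaction equal to
    one main effect) is rejected with the degenerate term named.
    """
    y = np.asarray(scores, dtype=float)
    inside = np.asarray(inside_flag, dtype=float)
    donor = np.asarray(donor_of_interest_flag, dtype=float)
    if y.shape[0] < 8:
        raise ValueError(f"need >= 8 samples, got {y.shape[0]}")
    for name, v in (("inside", inside), ("donor", donor)):
        if np.all(v == v[0]):
            raise ValueError(f"flag {name!r} does not vary")
    inter = inside * donor
    X = np.column_stack([inside, donor, inter])
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        for col, name in ((3, "inside:donor"), (2, "donor"), (1, "inside")):
            reduced = np.delete(design, col, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(design):
                raise ValueError(f"collinear design: term {name!r} is degenerate")
        raise ValueError("collinear design")
    fit = sm.OLS(y, design).fit()
    coef = float(fit.params[3])
    t = float(fit.tvalues[3])
    p = float(fit.pvalues[3])
    if one_sided:
        p = p / 2.0 if coef > 0 else 1.0 - p / 2.0
    return {"coef": coef, "t": t, "p": p, "sign": float(np.sign(coef))}
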