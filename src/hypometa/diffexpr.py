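"""Per-donor rank-based differential expression inside vs outside the mask.

For each donor and gene, expression is compared between cortical samples
inside and outside the hypometabolic regions with the Mann–Whitney U test;
the effect is reported as AUC = U / (n_in * n_out), the probability that a
random inside sample exceeds a random outside one.  One-sided p values per
direction (over- and under-expressed inside) are combined across donors
with Fisher's method, and the Benjamini–Hochberg step-up procedure
controls the FDR over genes within each direction.

The exact conditional Mann–Whitney distribution (enumeration over all
group labelings of the pooled midranks) is used when n_in + n_out <= 12;
larger groups use the tie-corrected, continuity-corrected normal
approximation.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import AnnotatedExpression

logger = logging.getLogger("hypometa")

__all__ = ["mw_test", "fisher_meta", "bh_fdr", "run_diffexpr"]

#: Largest pooled size for which the exact enumeration branch is used.
EXACT_MAX_N = 12


def _exact_mw(pooled_ranks: np.ndarray, n_in: int, u_obs: float):
    """Exact conditional null of U by enumerating all labelings of the
    pooled midranks.  Returns (p_up, p_down), each including the point mass."""
    n = pooled_ranks.shape[0]
    const = n_in * (n_in + 1) / 2.0
    u_all = np.array(
        [pooled_ranks[list(c)].sum() - const for c in combinations(range(n), n_in)]
    )
    # tolerance for float midranks
    p_up = float(np.mean(u_all >= u_obs - 1e-9))
    p_down = float(np.mean(u_all <= u_obs + 1e-9))
    return p_up, p_down


def mw_test(values_in, values_out) -> tuple[float, float, float, float]:
    """Mann–Whitney U test of inside vs outside values.

    Returns ``(U, AUC, p_up, p_down)`` where U counts (inside > outside)
    pairs with half-credit for ties, AUC = U/(n_in*n_out), and the
    one-sided p values test over- (p_up) and under-expression (p_down)
    inside.  All-identical values give AUC 0.5 and p = 1 both ways.
    """
    x = np.asarray(values_in, dtype=float)
    y = np.asarray(values_out, dtype=float)
    n_in, n_out = x.shape[0], y.shape[0]
    if n_in < 2 or n_out < 2:
        raise ValueError(f"need >= 2 values per group, got {n_in} and {n_out}")

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n_in].sum() - n_in * (n_in + 1) / 2.0)
    auc = u / (n_in * n_out)

    if np.all(pooled == pooled[0]):
        return u, 0.5, 1.0, 1.0

    if n_in + n_out <= EXACT_MAX_N:
        p_up, p_down = _exact_mw(ranks, n_in, u)
    else:
        p_up = float(
            stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic").pvalue
        )
        p_down = float(
            stats.mannwhitneyu(x, y, alternative="less", method="asymptotic").pvalue
        )
    return u, auc, p_up, p_down


def _mw_test_matrix(mat_in: np.ndarray, mat_out: np.ndarray) -> pd.DataFrame:
    """Vectorized Mann–Whitney over genes (rows); same branching as mw_test."""
    n_in, n_out = mat_in.shape[1], mat_out.shape[1]
    pooled = np.hstack([mat_in, mat_out])
    ranks = stats.rankdata(pooled, axis=1)
    u = ranks[:, :n_in].sum(axis=1) - n_in * (n_in + 1) / 2.0
    auc = u / (n_in * n_out)

    if n_in + n_out <= EXACT_MAX_N:
        p_up = np.empty(pooled.shape[0])
        p_down = np.empty(pooled.shape[0])
        const = n_in * (n_in + 1) / 2.0
        combos = list(combinations(range(n_in + n_out), n_in))
        sel = np.array(combos)  # (n_combos, n_in)
        u_all = ranks[:, sel].sum(axis=2) - const  # (genes, n_combos)
        p_up = (u_all >= u[:, None] - 1e-9).mean(axis=1)
        p_down = (u_all <= u[:, None] + 1e-9).mean(axis=1)
    else:
        res_up = stats.mannwhitneyu(
            mat_in, mat_out, alternative="greater", method="asymptotic", axis=1
        )
        res_down = stats.mannwhitneyu(
            mat_in, mat_out, alternative="less", method="asymptotic", axis=1
        )
        p_up = np.asarray(res_up.pvalue, dtype=float)
        p_down = np.asarray(res_down.pvalue, dtype=float)

    constant = np.all(pooled == pooled[:, :1], axis=1)
    auc[constant] = 0.5
    p_up = np.where(constant, 1.0, p_up)
    p_down = np.where(constant, 1.0, p_down)
    return pd.DataFrame({"U": u, "AUC": auc, "p_up": p_up, "p_down": p_down})


def fisher_meta(p_values) -> float:
    """Fisher's method: combine one-sided p values from independent donors.

    X = -2 sum(ln p) is referred to the chi-square distribution with 2k
    degrees of freedom; zero p values are clamped to the smallest positive
    normal with a logged warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("fisher_meta requires at least one p value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("fisher_meta: clamped %d zero p value(s)", int((p == 0).sum()))
        p = np.maximum(p, np.finfo(float).tiny)
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, df=2 * p.size))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def run_diffexpr(
    expr: AnnotatedExpression,
    donors: str | list[str] = "all",
    fdr_q: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per-donor Mann–Whitney tables plus the Fisher/BH meta table.

    Requires inside/outside labels (see :func:`hypometa.labeling.label_inside`)
    on cortex-filtered expression.  Donors with fewer than two inside or two
    outside samples are excluded from the meta-combination with a logged
    notice.  Returns ``{"per_donor": ..., "meta": ...}``; the meta table is
    present only for ``donors="all"`` and carries, per gene, Fisher meta p
    and BH q per direction plus a ``significant_up``/``significant_down``
    call at ``q < fdr_q``.
    """
    if not expr.has_inside_labels:
        raise ValueError("expression is not labeled; run label_inside first")
    all_donors = list(dict.fromkeys(expr.samples["donor_id"]))
    if donors == "all":
        use_donors = all_donors
    elif isinstance(donors, str):
        use_donors = [donors]
    else:
        use_donors = list(donors)
    unknown = [d for d in use_donors if d not in all_donors]
    if unknown:
        raise ValueError(f"unknown donor id(s): {unknown}")

    per_donor_frames = []
    tested_donors = []
    for donor in use_donors:
        sub = expr.samples["donor_id"] == donor
        inside = expr.samples.index[sub & expr.samples["inside"]]
        outside = expr.samples.index[sub & ~expr.samples["inside"]]
        if len(inside) < 2 or len(outside) < 2:
            logger.info(
                "run_diffexpr: donor %s excluded (%d inside / %d outside samples)",
                donor, len(inside), len(outside),
            )
            continue
        mat_in = expr.expression[list(inside)].to_numpy(dtype=float)
        mat_out = expr.expression[list(outside)].to_numpy(dtype=float)
        tab = _mw_test_matrix(mat_in, mat_out)
        tab.insert(0, "gene", expr.genes)
        tab.insert(1, "donor", donor)
        tab["n_inside"] = len(inside)
        tab["n_outside"] = len(outside)
        per_donor_frames.append(tab)
        tested_donors.append(donor)

    if not per_donor_frames:
        raise ValueError("no donor has at least two inside and two outside samples")
    per_donor = pd.concat(per_donor_frames, ignore_index=True)

    result = {"per_donor": per_donor}
    if donors == "all":
        wide_up = per_donor.pivot(index="gene", columns="donor", values="p_up")
        wide_down = per_donor.pivot(index="gene", columns="donor", values="p_down")
        wide_up = wide_up.loc[expr.genes]
        wide_down = wide_down.loc[expr.genes]
        meta_up = np.array([fisher_meta(row.dropna()) for _, row in wide_up.iterrows()])
        meta_down = np.array(
            [fisher_meta(row.dropna()) for _, row in wide_down.iterrows()]
        )
        meta = pd.DataFrame(
            {
                "gene": expr.genes,
                "n_donors": wide_up.notna().sum(axis=1).to_numpy(),
                "meta_p_up": meta_up,
                "meta_p_down": meta_down,
                "q_up": bh_fdr(meta_up),
                "q_down": bh_fdr(meta_down),
            }
        )
        meta["significant_up"] = meta["q_up"] < fdr_q
        meta["significant_down"] = meta["q_down"] < fdr_q
        result["meta"] = meta
        logger.info(
            "run_diffexpr: %d donors tested, %d genes; %d up / %d down at q<%.3g",
            len(tested_donors), len(expr.genes),
            int(meta["significant_up"].sum()), int(meta["significant_down"].sum()),
            fdr_q,
        )
    return result


def significant_counts_per_donor(
    per_donor: pd.DataFrame, fdr_q: float = 0.05
) -> pd.Series:
    """Per-donor count of genes significant after BH within the donor.

    BH is applied within each donor and direction over that donor's tested
    genes; a gene counts once if significant in either direction.
    """
    counts = {}
    for donor, grp in per_donor.groupby("donor", sort=False):
        q_up = bh_fdr(grp["p_up"].to_numpy())
        q_down = bh_fdr(grp["p_down"].to_numpy())
        counts[donor] = int(((q_up < fdr_q) | (q_down < fdr_q)).sum())
    return pd.Series(counts, name="n_significant")
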