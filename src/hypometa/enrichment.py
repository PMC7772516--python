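"""Gene-set enrichment over rankings and monotone state progression.

Three related tests:

* **AUC enrichment** — genes are ranked from most overexpressed to most
  underexpressed; for each gene set, the AUC of in-set vs out-of-set rank
  positions (the Mann–Whitney statistic normalized by the product of group
  sizes) scores where the set falls in the ranking: AUC > 0.5 means
  enrichment at the overexpressed end, AUC < 0.5 at the underexpressed end.
  Significance comes from the Mann–Whitney test with BH FDR across sets.
* **Monotone progression** — given per-gene mean expression across ordered
  cell states (e.g. microglia: normal → intermediate → disease-associated),
  a gene is flagged when its state means strictly increase in the given
  order; the hypergeometric upper tail then asks whether a set contains
  more flagged genes than expected from the background fraction.
* **Pairwise stage enrichment** — the AUC machinery applied to a single
  gene set on an externally supplied fold-change ranking between two
  adjacent pathology stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .datatypes import GeneSetCollection, HomologMap
from .diffexpr import bh_fdr, mw_test

logger = logging.getLogger("hypometa")

__all__ = [
    "GeneRanking",
    "rank_genes",
    "auc_enrichment",
    "monotone_flags",
    "hypergeom_enrichment",
    "progression_scan",
    "pairwise_stage_enrichment",
]

#: Default annotated-set size window for tested sets.
SET_MIN, SET_MAX = 10, 200


@dataclass(frozen=True)
class GeneRanking:
    """An ordered gene list, most-overexpressed first, with its statistic."""

    genes: tuple[str, ...]
    statistic: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranking contains duplicate genes")
        if len(self.genes) != len(self.statistic):
            raise ValueError("genes and statistic lengths differ")

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self) -> dict[str, int]:
        """0-based position per gene, 0 = most overexpressed."""
        return {g: i for i, g in enumerate(self.genes)}

    def reversed(self) -> "GeneRanking":
        return GeneRanking(self.genes[::-1], self.statistic[::-1])


def rank_genes(statistic: pd.Series, ascending: bool = False) -> GeneRanking:
    """Build a ranking from a per-gene statistic (higher = more overexpressed).

    Ties are broken by gene symbol lexicographic order for determinism.
    """
    df = pd.DataFrame(
        {"stat": statistic.astype(float).to_numpy(), "gene": statistic.index.astype(str)}
    )
    df = df.sort_values(["stat", "gene"], ascending=[ascending, True])
    return GeneRanking(tuple(df["gene"]), tuple(df["stat"]))


def _set_auc(ranking: GeneRanking, genes: list[str]):
    """AUC + Mann–Whitney p for one gene set on a ranking.

    Positions are scored so the top of the ranking gets the highest score;
    returns (n_in_universe, AUC, p_two_sided) or None when the overlap or
    its complement is below two genes.
    """
    pos = ranking.positions()
    n = len(ranking)
    member = np.zeros(n, dtype=bool)
    for g in set(genes):
        if g in pos:
            member[pos[g]] = True
    n_in = int(member.sum())
    if n_in < 2 or n - n_in < 2:
        return None
    scores = np.arange(n, 0, -1, dtype=float)  # top of ranking = highest
    _, auc, p_up, p_down = mw_test(scores[member], scores[~member])
    p = min(1.0, 2.0 * min(p_up, p_down))
    return n_in, auc, p


def auc_enrichment(
    ranking: GeneRanking,
    sets: GeneSetCollection,
    min_size: int = SET_MIN,
    max_size: int = SET_MAX,
) -> pd.DataFrame:
    """AUC-based enrichment of each gene set in a ranking.

    Set sizes are counted after intersecting with the ranking's universe;
    sets outside ``[min_size, max_size]`` are not tested.  Output columns
    mirror the usual reporting: set id, name, n annotated tested genes,
    AUC, two-sided Mann–Whitney p, BH q across tested sets, and direction
    ('up' for AUC > 0.5).  Sorted by ascending p (ties: set id).
    """
    rows = []
    for set_id, genes in sets.items():
        res = _set_auc(ranking, genes)
        if res is None:
            logger.info("auc_enrichment: set %s skipped (universe overlap < 2)", set_id)
            continue
        n_in, auc, p = res
        if not (min_size <= n_in <= max_size):
            continue
        rows.append(
            {
                "set_id": set_id,
                "name": sets.names[set_id],
                "n_genes": n_in,
                "AUC": auc,
                "p": p,
                "direction": "up" if auc > 0.5 else ("down" if auc < 0.5 else "none"),
            }
        )
    out = pd.DataFrame(
        rows, columns=["set_id", "name", "n_genes", "AUC", "p", "direction"]
    )
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values(["p", "set_id"], ignore_index=True)
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def monotone_flags(states: pd.DataFrame) -> tuple[pd.Series, float]:
    """Flag genes whose state means strictly increase across the column order.

    ``states`` is genes x ordered states (>= 2 columns, left = first
    state).  Genes with any missing state value are excluded from both the
    numerator and denominator and tallied in a logged count.  Returns the
    boolean flag series (excluded genes absent) and the flagged fraction.
    """
    if states.shape[1] < 2:
        raise ValueError("need at least 2 ordered states")
    vals = states.to_numpy(dtype=float)
    complete = np.all(np.isfinite(vals), axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info("monotone_flags: %d gene(s) excluded for missing values", n_excluded)
    sub = vals[complete]
    flags = np.all(np.diff(sub, axis=1) > 0, axis=1)
    series = pd.Series(flags, index=states.index[complete], name="monotone_increase")
    fraction = float(flags.mean()) if len(flags) else float("nan")
    return series, fraction


def hypergeom_enrichment(
    universe_n: int, universe_hits: int, set_n: int, set_hits: int
) -> float:
    """Upper-tail hypergeometric p: P(X >= set_hits) for a set of size
    ``set_n`` drawn from a universe of ``universe_n`` genes of which
    ``universe_hits`` are hits.  Computed in log space so extreme tails
    (p far below 1e-300) do not underflow.
    """
    if not (0 <= set_hits <= set_n <= universe_n and 0 <= universe_hits <= universe_n):
        raise ValueError(
            f"inconsistent counts: universe {universe_n}/{universe_hits}, "
            f"set {set_n}/{set_hits}"
        )
    if set_hits == 0:
        return 1.0
    kmax = min(set_n, universe_hits)
    if set_hits > kmax:
        return 0.0
    ks = np.arange(set_hits, kmax + 1)
    log_tail = logsumexp(hypergeom.logpmf(ks, universe_n, universe_hits, set_n))
    return float(min(1.0, np.exp(log_tail)))


def progression_scan(
    states: pd.DataFrame,
    sets: GeneSetCollection,
    homologs: HomologMap | None = None,
) -> pd.DataFrame:
    """Monotone-progression enrichment of gene sets across ordered states.

    The universe is the genes with complete data in the state matrix; the
    background hit rate is the universe's strictly-monotone fraction.  If a
    homolog map is supplied, set genes are translated first (one-to-many
    expands, untranslated genes are dropped) and the translated set is
    de-duplicated at the target-species level before counting.  Per set,
    the hypergeometric upper tail against the background is computed and
    BH-corrected across tested sets; output sorted ascending by p.
    """
    flags, _ = monotone_flags(states)
    universe = set(flags.index)
    universe_n = len(flags)
    universe_hits = int(flags.sum())

    rows = []
    for set_id, genes in sets.items():
        if homologs is not None:
            translated = {t for _, t in homologs.translate(genes)}
        else:
            translated = set(genes)
        members = sorted(translated & universe)
        if not members:
            logger.info("progression_scan: set %s skipped (no genes in universe)", set_id)
            continue
        set_n = len(members)
        set_hits = int(flags.loc[members].sum())
        p = hypergeom_enrichment(universe_n, universe_hits, set_n, set_hits)
        rows.append(
            {
                "set_id": set_id,
                "name": sets.names[set_id],
                "n_genes": set_n,
                "n_monotone": set_hits,
                "fraction_monotone": set_hits / set_n,
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["set_id", "name", "n_genes", "n_monotone", "fraction_monotone", "p"],
    )
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values(["p", "set_id"], ignore_index=True)
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def pairwise_stage_enrichment(
    de_ranking: GeneRanking, genes: list[str], set_id: str = "set"
) -> pd.Series:
    """AUC enrichment of one gene set on a stage-contrast fold-change ranking.

    Same machinery as :func:`auc_enrichment` for a single externally
    supplied set, with the size filter waived.
    """
    res = _set_auc(de_ranking, genes)
    if res is None:
        raise ValueError(f"set {set_id!r}: fewer than 2 genes overlap the ranking")
    n_in, auc, p = res
    return pd.Series(
        {
            "set_id": set_id,
            "n_genes": n_in,
            "AUC": auc,
            "p": p,
            "direction": "up" if auc > 0.5 else ("down" if auc < 0.5 else "none"),
        }
    )
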