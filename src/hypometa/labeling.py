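"""Spatial labeling of expression samples against a hypometabolism mask.

Samples carry MNI mm coordinates; each cortical sample is mapped to its
nearest voxel (inverse affine, rounding half away from zero) and labeled
inside or outside the binarized mask.  Samples falling outside the grid
count as outside, with a logged tally, so sample totals are preserved.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import AnnotatedExpression, ClusterMask, VoxelMap
from .io import filter_log

logger = logging.getLogger("hypometa")

__all__ = ["filter_cortex", "label_inside", "collapse_probes"]


def filter_cortex(expr: AnnotatedExpression) -> AnnotatedExpression:
    """Keep cerebral-cortex samples, excluding allocortex.

    Allocortical regions (hippocampal formation, piriform cortex) are
    flagged in the sample table, not looked up from an ontology.  Raises
    if no sample survives.
    """
    is_ctx = expr.samples["is_cerebral_cortex"].to_numpy(dtype=bool)
    is_allo = expr.samples["is_allocortex"].to_numpy(dtype=bool)
    keep = is_ctx & ~is_allo
    filter_log(
        "filter_cortex",
        kept=int(keep.sum()),
        removed={
            "non_cortex": int((~is_ctx).sum()),
            "allocortex": int((is_ctx & is_allo).sum()),
        },
    )
    if not keep.any():
        raise ValueError("no cerebral-cortex samples remain after filtering")
    return expr.subset_samples(list(expr.samples.index[keep]))


def label_inside(
    expr: AnnotatedExpression, mask: VoxelMap | ClusterMask
) -> AnnotatedExpression:
    """Label each sample inside/outside the binarized mask at its voxel.

    The mask and sample coordinates must share a space; any nonzero mask
    value counts as inside.  Idempotent and independent of sample order.
    """
    if isinstance(mask, ClusterMask):
        mask = mask.as_voxelmap()
    coords = expr.coordinates()
    idx = mask.mm_to_index(coords)
    in_grid = mask.in_bounds(idx)
    inside = np.zeros(len(idx), dtype=bool)
    if in_grid.any():
        ig = idx[in_grid]
        inside[in_grid] = mask.values[ig[:, 0], ig[:, 1], ig[:, 2]] > 0
    n_off = int((~in_grid).sum())
    if n_off:
        logger.warning("label_inside: %d sample(s) outside the grid labeled outside", n_off)
    out = expr.copy()
    out.samples["inside"] = inside
    logger.info(
        "label_inside: %d/%d samples inside the mask", int(inside.sum()), len(inside)
    )
    return out


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_to_gene: pd.Series | dict,
    keep_probes: list | None = None,
) -> pd.DataFrame:
    """Mean-average probe-level values per gene.

    ``probe_matrix`` is probes x samples; ``probe_to_gene`` maps each probe
    to at most one gene symbol.  An optional QC keep-list restricts to
    surviving probes first.  Returns a genes x samples matrix where each
    gene's value is the arithmetic mean of its surviving probes, per sample.
    """
    mapping = pd.Series(probe_to_gene)
    if keep_probes is not None:
        keep = [p for p in probe_matrix.index if p in set(keep_probes)]
        if not keep:
            raise ValueError("no probe survives the QC keep-list")
        probe_matrix = probe_matrix.loc[keep]
    mapped = [p for p in probe_matrix.index if p in mapping.index]
    dropped = probe_matrix.shape[0] - len(mapped)
    if dropped:
        logger.info("collapse_probes: %d unmapped probe(s) dropped", dropped)
    if not mapped:
        raise ValueError("no probe maps to a gene")
    sub = probe_matrix.loc[mapped]
    genes = mapping.loc[mapped]
    collapsed = sub.groupby(genes.to_numpy()).mean()
    collapsed.index.name = probe_matrix.index.name or "gene"
    logger.info(
        "collapse_probes: %d probes collapsed to %d genes",
        len(mapped), collapsed.shape[0],
    )
    return collapsed
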