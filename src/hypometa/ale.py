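"""Activation likelihood estimation (ALE) for coordinate-based meta-analysis.

Each experiment contributes a modeled-activation (MA) map: at every voxel,
the probability that at least one of that experiment's reported peaks lies
there, modeled as an isotropic 3-D Gaussian centred on each focus and
scaled so the value at the focus voxel equals the kernel mass contained in
one voxel (hence 0 < MA <= 1).  Within an experiment the per-focus maps
combine by the maximum, so repeated peaks in one study do not inflate
evidence.  Across experiments the ALE value is the probabilistic union

    ALE(v) = 1 - prod_i (1 - MA_i(v)).

Significance is calibrated by relocating every experiment's foci uniformly
at random within a brain mask, recomputing ALE, and comparing observed
values against the pooled null; Benjamini–Hochberg FDR across in-mask
voxels then yields a voxelwise ALE threshold.  Supra-threshold voxels are
grouped into connected components and small clusters (below a minimum
extent in mm^3) are discarded.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from .datatypes import ClusterMask, Experiment, FociSet, VoxelMap
from .diffexpr import bh_fdr

logger = logging.getLogger("hypometa")

__all__ = [
    "fwhm_to_sigma",
    "modeled_activation",
    "combine_ale",
    "compute_ale",
    "ale_null_threshold",
    "threshold_and_cluster",
]

#: Default kernel width (mm), full width at half maximum.
DEFAULT_FWHM_MM = 10.0

_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian standard deviation for a given full width at half maximum."""
    return float(fwhm_mm) / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _kernel_peak_height(sigma: float, spacing: np.ndarray) -> float:
    """Probability mass of the 3-D kernel inside one voxel centred on the focus."""
    half = np.asarray(spacing, dtype=float) / 2.0
    per_axis = norm.cdf(half / sigma) - norm.cdf(-half / sigma)
    return float(np.prod(per_axis))


def _voxel_centers_mm(grid: VoxelMap) -> np.ndarray:
    """(n_voxels, 3) mm coordinates of all voxel centers, C-order."""
    idx = np.indices(grid.shape).reshape(3, -1).T
    return grid.index_to_mm(idx)


def modeled_activation(
    experiment: Experiment, grid: VoxelMap, fwhm_mm: float = DEFAULT_FWHM_MM
) -> VoxelMap:
    """Per-experiment modeled-activation map: max-over-foci Gaussian kernel.

    Foci falling outside the grid bounds are logged and dropped; an
    experiment with no in-bounds focus is an error.
    """
    if fwhm_mm <= 0:
        raise ValueError(f"fwhm_mm must be positive, got {fwhm_mm}")
    sigma = fwhm_to_sigma(fwhm_mm)
    p0 = _kernel_peak_height(sigma, grid.spacing)

    idx = grid.mm_to_index(experiment.foci)
    keep = grid.in_bounds(idx)
    if not np.all(keep):
        logger.warning(
            "modeled_activation: experiment %s: dropped %d out-of-bounds focus/foci",
            experiment.experiment_id, int((~keep).sum()),
        )
    foci = experiment.foci[keep]
    if foci.shape[0] == 0:
        raise ValueError(
            f"experiment {experiment.experiment_id!r} has no in-bounds foci"
        )

    centers = _voxel_centers_mm(grid)  # (V, 3)
    # max over foci of p0 * exp(-r^2 / (2 sigma^2))
    ma = np.zeros(centers.shape[0])
    for focus in foci:
        d2 = np.sum((centers - focus) ** 2, axis=1)
        np.maximum(ma, p0 * np.exp(-d2 / (2.0 * sigma**2)), out=ma)
    return grid.like(ma.reshape(grid.shape))


def combine_ale(ma_maps: Sequence[VoxelMap]) -> VoxelMap:
    """Union of independent per-experiment probabilities.

    ALE(v) = 1 - prod_i (1 - MA_i(v)); permutation-invariant and monotone
    in every input.
    """
    if len(ma_maps) == 0:
        raise ValueError("combine_ale requires at least one MA map")
    first = ma_maps[0]
    log_comp = np.zeros(first.shape)
    for m in ma_maps:
        if m.shape != first.shape or not np.allclose(m.affine, first.affine):
            raise ValueError("MA maps are not on the same grid")
        log_comp += np.log1p(-np.clip(m.values, 0.0, 1.0 - 1e-15))
    return first.like(-np.expm1(log_comp))


def compute_ale(
    foci_set: FociSet,
    grid: VoxelMap,
    fwhm_mm: float = DEFAULT_FWHM_MM,
    fwhm_by_n: Mapping[int, float] | None = None,
) -> VoxelMap:
    """Full ALE map for a foci set: per-experiment MA maps, then the union.

    ``fwhm_by_n`` optionally maps sample size to kernel FWHM (the
    sample-size-dependent kernel lineage); each experiment then uses the
    entry with the nearest ``n_subjects`` key instead of the fixed
    ``fwhm_mm``.
    """
    def _fwhm(e: Experiment) -> float:
        if fwhm_by_n is None:
            return fwhm_mm
        keys = np.array(sorted(fwhm_by_n))
        nearest = keys[np.argmin(np.abs(keys - e.n_subjects))]
        return float(fwhm_by_n[int(nearest)])

    ma_maps = [modeled_activation(e, grid, _fwhm(e)) for e in foci_set]
    return combine_ale(ma_maps)


def ale_null_threshold(
    foci_set: FociSet,
    grid: VoxelMap,
    brain_mask: VoxelMap,
    n_permutations: int = 200,
    q: float = 0.05,
    fwhm_mm: float = DEFAULT_FWHM_MM,
    rng: np.random.Generator | int | None = None,
    pooled: bool = True,
) -> float:
    """FDR-calibrated voxelwise ALE threshold from a permutation null.

    Every permutation relocates each experiment's foci uniformly at random
    among in-mask voxel centers (focus count and kernel preserved) and the
    ALE map is recomputed.  Voxelwise p values are add-one exceedance
    fractions against the pooled in-mask null histogram (or against each
    voxel's own null when ``pooled=False``); Benjamini–Hochberg at level
    ``q`` across in-mask voxels then gives the threshold: the minimal
    observed ALE among significant voxels, or ``inf`` when none pass.
    """
    if n_permutations < 100:
        raise ValueError(
            f"n_permutations must be >= 100 for a stable tail, got {n_permutations}"
        )
    mask = brain_mask.values > 0
    if mask.shape != grid.shape:
        raise ValueError("brain_mask grid does not match the target grid")
    if not mask.any():
        raise ValueError("brain_mask has no interior voxels")
    rng = np.random.default_rng(rng)

    observed = compute_ale(foci_set, grid, fwhm_mm)
    obs_vals = observed.values[mask]

    mask_idx = np.argwhere(mask)
    mask_mm = grid.index_to_mm(mask_idx)
    counts = [e.foci.shape[0] for e in foci_set]
    n_vox = mask_mm.shape[0]

    if pooled:
        exceed = np.zeros(obs_vals.shape[0], dtype=np.int64)
        total = 0
    else:
        null_vals = np.empty((n_permutations, obs_vals.shape[0]))

    order = np.argsort(obs_vals)  # for pooled exceedance via searchsorted
    sorted_obs = obs_vals[order]

    for perm in range(n_permutations):
        perm_exps = []
        for e, k in zip(foci_set, counts):
            sel = rng.integers(0, n_vox, size=k)
            perm_exps.append(
                Experiment(e.experiment_id, e.n_subjects, mask_mm[sel])
            )
        null_map = compute_ale(FociSet(tuple(perm_exps)), grid, fwhm_mm)
        vals = null_map.values[mask]
        if pooled:
            # count null values >= each observed value
            ranks = np.searchsorted(np.sort(vals), sorted_obs, side="left")
            exceed[order] += vals.shape[0] - ranks
            total += vals.shape[0]
        else:
            null_vals[perm] = vals

    if pooled:
        p = (exceed + 1.0) / (total + 1.0)
    else:
        p = ((null_vals >= obs_vals[None, :]).sum(axis=0) + 1.0) / (n_permutations + 1.0)

    qvals = bh_fdr(p)
    sig = qvals <= q
    if not sig.any():
        logger.info("ale_null_threshold: no voxel significant at q=%.3g", q)
        return float("inf")
    threshold = float(obs_vals[sig].min())
    logger.info(
        "ale_null_threshold: %d/%d voxels significant at q=%.3g, threshold=%.6g",
        int(sig.sum()), int(mask.sum()), q, threshold,
    )
    return threshold


def threshold_and_cluster(
    ale_map: VoxelMap,
    threshold: float,
    min_extent_mm3: float = 500.0,
    connectivity: int = 26,
) -> ClusterMask:
    """Threshold an ALE map and extract connected clusters by extent.

    Voxels with value >= ``threshold`` form components under the given
    connectivity (6, 18 or 26); components below ``min_extent_mm3`` are
    discarded; surviving clusters are labeled 1..n in decreasing extent
    order (ties: higher peak value, then lexicographic peak index).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError(f"connectivity must be one of 6, 18, 26, got {connectivity}")
    supra = ale_map.values >= threshold
    labels, n_raw = ndimage.label(supra, structure=_CONNECTIVITY_STRUCTS[connectivity])
    voxvol = ale_map.voxel_volume_mm3

    records = []
    for lbl in range(1, n_raw + 1):
        comp = labels == lbl
        n_vox = int(comp.sum())
        extent = n_vox * voxvol
        if extent < min_extent_mm3:
            continue
        vals = np.where(comp, ale_map.values, -np.inf)
        peak_flat = int(np.argmax(vals))
        peak_idx = np.unravel_index(peak_flat, ale_map.shape)
        records.append(
            {
                "raw_label": lbl,
                "n_voxels": n_vox,
                "extent_mm3": extent,
                "peak_value": float(ale_map.values[peak_idx]),
                "peak_i": peak_idx[0],
                "peak_j": peak_idx[1],
                "peak_k": peak_idx[2],
            }
        )

    records.sort(
        key=lambda r: (
            -r["extent_mm3"],
            -r["peak_value"],
            (r["peak_i"], r["peak_j"], r["peak_k"]),
        )
    )
    out_labels = np.zeros(ale_map.shape, dtype=int)
    rows = []
    for new_lbl, rec in enumerate(records, start=1):
        out_labels[labels == rec["raw_label"]] = new_lbl
        peak_mm = ale_map.index_to_mm(
            np.array([[rec["peak_i"], rec["peak_j"], rec["peak_k"]]])
        )[0]
        rows.append(
            {
                "cluster_id": new_lbl,
                "n_voxels": rec["n_voxels"],
                "extent_mm3": rec["extent_mm3"],
                "peak_value": rec["peak_value"],
                "peak_i": rec["peak_i"],
                "peak_j": rec["peak_j"],
                "peak_k": rec["peak_k"],
                "peak_x_mm": peak_mm[0],
                "peak_y_mm": peak_mm[1],
                "peak_z_mm": peak_mm[2],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "n_voxels", "extent_mm3", "peak_value",
            "peak_i", "peak_j", "peak_k", "peak_x_mm", "peak_y_mm", "peak_z_mm",
        ],
    )
    return ClusterMask(
        labels=out_labels,
        affine=ale_map.affine.copy(),
        table=table,
        threshold=float(threshold),
        connectivity=connectivity,
    )
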