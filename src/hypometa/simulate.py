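"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator emits its ground truth alongside the data, so each stage
can be tested for recovery without any external download: spatially
clustered foci around planted region centers, expression matrices with an
inside-vs-outside shift planted in exactly one donor, gene x ordered-state
matrices with a planted strictly-monotone set, marker-gene expression
driven by latent cell-type proportion gradients, and decoy gene-set
collections.

A single global seed is expanded into independent per-stream substreams
(foci, expression, states, markers, sets) so changing one generator's
parameters does not perturb the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AnnotatedExpression,
    Experiment,
    FociSet,
    GeneSetCollection,
    HomologMap,
    VoxelMap,
)

__all__ = [
    "SimulationConfig",
    "make_grid",
    "gen_foci",
    "gen_expression",
    "gen_state_matrix",
    "gen_markers",
    "gen_decoy_sets",
    "gen_homolog_map",
]

_STREAMS = {"foci": 0, "expression": 1, "states": 2, "markers": 3, "sets": 4}

_CELL_TYPE_NAMES = [
    "astrocyte", "neuron", "oligodendrocyte",
    "oligodendrocyte_precursor", "microglia", "endothelial",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for all synthetic generators.

    Defaults mirror the real study designs the generators emulate: 33
    experiment samples of peak coordinates, six atlas donors with one
    aberrant donor carrying the planted inside-mask expression shift,
    three ordered microglial states, and 21 markers per cell type.
    """

    # voxel grid
    grid_shape: tuple[int, int, int] = (20, 24, 20)
    spacing_mm: float = 2.0
    # foci generation
    n_experiments: int = 33
    foci_per_experiment: int = 3
    decoy_foci_per_experiment: int = 0
    n_true_regions: int = 3
    jitter_sd_mm: float = 4.0
    min_region_separation_mm: float = 24.0
    # expression generation
    n_genes: int = 5000
    n_samples_per_donor: int = 100
    n_donors: int = 6
    aberrant_donor_index: int = 0
    effect_size_delta: float = 2.0
    allocortex_fraction: float = 0.1
    inside_sample_fraction: float | None = 0.08
    min_inside_per_donor: int = 2
    # planted structure
    planted_set_size: int = 200
    planted_monotone_fraction: float = 1.0
    monotone_step_sd: float = 5.0
    n_states: int = 3
    # markers
    n_cell_types: int = 6
    n_markers_per_type: int = 21
    n_marker_samples: int = 200
    marker_signal_sd: float = 1.0
    dirichlet_alpha: float = 2.0
    interaction_effect: float = 0.0
    # noise and reproducibility
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_experiments": self.n_experiments,
            "foci_per_experiment": self.foci_per_experiment,
            "n_true_regions": self.n_true_regions,
            "n_genes": self.n_genes,
            "n_samples_per_donor": self.n_samples_per_donor,
            "n_donors": self.n_donors,
            "planted_set_size": self.planted_set_size,
            "n_states": self.n_states,
            "n_cell_types": self.n_cell_types,
            "n_markers_per_type": self.n_markers_per_type,
            "n_marker_samples": self.n_marker_samples,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be positive, got {v}")
        if not 0.0 <= self.planted_monotone_fraction <= 1.0:
            raise ValueError("planted_monotone_fraction must lie in [0, 1]")
        if not 0 <= self.aberrant_donor_index < self.n_donors:
            raise ValueError("aberrant_donor_index out of range")
        if self.noise_sd < 0 or self.jitter_sd_mm < 0:
            raise ValueError("standard deviations must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream generator; identical config → identical draws."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )

    @property
    def donor_ids(self) -> list[str]:
        return [f"donor{i:02d}" for i in range(self.n_donors)]


def make_grid(
    shape: tuple[int, int, int] = (20, 24, 20), spacing_mm: float = 2.0
) -> VoxelMap:
    """Empty MNI-like grid: axis-aligned affine, origin at the grid center."""
    shape = tuple(int(s) for s in shape)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = spacing_mm
    affine[:3, 3] = -(np.array(shape) - 1) / 2.0 * spacing_mm
    return VoxelMap(values=np.zeros(shape), affine=affine)


def _grid_extent_mm(grid: VoxelMap) -> tuple[np.ndarray, np.ndarray]:
    corners = grid.index_to_mm(
        np.array([[0, 0, 0], [s - 1 for s in grid.shape]], dtype=float)
    )
    return corners.min(axis=0), corners.max(axis=0)


def gen_foci(
    config: SimulationConfig, grid: VoxelMap | None = None
) -> tuple[FociSet, np.ndarray]:
    """Experiments with foci jittered around planted region centers.

    Centers are drawn uniformly in the grid with a minimum pairwise
    separation (rejection sampling; an impossible placement errors out).
    Each focus is assigned a center uniformly at random and offset by
    isotropic Gaussian jitter; optional decoy foci are uniform in the
    grid.  Returns the foci set and the ``(n_true_regions, 3)`` centers.
    """
    grid = grid if grid is not None else make_grid(config.grid_shape, config.spacing_mm)
    rng = config.rng("foci")
    lo, hi = _grid_extent_mm(grid)
    # keep centers away from the edge so the jittered blobs stay in-grid
    margin = min(2.0 * config.jitter_sd_mm, float((hi - lo).min()) / 4.0)
    centers: list[np.ndarray] = []
    for _ in range(10_000):
        cand = rng.uniform(lo + margin, hi - margin)
        if all(np.linalg.norm(cand - c) >= config.min_region_separation_mm for c in centers):
            centers.append(cand)
        if len(centers) == config.n_true_regions:
            break
    else:
        raise ValueError(
            f"could not place {config.n_true_regions} region centers with "
            f"separation {config.min_region_separation_mm} mm in this grid"
        )
    centers_arr = np.array(centers)

    experiments = []
    for i in range(config.n_experiments):
        which = rng.integers(0, config.n_true_regions, size=config.foci_per_experiment)
        foci = centers_arr[which] + rng.normal(
            0.0, config.jitter_sd_mm, size=(config.foci_per_experiment, 3)
        )
        if config.decoy_foci_per_experiment:
            decoys = rng.uniform(lo, hi, size=(config.decoy_foci_per_experiment, 3))
            foci = np.vstack([foci, decoys])
        foci = np.clip(foci, lo, hi)
        experiments.append(
            Experiment(
                experiment_id=f"exp{i:02d}",
                n_subjects=int(rng.integers(10, 51)),
                foci=foci,
            )
        )
    return FociSet(tuple(experiments)), centers_arr


def gen_expression(
    config: SimulationConfig, mask: VoxelMap
) -> tuple[AnnotatedExpression, list[str]]:
    """Expression with an inside-mask shift planted in one donor only.

    Baseline values are i.i.d. normal per gene around a per-gene mean; for
    the aberrant donor, planted genes are shifted up by
    ``effect_size_delta * noise_sd`` in samples whose coordinate falls
    inside the binarized mask.  Sample coordinates are placed so that
    roughly ``inside_sample_fraction`` of each donor's samples fall inside
    the mask (the overlap regime of atlas samples with a hypometabolism
    mask); with ``inside_sample_fraction=None`` coordinates are uniform
    over the grid instead.  A configurable fraction of samples is flagged
    allocortical to exercise the cortex filter.  Returns the annotated
    expression and the planted gene symbols.
    """
    inside_vox = np.argwhere(mask.values > 0)
    if inside_vox.shape[0] == 0:
        raise ValueError("mask has no interior voxels")
    rng = config.rng("expression")
    shape = np.array(mask.shape)
    n_total = config.n_donors * config.n_samples_per_donor

    genes = [f"GENE{i:05d}" for i in range(config.n_genes)]
    planted = sorted(
        rng.choice(config.n_genes, size=min(config.planted_set_size, config.n_genes),
                   replace=False)
    )
    planted_genes = [genes[i] for i in planted]

    gene_mean = rng.normal(0.0, 1.0, size=config.n_genes)

    sample_rows = []
    inside_flags = np.zeros(n_total, dtype=bool)
    coords_mm = np.zeros((n_total, 3))
    pos = 0
    outside_vox = np.argwhere(mask.values <= 0)
    for d, donor in enumerate(config.donor_ids):
        if config.inside_sample_fraction is None or outside_vox.shape[0] == 0:
            idx = rng.integers(0, shape, size=(config.n_samples_per_donor, 3))
        else:
            n_in = int(round(config.inside_sample_fraction * config.n_samples_per_donor))
            n_in = min(max(n_in, config.min_inside_per_donor),
                       config.n_samples_per_donor)
            idx = np.vstack(
                [
                    inside_vox[rng.integers(0, inside_vox.shape[0], size=n_in)],
                    outside_vox[
                        rng.integers(0, outside_vox.shape[0],
                                     size=config.n_samples_per_donor - n_in)
                    ],
                ]
            )
            idx = rng.permutation(idx)
        is_in = mask.values[idx[:, 0], idx[:, 1], idx[:, 2]] > 0
        deficit = config.min_inside_per_donor - int(is_in.sum())
        if deficit > 0:
            # guarantee testability per donor: move the first samples inside
            repl = inside_vox[rng.integers(0, inside_vox.shape[0], size=deficit)]
            idx[:deficit] = repl
            is_in = mask.values[idx[:, 0], idx[:, 1], idx[:, 2]] > 0
        mm = mask.index_to_mm(idx)
        allo = rng.random(config.n_samples_per_donor) < config.allocortex_fraction
        for s in range(config.n_samples_per_donor):
            sample_rows.append(
                {
                    "sample_id": f"{donor}_s{s:03d}",
                    "donor_id": donor,
                    "structure_name": (
                        "hippocampal formation" if allo[s] else f"ctx_region_{s % 8}"
                    ),
                    "is_cerebral_cortex": True,
                    "is_allocortex": bool(allo[s]),
                    "mni_x": mm[s, 0],
                    "mni_y": mm[s, 1],
                    "mni_z": mm[s, 2],
                }
            )
        inside_flags[pos : pos + config.n_samples_per_donor] = is_in
        coords_mm[pos : pos + config.n_samples_per_donor] = mm
        pos += config.n_samples_per_donor

    samples = pd.DataFrame(sample_rows)
    values = gene_mean[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, n_total)
    )
    aberrant = (
        samples["donor_id"] == config.donor_ids[config.aberrant_donor_index]
    ).to_numpy()
    target_cols = aberrant & inside_flags
    if target_cols.any():
        values[np.ix_(planted, np.flatnonzero(target_cols))] += (
            config.effect_size_delta * config.noise_sd
        )
    expression = pd.DataFrame(values, index=genes, columns=samples["sample_id"])
    return AnnotatedExpression(expression, samples), planted_genes


def gen_state_matrix(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[str]]:
    """Gene x ordered-state means with a planted monotone-increasing set.

    Background genes have exchangeable state means (i.i.d. noise); planted
    genes climb by ``monotone_step_sd * noise_sd`` per state.  The planted
    set has ``planted_set_size`` genes of which a ``planted_monotone_fraction``
    share actually receives the monotone profile (the rest stay background,
    modeling imperfect marker sets).  Returns the matrix and the planted
    (monotone) gene symbols.
    """
    if config.n_states < 2:
        raise ValueError("need at least 2 ordered states")
    rng = config.rng("states")
    genes = [f"mgene{i:05d}" for i in range(config.n_genes)]
    n_planted = min(config.planted_set_size, config.n_genes)
    chosen = sorted(rng.choice(config.n_genes, size=n_planted, replace=False))
    n_monotone = int(round(config.planted_monotone_fraction * n_planted))
    monotone_idx = chosen[:n_monotone]

    base = rng.normal(0.0, 1.0, size=config.n_genes)
    values = base[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, config.n_states)
    )
    step = config.monotone_step_sd * config.noise_sd
    values[monotone_idx] += step * np.arange(config.n_states)[None, :]

    states = pd.DataFrame(
        values, index=genes, columns=[f"state{k}" for k in range(config.n_states)]
    )
    return states, [genes[i] for i in monotone_idx]


def gen_markers(
    config: SimulationConfig,
) -> tuple[dict[str, list[str]], AnnotatedExpression, pd.DataFrame]:
    """Marker lists plus expression driven by latent cell-type proportions.

    Per-sample latent proportions come from a symmetric Dirichlet; each
    marker of a type scales linearly with that type's standardized latent
    proportion (slope ``marker_signal_sd``) plus Gaussian noise.  When
    ``interaction_effect`` is nonzero, the last cell type's proportion
    score is additionally raised by that many latent-sd units in samples
    that are both inside the mask and from the aberrant donor, planting the
    region x donor interaction.  Returns (marker lists, expression, truth
    table with latent proportions and flags).
    """
    rng = config.rng("markers")
    n_types = config.n_cell_types
    n_samp = config.n_marker_samples
    type_names = [
        _CELL_TYPE_NAMES[i] if i < len(_CELL_TYPE_NAMES) else f"celltype{i}"
        for i in range(n_types)
    ]
    props = rng.dirichlet(np.full(n_types, config.dirichlet_alpha), size=n_samp)
    latent = (props - props.mean(axis=0)) / props.std(axis=0, ddof=0)

    donors = np.array([config.donor_ids[i % config.n_donors] for i in range(n_samp)])
    inside = rng.random(n_samp) < 0.3
    aberrant = donors == config.donor_ids[config.aberrant_donor_index]
    if config.interaction_effect:
        latent[:, -1] = latent[:, -1] + config.interaction_effect * (
            inside & aberrant
        ).astype(float)

    markers: dict[str, list[str]] = {}
    rows = []
    gene_names: list[str] = []
    for t, tname in enumerate(type_names):
        names = [f"{tname.upper()}_M{j:02d}" for j in range(config.n_markers_per_type)]
        markers[tname] = names
        gene_names.extend(names)
        for _ in names:
            rows.append(
                config.marker_signal_sd * latent[:, t]
                + rng.normal(0.0, config.noise_sd, size=n_samp)
            )
    # background genes carrying no proportion signal
    for j in range(50):
        gene_names.append(f"BACKGROUND_{j:03d}")
        rows.append(rng.normal(0.0, config.noise_sd, size=n_samp))

    sample_ids = [f"msamp{i:03d}" for i in range(n_samp)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "donor_id": donors,
            "structure_name": [f"ctx_region_{i % 8}" for i in range(n_samp)],
            "is_cerebral_cortex": True,
            "is_allocortex": False,
            "mni_x": 0.0,
            "mni_y": 0.0,
            "mni_z": 0.0,
            "inside": inside,
        }
    )
    expression = pd.DataFrame(np.array(rows), index=gene_names, columns=sample_ids)
    truth = pd.DataFrame(latent, columns=type_names, index=sample_ids)
    truth["donor_id"] = donors
    truth["inside"] = inside
    return markers, AnnotatedExpression(expression, samples), truth


def gen_decoy_sets(
    universe: Sequence[str],
    n_sets: int,
    rng: np.random.Generator,
    size_min: int = 10,
    size_max: int = 200,
    prefix: str = "DECOY",
) -> GeneSetCollection:
    """Random gene sets drawn uniformly from a universe (null sets)."""
    universe = list(universe)
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(size_min, min(size_max, len(universe)) + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"{prefix}:{i:04d}"] = [universe[j] for j in sorted(members)]
    return GeneSetCollection(sets)


def gen_homolog_map(
    source_genes: Sequence[str],
    target_genes: Sequence[str],
    n_duplicated: int = 0,
) -> HomologMap:
    """One-to-one source→target pairs, with the first ``n_duplicated``
    source genes additionally mapped to a second target (one-to-many)."""
    pairs = list(zip(source_genes, target_genes))
    extra_targets = [t for t in target_genes if t not in dict(pairs).values()]
    for i in range(n_duplicated):
        spare = f"{target_genes[i]}_paralog"
        pairs.append((source_genes[i], spare))
    return HomologMap(tuple(pairs))
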