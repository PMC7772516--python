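"""Core in-memory containers shared across the pipeline.

The pipeline moves five kinds of objects between stages: peak-coordinate
tables for the coordinate-based meta-analysis (:class:`FociSet`), voxel
grids holding activation-likelihood values or binary masks
(:class:`VoxelMap`, :class:`ClusterMask`), annotated expression matrices
(:class:`AnnotatedExpression`), gene-set collections
(:class:`GeneSetCollection`), and cross-species homolog maps
(:class:`HomologMap`).  All containers validate their invariants at
construction time; readers in :mod:`hypometa.io` construct them from disk
formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Experiment",
    "FociSet",
    "GeneSetCollection",
    "HomologMap",
    "VoxelMap",
    "ClusterMask",
    "AnnotatedExpression",
]


@dataclass(frozen=True)
class Experiment:
    """One study/sample in a coordinate-based meta-analysis.

    Parameters
    ----------
    experiment_id
        Unique label of the study sample.
    n_subjects
        Number of subjects contributing to the contrast; must be >= 1.
    foci
        ``(k, 3)`` array of peak coordinates in MNI mm, ``k >= 1``.
    """

    experiment_id: str
    n_subjects: int
    foci: np.ndarray

    def __post_init__(self) -> None:
        foci = np.asarray(self.foci, dtype=float)
        if foci.ndim != 2 or foci.shape[1] != 3 or foci.shape[0] < 1:
            raise ValueError(
                f"experiment {self.experiment_id!r}: foci must be a (k, 3) "
                f"array with k >= 1, got shape {foci.shape}"
            )
        if not np.all(np.isfinite(foci)):
            raise ValueError(
                f"experiment {self.experiment_id!r}: non-finite focus coordinate"
            )
        if int(self.n_subjects) < 1:
            raise ValueError(
                f"experiment {self.experiment_id!r}: n_subjects must be >= 1, "
                f"got {self.n_subjects}"
            )
        object.__setattr__(self, "foci", foci)
        object.__setattr__(self, "n_subjects", int(self.n_subjects))


@dataclass(frozen=True)
class FociSet:
    """A set of experiments with hypometabolism peak coordinates."""

    experiments: tuple[Experiment, ...]

    def __post_init__(self) -> None:
        exps = tuple(self.experiments)
        ids = [e.experiment_id for e in exps]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate experiment ids: {dupes}")
        object.__setattr__(self, "experiments", exps)

    def __len__(self) -> int:
        return len(self.experiments)

    def __iter__(self):
        return iter(self.experiments)

    @property
    def n_foci(self) -> int:
        return sum(e.foci.shape[0] for e in self.experiments)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the on-disk tabular layout (experiment, n, x, y, z)."""
        rows = []
        for e in self.experiments:
            for x, y, z in e.foci:
                rows.append((e.experiment_id, e.n_subjects, x, y, z))
        return pd.DataFrame(rows, columns=["experiment", "n", "x", "y", "z"])


class GeneSetCollection:
    """A collection of named gene sets (e.g. one GO branch).

    Within-set duplicate symbols are collapsed; set order and within-set
    gene order are preserved from the input.
    """

    def __init__(
        self,
        sets: Mapping[str, Sequence[str]],
        names: Mapping[str, str] | None = None,
        namespace: str | None = None,
    ) -> None:
        self.sets: dict[str, list[str]] = {}
        self.names: dict[str, str] = {}
        self.namespace = namespace
        for set_id, genes in sets.items():
            seen: dict[str, None] = {}
            for g in genes:
                if not isinstance(g, str) or not g:
                    raise ValueError(f"set {set_id!r}: empty or non-string gene symbol")
                seen.setdefault(g)
            self.sets[set_id] = list(seen)
            self.names[set_id] = (names or {}).get(set_id, set_id)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def __getitem__(self, set_id: str) -> list[str]:
        return self.sets[set_id]

    def items(self):
        return self.sets.items()


@dataclass(frozen=True)
class HomologMap:
    """Ordered source→target gene symbol pairs; one-to-many both ways."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        pairs = tuple((str(a), str(b)) for a, b in self.pairs)
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate homolog pairs")
        object.__setattr__(self, "pairs", pairs)

    def translate(self, genes: Sequence[str]) -> list[tuple[str, str]]:
        """Expand genes to (source, target) rows; untranslated genes dropped.

        A source gene with several homologs contributes one row per target.
        """
        lookup: dict[str, list[str]] = {}
        for a, b in self.pairs:
            lookup.setdefault(a, []).append(b)
        out: list[tuple[str, str]] = []
        for g in genes:
            for t in lookup.get(g, []):
                out.append((g, t))
        return out


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (not banker's)."""
    return np.trunc(x + np.copysign(0.5, x)).astype(int)


@dataclass
class VoxelMap:
    """A 3-D scalar grid with an affine mapping voxel indices to MNI mm.

    ``values[i, j, k]`` lives at mm coordinate ``affine @ (i, j, k, 1)``.
    """

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got ndim={self.values.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm along the three index axes."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        homog = np.c_[idx, np.ones(len(idx))]
        return (self.affine @ homog.T).T[:, :3]

    def mm_to_index(self, mm: np.ndarray) -> np.ndarray:
        """Nearest-voxel index for mm coordinates (half away from zero)."""
        mm = np.atleast_2d(np.asarray(mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        homog = np.c_[mm, np.ones(len(mm))]
        cont = (inv @ homog.T).T[:, :3]
        return _round_half_away(cont)

    def in_bounds(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        shape = np.array(self.shape)
        return np.all((idx >= 0) & (idx < shape), axis=1)

    def like(self, values: np.ndarray) -> "VoxelMap":
        return VoxelMap(values=values, affine=self.affine.copy())


@dataclass
class ClusterMask:
    """Labeled connected components of a thresholded voxel map.

    ``labels`` holds 0 for background and 1..n for clusters ordered by
    decreasing extent.  ``table`` carries per-cluster extent (mm^3), voxel
    count, peak value and peak index.
    """

    labels: np.ndarray
    affine: np.ndarray
    table: pd.DataFrame
    threshold: float
    connectivity: int

    def as_voxelmap(self) -> VoxelMap:
        """Binary inside/outside map of all retained clusters."""
        return VoxelMap(values=(self.labels > 0).astype(float), affine=self.affine)

    @property
    def n_clusters(self) -> int:
        return int(self.table.shape[0])


#: Required columns in the per-sample annotation table.
SAMPLE_COLUMNS = [
    "sample_id",
    "donor_id",
    "structure_name",
    "is_cerebral_cortex",
    "is_allocortex",
    "mni_x",
    "mni_y",
    "mni_z",
]


class AnnotatedExpression:
    """Gene x sample expression with per-sample spatial annotations.

    Parameters
    ----------
    expression
        DataFrame with gene symbols as the index and sample ids as columns.
    samples
        DataFrame with one row per sample carrying donor id, anatomical
        structure, cortex/allocortex flags and MNI mm coordinates
        (columns in :data:`SAMPLE_COLUMNS`); an ``inside`` column appears
        only after :func:`hypometa.labeling.label_inside`.
    """

    def __init__(self, expression: pd.DataFrame, samples: pd.DataFrame) -> None:
        samples = samples.copy()
        if "sample_id" in samples.columns:
            samples = samples.set_index("sample_id", drop=False)
        missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        if list(expression.columns) != list(samples.index):
            if set(expression.columns) != set(samples.index):
                raise ValueError(
                    "expression columns and sample table ids do not match"
                )
            samples = samples.loc[list(expression.columns)]
        if expression.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression index")
        self.expression = expression
        self.samples = samples

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def has_inside_labels(self) -> bool:
        return "inside" in self.samples.columns

    def coordinates(self) -> np.ndarray:
        return self.samples[["mni_x", "mni_y", "mni_z"]].to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AnnotatedExpression":
        ids = list(sample_ids)
        return AnnotatedExpression(self.expression[ids], self.samples.loc[ids])

    def copy(self) -> "AnnotatedExpression":
        return AnnotatedExpression(self.expression.copy(), self.samples.copy())
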