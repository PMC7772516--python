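"""Readers and writers for every on-disk format the pipeline touches.

Formats: tab/comma-delimited foci tables, GMT gene-set collections,
NIfTI-1 voxel maps, TSV expression matrices (genes x samples) with a
sidecar sample-annotation TSV, two-column homolog maps, and gene x
ordered-state mean-expression TSVs.  Every reader validates and reports
the offending line or field on malformed input; ``write`` then ``read``
is the identity on validated objects.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import (
    SAMPLE_COLUMNS,
    AnnotatedExpression,
    Experiment,
    FociSet,
    GeneSetCollection,
    HomologMap,
    VoxelMap,
)

logger = logging.getLogger("hypometa")

__all__ = [
    "read_foci_table",
    "write_foci_table",
    "read_gmt",
    "write_gmt",
    "read_nifti",
    "write_nifti",
    "read_expression",
    "write_expression",
    "read_homolog_map",
    "write_homolog_map",
    "read_state_matrix",
    "write_state_matrix",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line/field."""


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_foci_table(path: str | Path) -> FociSet:
    """Read a peak-coordinate table into a :class:`FociSet`.

    The file is tab- or comma-delimited with header columns
    ``experiment, n, x, y, z``; one row per focus, rows grouped by
    experiment id (grouping is by id, not adjacency).
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = ["experiment", "n", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in ["n", "x", "y", "z"]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad) > 0:
            # +2: 1-based line numbers plus the header line
            raise ParseError(
                f"{path}: non-numeric value {df.loc[bad[0], col]!r} in column "
                f"{col!r} at line {bad[0] + 2}"
            )
        if converted.isna().any():
            row = int(converted.index[converted.isna()][0])
            raise ParseError(f"{path}: empty {col!r} at line {row + 2}")
        # numpy strtod is correctly rounded; pd.to_numeric's fast path is not
        df[col] = df[col].to_numpy(dtype=str).astype(float)
    bad_n = df.index[df["n"] < 1]
    if len(bad_n) > 0:
        raise ParseError(
            f"{path}: n < 1 for experiment {df.loc[bad_n[0], 'experiment']!r} "
            f"at line {bad_n[0] + 2}"
        )
    experiments = []
    for exp_id, grp in df.groupby("experiment", sort=False):
        n_vals = grp["n"].unique()
        if len(n_vals) > 1:
            raise ParseError(
                f"{path}: experiment {exp_id!r} has inconsistent n values {sorted(n_vals)}"
            )
        experiments.append(
            Experiment(
                experiment_id=str(exp_id),
                n_subjects=int(n_vals[0]),
                foci=grp[["x", "y", "z"]].to_numpy(dtype=float),
            )
        )
    foci_set = FociSet(tuple(experiments))
    logger.info(
        "read_foci_table: %d experiments, %d foci from %s",
        len(foci_set), foci_set.n_foci, path,
    )
    return foci_set


def write_foci_table(foci: FociSet, path: str | Path) -> None:
    foci.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line ``set_id<TAB>description<TAB>gene...``.

    Duplicate symbols within a set are collapsed with a logged warning;
    an empty file yields an empty collection.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "expected set_id, description, and at least one gene"
                )
            set_id, name, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if set_id in sets:
                raise ParseError(f"{path}: duplicate set id {set_id!r} at line {lineno}")
            if len(set(genes)) != len(genes):
                logger.warning(
                    "read_gmt: duplicate genes within set %s (line %d) collapsed",
                    set_id, lineno,
                )
            sets[set_id] = genes
            names[set_id] = name
    return GeneSetCollection(sets, names=names)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, genes in collection.items():
            fh.write("\t".join([set_id, collection.names[set_id], *genes]) + "\n")


def read_nifti(path: str | Path) -> VoxelMap:
    """Load a single-volume NIfTI-1 file as a :class:`VoxelMap`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise ValueError(
            f"{path}: expected a single 3-D volume, got shape {data.shape}; "
            "select one volume before loading"
        )
    return VoxelMap(values=np.asarray(data, dtype=float), affine=np.asarray(img.affine))


def write_nifti(vmap: VoxelMap, path: str | Path) -> None:
    img = nib.Nifti1Image(vmap.values.astype(np.float64), vmap.affine)
    nib.save(img, str(path))


def read_expression(
    expr_path: str | Path, samples_path: str | Path
) -> AnnotatedExpression:
    """Read a genes x samples TSV plus its sidecar sample-annotation TSV.

    The expression file has gene symbols in the first column; the sample
    table carries :data:`hypometa.datatypes.SAMPLE_COLUMNS` (an extra
    ``inside`` column is preserved if present).
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0, float_precision="round_trip")
    expr.columns = expr.columns.astype(str)
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str, "donor_id": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ParseError(f"{samples_path}: missing column(s) {missing}")
    for col in ("is_cerebral_cortex", "is_allocortex"):
        samples[col] = samples[col].astype(bool)
    if "inside" in samples.columns:
        samples["inside"] = samples["inside"].astype(bool)
    return AnnotatedExpression(expr, samples)


def write_expression(
    expr: AnnotatedExpression, expr_path: str | Path, samples_path: str | Path
) -> None:
    expr.expression.to_csv(expr_path, sep="\t", float_format="%.17g")
    expr.samples.to_csv(samples_path, sep="\t", index=False, float_format="%.17g")


def read_homolog_map(path: str | Path) -> HomologMap:
    """Read a two-column TSV of source→target gene symbol pairs."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        header = fh.readline()  # header row required, content free-form
        if not header.strip():
            return HomologMap(())
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ParseError(
                    f"{path}: line {lineno}: expected two non-empty tab-separated symbols"
                )
            pairs.append((fields[0], fields[1]))
    return HomologMap(tuple(pairs))


def write_homolog_map(hmap: HomologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source_gene\ttarget_gene\n")
        for a, b in hmap.pairs:
            fh.write(f"{a}\t{b}\n")


def read_state_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x ordered-state mean-expression TSV.

    Column order in the file defines the state order (left = first state).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need at least 2 state columns, got {df.shape[1]}")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ParseError(f"{path}: duplicate gene symbols {dupes}")
    return df


def write_state_matrix(states: pd.DataFrame, path: str | Path) -> None:
    states.to_csv(path, sep="\t", float_format="%.17g")


def filter_log(stage: str, kept: int, removed: dict[str, int]) -> None:
    """Machine-readable audit line for filtering rules (stderr via logging)."""
    parts = " ".join(f"removed_{k}={v}" for k, v in removed.items())
    logger.info("%s: kept=%d %s", stage, kept, parts)
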