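"""Reading, writing and bookkeeping of expression matrices and sample annotations.

The on-disk formats are plain tab-separated text:

* expression matrix — genes in rows, samples in columns, one header row of
  sample ids, first column holds gene ids;
* sample annotation — one row per sample with columns ``sample_id``,
  ``compound_id``, ``class_label``, ``vehicle``, ``replicate``, ``potency``.

In memory a :class:`Dataset` pairs the matrix (a ``pandas.DataFrame``,
genes x samples, log2-scale normalized intensities) with the annotation
table (indexed by sample id, in matrix column order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Reserved compound ids for unstimulated solvent controls.
VEHICLE_DMSO = "VEHICLE_DMSO"
VEHICLE_WATER = "VEHICLE_WATER"
VEHICLE_TOKENS = (VEHICLE_DMSO, VEHICLE_WATER)

CLASS_SENSITIZER = "sensitizer"
CLASS_NONSENSITIZER = "non_sensitizer"
CLASS_CONTROL = "vehicle_control"
CLASS_LABELS = (CLASS_SENSITIZER, CLASS_NONSENSITIZER, CLASS_CONTROL)

POTENCY_LEVELS = ("extreme", "strong", "moderate", "weak")
POTENCY_NONE = "none"

ANNOTATION_COLUMNS = ("compound_id", "class_label", "vehicle", "replicate", "potency")


class DataError(ValueError):
    """Raised when an input file or table violates a structural invariant."""


@dataclass
class Dataset:
    """An expression matrix aligned with its per-sample annotation.

    ``expr`` is genes x samples; ``annot`` is indexed by sample id with one
    row per matrix column, in the same order.
    """

    expr: pd.DataFrame
    annot: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.expr.columns) != list(self.annot.index):
            raise DataError("annotation sample ids do not match matrix columns in order")

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expr.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expr.columns)

    def compounds(self, chemicals_only: bool = True) -> list[str]:
        """Unique compound ids in annotation order.

        With ``chemicals_only`` the reserved vehicle-control tokens are
        dropped, leaving the test chemicals.
        """
        seen: dict[str, None] = {}
        for c in self.annot["compound_id"]:
            if chemicals_only and c in VEHICLE_TOKENS:
                continue
            seen.setdefault(c, None)
        return list(seen)

    def subset_samples(self, sample_ids: Sequence[str]) -> "Dataset":
        """New Dataset restricted to ``sample_ids`` (kept in given order)."""
        missing = [s for s in sample_ids if s not in self.expr.columns]
        if missing:
            raise DataError(f"unknown sample ids: {missing}")
        return Dataset(self.expr[list(sample_ids)], self.annot.loc[list(sample_ids)])

    def subset_compounds(self, compound_ids: Iterable[str]) -> "Dataset":
        wanted = set(compound_ids)
        keep = [s for s, c in self.annot["compound_id"].items() if c in wanted]
        return self.subset_samples(keep)

    def class_counts(self) -> dict[str, int]:
        return self.annot["class_label"].value_counts().to_dict()


def read_expression(path) -> pd.DataFrame:
    """Read a genes-x-samples TSV into a DataFrame (genes as index).

    Raises :class:`DataError` naming the offending id / line / cell for
    duplicate ids, ragged rows and non-numeric values.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 1:
            raise DataError(f"{path}: empty header")
        sample_ids = header[1:]
        dup = _first_duplicate(sample_ids)
        if dup is not None:
            raise DataError(f"{path}: duplicate sample id {dup!r}")
        gene_ids: list[str] = []
        rows: list[np.ndarray] = []
        ncol = len(header)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != ncol:
                raise DataError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected {ncol}"
                )
            gene_ids.append(fields[0])
            try:
                rows.append(np.asarray(fields[1:], dtype=float))
            except ValueError:
                for j, cell in enumerate(fields[1:], start=1):
                    try:
                        float(cell)
                    except ValueError:
                        # (row, col) are 1-based coordinates in the value matrix
                        raise DataError(
                            f"{path}: non-numeric value {cell!r} at "
                            f"({lineno - 1},{j})"
                        ) from None
        dup = _first_duplicate(gene_ids)
        if dup is not None:
            raise DataError(f"{path}: duplicate gene id {dup!r}")
    values = np.vstack(rows) if rows else np.empty((0, len(sample_ids)))
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise DataError(f"{path}: non-finite value at ({i + 1},{j + 1})")
    return pd.DataFrame(values, index=gene_ids, columns=sample_ids)


def write_expression(expr: pd.DataFrame, path) -> None:
    """Write a genes-x-samples matrix as TSV (inverse of :func:`read_expression`)."""
    out = expr.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_annotation(path) -> pd.DataFrame:
    """Read a sample-annotation TSV, indexed by sample_id."""
    annot = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "compound_id": str})
    missing = [c for c in ("sample_id", *ANNOTATION_COLUMNS) if c not in annot.columns]
    if missing:
        raise DataError(f"{path}: missing annotation columns {missing}")
    dup = _first_duplicate(list(annot["sample_id"]))
    if dup is not None:
        raise DataError(f"{path}: duplicate sample id {dup!r}")
    annot = annot.set_index("sample_id")
    _validate_annotation(annot, origin=str(path))
    return annot


def write_annotation(annot: pd.DataFrame, path) -> None:
    out = annot.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def _validate_annotation(annot: pd.DataFrame, origin: str = "annotation") -> None:
    bad = set(annot["class_label"]) - set(CLASS_LABELS)
    if bad:
        raise DataError(f"{origin}: unknown class labels {sorted(bad)}")
    for sid, row in annot.iterrows():
        is_vehicle = row["compound_id"] in VEHICLE_TOKENS
        if is_vehicle != (row["class_label"] == CLASS_CONTROL):
            raise DataError(
                f"{origin}: sample {sid!r} — class_label must be "
                f"{CLASS_CONTROL!r} iff compound_id is a vehicle token"
            )
        is_sens = row["class_label"] == CLASS_SENSITIZER
        has_potency = row["potency"] != POTENCY_NONE
        if is_sens != has_potency:
            raise DataError(
                f"{origin}: sample {sid!r} — potency must be set iff the "
                "sample is a sensitizer"
            )
        if has_potency and row["potency"] not in POTENCY_LEVELS:
            raise DataError(f"{origin}: sample {sid!r} — unknown potency {row['potency']!r}")


def assemble_dataset(expr: pd.DataFrame, annot: pd.DataFrame) -> Dataset:
    """Pair an expression matrix with its annotation table.

    The annotation is reordered to match the matrix column order.  Every
    sample must be annotated exactly once; unmatched ids on either side are
    an error.
    """
    matrix_ids = set(expr.columns)
    annot_ids = set(annot.index)
    unannotated = sorted(matrix_ids - annot_ids)
    orphans = sorted(annot_ids - matrix_ids)
    if unannotated or orphans:
        raise DataError(
            f"sample/annotation mismatch: unannotated samples {unannotated}, "
            f"orphan annotations {orphans}"
        )
    _validate_annotation(annot)
    ds = Dataset(expr, annot.loc[list(expr.columns)])
    logger.info(
        "assembled dataset: %d genes x %d samples; per-class counts %s",
        ds.n_genes, ds.n_samples, ds.class_counts(),
    )
    return ds


def remove_samples(
    ds: Dataset,
    drop_compounds: Sequence[str] = (),
    drop_samples: Sequence[str] = (),
) -> Dataset:
    """Remove all replicates of named compounds and individually named samples.

    Mirrors the usual QC bookkeeping after array quality control: whole
    compounds whose stimulations were outliers are dropped with all their
    replicates, single faulty arrays are dropped by sample id.  Expression
    values of retained samples are untouched.
    """
    known_compounds = set(ds.annot["compound_id"])
    unknown = sorted(set(drop_compounds) - known_compounds)
    if unknown:
        raise DataError(f"unknown compounds: {unknown}")
    unknown = sorted(set(drop_samples) - set(ds.sample_ids))
    if unknown:
        raise DataError(f"unknown samples: {unknown}")
    drop_c = set(drop_compounds)
    drop_s = set(drop_samples)
    keep = [
        sid
        for sid in ds.sample_ids
        if sid not in drop_s and ds.annot.at[sid, "compound_id"] not in drop_c
    ]
    before = ds.class_counts()
    out = ds.subset_samples(keep)
    logger.info(
        "remove_samples: %d -> %d samples (per-class before %s, after %s)",
        ds.n_samples, out.n_samples, before, out.class_counts(),
    )
    return out


class OutlierScore(NamedTuple):
    compound_id: str
    score: float
    flagged: bool


def flag_outlier_compounds(
    ds: Dataset, k_components: int = 5, mad_threshold: float = 6.0
) -> list[OutlierScore]:
    """Advisory screen for compounds whose profiles dominate the dataset.

    Samples are projected onto the top ``k_components`` principal components;
    each sample's Euclidean distance from the grand centroid is converted to
    a robust z-score (median/MAD over all samples), and a compound's score is
    the median robust z of its replicates.  Compounds scoring above
    ``mad_threshold`` are flagged.  Flags are advisory only — removal stays
    an explicit :func:`remove_samples` call.
    """
    if len(ds.compounds(chemicals_only=False)) < 3:
        raise DataError("outlier screen needs at least 3 compounds")
    X = ds.expr.to_numpy().T  # samples x genes
    Xc = X - X.mean(axis=0)
    feasible = min(ds.n_samples - 1, ds.n_genes)
    if k_components > feasible:
        raise DataError(
            f"k_components={k_components} exceeds feasible rank {feasible}"
        )
    # PCA by SVD of the centered sample matrix
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = u[:, :k_components] * s[:k_components]
    dist = np.linalg.norm(scores, axis=1)
    med = np.median(dist)
    mad = np.median(np.abs(dist - med))
    if mad == 0.0:
        robust_z = np.where(dist == med, 0.0, np.inf)
    else:
        robust_z = (dist - med) / (1.4826 * mad)
    z = pd.Series(robust_z, index=ds.sample_ids)
    out: list[OutlierScore] = []
    for comp in ds.compounds(chemicals_only=False):
        sids = ds.annot.index[ds.annot["compound_id"] == comp]
        score = float(np.median(z.loc[sids]))
        out.append(OutlierScore(comp, score, score > mad_threshold))
    out.sort(key=lambda r: (-r.score, r.compound_id))
    return out
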