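"""Multi-modal dataset container and TSV / PLINK-raw readers and writers.

A :class:`MultiModalDataset` holds one samples-by-features matrix whose
columns are partitioned into contiguous, named modality blocks (for example
an ``imaging`` block of continuous structural-MRI measures and an ``snp``
block of additive genotype codes 0/1/2), together with per-sample string
IDs and class labels.

Orientation convention: the in-memory matrix is **samples as rows**
(N x d), matching the on-disk layout.  Algorithms that work in the
features-as-rows orientation (the multi-task selector) transpose through
the accessors; the raw attribute is never re-oriented.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataFormatError

GENOTYPE_VALUES = (0.0, 1.0, 2.0)


@dataclass
class MultiModalDataset:
    """Samples-by-features matrix with a modality partition and labels.

    Attributes
    ----------
    X : ndarray of shape (N, d)
        Feature matrix, samples as rows.
    y : ndarray of shape (N,), dtype str
        Per-sample class label.
    modality_blocks : list of (str, (int, int))
        Ordered ``(name, (start, stop))`` column ranges; they must
        partition ``[0, d)`` contiguously with no gap or overlap.
    feature_names : list of str, length d
    sample_ids : list of str, length N
    class_order : list of str
        All classes in increasing disease-stage order; the last entry is
        treated as the positive class by the evaluation module.  Defaults
        to the sorted unique labels.
    """

    X: np.ndarray
    y: np.ndarray
    modality_blocks: list[tuple[str, tuple[int, int]]]
    feature_names: list[str]
    sample_ids: list[str]
    class_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=str)
        if not self.class_order:
            self.class_order = sorted(np.unique(self.y).tolist())
        self.validate()

    # -- shape accessors -------------------------------------------------
    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def c(self) -> int:
        return len(self.class_order)

    @property
    def block_names(self) -> list[str]:
        return [name for name, _ in self.modality_blocks]

    def block_slice(self, name: str) -> slice:
        for bname, (start, stop) in self.modality_blocks:
            if bname == name:
                return slice(start, stop)
        raise KeyError(f"unknown modality block {name!r}")

    def block(self, name: str) -> np.ndarray:
        """Column view of one modality block (samples as rows)."""
        return self.X[:, self.block_slice(name)]

    def block_feature_names(self, name: str) -> list[str]:
        s = self.block_slice(name)
        return self.feature_names[s]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.X.ndim != 2:
            raise ConfigurationError("X must be a 2-D samples-by-features matrix")
        n, d = self.X.shape
        if len(self.sample_ids) != n:
            raise ConfigurationError(f"{len(self.sample_ids)} sample IDs for {n} rows")
        if len(set(self.sample_ids)) != n:
            raise DataFormatError("duplicate sample IDs")
        if len(self.feature_names) != d:
            raise ConfigurationError(f"{len(self.feature_names)} feature names for {d} columns")
        if self.y.shape != (n,):
            raise ConfigurationError("y must have one label per sample")
        if not np.isfinite(self.X).all():
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise DataFormatError(
                f"non-finite value at sample {self.sample_ids[bad[0]]}, "
                f"feature {self.feature_names[bad[1]]}"
            )
        cursor = 0
        seen = set()
        for name, (start, stop) in self.modality_blocks:
            if name in seen:
                raise ConfigurationError(f"duplicate modality block {name!r}")
            seen.add(name)
            if start != cursor or stop <= start:
                raise ConfigurationError(
                    f"modality blocks must partition [0, {d}) contiguously; "
                    f"block {name!r} spans [{start}, {stop}) after cursor {cursor}"
                )
            cursor = stop
        if cursor != d:
            raise ConfigurationError(f"modality blocks cover [0, {cursor}) but d={d}")
        declared = set(self.class_order)
        present = set(np.unique(self.y).tolist())
        if not present <= declared:
            raise ConfigurationError(f"labels {present - declared} not in class_order")
        if not declared <= present:
            raise ConfigurationError(f"declared classes {declared - present} absent from y")

    # -- functional updates ----------------------------------------------
    def with_matrix(self, X: np.ndarray) -> "MultiModalDataset":
        """Same metadata, new values (shape must match)."""
        if X.shape != self.X.shape:
            raise ConfigurationError("replacement matrix shape mismatch")
        return MultiModalDataset(
            X=X, y=self.y.copy(), modality_blocks=list(self.modality_blocks),
            feature_names=list(self.feature_names), sample_ids=list(self.sample_ids),
            class_order=list(self.class_order),
        )

    def subset_samples(self, idx: Sequence[int]) -> "MultiModalDataset":
        idx = np.asarray(idx, dtype=int)
        return MultiModalDataset(
            X=self.X[idx], y=self.y[idx], modality_blocks=list(self.modality_blocks),
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in idx],
            class_order=list(self.class_order),
        )

    def subset_features(self, keep: Sequence[int]) -> "MultiModalDataset":
        """Column subset; block boundaries are recomputed from surviving columns.

        ``keep`` must be sorted ascending so original feature order is kept.
        """
        keep = np.asarray(keep, dtype=int)
        if np.any(np.diff(keep) <= 0):
            raise ConfigurationError("feature subset indices must be strictly ascending")
        new_blocks: list[tuple[str, tuple[int, int]]] = []
        cursor = 0
        for name, (start, stop) in self.modality_blocks:
            width = int(np.sum((keep >= start) & (keep < stop)))
            if width:
                new_blocks.append((name, (cursor, cursor + width)))
                cursor += width
        return MultiModalDataset(
            X=self.X[:, keep], y=self.y.copy(), modality_blocks=new_blocks,
            feature_names=[self.feature_names[i] for i in keep],
            sample_ids=list(self.sample_ids), class_order=list(self.class_order),
        )

    def equals(self, other: "MultiModalDataset") -> bool:
        return (
            np.array_equal(self.X, other.X)
            and np.array_equal(self.y, other.y)
            and self.modality_blocks == other.modality_blocks
            and self.feature_names == other.feature_names
            and self.sample_ids == other.sample_ids
            and self.class_order == other.class_order
        )


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def _read_tsv_block(path: Path, genotype: bool) -> pd.DataFrame:
    if not path.exists():
        raise DataFormatError(f"missing file {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"empty file {path}") from exc
    except pd.errors.ParserError as exc:
        raise DataFormatError(f"ragged or malformed rows in {path}: {exc}") from exc
    if df.empty or "sample_id" not in df.columns:
        raise DataFormatError(f"{path}: first column must be 'sample_id' with data rows")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataFormatError(f"{path}: duplicate sample ID {dup!r}")
    values = df.drop(columns="sample_id")
    for col in values.columns:
        numeric = pd.to_numeric(values[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise DataFormatError(
                f"{path}: missing or non-numeric value at row {row}, column {col!r}"
            )
        if genotype and not numeric.isin([0, 1, 2]).all():
            row = int((~numeric.isin([0, 1, 2])).idxmax())
            raise DataFormatError(
                f"{path}: genotype value {numeric[row]} at row {row}, column {col!r} "
                "(valid values are 0/1/2)"
            )
        values[col] = numeric.astype(float)
    values.index = df["sample_id"]
    return values


def write_dataset(ds: MultiModalDataset, prefix: str | Path) -> list[Path]:
    """Write one TSV per modality block plus labels and a block manifest.

    Files: ``<prefix>_<block>.tsv`` (sample_id + feature columns),
    ``<prefix>_labels.tsv`` and ``<prefix>_manifest.json`` recording block
    order, genotype coding and the class order.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest = {"blocks": [], "class_order": ds.class_order}
    for name, (start, stop) in ds.modality_blocks:
        sub = ds.X[:, start:stop]
        genotype = bool(np.isin(sub, GENOTYPE_VALUES).all())
        df = pd.DataFrame(sub, columns=ds.feature_names[start:stop])
        if genotype:
            df = df.astype(int)
        else:
            df = df.map(lambda v: repr(float(v)))   # shortest exact round-trip decimal
        df.insert(0, "sample_id", ds.sample_ids)
        path = prefix.parent / f"{prefix.name}_{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
        manifest["blocks"].append({"name": name, "genotype": genotype})
    labels = pd.DataFrame({"sample_id": ds.sample_ids, "label": ds.y})
    lab_path = prefix.parent / f"{prefix.name}_labels.tsv"
    labels.to_csv(lab_path, sep="\t", index=False)
    written.append(lab_path)
    man_path = prefix.parent / f"{prefix.name}_manifest.json"
    man_path.write_text(json.dumps(manifest, indent=1))
    written.append(man_path)
    return written


def read_dataset(prefix: str | Path, block_names: Sequence[str] | None = None) -> MultiModalDataset:
    """Read a dataset written by :func:`write_dataset`.

    Without a manifest, ``block_names`` defaults to ``("imaging", "snp")``
    and the SNP block is validated as 0/1/2 genotype codes.
    """
    prefix = Path(prefix)
    man_path = prefix.parent / f"{prefix.name}_manifest.json"
    class_order: list[str] = []
    if man_path.exists():
        manifest = json.loads(man_path.read_text())
        blocks_meta = [(b["name"], b["genotype"]) for b in manifest["blocks"]]
        class_order = manifest.get("class_order", [])
    else:
        names = block_names if block_names is not None else ("imaging", "snp")
        blocks_meta = [(n, n == "snp") for n in names]

    lab_path = prefix.parent / f"{prefix.name}_labels.tsv"
    if not lab_path.exists():
        raise DataFormatError(f"missing labels file {lab_path}")
    try:
        labels = pd.read_csv(lab_path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"empty file {lab_path}") from exc
    if labels.empty or list(labels.columns[:2]) != ["sample_id", "label"]:
        raise DataFormatError(f"{lab_path}: expected columns sample_id, label")
    if labels["label"].isna().any():
        raise DataFormatError(f"{lab_path}: missing label")
    sample_ids = labels["sample_id"].tolist()

    frames, blocks, feature_names = [], [], []
    cursor = 0
    for name, genotype in blocks_meta:
        path = prefix.parent / f"{prefix.name}_{name}.tsv"
        df = _read_tsv_block(path, genotype=genotype)
        if list(df.index) != sample_ids:
            raise DataFormatError(f"{path}: sample IDs disagree with labels file")
        frames.append(df.to_numpy(dtype=float))
        feature_names.extend(df.columns.tolist())
        blocks.append((name, (cursor, cursor + df.shape[1])))
        cursor += df.shape[1]
    return MultiModalDataset(
        X=np.hstack(frames), y=labels["label"].to_numpy(dtype=str),
        modality_blocks=blocks, feature_names=feature_names,
        sample_ids=sample_ids, class_order=class_order,
    )


# ---------------------------------------------------------------------------
# PLINK .raw additive coding
# ---------------------------------------------------------------------------

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_plink_raw(path: str | Path) -> tuple[list[str], np.ndarray, list[str]]:
    """Parse a PLINK ``.raw`` additive-coding table.

    Only the IID column and the 0/1/2 allele-count columns are consumed.
    Returns ``(sample_ids, genotype matrix N x d, snp_names)``.
    """
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"missing file {path}")
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype={"IID": str, "FID": str})
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"empty file {path}") from exc
    if df.empty or list(df.columns[: len(_PLINK_META)]) != _PLINK_META:
        raise DataFormatError(f"{path}: expected PLINK .raw header {' '.join(_PLINK_META)} ...")
    snp_cols = df.columns[len(_PLINK_META):].tolist()
    if not snp_cols:
        raise DataFormatError(f"{path}: no genotype columns after the six metadata columns")
    if df["IID"].duplicated().any():
        raise DataFormatError(f"{path}: duplicate IID")
    geno = df[snp_cols].apply(pd.to_numeric, errors="coerce")
    if geno.isna().any().any():
        col = geno.columns[geno.isna().any()][0]
        row = int(geno[col].isna().idxmax())
        raise DataFormatError(f"{path}: missing genotype at row {row}, column {col!r}")
    if not geno.isin([0, 1, 2]).all().all():
        col = geno.columns[(~geno.isin([0, 1, 2])).any()][0]
        raise DataFormatError(f"{path}: column {col!r} has values outside 0/1/2")
    return df["IID"].tolist(), geno.to_numpy(dtype=float), snp_cols
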