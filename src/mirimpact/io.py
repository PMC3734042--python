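"""Data model and readers/writers for the pipeline's text formats.

The pipeline consumes already-normalized, log2-scale expression matrices
(features x samples, TSV), a sample sheet assigning each sample to the
``case`` or ``control`` group (CSV), boolean detection-call matrices (TSV of
0/1), and gene sets / miRNA target predictions in standard GMT.  Readers
validate, never transform: expression values are log2 by contract because
probe-level normalization happens upstream of this package.

Two small published result tables ship with the package as tab-separated
fixtures: per-probe fold changes and p-values for differentially expressed
small nucleolar RNAs, and per-miRNA fold changes with the two
target-database Kolmogorov-Smirnov impact p-values (which may be the
sentinels ``NA`` — no predictions available — or ``NS`` — computed but not
significant).
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, PackagingError

GROUP_LABELS = ("case", "control")

__all__ = [
    "ExpressionMatrix",
    "DetectionMatrix",
    "TargetMap",
    "GeneSetCollection",
    "Sentinel",
    "MirnaResultRow",
    "SnornaResultRow",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_detection_matrix",
    "write_detection_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "read_gene_sets",
    "read_target_map",
    "write_gmt",
    "load_table1_fixture",
    "load_table2_fixture",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConsistencyError(f"duplicate {what} IDs: {dupes[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """A validated log2 feature x sample matrix with two-group labels.

    Attributes
    ----------
    feature_ids, sample_ids:
        Unique identifiers, in file order.
    values:
        ``(n_features, n_samples)`` float array of log2 intensities.
    groups:
        Mapping of every sample ID to ``"case"`` or ``"control"``; both
        groups must be non-empty.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.feature_ids = _check_ids(self.feature_ids, "feature")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ConsistencyError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ConsistencyError(f"samples missing from sample sheet: {missing[:5]}")
        bad = {g for g in self.groups.values() if g not in GROUP_LABELS}
        if bad:
            raise ConsistencyError(f"unknown group labels {sorted(bad)}; expected {GROUP_LABELS}")
        labels = [self.groups[s] for s in self.sample_ids]
        for g in GROUP_LABELS:
            if g not in labels:
                raise ConsistencyError(f"group {g!r} is empty")

    # -- convenience views -------------------------------------------------

    @property
    def case_columns(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.sample_ids) if self.groups[s] == "case"])

    @property
    def control_columns(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.sample_ids) if self.groups[s] == "control"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, keep: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset preserving the original feature order."""
        keep_set = set(keep)
        idx = [i for i, f in enumerate(self.feature_ids) if f in keep_set]
        return ExpressionMatrix(
            [self.feature_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[idx, :],
            dict(self.groups),
        )


@dataclass
class DetectionMatrix:
    """Boolean detection calls, same layout as a companion ExpressionMatrix."""

    feature_ids: list[str]
    sample_ids: list[str]
    detected: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = _check_ids(self.feature_ids, "feature")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.detected.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ConsistencyError("detection matrix shape does not match ID lists")


@dataclass
class TargetMap:
    """Predicted targets per miRNA from one prediction source.

    A miRNA *absent* from ``sets`` means "no predictions available" (the NA
    state of the printed results table), which is distinct from a miRNA
    present with targets.  Empty sets are rejected.
    """

    source_name: str
    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for mirna, genes in self.sets.items():
            genes = frozenset(str(g) for g in genes)
            if not genes:
                raise ConsistencyError(f"empty target set for {mirna!r}")
            clean[str(mirna)] = genes
        self.sets = clean

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in self.sets


@dataclass
class GeneSetCollection:
    """Named gene sets (GO terms, functional modules, immune annotation)."""

    sets: dict[str, tuple[str, frozenset[str]]]
    ontology_label: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, frozenset[str]]] = {}
        for term, (name, genes) in self.sets.items():
            genes = frozenset(str(g) for g in genes)
            if not genes:
                raise ConsistencyError(f"empty gene set for term {term!r}")
            clean[str(term)] = (str(name), genes)
        self.sets = clean

    def members(self, term_id: str) -> frozenset[str]:
        return self.sets[term_id][1]

    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)


class Sentinel(Enum):
    """Non-numeric states of a published KS impact cell."""

    NA = "NA"  # no target predictions available in that database
    NS = "NS"  # test computed but not significant; value not printed


@dataclass(frozen=True)
class MirnaResultRow:
    mirna_id: str
    fold_change: float
    p_value: float
    ks_p_targetscan: float | Sentinel
    ks_p_miranda: float | Sentinel


@dataclass(frozen=True)
class SnornaResultRow:
    probe_id: str
    fold_change: float
    p_value: float


# ---------------------------------------------------------------------------
# expression / detection / sample sheet IO
# ---------------------------------------------------------------------------


def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise FormatError(f"{path}: duplicate sample IDs in header")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"{path}: duplicate feature IDs {dupes[:5]}")
    df.columns = samples
    return df


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Read a ``sample_id,group`` CSV into a mapping."""
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: sample sheet needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample IDs in sample sheet")
    return dict(zip(df["sample_id"], df["group"]))


def write_sample_sheet(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "group"])
        for sample, group in groups.items():
            w.writerow([sample, group])


def read_expression_matrix(path: str | Path, sample_sheet_path: str | Path) -> ExpressionMatrix:
    """Read a log2 expression TSV plus its sample sheet.

    The first column holds feature IDs, the header row sample IDs; file
    order is preserved.  Duplicate IDs raise :class:`FormatError`; a sample
    present in the matrix but missing from the sheet raises
    :class:`ConsistencyError`.
    """
    df = _read_tsv_matrix(path)
    groups = read_sample_sheet(sample_sheet_path)
    return ExpressionMatrix(list(df.index), list(df.columns), df.to_numpy(float), groups)


def write_expression_matrix(
    expr: ExpressionMatrix,
    path: str | Path,
    sample_sheet_path: str | Path | None = None,
) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="feature_id")
    if sample_sheet_path is not None:
        write_sample_sheet({s: expr.groups[s] for s in expr.sample_ids}, sample_sheet_path)


def read_detection_matrix(path: str | Path) -> DetectionMatrix:
    df = _read_tsv_matrix(path)
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise FormatError(f"{path}: detection calls must be 0/1")
    return DetectionMatrix(list(df.index), list(df.columns), values.astype(bool))


def write_detection_matrix(det: DetectionMatrix, path: str | Path) -> None:
    pd.DataFrame(
        det.detected.astype(int), index=det.feature_ids, columns=det.sample_ids
    ).to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def _read_gmt_records(path: str | Path) -> list[tuple[str, str, frozenset[str]]]:
    records: list[tuple[str, str, frozenset[str]]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            records.append((name, desc, members))
    return records


def read_gene_sets(path: str | Path, ontology_label: str = "") -> GeneSetCollection:
    """Read a GMT file as a gene-set collection (term descriptions kept)."""
    records = _read_gmt_records(path)
    return GeneSetCollection(
        {name: (desc, members) for name, desc, members in records},
        ontology_label=ontology_label or Path(path).stem,
    )


def read_target_map(path: str | Path, source_name: str = "") -> TargetMap:
    """Read a GMT file as a miRNA -> predicted-target map."""
    records = _read_gmt_records(path)
    return TargetMap(
        source_name or Path(path).stem,
        {name: members for name, _desc, members in records},
    )


# default reader: GMT as a gene-set collection
read_gmt = read_gene_sets


def write_gmt(obj: GeneSetCollection | TargetMap, path: str | Path) -> None:
    """Write a collection or target map as canonical GMT (members sorted)."""
    with open(path, "w") as fh:
        if isinstance(obj, TargetMap):
            for mirna in obj.sets:
                fh.write("\t".join([mirna, obj.source_name, *sorted(obj.sets[mirna])]) + "\n")
        else:
            for term, (desc, members) in obj.sets.items():
                fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

# sha256 of the packaged fixture files, pinned so loaders fail loudly on a
# corrupted installation rather than returning silently different tables
_FIXTURE_SHA256 = {
    "table1.tsv": "0895061f3e22dd01b325bd4cac9af1d16d1947afc6b226c36f4cd9a8a5a804aa",
    "table2.tsv": "b028774071258c3025e774f1c17ae1b21be9c587b15416219d928a2c37fcfa6b",
}


def _fixture_text(filename: str) -> str:
    try:
        data = (resources.files("mirimpact") / "data" / filename).read_bytes()
    except (FileNotFoundError, ModuleNotFoundError) as exc:  # pragma: no cover
        raise PackagingError(f"packaged fixture {filename} is missing") from exc
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[filename]:
        raise PackagingError(
            f"packaged fixture {filename} is corrupt (sha256 {digest})"
        )
    return data.decode()


def _parse_ks_cell(token: str) -> float | Sentinel:
    if token == "NA":
        return Sentinel.NA
    if token == "NS":
        return Sentinel.NS
    return float(token)


def load_table2_fixture() -> list[MirnaResultRow]:
    """Published per-miRNA results: fold change, t-test p, and the two
    target-database KS impact p-values (``NA``/``NS`` kept as sentinels)."""
    rows: list[MirnaResultRow] = []
    lines = _fixture_text("table2.tsv").splitlines()
    for line in lines[1:]:
        mirna, fc, p, ts, mir = line.split("\t")
        rows.append(
            MirnaResultRow(mirna, float(fc), float(p), _parse_ks_cell(ts), _parse_ks_cell(mir))
        )
    return rows


def load_table1_fixture() -> list[SnornaResultRow]:
    """Published differentially expressed small nucleolar RNA probes."""
    rows: list[SnornaResultRow] = []
    lines = _fixture_text("table1.tsv").splitlines()
    for line in lines[1:]:
        probe, fc, p = line.split("\t")
        rows.append(SnornaResultRow(probe, float(fc), float(p)))
    return rows
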