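"""Readers/writers for expression matrices, clinical tables and mutation tables.

Expression matrices travel as TSV with features in rows and samples in
columns (header row of sample IDs); clinical data as CSV with one row per
patient. All downstream stages consume *aligned* bundles: the three inputs
restricted to their common samples in one fixed order. Values are assumed
already normalized/log-scaled; per-feature z-scoring happens at distance
computation time (see :mod:`oligosnf.snf`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("oligosnf")

#: canonical order of the five Clinical Risk Score feature columns
CRS_FEATURES = (
    "dfi_lt_12mo",   # disease-free interval primary -> metastasis < 12 months
    "mets_gt_1",     # more than one liver metastasis
    "size_gt_5cm",   # largest metastasis > 5 cm
    "node_positive", # lymph-node-positive primary tumor
    "cea_ge_200",    # CEA at/above 200 ng/mL
)

CLINICAL_COLUMNS = ("sample_id", "time_months", "event", *CRS_FEATURES, "recurrence_count")


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclasses.dataclass
class ExpressionMatrix:
    """Feature x sample real-valued expression for one platform.

    Parameters
    ----------
    values : ndarray of shape (n_features, n_samples)
    feature_ids, sample_ids : unique identifier lists
    platform : ``"mrna"`` or ``"mirna"``
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    platform: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DataError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample identifiers")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise DataError("duplicate feature identifiers")
        if np.isnan(self.values).any():
            bad = np.argwhere(np.isnan(self.values))[0]
            raise DataError(
                f"missing value at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``sample_ids`` in the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            cols = [index[s] for s in sample_ids]
        except KeyError as exc:
            raise DataError(f"sample {exc.args[0]!r} absent from matrix") from exc
        return ExpressionMatrix(
            self.values[:, cols], list(self.feature_ids), list(sample_ids), self.platform
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclasses.dataclass
class PatientRecord:
    """One patient's survival outcome, CRS features and recurrence burden.

    ``time`` is months since hepatic resection; ``event`` is the death
    indicator (overall survival: death from any cause, right-censored).
    ``crs_features`` holds the five pre-thresholded adverse-feature booleans
    keyed by :data:`CRS_FEATURES`. ``recurrence_count`` is the number of
    subsequent metastases (0 = no recurrence), or None if unknown.
    """

    sample_id: str
    time: float
    event: int
    crs_features: dict[str, bool]
    recurrence_count: int | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DataError(f"negative survival time for {self.sample_id!r}")
        if self.event not in (0, 1):
            raise DataError(f"event must be 0/1, got {self.event!r}")


# ---------------------------------------------------------------------------
# expression I/O

def load_expression(path: str | Path, platform: str) -> ExpressionMatrix:
    """Load a feature x sample TSV into an :class:`ExpressionMatrix`.

    Raises :class:`DataError` on non-numeric cells (naming the offending
    row/column), duplicated identifiers, or missing values.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = next(h for h in header if header.count(h) > 1)
        raise DataError(f"{path}: duplicated sample header {dup!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DataError(f"{path}: duplicated feature id {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise DataError(f"{path}: non-numeric cell at feature {row!r}, sample {col!r}")
        df[col] = coerced
    mat = ExpressionMatrix(df.to_numpy(float), list(df.index), list(df.columns), platform)
    logger.info("loaded %s: %d features x %d samples from %s",
                platform, mat.n_features, mat.n_samples, path)
    return mat


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# clinical I/O

def clinical_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "time_months": r.time, "event": r.event}
        row.update({k: int(bool(r.crs_features[k])) for k in CRS_FEATURES})
        row["recurrence_count"] = r.recurrence_count
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CLINICAL_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for _, row in df.iterrows():
        feats = {k: bool(int(row[k])) for k in CRS_FEATURES if pd.notna(row.get(k))}
        rc = row.get("recurrence_count")
        records.append(
            PatientRecord(
                sample_id=str(row["sample_id"]),
                time=float(row["time_months"]),
                event=int(row["event"]),
                crs_features=feats,
                recurrence_count=None if pd.isna(rc) else int(rc),
            )
        )
    return records


def load_clinical(path: str | Path) -> list[PatientRecord]:
    """Load a clinical CSV (``sample_id,time_months,event,<CRS flags>,recurrence_count``)."""
    df = pd.read_csv(path)
    missing = {"sample_id", "time_months", "event"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing required columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise DataError(f"{path}: duplicated sample_id {dup!r}")
    records = frame_to_records(df)
    logger.info("loaded clinical table: %d patients from %s", len(records), path)
    return records


def write_clinical(records: Sequence[PatientRecord], path: str | Path) -> None:
    clinical_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# mutation I/O

def load_mutations(path: str | Path) -> pd.DataFrame:
    """Binary gene x sample TSV -> DataFrame of 0/1 ints."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.isin([0, 1]).all().all():
        raise DataError(f"{path}: mutation table must be binary 0/1")
    return df.astype(int)


def write_mutations(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample alignment

def align_samples(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    clinical: Sequence[PatientRecord],
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[PatientRecord]]:
    """Restrict all three inputs to their common samples, in a single order.

    The output order follows the mRNA matrix's column order filtered to the
    intersection. Dropped sample IDs are logged. An empty intersection is an
    error.
    """
    clin_by_id = {r.sample_id: r for r in clinical}
    common = set(mrna.sample_ids) & set(mirna.sample_ids) & set(clin_by_id)
    if not common:
        raise DataError("no samples shared by mRNA, miRNA and clinical inputs")
    order = [s for s in mrna.sample_ids if s in common]
    dropped = (set(mrna.sample_ids) | set(mirna.sample_ids) | set(clin_by_id)) - common
    if dropped:
        logger.info("align_samples dropped %d samples: %s", len(dropped), sorted(dropped))
    return (
        mrna.subset_samples(order),
        mirna.subset_samples(order),
        [clin_by_id[s] for s in order],
    )


def check_aligned(*sample_id_lists: Sequence[str]) -> None:
    """Fail fast if sample ID lists are not identical and identically ordered."""
    first = list(sample_id_lists[0])
    for other in sample_id_lists[1:]:
        if list(other) != first:
            raise DataError("sample lists are not aligned; call align_samples first")


# ---------------------------------------------------------------------------
# provenance

def write_provenance(out_dir: str | Path, seed: int | None, config: dict | None) -> Path:
    """Write a provenance block (config hash, seed, library versions) for a run."""
    import scipy
    import sklearn

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    block = {
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config or {},
        "versions": {
            "oligosnf": "0.1.0",
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(block, indent=2, sort_keys=True) + "\n")
    return path
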