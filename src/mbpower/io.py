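"""Count-table and metadata I/O, validation, and low-abundance pre-filtering.

The central container is :class:`CountMatrix`: a taxa-by-samples table of
non-negative integer counts together with a per-sample group label
(control/treatment).  Counts are stored as a dense integer array because
amplicon (16S ASV) tables at pilot-study scale are small; sparsity is a
property of the data, not of the storage here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
TREATMENT = "treatment"


class ValidationError(ValueError):
    """Raised when a count table or metadata table violates an invariant."""


@dataclass(frozen=True)
class CountMatrix:
    """Taxa x samples count table with a two-group design.

    Parameters
    ----------
    counts : ndarray of shape (n_taxa, n_samples)
        Non-negative integer counts K_ij.
    taxon_ids, sample_ids : list of str
        Unique row / column identifiers.
    group : ndarray of str
        Per-sample label, each either ``"control"`` or ``"treatment"``.
    """

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    group: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.size and (not np.issubdtype(counts.dtype, np.integer)):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("counts must be integral")
            counts = np.round(counts).astype(np.int64)
        object.__setattr__(self, "counts", np.asarray(counts, dtype=np.int64))
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.taxon_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        _check_unique(self.taxon_ids, "taxon id")
        _check_unique(self.sample_ids, "sample id")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        group = np.asarray(self.group, dtype=object)
        object.__setattr__(self, "group", group)
        if group.shape != (len(self.sample_ids),):
            raise ValidationError("group must have one label per sample")
        labels = set(group.tolist())
        if not labels <= {CONTROL, TREATMENT}:
            raise ValidationError(
                f"group labels must be {CONTROL!r}/{TREATMENT!r}, got {sorted(labels)}"
            )
        for lab in (CONTROL, TREATMENT):
            if int((group == lab).sum()) < 2:
                raise ValidationError(f"fewer than 2 samples in group {lab!r}")

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def treatment_indicator(self) -> np.ndarray:
        """0/1 covariate: 1 for treatment samples."""
        return (self.group == TREATMENT).astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def subset_taxa(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            counts=self.counts[keep],
            taxon_ids=[self.taxon_ids[i] for i in keep],
        )


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicated {what}: {i!r}")
        seen.add(i)


def _sniff_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_counts(
    counts_path: str | Path,
    metadata_path: str | Path,
    group_column: str = "group",
    control_label: str = CONTROL,
    sep: str | None = None,
) -> CountMatrix:
    """Read a taxa x samples count table plus sample metadata.

    The counts file is a delimited table whose first column holds taxon ids
    and whose header row holds sample ids.  If the table instead has sample
    ids on rows (as judged by overlap with the metadata sample ids), it is
    transposed with a log message.  Samples are matched to metadata by id,
    never by position.  Metadata labels equal to ``control_label`` become
    ``"control"``; every other label becomes ``"treatment"``.
    """
    counts_path, metadata_path = Path(counts_path), Path(metadata_path)
    table = pd.read_csv(counts_path, sep=_sniff_sep(counts_path, sep), index_col=0)
    meta = pd.read_csv(metadata_path, sep=_sniff_sep(metadata_path, sep))
    if "sample_id" not in meta.columns:
        raise ValidationError("metadata must contain a 'sample_id' column")
    if group_column not in meta.columns:
        raise ValidationError(f"metadata lacks group column {group_column!r}")
    meta = meta.astype({"sample_id": str})
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicated sample id in metadata: {dup!r}")
    meta_ids = set(meta["sample_id"])

    table.index = table.index.map(str)
    table.columns = table.columns.map(str)
    col_hits = len(meta_ids & set(table.columns))
    row_hits = len(meta_ids & set(table.index))
    if row_hits > col_hits:
        logger.info("sample ids found on rows; transposing count table")
        table = table.T

    missing = [s for s in table.columns if s not in meta_ids]
    if missing:
        raise ValidationError(
            f"samples present in counts but missing from metadata: {missing[:5]}"
        )
    group_of = dict(zip(meta["sample_id"], meta[group_column].astype(str)))
    labels = np.array(
        [CONTROL if group_of[s] == control_label else TREATMENT for s in table.columns],
        dtype=object,
    )
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("count table contains non-numeric entries")
    return CountMatrix(
        counts=values,
        taxon_ids=list(table.index),
        sample_ids=list(table.columns),
        group=labels,
    )


def write_counts(cm: CountMatrix, counts_path: str | Path, metadata_path: str | Path) -> None:
    """Write a CountMatrix in the same TSV dialect :func:`read_counts` reads."""
    counts_path, metadata_path = Path(counts_path), Path(metadata_path)
    df = cm.to_frame()
    df.index.name = "taxon_id"
    df.to_csv(counts_path, sep=_sniff_sep(counts_path, None))
    pd.DataFrame({"sample_id": cm.sample_ids, "group": cm.group}).to_csv(
        metadata_path, sep=_sniff_sep(metadata_path, None), index=False
    )


def filter_low_abundance(
    cm: CountMatrix, min_count: int = 5, min_samples: int = 3
) -> CountMatrix:
    """Drop rare taxa: keep taxa with >= ``min_count`` reads in >= ``min_samples`` samples.

    The defaults (5 reads, 3 samples) are the standard pre-filter for ASV
    tables ahead of differential abundance testing.  Idempotent; with
    ``min_count=0`` it is the identity.
    """
    n_hit = (cm.counts >= min_count).sum(axis=1)
    keep = n_hit >= min_samples
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValidationError(
            "pre-filter removed every taxon; relax min_count/min_samples"
        )
    if n_removed:
        logger.info("pre-filter removed %d of %d taxa", n_removed, cm.n_taxa)
    return cm.subset_taxa(keep)
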