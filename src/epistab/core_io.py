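"""Validated containers and text readers/writers for methylation-array data.

The universal substrate of the pipeline is the β-value matrix: CpG probes in
rows, samples in columns, every entry a methylation fraction in [0, 1]
(fraction of methylated signal at that locus). Matrices, probe-annotation
manifests, sample metadata and survival tables are all exchanged as plain
tab-delimited text with a single header row; empty cells and ``NA`` denote
missing values.

Conventions fixed here and relied on downstream:

* probes in rows by default; an explicit ``orientation`` flag, never guessing;
* genomic positions are 1-based; ``tss_distance`` is signed with negative
  values upstream of the transcription start site and 0 at the TSS;
* missing β-values stay missing (``NaN``) — downstream statistics use
  complete-observation rules stated per operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "CGI_RELATIONS",
    "BLOCKLIST_FLAGS",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_survival_table",
    "write_survival_table",
    "harmonize_probe_sets",
]

#: Vocabulary for a probe's position relative to a CpG island.
CGI_RELATIONS = ("island", "shore", "shelf", "open_sea")

#: Boolean exclusion flags carried by the annotation manifest.
BLOCKLIST_FLAGS = (
    "near_snp",
    "cross_reactive",
    "age_associated",
    "sex_chromosome",
    "non_cpg",
)

_SEX_CHROMOSOMES = {"chrX", "chrY", "X", "Y"}
_NA_VALUES = ["", "NA", "NaN", "nan"]
_TIMEPOINTS = ("diagnosis", "remission", "relapse", "followup", "none")


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dup = labels[labels.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what}: {dup}")


@dataclass
class BetaMatrix:
    """Probes × samples grid of methylation fractions.

    ``values`` is a float DataFrame indexed by probe ID with sample IDs as
    columns; ``NaN`` marks missing observations. Construction validates the
    container invariants: unique identifiers, matching dimensions, and every
    non-missing value in [0, 1].
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "probe identifiers")
        _check_unique(self.values.columns, "sample identifiers")
        arr = self.values.to_numpy()
        bad = (arr < 0.0) | (arr > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"β-value out of [0, 1] at probe {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}: {arr[i, j]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_probes(self, probes: Sequence[str] | pd.Index) -> "BetaMatrix":
        """Restrict to ``probes`` in the given order; unknown probes are an error."""
        probes = pd.Index(probes)
        missing = probes.difference(self.values.index)
        if len(missing):
            raise KeyError(f"probes absent from matrix: {missing.tolist()[:5]}")
        return BetaMatrix(self.values.loc[probes])

    def select_samples(self, samples: Sequence[str] | pd.Index) -> "BetaMatrix":
        samples = pd.Index(samples)
        missing = samples.difference(self.values.columns)
        if len(missing):
            raise KeyError(f"samples absent from matrix: {missing.tolist()[:5]}")
        return BetaMatrix(self.values.loc[:, samples])

    def equals(self, other: "BetaMatrix") -> bool:
        return self.values.equals(other.values)


def read_beta_matrix(path: str | Path, orientation: str = "probes_in_rows") -> BetaMatrix:
    """Read a tab-delimited β-value table into a validated :class:`BetaMatrix`.

    The first column holds row labels and the header row holds column labels.
    ``orientation`` is ``probes_in_rows`` (default) or ``samples_in_rows``;
    the latter transposes after reading so probes always end up in rows.
    """
    if orientation not in ("probes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=_NA_VALUES, keep_default_na=False,
        float_precision="round_trip",
    )
    if orientation == "samples_in_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    """Write probes-in-rows tab-delimited text; missing values become ``NA``.

    Floats are written at full ``repr`` precision so a read/write round trip
    is exact.
    """
    matrix.values.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def _parse_bool(col: pd.Series, name: str) -> pd.Series:
    if col.dtype == bool:
        return col
    out = col.astype(str).str.strip().str.lower().map(_BOOL_MAP)
    if out.isna().any():
        bad = col[out.isna()].iloc[0]
        raise ValueError(f"cannot parse boolean flag {name!r} value {bad!r}")
    return out.astype(bool)


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Read a probe-annotation manifest keyed by probe ID.

    Required columns: probe_id, chromosome, position, cgi_relation,
    nearest_gene, tss_distance, and the five blocklist flags. ``cgi_relation``
    must come from the four-level island/shore/shelf/open_sea vocabulary, and
    the ``sex_chromosome`` flag must agree with the chromosome label.
    """
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    required = ["probe_id", "chromosome", "position", "cgi_relation",
                "nearest_gene", "tss_distance", *BLOCKLIST_FLAGS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"annotation manifest missing columns: {missing}")
    df["probe_id"] = df["probe_id"].astype(str)
    _check_unique(pd.Index(df["probe_id"]), "probe identifiers")
    bad_rel = ~df["cgi_relation"].isin(CGI_RELATIONS)
    if bad_rel.any():
        raise ValueError(
            f"unknown cgi_relation {df.loc[bad_rel, 'cgi_relation'].iloc[0]!r}; "
            f"expected one of {CGI_RELATIONS}"
        )
    for flag in BLOCKLIST_FLAGS:
        df[flag] = _parse_bool(df[flag], flag)
    is_sex = df["chromosome"].astype(str).isin(_SEX_CHROMOSOMES)
    if (df["sex_chromosome"] != is_sex).any():
        probe = df.loc[df["sex_chromosome"] != is_sex, "probe_id"].iloc[0]
        raise ValueError(
            f"sex_chromosome flag inconsistent with chromosome label for {probe!r}"
        )
    df["tss_distance"] = pd.to_numeric(df["tss_distance"])
    df["position"] = pd.to_numeric(df["position"])
    return df.set_index("probe_id")


def write_probe_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata keyed by sample ID.

    Validates that clone VAFs (variant-allele fractions, a genetic proxy for
    clone size) lie in [0, 1] and that (patient, timepoint) pairs are unique
    within the longitudinal subset.
    """
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError("sample metadata must contain a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    _check_unique(pd.Index(df["sample_id"]), "sample identifiers")
    if "clone_vaf" in df.columns:
        vaf = pd.to_numeric(df["clone_vaf"])
        if ((vaf < 0) | (vaf > 1)).any():
            raise ValueError("clone_vaf outside [0, 1]")
        df["clone_vaf"] = vaf
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"])
    if "timepoint" in df.columns:
        bad = df["timepoint"].notna() & ~df["timepoint"].isin(_TIMEPOINTS)
        if bad.any():
            raise ValueError(
                f"unknown timepoint {df.loc[bad, 'timepoint'].iloc[0]!r}"
            )
        longi = df[df["timepoint"].notna() & (df["timepoint"] != "none")]
        if longi.duplicated(subset=["patient_id", "timepoint"]).any():
            raise ValueError("duplicated (patient_id, timepoint) in longitudinal set")
    return df.set_index("sample_id")


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def read_survival_table(path: str | Path, event_cols: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a time-to-event table keyed by sample ID.

    ``time`` must be strictly positive throughout (one common unit); every
    column named ``event_*`` (or listed in ``event_cols``) must be binary 0/1.
    """
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    if "sample_id" not in df.columns or "time" not in df.columns:
        raise ValueError("survival table must contain sample_id and time columns")
    df["sample_id"] = df["sample_id"].astype(str)
    _check_unique(pd.Index(df["sample_id"]), "sample identifiers")
    df["time"] = pd.to_numeric(df["time"])
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be strictly positive")
    if event_cols is None:
        event_cols = [c for c in df.columns if c.startswith("event")]
    for col in event_cols:
        vals = pd.to_numeric(df[col])
        if not vals.isin([0, 1]).all():
            raise ValueError(f"event indicator {col!r} must be binary 0/1")
        df[col] = vals.astype(int)
    return df.set_index("sample_id")


def write_survival_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def harmonize_probe_sets(matrices: Sequence[BetaMatrix]) -> list[BetaMatrix]:
    """Restrict every matrix to the common probe set, in a common order.

    Mirrors cross-platform harmonization (e.g., keeping only probes shared
    between 450K and EPIC arrays). The output order is the first matrix's
    probe order restricted to the intersection, so the operation is
    idempotent and its result *set* does not depend on input order.
    """
    if len(matrices) < 2:
        raise ValueError("harmonize_probe_sets requires at least two matrices")
    common = matrices[0].probe_ids
    for m in matrices[1:]:
        common = common.intersection(m.probe_ids)
    if len(common) == 0:
        raise ValueError("probe sets have an empty intersection")
    ordered = matrices[0].probe_ids[matrices[0].probe_ids.isin(common)]
    return [m.select_probes(ordered) for m in matrices]
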