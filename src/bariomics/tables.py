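"""Feature-table and sample-metadata containers with TSV readers/writers.

The two central data objects of the pipeline live here:

* :class:`FeatureTable` — a samples × taxa abundance matrix together with a
  Greengenes-style lineage per feature and a ``stage`` tag recording how far
  along the normalization chain the values are (``raw`` → ``collapsed`` →
  ``filtered`` → ``logged`` → ``zscored``).
* sample metadata — a plain :class:`pandas.DataFrame` indexed by sample id
  with subject id, longitudinal time-point code, BMI, A1C, age, gender and
  follow-up BMI columns, validated by :func:`read_metadata` /
  :func:`validate_metadata`.

All interchange is tab-separated text: row ids in the first column, a header
row of column ids, taxonomy either as a final ``taxonomy`` column or a
two-column sidecar file.  Missing metadata is an empty cell on disk and NaN
in memory, never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Taxonomic ranks in lineage order, Greengenes style.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

#: Longitudinal codes: A enrollment, B post-diet/presurgery, C two weeks
#: post-op, D three months, E six months; H marks the lean control group.
TIMEPOINTS = ("A", "B", "C", "D", "E", "H")
TIMEPOINT_ORDER = {"A": 0, "B": 1, "C": 2, "D": 3, "E": 4}

STAGES = ("raw", "collapsed", "filtered", "logged", "zscored")

METADATA_COLUMNS = (
    "subject_id", "timepoint", "bmi", "a1c", "age", "gender",
    "bmi_6m", "bmi_12m", "bmi_18m",
)
FOLLOWUP_COLUMNS = {"6m": "bmi_6m", "12m": "bmi_12m", "18m": "bmi_18m"}


def parse_lineage(lineage: str, line: int | None = None) -> tuple[str, ...]:
    """Split a ``"k__X; p__Y; ..."`` lineage into a 7-tuple of rank names.

    Rank prefixes are stripped; unassigned trailing ranks come back as empty
    strings (never dropped).  A segment carrying the wrong prefix for its
    position is rejected.
    """
    where = f" (line {line})" if line is not None else ""
    parts = [p.strip() for p in str(lineage).split(";")]
    if len(parts) > len(RANKS):
        raise ValueError(
            f"lineage has {len(parts)} ranks, at most {len(RANKS)} supported{where}: {lineage!r}"
        )
    names = []
    for i, part in enumerate(parts):
        if part == "" or part == RANK_PREFIXES[i]:
            names.append("")
        elif part.startswith(RANK_PREFIXES[i]):
            names.append(part[len(RANK_PREFIXES[i]):])
        elif "__" in part:
            raise ValueError(
                f"unparseable lineage segment {part!r} at rank "
                f"{RANKS[i]!r}{where}: {lineage!r}"
            )
        else:
            # bare name without a rank prefix is accepted as-is
            names.append(part)
    names.extend([""] * (len(RANKS) - len(names)))
    return tuple(names)


def format_lineage(names: tuple[str, ...] | list[str], depth: int | None = None) -> str:
    """Inverse of :func:`parse_lineage`: render names back to prefixed form."""
    if depth is None:
        depth = len(names)
    return "; ".join(RANK_PREFIXES[i] + names[i] for i in range(depth))


@dataclass
class FeatureTable:
    """Samples × features abundance matrix with per-feature taxonomy.

    Parameters
    ----------
    data
        DataFrame with sample ids as the index and feature ids as columns.
    taxonomy
        Mapping feature id → lineage string; every feature must be present
        (possibly with empty trailing ranks).
    stage
        One of ``raw, collapsed, filtered, logged, zscored``.
    """

    data: pd.DataFrame
    taxonomy: dict[str, str] = field(default_factory=dict)
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.data.index.name = None
        self.data.columns.name = None
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def lineage_names(self, feature_id: str) -> tuple[str, ...]:
        return parse_lineage(self.taxonomy[feature_id])

    def with_data(self, data: pd.DataFrame, stage: str | None = None,
                  taxonomy: dict[str, str] | None = None) -> "FeatureTable":
        """Return a copy with replaced matrix (and optionally stage/taxonomy)."""
        return FeatureTable(
            data=data.copy(),
            taxonomy=dict(self.taxonomy if taxonomy is None else taxonomy),
            stage=self.stage if stage is None else stage,
        )

    def validate(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        dup_s = self.data.index[self.data.index.duplicated()]
        if len(dup_s):
            raise ValueError(f"duplicate sample id: {dup_s[0]!r}")
        dup_f = self.data.columns[self.data.columns.duplicated()]
        if len(dup_f):
            raise ValueError(f"duplicate feature id: {dup_f[0]!r}")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()][0]
            raise ValueError(f"missing value in feature {bad!r}; empty cells are not zeros")
        if self.stage == "raw" and (self.data.to_numpy() < 0).any():
            raise ValueError("raw-stage table contains negative abundances")
        if self.stage == "zscored" and self.data.shape[0] > 0:
            # whitening may have been per feature (default) or per sample;
            # accept either axis satisfying mean 0 / SD 1 (or 0)
            values = self.data.to_numpy()
            ok = False
            for ax in (0, 1):
                mean = values.mean(axis=ax)
                sd = values.std(axis=ax)
                nonconst = sd > 1e-12
                if (np.abs(mean).max(initial=0.0) <= 1e-9
                        and (not nonconst.any()
                             or np.abs(sd[nonconst] - 1).max() <= 1e-9)):
                    ok = True
                    break
            if not ok:
                raise ValueError(
                    "zscored stage violated: no axis has mean 0 and unit SD")
        missing_tax = [f for f in self.data.columns if f not in self.taxonomy]
        if missing_tax:
            raise ValueError(f"feature {missing_tax[0]!r} has no taxonomy entry")
        for fid in self.data.columns:
            parse_lineage(self.taxonomy[fid])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    # pandas mangles duplicate header names (S1, S1.1), so check them raw
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = set()
    for name in header:
        if name in seen:
            raise ValueError(f"duplicate column id in {path}: {name!r}")
        seen.add(name)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return df


def read_feature_table(path, orientation: str = "features_as_rows",
                       taxonomy_path=None, stage: str = "raw") -> FeatureTable:
    """Read a feature table from TSV (raw stage unless told otherwise).

    The default orientation follows the QIIME2 export convention: one row
    per feature, one column per sample.  Taxonomy comes either from a final
    ``taxonomy`` column or from a two-column sidecar file
    (``feature_id <TAB> lineage``); one of the two must be present.
    Negative values are rejected only at the raw stage (log/z-scored tables
    legitimately contain them).
    """
    if orientation not in ("features_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_tsv(path)

    taxonomy: dict[str, str] = {}
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str)
        taxonomy = {str(k): str(v) for k, v in tax.iloc[:, 0].items()}
    elif "taxonomy" in raw.columns:
        if orientation != "features_as_rows":
            raise ValueError("inline taxonomy column requires features_as_rows orientation")
        taxonomy = {str(k): ("" if pd.isna(v) else str(v))
                    for k, v in raw["taxonomy"].items()}
        raw = raw.drop(columns=["taxonomy"])
    else:
        raise ValueError("no taxonomy: supply a 'taxonomy' column or a sidecar file")

    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate row id in {path}: {dup[0]!r}")
    dup = raw.columns[raw.columns.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate column id in {path}: {dup[0]!r}")

    try:
        values = raw.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric abundance in {path}: {exc}") from exc
    if values.isna().any().any():
        row = values.index[values.isna().any(axis=1)][0]
        raise ValueError(f"missing abundance cell in row {row!r}; blanks are errors, not zeros")
    if stage == "raw" and (values.to_numpy() < 0).any():
        row = values.index[(values < 0).any(axis=1)][0]
        raise ValueError(f"negative abundance in row {row!r}")

    if orientation == "features_as_rows":
        data = values.T
    else:
        data = values

    missing = [f for f in data.columns if f not in taxonomy]
    if missing:
        raise ValueError(f"feature {missing[0]!r} missing from taxonomy map")
    for lineno, fid in enumerate(data.columns, start=2):
        parse_lineage(taxonomy[fid], line=lineno)
    taxonomy = {f: taxonomy[f] for f in data.columns}
    data.index = data.index.astype(str)
    data.columns = data.columns.astype(str)
    return FeatureTable(data=data, taxonomy=taxonomy, stage=stage)


def write_feature_table(table: FeatureTable, path, taxonomy_path=None,
                        orientation: str = "features_as_rows") -> None:
    """Write a feature table (any stage) plus optional taxonomy sidecar.

    Values are written with full ``repr`` precision so a read/write
    round-trip is exact.
    """
    df = table.data.T if orientation == "features_as_rows" else table.data
    df = df.copy()
    df.index.name = "id"
    df.to_csv(path, sep="\t")
    if taxonomy_path is not None:
        tax = pd.DataFrame(
            {"taxonomy": [table.taxonomy[f] for f in table.feature_ids]},
            index=pd.Index(table.feature_ids, name="feature_id"),
        )
        tax.to_csv(taxonomy_path, sep="\t")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a metadata frame indexed by sample id."""
    meta = meta.copy()
    required = {"subject_id", "timepoint", "bmi"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")
    dup = meta.index[meta.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample id in metadata: {dup[0]!r}")
    bad_tp = set(meta["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoint code {sorted(bad_tp)[0]!r}")
    for col in ("bmi", "a1c", "age", "gender", "bmi_6m", "bmi_12m", "bmi_18m"):
        if col in meta.columns:
            meta[col] = pd.to_numeric(meta[col], errors="raise")
        else:
            meta[col] = np.nan
    if meta["bmi"].isna().any():
        raise ValueError("bmi is required for every sample")
    if (meta["bmi"] <= 0).any():
        sid = meta.index[meta["bmi"] <= 0][0]
        raise ValueError(f"nonpositive BMI for sample {sid!r}")
    dup_tp = meta.duplicated(subset=["subject_id", "timepoint"])
    if dup_tp.any():
        sid = meta.index[dup_tp][0]
        raise ValueError(f"subject {meta.loc[sid, 'subject_id']!r} sampled twice "
                         f"at timepoint {meta.loc[sid, 'timepoint']!r}")
    lean = meta["timepoint"] == "H"
    if lean.any():
        fu = meta.loc[lean, ["bmi_6m", "bmi_12m", "bmi_18m"]]
        if fu.notna().any().any():
            sid = fu.index[fu.notna().any(axis=1)][0]
            raise ValueError(f"lean (H) sample {sid!r} carries follow-up BMI")
    meta["subject_id"] = meta["subject_id"].astype(str)
    meta["timepoint"] = meta["timepoint"].astype(str)
    meta.index = meta.index.astype(str)
    meta.index.name = "sample_id"
    return meta


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample clinical metadata from TSV; empty cells become NaN."""
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def align(table: FeatureTable, meta: pd.DataFrame) -> tuple[FeatureTable, pd.DataFrame]:
    """Restrict table and metadata to their common samples, same order.

    Ordering follows the feature table.  Idempotent; the number of dropped
    samples on each side is logged.
    """
    common = [s for s in table.sample_ids if s in set(meta.index)]
    if not common:
        raise ValueError("feature table and metadata share no sample ids")
    dropped_t = table.n_samples - len(common)
    dropped_m = len(meta) - len(common)
    if dropped_t or dropped_m:
        logger.info("align: dropped %d table samples and %d metadata rows",
                    dropped_t, dropped_m)
    new_table = table.with_data(table.data.loc[common])
    return new_table, meta.loc[common].copy()
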