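"""Preprocessing chain for 16S feature tables.

The chain turns a raw relative-frequency table into the whitened matrix the
decomposition works on:

1. collapse features to a taxonomic rank (arithmetic mean of member features);
2. drop known contaminant lineages (substring match);
3. drop taxa present in fewer than a minimum number of samples;
4. ``log10(v + 0.1)`` — the pseudocount guards against log of zero and the
   log tames the heavy-tailed abundance distribution;
5. z-score (population SD) per feature, so every taxon enters the PCA on an
   equal footing.

Each step is also available on its own; ``normalize_pipeline`` fixes the
order, which matters: prevalence is counted on collapsed taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import RANKS, FeatureTable, format_lineage, parse_lineage

logger = logging.getLogger(__name__)

DEFAULT_CONTAMINANTS = ("Thermi", "S24-7", "Chloroplast")


@dataclass
class NormalizationConfig:
    """Tunable knobs of the preprocessing chain with study defaults.

    ``pseudocount`` is added on the scale of the input values (relative
    frequencies as given); ``min_prevalence`` counts samples with strictly
    positive abundance; ``zscore_axis`` selects whether whitening is per
    feature (default, the conventional pre-PCA standardization) or per
    sample.
    """

    collapse_rank: str = "genus"
    min_prevalence: int = 5
    pseudocount: float = 0.1
    log_base: float = 10.0
    contaminant_patterns: tuple[str, ...] = DEFAULT_CONTAMINANTS
    zscore_axis: str = "feature"

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.min_prevalence < 0:
            raise ValueError("min_prevalence must be >= 0")
        if self.collapse_rank not in RANKS:
            raise ValueError(f"unknown rank {self.collapse_rank!r}")
        if self.zscore_axis not in ("feature", "sample"):
            raise ValueError("zscore_axis must be 'feature' or 'sample'")

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationConfig":
        d = dict(d)
        if "contaminant_patterns" in d:
            d["contaminant_patterns"] = tuple(d["contaminant_patterns"])
        return cls(**d)


def collapse_to_rank(table: FeatureTable, rank: str = "genus") -> FeatureTable:
    """Average all features sharing a lineage prefix at ``rank`` into one taxon.

    Features unassigned at ``rank`` are grouped under their deepest assigned
    lineage prefix, so e.g. two features known only to the family level end
    up in the same family-labelled taxon.  Output values are arithmetic
    means of the member features per sample.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if table.stage not in ("raw", "logged"):
        raise ValueError(f"collapse expects a raw or logged table, got stage {table.stage!r}")
    depth = RANKS.index(rank) + 1

    groups: dict[str, list[str]] = {}
    for fid in table.feature_ids:
        names = parse_lineage(table.taxonomy[fid])
        truncated = list(names[:depth])
        # trim unassigned trailing ranks: group under deepest assigned prefix
        while truncated and truncated[-1] == "":
            truncated.pop()
        key = format_lineage(tuple(truncated) + ("",) * (len(RANKS) - len(truncated)),
                             depth=max(len(truncated), 1))
        groups.setdefault(key, []).append(fid)

    cols = {}
    taxonomy = {}
    for key in sorted(groups):
        members = groups[key]
        cols[key] = table.data[members].mean(axis=1)
        taxonomy[key] = key
    data = pd.DataFrame(cols, index=table.data.index)
    stage = "collapsed" if table.stage == "raw" else table.stage
    return FeatureTable(data=data, taxonomy=taxonomy, stage=stage)


def filter_contaminants(table: FeatureTable,
                        patterns=DEFAULT_CONTAMINANTS) -> FeatureTable:
    """Drop features whose lineage contains any contaminant pattern.

    Matching is case-sensitive substring search on the full lineage string.
    """
    patterns = tuple(patterns)
    keep = [f for f in table.feature_ids
            if not any(p in table.taxonomy[f] for p in patterns)]
    dropped = table.n_features - len(keep)
    logger.info("filter_contaminants: removed %d features", dropped)
    return table.with_data(table.data[keep],
                           taxonomy={f: table.taxonomy[f] for f in keep})


def filter_prevalence(table: FeatureTable, min_samples: int = 5) -> FeatureTable:
    """Keep features with strictly positive abundance in >= ``min_samples`` samples."""
    if table.stage not in ("raw", "collapsed"):
        raise ValueError("prevalence filter applies before the log transform")
    prevalence = (table.data > 0).sum(axis=0)
    keep = [f for f in table.feature_ids if prevalence[f] >= min_samples]
    logger.info("filter_prevalence(min=%d): kept %d of %d features",
                min_samples, len(keep), table.n_features)
    return table.with_data(table.data[keep],
                           taxonomy={f: table.taxonomy[f] for f in keep},
                           stage="filtered" if table.stage == "collapsed" else table.stage)


def log_transform(table: FeatureTable, pseudocount: float = 0.1,
                  base: float = 10.0) -> FeatureTable:
    """``v -> log_base(v + pseudocount)`` per cell; strictly monotone."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (table.data.to_numpy() < 0).any():
        raise ValueError("log transform requires nonnegative values")
    data = np.log(table.data + pseudocount) / np.log(base)
    return table.with_data(data, stage="logged")


def zscore(table: FeatureTable, axis: str = "feature") -> FeatureTable:
    """Center and scale to unit population SD per feature (or per sample).

    Zero-variance features (or samples) map to all-zeros rather than raising;
    a constant taxon simply carries no information for the decomposition.
    """
    if axis not in ("feature", "sample"):
        raise ValueError("axis must be 'feature' or 'sample'")
    if table.n_features == 0:
        raise ValueError("cannot z-score a table with no features")
    values = table.data.to_numpy(dtype=float)
    ax = 0 if axis == "feature" else 1
    mean = values.mean(axis=ax, keepdims=True)
    sd = values.std(axis=ax, keepdims=True)  # population SD, divisor n
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    # second centering pass: cancellation error in (v - m)/s can leave the
    # mean off by far more than 1e-9 when s is many orders below |m|
    z = z - z.mean(axis=ax, keepdims=True)
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    data = pd.DataFrame(z, index=table.data.index, columns=table.data.columns)
    return table.with_data(data, stage="zscored")


def normalize_pipeline(table: FeatureTable,
                       config: NormalizationConfig | None = None) -> FeatureTable:
    """Run the full chain collapse → contaminants → prevalence → log → z-score."""
    if config is None:
        config = NormalizationConfig()
    if table.stage != "raw":
        raise ValueError(f"pipeline expects a raw table, got stage {table.stage!r}")
    out = collapse_to_rank(table, config.collapse_rank)
    logger.info("pipeline: %d taxa after collapse to %s", out.n_features, config.collapse_rank)
    out = filter_contaminants(out, config.contaminant_patterns)
    logger.info("pipeline: %d taxa after contaminant filter", out.n_features)
    out = filter_prevalence(out, config.min_prevalence)
    logger.info("pipeline: %d taxa after prevalence filter", out.n_features)
    out = log_transform(out, config.pseudocount, config.log_base)
    out = zscore(out, config.zscore_axis)
    return out
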