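"""Mapping metagenomic species onto the reconstruction catalog.

Species names are matched after a deterministic normalization (case-fold,
spaces/periods to underscores); unmapped species are dropped with their
abundance mass accounted for, abundances are renormalized to closure, and
entries strictly below the relative-abundance threshold (default 1e-7, i.e.
0.00001%) are removed before a final renormalization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoverageReport",
    "MappingError",
    "normalize_species_name",
    "map_taxa",
    "renormalize",
    "apply_abundance_threshold",
    "coverage_stats",
    "DEFAULT_ABUNDANCE_THRESHOLD",
]

#: relative-abundance filter, as a fraction (0.00001%)
DEFAULT_ABUNDANCE_THRESHOLD = 1e-7

_CLOSURE_TOL = 1e-9


class MappingError(ValueError):
    pass


def normalize_species_name(name: str) -> str:
    """Case-fold and map runs of spaces/periods to single underscores."""
    return re.sub(r"[ .]+", "_", name.strip()).lower()


def map_taxa(
    table: pd.DataFrame, catalog_species: Iterable[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict the abundance table to catalog species.

    Returns the mapped table (rows relabeled to catalog IDs) and the
    unmapped rows with their pre-mapping abundances. Raises when a sample
    maps no species at all.
    """
    catalog = {normalize_species_name(s): s for s in catalog_species}
    if not catalog:
        raise MappingError("catalog_species must be non-empty")
    mapped_rows, unmapped_rows = [], []
    new_names = {}
    for species in table.index:
        key = normalize_species_name(str(species))
        if key in catalog:
            mapped_rows.append(species)
            new_names[species] = catalog[key]
        else:
            unmapped_rows.append(species)
    mapped = table.loc[mapped_rows].rename(index=new_names)
    unmapped = table.loc[unmapped_rows]
    empty = mapped.columns[(mapped.sum(axis=0) <= 0)]
    if len(empty):
        raise MappingError(
            f"no catalog species mapped in sample(s): {list(empty)}")
    return mapped, unmapped


def renormalize(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to sum to one (proportions preserved)."""
    sums = table.sum(axis=0)
    zero = sums.index[sums <= 0]
    if len(zero):
        raise MappingError(f"cannot renormalize all-zero sample(s): {list(zero)}")
    return table / sums


def apply_abundance_threshold(
    table: pd.DataFrame, threshold_fraction: float = DEFAULT_ABUNDANCE_THRESHOLD
) -> pd.DataFrame:
    """Zero entries strictly below the threshold, renormalize, drop empty rows."""
    if threshold_fraction < 0:
        raise MappingError("threshold must be non-negative")
    out = table.where(table >= threshold_fraction, 0.0)
    dead = out.columns[out.sum(axis=0) <= 0]
    if len(dead):
        raise MappingError(
            f"threshold {threshold_fraction} removes all species in "
            f"sample(s): {list(dead)}")
    out = renormalize(out)
    return out.loc[(out != 0).any(axis=1)]


@dataclass
class CoverageReport:
    """Per-sample mapped-read fractions and richness, with cohort summaries."""

    per_sample: pd.DataFrame  # columns: mapped_fraction, pre_richness, post_richness
    pre_species: int
    post_species: int

    @property
    def mean_mapped_fraction(self) -> float:
        return float(self.per_sample["mapped_fraction"].mean())

    def summary(self) -> pd.DataFrame:
        ps = self.per_sample
        return pd.DataFrame({
            "statistic": ["total_species", "mean_richness", "sd_richness",
                          "mean_mapped_fraction"],
            "before": [self.pre_species, ps["pre_richness"].mean(),
                       ps["pre_richness"].std(ddof=1), 1.0],
            "after": [self.post_species, ps["post_richness"].mean(),
                      ps["post_richness"].std(ddof=1),
                      self.mean_mapped_fraction],
        })


def coverage_stats(pre_table: pd.DataFrame, post_table: pd.DataFrame) -> CoverageReport:
    """Mapped-read fraction and species richness before/after mapping.

    The mapped fraction of a sample is the summed *pre-mapping* abundance of
    the species retained in the post table, so per sample the mapped fraction
    and the dropped mass add to one.
    """
    if set(pre_table.columns) != set(post_table.columns):
        raise MappingError("pre and post tables must cover identical samples")
    post = post_table[pre_table.columns]
    post_keys = {normalize_species_name(str(s)) for s in post.index}
    retained = [s for s in pre_table.index
                if normalize_species_name(str(s)) in post_keys]
    frac = pre_table.loc[retained].sum(axis=0)
    per_sample = pd.DataFrame({
        "mapped_fraction": frac,
        "pre_richness": (pre_table != 0).sum(axis=0),
        "post_richness": (post != 0).sum(axis=0),
    })
    return CoverageReport(per_sample=per_sample,
                          pre_species=int((pre_table != 0).any(axis=1).sum()),
                          post_species=int((post != 0).any(axis=1).sum()))
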