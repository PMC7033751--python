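"""Ighv locus accessibility from a gene-level expression count matrix.

Reproduces the aggregation used to compare locus accessibility between pro
B cell subsets: size-factor (median-of-ratios) normalization of raw counts,
then, per sample group, the mean of normalized counts across replicates per
Ighv gene, summed into VH-family and four-domain totals and frequencies.
Differential-expression testing is deliberately not part of this module;
only the normalization and the domain/family summation are.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .reference import strip_allele

logger = logging.getLogger(__name__)

__all__ = [
    "size_factor_normalize",
    "DomainUsage",
    "domain_family_usage",
    "read_counts_tsv",
    "read_map_tsv",
]


def read_counts_tsv(path) -> pd.DataFrame:
    """Genes x samples counts; first column is the gene name."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.astype(float)


def read_map_tsv(path, value_col: str) -> dict[str, object]:
    """Two-column TSV ``gene <tab> value`` -> dict (e.g. domain or family map)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "gene" not in frame.columns or value_col not in frame.columns:
        raise ValueError(f"map TSV needs columns 'gene' and {value_col!r}")
    values = frame[value_col]
    if value_col == "domain":
        values = values.astype(int)
    return dict(zip(frame["gene"], values))


def size_factor_normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size-factor normalization (genes x samples).

    For genes with positive counts in every sample, each sample's factor is
    the median ratio of its counts to the per-gene geometric mean; the
    normalized matrix is raw counts divided by the factors. All-zero gene
    rows are preserved and carry no ratio information.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; "
            "add a pseudo-count before normalizing"
        )
    log_counts = np.log(counts.loc[positive])
    log_geomean = log_counts.mean(axis=1)
    factors = np.exp(log_counts.sub(log_geomean, axis=0).median(axis=0))
    factors.name = "size_factor"
    return counts.div(factors, axis=1), factors


@dataclass
class DomainUsage:
    """Per-group Ighv domain and family usage from normalized counts."""

    group: str
    domain_totals: pd.Series  # index: domain 1..4
    domain_freq: pd.Series
    family_totals: pd.Series
    family_freq: pd.Series

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level": "domain", "name": f"domain{d}", "total": t, "freq": f}
            for d, t, f in zip(
                self.domain_totals.index, self.domain_totals, self.domain_freq
            )
        ] + [
            {"level": "family", "name": n, "total": t, "freq": f}
            for n, t, f in zip(
                self.family_totals.index, self.family_totals, self.family_freq
            )
        ]
        frame = pd.DataFrame(rows)
        frame.insert(0, "group", self.group)
        return frame


def _canon(gene: str) -> str:
    return strip_allele(gene).lower()


def domain_family_usage(
    normalized: pd.DataFrame,
    domain_map: Mapping[str, int],
    family_map: Mapping[str, str],
    sample_groups: Mapping[str, str],
) -> dict[str, DomainUsage]:
    """Aggregate normalized Ighv counts into domain and family usage per group.

    Replicate samples sharing a group label are averaged per gene before
    summation (means of normalized counts, then sums over grouped genes).
    Gene matching is case-insensitive and allele-stripped; genes absent from
    either map are excluded and logged.
    """
    domain_lookup = {_canon(g): d for g, d in domain_map.items()}
    family_lookup = {_canon(g): f for g, f in family_map.items()}
    keep, domains, families = [], [], []
    dropped = []
    for gene in normalized.index:
        key = _canon(str(gene))
        if key in domain_lookup and key in family_lookup:
            keep.append(gene)
            domains.append(domain_lookup[key])
            families.append(family_lookup[key])
        else:
            dropped.append(gene)
    if dropped:
        logger.warning("excluding %d gene(s) absent from maps: %s", len(dropped), dropped)

    sub = normalized.loc[keep]
    groups = sorted(set(sample_groups.values()))
    out: dict[str, DomainUsage] = {}
    for group in groups:
        samples = [s for s in normalized.columns if sample_groups.get(s) == group]
        if not samples:
            raise ValueError(f"empty group {group!r}")
        gene_means = sub[samples].mean(axis=1)
        by_domain = gene_means.groupby(pd.Index(domains, name="domain")).sum()
        by_domain = by_domain.reindex([1, 2, 3, 4], fill_value=0.0)
        by_family = gene_means.groupby(pd.Index(families, name="family")).sum().sort_index()
        d_total = by_domain.sum()
        f_total = by_family.sum()
        out[group] = DomainUsage(
            group=group,
            domain_totals=by_domain,
            domain_freq=by_domain / d_total if d_total else by_domain * np.nan,
            family_totals=by_family,
            family_freq=by_family / f_total if f_total else by_family * np.nan,
        )
    return out
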