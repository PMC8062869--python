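"""Bulk-chemistry aggregation and community-level statistics.

Covers the operationally defined community analyses: abundance/prevalence
taxa filtering, taxa-vs-bulk-chemistry correlation matrices with
hierarchical ordering, Bray-Curtis dissimilarity, and SIMPER
(similarity-percentage) decomposition of between-group dissimilarity.

SIMPER: for each between-group sample pair (a, b), taxon i contributes
``|x_ai - x_bi| / sum_k (x_ak + x_bk)`` to the pair's Bray-Curtis
dissimilarity; contributions are averaged over all between-group pairs.
By construction the per-taxon contributions sum exactly to the mean
between-group Bray-Curtis dissimilarity. The "selected set" is the
smallest descending-ranked prefix whose cumulative share reaches the
cutoff (default 75%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import complete, leaves_list
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr


@dataclass
class CommunityTable:
    """Relative-abundance table: samples x taxa, with group labels.

    Rows of a freshly built table sum to 1 (tolerance 1e-6); tables
    produced by :func:`filter_taxa` keep their original (un-renormalised)
    abundances and set ``renormalized_rows=False`` in their metadata.
    """

    abundance: pd.DataFrame  # index = sample ids, columns = taxa
    groups: pd.Series | None = None  # per-sample group / substrate label
    metadata: dict = field(default_factory=dict)
    validate_rows: bool = True

    def __post_init__(self) -> None:
        ab = self.abundance
        if (ab.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.validate_rows and len(ab):
            sums = ab.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                bad = sums[~np.isclose(sums, 1.0, atol=1e-6)].index.tolist()
                raise ValueError(f"rows do not sum to 1: {bad}")
        if self.groups is not None:
            self.groups = pd.Series(self.groups).reindex(ab.index)

    @property
    def samples(self) -> list:
        return list(self.abundance.index)

    @property
    def taxa(self) -> list:
        return list(self.abundance.columns)


@dataclass
class BulkChemistry:
    """Substrates x elements weight-% matrix from averaged broad-area scans."""

    weight_pct: pd.DataFrame  # index = substrate ids, columns = element symbols

    def __post_init__(self) -> None:
        w = self.weight_pct
        if (w.to_numpy() < 0).any():
            raise ValueError("weight percents must be non-negative")
        totals = w.sum(axis=1)
        if (totals > 100 + 1e-6).any():
            warnings.warn("substrate totals exceed 100 weight-%")


def bulk_chemistry(scans: list[dict[str, float]] | pd.DataFrame,
                   substrate: str = "substrate") -> pd.Series:
    """Element-wise mean composition across replicate broad-area scans."""
    if isinstance(scans, pd.DataFrame):
        df = scans
    else:
        if not scans:
            raise ValueError("need at least one scan")
        keys = set(scans[0])
        for k, sc in enumerate(scans):
            if set(sc) != keys:
                raise ValueError(f"scan {k} has inconsistent element set")
        df = pd.DataFrame(scans)
    mean = df.mean(axis=0)
    mean.name = substrate
    return mean


def filter_taxa(table: CommunityTable, min_abundance: float = 0.01,
                min_prevalence: float = 0.5) -> CommunityTable:
    """Keep taxa reaching ``min_abundance`` in at least one sample AND
    present (> 0) in at least ``min_prevalence`` of samples.

    Abundances are *not* renormalised after filtering, so retained values
    stay interpretable against the original whole community.
    """
    ab = table.abundance
    if ab.empty:
        return CommunityTable(ab.copy(), table.groups,
                              metadata=dict(table.metadata), validate_rows=False)
    reaches = (ab >= min_abundance).any(axis=0)
    prevalence = (ab > 0).mean(axis=0) >= min_prevalence
    keep = ab.columns[reaches & prevalence]
    if len(keep) == 0:
        warnings.warn("taxa filter removed every taxon")
    meta = dict(table.metadata)
    meta.update({"renormalized_rows": False,
                 "filter": {"min_abundance": min_abundance,
                            "min_prevalence": min_prevalence}})
    return CommunityTable(ab[keep].copy(), table.groups, metadata=meta,
                          validate_rows=False)


def taxa_chem_correlation(
    table: CommunityTable,
    chem: BulkChemistry,
    sample_substrate: pd.Series | None = None,
    method: str = "pearson",
    cluster: bool = True,
) -> pd.DataFrame:
    """Taxa x elements correlation matrix across samples.

    Each sample maps to a substrate (via ``sample_substrate`` or the
    table's group labels); a taxon's abundances are correlated against the
    substrate's element weight-%. Zero-variance taxa or elements yield NaN
    (undefined, distinct from 0). Rows and columns are ordered by
    complete-linkage clustering of correlation distance unless
    ``cluster=False``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    subs = sample_substrate if sample_substrate is not None else table.groups
    if subs is None:
        raise ValueError("need a sample -> substrate mapping")
    subs = pd.Series(subs).reindex(table.abundance.index)
    missing = set(subs) - set(chem.weight_pct.index)
    if missing:
        raise ValueError(f"substrates missing from chemistry table: {missing}")
    if len(table.abundance) < 3:
        raise ValueError("need at least 3 samples for correlations")
    elem = chem.weight_pct.loc[subs].to_numpy()  # samples x elements
    corr_fn = pearsonr if method == "pearson" else spearmanr

    taxa = table.taxa
    elements = list(chem.weight_pct.columns)
    ab = table.abundance.to_numpy()
    out = np.full((len(taxa), len(elements)), np.nan)
    for i in range(len(taxa)):
        xi = ab[:, i]
        if np.std(xi) == 0:
            continue
        for j in range(len(elements)):
            ej = elem[:, j]
            if np.std(ej) == 0:
                continue
            out[i, j] = corr_fn(xi, ej)[0]
    mat = pd.DataFrame(out, index=taxa, columns=elements)
    if cluster and mat.shape[0] > 2 and mat.shape[1] > 2:
        mat = _cluster_order(mat)
    return mat


def _cluster_order(mat: pd.DataFrame) -> pd.DataFrame:
    """Complete-linkage ordering of rows and columns (correlation distance)."""
    filled = mat.fillna(0.0).to_numpy()

    def order(m):
        if len(m) < 3:
            return np.arange(len(m))
        with np.errstate(invalid="ignore"):
            d = pdist(m, metric="correlation")
        d = np.nan_to_num(d, nan=1.0)
        return leaves_list(complete(d))

    ri = order(filled)
    ci = order(filled.T)
    return mat.iloc[ri, ci]


def bray_curtis(table: CommunityTable) -> pd.DataFrame:
    """Samples x samples Bray-Curtis dissimilarity matrix.

    ``d(a, b) = sum_i |x_ai - x_bi| / sum_i (x_ai + x_bi)``; symmetric,
    zero diagonal, entries in [0, 1]. All-zero samples are rejected.
    """
    ab = table.abundance.to_numpy()
    if len(ab) and (ab.sum(axis=1) == 0).any():
        bad = table.abundance.index[ab.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero sample rows: {bad}")
    d = squareform(pdist(ab, metric="braycurtis")) if len(ab) > 1 else (
        np.zeros((len(ab), len(ab))))
    return pd.DataFrame(d, index=table.samples, columns=table.samples)


@dataclass
class SimperResult:
    """Per-taxon contributions to mean between-group Bray-Curtis dissimilarity."""

    contributions: pd.Series  # descending, indexed by taxon
    mean_dissimilarity: float
    cumulative_fraction: pd.Series
    selected: list  # smallest prefix reaching the cutoff
    cutoff: float
    group_a: str
    group_b: str

    def to_dict(self) -> dict:
        return {
            "group_a": str(self.group_a),
            "group_b": str(self.group_b),
            "mean_between_group_dissimilarity": float(self.mean_dissimilarity),
            "cutoff": self.cutoff,
            "selected": [str(t) for t in self.selected],
            "contributions": {str(t): float(v)
                              for t, v in self.contributions.items()},
        }


def simper(table: CommunityTable, group_a, group_b,
           cutoff: float = 0.75) -> SimperResult:
    """SIMPER decomposition of between-group Bray-Curtis dissimilarity.

    Averages per-taxon contributions over every between-group sample pair;
    the contributions sum exactly to the mean between-group dissimilarity.
    ``selected`` is the smallest descending prefix with cumulative share
    >= ``cutoff`` (the "top 75%" convention by default).
    """
    if table.groups is None:
        raise ValueError("table has no group labels")
    ia = np.flatnonzero(table.groups.to_numpy() == group_a)
    ib = np.flatnonzero(table.groups.to_numpy() == group_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError(f"empty group: {group_a if not len(ia) else group_b}")
    ab = table.abundance.to_numpy()
    total = np.zeros(ab.shape[1])
    n_pairs = 0
    for i in ia:
        for j in ib:
            denom = (ab[i] + ab[j]).sum()
            if denom == 0:
                raise ValueError("pair of all-zero samples")
            total += np.abs(ab[i] - ab[j]) / denom
            n_pairs += 1
    contrib = pd.Series(total / n_pairs, index=table.taxa)
    contrib = contrib.sort_values(ascending=False, kind="stable")
    mean_d = float(contrib.sum())
    if mean_d > 0:
        cum = contrib.cumsum() / mean_d
        n_sel = int(np.searchsorted(cum.to_numpy(), cutoff) + 1)
        n_sel = min(n_sel, len(cum))
        selected = list(contrib.index[:n_sel])
    else:
        cum = contrib * 0.0
        selected = []
    return SimperResult(contrib, mean_d, cum, selected, cutoff,
                        str(group_a), str(group_b))
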