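"""Core-community selection.

A phylotype belongs to the soil core community of a kingdom when it is (i)
among the top fraction (default 10%) of phylotypes by mean relative
abundance over all samples, zeros included, and (ii) present in at least
``min_cwps`` (default 4) distinct CWP species.  Selection runs per kingdom
on the pooled sample table.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd


@dataclasses.dataclass
class CoreSet:
    kingdom: str | None
    taxa: list[str]
    stats: pd.DataFrame          # per final core taxon: mean_rel_abund, cwp_prevalence
    abundant_taxa: list[str]     # step-1 set (top fraction by abundance)
    top_fraction: float
    min_cwps: int
    read_share: float            # core reads / total reads
    richness_share: float        # |core| / total taxa


def cwp_prevalence(presence: pd.DataFrame, site_table: pd.DataFrame) -> pd.Series:
    """Number of CWP species with >= 1 sample where each taxon is present."""
    cwps = site_table.loc[presence.columns, "cwp_species"]
    by_cwp = presence.T.groupby(cwps.to_numpy()).any()
    return by_cwp.sum(axis=0)


def select_core(
    rel_abund: pd.DataFrame,
    presence: pd.DataFrame,
    site_table: pd.DataFrame,
    counts: pd.DataFrame | None = None,
    top_fraction: float = 0.10,
    min_cwps: int = 4,
    kingdom: str | None = None,
) -> CoreSet:
    """Two-step core selection: abundance decile, then CWP prevalence.

    Step 1 keeps the ceil(top_fraction x S) taxa of highest mean relative
    abundance (ties at the boundary value are all kept, so the result is
    order-free).  Step 2 keeps those present in at least ``min_cwps``
    distinct CWP species.  ``counts`` (if given) is used to report the
    core's share of total reads.
    """
    if rel_abund.empty:
        raise ValueError("empty abundance table")
    if not rel_abund.index.equals(presence.index) or not rel_abund.columns.equals(
        presence.columns
    ):
        raise ValueError("rel_abund and presence must share taxa and samples")
    n_cwps_total = site_table["cwp_species"].nunique()
    if min_cwps > n_cwps_total:
        raise ValueError(
            f"min_cwps={min_cwps} exceeds the {n_cwps_total} CWP species present"
        )

    mean_ra = rel_abund.mean(axis=1)
    n_keep = math.ceil(top_fraction * len(mean_ra))
    ranked = mean_ra.sort_values(ascending=False, kind="mergesort")
    boundary = ranked.iloc[n_keep - 1]
    abundant = ranked[ranked >= boundary].index.tolist()  # ties at boundary included

    prev = cwp_prevalence(presence.loc[abundant], site_table)
    core_taxa = [t for t in abundant if prev[t] >= min_cwps]

    if counts is not None:
        total = counts.to_numpy().sum()
        read_share = counts.loc[core_taxa].to_numpy().sum() / total if total else np.nan
    else:
        read_share = float(mean_ra[core_taxa].sum())
    stats = pd.DataFrame(
        {
            "mean_rel_abund": mean_ra[core_taxa],
            "cwp_prevalence": prev[core_taxa].astype(int),
        }
    )
    stats.index.name = "taxon"
    return CoreSet(
        kingdom=kingdom,
        taxa=core_taxa,
        stats=stats,
        abundant_taxa=abundant,
        top_fraction=top_fraction,
        min_cwps=min_cwps,
        read_share=float(read_share),
        richness_share=len(core_taxa) / len(mean_ra),
    )


def overlap_counts(
    core: CoreSet, presence: pd.DataFrame, site_table: pd.DataFrame
) -> pd.DataFrame:
    """Upset-style intersection counts over CWP species.

    Each core taxon has a signature: the set of CWP species in whose sites
    it occurs.  The table lists every realized signature with the number of
    core taxa carrying exactly that signature; counts sum to |core|.
    """
    if not core.taxa:
        raise ValueError("empty core set")
    cwps = site_table.loc[presence.columns, "cwp_species"]
    by_cwp = presence.loc[core.taxa].T.groupby(cwps.to_numpy()).any().T
    signatures = by_cwp.apply(
        lambda row: "|".join(sorted(by_cwp.columns[row.to_numpy(bool)])), axis=1
    )
    out = (
        signatures.value_counts()
        .rename_axis("cwp_signature")
        .reset_index(name="n_taxa")
        .assign(degree=lambda d: d["cwp_signature"].str.count(r"\|") + 1)
        .sort_values(["degree", "n_taxa"], ascending=[True, False], kind="mergesort")
        .reset_index(drop=True)
    )
    return out
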