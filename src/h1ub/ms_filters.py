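"""Crosslink and PTM-site filtering, collapsing, weighting and classification.

Crosslink identification tables (xQuest-style TSV) are consumed as pandas
DataFrames with columns ``protein_a, residue_a, protein_b, residue_b,
ld_score, deltaS, fdr, replicate``. Two canned policies reflect standard
practice: a strict plotting policy (ld score > 30, deltaS < 0.95,
FDR < 0.05, site present in all biological replicates) and a permissive
modeling policy (ld score >= 20, same deltaS/FDR cuts, site present in at
least one replicate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "FilterPolicy",
    "PLOTTING_POLICY",
    "MODELING_POLICY",
    "WeightedCrossLink",
    "filter_crosslinks",
    "collapse_and_weight",
    "filter_ptm_sites",
    "export_link_map",
    "DEFAULT_LD_CLASS_BOUNDS",
]

REQUIRED_COLUMNS = (
    "protein_a", "residue_a", "protein_b", "residue_b",
    "ld_score", "deltaS", "fdr", "replicate",
)

# Ordinal ld-score classes; boundaries configurable (three classes are the
# field convention, exact boundaries are a tool choice).
DEFAULT_LD_CLASS_BOUNDS = (20.0, 30.0, 40.0)


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds plus a replicate rule, applied at the unique-site level.

    ``min_ld_inclusive`` encodes strictness exactly: the plotting policy
    uses a strict ``ld > 30``, the modeling policy an inclusive ``ld >= 20``.
    """

    min_ld: float = 30.0
    min_ld_inclusive: bool = False
    max_deltaS: float = 0.95
    max_fdr: float = 0.05
    replicate_rule: Literal["all_replicates", "any_replicate"] = "all_replicates"
    n_replicates: int = 3

    def __post_init__(self) -> None:
        for v in (self.min_ld, self.max_deltaS, self.max_fdr):
            if not np.isfinite(v):
                raise ValueError("policy thresholds must be finite")


PLOTTING_POLICY = FilterPolicy(
    min_ld=30.0, min_ld_inclusive=False, replicate_rule="all_replicates"
)
MODELING_POLICY = FilterPolicy(
    min_ld=20.0, min_ld_inclusive=True, replicate_rule="any_replicate"
)


@dataclass(frozen=True)
class WeightedCrossLink:
    """One unique residue pair after collapsing replicates.

    ``weight`` equals the number of distinct replicates containing the site
    (a link found in all three biological replicates therefore enters the
    scoring with three times the weight of a single-replicate link);
    ``ld_class`` is the ordinal class index (0-based) of ``best_ld``.
    """

    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    weight: int
    best_ld: float
    ld_class: int

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ValueError("weight must be >= 1")


def _validate_schema(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"crosslink table missing required columns: {missing}")


def canonical_site(row) -> tuple[str, int, str, int]:
    """Canonically ordered unordered site pair: sort by (protein, residue)."""
    a = (str(row.protein_a), int(row.residue_a))
    b = (str(row.protein_b), int(row.residue_b))
    lo, hi = sorted([a, b])
    return (lo[0], lo[1], hi[0], hi[1])


def _add_site_key(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    keys = [canonical_site(r) for r in out.itertuples(index=False)]
    out["_site"] = [f"{a}:{ra}--{b}:{rb}" for a, ra, b, rb in keys]
    return out


def filter_crosslinks(table: pd.DataFrame, policy: FilterPolicy) -> pd.DataFrame:
    """Apply score thresholds row-wise, then the replicate rule site-wise.

    Rows failing any threshold are removed first; the replicate rule is then
    evaluated per unique (canonically ordered) site pair on the surviving
    rows: ``all_replicates`` keeps sites present in ``policy.n_replicates``
    distinct replicates, ``any_replicate`` keeps any surviving site.
    """
    if table.empty:
        return table.copy()
    _validate_schema(table)
    ld = table["ld_score"]
    ld_ok = ld >= policy.min_ld if policy.min_ld_inclusive else ld > policy.min_ld
    keep = ld_ok & (table["deltaS"] < policy.max_deltaS) & (table["fdr"] < policy.max_fdr)
    out = _add_site_key(table.loc[keep])
    if out.empty:
        return out.drop(columns="_site")
    if policy.replicate_rule == "all_replicates":
        counts = out.groupby("_site")["replicate"].nunique()
        good = counts[counts >= policy.n_replicates].index
        out = out[out["_site"].isin(good)]
    return out.drop(columns="_site").reset_index(drop=True)


def collapse_and_weight(
    table: pd.DataFrame,
    class_bounds: tuple[float, ...] = DEFAULT_LD_CLASS_BOUNDS,
) -> list[WeightedCrossLink]:
    """Collapse an already-filtered table to one record per unique site pair.

    Within each replicate the highest-scoring entry for a site is chosen;
    the weight is the count of distinct replicates containing the site, and
    ``best_ld`` the maximum over those per-replicate top entries.
    """
    if table.empty:
        return []
    _validate_schema(table)
    out = _add_site_key(table)
    # per (site, replicate): top-scoring entry
    top = out.loc[out.groupby(["_site", "replicate"])["ld_score"].idxmax()]
    links = []
    for site, grp in top.groupby("_site"):
        row = grp.loc[grp["ld_score"].idxmax()]
        a, ra, b, rb = canonical_site(row)
        best = float(row.ld_score)
        ld_class = int(np.searchsorted(np.asarray(class_bounds), best, side="right")) - 1
        links.append(
            WeightedCrossLink(
                protein_a=a,
                residue_a=ra,
                protein_b=b,
                residue_b=rb,
                weight=int(grp["replicate"].nunique()),
                best_ld=best,
                ld_class=max(ld_class, 0),
            )
        )
    links.sort(key=lambda l: (l.protein_a, l.residue_a, l.protein_b, l.residue_b))
    return links


def filter_ptm_sites(
    psm_table: pd.DataFrame,
    min_site_prob: float = 0.75,
    min_replicates: int = 1,
    max_mods_per_peptide: int = 3,
    n_total_replicates: int | None = None,
) -> pd.DataFrame:
    """Apply site-probability, per-peptide modification-count and replicate filters.

    Expects columns ``protein, site, site_prob, peptide, n_mods, replicate``.
    A site survives if its localization probability meets ``min_site_prob``,
    its peptide carries at most ``max_mods_per_peptide`` modifications, and
    after those row filters it is detected in at least ``min_replicates``
    distinct replicates.
    """
    if n_total_replicates is not None and min_replicates > n_total_replicates:
        raise ValueError(
            f"min_replicates ({min_replicates}) exceeds total replicates ({n_total_replicates})"
        )
    if psm_table.empty:
        return psm_table.copy()
    required = ("protein", "site", "site_prob", "n_mods", "replicate")
    missing = [c for c in required if c not in psm_table.columns]
    if missing:
        raise KeyError(f"PTM table missing required columns: {missing}")
    if ((psm_table["site_prob"] < 0) | (psm_table["site_prob"] > 1)).any():
        raise ValueError("site probabilities must lie in [0, 1]")
    keep = (psm_table["site_prob"] >= min_site_prob) & (
        psm_table["n_mods"] <= max_mods_per_peptide
    )
    out = psm_table.loc[keep]
    if out.empty:
        return out.reset_index(drop=True)
    support = out.groupby(["protein", "site"])["replicate"].nunique()
    good = support[support >= min_replicates].index
    mask = out.set_index(["protein", "site"]).index.isin(good)
    return out.loc[mask].reset_index(drop=True)


def export_link_map(
    links: Iterable[WeightedCrossLink],
    protein_lengths: dict[str, int],
) -> pd.DataFrame:
    """Tabulate links with protein coordinates for 2-D link-map plotting.

    Each record carries both protein ids, residue positions, protein lengths,
    the intra/inter classification, weight and ld class. Residues beyond the
    annotated protein length raise a validation error.
    """
    rows = []
    for link in links:
        for prot, res in ((link.protein_a, link.residue_a), (link.protein_b, link.residue_b)):
            if prot not in protein_lengths:
                raise KeyError(f"no length annotation for protein {prot!r}")
            if not 1 <= res <= protein_lengths[prot]:
                raise ValueError(
                    f"residue {res} outside protein {prot!r} (length {protein_lengths[prot]})"
                )
        rows.append(
            {
                "protein_a": link.protein_a,
                "residue_a": link.residue_a,
                "len_a": protein_lengths[link.protein_a],
                "protein_b": link.protein_b,
                "residue_b": link.residue_b,
                "len_b": protein_lengths[link.protein_b],
                "link_type": "intra" if link.protein_a == link.protein_b else "inter",
                "weight": link.weight,
                "best_ld": link.best_ld,
                "ld_class": link.ld_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_a", "residue_a", "len_a", "protein_b", "residue_b", "len_b",
            "link_type", "weight", "best_ld", "ld_class",
        ],
    )
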