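"""Blood-compound deconvolution of whole-blood miRNAs.

miRNAs are partitioned by their exact presence signature over the ten
blood compounds (serum, microvesicles, red blood cells, CD15 neutrophils,
CD19 B cells, CD8 cytotoxic T, CD56 NK, CD4 T-helper, CD14 monocytes,
cell-free); single-compound signatures are the "specific" miRNAs.  Age
clusters are tested for compound enrichment against the unaltered cluster
as background (per-compound hypergeometric, BH-adjusted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stats import adjust_bh


@dataclass
class SignatureGroups:
    groups: dict[tuple[str, ...], list[str]]   # signature -> members
    unassigned: list[str]

    def sizes(self) -> list[int]:
        return sorted((len(v) for v in self.groups.values()), reverse=True)

    def specific(self) -> dict[str, list[str]]:
        """Members whose signature is a single compound, keyed by compound."""
        return {sig[0]: members for sig, members in self.groups.items()
                if len(sig) == 1}


def signature_groups(presence: pd.DataFrame) -> SignatureGroups:
    """Exact-signature partition of miRNAs, sorted by group size."""
    groups: dict[tuple[str, ...], list[str]] = {}
    unassigned: list[str] = []
    compounds = list(presence.columns)
    arr = presence.to_numpy(dtype=bool)
    for i, fid in enumerate(presence.index):
        sig = tuple(c for c, present in zip(compounds, arr[i]) if present)
        if not sig:
            unassigned.append(fid)
        else:
            groups.setdefault(sig, []).append(fid)
    ordered = dict(sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0])))
    return SignatureGroups(ordered, unassigned)


def compound_distribution(members, presence: pd.DataFrame) -> pd.Series:
    """Relative per-compound presence of a member set, normalized to 1."""
    members = list(members)
    if not members:
        raise ValueError("empty member set")
    rates = presence.loc[members].mean(axis=0)
    total = rates.sum()
    if total == 0:
        raise ValueError("members absent from every compound")
    return rates / total


def cluster_compound_enrichment(
    up_members, down_members, background, presence: pd.DataFrame
) -> pd.DataFrame:
    """Compound enrichment of age-up and age-down clusters vs background.

    Ratios compare each set's per-compound presence rate with the
    background rate; p-values are upper-tail hypergeometric with universe
    up + down + background, BH-adjusted across compounds within each set.
    """
    up, down, bg = set(up_members), set(down_members), set(background)
    if not bg:
        raise ValueError("empty background")
    if up & down or up & bg or down & bg:
        raise ValueError("up, down and background sets must be disjoint")
    universe = sorted(up | down | bg)
    uni = presence.loc[universe]
    bg_rate = presence.loc[sorted(bg)].mean(axis=0)
    out = {}
    for label, members in (("up", up), ("down", down)):
        sub = presence.loc[sorted(members)]
        rate = sub.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = rate / bg_rate.replace(0, np.nan)
        pvals = []
        for comp in presence.columns:
            M = len(universe)
            K = int(uni[comp].sum())
            N = len(members)
            k = int(sub[comp].sum())
            pvals.append(float(stats.hypergeom.sf(k - 1, M, K, N)))
        out[f"ratio_{label}"] = ratio
        out[f"p_{label}"] = pd.Series(pvals, index=presence.columns)
        out[f"p_adj_{label}"] = pd.Series(adjust_bh(pvals), index=presence.columns)
    return pd.DataFrame(out)
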