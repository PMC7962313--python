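"""Gamma-calibrated detection of mobile elements with atypical composition.

For each taxonomic family, the Euclidean distance of every element's
profile to the family's barycenter (arithmetic mean profile) is computed;
a single gamma distribution is fitted by maximum likelihood to the pooled
distances across all families, and elements whose distance exceeds the
gamma quantile at the chosen confidence level (default 0.95) are flagged.

The original two-stage protocol (systematic flags, then manual removals
and additions after visual dendrogram inspection) is represented by an
override list: the final report records the provenance of every flag
(systematic, manual_add, manual_remove).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)


def family_barycenter_distances(
    profiles: pd.DataFrame, families
) -> tuple[pd.Series, list[str]]:
    """Distance of each element to its own family's mean profile.

    Elements in singleton families are excluded (their distance would be 0
    by construction) and returned in the second element.
    """
    fam = pd.Series(list(families), index=profiles.index)
    counts = fam.value_counts()
    eligible = counts[counts >= 2].index
    if len(eligible) == 0:
        raise ValueError("no family with >= 2 members")
    excluded = list(profiles.index[~fam.isin(eligible)])
    if excluded:
        logger.info("excluding %d singleton-family elements", len(excluded))
    dists = {}
    for f in eligible:
        idx = fam[fam == f].index
        X = profiles.loc[idx].to_numpy(dtype=float)
        bary = X.mean(axis=0)
        d = np.sqrt(((X - bary) ** 2).sum(axis=1))
        for gid, val in zip(idx, d):
            dists[gid] = val
    out = pd.Series(dists, name="distance")
    return out.loc[[i for i in profiles.index if i in dists]], excluded


def fit_gamma(distances) -> tuple[float, float]:
    """Maximum-likelihood gamma fit (location fixed at 0) on the pooled
    barycenter distances; zeros are dropped with a warning."""
    d = np.asarray(list(distances), dtype=float)
    zeros = d <= 0
    if zeros.any():
        warnings.warn(f"dropping {int(zeros.sum())} non-positive distances", stacklevel=2)
        d = d[~zeros]
    if len(d) < 10:
        raise ValueError(f"need >= 10 positive distances, got {len(d)}")
    if np.ptp(d) < 1e-12 * max(1.0, d.mean()):
        raise ValueError("degenerate fit: all distances (nearly) equal")
    shape, _, scale = scipy.stats.gamma.fit(d, floc=0)
    return float(shape), float(scale)


def flag_outliers(
    distances, shape: float, scale: float, confidence: float = 0.95
) -> tuple[pd.Series, float]:
    """Flags (strictly above the gamma quantile at ``confidence``) and the
    threshold itself."""
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    threshold = float(scipy.stats.gamma.ppf(confidence, shape, scale=scale))
    d = pd.Series(distances)
    return d > threshold, threshold


@dataclass
class OutlierReport:
    table: pd.DataFrame  # id, family, distance, threshold, flag, provenance
    shape: float
    scale: float
    confidence: float
    threshold: float
    excluded: list[str]

    @property
    def n_systematic(self) -> int:
        return int((self.table["provenance"] == "systematic").sum())

    @property
    def n_manual_add(self) -> int:
        return int((self.table["provenance"] == "manual_add").sum())

    @property
    def n_manual_remove(self) -> int:
        return int((self.table["provenance"] == "manual_remove").sum())

    @property
    def n_outliers(self) -> int:
        """Final count: systematic flags minus removals plus additions."""
        return int(self.table["flag"].sum())

    @property
    def flagged_ids(self) -> list[str]:
        return list(self.table.loc[self.table["flag"], "id"])


def outlier_report(
    profiles: pd.DataFrame,
    families,
    confidence: float = 0.95,
    manual_add=(),
    manual_remove=(),
) -> OutlierReport:
    """Full outlier analysis: distances, gamma fit, systematic flags,
    manual overrides, and per-element provenance."""
    fam = pd.Series(list(families), index=profiles.index)
    dists, excluded = family_barycenter_distances(profiles, fam)
    shape, scale = fit_gamma(dists)
    flags, threshold = flag_outliers(dists, shape, scale, confidence)
    provenance = []
    final = []
    for gid in dists.index:
        systematic = bool(flags[gid])
        if gid in manual_remove:
            provenance.append("manual_remove")
            final.append(False)
        elif gid in manual_add:
            provenance.append("manual_add")
            final.append(True)
        elif systematic:
            provenance.append("systematic")
            final.append(True)
        else:
            provenance.append("")
            final.append(False)
    table = pd.DataFrame(
        {
            "id": dists.index,
            "family": fam.loc[dists.index].to_numpy(),
            "distance": dists.to_numpy(),
            "threshold": threshold,
            "flag": final,
            "provenance": provenance,
        }
    ).reset_index(drop=True)
    return OutlierReport(
        table=table,
        shape=shape,
        scale=scale,
        confidence=confidence,
        threshold=threshold,
        excluded=excluded,
    )
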