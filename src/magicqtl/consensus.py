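"""Consensus QTL co-localization across traits, years and methods.

Two detected QTL are declared co-localized when they lie on the same
chromosome, their peaks are at most 20 cM apart, and the Pearson
correlation of their eight-founder effect vectors exceeds 0.6.  Single
linkage agglomeration on the resulting 0/1 distance matrix, cut at 0.5,
then groups QTL into pleiotropic consensus clusters — equivalent to the
connected components of the co-localization graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .scan import QTLRecord

DEFAULT_MAX_DISTANCE_CM = 20.0
DEFAULT_MIN_FOUNDER_R = 0.6


def founder_effect_correlation(v1: np.ndarray, v2: np.ndarray) -> float:
    """Pearson correlation of two eight-founder effect vectors.

    Returns NaN when either vector has zero variance (correlation
    undefined); callers treat NaN as "not co-localized".
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    s1, s2 = v1.std(), v2.std()
    if s1 <= 0 or s2 <= 0:
        return float("nan")
    return float(np.corrcoef(v1, v2)[0, 1])


def colocalized(
    q1: QTLRecord,
    q2: QTLRecord,
    max_distance_cM: float = DEFAULT_MAX_DISTANCE_CM,
    min_founder_r: float = DEFAULT_MIN_FOUNDER_R,
) -> bool:
    """Co-localization predicate: same chromosome, peaks within 20 cM
    (inclusive), founder-effect correlation strictly above 0.6."""
    if q1.chrom != q2.chrom:
        return False
    if abs(q1.peak_cM - q2.peak_cM) > max_distance_cM:
        return False
    r = founder_effect_correlation(q1.founder_effects, q2.founder_effects)
    if np.isnan(r):
        return False
    return r > min_founder_r


@dataclass
class ConsensusGroup:
    """A cluster of QTL declared to be one pleiotropic locus."""

    group_id: int
    members: list[QTLRecord]
    chrom: str = field(init=False)
    median_peak_cM: float = field(init=False)
    traits: list[str] = field(init=False)
    years: list = field(init=False)
    methods: list[str] = field(init=False)
    mean_founder_effects: np.ndarray | None = field(init=False)

    def __post_init__(self) -> None:
        self.chrom = self.members[0].chrom
        self.median_peak_cM = float(np.median([m.peak_cM for m in self.members]))
        self.traits = sorted({m.trait for m in self.members})
        self.years = sorted({str(m.year) for m in self.members})
        self.methods = sorted({m.method for m in self.members})
        hap = [m.founder_effects for m in self.members if m.method == "haplotype"]
        self.mean_founder_effects = (
            np.mean(np.vstack(hap), axis=0) if hap else None
        )

    @property
    def size(self) -> int:
        return len(self.members)


def colocalization_matrix(
    qtls: list[QTLRecord],
    max_distance_cM: float = DEFAULT_MAX_DISTANCE_CM,
    min_founder_r: float = DEFAULT_MIN_FOUNDER_R,
) -> np.ndarray:
    """0/1 distance matrix over all QTL pairs (0 = co-localized)."""
    n = len(qtls)
    D = np.ones((n, n))
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            if colocalized(qtls[i], qtls[j], max_distance_cM, min_founder_r):
                D[i, j] = D[j, i] = 0.0
    return D


def consensus_groups(
    qtls: list[QTLRecord],
    max_distance_cM: float = DEFAULT_MAX_DISTANCE_CM,
    min_founder_r: float = DEFAULT_MIN_FOUNDER_R,
) -> list[ConsensusGroup]:
    """Single-linkage clustering of the 0/1 co-localization distances.

    The dendrogram cut at 0.5 merges exactly the chains of co-localized
    pairs, i.e. the connected components of the co-localization graph;
    each component becomes one consensus group with its summary.
    """
    if not qtls:
        return []
    if len(qtls) == 1:
        return [ConsensusGroup(1, list(qtls))]
    D = colocalization_matrix(qtls, max_distance_cM, min_founder_r)
    Z = linkage(squareform(D, checks=False), method="single")
    labels = fcluster(Z, t=0.5, criterion="distance")
    groups = []
    for gid in sorted(set(labels)):
        members = [q for q, lab in zip(qtls, labels) if lab == gid]
        groups.append(ConsensusGroup(int(gid), members))
    # stable, order-independent presentation: by chromosome then position
    groups.sort(key=lambda g: (g.chrom, g.median_peak_cM))
    for new_id, g in enumerate(groups, start=1):
        g.group_id = new_id
    return groups


def pleiotropy_report(groups: list[ConsensusGroup]) -> pd.DataFrame:
    """Per-group summary plus genome-wide totals.

    Columns: group id, chromosome, median peak, member count, distinct
    traits/years/methods, and the high/low confidence composition; a final
    TOTAL row aggregates counts over the genome.
    """
    rows = []
    for g in groups:
        high = sum(m.confidence == "high" for m in g.members)
        rows.append(
            {
                "group_id": g.group_id,
                "chrom": g.chrom,
                "median_peak_cM": g.median_peak_cM,
                "n_members": g.size,
                "n_traits": len(g.traits),
                "traits": ";".join(g.traits),
                "n_years": len(g.years),
                "n_methods": len(g.methods),
                "n_high_confidence": high,
                "n_low_confidence": g.size - high,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "group_id",
            "chrom",
            "median_peak_cM",
            "n_members",
            "n_traits",
            "traits",
            "n_years",
            "n_methods",
            "n_high_confidence",
            "n_low_confidence",
        ],
    )
    if len(report):
        total = {
            "group_id": "TOTAL",
            "chrom": "",
            "median_peak_cM": np.nan,
            "n_members": int(report["n_members"].sum()),
            "n_traits": np.nan,
            "traits": "",
            "n_years": np.nan,
            "n_methods": np.nan,
            "n_high_confidence": int(report["n_high_confidence"].sum()),
            "n_low_confidence": int(report["n_low_confidence"].sum()),
        }
        report = pd.concat([report, pd.DataFrame([total])], ignore_index=True)
    return report


def edge_list(
    qtls: list[QTLRecord],
    max_distance_cM: float = DEFAULT_MAX_DISTANCE_CM,
    min_founder_r: float = DEFAULT_MIN_FOUNDER_R,
) -> pd.DataFrame:
    """Audit table of all co-localized pairs with distance and founder r."""
    rows = []
    for i, q1 in enumerate(qtls):
        for j in range(i + 1, len(qtls)):
            q2 = qtls[j]
            if colocalized(q1, q2, max_distance_cM, min_founder_r):
                rows.append(
                    {
                        "i": i,
                        "j": j,
                        "trait_i": q1.trait,
                        "trait_j": q2.trait,
                        "chrom": q1.chrom,
                        "distance_cM": abs(q1.peak_cM - q2.peak_cM),
                        "founder_r": founder_effect_correlation(
                            q1.founder_effects, q2.founder_effects
                        ),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["i", "j", "trait_i", "trait_j", "chrom", "distance_cM", "founder_r"],
    )
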