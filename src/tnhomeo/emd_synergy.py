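"""Earth Mover's Distance between condition essentiality profiles.

A condition profile is the per-gene median count (total or unique channel)
across replicates, restricted to the genes retained by the selection rules;
two profiles are compared as unlabeled 1-D distributions with equal weight
per gene.  In one dimension the Wasserstein-1 distance is the integral of
the absolute difference of the empirical CDFs, and high distance between
two stresses within a strain predicts a synergistic growth defect when the
stresses are combined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .counts_io import CountMatrix, SampleDesign

log = logging.getLogger(__name__)

TIERS = ("low", "moderate", "high")


def condition_profile(counts: CountMatrix, design: SampleDesign, strain: str,
                      stress: str, level: str,
                      genes: list[str]) -> np.ndarray:
    """Median count per retained gene across the condition's replicates."""
    if not genes:
        raise ValueError(
            "empty retained gene set; relax the selection thresholds "
            "(tau_ess / rho_fc / lfdr cut) to retain genes")
    t = design.table
    ids = t.loc[(t["strain"] == strain) & (t["stress"] == stress)
                & (t["level"] == level), "sample_id"].tolist()
    if not ids:
        raise ValueError(f"no samples for {strain}/{stress}/{level}")
    if len(ids) == 1:
        log.warning("condition %s/%s/%s has a single replicate; median "
                    "equals that replicate", strain, stress, level)
    sub = counts.subset_genes(genes)
    df = sub.to_frame()[ids]
    return df.median(axis=1).to_numpy(dtype=float)


def emd_1d(P: np.ndarray, Q: np.ndarray) -> float:
    """Wasserstein-1 distance between two 1-D samples with uniform weights.

    Computed as the integral of |F_P - F_Q| over the merged support; when
    |P| = |Q| = m this equals (1/m) sum |p_(i) - q_(i)| over sorted values.
    """
    P = np.sort(np.asarray(P, dtype=float))
    Q = np.sort(np.asarray(Q, dtype=float))
    if len(P) == 0 or len(Q) == 0:
        raise ValueError("profiles must be non-empty")
    grid = np.sort(np.concatenate([P, Q]))
    deltas = np.diff(grid)
    Fp = np.searchsorted(P, grid[:-1], side="right") / len(P)
    Fq = np.searchsorted(Q, grid[:-1], side="right") / len(Q)
    return float(np.sum(np.abs(Fp - Fq) * deltas))


@dataclass
class SynergyMatrix:
    """Pairwise condition distances within one strain and channel."""

    strain: str
    channel: str
    conditions: list[str]             # "stress/level" labels
    distances: pd.DataFrame           # symmetric, zero diagonal
    genes_used: list[str]

    def long(self) -> pd.DataFrame:
        rows = []
        for a, b in combinations(self.conditions, 2):
            rows.append({"strain": self.strain, "channel": self.channel,
                         "condition_a": a, "condition_b": b,
                         "emd": self.distances.loc[a, b]})
        return pd.DataFrame(rows)


def condition_distances(counts: CountMatrix, design: SampleDesign,
                        strain: str, genes: list[str],
                        normalize: bool = False,
                        paired: bool = False) -> SynergyMatrix:
    """All pairwise EMDs between the strain's stressed conditions.

    ``normalize`` divides each profile by its mean before the distance (off
    by default; logged when used).  ``paired`` switches to per-gene
    transport — mean |p_g - q_g| over the shared gene order — a sensitivity
    variant; the default treats each profile as an unlabeled distribution.
    """
    t = design.table
    conds = (t.loc[(t["strain"] == strain) & (t["stress"] != "control"),
                   ["stress", "level"]]
             .drop_duplicates().itertuples(index=False))
    labels, profiles = [], []
    for stress, level in conds:
        prof = condition_profile(counts, design, strain, stress, level, genes)
        if normalize:
            prof = prof / max(prof.mean(), 1e-12)
        labels.append(f"{stress}/{level}")
        profiles.append(prof)
    if normalize:
        log.info("condition_distances: profiles mean-scaled before EMD")
    if paired:
        log.info("condition_distances: paired per-gene transport variant")
    D = pd.DataFrame(0.0, index=labels, columns=labels)
    for (i, a), (j, b) in combinations(enumerate(labels), 2):
        if paired:
            d = float(np.mean(np.abs(profiles[i] - profiles[j])))
        else:
            d = emd_1d(profiles[i], profiles[j])
        D.loc[a, b] = D.loc[b, a] = d
    return SynergyMatrix(strain, counts.channel, labels, D, list(genes))


def synergy_rank(S: SynergyMatrix) -> pd.DataFrame:
    """Rank condition pairs by EMD and tier them by within-strain tertiles.

    The returned frame is sorted by descending EMD (ties broken by the
    lexicographic pair label); pairs in the high tier are the predicted
    synergistic combinations.
    """
    if len(S.conditions) < 2:
        raise ValueError("need at least two conditions to rank pairs")
    tab = S.long()
    tab["pair"] = tab["condition_a"] + " vs " + tab["condition_b"]
    lo, hi = np.quantile(tab["emd"], [1 / 3, 2 / 3])
    tab["tier"] = np.where(tab["emd"] > hi, "high",
                           np.where(tab["emd"] > lo, "moderate", "low"))
    tab["predicted_synergistic"] = tab["tier"] == "high"
    tab = tab.sort_values(["emd", "pair"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab
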