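"""Fitness-effect classification and log2 fitness-defect values.

Classification works on batch-adjusted unique insertion counts and uses
medians across replicates for robustness to outlying values.  With
``m`` the median unique count of a gene in a condition and ``m_ctrl`` the
median in the strain-matched unstressed control:

* essential            — m <= tau_ess in the control and in every condition
                         of the strain;
* cond_essential       — m_cond <= tau_ess < m_ctrl;
* cond_beneficial      — m_cond <= m_ctrl / rho_fc and m_cond > tau_ess
                         (loss of the gene costs fitness under the stress);
* cond_detrimental     — m_cond >= rho_fc * m_ctrl (loss helps);
* cond_neutral         — otherwise.

Defaults tau_ess = 3 unique insertions and rho_fc = 4 are explicit,
configurable stand-ins recorded in every output.

Fitness values for knockoff selection are
``log2((counts under a condition + 1) / (counts under no stress + 1))``,
with the pseudocount keeping every value finite.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts_io import CONTROL_STRESS, CountMatrix, SampleDesign

log = logging.getLogger(__name__)

DEFAULT_TAU_ESS = 3.0
DEFAULT_RHO_FC = 4.0

_COEF_STRAIN = re.compile(r"^[es]\|.*\[([^:\]]+):")


@dataclass
class FitnessCallTable:
    """Per-(gene, strain, stress, level) classification with the medians
    behind it and the thresholds used."""

    table: pd.DataFrame   # locus_tag strain stress level class m_cond m_ctrl
    tau_ess: float = DEFAULT_TAU_ESS
    rho_fc: float = DEFAULT_RHO_FC

    def genes_with_class(self, cls: str, strain: str | None = None) -> list[str]:
        t = self.table
        m = t["gene_class"] == cls
        if strain is not None:
            m &= t["strain"] == strain
        return list(dict.fromkeys(t.loc[m, "locus_tag"]))


@dataclass
class FitnessMatrix:
    """log2 fitness-defect values, per stressed sample and per condition."""

    per_sample: pd.DataFrame     # genes x stressed-sample columns
    per_condition: pd.DataFrame  # genes x "strain/stress/level" columns
    design: SampleDesign = field(repr=False, default=None)


def _medians(counts: CountMatrix, design: SampleDesign) -> pd.DataFrame:
    """Median count across replicates per (strain, stress, level)."""
    df = counts.to_frame()
    t = design.table
    groups = t.groupby(["strain", "stress", "level"])["sample_id"].apply(list)
    med = {key: df[ids].median(axis=1) for key, ids in groups.items()}
    out = pd.DataFrame(med)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["strain", "stress", "level"])
    return out


def classify_genes(counts_unique: CountMatrix, design: SampleDesign,
                   tau_ess: float = DEFAULT_TAU_ESS,
                   rho_fc: float = DEFAULT_RHO_FC) -> FitnessCallTable:
    """Classify every gene in every (strain, stress, level) condition."""
    design.require_controls()
    counts_unique = counts_unique.reorder_samples(design.sample_ids)
    med = _medians(counts_unique, design)
    rows = []
    for g in design.strains:
        sub = med[g]
        m_ctrl = sub[CONTROL_STRESS].iloc[:, 0]
        stress_cols = [c for c in sub.columns if c[0] != CONTROL_STRESS]
        cond = sub[stress_cols]
        essential = (m_ctrl <= tau_ess) & (cond.le(tau_ess).all(axis=1))
        for (e, s) in stress_cols:
            m_cond = cond[(e, s)]
            cls = np.where(
                essential, "essential",
                np.where((m_cond <= tau_ess) & (m_ctrl > tau_ess),
                         "cond_essential",
                         np.where((m_cond <= m_ctrl / rho_fc)
                                  & (m_cond > tau_ess), "cond_beneficial",
                                  np.where(m_cond >= rho_fc * m_ctrl,
                                           "cond_detrimental", "cond_neutral"))))
            rows.append(pd.DataFrame({
                "locus_tag": counts_unique.genes, "strain": g, "stress": e,
                "level": s, "gene_class": cls,
                "m_cond": m_cond.to_numpy(), "m_ctrl": m_ctrl.to_numpy()}))
    return FitnessCallTable(pd.concat(rows, ignore_index=True),
                            tau_ess=tau_ess, rho_fc=rho_fc)


def fitness_defect(counts: CountMatrix, design: SampleDesign) -> FitnessMatrix:
    """log2((counts + 1) / (reference + 1)) against strain-matched controls.

    The reference for a stressed sample is the median unique count of the
    strain's unstressed controls in the same batch when that batch has
    controls, else the median over all of the strain's controls.
    """
    design.require_controls()
    counts = counts.reorder_samples(design.sample_ids)
    df = counts.to_frame()
    t = design.table
    per_sample = {}
    for _, row in t[t["stress"] != CONTROL_STRESS].iterrows():
        ctrl = t[(t["strain"] == row["strain"])
                 & (t["stress"] == CONTROL_STRESS)]
        same_batch = ctrl[ctrl["batch"] == row["batch"]]
        use = same_batch if len(same_batch) else ctrl
        ref = df[use["sample_id"].tolist()].median(axis=1)
        per_sample[row["sample_id"]] = np.log2(
            (df[row["sample_id"]] + 1.0) / (ref + 1.0))
    ps = pd.DataFrame(per_sample)
    cond_cols = {}
    for (g, e, s), ids in t[t["stress"] != CONTROL_STRESS].groupby(
            ["strain", "stress", "level"])["sample_id"]:
        cond_cols[f"{g}/{e}/{s}"] = ps[list(ids)].mean(axis=1)
    return FitnessMatrix(per_sample=ps, per_condition=pd.DataFrame(cond_cols),
                         design=design)


def subset_for_selection(calls: FitnessCallTable,
                         glm_calls: pd.DataFrame | None = None
                         ) -> dict[str, list[str]]:
    """Genes retained for downstream selection, per strain.

    Union of genes called ``cond_essential`` by the median-count rule in at
    least one condition of the strain, and genes called beneficial or
    detrimental by the GLM local-FDR analysis (``glm_calls`` with columns
    ``locus_tag``, ``coefficient``, ``call``; the strain is parsed from the
    nested coefficient name).  Order follows the call table's gene order.
    """
    out: dict[str, list[str]] = {}
    strains = list(dict.fromkeys(calls.table["strain"]))
    gene_order = list(dict.fromkeys(calls.table["locus_tag"]))
    rank = {g: i for i, g in enumerate(gene_order)}
    for g in strains:
        kept = set(calls.genes_with_class("cond_essential", strain=g))
        if glm_calls is not None and len(glm_calls):
            hits = glm_calls[glm_calls["call"].isin(["beneficial",
                                                     "detrimental"])]
            for _, r in hits.iterrows():
                m = _COEF_STRAIN.match(str(r["coefficient"]))
                if m and m.group(1) == g:
                    kept.add(r["locus_tag"])
        ordered = sorted(kept, key=lambda x: rank.get(x, len(rank)))
        if not ordered:
            log.warning("subset_for_selection: no genes retained for "
                        "strain %s", g)
        out[g] = ordered
    return out
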