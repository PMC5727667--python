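"""Kinase-substrate enrichment analysis (KSEA).

Infers kinase activity change from the aggregate oriented log2 fold change
of its substrate phosphosites. For kinase K with m contributing substrate
units of mean fold change s_bar, against a background of all quantified
units with mean p_bar and standard deviation delta:

    z = (s_bar - p_bar) * sqrt(m) / delta

z is converted to a two-sided normal p value and Benjamini-Hochberg
adjusted across scored kinases. A positive activity score (s_bar) means the
kinase's substrates gained phosphorylation in the deficient condition,
i.e. inferred higher activity.

By default only regulated substrates contribute (the emulated analysis
averages the regulated phosphopeptides in each substrate set); pass
``regulated_only=False`` for classical all-quantified-substrate KSEA.
Curated and predicted kinase-substrate relationships are analyzed as
separate runs via the ``source`` filter, never pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ValidationError
from .diffreg import STATUS_DOWN, STATUS_UP, RegulationCall


class DegenerateDispersionError(ValueError):
    """The background fold-change dispersion is zero."""


@dataclass(frozen=True)
class KinaseScore:
    kinase: str
    m: int
    s_bar: float
    p_bar: float
    delta: float
    z: float
    p: float
    q: float


def map_substrates(calls: Sequence[RegulationCall], ksr: pd.DataFrame,
                   source: str | None = None, regulated_only: bool = True,
                   ) -> dict[str, list[RegulationCall]]:
    """Map each kinase to its contributing quantified units.

    A unit contributes to kinase K iff its (protein, position) matches a KSR
    row passing the source filter and, when ``regulated_only``, its status is
    up or down. Distinct multiplicity forms of a site each contribute once.
    Kinases with no contributing unit are omitted.
    """
    if source is not None:
        ksr = ksr[ksr["source"] == source]
    by_site: dict[tuple[str, int], list[RegulationCall]] = {}
    for c in calls:
        pid, pos, _mult = c.unit_key
        if regulated_only and c.status not in (STATUS_UP, STATUS_DOWN):
            continue
        if c.n_quantified == 0 or math.isnan(c.mean_log2fc):
            continue
        by_site.setdefault((pid, pos), []).append(c)
    out: dict[str, list[RegulationCall]] = {}
    pairs = ksr[["kinase", "substrate_protein",
                 "substrate_position"]].drop_duplicates()
    for kinase, pid, pos in pairs.itertuples(index=False):
        units = by_site.get((pid, int(pos)))
        if units:
            out.setdefault(kinase, []).extend(units)
    # a site matched by several KSR sources contributes once per kinase
    for k in out:
        seen = set()
        uniq = []
        for c in out[k]:
            if c.unit_key not in seen:
                seen.add(c.unit_key)
                uniq.append(c)
        out[k] = uniq
    return out


def background_stats(calls: Sequence[RegulationCall],
                     ) -> tuple[float, float, int]:
    """(p_bar, delta, n): mean and sample sd of mean oriented log2 fold
    change over all quantified units."""
    fc = np.array([c.mean_log2fc for c in calls
                   if c.n_quantified > 0 and not math.isnan(c.mean_log2fc)])
    if len(fc) < 2:
        raise ValidationError("need >= 2 quantified units for background")
    delta = float(np.std(fc, ddof=1))
    if delta == 0:
        raise DegenerateDispersionError(
            "zero dispersion of background fold changes")
    return float(np.mean(fc)), delta, len(fc)


def ksea_scores(substrate_map: Mapping[str, Sequence[RegulationCall]],
                calls: Sequence[RegulationCall],
                m_min: int = 1) -> list[KinaseScore]:
    """Score every kinase with at least ``m_min`` contributing units.

    Results are sorted by descending z, ties broken by kinase name.
    """
    p_bar, delta, _ = background_stats(calls)
    rows = []
    for kinase in sorted(substrate_map):
        units = substrate_map[kinase]
        m = len(units)
        if m < m_min:
            continue
        s_bar = float(np.mean([c.mean_log2fc for c in units]))
        z = (s_bar - p_bar) * math.sqrt(m) / delta
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((kinase, m, s_bar, z, min(p, 1.0)))
    if not rows:
        return []
    q = bh_fdr([r[4] for r in rows])
    scores = [KinaseScore(kinase=k, m=m, s_bar=s, p_bar=p_bar, delta=delta,
                          z=z, p=p, q=qv)
              for (k, m, s, z, p), qv in zip(rows, q)]
    scores.sort(key=lambda s: (-s.z, s.kinase))
    return scores


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p values must lie in [0,1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def scores_to_frame(scores: Sequence[KinaseScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"kinase": s.kinase, "m": s.m, "activity_score": s.s_bar,
          "p_bar": s.p_bar, "delta": s.delta, "z": s.z, "p": s.p, "q": s.q}
         for s in scores],
        columns=["kinase", "m", "activity_score", "p_bar", "delta",
                 "z", "p", "q"])


def run_ksea(calls: Sequence[RegulationCall], ksr: pd.DataFrame,
             source: str | None = "predicted", regulated_only: bool = True,
             m_min: int = 1) -> list[KinaseScore]:
    """Map substrates and score kinases in one step."""
    smap = map_substrates(calls, ksr, source=source,
                          regulated_only=regulated_only)
    return ksea_scores(smap, calls, m_min=m_min)
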