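"""Orientation, robust-z normalization, and regulation calling.

The pipeline compares a deficient line against a heterozygous control in a
four-replicate SILAC label-swap design. Raw H/L ratios are log2-transformed
and oriented so every replicate reads deficient-over-control (reverse
replicates are negated). Each replicate column is then median-centered and
scaled by its median absolute deviation (MAD), giving a per-replicate robust
z score per unit. A unit is called regulated when it exceeds the z threshold
in the same direction in at least ``r_min`` replicates with no replicate
beyond the threshold in the opposite direction.

Defaults follow the emulated analysis: localization-probability filter at
0.75 (class I sites), z threshold 2 for phosphosites (roughly a 1.8-fold
change in that dataset) and 2.5 for proteins, r_min 3 of 4, raw MAD without
the 1.4826 normal-consistency factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    N_REPLICATES,
    PhosphoPeptideRecord,
    ProteinRecord,
    ReplicateDesign,
    ValidationError,
)

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_UNCHANGED = "unchanged"
STATUS_INSUFFICIENT = "insufficient_data"

CONCORDANCE_CLASSES = ("up_both", "up_phospho_only", "down_phospho_only",
                       "down_both", "discordant", "other")

NORMAL_MAD_FACTOR = 1.4826


class DegenerateScaleError(ValueError):
    """A replicate column has zero MAD and cannot be scaled."""


@dataclass(frozen=True)
class RegulationCall:
    unit_key: tuple
    gene: str
    z: tuple[float, ...]          # NaN where not quantified
    n_up: int
    n_down: int
    n_quantified: int
    status: str
    mean_log2fc: float


def filter_class1(records: Sequence[PhosphoPeptideRecord],
                  p_min: float = 0.75,
                  inclusive: bool = True) -> list[PhosphoPeptideRecord]:
    """Keep sites localizable at probability >= p_min (class I at 0.75).

    ``inclusive=False`` switches to a strict > comparison.
    """
    if not (0.0 <= p_min <= 1.0):
        raise ValidationError(f"p_min={p_min} outside [0,1]")
    if inclusive:
        kept = [r for r in records if r.loc_prob >= p_min]
    else:
        kept = [r for r in records if r.loc_prob > p_min]
    if records and not kept:
        warnings.warn("localization filter removed every site; "
                      "pipeline continues with an empty table")
    return kept


def orient_ratios(records: Sequence[PhosphoPeptideRecord | ProteinRecord],
                  design: ReplicateDesign) -> pd.DataFrame:
    """Oriented log2 ratio matrix, one row per unit, one column per replicate.

    Forward replicates keep log2(H/L); reverse replicates are negated so all
    columns read deficient-over-control. Missing stays missing (NaN).
    """
    signs = design.orientation_signs
    mat = np.full((len(records), N_REPLICATES), np.nan)
    index = []
    genes = []
    for i, rec in enumerate(records):
        if isinstance(rec, PhosphoPeptideRecord):
            index.append(rec.unit_key)
        else:
            index.append(rec.protein_id)
        genes.append(rec.gene)
        for j, v in enumerate(rec.ratios):
            if v is not None:
                mat[i, j] = signs[j] * np.log2(v)
    df = pd.DataFrame(mat, columns=[f"r{j + 1}" for j in range(N_REPLICATES)])
    df.index = pd.Index(index, tupleize_cols=False, name="unit")
    df.attrs["genes"] = dict(zip(df.index, genes))
    return df


def normalize_replicate(column: np.ndarray | pd.Series,
                        mad_scaled: bool = False) -> np.ndarray:
    """Robust z for one replicate column: (x - median) / MAD.

    Median and MAD are computed over quantified (non-NaN) cells only. By
    default MAD is the raw median absolute deviation; ``mad_scaled=True``
    applies the 1.4826 normal-consistency factor.
    """
    x = np.asarray(column, dtype=float)
    quant = x[~np.isnan(x)]
    if len(quant) < 3:
        raise ValidationError(
            "replicate column needs >= 3 quantified values to normalize")
    med = np.median(quant)
    mad = np.median(np.abs(quant - med))
    if mad == 0:
        raise DegenerateScaleError("replicate column has zero MAD")
    if mad_scaled:
        mad *= NORMAL_MAD_FACTOR
    return (x - med) / mad


def normalize_matrix(oriented: pd.DataFrame,
                     mad_scaled: bool = False) -> pd.DataFrame:
    """Apply :func:`normalize_replicate` column-wise."""
    out = oriented.copy()
    for j, col in enumerate(oriented.columns):
        try:
            out[col] = normalize_replicate(oriented[col].to_numpy(),
                                           mad_scaled=mad_scaled)
        except DegenerateScaleError as exc:
            raise DegenerateScaleError(f"replicate {col}: {exc}") from exc
    out.attrs = dict(oriented.attrs)
    return out


def call_regulated(z_matrix: pd.DataFrame, oriented: pd.DataFrame,
                   tau: float = 2.0, r_min: int = 3,
                   ) -> list[RegulationCall]:
    """Per-unit regulation status from the robust-z matrix.

    up: >= r_min replicates with z >= +tau and none with z <= -tau;
    down symmetric; a direction conflict (replicates beyond the threshold on
    both sides) vetoes the call; units with fewer than r_min quantified
    replicates are insufficient_data.
    """
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    if r_min > z_matrix.shape[1]:
        raise ValidationError("r_min exceeds replicate count")
    genes = z_matrix.attrs.get("genes", {})
    calls = []
    zvals = z_matrix.to_numpy()
    fc = oriented.to_numpy()
    for i, unit in enumerate(z_matrix.index):
        z = zvals[i]
        quant = ~np.isnan(z)
        n_q = int(quant.sum())
        n_up = int(np.sum(z[quant] >= tau))
        n_down = int(np.sum(z[quant] <= -tau))
        if n_q < r_min:
            status = STATUS_INSUFFICIENT
        elif n_up >= r_min and n_down == 0:
            status = STATUS_UP
        elif n_down >= r_min and n_up == 0:
            status = STATUS_DOWN
        else:
            status = STATUS_UNCHANGED
        row_fc = fc[i][~np.isnan(fc[i])]
        mean_fc = float(np.mean(row_fc)) if len(row_fc) else float("nan")
        calls.append(RegulationCall(
            unit_key=unit, gene=genes.get(unit, ""),
            z=tuple(float(v) for v in z),
            n_up=n_up, n_down=n_down, n_quantified=n_q,
            status=status, mean_log2fc=mean_fc))
    return calls


def run_diffreg(records: Sequence[PhosphoPeptideRecord],
                design: ReplicateDesign, tau: float = 2.0, r_min: int = 3,
                loc_min: float | None = 0.75, mad_scaled: bool = False,
                ) -> list[RegulationCall]:
    """Filter (phospho only), orient, normalize, and call in one step."""
    if loc_min is not None and records and isinstance(
            records[0], PhosphoPeptideRecord):
        records = filter_class1(records, loc_min)
    oriented = orient_ratios(records, design)
    z = normalize_matrix(oriented, mad_scaled=mad_scaled)
    return call_regulated(z, oriented, tau=tau, r_min=r_min)


def calls_to_frame(calls: Sequence[RegulationCall],
                   phospho: bool = True) -> pd.DataFrame:
    rows = []
    for c in calls:
        if phospho:
            pid, pos, mult = c.unit_key
            key = {"protein_id": pid, "position": pos, "multiplicity": mult}
        else:
            key = {"protein_id": c.unit_key}
        row = {**key, "gene": c.gene}
        for j, zv in enumerate(c.z):
            row[f"z_r{j + 1}"] = zv
        row.update(n_up=c.n_up, n_down=c.n_down, n_quantified=c.n_quantified,
                   status=c.status, mean_log2fc=c.mean_log2fc)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# proteome / phosphoproteome concordance
# ---------------------------------------------------------------------------

def gene_direction_sets(calls: Sequence[RegulationCall],
                        ) -> tuple[set[str], set[str]]:
    """(up genes, down genes) at gene level; a gene with both up and down
    units appears in both sets."""
    up = {c.gene for c in calls if c.status == STATUS_UP}
    down = {c.gene for c in calls if c.status == STATUS_DOWN}
    return up, down


def categorize_concordance(phospho_calls: Sequence[RegulationCall],
                           protein_calls: Sequence[RegulationCall],
                           ) -> pd.DataFrame:
    """Classify genes by agreement between phosphosite and protein calls.

    Classes: up_both / down_both (same direction at both levels),
    up/down_phospho_only (protein unchanged or unmeasured), discordant
    (opposite directions, or a gene with both up- and down-regulated
    phosphosites), other. Only genes with at least one regulated phosphosite
    are classified.
    """
    p_up, p_down = gene_direction_sets(phospho_calls)
    prot_status: dict[str, str] = {}
    for c in protein_calls:
        prot_status[c.gene] = c.status
    rows = []
    for gene in sorted(p_up | p_down):
        ps = prot_status.get(gene, STATUS_UNCHANGED)
        if ps == STATUS_INSUFFICIENT:
            ps = STATUS_UNCHANGED
        if gene in p_up and gene in p_down:
            cls = "discordant"
        elif gene in p_up:
            cls = {STATUS_UP: "up_both", STATUS_DOWN: "discordant"}.get(
                ps, "up_phospho_only")
        else:
            cls = {STATUS_DOWN: "down_both", STATUS_UP: "discordant"}.get(
                ps, "down_phospho_only")
        rows.append({"gene": gene, "class": cls,
                     "phospho_up": gene in p_up,
                     "phospho_down": gene in p_down,
                     "protein_status": ps})
    return pd.DataFrame(rows,
                        columns=["gene", "class", "phospho_up",
                                 "phospho_down", "protein_status"])
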