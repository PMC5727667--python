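"""Domain types and tabular I/O for the phosphoproteome pipeline.

All quantitative tables are tab-separated text. SILAC heavy/light ratios are
stored on the *linear* scale on disk (MaxQuant convention) and log2-transformed
only inside the differential-regulation stage. Residue positions are 1-based.
Missing ratios are written as empty cells; empty cells and "NaN" are both read
back as missing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

N_REPLICATES = 4
RATIO_COLUMNS = tuple(f"ratio_r{i + 1}" for i in range(N_REPLICATES))

PHOSPHO_COLUMNS = ("protein_id", "gene", "position", "residue",
                   "multiplicity", "loc_prob") + RATIO_COLUMNS
PROTEIN_COLUMNS = ("protein_id", "gene") + RATIO_COLUMNS
KSR_COLUMNS = ("kinase", "substrate_protein", "substrate_position", "source")
TF_COLUMNS = ("tf", "target_gene")
INTERACTION_COLUMNS = ("node_a", "node_b", "confidence")

VALID_RESIDUES = frozenset({"S", "T", "Y"})
KSR_SOURCES = frozenset({"curated", "predicted"})


class FormatError(ValueError):
    """A table does not conform to its declared format."""


class ValidationError(ValueError):
    """A record violates a domain-type invariant."""


@dataclass(frozen=True)
class PhosphoPeptideRecord:
    """One quantified (site, multiplicity) unit.

    ``ratios`` holds raw linear H/L ratios, one per replicate; ``None`` marks
    a replicate in which the unit was not quantified.
    """

    protein_id: str
    gene: str
    position: int
    residue: str
    multiplicity: int
    loc_prob: float
    ratios: tuple[float | None, ...]

    def __post_init__(self) -> None:
        if self.residue not in VALID_RESIDUES:
            raise ValidationError(
                f"residue {self.residue!r} not in {{S,T,Y}} "
                f"({self.protein_id}:{self.position})")
        if not (0.0 <= self.loc_prob <= 1.0):
            raise ValidationError(
                f"loc_prob {self.loc_prob} outside [0,1] "
                f"({self.protein_id}:{self.position})")
        if self.position < 1:
            raise ValidationError(
                f"position {self.position} must be >= 1 ({self.protein_id})")
        if self.multiplicity < 1:
            raise ValidationError(
                f"multiplicity {self.multiplicity} must be >= 1 "
                f"({self.protein_id}:{self.position})")
        if len(self.ratios) != N_REPLICATES:
            raise ValidationError(
                f"expected {N_REPLICATES} ratio slots, got {len(self.ratios)}")

    @property
    def unit_key(self) -> tuple[str, int, int]:
        return (self.protein_id, self.position, self.multiplicity)


@dataclass(frozen=True)
class ProteinRecord:
    """One quantified protein with raw linear H/L ratios per replicate."""

    protein_id: str
    gene: str
    ratios: tuple[float | None, ...]

    def __post_init__(self) -> None:
        if len(self.ratios) != N_REPLICATES:
            raise ValidationError(
                f"expected {N_REPLICATES} ratio slots, got {len(self.ratios)}")


@dataclass(frozen=True)
class ReplicateDesign:
    """Label-swap orientation of each SILAC replicate.

    ``forward`` means the heavy channel carries the perturbed (deficient)
    condition; ``reverse`` means heavy carries the reference, so its log
    ratios must be negated to reach the common perturbed/reference scale.
    """

    labels: tuple[str, ...] = ("forward", "forward", "reverse", "reverse")

    def __post_init__(self) -> None:
        if len(self.labels) != N_REPLICATES:
            raise ValidationError(
                f"design must cover {N_REPLICATES} replicates")
        bad = set(self.labels) - {"forward", "reverse"}
        if bad:
            raise ValidationError(f"unknown replicate labels: {sorted(bad)}")

    @property
    def orientation_signs(self) -> np.ndarray:
        """+1 for forward replicates, -1 for reverse."""
        return np.array([1.0 if lab == "forward" else -1.0
                         for lab in self.labels])

    def flipped(self) -> "ReplicateDesign":
        swap = {"forward": "reverse", "reverse": "forward"}
        return ReplicateDesign(tuple(swap[lab] for lab in self.labels))


@dataclass
class AnnotationTables:
    """TF target sets, gene-set collection, and the weighted interactome."""

    tf_targets: dict[str, set[str]] = field(default_factory=dict)
    gene_sets: dict[str, set[str]] = field(default_factory=dict)
    gene_set_categories: dict[str, str] = field(default_factory=dict)
    interactions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=INTERACTION_COLUMNS))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str],
                     what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{what} table is missing required column(s): "
            f"{', '.join(missing)}")


def _parse_ratio(cell) -> float | None:
    """Empty / NaN / non-positive cells are treated as not quantified."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    s = str(cell).strip()
    if s == "" or s.lower() == "nan":
        return None
    try:
        v = float(s)
    except ValueError:
        return None
    if not math.isfinite(v) or v <= 0:
        return None
    return v


def read_phospho_table(path: str | os.PathLike,
                       design: ReplicateDesign | None = None,
                       ) -> list[PhosphoPeptideRecord]:
    """Read a phosphosite quantification TSV into records.

    One record per (site, multiplicity) row. Ratio columns map positionally
    to the replicates of ``design``. Raises :class:`FormatError` on a missing
    column and :class:`ValidationError` (with the offending row number) on an
    invalid residue or out-of-range field.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, PHOSPHO_COLUMNS, "phospho")
    records: list[PhosphoPeptideRecord] = []
    seen: set[tuple[str, int, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            rec = PhosphoPeptideRecord(
                protein_id=row["protein_id"],
                gene=row["gene"],
                position=int(row["position"]),
                residue=row["residue"],
                multiplicity=int(row["multiplicity"]),
                loc_prob=float(row["loc_prob"]),
                ratios=tuple(_parse_ratio(row[c]) for c in RATIO_COLUMNS),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        if rec.unit_key in seen:
            raise ValidationError(
                f"row {i}: duplicate unit {rec.unit_key}")
        seen.add(rec.unit_key)
        records.append(rec)
    return records


def read_protein_table(path: str | os.PathLike) -> list[ProteinRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, PROTEIN_COLUMNS, "protein")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        pid = row["protein_id"]
        if pid in seen:
            raise ValidationError(f"row {i}: duplicate protein_id {pid!r}")
        seen.add(pid)
        records.append(ProteinRecord(
            protein_id=pid, gene=row["gene"],
            ratios=tuple(_parse_ratio(row[c]) for c in RATIO_COLUMNS)))
    return records


def read_design(path: str | os.PathLike) -> ReplicateDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("replicate", "label"), "design")
    df = df.sort_values("replicate")
    return ReplicateDesign(tuple(df["label"]))


def read_ksr_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read kinase-substrate relationships; exact duplicates are collapsed."""
    df = pd.read_csv(path, sep="\t", dtype={"kinase": str,
                                            "substrate_protein": str,
                                            "substrate_position": int,
                                            "source": str})
    _require_columns(df, KSR_COLUMNS, "KSR")
    bad = set(df["source"]) - KSR_SOURCES
    if bad:
        raise ValidationError(f"unknown KSR source(s): {sorted(bad)}")
    return (df.drop_duplicates(list(KSR_COLUMNS))
              .sort_values(list(KSR_COLUMNS))
              .reset_index(drop=True))


def read_tf_targets(path: str | os.PathLike) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, TF_COLUMNS, "TF target")
    out: dict[str, set[str]] = {}
    for tf, sub in df.groupby("tf"):
        out[tf] = set(sub["target_gene"])
    return out


def read_gmt(path: str | os.PathLike) -> tuple[dict[str, set[str]],
                                               dict[str, str]]:
    """Parse a GMT gene-set file.

    Returns (term -> member set, term -> category tag). The GMT description
    field is used as the category tag. Lines with fewer than 3 fields raise
    :class:`FormatError` with the line number.
    """
    gene_sets: dict[str, set[str]] = {}
    categories: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}")
            term, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"GMT line {lineno}: empty gene set")
            gene_sets[term] = set(genes)
            categories[term] = desc
    return gene_sets, categories


def read_interactions(path: str | os.PathLike) -> pd.DataFrame:
    """Read the weighted edge list; unordered duplicates keep max confidence."""
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str,
                                            "confidence": float})
    _require_columns(df, INTERACTION_COLUMNS, "interaction")
    if ((df["confidence"] < 0) | (df["confidence"] > 1)).any():
        raise ValidationError("interaction confidence outside [0,1]")
    a, b = df["node_a"].to_numpy(), df["node_b"].to_numpy()
    swap = a > b
    canon = df.assign(node_a=np.where(swap, b, a),
                      node_b=np.where(swap, a, b))
    canon = canon[canon["node_a"] != canon["node_b"]]
    out = (canon.groupby(["node_a", "node_b"], as_index=False)["confidence"]
                .max()
                .sort_values(["node_a", "node_b"])
                .reset_index(drop=True))
    return out


def read_annotations(gmt_path, tf_path, ksr_path, interactions_path,
                     ) -> tuple[AnnotationTables, pd.DataFrame]:
    """Convenience loader for all annotation inputs."""
    gene_sets, categories = read_gmt(gmt_path)
    tables = AnnotationTables(
        tf_targets=read_tf_targets(tf_path),
        gene_sets=gene_sets,
        gene_set_categories=categories,
        interactions=read_interactions(interactions_path),
    )
    return tables, read_ksr_table(ksr_path)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _fmt_ratio(v: float | None) -> str:
    return "" if v is None else repr(float(v))


def phospho_records_to_frame(records: Iterable[PhosphoPeptideRecord],
                             ) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"protein_id": r.protein_id, "gene": r.gene,
               "position": r.position, "residue": r.residue,
               "multiplicity": r.multiplicity, "loc_prob": repr(r.loc_prob)}
        for c, v in zip(RATIO_COLUMNS, r.ratios):
            row[c] = _fmt_ratio(v)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(PHOSPHO_COLUMNS))


def protein_records_to_frame(records: Iterable[ProteinRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"protein_id": r.protein_id, "gene": r.gene}
        for c, v in zip(RATIO_COLUMNS, r.ratios):
            row[c] = _fmt_ratio(v)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(PROTEIN_COLUMNS))


def write_phospho_table(records, path) -> None:
    phospho_records_to_frame(records).to_csv(path, sep="\t", index=False)


def write_protein_table(records, path) -> None:
    protein_records_to_frame(records).to_csv(path, sep="\t", index=False)


def write_design(design: ReplicateDesign, path) -> None:
    pd.DataFrame({"replicate": [f"r{i + 1}" for i in range(N_REPLICATES)],
                  "label": list(design.labels)}
                 ).to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(tables: Mapping[str, pd.DataFrame], out_dir,
                  summary: Mapping | None = None) -> dict:
    """Write named result tables as sorted TSVs plus a JSON run summary.

    Every frame is sorted by all its columns before writing so that outputs
    are byte-identical across runs with the same inputs and seed. Returns a
    manifest mapping file name -> {rows, sha256}.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict[str, dict] = {}
    for name, df in tables.items():
        fname = f"{name}.tsv"
        path = os.path.join(out_dir, fname)
        if len(df.columns) and len(df):
            df = df.sort_values(list(df.columns), kind="mergesort")
        df.to_csv(path, sep="\t", index=False)
        manifest[fname] = {"rows": int(len(df)), "sha256": sha256_of(path)}
    if summary is not None:
        spath = os.path.join(out_dir, "run_summary.json")
        with open(spath, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["run_summary.json"] = {"rows": None,
                                        "sha256": sha256_of(spath)}
    mpath = os.path.join(out_dir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def record_to_dict(rec) -> dict:
    return dataclasses.asdict(rec)
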