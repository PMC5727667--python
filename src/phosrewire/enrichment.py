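"""Over-representation and ranked-list enrichment.

Three flavours, mirroring the emulated analysis:

* one-sided Fisher's exact (upper-tail hypergeometric) over-representation
  of a term's or transcription factor's annotated genes among a regulated
  set, against a dataset-wide background; up- and down-regulated sets are
  tested separately;
* a pre-ranked gene list built from per-gene phosphopeptide fold changes
  (the most regulated peptide's fold change, falling back to the highest
  fold change for genes without a regulated peptide);
* pre-ranked GSEA: weighted Kolmogorov-Smirnov running-sum enrichment score
  (weight exponent 1) with significance from random same-size gene-set
  permutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ValidationError
from .diffreg import STATUS_DOWN, STATUS_UP, RegulationCall
from .ksea import bh_fdr


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table for over-representation of an annotated set.

    a: regulated and annotated; b: regulated, not annotated;
    c: annotated, not regulated; d: neither. N = a+b+c+d is the background.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    direction: str
    table: ContingencyTable
    fold_enrichment: float
    p: float
    q: float


@dataclass(frozen=True)
class GseaResult:
    term: str
    es: float
    p: float
    n_perm: int
    n_hits: int


def fisher_onesided(table: ContingencyTable) -> float:
    """Upper-tail p: P(X >= a), X ~ Hypergeom(N, K=a+c, n=a+b)."""
    return float(stats.hypergeom.sf(table.a - 1, table.n,
                                    table.a + table.c, table.a + table.b))


def make_table(regulated: set[str], annotated: set[str],
               background: set[str]) -> ContingencyTable:
    reg = regulated & background
    ann = annotated & background
    a = len(reg & ann)
    return ContingencyTable(a=a, b=len(reg) - a, c=len(ann) - a,
                            d=len(background) - len(reg) - len(ann) + a)


def fold_enrichment(table: ContingencyTable) -> float:
    """(a/(a+b)) / ((a+c)/N); 0 when the regulated set is empty."""
    n_reg = table.a + table.b
    n_ann = table.a + table.c
    if n_reg == 0 or n_ann == 0:
        return 0.0
    return (table.a / n_reg) / (n_ann / table.n)


def term_enrichment(up: set[str], down: set[str], background: set[str],
                    annotated_sets: Mapping[str, set[str]],
                    min_genes: int = 3,
                    ) -> list[EnrichmentResult]:
    """Test every annotated set against the up and down sets separately.

    Sets with overlap a < min_genes are excluded before testing; BH q is
    computed within each direction block over the tested sets. Results are
    sorted by direction, then p, then term name.
    """
    if not background:
        raise ValidationError("empty background")
    results: list[EnrichmentResult] = []
    for direction, reg in (("up", up), ("down", down)):
        block: list[tuple[str, ContingencyTable, float]] = []
        for term in sorted(annotated_sets):
            table = make_table(reg, annotated_sets[term], background)
            if table.a < min_genes:
                continue
            block.append((term, table, fisher_onesided(table)))
        qs = bh_fdr([p for _, _, p in block])
        for (term, table, p), q in zip(block, qs):
            results.append(EnrichmentResult(
                term=term, direction=direction, table=table,
                fold_enrichment=fold_enrichment(table), p=p, q=q))
    results.sort(key=lambda r: (r.direction, r.p, r.term))
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"term": r.term, "direction": r.direction,
          "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
          "fold_enrichment": r.fold_enrichment, "p": r.p, "q": r.q}
         for r in results],
        columns=["term", "direction", "a", "b", "c", "d",
                 "fold_enrichment", "p", "q"])


# ---------------------------------------------------------------------------
# ranked list
# ---------------------------------------------------------------------------

def build_ranked_list(calls: Sequence[RegulationCall],
                      use_abs: bool = True) -> pd.DataFrame:
    """One metric per gene, ordered descending for pre-ranked GSEA.

    For genes with at least one regulated peptide, the metric is the fold
    change of maximal absolute value among the regulated peptides (ties
    resolved toward the larger signed value); otherwise the maximal fold
    change among the gene's quantified peptides. ``use_abs=False`` takes
    the highest signed fold change among regulated peptides instead.
    Ties across genes break by larger metric, then gene name.
    """
    best: dict[str, tuple[bool, float]] = {}
    for c in calls:
        if c.n_quantified == 0 or math.isnan(c.mean_log2fc):
            continue
        fc = c.mean_log2fc
        regulated = c.status in (STATUS_UP, STATUS_DOWN)
        prev = best.get(c.gene)
        if prev is None:
            best[c.gene] = (regulated, fc)
            continue
        prev_reg, prev_fc = prev
        if regulated and not prev_reg:
            best[c.gene] = (True, fc)
        elif regulated == prev_reg:
            if regulated and use_abs:
                # larger |fc| wins; exact tie -> larger signed value
                if (abs(fc), fc) > (abs(prev_fc), prev_fc):
                    best[c.gene] = (regulated, fc)
            else:
                if fc > prev_fc:
                    best[c.gene] = (regulated, fc)
    rows = sorted(((g, fc) for g, (_, fc) in best.items()),
                  key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["gene", "metric"])


# ---------------------------------------------------------------------------
# pre-ranked GSEA
# ---------------------------------------------------------------------------

def _enrichment_score(metrics: np.ndarray, hit_mask: np.ndarray) -> float:
    """Signed maximal deviation of the weighted KS running sum.

    Hits increment by |metric| normalized over the in-set |metric| sum;
    misses decrement by 1/(N - n_hits).
    """
    n = len(metrics)
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits >= n:
        raise ValidationError(
            "gene set must hit >= 1 and < all ranked genes")
    weights = np.abs(metrics) * hit_mask
    total = weights.sum()
    if total == 0:
        # all in-set metrics are exactly 0: fall back to equal hit weights
        steps = hit_mask / n_hits - (~hit_mask) / (n - n_hits)
    else:
        steps = weights / total - (~hit_mask) / (n - n_hits)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_preranked(ranked: pd.DataFrame, gene_set: Iterable[str],
                   n_perm: int = 1000, seed: int = 0,
                   term: str = "") -> GseaResult:
    """Enrichment score and gene-set permutation p for one gene set.

    p is the add-one-corrected fraction of ``n_perm`` random same-size gene
    sets whose |ES| meets or exceeds the observed |ES|. Reproducible from
    ``seed``.
    """
    genes = ranked["gene"].to_numpy()
    metrics = ranked["metric"].to_numpy(dtype=float)
    members = set(gene_set) & set(genes)
    hit_mask = np.isin(genes, sorted(members))
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValidationError("gene set does not intersect the ranked list")
    if n_hits >= len(genes):
        raise ValidationError("gene set covers the entire ranked list")
    es = _enrichment_score(metrics, hit_mask)
    rng = np.random.default_rng(seed)
    n = len(genes)
    exceed = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=n_hits, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        if abs(_enrichment_score(metrics, mask)) >= abs(es):
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return GseaResult(term=term, es=es, p=p, n_perm=n_perm, n_hits=n_hits)


def gsea_collection(ranked: pd.DataFrame,
                    gene_sets: Mapping[str, set[str]],
                    n_perm: int = 1000, seed: int = 0,
                    min_hits: int = 3) -> pd.DataFrame:
    """Run pre-ranked GSEA over a collection; sets hitting < min_hits genes
    are skipped. Each set gets an independent child seed."""
    rows = []
    terms = sorted(gene_sets)
    children = np.random.SeedSequence(seed).spawn(len(terms))
    for term, child in zip(terms, children):
        members = gene_sets[term] & set(ranked["gene"])
        if len(members) < min_hits or len(members) >= len(ranked):
            continue
        res = gsea_preranked(ranked, members, n_perm=n_perm,
                             seed=child.generate_state(1)[0] % (2**31),
                             term=term)
        rows.append({"term": term, "es": res.es, "p": res.p,
                     "n_perm": res.n_perm, "n_hits": res.n_hits})
    return pd.DataFrame(rows, columns=["term", "es", "p", "n_perm",
                                       "n_hits"])


def overlap_edges(gene_sets: Mapping[str, set[str]],
                  significant: Iterable[str],
                  min_jaccard: float = 0.25) -> pd.DataFrame:
    """Pairwise Jaccard-overlap edge table among significant sets, for
    enrichment-map-style visualization downstream."""
    sig = sorted(set(significant))
    rows = []
    for i, s in enumerate(sig):
        for t in sig[i + 1:]:
            inter = len(gene_sets[s] & gene_sets[t])
            union = len(gene_sets[s] | gene_sets[t])
            j = inter / union if union else 0.0
            if j >= min_jaccard:
                rows.append({"term_a": s, "term_b": t, "jaccard": j})
    return pd.DataFrame(rows, columns=["term_a", "term_b", "jaccard"])
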