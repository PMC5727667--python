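"""Synthetic SILAC phosphoproteome study generator with known ground truth.

The generator emulates the structure of a four-replicate label-swap SILAC
experiment comparing a gene-deficient line against its heterozygous control:

* two forward replicates (heavy channel = deficient) and two reverse
  replicates (heavy = control), so raw reverse log-ratios carry the opposite
  sign of the true effect;
* ~8,000 quantified (site, multiplicity) units on ~2,600 proteins, with a
  class-I fraction (localization probability >= 0.75) of ~0.83 and a peptide
  multiplicity mix of ~87% singly / ~11% doubly / ~2% triply phosphorylated;
* a planted regulated subset with signed log2 effects, Gaussian replicate
  noise, and completely-at-random missingness;
* kinase-substrate and TF-target annotations whose "active" entries are
  enriched for same-signed regulated units, plus decoys;
* a stochastic-block-model interactome with planted communities.

Every quantity is reproducible from ``SimConfig.seed``; the three stages draw
from independently derived child seeds so each can be re-run in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import (
    N_REPLICATES,
    AnnotationTables,
    PhosphoPeptideRecord,
    ProteinRecord,
    ReplicateDesign,
    KSR_COLUMNS,
    INTERACTION_COLUMNS,
)


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults mirror the emulated study: 8,000 sites, 83% class I, 87/11/2%
    multiplicity mix, ~5% regulated units with a 362:220 up:down balance,
    mean |log2 effect| 1.2, replicate noise sd 0.25 (log2).
    """

    n_sites: int = 8000
    n_proteins: int = 2600
    frac_regulated: float = 0.05
    frac_up: float = 362 / 582
    effect_log2: float = 1.2
    noise_sd: float = 0.25
    frac_class1: float = 0.83
    multiplicity_probs: tuple[float, float, float] = (0.87, 0.11, 0.02)
    missing_rate: float = 0.05
    # protein-level experiment (concordance / TF enrichment surface)
    frac_regulated_proteins: float = 0.05
    # annotations
    n_kinases: int = 50
    substrates_per_kinase: int = 10
    active_kinases: int = 5
    n_tfs: int = 30
    targets_per_tf: int = 25
    active_tfs: int = 5
    enrichment_strength: float = 1.0
    # interactome
    community_sizes: tuple[int, ...] = (70, 70, 70, 72)
    p_within: float = 0.2
    p_between: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_regulated", "frac_up", "frac_class1",
                     "missing_rate", "frac_regulated_proteins",
                     "enrichment_strength", "p_within", "p_between"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0,1]")
        if abs(sum(self.multiplicity_probs) - 1.0) > 1e-9:
            raise ConfigError("multiplicity_probs must sum to 1")
        if self.effect_log2 <= 0 or self.noise_sd < 0:
            raise ConfigError("effect_log2 must be > 0 and noise_sd >= 0")
        n_reg = round(self.frac_regulated * self.n_sites)
        if self.frac_regulated > 0 and n_reg < 1:
            raise ConfigError(
                "frac_regulated > 0 but rounds to zero regulated units")
        if self.substrates_per_kinase > self.n_sites:
            raise ConfigError("substrates_per_kinase exceeds number of units")
        if self.p_within <= self.p_between:
            raise ConfigError("p_within must exceed p_between")


@dataclass
class GroundTruth:
    """Planted signal, for parameter-recovery tests.

    ``regulated_units`` maps (protein_id, position, multiplicity) to the
    signed true log2 effect; ``regulated_proteins`` is the protein-level
    analogue; kinase/TF maps carry the planted activity sign (+1/-1);
    ``community_assignment`` maps interactome node to its planted block.
    """

    regulated_units: dict[tuple[str, int, int], float] = field(
        default_factory=dict)
    regulated_proteins: dict[str, float] = field(default_factory=dict)
    active_kinases: dict[str, int] = field(default_factory=dict)
    active_tfs: dict[str, int] = field(default_factory=dict)
    community_assignment: dict[str, int] = field(default_factory=dict)
    gene_of_protein: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "regulated_units": {
                f"{p}|{pos}|{m}": eff
                for (p, pos, m), eff in sorted(self.regulated_units.items())},
            "regulated_proteins": dict(sorted(
                self.regulated_proteins.items())),
            "active_kinases": dict(sorted(self.active_kinases.items())),
            "active_tfs": dict(sorted(self.active_tfs.items())),
            "community_assignment": dict(sorted(
                self.community_assignment.items())),
            "gene_of_protein": dict(sorted(self.gene_of_protein.items())),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        units = {}
        for key, eff in payload["regulated_units"].items():
            p, pos, m = key.split("|")
            units[(p, int(pos), int(m))] = eff
        return cls(
            regulated_units=units,
            regulated_proteins=payload["regulated_proteins"],
            active_kinases=payload["active_kinases"],
            active_tfs=payload["active_tfs"],
            community_assignment=payload["community_assignment"],
            gene_of_protein=payload["gene_of_protein"],
        )


def _child_rngs(seed: int) -> tuple[np.random.Generator, ...]:
    ss = np.random.SeedSequence(seed)
    return tuple(np.random.default_rng(c) for c in ss.spawn(3))


def _draw_loc_probs(rng: np.random.Generator, n: int,
                    frac_class1: float) -> np.ndarray:
    """Two-component mixture: class-I mass near 0.97, the rest below 0.75."""
    is_class1 = rng.random(n) < frac_class1
    probs = np.empty(n)
    n1 = int(is_class1.sum())
    probs[is_class1] = 0.75 + 0.25 * rng.beta(8.0, 1.0, size=n1)
    probs[~is_class1] = 0.75 * rng.beta(4.0, 2.0, size=n - n1)
    return np.clip(probs, 0.0, 1.0)


def _draw_effects(rng: np.random.Generator, n: int, frac_up: float,
                  effect_log2: float) -> np.ndarray:
    """Signed log2 effects: |effect| ~ Normal(mu, 0.2 mu) lower-truncated
    at 0.5; a frac_up share positive."""
    mags = rng.normal(effect_log2, 0.2 * effect_log2, size=n)
    mags = np.maximum(mags, 0.5)
    n_up = round(frac_up * n)
    signs = np.full(n, -1.0)
    signs[:n_up] = 1.0
    rng.shuffle(signs)
    return signs * mags


def _observed_ratios(rng, mu: np.ndarray, design: ReplicateDesign,
                     noise_sd: float, missing_rate: float) -> np.ndarray:
    """Linear H/L ratio matrix (n_units x 4) with NaN for missing cells."""
    n = len(mu)
    noise = rng.normal(0.0, noise_sd, size=(n, N_REPLICATES))
    oriented_log2 = mu[:, None] + noise
    raw_log2 = oriented_log2 * design.orientation_signs[None, :]
    ratios = np.exp2(raw_log2)
    if missing_rate > 0:
        ratios[rng.random((n, N_REPLICATES)) < missing_rate] = np.nan
    return ratios


def simulate_phospho_experiment(config: SimConfig,
                                ) -> tuple[list[PhosphoPeptideRecord],
                                           list[ProteinRecord],
                                           ReplicateDesign,
                                           GroundTruth]:
    """Generate the phosphosite and protein quantification tables.

    The true oriented log2 ratio of a regulated unit is its signed planted
    effect, 0 for null units; each replicate observes
    orientation_sign x (mu + Normal(0, noise_sd)), reported as a linear H/L
    ratio. Regulated units are planted among class-I sites only, since the
    downstream analysis discards sub-threshold-localization sites by design.
    """
    rng, _, _ = _child_rngs(config.seed)
    design = ReplicateDesign()
    n = config.n_sites

    protein_ids = [f"P{i:04d}" for i in range(1, config.n_proteins + 1)]
    genes = [f"GEN{i:04d}" for i in range(1, config.n_proteins + 1)]
    gene_of = dict(zip(protein_ids, genes))

    site_protein_idx = rng.integers(0, config.n_proteins, size=n)
    positions = np.empty(n, dtype=int)
    counters: dict[int, int] = {}
    steps = rng.integers(1, 50, size=n)
    for i, p_idx in enumerate(site_protein_idx):
        counters[p_idx] = counters.get(p_idx, 0) + int(steps[i])
        positions[i] = counters[p_idx]
    residues = rng.choice(["S", "T", "Y"], size=n, p=[0.86, 0.12, 0.02])
    multiplicities = rng.choice([1, 2, 3], size=n,
                                p=list(config.multiplicity_probs))
    loc_probs = _draw_loc_probs(rng, n, config.frac_class1)

    n_reg = round(config.frac_regulated * n)
    class1_idx = np.flatnonzero(loc_probs >= 0.75)
    if n_reg > len(class1_idx):
        raise ConfigError("more regulated units requested than class-I sites")
    reg_idx = rng.choice(class1_idx, size=n_reg, replace=False)
    mu = np.zeros(n)
    mu[reg_idx] = _draw_effects(rng, n_reg, config.frac_up,
                                config.effect_log2)

    ratios = _observed_ratios(rng, mu, design, config.noise_sd,
                              config.missing_rate)

    records = []
    truth = GroundTruth(gene_of_protein=gene_of)
    for i in range(n):
        pid = protein_ids[site_protein_idx[i]]
        rec = PhosphoPeptideRecord(
            protein_id=pid,
            gene=gene_of[pid],
            position=int(positions[i]),
            residue=str(residues[i]),
            multiplicity=int(multiplicities[i]),
            loc_prob=float(loc_probs[i]),
            ratios=tuple(None if np.isnan(v) else float(v)
                         for v in ratios[i]),
        )
        records.append(rec)
        if mu[i] != 0.0:
            truth.regulated_units[rec.unit_key] = float(mu[i])

    # protein-level experiment on the same replicate design
    n_reg_prot = round(config.frac_regulated_proteins * config.n_proteins)
    prot_reg_idx = rng.choice(config.n_proteins, size=n_reg_prot,
                              replace=False)
    prot_mu = np.zeros(config.n_proteins)
    prot_mu[prot_reg_idx] = _draw_effects(rng, n_reg_prot, config.frac_up,
                                          config.effect_log2)
    prot_ratios = _observed_ratios(rng, prot_mu, design, config.noise_sd,
                                   config.missing_rate)
    proteins = []
    for j, pid in enumerate(protein_ids):
        proteins.append(ProteinRecord(
            protein_id=pid, gene=gene_of[pid],
            ratios=tuple(None if np.isnan(v) else float(v)
                         for v in prot_ratios[j])))
        if prot_mu[j] != 0.0:
            truth.regulated_proteins[pid] = float(prot_mu[j])

    return records, proteins, design, truth


def _signed_pool(truth: GroundTruth, sign: int) -> list:
    return sorted(k for k, eff in truth.regulated_units.items()
                  if np.sign(eff) == sign)


def simulate_annotations(config: SimConfig, truth: GroundTruth,
                         phospho: Sequence[PhosphoPeptideRecord],
                         proteins: Sequence[ProteinRecord],
                         ) -> tuple[AnnotationTables, pd.DataFrame]:
    """Generate KSR, TF-target, and gene-set annotations with planted signal.

    Each active kinase draws a fraction ``enrichment_strength`` of its
    substrates from regulated units sharing its sign (all of them at
    strength 1), the remainder uniformly; inactive kinases draw uniformly,
    so their substrate regulated-fraction matches ``frac_regulated`` in
    expectation. Active TFs do the same over regulated proteins' genes.
    All predicted KSR rows are emitted; rows pointing at regulated units are
    additionally emitted as curated with probability 0.5, giving the curated
    kinome network a non-trivial regulated core.
    """
    _, rng, _ = _child_rngs(config.seed)
    if config.substrates_per_kinase > len(phospho):
        raise ConfigError("substrates_per_kinase exceeds number of units")

    unit_keys = [r.unit_key for r in phospho]
    kinases = [f"KIN{i:02d}" for i in range(1, config.n_kinases + 1)]
    active = kinases[:config.active_kinases]
    for i, k in enumerate(active):
        truth.active_kinases[k] = 1 if i % 2 == 0 else -1

    ksr_rows = []
    for k in kinases:
        n_sub = config.substrates_per_kinase
        chosen: list = []
        if k in truth.active_kinases:
            pool = _signed_pool(truth, truth.active_kinases[k])
            n_signal = min(round(config.enrichment_strength * n_sub),
                           len(pool))
            if n_signal:
                picked = rng.choice(len(pool), size=n_signal, replace=False)
                chosen.extend(pool[i] for i in picked)
        remaining = n_sub - len(chosen)
        if remaining:
            taken = {c for c in chosen}
            free = [u for u in unit_keys if u not in taken]
            picked = rng.choice(len(free), size=remaining, replace=False)
            chosen.extend(free[i] for i in picked)
        for (pid, pos, _mult) in chosen:
            ksr_rows.append((k, pid, pos, "predicted"))
            if ((pid, pos, _mult) in truth.regulated_units
                    and rng.random() < 0.5):
                ksr_rows.append((k, pid, pos, "curated"))
    ksr = (pd.DataFrame(ksr_rows, columns=list(KSR_COLUMNS))
             .drop_duplicates(list(KSR_COLUMNS))
             .sort_values(list(KSR_COLUMNS))
             .reset_index(drop=True))

    # TF target sets over the protein gene namespace
    all_genes = sorted({p.gene for p in proteins})
    gene_of = truth.gene_of_protein
    up_prot = sorted({gene_of[p] for p, e in truth.regulated_proteins.items()
                      if e > 0})
    down_prot = sorted({gene_of[p] for p, e in
                        truth.regulated_proteins.items() if e < 0})
    tfs = [f"TF{i:02d}" for i in range(1, config.n_tfs + 1)]
    active_tfs = tfs[:config.active_tfs]
    for i, tf in enumerate(active_tfs):
        truth.active_tfs[tf] = 1 if i % 2 == 0 else -1
    tf_targets: dict[str, set[str]] = {}
    for tf in tfs:
        n_t = config.targets_per_tf
        chosen_genes: list[str] = []
        if tf in truth.active_tfs:
            pool = up_prot if truth.active_tfs[tf] > 0 else down_prot
            n_signal = min(round(config.enrichment_strength * n_t), len(pool))
            if n_signal:
                picked = rng.choice(len(pool), size=n_signal, replace=False)
                chosen_genes.extend(pool[i] for i in picked)
        remaining = n_t - len(chosen_genes)
        if remaining:
            free = [g for g in all_genes if g not in set(chosen_genes)]
            picked = rng.choice(len(free), size=remaining, replace=False)
            chosen_genes.extend(free[i] for i in picked)
        tf_targets[tf] = set(chosen_genes)

    # gene sets: one concentrated at the top of the true-effect ranking,
    # one uniform, plus random decoys
    phospho_gene_effect: dict[str, float] = {}
    for (pid, pos, mult), eff in truth.regulated_units.items():
        g = gene_of[pid]
        if abs(eff) > abs(phospho_gene_effect.get(g, 0.0)):
            phospho_gene_effect[g] = eff
    top_genes = [g for g, _ in sorted(phospho_gene_effect.items(),
                                      key=lambda kv: -kv[1])[:50]]
    set_size = min(50, len(all_genes))
    gene_sets: dict[str, set[str]] = {}
    categories: dict[str, str] = {}
    if top_genes:
        gene_sets["top_concentrated"] = set(top_genes)
        categories["top_concentrated"] = "planted"
    uni = rng.choice(len(all_genes), size=set_size, replace=False)
    gene_sets["uniform_set"] = {all_genes[i] for i in uni}
    categories["uniform_set"] = "null"
    for d in range(1, 9):
        pick = rng.choice(len(all_genes), size=set_size, replace=False)
        gene_sets[f"decoy_{d:02d}"] = {all_genes[i] for i in pick}
        categories[f"decoy_{d:02d}"] = "decoy"

    tables = AnnotationTables(tf_targets=tf_targets, gene_sets=gene_sets,
                              gene_set_categories=categories)
    return tables, ksr


def simulate_interactome(config: SimConfig, truth: GroundTruth,
                         nodes: Sequence[str]) -> pd.DataFrame:
    """Stochastic-block-model interactome over the given node names.

    Edges appear within a planted block with probability ``p_within`` and
    across blocks with ``p_between``; confidences are Uniform(0.5, 1).
    ``truth.community_assignment`` records the planted block of each node.
    """
    _, _, rng = _child_rngs(config.seed)
    sizes = list(config.community_sizes)
    if sum(sizes) != len(nodes):
        raise ConfigError(
            f"sum(community_sizes)={sum(sizes)} != number of network "
            f"nodes={len(nodes)}")
    k = len(sizes)
    pmat = [[config.p_within if i == j else config.p_between
             for j in range(k)] for i in range(k)]
    order = list(rng.permutation(len(nodes)))
    shuffled = [nodes[i] for i in order]
    g = nx.stochastic_block_model(sizes, pmat, seed=rng)
    block_of = nx.get_node_attributes(g, "block")
    truth.community_assignment.update(
        {shuffled[i]: int(block_of[i]) for i in g.nodes})
    edges = sorted(
        tuple(sorted((shuffled[u], shuffled[v])))
        for u, v in g.edges)
    conf = 0.5 + 0.5 * rng.random(len(edges))
    return pd.DataFrame(
        [(a, b, float(c)) for (a, b), c in zip(edges, conf)],
        columns=list(INTERACTION_COLUMNS))


@dataclass
class SimulatedStudy:
    """Bundle of everything one simulated study produces."""

    config: SimConfig
    phospho: list[PhosphoPeptideRecord]
    proteins: list[ProteinRecord]
    design: ReplicateDesign
    annotations: AnnotationTables
    ksr: pd.DataFrame
    truth: GroundTruth


def _interactome_nodes(config: SimConfig, truth: GroundTruth,
                       proteins: Sequence[ProteinRecord],
                       rng: np.random.Generator) -> list[str]:
    """Node pool: TFs, regulated phosphoprotein genes, then filler genes."""
    n_nodes = sum(config.community_sizes)
    gene_of = truth.gene_of_protein
    reg_genes = sorted({gene_of[p] for (p, _, _) in truth.regulated_units})
    tf_nodes = sorted(f"TF{i:02d}" for i in range(1, config.n_tfs + 1))
    slots = n_nodes - len(tf_nodes)
    n_reg = min(len(reg_genes), max(0, int(0.6 * slots)))
    picked = sorted(rng.choice(len(reg_genes), size=n_reg, replace=False)
                    ) if n_reg else []
    chosen = [reg_genes[i] for i in picked]
    others = sorted({p.gene for p in proteins} - set(chosen))
    n_fill = slots - n_reg
    fill_idx = sorted(rng.choice(len(others), size=n_fill, replace=False))
    return tf_nodes + chosen + [others[i] for i in fill_idx]


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run all three generator stages in order and bundle the results."""
    phospho, proteins, design, truth = simulate_phospho_experiment(config)
    annotations, ksr = simulate_annotations(config, truth, phospho, proteins)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(4)[3])
    nodes = _interactome_nodes(config, truth, proteins, rng)
    annotations.interactions = simulate_interactome(config, truth, nodes)
    return SimulatedStudy(config=config, phospho=phospho, proteins=proteins,
                          design=design, annotations=annotations, ksr=ksr,
                          truth=truth)


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["multiplicity_probs"] = list(config.multiplicity_probs)
    d["community_sizes"] = list(config.community_sizes)
    return d
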