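"""End-to-end orchestration: simulate → diffreg → ksea → enrich → network.

A single :class:`RunConfig` carries every stage's parameters with defaults
matching the emulated analysis (z threshold 2 for phosphosites, 2.5 for
proteins, 3-of-4 replicates, localization >= 0.75, >= 3 genes per tested
term, raw-p selection thresholds 0.01 for terms and 0.05 for TFs). All
randomness flows from one global seed through per-stage derived seeds, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import datamodel, diffreg, enrichment, ksea, network, simulate
from .datamodel import ValidationError

log = logging.getLogger("phosrewire")


@dataclass
class DiffregParams:
    tau: float = 2.0
    tau_protein: float = 2.5
    r_min: int = 3
    loc_min: float = 0.75
    mad_scaled: bool = False

    def validate(self) -> None:
        if not (0.0 <= self.loc_min <= 1.0):
            raise ValidationError(f"loc_min={self.loc_min} outside [0,1]")
        if self.tau <= 0 or self.tau_protein <= 0:
            raise ValidationError("tau thresholds must be > 0")
        if not (1 <= self.r_min <= datamodel.N_REPLICATES):
            raise ValidationError("r_min outside [1, n_replicates]")


@dataclass
class KseaParams:
    source: str = "predicted"
    regulated_only: bool = True
    m_min: int = 1


@dataclass
class EnrichParams:
    min_genes: int = 3
    alpha_terms: float = 0.01
    alpha_tf: float = 0.05
    n_perm: int = 1000


@dataclass
class NetworkParams:
    conf_min: float = 0.7
    include_bridging: bool = False


@dataclass
class RunConfig:
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    diffreg: DiffregParams = field(default_factory=DiffregParams)
    ksea: KseaParams = field(default_factory=KseaParams)
    enrich: EnrichParams = field(default_factory=EnrichParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    seed: int = 0
    out_dir: str = "phosrewire_out"

    def validate(self) -> None:
        self.diffreg.validate()
        if not (0.0 <= self.network.conf_min <= 1.0):
            raise ValidationError("conf_min outside [0,1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "sim" in raw:
            cfg.sim = simulate.SimConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["sim"].items()})
        for name, klass in (("diffreg", DiffregParams),
                            ("ksea", KseaParams),
                            ("enrich", EnrichParams),
                            ("network", NetworkParams)):
            if name in raw:
                setattr(cfg, name, klass(**raw[name]))
        for key in ("seed", "out_dir"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence(seed).generate_state(stage + 1)[stage]
               % (2 ** 31))


def run_all(config: RunConfig) -> dict:
    """Execute every stage on a simulated study and write all outputs.

    Returns the manifest. A stage failure aborts with the stage name in the
    raised error's message.
    """
    config.validate()
    t0 = time.time()
    os.makedirs(config.out_dir, exist_ok=True)
    stage = "simulate"
    try:
        sim_cfg = config.sim
        sim_cfg.seed = _stage_seed(config.seed, 0)
        study = simulate.simulate_study(sim_cfg)
        log.info("stage=%s n_sites=%d n_proteins=%d elapsed=%.1fs",
                 stage, len(study.phospho), len(study.proteins),
                 time.time() - t0)

        stage = "diffreg"
        p = config.diffreg
        phospho_calls = diffreg.run_diffreg(
            study.phospho, study.design, tau=p.tau, r_min=p.r_min,
            loc_min=p.loc_min, mad_scaled=p.mad_scaled)
        protein_calls = diffreg.run_diffreg(
            study.proteins, study.design, tau=p.tau_protein, r_min=p.r_min,
            loc_min=None, mad_scaled=p.mad_scaled)
        concordance = diffreg.categorize_concordance(phospho_calls,
                                                     protein_calls)
        n_reg = sum(c.status in ("up", "down") for c in phospho_calls)
        log.info("stage=%s n_regulated=%d elapsed=%.1fs", stage, n_reg,
                 time.time() - t0)

        stage = "ksea"
        kin_scores = ksea.run_ksea(
            phospho_calls, study.ksr, source=config.ksea.source,
            regulated_only=config.ksea.regulated_only,
            m_min=config.ksea.m_min)
        log.info("stage=%s n_kinases=%d elapsed=%.1fs", stage,
                 len(kin_scores), time.time() - t0)

        stage = "enrich"
        e = config.enrich
        prot_up, prot_down = diffreg.gene_direction_sets(protein_calls)
        background = {c.gene for c in protein_calls if c.n_quantified > 0}
        tf_results = enrichment.term_enrichment(
            prot_up, prot_down, background, study.annotations.tf_targets,
            min_genes=e.min_genes)
        significant_tfs = sorted({r.term for r in tf_results
                                  if r.p < e.alpha_tf})
        tf_direction = {}
        for r in tf_results:
            if r.p < e.alpha_tf and r.term not in tf_direction:
                tf_direction[r.term] = r.direction
        phos_up, phos_down = diffreg.gene_direction_sets(phospho_calls)
        phos_background = {c.gene for c in phospho_calls
                           if c.n_quantified > 0}
        term_results = enrichment.term_enrichment(
            phos_up, phos_down, phos_background,
            study.annotations.gene_sets, min_genes=e.min_genes)
        ranked = enrichment.build_ranked_list(phospho_calls)
        gsea = enrichment.gsea_collection(
            ranked, study.annotations.gene_sets, n_perm=e.n_perm,
            seed=_stage_seed(config.seed, 1))
        log.info("stage=%s n_sig_tfs=%d elapsed=%.1fs", stage,
                 len(significant_tfs), time.time() - t0)

        stage = "network"
        ppi = network.filter_high_confidence(study.annotations.interactions,
                                             config.network.conf_min)
        kinome = network.build_kinome_network(
            phospho_calls, study.ksr, interactions=ppi, source="curated")
        integrated = network.build_integrated_network(
            phospho_calls, significant_tfs,
            study.annotations.interactions,
            tf_direction=tf_direction,
            include_bridging=config.network.include_bridging)
        if integrated.number_of_nodes():
            comm = network.detect_communities(
                integrated, seed=_stage_seed(config.seed, 2))
            comm_df = network.communities_frame(comm)
            modularity = comm.modularity
        else:
            comm_df = pd.DataFrame(columns=["node", "community"])
            modularity = float("nan")
        log.info("stage=%s nodes=%d edges=%d elapsed=%.1fs", stage,
                 integrated.number_of_nodes(),
                 integrated.number_of_edges(), time.time() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "write"
    tables = {
        "phospho_calls": diffreg.calls_to_frame(phospho_calls, phospho=True),
        "protein_calls": diffreg.calls_to_frame(protein_calls,
                                                phospho=False),
        "concordance": concordance,
        "kinase_scores": ksea.scores_to_frame(kin_scores),
        "tf_enrichment": enrichment.enrichment_to_frame(tf_results),
        "term_enrichment": enrichment.enrichment_to_frame(term_results),
        "ranked_list": ranked,
        "gsea": gsea,
        "integrated_nodes": network.nodes_frame(integrated),
        "integrated_edges": network.edges_frame(integrated),
        "kinome_nodes": network.nodes_frame(kinome),
        "kinome_edges": network.edges_frame(kinome),
        "communities": comm_df,
    }
    summary = {
        "seed": config.seed,
        "sim": simulate.config_to_dict(config.sim),
        "diffreg": asdict(config.diffreg),
        "ksea": asdict(config.ksea),
        "enrich": asdict(config.enrich),
        "network": asdict(config.network),
        "n_phospho_units": len(study.phospho),
        "n_regulated_units": int(n_reg),
        "n_scored_kinases": len(kin_scores),
        "n_significant_tfs": len(significant_tfs),
        "integrated_n_nodes": integrated.number_of_nodes(),
        "integrated_n_edges": integrated.number_of_edges(),
        "modularity": modularity,
        "concordance_counts": {
            cls: int((concordance["class"] == cls).sum())
            for cls in diffreg.CONCORDANCE_CLASSES},
    }
    manifest = datamodel.write_outputs(tables, config.out_dir,
                                       summary=summary)
    study.truth.to_json(os.path.join(config.out_dir, "ground_truth.json"))
    network.write_graphml(integrated,
                          os.path.join(config.out_dir, "integrated.graphml"))
    log.info("stage=%s files=%d elapsed=%.1fs", stage, len(manifest),
             time.time() - t0)
    return manifest
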