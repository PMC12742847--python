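"""Pipeline configuration and stage orchestration.

:class:`PipelineConfig` houses every numeric default of the analysis
(co-occurrence threshold 0.5, population frequency filter 10, embedding
dimension 50, 250 training epochs, 20% mask fraction, 15 runs per relation,
100 evaluation negatives, exploratory top fraction 1e-7, q threshold 0.05,
the AD/ADRD ICD-9 cohort codes, the seven evaluated relation classes, the
23-gene immune panel).  :func:`run_pipeline` executes the selected stages in
dependency order over synthetic inputs, writing each stage's outputs plus a
JSON manifest (inputs, config hash, seed) so a rerun with the identical
config reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kgio
from .ehr import (DEFAULT_TARGET_ICD9, DictionarySDoHExtractor,
                  build_population_kg, patient_entity_set, select_cohort)
from .fusion import align_and_merge, remove_mirrored_edges
from .kg import KnowledgeGraph
from .linkpred import (GCNConfig, evaluate_split, random_mask_split,
                       train_link_model)
from .omics import consensus_features, differential_abundance
from .stats import mean_reciprocal_rank, summarize_comparison
from .synthetic import (RELATION_CLASSES, CorpusConfig, KGConfig,
                        OmicsSimConfig, PatientSimConfig, generate_bio_kg,
                        generate_corpus, generate_omics,
                        generate_patient_table)
from .textmine import (SDOH_CATEGORIES, DictionaryClassifier,
                       extract_literature_triplets)

logger = logging.getLogger(__name__)

#: Immune genes most strongly associated with AD (targeted-mask panel).
AD_IMMUNE_GENES = (
    "ABCA7", "ABI3", "ADAMTS1", "APOE", "BIN1", "C7", "CASS4", "CD2AP",
    "CD33", "CLNK", "CLU", "CR1", "EPHA1", "INPP5D", "MEF2C", "PICALM",
    "PLCG2", "PTK2B", "SHARPIN", "SORL1", "SPI1", "TREM2", "TREML2",
)

ALL_STAGES = ("simulate", "mine", "build-ehr", "fuse", "train",
              "evaluate", "summarize", "omics")


@dataclass
class PipelineConfig:
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    #: global size multiplier for the synthetic inputs (documents, patients,
    #: KG node counts, omics features); 1.0 reproduces the study conditions.
    scale: float = 1.0

    cooccurrence_threshold: float = 0.5
    min_freq: int = 10
    feature_dim: int = 50
    epochs: int = 250
    mask_fraction: float = 0.2
    runs: int = 15
    eval_negatives: int = 100
    top_fraction: float = 1e-7
    q_threshold: float = 0.05
    target_icd9: tuple[str, ...] = DEFAULT_TARGET_ICD9
    relation_classes: tuple[str, ...] = tuple(sorted(RELATION_CLASSES))
    sdoh_categories: tuple[str, ...] = SDOH_CATEGORIES
    gene_panel: tuple[str, ...] = AD_IMMUNE_GENES
    #: relations actually evaluated by the `evaluate` stage (the masking
    #: experiment trains 2 models per run per relation, so this defaults to
    #: the relation whose endpoints carry the planted SDoH signal).
    eval_relations: tuple[str, ...] = ("disease_gene",)
    #: Bonferroni family size for the relation table (the seven relations).
    family_size: int = 7

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if not 0.0 <= self.cooccurrence_threshold <= 1.0:
            raise ValueError("cooccurrence_threshold outside [0, 1]")
        if self.min_freq < 1 or self.runs < 2 or self.family_size < 1:
            raise ValueError("min_freq, runs and family_size must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def gcn_config(self) -> GCNConfig:
        return GCNConfig(feature_dim=self.feature_dim, epochs=self.epochs,
                         seed=self.seed)


class DependencyError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# the paired augmentation experiment (the study's central comparison)
# ---------------------------------------------------------------------------

def paired_augmentation_runs(
    kg_augmented: KnowledgeGraph,
    relation: str,
    runs: int = 15,
    gcn_config: GCNConfig | None = None,
    mask_fraction: float = 0.2,
    eval_negatives: int = 100,
    base_seed: int = 0,
    aux_node_type: str = "sdoh",
) -> tuple[np.ndarray, np.ndarray]:
    """Seed-paired MRRs on the base graph vs the SDoH-augmented graph.

    The base arm removes all ``aux_node_type`` nodes (and their edges) from
    the augmented graph, so both arms share the evaluated relation's edge
    set; run ``r`` masks the same edges, initializes with the same seed and
    samples the same evaluation negatives in both arms, making the
    comparison strictly paired.
    """
    gcn_config = gcn_config or GCNConfig()
    kg_base = kg_augmented.without_node_type(aux_node_type)
    mrr = {"base": [], "augmented": []}
    for r in range(runs):
        run_seed = (base_seed + 7919 * (r + 1)) % (2**31 - 1)
        for arm, graph in (("base", kg_base), ("augmented", kg_augmented)):
            split = random_mask_split(graph, relation, mask_fraction,
                                     seed=run_seed)
            cfg = replace(gcn_config, seed=run_seed)
            emb = train_link_model(split.training_graph, cfg)
            rr = evaluate_split(split, emb, eval_negatives, seed=run_seed + 1)
            mrr[arm].append(mean_reciprocal_rank(rr))
        logger.info("relation %s run %d/%d: base=%.4f augmented=%.4f",
                    relation, r + 1, runs, mrr["base"][-1], mrr["augmented"][-1])
    return np.array(mrr["base"]), np.array(mrr["augmented"])


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _write_manifest(stage_dir: Path, stage: str, config: PipelineConfig,
                    inputs: list[str]) -> None:
    manifest = {
        "stage": stage,
        "inputs": sorted(inputs),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    (stage_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage {stage!r} requires missing upstream artifact {path}"
        )
    return path


def _scaled(count: int, scale: float, floor: int = 1) -> int:
    return max(floor, int(round(count * scale)))


def _default_corpus_config(config: PipelineConfig) -> CorpusConfig:
    return CorpusConfig(n_docs=_scaled(200, config.scale), seed=config.seed)


def _default_classifier(corpus_config: CorpusConfig,
                        patient_config: PatientSimConfig) -> DictionaryClassifier:
    table = {
        name: (cat, sub) for name, cat, sub in corpus_config.sdoh_entity_inventory
    }
    for term in patient_config.sdoh_term_inventory:
        table.setdefault(term, ("Social and Community Context", "social circumstance"))
    return DictionaryClassifier(table)


def run_pipeline(config: PipelineConfig, out_dir, force: bool = False) -> Path:
    """Execute the selected stages over synthetic inputs; returns the out dir.

    Refuses to reuse an output directory whose cached artifacts were produced
    under a different config hash unless ``force`` is set.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hash_file = out / "config_hash.txt"
    current = config.config_hash()
    if hash_file.exists():
        cached = hash_file.read_text().strip()
        if cached != current and not force:
            raise DependencyError(
                f"output directory {out} holds artifacts for config hash "
                f"{cached}, current config is {current}; pass force=True to overwrite"
            )
    hash_file.write_text(current + "\n")

    corpus_config = _default_corpus_config(config)
    patient_config = PatientSimConfig(
        n_patients=_scaled(200, config.scale, floor=10), seed=config.seed + 1)
    kg_config = KGConfig(seed=config.seed + 2)
    if config.scale != 1.0:
        kg_config.node_counts = {
            t: _scaled(c, config.scale, floor=kg_config.n_blocks)
            for t, c in kg_config.node_counts.items()
        }
    classifier = _default_classifier(corpus_config, patient_config)

    stages = [s for s in ALL_STAGES if s in config.stages]

    if "simulate" in stages:
        stage = out / "simulate"
        stage.mkdir(exist_ok=True)
        docs, corpus_gt = generate_corpus(corpus_config)
        kgio.write_documents(docs, stage / "corpus.jsonl")
        kgio.write_ground_truth(corpus_gt, stage / "corpus_truth.json")
        records, patient_gt = generate_patient_table(patient_config)
        kgio.write_patient_tables(records, stage / "tables")
        kgio.write_ground_truth(patient_gt, stage / "patient_truth.json")
        bio_kg, kg_gt = generate_bio_kg(kg_config)
        kgio.write_kg(bio_kg, stage / "bio_kg")
        kgio.write_ground_truth(kg_gt, stage / "bio_kg_truth.json")
        n_feat = _scaled(1000, config.scale, floor=20)
        matrix, groups, covariates, omics_gt = generate_omics(
            OmicsSimConfig(n_features=n_feat, seed=config.seed + 3))
        kgio.write_omics(matrix, groups, covariates, stage / "omics_a")
        kgio.write_ground_truth(omics_gt, stage / "omics_a_truth.json")
        # the second cohort shares the planted biology of the first; only the
        # samples and noise are independent (mirrors two proteomics studies
        # assaying the same disease contrast)
        planted_idx = [int(f.lstrip("F")) for f in omics_gt.planted_de_set]
        matrix_b, groups_b, cov_b, omics_gt_b = generate_omics(
            OmicsSimConfig(n_features=n_feat, planted_de_set=planted_idx,
                           seed=config.seed + 4))
        kgio.write_omics(matrix_b, groups_b, cov_b, stage / "omics_b")
        kgio.write_ground_truth(omics_gt_b, stage / "omics_b_truth.json")
        _write_manifest(stage, "simulate", config, [])

    if "mine" in stages:
        stage = out / "mine"
        stage.mkdir(exist_ok=True)
        docs = kgio.read_documents(_require(out / "simulate" / "corpus.jsonl", "mine"))
        triplets = extract_literature_triplets(
            docs, threshold=config.cooccurrence_threshold)
        kgio.write_triplets_tsv(triplets, stage / "literature_triplets.tsv")
        lit_kg = KnowledgeGraph()
        for t in triplets:
            lit_kg.add_edge(t)
        kgio.write_kg(lit_kg, stage / "literature_kg")
        _write_manifest(stage, "mine", config, ["simulate/corpus.jsonl"])

    if "build-ehr" in stages:
        stage = out / "build-ehr"
        stage.mkdir(exist_ok=True)
        records = kgio.read_patient_tables(
            _require(out / "simulate" / "tables", "build-ehr"))
        cohort = select_cohort(records, config.target_icd9)
        extractor = DictionarySDoHExtractor(
            classifier, patient_config.sdoh_term_inventory)
        entity_sets = [patient_entity_set(r, extractor) for r in cohort]
        ehr_kg = build_population_kg(entity_sets, min_freq=config.min_freq)
        kgio.write_kg(ehr_kg, stage / "ehr_kg")
        _write_manifest(stage, "build-ehr", config, ["simulate/tables"])

    if "fuse" in stages:
        stage = out / "fuse"
        stage.mkdir(exist_ok=True)
        lit_kg = kgio.read_kg(_require(out / "mine" / "literature_kg", "fuse"))
        ehr_kg = kgio.read_kg(_require(out / "build-ehr" / "ehr_kg", "fuse"))
        sdoh_kg, merge_map = align_and_merge(lit_kg, ehr_kg)
        sdoh_kg = remove_mirrored_edges(sdoh_kg)
        kgio.write_kg(sdoh_kg, stage / "sdoh_kg")
        (stage / "merge_map.json").write_text(json.dumps({
            "n_merged_pairs": len(merge_map.merged_pairs),
            "merged_pairs": [list(p) for p in merge_map.merged_pairs],
        }, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        _write_manifest(stage, "fuse", config,
                        ["mine/literature_kg", "build-ehr/ehr_kg"])

    if "train" in stages:
        stage = out / "train"
        stage.mkdir(exist_ok=True)
        bio_kg = kgio.read_kg(_require(out / "simulate" / "bio_kg", "train"))
        emb = train_link_model(bio_kg, config.gcn_config())
        kgio.write_embeddings(emb, stage / "embeddings.csv")
        pd.DataFrame({"epoch": range(len(emb.loss_curve)),
                      "loss": emb.loss_curve}).to_csv(
            stage / "loss_curve.csv", index=False, float_format="%.10g")
        _write_manifest(stage, "train", config, ["simulate/bio_kg"])

    if "evaluate" in stages:
        stage = out / "evaluate"
        stage.mkdir(exist_ok=True)
        bio_kg = kgio.read_kg(_require(out / "simulate" / "bio_kg", "evaluate"))
        rows = []
        for relation in config.eval_relations:
            base, aug = paired_augmentation_runs(
                bio_kg, relation, runs=config.runs,
                gcn_config=config.gcn_config(),
                mask_fraction=config.mask_fraction,
                eval_negatives=config.eval_negatives,
                base_seed=config.seed)
            for r, (b, a) in enumerate(zip(base, aug)):
                rows.append({"label": relation, "run": r, "arm": "base",
                             "mrr": b, "seed": config.seed})
                rows.append({"label": relation, "run": r, "arm": "augmented",
                             "mrr": a, "seed": config.seed})
        kgio.write_run_results(rows, stage / "run_results.csv")
        _write_manifest(stage, "evaluate", config, ["simulate/bio_kg"])

    if "summarize" in stages:
        stage = out / "summarize"
        stage.mkdir(exist_ok=True)
        runs = kgio.read_run_results(
            _require(out / "evaluate" / "run_results.csv", "summarize"))
        base = {label: grp.sort_values("run")["mrr"].to_numpy()
                for label, grp in runs[runs.arm == "base"].groupby("label")}
        aug = {label: grp.sort_values("run")["mrr"].to_numpy()
               for label, grp in runs[runs.arm == "augmented"].groupby("label")}
        summary = summarize_comparison(base, aug, m_corrections=config.family_size)
        kgio.float_format_csv(summary, stage / "comparison.csv")
        _write_manifest(stage, "summarize", config, ["evaluate/run_results.csv"])

    if "omics" in stages:
        stage = out / "omics"
        stage.mkdir(exist_ok=True)
        results = {}
        for name in ("omics_a", "omics_b"):
            matrix, groups, covariates = kgio.read_omics(
                _require(out / "simulate" / name, "omics"))
            res = differential_abundance(matrix, groups, covariates,
                                         q_threshold=config.q_threshold)
            kgio.float_format_csv(res, stage / f"{name}_de.csv")
            results[name] = res
        consensus = consensus_features(results["omics_a"], results["omics_b"])
        (stage / "consensus.txt").write_text(
            "\n".join(consensus) + "\n", encoding="utf-8")
        _write_manifest(stage, "omics",
                        config, ["simulate/omics_a", "simulate/omics_b"])

    return out
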