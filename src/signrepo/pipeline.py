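"""End-to-end orchestration: network → vectors → classifiers → predictions.

One :class:`RunConfig` fully determines a run; the manifest written next to
the outputs records the config, seed and library versions so a run can be
reproduced exactly.  Each disease is processed in isolation — a failure
(no scoreable known drugs, no in-network genes, ...) skips that disease
with a logged reason and never aborts the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import (
    ClassifierResult,
    PredictionRecord,
    filter_eligible_diseases,
    predict_candidates,
    read_known_associations,
    repeat_and_select,
    write_predictions,
)
from .network import DirectedSignedNetwork, read_network
from .paths import DEFAULT_MAX_LENGTH
from .validate import (
    ModuleCatalog,
    compare_groups,
    enrichment_test,
    module_enrichment,
    path_gene_signs,
    read_module_catalog,
    read_reference_pairs,
    similarity_to_known,
)
from .vectors import (
    DiseaseSkippedError,
    DrugTargetInteraction,
    build_disease_matrix,
    read_disease_genes,
    read_drug_targets,
    write_matrix,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "build_matrices",
           "train_disease", "module_similarity_validation"]


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run.

    Defaults follow the method's stated procedure: shortest paths capped at
    6 edges, diseases eligible with more than 10 known drugs, negatives
    sampled at 3× the positives, 10-fold cross-validation repeated 100
    times, candidate threshold 0.5.
    """

    edges: str | Path = ""
    drug_targets: str | Path = ""
    disease_genes: str | Path = ""
    known_associations: str | Path = ""
    modules: str | Path | None = None
    reference_pairs: str | Path | None = None
    out_dir: str | Path = "signrepo_out"

    max_length: int = DEFAULT_MAX_LENGTH
    min_known: int = 10
    ratio: int = 3
    repetitions: int = 100
    folds: int = 10
    model_kinds: tuple[str, ...] = ("random_forest", "neural_network")
    threshold: float = 0.5
    tune: bool = True
    alpha: float = 0.05
    base_seed: int = 0


@dataclass
class RunResult:
    predictions: list[PredictionRecord]
    auc_report: pd.DataFrame
    eligible: list[str]
    skipped: dict[str, str]
    enrichment_p: float | None = None
    wilcoxon: pd.DataFrame | None = None
    matrices: dict[str, pd.DataFrame] = field(default_factory=dict)


def build_matrices(
    net: DirectedSignedNetwork,
    drug_targets: list[DrugTargetInteraction],
    disease_genes: dict[str, set[str]],
    *,
    max_length: int = DEFAULT_MAX_LENGTH,
) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """DV matrix per disease; returns (matrices, skipped-with-reason)."""
    matrices, skipped = {}, {}
    for disease in sorted(disease_genes):
        try:
            matrices[disease] = build_disease_matrix(
                net, drug_targets, disease, disease_genes[disease],
                max_length=max_length,
            )
        except DiseaseSkippedError as exc:
            skipped[disease] = str(exc)
            logger.warning("disease %s skipped: %s", disease, exc)
    return matrices, skipped


def train_disease(
    matrix: pd.DataFrame,
    known: set[str],
    disease: str,
    config: RunConfig,
) -> tuple[list[dict], list[ClassifierResult]]:
    """Train every configured model kind; return AUC-report rows and the
    classifiers tied at the overall best AUC across kinds."""
    rows, all_results = [], []
    for kind in config.model_kinds:
        rep = repeat_and_select(
            matrix, known, kind, disease=disease,
            repetitions=config.repetitions, base_seed=config.base_seed,
            folds=config.folds, ratio=config.ratio, tune=config.tune,
        )
        rows.append({
            "disease_id": disease, "model": kind,
            "mean_auc": rep.mean_auc, "sd_auc": rep.sd_auc,
            "best_auc": max(rep.aucs),
        })
        all_results.extend(rep.best)
    top = max(r.auc for r in all_results)
    best = [r for r in all_results if r.auc == top]
    return rows, best


def module_similarity_validation(
    net: DirectedSignedNetwork,
    drug_targets: list[DrugTargetInteraction],
    disease: str,
    genes: set[str],
    matrix: pd.DataFrame,
    known: set[str],
    candidates: set[str],
    catalog: ModuleCatalog,
    *,
    max_length: int = DEFAULT_MAX_LENGTH,
    alpha: float = 0.05,
) -> dict | None:
    """Wilcoxon comparison of candidate vs non-candidate module similarity.

    Every drug's up/down path-gene sets are enriched against the catalog
    separately and the significant modules unioned into its profile; each
    non-known drug scores its best Jaccard similarity to a known drug's
    profile.  Returns None when either group is empty.
    """
    by_drug: dict[str, list[DrugTargetInteraction]] = {}
    for t in drug_targets:
        by_drug.setdefault(t.drug, []).append(t)

    def profile(drug: str) -> set[str]:
        up, down = path_gene_signs(net, by_drug.get(drug, []), genes,
                                   max_length=max_length)
        return (module_enrichment(up, catalog, alpha=alpha)
                | module_enrichment(down, catalog, alpha=alpha))

    known_in = sorted(set(matrix.index) & known)
    if not known_in:
        return None
    known_profiles = [profile(d) for d in known_in]
    cand = sorted(candidates)
    noncand = sorted(set(matrix.index) - known - candidates)
    if not cand or not noncand:
        return None
    cand_scores = [similarity_to_known(profile(d), known_profiles) for d in cand]
    noncand_scores = [similarity_to_known(profile(d), known_profiles)
                      for d in noncand]
    p = compare_groups(cand_scores, noncand_scores)
    return {
        "disease_id": disease, "n_candidates": len(cand),
        "n_noncandidates": len(noncand), "wilcoxon_p": p,
        "significant": p < alpha,
    }


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write all artifacts to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    net = read_network(config.edges)
    drug_targets = read_drug_targets(config.drug_targets)
    disease_genes = read_disease_genes(config.disease_genes)
    associations = read_known_associations(config.known_associations)
    logger.info("network: %d genes, %d edges", len(net.genes), net.n_edges)

    matrices, skipped = build_matrices(
        net, drug_targets, disease_genes, max_length=config.max_length
    )
    for disease, matrix in matrices.items():
        write_matrix(matrix, out / f"matrix_{disease}.tsv")

    # eligibility restricted to each disease's scoreable (matrix-row) drugs
    eligible = [
        d for d in sorted(matrices)
        if filter_eligible_diseases(
            {d: associations.get(d, set())},
            min_known=config.min_known,
            scoreable_drugs=set(matrices[d].index),
        )
    ]
    for disease in sorted(matrices):
        if disease not in eligible:
            skipped[disease] = (
                f"fewer than {config.min_known + 1} scoreable known drugs"
            )

    catalog = (read_module_catalog(config.modules, background=set(net.genes))
               if config.modules else None)
    reference = (read_reference_pairs(config.reference_pairs)
                 if config.reference_pairs else None)

    predictions: list[PredictionRecord] = []
    auc_rows: list[dict] = []
    wilcoxon_rows: list[dict] = []
    for disease in eligible:
        matrix = matrices[disease]
        known = associations.get(disease, set()) & set(matrix.index)
        try:
            rows, best = train_disease(matrix, known, disease, config)
            records = predict_candidates(
                best, matrix, known, disease,
                threshold=config.threshold, tune=config.tune,
            )
        except Exception as exc:  # per-disease isolation
            skipped[disease] = f"training failed: {exc}"
            logger.exception("disease %s failed", disease)
            continue
        auc_rows.extend(rows)
        predictions.extend(records)
        if catalog is not None:
            row = module_similarity_validation(
                net, drug_targets, disease, disease_genes[disease],
                matrix, known, {r.drug for r in records}, catalog,
                max_length=config.max_length, alpha=config.alpha,
            )
            if row is not None:
                wilcoxon_rows.append(row)

    predictions.sort(key=lambda r: (r.disease, -r.probability, r.drug))
    write_predictions(predictions, out / "predictions.tsv")

    auc_report = pd.DataFrame(
        auc_rows, columns=["disease_id", "model", "mean_auc", "sd_auc", "best_auc"]
    )
    auc_report.to_csv(out / "auc_report.tsv", sep="\t", index=False,
                      float_format="%.6f")

    enrichment_p = None
    if reference is not None and predictions:
        try:
            enrichment_p = enrichment_test(
                {(r.drug, r.disease) for r in predictions}, reference
            )
        except ValueError as exc:
            logger.warning("enrichment test undefined: %s", exc)

    wilcoxon = pd.DataFrame(
        wilcoxon_rows,
        columns=["disease_id", "n_candidates", "n_noncandidates",
                 "wilcoxon_p", "significant"],
    ) if catalog is not None else None
    if wilcoxon is not None:
        wilcoxon.to_csv(out / "module_similarity.tsv", sep="\t", index=False,
                        float_format="%.6g")

    manifest = {
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in asdict(config).items()},
        "signrepo_version": __version__,
        "n_genes": len(net.genes),
        "n_edges": net.n_edges,
        "eligible_diseases": eligible,
        "skipped_diseases": skipped,
        "n_predictions": len(predictions),
        "enrichment_p": enrichment_p,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )

    if not eligible:
        logger.warning("no eligible diseases; empty result set")

    return RunResult(
        predictions=predictions, auc_report=auc_report, eligible=eligible,
        skipped=skipped, enrichment_p=enrichment_p, wilcoxon=wilcoxon,
        matrices=matrices,
    )
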