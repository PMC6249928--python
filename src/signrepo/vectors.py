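"""Drug–disease vectors: per-disease-gene DV values and disease matrices.

For one drug and one disease gene, each drug target contributes the
gene-pair score ``V`` of its shortest paths, multiplied by +1 for a positive
drug–target interaction and −1 for a negative one (a neutral binding target
contributes ``V`` unchanged):

    DV = Σ_targets sign(T_i) · V_i

The constraint on shortest paths depends on the drug–target interaction: a
neutral target requires at least one signed edge on the path, a signed
target allows all-neutral paths.  Stacking the DV vectors of every scoreable
drug against a disease's gene set gives the disease matrix used for
classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .network import DirectedSignedNetwork, EdgeType
from .paths import DEFAULT_MAX_LENGTH, gene_pair_score

logger = logging.getLogger(__name__)

__all__ = [
    "DrugTargetInteraction",
    "MissingDrugError",
    "DiseaseSkippedError",
    "drug_target_sign",
    "compute_dv",
    "build_drug_disease_vector",
    "build_disease_matrix",
    "read_drug_targets",
    "read_disease_genes",
    "write_matrix",
]


@dataclass(frozen=True)
class DrugTargetInteraction:
    drug: str
    target: str
    type: EdgeType


class MissingDrugError(ValueError):
    """Drug has no usable (in-network) targets — DV is undefined."""


class DiseaseSkippedError(ValueError):
    """Disease has no usable gene set after intersection with the network."""


def drug_target_sign(etype: EdgeType) -> int:
    """Sign factor of a drug–target interaction: −1 for negative, else +1.

    A neutral (binding) interaction does not flip the sign of V.
    """
    return -1 if etype is EdgeType.NEGATIVE else 1


def compute_dv(
    net: DirectedSignedNetwork,
    drug_targets: list[DrugTargetInteraction],
    disease_gene: str,
    *,
    max_length: int = DEFAULT_MAX_LENGTH,
    target_is_gene_value: float = 1.0,
    **path_kwargs,
) -> float:
    """DV of one drug for one disease gene.

    Targets absent from the network are skipped with a warning; a drug with
    no in-network target raises :class:`MissingDrugError`.  A target equal to
    the disease gene itself contributes ``sign · target_is_gene_value``
    (direct regulation with full weight by default; set 0 to ignore).
    """
    usable = [t for t in drug_targets if t.target in net]
    for t in drug_targets:
        if t.target not in net:
            logger.warning("target %s of drug %s not in network; skipped",
                           t.target, t.drug)
    if not usable:
        drug = drug_targets[0].drug if drug_targets else "<unknown>"
        raise MissingDrugError(f"drug {drug!r} has no in-network targets")

    dv = 0.0
    for t in usable:
        sign = drug_target_sign(t.type)
        if t.target == disease_gene:
            dv += sign * target_is_gene_value
            continue
        score = gene_pair_score(
            net, t.target, disease_gene,
            require_signed=(t.type is EdgeType.NEUTRAL),
            max_length=max_length,
            **path_kwargs,
        )
        dv += sign * score.value
    return dv


def build_drug_disease_vector(
    net: DirectedSignedNetwork,
    drug: str,
    drug_targets: list[DrugTargetInteraction],
    disease: str,
    disease_genes: set[str],
    *,
    max_length: int = DEFAULT_MAX_LENGTH,
    **kwargs,
) -> dict[str, float]:
    """DV values for one drug over a disease's in-network genes."""
    usable_genes = sorted(g for g in disease_genes if g in net)
    dropped = len(disease_genes) - len(usable_genes)
    if dropped:
        logger.info("disease %s: %d gene(s) outside the network dropped",
                    disease, dropped)
    if not usable_genes:
        raise DiseaseSkippedError(
            f"disease {disease!r}: no disease genes in the network"
        )
    mine = [t for t in drug_targets if t.drug == drug]
    return {
        g: compute_dv(net, mine, g, max_length=max_length, **kwargs)
        for g in usable_genes
    }


def build_disease_matrix(
    net: DirectedSignedNetwork,
    all_drug_targets: list[DrugTargetInteraction],
    disease: str,
    disease_genes: set[str],
    *,
    max_length: int = DEFAULT_MAX_LENGTH,
    **kwargs,
) -> pd.DataFrame:
    """DV matrix for one disease: one row per scoreable drug, one column per
    in-network disease gene, lexicographic row/column order.

    Drugs whose targets all lack network membership are excluded (they
    cannot be scored).  Unreachable genes keep all-zero columns at this
    stage; column dropping belongs to training-set construction.
    """
    usable_genes = sorted(g for g in disease_genes if g in net)
    if not usable_genes:
        raise DiseaseSkippedError(
            f"disease {disease!r}: no disease genes in the network"
        )
    by_drug: dict[str, list[DrugTargetInteraction]] = {}
    for t in all_drug_targets:
        by_drug.setdefault(t.drug, []).append(t)

    rows = {}
    for drug in sorted(by_drug):
        targets = [t for t in by_drug[drug] if t.target in net]
        if not targets:
            logger.info("drug %s has no in-network targets; excluded", drug)
            continue
        rows[drug] = [
            compute_dv(net, targets, g, max_length=max_length, **kwargs)
            for g in usable_genes
        ]
    matrix = pd.DataFrame.from_dict(
        rows, orient="index", columns=usable_genes, dtype=float
    )
    matrix.index.name = "drug_id"
    return matrix.sort_index()


# -- table I/O --------------------------------------------------------


def read_drug_targets(path: str | Path) -> list[DrugTargetInteraction]:
    """Read ``drug_id  gene  type`` TSV (type ∈ positive/negative/neutral)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["drug", "target", "type"], dtype=str, comment="#")
    return [
        DrugTargetInteraction(r.drug, r.target, EdgeType.from_label(r.type))
        for r in df.itertuples(index=False)
    ]


def read_disease_genes(path: str | Path) -> dict[str, set[str]]:
    """Read ``disease_id  gene`` TSV into disease → gene-set mapping."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["disease", "gene"], dtype=str, comment="#")
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.disease, set()).add(r.gene)
    return out


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index=True, float_format="%.10g")
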