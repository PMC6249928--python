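"""Statistical validation of predictions.

Two complementary checks:

* **Reference enrichment** — an exact upper-tail hypergeometric test of the
  overlap between predicted drug–disease pairs and a curated reference pair
  set (for instance, pairs under clinical investigation), with the
  population taken as all drug × disease combinations of the reference
  universes.
* **Module similarity** — genes on the shortest paths between a drug and a
  disease are split into up- and down-regulated sets (prefix sign product of
  the path edges times the drug–target sign), each set is tested for
  enrichment against a catalog of functional modules, and drugs are compared
  by Jaccard similarity of their significant-module profiles.  Candidate and
  non-candidate drugs are then compared by a one-tailed Wilcoxon rank-sum
  test of their best similarity to a known drug.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .network import DirectedSignedNetwork, EdgeType
from .paths import DEFAULT_MAX_LENGTH, find_shortest_paths
from .vectors import DrugTargetInteraction, drug_target_sign

__all__ = [
    "ReferencePairSet",
    "ModuleCatalog",
    "enrichment_test",
    "path_gene_signs",
    "module_enrichment",
    "jaccard",
    "similarity_to_known",
    "compare_groups",
    "read_reference_pairs",
    "read_module_catalog",
]


@dataclass(frozen=True)
class ReferencePairSet:
    """A curated set of (drug, disease) pairs with its universes."""

    pairs: frozenset[tuple[str, str]]
    drugs: frozenset[str]
    diseases: frozenset[str]

    @classmethod
    def from_pairs(cls, pairs) -> "ReferencePairSet":
        pairs = frozenset(pairs)
        return cls(
            pairs=pairs,
            drugs=frozenset(d for d, _ in pairs),
            diseases=frozenset(s for _, s in pairs),
        )

    def __post_init__(self) -> None:
        for drug, disease in self.pairs:
            if drug not in self.drugs or disease not in self.diseases:
                raise ValueError("pair members must be in the universes")


@dataclass(frozen=True)
class ModuleCatalog:
    """Functional modules (gene sets) over a background gene universe."""

    modules: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for mid, genes in self.modules.items():
            if not genes <= self.background:
                raise ValueError(f"module {mid!r} has genes outside the background")


def enrichment_test(predicted, reference: ReferencePairSet) -> float:
    """Upper-tail hypergeometric p-value of predicted/reference pair overlap.

    Predictions are first restricted to drugs and diseases present in the
    reference universes.  Population N = |drugs| × |diseases|, successes
    K = |reference pairs|, draws n = |restricted predictions|, observed
    k = overlap; p = P(X >= k).
    """
    restricted = {
        (d, s) for d, s in predicted
        if d in reference.drugs and s in reference.diseases
    }
    n = len(restricted)
    if n == 0:
        raise ValueError("no predicted pair lies in the reference universes")
    N = len(reference.drugs) * len(reference.diseases)
    K = len(reference.pairs)
    k = len(restricted & reference.pairs)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def path_gene_signs(
    net: DirectedSignedNetwork,
    drug_targets: list[DrugTargetInteraction],
    disease_genes: set[str],
    *,
    max_length: int = DEFAULT_MAX_LENGTH,
    **path_kwargs,
) -> tuple[set[str], set[str]]:
    """Split genes on the drug→disease shortest paths into up/down sets.

    Every gene on every stored shortest path receives, per path, the
    drug–target sign factor multiplied by the product of signed-edge values
    on the path prefix ending at that gene (neutral edges contribute
    nothing to the product); the target itself receives the bare sign
    factor.  Genes with positive total are up-regulated, negative total
    down-regulated, zero excluded from both.
    """
    totals: dict[str, float] = {}
    for t in drug_targets:
        if t.target not in net:
            continue
        sign0 = drug_target_sign(t.type)
        for gene in disease_genes:
            if gene not in net:
                continue
            if gene == t.target:
                totals[gene] = totals.get(gene, 0) + sign0
                continue
            paths = find_shortest_paths(
                net, t.target, gene,
                require_signed=(t.type is EdgeType.NEUTRAL),
                max_length=max_length, **path_kwargs,
            )
            for p in paths:
                prefix = sign0
                totals[p.nodes[0]] = totals.get(p.nodes[0], 0) + prefix
                for node, etype in zip(p.nodes[1:], p.edge_types):
                    if etype.sign:
                        prefix *= etype.sign
                    totals[node] = totals.get(node, 0) + prefix
    up = {g for g, v in totals.items() if v > 0}
    down = {g for g, v in totals.items() if v < 0}
    return up, down


def module_enrichment(
    genes: set[str],
    catalog: ModuleCatalog,
    *,
    alpha: float = 0.05,
    correct: bool = False,
) -> set[str]:
    """Modules enriched for ``genes`` by an upper-tail hypergeometric test.

    The query is intersected with the background first.  Raw p < alpha by
    default; ``correct`` applies Benjamini–Hochberg across the catalog.
    """
    query = frozenset(genes) & catalog.background
    if not query:
        return set()
    N = len(catalog.background)
    n = len(query)
    mids, pvals = [], []
    for mid, module in sorted(catalog.modules.items()):
        K = len(module)
        k = len(query & module)
        pvals.append(float(stats.hypergeom.sf(k - 1, N, K, n)))
        mids.append(mid)
    pvals = np.asarray(pvals)
    if correct:
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        return {mid for mid, r in zip(mids, reject) if r}
    return {mid for mid, p in zip(mids, pvals) if p < alpha}


def jaccard(a: set, b: set) -> float:
    """|a∩b| / |a∪b|, with 0 for two empty sets."""
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def similarity_to_known(drug_modules: set, known_drug_modules: list[set]) -> float:
    """Highest Jaccard similarity of a drug's module profile to any known drug."""
    if not known_drug_modules:
        raise ValueError("at least one known drug is required")
    return max(jaccard(drug_modules, km) for km in known_drug_modules)


def compare_groups(candidate_scores, noncandidate_scores) -> float:
    """One-tailed Wilcoxon rank-sum p-value (candidates stochastically greater).

    Exact for small samples (≤ 50 total, no ties); normal approximation with
    tie correction otherwise.
    """
    x = np.asarray(list(candidate_scores), dtype=float)
    y = np.asarray(list(noncandidate_scores), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 50 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.pvalue)


# -- table I/O --------------------------------------------------------


def read_reference_pairs(path: str | Path) -> ReferencePairSet:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["drug", "disease"], dtype=str, comment="#")
    return ReferencePairSet.from_pairs(
        (r.drug, r.disease) for r in df.itertuples(index=False)
    )


def read_module_catalog(
    path: str | Path, background: set[str] | None = None
) -> ModuleCatalog:
    """Read long-format ``module_id  gene`` TSV; background defaults to the
    union of all module genes."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["module", "gene"], dtype=str, comment="#")
    modules: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        modules.setdefault(r.module, set()).add(r.gene)
    frozen = {m: frozenset(g) for m, g in modules.items()}
    if background is None:
        bg: frozenset[str] = frozenset().union(*frozen.values()) if frozen else frozenset()
    else:
        bg = frozenset(background)
    return ModuleCatalog(modules=frozen, background=bg)
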