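"""Per-trait drug-target gene sets from indication and target tables.

Traits are linked to drugs through an indication table and drugs to
genes through a drug-target table (optionally carrying interaction
confidence scores and interaction-type labels, as in STITCH-like
resources).  The default filters keep only high-confidence
relationships (score >= 700) of type "inhibition" or "activation".
Database-specific ETL is out of scope: identifiers are reconciled
through a generic two-column mapping table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

__all__ = [
    "TargetGeneSet",
    "build_target_sets",
    "jaccard",
    "background_enrichment_binomial",
    "write_gmt",
    "read_gmt",
]

#: STITCH-style confidence threshold for high-confidence interactions.
DEFAULT_MIN_CONFIDENCE = 700

#: Interaction types retained by default.
DEFAULT_ALLOWED_TYPES = frozenset({"inhibition", "activation"})

#: Number of protein-coding autosomal genes used as the default
#: enrichment universe in the human analyses this package emulates.
PROTEIN_CODING_UNIVERSE_SIZE = 19_430


@dataclass(frozen=True)
class TargetGeneSet:
    """Drug-target genes for one trait (union over its indicated drugs)."""

    trait_id: str
    genes: frozenset[str]
    n_drugs: int
    empty_flag: bool = field(default=False)

    def __len__(self) -> int:
        return len(self.genes)


def build_target_sets(
    indications: pd.DataFrame,
    drug_targets: pd.DataFrame,
    min_confidence: float | None = DEFAULT_MIN_CONFIDENCE,
    allowed_types: Iterable[str] | None = DEFAULT_ALLOWED_TYPES,
    id_map: Mapping[str, str] | pd.DataFrame | None = None,
    universe: Iterable[str] | None = None,
) -> dict[str, TargetGeneSet]:
    """Join trait -> drug -> target-gene tables under confidence filters.

    ``indications`` has columns ``trait_id, drug_id``; ``drug_targets``
    has ``drug_id, gene_id`` plus optional ``confidence`` and
    ``interaction_type``.  Filters only apply where the corresponding
    column exists (pass ``None`` to disable one).  ``id_map`` translates
    gene identifiers; unmapped genes are dropped with a reported count.
    Traits with no surviving target are retained with an empty, flagged
    set so downstream odds-ratio fallbacks are exercised.
    """
    ind = indications.drop_duplicates()
    tgt = drug_targets.drop_duplicates().copy()

    if min_confidence is not None and "confidence" in tgt.columns:
        tgt = tgt.loc[tgt["confidence"] >= min_confidence]
    if allowed_types is not None and "interaction_type" in tgt.columns:
        tgt = tgt.loc[tgt["interaction_type"].isin(set(allowed_types))]

    if id_map is not None:
        if isinstance(id_map, pd.DataFrame):
            id_map = dict(zip(id_map.iloc[:, 0], id_map.iloc[:, 1]))
        mapped = tgt["gene_id"].map(id_map)
        n_unmapped = int(mapped.isna().sum())
        if n_unmapped:
            warnings.warn(f"dropped {n_unmapped} target rows with unmapped gene ids")
        tgt = tgt.assign(gene_id=mapped).dropna(subset=["gene_id"])
    if universe is not None:
        allowed = set(universe)
        outside = ~tgt["gene_id"].isin(allowed)
        if outside.any():
            warnings.warn(f"dropped {int(outside.sum())} target rows outside universe")
        tgt = tgt.loc[~outside]

    joined = ind.merge(tgt, on="drug_id", how="left")
    out: dict[str, TargetGeneSet] = {}
    for trait, grp in joined.groupby("trait_id", sort=True):
        genes = frozenset(grp["gene_id"].dropna())
        n_drugs = int(grp["drug_id"].nunique())
        out[str(trait)] = TargetGeneSet(
            trait_id=str(trait), genes=genes, n_drugs=n_drugs,
            empty_flag=len(genes) == 0,
        )
    return out


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard index |a & b| / |a | b|; defined as 0 when both are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def background_enrichment_binomial(
    subset: Iterable[str],
    targets: Iterable[str],
    universe: Iterable[str],
) -> float:
    """Two-sided exact binomial test: is a gene subset enriched for targets?

    Successes are the subset genes that are drug targets, trials the
    targets within the universe, and the expected success probability
    the subset's share of the universe.  Used e.g. to ask whether the
    testable-protein set (genes with at least one pQTL) is itself
    enriched for drug targets, which inflates AUCs on that background.
    """
    subset, targets, universe = set(subset), set(targets), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not subset <= universe:
        raise ValueError("subset must be contained in the universe")
    trials = len(targets & universe)
    successes = len(subset & targets & universe)
    prob = len(subset) / len(universe)
    if trials == 0:
        return 1.0
    return float(stats.binomtest(successes, trials, prob, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# GMT gene-set serialization
# ---------------------------------------------------------------------------

def write_gmt(sets: Mapping[str, TargetGeneSet], path: str) -> None:
    """Write target sets in GMT format (name, description, members...)."""
    with open(path, "w") as fh:
        for name in sorted(sets):
            ts = sets[name]
            members = "\t".join(sorted(ts.genes))
            fh.write(f"{name}\tn_drugs={ts.n_drugs}\t{members}".rstrip("\t") + "\n")


def read_gmt(path: str) -> dict[str, frozenset[str]]:
    out: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            out[parts[0]] = frozenset(parts[2:])
    return out
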