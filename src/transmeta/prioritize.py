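"""Evidence-matrix gene prioritization for a fine-mapped locus.

Candidate genes at a locus are those linked to a credible-set marker by a
significant eQTL or mQTL (p < 1e-6) or by a protein-modifying variant.  Each
candidate is scored by counting its sources of supporting evidence, with all
eQTL datasets collapsed to a single unit and likewise all mQTL datasets —
expression and methylation QTL panels are highly correlated, and counting
each would bias the ranking toward genes covered by many panels.  With the
default five non-QTL sources the score ranges from 1 to 7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: significance threshold for a QTL hit to support candidacy/evidence
QTL_P_THRESHOLD = 1e-6

CATEGORIES = ("eqtl", "mqtl", "other")

#: default non-QTL evidence sources; the partition is a configurable table
DEFAULT_OTHER_SOURCES = (
    ("protein_modifying", "Protein-modifying credible-set variant"),
    ("diff_expression", "Differential expression in either disease"),
    ("mouse_phenotype", "Enriched mouse phenotype"),
    ("drug_target", "Drug target for either disease"),
    ("nearest_or_contact", "Nearest gene or promoter-capture Hi-C contact"),
)


class PrioritizeError(ValueError):
    pass


@dataclass(frozen=True)
class GeneScore:
    gene: str
    score: int
    contributing: tuple[str, ...]


@dataclass
class EvidenceMatrix:
    """Boolean gene x evidence-source matrix for one locus.

    ``cells`` is indexed by gene with one boolean column per source id;
    ``categories`` maps each source id to exactly one of ``eqtl``, ``mqtl``
    or ``other``.
    """

    locus_id: str
    cells: pd.DataFrame
    categories: dict[str, str]
    labels: dict[str, str] = field(default_factory=dict)
    qtl_p_threshold: float = QTL_P_THRESHOLD

    def __post_init__(self) -> None:
        for src in self.cells.columns:
            cat = self.categories.get(src)
            if cat not in CATEGORIES:
                raise PrioritizeError(f"source {src!r} has unknown category {cat!r}")
        self.cells = self.cells.astype(bool)

    @property
    def genes(self) -> list[str]:
        return list(self.cells.index)

    @property
    def sources(self) -> list[str]:
        return list(self.cells.columns)

    def _sources_in(self, category: str) -> list[str]:
        return [s for s in self.cells.columns if self.categories[s] == category]

    @property
    def max_score(self) -> int:
        """Upper bound on the aggregate score: 2 collapsed QTL units + others."""
        return 2 + len(self._sources_in("other"))

    @classmethod
    def from_table(cls, table: pd.DataFrame, locus_id: str = "locus",
                   qtl_p_threshold: float = QTL_P_THRESHOLD) -> "EvidenceMatrix":
        """Build from a long table with columns gene, source_id, category, hit
        and optionally p (QTL rows with p >= threshold are not evidence)."""
        required = {"gene", "source_id", "category", "hit"}
        missing = required - set(table.columns)
        if missing:
            raise PrioritizeError(f"evidence table missing column(s): {sorted(missing)}")
        t = table.copy()
        t["hit"] = t["hit"].astype(float) > 0
        if "p" in t.columns:
            qtl = t["category"].isin(["eqtl", "mqtl"]) & t["p"].notna()
            t.loc[qtl & (t["p"] >= qtl_p_threshold), "hit"] = False
        cats = t.drop_duplicates("source_id").set_index("source_id")["category"].to_dict()
        conflicting = t.groupby("source_id")["category"].nunique()
        if (conflicting > 1).any():
            bad = conflicting[conflicting > 1].index[0]
            raise PrioritizeError(f"source {bad!r} assigned to multiple categories")
        cells = (
            t.pivot_table(index="gene", columns="source_id", values="hit",
                          aggfunc="max", fill_value=False)
            .astype(bool)
        )
        cells = cells.loc[sorted(cells.index)]
        return cls(locus_id=locus_id, cells=cells, categories=cats,
                   qtl_p_threshold=qtl_p_threshold)


def admit_candidates(
    bci_markers,
    qtl_hits: pd.DataFrame | None = None,
    protein_effects: pd.DataFrame | None = None,
    qtl_p_threshold: float = QTL_P_THRESHOLD,
) -> list[str]:
    """Genes admitted as candidates for a locus.

    A gene is admitted iff some credible-set marker is a significant QTL for
    it (``qtl_hits`` columns: gene, marker, p; p < threshold, strict) or
    carries a protein-modifying annotation for it (``protein_effects``
    columns: gene, marker).  Returns a sorted, de-duplicated gene list; an
    empty admission is valid.
    """
    bci = set(bci_markers)
    admitted: set[str] = set()
    if qtl_hits is not None and not qtl_hits.empty:
        sig = qtl_hits[qtl_hits["marker"].isin(bci) & (qtl_hits["p"] < qtl_p_threshold)]
        admitted.update(sig["gene"])
    if protein_effects is not None and not protein_effects.empty:
        admitted.update(protein_effects.loc[protein_effects["marker"].isin(bci), "gene"])
    return sorted(admitted)


def score_gene(matrix: EvidenceMatrix, gene: str) -> GeneScore:
    """Aggregate evidence score with collapsed QTL counting.

    score = [any eQTL source true] + [any mQTL source true]
            + number of true "other" sources.
    """
    if gene not in matrix.cells.index:
        raise PrioritizeError(f"unknown gene {gene!r}")
    row = matrix.cells.loc[gene]
    contributing: list[str] = []
    score = 0
    for cat in ("eqtl", "mqtl"):
        srcs = [s for s in matrix._sources_in(cat) if row[s]]
        if srcs:
            score += 1
            contributing.append(f"{cat}(any: {', '.join(srcs)})")
    for s in matrix._sources_in("other"):
        if row[s]:
            score += 1
            contributing.append(s)
    return GeneScore(gene=gene, score=score, contributing=tuple(contributing))


def rank_locus(matrix: EvidenceMatrix) -> list[GeneScore]:
    """All genes scored and ordered by descending score, ties alphabetical."""
    scores = [score_gene(matrix, g) for g in matrix.genes]
    return sorted(scores, key=lambda gs: (-gs.score, gs.gene))


def scores_to_frame(scores: list[GeneScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene": gs.gene, "score": gs.score, "contributing": ";".join(gs.contributing)}
            for gs in scores
        ],
        columns=["gene", "score", "contributing"],
    )
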